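"""The organelle landscape: normalization, embedding, clustering, query mapping.

Particle marker profiles are normalized by per-particle size factors (total
signal over the geometric mean of totals), log1p-transformed, reduced by PCA
(all components for these 4-8 dimensional panels), batch-aligned by per-batch
mean-centering in PC space, and embedded in 2-D with UMAP.  Clusters come
from Leiden community detection on the k-nearest-neighbor graph built in the
embedding.  A query dataset is projected onto a trained reference landscape
through the reference's PCA and UMAP transforms, and reference cluster
labels are transferred by majority vote among the nearest reference
particles — the "metric learning" annotation of query particles.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import igraph as ig
import leidenalg
import numpy as np
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .io_formats import ParticleTable

__all__ = [
    "LandscapeModel",
    "QueryProjection",
    "size_factor_normalize",
    "embed",
    "cluster",
    "merge_clusters",
    "map_query",
    "fit_landscape",
]

logger = logging.getLogger(__name__)

#: Leiden resolution (RBConfiguration) frozen so that well-separated
#: organelle/endosome classes map one-to-one onto communities of the
#: embedding kNN graph across the package's class-recovery simulations;
#: see the methods note.
DEFAULT_RESOLUTION = 0.05
DEFAULT_N_NEIGHBORS = 15
DEFAULT_MIN_DIST = 0.1
LABEL_TRANSFER_NEIGHBORS = 10


class LandscapeError(ValueError):
    pass


@dataclass
class LandscapeModel:
    """Fitted landscape: normalization, PCA, batch offsets, UMAP, clusters."""

    markers: list[str]
    size_factors: np.ndarray  # per particle, geometric mean 1
    pca: PCA
    batch_offsets: dict  # batch label -> mean offset in PC space
    umap_model: object  # trained umap.UMAP
    embedding: np.ndarray  # (n, 2)
    pcs: np.ndarray  # aligned PC coordinates (n, d)
    seed: int
    cluster_labels: np.ndarray | None = None
    knn_k: int | None = None
    kept_index: np.ndarray | None = None  # row indices kept after zero drop


@dataclass
class QueryProjection:
    """A query dataset mapped onto a reference landscape."""

    embedding: np.ndarray  # (m, 2)
    labels: np.ndarray  # transferred reference cluster labels
    nearest_distance: np.ndarray  # distance to nearest reference particle
    kept_index: np.ndarray = field(default=None)  # type: ignore[assignment]


def size_factor_normalize(
    table: ParticleTable,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Size-factor normalize and log1p-transform marker intensities.

    The size factor of particle *i* is ``total_i / geomean(totals)`` where
    ``total_i`` sums the marker columns; normalized values are
    ``log1p(raw / factor)``.  Particles whose markers are all zero have no
    defined factor and are dropped with a warning.

    Returns
    -------
    (matrix, factors, kept) : normalized (n_kept x n_markers) matrix, the
    size factors (geometric mean exactly 1), and the positional indices of
    the kept rows.
    """
    raw = table.marker_matrix()
    totals = raw.sum(axis=1)
    kept = np.flatnonzero(totals > 0)
    if len(kept) < len(totals):
        warnings.warn(
            f"dropped {len(totals) - len(kept)} particle(s) with all-zero markers",
            stacklevel=2,
        )
    if len(kept) == 0:
        return np.zeros((0, raw.shape[1])), np.zeros(0), kept
    totals = totals[kept]
    factors = totals / np.exp(np.mean(np.log(totals)))
    matrix = np.log1p(raw[kept] / factors[:, None])
    return matrix, factors, kept


def embed(
    matrix: np.ndarray,
    batch_labels: np.ndarray | None = None,
    markers: list[str] | None = None,
    n_neighbors: int = DEFAULT_N_NEIGHBORS,
    min_dist: float = DEFAULT_MIN_DIST,
    n_components: int | None = None,
    seed: int = 0,
) -> LandscapeModel:
    """PCA -> per-batch mean-centering -> 2-D UMAP with a fixed seed.

    PCA keeps all components by default (the marker panels are 4-8
    dimensional).  The batch aligner removes per-batch mean shifts in PC
    space, the transparent core of pooling replicate experiments; offsets
    are stored so queries can be aligned consistently.
    """
    import umap  # deferred: numba compilation on first import

    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or len(matrix) < 2:
        raise LandscapeError("need at least 2 particles to embed")
    if not np.all(np.isfinite(matrix)):
        raise LandscapeError("non-finite values in feature matrix")
    d = matrix.shape[1] if n_components is None else n_components
    if d > matrix.shape[1]:
        raise LandscapeError("n_components exceeds marker count")

    pca = PCA(n_components=d, svd_solver="full", random_state=seed)
    pcs = pca.fit_transform(matrix)

    offsets: dict = {}
    if batch_labels is not None:
        batch_labels = np.asarray(batch_labels)
        if len(batch_labels) != len(matrix):
            raise LandscapeError("batch_labels length mismatch")
        for b in np.unique(batch_labels):
            sel = batch_labels == b
            offsets[b] = pcs[sel].mean(axis=0)
            pcs[sel] -= offsets[b]

    reducer = umap.UMAP(
        n_neighbors=n_neighbors,
        min_dist=min_dist,
        metric="euclidean",
        n_components=2,
        random_state=seed,
    )
    emb = reducer.fit_transform(pcs)
    return LandscapeModel(
        markers=list(markers) if markers else [],
        size_factors=np.ones(len(matrix)),
        pca=pca,
        batch_offsets=offsets,
        umap_model=reducer,
        embedding=np.asarray(emb, dtype=float),
        pcs=pcs,
        seed=seed,
    )


def cluster(
    model: LandscapeModel,
    k: int = 60,
    resolution: float = DEFAULT_RESOLUTION,
    seed: int | None = None,
) -> np.ndarray:
    """Leiden communities of the kNN graph built in UMAP space.

    ``k`` is the neighbor count of the graph.  Labels are consecutive
    integers from 1, ordered by decreasing cluster size, and are stored on
    the model.  Deterministic given the seed.
    """
    n = len(model.embedding)
    if k >= n:
        raise LandscapeError(f"k={k} must be smaller than n={n}")
    seed = model.seed if seed is None else seed
    nn = NearestNeighbors(n_neighbors=k + 1).fit(model.embedding)
    _, idx = nn.kneighbors(model.embedding)
    edges = {(min(i, j), max(i, j)) for i in range(n) for j in idx[i, 1:]}
    g = ig.Graph(n=n, edges=list(edges), directed=False)
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=2,
    )
    membership = np.asarray(part.membership)
    # relabel 1..P by decreasing size
    ids, counts = np.unique(membership, return_counts=True)
    order = ids[np.argsort(-counts)]
    remap = {old: new for new, old in enumerate(order, start=1)}
    labels = np.array([remap[m] for m in membership])
    model.cluster_labels = labels
    model.knn_k = k
    return labels


def merge_clusters(labels: np.ndarray, groups: dict) -> np.ndarray:
    """Manually merge cluster labels: ``{new_label: [old labels]}``.

    Labels not listed in any group pass through unchanged; listing an
    unknown label is an error.  An empty group mapping is the identity.
    """
    labels = np.asarray(labels)
    out = labels.copy()
    present = set(np.unique(labels).tolist())
    seen: set = set()
    for new, olds in groups.items():
        for old in olds:
            if old not in present:
                raise LandscapeError(f"unknown cluster label: {old!r}")
            if old in seen:
                raise LandscapeError(f"label {old!r} listed in two groups")
            seen.add(old)
            out[labels == old] = new
    return out


def map_query(
    ref: LandscapeModel,
    query_matrix: np.ndarray,
    batch_labels: np.ndarray | None = None,
    n_label_neighbors: int = LABEL_TRANSFER_NEIGHBORS,
) -> QueryProjection:
    """Project a query feature matrix onto a trained reference landscape.

    The query matrix must already be normalized the same way as the
    reference input (use :func:`size_factor_normalize` with the query's own
    size factors).  It is pushed through the reference PCA, per-batch
    mean-centered (each query batch is centered onto the reference's PC
    origin), embedded by the trained UMAP transform, and labeled by majority
    vote of the ``n_label_neighbors`` nearest reference particles in
    embedding space (ties go to the single nearest neighbor).
    """
    if ref.cluster_labels is None:
        raise LandscapeError("reference model has no cluster labels")
    query_matrix = np.asarray(query_matrix, dtype=float)
    if query_matrix.shape[1] != ref.pca.n_features_in_:
        raise LandscapeError(
            f"query has {query_matrix.shape[1]} markers, reference expects "
            f"{ref.pca.n_features_in_}"
        )
    pcs = ref.pca.transform(query_matrix)
    if batch_labels is not None:
        batch_labels = np.asarray(batch_labels)
        for b in np.unique(batch_labels):
            sel = batch_labels == b
            pcs[sel] -= pcs[sel].mean(axis=0)
    emb = np.asarray(ref.umap_model.transform(pcs), dtype=float)

    nn = NearestNeighbors(n_neighbors=n_label_neighbors).fit(ref.embedding)
    dist, idx = nn.kneighbors(emb)
    neighbor_labels = ref.cluster_labels[idx]
    labels = np.empty(len(emb), dtype=ref.cluster_labels.dtype)
    for i in range(len(emb)):
        vals, counts = np.unique(neighbor_labels[i], return_counts=True)
        top = vals[counts == counts.max()]
        labels[i] = top[0] if len(top) == 1 else neighbor_labels[i, 0]
    return QueryProjection(
        embedding=emb, labels=labels, nearest_distance=dist[:, 0]
    )


def fit_landscape(
    table: ParticleTable,
    k: int = 60,
    resolution: float = DEFAULT_RESOLUTION,
    n_neighbors: int = DEFAULT_N_NEIGHBORS,
    min_dist: float = DEFAULT_MIN_DIST,
    seed: int = 0,
) -> LandscapeModel:
    """Full landscape pipeline: normalize -> PCA -> align -> UMAP -> cluster.

    Batch labels come from the table's ``replicate`` column when present.
    The fitted model carries the kept-row indices so callers can write
    PCA/UMAP/cluster columns back onto the original table.
    """
    matrix, factors, kept = size_factor_normalize(table)
    batches = None
    if "replicate" in table.data.columns:
        batches = table.data["replicate"].to_numpy()[kept]
    model = embed(matrix, batch_labels=batches, markers=table.markers, seed=seed)
    model.size_factors = factors
    model.kept_index = kept
    cluster(model, k=k, resolution=resolution, seed=seed)
    return model


def annotate_table(table: ParticleTable, model: LandscapeModel) -> ParticleTable:
    """Write PCA1/2, UMAP1/2 and cluster columns onto a copy of the table."""
    out = table.copy()
    kept = (
        model.kept_index
        if model.kept_index is not None
        else np.arange(len(model.embedding))
    )
    for col, vals in [
        ("PCA1", model.pcs[:, 0]),
        ("PCA2", model.pcs[:, 1] if model.pcs.shape[1] > 1 else model.pcs[:, 0]),
        ("UMAP1", model.embedding[:, 0]),
        ("UMAP2", model.embedding[:, 1]),
    ]:
        full = np.full(len(out.data), np.nan)
        full[kept] = vals
        out.data[col] = full
    if model.cluster_labels is not None:
        full = np.full(len(out.data), -1)
        full[kept] = model.cluster_labels
        out.data["cluster"] = full
    return out
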