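"""Particle extraction from unmixed channel images.

Per channel, pixel intensities are modeled as a 1-D Gaussian mixture with an
unequal-variance component per intensity population; the component count is
chosen by BIC (standard convention ``BIC = k ln n - 2 ln L``, minimized).
Pixels are assigned to the component with the highest responsibility;
intensities at which that argmax component switches are the crossing points,
and the foreground threshold is the highest crossing point.  Thresholded
channels are merged by union (channels can be excluded from mask building,
e.g. a marker whose foci are so numerous they dominate segmentation), the
union mask is connected-component labeled, and per-particle intensities are
summed from the pre-binary images for every channel, excluded or not.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.measure import label as cc_label
from sklearn.mixture import GaussianMixture

from .io_formats import ChannelImage, ParticleTable
import pandas as pd

__all__ = [
    "ThresholdModel",
    "ParticleMask",
    "fit_pixel_gmm",
    "compute_threshold",
    "binarize_and_merge",
    "extract_particles",
]

logger = logging.getLogger(__name__)

MAX_FIT_PIXELS = 200_000  # EM is fit on at most this many sampled pixels


class GmmFitError(RuntimeError):
    pass


@dataclass
class ThresholdModel:
    """Fitted per-channel mixture and the threshold derived from it."""

    channel: str
    n_components: int
    weights: np.ndarray
    means: np.ndarray
    variances: np.ndarray
    bic: dict[int, float]  # candidate K -> BIC
    data_range: tuple[float, float] | None = None
    crossing_points: np.ndarray = field(default=None)  # type: ignore[assignment]
    threshold: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        order = np.argsort(self.means)
        self.means = np.asarray(self.means, dtype=float)[order]
        self.weights = np.asarray(self.weights, dtype=float)[order]
        self.variances = np.asarray(self.variances, dtype=float)[order]
        if not np.isclose(self.weights.sum(), 1.0):
            raise GmmFitError("mixture weights must sum to 1")
        if np.any(self.variances <= 0):
            raise GmmFitError("mixture variances must be positive")
        if self.crossing_points is None:
            self.crossing_points = _crossing_points(
                self.weights, self.means, self.variances
            )
            if self.data_range is not None:
                # only switches inside the observed intensity range count:
                # density argmax can flip again far out in the tails where
                # no pixel lives
                lo, hi = self.data_range
                self.crossing_points = self.crossing_points[
                    (self.crossing_points >= lo) & (self.crossing_points <= hi)
                ]
        if self.threshold is None and len(self.crossing_points):
            self.threshold = float(self.crossing_points[-1])

    def component_loglik(self, x: np.ndarray) -> np.ndarray:
        """``log(w_k N(x; mu_k, sigma_k^2))`` for each component, (n, K)."""
        x = np.atleast_1d(np.asarray(x, dtype=float))[:, None]
        return (
            np.log(self.weights)[None, :]
            - 0.5 * np.log(2 * np.pi * self.variances)[None, :]
            - (x - self.means[None, :]) ** 2 / (2 * self.variances[None, :])
        )

    def assign(self, x: np.ndarray) -> np.ndarray:
        """Highest-responsibility component index per value."""
        return np.argmax(self.component_loglik(x), axis=1)

    def to_dict(self) -> dict:
        return {
            "channel": self.channel,
            "n_components": int(self.n_components),
            "weights": self.weights.tolist(),
            "means": self.means.tolist(),
            "variances": self.variances.tolist(),
            "bic": {str(k): v for k, v in self.bic.items()},
            "crossing_points": np.asarray(self.crossing_points).tolist(),
            "threshold": None if self.threshold is None else float(self.threshold),
        }


@dataclass
class ParticleMask:
    """Labeled particle image plus the per-channel binaries that built it."""

    labels: np.ndarray  # (H, W) int, 0 = background
    binaries: dict[str, np.ndarray]

    @property
    def n_particles(self) -> int:
        return int(self.labels.max())


def fit_pixel_gmm(
    intensities: np.ndarray,
    k_candidates: tuple[int, ...] = (1, 2, 3, 4, 5, 6),
    seed: int = 0,
    channel: str = "",
    max_iter: int = 500,
    tol: float = 1e-8,
) -> ThresholdModel:
    """Fit 1-D unequal-variance Gaussian mixtures and select K by BIC.

    EM is initialized at quantile-spaced means with a shared variance and run
    to ``tol`` on the mean log-likelihood (at most ``max_iter`` iterations).
    When the input exceeds ``MAX_FIT_PIXELS`` the fit uses a seeded subsample;
    assignment and thresholding remain exact for all pixels.
    """
    x = np.asarray(intensities, dtype=float).ravel()
    if len(x) < 100:
        raise GmmFitError(f"need >= 100 pixels to fit a mixture, got {len(x)}")
    if np.ptp(x) == 0:
        raise GmmFitError("constant input: no mixture structure to fit")
    if any(k < 1 or k > 6 for k in k_candidates):
        raise GmmFitError("k_candidates must lie in 1..6")

    rng = np.random.default_rng(seed)
    if len(x) > MAX_FIT_PIXELS:
        x_fit = rng.choice(x, size=MAX_FIT_PIXELS, replace=False)
    else:
        x_fit = x
    X = x_fit[:, None]

    best: GaussianMixture | None = None
    best_k = 0
    bics: dict[int, float] = {}
    for k in k_candidates:
        qs = np.quantile(x_fit, (np.arange(k) + 0.5) / k)
        gm = GaussianMixture(
            n_components=k,
            covariance_type="full",
            max_iter=max_iter,
            tol=tol,
            reg_covar=1e-6,
            means_init=qs[:, None],
            weights_init=np.full(k, 1.0 / k),
            random_state=seed,
        )
        gm.fit(X)
        if not gm.converged_:
            # a candidate that cannot converge (typically over-fitting a
            # simpler distribution) is dropped from model selection
            logger.warning(
                "EM did not converge for K=%d (channel %r, n=%d); skipped",
                k, channel, len(x_fit),
            )
            continue
        bics[k] = float(gm.bic(X))
        if best is None or bics[k] < bics[best_k]:
            best, best_k = gm, k

    if best is None:
        raise GmmFitError(
            f"EM converged for no candidate K in {tuple(k_candidates)} after "
            f"{max_iter} iterations (channel {channel!r}, n={len(x_fit)})"
        )
    return ThresholdModel(
        channel=channel,
        n_components=best_k,
        weights=best.weights_.copy(),
        means=best.means_.ravel().copy(),
        variances=best.covariances_.reshape(-1).copy(),
        bic=bics,
        data_range=(float(x.min()), float(x.max())),
    )


def _crossing_points(
    weights: np.ndarray, means: np.ndarray, variances: np.ndarray
) -> np.ndarray:
    """Intensities where the argmax weighted component density switches.

    Candidate points are the real roots of the pairwise log-density
    equalities (each a quadratic in x); a candidate is a crossing point iff
    the global argmax component differs immediately below and above it.
    Evaluation at the midpoints between consecutive candidates makes the
    below/above argmax well defined; ties break toward higher intensity by
    taking the argmax with ``np.argmax`` on components sorted by mean.
    """
    K = len(means)
    if K < 2:
        return np.array([])
    roots: list[float] = []
    for i in range(K):
        for j in range(i + 1, K):
            a = 1.0 / (2 * variances[j]) - 1.0 / (2 * variances[i])
            b = means[i] / variances[i] - means[j] / variances[j]
            c = (
                means[j] ** 2 / (2 * variances[j])
                - means[i] ** 2 / (2 * variances[i])
                + np.log(weights[i] / weights[j])
                + 0.5 * np.log(variances[j] / variances[i])
            )
            if abs(a) < 1e-300:
                if b != 0:
                    roots.append(-c / b)
            else:
                disc = b * b - 4 * a * c
                if disc >= 0:
                    sq = np.sqrt(disc)
                    roots.extend([(-b - sq) / (2 * a), (-b + sq) / (2 * a)])
    if not roots:
        return np.array([])
    cand = np.unique(np.array(roots))
    # evaluate argmax in each open interval between candidates
    lo = min(means.min(), cand.min()) - 10 * np.sqrt(variances.max())
    hi = max(means.max(), cand.max()) + 10 * np.sqrt(variances.max())
    probes = np.concatenate([[lo], (cand[:-1] + cand[1:]) / 2, [hi]])
    ll = (
        np.log(weights)[None, :]
        - 0.5 * np.log(2 * np.pi * variances)[None, :]
        - (probes[:, None] - means[None, :]) ** 2 / (2 * variances[None, :])
    )
    arg = np.argmax(ll, axis=1)
    switches = cand[arg[:-1] != arg[1:]]
    return np.sort(switches)


def compute_threshold(model: ThresholdModel) -> float:
    """The foreground threshold: the highest crossing point.

    Raises :class:`GmmFitError` for a single-component model (no crossing:
    the channel carries no separable foreground population).
    """
    if model.n_components < 2 or len(model.crossing_points) == 0:
        raise GmmFitError(
            f"channel {model.channel!r}: K={model.n_components} mixture has "
            "no crossing point (no foreground population)"
        )
    return float(model.crossing_points[-1])


def binarize_and_merge(
    channels: ChannelImage,
    thresholds: dict[str, float],
    exclude: set[str] | frozenset[str] = frozenset(),
    connectivity: int = 2,
) -> ParticleMask:
    """Threshold each channel, union the binaries, label the particles.

    ``exclude`` names channels left out of mask construction (their
    intensities are still measured later).  A channel whose threshold is
    ``+inf`` (e.g. BIC selected K=1) contributes nothing, with a warning.
    """
    unknown = set(exclude) - set(channels.names)
    if unknown:
        raise ValueError(f"unknown channels in exclusion set: {sorted(unknown)}")
    used = [c for c in channels.names if c not in exclude]
    missing = [c for c in used if c not in thresholds]
    if missing:
        raise ValueError(f"no threshold for channels: {missing}")

    H, W, _ = channels.planes.shape
    union = np.zeros((H, W), dtype=bool)
    binaries: dict[str, np.ndarray] = {}
    for name in used:
        thr = thresholds[name]
        if not np.isfinite(thr):
            logger.warning("channel %s has no finite threshold; skipped", name)
            binaries[name] = np.zeros((H, W), dtype=bool)
            continue
        b = channels.channel(name) >= thr
        binaries[name] = b
        union |= b
    labels = cc_label(union, connectivity=connectivity)
    return ParticleMask(labels=labels, binaries=binaries)


def extract_particles(
    mask: ParticleMask,
    channels: ChannelImage,
    replicate: int | str = 1,
    drop_border: bool = False,
) -> ParticleTable:
    """Measure per-particle summed intensities from the pre-binary images.

    Every channel is measured over every particle's pixels — including
    channels excluded from mask construction.  ``area`` is the pixel count.
    Border-touching particles are kept unless ``drop_border``.
    """
    labels = mask.labels
    if labels.shape != channels.planes.shape[:2]:
        raise ValueError(
            f"mask {labels.shape} and channels {channels.planes.shape[:2]} "
            "geometry mismatch"
        )
    n = int(labels.max())
    idx = np.arange(1, n + 1)
    if drop_border and n:
        border = np.unique(
            np.concatenate(
                [labels[0], labels[-1], labels[:, 0], labels[:, -1]]
            )
        )
        keep = np.setdiff1d(idx, border)
    else:
        keep = idx
    cols: dict[str, np.ndarray] = {"replicate": np.full(len(keep), replicate)}
    for k, name in enumerate(channels.names):
        sums = ndimage.sum_labels(channels.planes[:, :, k], labels, keep)
        # unconstrained unmixing can leave slightly negative abundances in
        # dim channels; intensities in the table are non-negative by contract
        cols[name] = np.maximum(sums, 0.0)
    cols["area"] = ndimage.sum_labels(
        np.ones_like(labels, dtype=float), labels, keep
    ).astype(int)
    df = pd.DataFrame(cols)
    return ParticleTable(df, list(channels.names))
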