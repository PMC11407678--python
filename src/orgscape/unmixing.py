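"""Reference-spectrum estimation and linear spectral unmixing.

A measured pixel spectrum is modeled as a non-negative combination of known
fluorophore emission spectra: ``y = A^T x + noise`` with ``A`` the
(n_fluorophores x n_windows) reference matrix and ``x`` the per-pixel
abundances.  Unmixing solves the per-pixel least-squares problem, by
default unconstrained (the behavior of standard instrument "normal
unmixing"), optionally with an ``x >= 0`` constraint.  Reference spectra are
estimated from single-fluorophore stacks as the background-subtracted mean
spectrum of the brightest pixels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import nnls

from .io_formats import ChannelImage, SpectralStack, SpectralWindow

__all__ = ["EmissionReference", "estimate_reference_spectra", "unmix"]


class UnmixingError(ValueError):
    pass


@dataclass
class EmissionReference:
    """Unit-sum emission spectra, one row per fluorophore."""

    matrix: np.ndarray  # (n_fluorophores, n_windows)
    names: list[str]
    windows: list[SpectralWindow]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != len(self.names):
            raise UnmixingError("reference matrix rows must match fluorophore names")
        if self.matrix.shape[1] != len(self.windows):
            raise UnmixingError("reference matrix columns must match windows")
        if np.any(self.matrix < 0):
            raise UnmixingError("reference spectra must be non-negative")
        sums = self.matrix.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise UnmixingError("each reference spectrum must sum to 1")

    @property
    def n_fluorophores(self) -> int:
        return self.matrix.shape[0]

    def row(self, name: str) -> np.ndarray:
        return self.matrix[self.names.index(name)]

    def condition_number(self) -> float:
        return float(np.linalg.cond(self.matrix))


def _check_shared_windows(stacks: dict[str, SpectralStack]) -> list[SpectralWindow]:
    layouts = [s.windows for s in stacks.values()]
    first = layouts[0]
    for lay in layouts[1:]:
        if lay != first:
            raise UnmixingError("single-color stacks have mismatched window layouts")
    return list(first)


def estimate_reference_spectra(
    single_color_stacks: dict[str, SpectralStack],
    top_fraction: float = 0.01,
    background_fraction: float = 0.5,
) -> EmissionReference:
    """Estimate per-fluorophore spectra from single-color lambda stacks.

    For each stack, pixels are ranked by total counts across windows; the
    estimated spectrum is the mean spectrum of the top ``top_fraction`` of
    pixels minus the median spectrum of the dimmest ``background_fraction``
    (a background estimate), clipped at zero and normalized to unit sum.

    Parameters
    ----------
    single_color_stacks
        Mapping fluorophore name -> its single-color stack.  All stacks must
        share a window layout.
    """
    if not single_color_stacks:
        raise UnmixingError("no single-color stacks given")
    windows = _check_shared_windows(single_color_stacks)
    rows, names = [], []
    for name, stack in single_color_stacks.items():
        pix = stack.planes.reshape(-1, stack.n_windows).astype(float)
        totals = pix.sum(axis=1)
        if totals.max() == 0:
            raise UnmixingError(f"stack for {name!r} is all zero")
        order = np.argsort(totals)
        n_top = max(1, int(np.ceil(top_fraction * len(totals))))
        n_bg = max(1, int(np.floor(background_fraction * len(totals))))
        mean_top = pix[order[-n_top:]].mean(axis=0)
        bg = np.median(pix[order[:n_bg]], axis=0)
        spec = np.clip(mean_top - bg, 0.0, None)
        if spec.sum() == 0:
            raise UnmixingError(
                f"spectrum for {name!r} vanished after background subtraction"
            )
        rows.append(spec / spec.sum())
        names.append(name)
    return EmissionReference(np.stack(rows), names, windows)


def _collinear_pairs(matrix: np.ndarray, names: list[str]) -> list[tuple[str, str]]:
    normed = matrix / np.linalg.norm(matrix, axis=1, keepdims=True)
    cos = normed @ normed.T
    pairs = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            if cos[i, j] > 1 - 1e-10:
                pairs.append((names[i], names[j]))
    return pairs


def unmix(
    stack: SpectralStack,
    ref: EmissionReference,
    nonneg: bool = False,
) -> tuple[ChannelImage, np.ndarray]:
    """Linear-unmix a lambda stack into per-fluorophore abundance images.

    Per pixel, finds abundances minimizing ``||y - A^T x||^2`` (with
    ``x >= 0`` when ``nonneg``).  Returns the channel image and the per-pixel
    residual norm map (H x W).

    Raises
    ------
    UnmixingError
        If the window layouts differ, there are fewer windows than
        fluorophores, or the reference is rank-deficient (the error names
        the collinear fluorophores).
    """
    if stack.windows != ref.windows:
        raise UnmixingError("stack and reference window layouts differ")
    if stack.n_windows < ref.n_fluorophores:
        raise UnmixingError("need at least as many windows as fluorophores")
    A = ref.matrix.T  # (n_windows, n_fluor)
    if np.linalg.matrix_rank(A, tol=1e-10) < ref.n_fluorophores:
        pairs = _collinear_pairs(ref.matrix, ref.names)
        raise UnmixingError(
            f"rank-deficient reference; collinear fluorophores: {pairs or 'unknown'}"
        )
    H, W, nw = stack.shape
    Y = stack.planes.reshape(-1, nw).astype(float).T  # (nw, n_pix)
    if nonneg:
        X = np.empty((ref.n_fluorophores, Y.shape[1]))
        for p in range(Y.shape[1]):
            X[:, p], _ = nnls(A, Y[:, p])
    else:
        X, *_ = np.linalg.lstsq(A, Y, rcond=None)
    resid = np.linalg.norm(Y - A @ X, axis=0).reshape(H, W)
    channels = ChannelImage(
        planes=X.T.reshape(H, W, ref.n_fluorophores), names=list(ref.names)
    )
    return channels, resid
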