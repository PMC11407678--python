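"""On-disk formats for lambda stacks, channel images and particle tables.

A lambda (spectral) stack is stored as a multi-page 16-bit grayscale TIFF,
one page per emission window, with a JSON sidecar (``<stem>.windows.json``)
describing each window: center wavelength, bandwidth, spectrometer block and
excitation laser.  Particle feature tables are plain CSV with a header row;
marker intensity columns are any columns not in the reserved schema set.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "SpectralWindow",
    "SpectralStack",
    "ChannelImage",
    "ParticleTable",
    "default_lambda_layout",
    "read_stack",
    "write_stack",
    "read_particles",
    "write_particles",
]

#: columns that are never interpreted as marker intensities
RESERVED_COLUMNS = frozenset(
    {
        "replicate",
        "condition",
        "timepoint",
        "area",
        "PCA1",
        "PCA2",
        "UMAP1",
        "UMAP2",
        "cluster",
        "class_label",
        "is_contact",
    }
)

MAX_COUNT = 65535  # 16-bit detector range


class FormatError(ValueError):
    """Raised when an on-disk artifact violates its format contract."""


@dataclass(frozen=True)
class SpectralWindow:
    """One emission window of a lambda scan."""

    center_nm: float
    bandwidth_nm: float
    spectrometer: int
    excitation_nm: float

    def to_dict(self) -> dict:
        return {
            "center_nm": self.center_nm,
            "bandwidth_nm": self.bandwidth_nm,
            "spectrometer": self.spectrometer,
            "excitation_nm": self.excitation_nm,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SpectralWindow":
        return cls(
            center_nm=float(d["center_nm"]),
            bandwidth_nm=float(d["bandwidth_nm"]),
            spectrometer=int(d["spectrometer"]),
            excitation_nm=float(d["excitation_nm"]),
        )


def default_lambda_layout() -> list[SpectralWindow]:
    """The default 52-window, 4-spectrometer acquisition geometry.

    Four detector blocks cover 411-481, 494-554, 569-634 and 646-731 nm with
    13, 11, 12 and 16 windows respectively (10-nm bandwidth each); each block
    is excited by the laser matched to its band (405/488/561/640 nm).  Window
    centers are spaced evenly between each block's endpoints.
    """
    blocks = [
        (411.0, 481.0, 13, 1, 405.0),
        (494.0, 554.0, 11, 2, 488.0),
        (569.0, 634.0, 12, 3, 561.0),
        (646.0, 731.0, 16, 4, 640.0),
    ]
    windows: list[SpectralWindow] = []
    for lo, hi, n, spec, laser in blocks:
        for c in np.linspace(lo, hi, n):
            windows.append(
                SpectralWindow(
                    center_nm=round(float(c), 3),
                    bandwidth_nm=10.0,
                    spectrometer=spec,
                    excitation_nm=laser,
                )
            )
    return windows


@dataclass
class SpectralStack:
    """Lambda-series image stack: ``planes[h, w, window]`` photon counts.

    In memory the planes may be floating point (e.g. a noiseless synthetic
    rendering); on disk they are always 16-bit unsigned integers.
    """

    planes: np.ndarray  # (H, W, n_windows)
    windows: list[SpectralWindow]

    def __post_init__(self) -> None:
        self.planes = np.asarray(self.planes)
        if self.planes.ndim != 3:
            raise FormatError(
                f"planes must be H x W x n_windows, got shape {self.planes.shape}"
            )
        if self.planes.shape[2] != len(self.windows):
            raise FormatError(
                f"{self.planes.shape[2]} planes but {len(self.windows)} "
                "window metadata entries"
            )
        if np.any(self.planes < 0):
            raise FormatError("negative counts in spectral stack")
        # windows must be sorted ascending within each spectrometer block
        for spec in sorted({w.spectrometer for w in self.windows}):
            centers = [w.center_nm for w in self.windows if w.spectrometer == spec]
            if any(b <= a for a, b in zip(centers, centers[1:])):
                raise FormatError(
                    f"windows of spectrometer {spec} not strictly ascending"
                )

    @property
    def n_windows(self) -> int:
        return len(self.windows)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.planes.shape  # type: ignore[return-value]


@dataclass
class ChannelImage:
    """Per-fluorophore unmixed abundance images: ``planes[h, w, channel]``."""

    planes: np.ndarray  # (H, W, n_fluorophores), real-valued
    names: list[str]

    def __post_init__(self) -> None:
        self.planes = np.asarray(self.planes, dtype=float)
        if self.planes.ndim != 3 or self.planes.shape[2] != len(self.names):
            raise FormatError(
                f"channel planes {self.planes.shape} inconsistent with "
                f"{len(self.names)} names"
            )
        if not np.all(np.isfinite(self.planes)):
            raise FormatError("non-finite values in channel image")

    def channel(self, name: str) -> np.ndarray:
        return self.planes[:, :, self.names.index(name)]


@dataclass
class ParticleTable:
    """Per-particle feature table: one row per particle.

    ``markers`` lists the intensity columns; everything else (replicate,
    condition, timepoint, area, embedding coordinates, cluster) is metadata.
    Unknown extra columns are carried through untouched.
    """

    data: pd.DataFrame
    markers: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.markers:
            self.markers = [
                c for c in self.data.columns if c not in RESERVED_COLUMNS
            ]
        missing = [m for m in self.markers if m not in self.data.columns]
        if missing:
            raise FormatError(f"missing marker columns: {missing}")
        if len(self.data):
            vals = self.data[self.markers].to_numpy(dtype=float)
            if np.any(~np.isfinite(vals)):
                raise FormatError(
                    "non-finite marker intensities (truncated or corrupt table?)"
                )
            if np.any(vals < 0):
                raise FormatError("negative marker intensities")
            if "area" in self.data.columns and np.any(
                self.data["area"].to_numpy() < 1
            ):
                raise FormatError("particle area must be a positive pixel count")

    def __len__(self) -> int:
        return len(self.data)

    def marker_matrix(self) -> np.ndarray:
        return self.data[self.markers].to_numpy(dtype=float)

    def copy(self) -> "ParticleTable":
        return ParticleTable(self.data.copy(), list(self.markers))


# ---------------------------------------------------------------------------
# stack I/O


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".windows.json")


def write_stack(stack: SpectralStack, path: str | Path) -> None:
    """Write a stack as multi-page 16-bit TIFF plus JSON window sidecar.

    Floating-point planes are rounded to the nearest integer count; values
    outside the 16-bit range raise before anything is written.
    """
    path = Path(path)
    counts = np.rint(np.moveaxis(stack.planes, 2, 0))
    if counts.min() < 0 or counts.max() > MAX_COUNT:
        raise FormatError(
            f"counts outside 16-bit range [0, {MAX_COUNT}]: "
            f"[{counts.min()}, {counts.max()}]"
        )
    tifffile.imwrite(path, counts.astype(np.uint16))
    meta = {"windows": [w.to_dict() for w in stack.windows]}
    _sidecar_path(path).write_text(json.dumps(meta, indent=1, sort_keys=True))


def read_stack(path: str | Path) -> SpectralStack:
    """Read a lambda stack written by :func:`write_stack`."""
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FormatError(f"window sidecar not found: {sidecar}")
    meta = json.loads(sidecar.read_text())
    windows = [SpectralWindow.from_dict(d) for d in meta["windows"]]
    planes = tifffile.imread(path)
    if planes.ndim == 2:  # single page
        planes = planes[None, :, :]
    planes = np.moveaxis(planes, 0, 2)
    if planes.shape[2] != len(windows):
        raise FormatError(
            f"{planes.shape[2]} TIFF pages but {len(windows)} sidecar windows"
        )
    return SpectralStack(planes=planes, windows=windows)


# ---------------------------------------------------------------------------
# particle-table I/O

_FLOAT_FORMAT = "%.10g"


def write_particles(table: ParticleTable, path: str | Path) -> None:
    """Write a particle table as CSV (UTF-8, '.' decimal, fixed float format).

    Deterministic: identical tables produce byte-identical files.
    """
    table.data.to_csv(path, index=False, float_format=_FLOAT_FORMAT)


def read_particles(
    path: str | Path, markers: list[str] | None = None
) -> ParticleTable:
    """Read a particle CSV.

    If ``markers`` is omitted, every non-reserved column is treated as a
    marker intensity column.  Raises :class:`FormatError` on missing marker
    columns or an absent header.
    """
    path = Path(path)
    raw = path.read_bytes()
    if raw and not raw.endswith(b"\n"):
        raise FormatError(f"{path.name} is truncated (no trailing newline)")
    df = pd.read_csv(path)
    if markers is not None:
        missing = [m for m in markers if m not in df.columns]
        if missing:
            raise FormatError(f"missing marker columns in {path.name}: {missing}")
    return ParticleTable(df, list(markers) if markers else [])
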