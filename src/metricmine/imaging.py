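"""Image container, file I/O and the histogram/entropy primitives shared by all metrics.

Images are dense 2-D or 3-D scalar voxel grids.  Two on-disk formats are
supported: NIfTI-1 (via nibabel; the affine is carried along as opaque
metadata and never used by any metric) and a plain "grid-text" format whose
first line gives the shape and whose remaining whitespace-separated tokens
give the intensities in row-major (C) order.

All probability-based quantities here use equal-width binning over an
explicit range.  When two images are compared their histograms are built over
the *union* of their intensity ranges so that identical images always yield
identical histograms.  Entropies are in bits (log base 2); variances are
population (divide-by-N) moments.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Tuple, Union

import nibabel as nib
import numpy as np

__all__ = [
    "Image",
    "IntensityHistogram",
    "JointHistogram",
    "ConditionalStats",
    "read_image",
    "write_image",
    "shared_range",
    "marginal_histogram",
    "joint_histogram",
    "entropy",
    "conditional_stats",
]

DEFAULT_BINS = 64


class ImageValidationError(ValueError):
    """Raised when voxel data violates the image invariants (NaN/Inf, bad shape)."""


@dataclass
class Image:
    """A dense scalar voxel grid (2-D or 3-D) with optional NIfTI affine metadata."""

    voxels: np.ndarray
    affine: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels, dtype=np.float64)
        if vox.ndim not in (2, 3):
            raise ImageValidationError(
                f"expected a 2-D or 3-D voxel grid, got ndim={vox.ndim}"
            )
        if vox.size == 0:
            raise ImageValidationError("empty voxel grid")
        if not np.all(np.isfinite(vox)):
            raise ImageValidationError("voxel grid contains NaN or Inf values")
        self.voxels = vox

    @property
    def shape(self) -> Tuple[int, ...]:
        return self.voxels.shape

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.size)

    @property
    def intensity_range(self) -> Tuple[float, float]:
        return float(self.voxels.min()), float(self.voxels.max())

    @property
    def is_constant(self) -> bool:
        lo, hi = self.intensity_range
        return lo == hi

    def ravel(self, mask: Optional[np.ndarray] = None) -> np.ndarray:
        """Flattened intensities, optionally restricted to a boolean mask."""
        if mask is None:
            return self.voxels.ravel()
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != self.voxels.shape:
            raise ValueError(
                f"mask shape {mask.shape} does not match image shape {self.voxels.shape}"
            )
        return self.voxels[mask]


def _parse_grid_text(text: str, path: Union[str, Path]) -> Image:
    lines = text.strip().splitlines()
    if not lines:
        raise IOError(f"empty grid-text file: {path}")
    shape = tuple(int(tok) for tok in lines[0].split())
    values = np.array(" ".join(lines[1:]).split(), dtype=np.float64)
    expected = int(np.prod(shape))
    if values.size != expected:
        raise IOError(
            f"grid-text file {path}: shape {shape} implies {expected} values, found {values.size}"
        )
    return Image(values.reshape(shape))


def read_image(path: Union[str, Path], format: Optional[str] = None) -> Image:
    """Read an :class:`Image` from NIfTI (``nifti``) or plain text (``grid-text``).

    When *format* is omitted it is inferred from the file suffix
    (``.nii``/``.nii.gz`` -> nifti, anything else -> grid-text).
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"image file not found: {path}")
    if format is None:
        name = path.name.lower()
        format = "nifti" if name.endswith(".nii") or name.endswith(".nii.gz") else "grid-text"
    if format == "nifti":
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj, dtype=np.float64)
        data = np.squeeze(data)
        return Image(data, affine=np.asarray(img.affine))
    if format == "grid-text":
        opener = gzip.open if path.suffix == ".gz" else open
        with opener(path, "rt") as fh:
            return _parse_grid_text(fh.read(), path)
    raise ValueError(f"unknown image format: {format!r}")


def write_image(img: Image, path: Union[str, Path], format: Optional[str] = None) -> Path:
    """Write an :class:`Image`; the inverse of :func:`read_image`."""
    path = Path(path)
    if format is None:
        name = path.name.lower()
        format = "nifti" if name.endswith(".nii") or name.endswith(".nii.gz") else "grid-text"
    path.parent.mkdir(parents=True, exist_ok=True)
    if format == "nifti":
        affine = img.affine if img.affine is not None else np.eye(4)
        nib.save(nib.Nifti1Image(img.voxels.astype(np.float32), affine), str(path))
        return path
    if format == "grid-text":
        with open(path, "wt") as fh:
            fh.write(" ".join(str(n) for n in img.shape) + "\n")
            for row in img.voxels.reshape(img.shape[0], -1):
                fh.write(" ".join(repr(float(v)) for v in row) + "\n")
        return path
    raise ValueError(f"unknown image format: {format!r}")


def shared_range(r: Image, s: Image) -> Tuple[float, float]:
    """Union of the two images' intensity ranges (so R==S bins identically)."""
    rlo, rhi = r.intensity_range
    slo, shi = s.intensity_range
    return min(rlo, slo), max(rhi, shi)


@dataclass
class IntensityHistogram:
    """Equal-width binned marginal intensity distribution of one image."""

    bin_edges: np.ndarray
    counts: np.ndarray

    @property
    def bin_count(self) -> int:
        return int(self.counts.size)

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def probabilities(self) -> np.ndarray:
        total = self.counts.sum()
        if total == 0:
            return np.zeros_like(self.counts, dtype=np.float64)
        return self.counts / total


@dataclass
class JointHistogram:
    """Binned joint intensity distribution of a pair of same-shape images."""

    edges_r: np.ndarray
    edges_s: np.ndarray
    counts: np.ndarray  # (B_R, B_S)

    @property
    def bin_counts(self) -> Tuple[int, int]:
        return self.counts.shape  # type: ignore[return-value]

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def probabilities(self) -> np.ndarray:
        total = self.counts.sum()
        if total == 0:
            return np.zeros_like(self.counts, dtype=np.float64)
        return self.counts / total

    def marginal_r(self) -> IntensityHistogram:
        return IntensityHistogram(self.edges_r, self.counts.sum(axis=1))

    def marginal_s(self) -> IntensityHistogram:
        return IntensityHistogram(self.edges_s, self.counts.sum(axis=0))


def _resolve_range(values: np.ndarray, range: Optional[Tuple[float, float]]) -> Tuple[float, float]:
    if range is None:
        lo, hi = float(values.min()), float(values.max())
    else:
        lo, hi = float(range[0]), float(range[1])
        if not lo < hi and values.min() != values.max():
            raise ValueError(f"invalid histogram range ({lo}, {hi})")
    if hi - lo <= 1e-12 * max(abs(lo), abs(hi), 1.0):
        # (near-)constant data: widen symmetrically so all values land in one bin
        mid = 0.5 * (lo + hi)
        lo, hi = mid - 0.5, mid + 0.5
    return lo, hi


def marginal_histogram(
    img: Image,
    bins: int = DEFAULT_BINS,
    range: Optional[Tuple[float, float]] = None,
    mask: Optional[np.ndarray] = None,
) -> IntensityHistogram:
    """Equal-width histogram of image intensities.

    Bins are half-open except the last, which is closed (numpy convention), so
    values equal to ``range[1]`` fall in the final bin.
    """
    if bins < 1:
        raise ValueError("bins must be >= 1")
    values = img.ravel(mask)
    if values.size == 0:
        raise ValueError("no voxels to histogram (empty mask?)")
    lo, hi = _resolve_range(values, range)
    counts, edges = np.histogram(values, bins=bins, range=(lo, hi))
    return IntensityHistogram(edges, counts)


def joint_histogram(
    r: Image,
    s: Image,
    bins: Tuple[int, int] = (DEFAULT_BINS, DEFAULT_BINS),
    range: Optional[Tuple[float, float]] = None,
    mask: Optional[np.ndarray] = None,
) -> JointHistogram:
    """Joint 2-D histogram of intensities at corresponding voxels.

    By default both axes are binned over the shared (union) intensity range of
    the pair, so ``joint_histogram(r, r)`` concentrates on the diagonal.
    """
    if r.shape != s.shape:
        raise ValueError(f"shape mismatch: reference {r.shape} vs candidate {s.shape}")
    if range is None:
        range = shared_range(r, s)
    rv, sv = r.ravel(mask), s.ravel(mask)
    lo, hi = _resolve_range(np.concatenate([rv, sv]), range)
    counts, er, es = np.histogram2d(rv, sv, bins=bins, range=((lo, hi), (lo, hi)))
    return JointHistogram(er, es, counts.astype(np.int64))


def entropy(hist: Union[IntensityHistogram, JointHistogram, np.ndarray]) -> float:
    """Shannon entropy in bits of a histogram's probability distribution.

    Accepts a marginal or joint histogram, or a raw array of counts or
    probabilities.  Empty support yields 0.
    """
    if isinstance(hist, (IntensityHistogram, JointHistogram)):
        p = hist.probabilities
    else:
        p = np.asarray(hist, dtype=np.float64)
        total = p.sum()
        if total > 0:
            p = p / total
    p = p[p > 0]
    if p.size == 0:
        return 0.0
    return float(-np.sum(p * np.log2(p)))


@dataclass
class ConditionalStats:
    """Per-level statistics of S conditioned on the intensity level of R.

    Levels are either exact distinct intensity values of R (``bins=None``, the
    default, matching N(i) = number of voxels of R with intensity i) or
    equal-width bins of R.  sigma/var are population (1/N) moments.
    """

    levels: np.ndarray          # representative R value per level
    counts: np.ndarray          # N(i)
    mean: np.ndarray            # mu(i) of S within level i
    std: np.ndarray             # sigma(i)
    var: np.ndarray             # sigma^2(i)
    global_mean: float          # mean of S
    global_var: float           # population variance of S
    n: int = field(default=0)

    def __post_init__(self) -> None:
        if self.n == 0:
            self.n = int(self.counts.sum())


def conditional_stats(
    r: Image,
    s: Image,
    bins: Optional[int] = None,
    mask: Optional[np.ndarray] = None,
) -> ConditionalStats:
    """Mean/variance of S's intensities within each intensity level of R."""
    if r.shape != s.shape:
        raise ValueError(f"shape mismatch: reference {r.shape} vs candidate {s.shape}")
    rv, sv = r.ravel(mask), s.ravel(mask)
    if bins is None:
        levels, inverse = np.unique(rv, return_inverse=True)
    else:
        if bins < 1:
            raise ValueError("bins must be >= 1")
        lo, hi = _resolve_range(rv, None)
        edges = np.linspace(lo, hi, bins + 1)
        idx = np.clip(np.digitize(rv, edges[1:-1]), 0, bins - 1)
        used = np.unique(idx)
        levels = 0.5 * (edges[used] + edges[used + 1])
        remap = {b: k for k, b in enumerate(used)}
        inverse = np.array([remap[b] for b in idx])
    k = levels.size
    counts = np.bincount(inverse, minlength=k).astype(np.int64)
    sums = np.bincount(inverse, weights=sv, minlength=k)
    mean = sums / counts
    # two-pass variance: exact zero for constant groups (one-pass cancellation
    # would leave residues that explode in sigma/mu ratios)
    resid = sv - mean[inverse]
    var = np.bincount(inverse, weights=resid**2, minlength=k) / counts
    return ConditionalStats(
        levels=levels,
        counts=counts,
        mean=mean,
        std=np.sqrt(var),
        var=var,
        global_mean=float(sv.mean()),
        global_var=float(sv.var()),
    )
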