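"""Synthetic phantoms and graded perturbations with known ground-truth quality.

Real evaluation campaigns compare registration outputs against a reference
scan; those outputs are produced by external tools.  To exercise the full
pipeline without external data, this module builds smooth multi-blob
phantoms and degrades them with the failure modes a misregistration
produces: a rigid transform (translation + in-plane rotation, linear
interpolation, background padding), a multiplicative low-frequency intensity
bias field, and additive Gaussian noise.  A single ``severity`` knob scales
all three, so severity orders candidate quality by construction: severity 0
reproduces the reference voxelwise.

All randomness is seeded; manifests record every spec so candidate sets are
bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy import ndimage

from .imaging import Image, write_image

__all__ = [
    "PerturbationSpec",
    "CandidateSet",
    "make_phantom",
    "perturb",
    "make_candidate_set",
]


@dataclass
class PerturbationSpec:
    """Degradation recipe for one candidate.

    ``severity`` is the master knob in [0, inf): the applied translation,
    rotation, bias amplitude and noise standard deviation are each
    ``severity`` times the magnitudes below.  severity 0 reproduces the
    input exactly.

    translation : voxels, per-axis magnitude at severity 1
    rotation : degrees (in the plane of the first two axes) at severity 1
    intensity_bias : multiplicative bias-field amplitude at severity 1
    noise_sd : additive Gaussian sigma, in intensity units, at severity 1
    """

    severity: float
    translation: float = 3.0
    rotation: float = 10.0
    intensity_bias: float = 0.2
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.severity < 0:
            raise ValueError("severity must be >= 0")


@dataclass
class CandidateSet:
    """A reference image plus perturbed candidates with ground-truth severity."""

    reference: Image
    candidates: List[Image]
    specs: List[PerturbationSpec]
    severities: List[float]
    run_ids: List[str]

    @property
    def n(self) -> int:
        return len(self.candidates)

    def write(self, out_dir: Union[str, Path], format: str = "nifti") -> Path:
        """Write reference + candidates + JSON manifest; returns manifest path."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        ext = ".nii.gz" if format == "nifti" else ".txt"
        ref_path = out_dir / f"reference{ext}"
        write_image(self.reference, ref_path, format=format)
        entries = []
        for rid, img, spec, sev in zip(
            self.run_ids, self.candidates, self.specs, self.severities
        ):
            fname = rid.replace("/", "_") + ext
            write_image(img, out_dir / fname, format=format)
            entries.append(
                {
                    "run_id": rid,
                    "path": fname,
                    "ground_truth_severity": sev,
                    "spec": asdict(spec),
                }
            )
        manifest = {
            "reference": ref_path.name,
            "format": format,
            "candidates": entries,
        }
        manifest_path = out_dir / "manifest.json"
        with open(manifest_path, "w") as fh:
            json.dump(manifest, fh, indent=2)
        return manifest_path


def make_phantom(
    shape: Sequence[int] = (16, 16, 8), n_blobs: int = 6, seed: int = 0,
    levels: int = 256,
) -> Image:
    """Smooth multi-blob phantom on a dark background, intensities in [0, 1].

    Blob centers, widths and amplitudes are drawn from a seeded generator, so
    the image is deterministic given (shape, n_blobs, seed) and has a rich
    intensity histogram (many distinct levels) suitable for the statistical
    metrics.

    Intensities are quantized to ``levels`` equally spaced values (as a
    scanner's integer-valued output would be); several voxels share each
    level, which is what makes conditioning on "voxels of R having intensity
    i" (the correlation-ratio and Woods metrics) statistically meaningful.
    """
    shape = tuple(int(s) for s in shape)
    if any(s < 8 for s in shape) or len(shape) not in (2, 3):
        raise ValueError(f"degenerate phantom shape: {shape}")
    if n_blobs < 1:
        raise ValueError("n_blobs must be >= 1")
    rng = np.random.default_rng(seed)
    grids = np.meshgrid(*[np.arange(s, dtype=np.float64) for s in shape], indexing="ij")
    vol = np.zeros(shape, dtype=np.float64)
    for _ in range(n_blobs):
        center = [rng.uniform(0.2 * s, 0.8 * s) for s in shape]
        width = [rng.uniform(0.08, 0.22) * s for s in shape]
        amp = rng.uniform(0.4, 1.0)
        q = sum(((g - c) / w) ** 2 for g, c, w in zip(grids, center, width))
        vol += amp * np.exp(-0.5 * q)
    vol /= vol.max()
    if levels >= 2:
        vol = np.round(vol * (levels - 1)) / (levels - 1)
    return Image(vol)


def _rotation_matrix(ndim: int, degrees: float) -> np.ndarray:
    theta = np.deg2rad(degrees)
    rot = np.eye(ndim)
    rot[0, 0] = np.cos(theta)
    rot[0, 1] = -np.sin(theta)
    rot[1, 0] = np.sin(theta)
    rot[1, 1] = np.cos(theta)
    return rot


def _bias_field(shape: Tuple[int, ...], amplitude: float, rng: np.random.Generator) -> np.ndarray:
    """Multiplicative low-frequency field 1 + amplitude * smooth(-1..1)."""
    coords = np.meshgrid(
        *[np.linspace(0.0, 1.0, s) for s in shape], indexing="ij"
    )
    phases = rng.uniform(0, 2 * np.pi, size=len(shape))
    freqs = rng.uniform(0.5, 1.5, size=len(shape))
    smooth = sum(
        np.sin(2 * np.pi * f * c + ph) for c, f, ph in zip(coords, freqs, phases)
    ) / len(shape)
    return 1.0 + amplitude * smooth


def perturb(img: Image, spec: PerturbationSpec, background: float = 0.0) -> Image:
    """Apply the rigid + bias + noise degradation described by *spec*.

    Deterministic given ``spec.seed``.  severity 0 returns an identical copy
    (no interpolation is performed)."""
    if spec.severity == 0.0:
        return Image(img.voxels.copy(), affine=img.affine)
    rng = np.random.default_rng(spec.seed)
    vox = img.voxels
    ndim = vox.ndim

    angle = spec.severity * spec.rotation
    direction = rng.normal(size=ndim)
    direction /= np.linalg.norm(direction)
    shift = spec.severity * spec.translation * direction

    if angle != 0.0 or np.any(shift != 0.0):
        rot = _rotation_matrix(ndim, angle)
        center = (np.array(vox.shape) - 1) / 2.0
        # affine_transform maps output coords o to input coords rot@o + offset
        offset = center - rot @ center + shift
        vox = ndimage.affine_transform(
            vox, rot, offset=offset, order=1, mode="constant", cval=background
        )

    bias_amp = spec.severity * spec.intensity_bias
    if bias_amp != 0.0:
        vox = vox * _bias_field(vox.shape, bias_amp, rng)

    sigma = spec.severity * spec.noise_sd
    if sigma != 0.0:
        vox = vox + rng.normal(0.0, sigma, size=vox.shape)

    return Image(vox, affine=img.affine)


def make_candidate_set(
    reference: Image,
    n: int,
    severity_grid: Optional[Sequence[float]] = None,
    seed: int = 0,
    run_prefix: str = "synthetic",
) -> CandidateSet:
    """Build *n* candidates with known graded severities.

    Severities are taken from ``severity_grid`` (cycled to length n; default
    n points evenly spaced on [0, 1], always including 0).  Per-candidate
    perturbation seeds are derived deterministically from ``seed``.
    """
    if severity_grid is None:
        severity_grid = list(np.linspace(0.0, 1.0, n))
    severity_grid = list(severity_grid)
    if not severity_grid:
        raise ValueError("empty severity grid")
    rng = np.random.default_rng(seed)
    candidates, specs, severities, run_ids = [], [], [], []
    for i in range(n):
        sev = float(severity_grid[i % len(severity_grid)])
        spec = PerturbationSpec(
            severity=sev, seed=int(rng.integers(0, 2**31 - 1))
        )
        candidates.append(perturb(reference, spec))
        specs.append(spec)
        severities.append(sev)
        run_ids.append(f"{run_prefix}/{i:04d}")
    return CandidateSet(
        reference=reference,
        candidates=candidates,
        specs=specs,
        severities=severities,
        run_ids=run_ids,
    )
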