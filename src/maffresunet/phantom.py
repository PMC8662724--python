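"""Synthetic multimodal phantom cases with BraTS-compatible structure.

Each phantom is a brain-shaped ellipsoid of nonzero tissue containing three
concentric tumor ellipsoids labeled from the inside out as enhancing tumor
(4), necrotic/non-enhancing core (1) and edema (2), so the nested
WT ⊇ TC ⊇ ET structure of real gliomas holds by construction. The four
modality volumes share geometry but differ in per-tissue mean intensity —
loosely imitating Flair-bright edema and a T1ce-bright enhancing rim — plus
Gaussian noise, which makes the modalities non-redundant without any
attempt at radiological realism.

Generation is deterministic per (seed, case index), so tests and
experiments are reproducible bit-for-bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io_preprocess import Case, MODALITIES, write_case

# Per-modality mean intensity for each tissue class (arbitrary units).
# Keys: healthy brain, edema (label 2), necrotic core (label 1),
# enhancing tumor (label 4).
DEFAULT_CONTRAST: dict[str, dict[str, float]] = {
    "t1":    {"brain": 1.00, "edema": 0.75, "necrosis": 0.55, "enhancing": 0.90},
    "t1ce":  {"brain": 1.00, "edema": 0.80, "necrosis": 0.45, "enhancing": 1.90},
    "t2":    {"brain": 1.00, "edema": 1.55, "necrosis": 1.35, "enhancing": 1.15},
    "flair": {"brain": 1.00, "edema": 1.85, "necrosis": 1.10, "enhancing": 1.25},
}


@dataclass
class PhantomSpec:
    """Parameters of the phantom generator.

    The default shape (32, 96, 96) is deliberately smaller than real BraTS
    volumes (155, 240, 240) so CPU pipelines run in seconds; a full-size
    phantom only needs a different ``shape``. ``tumor_radius_range`` is the
    in-plane semi-axis interval (voxels) of the outer (edema) ellipsoid.
    """

    shape: tuple[int, int, int] = (32, 96, 96)
    n_cases: int = 4
    tumor_radius_range: tuple[float, float] = (10.0, 18.0)
    modality_contrast: dict[str, dict[str, float]] = field(
        default_factory=lambda: {m: dict(v) for m, v in DEFAULT_CONTRAST.items()})
    noise_std: float = 0.05
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.tumor_radius_range
        if not (0 < lo <= hi):
            raise ValueError(f"invalid tumor_radius_range {self.tumor_radius_range}")
        if hi >= min(self.shape[1], self.shape[2]) / 2:
            raise ValueError(
                f"tumor radius {hi} too large for in-plane shape "
                f"{self.shape[1:]} (must be < half the smallest dimension)")
        if self.noise_std < 0:
            raise ValueError("noise_std must be >= 0")
        if set(self.modality_contrast) != set(MODALITIES):
            raise ValueError(f"modality_contrast must cover {MODALITIES}")


def _ellipsoid_mask(shape: tuple[int, int, int],
                    center: tuple[float, float, float],
                    semi_axes: tuple[float, float, float]) -> np.ndarray:
    zz, yy, xx = np.meshgrid(*(np.arange(s, dtype=np.float64) for s in shape),
                             indexing="ij")
    return (((zz - center[0]) / semi_axes[0]) ** 2
            + ((yy - center[1]) / semi_axes[1]) ** 2
            + ((xx - center[2]) / semi_axes[2]) ** 2) <= 1.0


def generate_case(spec: PhantomSpec, index: int) -> Case:
    """Generate one deterministic phantom Case for (spec.seed, index)."""
    rng = np.random.default_rng([spec.seed, index])
    d, h, w = spec.shape
    brain_center = (d / 2.0, h / 2.0, w / 2.0)
    brain_axes = (0.45 * d, 0.42 * h, 0.42 * w)
    brain = _ellipsoid_mask(spec.shape, brain_center, brain_axes)

    lo, hi = spec.tumor_radius_range
    r_wt = float(rng.uniform(lo, hi))
    # through-plane semi-axis scaled to the anisotropic default geometry
    r_wt_z = r_wt * d / min(h, w)
    # place the tumor center so the outer ellipsoid stays inside the brain
    margin = 0.6
    center = (
        brain_center[0] + rng.uniform(-1, 1) * max(brain_axes[0] * margin - r_wt_z, 0),
        brain_center[1] + rng.uniform(-1, 1) * max(brain_axes[1] * margin - r_wt, 0),
        brain_center[2] + rng.uniform(-1, 1) * max(brain_axes[2] * margin - r_wt, 0),
    )
    wt = _ellipsoid_mask(spec.shape, center, (r_wt_z, r_wt, r_wt))
    tc = _ellipsoid_mask(spec.shape, center,
                         (r_wt_z * 0.65, r_wt * 0.65, r_wt * 0.65))
    et = _ellipsoid_mask(spec.shape, center,
                         (r_wt_z * 0.35, r_wt * 0.35, r_wt * 0.35))
    if not (wt & ~brain).sum() == 0:
        raise ValueError(
            f"phantom {index}: tumor ellipsoid (r={r_wt:.1f}) does not fit "
            "inside the brain mask")
    if not et.any():
        raise ValueError(
            f"phantom {index}: enhancing core empty; increase radius range")

    labels = np.zeros(spec.shape, dtype=np.int16)
    labels[wt] = 2          # edema shell
    labels[tc] = 1          # necrotic / non-enhancing shell
    labels[et] = 4          # enhancing core

    tissue_of_label = {0: "brain", 2: "edema", 1: "necrosis", 4: "enhancing"}
    modalities = {}
    for mod in MODALITIES:
        contrast = spec.modality_contrast[mod]
        vol = np.zeros(spec.shape, dtype=np.float64)
        for label_value, tissue in tissue_of_label.items():
            region = brain & (labels == label_value) if label_value == 0 \
                else (labels == label_value)
            vol[region] = contrast[tissue]
        if spec.noise_std > 0:
            noise = rng.normal(0.0, spec.noise_std, spec.shape)
            vol[brain] += noise[brain]
            # keep brain voxels strictly positive so the zero-background
            # brain-mask convention survives
            vol[brain] = np.maximum(vol[brain], 1e-3)
        modalities[mod] = vol
    return Case(case_id=f"phantom_{spec.seed:04d}_{index:03d}",
                modalities=modalities, labels=labels, grade="unknown")


def generate_dataset(spec: PhantomSpec, out_dir: str | Path) -> list[str]:
    """Write ``spec.n_cases`` phantoms in BraTS NIfTI layout plus a manifest.

    Returns the list of case ids; every written case round-trips through
    :func:`maffresunet.io_preprocess.read_case`.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    case_ids = []
    for index in range(spec.n_cases):
        case = generate_case(spec, index)
        try:
            write_case(case, out_dir)
        except OSError as exc:
            raise OSError(f"failed writing phantom case {case.case_id} "
                          f"under {out_dir}: {exc}") from exc
        case_ids.append(case.case_id)
    manifest = {
        "case_ids": case_ids,
        "shape": list(spec.shape),
        "seed": spec.seed,
        "n_cases": spec.n_cases,
        "tumor_radius_range": list(spec.tumor_radius_range),
        "noise_std": spec.noise_std,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return case_ids
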