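"""Reading, preprocessing and slicing of BraTS-layout multimodal MRI cases.

A case is four co-registered, skull-stripped scalar volumes (T1, T1ce, T2,
Flair) plus an integer label volume with values {0, 1, 2, 4}:

* 0 — background,
* 1 — necrosis and non-enhancing tumor,
* 2 — edema,
* 4 — enhancing tumor.

The evaluation subregions are nested: enhancing tumor ET = {4}, tumor core
TC = {1, 4}, whole tumor WT = {1, 2, 4}, with ET ⊆ TC ⊆ WT.

The preprocessing pipeline per modality volume is: winsorize intensities to
the 1st/99th percentile of the nonzero (brain) voxels, z-score normalize
over the brain voxels (background stays exactly 0), slice along the axial
(first) axis, drop slices whose label plane contains no tumor, center-crop
to ``crop_size``², and stack the four modalities as channels. Retained
slices are partitioned 80/10/10 into train/val/test at slice level with a
seeded shuffle.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

MODALITIES = ("t1", "t1ce", "t2", "flair")
SUBREGIONS = ("WT", "TC", "ET")
VALID_LABELS = frozenset({0, 1, 2, 4})

DEFAULT_CROP_SIZE = 160
DEFAULT_CLIP_PERCENTILES = (1.0, 99.0)
DEFAULT_SPLIT_FRACTIONS = (0.8, 0.1, 0.1)
DEFAULT_SPLIT_SEED = 42


@dataclass
class Case:
    """One subject: four modality volumes plus an optional label volume."""

    case_id: str
    modalities: dict[str, np.ndarray]
    labels: np.ndarray | None = None
    grade: str = "unknown"

    def __post_init__(self):
        shapes = {m: v.shape for m, v in self.modalities.items()}
        if set(self.modalities) != set(MODALITIES):
            raise ValueError(
                f"case {self.case_id}: expected modalities {MODALITIES}, "
                f"got {tuple(self.modalities)}")
        ref = next(iter(shapes.values()))
        for m, s in shapes.items():
            if s != ref:
                raise ValueError(
                    f"case {self.case_id}: shape mismatch, {m} has {s} "
                    f"but others have {ref}")
        if self.labels is not None:
            if self.labels.shape != ref:
                raise ValueError(
                    f"case {self.case_id}: label shape {self.labels.shape} "
                    f"!= modality shape {ref}")
            present = set(np.unique(self.labels).astype(int).tolist())
            invalid = present - VALID_LABELS
            if invalid:
                raise ValueError(
                    f"case {self.case_id}: invalid label values {sorted(invalid)}; "
                    f"allowed values are {sorted(VALID_LABELS)}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.modalities[MODALITIES[0]].shape


@dataclass
class NormalizedVolume:
    """A z-scored volume with the statistics used for standardization."""

    values: np.ndarray
    source_mean: float
    source_std: float


@dataclass
class SlicePair:
    """A preprocessed 4-channel axial slice with its 3-channel nested target.

    ``image`` is (4, crop, crop) float in modality order T1, T1ce, T2,
    Flair; ``target`` is (3, crop, crop) binary in subregion order WT, TC,
    ET.
    """

    image: np.ndarray
    target: np.ndarray
    case_id: str
    slice_index: int


@dataclass
class SplitManifest:
    train: list[tuple[str, int]]
    val: list[tuple[str, int]]
    test: list[tuple[str, int]]
    seed: int
    fractions: tuple[float, float, float]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "train": [list(r) for r in self.train],
            "val": [list(r) for r in self.val],
            "test": [list(r) for r in self.test],
            "seed": self.seed,
            "fractions": list(self.fractions),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SplitManifest":
        payload = json.loads(Path(path).read_text())
        return cls(
            train=[(c, int(i)) for c, i in payload["train"]],
            val=[(c, int(i)) for c, i in payload["val"]],
            test=[(c, int(i)) for c, i in payload["test"]],
            seed=int(payload["seed"]),
            fractions=tuple(payload["fractions"]),
        )


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------

def _find_nifti(case_dir: Path, case_id: str, suffix: str) -> Path | None:
    for ext in (".nii.gz", ".nii"):
        candidate = case_dir / f"{case_id}_{suffix}{ext}"
        if candidate.exists():
            return candidate
    return None


def read_case(path: str | Path, case_id: str) -> Case:
    """Read one BraTS-layout case from ``path`` (or ``path/case_id``).

    Expects NIfTI files named ``<case_id>_<mod>.nii[.gz]`` for
    mod ∈ {t1, t1ce, t2, flair} and optionally ``<case_id>_seg``.
    """
    path = Path(path)
    case_dir = path / case_id if (path / case_id).is_dir() else path
    modalities = {}
    for mod in MODALITIES:
        f = _find_nifti(case_dir, case_id, mod)
        if f is None:
            raise FileNotFoundError(
                f"case {case_id}: missing modality file "
                f"{case_id}_{mod}.nii[.gz] in {case_dir}")
        modalities[mod] = np.asarray(nib.load(str(f)).dataobj, dtype=np.float64)
    labels = None
    seg = _find_nifti(case_dir, case_id, "seg")
    if seg is not None:
        labels = np.rint(np.asarray(nib.load(str(seg)).dataobj)).astype(np.int16)
    grade = "unknown"
    for g in ("HGG", "LGG"):
        if g in case_dir.as_posix().upper().split("/"):
            grade = g
    return Case(case_id=case_id, modalities=modalities, labels=labels,
                grade=grade)


def write_case(case: Case, out_dir: str | Path) -> Path:
    """Write a case as a BraTS-style directory of NIfTI files."""
    case_dir = Path(out_dir) / case.case_id
    case_dir.mkdir(parents=True, exist_ok=True)
    affine = np.eye(4)
    for mod, vol in case.modalities.items():
        nib.save(nib.Nifti1Image(vol.astype(np.float32), affine),
                 str(case_dir / f"{case.case_id}_{mod}.nii.gz"))
    if case.labels is not None:
        nib.save(nib.Nifti1Image(case.labels.astype(np.int16), affine),
                 str(case_dir / f"{case.case_id}_seg.nii.gz"))
    return case_dir


# ---------------------------------------------------------------------------
# Intensity pipeline
# ---------------------------------------------------------------------------

def clip_intensities(volume: np.ndarray, lower_pct: float = 1.0,
                     upper_pct: float = 99.0) -> np.ndarray:
    """Winsorize brain-voxel intensities to the given percentiles.

    Percentiles are computed over nonzero voxels only and the clamping is
    applied to those voxels; background voxels (exact zeros, the
    skull-stripped exterior) are left untouched so the brain mask survives
    the pipeline.
    """
    if not (0 <= lower_pct < upper_pct <= 100):
        raise ValueError(
            f"invalid percentiles ({lower_pct}, {upper_pct}): need "
            "0 <= lower < upper <= 100")
    mask = volume != 0
    if not mask.any():
        raise ValueError("volume has no nonzero voxels (no brain region)")
    brain = volume[mask]
    lo, hi = np.percentile(brain, [lower_pct, upper_pct])
    out = volume.astype(np.float64, copy=True)
    out[mask] = np.clip(brain, lo, hi)
    return out


def z_score_normalize(volume: np.ndarray) -> NormalizedVolume:
    """Standardize brain voxels to zero mean and unit variance.

    z_i = (x_i − μ)/σ with μ, σ taken over the nonzero (brain) voxels;
    background voxels remain exactly 0.
    """
    mask = volume != 0
    if not mask.any():
        raise ValueError("volume has no nonzero voxels (no brain region)")
    brain = volume[mask]
    mu = float(brain.mean())
    sigma = float(brain.std())
    if sigma == 0:
        raise ValueError("degenerate volume: zero standard deviation over "
                         "brain voxels")
    out = np.zeros_like(volume, dtype=np.float64)
    out[mask] = (brain - mu) / sigma
    return NormalizedVolume(values=out, source_mean=mu, source_std=sigma)


def labels_to_subregions(labels: np.ndarray) -> np.ndarray:
    """Map an integer label array to stacked binary WT/TC/ET masks.

    WT = labels ∈ {1,2,4}; TC = labels ∈ {1,4}; ET = labels = 4. The output
    gains a leading channel axis of size 3 (order WT, TC, ET); nesting
    ET ⊆ TC ⊆ WT holds by construction.
    """
    present = set(np.unique(labels).astype(int).tolist())
    invalid = present - VALID_LABELS
    if invalid:
        raise ValueError(f"invalid label values {sorted(invalid)}; allowed "
                         f"values are {sorted(VALID_LABELS)}")
    wt = np.isin(labels, (1, 2, 4))
    tc = np.isin(labels, (1, 4))
    et = labels == 4
    return np.stack([wt, tc, et]).astype(np.uint8)


def preprocess_case(case: Case,
                    clip_percentiles: tuple[float, float] = DEFAULT_CLIP_PERCENTILES,
                    ) -> Case:
    """Apply per-modality winsorization + z-score to a raw case."""
    modalities = {
        mod: z_score_normalize(clip_intensities(vol, *clip_percentiles)).values
        for mod, vol in case.modalities.items()
    }
    return Case(case_id=case.case_id, modalities=modalities,
                labels=case.labels, grade=case.grade)


def center_crop_2d(plane: np.ndarray, crop_size: int) -> np.ndarray:
    """Center crop the trailing two axes to crop_size × crop_size."""
    h, w = plane.shape[-2:]
    if crop_size > h or crop_size > w:
        raise ValueError(f"crop_size {crop_size} exceeds slice dims {h}x{w}")
    top = (h - crop_size) // 2
    left = (w - crop_size) // 2
    return plane[..., top:top + crop_size, left:left + crop_size]


def slice_and_filter(case: Case, crop_size: int = DEFAULT_CROP_SIZE
                     ) -> list[SlicePair]:
    """Slice a preprocessed case axially into tumor-containing SlicePairs.

    Slices whose label plane is entirely background are excluded; the crop
    is applied identically to image channels and target.
    """
    if case.labels is None:
        raise ValueError(f"case {case.case_id}: no label volume; cannot "
                         "build training slices")
    depth = case.shape[0]
    pairs: list[SlicePair] = []
    for d in range(depth):
        label_plane = case.labels[d]
        if not (label_plane != 0).any():
            continue
        image = np.stack([
            center_crop_2d(case.modalities[mod][d], crop_size)
            for mod in MODALITIES
        ])
        target = labels_to_subregions(center_crop_2d(label_plane, crop_size))
        pairs.append(SlicePair(image=image.astype(np.float64), target=target,
                               case_id=case.case_id, slice_index=d))
    return pairs


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------

def make_split(slices: list, fractions: tuple[float, float, float]
               = DEFAULT_SPLIT_FRACTIONS,
               seed: int = DEFAULT_SPLIT_SEED) -> SplitManifest:
    """Randomly partition slices into train/val/test at slice level.

    ``slices`` may be SlicePairs or (case_id, slice_index) tuples. Val and
    test sizes are floor(n·fraction); train receives the remainder. The
    shuffle is a seeded permutation, so regeneration is bit-identical.
    """
    fractions = tuple(float(f) for f in fractions)
    if len(fractions) != 3 or any(f <= 0 for f in fractions):
        raise ValueError(f"need three positive fractions, got {fractions}")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got sum {sum(fractions)}")
    refs = [(s.case_id, s.slice_index) if isinstance(s, SlicePair)
            else (str(s[0]), int(s[1])) for s in slices]
    n = len(refs)
    n_val = int(n * fractions[1])
    n_test = int(n * fractions[2])
    n_train = n - n_val - n_test
    if min(n_train, n_val, n_test) < 1:
        raise ValueError(
            f"{n} slices cannot fill three partitions with fractions "
            f"{fractions}: sizes would be ({n_train}, {n_val}, {n_test})")
    order = np.random.default_rng(seed).permutation(n)
    shuffled = [refs[i] for i in order]
    return SplitManifest(
        train=shuffled[:n_train],
        val=shuffled[n_train:n_train + n_val],
        test=shuffled[n_train + n_val:],
        seed=seed,
        fractions=fractions,
    )


# ---------------------------------------------------------------------------
# Slice dataset persistence
# ---------------------------------------------------------------------------

def save_slice_dataset(pairs: list[SlicePair], manifest: SplitManifest,
                       out_dir: str | Path) -> Path:
    """Write slices as a compressed array archive plus a JSON index."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    split_of = {}
    for name in ("train", "val", "test"):
        for ref in getattr(manifest, name):
            split_of[tuple(ref)] = name
    arrays = {}
    index = []
    for p in pairs:
        key = f"{p.case_id}__{p.slice_index}"
        arrays[f"{key}__image"] = p.image.astype(np.float32)
        arrays[f"{key}__target"] = p.target
        index.append({"case_id": p.case_id, "slice_index": p.slice_index,
                      "split": split_of.get((p.case_id, p.slice_index))})
    np.savez_compressed(out_dir / "slices.npz", **arrays)
    (out_dir / "index.json").write_text(json.dumps(index, indent=1))
    manifest.to_json(out_dir / "split.json")
    return out_dir


def load_slice_dataset(in_dir: str | Path
                       ) -> tuple[dict[str, list[SlicePair]], SplitManifest]:
    """Inverse of :func:`save_slice_dataset`: slices grouped by split."""
    in_dir = Path(in_dir)
    index = json.loads((in_dir / "index.json").read_text())
    manifest = SplitManifest.from_json(in_dir / "split.json")
    with np.load(in_dir / "slices.npz") as archive:
        by_split: dict[str, list[SlicePair]] = {"train": [], "val": [],
                                                "test": []}
        for entry in index:
            key = f"{entry['case_id']}__{entry['slice_index']}"
            pair = SlicePair(
                image=archive[f"{key}__image"].astype(np.float64),
                target=archive[f"{key}__target"],
                case_id=entry["case_id"],
                slice_index=int(entry["slice_index"]),
            )
            if entry["split"] is not None:
                by_split[entry["split"]].append(pair)
    return by_split, manifest
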