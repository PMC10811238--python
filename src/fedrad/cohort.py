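"""Synthetic multi-centre CT-lesion cohorts and ROI preprocessing.

Real multi-centre gastric-cancer CT data is private, so experiments run on a
reproducible synthetic stand-in: each centre draws 2-D grey-level lesion
patches whose class signal (recurrent vs non-recurrent) lives in lesion
margin irregularity, internal texture heterogeneity and a mild contrast
difference, while inter-centre heterogeneity (the non-IID problem federated
personalization addresses) is induced by per-centre intensity offsets, noise
levels and background texture frequencies.

The default four-centre layout reproduces the published cohort exactly:
293 + 140 + 109 + 99 = 641 patients with the per-centre train/test and
class-count cells, and clinical covariates (sex, age, T-stage, N-stage,
CA199) allocated to match the printed per-cell marginals.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from skimage.transform import resize as _sk_resize

__all__ = [
    "CentreSpec",
    "SyntheticPatient",
    "Cohort",
    "ClinicalMarginals",
    "reference_cohort_specs",
    "generate_cohort",
    "crop_roi",
    "normalize_patch",
    "save_cohort",
    "load_manifest",
]

N_STAGES = ("0", "1", "2", "3a", "3b")
T_STAGES = ("1", "2", "3", "4")


@dataclass(frozen=True)
class ClinicalMarginals:
    """Marginal covariate counts for one (split, label) cohort cell."""

    n: int
    male: int
    female: int
    age_mean: float
    age_std: float
    n_stage: tuple[int, int, int, int, int]
    t_stage: tuple[int, int, int, int]
    ca199: tuple[int, int]  # (absent, present)

    def __post_init__(self) -> None:
        for name, total in (
            ("sex", self.male + self.female),
            ("n_stage", sum(self.n_stage)),
            ("t_stage", sum(self.t_stage)),
            ("ca199", sum(self.ca199)),
        ):
            if total != self.n:
                raise ValueError(f"{name} counts sum to {total}, expected {self.n}")


@dataclass(frozen=True)
class CentreSpec:
    """One centre's cohort sizes and its non-IID shift parameters."""

    centre_id: str
    n_train_pos: int
    n_train_neg: int
    n_test_pos: int
    n_test_neg: int
    intensity_offset: float = 0.0
    noise_sigma: float = 40.0
    texture_freq: float = 4.0
    seed: int = 0
    clinical: dict = field(default_factory=dict, compare=False)  # (split, label) -> ClinicalMarginals

    def __post_init__(self) -> None:
        counts = (self.n_train_pos, self.n_train_neg, self.n_test_pos, self.n_test_neg)
        if any(c < 0 for c in counts):
            raise ValueError("cohort counts must be non-negative")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.texture_freq <= 0:
            raise ValueError("texture_freq must be > 0")

    @property
    def n_total(self) -> int:
        return self.n_train_pos + self.n_train_neg + self.n_test_pos + self.n_test_neg


@dataclass
class SyntheticPatient:
    patient_id: str
    image: np.ndarray
    lesion_mask: np.ndarray
    label: int
    sex: str
    age: int
    t_stage: str
    n_stage: str
    ca199: str
    centre_id: str

    def __post_init__(self) -> None:
        if self.image.shape != self.lesion_mask.shape:
            raise ValueError("image and lesion mask shapes differ")
        if not self.lesion_mask.any():
            raise ValueError("lesion mask is empty")
        if self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")


@dataclass
class Cohort:
    patients: list[SyntheticPatient]
    split: str
    spec: CentreSpec

    def __len__(self) -> int:
        return len(self.patients)

    @property
    def labels(self) -> np.ndarray:
        return np.array([p.label for p in self.patients])

    @property
    def images(self) -> np.ndarray:
        return np.stack([p.image for p in self.patients])

    def clinical_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "patient_id": [p.patient_id for p in self.patients],
                "centre": [p.centre_id for p in self.patients],
                "label": self.labels,
                "sex": [p.sex for p in self.patients],
                "age": [p.age for p in self.patients],
                "t_stage": [p.t_stage for p in self.patients],
                "n_stage": [p.n_stage for p in self.patients],
                "ca199": [p.ca199 for p in self.patients],
            }
        )


# ---------------------------------------------------------------------------
# Published four-centre cohort structure.
#
# Per-cell tuples: (n, male, female, age_mean, age_std,
#                   N-stage counts [0,1,2,3a,3b], T-stage counts [1,2,3,4],
#                   CA199 counts [absent, present]).
_REFERENCE_COHORT = {
    "A": {
        ("train", 1): (51, 33, 18, 59.84, 11.80, (8, 4, 15, 10, 14), (0, 2, 32, 17), (45, 6)),
        ("train", 0): (130, 88, 42, 60.28, 12.85, (39, 24, 20, 40, 7), (0, 13, 79, 38), (112, 18)),
        ("test", 1): (40, 25, 15, 60.73, 10.36, (4, 11, 5, 13, 7), (0, 0, 25, 15), (34, 6)),
        ("test", 0): (72, 39, 33, 60.19, 12.59, (22, 11, 12, 18, 9), (0, 8, 32, 32), (61, 11)),
    },
    "B": {
        ("train", 1): (22, 17, 5, 65.63, 10.28, (3, 3, 6, 7, 3), (0, 0, 13, 9), (17, 5)),
        ("train", 0): (49, 33, 16, 61.27, 11.20, (19, 9, 9, 8, 4), (0, 6, 23, 20), (44, 5)),
        ("test", 1): (27, 22, 5, 63.27, 10.35, (4, 2, 7, 7, 7), (0, 2, 17, 8), (25, 2)),
        ("test", 0): (42, 25, 17, 61.35, 11.02, (7, 10, 12, 6, 7), (0, 8, 21, 13), (34, 8)),
    },
    "C": {
        ("train", 1): (24, 15, 9, 58.46, 12.74, (7, 3, 5, 6, 3), (0, 6, 5, 13), (21, 3)),
        ("train", 0): (32, 19, 13, 54.84, 10.46, (13, 6, 5, 7, 1), (0, 8, 6, 18), (28, 4)),
        ("test", 1): (26, 16, 10, 58.19, 13.64, (7, 4, 7, 6, 2), (0, 7, 6, 13), (17, 9)),
        ("test", 0): (27, 14, 13, 53.26, 13.17, (8, 8, 6, 4, 1), (0, 8, 3, 16), (22, 5)),
    },
    "D": {
        ("train", 1): (4, 2, 2, 53.75, 12.45, (2, 1, 0, 1, 0), (0, 2, 1, 1), (3, 1)),
        ("train", 0): (34, 20, 14, 57.85, 11.66, (11, 8, 6, 5, 4), (4, 7, 9, 14), (30, 4)),
        ("test", 1): (11, 7, 4, 54.64, 13.68, (1, 0, 5, 5, 0), (1, 0, 8, 2), (8, 3)),
        ("test", 0): (50, 26, 24, 55.00, 12.81, (22, 12, 6, 6, 4), (14, 8, 17, 11), (45, 5)),
    },
}

# Per-centre non-IID shifts (arbitrary 16-bit grey units), chosen pairwise
# distinct so pooled intensity tests separate any two centres.
_CENTRE_SHIFTS = {
    "A": dict(intensity_offset=0.0, noise_sigma=40.0, texture_freq=4.0),
    "B": dict(intensity_offset=150.0, noise_sigma=60.0, texture_freq=6.0),
    "C": dict(intensity_offset=-120.0, noise_sigma=25.0, texture_freq=3.0),
    "D": dict(intensity_offset=260.0, noise_sigma=80.0, texture_freq=8.0),
}


def reference_cohort_specs(seed: int = 0) -> list[CentreSpec]:
    """The four published centres with exact cohort cells and distinct shifts."""
    specs = []
    for i, (cid, cells) in enumerate(sorted(_REFERENCE_COHORT.items())):
        clinical = {key: ClinicalMarginals(*vals) for key, vals in cells.items()}
        specs.append(
            CentreSpec(
                centre_id=cid,
                n_train_pos=cells[("train", 1)][0],
                n_train_neg=cells[("train", 0)][0],
                n_test_pos=cells[("test", 1)][0],
                n_test_neg=cells[("test", 0)][0],
                seed=seed + i,
                clinical=clinical,
                **_CENTRE_SHIFTS[cid],
            )
        )
    return specs


# ---------------------------------------------------------------------------
# Image synthesis

_BASE_INTENSITY = 3000.0
_LESION_CONTRAST = {0: 300.0, 1: 360.0}
_MARGIN_IRREGULARITY = {0: 0.04, 1: 0.11}
_TEXTURE_SD = {0: 50.0, 1: 120.0}
_BACKGROUND_TEXTURE_AMP = 60.0


def _render_patient(spec: CentreSpec, label: int, patch_size: int, rng: np.random.Generator):
    s = patch_size
    yy, xx = np.mgrid[0:s, 0:s].astype(float)
    # background: centre-specific offset + directional sinusoidal texture
    phi = rng.uniform(0, np.pi)
    phase = rng.uniform(0, 2 * np.pi)
    proj = (xx * np.cos(phi) + yy * np.sin(phi)) / s
    img = _BASE_INTENSITY + spec.intensity_offset
    img = img + _BACKGROUND_TEXTURE_AMP * np.sin(2 * np.pi * spec.texture_freq * proj + phase)

    # lesion geometry: rotated ellipse with harmonic margin perturbation
    cx = s / 2 + rng.uniform(-0.05, 0.05) * s
    cy = s / 2 + rng.uniform(-0.05, 0.05) * s
    r1 = rng.uniform(0.18, 0.28) * s
    r2 = rng.uniform(0.18, 0.28) * s
    rot = rng.uniform(0, np.pi)
    amp = _MARGIN_IRREGULARITY[label]
    harmonics = [(k, rng.uniform(0.5, 1.0) * amp, rng.uniform(0, 2 * np.pi)) for k in (2, 3, 5)]

    dx, dy = xx - cx, yy - cy
    u = dx * np.cos(rot) + dy * np.sin(rot)
    v = -dx * np.sin(rot) + dy * np.cos(rot)
    theta = np.arctan2(v / r2, u / r1)
    boundary = np.ones_like(theta)
    for k, a, ph in harmonics:
        boundary += a * np.sin(k * theta + ph)
    rho = np.sqrt((u / r1) ** 2 + (v / r2) ** 2)
    mask = rho <= boundary
    if not mask.any():
        mask[s // 2, s // 2] = True

    max_extent = max(r1, r2) * (1 + 3 * amp)
    if max_extent > s / 2 - 1:
        raise ValueError(
            f"patch size {s} too small to contain the lesion margin (extent {max_extent:.1f})"
        )

    # internal heterogeneity: smoothed noise field, class-dependent variance
    rough = rng.normal(0.0, 1.0, size=(s, s))
    kernel = np.ones(3) / 3.0
    smooth = np.apply_along_axis(lambda r: np.convolve(r, kernel, mode="same"), 0, rough)
    smooth = np.apply_along_axis(lambda r: np.convolve(r, kernel, mode="same"), 1, smooth)
    smooth /= max(smooth.std(), 1e-12)
    img = img + mask * (_LESION_CONTRAST[label] + _TEXTURE_SD[label] * smooth)

    img = img + rng.normal(0.0, spec.noise_sigma, size=(s, s))
    return np.clip(img, 0.0, 65535.0), mask


def _allocate_categories(n: int, counts, categories, rng: np.random.Generator) -> list[str]:
    """Assign categories to n patients, matching ``counts`` exactly when they
    sum to n and sampling from their frequencies otherwise."""
    counts = np.asarray(counts, dtype=int)
    if counts.sum() == n:
        pool = np.repeat(np.arange(len(categories)), counts)
        rng.shuffle(pool)
    else:
        p = counts / counts.sum() if counts.sum() > 0 else np.full(len(categories), 1 / len(categories))
        pool = rng.choice(len(categories), size=n, p=p)
    return [categories[i] for i in pool]


_DEFAULT_MARGINALS = {
    1: ClinicalMarginals(4, 2, 2, 59.0, 12.0, (1, 1, 1, 1, 0), (0, 1, 2, 1), (3, 1)),
    0: ClinicalMarginals(10, 6, 4, 58.0, 12.0, (4, 2, 2, 1, 1), (0, 2, 5, 3), (9, 1)),
}


def _sample_clinical(spec: CentreSpec, split: str, label: int, n: int, rng: np.random.Generator):
    marg = spec.clinical.get((split, label), _DEFAULT_MARGINALS[label])
    sex = _allocate_categories(n, (marg.male, marg.female), ("M", "F"), rng)
    n_stage = _allocate_categories(n, marg.n_stage, N_STAGES, rng)
    t_stage = _allocate_categories(n, marg.t_stage, T_STAGES, rng)
    ca199 = _allocate_categories(n, marg.ca199, ("absent", "present"), rng)
    ages = np.clip(np.round(rng.normal(marg.age_mean, marg.age_std, size=n)), 18, 95).astype(int)
    return sex, ages, t_stage, n_stage, ca199


def generate_cohort(spec: CentreSpec, patch_size: int = 64) -> tuple[Cohort, Cohort]:
    """Draw this centre's full (train, test) cohorts, reproducibly from its seed."""
    if patch_size < 16:
        raise ValueError("patch_size must be >= 16")
    cohorts = {}
    for split_code, split in enumerate(("train", "test")):
        patients: list[SyntheticPatient] = []
        for label, n in (
            (1, spec.n_train_pos if split == "train" else spec.n_test_pos),
            (0, spec.n_train_neg if split == "train" else spec.n_test_neg),
        ):
            clin_rng = np.random.default_rng([spec.seed, split_code, label, 10_007])
            sex, ages, t_stage, n_stage, ca199 = _sample_clinical(spec, split, label, n, clin_rng)
            for i in range(n):
                rng = np.random.default_rng([spec.seed, split_code, label, i])
                img, mask = _render_patient(spec, label, patch_size, rng)
                patients.append(
                    SyntheticPatient(
                        patient_id=f"{spec.centre_id}-{split}-{label}-{i:04d}",
                        image=img,
                        lesion_mask=mask,
                        label=label,
                        sex=sex[i],
                        age=int(ages[i]),
                        t_stage=t_stage[i],
                        n_stage=n_stage[i],
                        ca199=ca199[i],
                        centre_id=spec.centre_id,
                    )
                )
        cohorts[split] = Cohort(patients=patients, split=split, spec=spec)
    return cohorts["train"], cohorts["test"]


# ---------------------------------------------------------------------------
# ROI preprocessing


def crop_roi(image: np.ndarray, lesion_mask: np.ndarray, margin: int = 0) -> np.ndarray:
    """Axis-aligned bounding box of the lesion, expanded by ``margin`` pixels
    and clipped to the image bounds (0-based, half-open)."""
    if image.shape != lesion_mask.shape:
        raise ValueError("image and mask shapes differ")
    rows, cols = np.nonzero(lesion_mask)
    if rows.size == 0:
        raise ValueError("cannot crop an empty lesion mask")
    r0 = max(int(rows.min()) - margin, 0)
    r1 = min(int(rows.max()) + 1 + margin, image.shape[0])
    c0 = max(int(cols.min()) - margin, 0)
    c1 = min(int(cols.max()) + 1 + margin, image.shape[1])
    return image[r0:r1, c0:c1]


def normalize_patch(patch: np.ndarray, target_size: int = 64) -> np.ndarray:
    """Bilinear resize to ``target_size`` square, then per-patch z-scoring.

    A constant patch (variance below the 1e-8 floor) comes back all zeros.
    """
    patch = np.asarray(patch, dtype=float)
    if patch.ndim != 2 or min(patch.shape) < 1:
        raise ValueError("patch must be a non-degenerate 2-D array")
    if patch.shape != (target_size, target_size):
        patch = _sk_resize(
            patch, (target_size, target_size), order=1, preserve_range=True, anti_aliasing=False
        )
    mean = patch.mean()
    var = patch.var()
    return (patch - mean) / np.sqrt(max(var, 1e-8))


# ---------------------------------------------------------------------------
# Fixture layout: centres/<id>/{train,test}/img_####.png + manifest.csv


def save_cohort(cohorts: list[Cohort], out_dir: str | Path) -> Path:
    out = Path(out_dir)
    rows = []
    for cohort in cohorts:
        sub = out / "centres" / cohort.spec.centre_id / cohort.split
        sub.mkdir(parents=True, exist_ok=True)
        for i, p in enumerate(cohort.patients):
            rel = Path("centres") / p.centre_id / cohort.split / f"img_{i:04d}.png"
            arr = np.clip(np.round(p.image), 0, 65535).astype(np.uint16)
            Image.fromarray(arr).save(out / rel)
            rows.append(
                dict(
                    centre=p.centre_id,
                    split=cohort.split,
                    patient_id=p.patient_id,
                    label=p.label,
                    sex=p.sex,
                    age=p.age,
                    t_stage=p.t_stage,
                    n_stage=p.n_stage,
                    ca199=p.ca199,
                    path=str(rel),
                )
            )
    manifest = out / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def load_manifest(manifest_path: str | Path) -> pd.DataFrame:
    """Read a cohort manifest; image arrays load lazily via their paths."""
    df = pd.read_csv(manifest_path, dtype={"t_stage": str, "n_stage": str})
    df.attrs["root"] = str(Path(manifest_path).parent)
    return df


def load_image(manifest: pd.DataFrame, row: int) -> np.ndarray:
    root = Path(manifest.attrs["root"])
    return np.asarray(Image.open(root / manifest.iloc[row]["path"]), dtype=float)
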