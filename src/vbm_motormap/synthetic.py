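"""Synthetic cohort generator with known ground truth.

Real studies of this kind consume smoothed, modulated grey-matter
partial-volume maps from a repository such as PPMI together with
item-level MDS-UPDRS III tables.  This module fabricates both so that
every pipeline stage can be tested against a known answer:

* a toy atlas of eight mirror-symmetric "anatomical" regions (caudate,
  putamen, precentral, hippocampal complex; left/right) on an MNI-like
  grid centred on x = 0;
* an item-level clinical table whose four motor subscores realize a
  target cross-correlation structure via a Gaussian copula, with age,
  sex and medication marginals matching published cohort demographics;
* a GM image stack ``baseline + b*score + c*age + noise``, Gaussian
  smoothed at sigma = 3 mm (the preprocessing kernel the maps emulate)
  and clipped at zero — with the planted slopes, masks and noise level
  retained as :class:`GroundTruth`, including closed-form expected
  voxel-level and cluster-mean correlations.

What the generator does *not* emulate: registration error, segmentation
failure, anatomical covariance between regions, and heavy-tailed or
spatially non-stationary noise.  Tests passing on these cohorts show the
statistical machinery is correct, not that real data meet its
assumptions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

from vbm_motormap.clinical import (
    AXIAL_ITEMS,
    BRADYKINESIA_ITEMS,
    SUBSCORE_LABELS,
    TREMOR_ITEMS,
)
from vbm_motormap.clusters import AtlasVolume
from vbm_motormap.voxelstats import GMVolumeStack

__all__ = [
    "TARGET_CORRELATIONS",
    "SUBSCORE_MARGINALS",
    "GroundTruth",
    "make_toy_atlas",
    "brain_mask",
    "simulate_clinical",
    "simulate_gm",
    "gaussian_smooth",
    "calibrate_noise_sd",
    "default_ground_truth",
    "save_cohort",
]

#: Published cross-correlation structure of the subscores and total
#: (order: axial, bradykinesia, rigidity, tremor, total).  The 4x4
#: subscore block drives the Gaussian copula; the total emerges from the
#: item sums.
TARGET_CORRELATIONS = np.array(
    [
        [1.0000, 0.4850, 0.3885, 0.1031, 0.5740],
        [0.4850, 1.0000, 0.6181, 0.1985, 0.8879],
        [0.3885, 0.6181, 1.0000, 0.2040, 0.7715],
        [0.1031, 0.1985, 0.2040, 1.0000, 0.5351],
        [0.5740, 0.8879, 0.7715, 0.5351, 1.0000],
    ]
)

#: Cohort marginal means/SDs for the subscores (axial, bradykinesia,
#: rigidity, tremor), matching published early-PD demographics.
SUBSCORE_MARGINALS = {
    "axial": (2.08, 1.48),
    "bradykinesia": (9.68, 5.56),
    "rigidity": (4.12, 2.89),
    "tremor": (5.76, 3.42),
}

AGE_MEAN, AGE_SD = 62.12, 9.77
MALE_FRACTION = 235 / 364
MEDICATED_FRACTION = 117 / 364

#: Toy atlas regions: right-hemisphere centre (mm, MNI-like) and radius
#: (mm); left homologues are exact mirror images under x -> -x.
ATLAS_REGIONS: dict[str, tuple[tuple[float, float, float], float]] = {
    "caudate": ((10.0, 14.0, 8.0), 10.0),
    "putamen": ((28.0, 0.0, -2.0), 12.0),
    "precentral": ((38.0, -12.0, 44.0), 12.0),
    "hippocampal_complex": ((26.0, -22.0, -18.0), 12.0),
}

DEFAULT_SHAPE = (40, 48, 40)
DEFAULT_SPACING = 4.0
DEFAULT_SIGMA_MM = 3.0
#: Default planted slope of GM on the total score (GM units per point).
DEFAULT_SLOPE_B = -0.002
#: Default planted slope of GM on age (GM units per year).
DEFAULT_SLOPE_C = -0.0015
#: Interior-voxel true correlation the default noise level is calibrated
#: to.  Chosen by an a-priori closed-form power analysis: with 3 mm
#: smoothing the planted regions' boundary voxels carry only ~0.5-0.7 of
#: the interior slope, and detecting >= 80% of planted voxels under a
#: maxT small-volume threshold (|r| ~ 0.19 at n = 364) requires an
#: interior correlation of about this size.
DEFAULT_RHO_VOXEL = -0.40


def _mni_like_affine(shape, spacing_mm: float) -> np.ndarray:
    """Axis-aligned affine placing the grid symmetrically about x=y=z=0."""
    affine = np.diag([spacing_mm, spacing_mm, spacing_mm, 1.0])
    affine[:3, 3] = -(np.asarray(shape) - 1) / 2.0 * spacing_mm
    return affine


def make_toy_atlas(
    shape: tuple[int, int, int] = DEFAULT_SHAPE, spacing_mm: float = DEFAULT_SPACING
) -> AtlasVolume:
    """Eight disjoint spherical regions on an MNI-like grid.

    Right-hemisphere spheres are built in world coordinates; the left
    homologues are index mirrors, so L/R masks are exact mirror images.
    Raises if the grid cannot hold all regions disjointly.
    """
    affine = _mni_like_affine(shape, spacing_mm)
    ii, jj, kk = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    coords = np.stack([ii, jj, kk], axis=-1) * spacing_mm + affine[:3, 3]

    labels = np.zeros(shape, dtype=np.int32)
    name_map: dict[int, str] = {}
    next_id = 1
    for name, (centre, radius) in ATLAS_REGIONS.items():
        centre = np.asarray(centre, float)
        right = np.sum((coords - centre) ** 2, axis=-1) <= radius**2
        left = np.flip(right, axis=0)
        for side, mask in (("L", left), ("R", right)):
            if not mask.any():
                raise ValueError(f"grid {shape} too small: region {name}_{side} is empty")
            if np.any(labels[mask] != 0):
                raise ValueError(f"grid {shape} too small: region {name}_{side} overlaps")
            labels[mask] = next_id
            name_map[next_id] = f"{name}_{side}"
            next_id += 1
    return AtlasVolume(labels=labels, name_map=name_map, affine=affine)


def brain_mask(shape=DEFAULT_SHAPE, spacing_mm: float = DEFAULT_SPACING) -> np.ndarray:
    """Ellipsoidal 'brain' support covering ~half the grid volume."""
    affine = _mni_like_affine(shape, spacing_mm)
    ii, jj, kk = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    coords = np.stack([ii, jj, kk], axis=-1) * spacing_mm + affine[:3, 3]
    semi = (np.asarray(shape) - 1) / 2.0 * spacing_mm * np.array([0.85, 0.9, 0.85])
    return np.sum((coords / semi) ** 2, axis=-1) <= 1.0


def gaussian_smooth(volume: np.ndarray, sigma_mm: float, spacing_mm: float) -> np.ndarray:
    """Isotropic Gaussian smoothing with sigma given in mm.

    Reflective boundary handling, which preserves total mass; sigma 0 is
    the identity.
    """
    if sigma_mm < 0:
        raise ValueError(f"sigma_mm must be >= 0, got {sigma_mm}")
    if sigma_mm == 0:
        return np.asarray(volume, dtype=float).copy()
    return ndimage.gaussian_filter(
        np.asarray(volume, dtype=float), sigma=sigma_mm / spacing_mm, mode="reflect"
    )


def _kernel_l2_factor(sigma_mm: float, spacing_mm: float) -> float:
    """sqrt(sum of squared kernel weights): ratio of smoothed to raw white-noise SD."""
    if sigma_mm == 0:
        return 1.0
    half = max(1, int(np.ceil(6 * sigma_mm / spacing_mm)))
    size = 2 * half + 1
    delta = np.zeros((size, size, size))
    delta[half, half, half] = 1.0
    k = ndimage.gaussian_filter(delta, sigma=sigma_mm / spacing_mm, mode="constant")
    return float(np.sqrt((k**2).sum()))


def calibrate_noise_sd(
    slope_b: float = DEFAULT_SLOPE_B,
    score_sd: float = 9.85,
    rho_voxel: float = DEFAULT_RHO_VOXEL,
    sigma_mm: float = DEFAULT_SIGMA_MM,
    spacing_mm: float = DEFAULT_SPACING,
) -> float:
    """Raw (pre-smoothing) noise SD giving interior-voxel correlation rho.

    From ``rho = b*sd_score / sqrt(b^2 sd_score^2 + sd_noise_sm^2)`` with
    the smoothed-noise SD mapped back through the kernel's L2 norm.
    """
    if not 0 < abs(rho_voxel) < 1:
        raise ValueError("rho_voxel must lie in (0, 1) in magnitude")
    signal_sd = abs(slope_b) * score_sd
    smoothed_sd = signal_sd * np.sqrt(1.0 / rho_voxel**2 - 1.0)
    return smoothed_sd / _kernel_l2_factor(sigma_mm, spacing_mm)


@dataclass
class GroundTruth:
    """Planted effects and noise model behind a simulated GM stack.

    ``effect_map_b``/``effect_map_c`` are the true per-voxel slopes of GM
    on total score and on age (zero outside their region masks);
    ``baseline`` is the noise-free, effect-free GM volume.  The closed
    forms below give the correlations the pipeline should recover.
    """

    effect_map_b: np.ndarray
    effect_map_c: np.ndarray
    region_masks: dict[str, np.ndarray]
    noise_sd: float
    baseline: np.ndarray
    smoothing_sigma_mm: float
    seed: int
    spacing_mm: float = DEFAULT_SPACING
    target_correlations: np.ndarray = field(
        default_factory=lambda: TARGET_CORRELATIONS.copy()
    )

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if np.any(self.baseline < 0):
            raise ValueError("baseline must be non-negative")
        for name, mask in self.region_masks.items():
            if mask.shape != self.baseline.shape:
                raise ValueError(f"region mask {name} is not on the baseline grid")
        outside_b = ~np.any([m for m in self.region_masks.values()], axis=0)
        if np.any(self.effect_map_b[outside_b] != 0) or np.any(
            self.effect_map_c[outside_b] != 0
        ):
            raise ValueError("planted effects must be zero outside the region masks")

    # -- closed-form expectations ------------------------------------------

    def smoothed_noise_sd(self) -> float:
        return self.noise_sd * _kernel_l2_factor(self.smoothing_sigma_mm, self.spacing_mm)

    def expected_voxel_r(self, score_sd: float) -> np.ndarray:
        """True per-voxel correlation of smoothed GM with the total score."""
        slope = gaussian_smooth(self.effect_map_b, self.smoothing_sigma_mm, self.spacing_mm)
        sig = slope * score_sd
        return sig / np.sqrt(sig**2 + self.smoothed_noise_sd() ** 2)

    def expected_cluster_r(self, region: str, score_sd: float) -> float:
        """True correlation of the region-mean smoothed GM with the score.

        The region mean of smoothed white noise has SD
        ``noise_sd * ||smooth(1_R)||_2 / |R|``; the region-mean slope is
        the mean of the smoothed effect map over the region.
        """
        mask = self.region_masks[region]
        nvox = int(mask.sum())
        slope = gaussian_smooth(self.effect_map_b, self.smoothing_sigma_mm, self.spacing_mm)
        mean_slope = float(slope[mask].mean())
        weights = gaussian_smooth(mask.astype(float), self.smoothing_sigma_mm, self.spacing_mm)
        noise_sd = self.noise_sd * float(np.sqrt((weights**2).sum())) / nvox
        sig = mean_slope * score_sd
        return float(sig / np.sqrt(sig**2 + noise_sd**2))

    # -- serialization ------------------------------------------------------

    def save(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        affine = _mni_like_affine(self.baseline.shape, self.spacing_mm)
        for name, arr in (
            ("effect_map_b", self.effect_map_b),
            ("effect_map_c", self.effect_map_c),
            ("baseline", self.baseline),
        ):
            nib.save(nib.Nifti1Image(arr.astype(np.float64), affine), outdir / f"{name}.nii.gz")
        for name, mask in self.region_masks.items():
            nib.save(
                nib.Nifti1Image(mask.astype(np.uint8), affine),
                outdir / f"region_{name}.nii.gz",
            )
        meta = {
            "noise_sd": self.noise_sd,
            "smoothing_sigma_mm": self.smoothing_sigma_mm,
            "seed": self.seed,
            "spacing_mm": self.spacing_mm,
            "regions": sorted(self.region_masks),
            "target_correlations": self.target_correlations.tolist(),
        }
        (outdir / "truth.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, outdir) -> "GroundTruth":
        outdir = Path(outdir)
        meta = json.loads((outdir / "truth.json").read_text())
        arr = lambda name: np.asarray(  # noqa: E731
            nib.load(outdir / f"{name}.nii.gz").dataobj, dtype=np.float64
        )
        return cls(
            effect_map_b=arr("effect_map_b"),
            effect_map_c=arr("effect_map_c"),
            region_masks={
                name: np.asarray(nib.load(outdir / f"region_{name}.nii.gz").dataobj) > 0
                for name in meta["regions"]
            },
            noise_sd=meta["noise_sd"],
            baseline=arr("baseline"),
            smoothing_sigma_mm=meta["smoothing_sigma_mm"],
            seed=meta["seed"],
            spacing_mm=meta["spacing_mm"],
            target_correlations=np.asarray(meta["target_correlations"]),
        )


def _nearest_psd_check(target: np.ndarray) -> None:
    target = np.asarray(target, float)
    if target.shape[0] != target.shape[1] or not np.allclose(target, target.T, atol=1e-10):
        raise ValueError("target correlation matrix must be square and symmetric")
    eigmin = float(np.linalg.eigvalsh(target).min())
    if eigmin < -1e-10:
        raise ValueError(
            f"target correlation matrix is not positive semi-definite "
            f"(min eigenvalue {eigmin:.3e}); project it to the nearest PSD "
            "matrix (clip negative eigenvalues and renormalize) first"
        )


def simulate_clinical(
    n: int = 364,
    target: np.ndarray | None = None,
    seed: int = 0,
    base_date: str = "2015-01-15",
) -> pd.DataFrame:
    """Item-level clinical table with a target subscore correlation structure.

    Latent Gaussian subscore vectors with the target 4x4 correlation
    (axial, bradykinesia, rigidity, tremor block of ``target``) are mapped
    monotonically to non-negative integer subscores using the cohort
    marginals, then distributed over the instrument items so that the
    group sums reproduce the subscores exactly (item 9 serves both the
    bradykinesia and the axial sum).  Age, sex and medication flags are
    drawn from the cohort demographics.  Returns one row per subject with
    ``item_1..item_18``, covariates, and the realized subscore columns.
    """
    if n < 10:
        raise ValueError("need n >= 10 subjects")
    if target is None:
        target = TARGET_CORRELATIONS
    _nearest_psd_check(target)
    latent_corr = np.asarray(target, float)[:4, :4]
    rng = np.random.default_rng(seed)

    z = rng.multivariate_normal(np.zeros(4), latent_corr, size=n, method="cholesky")
    subs = {}
    for j, lab in enumerate(("axial", "bradykinesia", "rigidity", "tremor")):
        mu, sd = SUBSCORE_MARGINALS[lab]
        subs[lab] = np.maximum(0, np.rint(mu + sd * z[:, j])).astype(int)

    items = np.zeros((n, 19), dtype=int)  # 1-based item columns
    brady_rest = tuple(i for i in BRADYKINESIA_ITEMS if i != 9)
    axial_rest = tuple(i for i in AXIAL_ITEMS if i != 9)
    for s in range(n):
        items[s, 3] = subs["rigidity"][s]
        items[s, list(TREMOR_ITEMS)] = rng.multinomial(
            subs["tremor"][s], np.full(len(TREMOR_ITEMS), 1 / len(TREMOR_ITEMS))
        )
        # item 9 contributes to both the bradykinesia and the axial sum
        i9 = int(min(rng.binomial(2, 0.15), subs["bradykinesia"][s], subs["axial"][s]))
        items[s, 9] = i9
        items[s, list(brady_rest)] = rng.multinomial(
            subs["bradykinesia"][s] - i9, np.full(len(brady_rest), 1 / len(brady_rest))
        )
        items[s, list(axial_rest)] = rng.multinomial(
            subs["axial"][s] - i9, np.full(len(axial_rest), 1 / len(axial_rest))
        )

    age = np.clip(rng.normal(AGE_MEAN, AGE_SD, size=n), 30.0, 90.0)
    frame = pd.DataFrame(
        {
            "subject_id": [f"S{idx:04d}" for idx in range(n)],
            "visit_date": base_date,
            **{f"item_{i}": items[:, i] for i in range(1, 19)},
            "age": np.round(age, 1),
            "sex": (rng.random(n) < MALE_FRACTION).astype(int),
            "on_medication": rng.random(n) < MEDICATED_FRACTION,
        }
    )
    for lab in ("axial", "bradykinesia", "rigidity", "tremor"):
        frame[lab] = subs[lab]
    frame["total"] = items[:, 1:].sum(axis=1)
    return frame


def default_ground_truth(
    atlas: AtlasVolume,
    slope_b: float = DEFAULT_SLOPE_B,
    slope_c: float = DEFAULT_SLOPE_C,
    noise_sd: float | None = None,
    rho_voxel: float = DEFAULT_RHO_VOXEL,
    score_sd: float = 9.85,
    sigma_mm: float = DEFAULT_SIGMA_MM,
    seed: int = 0,
    effect_regions_b: tuple[str, ...] = ("caudate_L", "caudate_R", "putamen_L", "putamen_R"),
    effect_regions_c: tuple[str, ...] = ("hippocampal_complex_L", "hippocampal_complex_R"),
    baseline_level: float = 0.5,
) -> GroundTruth:
    """Ground truth with a striatal score effect and a hippocampal age effect.

    When ``noise_sd`` is omitted it is calibrated so that the true
    interior-voxel correlation equals ``rho_voxel``.
    """
    shape = atlas.labels.shape
    spacing = float(abs(atlas.affine[0, 0])) if atlas.affine is not None else DEFAULT_SPACING
    masks = {name: atlas.labels == lid for lid, name in atlas.name_map.items()}
    effect_b = np.zeros(shape)
    for name in effect_regions_b:
        effect_b[masks[name]] = slope_b
    effect_c = np.zeros(shape)
    for name in effect_regions_c:
        effect_c[masks[name]] = slope_c
    if noise_sd is None:
        noise_sd = calibrate_noise_sd(slope_b or DEFAULT_SLOPE_B, score_sd, rho_voxel, sigma_mm, spacing)
    baseline = baseline_level * brain_mask(shape, spacing).astype(float)
    return GroundTruth(
        effect_map_b=effect_b,
        effect_map_c=effect_c,
        region_masks=masks,
        noise_sd=float(noise_sd),
        baseline=baseline,
        smoothing_sigma_mm=sigma_mm,
        seed=seed,
        spacing_mm=spacing,
    )


def simulate_gm(
    clinical: pd.DataFrame, atlas: AtlasVolume, truth: GroundTruth
) -> GMVolumeStack:
    """GM stack realizing the planted linear model.

    Per subject: ``smooth(baseline + b*total + c*age + noise)`` clipped at
    zero.  Smoothing is linear, so the deterministic parts are smoothed
    once and only the noise field is smoothed per subject.
    """
    if atlas.labels.shape != truth.baseline.shape:
        raise ValueError("atlas grid does not match ground-truth grid")
    rng = np.random.default_rng(truth.seed)
    shape = truth.baseline.shape
    sig, sp = truth.smoothing_sigma_mm, truth.spacing_mm

    base_sm = gaussian_smooth(truth.baseline, sig, sp)
    eff_b_sm = gaussian_smooth(truth.effect_map_b, sig, sp)
    eff_c_sm = gaussian_smooth(truth.effect_map_c, sig, sp)

    total = clinical["total"].to_numpy(dtype=float)
    age = clinical["age"].to_numpy(dtype=float)
    n = len(clinical)
    data = np.empty((n,) + shape, dtype=np.float32)
    for s in range(n):
        noise = gaussian_smooth(rng.normal(0.0, truth.noise_sd, size=shape), sig, sp)
        vol = base_sm + eff_b_sm * total[s] + eff_c_sm * age[s] + noise
        data[s] = np.maximum(vol, 0.0)
    affine = atlas.affine if atlas.affine is not None else _mni_like_affine(shape, sp)
    return GMVolumeStack(
        data=data, affine=affine, subject_ids=list(clinical["subject_id"].astype(str))
    )


def save_cohort(outdir, clinical: pd.DataFrame, atlas: AtlasVolume, stack: GMVolumeStack, truth: GroundTruth) -> None:
    """Write gm4d.nii.gz, atlas.nii.gz + names, clinical.csv and the truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stack.to_nifti(outdir / "gm4d.nii.gz")
    atlas.to_nifti(outdir / "atlas.nii.gz", outdir / "atlas_names.tsv")
    clinical.to_csv(outdir / "clinical.csv", index=False)
    truth.save(outdir / "truth")
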