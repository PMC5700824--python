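"""Mass-univariate voxel statistics with permutation FWE correction.

Each voxel of a co-registered grey-matter stack is tested against a
per-subject motor score, either by Pearson correlation (with the Fisher-z
and Student-t conversions ``z = atanh(r)``, ``t = r*sqrt(df/(1-r^2))``,
``df = n - 2``) or through an ordinary-least-squares GLM

    GM = a + b*score + c*age + d*sex + e

whose coefficient t statistics use ``df = n - p``.  Family-wise error
across the mask is controlled by the permutation maxT method: the score
column is relabelled across subjects (Freedman-Lane residual permutation
when nuisance covariates are present), the tail-extreme statistic over the
mask is recorded per permutation, and the FWE threshold is the appropriate
empirical quantile of that null.  Restricting the mask to an a-priori
region gives small-volume correction.  A Bonferroni threshold is provided
as an assumption-free cross-check.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GMVolumeStack",
    "MaskVolume",
    "StatMap",
    "GLMResult",
    "PermutationNull",
    "build_analysis_mask",
    "voxelwise_pearson",
    "r_to_t",
    "fisher_z",
    "fit_voxelwise_glm",
    "fwe_maxT",
    "small_volume_correction",
    "bonferroni_threshold",
]

#: Finite stand-in for an infinite t when |r| reaches 1.
T_CLAMP = 1e6

_TAILS = ("one_neg", "one_pos", "two")


@dataclass
class GMVolumeStack:
    """Subjects x 3-D grey-matter intensities with a voxel->mm affine."""

    data: np.ndarray
    affine: np.ndarray
    subject_ids: list[str]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(f"expected 4-D (subjects, x, y, z) data, got {self.data.ndim}-D")
        if self.data.shape[0] != len(self.subject_ids):
            raise ValueError("subject_ids length does not match data axis 0")
        if self.data.shape[0] < 3:
            raise ValueError("need at least 3 subjects")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("GM intensities must be finite")
        if np.any(self.data < 0):
            raise ValueError("GM intensities must be non-negative")
        if self.affine.shape != (4, 4) or abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValueError("affine must be an invertible 4x4 matrix")

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape[1:]

    @classmethod
    def from_nifti(cls, path, subject_ids: Sequence[str] | None = None) -> "GMVolumeStack":
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=np.float32)
        if data.ndim != 4:
            raise ValueError(f"{path}: expected a 4-D NIfTI, got {data.ndim}-D")
        data = np.moveaxis(data, -1, 0)  # NIfTI stores subjects on the last axis
        n = data.shape[0]
        ids = list(subject_ids) if subject_ids is not None else [f"sub-{i:04d}" for i in range(n)]
        return cls(data=data, affine=img.affine, subject_ids=ids)

    def to_nifti(self, path) -> None:
        img = nib.Nifti1Image(np.moveaxis(self.data, 0, -1).astype(np.float32), self.affine)
        nib.save(img, str(path))


@dataclass
class MaskVolume:
    """Binary voxel mask on the analysis grid."""

    data: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if not np.isin(arr, (0, 1)).all():
            raise ValueError("mask values must be 0/1")
        self.data = arr.astype(bool)
        if not self.data.any():
            raise ValueError("mask has no nonzero voxels")

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    @classmethod
    def from_nifti(cls, path, provenance: str = "") -> "MaskVolume":
        img = nib.load(str(path))
        return cls(np.asarray(img.dataobj) > 0, provenance or str(path))

    def to_nifti(self, path, affine: np.ndarray) -> None:
        nib.save(nib.Nifti1Image(self.data.astype(np.uint8), affine), str(path))


@dataclass
class StatMap:
    """Per-voxel r / Fisher-z / t / p volumes (NaN outside the mask)."""

    r: np.ndarray
    z: np.ndarray
    t: np.ndarray
    p: np.ndarray
    df: int
    tail: str

    def __post_init__(self) -> None:
        if self.tail not in _TAILS:
            raise ValueError(f"tail must be one of {_TAILS}, got {self.tail!r}")


@dataclass
class GLMResult:
    """Voxel-wise OLS fit of GM intensity on the design columns.

    ``coef`` and ``t_coef`` map design column name -> 3-D array; the
    intercept column is named ``"intercept"``.
    """

    coef: dict[str, np.ndarray]
    t_coef: dict[str, np.ndarray]
    residual_df: int
    design_summary: pd.DataFrame


@dataclass
class PermutationNull:
    """MaxT permutation null and the FWE-corrected maps derived from it.

    ``max_stats`` holds the tail-extreme statistic over mask voxels for
    each permutation (minima for ``one_neg``, maxima of |t| for ``two``).
    ``threshold`` is the empirical FWE critical value at ``alpha``
    (negative for ``one_neg``).  ``corrected_p`` uses the add-one
    convention ``(1 + #{perm extreme beats observed}) / (n_perm + 1)``.
    """

    max_stats: np.ndarray
    n_perm: int
    seed: int
    alpha: float
    tail: str
    threshold: float
    observed_t: np.ndarray
    corrected_p: np.ndarray
    exhaustive: bool = False
    mask: np.ndarray | None = field(default=None, repr=False)

    def significant(self) -> np.ndarray:
        """Boolean volume of voxels surviving FWE at ``alpha``."""
        t = self.observed_t
        with np.errstate(invalid="ignore"):
            if self.tail == "one_neg":
                return np.nan_to_num(t, nan=0.0) < self.threshold
            if self.tail == "one_pos":
                return np.nan_to_num(t, nan=0.0) > self.threshold
            return np.abs(np.nan_to_num(t, nan=0.0)) > self.threshold


def build_analysis_mask(
    stack: GMVolumeStack,
    min_mean_intensity: float = 0.05,
    atlas_mask: MaskVolume | None = None,
) -> MaskVolume:
    """Voxels with mean intensity above threshold and nonzero variance.

    Zero-variance voxels are excluded here (rather than assigned r = 0
    downstream) so every tested voxel has a well-defined statistic.
    """
    mean = stack.data.mean(axis=0)
    var = stack.data.var(axis=0)
    keep = (mean >= min_mean_intensity) & (var > 0)
    if atlas_mask is not None:
        keep &= atlas_mask.data
    if not keep.any():
        raise ValueError("analysis mask is empty: no voxel passes intensity/variance checks")
    return MaskVolume(keep, provenance=f"analysis mask (min mean {min_mean_intensity})")


def r_to_t(r, df: int):
    """Convert Pearson r to a Student-t value, ``t = r*sqrt(df/(1-r^2))``.

    Values with |r| >= 1 are clamped to +/-1e6 with a warning instead of
    returning infinity.
    """
    if df < 1:
        raise ValueError(f"df must be >= 1, got {df}")
    r_arr = np.asarray(r, dtype=float)
    out = np.empty_like(r_arr)
    # |r| within 1e-12 of 1 would give t beyond the clamp anyway
    saturated = np.abs(r_arr) >= 1.0 - 1e-12
    if saturated.any():
        warnings.warn(
            "|r| >= 1 encountered; t clamped to +/-1e6", RuntimeWarning, stacklevel=2
        )
        out[saturated] = np.sign(r_arr[saturated]) * T_CLAMP
    ok = ~saturated
    out[ok] = r_arr[ok] * np.sqrt(df / (1.0 - r_arr[ok] ** 2))
    return float(out) if np.isscalar(r) else out


def fisher_z(r):
    """Variance-stabilizing atanh transform of r."""
    return np.arctanh(np.clip(r, -1.0, 1.0))


def _t_to_p(t: np.ndarray, df: int, tail: str) -> np.ndarray:
    if tail == "one_neg":
        return stats.t.cdf(t, df)
    if tail == "one_pos":
        return stats.t.sf(t, df)
    return 2.0 * stats.t.sf(np.abs(t), df)


def voxelwise_pearson(
    stack: GMVolumeStack, x: np.ndarray, mask: MaskVolume, tail: str = "two"
) -> StatMap:
    """Pearson correlation of each mask voxel's GM series with score x.

    Returns r, Fisher z, t (df = n - 2) and the tail p value, NaN outside
    the mask.
    """
    x = np.asarray(x, dtype=float)
    if x.shape != (stack.n_subjects,):
        raise ValueError(f"score vector length {x.shape} != n_subjects {stack.n_subjects}")
    if np.std(x) == 0:
        raise ValueError("score vector has zero variance")
    if tail not in _TAILS:
        raise ValueError(f"tail must be one of {_TAILS}")

    n = stack.n_subjects
    df = n - 2
    Y = stack.data[:, mask.data].astype(np.float64)  # n x V
    r_flat = _pearson_flat(x, Y)

    shape = stack.shape
    r = np.full(shape, np.nan)
    z = np.full(shape, np.nan)
    t = np.full(shape, np.nan)
    p = np.full(shape, np.nan)
    r[mask.data] = r_flat
    z[mask.data] = fisher_z(r_flat)
    t_flat = r_to_t(r_flat, df)
    t[mask.data] = t_flat
    p[mask.data] = _t_to_p(t_flat, df, tail)
    return StatMap(r=r, z=z, t=t, p=p, df=df, tail=tail)


def _pearson_flat(x: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Pearson r of x against each column of Y (n x V); clipped to [-1, 1]."""
    n = len(x)
    xc = x - x.mean()
    Yc = Y - Y.mean(axis=0)
    xnorm = np.linalg.norm(xc)
    ynorm = np.linalg.norm(Yc, axis=0)
    if np.any(ynorm == 0):
        raise ValueError("zero-variance voxel inside mask; rebuild the analysis mask")
    return np.clip((xc @ Yc) / (xnorm * ynorm), -1.0, 1.0)


def _build_design(covariates: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    names = ["intercept", *covariates.columns]
    X = np.column_stack([np.ones(len(covariates)), covariates.to_numpy(dtype=float)])
    cond = np.linalg.cond(X)
    if cond > 1e8 or np.linalg.matrix_rank(X) < X.shape[1]:
        corr = np.corrcoef(X[:, 1:], rowvar=False) if X.shape[1] > 2 else np.array([[1.0]])
        pairs = [
            f"{covariates.columns[i]}~{covariates.columns[j]}"
            for i in range(corr.shape[0])
            for j in range(i + 1, corr.shape[0])
            if abs(corr[i, j]) > 0.999
        ]
        detail = f" (near-collinear: {', '.join(pairs)})" if pairs else ""
        raise ValueError(
            f"design matrix is rank-deficient or ill-conditioned (cond={cond:.2e}) "
            f"for columns {names}{detail}"
        )
    return X, names


def fit_voxelwise_glm(
    stack: GMVolumeStack, covariates: pd.DataFrame, mask: MaskVolume
) -> GLMResult:
    """OLS fit of GM intensity on (intercept + covariate columns) per voxel.

    ``covariates`` typically holds UPDRS3, Age, Sex; with only the score
    column the coefficient t map reduces exactly to the Pearson t map.
    Coefficient t statistics use residual df = n - p.
    """
    n = stack.n_subjects
    if len(covariates) != n:
        raise ValueError("covariate table length does not match n_subjects")
    X, names = _build_design(covariates)
    p = X.shape[1]
    if n <= p:
        raise ValueError(f"need n > {p} subjects for a {p}-column design")
    rdf = n - p

    Y = stack.data[:, mask.data].astype(np.float64)
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ (X.T @ Y)  # p x V
    resid = Y - X @ beta
    sigma2 = np.einsum("ij,ij->j", resid, resid) / rdf
    se = np.sqrt(np.outer(np.diag(XtX_inv), sigma2))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, beta / se, np.sign(beta) * T_CLAMP)

    shape = stack.shape
    coef, t_coef = {}, {}
    for k, name in enumerate(names):
        c = np.full(shape, np.nan)
        tv = np.full(shape, np.nan)
        c[mask.data] = beta[k]
        tv[mask.data] = tvals[k]
        coef[name] = c
        t_coef[name] = tv

    summary = pd.DataFrame(
        {
            "column": names,
            "mean": X.mean(axis=0),
            "sd": X.std(axis=0, ddof=1),
        }
    )
    return GLMResult(coef=coef, t_coef=t_coef, residual_df=rdf, design_summary=summary)


# ---------------------------------------------------------------------------
# Permutation maxT

def _iter_permutations(n: int, n_perm: int, rng: np.random.Generator):
    """Yield permutation index arrays; exhaustive when n! <= n_perm."""
    n_distinct = math.factorial(n)
    if n_distinct <= n_perm:
        warnings.warn(
            f"n_perm={n_perm} >= {n}! = {n_distinct}; enumerating all permutations",
            RuntimeWarning,
            stacklevel=3,
        )
        return (np.array(p) for p in itertools.permutations(range(n))), n_distinct, True
    return (rng.permutation(n) for _ in range(n_perm)), n_perm, False


def _pearson_t_flat(x: np.ndarray, Yc: np.ndarray, ynorm: np.ndarray, df: int) -> np.ndarray:
    xc = x - x.mean()
    r = np.clip((xc @ Yc) / (np.linalg.norm(xc) * ynorm), -1.0, 1.0)
    r = np.clip(r, -1.0 + 1e-15, 1.0 - 1e-15)
    return r * np.sqrt(df / (1.0 - r**2))


class _FreedmanLane:
    """Freedman-Lane t statistics for one tested column with nuisance Z.

    The nuisance-reduced residuals of Y are permuted; the full-model t for
    the tested coefficient is then recomputed in closed form using the
    orthogonality of the residualized regressor to Z.
    """

    def __init__(self, x: np.ndarray, Z: np.ndarray, Y: np.ndarray):
        n = len(x)
        self.Qz, _ = np.linalg.qr(Z)
        xr = x - self.Qz @ (self.Qz.T @ x)
        self.xr = xr
        self.xr_ss = float(xr @ xr)
        if self.xr_ss <= 1e-12 * float(x @ x):
            raise ValueError("tested column is collinear with nuisance covariates")
        self.E = Y - self.Qz @ (self.Qz.T @ Y)  # reduced-model residuals, n x V
        self.E_ss = np.einsum("ij,ij->j", self.E, self.E)
        self.df = n - Z.shape[1] - 1

    def t_for(self, perm: np.ndarray) -> np.ndarray:
        Ep = self.E[perm]
        num = self.xr @ Ep
        # ||R_z Ep||^2 = ||Ep||^2 - ||Q_z^T Ep||^2 ; column norms are permutation-invariant
        G = self.Qz.T @ Ep
        rss_reduced = self.E_ss - np.einsum("ij,ij->j", G, G)
        rss_full = np.maximum(rss_reduced - num**2 / self.xr_ss, 0.0)
        sigma2 = rss_full / self.df
        with np.errstate(divide="ignore", invalid="ignore"):
            t = num / self.xr_ss / np.sqrt(sigma2 / self.xr_ss)
        return np.where(np.isfinite(t), t, np.sign(num) * T_CLAMP)

    def t_observed(self) -> np.ndarray:
        return self.t_for(np.arange(len(self.xr)))


def fwe_maxT(
    stack: GMVolumeStack,
    design: pd.DataFrame,
    test: str,
    mask: MaskVolume,
    alpha: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
    tail: str = "one_neg",
    score_col: str = "UPDRS3",
) -> PermutationNull:
    """Permutation maxT family-wise-error correction over the mask.

    ``test`` selects the statistic: ``"pearson"`` (simple relabelling of
    the score), ``"glm_b"`` (Freedman-Lane test of the score coefficient
    with the remaining design columns as nuisance) or ``"glm_c"`` (same
    for the Age column).  The FWE threshold is the empirical (1 - alpha)
    quantile of the per-permutation extreme statistic (alpha quantile of
    the minima for the negative tail); corrected p values use the add-one
    convention.  With n_perm at or above n!, all distinct permutations are
    enumerated instead.
    """
    if test not in ("pearson", "glm_b", "glm_c"):
        raise ValueError(f"unknown test {test!r}")
    if tail not in _TAILS:
        raise ValueError(f"tail must be one of {_TAILS}")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100 for a usable null")

    n = stack.n_subjects
    Y = stack.data[:, mask.data].astype(np.float64)
    rng = np.random.default_rng(seed)
    perms, n_total, exhaustive = _iter_permutations(n, n_perm, rng)

    if test == "pearson":
        x = design[score_col].to_numpy(dtype=float)
        if np.std(x) == 0:
            raise ValueError("score vector has zero variance")
        df = n - 2
        Yc = Y - Y.mean(axis=0)
        ynorm = np.linalg.norm(Yc, axis=0)
        if np.any(ynorm == 0):
            raise ValueError("zero-variance voxel inside mask")
        t_obs = _pearson_t_flat(x, Yc, ynorm, df)
        stat = lambda perm: _pearson_t_flat(x[perm], Yc, ynorm, df)  # noqa: E731
    else:
        tested = score_col if test == "glm_b" else "Age"
        if tested not in design.columns:
            raise ValueError(f"design lacks required column {tested!r}")
        nuisance = [c for c in design.columns if c != tested]
        Z = np.column_stack([np.ones(n), design[nuisance].to_numpy(dtype=float)])
        fl = _FreedmanLane(design[tested].to_numpy(dtype=float), Z, Y)
        t_obs = fl.t_observed()
        stat = fl.t_for

    max_stats = np.empty(n_total)
    for b, perm in enumerate(perms):
        tb = stat(perm)
        if tail == "one_neg":
            max_stats[b] = tb.min()
        elif tail == "one_pos":
            max_stats[b] = tb.max()
        else:
            max_stats[b] = np.abs(tb).max()

    if tail == "one_neg":
        threshold = float(np.quantile(max_stats, alpha, method="lower"))
        exceed = max_stats[:, None] <= t_obs[None, :]
    elif tail == "one_pos":
        threshold = float(np.quantile(max_stats, 1 - alpha, method="higher"))
        exceed = max_stats[:, None] >= t_obs[None, :]
    else:
        threshold = float(np.quantile(max_stats, 1 - alpha, method="higher"))
        exceed = max_stats[:, None] >= np.abs(t_obs)[None, :]
    p_flat = (1.0 + exceed.sum(axis=0)) / (n_total + 1.0)

    shape = stack.shape
    observed_t = np.full(shape, np.nan)
    corrected_p = np.full(shape, np.nan)
    observed_t[mask.data] = t_obs
    corrected_p[mask.data] = p_flat
    return PermutationNull(
        max_stats=max_stats,
        n_perm=n_total,
        seed=seed,
        alpha=alpha,
        tail=tail,
        threshold=threshold,
        observed_t=observed_t,
        corrected_p=corrected_p,
        exhaustive=exhaustive,
        mask=mask.data,
    )


def small_volume_correction(
    stack: GMVolumeStack,
    design: pd.DataFrame,
    test: str,
    analysis_mask: MaskVolume,
    svc_mask: MaskVolume,
    **kwargs,
) -> PermutationNull:
    """FWE maxT restricted to an a-priori small-volume mask.

    The correction runs over ``svc_mask & analysis_mask``; a small-volume
    mask disjoint from the analysis mask is an error.
    """
    inter = svc_mask.data & analysis_mask.data
    if not inter.any():
        raise ValueError("small-volume mask is disjoint from the analysis mask")
    mask = MaskVolume(inter, provenance=f"SVC: {svc_mask.provenance}")
    return fwe_maxT(stack, design, test, mask, **kwargs)


def bonferroni_threshold(alpha: float, n_voxels: int, df: int, tail: str = "one_neg") -> float:
    """Student-t threshold at per-voxel level alpha / n_voxels.

    Conservative FWE cross-check against the permutation maxT threshold.
    """
    if n_voxels < 1:
        raise ValueError("n_voxels must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if tail == "one_neg":
        return float(stats.t.ppf(alpha / n_voxels, df))
    if tail == "one_pos":
        return float(stats.t.isf(alpha / n_voxels, df))
    if tail == "two":
        return float(stats.t.isf(alpha / (2 * n_voxels), df))
    raise ValueError(f"tail must be one of {_TAILS}")
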