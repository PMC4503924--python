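"""Statistical layer: Bray-Curtis, Mantel tests, and cycle-bias regressions.

These are the analyses used to quantify two-step-PCR biases: community
profiles are compared by Bray-Curtis dissimilarity on relative abundances; a
one-sided Mantel permutation test relates community dissimilarity to
differences in total PCR cycle number; ordinary least squares relates
contaminant burden to step-1/step-2 cycle numbers, read depth, and community
structure, and observed:expected library fractions to pooling covariates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy.spatial.distance import braycurtis as _scipy_braycurtis

__all__ = [
    "CycleDesign",
    "DistanceMatrix",
    "MantelResult",
    "RegressionFit",
    "bray_curtis",
    "bray_curtis_matrix",
    "cycle_distance_matrix",
    "mantel",
    "ols_fit",
    "obs_exp_ratios",
]


@dataclass(frozen=True)
class CycleDesign:
    """PCR design for one library: step-1/step-2 cycles, community, depth."""

    library_id: str
    cycles_step1: int
    cycles_step2: int
    community: str = "other"  # "even" | "uneven" | "other"
    read_depth: int = 0

    def __post_init__(self) -> None:
        if self.cycles_step1 < 0 or self.cycles_step2 < 0:
            raise ValueError("cycle numbers must be non-negative")

    @property
    def total_cycles(self) -> int:
        return self.cycles_step1 + self.cycles_step2


@dataclass
class DistanceMatrix:
    """A labeled symmetric distance matrix with zero diagonal."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != len(self.labels):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0):
            raise ValueError("distance matrix must have a zero diagonal")
        if (v < 0).any():
            raise ValueError("distances must be non-negative")
        self.values = v

    def condensed(self) -> np.ndarray:
        """Strictly-lower-triangle entries, row-major."""
        i, j = np.tril_indices(len(self.labels), k=-1)
        return self.values[i, j]


@dataclass
class MantelResult:
    r: float
    p: float
    n_permutations: int
    seed: int | None = None


@dataclass
class RegressionFit:
    """OLS estimates with classical standard errors and type-I ANOVA."""

    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    rsquared: float
    rsquared_adj: float
    f_pvalue: float
    df_resid: float
    anova_typeI: pd.DataFrame | None = None
    residuals: np.ndarray = field(default_factory=lambda: np.array([]))


def _normalize(profile: Sequence[float]) -> np.ndarray:
    x = np.asarray(profile, dtype=float)
    if (x < 0).any():
        raise ValueError("abundances must be non-negative")
    total = x.sum()
    if total == 0:
        raise ValueError("all-zero abundance profile")
    return x / total


def bray_curtis(x: Sequence[float], y: Sequence[float]) -> float:
    """Bray-Curtis dissimilarity of two profiles, after normalizing each to
    relative abundance (so libraries of unequal depth are comparable)."""
    xn, yn = _normalize(x), _normalize(y)
    if len(xn) != len(yn):
        raise ValueError("profiles must have equal length")
    return float(_scipy_braycurtis(xn, yn))


def bray_curtis_matrix(profiles: pd.DataFrame) -> DistanceMatrix:
    """All-pairs Bray-Curtis over profile columns (one column per library)."""
    labels = list(profiles.columns)
    n = len(labels)
    values = np.zeros((n, n))
    normed = [_normalize(profiles[c].to_numpy()) for c in labels]
    for i in range(n):
        for j in range(i):
            values[i, j] = values[j, i] = _scipy_braycurtis(normed[i], normed[j])
    return DistanceMatrix(labels, values)


def cycle_distance_matrix(designs: Sequence[CycleDesign]) -> DistanceMatrix:
    """Pairwise absolute differences in total (step 1 + step 2) cycle number."""
    if len(designs) < 2:
        raise ValueError("need at least two designs")
    totals = np.array([d.total_cycles for d in designs], dtype=float)
    return DistanceMatrix([d.library_id for d in designs], np.abs(totals[:, None] - totals[None, :]))


def mantel(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    n_permutations: int = 999,
    seed: int | None = None,
) -> MantelResult:
    """One-sided (greater) Mantel permutation test between two distance matrices.

    r is the Pearson correlation of the strictly-lower-triangle entries; the
    null distribution permutes rows/columns of ``d2`` simultaneously;
    p = (1 + #{r_perm >= r_obs}) / (1 + n_permutations).
    """
    if d1.labels != d2.labels:
        raise ValueError("distance matrices must share labels in the same order")
    x = d1.condensed()
    v2 = d2.values
    y = d2.condensed()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant lower triangle: Mantel correlation undefined")

    xc = (x - x.mean()) / x.std()
    n = len(d1.labels)
    il, jl = np.tril_indices(n, k=-1)

    def corr(yv: np.ndarray) -> float:
        ys = yv.std()
        if ys == 0:
            return 0.0
        return float(np.mean(xc * (yv - yv.mean()) / ys))

    r_obs = corr(y)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        p = rng.permutation(n)
        if corr(v2[p[il], p[jl]]) >= r_obs:
            hits += 1
    pval = (1 + hits) / (1 + n_permutations)
    return MantelResult(r_obs, pval, n_permutations, seed)


def _formula_terms(design: pd.DataFrame) -> list[str]:
    terms = []
    for col in design.columns:
        if design[col].dtype == object or isinstance(design[col].dtype, pd.CategoricalDtype):
            terms.append(f"C({col})")
        else:
            terms.append(col)
    return terms


def ols_fit(response: Sequence[float], design: pd.DataFrame, anova: bool = True) -> RegressionFit:
    """Ordinary least squares of a response on numeric + categorical terms.

    Categorical columns are dummy-coded against their alphabetically first
    level. Classical standard errors; two-sided t p-values; sequential
    (type-I) ANOVA per term when ``anova``. A rank-deficient design raises,
    naming a collinear term.
    """
    df = design.copy()
    df["__y"] = np.asarray(response, dtype=float)
    if len(df) <= len(design.columns) + 1:
        raise ValueError("more model terms than observations")
    formula = "__y ~ " + " + ".join(_formula_terms(design))
    model = smf.ols(formula, data=df)
    rank = np.linalg.matrix_rank(model.exog)
    if rank < model.exog.shape[1]:
        # Identify a column involved in the collinearity via QR diagonal.
        _, rdiag = np.linalg.qr(model.exog)
        bad = model.exog_names[int(np.argmin(np.abs(np.diag(rdiag))))]
        raise ValueError(f"rank-deficient design: term {bad!r} is collinear")
    fit = model.fit()
    anova_tab = sm.stats.anova_lm(fit, typ=1) if anova else None
    return RegressionFit(
        params=fit.params,
        bse=fit.bse,
        tvalues=fit.tvalues,
        pvalues=fit.pvalues,
        rsquared=float(fit.rsquared),
        rsquared_adj=float(fit.rsquared_adj),
        f_pvalue=float(fit.f_pvalue),
        df_resid=float(fit.df_resid),
        anova_typeI=anova_tab,
        residuals=np.asarray(fit.resid),
    )


def obs_exp_ratios(
    counts: pd.Series, multipliers: pd.Series, design: pd.DataFrame | None = None
) -> tuple[pd.Series, pd.DataFrame | None]:
    """Observed:expected library fraction per library.

    ``multipliers`` are molar pooling weights (e.g., 2 for amplicons spiked
    in twice because their length exceeds 600 bp, else 1); the expected
    fraction of a library is its multiplier over the sum of multipliers. The
    optional ``design`` (preparer, gene target, amplicon length, ...) is
    aligned and returned for regression with :func:`ols_fit`.
    """
    if (multipliers < 1).any():
        raise ValueError("multipliers must be >= 1")
    total = counts.sum()
    if total == 0:
        raise ValueError("zero total counts")
    observed = counts / total
    expected = multipliers / multipliers.sum()
    ratios = (observed / expected).rename("obs_exp_ratio")
    aligned = design.loc[ratios.index] if design is not None else None
    return ratios, aligned
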