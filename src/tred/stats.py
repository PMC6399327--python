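"""Population-level statistics for receptor-dynamics phenotyping.

Per-trajectory diffusivities and confinement sizes are broadly distributed
and approximately lognormal, so population structure is resolved by fitting
Gaussian mixtures to log10 values with the number of components chosen by
AIC (1–3 components for D, 1–2 for L).  Log-space component moments are
converted to arithmetic means/SDs for reporting.  Group comparisons follow
the F-test-gated unpaired t-test convention: an F-test on the variance
ratio decides between the pooled-variance and Welch variants.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from sklearn.mixture import GaussianMixture

__all__ = [
    "MixtureFit",
    "GroupSummary",
    "TestResult",
    "fit_log_mixture",
    "lognormal_moments",
    "summarize_group",
    "compare_groups",
    "percent_difference",
    "correlate",
    "significance_stars",
]

_LN10 = math.log(10.0)

_LABELS = {1: ["all"], 2: ["small", "large"], 3: ["immobile", "less_mobile", "mobile"]}


@dataclass
class MixtureFit:
    """K-component Gaussian fit of log10 values, AIC-selected.

    Components are sorted ascending by log-mean; arithmetic moments are the
    lognormal mean/SD implied by each component's log10 parameters.
    """

    K: int
    weights: np.ndarray
    means_log10: np.ndarray
    sds_log10: np.ndarray
    aic: float
    arithmetic_means: np.ndarray = field(default=None)  # type: ignore[assignment]
    arithmetic_sds: np.ndarray = field(default=None)  # type: ignore[assignment]
    component_labels: list[str] = field(default_factory=list)
    aic_by_k: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.arithmetic_means is None:
            moments = [lognormal_moments(m, s) for m, s in zip(self.means_log10, self.sds_log10)]
            self.arithmetic_means = np.array([m for m, _ in moments])
            self.arithmetic_sds = np.array([s for _, s in moments])
        if not self.component_labels:
            self.component_labels = _LABELS.get(self.K, [f"c{i}" for i in range(self.K)])


@dataclass
class GroupSummary:
    n: int
    mean: float
    sd: float
    sem: float


@dataclass
class TestResult:
    t_stat: float
    df: float
    p_value: float
    variance_test_p: float
    variant: str  # "pooled" or "welch"


def fit_log_mixture(
    values: np.ndarray,
    k_min: int = 1,
    k_max: int = 3,
    seed: int = 0,
    n_restarts: int = 10,
    variance_floor: float = 1e-4,
) -> MixtureFit:
    """Fit Gaussian mixtures to log10(values) by EM; pick K by smallest AIC.

    AIC = 2p − 2·loglik with p = 3K − 1 free parameters (K means, K SDs,
    K − 1 weights).  Each K is fitted from ``n_restarts`` initializations;
    ``variance_floor`` (in log10² units) regularizes against component
    collapse.  A K whose EM degenerates entirely is skipped with a warning.
    """
    values = np.asarray(values, dtype=float)
    if np.any(values <= 0) or np.any(~np.isfinite(values)):
        raise ValueError("fit_log_mixture requires finite positive values")
    if len(values) < 10 * k_max:
        raise ValueError(f"need >= {10 * k_max} values for k_max={k_max}")
    logv = np.log10(values).reshape(-1, 1)

    best: GaussianMixture | None = None
    best_aic = np.inf
    best_k = 0
    aic_by_k: dict[int, float] = {}
    for k in range(k_min, k_max + 1):
        try:
            gm = GaussianMixture(
                n_components=k,
                covariance_type="full",
                reg_covar=variance_floor,
                n_init=n_restarts,
                random_state=seed,
            ).fit(logv)
        except ValueError as exc:  # all restarts degenerate
            warnings.warn(f"mixture with K={k} failed to fit ({exc}); skipped")
            continue
        aic = float(gm.aic(logv))  # == 2(3K-1) - 2 loglik for 1-D full covariance
        aic_by_k[k] = aic
        if aic < best_aic:
            best, best_aic, best_k = gm, aic, k
    if best is None:
        raise RuntimeError("no mixture size could be fitted")

    mus = best.means_.ravel()
    sds = np.sqrt(best.covariances_.ravel())
    wts = best.weights_
    order = np.argsort(mus)
    return MixtureFit(
        K=best_k,
        weights=wts[order],
        means_log10=mus[order],
        sds_log10=sds[order],
        aic=best_aic,
        aic_by_k=aic_by_k,
    )


def lognormal_moments(mu_log10: float, sigma_log10: float) -> tuple[float, float]:
    """Arithmetic mean and SD of 10^X with X ~ N(mu_log10, sigma_log10²).

    With a = ln 10: mean = exp(a·µ + a²σ²/2), sd = mean·√(exp(a²σ²) − 1).
    """
    if sigma_log10 < 0:
        raise ValueError("sigma_log10 must be >= 0")
    a = _LN10
    mean = math.exp(a * mu_log10 + (a * sigma_log10) ** 2 / 2.0)
    sd = mean * math.sqrt(math.expm1((a * sigma_log10) ** 2))
    return mean, sd


def summarize_group(values: np.ndarray) -> GroupSummary:
    """Sample mean, SD (n−1 denominator) and SEM = SD/√n."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < 2:
        raise ValueError("summarize_group needs n >= 2")
    sd = float(values.std(ddof=1))
    return GroupSummary(n=n, mean=float(values.mean()), sd=sd, sem=sd / math.sqrt(n))


def compare_groups(a: np.ndarray, b: np.ndarray, alpha: float = 0.05) -> TestResult:
    """F-test-gated unpaired two-sample t-test.

    A two-sided F-test on the variance ratio decides the t-test variant:
    Welch (Satterthwaite df) when the F-test rejects at ``alpha``, pooled
    variance otherwise.  Degenerate zero-variance inputs follow the
    convention p = 1 for identical means and p = 0 otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("compare_groups needs n >= 2 per group")
    va, vb = a.var(ddof=1), b.var(ddof=1)

    if va == 0.0 and vb == 0.0:
        same = math.isclose(a.mean(), b.mean(), rel_tol=0, abs_tol=0)
        p = 1.0 if same else 0.0
        return TestResult(0.0 if same else math.inf, len(a) + len(b) - 2, p, 1.0, "pooled")

    if va == 0.0 or vb == 0.0:
        f_p = 0.0  # maximally unequal variances
    else:
        F = va / vb
        cdf = sps.f.cdf(F, len(a) - 1, len(b) - 1)
        f_p = 2.0 * min(cdf, 1.0 - cdf)

    equal_var = f_p >= alpha
    res = sps.ttest_ind(a, b, equal_var=equal_var)
    return TestResult(
        t_stat=float(res.statistic),
        df=float(res.df),
        p_value=float(res.pvalue),
        variance_test_p=float(f_p),
        variant="pooled" if equal_var else "welch",
    )


def percent_difference(x: float, reference: float, rounded: bool = False) -> float:
    """100·(x − reference)/reference; rounded to integer percent for reports."""
    if reference <= 0:
        raise ValueError("reference must be > 0")
    pct = 100.0 * (x - reference) / reference
    return float(round(pct)) if rounded else pct


def correlate(per_condition_values: np.ndarray, scores: np.ndarray) -> float:
    """Pearson correlation between per-condition values and external scores."""
    x = np.asarray(per_condition_values, dtype=float)
    y = np.asarray(scores, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("correlate needs paired vectors of length >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("correlation undefined for zero-variance input")
    return float(sps.pearsonr(x, y).statistic)


def significance_stars(p: float) -> str:
    """Three-tier convention: *** p<0.001, ** p<0.01, * p<0.05, else ns."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"
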