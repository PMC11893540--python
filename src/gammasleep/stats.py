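"""Hypothesis-testing battery with assumption-gated test selection.

Pairwise condition contrasts use a paired t-test when the pair differences
pass Shapiro-Wilk normality (alpha = .05) and a 3xIQR outlier screen, and a
Wilcoxon signed-rank test otherwise; the stage contrast across the four
analysis stages uses a repeated-measures ANOVA (with Mauchly sphericity as
an additional gate and Tukey post-hocs on the repeated-measures error term)
or a Friedman test with pairwise signed-rank post-hocs, Bonferroni-Holm
corrected.  Effect sizes: Cohen's dz (CI by noncentral-t inversion),
rank-biserial r (normal-approximation CI), classical eta^2 for the rmANOVA
and Kendall's W for Friedman (bootstrap CIs over subjects).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats as sst

__all__ = ["PairedSample", "EffectSize", "TestResult", "check_assumptions",
           "paired_compare", "multilevel_compare", "holm_adjust",
           "power_simulation", "paired_t_power"]

ALPHA = 0.05


@dataclass
class PairedSample:
    """Per-subject value pairs (condition A, condition B)."""

    a: np.ndarray
    b: np.ndarray
    variable: str = ""
    stage: str = ""

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        if self.a.shape != self.b.shape or self.a.ndim != 1:
            raise ValueError("a and b must be equal-length 1-D arrays")
        if self.a.size < 3:
            raise ValueError("need at least 3 pairs")

    @property
    def differences(self) -> np.ndarray:
        return self.b - self.a

    @property
    def n(self) -> int:
        return self.a.size


@dataclass
class EffectSize:
    kind: str          # cohen_dz | rank_biserial_r | eta_squared | kendall_w
    value: float
    ci95: tuple | None = None

    def __post_init__(self) -> None:
        if self.kind == "rank_biserial_r" and not -1 <= self.value <= 1:
            raise ValueError("rank-biserial r must lie in [-1, 1]")
        if self.kind in ("eta_squared", "kendall_w") and \
                not 0 <= self.value <= 1 + 1e-12:
            raise ValueError(f"{self.kind} must lie in [0, 1]")


@dataclass
class TestResult:
    test: str
    statistic: float
    p_raw: float
    p_adjusted: float
    tail: str
    effect: EffectSize | None = None
    posthoc: list | None = None
    assumptions: dict | None = None
    flags: list | None = None

    def __post_init__(self) -> None:
        for p in (self.p_raw, self.p_adjusted):
            if not (0 <= p <= 1 or np.isnan(p)):
                raise ValueError("p-values must lie in [0, 1]")


# ---------------------------------------------------------------------------
# assumptions
# ---------------------------------------------------------------------------

def _iqr_outliers(x: np.ndarray, k: float = 3.0) -> bool:
    q1, q3 = np.percentile(x, [25, 75])
    iqr = q3 - q1
    return bool(np.any((x < q1 - k * iqr) | (x > q3 + k * iqr)))


def check_assumptions(sample: PairedSample, *,
                      multilevel: np.ndarray | None = None) -> dict:
    """Normality (Shapiro-Wilk on differences), 3xIQR outliers, and --
    for >= 3-level designs passed via ``multilevel`` -- Mauchly sphericity.

    Constant differences make Shapiro-Wilk undefined; normality is then
    reported as None (n/a).
    """
    d = sample.differences
    if np.ptp(d) < 1e-12:
        normality = None
    else:
        normality = bool(sst.shapiro(d).pvalue >= ALPHA)
    out = {"normality": normality, "outliers": _iqr_outliers(d),
           "sphericity": None}
    if multilevel is not None:
        out["sphericity"] = _sphericity_ok(np.asarray(multilevel, float))
    return out


def _sphericity_ok(values: np.ndarray) -> bool | None:
    import pandas as pd
    import pingouin as pg
    n, k = values.shape
    if k < 3:
        return None
    long = pd.DataFrame({
        "subject": np.repeat(np.arange(n), k),
        "level": np.tile(np.arange(k), n),
        "value": values.ravel(),
    })
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = pg.sphericity(long, dv="value", within="level",
                                subject="subject")
        return bool(res.pval >= ALPHA)
    except Exception:
        return None


# ---------------------------------------------------------------------------
# effect sizes
# ---------------------------------------------------------------------------

def _dz_ci(dz: float, n: int, conf: float = 0.95) -> tuple:
    """CI for Cohen's dz by inversion of the noncentral-t distribution."""
    t_obs = dz * np.sqrt(n)
    df = n - 1
    lo_q, hi_q = (1 + conf) / 2, (1 - conf) / 2

    def bound(q):
        f = lambda nc: sst.nct.cdf(t_obs, df, nc) - q
        span = 10 * (abs(t_obs) + 2)
        try:
            return optimize.brentq(f, -span, span, xtol=1e-6)
        except ValueError:
            return np.sign(q - 0.5) * -span
    return (bound(lo_q) / np.sqrt(n), bound(hi_q) / np.sqrt(n))


def _rank_biserial(d: np.ndarray) -> tuple[float, tuple]:
    """Matched-pairs rank-biserial correlation with a normal-approx CI."""
    nz = d[d != 0]
    n = nz.size
    if n == 0:
        return 0.0, (0.0, 0.0)
    ranks = sst.rankdata(np.abs(nz))
    w_plus = ranks[nz > 0].sum()
    total = n * (n + 1) / 2.0
    r = 2.0 * w_plus / total - 1.0
    se = np.sqrt(2.0 * (2 * n + 1) / (3.0 * n * (n + 1)))
    lo, hi = r - 1.96 * se, r + 1.96 * se
    return float(r), (float(max(lo, -1.0)), float(min(hi, 1.0)))


# ---------------------------------------------------------------------------
# pairwise comparison
# ---------------------------------------------------------------------------

def paired_compare(sample: PairedSample, tail: str = "two-sided", *,
                   ci: bool = True, force_test: str | None = None
                   ) -> TestResult:
    """Assumption-gated paired comparison of ``b`` against ``a``.

    ``tail='greater'`` tests mean(b - a) > 0.  Gating: paired t-test when
    the differences are normal with no extreme outliers, Wilcoxon
    signed-rank otherwise (``force_test`` in {'t', 'wilcoxon'} overrides).
    ``ci=False`` skips the effect-size confidence interval (cheap mode for
    large Monte-Carlo calibrations).
    """
    if tail not in ("two-sided", "greater", "less"):
        raise ValueError("tail must be two-sided/greater/less")
    d = sample.differences
    n = sample.n
    assumptions = check_assumptions(sample)
    flags = []

    if np.ptp(d) < 1e-12 and abs(d[0]) < 1e-12:
        flags.append("degenerate: all differences zero")
        return TestResult("degenerate", 0.0, 1.0, 1.0, tail,
                          EffectSize("cohen_dz", 0.0, (0.0, 0.0)),
                          assumptions=assumptions, flags=flags)

    use_t = (assumptions["normality"] is True
             and not assumptions["outliers"])
    if force_test is not None:
        use_t = force_test == "t"

    if use_t:
        res = sst.ttest_rel(sample.b, sample.a, alternative=tail)
        sd = d.std(ddof=1)
        dz = float(d.mean() / sd) if sd > 0 else 0.0
        eff = EffectSize("cohen_dz", dz, _dz_ci(dz, n) if ci else None)
        return TestResult("paired_t", float(res.statistic),
                          float(res.pvalue), float(res.pvalue), tail, eff,
                          assumptions=assumptions, flags=flags)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sst.wilcoxon(sample.b, sample.a, alternative=tail,
                           zero_method="wilcox")
    r, r_ci = _rank_biserial(d)
    eff = EffectSize("rank_biserial_r", r, r_ci if ci else None)
    return TestResult("wilcoxon", float(res.statistic), float(res.pvalue),
                      float(res.pvalue), tail, eff,
                      assumptions=assumptions, flags=flags)


# ---------------------------------------------------------------------------
# multilevel comparison
# ---------------------------------------------------------------------------

def _rm_anova(values: np.ndarray) -> tuple[float, float, float, float, int,
                                           int]:
    """One-way repeated-measures ANOVA decomposition.

    Returns (F, p, eta_squared, ms_error, df_effect, df_error) with the
    classical eta^2 = SS_effect / (SS_effect + SS_error).
    """
    n, k = values.shape
    grand = values.mean()
    subj_means = values.mean(axis=1, keepdims=True)
    cond_means = values.mean(axis=0, keepdims=True)
    ss_cond = n * np.sum((cond_means - grand) ** 2)
    resid = values - subj_means - cond_means + grand
    ss_err = np.sum(resid ** 2)
    df_c, df_e = k - 1, (n - 1) * (k - 1)
    ms_c, ms_e = ss_cond / df_c, ss_err / df_e
    if ms_e <= 0:
        return np.inf, 0.0, 1.0, 0.0, df_c, df_e
    F = ms_c / ms_e
    p = float(sst.f.sf(F, df_c, df_e))
    eta2 = float(ss_cond / (ss_cond + ss_err))
    return float(F), p, eta2, float(ms_e), df_c, df_e


def _bootstrap_ci(values: np.ndarray, statistic, n_boot: int = 2000,
                  seed: int = 0) -> tuple:
    rng = np.random.default_rng(seed)
    n = values.shape[0]
    out = np.empty(n_boot)
    for i in range(n_boot):
        out[i] = statistic(values[rng.integers(0, n, n)])
    return (float(np.percentile(out, 2.5)), float(np.percentile(out, 97.5)))


def _kendall_w(values: np.ndarray) -> float:
    n, k = values.shape
    ranks = np.apply_along_axis(sst.rankdata, 1, values)
    col = ranks.sum(axis=0)
    s = np.sum((col - col.mean()) ** 2)
    return float(12.0 * s / (n ** 2 * (k ** 3 - k)))


def multilevel_compare(values: np.ndarray, levels=None, *,
                       posthoc: bool = True, seed: int = 0,
                       force_test: str | None = None) -> TestResult:
    """Stage contrast across >= 3 within-subject levels (complete cases).

    Repeated-measures ANOVA with eta^2 and Tukey post-hocs (studentized
    range on the repeated-measures error term) when normality, outliers and
    sphericity pass; otherwise Friedman with Kendall's W and pairwise
    signed-rank post-hocs.  Post-hoc p-values are Bonferroni-Holm adjusted
    in the Friedman branch; the Tukey procedure controls its family-wise
    rate by construction (which correction applied is recorded in flags).
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[1] < 3:
        raise ValueError("values must be subjects x levels with >= 3 levels")
    if np.isnan(values).any():
        raise ValueError("missing cells: multilevel design needs complete "
                         "cases")
    n, k = values.shape
    levels = list(levels) if levels is not None else list(range(k))
    flags: list[str] = []

    resid = values - values.mean(axis=1, keepdims=True) \
        - values.mean(axis=0, keepdims=True) + values.mean()
    if np.ptp(values - values.mean(axis=1, keepdims=True)) < 1e-12:
        # no within-subject variation at all: nothing to test
        flags.append("degenerate: identical values across levels")
        return TestResult("degenerate", 0.0, 1.0, 1.0, "two-sided",
                          EffectSize("eta_squared", 0.0, (0.0, 0.0)),
                          posthoc=[], flags=flags)

    normality = (bool(sst.shapiro(resid.ravel()).pvalue >= ALPHA)
                 if np.ptp(resid) > 1e-12 else None)
    outliers = _iqr_outliers(resid.ravel())
    sphericity = _sphericity_ok(values)
    assumptions = {"normality": normality, "outliers": outliers,
                   "sphericity": sphericity}
    parametric = normality is True and not outliers and sphericity is not False
    if force_test is not None:
        if force_test not in ("rm_anova", "friedman"):
            raise ValueError("force_test must be 'rm_anova' or 'friedman'")
        parametric = force_test == "rm_anova"

    pairs = [(i, j) for i in range(k) for j in range(i + 1, k)]

    if parametric:
        F, p, eta2, ms_e, df_c, df_e = _rm_anova(values)
        ci = _bootstrap_ci(values, lambda v: _rm_anova(v)[2], seed=seed)
        eff = EffectSize("eta_squared", eta2, ci)
        ph = []
        if posthoc:
            flags.append("posthoc: Tukey on the repeated-measures error term")
            means = values.mean(axis=0)
            se = np.sqrt(ms_e / n)
            for i, j in pairs:
                q = abs(means[i] - means[j]) / se if se > 0 else np.inf
                p_ij = float(sst.studentized_range.sf(q, k, df_e)) \
                    if np.isfinite(q) else 0.0
                ph.append({"a": levels[i], "b": levels[j],
                           "p_adjusted": min(p_ij, 1.0)})
        return TestResult("rm_anova", F, p, p, "two-sided", eff, posthoc=ph,
                          assumptions=assumptions, flags=flags)

    chi2, p = sst.friedmanchisquare(*[values[:, j] for j in range(k)])
    w = _kendall_w(values)
    ci = _bootstrap_ci(values, _kendall_w, seed=seed)
    eff = EffectSize("kendall_w", w, ci)
    ph = []
    if posthoc:
        flags.append("posthoc: pairwise signed-rank, Bonferroni-Holm")
        raw = []
        for i, j in pairs:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                try:
                    pv = float(sst.wilcoxon(values[:, i],
                                            values[:, j]).pvalue)
                except ValueError:   # all differences zero
                    pv = 1.0
            raw.append(pv)
        adj = holm_adjust(raw)
        ph = [{"a": levels[i], "b": levels[j], "p_adjusted": a}
              for (i, j), a in zip(pairs, adj)]
    return TestResult("friedman", float(chi2), float(p), float(p),
                      "two-sided", eff, posthoc=ph,
                      assumptions=assumptions, flags=flags)


# ---------------------------------------------------------------------------
# multiplicity and power
# ---------------------------------------------------------------------------

def holm_adjust(p_values) -> list:
    """Step-down Bonferroni-Holm adjustment (monotone, capped at 1)."""
    p = np.asarray(list(p_values), dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    from statsmodels.stats.multitest import multipletests
    if p.size == 0:
        return []
    _, adj, _, _ = multipletests(p, method="holm")
    return [float(x) for x in adj]


def paired_t_power(effect_d: float, n: int, alpha: float = ALPHA,
                   tail: str = "two-sided") -> float:
    """Closed-form power of the paired t-test via the noncentral t."""
    df = n - 1
    nc = effect_d * np.sqrt(n)
    if tail == "two-sided":
        crit = sst.t.ppf(1 - alpha / 2, df)
        return float(sst.nct.sf(crit, df, nc) + sst.nct.cdf(-crit, df, nc))
    if tail == "greater":
        crit = sst.t.ppf(1 - alpha, df)
        return float(sst.nct.sf(crit, df, nc))
    raise ValueError("tail must be 'two-sided' or 'greater'")


def power_simulation(effect_d: float, alpha: float = ALPHA,
                     n_grid=(10, 20, 30), n_sims: int = 10000,
                     seed: int = 0, tail: str = "two-sided") -> dict:
    """Monte-Carlo power of the paired t comparison across sample sizes.

    Differences are drawn N(effect_d, 1); the t statistic is evaluated
    vectorised over simulations.  Returns {n: power}.  With
    ``effect_d = 0`` this measures the type-I rate (~= alpha).
    """
    if effect_d < 0:
        raise ValueError("effect_d must be >= 0")
    rng = np.random.default_rng(seed)
    out = {}
    for n in n_grid:
        d = rng.standard_normal((n_sims, n)) + effect_d
        t = d.mean(axis=1) / (d.std(axis=1, ddof=1) / np.sqrt(n))
        df = n - 1
        if tail == "two-sided":
            rej = np.abs(t) > sst.t.ppf(1 - alpha / 2, df)
        elif tail == "greater":
            rej = t > sst.t.ppf(1 - alpha, df)
        else:
            raise ValueError("tail must be 'two-sided' or 'greater'")
        out[int(n)] = float(rej.mean())
    return out
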