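"""Case/control burden statistics and shared inferential utilities.

Carrier burden in each stratum is summarized as a 2x2 table (carrier status
x disease status).  Association is tested with the likelihood-ratio (LR)
test of the binomial logistic model with carrier status as the only
predictor; for a 2x2 table this LR statistic equals the classical
G-statistic ``2 * sum O*ln(O/E)`` and is referred to a chi-square with one
degree of freedom.  Confidence intervals for the odds ratio invert the same
LR test (profile likelihood), which reproduces the published intervals
where the Woolf log-OR approximation does not.  Multiplicity across strata
is handled with Benjamini-Hochberg FDR.

``anova_dunnett`` implements the many-to-one (Dunnett) comparison used
throughout the functional assays.  The comparison statistics have the
one-factor correlation structure rho_ij = a_i * a_j with
a_i = sqrt(n_i / (n_i + n_ref)), for balanced *and* unbalanced designs, so
family-wise adjusted p-values are computed exactly by a two-dimensional
quadrature over the common normal factor and the pooled-variance chi
factor — no Monte Carlo is required.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ContingencyTable",
    "AssociationResult",
    "DunnettResult",
    "sample_or",
    "lr_test",
    "profile_ci",
    "fisher_exact_2x2",
    "bh_adjust",
    "carrier_frequency",
    "anova_dunnett",
    "burden_table",
]


@dataclass(frozen=True)
class ContingencyTable:
    """Carrier counts: a/b = carriers/non-carriers in cases, c/d in controls."""

    a: int
    b: int
    c: int
    d: int
    stratum: str = ""

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be nonnegative")

    @classmethod
    def from_counts(
        cls, cases_carriers: int, cases_total: int,
        controls_carriers: int, controls_total: int, stratum: str = "",
    ) -> "ContingencyTable":
        return cls(
            cases_carriers,
            cases_total - cases_carriers,
            controls_carriers,
            controls_total - controls_carriers,
            stratum,
        )

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


@dataclass(frozen=True)
class AssociationResult:
    stratum: str
    or_hat: float  # NaN when not estimable (zero carrier cell)
    ci_low: float
    ci_high: float
    lr_stat: float
    p: float
    p_adj: float = math.nan
    estimable: bool = True
    ci_method: str = "profile"
    level: float = 0.95


def sample_or(t: ContingencyTable) -> float:
    """Sample odds ratio (a*d)/(b*c); NaN when a or c is zero (no
    continuity correction)."""
    if t.a == 0 or t.c == 0:
        return math.nan
    return (t.a * t.d) / (t.b * t.c)


def _xlogy(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    return special.xlogy(x, y)


def lr_test(t: ContingencyTable) -> tuple[float, float]:
    """Likelihood-ratio test of carrier/disease association.

    Equals the G-statistic 2*sum O*ln(O/E) with the 0*ln0 := 0 convention;
    p from the upper tail of chi-square with 1 df.  Empty margins give
    (0.0, 1.0).
    """
    obs = t.as_array()
    n = obs.sum()
    if n == 0 or (obs.sum(axis=1) == 0).any() or (obs.sum(axis=0) == 0).any():
        return 0.0, 1.0
    exp = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / n
    g = 2.0 * (_xlogy(obs, obs).sum() - _xlogy(obs, exp).sum())
    g = max(g, 0.0)
    return float(g), float(sps.chi2.sf(g, df=1))


def _loglik(t: ContingencyTable, beta: float, alpha: float) -> float:
    # logistic model: logit P(case) = alpha + beta * carrier
    lp1, lp0 = alpha + beta, alpha
    # log expit / log(1-expit) via logaddexp for numerical safety
    def l(x):  # (log p, log 1-p)
        return -np.logaddexp(0.0, -x), -np.logaddexp(0.0, x)
    lp1_p, lp1_q = l(lp1)
    lp0_p, lp0_q = l(lp0)
    return t.a * lp1_p + t.c * lp1_q + t.b * lp0_p + t.d * lp0_q


def _profile_loglik(t: ContingencyTable, beta: float) -> float:
    res = optimize.minimize_scalar(
        lambda al: -_loglik(t, beta, al),
        bounds=(-30.0, 10.0), method="bounded",
        options={"xatol": 1e-12},
    )
    return -res.fun


def _saturated_loglik(t: ContingencyTable) -> float:
    out = 0.0
    for k, n in ((t.a, t.a + t.c), (t.b, t.b + t.d)):
        if 0 < k < n:
            out += k * math.log(k / n) + (n - k) * math.log(1 - k / n)
    return out


def profile_ci(t: ContingencyTable, level: float = 0.95) -> tuple[float, float]:
    """Profile-likelihood CI for the odds ratio (inverted LR test).

    With a zero carrier cell the interval degenerates to a one-sided bound:
    (0, upper) when ``a == 0`` and (lower, inf) when ``c == 0``.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    crit = sps.chi2.ppf(level, df=1) / 2.0
    lmax = _saturated_loglik(t)
    f = lambda beta: _profile_loglik(t, beta) - (lmax - crit)

    def _root(lo: float, hi: float) -> float:
        return optimize.brentq(f, lo, hi, xtol=1e-10)

    if t.a == 0 and t.c == 0:
        return 0.0, math.inf
    if t.a == 0:
        hi = 1.0
        while f(hi) > 0:
            hi += 2.0
        return 0.0, math.exp(_root(hi - 2.0 if f(hi - 2.0) > 0 else -30.0, hi))
    if t.c == 0:
        lo = -1.0
        while f(lo) > 0:
            lo -= 2.0
        return math.exp(_root(lo, lo + 2.0 if f(lo + 2.0) > 0 else 30.0)), math.inf

    bhat = math.log(sample_or(t))
    lo = bhat - 1.0
    while f(lo) > 0:
        lo -= 1.0
    hi = bhat + 1.0
    while f(hi) > 0:
        hi += 1.0
    return math.exp(_root(lo, bhat)), math.exp(_root(bhat, hi))


def fisher_exact_2x2(t: ContingencyTable) -> float:
    """Two-sided Fisher exact p (probability-mass rule: sum of tables with
    hypergeometric probability <= that of the observed table)."""
    return float(sps.fisher_exact(t.as_array(), alternative="two-sided")[1])


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def carrier_frequency(k: int, n: int) -> str | None:
    """Format carrier frequency as "1:N", N = n/k rounded to nearest 100.

    Returns None (undefined) when there are no carriers.
    """
    if k == 0:
        return None
    if k < 0 or n < k:
        raise ValueError("need 0 <= k <= n")
    denom = int(round(n / k / 100.0)) * 100
    return f"1:{denom}"


# ---------------------------------------------------------------------------
# Dunnett many-to-one comparisons


@dataclass(frozen=True)
class DunnettResult:
    labels: tuple[str, ...]
    reference: str
    diffs: tuple[float, ...]       # group mean - reference mean
    t_stats: tuple[float, ...]
    p_adjusted: tuple[float, ...]
    df: int
    f_stat: float
    anova_p: float
    alpha: float = 0.05


_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite.hermgauss(80)
_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(96)


def _prob_max_abs_le(c: float, a: np.ndarray, df: float) -> float:
    """P(max_j |T_j| <= c) for many-to-one t statistics with loading
    vector ``a`` (T_j = (a_j Z0 + sqrt(1-a_j^2) Z_j) / S, S^2 ~ chi2_df/df).

    The common-factor integral uses Gauss-Hermite nodes; the chi factor is
    integrated in its quantile domain (Gauss-Legendre on (0,1)), which
    stays accurate for any df including the normal limit.
    """
    if c <= 0:
        return 0.0
    if len(a) == 1:
        # single comparison: plain two-sided t probability, exactly
        if math.isinf(df):
            return float(1.0 - 2.0 * sps.norm.sf(c))
        return float(1.0 - 2.0 * sps.t.sf(c, df))
    z = math.sqrt(2.0) * _GH_NODES      # standard-normal nodes
    w = _GH_WEIGHTS / math.sqrt(math.pi)
    b = np.sqrt(1.0 - a ** 2)

    def inner(s: np.ndarray) -> np.ndarray:
        # s broadcast over leading axis; returns P(all |T_j| <= c | S=s)
        cs = np.atleast_1d(c * s)[:, None, None]
        za = np.outer(z, a)[None, :, :]
        probs = sps.norm.cdf((cs - za) / b) - sps.norm.cdf((-cs - za) / b)
        return np.prod(probs, axis=2) @ w

    if math.isinf(df):
        return float(inner(np.array([1.0]))[0])
    u = 0.5 * (_GL_NODES + 1.0)          # quantiles in (0, 1)
    du = 0.5 * _GL_WEIGHTS
    s = np.sqrt(sps.chi2.ppf(u, df) / df)
    return float(min(inner(s) @ du, 1.0))


def dunnett_critical_value(a: np.ndarray, df: int, alpha: float = 0.05) -> float:
    """Two-sided Dunnett critical value c with P(max|T| >= c) = alpha."""
    f = lambda c: _prob_max_abs_le(c, a, df) - (1.0 - alpha)
    hi = 3.0
    while f(hi) < 0:
        hi *= 1.5
    return optimize.brentq(f, 1e-6, hi, xtol=1e-8)


def anova_dunnett(
    groups: Sequence[tuple[str, Sequence[float]]],
    reference: str,
    alpha: float = 0.05,
) -> DunnettResult:
    """One-way ANOVA plus Dunnett's many-to-one comparison vs a reference.

    Each comparison group's mean is compared with the reference group using
    pooled-variance t statistics; family-wise adjusted p-values come from
    the exact multivariate-t distribution of the maximum absolute
    statistic.  With a single comparison group the adjusted p equals the
    pooled two-sample t-test p.
    """
    labels = [g[0] for g in groups]
    if reference not in labels:
        raise ValueError(f"reference group {reference!r} not among groups")
    data = {lab: np.asarray(vals, dtype=float) for lab, vals in groups}
    for lab, vals in data.items():
        if vals.size < 2:
            raise ValueError(f"group {lab!r} has fewer than 2 replicates")

    ref = data[reference]
    comps = [lab for lab in labels if lab != reference]
    if not comps:
        raise ValueError("need at least one comparison group")

    k_total = len(labels)
    n_tot = sum(v.size for v in data.values())
    df = n_tot - k_total
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in data.values())
    s2 = ss_within / df
    if s2 == 0:
        s2 = np.finfo(float).tiny  # all groups constant -> degenerate

    n0 = ref.size
    ns = np.array([data[lab].size for lab in comps], dtype=float)
    diffs = np.array([data[lab].mean() - ref.mean() for lab in comps])
    se = np.sqrt(s2 * (1.0 / ns + 1.0 / n0))
    t_stats = diffs / se
    a = np.sqrt(ns / (ns + n0))

    p_adj = np.array(
        [1.0 - _prob_max_abs_le(abs(t), a, df) for t in t_stats]
    )
    p_adj = np.clip(p_adj, 0.0, 1.0)

    f_stat, anova_p = sps.f_oneway(*(data[lab] for lab in labels))
    return DunnettResult(
        labels=tuple(comps),
        reference=reference,
        diffs=tuple(diffs),
        t_stats=tuple(t_stats),
        p_adjusted=tuple(p_adj),
        df=df,
        f_stat=float(f_stat),
        anova_p=float(anova_p),
        alpha=alpha,
    )


# ---------------------------------------------------------------------------
# Stratified burden table


def burden_table(
    counts: pd.DataFrame,
    level: float = 0.95,
    ci: str = "profile",
) -> pd.DataFrame:
    """Reproduce the stratified burden table from tidy carrier counts.

    ``counts`` columns: stratum, cases_carriers, cases_total,
    controls_carriers, controls_total.  Output mirrors the published table:
    OR, CI bounds, LR p, and BH-adjusted p across all supplied strata (the
    FDR family is the set of rows given).  Strata with a zero carrier cell
    are reported as not estimable with a one-sided CI bound.
    """
    if ci not in ("profile", "woolf"):
        raise ValueError("ci must be 'profile' or 'woolf'")
    results = []
    for _, row in counts.iterrows():
        t = ContingencyTable.from_counts(
            int(row["cases_carriers"]), int(row["cases_total"]),
            int(row["controls_carriers"]), int(row["controls_total"]),
            str(row["stratum"]),
        )
        orr = sample_or(t)
        lr, p = lr_test(t)
        if ci == "profile":
            lo, hi = profile_ci(t, level)
        else:
            lo, hi = _woolf_ci(t, level)
        results.append(
            AssociationResult(
                stratum=t.stratum, or_hat=orr, ci_low=lo, ci_high=hi,
                lr_stat=lr, p=p, estimable=not math.isnan(orr),
                ci_method=ci, level=level,
            )
        )
    p_adj = bh_adjust([r.p for r in results])
    out = pd.DataFrame(
        {
            "stratum": [r.stratum for r in results],
            "or": [r.or_hat for r in results],
            "ci_low": [r.ci_low for r in results],
            "ci_high": [r.ci_high for r in results],
            "lr_stat": [r.lr_stat for r in results],
            "p": [r.p for r in results],
            "p_adj": p_adj,
            "estimable": [r.estimable for r in results],
        }
    )
    return out


def _woolf_ci(t: ContingencyTable, level: float) -> tuple[float, float]:
    """Woolf log-OR normal-approximation CI (alternative to profile)."""
    if min(t.a, t.b, t.c, t.d) == 0:
        return math.nan, math.nan
    log_or = math.log(sample_or(t))
    se = math.sqrt(1 / t.a + 1 / t.b + 1 / t.c + 1 / t.d)
    z = sps.norm.ppf(0.5 + level / 2.0)
    return math.exp(log_or - z * se), math.exp(log_or + z * se)
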