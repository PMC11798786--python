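"""Two-sample MR estimators and sensitivity analyses.

Implements the Wald ratio, inverse-variance-weighted (fixed and
multiplicative-random-effects), Egger regression with pleiotropy
intercept, weighted median, and simple/weighted mode estimators,
plus Cochran's Q, leave-one-out, and odds-ratio reporting.

All estimators consume a :class:`~mrmediate.sumstats.HarmonizedSet`.
First-order Wald-ratio variances (``se_Gamma^2 / gamma^2``) are the
default weighting everywhere; the second-order form is available on
the Wald ratio itself.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from mrmediate.sumstats import HarmonizedSet

logger = logging.getLogger(__name__)

Z95 = 1.959963984540054  # scipy.stats.norm.ppf(0.975)
MODE_GRID_POINTS = 512


class EstimatorError(ValueError):
    """An estimator's preconditions are not met."""


@dataclass
class MREstimate:
    """A causal-effect estimate on the per-SD (log-OR) scale."""

    method: str
    beta: float
    se: float
    pvalue: float
    ci_low: float
    ci_high: float
    n_snps: int

    @property
    def or_scale(self) -> tuple[float, float, float]:
        """(OR, CI low, CI high) = exp of the beta-scale triple."""
        return (
            float(np.exp(self.beta)),
            float(np.exp(self.ci_low)),
            float(np.exp(self.ci_high)),
        )

    def to_row(self) -> dict:
        or_, lo, hi = self.or_scale
        return {
            "method": self.method,
            "n_snps": self.n_snps,
            "beta": self.beta,
            "se": self.se,
            "pvalue": self.pvalue,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "or": or_,
            "or_ci_low": lo,
            "or_ci_high": hi,
        }


@dataclass
class SensitivityReport:
    """Heterogeneity, pleiotropy-intercept, and influence diagnostics."""

    cochran_q: float
    q_df: int
    q_pvalue: float
    egger_intercept: float
    intercept_se: float
    intercept_pvalue: float
    leave_one_out: pd.DataFrame
    wald_ratios: pd.DataFrame


def _arrays(hset: HarmonizedSet):
    t = hset.table
    return (
        t["gamma"].to_numpy(dtype=float),
        t["se_gamma"].to_numpy(dtype=float),
        t["big_gamma"].to_numpy(dtype=float),
        t["se_big_gamma"].to_numpy(dtype=float),
    )


def _normal_estimate(method: str, beta: float, se: float, k: int) -> MREstimate:
    z = beta / se if se > 0 else np.inf * np.sign(beta)
    p = 2.0 * stats.norm.sf(abs(z))
    return MREstimate(
        method=method,
        beta=float(beta),
        se=float(se),
        pvalue=float(p),
        ci_low=float(beta - Z95 * se),
        ci_high=float(beta + Z95 * se),
        n_snps=k,
    )


def wald_ratio(
    gamma: float,
    se_gamma: float,
    big_gamma: float,
    se_big_gamma: float,
    second_order: bool = False,
) -> MREstimate:
    """Single-instrument ratio estimate ``Gamma / gamma``.

    The default SE is the first-order ``se_Gamma / |gamma|``; with
    ``second_order=True`` the SNP-exposure uncertainty is propagated as
    well.
    """
    if gamma == 0:
        raise EstimatorError("null instrument: gamma = 0")
    beta = big_gamma / gamma
    if second_order:
        se = np.sqrt(
            se_big_gamma**2 / gamma**2
            + big_gamma**2 * se_gamma**2 / gamma**4
        )
    else:
        se = se_big_gamma / abs(gamma)
    return _normal_estimate("wald_ratio", beta, se, 1)


def _ivw_core(g, G, se_G):
    """Fixed-effect IVW beta, fixed SE, Q, and per-SNP weights."""
    w = g**2 / se_G**2
    r = G / g
    beta = np.sum(w * r) / np.sum(w)
    se_fixed = 1.0 / np.sqrt(np.sum(w))
    q = float(np.sum(w * (r - beta) ** 2))
    return float(beta), float(se_fixed), q, w, r


def ivw(
    hset: HarmonizedSet, variance_mode: str = "multiplicative_random"
) -> MREstimate:
    """Inverse-variance-weighted estimate.

    Equivalent to weighted regression of Gamma on gamma through the
    origin with weights ``1/se_Gamma^2``.  The default multiplicative
    random-effects SE inflates the fixed-effect SE by
    ``sqrt(max(1, Q/(k-1)))``; the floor at 1 keeps it no smaller than
    the fixed-effect SE.
    """
    if variance_mode not in ("fixed", "multiplicative_random"):
        raise ValueError(f"unknown variance_mode {variance_mode!r}")
    g, se_g, G, se_G = _arrays(hset)
    k = g.size
    if k == 0:
        raise EstimatorError("empty harmonized set")
    if k == 1:
        logger.info("ivw on a single SNP degrades to the Wald ratio")
        est = wald_ratio(g[0], se_g[0], G[0], se_G[0])
        return MREstimate(**{**est.__dict__, "method": "ivw"})
    beta, se, q, _, _ = _ivw_core(g, G, se_G)
    if variance_mode == "multiplicative_random":
        se *= np.sqrt(max(1.0, q / (k - 1)))
    est = _normal_estimate("ivw", beta, se, k)
    return est


def egger(hset: HarmonizedSet) -> tuple[MREstimate, tuple[float, float, float]]:
    """MR-Egger regression: slope estimate plus intercept triple.

    SNPs are oriented so every gamma is non-negative, then Gamma is
    regressed on gamma with an unconstrained intercept and weights
    ``1/se_Gamma^2``.  SEs carry the multiplicative inflation
    ``sqrt(max(1, RSS_w/(k-2)))`` and p-values use the t distribution
    with ``k-2`` degrees of freedom.

    Returns ``(slope_estimate, (intercept, intercept_se, intercept_p))``.
    """
    g, se_g, G, se_G = _arrays(hset)
    k = g.size
    if k < 3:
        raise EstimatorError("insufficient instruments for Egger (need >= 3)")
    sign = np.where(g < 0, -1.0, 1.0)
    g = g * sign
    G = G * sign
    w = 1.0 / se_G**2

    X = np.column_stack([np.ones(k), g])
    A = X.T @ (w[:, None] * X)
    b = X.T @ (w * G)
    coef = np.linalg.solve(A, b)
    resid = G - X @ coef
    rss_w = float(np.sum(w * resid**2))
    sigma2 = max(1.0, rss_w / (k - 2))
    cov = np.linalg.inv(A) * sigma2
    se_int, se_slope = np.sqrt(np.diag(cov))

    tq = stats.t.ppf(0.975, k - 2)
    slope = float(coef[1])
    p_slope = 2.0 * stats.t.sf(abs(slope / se_slope), k - 2)
    slope_est = MREstimate(
        method="egger",
        beta=slope,
        se=float(se_slope),
        pvalue=float(p_slope),
        ci_low=slope - tq * se_slope,
        ci_high=slope + tq * se_slope,
        n_snps=k,
    )
    intercept = float(coef[0])
    p_int = float(2.0 * stats.t.sf(abs(intercept / se_int), k - 2))
    return slope_est, (intercept, float(se_int), p_int)


def _weighted_median_point(r: np.ndarray, w: np.ndarray) -> float:
    """Interpolated weighted median of ratios r under weights w."""
    order = np.argsort(r, kind="stable")
    r = r[order]
    w = w[order] / np.sum(w)
    s = np.cumsum(w)
    p = s - w / 2.0
    return float(np.interp(0.5, p, r))


def weighted_median(
    hset: HarmonizedSet, n_boot: int = 1000, seed: int | None = None
) -> MREstimate:
    """Weighted-median estimator with parametric-bootstrap SE.

    Weights are normalized inverse first-order Wald variances.  The
    bootstrap resamples (gamma_j, Gamma_j) from their normal sampling
    distributions and recomputes the weighted median; the SE is the
    standard deviation across replicates.
    """
    g, se_g, G, se_G = _arrays(hset)
    k = g.size
    if k < 3:
        raise EstimatorError("weighted median requires >= 3 instruments")
    w = g**2 / se_G**2
    beta = _weighted_median_point(G / g, w)

    rng = np.random.default_rng(seed)
    gs = rng.normal(g, se_g, size=(n_boot, k))
    Gs = rng.normal(G, se_G, size=(n_boot, k))
    boots = np.empty(n_boot)
    for i in range(n_boot):
        wb = gs[i] ** 2 / se_G**2
        boots[i] = _weighted_median_point(Gs[i] / gs[i], wb)
    se = float(np.std(boots, ddof=1))
    return _normal_estimate("weighted_median", beta, se, k)


def _mode_point(r: np.ndarray, w: np.ndarray, bandwidth_factor: float) -> float:
    """Argmax of a normal-kernel weighted density over the ratios."""
    s = np.std(r, ddof=1) if r.size > 1 else 0.0
    iqr = np.subtract(*np.percentile(r, [75, 25]))
    scale = min(s, iqr / 1.349) if iqr > 0 else s
    if scale <= 0:
        return float(r[0])
    h = bandwidth_factor * 0.9 * scale * r.size ** (-1 / 5)
    grid = np.linspace(r.min() - 3 * h, r.max() + 3 * h, MODE_GRID_POINTS)
    dens = np.exp(-0.5 * ((grid[:, None] - r[None, :]) / h) ** 2) @ w
    return float(grid[np.argmax(dens)])


def mode_estimate(
    hset: HarmonizedSet,
    weighted: bool = False,
    bandwidth_factor: float = 1.0,
    n_boot: int = 1000,
    seed: int | None = None,
) -> MREstimate:
    """Simple (uniform-weight) or weighted mode estimator.

    The point estimate is the maximizer of a normal-kernel smoothed
    density over the per-SNP ratio estimates, located on a 512-point
    grid spanning the ratio range plus three bandwidths; the bandwidth
    is ``bandwidth_factor`` times a modified-Silverman scale
    (0.9 * min(sd, IQR/1.349) * k^(-1/5)).  SE by parametric bootstrap.
    """
    g, se_g, G, se_G = _arrays(hset)
    k = g.size
    if k < 3:
        raise EstimatorError("mode estimators require >= 3 instruments")

    def weights(gv):
        if weighted:
            w = gv**2 / se_G**2
        else:
            w = np.ones_like(gv)
        return w / np.sum(w)

    beta = _mode_point(G / g, weights(g), bandwidth_factor)

    rng = np.random.default_rng(seed)
    gs = rng.normal(g, se_g, size=(n_boot, k))
    Gs = rng.normal(G, se_G, size=(n_boot, k))
    boots = np.empty(n_boot)
    for i in range(n_boot):
        boots[i] = _mode_point(Gs[i] / gs[i], weights(gs[i]), bandwidth_factor)
    se = float(np.std(boots, ddof=1))
    method = "weighted_mode" if weighted else "simple_mode"
    return _normal_estimate(method, beta, se, k)


def cochran_q(
    hset: HarmonizedSet, beta_ref: float | MREstimate | None = None
) -> tuple[float, int, float]:
    """Cochran's Q heterogeneity statistic around a reference estimate.

    Q = sum of w_j (r_j - beta_ref)^2 with first-order inverse Wald
    variances as weights; p from chi-square with k-1 df.  When
    ``beta_ref`` is omitted the fixed-effect IVW estimate is used.
    """
    g, _, G, se_G = _arrays(hset)
    k = g.size
    if k < 2:
        raise EstimatorError("Cochran's Q requires >= 2 instruments")
    if beta_ref is None:
        beta_ref = _ivw_core(g, G, se_G)[0]
    elif isinstance(beta_ref, MREstimate):
        beta_ref = beta_ref.beta
    w = g**2 / se_G**2
    r = G / g
    q = float(np.sum(w * (r - beta_ref) ** 2))
    p = float(stats.chi2.sf(q, k - 1))
    return q, k - 1, p


def leave_one_out(
    hset: HarmonizedSet, variance_mode: str = "multiplicative_random"
) -> pd.DataFrame:
    """IVW re-estimated with each SNP removed in turn (k rows)."""
    t = hset.table
    k = len(t)
    if k < 3:
        raise EstimatorError("leave-one-out requires >= 3 instruments")
    rows = []
    for i in range(k):
        rest = HarmonizedSet(
            hset.exposure_trait,
            hset.outcome_trait,
            t.drop(index=i).reset_index(drop=True),
        )
        est = ivw(rest, variance_mode=variance_mode)
        rows.append(
            {
                "snp_id": t["snp_id"].iloc[i],
                "beta": est.beta,
                "se": est.se,
                "pvalue": est.pvalue,
            }
        )
    return pd.DataFrame(rows)


def per_snp_wald_ratios(hset: HarmonizedSet) -> pd.DataFrame:
    """Per-SNP ratio estimates with SEs (forest/funnel plot data)."""
    g, se_g, G, se_G = _arrays(hset)
    return pd.DataFrame(
        {
            "snp_id": hset.table["snp_id"],
            "beta": G / g,
            "se": se_G / np.abs(g),
        }
    )


def sensitivity_report(hset: HarmonizedSet) -> SensitivityReport:
    """Q test, Egger intercept, leave-one-out, and per-SNP ratios."""
    q, df, qp = cochran_q(hset)
    _, (a, se_a, p_a) = egger(hset)
    return SensitivityReport(
        cochran_q=q,
        q_df=df,
        q_pvalue=qp,
        egger_intercept=a,
        intercept_se=se_a,
        intercept_pvalue=p_a,
        leave_one_out=leave_one_out(hset),
        wald_ratios=per_snp_wald_ratios(hset),
    )


def to_odds_ratio(beta: float, se: float) -> tuple[float, float, float]:
    """Exponentiate a log-OR and its 95% CI: (OR, low, high)."""
    if se < 0:
        raise ValueError("se must be non-negative")
    return (
        float(np.exp(beta)),
        float(np.exp(beta - 1.96 * se)),
        float(np.exp(beta + 1.96 * se)),
    )


def all_estimates(
    hset: HarmonizedSet, n_boot: int = 1000, seed: int | None = None
) -> list[MREstimate]:
    """The five-method battery on one harmonized set."""
    seed_seq = np.random.SeedSequence(seed)
    s_med, s_smode, s_wmode = [
        int(s.generate_state(1)[0]) for s in seed_seq.spawn(3)
    ]
    out = [ivw(hset)]
    if len(hset) >= 3:
        out.append(egger(hset)[0])
        out.append(weighted_median(hset, n_boot=n_boot, seed=s_med))
        out.append(
            mode_estimate(hset, weighted=False, n_boot=n_boot, seed=s_smode)
        )
        out.append(
            mode_estimate(hset, weighted=True, n_boot=n_boot, seed=s_wmode)
        )
    return out
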