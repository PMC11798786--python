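"""MR-PRESSO: simulation-based global, outlier, and distortion tests.

The global stage compares the observed weighted residual sum of
squares — residuals taken against leave-one-out IVW slopes — to its
null distribution obtained by parametric simulation from the
per-SNP sampling model.  The outlier stage localizes the signal per
SNP with Bonferroni control, and the distortion stage quantifies how
much removing the flagged SNPs moves the IVW estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from mrmediate.mr import EstimatorError, ivw
from mrmediate.sumstats import HarmonizedSet

DEFAULT_N_SIM = 1000
DEFAULT_ALPHA = 0.05


@dataclass
class DistortionResult:
    applicable: bool
    coefficient: float = float("nan")
    pvalue: float = float("nan")


@dataclass
class PressoReport:
    rss_observed: float
    global_pvalue: float
    outlier_pvalues: pd.DataFrame
    outliers: list[str]
    distortion: DistortionResult
    corrected_ivw: object | None
    n_simulations: int
    seed: int | None
    alpha: float = DEFAULT_ALPHA


def _loo_slopes(g: np.ndarray, G: np.ndarray, se_G: np.ndarray) -> np.ndarray:
    """Fixed-effect IVW slope with each SNP removed, vectorized.

    Works on 1-D arrays or 2-D (n_sim, k) matrices.
    """
    num = g * G / se_G**2
    den = g**2 / se_G**2
    sn = num.sum(axis=-1, keepdims=True)
    sd = den.sum(axis=-1, keepdims=True)
    return (sn - num) / (sd - den)


def _core(hset: HarmonizedSet, n_sim: int, seed):
    t = hset.table
    g = t["gamma"].to_numpy(dtype=float)
    se_g = t["se_gamma"].to_numpy(dtype=float)
    G = t["big_gamma"].to_numpy(dtype=float)
    se_G = t["se_big_gamma"].to_numpy(dtype=float)
    k = g.size
    if k < 4:
        raise EstimatorError("MR-PRESSO requires >= 4 instruments")

    slopes = _loo_slopes(g, G, se_G)
    obs_resid2 = (G - slopes * g) ** 2 / se_G**2
    rss_obs = float(obs_resid2.sum())

    rng = np.random.default_rng(seed)
    g_sim = rng.normal(g, se_g, size=(n_sim, k))
    G_sim = rng.normal(slopes * g, se_G, size=(n_sim, k))
    slopes_sim = _loo_slopes(g_sim, G_sim, se_G)
    sim_resid2 = (G_sim - slopes_sim * g_sim) ** 2 / se_G**2
    rss_sim = sim_resid2.sum(axis=1)

    return t["snp_id"].to_list(), obs_resid2, rss_obs, sim_resid2, rss_sim


def presso_global(
    hset: HarmonizedSet, n_sim: int = DEFAULT_N_SIM, seed=None
) -> tuple[float, float]:
    """Global pleiotropy test: ``(rss_observed, global_pvalue)``.

    The add-one rule ``p = (1 + #{RSS* >= RSS_obs}) / (1 + n_sim)``
    bounds the attainable p away from zero at ``1/(1 + n_sim)``.
    """
    _, _, rss_obs, _, rss_sim = _core(hset, n_sim, seed)
    p = (1.0 + np.sum(rss_sim >= rss_obs)) / (1.0 + n_sim)
    return rss_obs, float(p)


def presso_outlier(
    hset: HarmonizedSet,
    n_sim: int = DEFAULT_N_SIM,
    seed=None,
    alpha: float = DEFAULT_ALPHA,
) -> tuple[pd.DataFrame, list[str]]:
    """Per-SNP outlier p-values and the Bonferroni-flagged outlier list."""
    snp_ids, obs_resid2, _, sim_resid2, _ = _core(hset, n_sim, seed)
    k = len(snp_ids)
    pvals = (1.0 + np.sum(sim_resid2 >= obs_resid2[None, :], axis=0)) / (
        1.0 + n_sim
    )
    table = pd.DataFrame({"snp_id": snp_ids, "pvalue": pvals})
    cutoff = alpha / k
    outliers = table.loc[table["pvalue"] < cutoff, "snp_id"].to_list()
    return table, outliers


def presso_distortion(
    hset: HarmonizedSet,
    outliers: list[str],
    n_draws: int = DEFAULT_N_SIM,
    seed=None,
) -> DistortionResult:
    """Distortion of the IVW estimate caused by the flagged outliers.

    Coefficient = 100 * (beta_without_outliers - beta_all) /
    |beta_without_outliers|.  The p-value compares the observed shift
    against shifts from removing random same-size SNP subsets.
    """
    if not outliers:
        return DistortionResult(applicable=False)
    t = hset.table
    snp_ids = t["snp_id"].to_list()
    out_set = set(outliers)
    keep_mask = ~t["snp_id"].isin(out_set).to_numpy()
    if not keep_mask.any():
        raise EstimatorError("cannot remove every instrument as an outlier")

    g = t["gamma"].to_numpy(dtype=float)
    G = t["big_gamma"].to_numpy(dtype=float)
    se_G = t["se_big_gamma"].to_numpy(dtype=float)

    def _slope(mask):
        w = g[mask] ** 2 / se_G[mask] ** 2
        return float(np.sum(w * (G[mask] / g[mask])) / np.sum(w))

    beta_all = _slope(np.ones(len(t), dtype=bool))
    beta_no = _slope(keep_mask)
    coef = 100.0 * (beta_no - beta_all) / abs(beta_no)
    obs_shift = abs(beta_no - beta_all)

    rng = np.random.default_rng(seed)
    k = len(snp_ids)
    n_out = len(out_set & set(snp_ids))
    shifts = np.empty(n_draws)
    for i in range(n_draws):
        drop = rng.choice(k, size=n_out, replace=False)
        mask = np.ones(k, dtype=bool)
        mask[drop] = False
        shifts[i] = abs(_slope(mask) - beta_all)
    p = (1.0 + np.sum(shifts >= obs_shift)) / (1.0 + n_draws)
    return DistortionResult(applicable=True, coefficient=coef, pvalue=float(p))


def run_presso(
    hset: HarmonizedSet,
    n_sim: int = DEFAULT_N_SIM,
    seed=None,
    alpha: float = DEFAULT_ALPHA,
) -> PressoReport:
    """All three PRESSO stages on one harmonized set."""
    snp_ids, obs_resid2, rss_obs, sim_resid2, rss_sim = _core(
        hset, n_sim, seed
    )
    k = len(snp_ids)
    global_p = float((1.0 + np.sum(rss_sim >= rss_obs)) / (1.0 + n_sim))
    pvals = (1.0 + np.sum(sim_resid2 >= obs_resid2[None, :], axis=0)) / (
        1.0 + n_sim
    )
    table = pd.DataFrame({"snp_id": snp_ids, "pvalue": pvals})
    outliers = table.loc[table["pvalue"] < alpha / k, "snp_id"].to_list()

    distortion = presso_distortion(hset, outliers, n_draws=n_sim, seed=seed)
    corrected = None
    if outliers and len(outliers) < k - 1:
        corrected = ivw(hset.subset(set(snp_ids) - set(outliers)))
    return PressoReport(
        rss_observed=rss_obs,
        global_pvalue=global_p,
        outlier_pvalues=table,
        outliers=outliers,
        distortion=distortion,
        corrected_ivw=corrected,
        n_simulations=n_sim,
        seed=seed,
        alpha=alpha,
    )
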