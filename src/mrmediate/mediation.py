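"""Two-step MR mediation: decomposition, adjusted step-2 estimation,
and the pathway scan.

The indirect (mediation) effect is the product of the
exposure->mediator effect (beta1) and the adjusted mediator->outcome
effect (beta2); the direct effect is the total effect minus the
indirect one.  Confidence intervals use the first-order delta method
with independence between beta1 and beta2 (separate instrument sets
after adjustment).  Reporting rules: the proportion mediated is only
computed when the indirect and total effects agree in sign, and its
CI is suppressed whenever the indirect-effect CI spans zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from mrmediate.instruments import (
    DEFAULT_CLUMP_R2,
    DEFAULT_P_THRESHOLD,
    DEFAULT_WINDOW_KB,
    LDLookup,
    clump,
    select_candidates,
)
from mrmediate.mr import MREstimate, Z95, ivw
from mrmediate.sumstats import HarmonizedSet, harmonize

logger = logging.getLogger(__name__)


class MediationError(ValueError):
    """Mediation step cannot be identified."""


@dataclass
class MediationResult:
    """One exposure -> mediator -> outcome pathway decomposition."""

    exposure: str
    mediator: str
    outcome: str
    beta1: float
    se1: float
    beta2: float
    se2: float
    beta_all: float
    se_all: float
    beta12: float
    se12: float
    ci12: tuple[float, float]
    pvalue12: float
    direct_effect: float
    proportion: float | None
    proportion_ci: tuple[float, float] | None
    ci_spans_zero: bool
    directions_inconsistent: bool
    adjustment_mode: str = "snp_exclusion"

    def to_row(self) -> dict:
        flags = []
        if self.ci_spans_zero:
            flags.append("ci_spans_zero")
        if self.directions_inconsistent:
            flags.append("directions_inconsistent")
        return {
            "exposure": self.exposure,
            "mediator": self.mediator,
            "outcome": self.outcome,
            "beta_all": self.beta_all,
            "direct": self.direct_effect,
            "beta12": self.beta12,
            "ci12_low": self.ci12[0],
            "ci12_high": self.ci12[1],
            "pvalue": self.pvalue12,
            "proportion": self.proportion,
            "prop_ci_low": None
            if self.proportion_ci is None
            else self.proportion_ci[0],
            "prop_ci_high": None
            if self.proportion_ci is None
            else self.proportion_ci[1],
            "flags": ";".join(flags),
            "adjustment_mode": self.adjustment_mode,
        }


def mediation_effect_from_totals(beta_all: float, direct: float) -> float:
    """Indirect effect implied by the identity direct = total - indirect."""
    return beta_all - direct


def mediation_proportion(beta12: float, beta_all: float) -> float:
    """Proportion mediated, percent: 100 * beta12 / beta_all."""
    if beta_all == 0:
        raise MediationError("total effect is zero; proportion undefined")
    return 100.0 * beta12 / beta_all


def decompose(
    beta_all: float,
    se_all: float,
    beta1: float,
    se1: float,
    beta2: float,
    se2: float,
    exposure: str = "exposure",
    mediator: str = "mediator",
    outcome: str = "outcome",
    adjustment_mode: str = "snp_exclusion",
) -> MediationResult:
    """Decompose a total effect into indirect and direct components.

    beta12 = beta1 * beta2 with first-order delta SE
    ``sqrt(beta2^2 se1^2 + beta1^2 se2^2)``; direct = beta_all - beta12.
    The proportion mediated and its delta-method CI follow the
    reporting rules documented in the module docstring.
    """
    for se in (se_all, se1, se2):
        if se < 0:
            raise ValueError("standard errors must be non-negative")
    beta12 = beta1 * beta2
    se12 = float(np.sqrt(beta2**2 * se1**2 + beta1**2 * se2**2))
    ci12 = (beta12 - Z95 * se12, beta12 + Z95 * se12)
    if se12 > 0:
        p12 = float(2.0 * stats.norm.sf(abs(beta12 / se12)))
    else:
        p12 = 1.0 if beta12 == 0 else 0.0
    direct = beta_all - beta12
    ci_spans_zero = ci12[0] <= 0.0 <= ci12[1]

    directions_inconsistent = (
        beta_all == 0 or np.sign(beta12) * np.sign(beta_all) < 0
    )
    proportion = None
    proportion_ci = None
    if not directions_inconsistent:
        proportion = 100.0 * beta12 / beta_all
        if not ci_spans_zero:
            # delta method on the ratio, zero covariance assumed
            rel_var = 0.0
            if beta12 != 0:
                rel_var += se12**2 / beta12**2
            rel_var += se_all**2 / beta_all**2
            se_prop = abs(proportion) * float(np.sqrt(rel_var))
            proportion_ci = (
                proportion - Z95 * se_prop,
                proportion + Z95 * se_prop,
            )
    return MediationResult(
        exposure=exposure,
        mediator=mediator,
        outcome=outcome,
        beta1=beta1,
        se1=se1,
        beta2=beta2,
        se2=se2,
        beta_all=beta_all,
        se_all=se_all,
        beta12=beta12,
        se12=se12,
        ci12=ci12,
        pvalue12=p12,
        direct_effect=direct,
        proportion=proportion,
        proportion_ci=proportion_ci,
        ci_spans_zero=ci_spans_zero,
        directions_inconsistent=directions_inconsistent,
        adjustment_mode=adjustment_mode,
    )


def _instrument_ids(
    stats_table: pd.DataFrame,
    ld: pd.DataFrame | None,
    p_threshold: float,
    r2_max: float,
    window_kb: float,
) -> list[str]:
    cands = select_candidates(stats_table, p_threshold)
    return clump(cands, ld, r2_max=r2_max, window_kb=window_kb)


def adjusted_step2(
    mediator_stats: pd.DataFrame,
    outcome_stats: pd.DataFrame,
    exposure_stats: pd.DataFrame,
    mode: str = "snp_exclusion",
    p_threshold: float = DEFAULT_P_THRESHOLD,
    r2_max: float = DEFAULT_CLUMP_R2,
    window_kb: float = DEFAULT_WINDOW_KB,
    ld: pd.DataFrame | None = None,
) -> tuple[MREstimate, dict]:
    """Mediator -> outcome effect adjusted for the exposure (beta2).

    ``snp_exclusion`` removes mediator instruments that are associated
    with the exposure at the instrument threshold or in LD with an
    exposure instrument, then runs IVW mediator -> outcome.  ``mvmr``
    jointly regresses the outcome effects on the exposure and mediator
    effects over the union instrument set with weights
    ``1/se_Gamma^2`` and reports the mediator coefficient.

    Returns ``(estimate, info)`` where info logs instrument counts
    before and after adjustment.
    """
    if mode not in ("snp_exclusion", "mvmr"):
        raise ValueError(f"unknown adjustment mode {mode!r}")

    med_ids = _instrument_ids(
        mediator_stats, ld, p_threshold, r2_max, window_kb
    )
    info: dict = {"mode": mode, "n_before": len(med_ids)}

    if mode == "snp_exclusion":
        exp_p = exposure_stats.set_index("snp_id")["pvalue"]
        lookup = LDLookup(ld)
        try:
            exp_ids = _instrument_ids(
                exposure_stats, ld, p_threshold, r2_max, window_kb
            )
        except Exception:
            exp_ids = []
        kept = []
        for sid in med_ids:
            if sid in exp_p.index and exp_p[sid] < p_threshold:
                continue
            if any(lookup.r2(sid, e) >= r2_max for e in exp_ids if e != sid):
                continue
            kept.append(sid)
        info["n_after"] = len(kept)
        if len(kept) < 2:
            raise MediationError("underidentified step 2")
        hset = harmonize(
            mediator_stats[mediator_stats["snp_id"].isin(kept)],
            outcome_stats,
            exposure_trait="mediator",
            outcome_trait="outcome",
        )
        return ivw(hset), info

    # multivariable MR over the union instrument set
    exp_ids = _instrument_ids(exposure_stats, ld, p_threshold, r2_max, window_kb)
    union = sorted(set(med_ids) | set(exp_ids))
    info["n_after"] = len(union)
    h_exp = harmonize(
        exposure_stats[exposure_stats["snp_id"].isin(union)],
        outcome_stats,
        exposure_trait="exposure",
        outcome_trait="outcome",
    )
    h_med = harmonize(
        mediator_stats[mediator_stats["snp_id"].isin(union)],
        outcome_stats,
        exposure_trait="mediator",
        outcome_trait="outcome",
    )
    merged = h_exp.table.merge(
        h_med.table, on="snp_id", suffixes=("_exp", "_med")
    )
    k = len(merged)
    if k < 3:
        raise MediationError("underidentified step 2")
    g_exp = merged["gamma_exp"].to_numpy(dtype=float)
    g_med = merged["gamma_med"].to_numpy(dtype=float)
    G = merged["big_gamma_exp"].to_numpy(dtype=float)
    se_G = merged["se_big_gamma_exp"].to_numpy(dtype=float)
    w = 1.0 / se_G**2
    X = np.column_stack([g_exp, g_med])
    A = X.T @ (w[:, None] * X)
    b = X.T @ (w * G)
    coef = np.linalg.solve(A, b)
    resid = G - X @ coef
    sigma2 = max(1.0, float(np.sum(w * resid**2)) / (k - 2))
    cov = np.linalg.inv(A) * sigma2
    beta2 = float(coef[1])
    se2 = float(np.sqrt(cov[1, 1]))
    p2 = float(2.0 * stats.t.sf(abs(beta2 / se2), k - 2))
    info["exposure_coefficient"] = float(coef[0])
    info["exposure_coefficient_se"] = float(np.sqrt(cov[0, 0]))
    est = MREstimate(
        method="mvmr",
        beta=beta2,
        se=se2,
        pvalue=p2,
        ci_low=beta2 - Z95 * se2,
        ci_high=beta2 + Z95 * se2,
        n_snps=k,
    )
    return est, info


@dataclass
class MediationScanConfig:
    """Inputs and thresholds for a full mediation pathway scan."""

    exposures: dict[str, pd.DataFrame]
    mediators: dict[str, pd.DataFrame]
    outcome: pd.DataFrame
    outcome_trait: str = "outcome"
    ld: pd.DataFrame | None = None
    p_threshold: float = DEFAULT_P_THRESHOLD
    r2_max: float = DEFAULT_CLUMP_R2
    window_kb: float = DEFAULT_WINDOW_KB
    exposure_sig: float = 0.05
    mediator_sig: float = 0.01
    step1_sig: float = 0.05
    adjustment_mode: str = "snp_exclusion"


def _simple_mr(
    exposure_stats: pd.DataFrame,
    outcome_stats: pd.DataFrame,
    cfg: MediationScanConfig,
    exposure_trait: str,
    outcome_trait: str,
) -> MREstimate:
    ids = _instrument_ids(
        exposure_stats, cfg.ld, cfg.p_threshold, cfg.r2_max, cfg.window_kb
    )
    hset = harmonize(
        exposure_stats[exposure_stats["snp_id"].isin(ids)],
        outcome_stats,
        exposure_trait=exposure_trait,
        outcome_trait=outcome_trait,
    )
    return ivw(hset)


def mediation_scan(config: MediationScanConfig) -> list[MediationResult]:
    """Scan every (significant exposure, significant mediator) pair.

    An exposure qualifies when its IVW effect on the outcome is
    significant at ``exposure_sig``; a mediator at ``mediator_sig``.
    For each qualifying pair the exposure -> mediator effect must be
    significant at ``step1_sig``; then the adjusted step-2 estimate is
    combined into a full decomposition.  Results are sorted by
    decreasing absolute indirect effect.
    """
    results: list[MediationResult] = []

    total_effects: dict[str, MREstimate] = {}
    for name, stats_table in config.exposures.items():
        try:
            est = _simple_mr(
                stats_table, config.outcome, config, name, config.outcome_trait
            )
        except Exception as exc:  # skip unusable exposures
            logger.warning("exposure %s skipped: %s", name, exc)
            continue
        if est.pvalue < config.exposure_sig:
            total_effects[name] = est

    mediator_hits: dict[str, MREstimate] = {}
    for name, stats_table in config.mediators.items():
        try:
            est = _simple_mr(
                stats_table, config.outcome, config, name, config.outcome_trait
            )
        except Exception as exc:
            logger.warning("mediator %s skipped: %s", name, exc)
            continue
        if est.pvalue < config.mediator_sig:
            mediator_hits[name] = est

    if not total_effects or not mediator_hits:
        logger.warning("mediation scan: no qualifying pathways")
        return []

    for exp_name, total in total_effects.items():
        for med_name in mediator_hits:
            try:
                step1 = _simple_mr(
                    config.exposures[exp_name],
                    config.mediators[med_name],
                    config,
                    exp_name,
                    med_name,
                )
                if step1.pvalue >= config.step1_sig:
                    continue
                step2, _ = adjusted_step2(
                    config.mediators[med_name],
                    config.outcome,
                    config.exposures[exp_name],
                    mode=config.adjustment_mode,
                    p_threshold=config.p_threshold,
                    r2_max=config.r2_max,
                    window_kb=config.window_kb,
                    ld=config.ld,
                )
            except Exception as exc:
                logger.warning(
                    "pathway %s -> %s skipped: %s", exp_name, med_name, exc
                )
                continue
            results.append(
                decompose(
                    total.beta,
                    total.se,
                    step1.beta,
                    step1.se,
                    step2.beta,
                    step2.se,
                    exposure=exp_name,
                    mediator=med_name,
                    outcome=config.outcome_trait,
                    adjustment_mode=config.adjustment_mode,
                )
            )
    results.sort(key=lambda r: -abs(r.beta12))
    return results


def mediation_table(results: list[MediationResult]) -> pd.DataFrame:
    """Table-2-shaped frame, one row per pathway."""
    cols = [
        "exposure",
        "mediator",
        "outcome",
        "beta_all",
        "direct",
        "beta12",
        "ci12_low",
        "ci12_high",
        "pvalue",
        "proportion",
        "prop_ci_low",
        "prop_ci_high",
        "flags",
        "adjustment_mode",
    ]
    if not results:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame([r.to_row() for r in results])[cols]
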