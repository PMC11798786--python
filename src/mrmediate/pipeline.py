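"""Study orchestration: multi-exposure screening, reverse MR, and
report-file generation, driven by a config object (or YAML via the CLI).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from mrmediate import __version__ as _version
from mrmediate.instruments import (
    DEFAULT_CLUMP_R2,
    DEFAULT_F_MIN,
    DEFAULT_P_THRESHOLD,
    DEFAULT_WINDOW_KB,
    GENOME_WIDE_P,
    select_instruments,
    steiger_filter,
)
from mrmediate.mediation import mediation_table
from mrmediate.mr import (
    all_estimates,
    egger,
    cochran_q,
    ivw,
    leave_one_out,
    per_snp_wald_ratios,
)
from mrmediate.presso import run_presso
from mrmediate.sumstats import harmonize

logger = logging.getLogger(__name__)


@dataclass
class ScreenConfig:
    """One screening run: many exposures against one outcome.

    ``exposures`` maps trait name to a validated summary-statistics
    frame; ``exposure_class`` maps trait name to ``lipid`` /
    ``metabolite`` / ``binary`` and controls the instrument p-value
    threshold and the significance gate applied to the IVW estimate.
    """

    exposures: dict[str, pd.DataFrame]
    outcome: pd.DataFrame
    outcome_trait: str = "outcome"
    exposure_class: dict[str, str] = field(default_factory=dict)
    ld: pd.DataFrame | None = None
    p_threshold: dict[str, float] = field(
        default_factory=lambda: {
            "lipid": DEFAULT_P_THRESHOLD,
            "metabolite": DEFAULT_P_THRESHOLD,
            "binary": GENOME_WIDE_P,
        }
    )
    significance: dict[str, float] = field(
        default_factory=lambda: {
            "lipid": 0.05,
            "metabolite": 0.01,
            "binary": 0.05,
        }
    )
    clump_r2: float = DEFAULT_CLUMP_R2
    window_kb: float = DEFAULT_WINDOW_KB
    f_min: float = DEFAULT_F_MIN
    egger_gate: float = 0.05
    apply_steiger: bool = True
    run_presso: bool = True
    presso_n_sim: int = 1000
    n_boot: int = 1000
    seed: int = 0

    def class_of(self, trait: str) -> str:
        return self.exposure_class.get(trait, "lipid")


@dataclass
class ExposureDetail:
    """Everything computed for one exposure during a screen."""

    estimates: list
    sensitivity_q: tuple[float, int, float]
    egger_intercept: tuple[float, float, float]
    leave_one_out: pd.DataFrame
    wald_ratios: pd.DataFrame
    presso: object | None
    instruments: object
    hset: object


_SCREEN_COLUMNS = [
    "exposure",
    "exposure_class",
    "outcome",
    "n_snps",
    "beta",
    "se",
    "pvalue",
    "ci_low",
    "ci_high",
    "or",
    "or_ci_low",
    "or_ci_high",
    "min_f",
    "q_pvalue",
    "egger_intercept_pvalue",
    "presso_global_pvalue",
    "pass_significance",
    "pass_intercept_gate",
    "pass_f_gate",
    "bh_qvalue",
]


def _bh_qvalues(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (logged for transparency)."""
    n = p.size
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.clip(ranked, 0, 1)
    return q


def run_screen(
    config: ScreenConfig,
) -> tuple[pd.DataFrame, dict[str, ExposureDetail]]:
    """Screen every exposure against the outcome.

    Per exposure: instrument selection (threshold, clump, F screen) ->
    harmonization -> optional Steiger filtering -> the five-estimator
    battery -> Q, Egger intercept, PRESSO, leave-one-out -> one summary
    row with pass/fail gate flags.  Exposures that fail instrument
    selection are logged and skipped, never fatal.
    """
    rows = []
    details: dict[str, ExposureDetail] = {}
    if not config.exposures:
        logger.warning("run_screen called with an empty exposure list")
        return pd.DataFrame(columns=_SCREEN_COLUMNS), details

    seed_seq = np.random.SeedSequence(config.seed)
    child_seeds = seed_seq.spawn(len(config.exposures))

    for (trait, stats_table), sseq in zip(
        sorted(config.exposures.items()), child_seeds
    ):
        cls = config.class_of(trait)
        try:
            inst = select_instruments(
                stats_table,
                ld=config.ld,
                p_threshold=config.p_threshold.get(cls, DEFAULT_P_THRESHOLD),
                r2_max=config.clump_r2,
                window_kb=config.window_kb,
                f_min=config.f_min,
                exposure_trait=trait,
            )
            hset = harmonize(
                stats_table[stats_table["snp_id"].isin(inst.snp_ids)],
                config.outcome,
                exposure_trait=trait,
                outcome_trait=config.outcome_trait,
            )
            if config.apply_steiger:
                before = len(hset)
                hset, _ = steiger_filter(hset)
                inst.n_removed_steiger = before - len(hset)
            if len(hset) == 0:
                raise ValueError("no instruments after Steiger filtering")

            s_batt, s_presso = [
                int(s.generate_state(1)[0]) for s in sseq.spawn(2)
            ]
            estimates = all_estimates(hset, n_boot=config.n_boot, seed=s_batt)
            primary = estimates[0]  # IVW
            q = cochran_q(hset) if len(hset) >= 2 else (np.nan, 0, np.nan)
            if len(hset) >= 3:
                _, intercept = egger(hset)
                loo = leave_one_out(hset)
            else:
                intercept = (np.nan, np.nan, np.nan)
                loo = pd.DataFrame(columns=["snp_id", "beta", "se", "pvalue"])
            presso_rep = None
            if config.run_presso and len(hset) >= 4:
                presso_rep = run_presso(
                    hset, n_sim=config.presso_n_sim, seed=s_presso
                )
        except Exception as exc:
            logger.warning("exposure %s skipped: %s", trait, exc)
            continue

        or_, or_lo, or_hi = primary.or_scale
        sig_threshold = config.significance.get(cls, 0.05)
        intercept_p = intercept[2]
        rows.append(
            {
                "exposure": trait,
                "exposure_class": cls,
                "outcome": config.outcome_trait,
                "n_snps": primary.n_snps,
                "beta": primary.beta,
                "se": primary.se,
                "pvalue": primary.pvalue,
                "ci_low": primary.ci_low,
                "ci_high": primary.ci_high,
                "or": or_,
                "or_ci_low": or_lo,
                "or_ci_high": or_hi,
                "min_f": float(np.min(inst.f_stats)),
                "q_pvalue": q[2],
                "egger_intercept_pvalue": intercept_p,
                "presso_global_pvalue": (
                    presso_rep.global_pvalue if presso_rep else np.nan
                ),
                "pass_significance": bool(primary.pvalue < sig_threshold),
                "pass_intercept_gate": bool(
                    np.isnan(intercept_p) or intercept_p > config.egger_gate
                ),
                "pass_f_gate": bool(np.min(inst.f_stats) > config.f_min),
            }
        )
        details[trait] = ExposureDetail(
            estimates=estimates,
            sensitivity_q=q,
            egger_intercept=intercept,
            leave_one_out=loo,
            wald_ratios=per_snp_wald_ratios(hset),
            presso=presso_rep,
            instruments=inst,
            hset=hset,
        )

    table = pd.DataFrame(rows, columns=_SCREEN_COLUMNS[:-1])
    if len(table):
        table["bh_qvalue"] = _bh_qvalues(table["pvalue"].to_numpy())
    else:
        table["bh_qvalue"] = pd.Series(dtype=float)
    return table, details


def reverse_mr(
    config: ScreenConfig, significant_traits: list[str] | None = None
) -> tuple[pd.DataFrame, dict[str, ExposureDetail]]:
    """Role-swapped screen: the outcome becomes the exposure.

    The original outcome trait is instrumented at the genome-wide
    threshold (5e-8) and tested against each previously significant
    exposure, reusing the forward machinery so the output schema is
    identical.
    """
    if significant_traits is None:
        significant_traits = list(config.exposures)
    results = []
    details: dict[str, ExposureDetail] = {}
    for trait in significant_traits:
        sub = ScreenConfig(
            exposures={config.outcome_trait: config.outcome},
            outcome=config.exposures[trait],
            outcome_trait=trait,
            exposure_class={config.outcome_trait: "binary"},
            ld=config.ld,
            p_threshold=config.p_threshold,
            significance=config.significance,
            clump_r2=config.clump_r2,
            window_kb=config.window_kb,
            f_min=config.f_min,
            egger_gate=config.egger_gate,
            apply_steiger=config.apply_steiger,
            run_presso=config.run_presso,
            presso_n_sim=config.presso_n_sim,
            n_boot=config.n_boot,
            seed=config.seed,
        )
        tab, det = run_screen(sub)
        results.append(tab)
        for key, value in det.items():
            details[f"{key}->{trait}"] = value
    if results:
        table = pd.concat(results, ignore_index=True)
    else:
        table = pd.DataFrame(columns=_SCREEN_COLUMNS)
    return table, details


def make_report(
    screen: pd.DataFrame,
    details: dict[str, ExposureDetail],
    outdir,
    config: ScreenConfig | None = None,
    mediation_results=None,
) -> dict[str, Path]:
    """Write the data files behind the standard MR figures.

    Emits volcano-, forest-, funnel-, and leave-one-out data TSVs, a
    full results TSV (all five estimators per exposure), optionally the
    mediation table, and a YAML manifest echoing every threshold and
    seed.  Nothing is recomputed here: every number is copied from the
    screening outputs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    screen.to_csv(outdir / "screen.tsv", sep="\t", index=False)
    paths["screen"] = outdir / "screen.tsv"

    with np.errstate(divide="ignore"):
        volcano = screen[["exposure", "beta", "pvalue"]].copy()
        volcano["minus_log10_p"] = -np.log10(volcano.pop("pvalue"))
    volcano.to_csv(outdir / "volcano.tsv", sep="\t", index=False)
    paths["volcano"] = outdir / "volcano.tsv"

    est_rows, forest_rows, loo_rows = [], [], []
    for trait in sorted(details):
        det = details[trait]
        for est in det.estimates:
            est_rows.append({"exposure": trait, **est.to_row()})
        wr = det.wald_ratios.copy()
        wr.insert(0, "exposure", trait)
        forest_rows.append(wr)
        loo = det.leave_one_out.copy()
        loo.insert(0, "exposure", trait)
        loo_rows.append(loo)
    pd.DataFrame(est_rows).to_csv(
        outdir / "estimates.tsv", sep="\t", index=False
    )
    paths["estimates"] = outdir / "estimates.tsv"
    if forest_rows:
        forest = pd.concat(forest_rows, ignore_index=True)
    else:
        forest = pd.DataFrame(columns=["exposure", "snp_id", "beta", "se"])
    forest.to_csv(outdir / "forest.tsv", sep="\t", index=False)
    paths["forest"] = outdir / "forest.tsv"
    # funnel data = the same per-SNP ratios with precision
    funnel = forest.copy()
    if len(funnel):
        funnel["precision"] = 1.0 / funnel["se"]
    funnel.to_csv(outdir / "funnel.tsv", sep="\t", index=False)
    paths["funnel"] = outdir / "funnel.tsv"
    if loo_rows:
        loo_all = pd.concat(loo_rows, ignore_index=True)
    else:
        loo_all = pd.DataFrame(columns=["exposure", "snp_id", "beta", "se"])
    loo_all.to_csv(outdir / "leave_one_out.tsv", sep="\t", index=False)
    paths["leave_one_out"] = outdir / "leave_one_out.tsv"

    if mediation_results is not None:
        mediation_table(mediation_results).to_csv(
            outdir / "mediation.tsv", sep="\t", index=False
        )
        paths["mediation"] = outdir / "mediation.tsv"

    manifest: dict = {"version": _version}
    if config is not None:
        manifest.update(
            {
                "outcome_trait": config.outcome_trait,
                "exposures": sorted(config.exposures),
                "exposure_class": {
                    t: config.class_of(t) for t in sorted(config.exposures)
                },
                "p_threshold": dict(config.p_threshold),
                "significance": dict(config.significance),
                "clump_r2": config.clump_r2,
                "window_kb": config.window_kb,
                "f_min": config.f_min,
                "egger_gate": config.egger_gate,
                "apply_steiger": config.apply_steiger,
                "run_presso": config.run_presso,
                "presso_n_sim": config.presso_n_sim,
                "n_boot": config.n_boot,
                "seed": config.seed,
            }
        )
    manifest_path = outdir / "manifest.yaml"
    manifest_path.write_text(
        yaml.safe_dump(manifest, sort_keys=True, default_flow_style=False)
    )
    paths["manifest"] = manifest_path
    return paths
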