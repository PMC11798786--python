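"""Synthetic three-trait GWAS summary statistics with known causal structure.

Simulates the exposure -> mediator -> outcome chain directly on the
summary-statistic scale for standardized traits: the per-SNP sampling
standard error is ``1/sqrt(2*maf*(1-maf)*N)`` and observed betas are
drawn around their generative truth.  Optional horizontal pleiotropy
(per-SNP direct outcome effects) and block LD structure (correlated
true effects and correlated estimation noise within blocks) make the
Egger/PRESSO/clumping machinery exercisable without real data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from mrmediate.sumstats import SUMSTAT_COLUMNS, write_sumstats

PLEIOTROPY_MODES = ("none", "balanced", "directional")

#: base-pair gap between independent loci; far larger than any clump window
_LOCUS_SPACING = 20_000_000
#: spacing between SNPs inside one LD block (well inside a 10,000 kb window)
_IN_BLOCK_SPACING = 1_000


@dataclass
class SimulationConfig:
    """Generative parameters for one synthetic three-trait study."""

    n_snps: int = 100
    n_instruments: int = 20
    maf_range: tuple[float, float] = (0.1, 0.5)
    n_exposure: int = 50_000
    n_mediator: int = 50_000
    n_outcome: int = 50_000
    beta1_true: float = 0.0
    beta2_true: float = 0.0
    direct_true: float = 0.0
    gamma_sd: float = 0.05
    # SNPs causal for the mediator independently of the exposure; these
    # make the adjusted step-2 effect identifiable in mediation runs
    n_mediator_instruments: int = 0
    delta_sd: float = 0.05
    pleiotropy_mode: str = "none"
    pleiotropy_sd: float = 0.0
    pleiotropy_frac: float = 1.0
    ld_blocks: list[tuple[int, float]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_instruments > self.n_snps:
            raise ValueError("n_instruments must not exceed n_snps")
        if self.n_instruments + self.n_mediator_instruments > self.n_snps:
            raise ValueError(
                "n_instruments + n_mediator_instruments must not exceed n_snps"
            )
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < low <= high <= 0.5")
        for n in (self.n_exposure, self.n_mediator, self.n_outcome):
            if n < 100:
                raise ValueError("sample sizes must be >= 100")
        if self.pleiotropy_mode not in PLEIOTROPY_MODES:
            raise ValueError(
                f"pleiotropy_mode must be one of {PLEIOTROPY_MODES}"
            )
        if not 0 <= self.pleiotropy_frac <= 1:
            raise ValueError("pleiotropy_frac must be in [0, 1]")
        for size, r in self.ld_blocks:
            if size < 1:
                raise ValueError("LD block size must be >= 1")
            if abs(r) > 1:
                raise ValueError(f"impossible LD specification |r|={abs(r)}>1")
        if sum(s for s, _ in self.ld_blocks) > self.n_snps:
            raise ValueError("LD blocks cover more SNPs than n_snps")


@dataclass
class SyntheticTruth:
    """Generative truth retained for parameter-recovery tests."""

    snp_id: list[str]
    gamma: np.ndarray            # per-SNP true exposure effect
    mediator_effect: np.ndarray  # beta1_true * gamma
    outcome_effect: np.ndarray   # direct_true*gamma + beta2_true*m + alpha
    alpha: np.ndarray            # per-SNP pleiotropic outcome effect
    beta1_true: float
    beta2_true: float
    direct_true: float

    @property
    def total_effect(self) -> float:
        return self.direct_true + self.beta1_true * self.beta2_true

    @property
    def mediation_proportion(self) -> float:
        """True proportion mediated, percent of the total effect."""
        total = self.total_effect
        if total == 0:
            return float("nan")
        return 100.0 * self.beta1_true * self.beta2_true / total


@dataclass
class SimulatedStudy:
    exposure: pd.DataFrame
    mediator: pd.DataFrame
    outcome: pd.DataFrame
    ld: pd.DataFrame
    truth: SyntheticTruth
    config: SimulationConfig


def true_total_effect(truth: SyntheticTruth) -> float:
    """Total exposure->outcome effect: direct plus mediated product."""
    return truth.direct_true + truth.beta1_true * truth.beta2_true


def _block_assignment(config: SimulationConfig) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP block label (-1 = independent) and within-block r."""
    labels = np.full(config.n_snps, -1, dtype=int)
    rs = np.zeros(config.n_snps)
    i = 0
    for b, (size, r) in enumerate(config.ld_blocks):
        labels[i : i + size] = b
        rs[i : i + size] = r
        i += size
    return labels, rs


def _correlated_noise(
    rng: np.random.Generator, labels: np.ndarray, rs: np.ndarray
) -> np.ndarray:
    """Standard-normal noise with equicorrelation r within each block."""
    n = labels.size
    z = rng.standard_normal(n)
    shared = rng.standard_normal(int(labels.max(initial=-1)) + 1 or 0)
    out = z.copy()
    for b in range(int(labels.max(initial=-1)) + 1):
        m = labels == b
        r = rs[m][0]
        out[m] = np.sign(r) * np.sqrt(abs(r)) * shared[b] + np.sqrt(
            1 - abs(r)
        ) * z[m]
    return out


def simulate_study(config: SimulationConfig) -> SimulatedStudy:
    """Draw one complete synthetic study from a single seeded stream.

    True per-SNP exposure effects are ``Normal(0, gamma_sd)`` for the
    first ``n_instruments`` SNPs and zero elsewhere; mediator effects
    are ``beta1_true * gamma``; outcome effects add the direct path,
    the mediated path and the pleiotropy term.  Observed effects are
    the truth plus noise at the analytic standard error, with
    within-block correlation matching the LD target so that clumping
    and duplicated-SNP behavior can be tested.
    """
    rng = np.random.default_rng(config.seed)
    m = config.n_snps
    labels, rs = _block_assignment(config)

    maf = rng.uniform(*config.maf_range, size=m)
    snp_id = [f"rs{i + 1:06d}" for i in range(m)]

    gamma = np.zeros(m)
    causal = np.zeros(m, dtype=bool)
    causal[: config.n_instruments] = True
    raw = config.gamma_sd * _correlated_noise(rng, labels, rs)
    gamma[causal] = raw[causal]
    # perfect LD means literally the same signal
    for b in range(int(labels.max(initial=-1)) + 1):
        blk = labels == b
        if rs[blk][0] == 1.0 and causal[blk].any():
            gamma[blk & causal] = gamma[np.flatnonzero(blk & causal)[0]]
            maf[blk] = maf[np.flatnonzero(blk)[0]]

    delta = np.zeros(m)
    if config.n_mediator_instruments:
        lo = config.n_instruments
        hi = lo + config.n_mediator_instruments
        delta[lo:hi] = rng.normal(0.0, config.delta_sd, config.n_mediator_instruments)

    mediator_effect = config.beta1_true * gamma + delta

    if config.pleiotropy_mode == "none" or config.pleiotropy_sd == 0:
        alpha = np.zeros(m)
    else:
        draws = rng.normal(0.0, config.pleiotropy_sd, size=m)
        if config.pleiotropy_mode == "directional":
            # directional relative to each instrument's exposure-increasing
            # allele, the orientation every ratio estimator works in;
            # a sign-free |draw| would cancel against symmetric gamma
            draws = np.abs(draws) * np.where(gamma < 0, -1.0, 1.0)
        alpha = np.zeros(m)
        n_pleio = int(round(config.pleiotropy_frac * config.n_instruments))
        alpha[:n_pleio] = draws[:n_pleio]

    outcome_effect = (
        config.direct_true * gamma
        + config.beta2_true * mediator_effect
        + alpha
    )

    truth = SyntheticTruth(
        snp_id=snp_id,
        gamma=gamma,
        mediator_effect=mediator_effect,
        outcome_effect=outcome_effect,
        alpha=alpha,
        beta1_true=config.beta1_true,
        beta2_true=config.beta2_true,
        direct_true=config.direct_true,
    )

    chrom = np.where(labels >= 0, 1 + labels % 22, 1 + np.arange(m) % 22)
    pos = np.empty(m, dtype=np.int64)
    locus = 0
    for j in range(m):
        if labels[j] >= 0 and j > 0 and labels[j] == labels[j - 1]:
            pos[j] = pos[j - 1] + _IN_BLOCK_SPACING
        else:
            locus += 1
            pos[j] = locus * _LOCUS_SPACING

    def _trait(true_beta: np.ndarray, n: int) -> pd.DataFrame:
        se = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n)
        beta = true_beta + se * _correlated_noise(rng, labels, rs)
        pvalue = 2.0 * stats.norm.sf(np.abs(beta / se))
        return pd.DataFrame(
            {
                "snp_id": snp_id,
                "chrom": chrom.astype(str),
                "pos": pos,
                "effect_allele": "A",
                "other_allele": "G",
                "eaf": maf,
                "beta": beta,
                "se": se,
                "pvalue": np.clip(pvalue, np.finfo(float).tiny, 1.0),
                "n": n,
            }
        )[SUMSTAT_COLUMNS]

    exposure = _trait(gamma, config.n_exposure)
    mediator = _trait(mediator_effect, config.n_mediator)
    outcome = _trait(outcome_effect, config.n_outcome)

    r2 = np.eye(m)
    for b in range(int(labels.max(initial=-1)) + 1):
        idx = np.flatnonzero(labels == b)
        r = rs[idx[0]]
        for a in idx:
            for c in idx:
                if a != c:
                    r2[a, c] = r * r
    ld = pd.DataFrame(r2, index=snp_id, columns=snp_id)

    return SimulatedStudy(exposure, mediator, outcome, ld, truth, config)


def write_study(study: SimulatedStudy, outdir) -> dict[str, Path]:
    """Write the study as TSVs plus a JSON truth file; return the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name in ("exposure", "mediator", "outcome"):
        p = outdir / f"{name}.tsv"
        write_sumstats(getattr(study, name), p)
        paths[name] = p
    ld_path = outdir / "ld.tsv"
    study.ld.to_csv(ld_path, sep="\t", index_label="snp_id")
    paths["ld"] = ld_path
    truth_path = outdir / "truth.json"
    t = study.truth
    payload = {
        "snp_id": t.snp_id,
        "gamma": t.gamma.tolist(),
        "mediator_effect": t.mediator_effect.tolist(),
        "outcome_effect": t.outcome_effect.tolist(),
        "alpha": t.alpha.tolist(),
        "beta1_true": t.beta1_true,
        "beta2_true": t.beta2_true,
        "direct_true": t.direct_true,
        "total_effect": t.total_effect,
        "mediation_proportion": t.mediation_proportion,
        "config": asdict(study.config),
    }
    truth_path.write_text(json.dumps(payload, indent=1))
    paths["truth"] = truth_path
    return paths
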