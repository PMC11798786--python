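"""Instrument selection: p-value thresholding, greedy LD clumping,
variance explained, F-statistic screening, and Steiger direction filtering."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from mrmediate.sumstats import HarmonizedSet

logger = logging.getLogger(__name__)

DEFAULT_P_THRESHOLD = 1e-5
GENOME_WIDE_P = 5e-8
DEFAULT_CLUMP_R2 = 0.001
DEFAULT_WINDOW_KB = 10_000
DEFAULT_F_MIN = 10.0


class InstrumentSelectionError(ValueError):
    """No instruments survive a selection stage."""


@dataclass
class InstrumentSet:
    """Retained instruments for one exposure, with audit trail."""

    exposure_trait: str
    snp_ids: list[str]
    r2: np.ndarray = field(default_factory=lambda: np.array([]))
    f_stats: np.ndarray = field(default_factory=lambda: np.array([]))
    n_candidates: int = 0
    n_removed_clump: int = 0
    n_removed_f: int = 0
    n_removed_steiger: int = 0

    @property
    def total_r2(self) -> float:
        return float(np.sum(self.r2))

    @property
    def overall_f(self) -> float:
        """Aggregate F from the summed variance explained."""
        n = getattr(self, "_n_ref", None)
        if n is None or not len(self.r2):
            return float("nan")
        return f_statistic(n, min(self.total_r2, 1 - 1e-12))

    def audit_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"snp_id": self.snp_ids, "r2": self.r2, "F": self.f_stats}
        )


def select_candidates(
    stats_table: pd.DataFrame, p_threshold: float = DEFAULT_P_THRESHOLD
) -> pd.DataFrame:
    """Return rows with ``pvalue < p_threshold`` sorted by ascending p.

    Ties are broken lexicographically on ``snp_id`` so downstream
    clumping is order-independent.
    """
    hits = stats_table[stats_table["pvalue"] < p_threshold]
    if hits.empty:
        raise InstrumentSelectionError(
            f"no instruments at threshold {p_threshold:g}"
        )
    return hits.sort_values(["pvalue", "snp_id"], kind="mergesort").reset_index(
        drop=True
    )


class LDLookup:
    """Pairwise r-squared lookup backed by a square matrix (or nothing).

    Missing pairs are treated as r^2 = 0 and counted, matching the
    behavior required when a supplied LD matrix does not cover every
    candidate pair.
    """

    def __init__(self, matrix: pd.DataFrame | None = None):
        self._index: dict[str, int] = {}
        self._values: np.ndarray | None = None
        if matrix is not None:
            self._index = {s: i for i, s in enumerate(matrix.index)}
            self._values = matrix.to_numpy(dtype=float)
        self.n_missing = 0

    def r2(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        ia = self._index.get(a)
        ib = self._index.get(b)
        if self._values is None or ia is None or ib is None:
            self.n_missing += 1
            return 0.0
        return float(self._values[ia, ib])


def clump(
    candidates: pd.DataFrame,
    ld: pd.DataFrame | LDLookup | None,
    r2_max: float = DEFAULT_CLUMP_R2,
    window_kb: float = DEFAULT_WINDOW_KB,
) -> list[str]:
    """Greedy LD clumping.

    Repeatedly take the lowest-p unclaimed SNP, retain it, and discard
    all unclaimed SNPs on the same chromosome within ``window_kb``
    whose r^2 with it is >= ``r2_max``.  Equal p-values are broken
    lexicographically on ``snp_id``, making the result invariant to
    input row order.
    """
    lookup = ld if isinstance(ld, LDLookup) else LDLookup(ld)
    order = candidates.sort_values(
        ["pvalue", "snp_id"], kind="mergesort"
    ).reset_index(drop=True)
    window_bp = window_kb * 1_000
    claimed: set[str] = set()
    retained: list[str] = []
    rows = list(
        order[["snp_id", "chrom", "pos"]].itertuples(index=False, name=None)
    )
    for i, (sid, chrom, pos) in enumerate(rows):
        if sid in claimed:
            continue
        retained.append(sid)
        claimed.add(sid)
        for other_sid, other_chrom, other_pos in rows[i + 1 :]:
            if other_sid in claimed:
                continue
            if other_chrom != chrom or abs(other_pos - pos) > window_bp:
                continue
            if lookup.r2(sid, other_sid) >= r2_max:
                claimed.add(other_sid)
    if lookup.n_missing:
        logger.info(
            "clump: %d candidate pair(s) absent from LD matrix, treated "
            "as r2=0",
            lookup.n_missing,
        )
    return retained


def snp_r2(beta, se, n):
    """Variance in the trait explained by one SNP: t^2/(t^2 + n - 2).

    Uses only the effect estimate, its SE and the sample size, which is
    the information available in every summary-statistics source here.
    Vectorized over inputs.
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any(se <= 0):
        raise ValueError("se must be positive")
    if np.any(n <= 2):
        raise ValueError("n must exceed 2")
    t2 = (beta / se) ** 2
    out = t2 / (t2 + n - 2.0)
    return out if out.ndim else float(out)


def snp_r2_eaf(beta, eaf):
    """EAF-based alternative for standardized traits: 2*maf*(1-maf)*beta^2."""
    beta = np.asarray(beta, dtype=float)
    eaf = np.asarray(eaf, dtype=float)
    out = 2.0 * eaf * (1.0 - eaf) * beta**2
    return out if out.ndim else float(out)


def f_statistic(n, r2):
    """Instrument-strength F = (N - 2) * R^2 / (1 - R^2)."""
    n = np.asarray(n, dtype=float)
    r2 = np.asarray(r2, dtype=float)
    if np.any(r2 >= 1) or np.any(r2 < 0):
        raise ValueError("r2 must lie in [0, 1)")
    if np.any(n <= 2):
        raise ValueError("n must exceed 2")
    out = (n - 2.0) * r2 / (1.0 - r2)
    return out if out.ndim else float(out)


def steiger_filter(
    hset: HarmonizedSet,
) -> tuple[HarmonizedSet, pd.DataFrame]:
    """Drop SNPs explaining more outcome than exposure variance.

    Returns the filtered set plus a per-SNP verdict table carrying the
    two variance-explained estimates, the forward/reverse call, and a
    two-sided z-test on the difference of Fisher-transformed
    correlations (reported for audit; not used for dropping).
    """
    t = hset.table
    r2_x = snp_r2(t["gamma"], t["se_gamma"], t["n_exposure"])
    r2_y = snp_r2(t["big_gamma"], t["se_big_gamma"], t["n_outcome"])
    forward = r2_x >= r2_y

    rx = np.sqrt(np.clip(r2_x, 0, 1 - 1e-15))
    ry = np.sqrt(np.clip(r2_y, 0, 1 - 1e-15))
    denom = np.sqrt(
        1.0 / (t["n_exposure"].to_numpy() - 3)
        + 1.0 / (t["n_outcome"].to_numpy() - 3)
    )
    z = (np.arctanh(rx) - np.arctanh(ry)) / denom
    pz = 2.0 * stats.norm.sf(np.abs(z))

    verdicts = pd.DataFrame(
        {
            "snp_id": t["snp_id"],
            "r2_exposure": r2_x,
            "r2_outcome": r2_y,
            "direction": np.where(forward, "forward", "reverse"),
            "z": z,
            "z_pvalue": pz,
        }
    )
    filtered = replace(
        hset, table=t.loc[np.asarray(forward)].reset_index(drop=True)
    )
    return filtered, verdicts


def select_instruments(
    stats_table: pd.DataFrame,
    ld: pd.DataFrame | None = None,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    r2_max: float = DEFAULT_CLUMP_R2,
    window_kb: float = DEFAULT_WINDOW_KB,
    f_min: float = DEFAULT_F_MIN,
    exposure_trait: str = "exposure",
) -> InstrumentSet:
    """Threshold, clump, and F-screen a summary-statistics table."""
    candidates = select_candidates(stats_table, p_threshold)
    retained = clump(candidates, ld, r2_max=r2_max, window_kb=window_kb)
    n_clumped = len(candidates) - len(retained)

    sub = candidates.set_index("snp_id").loc[retained]
    r2 = np.asarray(snp_r2(sub["beta"], sub["se"], sub["n"]))
    f = np.asarray(f_statistic(sub["n"], r2))
    strong = f > f_min
    n_weak = int((~strong).sum())
    if not strong.any():
        raise InstrumentSelectionError("no instruments pass the F screen")

    result = InstrumentSet(
        exposure_trait=exposure_trait,
        snp_ids=list(np.asarray(retained)[strong]),
        r2=r2[strong],
        f_stats=f[strong],
        n_candidates=len(candidates),
        n_removed_clump=n_clumped,
        n_removed_f=n_weak,
    )
    result._n_ref = int(sub["n"].iloc[0])
    return result
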