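"""GWAS summary-statistics I/O, validation, and allele harmonization.

The on-disk dialect is a UTF-8 TSV with the header
``snp_id chrom pos effect_allele other_allele eaf beta se pvalue n``
(CSV is accepted on read via delimiter sniffing).  Floats are written
with 6 significant digits so a write/read/write cycle is byte-stable.

Harmonization aligns SNP-outcome effects to the exposure's effect
allele: swapped alleles flip the sign of the outcome beta, strand
complements are resolved by complementing before comparison, and
palindromic (A/T, C/G) variants are kept only when both allele
frequencies are far enough from 0.5 to orient them.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

SUMSTAT_COLUMNS = [
    "snp_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pvalue",
    "n",
]

VALID_ALLELES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: relative tolerance for the p-value vs beta/se consistency warning
PVALUE_CONSISTENCY_RTOL = 0.10


class SumstatsError(ValueError):
    """Fatal problem with a summary-statistics table."""


class HarmonizationError(ValueError):
    """No usable instruments survive harmonization."""


def _complement(alleles: pd.Series) -> pd.Series:
    return alleles.map(_COMPLEMENT)


def _is_palindromic(ea: pd.Series, oa: pd.Series) -> pd.Series:
    return oa == ea.map(_COMPLEMENT)


# ---------------------------------------------------------------------------
# Validation


def validate_sumstats(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Enforce per-record invariants, dropping and logging offending rows.

    Returns ``(clean, drop_log)`` where ``drop_log`` has columns
    ``snp_id`` and ``reason``.  Rows violating any hard invariant
    (non-ACGT or identical alleles, nonpositive SE, EAF outside (0,1),
    p-value outside (0,1], nonpositive N, nonfinite beta) are removed.
    A p-value inconsistent with ``beta/se`` under a two-sided normal
    test (beyond 10% relative tolerance) only triggers a warning.
    """
    df = df.copy()
    df["snp_id"] = df["snp_id"].astype(str)
    df["chrom"] = df["chrom"].astype(str)
    for col in ("effect_allele", "other_allele"):
        df[col] = df[col].astype(str).str.upper()
    for col in ("eaf", "beta", "se", "pvalue"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df["pos"] = pd.to_numeric(df["pos"], errors="coerce")
    df["n"] = pd.to_numeric(df["n"], errors="coerce")

    reasons = pd.Series("", index=df.index, dtype=object)

    def _flag(mask: pd.Series, reason: str) -> None:
        fresh = mask & (reasons == "")
        reasons[fresh] = reason

    valid_allele = df["effect_allele"].isin(VALID_ALLELES) & df[
        "other_allele"
    ].isin(VALID_ALLELES)
    _flag(~valid_allele, "non-SNP or invalid allele")
    _flag(df["effect_allele"] == df["other_allele"], "identical alleles")
    _flag(~(df["se"] > 0), "nonpositive SE")
    _flag(~df["eaf"].between(0, 1, inclusive="neither"), "EAF outside (0,1)")
    _flag(~np.isfinite(df["beta"]), "nonfinite beta")
    _flag(~((df["pvalue"] > 0) & (df["pvalue"] <= 1)), "pvalue outside (0,1]")
    _flag(~(df["n"] > 0), "nonpositive N")
    _flag(~(df["pos"] >= 1), "invalid position")
    _flag(df["snp_id"].duplicated(keep="first"), "duplicated snp_id")

    bad = reasons != ""
    drop_log = pd.DataFrame(
        {"snp_id": df.loc[bad, "snp_id"], "reason": reasons[bad]}
    ).reset_index(drop=True)
    clean = df.loc[~bad].reset_index(drop=True)
    clean["pos"] = clean["pos"].astype(np.int64)
    clean["n"] = clean["n"].astype(np.int64)

    if len(clean):
        expected = 2.0 * stats.norm.sf(np.abs(clean["beta"] / clean["se"]))
        with np.errstate(divide="ignore", invalid="ignore"):
            rel = np.abs(clean["pvalue"] - expected) / np.maximum(
                expected, np.finfo(float).tiny
            )
        # rounded p-values are routine in real files -> warn, do not drop
        inconsistent = (rel > PVALUE_CONSISTENCY_RTOL) & (expected > 1e-300)
        n_bad = int(inconsistent.sum())
        if n_bad:
            warnings.warn(
                f"{n_bad} record(s) have p-values inconsistent with beta/se "
                f"beyond {PVALUE_CONSISTENCY_RTOL:.0%} relative tolerance",
                UserWarning,
                stacklevel=2,
            )
    if len(drop_log):
        logger.info("validate_sumstats dropped %d record(s)", len(drop_log))
    return clean, drop_log


def read_sumstats(
    path, column_map: dict[str, str] | None = None
) -> pd.DataFrame:
    """Read a delimited summary-statistics table and validate it.

    Parameters
    ----------
    path : path-like
        Tab- or comma-delimited file with a header row.
    column_map : dict, optional
        Mapping from names found in the file to the canonical column
        names in :data:`SUMSTAT_COLUMNS`.

    Returns
    -------
    pandas.DataFrame
        Validated records; the drop log is attached as
        ``df.attrs["drop_log"]``.
    """
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    if not header.strip():
        raise SumstatsError(f"empty summary-statistics file: {path}")
    sep = "\t" if "\t" in header else ","
    raw = pd.read_csv(path, sep=sep, dtype={"chrom": str})
    if column_map:
        raw = raw.rename(columns=column_map)
    missing = [c for c in SUMSTAT_COLUMNS if c not in raw.columns]
    if missing:
        raise SumstatsError(
            f"missing mandatory column(s) {missing} in {path}"
        )
    if raw.empty:
        raise SumstatsError(f"no records in summary-statistics file: {path}")
    clean, drop_log = validate_sumstats(raw[SUMSTAT_COLUMNS])
    clean.attrs["drop_log"] = drop_log
    return clean


def _format_float(x: float) -> str:
    return f"{x:.6g}"


def write_sumstats(records: pd.DataFrame, path) -> None:
    """Write records in the canonical TSV dialect (6 significant digits)."""
    out = records.copy()
    for col in ("eaf", "beta", "se", "pvalue"):
        out[col] = out[col].map(_format_float)
    out = out[SUMSTAT_COLUMNS]
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Harmonization


@dataclass
class HarmonizedSet:
    """Per-SNP exposure/outcome effects aligned to a common effect allele.

    ``table`` has one row per retained SNP with columns ``snp_id``,
    ``gamma``, ``se_gamma``, ``gamma_pvalue`` (SNP-exposure),
    ``big_gamma``, ``se_big_gamma`` (SNP-outcome), ``eaf`` (exposure
    effect-allele frequency), ``n_exposure`` and ``n_outcome``.
    ``log`` records one action per input SNP (kept / sign_flipped /
    strand_flipped / dropped...).
    """

    exposure_trait: str
    outcome_trait: str
    table: pd.DataFrame
    log: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["snp_id", "action", "reason"]
        )
    )

    @property
    def n_snps(self) -> int:
        return len(self.table)

    def __len__(self) -> int:
        return len(self.table)

    def subset(self, snp_ids) -> "HarmonizedSet":
        """Restrict to the given SNP identifiers (order preserved)."""
        keep = self.table["snp_id"].isin(set(snp_ids))
        return replace(self, table=self.table.loc[keep].reset_index(drop=True))

    @classmethod
    def from_arrays(
        cls,
        gamma,
        se_gamma,
        big_gamma,
        se_big_gamma,
        snp_id=None,
        eaf=None,
        n_exposure=10_000,
        n_outcome=10_000,
        exposure_trait="exposure",
        outcome_trait="outcome",
    ) -> "HarmonizedSet":
        """Build a set directly from effect arrays (already aligned)."""
        gamma = np.asarray(gamma, dtype=float)
        k = gamma.size
        se_gamma = np.broadcast_to(np.asarray(se_gamma, float), (k,))
        big_gamma = np.asarray(big_gamma, dtype=float)
        se_big_gamma = np.broadcast_to(np.asarray(se_big_gamma, float), (k,))
        if snp_id is None:
            snp_id = [f"snp{i}" for i in range(k)]
        table = pd.DataFrame(
            {
                "snp_id": snp_id,
                "gamma": gamma,
                "se_gamma": se_gamma,
                "gamma_pvalue": 2.0
                * stats.norm.sf(np.abs(gamma / se_gamma)),
                "big_gamma": big_gamma,
                "se_big_gamma": se_big_gamma,
                "eaf": 0.5 if eaf is None else eaf,
                "n_exposure": n_exposure,
                "n_outcome": n_outcome,
            }
        )
        return cls(exposure_trait, outcome_trait, table)


def harmonize(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    palindrome_eaf_window: float = 0.08,
    exposure_trait: str = "exposure",
    outcome_trait: str = "outcome",
) -> HarmonizedSet:
    """Align outcome effects to the exposure's effect alleles.

    Rules, applied per SNP shared between the tables (join on
    ``snp_id``):

    * same alleles -> kept as-is;
    * swapped alleles -> outcome beta negated, outcome EAF mirrored;
    * strand-complement alleles -> complemented before comparison
      (possibly combined with a swap/sign flip);
    * palindromic SNPs (A/T or C/G) are oriented by EAF and dropped as
      ambiguous when either EAF lies within ``palindrome_eaf_window``
      of 0.5;
    * anything else -> dropped as an allele mismatch.

    Raises
    ------
    HarmonizationError
        If no SNP survives.
    """
    if not 0 <= palindrome_eaf_window < 0.5:
        raise ValueError("palindrome_eaf_window must be in [0, 0.5)")

    exp = exposure.set_index("snp_id")
    out = outcome.set_index("snp_id")
    if exp.index.has_duplicates or out.index.has_duplicates:
        raise SumstatsError("duplicated snp_id in harmonization input")

    shared = exp.index.intersection(out.index)
    log_rows: list[tuple[str, str, str]] = []
    for sid in exp.index.difference(out.index):
        log_rows.append((sid, "dropped", "absent from outcome"))
    for sid in out.index.difference(exp.index):
        log_rows.append((sid, "dropped", "absent from exposure"))

    e = exp.loc[shared]
    o = out.loc[shared]

    eea, eoa = e["effect_allele"], e["other_allele"]
    oea, ooa = o["effect_allele"], o["other_allele"]
    c_oea, c_ooa = _complement(oea), _complement(ooa)

    palindromic = _is_palindromic(eea, eoa)

    same = (oea == eea) & (ooa == eoa)
    swapped = (oea == eoa) & (ooa == eea)
    strand_same = (c_oea == eea) & (c_ooa == eoa)
    strand_swapped = (c_oea == eoa) & (c_ooa == eea)

    action = pd.Series("dropped", index=shared, dtype=object)
    reason = pd.Series("allele mismatch", index=shared, dtype=object)
    flip = pd.Series(False, index=shared)

    np_mask = ~palindromic
    action[np_mask & same] = "kept"
    action[np_mask & swapped] = "sign_flipped"
    flip[np_mask & swapped] = True
    action[np_mask & strand_same] = "strand_flipped"
    action[np_mask & strand_swapped] = "strand_and_sign_flipped"
    flip[np_mask & strand_swapped] = True

    # palindromic: alleles cannot resolve strand; orient by EAF
    pal_match = palindromic & (same | swapped | strand_same | strand_swapped)
    w = palindrome_eaf_window
    ambiguous = pal_match & (
        ((e["eaf"] - 0.5).abs() <= w) | ((o["eaf"] - 0.5).abs() <= w)
    )
    action[ambiguous] = "dropped"
    reason[ambiguous] = "ambiguous palindromic"
    pal_ok = pal_match & ~ambiguous
    concordant = (e["eaf"] < 0.5) == (o["eaf"] < 0.5)
    action[pal_ok & concordant] = "kept"
    action[pal_ok & ~concordant] = "sign_flipped"
    flip[pal_ok & ~concordant] = True

    kept = action != "dropped"
    reason[kept] = ""

    sign = np.where(flip[kept], -1.0, 1.0)
    table = pd.DataFrame(
        {
            "snp_id": shared[kept.to_numpy()],
            "gamma": e.loc[kept, "beta"].to_numpy(),
            "se_gamma": e.loc[kept, "se"].to_numpy(),
            "gamma_pvalue": e.loc[kept, "pvalue"].to_numpy(),
            "big_gamma": sign * o.loc[kept, "beta"].to_numpy(),
            "se_big_gamma": o.loc[kept, "se"].to_numpy(),
            "eaf": e.loc[kept, "eaf"].to_numpy(),
            "n_exposure": e.loc[kept, "n"].to_numpy(),
            "n_outcome": o.loc[kept, "n"].to_numpy(),
        }
    ).reset_index(drop=True)

    for sid in shared:
        log_rows.append((sid, action[sid], reason[sid]))
    log = pd.DataFrame(log_rows, columns=["snp_id", "action", "reason"])

    if table.empty:
        raise HarmonizationError("no instruments after harmonization")
    return HarmonizedSet(exposure_trait, outcome_trait, table, log)


def write_harmonization_log(hset: HarmonizedSet, path) -> None:
    """Write the per-SNP harmonization log as TSV."""
    hset.log.to_csv(path, sep="\t", index=False)
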