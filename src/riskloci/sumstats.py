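"""Reading, validation and harmonization of GWAS and eQTL summary statistics.

GWAS summary statistics are held in a :class:`pandas.DataFrame` with one row
per SNP and columns

    ``snp_id, chrom, pos, effect_allele, other_allele, or_raw, p, z, or_folded``

where ``z`` is the signed z-score reconstructed from (p, OR) and
``or_folded = max(OR, 1/OR)`` puts risk and protective alleles on a common
magnitude scale.  eQTL records use

    ``snp_id, gene_id, b_eqtl, se_eqtl, p_eqtl, z_eqtl``

Positions are 1-based inclusive throughout; BED export converts to 0-based
half-open.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GWAS_DEFAULT_COLUMNS",
    "EQTL_DEFAULT_COLUMNS",
    "HarmonizeReport",
    "fold_or",
    "z_from_p_or",
    "read_gwas_sumstats",
    "write_gwas_sumstats",
    "read_eqtl",
    "write_eqtl",
    "validate_gwas",
    "harmonize_alleles",
]

#: default column names in GWAS summary TSV files -> internal names
GWAS_DEFAULT_COLUMNS = {
    "SNP": "snp_id",
    "CHR": "chrom",
    "BP": "pos",
    "A1": "effect_allele",
    "A2": "other_allele",
    "OR": "or_raw",
    "P": "p",
}

#: default column names in eQTL TSV files -> internal names
EQTL_DEFAULT_COLUMNS = {
    "SNP": "snp_id",
    "gene": "gene_id",
    "beta": "b_eqtl",
    "se": "se_eqtl",
    "p": "p_eqtl",
}

#: p-values of exactly 0 (underflow in the source file) are clamped here so
#: the normal quantile stays finite.
P_FLOOR = 1e-300

_BASES = frozenset("ACGT")
_AMBIGUOUS_PAIRS = {frozenset(("A", "T")), frozenset(("C", "G"))}


class SumStatsError(ValueError):
    """Malformed or invalid summary-statistics input."""


def fold_or(or_raw):
    """Fold an odds ratio onto the >= 1 scale: ``max(OR, 1/OR)``.

    Risk and protective alleles then carry comparable effect magnitudes.
    Accepts scalars or arrays; idempotent.

    Raises
    ------
    ValueError
        If any value is not strictly positive.
    """
    arr = np.asarray(or_raw, dtype=float)
    if np.any(~np.isfinite(arr)) or np.any(arr <= 0):
        raise ValueError("odds ratios must be finite and > 0")
    folded = np.where(arr >= 1.0, arr, 1.0 / arr)
    return folded if arr.ndim else float(folded)


def z_from_p_or(p, or_raw):
    """Signed z-score from a two-sided p-value and an odds ratio.

    ``|z|`` is the upper-tail standard-normal quantile of ``p/2``; the sign is
    that of ``ln OR`` (risk allele positive).  ``p == 1`` maps to ``z == 0``.
    """
    p_arr = np.asarray(p, dtype=float)
    or_arr = np.asarray(or_raw, dtype=float)
    if np.any(~np.isfinite(p_arr)) or np.any((p_arr <= 0) | (p_arr > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    if np.any(~np.isfinite(or_arr)) or np.any(or_arr <= 0):
        raise ValueError("odds ratios must be finite and > 0")
    magnitude = stats.norm.isf(p_arr / 2.0)
    z = np.sign(np.log(or_arr)) * magnitude
    # OR == 1 has sign 0; the association is then directionless and z = 0
    # is only consistent if p == 1, which validate_gwas enforces softly.
    out = np.where(or_arr == 1.0, 0.0, z)
    return out if p_arr.ndim or or_arr.ndim else float(out)


def _derive_columns(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    df["or_folded"] = fold_or(df["or_raw"].to_numpy())
    df["z"] = z_from_p_or(df["p"].to_numpy(), df["or_raw"].to_numpy())
    return df


def validate_gwas(df: pd.DataFrame, on_invalid: str = "error") -> pd.DataFrame:
    """Validate a GWAS summary table and derive ``z`` and ``or_folded``.

    Parameters
    ----------
    df
        Table with at least ``snp_id, chrom, pos, effect_allele,
        other_allele, or_raw, p``.
    on_invalid
        ``"error"`` raises :class:`SumStatsError` naming the offending rows;
        ``"drop"`` removes them with a warning.

    Underflowed ``p == 0`` entries are clamped to ``1e-300`` with a warning.
    Duplicate ``snp_id`` keeps the record with the smallest p.  Output is
    sorted by ``(chrom, pos)``.
    """
    if on_invalid not in ("error", "drop"):
        raise ValueError("on_invalid must be 'error' or 'drop'")
    required = ["snp_id", "chrom", "pos", "effect_allele", "other_allele", "or_raw", "p"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SumStatsError(f"missing required column(s): {', '.join(missing)}")
    df = df.copy()
    df["chrom"] = df["chrom"].astype(str)
    df["pos"] = pd.to_numeric(df["pos"], errors="coerce")
    df["or_raw"] = pd.to_numeric(df["or_raw"], errors="coerce")
    df["p"] = pd.to_numeric(df["p"], errors="coerce")

    zero_p = df["p"] == 0
    if zero_p.any():
        warnings.warn(
            f"{int(zero_p.sum())} p-value(s) of 0 clamped to {P_FLOOR:g} (underflow)",
            stacklevel=2,
        )
        df.loc[zero_p, "p"] = P_FLOOR

    bad = (
        df["pos"].isna()
        | (df["pos"] < 1)
        | df["or_raw"].isna()
        | (df["or_raw"] <= 0)
        | df["p"].isna()
        | (df["p"] <= 0)
        | (df["p"] > 1)
    )
    if bad.any():
        rows = [int(i) for i in df.index[bad][:20]]
        msg = f"{int(bad.sum())} invalid row(s) (OR <= 0, p outside (0,1], or bad position) at rows {rows}"
        if on_invalid == "error":
            raise SumStatsError(msg)
        warnings.warn("dropping " + msg, stacklevel=2)
        df = df[~bad]

    df["pos"] = df["pos"].astype(np.int64)
    # duplicate ids: keep the strongest association (smallest p), deterministic
    df = df.sort_values(["snp_id", "p"], kind="mergesort").drop_duplicates("snp_id", keep="first")
    df = _derive_columns(df)
    df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    return df


def _open_maybe_gzip(path, mode="rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_gwas_sumstats(path, column_map=None, on_invalid: str = "error") -> pd.DataFrame:
    """Read a GWAS summary TSV (optionally gzipped) into the internal schema.

    ``column_map`` maps file column names to internal names; defaults to
    :data:`GWAS_DEFAULT_COLUMNS` (SNP, CHR, BP, A1, A2, OR, P).
    """
    column_map = dict(column_map or GWAS_DEFAULT_COLUMNS)
    with _open_maybe_gzip(path) as fh:
        raw = pd.read_csv(fh, sep="\t", dtype={c: str for c in ("CHR", "chrom")})
    missing = [c for c in column_map if c not in raw.columns]
    if missing:
        raise SumStatsError(
            f"configured column(s) {', '.join(missing)} not found in {path} "
            f"(present: {', '.join(raw.columns)})"
        )
    df = raw.rename(columns=column_map)[list(column_map.values())]
    return validate_gwas(df, on_invalid=on_invalid)


def write_gwas_sumstats(df: pd.DataFrame, path, column_map=None) -> None:
    """Write a GWAS summary table back to TSV in the external dialect."""
    column_map = dict(column_map or GWAS_DEFAULT_COLUMNS)
    inverse = {v: k for k, v in column_map.items()}
    out = df[list(inverse)].rename(columns=inverse)
    with _open_maybe_gzip(path, "wt") as fh:
        out.to_csv(fh, sep="\t", index=False)


def read_eqtl(path, column_map=None) -> pd.DataFrame:
    """Read an eQTL summary TSV (SNP, gene, beta, se, p) and derive z."""
    column_map = dict(column_map or EQTL_DEFAULT_COLUMNS)
    with _open_maybe_gzip(path) as fh:
        raw = pd.read_csv(fh, sep="\t")
    missing = [c for c in column_map if c not in raw.columns]
    if missing:
        raise SumStatsError(f"configured column(s) {', '.join(missing)} not found in {path}")
    df = raw.rename(columns=column_map)[list(column_map.values())].copy()
    if np.any(df["se_eqtl"] <= 0):
        raise SumStatsError("eQTL standard errors must be > 0")
    df["z_eqtl"] = df["b_eqtl"] / df["se_eqtl"]
    return df


def write_eqtl(df: pd.DataFrame, path, column_map=None) -> None:
    column_map = dict(column_map or EQTL_DEFAULT_COLUMNS)
    inverse = {v: k for k, v in column_map.items()}
    out = df[list(inverse)].rename(columns=inverse)
    with _open_maybe_gzip(path, "wt") as fh:
        out.to_csv(fh, sep="\t", index=False)


@dataclass
class HarmonizeReport:
    """Bookkeeping from allele harmonization (drops are reported, not fatal)."""

    n_shared: int = 0
    n_kept: int = 0
    n_flipped: int = 0
    n_ambiguous: int = 0
    n_mismatch: int = 0
    n_non_acgt: int = 0
    dropped_snps: list = field(default_factory=list)


def harmonize_alleles(gwas: pd.DataFrame, eqtl: pd.DataFrame):
    """Align eQTL effect alleles to the GWAS effect allele per SNP.

    For SNPs present in both tables: if the two sources report the same
    allele pair but opposite effect alleles, the eQTL slope (and z) sign is
    flipped.  Strand-ambiguous SNPs (A/T, C/G) and non-matching allele pairs
    are dropped and counted, as are records whose alleles are not single
    bases (indel-style ids are accepted upstream but skipped here).

    Returns
    -------
    (merged, report)
        ``merged`` has one row per shared (snp_id, gene_id) with both the
        GWAS columns and sign-aligned eQTL columns.  Harmonizing an already
        harmonized pair is a no-op.
    """
    if "ea_eqtl" in eqtl.columns:
        eq = eqtl.copy()
    else:
        # eQTL tables without allele columns are taken to already be on the
        # GWAS effect-allele convention (the simulators emit them this way)
        eq = eqtl.copy()
        eq["ea_eqtl"] = eq["snp_id"].map(gwas.set_index("snp_id")["effect_allele"])
        eq["oa_eqtl"] = eq["snp_id"].map(gwas.set_index("snp_id")["other_allele"])

    merged = eq.merge(
        gwas[["snp_id", "chrom", "pos", "effect_allele", "other_allele", "or_raw", "or_folded", "p", "z"]],
        on="snp_id",
        how="inner",
    )
    report = HarmonizeReport(n_shared=len(merged))
    if merged.empty:
        return merged.assign(flipped=pd.Series(dtype=bool)), report

    ea_g = merged["effect_allele"].astype(str).str.upper()
    oa_g = merged["other_allele"].astype(str).str.upper()
    ea_e = merged["ea_eqtl"].astype(str).str.upper()
    oa_e = merged["oa_eqtl"].astype(str).str.upper()

    single = (
        ea_g.isin(_BASES) & oa_g.isin(_BASES) & ea_e.isin(_BASES) & oa_e.isin(_BASES)
    )
    ambiguous = single & (
        ((ea_g == "A") & (oa_g == "T")) | ((ea_g == "T") & (oa_g == "A"))
        | ((ea_g == "C") & (oa_g == "G")) | ((ea_g == "G") & (oa_g == "C"))
    )
    same = single & (ea_g == ea_e) & (oa_g == oa_e)
    swapped = single & (ea_g == oa_e) & (oa_g == ea_e) & ~same
    keep = ~ambiguous & (same | swapped)

    report.n_non_acgt = int((~single).sum())
    report.n_ambiguous = int(ambiguous.sum())
    report.n_mismatch = int((single & ~ambiguous & ~same & ~swapped).sum())
    report.dropped_snps = sorted(set(merged.loc[~keep, "snp_id"]))

    out = merged[keep].copy()
    flip = swapped[keep]
    out["b_eqtl"] = np.where(flip, -out["b_eqtl"], out["b_eqtl"])
    out["z_eqtl"] = np.where(flip, -out["z_eqtl"], out["z_eqtl"])
    # after flipping, the eQTL alleles are on the GWAS convention, so a second
    # harmonization pass finds nothing to flip
    out.loc[flip, ["ea_eqtl", "oa_eqtl"]] = out.loc[flip, ["effect_allele", "other_allele"]].to_numpy()
    out["flipped"] = flip.to_numpy()
    report.n_flipped = int(flip.sum())
    report.n_kept = len(out)
    return out.reset_index(drop=True), report
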