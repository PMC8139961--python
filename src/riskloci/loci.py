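"""OR-ranked 200-kb risk-locus construction and annotation.

A risk locus is anchored on an *index SNP*: a subthreshold SNP
(``p < p_subthresh``, default 1e-3) whose folded odds ratio is maximal among
all subthreshold SNPs within ``radius`` (default 100 kb) of it on the same
chromosome.  The locus spans ``index position +/- radius`` (1-based
inclusive, so the default width is 200,001 bp) and collects every
subthreshold SNP in that span as a member.  Loci anchored on nearby index
SNPs may overlap; only exactly identical intervals are de-duplicated.

Ties on the folded OR break toward the smaller GWAS p, then the smaller
position, so the construction is deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "select_index_snps",
    "annotate_known_loci",
    "map_genes",
    "fisher_enrichment",
    "correlate_region_or",
    "loci_to_bed",
    "EnrichmentResult",
]

LOCUS_COLUMNS = [
    "locus_id", "index_snp", "chrom", "start", "end",
    "max_or_folded", "index_p", "n_members", "member_snps",
]


def _beats(or_a, p_a, pos_a, or_b, p_b, pos_b) -> bool:
    """True if SNP a dominates SNP b under the (folded OR, p, position) rule."""
    if or_a != or_b:
        return or_a > or_b
    if p_a != p_b:
        return p_a < p_b
    return pos_a < pos_b


def select_index_snps(
    records: pd.DataFrame,
    p_subthresh: float = 1e-3,
    radius: int = 100_000,
) -> pd.DataFrame:
    """Identify index SNPs and build their 200-kb (2 x radius) risk loci.

    A subthreshold SNP is an index SNP iff no other subthreshold SNP within
    ``+- radius`` on the same chromosome beats it on folded OR (ties: smaller
    p, then smaller position).  An empty post-filter set yields an empty
    locus table, not an error.

    Returns a DataFrame with columns :data:`LOCUS_COLUMNS`; ``member_snps``
    holds the list of subthreshold SNP ids inside each locus span.
    """
    sub = records[records["p"] < p_subthresh]
    rows = []
    for chrom, grp in sub.groupby("chrom", sort=True):
        grp = grp.sort_values("pos", kind="mergesort")
        pos = grp["pos"].to_numpy()
        orf = grp["or_folded"].to_numpy()
        pval = grp["p"].to_numpy()
        ids = grp["snp_id"].to_numpy()
        n = len(grp)
        left = np.searchsorted(pos, pos - radius, side="left")
        right = np.searchsorted(pos, pos + radius, side="right")
        for i in range(n):
            is_index = True
            for j in range(left[i], right[i]):
                if j == i:
                    continue
                if _beats(orf[j], pval[j], pos[j], orf[i], pval[i], pos[i]):
                    is_index = False
                    break
            if is_index:
                start = int(pos[i] - radius)
                end = int(pos[i] + radius)
                members = ids[(pos >= start) & (pos <= end)].tolist()
                rows.append(
                    {
                        "locus_id": f"{chrom}:{start}-{end}",
                        "index_snp": ids[i],
                        "chrom": chrom,
                        "start": start,
                        "end": end,
                        "max_or_folded": float(orf[i]),
                        "index_p": float(pval[i]),
                        "n_members": len(members),
                        "member_snps": members,
                    }
                )
    loci = pd.DataFrame(rows, columns=LOCUS_COLUMNS)
    if loci.empty:
        return loci
    # overlapping loci are expected; drop only exactly identical intervals
    loci = loci.drop_duplicates(subset=["chrom", "start", "end"], keep="first")
    return loci.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)


def annotate_known_loci(
    loci: pd.DataFrame,
    known: pd.DataFrame,
    margin: int = 500_000,
):
    """Flag loci lying within ``margin`` of a previously reported interval.

    ``known`` needs columns ``chrom, start, end`` (1-based inclusive).  A
    locus overlaps iff its interval expanded by ``margin`` on both sides
    intersects any known interval on the same chromosome.

    Returns ``(annotated, counts)`` where counts is
    ``{"overlapping": ..., "novel": ...}``.
    """
    loci = loci.copy()
    flags = np.zeros(len(loci), dtype=bool)
    for chrom, grp in known.groupby(known["chrom"].astype(str)):
        ks = grp["start"].to_numpy()
        ke = grp["end"].to_numpy()
        mask = loci["chrom"].astype(str) == chrom
        if not mask.any():
            continue
        ls = loci.loc[mask, "start"].to_numpy() - margin
        le = loci.loc[mask, "end"].to_numpy() + margin
        hit = ((ls[:, None] <= ke[None, :]) & (le[:, None] >= ks[None, :])).any(axis=1)
        flags[np.flatnonzero(mask.to_numpy())] |= hit
    loci["known_overlap"] = flags
    counts = {"overlapping": int(flags.sum()), "novel": int((~flags).sum())}
    return loci, counts


def map_genes(
    locus,
    genes: pd.DataFrame,
    mode: str = "overlap",
    distance: int = 0,
) -> list:
    """Protein-coding genes assigned to a locus.

    ``mode="overlap"`` returns genes whose span intersects
    ``[start, end]``; ``mode="within_distance"`` expands the locus by
    ``distance`` bp on each side first (boundary inclusive).  ``locus`` is a
    mapping or namedtuple-like with ``chrom, start, end``.
    """
    if mode not in ("overlap", "within_distance"):
        raise ValueError("mode must be 'overlap' or 'within_distance'")
    pad = distance if mode == "within_distance" else 0
    chrom = str(locus["chrom"] if isinstance(locus, (dict, pd.Series)) else locus.chrom)
    start = int(locus["start"] if isinstance(locus, (dict, pd.Series)) else locus.start) - pad
    end = int(locus["end"] if isinstance(locus, (dict, pd.Series)) else locus.end) + pad
    g = genes
    if "biotype" in g.columns:
        g = g[g["biotype"] == "protein_coding"]
    hit = (g["chrom"].astype(str) == chrom) & (g["start"] <= end) & (g["end"] >= start)
    return g.loc[hit, "gene_id"].tolist()


@dataclass
class EnrichmentResult:
    """Two-sided Fisher's exact test of a gene set against hit genes."""

    table: tuple  # ((a, b), (c, d))
    odds_ratio: float  # sample OR, may be inf
    odds_ratio_haldane: float  # 0.5-continuity OR, for display only
    p_value: float


def fisher_enrichment(hit_genes, gene_set, background) -> EnrichmentResult:
    """Enrichment of ``hit_genes`` in ``gene_set`` over ``background``.

    The 2x2 table counts background genes by (in hits) x (in gene set); the
    two-sided p sums hypergeometric probabilities of tables at most as
    probable as the observed one.  A gene set disjoint from the background
    yields p = 1 with a warning.
    """
    hit_genes, gene_set, background = set(hit_genes), set(gene_set), set(background)
    if not background:
        raise ValueError("background gene set must be non-empty")
    if not hit_genes <= background:
        raise ValueError("hit_genes must be a subset of background")
    gene_set = gene_set & background
    a = len(hit_genes & gene_set)
    b = len(hit_genes - gene_set)
    c = len(gene_set - hit_genes)
    d = len(background) - a - b - c
    if not gene_set:
        warnings.warn("gene set is disjoint from background; p = 1", stacklevel=2)
        return EnrichmentResult(((a, b), (c, d)), np.nan, np.nan, 1.0)
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    odds = (a * d) / (b * c) if b * c > 0 else np.inf
    odds_h = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    return EnrichmentResult(((a, b), (c, d)), float(odds), float(odds_h), float(p))


def correlate_region_or(loci: pd.DataFrame):
    """Pearson correlation of ``-log10(p_region)`` with the index folded OR.

    Needs at least three loci with finite values (two points leave zero
    degrees of freedom for the t-based p).
    Returns ``(r, p, n)``.
    """
    x = loci["max_or_folded"].to_numpy(dtype=float)
    y = -np.log10(loci["p_region"].to_numpy(dtype=float))
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3:
        raise ValueError("need at least 3 loci with finite values for a correlation p")
    r, p = stats.pearsonr(x[ok], y[ok])
    return float(r), float(p), int(ok.sum())


def loci_to_bed(loci: pd.DataFrame, path) -> None:
    """Export loci as BED (0-based half-open)."""
    bed = pd.DataFrame(
        {
            "chrom": loci["chrom"],
            "start": loci["start"] - 1,  # 1-based inclusive -> 0-based half-open
            "end": loci["end"],
            "name": loci["locus_id"],
        }
    )
    bed.to_csv(path, sep="\t", index=False, header=False)
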