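"""Summary-based Mendelian randomization (SMR) linking risk loci to genes.

The single-SNP SMR statistic at a shared SNP is

    T_SMR = z_gwas^2 * z_eqtl^2 / (z_gwas^2 + z_eqtl^2),

compared against a 1-df chi-square; the ratio estimate of the effect of
expression on the trait is ``b_xy = b_gwas / b_eqtl``.  The multi-SNP
statistic combines per-SNP T_SMR over all eQTL SNPs passing
``p_eqtl < p_eqtl_max`` (default 1e-3) after greedy LD pruning at
``r^2 <= r2_max`` (default 0.9); its p-value comes from a seeded Monte
Carlo null in the strong-instrument regime: under H0 (a real eQTL but no
mediated GWAS signal) each per-SNP T_SMR is asymptotically the GWAS
chi-square, so null draws are ``z ~ MVN(0, R_set)`` with
``t_null = sum(z_i^2)``, preserving the LD correlation between the
per-SNP statistics.  This reduces exactly to the 1-df chi-square closed
form for a single SNP.  The combination rule and null are recorded in the
result metadata.  No heterogeneity (HEIDI-style) filter is applied.

Multi-SNP p-values are Bonferroni-adjusted over the (locus, gene) pairs
that produced a finite p; genes with adjusted p < 0.05 are the target
susceptibility genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .loci import map_genes
from .region import LDMatrix, ld_matrix

__all__ = [
    "eqtl_scan",
    "smr_single",
    "SmrSingle",
    "ld_prune",
    "smr_multi",
    "SmrMulti",
    "candidate_genes",
    "select_targets",
    "run_smr",
]

SMR_MODEL = (
    "sum of per-SNP T_SMR over thresholded, LD-pruned eQTL set; "
    "seeded strong-instrument Monte Carlo null (z ~ MVN(0, R_set), t_null = sum z^2)"
)


def eqtl_scan(genotypes, expression: pd.DataFrame, covariates=None) -> pd.DataFrame:
    """Per-(SNP, gene) linear eQTL mapping with covariate adjustment.

    ``genotypes`` is an :class:`~riskloci.simulate.LDPanel` or a samples x
    SNPs DataFrame; ``expression`` is genes x samples; ``covariates`` is a
    samples x covariates table (an intercept is always included).  Both
    sides are residualized on the covariate design (Frisch–Waugh–Lovell),
    and p-values use the t reference with residual degrees of freedom
    ``n - k_cov - 1``.

    Returns a DataFrame ``snp_id, gene_id, b_eqtl, se_eqtl, p_eqtl, z_eqtl``
    sorted by gene then p.
    """
    if hasattr(genotypes, "dosages"):
        G = genotypes.dosages
        snp_ids = genotypes.snp_ids
    else:
        G = genotypes.to_numpy(dtype=float)
        snp_ids = list(genotypes.columns)
    n = G.shape[0]
    if expression.shape[1] != n:
        raise ValueError("expression columns must align with genotype samples")

    X = np.ones((n, 1))
    if covariates is not None and len(covariates.columns):
        C = covariates.to_numpy(dtype=float)
        X = np.hstack([X, C])
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            # identify the collinear columns by rank-increment scanning
            names, cols, bad = ["intercept"] + list(covariates.columns), X, []
            kept = cols[:, :1]
            for j in range(1, cols.shape[1]):
                trial = np.hstack([kept, cols[:, j : j + 1]])
                if np.linalg.matrix_rank(trial) > kept.shape[1]:
                    kept = trial
                else:
                    bad.append(names[j])
            raise ValueError(f"rank-deficient covariate design; collinear column(s): {bad}")
    k = X.shape[1]
    df = n - k - 1
    if df < 1:
        raise ValueError("not enough samples for the covariate design")

    # residualize dosages and expression on the covariate design
    Q, _ = np.linalg.qr(X)
    Gr = G - Q @ (Q.T @ G)
    Y = expression.to_numpy(dtype=float).T  # samples x genes
    Yr = Y - Q @ (Q.T @ Y)

    sxx = (Gr**2).sum(axis=0)  # per SNP
    if np.any(sxx == 0):
        bad = [snp_ids[i] for i in np.flatnonzero(sxx == 0)]
        raise ValueError(f"constant (post-adjustment) dosage for SNP(s) {bad}")
    syy = (Yr**2).sum(axis=0)  # per gene
    sxy = Gr.T @ Yr  # SNPs x genes

    slope = sxy / sxx[:, None]
    rss = np.maximum(syy[None, :] - slope * sxy, 0.0)
    sigma2 = rss / df
    se = np.sqrt(sigma2 / sxx[:, None])
    with np.errstate(divide="ignore", invalid="ignore"):
        tval = np.where(se > 0, slope / se, np.inf * np.sign(slope))
    p = 2.0 * stats.t.sf(np.abs(tval), df)
    p = np.clip(p, 1e-300, 1.0)

    genes = list(expression.index)
    out = pd.DataFrame(
        {
            "snp_id": np.repeat(snp_ids, len(genes)),
            "gene_id": np.tile(genes, len(snp_ids)),
            "b_eqtl": slope.ravel(),
            "se_eqtl": se.ravel(),
            "p_eqtl": p.ravel(),
            "z_eqtl": np.where(np.isfinite(se.ravel()) & (se.ravel() > 0),
                               slope.ravel() / np.where(se.ravel() > 0, se.ravel(), 1.0),
                               np.inf * np.sign(slope.ravel())),
        }
    )
    return out.sort_values(["gene_id", "p_eqtl"], kind="mergesort").reset_index(drop=True)


@dataclass
class SmrSingle:
    b_xy: float  # ratio estimate b_gwas / b_eqtl (nan if betas not given)
    t_smr: float
    p_smr: float


def smr_single(z_gwas: float, z_eqtl: float, b_gwas=None, b_eqtl=None) -> SmrSingle:
    """Single-SNP SMR statistic and p-value at one shared SNP.

    ``T_SMR = z1^2 z2^2 / (z1^2 + z2^2)`` is bounded by the weaker of the
    two component chi-squares; the p-value is the upper 1-df chi-square
    tail.  Both z-scores zero leaves the statistic undefined.
    """
    z1sq, z2sq = float(z_gwas) ** 2, float(z_eqtl) ** 2
    if z1sq == 0 and z2sq == 0:
        raise ValueError("T_SMR undefined when both z-scores are zero")
    if np.isinf(z1sq):
        t = z2sq
    elif np.isinf(z2sq):
        t = z1sq
    else:
        t = z1sq * z2sq / (z1sq + z2sq)
    p = float(stats.chi2.sf(t, 1))
    b_xy = np.nan
    if b_gwas is not None and b_eqtl is not None:
        if b_eqtl == 0:
            raise ValueError("b_xy undefined for b_eqtl = 0")
        b_xy = float(b_gwas) / float(b_eqtl)
    return SmrSingle(b_xy=b_xy, t_smr=float(t), p_smr=p)


def _t_smr_array(z1: np.ndarray, z2: np.ndarray) -> np.ndarray:
    a, b = z1**2, z2**2
    denom = a + b
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(denom > 0, a * b / denom, 0.0)
    return t


def ld_prune(snp_ids, ld: LDMatrix, r2_max: float = 0.9) -> list:
    """Greedy LD pruning of a p-ordered SNP list.

    Walk ``snp_ids`` (ordered by ascending eQTL p); keep a SNP iff its r^2
    with every already-kept SNP is <= ``r2_max``.
    """
    pos = {s: i for i, s in enumerate(ld.snp_ids)}
    kept: list = []
    for s in snp_ids:
        i = pos[s]
        if all(ld.R[i, pos[k]] ** 2 <= r2_max for k in kept):
            kept.append(s)
    return kept


@dataclass
class SmrMulti:
    t_multi: float
    p_smr_multi: float
    m_used: int
    snps: list
    top_snp: str


def smr_multi(
    gene: str,
    eqtl: pd.DataFrame,
    gwas: pd.DataFrame,
    ld: LDMatrix,
    p_eqtl_max: float = 1e-3,
    r2_max: float = 0.9,
    n_null: int = 10_000,
    seed: int = 0,
):
    """Multi-SNP SMR for one gene.

    Candidate SNPs pass ``p_eqtl < p_eqtl_max`` and survive greedy pruning
    at ``r2_max``; the observed statistic sums their per-SNP T_SMR.  The
    null draws GWAS z vectors from MVN(0, R_set) — the strong-instrument
    limit in which each per-SNP T_SMR is the GWAS chi-square — and the
    Monte Carlo p is ``(1 + #null >= observed) / (n_null + 1)``.

    Returns an :class:`SmrMulti`, or ``None`` (gene skipped) when no SNP
    passes the eQTL threshold.
    """
    sub = eqtl[(eqtl["gene_id"] == gene) & (eqtl["p_eqtl"] < p_eqtl_max)]
    sub = sub[sub["snp_id"].isin(ld.snp_ids)].sort_values("p_eqtl", kind="mergesort")
    if sub.empty:
        return None
    ordered = sub["snp_id"].tolist()
    kept = ld_prune(ordered, ld, r2_max=r2_max)

    z_gwas = gwas.set_index("snp_id")["z"].reindex(kept).to_numpy(dtype=float)
    if np.any(~np.isfinite(z_gwas)):
        missing = [s for s, z in zip(kept, z_gwas) if not np.isfinite(z)]
        raise KeyError(f"GWAS z missing for SNP(s) {missing}")
    z_eqtl = sub.set_index("snp_id")["z_eqtl"].reindex(kept).to_numpy(dtype=float)

    t_obs = float(_t_smr_array(z_gwas, z_eqtl).sum())
    R_set = ld.submatrix(kept)
    w, V = np.linalg.eigh(R_set.R)
    L = V * np.sqrt(np.clip(w, 0.0, None))

    rng = np.random.default_rng(seed)
    m = len(kept)
    Zg = rng.standard_normal((n_null, m)) @ L.T
    t_null = (Zg**2).sum(axis=1)
    p = (1.0 + np.count_nonzero(t_null >= t_obs)) / (n_null + 1.0)
    return SmrMulti(
        t_multi=t_obs,
        p_smr_multi=float(p),
        m_used=m,
        snps=kept,
        top_snp=ordered[0],
    )


def candidate_genes(locus, genes: pd.DataFrame, window: int = 1_000_000) -> list:
    """Protein-coding genes within ``window`` (default 1 Mb) of the locus."""
    return map_genes(locus, genes, mode="within_distance", distance=window)


def select_targets(results: pd.DataFrame, n_tests=None, alpha: float = 0.05) -> pd.DataFrame:
    """Bonferroni-adjust multi-SNP p-values and flag target genes.

    ``n_tests`` defaults to the number of (locus, gene) rows with a finite
    ``p_smr_multi`` in this run; an explicit integer overrides it.
    """
    results = results.copy()
    finite = np.isfinite(results["p_smr_multi"].to_numpy(dtype=float))
    if n_tests is None:
        n_tests = int(finite.sum())
    if n_tests < 1:
        results["adj_p_smr_multi"] = np.nan
        results["target"] = False
        return results
    adj = np.minimum(1.0, n_tests * results["p_smr_multi"].to_numpy(dtype=float))
    results["adj_p_smr_multi"] = np.where(finite, adj, np.nan)
    results["target"] = finite & (adj < alpha)
    results.attrs["n_tests"] = n_tests
    return results


def run_smr(
    loci: pd.DataFrame,
    genes: pd.DataFrame,
    gwas: pd.DataFrame,
    eqtl: pd.DataFrame,
    panel,
    window: int = 1_000_000,
    p_eqtl_max: float = 1e-3,
    r2_max: float = 0.9,
    n_null: int = 10_000,
    alpha: float = 0.05,
    n_tests=None,
    seed: int = 0,
):
    """SMR over every (locus, candidate gene) pair.

    For each locus, candidate genes lie within ``window`` of its span; the
    per-gene eQTL SNP set is restricted to SNPs present in both the GWAS
    table and the reference panel.  Single-SNP results are reported at the
    top (smallest-p) eQTL SNP.  Genes with no SNP passing the eQTL
    threshold are skipped with a reason code.

    Returns ``(results, skipped, meta)``.
    """
    gwas_snps = set(gwas["snp_id"])
    panel_snps = set(panel.snp_ids)
    rows, skipped = [], []
    pair_index = 0
    for locus in loci.itertuples(index=False):
        cand = candidate_genes(locus, genes, window=window)
        index_pos = None
        hit = gwas.loc[gwas["snp_id"] == locus.index_snp, "pos"]
        if len(hit):
            index_pos = int(hit.iloc[0])
        for gene in cand:
            sub = eqtl[eqtl["gene_id"] == gene]
            usable = sub[sub["snp_id"].isin(gwas_snps & panel_snps)]
            if usable.empty or (usable["p_eqtl"] >= p_eqtl_max).all():
                skipped.append({"locus_id": locus.locus_id, "gene_id": gene,
                                "reason": "no_eqtl_snp_below_threshold"})
                continue
            snp_ids = usable.loc[usable["p_eqtl"] < p_eqtl_max] \
                .sort_values("p_eqtl", kind="mergesort")["snp_id"].tolist()
            ld = ld_matrix(panel, snp_ids)
            multi = smr_multi(
                gene, usable, gwas, ld,
                p_eqtl_max=p_eqtl_max, r2_max=r2_max, n_null=n_null,
                seed=(seed * 100 + pair_index) % (2**31),
            )
            pair_index += 1
            if multi is None:  # pragma: no cover - guarded by the threshold check above
                continue
            top = usable.sort_values("p_eqtl", kind="mergesort").iloc[0]
            gw_top = gwas.set_index("snp_id").loc[top["snp_id"]]
            z_g = float(gw_top["z"])
            single = smr_single(z_g, top["z_eqtl"],
                                b_gwas=float(np.log(gw_top["or_raw"])), b_eqtl=top["b_eqtl"])
            grow = genes.set_index("gene_id").loc[gene]
            dist_mb = np.nan
            if index_pos is not None:
                gene_mid = (int(grow["start"]) + int(grow["end"])) / 2.0
                dist_mb = round(abs(gene_mid - index_pos) / 1e6, 3)
            rows.append(
                {
                    "locus_id": locus.locus_id,
                    "gene_id": gene,
                    "top_snp": multi.top_snp,
                    "distance_mb": dist_mb,
                    "b_xy": single.b_xy,
                    "t_smr": single.t_smr,
                    "p_smr": single.p_smr,
                    "m_used": multi.m_used,
                    "t_multi": multi.t_multi,
                    "p_smr_multi": multi.p_smr_multi,
                }
            )
    results = pd.DataFrame(
        rows,
        columns=["locus_id", "gene_id", "top_snp", "distance_mb", "b_xy",
                 "t_smr", "p_smr", "m_used", "t_multi", "p_smr_multi"],
    )
    results = select_targets(results, n_tests=n_tests, alpha=alpha)
    meta = {
        "model": SMR_MODEL,
        "p_eqtl_max": p_eqtl_max,
        "r2_max": r2_max,
        "n_null": n_null,
        "window": window,
        "alpha": alpha,
        "n_tests": results.attrs.get("n_tests", 0),
        "seed": seed,
    }
    return results, pd.DataFrame(skipped, columns=["locus_id", "gene_id", "reason"]), meta
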