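"""Synthetic cohorts with known ground truth.

Every downstream stage — locus building, the LD-aware region test, eQTL
mapping, SMR, meta-analysis and the methylation scan — is exercised on data
from this module, so each generator is a pure function of its parameters and
a seed.

The LD model is a latent-Gaussian AR(1): haplotype ``j`` carries the minor
allele when a latent AR(1) Gaussian falls below the MAF quantile, so
adjacent SNPs are correlated with decay ``rho**distance`` on the latent
scale.  This reproduces the block-correlation structure the region and SMR
statistics consume without a coalescent simulator.

GWAS summary statistics are simulated at the z-score level,
``z ~ MVN(R @ lam, R)`` with ``R`` the panel LD matrix and ``lam`` the
non-centrality loaded on causal SNPs — the standard null/alternative for
LD-aware region statistics.  Odds ratios are reconstructed as
``exp(z * se_nominal)`` with a nominal standard error so the fold/quantile
round trips hold.

A single pipeline seed fans out to per-generator child seeds through fixed
offsets (see :data:`SEED_OFFSETS`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy import stats

__all__ = [
    "LDPanel",
    "TruthRecord",
    "simulate_ld_panel",
    "simulate_gwas_z",
    "simulate_eqtl_cohort",
    "simulate_expression_studies",
    "simulate_methylation",
    "simulate_smr_scenario",
    "child_seed",
]

#: fixed fan-out offsets: child_seed = (seed * 1000 + offset) mod 2**31
SEED_OFFSETS = {
    "panel": 11,
    "gwas": 23,
    "eqtl": 37,
    "expression": 53,
    "methylation": 71,
    "scenario": 89,
}


def child_seed(seed: int, stage: str) -> int:
    """Derive a per-stage child seed from the global seed (stays < 2**31)."""
    return (int(seed) * 1000 + SEED_OFFSETS[stage]) % (2**31)


@dataclass
class LDPanel:
    """Reference genotype panel: dosage matrix plus SNP map.

    ``dosages`` is samples x SNPs with values in {0, 1, 2} (minor-allele
    counts); ``snp_map`` has one row per SNP with columns
    ``snp_id, chrom, pos, effect_allele, other_allele, maf``.
    Constant dosage columns are rejected at construction.
    """

    dosages: np.ndarray
    snp_map: pd.DataFrame

    def __post_init__(self):
        if self.dosages.shape[1] != len(self.snp_map):
            raise ValueError("dosage column count must equal SNP map length")
        std = self.dosages.std(axis=0)
        if np.any(std == 0):
            bad = self.snp_map["snp_id"].iloc[np.flatnonzero(std == 0)[:5]].tolist()
            raise ValueError(f"constant dosage column(s): {bad}")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def m_snps(self) -> int:
        return self.dosages.shape[1]

    @property
    def snp_ids(self) -> list:
        return self.snp_map["snp_id"].tolist()

    def dosage_for(self, snp_ids) -> np.ndarray:
        idx = self.snp_map.reset_index(drop=True).set_index("snp_id").index
        positions = [idx.get_loc(s) for s in snp_ids]
        return self.dosages[:, positions]

    def write_tsv(self, path) -> None:
        df = pd.DataFrame(self.dosages, columns=self.snp_map["snp_id"])
        df.insert(0, "sample_id", [f"S{i:04d}" for i in range(self.n_samples)])
        df.to_csv(path, sep="\t", index=False)


def write_panel(panel: LDPanel, dosage_path, map_path) -> None:
    """Write a panel as two TSVs: dosage matrix and SNP map."""
    panel.write_tsv(dosage_path)
    panel.snp_map.to_csv(map_path, sep="\t", index=False)


def read_panel(dosage_path, map_path) -> LDPanel:
    """Read a panel written by :func:`write_panel`."""
    snp_map = pd.read_csv(map_path, sep="\t", dtype={"chrom": str})
    dosages = pd.read_csv(dosage_path, sep="\t")
    dosages = dosages[snp_map["snp_id"]].to_numpy(dtype=float)
    return LDPanel(dosages=dosages, snp_map=snp_map)


@dataclass
class TruthRecord:
    """Ground truth for a simulated scenario, for parameter-recovery tests."""

    causal_gwas: dict  # snp_id -> non-centrality lambda
    causal_eqtl: dict  # gene_id -> (snp_id, slope)
    scenario: str  # pleiotropy | linkage | null
    seed: int

    def __post_init__(self):
        if self.scenario not in ("pleiotropy", "linkage", "null"):
            raise ValueError(f"unknown scenario {self.scenario!r}")
        gwas_snps = set(self.causal_gwas)
        eqtl_snps = {s for s, _ in self.causal_eqtl.values()}
        shared = gwas_snps & eqtl_snps
        if self.scenario == "pleiotropy" and not shared:
            raise ValueError("pleiotropy scenario requires a shared causal SNP")
        if self.scenario == "linkage" and shared:
            raise ValueError("linkage scenario requires distinct causal SNPs")

    def to_yaml(self, path) -> None:
        payload = {
            "scenario": self.scenario,
            "seed": int(self.seed),
            "causal_gwas": {k: float(v) for k, v in self.causal_gwas.items()},
            "causal_eqtl": {g: [s, float(b)] for g, (s, b) in self.causal_eqtl.items()},
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)


def simulate_ld_panel(
    n_samples: int,
    m_snps: int,
    rho: float = 0.8,
    maf_range=(0.05, 0.5),
    spacing_bp: float = 5_000.0,
    chrom: str = "1",
    start_bp: int = 1_000_000,
    seed: int = 0,
) -> LDPanel:
    """Simulate a reference LD panel with AR(1) latent-Gaussian haplotypes.

    Two haplotypes per sample are drawn independently; haplotype alleles are
    indicators of the latent AR(1) process falling below the per-SNP MAF
    quantile, and dosages are the haplotype sum.  Inter-SNP distances are
    exponential with mean ``spacing_bp``.  Panels with a monomorphic SNP are
    redrawn from a child seed (bounded retries) so construction invariants
    hold at small n.
    """
    if n_samples < 30:
        raise ValueError("n_samples must be >= 30 for a usable reference panel")
    if m_snps < 2:
        raise ValueError("m_snps must be >= 2")
    if not (0 <= rho < 1):
        raise ValueError("rho must lie in [0, 1)")
    lo, hi = maf_range
    if not (0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")

    rng = np.random.default_rng(seed)
    positions = start_bp + np.cumsum(
        np.maximum(1, rng.exponential(spacing_bp, size=m_snps).astype(np.int64))
    )
    mafs = rng.uniform(lo, hi, size=m_snps)
    thresholds = stats.norm.ppf(mafs)

    for _ in range(100):
        eps = rng.standard_normal((2 * n_samples, m_snps))
        latent = np.empty_like(eps)
        latent[:, 0] = eps[:, 0]
        scale = np.sqrt(1.0 - rho**2)
        for j in range(1, m_snps):
            latent[:, j] = rho * latent[:, j - 1] + scale * eps[:, j]
        haplo = (latent < thresholds).astype(np.int8)
        dosages = (haplo[:n_samples] + haplo[n_samples:]).astype(np.float64)
        if np.all(dosages.std(axis=0) > 0):
            break
    else:
        raise RuntimeError("could not draw a polymorphic panel in 100 attempts")

    emp_maf = dosages.mean(axis=0) / 2.0
    emp_maf = np.minimum(emp_maf, 1.0 - emp_maf)
    snp_map = pd.DataFrame(
        {
            "snp_id": [f"rs{chrom}_{p}" for p in positions],
            "chrom": str(chrom),
            "pos": positions,
            "effect_allele": "A",
            "other_allele": "G",
            "maf": emp_maf,
        }
    )
    return LDPanel(dosages=dosages, snp_map=snp_map)


def _ld_correlation(panel: LDPanel, ridge: float = 1e-6) -> np.ndarray:
    R = np.corrcoef(panel.dosages, rowvar=False)
    R = (R + R.T) / 2.0
    R[np.diag_indices_from(R)] = 1.0 + ridge
    return R


def _psd_factor(R: np.ndarray) -> np.ndarray:
    """Factor L with L @ L.T = PSD-projection of R (eigenvalue clipping)."""
    w, V = np.linalg.eigh(R)
    if w[-1] <= 0:
        raise np.linalg.LinAlgError(
            f"LD matrix is not positive semi-definite after ridge (eigenvalues {w[:5]}...)"
        )
    w = np.clip(w, 0.0, None)
    return V * np.sqrt(w)


def simulate_gwas_z(
    panel: LDPanel,
    lam=None,
    seed: int = 0,
    se_nominal: float = 0.05,
    ridge: float = 1e-6,
):
    """Draw GWAS z-scores ``z ~ MVN(R @ lam, R)`` and summary records.

    ``lam`` maps causal snp_ids to non-centralities (or is a full vector over
    panel SNPs; ``None`` means the global null).  Returns ``(z, sumstats)``
    where ``sumstats`` is a validated GWAS summary DataFrame with
    ``OR = exp(z * se_nominal)`` and two-sided normal p-values.
    """
    from .sumstats import validate_gwas

    m = panel.m_snps
    lam_vec = np.zeros(m)
    if lam is not None:
        if isinstance(lam, dict):
            index = {s: i for i, s in enumerate(panel.snp_ids)}
            for snp, value in lam.items():
                if snp not in index:
                    raise KeyError(f"causal SNP {snp} not in panel")
                lam_vec[index[snp]] = value
        else:
            lam_vec = np.asarray(lam, dtype=float)
            if lam_vec.shape != (m,):
                raise ValueError("lam vector length must equal panel SNP count")

    rng = np.random.default_rng(seed)
    R = _ld_correlation(panel, ridge=ridge)
    L = _psd_factor(R)
    z = R @ lam_vec + L @ rng.standard_normal(m)

    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.clip(p, 1e-300, 1.0)
    records = panel.snp_map.copy()
    records["or_raw"] = np.exp(z * se_nominal)
    records["p"] = p
    return z, validate_gwas(records)


def _default_covariates(n: int, rng) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "age": rng.normal(50.0, 10.0, size=n),
            "pmi": rng.normal(12.0, 4.0, size=n),  # post-mortem interval, hours
            "sex": rng.integers(0, 2, size=n).astype(float),
        }
    )


def simulate_eqtl_cohort(
    panel: LDPanel,
    gene: str,
    causal_snp: str | None,
    slope: float = 0.0,
    h2_like: float | None = None,
    covariate_effects=None,
    seed: int = 0,
):
    """Simulate one gene's expression over the panel samples.

    ``expression = slope * dosage + covariates @ effects + noise``; when
    ``h2_like`` is given the noise variance is scaled so the causal SNP
    explains that fraction of the total variance (``h2_like = 1`` gives
    noise-free expression).  Covariates are two continuous (age, post-mortem
    interval) and one binary (sex), returned for adjustment tests.

    Returns ``(expression, covariates)`` with expression a pandas Series
    indexed like the panel samples.
    """
    rng = np.random.default_rng(seed)
    n = panel.n_samples
    covariates = _default_covariates(n, rng)
    cov_contrib = np.zeros(n)
    if covariate_effects:
        for name, eff in covariate_effects.items():
            cov_contrib += eff * covariates[name].to_numpy()

    genetic = np.zeros(n)
    if causal_snp is not None and slope != 0.0:
        genetic = slope * panel.dosage_for([causal_snp])[:, 0]

    var_g = float(np.var(genetic))
    var_c = float(np.var(cov_contrib))
    if h2_like is None:
        noise_sd = 1.0
    elif not (0 <= h2_like <= 1):
        raise ValueError("h2_like must lie in [0, 1]")
    elif h2_like == 1.0:
        noise_sd = 0.0
    elif var_g == 0.0 or h2_like == 0.0:
        noise_sd = 1.0
    else:
        var_noise = var_g * (1.0 - h2_like) / h2_like - var_c
        if var_noise < 0:
            raise ValueError(
                "covariate variance exceeds the budget implied by h2_like; "
                "reduce covariate_effects or h2_like"
            )
        noise_sd = np.sqrt(var_noise)

    expr = genetic + cov_contrib + noise_sd * rng.standard_normal(n)
    return pd.Series(expr, name=gene), covariates


def simulate_expression_studies(
    k_studies: int,
    n_case,
    n_control,
    true_smd: float = 0.0,
    tau: float = 0.0,
    seed: int = 0,
):
    """Simulate per-study case/control expression vectors for meta-analysis.

    Study ``i`` draws its own standardized effect from
    ``Normal(true_smd, tau^2)`` (between-study heterogeneity), then case and
    control samples from unit-variance normals separated by that effect.
    ``n_case``/``n_control`` may be scalars or per-study sequences.

    Returns a list of dicts ``{study_id, case, control, true_effect}``.
    """
    if k_studies < 1:
        raise ValueError("k_studies must be >= 1")
    n_case = np.broadcast_to(np.asarray(n_case), (k_studies,)).astype(int)
    n_control = np.broadcast_to(np.asarray(n_control), (k_studies,)).astype(int)
    rng = np.random.default_rng(seed)
    studies = []
    for i in range(k_studies):
        effect = rng.normal(true_smd, tau) if tau > 0 else true_smd
        studies.append(
            {
                "study_id": f"study{i + 1}",
                "case": rng.standard_normal(n_case[i]) + effect,
                "control": rng.standard_normal(n_control[i]),
                "true_effect": float(effect),
            }
        )
    return studies


def simulate_methylation(
    n_cases: int,
    n_controls: int,
    m_probes: int,
    n_dmp: int = 0,
    effect: float = 0.0,
    covariate_confounding: float = 0.0,
    covariate_probe_effect: float = 1.0,
    seed: int = 0,
):
    """Simulate a methylation beta matrix (probes x samples) with labels.

    Latent M-like values are Gaussian per probe; the first ``n_dmp`` probes
    carry a case-vs-control shift of ``effect`` on the latent scale, and the
    logistic transform maps latent values into beta space (0, 1).  With
    ``covariate_confounding = c`` the binary "race" covariate has frequency
    ``0.5 + c/2`` in cases and ``0.5 - c/2`` in controls and shifts every
    probe by ``covariate_probe_effect`` — a confounder that inflates an
    unadjusted scan but not an adjusted one.

    Returns ``(beta, labels, covariates, truth_probes)``.
    """
    if not (0 <= covariate_confounding <= 1):
        raise ValueError("covariate_confounding must lie in [0, 1]")
    if n_dmp > m_probes:
        raise ValueError("n_dmp cannot exceed m_probes")
    rng = np.random.default_rng(seed)
    n = n_cases + n_controls
    group = np.array([1] * n_cases + [0] * n_controls)

    p_race = 0.5 + covariate_confounding / 2.0 * np.where(group == 1, 1.0, -1.0)
    race = (rng.uniform(size=n) < p_race).astype(float)
    sex = rng.integers(0, 2, size=n).astype(float)

    baseline = rng.normal(0.0, 1.0, size=m_probes)
    latent = baseline[:, None] + rng.standard_normal((m_probes, n))
    truth_probes = [f"cg{j:06d}" for j in range(n_dmp)]
    if n_dmp:
        latent[:n_dmp] += effect * group[None, :]
    latent += covariate_probe_effect * race[None, :] if covariate_confounding > 0 else 0.0

    beta = 1.0 / (1.0 + np.exp(-latent))
    beta_df = pd.DataFrame(
        beta,
        index=[f"cg{j:06d}" for j in range(m_probes)],
        columns=[f"M{j:04d}" for j in range(n)],
    )
    labels = pd.Series(group, index=beta_df.columns, name="group")
    covariates = pd.DataFrame({"sex": sex, "race": race}, index=beta_df.columns)
    return beta_df, labels, covariates, truth_probes


def _pick_linked_snp(panel: LDPanel, causal_idx: int, target_r: float) -> int:
    """Index of the SNP whose dosage correlation with the causal SNP is
    closest to ``target_r`` (excluding the causal SNP itself)."""
    g = panel.dosages
    x = g[:, causal_idx]
    r = np.array(
        [np.corrcoef(x, g[:, j])[0, 1] if j != causal_idx else np.nan for j in range(g.shape[1])]
    )
    return int(np.nanargmin(np.abs(r - target_r)))


def simulate_smr_scenario(
    scenario: str = "pleiotropy",
    n_ref: int = 500,
    m_snps: int = 60,
    rho: float = 0.8,
    lam: float = 6.0,
    h2_like: float = 0.1,
    n_genes: int = 5,
    linkage_r: float = 0.4,
    se_nominal: float = 0.05,
    seed: int = 0,
) -> dict:
    """Build a complete synthetic study for the locus -> SMR pipeline.

    One causal GWAS SNP mid-panel carries non-centrality ``lam``; gene
    ``G1`` is the eQTL gene — sharing the causal SNP (pleiotropy), using a
    distinct SNP at LD ~ ``linkage_r`` (linkage), or having no eQTL (null).
    The remaining ``n_genes - 1`` genes are expression noise.  Gene spans
    are laid out within 1 Mb of the causal position so they are candidate
    genes of the resulting locus.

    Returns a dict with keys ``panel, sumstats, z, expression, covariates,
    genes, truth``.
    """
    base = child_seed(seed, "scenario")
    panel = simulate_ld_panel(n_ref, m_snps, rho=rho, seed=child_seed(base, "panel"))
    causal_idx = m_snps // 2
    causal_snp = panel.snp_ids[causal_idx]

    z, sumstats = simulate_gwas_z(
        panel, {causal_snp: lam}, seed=child_seed(base, "gwas"), se_nominal=se_nominal
    )

    if scenario == "pleiotropy":
        eqtl_snp = causal_snp
    elif scenario == "linkage":
        eqtl_snp = panel.snp_ids[_pick_linked_snp(panel, causal_idx, linkage_r)]
    elif scenario == "null":
        eqtl_snp = None
    else:
        raise ValueError(f"unknown scenario {scenario!r}")

    expression = {}
    covariates = None
    causal_eqtl = {}
    for g in range(n_genes):
        gene = f"G{g + 1}"
        gene_seed = child_seed(base, "eqtl") + g
        if g == 0 and eqtl_snp is not None:
            expr, covariates = simulate_eqtl_cohort(
                panel, gene, eqtl_snp, slope=1.0, h2_like=h2_like, seed=gene_seed
            )
            causal_eqtl[gene] = (eqtl_snp, 1.0)
        else:
            expr, cov = simulate_eqtl_cohort(panel, gene, None, seed=gene_seed)
            if covariates is None:
                covariates = cov
        expression[gene] = expr
    expression = pd.DataFrame(expression).T  # genes x samples

    causal_pos = int(panel.snp_map["pos"].iloc[causal_idx])
    chrom = panel.snp_map["chrom"].iloc[0]
    rng = np.random.default_rng(child_seed(base, "expression"))
    starts = causal_pos + rng.integers(-800_000, 600_000, size=n_genes)
    genes = pd.DataFrame(
        {
            "gene_id": [f"G{g + 1}" for g in range(n_genes)],
            "chrom": chrom,
            "start": starts,
            "end": starts + rng.integers(5_000, 200_000, size=n_genes),
            "biotype": "protein_coding",
        }
    )

    truth = TruthRecord(
        causal_gwas={causal_snp: lam},
        causal_eqtl=causal_eqtl,
        scenario=scenario,
        seed=seed,
    )
    return {
        "panel": panel,
        "sumstats": sumstats,
        "z": z,
        "expression": expression,
        "covariates": covariates,
        "genes": genes,
        "truth": truth,
    }
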