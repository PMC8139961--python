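"""Build OR-ranked 200-kb risk loci from simulated GWAS summary statistics.

Simulates a small GWAS over an LD panel with one causal SNP, keeps the
subthreshold SNPs (p < 1e-3), and anchors a 200-kb locus on every SNP whose
folded odds ratio is the local maximum within +/-100 kb.
"""

from riskloci import loci, simulate

panel = simulate.simulate_ld_panel(n_samples=300, m_snps=50, rho=0.9, seed=7)
causal = panel.snp_ids[25]
z, sumstats = simulate.simulate_gwas_z(panel, {causal: 7.0}, seed=8)

locus_table = loci.select_index_snps(sumstats, p_subthresh=1e-3, radius=100_000)

print(f"{(sumstats['p'] < 1e-3).sum()} subthreshold SNPs "
      f"-> {len(locus_table)} risk locus/loci\n")
for row in locus_table.itertuples(index=False):
    print(f"locus {row.locus_id}: index SNP {row.index_snp} "
          f"(folded OR {row.max_or_folded:.3f}, p {row.index_p:.2e}), "
          f"{row.n_members} member SNPs")
print(f"\nplanted causal SNP: {causal}")
# The index SNP is the member with the largest folded OR; because the causal
# signal spreads over the LD block, the index SNP may be an LD proxy of the
# planted SNP rather than the planted SNP itself.
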