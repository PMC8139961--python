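"""Index-SNP locus construction, annotation and enrichment, vs brute force."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from riskloci import loci as lm
from riskloci import sumstats as ss


def random_sumstats(rng, n=200, n_chrom=2, span=2_000_000):
    df = pd.DataFrame(
        {
            "snp_id": [f"rs{i}" for i in range(n)],
            "chrom": rng.choice([str(c) for c in range(1, n_chrom + 1)], size=n),
            "pos": rng.integers(1, span, size=n),
            "effect_allele": "A",
            "other_allele": "G",
            "or_raw": np.exp(rng.normal(0, 0.1, size=n)),
            "p": rng.uniform(1e-8, 1.0, size=n) ** 3,
        }
    )
    df = df.drop_duplicates(subset=["chrom", "pos"])
    return ss.validate_gwas(df)


def brute_force_index_snps(records, p_subthresh=1e-3, radius=100_000):
    """Quadratic local-maximum oracle, independent of the implementation."""
    sub = records[records["p"] < p_subthresh]
    out = []
    for _, a in sub.iterrows():
        dominated = False
        for _, b in sub.iterrows():
            if b["snp_id"] == a["snp_id"] or b["chrom"] != a["chrom"]:
                continue
            if abs(b["pos"] - a["pos"]) > radius:
                continue
            key_b = (b["or_folded"], -b["p"], -b["pos"])
            key_a = (a["or_folded"], -a["p"], -a["pos"])
            if key_b > key_a:
                dominated = True
                break
        if not dominated:
            out.append(a["snp_id"])
    return sorted(out)


class TestSelectIndexSnps:
    def test_single_subthreshold_snp(self):
        rec = ss.validate_gwas(
            pd.DataFrame(
                {
                    "snp_id": ["rs1", "rs2"],
                    "chrom": "1",
                    "pos": [500_000, 600_000],
                    "effect_allele": "A",
                    "other_allele": "G",
                    "or_raw": [1.3, 1.5],
                    "p": [1e-5, 0.5],  # rs2 fails the subthreshold filter
                }
            )
        )
        loci = lm.select_index_snps(rec)
        assert len(loci) == 1
        row = loci.iloc[0]
        assert row["index_snp"] == "rs1"
        assert (row["start"], row["end"]) == (400_000, 600_000)
        assert row["end"] - row["start"] + 1 == 200_001
        assert row["member_snps"] == ["rs1"]

    def test_three_snp_dominance_pattern(self):
        # ORs 1.30 @ 0k, 1.25 @ 50k, 1.28 @ 150k: middle SNP dominated by
        # both neighbors -> two overlapping loci
        rec = ss.validate_gwas(
            pd.DataFrame(
                {
                    "snp_id": ["a", "b", "c"],
                    "chrom": "1",
                    "pos": [1_000_000, 1_050_000, 1_150_000],
                    "effect_allele": "A",
                    "other_allele": "G",
                    "or_raw": [1.30, 1.25, 1.28],
                    "p": [1e-4] * 3,
                }
            )
        )
        loci = lm.select_index_snps(rec)
        assert sorted(loci["index_snp"]) == ["a", "c"]
        assert len(loci) == 2  # overlapping loci are retained

    def test_window_arithmetic_at_realistic_coordinates(self):
        # an index SNP at chr10:104,856,100 spans 104,756,100-104,956,100
        rec = ss.validate_gwas(
            pd.DataFrame(
                {
                    "snp_id": ["rs77593808"],
                    "chrom": "10",
                    "pos": [104_856_100],
                    "effect_allele": "A",
                    "other_allele": "G",
                    "or_raw": [1.21],
                    "p": [1.55e-5],
                }
            )
        )
        loci = lm.select_index_snps(rec)
        assert loci.iloc[0]["locus_id"] == "10:104756100-104956100"

    def test_empty_after_filter(self, rng):
        rec = random_sumstats(rng, n=20)
        rec = rec[rec["p"] > 0.5]
        assert len(lm.select_index_snps(rec)) == 0

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        for rep in range(25):
            rec = random_sumstats(rng, n=150, span=1_500_000)
            got = sorted(lm.select_index_snps(rec)["index_snp"])
            assert got == brute_force_index_snps(rec), f"replicate {rep}"

    def test_every_subthreshold_snp_covered_or_dominated(self):
        rng = np.random.default_rng(9)
        rec = random_sumstats(rng, n=300)
        loci = lm.select_index_snps(rec)
        sub = rec[rec["p"] < 1e-3]
        members = set(itertools.chain.from_iterable(loci["member_snps"]))
        by_id = sub.set_index("snp_id")
        for snp_id, row in by_id.iterrows():
            if snp_id in members:
                continue
            near = sub[
                (sub["chrom"] == row["chrom"])
                & (abs(sub["pos"] - row["pos"]) <= 100_000)
            ]
            assert (near["or_folded"] > row["or_folded"]).any()


class TestAnnotateKnown:
    def make_loci(self, positions, chrom="1"):
        return pd.DataFrame(
            {
                "locus_id": [f"L{i}" for i in range(len(positions))],
                "chrom": chrom,
                "start": [p - 100_000 for p in positions],
                "end": [p + 100_000 for p in positions],
            }
        )

    def test_exact_match_overlaps(self):
        loci = self.make_loci([1_000_000])
        known = pd.DataFrame({"chrom": ["1"], "start": [900_000], "end": [1_100_000]})
        out, counts = lm.annotate_known_loci(loci, known)
        assert out["known_overlap"].all()
        assert counts == {"overlapping": 1, "novel": 0}

    def test_margin_boundary(self):
        loci = self.make_loci([1_000_000])
        near = pd.DataFrame({"chrom": ["1"], "start": [1_599_999], "end": [1_700_000]})
        far = pd.DataFrame({"chrom": ["1"], "start": [1_600_001], "end": [1_700_000]})
        assert lm.annotate_known_loci(loci, near)[0]["known_overlap"].all()
        assert not lm.annotate_known_loci(loci, far)[0]["known_overlap"].any()

    def test_matches_quadratic_oracle(self, rng):
        loci = self.make_loci(rng.integers(200_000, 5_000_000, size=40).tolist())
        known = pd.DataFrame(
            {
                "chrom": "1",
                "start": rng.integers(1, 5_000_000, size=15),
            }
        )
        known["end"] = known["start"] + rng.integers(1000, 400_000, size=15)
        out, counts = lm.annotate_known_loci(loci, known, margin=500_000)
        margin = 500_000
        expected = [
            any(
                ls - margin <= ke and le + margin >= ks
                for ks, ke in zip(known["start"], known["end"])
            )
            for ls, le in zip(loci["start"], loci["end"])
        ]
        assert out["known_overlap"].tolist() == expected


class TestMapGenes:
    genes = pd.DataFrame(
        {
            "gene_id": ["inside", "edge_out", "far", "rna"],
            "chrom": "1",
            "start": [1_010_000, 1_100_001, 3_000_000, 1_020_000],
            "end": [1_050_000, 1_200_000, 3_100_000, 1_030_000],
            "biotype": ["protein_coding", "protein_coding", "protein_coding", "lincRNA"],
        }
    )
    locus = {"chrom": "1", "start": 1_000_000, "end": 1_100_000}

    def test_overlap_mode(self):
        got = lm.map_genes(self.locus, self.genes, mode="overlap")
        assert got == ["inside"]  # 1 bp outside excluded; non-coding excluded

    def test_within_distance_mode(self):
        got = lm.map_genes(self.locus, self.genes, mode="within_distance",
                           distance=1_900_000)
        assert got == ["inside", "edge_out", "far"]

    def test_matches_interval_oracle(self, rng):
        genes = pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(60)],
                "chrom": "1",
                "start": rng.integers(1, 3_000_000, size=60),
                "biotype": "protein_coding",
            }
        )
        genes["end"] = genes["start"] + rng.integers(100, 300_000, size=60)
        got = lm.map_genes(self.locus, genes, mode="overlap")
        expected = [
            g["gene_id"]
            for _, g in genes.iterrows()
            if g["start"] <= self.locus["end"] and g["end"] >= self.locus["start"]
        ]
        assert got == expected


class TestFisherEnrichment:
    def test_extreme_table(self):
        res = lm.fisher_enrichment({"a", "b"}, {"a", "b"}, {"a", "b", "c", "d"})
        assert res.odds_ratio == np.inf
        assert res.p_value < 1.0

    def test_disjoint_gene_set_p_one(self):
        with pytest.warns(UserWarning, match="disjoint"):
            res = lm.fisher_enrichment({"a"}, {"x"}, {"a", "b"})
        assert res.p_value == 1.0

    def test_empty_background_error(self):
        with pytest.raises(ValueError, match="background"):
            lm.fisher_enrichment(set(), set(), set())

    def test_against_hypergeometric_enumeration(self):
        # p from summing hypergeometric pmf over all tables at most as
        # probable as the observed one (margins fixed)
        def enum_p(a, b, c, d):
            n = a + b + c + d
            row1, col1 = a + b, a + c
            p_obs = stats.hypergeom.pmf(a, n, row1, col1)
            total = 0.0
            for x in range(max(0, row1 + col1 - n), min(row1, col1) + 1):
                px = stats.hypergeom.pmf(x, n, row1, col1)
                if px <= p_obs * (1 + 1e-9):
                    total += px
            return min(total, 1.0)

        background = {f"g{i}" for i in range(300)}
        hits = {f"g{i}" for i in range(10)}
        gene_set = {f"g{i}" for i in range(5, 15)}
        res = lm.fisher_enrichment(hits, gene_set, background)
        (a, b), (c, d) = res.table
        assert (a, b, c, d) == (5, 5, 5, 285)
        assert res.p_value == pytest.approx(enum_p(a, b, c, d), rel=1e-9)

    def test_transpose_symmetry(self):
        _, p1 = stats.fisher_exact([[5, 5], [5, 285]])
        _, p2 = stats.fisher_exact([[5, 5], [5, 285]][::-1])
        res = lm.fisher_enrichment(
            {f"g{i}" for i in range(10)},
            {f"g{i}" for i in range(5, 15)},
            {f"g{i}" for i in range(300)},
        )
        assert res.p_value == pytest.approx(p1) == pytest.approx(p2)


class TestCorrelateRegionOr:
    def test_collinear(self):
        loci = pd.DataFrame(
            {"max_or_folded": [1.0, 1.1, 1.2, 1.3],
             "p_region": 10.0 ** -(np.array([1.0, 1.1, 1.2, 1.3]) * 10)}
        )
        r, p, n = lm.correlate_region_or(loci)
        assert r == pytest.approx(1.0)
        assert n == 4

    def test_too_few_loci(self):
        loci = pd.DataFrame({"max_or_folded": [1.0, 1.1], "p_region": [0.5, 0.01]})
        with pytest.raises(ValueError, match="at least 3"):
            lm.correlate_region_or(loci)

    def test_planted_coupling_positive(self):
        # monotone OR -> signal coupling yields positive correlation
        from riskloci import region as rg
        from riskloci import simulate as si

        pos_count = 0
        for rep in range(20):
            rng = np.random.default_rng(rep)
            panel = si.simulate_ld_panel(150, 12, rho=0.6, seed=rep)
            rows = []
            for lam_target in (1.0, 2.5, 4.0, 5.5, 7.0):
                snp = panel.snp_ids[6]
                z, rec = si.simulate_gwas_z(panel, {snp: lam_target},
                                            seed=int(rng.integers(2**31)))
                ld = rg.ld_matrix(panel, panel.snp_ids)
                S = rg.region_statistic(z, ld)
                rows.append(
                    {"max_or_folded": np.exp(abs(lam_target) * 0.05),
                     "p_region": rg.region_pvalue(S, ld)}
                )
            r, _, _ = lm.correlate_region_or(pd.DataFrame(rows))
            pos_count += r > 0
        assert pos_count >= 17


class TestBedExport:
    def test_zero_based_half_open(self, tmp_path):
        loci = pd.DataFrame(
            {"locus_id": ["L1"], "chrom": ["1"], "start": [101], "end": [300]}
        )
        lm.loci_to_bed(loci, tmp_path / "l.bed")
        line = (tmp_path / "l.bed").read_text().strip().split("\t")
        assert line[1] == "100" and line[2] == "300"
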