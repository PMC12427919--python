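"""Region assignment, binding-density enrichment, motif scans, intersections."""

import numpy as np
import pytest

from translight.enrichment import (
    BindingSite,
    GeneModel,
    GenomicInterval,
    RegionIndex,
    assign_region,
    categorize_rbps,
    density_enrichment,
    intersection_counts,
    rbps_bound_to_genes,
    scan_au_rich,
    scan_pyrimidine_rich,
)
from translight.synthetic import synth_eclip, synth_gene_models


def toy_model(gene="G1", strand="+", offset=0):
    """5'UTR [0,100), CDS [100,400)+[500,800), intron [400,500), 3'UTR [800,1200)."""
    gm = GeneModel(gene, f"{gene}.1", "chr1", strand)
    o = offset
    gm.regions = {
        "five_prime_utr": [(o + 0, o + 100)],
        "cds": [(o + 100, o + 400), (o + 500, o + 800)],
        "intron": [(o + 400, o + 500)],
        "three_prime_utr": [(o + 800, o + 1200)],
    }
    return gm


def site(start, end, strand="+", rbp="R", chrom="chr1"):
    return BindingSite(rbp, GenomicInterval(chrom, start, end, strand))


class TestAssignRegion:
    def test_site_inside_three_prime_utr(self):
        models = {"G1": toy_model()}
        assert assign_region(site(900, 950), models) == ("three_prime_utr", "G1")

    def test_maximal_overlap_wins(self):
        # 30 nt of CDS vs 80 nt of intron -> intron
        models = {"G1": toy_model()}
        assert assign_region(site(370, 480), models) == ("intron", "G1")

    def test_opposite_strand_is_intergenic(self):
        models = {"G1": toy_model(strand="+")}
        assert assign_region(site(900, 950, strand="-"), models) == ("intergenic", None)

    def test_tie_break_prefers_three_prime_utr(self):
        # 50 nt in CDS and 50 nt in 3'UTR on a model where they touch
        gm = GeneModel("G2", "G2.1", "chr1", "+")
        gm.regions = {"cds": [(0, 100)], "three_prime_utr": [(100, 200)]}
        assert assign_region(site(50, 150), {"G2": gm}) == ("three_prime_utr", "G2")

    def test_malformed_interval_rejected(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 10, 10)

    def test_translation_invariance(self):
        sites = [site(50, 90), site(370, 480), site(810, 1100), site(1500, 1600)]
        labels0 = [assign_region(s, {"G1": toy_model()})[0] for s in sites]
        shift = 10_000
        moved = [
            site(s.interval.start + shift, s.interval.end + shift) for s in sites
        ]
        labels1 = [
            assign_region(s, {"G1": toy_model(offset=shift)})[0] for s in moved
        ]
        assert labels0 == labels1
        assert labels0[-1] == "intergenic"


class TestRbpsBoundToGenes:
    def test_hand_enumerated_distinct_count(self):
        # 3 RBPs bind G1, 2 bind G2, one shared -> 4 distinct
        models = {"G1": toy_model("G1"), "G2": toy_model("G2", offset=5000)}
        sites = [
            site(900, 950, rbp="A"), site(150, 200, rbp="B"), site(50, 80, rbp="C"),
            site(5900, 5950, rbp="A"), site(5150, 5200, rbp="D"),
        ]
        bound, count = rbps_bound_to_genes(sites, ["G1", "G2"], models)
        assert bound == {"G1": {"A", "B", "C"}, "G2": {"A", "D"}}
        assert count == 4

    def test_duplicate_sites_collapse(self):
        models = {"G1": toy_model()}
        sites = [site(900, 950, rbp="A")] * 3
        bound, count = rbps_bound_to_genes(sites, ["G1"], models)
        assert bound["G1"] == {"A"} and count == 1

    def test_no_sites_and_unknown_gene(self):
        models = {"G1": toy_model()}
        with pytest.warns(UserWarning, match="unknown gene"):
            bound, count = rbps_bound_to_genes([], ["G1", "NOPE"], models)
        assert bound == {"G1": set()} and count == 0


def ten_gene_models():
    """Ten genes, each with a 10 kb 3'UTR (100 kb total)."""
    models = {}
    for i in range(10):
        gid = f"G{i}"
        gm = GeneModel(gid, f"{gid}.1", "chr1", "+")
        base = i * 20_000
        gm.regions = {
            "cds": [(base, base + 300)],
            "three_prime_utr": [(base + 300, base + 10_300)],
        }
        models[gid] = gm
    return models


class TestDensityEnrichment:
    def test_self_comparison_is_flat(self):
        models = ten_gene_models()
        sites = [site(i * 20_000 + 400 + j, i * 20_000 + 440 + j)
                 for i in range(10) for j in range(0, 50, 10)]
        res = density_enrichment(sites, list(models), models)
        assert np.allclose(res["fold"], 1.0)
        assert np.allclose(res["p"], 1.0)

    def test_worked_fold_arithmetic(self):
        # 20 sites in the 10 kb DE 3'UTR, 50 sites / 100 kb overall -> fold 4
        models = ten_gene_models()
        sites = [site(400 + 50 * j, 440 + 50 * j, rbp="R") for j in range(20)]
        sites += [site(20_000 * i + 400 + 50 * j, 20_000 * i + 440 + 50 * j, rbp="R")
                  for i in range(1, 4) for j in range(10)]
        res = density_enrichment(sites, ["G0"], models).set_index("rbp")
        assert res.loc["R", "n_sites_de"] == 20
        assert res.loc["R", "n_sites_bg"] == 50
        assert res.loc["R", "fold"] == pytest.approx(4.0)

    def test_zero_de_sites(self):
        models = ten_gene_models()
        sites = [site(20_400, 20_440, rbp="R")]
        res = density_enrichment(sites, ["G0"], models).set_index("rbp")
        assert res.loc["R", "fold"] == 0.0 and res.loc["R", "p"] == 1.0

    def test_empty_de_genes_rejected(self):
        with pytest.raises(ValueError):
            density_enrichment([], [], ten_gene_models())

    def test_planted_fold_recovered_on_synthetic_sites(self):
        models = synth_gene_models(150, seed=21)
        rbps = [f"R{i}" for i in range(10)]
        de = sorted(models)[:15]
        sites, _ = synth_eclip(
            models, rbps, background_density=4.0, de_genes=de,
            enriched_rbps={"R0": 3.0}, seed=22,
        )
        res = density_enrichment(sites, de, models).set_index("rbp")
        assert 2.25 <= res.loc["R0", "fold"] <= 3.75
        assert res.loc["R0", "p_adj"] < 0.05


class TestMotifScans:
    def test_au_rich_examples(self):
        assert scan_au_rich("AUUUA") == (1, True)
        assert scan_au_rich("GCGCGC") == (0, False)
        assert scan_au_rich("AUUUAUUUA") == (2, True)  # overlap at 0 and 4
        assert scan_au_rich("ATTTA") == (1, True)      # DNA alphabet accepted

    def test_pyrimidine_examples(self):
        assert scan_pyrimidine_rich("U" * 20) == (1.0, True)
        assert scan_pyrimidine_rich("G" * 20) == (0.0, False)
        frac, pos = scan_pyrimidine_rich("C" * 16 + "G" * 4)
        assert frac == pytest.approx(0.8) and pos

    def test_errors(self):
        with pytest.raises(ValueError):
            scan_au_rich("")
        with pytest.raises(ValueError):
            scan_au_rich("AXU")
        with pytest.raises(ValueError):
            scan_pyrimidine_rich("ACGU", window=20)

    def test_oracle_equivalence_on_random_sequences(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            seq = "".join(rng.choice(list("ACGU"), size=200))
            n_naive = sum(seq[i : i + 5] == "AUUUA" for i in range(len(seq) - 4))
            assert scan_au_rich(seq)[0] == n_naive
            fr_naive = max(
                sum(ch in "CU" for ch in seq[i : i + 20]) / 20
                for i in range(len(seq) - 19)
            )
            assert scan_pyrimidine_rich(seq)[0] == pytest.approx(fr_naive)


class TestIntersections:
    def test_printed_two_set_structure(self):
        universe = set(range(31))
        a = set(range(21))                      # 21 elements
        b = set(range(8, 26))                   # 18 elements, overlap 13
        counts = intersection_counts({"pyr": a, "au": b}, universe)
        assert counts[frozenset({"pyr", "au"})] == 13
        assert counts[frozenset({"pyr"})] == 8
        assert counts[frozenset({"au"})] == 5
        assert counts[frozenset()] == 5

    def test_disjoint_and_nested(self):
        u = set(range(10))
        c = intersection_counts({"a": {0, 1}, "b": {5, 6}}, u)
        assert frozenset({"a", "b"}) not in c
        c = intersection_counts({"a": {0, 1}, "b": {0, 1, 2}}, u)
        assert frozenset({"a"}) not in c        # A subset of B -> no A-only
        assert c[frozenset({"a", "b"})] == 2

    def test_counts_sum_to_universe(self):
        rng = np.random.default_rng(5)
        u = set(range(100))
        sets = {f"s{i}": set(rng.choice(100, rng.integers(0, 60))) for i in range(4)}
        counts = intersection_counts(sets, u)
        assert sum(counts.values()) == 100

    def test_element_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            intersection_counts({"a": {99}}, {1, 2})


class TestGtfRoundTrip:
    def test_models_survive_write_and_read(self, tmp_path):
        from translight.enrichment import read_gtf_models
        from translight.io import write_gtf

        models = synth_gene_models(20, seed=31)
        path = tmp_path / "genes.gtf"
        write_gtf(models, path)
        back = read_gtf_models(str(path))
        assert set(back) == set(models)
        for gid, gm in models.items():
            rt = back[gid]
            assert (rt.chrom, rt.strand) == (gm.chrom, gm.strand)
            for region in ("five_prime_utr", "cds", "three_prime_utr", "intron"):
                assert rt.region_length(region) == gm.region_length(region)


class TestCategories:
    def test_default_table_assignments(self):
        df = categorize_rbps(["G3BP1", "DDX6", "RBM15", "NOVEL1"]).set_index("rbp")
        assert df.loc["G3BP1", "stress_granule"]
        assert df.loc["DDX6", "p_body"]
        assert df.loc["RBM15", "m6a_reader"]
        assert df.loc["NOVEL1", "uncategorized"]

    def test_empty_list(self):
        assert len(categorize_rbps([])) == 0
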