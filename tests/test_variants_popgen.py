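"""Filtering, heterozygosity windows, allele-frequency profiles, IUPAC
encoding, p-distances and neighbor joining."""

import numpy as np
import pandas as pd
import pytest

from hybridtriad import synthetic_data as sd
from hybridtriad.variants_popgen import (
    AlleleFrequencyProfile, FilterPolicy, VariantTable, allele_frequency_profile,
    encode_iupac_matrix, filter_variants, heterozygosity_windows,
    neighbor_joining, object_table, p_distance_matrix, tree_path_lengths,
    ParameterError)


def toy_table(rows, samples, ploidy=None, contigs=None):
    """rows: list of (chrom, pos, ref, alts, qual, [(gt, ad, dp) per sample])."""
    sites = pd.DataFrame([r[:5] for r in rows],
                         columns=["chrom", "pos", "ref", "alts", "qual"])
    gt = object_table([[c[0] for c in r[5]] for r in rows], len(samples))
    ad = object_table([[c[1] for c in r[5]] for r in rows], len(samples))
    dp = (np.array([[c[2] for c in r[5]] for r in rows], dtype=int)
          if rows else np.empty((0, len(samples)), int))
    return VariantTable(sites=sites, samples=samples, gt=gt, ad=ad, dp=dp,
                       ploidy=ploidy or {s: 2 for s in samples},
                       contig_lengths=contigs or {})


class TestFilterVariants:
    def test_low_qual_site_dropped_via_missingness(self):
        t = toy_table([
            ("c", 10, "A", ("G",), 19.0, [((0, 1), (10, 10), 20)] * 2),
            ("c", 20, "A", ("G",), 50.0, [((0, 1), (10, 10), 20)] * 2),
        ], ["s1", "s2"])
        out = filter_variants(t, FilterPolicy(min_maf=0.0))
        assert list(out.sites["pos"]) == [20]

    def test_dp_bounds_mask_genotypes(self):
        t = toy_table([
            ("c", 10, "A", ("G",), 99.0,
             [((0, 1), (5, 4), 9), ((0, 1), (200, 201), 401)]),
        ], ["lo", "hi"])
        out = filter_variants(t, FilterPolicy(min_maf=0.0,
                                              max_missing_fraction=1.0))
        assert out.gt[0, 0] is None and out.gt[0, 1] is None

    def test_toy_policy_application(self):
        """10 biallelic-ish sites: one with MAF 0.01-like minor allele, one
        triallelic; both drop, leaving 8."""
        good = [((0, 1), (10, 10), 20)] * 25
        rows = [("c", 10 * (i + 1), "A", ("G",), 99.0, list(good))
                for i in range(8)]
        # site 9: minor allele once in 50 alleles (MAF 0.02 boundary -> keep
        # at exactly 0.02, so use 1/50 = 0.02... make it 0/50 + one het)
        rare = [((0, 0), (20, 0), 20)] * 24 + [((0, 1), (10, 10), 20)]
        rows.append(("c", 90, "A", ("G",), 99.0, rare))  # MAF 1/50 = 0.02 keeps; lower it
        rows[-1] = ("c", 90, "A", ("G",), 99.0,
                    [((0, 0), (20, 0), 20)] * 25)  # MAF 0 -> dropped
        rows.append(("c", 100, "A", ("G", "T"), 99.0, list(good)))  # triallelic
        t = toy_table(rows, [f"s{i}" for i in range(25)])
        out = filter_variants(t)
        assert out.n_sites == 8

    def test_permissive_policy_is_identity(self, variant_table):
        policy = FilterPolicy(min_qual=0, min_dp=1, max_dp=10**9, min_maf=0.0,
                              max_missing_fraction=1.0, biallelic_only=False)
        out = filter_variants(variant_table, policy)
        assert out.n_sites == variant_table.n_sites

    def test_idempotent(self, variant_table):
        once = filter_variants(variant_table)
        twice = filter_variants(once)
        assert once.n_sites == twice.n_sites
        pd.testing.assert_frame_equal(once.sites, twice.sites)
        assert all((once.gt[i, s] == twice.gt[i, s])
                   or (once.gt[i, s] is None and twice.gt[i, s] is None)
                   for i in range(once.n_sites) for s in range(3))

    def test_invalid_policy_rejected(self):
        with pytest.raises(ParameterError):
            FilterPolicy(min_dp=500, max_dp=400).validate()

    def test_empty_table_passes_through(self):
        t = toy_table([], ["s"])
        assert filter_variants(t).n_sites == 0


class TestHeterozygosityWindows:
    def test_per_snp_ratio(self):
        recs = [("c", i + 1, "A", ("G",), 99.0,
                 [((0, 1) if i < 3 else (0, 0), (10, 10), 20)])
                for i in range(100)]
        t = toy_table(recs, ["s"], contigs={"c": 1000})
        track = heterozygosity_windows(t, window_bp=1000)
        assert track.loc[0, "value"] == pytest.approx(0.03)
        assert track.loc[0, "n_snps"] == 100 and track.loc[0, "n_het"] == 3

    def test_empty_window_is_missing_not_zero(self):
        t = toy_table([("c", 5, "A", ("G",), 99.0, [((0, 1), (10, 10), 20)])],
                      ["s"], contigs={"c": 2000})
        track = heterozygosity_windows(t, window_bp=1000)
        assert len(track) == 2
        assert np.isnan(track.loc[1, "value"])

    def test_per_bp_mode(self):
        t = toy_table([("c", 5, "A", ("G",), 99.0, [((0, 1), (10, 10), 20)])],
                      ["s"], contigs={"c": 1000})
        track = heterozygosity_windows(t, window_bp=1000, mode="per_bp")
        assert track.loc[0, "value"] == pytest.approx(1 / 1000)

    def test_recovers_planted_het_density(self, two_lineages, hybrid,
                                          variant_table):
        track = heterozygosity_windows(variant_table, window_bp=100_000)
        hyb = track[track["sample"] == "hybrid"]
        # every retained site is heterozygous in the hybrid by construction
        assert hyb["value"].iloc[0] == pytest.approx(1.0)
        # and per_bp density matches the direct haplotype comparison
        per_bp = heterozygosity_windows(variant_table, window_bp=100_000,
                                        mode="per_bp")
        hyb_bp = per_bp[per_bp["sample"] == "hybrid"]["value"].iloc[0]
        direct = len(sd.hybrid_het_sites(two_lineages, hybrid)) / 100_000
        assert hyb_bp == pytest.approx(direct)

    def test_bad_window_rejected(self, variant_table):
        with pytest.raises(ParameterError):
            heterozygosity_windows(variant_table, window_bp=0)


class TestAlleleFrequencyProfile:
    def test_equal_depths_give_half(self):
        t = toy_table([("c", 1, "A", ("G",), 99.0, [((0, 1), (10, 10), 20)])],
                      ["s"])
        prof = allele_frequency_profile(t, "s")
        assert prof.fractions[0] == pytest.approx(0.5)

    def test_haploid_modal_frequency_is_one(self, variant_table):
        prof = allele_frequency_profile(variant_table, "L1")
        assert prof.modal_frequency == pytest.approx(1.0)

    def test_diploid_modal_frequency_is_half(self, variant_table):
        prof = allele_frequency_profile(variant_table, "hybrid")
        assert prof.modal_frequency == pytest.approx(0.5)
        assert len(prof.fractions) >= 1000

    def test_zero_depth_site_skipped(self):
        t = toy_table([("c", 1, "A", ("G",), 99.0, [((0, 1), (0, 0), 0)]),
                       ("c", 2, "A", ("G",), 99.0, [((0, 1), (10, 10), 20)])],
                      ["s"])
        prof = allele_frequency_profile(t, "s")
        assert prof.n_skipped == 1 and len(prof.fractions) == 1

    def test_histogram_mass_equals_site_count(self, variant_table):
        prof = allele_frequency_profile(variant_table, "hybrid")
        assert prof.histogram.sum() == len(prof.fractions)


class TestIupacEncoding:
    def test_codes(self):
        t = toy_table([
            ("c", 1, "G", ("T",), 99.0, [((0, 1), (10, 10), 20),
                                         ((0, 0), (20, 0), 20),
                                         (None, (0, 0), 0)]),
        ], ["het", "hom", "mis"])
        m = encode_iupac_matrix(t)
        assert m.loc["het"].iloc[0] == "K"
        assert m.loc["hom"].iloc[0] == "G"
        assert m.loc["mis"].iloc[0] == "N"

    def test_indel_sites_skipped(self):
        t = toy_table([("c", 1, "GT", ("G",), 99.0, [((0, 1), (10, 10), 20)]),
                       ("c", 2, "A", ("C",), 99.0, [((0, 1), (10, 10), 20)])],
                      ["s"])
        m = encode_iupac_matrix(t)
        assert m.shape[1] == 1


class TestPDistance:
    def test_examples(self):
        m = pd.DataFrame([list("ACGT"), list("ACGT"), list("ACGA"),
                          list("ACGK")], index=list("wxyz"))
        d = p_distance_matrix(m)
        assert d.loc["w", "x"] == 0
        assert d.loc["w", "y"] == pytest.approx(0.25)
        # degenerate K vs T compared as literal symbols -> mismatch
        assert d.loc["w", "z"] == pytest.approx(0.25)

    def test_n_excluded_and_nan_for_no_overlap(self):
        m = pd.DataFrame([["A", "N"], ["N", "C"]], index=["a", "b"])
        d = p_distance_matrix(m)
        assert np.isnan(d.loc["a", "b"])
        with pytest.raises(ParameterError):
            neighbor_joining(pd.DataFrame(
                [[0, np.nan, 1], [np.nan, 0, 1], [1, 1, 0]],
                index=list("abc"), columns=list("abc")))

    def test_properties(self, variant_table):
        m = encode_iupac_matrix(filter_variants(variant_table))
        d = p_distance_matrix(m)
        assert np.allclose(d, d.T, atol=1e-12)
        assert (np.diag(d) == 0).all()
        assert ((d.to_numpy() >= 0) & (d.to_numpy() <= 1)).all()


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        d = pd.DataFrame([[0, 0.2, 0.3], [0.2, 0, 0.4], [0.3, 0.4, 0]],
                         index=list("abc"), columns=list("abc"), dtype=float)
        pl = tree_path_lengths(neighbor_joining(d))
        # closed form: la=0.05, lb=0.15, lc=0.25
        assert pl.loc["a", "b"] == pytest.approx(0.2)
        assert pl.loc["a", "c"] == pytest.approx(0.3)
        assert pl.loc["b", "c"] == pytest.approx(0.4)

    def test_four_taxon_additive_recovery(self):
        # tree ((a:1,b:2):3,(c:4,d:5)) -> additive distances
        d = pd.DataFrame([[0, 3, 8, 9], [3, 0, 9, 10], [8, 9, 0, 9],
                          [9, 10, 9, 0]], index=list("abcd"),
                         columns=list("abcd"), dtype=float)
        pl = tree_path_lengths(neighbor_joining(d))
        for i in "abcd":
            for j in "abcd":
                if i != j:
                    assert pl.loc[i, j] == pytest.approx(d.loc[i, j], abs=1e-9)

    def test_topology_vs_exhaustive_quartets(self):
        """On additive data the (ab|cd) quartet must be recovered: the a-b
        path shares no edge with c-d, so d(a,b)+d(c,d) < the two alternative
        pairings (four-point condition checked directly on the NJ tree)."""
        d = pd.DataFrame([[0, 3, 8, 9], [3, 0, 9, 10], [8, 9, 0, 9],
                          [9, 10, 9, 0]], index=list("abcd"),
                         columns=list("abcd"), dtype=float)
        pl = tree_path_lengths(neighbor_joining(d))
        s_ab = pl.loc["a", "b"] + pl.loc["c", "d"]
        s_ac = pl.loc["a", "c"] + pl.loc["b", "d"]
        s_ad = pl.loc["a", "d"] + pl.loc["b", "c"]
        assert s_ab < s_ac and s_ab < s_ad and s_ac == pytest.approx(s_ad)

    def test_matches_skbio_on_random_additive_matrix(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(0)
        # random additive matrix from a random tree via random splits
        n = 6
        labels = [f"t{i}" for i in range(n)]
        base = rng.uniform(0.1, 1.0, size=(n, n))
        d = (base + base.T) / 2
        np.fill_diagonal(d, 0)
        dm = pd.DataFrame(d, index=labels, columns=labels)
        ours = tree_path_lengths(neighbor_joining(dm))
        ref = skbio.tree.nj(skbio.DistanceMatrix(d, ids=labels))
        for i in labels:
            for j in labels:
                if i != j:
                    assert ours.loc[i, j] == pytest.approx(
                        ref.find(i).distance(ref.find(j)), abs=1e-9)

    def test_tie_break_is_deterministic(self):
        d = pd.DataFrame(0.5 * (1 - np.eye(4)), index=list("abcd"),
                         columns=list("abcd"))
        nwk1 = neighbor_joining(d)
        nwk2 = neighbor_joining(d)
        assert nwk1 == nwk2
        assert nwk1.startswith("((a:")  # lexicographically smallest pair first

    def test_two_clades_resolved(self, four_lineage_panel):
        vt = sd.simulate_variant_table(
            four_lineage_panel, {k: k for k in four_lineage_panel.genomes},
            depth=30, seed=17)
        m = encode_iupac_matrix(filter_variants(vt))
        nwk = neighbor_joining(p_distance_matrix(m))
        pl = tree_path_lengths(nwk)
        # within-clade path lengths must undercut every between-clade one
        within = [pl.loc["L1", "L2"], pl.loc["L3", "L4"]]
        between = [pl.loc[a, b] for a in ("L1", "L2") for b in ("L3", "L4")]
        assert max(within) < min(between)
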