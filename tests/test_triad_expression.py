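"""TMM/CPM/FPKM, differential tests, homoeolog bias, triad categories,
ASE rules and the cis/trans partition."""

import subprocess

import numpy as np
import pandas as pd
import pytest

from hybridtriad import synthetic_data as sd
from hybridtriad import triad_expression as te


def _naive_tmm_factor(obs, ref, lib_obs, lib_ref):
    """Independent brute-force trim-and-weight estimator (reference path)."""
    from scipy.stats import rankdata
    keep = (obs > 0) & (ref > 0)
    o, r = obs[keep].astype(float), ref[keep].astype(float)
    m = np.log2((o / lib_obs) / (r / lib_ref))
    a = 0.5 * np.log2((o / lib_obs) * (r / lib_ref))
    if np.allclose(m, 0, atol=1e-10):
        return 1.0
    n = len(m)
    lo_m = np.floor(n * 0.3) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * 0.05) + 1
    hi_a = n + 1 - lo_a
    rm, ra = rankdata(m), rankdata(a)
    sel = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    w = 1.0 / ((lib_obs - o) / (lib_obs * o) + (lib_ref - r) / (lib_ref * r))
    return 2.0 ** (np.sum(w[sel] * m[sel]) / np.sum(w[sel]))


def triad_from_means(p1, p2, h, reps=3, noise=0.02, seed=0, lengths=None,
                     n_background=200):
    """Tiny count matrix with near-deterministic counts around given means.

    Background genes with identical means across roles keep library sizes
    comparable so TMM/CPM normalization does not distort the toy genes.
    """
    rng = np.random.default_rng(seed)
    genes = [f"g{i}" for i in range(len(p1))]
    if n_background:
        genes += [f"bg{i}" for i in range(n_background)]
        if lengths is not None:
            lengths = list(lengths) + [1000] * n_background
        p1 = list(p1) + [100] * n_background
        p2 = list(p2) + [100] * n_background
        h = list(h) + [100] * n_background
    cols, sheet = {}, []
    for r in range(reps):
        for role, mu in (("parent1", p1), ("parent2", p2), ("hybrid", h)):
            s = f"{role}_r{r + 1}"
            cols[s] = np.maximum(
                rng.normal(np.asarray(mu, float), noise * np.asarray(mu, float)),
                0).round().astype(int)
            if r == 0:
                pass
    counts = pd.DataFrame(cols, index=genes)
    sheet = pd.DataFrame(
        [(c, c.rsplit("_", 1)[0], int(c[-1]), "default") for c in counts.columns],
        columns=["sample", "role", "replicate", "condition"])
    hyb_cols = [c for c in counts.columns if c.startswith("hybrid")]
    a = (counts[hyb_cols] * 0.5).round().astype(int)
    return te.TriadCountMatrix(
        counts=counts, sample_sheet=sheet, homoeolog_a=a,
        homoeolog_b=counts[hyb_cols] - a,
        gene_lengths=pd.Series(lengths if lengths is not None else 1000,
                               index=genes))


class TestTmm:
    def test_pure_library_scaling_gives_unit_factors(self):
        rng = np.random.default_rng(1)
        a = rng.poisson(100, 300).astype(float) + 1
        counts = pd.DataFrame({"A": a, "B": 2 * a})
        norm = te.tmm_normalize(counts)
        assert np.allclose(norm.tmm_factors, 1.0)
        assert np.allclose(norm.cpm["A"], norm.cpm["B"])

    def test_matches_naive_estimator(self):
        rng = np.random.default_rng(2)
        counts = pd.DataFrame(rng.negative_binomial(10, 0.05, size=(400, 3)),
                              columns=list("ABC")).astype(float) + 1
        counts.iloc[0, 1] *= 10  # one strongly DE gene
        norm = te.tmm_normalize(counts, ref_sample="A")
        lib = counts.sum(axis=0)
        raw = {"A": 1.0}
        for s in "BC":
            raw[s] = _naive_tmm_factor(counts[s].to_numpy(), counts["A"].to_numpy(),
                                       lib[s], lib["A"])
        f = pd.Series(raw)
        f /= np.exp(np.mean(np.log(f)))
        for s in "ABC":
            assert norm.tmm_factors[s] == pytest.approx(f[s], rel=1e-9)

    def test_matches_edger_calcnormfactors(self, tmp_path):
        rng = np.random.default_rng(3)
        counts = pd.DataFrame(rng.negative_binomial(20, 0.09, size=(200, 4)),
                              columns=list("ABCD")).astype(float)
        counts["B"] *= 2
        counts.iloc[0, 2] *= 10
        norm = te.tmm_normalize(counts)
        csv = tmp_path / "c.tsv"
        counts.to_csv(csv, sep="\t")
        rfile = tmp_path / "t.R"
        rfile.write_text(
            "suppressMessages(library(edgeR))\n"
            f"x <- read.delim('{csv}', row.names=1)\n"
            "f <- calcNormFactors(as.matrix(x), method='TMM')\n"
            "cat(round(f, 8))\n")
        res = subprocess.run(["Rscript", str(rfile)], capture_output=True,
                             text=True, check=True)
        ref = [float(x) for x in res.stdout.split()]
        assert np.allclose(norm.tmm_factors.to_numpy(), ref, atol=1e-6)

    def test_scale_invariance_of_cpm(self):
        """Scaling one sample's counts moves only its factor and leaves CPMs
        (nearly) unchanged; the invariance is approximate because the
        precision weights of the M-value mean depend on absolute library
        sizes (edgeR behaves identically)."""
        rng = np.random.default_rng(4)
        counts = pd.DataFrame(rng.poisson(50, size=(200, 3)),
                              columns=list("ABC")).astype(float) + 1
        base = te.tmm_normalize(counts, ref_sample="A")
        scaled = counts.copy()
        scaled["B"] *= 7
        other = te.tmm_normalize(scaled, ref_sample="A")
        assert np.allclose(base.cpm, other.cpm, rtol=2e-3)

    def test_single_shared_gene_falls_back_with_warning(self):
        counts = pd.DataFrame({"A": [10, 0, 5], "B": [8, 3, 0]}, dtype=float)
        with pytest.warns(UserWarning, match="single shared gene"):
            norm = te.tmm_normalize(counts, ref_sample="A")
        assert norm.tmm_factors["B"] == pytest.approx(1.0)

    def test_disjoint_samples_rejected(self):
        counts = pd.DataFrame({"A": [10, 0], "B": [0, 3]}, dtype=float)
        with pytest.raises(te.ParameterError, match="B"):
            te.tmm_normalize(counts, ref_sample="A")


class TestFpkm:
    @pytest.mark.parametrize("cpm,length,expected",
                             [(100.0, 1000, 100.0), (100.0, 500, 200.0),
                              (0.0, 1000, 0.0)])
    def test_values(self, cpm, length, expected):
        norm = te.NormalizedExpression(
            cpm=pd.DataFrame({"s1": [cpm], "s2": [cpm]}, index=["g"]),
            tmm_factors=pd.Series({"s1": 1.0, "s2": 1.0}),
            library_sizes=pd.Series({"s1": 1e6, "s2": 1e6}))
        out = te.fpkm(norm, pd.Series({"g": length}))
        assert out.fpkm.loc["g", "s1"] == pytest.approx(expected)

    def test_missing_length_excluded_with_warning(self):
        norm = te.NormalizedExpression(
            cpm=pd.DataFrame({"s1": [1.0, 2.0], "s2": [1.0, 2.0]},
                             index=["g1", "g2"]),
            tmm_factors=pd.Series({"s1": 1.0, "s2": 1.0}),
            library_sizes=pd.Series({"s1": 1e6, "s2": 1e6}))
        with pytest.warns(UserWarning, match="lack a length"):
            out = te.fpkm(norm, pd.Series({"g1": 500}))
        assert list(out.fpkm.index) == ["g1"]


class TestDeTest:
    def test_identical_groups_not_significant(self):
        g = pd.DataFrame([[10.0, 11.0, 9.0]] * 5)
        res = te.de_test(g, g)
        assert (res["log2fc"] == 0).all()
        assert not res["significant"].any()

    def test_zero_variance_cases(self):
        eq = te.de_test(np.array([[5.0, 5.0, 5.0]]), np.array([[5.0, 5.0, 5.0]]))
        assert eq["p"].iloc[0] == 1.0 and not eq["degenerate"].iloc[0]
        ne = te.de_test(np.array([[5.0, 5.0, 5.0]]), np.array([[9.0, 9.0, 9.0]]))
        assert ne["p"].iloc[0] == 0.0 and ne["degenerate"].iloc[0]

    def test_power_at_planted_fourfold_effect(self):
        rng = np.random.default_rng(5)
        G, n_eff = 2000, 400
        mu1 = np.full(G, 200.0)
        mu2 = mu1.copy()
        mu2[:n_eff] *= 4
        nb = lambda mu: rng.negative_binomial(20, 20 / (20 + mu))
        g1 = pd.DataFrame(np.column_stack([nb(mu1) for _ in range(3)]))
        g2 = pd.DataFrame(np.column_stack([nb(mu2) for _ in range(3)]))
        res = te.de_test(g1, g2)
        assert res["significant"][:n_eff].mean() >= 0.9
        assert res["significant"][n_eff:].mean() <= 0.01

    def test_too_few_replicates_rejected(self):
        with pytest.raises(te.ParameterError):
            te.de_test(np.array([[1.0]]), np.array([[2.0]]))


class TestHomoeologBias:
    def test_fourfold_pair_is_dominant_toward_a(self):
        tcm = triad_from_means([100] * 20, [100] * 20, [200] * 20, seed=6)
        tcm.homoeolog_a.iloc[0] = 160
        tcm.homoeolog_b.iloc[0] = 40
        res = te.homoeolog_bias(tcm)
        assert res.per_gene["direction"].iloc[0] == "A"
        assert res.per_gene["log2_ratio"].iloc[0] == pytest.approx(2.0, abs=0.1)

    def test_planted_bias_recovery(self, triad_sim):
        cfg, tcm, _, truth = triad_sim
        res = te.homoeolog_bias(tcm)
        tt = truth.triad_truth.set_index("gene")
        called = res.per_gene[res.per_gene["dominant"]]
        truth_dir = np.where(tt["bias_log2"] > 0, "A",
                             np.where(tt["bias_log2"] < 0, "B", "unbiased"))
        truth_dir = pd.Series(truth_dir, index=tt.index)
        biased = truth_dir[truth_dir != "unbiased"]
        hits = called.index.intersection(biased.index)
        sensitivity = len(hits) / len(biased.index.intersection(res.per_gene.index))
        fdr = 1 - len(hits) / max(len(called), 1)
        assert sensitivity >= 0.9
        assert fdr <= 0.1
        assert (called.loc[hits, "direction"] == biased.loc[hits]).all()

    def test_balanced_simulation_has_no_global_bias(self):
        import warnings
        flags = []
        for seed in range(8):
            tcm, _, _ = sd.simulate_triad_counts(sd.TriadSimConfig(
                n_genes=400, seed=200 + seed, homoeolog_bias_fraction=0.0,
                category_proportions={"Additive": 1.0}))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                flags.append(te.homoeolog_bias(tcm).global_p > 0.05)
        assert np.mean(flags) >= 0.75


class TestClassifyTriads:
    def test_constructed_categories(self):
        tcm = triad_from_means(
            p1=[100, 50, 50, 100, 100, 400],
            p2=[100, 150, 150, 100, 100, 25600],
            h=[400, 100, 150, 100, 6, 2200],
            seed=7)
        cls = te.classify_triads(tcm)
        cats = list(cls.per_gene["category"])
        assert cats[0] == "TUR"
        assert cls.per_gene["tur_subtype"].iloc[0] == "NDE-TUR"
        assert cats[1] == "Additive"   # exact mid-parent
        assert cats[2] == "ELD_P2"     # matches parent2, differs from parent1
        assert cats[3] == "Additive"
        assert cats[4] == "TDR"
        assert cats[5] == "UC"         # between distant parents, off mid

    def test_categories_exhaustive_and_exclusive(self, triad_sim):
        _, tcm, _, _ = triad_sim
        cls = te.classify_triads(tcm)
        assert cls.per_gene["category"].isin(te.TRIAD_CATEGORIES).all()
        assert cls.counts().sum() + cls.n_excluded == len(tcm.counts)

    def test_confusion_matrix_diagonal(self, triad_sim):
        _, tcm, _, truth = triad_sim
        cls = te.classify_triads(tcm)
        tt = truth.triad_truth.set_index("gene")
        cm = pd.crosstab(tt["category"], cls.per_gene["category"])
        for cat in te.TRIAD_CATEGORIES:
            assert cm.loc[cat, cat] / cm.loc[cat].sum() >= 0.9, cat

    def test_label_swap_equivariance(self, triad_sim):
        _, tcm, _, _ = triad_sim
        swapped_sheet = tcm.sample_sheet.copy()
        swapped_sheet["role"] = swapped_sheet["role"].map(
            {"parent1": "parent2", "parent2": "parent1", "hybrid": "hybrid"})
        tcm2 = te.TriadCountMatrix(counts=tcm.counts, sample_sheet=swapped_sheet,
                                   homoeolog_a=tcm.homoeolog_a,
                                   homoeolog_b=tcm.homoeolog_b,
                                   gene_lengths=tcm.gene_lengths)
        a = te.classify_triads(tcm).per_gene["category"]
        b = te.classify_triads(tcm2).per_gene["category"]
        swap = {"ELD_P1": "ELD_P2", "ELD_P2": "ELD_P1"}
        assert (b == a.map(lambda c: swap.get(c, c))).mean() > 0.99

    def test_null_mostly_additive_and_tur_fpr_bounded(self):
        tcm, _, _ = sd.simulate_triad_counts(sd.TriadSimConfig(
            n_genes=2000, seed=9, category_proportions={"Additive": 1.0},
            homoeolog_bias_fraction=0.0))
        cls = te.classify_triads(tcm, alpha=0.05)
        frac_add = (cls.per_gene["category"] == "Additive").mean()
        assert frac_add >= 0.95
        tur_rate = (cls.per_gene["category"] == "TUR").mean()
        assert tur_rate <= 0.05 ** 2 + 0.005


class TestSelectTurHeatmapGenes:
    def test_hand_built_gate(self):
        # 10 NDE-TUR-like genes with hand-set FPKM via gene lengths
        p1 = [100] * 10
        h = [100 * f for f in (8, 8, 3, 8, 8, 8, 8, 8, 2, 16)]
        tcm = triad_from_means(p1, p1, h, seed=10,
                               lengths=[1000] * 8 + [1000, 1000])
        cls = te.classify_triads(tcm)
        norm = te.fpkm(cls.norm, tcm.gene_lengths)
        # force FPKM of g1 under the floor by a huge length
        tcm.gene_lengths["g1"] = 10_000_000
        norm = te.fpkm(cls.norm, tcm.gene_lengths)
        sel = te.select_tur_heatmap_genes(cls, norm, tcm, min_fpkm=5.0,
                                          min_log2fc=2.0)
        pg = cls.per_gene
        nde = set(pg.index[(pg["category"] == "TUR")
                           & (pg["tur_subtype"] == "NDE-TUR")])
        hyb = norm.fpkm[tcm.samples_for("hybrid")].mean(axis=1)
        par = np.maximum(norm.fpkm[tcm.samples_for("parent1")].mean(axis=1),
                         norm.fpkm[tcm.samples_for("parent2")].mean(axis=1))
        expected = {g for g in nde
                    if hyb[g] > 5.0 and np.log2(hyb[g] / par[g]) > 2.0}
        assert set(sel.index) == expected
        assert "g1" not in sel.index          # FPKM floor
        assert "g2" not in sel.index          # log2FC gate (3x < 4x)
        assert (sel["log2fc"].diff().dropna() <= 0).all()  # sorted descending


def build_ase(gene, n_p1, n_p2, n_conflict, n_single=0):
    rows = []
    rid = 0
    for _ in range(n_p1):
        rows += [(f"{gene}r{rid}", gene, f"s{i}", "A", "P1") for i in range(2)]
        rid += 1
    for _ in range(n_p2):
        rows += [(f"{gene}r{rid}", gene, f"s{i}", "A", "P2") for i in range(2)]
        rid += 1
    for _ in range(n_conflict):
        rows += [(f"{gene}r{rid}", gene, "s0", "A", "P1"),
                 (f"{gene}r{rid}", gene, "s1", "A", "P2")]
        rid += 1
    for _ in range(n_single):
        rows += [(f"{gene}r{rid}", gene, "s0", "A", "P1")]
        rid += 1
    return rows


class TestSummarizeAse:
    def test_threshold_arithmetic(self):
        obs = pd.DataFrame(
            build_ase("gPass", 15, 10, 2) + build_ase("gFew", 12, 7, 0)
            + build_ase("gConf", 20, 10, 4),
            columns=["read_id", "gene", "site", "allele", "parent_match"])
        res = te.summarize_ase(obs).per_gene
        assert bool(res.loc["gPass", "passed"])
        assert res.loc["gPass", "ratio"] == pytest.approx(0.6)
        assert not res.loc["gFew", "passed"]      # 19 < 20 assigned reads
        assert not res.loc["gConf", "passed"]     # 4/34 = 11.8% >= 10%

    def test_single_site_reads_uninformative(self):
        obs = pd.DataFrame(build_ase("g", 20, 5, 0, n_single=30),
                           columns=["read_id", "gene", "site", "allele",
                                    "parent_match"])
        res = te.summarize_ase(obs).per_gene
        assert res.loc["g", "n_uninformative"] == 30
        assert res.loc["g", "n_p1"] == 20

    def test_min_snps_flag_relaxable(self):
        obs = pd.DataFrame(build_ase("g", 10, 10, 0, n_single=10),
                           columns=["read_id", "gene", "site", "allele",
                                    "parent_match"])
        res = te.summarize_ase(obs, min_snps_per_read=1).per_gene
        assert res.loc["g", "n_p1"] + res.loc["g", "n_p2"] == 30

    def test_assigned_plus_conflicting_partition(self, triad_sim):
        _, _, ase, _ = triad_sim
        res = te.summarize_ase(ase.head(50_000)).per_gene
        per_read = ase.head(50_000).groupby(["gene", "read_id"]).size()
        informative = (per_read >= 2).groupby("gene").sum()
        total = (res["n_p1"] + res["n_p2"] + res["n_conflicting"])
        assert (total == informative.reindex(total.index)).all()


class TestCisTrans:
    @staticmethod
    def summary_from_counts(genes, n1, n2):
        per = pd.DataFrame({"n_p1": n1, "n_p2": n2, "n_conflicting": 0,
                            "n_uninformative": 0}, index=genes)
        per["passed"] = True
        per["ratio"] = per["n_p1"] / (per["n_p1"] + per["n_p2"])
        return te.AseGeneSummary(per_gene=per)

    def test_identity_cis_plus_trans_equals_parental(self):
        rng = np.random.default_rng(11)
        genes = [f"g{i}" for i in range(50)]
        ase = self.summary_from_counts(genes, rng.integers(10, 90, 50),
                                       rng.integers(10, 90, 50))
        p1 = pd.DataFrame(rng.poisson(100, (50, 3)), index=genes)
        p2 = pd.DataFrame(rng.poisson(150, (50, 3)), index=genes)
        ct = te.cis_trans_partition(ase, p1, p2)
        assert np.allclose(ct["cis"] + ct["trans"], ct["parental_log2"],
                           atol=1e-12)

    def test_ratios_agree_is_cis_only(self):
        genes = ["g"]
        ase = self.summary_from_counts(genes, [80], [20])
        rng = np.random.default_rng(12)
        p1 = pd.DataFrame(rng.poisson(400, (1, 3)), index=genes)
        p2 = pd.DataFrame(rng.poisson(100, (1, 3)), index=genes)
        ct = te.cis_trans_partition(ase, p1, p2)
        assert ct["category"].iloc[0] == "cis-only"
        assert abs(ct["trans"].iloc[0]) < 0.5

    def test_equalized_hybrid_is_trans_only(self):
        genes = ["g"]
        ase = self.summary_from_counts(genes, [50], [50])
        rng = np.random.default_rng(13)
        p1 = pd.DataFrame(rng.poisson(400, (1, 3)), index=genes)
        p2 = pd.DataFrame(rng.poisson(100, (1, 3)), index=genes)
        ct = te.cis_trans_partition(ase, p1, p2)
        assert ct["category"].iloc[0] == "trans-only"

    def test_class_recovery_on_planted_simulation(self):
        rng = np.random.default_rng(14)
        G = 300
        cats = np.array(["cis-only"] * 90 + ["trans-only"] * 90
                        + ["conserved"] * 120)
        p1mu = np.full(G, 200.0)
        p2mu = np.full(G, 200.0)
        theta = np.full(G, 0.5)
        p2mu[cats == "cis-only"] = 50
        theta[cats == "cis-only"] = 0.8
        p2mu[cats == "trans-only"] = 50
        genes = [f"g{i}" for i in range(G)]
        n1 = rng.binomial(100, theta)
        ase = self.summary_from_counts(genes, n1, 100 - n1)
        p1 = pd.DataFrame(rng.poisson(p1mu[:, None], (G, 3)), index=genes)
        p2 = pd.DataFrame(rng.poisson(p2mu[:, None], (G, 3)), index=genes)
        ct = te.cis_trans_partition(ase, p1, p2)
        for cat in ("cis-only", "trans-only", "conserved"):
            mask = cats == cat
            assert (ct["category"][mask] == cat).mean() >= 0.85, cat

    def test_swapping_parents_negates_components(self):
        rng = np.random.default_rng(15)
        genes = [f"g{i}" for i in range(30)]
        n1 = rng.integers(20, 80, 30)
        ase_f = self.summary_from_counts(genes, n1, 100 - n1)
        ase_r = self.summary_from_counts(genes, 100 - n1, n1)
        p1 = pd.DataFrame(rng.poisson(300, (30, 3)), index=genes)
        p2 = pd.DataFrame(rng.poisson(100, (30, 3)), index=genes)
        fwd = te.cis_trans_partition(ase_f, p1, p2)
        rev = te.cis_trans_partition(ase_r, p2, p1)
        assert np.allclose(fwd["cis"], -rev["cis"], atol=1e-12)
        assert np.allclose(fwd["trans"], -rev["trans"], atol=1e-9)


class TestSyntheticDiploidReference:
    def test_concatenation_and_tags(self):
        p1 = pd.DataFrame({"gene": [f"a{i}" for i in range(100)]})
        p2 = pd.DataFrame({"gene": [f"b{i}" for i in range(100)]})
        joint = te.build_synthetic_diploid_reference(p1, p2)
        assert len(joint) == 200
        assert (joint["subgenome"].value_counts() == 100).all()

    def test_duplicate_ids_rejected(self):
        p1 = pd.DataFrame({"gene": ["x", "x"]})
        p2 = pd.DataFrame({"gene": ["y"]})
        with pytest.raises(te.ParameterError, match="duplicate"):
            te.build_synthetic_diploid_reference(p1, p2)

    def test_truth_pairing_is_bijective(self):
        p1 = pd.DataFrame({"gene": ["a1", "a2"]})
        p2 = pd.DataFrame({"gene": ["b1", "b2"]})
        pairing = pd.DataFrame({"gene1": ["a1", "a2"], "gene2": ["b1", "b2"]})
        joint = te.build_synthetic_diploid_reference(p1, p2, pairing=pairing)
        hom = joint.set_index("gene")["homoeolog"].dropna()
        assert len(hom) == 4
        assert (hom[hom.map(hom)] .index == hom.map(hom)).all()

    def test_reciprocal_best_pairing_at_two_percent_divergence(self,
                                                               two_lineages):
        rng = np.random.default_rng(16)
        # carve 20 "CDS" pairs out of the two diverged haplotypes
        a = two_lineages.genomes["L1"]["chr1"]
        b = two_lineages.genomes["L2"]["chr1"]
        cds1 = {f"a{i}": a[i * 2000:(i * 2000) + 900] for i in range(20)}
        cds2 = {f"b{i}": b[i * 2000:(i * 2000) + 900] for i in range(20)}
        p1 = pd.DataFrame({"gene": list(cds1)})
        p2 = pd.DataFrame({"gene": list(cds2)})
        joint = te.build_synthetic_diploid_reference(p1, p2, cds1=cds1,
                                                     cds2=cds2)
        hom = joint.set_index("gene")["homoeolog"].dropna()
        for i in range(20):
            assert hom[f"A|a{i}"] == f"B|b{i}"
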