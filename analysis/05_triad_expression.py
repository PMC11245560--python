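"""Triad expression analysis: TMM/CPM/FPKM normalization, homoeolog bias,
additive/nonadditive classification with the NDE-TUR split, the heatmap gene
gate, allele-specific read rules, and the cis/trans partition — all compared
against the planted truth.
"""

import argparse
from pathlib import Path

import pandas as pd

from hybridtriad import synthetic_data as sd
from hybridtriad import triad_expression as te


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--data-dir", type=Path, default=Path("results/data"))
    ap.add_argument("--out-dir", type=Path, default=Path("results/triad"))
    args = ap.parse_args()
    out = args.out_dir
    out.mkdir(parents=True, exist_ok=True)

    tcm = te.TriadCountMatrix(
        counts=pd.read_csv(args.data_dir / "triad_counts.tsv", sep="\t",
                           index_col=0),
        sample_sheet=pd.read_csv(args.data_dir / "sample_sheet.tsv", sep="\t"),
        homoeolog_a=pd.read_csv(args.data_dir / "homoeolog_a.tsv", sep="\t",
                                index_col=0),
        homoeolog_b=pd.read_csv(args.data_dir / "homoeolog_b.tsv", sep="\t",
                                index_col=0),
        gene_lengths=pd.read_csv(args.data_dir / "gene_lengths.tsv", sep="\t",
                                 index_col=0)["length"])
    truth = sd.TruthSet.from_json((args.data_dir / "truth.json").read_text())
    tt = truth.triad_truth.set_index("gene")

    cls = te.classify_triads(tcm, alpha=0.05, min_abs_log2fc=1.0)
    norm = te.fpkm(cls.norm, tcm.gene_lengths)
    cls.per_gene.to_csv(out / "triad_classification.tsv", sep="\t")
    counts = cls.counts()
    print("triad categories :",
          ", ".join(f"{c}={n}" for c, n in counts.items()))
    cm = pd.crosstab(tt["category"], cls.per_gene["category"])
    cm.to_csv(out / "confusion_matrix.tsv", sep="\t")
    diag = {c: cm.loc[c, c] / cm.loc[c].sum() for c in cm.index}
    print("recovery vs truth:",
          ", ".join(f"{c}={v:.2f}" for c, v in diag.items()))

    bias = te.homoeolog_bias(tcm)
    bias.per_gene.to_csv(out / "homoeolog_bias.tsv", sep="\t")
    print(f"homoeolog bias   : {bias.n_dominant_a} dominant-A, "
          f"{bias.n_dominant_b} dominant-B, {bias.n_unbiased} unbiased "
          f"(global p = {bias.global_p:.3f})")

    sel = te.select_tur_heatmap_genes(cls, norm, tcm, min_fpkm=5.0,
                                      min_log2fc=2.0)
    sel.to_csv(out / "tur_heatmap_genes.tsv", sep="\t")
    nde = ((cls.per_gene["category"] == "TUR")
           & (cls.per_gene["tur_subtype"] == "NDE-TUR")).sum()
    print(f"NDE-TUR genes    : {nde}; heatmap gate (FPKM>5, log2FC>2) keeps "
          f"{len(sel)}")

    ase_obs = pd.read_csv(args.data_dir / "ase_observations.tsv", sep="\t")
    ase = te.summarize_ase(ase_obs, min_snps_per_read=2, min_reads=20,
                           max_conflict_fraction=0.10)
    ase.per_gene.to_csv(out / "ase_summary.tsv", sep="\t")
    print(f"ASE gene gate    : {int(ase.per_gene['passed'].sum())}/"
          f"{len(ase.per_gene)} genes pass (>=20 reads, <10% conflict)")

    ct = te.cis_trans_partition(
        ase, cls.norm.cpm[tcm.samples_for("parent1")],
        cls.norm.cpm[tcm.samples_for("parent2")], alpha=0.05)
    ct.to_csv(out / "cis_trans.tsv", sep="\t")
    print("cis/trans classes:",
          ", ".join(f"{c}={n}" for c, n in
                    ct["category"].value_counts().items()))
    print(f"outputs in {out}")


if __name__ == "__main__":
    main()
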