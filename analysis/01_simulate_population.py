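"""Simulate the study population: four haploid lineages in two clades, a
diploid hybrid between clades, genotype tables, triad expression counts and a
GO annotation — all with serialized ground truth.

Writes FASTA genomes, a multi-sample VCF, count/ASE/annotation TSVs and
truth.json under results/data/.  Every later analysis step reads these files.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from hybridtriad import synthetic_data as sd

WITHIN, BETWEEN = 0.005, 0.02


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out-dir", type=Path, default=Path("results/data"))
    args = ap.parse_args()
    out = args.out_dir
    out.mkdir(parents=True, exist_ok=True)

    w, d = WITHIN, BETWEEN
    lin = sd.simulate_lineages(sd.LineageSimConfig(
        n_chromosomes=2, chrom_length=250_000,
        divergence_matrix=[[0, w, d, d], [w, 0, d, d],
                           [d, d, 0, w], [d, d, w, 0]], seed=args.seed))
    hybrid = sd.make_hybrid(lin, sd.HybridSimConfig(
        "L1", "L3", novel_mutation_rate=1e-5, seed=args.seed + 1))

    sd.write_fasta(lin.ancestor, out / "ancestor.fa")
    for lid, chroms in lin.genomes.items():
        sd.write_fasta(chroms, out / f"{lid}.fa")
    sd.write_fasta(hybrid.all_sequences(), out / "hybrid.fa")

    table = sd.simulate_variant_table(
        lin, {**{k: k for k in lin.genomes}, "hybrid": hybrid},
        depth=50, seed=args.seed + 2)
    table.write_vcf(out / "variants.vcf")

    tcm, ase, triad_truth = sd.simulate_triad_counts(
        sd.TriadSimConfig(n_genes=2000, seed=args.seed + 3))
    tcm.counts.to_csv(out / "triad_counts.tsv", sep="\t")
    tcm.sample_sheet.to_csv(out / "sample_sheet.tsv", sep="\t", index=False)
    tcm.homoeolog_a.to_csv(out / "homoeolog_a.tsv", sep="\t")
    tcm.homoeolog_b.to_csv(out / "homoeolog_b.tsv", sep="\t")
    tcm.gene_lengths.to_frame().to_csv(out / "gene_lengths.tsv", sep="\t")
    ase.to_csv(out / "ase_observations.tsv", sep="\t", index=False)

    tur_genes = triad_truth.triad_truth.loc[
        triad_truth.triad_truth["category"] == "TUR", "gene"].tolist()
    ann, go_truth = sd.simulate_go_annotation(
        n_genes=2000, n_terms=60, term_size_range=(15, 80),
        spiked_terms=[("GO:0000001", 12.0), ("GO:0000002", 8.0)],
        selected_genes=tur_genes, seed=args.seed + 4)
    ann.to_csv(out / "annotation.tsv", sep="\t", index=False)

    truth = sd.TruthSet()
    for t in (lin.truth, hybrid.truth, triad_truth, go_truth):
        truth.merge(t)
    (out / "truth.json").write_text(truth.to_json())

    prov = hybrid.truth.variant_provenance
    print(f"lineages      : {', '.join(lin.genomes)} "
          f"(within-clade {w:.1%}, between-clade {d:.1%})")
    print(f"hybrid        : L1 x L3 diploid, "
          f"{len(sd.hybrid_het_sites(lin, hybrid))} heterozygous sites, "
          f"{(prov['origin'] == 'novel').sum()} novel alleles")
    print(f"variant table : {table.n_sites} sites x {len(table.samples)} samples")
    print(f"triad counts  : {tcm.counts.shape[0]} genes, "
          f"{tcm.counts.shape[1]} libraries; ASE rows {len(ase)}")
    print(f"outputs in {out}")


if __name__ == "__main__":
    main()
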