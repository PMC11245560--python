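"""End-to-end pipeline: simulate -> ploidy -> popgen -> parentage/subgenomes
-> triad classification -> enrichment.

Plain files-in-directories execution: every stage reads its inputs from and
writes its outputs into the run directory, and a ``manifest.json`` records
the configuration, seeds, per-stage row counts and SHA-256 checksums of every
output, so a rerun with an identical config is byte-identical and verifiable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import synthetic_data as sd
from . import variants_popgen as vp
from . import kmer_ploidy as kp
from . import hybrid_origin as ho
from . import triad_expression as te
from . import enrichment as en

logger = logging.getLogger(__name__)

STAGES = ("simulate", "ploidy", "popgen", "parentage", "triad", "enrich")
_DEPS = {
    "simulate": (),
    "ploidy": ("simulate",),
    "popgen": ("simulate",),
    "parentage": ("simulate",),
    "triad": ("simulate",),
    "enrich": ("simulate", "triad"),
}


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """All pipeline parameters, defaulting to the study's printed thresholds
    (k = 17 spectra, 100-kb heterozygosity windows, 2-fold dominance, >= 2
    SNPs per allele-specific read, >= 20 reads, < 10% conflict, alpha 0.05,
    heatmap gate FPKM > 5 and log2FC > 2) at desk-scale simulation sizes."""

    seed: int = 1
    # simulation
    n_chromosomes: int = 2
    chrom_length: int = 150_000
    divergence: float = 0.02
    novel_mutation_rate: float = 1e-5
    read_depth: int = 60
    read_length: int = 150
    variant_depth: int = 50
    n_genes: int = 1000
    n_replicates: int = 3
    # analysis thresholds (the study's printed values)
    kmer_k: int = 17
    het_window_bp: int = 100_000
    identity_window_bp: int = 500
    alpha: float = 0.05
    min_abs_log2fc: float = 1.0
    min_snps_per_read: int = 2
    min_ase_reads: int = 20
    max_conflict_fraction: float = 0.10
    heatmap_min_fpkm: float = 5.0
    heatmap_min_log2fc: float = 2.0
    stages: tuple = STAGES

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        if "stages" in data:
            data = {**data, "stages": tuple(data["stages"])}
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _closure(stages) -> list[str]:
    wanted = set(stages)
    changed = True
    while changed:
        changed = False
        for s in list(wanted):
            for dep in _DEPS[s]:
                if dep not in wanted:
                    wanted.add(dep)
                    changed = True
    return [s for s in STAGES if s in wanted]


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute the requested stages (plus dependencies) and return the
    manifest dict (also written to ``out_dir/manifest.json``)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = _closure(config.stages)
    manifest = {"config": {**asdict(config), "stages": list(stages)},
                "package_version": __import__("hybridtriad").__version__,
                "stages": {}}
    t0 = time.time()
    state: dict = {}
    for stage in stages:
        t = time.time()
        outputs = _RUNNERS[stage](config, out, state)
        manifest["stages"][stage] = {
            "outputs": {name: {"sha256": _sha256(p), "path": p.name}
                        for name, p in outputs.items()},
            "rows": {name: _row_count(p) for name, p in outputs.items()},
        }
        logger.info("stage %s finished in %.1fs", stage, time.time() - t)
    logger.info("pipeline finished in %.1fs", time.time() - t0)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _row_count(path: Path) -> int:
    if path.suffix in (".tsv", ".vcf", ".fa", ".fasta", ".nwk", ".json"):
        return sum(1 for _ in open(path))
    return -1


# ---------------------------------------------------------------------------
# stage runners
# ---------------------------------------------------------------------------

def _stage_simulate(cfg: PipelineConfig, out: Path, state: dict) -> dict:
    lin_cfg = sd.LineageSimConfig(
        n_chromosomes=cfg.n_chromosomes, chrom_length=cfg.chrom_length,
        divergence_matrix=[[0.0, cfg.divergence], [cfg.divergence, 0.0]],
        seed=cfg.seed)
    lineages = sd.simulate_lineages(lin_cfg)
    hybrid = sd.make_hybrid(lineages, sd.HybridSimConfig(
        parent_a_id="L1", parent_b_id="L2",
        novel_mutation_rate=cfg.novel_mutation_rate, seed=cfg.seed + 1))
    table = sd.simulate_variant_table(
        lineages, {"L1": "L1", "L2": "L2", "hybrid": hybrid},
        depth=cfg.variant_depth, seed=cfg.seed + 2)
    tcm, ase, triad_truth = sd.simulate_triad_counts(sd.TriadSimConfig(
        n_genes=cfg.n_genes, n_replicates=cfg.n_replicates, seed=cfg.seed + 3))
    selected = [f"g{i:05d}" for i in range(200)]
    ann, go_truth = sd.simulate_go_annotation(
        n_genes=cfg.n_genes, n_terms=50, term_size_range=(10, 60),
        spiked_terms=[("GO:0000001", 10.0)], selected_genes=selected,
        seed=cfg.seed + 4)

    state.update(lineages=lineages, hybrid=hybrid, table=table, tcm=tcm,
                 ase=ase, triad_truth=triad_truth, annotation=ann)
    outputs = {}
    for lid, chroms in lineages.genomes.items():
        p = out / f"{lid}.fa"
        sd.write_fasta(chroms, p)
        outputs[f"genome_{lid}"] = p
    p = out / "hybrid.fa"
    sd.write_fasta(hybrid.all_sequences(), p)
    outputs["genome_hybrid"] = p
    p = out / "variants.vcf"
    table.write_vcf(p)
    outputs["variants"] = p
    p = out / "triad_counts.tsv"
    tcm.counts.to_csv(p, sep="\t")
    outputs["triad_counts"] = p
    p = out / "ase_observations.tsv"
    ase.to_csv(p, sep="\t", index=False)
    outputs["ase_observations"] = p
    p = out / "annotation.tsv"
    ann.to_csv(p, sep="\t", index=False)
    outputs["annotation"] = p
    p = out / "truth.json"
    truth = sd.TruthSet()
    truth.merge(lineages.truth)
    truth.merge(hybrid.truth)
    truth.merge(triad_truth)
    truth.merge(go_truth)
    p.write_text(truth.to_json())
    outputs["truth"] = p
    return outputs


def _stage_ploidy(cfg: PipelineConfig, out: Path, state: dict) -> dict:
    hybrid = state["hybrid"]
    reads = sd.simulate_reads([hybrid.haplotypes["A"], hybrid.haplotypes["B"]],
                              depth=cfg.read_depth, read_length=cfg.read_length,
                              seed=cfg.seed + 10)
    spectrum = kp.count_kmers(reads, k=cfg.kmer_k)
    peaks = kp.detect_peaks(spectrum)
    call = kp.call_ploidy(peaks)
    p = out / "kmer_spectrum.tsv"
    spectrum.write_tsv(p)
    p2 = out / "ploidy_call.json"
    p2.write_text(json.dumps({
        "call": call.call,
        "peaks": [[pk.position, pk.height] for pk in call.peaks],
        "peak_position_ratio": call.peak_position_ratio,
    }, indent=2, sort_keys=True))
    return {"kmer_spectrum": p, "ploidy_call": p2}


def _stage_popgen(cfg: PipelineConfig, out: Path, state: dict) -> dict:
    table = vp.filter_variants(state["table"], vp.FilterPolicy())
    het = vp.heterozygosity_windows(table, window_bp=cfg.het_window_bp)
    p1 = out / "heterozygosity.tsv"
    het.to_csv(p1, sep="\t", index=False)
    profs = {s: vp.allele_frequency_profile(table, s) for s in table.samples}
    p2 = out / "allele_frequency_modes.tsv"
    pd.DataFrame({"sample": list(profs), "modal_frequency":
                  [pr.modal_frequency for pr in profs.values()]}
                 ).to_csv(p2, sep="\t", index=False)
    outputs = {"heterozygosity": p1, "af_modes": p2}
    if len(table.samples) >= 3:
        mat = vp.encode_iupac_matrix(table)
        dm = vp.p_distance_matrix(mat)
        p3 = out / "p_distance.tsv"
        dm.to_csv(p3, sep="\t")
        newick = vp.neighbor_joining(dm)
        p4 = out / "nj_tree.nwk"
        p4.write_text(newick + "\n")
        outputs.update(p_distance=p3, nj_tree=p4)
    state["filtered_table"] = table
    return outputs


def _stage_parentage(cfg: PipelineConfig, out: Path, state: dict) -> dict:
    lineages, hybrid = state["lineages"], state["hybrid"]
    het = sd.hybrid_het_sites(lineages, hybrid)
    cand = pd.DataFrame({
        lid: [_lineage_allele(lineages, lid, r.chrom, r.pos)
              for r in het.itertuples(index=False)]
        for lid in lineages.genomes})
    diag = ho.classify_diagnostic_snps(het, cand)
    ranking = ho.score_parental_pairs(diag)
    p1 = out / "parental_pair_scores.tsv"
    ranking.as_frame().to_csv(p1, sep="\t", index=False)
    p2 = out / "diagnostic_class_counts.tsv"
    diag["site_class"].value_counts().rename_axis("class").to_frame("n").to_csv(
        p2, sep="\t")
    part = ho.assign_subgenomes(
        hybrid.all_sequences(),
        lineages.genomes[hybrid.parent_a], lineages.genomes[hybrid.parent_b],
        parent_names=(hybrid.parent_a, hybrid.parent_b))
    p3 = out / "subgenome_partition.tsv"
    part.table.to_csv(p3, sep="\t", index=False)
    return {"pair_scores": p1, "diagnostic_classes": p2, "subgenomes": p3}


def _lineage_allele(lineages, lid, chrom, pos):
    return lineages.truth.lineage_mutations[lid].get((chrom, pos),
                                                     lineages.ancestor[chrom][pos])


def _stage_triad(cfg: PipelineConfig, out: Path, state: dict) -> dict:
    tcm = state["tcm"]
    cls = te.classify_triads(tcm, alpha=cfg.alpha, min_abs_log2fc=cfg.min_abs_log2fc)
    norm = te.fpkm(cls.norm, tcm.gene_lengths)
    p1 = out / "triad_classification.tsv"
    cls.per_gene.to_csv(p1, sep="\t")
    bias = te.homoeolog_bias(tcm, alpha=cfg.alpha)
    p2 = out / "homoeolog_bias.tsv"
    bias.per_gene.to_csv(p2, sep="\t")
    sel = te.select_tur_heatmap_genes(cls, norm, tcm,
                                      min_fpkm=cfg.heatmap_min_fpkm,
                                      min_log2fc=cfg.heatmap_min_log2fc)
    p3 = out / "tur_heatmap_genes.tsv"
    sel.to_csv(p3, sep="\t")
    ase = te.summarize_ase(state["ase"], min_snps_per_read=cfg.min_snps_per_read,
                           min_reads=cfg.min_ase_reads,
                           max_conflict_fraction=cfg.max_conflict_fraction)
    p4 = out / "ase_summary.tsv"
    ase.per_gene.to_csv(p4, sep="\t")
    ct = te.cis_trans_partition(
        ase, cls.norm.cpm[tcm.samples_for("parent1")],
        cls.norm.cpm[tcm.samples_for("parent2")], alpha=cfg.alpha)
    p5 = out / "cis_trans.tsv"
    ct.to_csv(p5, sep="\t")
    state["classification"] = cls
    state["tur_selection"] = sel
    return {"classification": p1, "bias": p2, "tur_heatmap": p3,
            "ase_summary": p4, "cis_trans": p5}


def _stage_enrich(cfg: PipelineConfig, out: Path, state: dict) -> dict:
    ann = state["annotation"]
    cls = state["classification"]
    pg = cls.per_gene
    tur = set(pg.index[pg["category"] == "TUR"])
    universe = set(ann["gene"]) & set(pg.index)
    p = out / "enrichment.tsv"
    if tur & universe:
        table = en.hypergeom_enrich(tur & universe, ann, universe)
    else:
        table = pd.DataFrame(columns=["N", "K", "n", "k", "fold", "p", "padj"])
    table.to_csv(p, sep="\t")
    return {"enrichment": p}


_RUNNERS = {
    "simulate": _stage_simulate,
    "ploidy": _stage_ploidy,
    "popgen": _stage_popgen,
    "parentage": _stage_parentage,
    "triad": _stage_triad,
    "enrich": _stage_enrich,
}
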