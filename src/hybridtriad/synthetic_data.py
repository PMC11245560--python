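"""Synthetic genomes, reads, genotype tables and triad count matrices.

Every input the pipeline consumes can be simulated here with a known ground
truth, so each downstream stage is testable end to end:

* :func:`simulate_lineages` draws an ancestral genome and derives diverged
  haploid lineages from it (star topology, substitution-only), optionally with
  chromosomal fusion and fission events (dysploidy).
* :func:`make_hybrid` merges two lineage genomes into a diploid hybrid carrying
  one haplotype from each parent plus novel post-hybridization mutations.
* :func:`simulate_reads` draws error-prone uniform shotgun reads from one or
  two haplotype sets (FASTQ-serialisable), the substrate for k-mer spectra.
* :func:`simulate_variant_table` builds a VCF-like genotype table against the
  ancestral reference, with binomial allele-depth sampling at heterozygous
  diploid sites (the allele-frequency ploidy signature).
* :func:`simulate_triad_counts` plants additive / expression-level-dominance /
  transgressive categories into negative-binomial triad count matrices, with
  homoeolog splits and allele-informative read observations.
* :func:`simulate_go_annotation` builds a gene-to-term map with optional
  over-represented ("spiked") terms for enrichment power/null studies.

Divergence model
----------------
Lineages radiate from the ancestor independently (a star tree).  Per-lineage
mutation probabilities ``m_i`` are solved from the requested pairwise
divergence matrix in log space, ``log(1-m_i) + log(1-m_j) = log(1-d_ij)``,
which is exact because sites hit in more than one lineage are forced to carry
distinct derived bases: two lineages match at a site iff neither mutated it,
so ``P(mismatch) = 1 - (1-m_i)(1-m_j) = d_ij`` in expectation.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .triad_expression import TriadCountMatrix

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMPLEMENT = {65: 84, 67: 71, 71: 67, 84: 65}

TRIAD_CATEGORIES = ("Additive", "ELD_P1", "ELD_P2", "TUR", "TDR", "UC")


class ParameterError(ValueError):
    """A simulation configuration violates its invariants."""


# ---------------------------------------------------------------------------
# configs
# ---------------------------------------------------------------------------

@dataclass
class LineageSimConfig:
    """Configuration for the haploid lineage radiation.

    Parameters
    ----------
    n_chromosomes, chrom_length:
        Ancestral karyotype (every chromosome the same length, in bp).
    divergence_matrix:
        Symmetric zero-diagonal per-bp substitution probability between each
        lineage pair, each entry in [0, 1).
    fusion_fission_events:
        Optional dysploidy events applied per lineage after mutation, each a
        tuple ``(lineage, "fusion", (i, j))`` concatenating chromosomes ``i``
        and ``j``, or ``(lineage, "fission", (i, breakpoint_bp))`` splitting
        chromosome ``i`` strictly inside its span.
    """

    n_chromosomes: int
    chrom_length: int
    divergence_matrix: Sequence[Sequence[float]]
    fusion_fission_events: Sequence[tuple] = ()
    lineage_names: Sequence[str] | None = None
    seed: int = 0

    def validate(self) -> np.ndarray:
        d = np.asarray(self.divergence_matrix, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1] or d.shape[0] < 1:
            raise ParameterError("divergence_matrix must be square")
        if not np.allclose(d, d.T):
            raise ParameterError("divergence_matrix must be symmetric")
        if np.any(np.diag(d) != 0):
            raise ParameterError("divergence_matrix diagonal must be zero")
        if np.any(d < 0) or np.any(d >= 1):
            raise ParameterError("divergence entries must lie in [0, 1)")
        if self.n_chromosomes < 1 or self.chrom_length < 1:
            raise ParameterError("need at least one chromosome of positive length")
        for ev in self.fusion_fission_events:
            _, kind, payload = ev
            if kind not in ("fusion", "fission"):
                raise ParameterError(f"unknown event kind {kind!r}")
            if kind == "fission":
                _, bp = payload
                if not 0 < bp:
                    raise ParameterError("fission breakpoint must be strictly inside the chromosome")
        return d

    def names(self) -> list[str]:
        n = np.asarray(self.divergence_matrix).shape[0]
        if self.lineage_names is not None:
            if len(self.lineage_names) != n:
                raise ParameterError("lineage_names length must match divergence matrix")
            return list(self.lineage_names)
        return [f"L{i + 1}" for i in range(n)]


@dataclass
class HybridSimConfig:
    parent_a_id: str
    parent_b_id: str
    novel_mutation_rate: float = 0.0
    #: optional post-hybridization fusion: (haplotype 'A'|'B', chrom index i, chrom index j)
    fusion_event: tuple | None = None
    name: str = "hybrid"
    seed: int = 0

    def validate(self) -> None:
        if self.parent_a_id == self.parent_b_id:
            raise ParameterError("parent ids must be distinct")
        if not 0 <= self.novel_mutation_rate < 1:
            raise ParameterError("novel_mutation_rate must lie in [0, 1)")


@dataclass
class TriadSimConfig:
    """Planted-truth triad expression simulation.

    ``category_proportions`` spans Additive, ELD_P1, ELD_P2, TUR, TDR, UC and
    must sum to 1.  ``effect_log2fc`` is the planted effect magnitude in log2
    units; ``nb_dispersion`` is the negative-binomial dispersion alpha in
    ``var = mu + alpha * mu**2`` (0 gives Poisson counts).
    ``tur_de_fraction`` controls how many transgressively upregulated genes
    additionally carry a parental differential (DE-TUR vs NDE-TUR truth).
    """

    n_genes: int = 2000
    n_replicates: int = 3
    category_proportions: Mapping[str, float] = field(
        default_factory=lambda: {
            "Additive": 0.55, "ELD_P1": 0.10, "ELD_P2": 0.10,
            "TUR": 0.10, "TDR": 0.10, "UC": 0.05,
        })
    effect_log2fc: float = 2.0
    nb_dispersion: float = 0.05
    baseline_mean: float = 200.0
    homoeolog_bias_fraction: float = 0.10
    homoeolog_bias_log2: float = 2.0
    ase_conflict_rate: float = 0.05
    ase_reads_per_gene: float = 100.0
    tur_de_fraction: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        props = dict(self.category_proportions)
        if set(props) - set(TRIAD_CATEGORIES):
            raise ParameterError(f"unknown categories {set(props) - set(TRIAD_CATEGORIES)}")
        vals = np.array([props.get(c, 0.0) for c in TRIAD_CATEGORIES])
        if np.any(vals < 0) or abs(vals.sum() - 1.0) > 1e-9:
            raise ParameterError("category proportions must be nonnegative and sum to 1")
        if self.nb_dispersion < 0:
            raise ParameterError("nb_dispersion must be >= 0")
        if not 0 <= self.ase_conflict_rate < 1:
            raise ParameterError("ase_conflict_rate must lie in [0, 1)")
        if self.n_replicates < 2:
            raise ParameterError("need >= 2 replicates per condition")


# ---------------------------------------------------------------------------
# truth
# ---------------------------------------------------------------------------

@dataclass
class TruthSet:
    """Ground-truth labels for everything a simulation emitted.

    Mutations are recorded in ancestral coordinates (0-based) so they stay
    valid across fusion/fission rearrangements.  Serialises to JSON and
    round-trips losslessly.
    """

    #: lineage -> {(anc_chrom, pos0): derived base}
    lineage_mutations: dict = field(default_factory=dict)
    #: list of event dicts (fusion/fission coordinates per lineage)
    events: list = field(default_factory=list)
    #: hybrid chromosome name -> subgenome label 'A' | 'B'
    subgenome_labels: dict = field(default_factory=dict)
    #: DataFrame: chrom, pos (ancestral 0-based), haplotype, allele, origin
    variant_provenance: pd.DataFrame | None = None
    #: DataFrame: gene, category, tur_subtype, bias_log2, theta, parent1_mean,
    #: parent2_mean, hybrid_mean
    triad_truth: pd.DataFrame | None = None
    #: list of truly enriched term ids
    enriched_terms: list = field(default_factory=list)
    warnings: list = field(default_factory=list)

    def merge(self, other: "TruthSet") -> "TruthSet":
        self.lineage_mutations.update(other.lineage_mutations)
        self.events.extend(other.events)
        self.subgenome_labels.update(other.subgenome_labels)
        for attr in ("variant_provenance", "triad_truth"):
            if getattr(other, attr) is not None:
                setattr(self, attr, getattr(other, attr))
        self.enriched_terms.extend(other.enriched_terms)
        self.warnings.extend(other.warnings)
        return self

    def to_json(self) -> str:
        payload = {
            "lineage_mutations": {
                lin: [[c, int(p), b] for (c, p), b in sorted(muts.items())]
                for lin, muts in self.lineage_mutations.items()
            },
            "events": self.events,
            "subgenome_labels": self.subgenome_labels,
            "variant_provenance": _frame_payload(self.variant_provenance),
            "triad_truth": _frame_payload(self.triad_truth),
            "enriched_terms": self.enriched_terms,
            "warnings": self.warnings,
        }
        return json.dumps(payload, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "TruthSet":
        payload = json.loads(text)
        return cls(
            lineage_mutations={
                lin: {(c, int(p)): b for c, p, b in muts}
                for lin, muts in payload["lineage_mutations"].items()
            },
            events=[tuple(e) if isinstance(e, list) else e for e in payload["events"]],
            subgenome_labels=payload["subgenome_labels"],
            variant_provenance=_frame_restore(payload["variant_provenance"]),
            triad_truth=_frame_restore(payload["triad_truth"]),
            enriched_terms=payload["enriched_terms"],
            warnings=payload["warnings"],
        )


def _frame_payload(df):
    if df is None:
        return None
    return {"columns": list(df.columns),
            "data": df.to_numpy(dtype=object).tolist()}


def _frame_restore(payload):
    if payload is None:
        return None
    df = pd.DataFrame(payload["data"], columns=payload["columns"])
    return df.infer_objects()


@dataclass
class LineageSet:
    """Haploid lineage genomes plus the shared ancestor and coordinate maps."""

    ancestor: dict  # chrom -> str
    genomes: dict   # lineage -> {chrom -> str}
    #: lineage -> {chrom -> [(anc_chrom, anc_start, anc_end), ...]} in order
    segments: dict
    truth: TruthSet

    def to_ancestral(self, lineage: str, chrom: str, pos0: int) -> tuple[str, int]:
        """Map a 0-based position on a (possibly rearranged) lineage chromosome
        back to ancestral coordinates."""
        offset = 0
        for anc_chrom, s, e in self.segments[lineage][chrom]:
            if pos0 < offset + (e - s):
                return anc_chrom, s + (pos0 - offset)
            offset += e - s
        raise IndexError(f"position {pos0} beyond {lineage}:{chrom}")


@dataclass
class HybridGenome:
    """A diploid hybrid: two labelled haplotype sets in one nucleus."""

    name: str
    parent_a: str
    parent_b: str
    #: 'A' | 'B' -> {chrom name -> sequence}
    haplotypes: dict
    #: 'A' | 'B' -> {chrom -> ancestral segments}, as in LineageSet
    segments: dict
    truth: TruthSet

    def all_sequences(self) -> dict:
        out = {}
        for hap in ("A", "B"):
            out.update(self.haplotypes[hap])
        return out


# ---------------------------------------------------------------------------
# lineage simulation
# ---------------------------------------------------------------------------

def _solve_lineage_rates(d: np.ndarray) -> np.ndarray:
    """Per-lineage mutation probabilities under the star model (see module
    docstring); least squares in log space, exact for <= 3 lineages."""
    n = d.shape[0]
    if n == 1:
        return np.zeros(1)
    rows, rhs = [], []
    for i in range(n):
        for j in range(i + 1, n):
            row = np.zeros(n)
            row[i] = row[j] = 1.0
            rows.append(row)
            rhs.append(np.log1p(-d[i, j]))
    x, *_ = np.linalg.lstsq(np.asarray(rows), np.asarray(rhs), rcond=None)
    m = 1.0 - np.exp(np.minimum(x, 0.0))
    return np.clip(m, 0.0, 0.999)


def _mutate_star(anc_names, anc_arrays, names, rates, rng, chrom_length):
    """Independent radiation from the ancestor (exact for <= 2 lineages):
    sites hit in both lineages get distinct derived bases, so
    P(mismatch) = 1 - (1-m_i)(1-m_j) exactly."""
    site_hits: dict = {c: {} for c in anc_names}
    per_lineage_sites: list = []
    for li, m in enumerate(rates):
        sites = {}
        for c in anc_names:
            if m > 0:
                pos = np.nonzero(rng.random(chrom_length) < m)[0]
            else:
                pos = np.empty(0, dtype=int)
            sites[c] = pos
            for p in pos:
                site_hits[c].setdefault(int(p), []).append(li)
        per_lineage_sites.append(sites)

    derived: dict = {}
    for c in anc_names:
        for p, hit in site_hits[c].items():
            anc_base = chr(anc_arrays[c][p])
            alts = [b for b in "ACGT" if b != anc_base]
            picks = rng.choice(3, size=len(hit), replace=False)
            derived[(c, p)] = {li: alts[k] for li, k in zip(hit, picks)}

    out = {}
    for li, name in enumerate(names):
        chroms = {}
        for c in anc_names:
            arr = anc_arrays[c].copy()
            for p in per_lineage_sites[li][c]:
                arr[p] = ord(derived[(c, int(p))][li])
            chroms[c] = arr
        out[name] = chroms
    return out


def _mutate_tree(anc_names, anc_arrays, names, d, rng):
    """Radiate lineages along an NJ tree fit to -log(1 - d); branch lengths
    convert back to per-bp substitution probabilities 1 - exp(-length)."""
    from io import StringIO

    from Bio import Phylo

    from .variants_popgen import neighbor_joining

    dprime = pd.DataFrame(-np.log1p(-d), index=names, columns=names)
    np.fill_diagonal(dprime.values, 0.0)
    tree = Phylo.read(StringIO(neighbor_joining(dprime)), "newick")

    out: dict = {}

    def walk(clade, arrays):
        p_mut = 1.0 - np.exp(-(clade.branch_length or 0.0))
        if p_mut > 0:
            arrays = {c: a.copy() for c, a in arrays.items()}
            for c, arr in arrays.items():
                for p in np.nonzero(rng.random(len(arr)) < p_mut)[0]:
                    cur = chr(arr[p])
                    arr[p] = ord(rng.choice([b for b in "ACGT" if b != cur]))
        if clade.is_terminal():
            out[clade.name] = arrays
        else:
            for child in clade.clades:
                walk(child, arrays)

    walk(tree.root, anc_arrays)
    return out


def _seq_to_array(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8).copy()


def _array_to_seq(arr: np.ndarray) -> str:
    return arr.tobytes().decode()


def simulate_lineages(config: LineageSimConfig) -> LineageSet:
    """Draw an ancestral genome and radiate haploid lineages from it.

    Returns a :class:`LineageSet` whose truth records every substitution (in
    ancestral coordinates) and every fusion/fission event.
    """
    d = config.validate()
    names = config.names()
    rng = np.random.default_rng(config.seed)
    rates = _solve_lineage_rates(d)

    anc_names = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    ancestor = {}
    anc_arrays = {}
    for c in anc_names:
        arr = BASES[rng.integers(0, 4, size=config.chrom_length)]
        anc_arrays[c] = arr
        ancestor[c] = _array_to_seq(arr)

    truth = TruthSet()
    genomes: dict = {}
    segments: dict = {}
    if len(names) <= 2:
        lineage_arrays = _mutate_star(anc_names, anc_arrays, names, rates, rng,
                                      config.chrom_length)
    else:
        # a star cannot realise clade-structured divergence matrices (shared
        # internal branches are needed), so radiate along a neighbor-joining
        # tree fit in -log(1 - d) space, where independent substitutions are
        # additive; mutations on internal branches are inherited by all
        # descendant lineages
        lineage_arrays = _mutate_tree(anc_names, anc_arrays, names, d, rng)

    for name in names:
        muts = {}
        chroms = {}
        segs = {}
        for c in anc_names:
            arr = lineage_arrays[name][c]
            diff = np.nonzero(arr != anc_arrays[c])[0]
            for p in diff:
                muts[(c, int(p))] = chr(arr[p])
            chroms[c] = _array_to_seq(arr)
            segs[c] = [(c, 0, config.chrom_length)]
        genomes[name] = chroms
        segments[name] = segs
        truth.lineage_mutations[name] = muts

    # dysploidy events, applied in order
    for lineage, kind, payload in config.fusion_fission_events:
        if lineage not in genomes:
            raise ParameterError(f"unknown lineage {lineage!r} in event")
        chrom_names = list(genomes[lineage])
        if kind == "fusion":
            i, j = payload
            ci, cj = chrom_names[i], chrom_names[j]
            fused = f"{ci}+{cj}"
            genomes[lineage][fused] = genomes[lineage].pop(ci) + genomes[lineage].pop(cj)
            segments[lineage][fused] = segments[lineage].pop(ci) + segments[lineage].pop(cj)
            truth.events.append({"lineage": lineage, "kind": "fusion",
                                 "chromosomes": [ci, cj], "result": fused})
        else:
            i, bp = payload
            ci = chrom_names[i]
            seq = genomes[lineage].pop(ci)
            if not 0 < bp < len(seq):
                raise ParameterError("fission breakpoint must lie strictly inside the chromosome")
            left, right = f"{ci}.1", f"{ci}.2"
            genomes[lineage][left], genomes[lineage][right] = seq[:bp], seq[bp:]
            segs = segments[lineage].pop(ci)
            lsegs, rsegs, off = [], [], 0
            for anc_chrom, s, e in segs:
                seg_len = e - s
                if off + seg_len <= bp:
                    lsegs.append((anc_chrom, s, e))
                elif off >= bp:
                    rsegs.append((anc_chrom, s, e))
                else:
                    cut = s + (bp - off)
                    lsegs.append((anc_chrom, s, cut))
                    rsegs.append((anc_chrom, cut, e))
                off += seg_len
            segments[lineage][left], segments[lineage][right] = lsegs, rsegs
            truth.events.append({"lineage": lineage, "kind": "fission",
                                 "chromosome": ci, "breakpoint": int(bp),
                                 "result": [left, right]})

    return LineageSet(ancestor=ancestor, genomes=genomes, segments=segments, truth=truth)


# ---------------------------------------------------------------------------
# hybridization
# ---------------------------------------------------------------------------

def make_hybrid(lineages: LineageSet, config: HybridSimConfig) -> HybridGenome:
    """Merge two haploid lineage genomes into a diploid hybrid.

    Haplotype A is a copy of parent_a, haplotype B of parent_b, each carrying
    fresh ("novel") mutations at ``novel_mutation_rate``.  The truth labels
    every site at which the hybrid differs from the ancestor as parent_a- /
    parent_b-derived or novel, in ancestral coordinates.
    """
    config.validate()
    for pid in (config.parent_a_id, config.parent_b_id):
        if pid not in lineages.genomes:
            raise ParameterError(f"unknown parent lineage {pid!r}")
    rng = np.random.default_rng(config.seed)
    truth = TruthSet()

    n_a = len(lineages.genomes[config.parent_a_id])
    n_b = len(lineages.genomes[config.parent_b_id])
    if n_a != n_b:
        truth.warnings.append(
            f"parents have unequal chromosome counts ({n_a} vs {n_b}): dysploid hybrid")
        warnings.warn("parents have unequal chromosome counts: dysploid hybrid",
                      stacklevel=2)

    haplotypes: dict = {}
    segments: dict = {}
    novel: dict = {"A": {}, "B": {}}  # hap -> {(anc_chrom, anc_pos): new base}
    for hap, pid in (("A", config.parent_a_id), ("B", config.parent_b_id)):
        haplotypes[hap] = {}
        segments[hap] = {}
        for chrom, seq in lineages.genomes[pid].items():
            arr = _seq_to_array(seq)
            if config.novel_mutation_rate > 0:
                pos = np.nonzero(rng.random(len(arr)) < config.novel_mutation_rate)[0]
                for p in pos:
                    cur = chr(arr[p])
                    new = rng.choice([b for b in "ACGT" if b != cur])
                    arr[p] = ord(new)
                    anc = _make_anc_lookup(lineages.segments[pid][chrom], int(p))
                    novel[hap][anc] = str(new)
            name = f"{config.name}_{hap}_{chrom}"
            haplotypes[hap][name] = _array_to_seq(arr)
            segments[hap][name] = list(lineages.segments[pid][chrom])
            truth.subgenome_labels[name] = hap

    if config.fusion_event is not None:
        hap, i, j = config.fusion_event
        chrom_names = list(haplotypes[hap])
        ci, cj = chrom_names[i], chrom_names[j]
        fused = f"{ci}+{cj.split('_')[-1]}"
        haplotypes[hap][fused] = haplotypes[hap].pop(ci) + haplotypes[hap].pop(cj)
        segments[hap][fused] = segments[hap].pop(ci) + segments[hap].pop(cj)
        truth.subgenome_labels.pop(ci)
        truth.subgenome_labels.pop(cj)
        truth.subgenome_labels[fused] = hap
        truth.events.append({"lineage": config.name, "kind": "fusion",
                             "haplotype": hap, "chromosomes": [ci, cj], "result": fused})

    # provenance: every ancestral site at which either haplotype differs
    rows = []
    mut_a = dict(lineages.truth.lineage_mutations[config.parent_a_id])
    mut_b = dict(lineages.truth.lineage_mutations[config.parent_b_id])
    for hap, parental, origin in (("A", mut_a, "parent_a"), ("B", mut_b, "parent_b")):
        effective = dict(parental)
        for site, base in novel[hap].items():
            effective[site] = base  # novel overrides inherited state
        for (chrom, pos), base in effective.items():
            is_novel = site_is_novel = (chrom, pos) in novel[hap]
            rows.append((chrom, pos, hap, base, "novel" if is_novel else origin))
    prov = pd.DataFrame(rows, columns=["chrom", "pos", "haplotype", "allele", "origin"])
    truth.variant_provenance = prov.sort_values(["chrom", "pos", "haplotype"],
                                                ignore_index=True)
    return HybridGenome(name=config.name, parent_a=config.parent_a_id,
                        parent_b=config.parent_b_id, haplotypes=haplotypes,
                        segments=segments, truth=truth)


def _make_anc_lookup(segs: list, pos0: int) -> tuple[str, int]:
    offset = 0
    for anc_chrom, s, e in segs:
        if pos0 < offset + (e - s):
            return anc_chrom, s + (pos0 - offset)
        offset += e - s
    raise IndexError(pos0)


def hybrid_het_sites(lineages: LineageSet, hybrid: HybridGenome) -> pd.DataFrame:
    """Heterozygous sites of the hybrid in ancestral coordinates.

    Columns: chrom, pos, allele_a, allele_b (the two haplotype alleles, which
    differ by definition).
    """
    prov = hybrid.truth.variant_provenance
    anc = lineages.ancestor
    state: dict = {}
    for row in prov.itertuples(index=False):
        state.setdefault((row.chrom, row.pos), {})[row.haplotype] = row.allele
    rows = []
    for (chrom, pos), alleles in state.items():
        ref = anc[chrom][pos]
        a = alleles.get("A", ref)
        b = alleles.get("B", ref)
        if a != b:
            rows.append((chrom, pos, a, b))
    return (pd.DataFrame(rows, columns=["chrom", "pos", "allele_a", "allele_b"])
            .sort_values(["chrom", "pos"], ignore_index=True))


# ---------------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------------

class ReadSet:
    """Shotgun reads held as a dense uint8 ASCII matrix (reads x length)."""

    def __init__(self, matrix: np.ndarray, names: list[str], seed: int | None = None):
        self.matrix = matrix
        self.names = names
        self.seed = seed

    def __len__(self) -> int:
        return self.matrix.shape[0]

    @property
    def read_length(self) -> int:
        return self.matrix.shape[1]

    def sequences(self) -> Iterable[str]:
        for row in self.matrix:
            yield row.tobytes().decode()

    def write_fastq(self, path: str | Path) -> None:
        qual = "I" * self.read_length
        with open(path, "w") as fh:
            if self.seed is not None:
                pass  # seed travels in read names
            for name, row in zip(self.names, self.matrix):
                fh.write(f"@{name}\n{row.tobytes().decode()}\n+\n{qual}\n")


def simulate_reads(haplotypes, depth: float, read_length: int = 150,
                   error_rate: float = 0.0, seed: int = 0) -> ReadSet:
    """Uniform shotgun reads from one or more haplotype sets.

    ``haplotypes`` is a single ``{chrom: seq}`` dict or a sequence of them
    (one per haplotype).  ``depth`` is the TOTAL expected per-base coverage
    over the organism: with two haplotypes each is covered at ``depth/2``.
    Substitution errors at ``error_rate`` per base; half the reads are
    reverse-complemented.
    """
    if isinstance(haplotypes, Mapping):
        haplotypes = [haplotypes]
    if depth <= 0:
        raise ParameterError("depth must be positive")
    per_hap_cov = depth / len(haplotypes)
    rng = np.random.default_rng(seed)

    chunks, names = [], []
    ridx = 0
    comp = np.zeros(256, dtype=np.uint8)
    for a, b in zip(b"ACGT", b"TGCA"):
        comp[a] = b
    for hi, hap in enumerate(haplotypes):
        for chrom, seq in hap.items():
            L = len(seq)
            if read_length > L:
                raise ParameterError(
                    f"read_length {read_length} exceeds chromosome {chrom} ({L} bp)")
            n = int(round(per_hap_cov * L / read_length))
            arr = _seq_to_array(seq)
            starts = rng.integers(0, L - read_length + 1, size=n)
            reads = arr[starts[:, None] + np.arange(read_length)]
            flip = rng.random(n) < 0.5
            if flip.any():
                reads[flip] = comp[reads[flip][:, ::-1]]
            if error_rate > 0:
                err = rng.random(reads.shape) < error_rate
                if err.any():
                    idx2 = (np.searchsorted(BASES, reads[err])
                            + rng.integers(1, 4, size=int(err.sum()))) % 4
                    reads[err] = BASES[idx2]
            chunks.append(reads)
            names.extend(f"r{ridx + i}:{chrom}:{s}" for i, s in enumerate(starts))
            ridx += n
    matrix = np.concatenate(chunks, axis=0) if chunks else np.empty((0, read_length), np.uint8)
    return ReadSet(matrix, names, seed=seed)


# ---------------------------------------------------------------------------
# variant tables
# ---------------------------------------------------------------------------

def simulate_variant_table(lineages: LineageSet,
                           samples: Mapping[str, object],
                           depth: int = 50,
                           low_qual_fraction: float = 0.0,
                           seed: int = 0):
    """Genotype table of haploid lineages and diploid hybrids vs the ancestor.

    ``samples`` maps sample name to either a lineage id (haploid sample) or a
    :class:`HybridGenome` (diploid sample).  Sites are the union of all
    variant positions across the chosen samples.  At heterozygous diploid
    sites the allele depths are split Binomial(depth, 0.5); homozygous and
    haploid sites place all reads on the single allele.  DP is ``depth`` at
    every site so allele depths always sum to the site depth.
    """
    from .variants_popgen import VariantTable

    if depth <= 0:
        raise ParameterError("depth must be positive")
    rng = np.random.default_rng(seed)

    # collect per-sample allele state in ancestral coordinates
    sample_alleles: dict = {}
    ploidy: dict = {}
    for sname, spec in samples.items():
        if isinstance(spec, HybridGenome):
            ploidy[sname] = 2
            state: dict = {}
            for row in spec.truth.variant_provenance.itertuples(index=False):
                state.setdefault((row.chrom, row.pos), {})[row.haplotype] = row.allele
            sample_alleles[sname] = state
        else:
            ploidy[sname] = 1
            muts = lineages.truth.lineage_mutations[str(spec)]
            sample_alleles[sname] = {site: {"H": base} for site, base in muts.items()}

    all_sites = sorted({site for st in sample_alleles.values() for site in st})
    chroms, poss, refs, alts_list, quals = [], [], [], [], []
    gts, ads, dps = [], [], []
    snames = list(samples)
    for chrom, pos in all_sites:
        ref = lineages.ancestor[chrom][pos]
        alleles = [ref]
        site_gt, site_ad = [], []
        for sname in snames:
            st = sample_alleles[sname].get((chrom, pos))
            if ploidy[sname] == 1:
                base = st["H"] if st else ref
                if base not in alleles:
                    alleles.append(base)
                ai = alleles.index(base)
                site_gt.append((ai,))
                ad = [0] * 4
                ad[ai] = depth
                site_ad.append(ad)
            else:
                a = st.get("A", ref) if st else ref
                b = st.get("B", ref) if st else ref
                for base in (a, b):
                    if base not in alleles:
                        alleles.append(base)
                ia, ib = alleles.index(a), alleles.index(b)
                ad = [0] * 4
                if ia == ib:
                    ad[ia] = depth
                else:
                    k = int(rng.binomial(depth, 0.5))
                    ad[ia] = k
                    ad[ib] = depth - k
                site_gt.append((min(ia, ib), max(ia, ib)))
                site_ad.append(ad)
        n_alleles = len(alleles)
        chroms.append(chrom)
        poss.append(pos + 1)  # VCF is 1-based
        refs.append(ref)
        alts_list.append(tuple(alleles[1:]))
        if rng.random() < low_qual_fraction:
            quals.append(float(rng.uniform(0, 19.9)))
        else:
            quals.append(float(rng.uniform(50, 1000)))
        gts.append([tuple(g) for g in site_gt])
        ads.append([tuple(ad[:n_alleles]) for ad in site_ad])
        dps.append([depth] * len(snames))

    from .variants_popgen import object_table

    sites = pd.DataFrame({"chrom": chroms, "pos": poss, "ref": refs,
                          "alts": alts_list, "qual": quals})
    contig_lengths = {c: len(s) for c, s in lineages.ancestor.items()}
    return VariantTable(sites=sites, samples=snames,
                        gt=object_table(gts, len(snames)),
                        ad=object_table(ads, len(snames)),
                        dp=np.array(dps, dtype=int) if dps else np.empty((0, len(snames)), int),
                        ploidy=ploidy, contig_lengths=contig_lengths)


# ---------------------------------------------------------------------------
# triad counts
# ---------------------------------------------------------------------------

def _nb_draw(rng, mean, dispersion, size):
    mean = np.broadcast_to(np.asarray(mean, dtype=float), size)
    if dispersion <= 0:
        return rng.poisson(mean)
    n = 1.0 / dispersion
    p = n / (n + mean)
    return rng.negative_binomial(n, p)


def simulate_triad_counts(config: TriadSimConfig):
    """Negative-binomial triad count matrix with planted expression categories.

    Per gene, parental means are drawn log-normally around ``baseline_mean``;
    the hybrid mean is set by the planted category (Additive: mid-parent;
    ELD_Pi: parent i; TUR: max-parent x 2^effect; TDR: min-parent / 2^effect;
    UC: between the parents but off mid-parent).  The hybrid total is split
    into homoeolog A/B counts, biased 2^``homoeolog_bias_log2``-fold for a
    ``homoeolog_bias_fraction`` of genes, and allele-informative read
    observations are drawn with the configured conflict rate.

    Returns ``(TriadCountMatrix, ase_observations DataFrame, TruthSet)``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, reps = config.n_genes, config.n_replicates
    genes = [f"g{i:05d}" for i in range(n)]

    props = np.array([dict(config.category_proportions).get(c, 0.0)
                      for c in TRIAD_CATEGORIES])
    cats = rng.choice(len(TRIAD_CATEGORIES), size=n, p=props)
    cat_names = np.array(TRIAD_CATEGORIES)[cats]
    eff = 2.0 ** config.effect_log2fc

    base = config.baseline_mean * np.exp(rng.normal(0, 0.5, size=n))
    p1 = base.copy()
    p2 = base.copy()
    hyb = np.empty(n)
    tur_subtype = np.array(["n/a"] * n, dtype=object)
    for i, cat in enumerate(cat_names):
        if cat == "UC":
            # intermediate-but-off-mid expression is only resolvable from
            # Additive and ELD when the parents are far apart: spread them
            # 2.5x the effect (in log2) and park the hybrid 1.2x the effect
            # above the low parent
            lo = p1[i]
            p2[i] = lo * 2.0 ** (2.5 * config.effect_log2fc)
            hyb[i] = lo * 2.0 ** (1.2 * config.effect_log2fc)
            if rng.random() < 0.5:
                p1[i], p2[i] = p2[i], p1[i]
            continue
        if cat in ("ELD_P1", "ELD_P2"):
            # parents must differ for dominance to exist
            if rng.random() < 0.5:
                p2[i] = p1[i] * eff
            else:
                p2[i] = p1[i] / eff
        elif cat in ("TUR", "TDR") and rng.random() < config.tur_de_fraction:
            p2[i] = p1[i] * eff if rng.random() < 0.5 else p1[i] / eff
            if cat == "TUR":
                tur_subtype[i] = "DE-TUR"
        elif cat == "TUR":
            tur_subtype[i] = "NDE-TUR"
        mid = 0.5 * (p1[i] + p2[i])
        if cat == "Additive":
            hyb[i] = mid
        elif cat == "ELD_P1":
            hyb[i] = p1[i]
        elif cat == "ELD_P2":
            hyb[i] = p2[i]
        elif cat == "TUR":
            hyb[i] = max(p1[i], p2[i]) * eff
        else:  # TDR
            hyb[i] = min(p1[i], p2[i]) / eff

    # homoeolog bias
    biased = rng.random(n) < config.homoeolog_bias_fraction
    direction = np.where(rng.random(n) < 0.5, 1.0, -1.0)
    bias_log2 = np.where(biased, direction * config.homoeolog_bias_log2, 0.0)
    theta = 2.0 ** bias_log2 / (1.0 + 2.0 ** bias_log2)  # P(read from homoeolog A)

    counts = {}
    homoeolog_a, homoeolog_b = {}, {}
    sheet_rows = []
    for r in range(reps):
        for role, mean in (("parent1", p1), ("parent2", p2)):
            sname = f"{role}_r{r + 1}"
            counts[sname] = _nb_draw(rng, mean, config.nb_dispersion, (n,))
            sheet_rows.append((sname, role, r + 1, "default"))
        sname = f"hybrid_r{r + 1}"
        total = _nb_draw(rng, hyb, config.nb_dispersion, (n,))
        a = rng.binomial(total, theta)
        counts[sname] = total
        homoeolog_a[sname] = a
        homoeolog_b[sname] = total - a
        sheet_rows.append((sname, "hybrid", r + 1, "default"))

    count_df = pd.DataFrame(counts, index=genes)
    sheet = pd.DataFrame(sheet_rows, columns=["sample", "role", "replicate", "condition"])
    lengths = pd.Series(rng.integers(300, 3001, size=n), index=genes, name="length")
    tcm = TriadCountMatrix(
        counts=count_df, sample_sheet=sheet,
        homoeolog_a=pd.DataFrame(homoeolog_a, index=genes),
        homoeolog_b=pd.DataFrame(homoeolog_b, index=genes),
        gene_lengths=lengths)

    # allele-informative read observations (RNA reads spanning >= 1 diagnostic site)
    ase_rows = []
    n_reads = rng.poisson(config.ase_reads_per_gene, size=n)
    for i, g in enumerate(genes):
        for j in range(n_reads[i]):
            rid = f"{g}_read{j}"
            n_sites = 1 if rng.random() < 0.1 else int(rng.integers(2, 5))
            true_parent = "P1" if rng.random() < theta[i] else "P2"
            matches = [true_parent] * n_sites
            if n_sites >= 2 and rng.random() < config.ase_conflict_rate:
                flip = int(rng.integers(0, n_sites))
                matches[flip] = "P2" if true_parent == "P1" else "P1"
            for s, m in enumerate(matches):
                ase_rows.append((rid, g, f"{g}_s{s}", "ACGT"[int(rng.integers(0, 4))], m))
    ase = pd.DataFrame(ase_rows,
                       columns=["read_id", "gene", "site", "allele", "parent_match"])

    truth = TruthSet(triad_truth=pd.DataFrame({
        "gene": genes, "category": cat_names, "tur_subtype": tur_subtype,
        "bias_log2": bias_log2, "theta": theta,
        "parent1_mean": p1, "parent2_mean": p2, "hybrid_mean": hyb,
    }))
    return tcm, ase, truth


# ---------------------------------------------------------------------------
# GO annotation
# ---------------------------------------------------------------------------

def simulate_go_annotation(n_genes: int, n_terms: int,
                           term_size_range: tuple[int, int],
                           spiked_terms: Sequence[tuple[str, float]] = (),
                           selected_genes: Sequence[str] | None = None,
                           seed: int = 0):
    """Random gene-to-term annotation with optional over-represented terms.

    Spiked terms sample their members with ``odds``-fold weight on the
    designated ``selected_genes`` subset, producing true enrichment in that
    subset.  Returns ``(annotation DataFrame[gene, term], TruthSet)``.
    """
    lo, hi = term_size_range
    if lo < 1 or hi > n_genes or lo > hi:
        raise ParameterError("term_size_range must satisfy 1 <= lo <= hi <= n_genes")
    for term, odds in spiked_terms:
        if odds < 1:
            raise ParameterError(f"spiked term {term!r} has odds {odds} < 1")
    if spiked_terms and not selected_genes:
        raise ParameterError("spiked terms require a designated selected gene set")
    rng = np.random.default_rng(seed)
    genes = np.array([f"g{i:05d}" for i in range(n_genes)])
    sel_mask = np.zeros(n_genes, dtype=bool)
    if selected_genes is not None:
        sel_idx = {g: i for i, g in enumerate(genes)}
        for g in selected_genes:
            sel_mask[sel_idx[g]] = True
    spiked = dict(spiked_terms)

    rows = []
    term_ids = [f"GO:{i:07d}" for i in range(n_terms)]
    for term in term_ids:
        size = int(rng.integers(lo, hi + 1))
        w = np.ones(n_genes)
        if term in spiked:
            w[sel_mask] = spiked[term]
        members = rng.choice(n_genes, size=size, replace=False, p=w / w.sum())
        rows.extend((genes[m], term) for m in members)
    ann = pd.DataFrame(rows, columns=["gene", "term"])
    truth = TruthSet(enriched_terms=sorted(spiked))
    return ann, truth


# ---------------------------------------------------------------------------
# serialization helpers
# ---------------------------------------------------------------------------

def write_fasta(sequences: Mapping[str, str], path: str | Path,
                width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_fasta(path: str | Path) -> dict:
    from Bio import SeqIO
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_gene_gff(genes: pd.DataFrame, path: str | Path) -> None:
    """Write gene models (columns chrom, start0, end, gene) as GFF3."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in genes.itertuples(index=False):
            fh.write(f"{row.chrom}\thybridtriad\tgene\t{row.start0 + 1}\t{row.end}\t"
                     f".\t+\t.\tID={row.gene}\n")
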