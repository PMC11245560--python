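"""Parental origin of a diploid hybrid and its subgenome structure.

* :func:`classify_diagnostic_snps` bins each heterozygous hybrid site, within
  single-copy-gene intervals, by how its two alleles relate to the candidate
  haploid parents (pair-explained / shared / novel-allele / conflicting).
* :func:`score_parental_pairs` ranks all candidate parent pairs by the
  fraction of heterozygous sites they jointly explain — the diagnostic-SNP
  parentage test; a best fraction below the floor flags a possibly missing
  (extinct) parent.
* :func:`assign_subgenomes` labels each hybrid chromosome A or B by canonical
  k-mer containment in the two designated parents (or an ingested coverage
  table), mirroring coverage-difference subgenome assignment.
* :func:`identity_windows` converts extended-CIGAR pairwise alignments into
  500-bp query-anchored identity tracks with SNP and indel-event counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .kmer_ploidy import genome_kmer_set

logger = logging.getLogger(__name__)


class ParameterError(ValueError):
    pass


# ---------------------------------------------------------------------------
# diagnostic SNPs and parentage
# ---------------------------------------------------------------------------

def _in_intervals(chrom: str, pos: int, intervals: pd.DataFrame | None) -> bool:
    if intervals is None:
        return True
    sub = intervals[intervals["chrom"] == chrom]
    return bool(((sub["start"] <= pos) & (pos < sub["end"])).any())


def classify_diagnostic_snps(het_sites: pd.DataFrame,
                             candidate_alleles: pd.DataFrame,
                             restrict_to: pd.DataFrame | None = None) -> pd.DataFrame:
    """Classify each heterozygous hybrid site against every candidate pair.

    ``het_sites``: columns chrom, pos, allele_a, allele_b (the two hybrid
    alleles).  ``candidate_alleles``: one column per candidate haploid parent
    giving its allele at each site, aligned to ``het_sites`` by row.
    ``restrict_to``: optional 0-based half-open single-copy-gene intervals
    (chrom, start, end); sites outside all intervals are excluded (count
    logged).

    Per site: ``explained(p,q)`` iff {hybrid alleles} == {allele_p, allele_q}
    with the two parental alleles distinct; site class is ``novel-allele``
    iff a hybrid allele occurs in no candidate, ``shared`` iff all candidates
    carry one identical allele that is among the hybrid alleles,
    ``pair-explained`` iff some pair explains it, else ``conflicting``.
    """
    if candidate_alleles.shape[1] < 2:
        raise ParameterError("need >= 2 candidate parents")
    parents = list(candidate_alleles.columns)
    keep = np.array([_in_intervals(r.chrom, r.pos, restrict_to)
                     for r in het_sites.itertuples(index=False)])
    n_excluded = int((~keep).sum())
    if n_excluded:
        logger.info("classify_diagnostic_snps: %d sites outside single-copy intervals",
                    n_excluded)
    sites = het_sites.loc[keep].reset_index(drop=True)
    cand = candidate_alleles.loc[keep].reset_index(drop=True)

    out = sites.copy()
    hyb = [frozenset((a, b)) for a, b in zip(sites["allele_a"], sites["allele_b"])]
    for p, q in combinations(parents, 2):
        col = [hyb[i] == frozenset((cand[p].iat[i], cand[q].iat[i]))
               and cand[p].iat[i] != cand[q].iat[i]
               for i in range(len(sites))]
        out[f"explained:{p}|{q}"] = col
    classes = []
    for i in range(len(sites)):
        cand_alleles = set(cand.iloc[i])
        if any(a not in cand_alleles for a in hyb[i]):
            classes.append("novel-allele")
        elif len(cand_alleles) == 1 and next(iter(cand_alleles)) in hyb[i]:
            classes.append("shared")
        elif any(out[f"explained:{p}|{q}"].iat[i] for p, q in combinations(parents, 2)):
            classes.append("pair-explained")
        else:
            classes.append("conflicting")
    out["site_class"] = classes
    out.attrs["n_excluded"] = n_excluded
    out.attrs["parents"] = parents
    return out


@dataclass
class ParentalPairScore:
    pair: tuple[str, str]
    n_explained: int
    n_unexplained: int

    @property
    def explained_fraction(self) -> float:
        total = self.n_explained + self.n_unexplained
        return self.n_explained / total if total else 0.0


@dataclass
class ParentalPairRanking:
    scores: list            # ParentalPairScore, best first
    best_pair: tuple[str, str]
    margin: float           # best minus runner-up explained fraction
    missing_parent_flag: bool

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(s.pair[0], s.pair[1], s.n_explained, s.n_unexplained,
              s.explained_fraction) for s in self.scores],
            columns=["parent_p", "parent_q", "n_explained", "n_unexplained",
                     "explained_fraction"])


def score_parental_pairs(table: pd.DataFrame,
                         floor: float = 0.9) -> ParentalPairRanking:
    """Rank candidate parent pairs by the fraction of heterozygous sites each
    explains; raise the missing-parent flag when the best fraction falls
    below ``floor``."""
    if len(table) == 0:
        raise ParameterError("no evaluated sites")
    parents = table.attrs.get("parents")
    if parents is None:
        parents = sorted({c.split(":", 1)[1].split("|")[0] for c in table.columns
                          if c.startswith("explained:")}
                         | {c.split("|")[1] for c in table.columns
                            if c.startswith("explained:")})
    scores = []
    n = len(table)
    for p, q in combinations(parents, 2):
        col = table[f"explained:{p}|{q}"]
        k = int(col.sum())
        scores.append(ParentalPairScore(pair=(p, q), n_explained=k,
                                        n_unexplained=n - k))
    scores.sort(key=lambda s: (-s.explained_fraction, s.pair))
    best = scores[0]
    margin = (best.explained_fraction - scores[1].explained_fraction
              if len(scores) > 1 else best.explained_fraction)
    return ParentalPairRanking(scores=scores, best_pair=best.pair, margin=margin,
                               missing_parent_flag=best.explained_fraction < floor)


# ---------------------------------------------------------------------------
# subgenome assignment
# ---------------------------------------------------------------------------

@dataclass
class SubgenomePartition:
    """Per-chromosome subgenome labels with per-parent support scores."""

    table: pd.DataFrame  # chrom, support_a, support_b, margin, label
    parent_a: str
    parent_b: str

    def labels(self) -> dict:
        return dict(zip(self.table["chrom"], self.table["label"]))


def assign_subgenomes(hybrid_sequences: Mapping[str, str],
                      parent_a_sequences: Mapping[str, str],
                      parent_b_sequences: Mapping[str, str],
                      k: int = 31, ambiguity_margin: float = 0.05,
                      unique_parent_kmers: bool = False,
                      parent_names: tuple[str, str] = ("parent_a", "parent_b"),
                      coverage_table: pd.DataFrame | None = None) -> SubgenomePartition:
    """Assign each hybrid chromosome to subgenome A or B.

    Support toward a parent is the fraction of the chromosome's distinct
    canonical k-mers contained anywhere in that parent's genome (with
    ``unique_parent_kmers`` multi-copy parental k-mers are excluded — a
    repeat mask).  The label is A when support_a - support_b >= margin, B for
    the converse, ambiguous otherwise.  Alternatively ``coverage_table``
    (columns chrom, support_a, support_b, e.g. read-mapping coverage
    fractions) bypasses the k-mer path entirely.
    """
    rows = []
    if coverage_table is not None:
        for r in coverage_table.itertuples(index=False):
            rows.append((r.chrom, float(r.support_a), float(r.support_b)))
    else:
        set_a = genome_kmer_set(parent_a_sequences, k=k, unique_only=unique_parent_kmers)
        set_b = genome_kmer_set(parent_b_sequences, k=k, unique_only=unique_parent_kmers)
        for chrom, seq in hybrid_sequences.items():
            if len(seq) < k:
                logger.warning("chromosome %s shorter than k=%d: ambiguous", chrom, k)
                rows.append((chrom, 0.0, 0.0))
                continue
            kmers = genome_kmer_set({chrom: seq}, k=k)
            if kmers.size == 0:
                rows.append((chrom, 0.0, 0.0))
                continue
            in_a = np.isin(kmers, set_a, assume_unique=True).mean()
            in_b = np.isin(kmers, set_b, assume_unique=True).mean()
            rows.append((chrom, float(in_a), float(in_b)))
    table = pd.DataFrame(rows, columns=["chrom", "support_a", "support_b"])
    table["margin"] = (table["support_a"] - table["support_b"]).abs()
    table["label"] = np.where(
        table["support_a"] - table["support_b"] >= ambiguity_margin, "A",
        np.where(table["support_b"] - table["support_a"] >= ambiguity_margin, "B",
                 "ambiguous"))
    return SubgenomePartition(table=table, parent_a=parent_names[0],
                              parent_b=parent_names[1])


# ---------------------------------------------------------------------------
# pairwise identity windows
# ---------------------------------------------------------------------------

@dataclass
class AlignmentBlock:
    """One pairwise alignment with per-column operations.

    ``cigar`` is a list of (op, length) with op in ``=X ID`` (extended form:
    matches and mismatches must be distinguished; plain ``M`` is rejected).
    ``qstart`` is 0-based on the query.
    """

    query: str
    qstart: int
    qend: int
    target: str
    tstart: int
    tend: int
    cigar: list = field(default_factory=list)


def read_paf(path: str | Path) -> list[AlignmentBlock]:
    """Read alignments from PAF, requiring the extended cg:Z CIGAR tag."""
    blocks = []
    with open(path) as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            cg = next((x[5:] for x in f[12:] if x.startswith("cg:Z:")), None)
            if cg is None:
                raise ParameterError(f"PAF line without cg:Z CIGAR: {f[0]} vs {f[5]}")
            blocks.append(AlignmentBlock(
                query=f[0], qstart=int(f[2]), qend=int(f[3]),
                target=f[5], tstart=int(f[7]), tend=int(f[8]),
                cigar=_parse_cigar(cg)))
    return blocks


def _parse_cigar(text: str) -> list:
    import re
    ops = []
    for length, op in re.findall(r"(\d+)([=XIDM])", text):
        ops.append((op, int(length)))
    if sum(l for _, l in ops) == 0:
        raise ParameterError("empty CIGAR")
    return ops


def align_haplotypes(query: str, target: str) -> list:
    """Extended CIGAR of a global edlib alignment (testing/simulation aid)."""
    import edlib
    r = edlib.align(query, target, task="path", mode="NW")
    return _parse_cigar(r["cigar"])


@dataclass
class IdentityTrack:
    windows: pd.DataFrame   # query, start, end, aligned, matches, mismatches, indel_cols, identity
    n_snps: int             # genome-wide mismatch columns
    n_indel_events: int     # genome-wide distinct gap runs


def identity_windows(blocks: Sequence[AlignmentBlock], window_bp: int = 500,
                     coverage_floor: float = 0.5,
                     query_lengths: Mapping[str, int] | None = None) -> IdentityTrack:
    """Windowed identity over the query, with SNP and indel-event counts.

    The query is tiled with non-overlapping ``window_bp`` windows.  Alignment
    columns are assigned to windows query-anchored: columns consuming a query
    base at their query position, gap columns (deletions from the query /
    insertions in the target) at the current query position.  Per window,
    ``identity = matches / (matches + mismatches + indel columns)``; windows
    whose aligned query coverage (match + mismatch columns) is below
    ``coverage_floor x window_bp`` are reported with identity NaN.
    """
    if window_bp <= 0:
        raise ParameterError("window_bp must be positive")
    for b in blocks:
        if not b.cigar:
            raise ParameterError(f"alignment {b.query} vs {b.target} lacks per-base "
                                 "operations: extended CIGAR required")
        if any(op == "M" for op, _ in b.cigar):
            raise ParameterError("plain M operations are ambiguous: extended "
                                 "(=/X) CIGAR required")

    acc: dict = {}  # query -> window idx -> [matches, mismatches, indel_cols]
    n_snps = 0
    n_indel_events = 0
    for b in blocks:
        wins = acc.setdefault(b.query, {})
        qpos = b.qstart
        for op, length in b.cigar:
            if op in "=X":
                if op == "X":
                    n_snps += length
                pos = qpos
                remaining = length
                while remaining > 0:
                    w = pos // window_bp
                    take = min(remaining, (w + 1) * window_bp - pos)
                    cell = wins.setdefault(w, [0, 0, 0])
                    cell[0 if op == "=" else 1] += take
                    pos += take
                    remaining -= take
                qpos += length
            elif op == "I":
                # insertion in the query relative to the target: consumes
                # query, matches nothing -> non-matching aligned columns
                n_indel_events += 1
                pos = qpos
                remaining = length
                while remaining > 0:
                    w = pos // window_bp
                    take = min(remaining, (w + 1) * window_bp - pos)
                    wins.setdefault(w, [0, 0, 0])[2] += take
                    pos += take
                    remaining -= take
                qpos += length
            elif op == "D":
                # gap in the query: columns anchored at the preceding query base
                n_indel_events += 1
                w = max(qpos - 1, 0) // window_bp
                wins.setdefault(w, [0, 0, 0])[2] += length

    rows = []
    for query, wins in acc.items():
        qlen = query_lengths.get(query) if query_lengths else None
        max_w = max(wins) if wins else 0
        n_windows = (int(np.ceil(qlen / window_bp)) if qlen else max_w + 1)
        for w in range(n_windows):
            m, x, g = wins.get(w, [0, 0, 0])
            aligned = m + x + g
            covered = m + x
            end = (w + 1) * window_bp
            if qlen:
                end = min(end, qlen)
            span = end - w * window_bp
            if covered < coverage_floor * span or aligned == 0:
                ident = np.nan
            else:
                ident = m / aligned
            rows.append((query, w * window_bp, end, aligned, m, x, g, ident))
    windows = pd.DataFrame(rows, columns=["query", "start", "end", "aligned",
                                          "matches", "mismatches", "indel_cols",
                                          "identity"])
    return IdentityTrack(windows=windows, n_snps=n_snps,
                         n_indel_events=n_indel_events)
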