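"""Population-genomic SNP analyses: filtering, heterozygosity, allele
frequencies, IUPAC encoding, p-distances and neighbor joining.

The :class:`VariantTable` mirrors a multi-sample VCF with per-sample genotype
(GT), allele depths (AD) and total depth (DP) plus the site QUAL.  Filtering
follows the two-stage convention of short-read SNP callers: a per-sample mask
(QUAL, DP bounds) applied first, then site-level filters (minor-allele
frequency, missingness, biallelic restriction) computed on what survives.
Windows are 0-based half-open internally; VCF positions (1-based) are
converted at the boundary.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: unordered base pair -> IUPAC degenerate code
IUPAC_CODES = {
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("GT"): "K",
    frozenset("AC"): "M", frozenset("CG"): "S", frozenset("AT"): "W",
}


class ParameterError(ValueError):
    pass


def object_table(rows: Sequence[Sequence], n_cols: int) -> np.ndarray:
    """2-D object array that keeps tuples as scalar cells (np.array would
    otherwise collapse same-length genotype tuples into a third axis)."""
    arr = np.empty((len(rows), n_cols), dtype=object)
    for i, row in enumerate(rows):
        for j, v in enumerate(row):
            arr[i, j] = v
    return arr


# ---------------------------------------------------------------------------
# VariantTable
# ---------------------------------------------------------------------------

@dataclass
class VariantTable:
    """Per-site, per-sample genotypes with allele depths.

    ``sites`` columns: chrom, pos (1-based), ref, alts (tuple), qual.
    ``gt[i, s]`` is a tuple of allele indices (len = ploidy) or ``None`` for
    missing; ``ad[i, s]`` a tuple of per-allele read depths; ``dp[i, s]`` the
    site depth.  ``ploidy`` maps sample -> 1 or 2.
    """

    sites: pd.DataFrame
    samples: list[str]
    gt: np.ndarray
    ad: np.ndarray
    dp: np.ndarray
    ploidy: dict = field(default_factory=dict)
    contig_lengths: dict = field(default_factory=dict)

    def __post_init__(self):
        for chrom, grp in self.sites.groupby("chrom", sort=False):
            if not grp["pos"].is_monotonic_increasing or grp["pos"].duplicated().any():
                raise ParameterError(f"positions not strictly increasing on {chrom}")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def sample_index(self, sample: str) -> int:
        return self.samples.index(sample)

    def n_alleles(self, i: int) -> int:
        return 1 + len(self.sites["alts"].iat[i])

    def is_het(self, i: int, s: int) -> bool:
        g = self.gt[i, s]
        return g is not None and len(set(g)) > 1

    def subset_sites(self, mask: np.ndarray) -> "VariantTable":
        return replace(self, sites=self.sites.loc[mask].reset_index(drop=True),
                       gt=self.gt[mask], ad=self.ad[mask], dp=self.dp[mask])

    # ---- VCF round trip ----------------------------------------------------

    def write_vcf(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            for c, ln in self.contig_lengths.items():
                fh.write(f"##contig=<ID={c},length={ln}>\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">\n')
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">\n')
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                     + "\t".join(self.samples) + "\n")
            for i, row in enumerate(self.sites.itertuples(index=False)):
                alts = ",".join(row.alts) if row.alts else "."
                cells = []
                for s in range(len(self.samples)):
                    g = self.gt[i, s]
                    gtxt = "/".join(str(a) for a in g) if g is not None \
                        else "/".join("." * self.ploidy.get(self.samples[s], 2))
                    adv = self.ad[i, s]
                    adtxt = ",".join(str(x) for x in adv) if adv is not None else "."
                    cells.append(f"{gtxt}:{adtxt}:{self.dp[i, s]}")
                fh.write(f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{alts}\t"
                         f"{row.qual:.2f}\t.\t.\tGT:AD:DP\t" + "\t".join(cells) + "\n")

    @classmethod
    def read_vcf(cls, path: str | Path) -> "VariantTable":
        import cyvcf2
        vcf = cyvcf2.VCF(str(path), gts012=False)
        samples = list(vcf.samples)
        contig_lengths = dict(zip(vcf.seqnames, vcf.seqlens)) if vcf.seqlens else {}
        chroms, poss, refs, altss, quals = [], [], [], [], []
        gts, ads, dps = [], [], []
        ploidy: dict = {}
        for rec in vcf:
            chroms.append(rec.CHROM)
            poss.append(rec.POS)
            refs.append(rec.REF)
            altss.append(tuple(rec.ALT))
            quals.append(rec.QUAL if rec.QUAL is not None else 0.0)
            row_gt, row_ad = [], []
            ad_arr = rec.format("AD")
            dp_arr = rec.format("DP")
            for s in range(len(samples)):
                alleles = [a for a in rec.genotypes[s][:-1] if a != -2]
                ploidy.setdefault(samples[s], len(alleles) or 2)
                if any(a < 0 for a in alleles) or not alleles:
                    row_gt.append(None)
                else:
                    row_gt.append(tuple(int(a) for a in alleles))
                if ad_arr is not None:
                    vals = tuple(int(x) for x in ad_arr[s] if x >= 0)
                    row_ad.append(vals)
                else:
                    row_ad.append(None)
            gts.append(row_gt)
            ads.append(row_ad)
            dps.append([int(dp_arr[s][0]) if dp_arr is not None else 0
                        for s in range(len(samples))])
        sites = pd.DataFrame({"chrom": chroms, "pos": poss, "ref": refs,
                              "alts": altss, "qual": quals})
        n = len(sites)
        return cls(sites=sites, samples=samples,
                   gt=object_table(gts, len(samples)),
                   ad=object_table(ads, len(samples)),
                   dp=np.array(dps, dtype=int) if n else np.empty((0, len(samples)), int),
                   ploidy=ploidy, contig_lengths=contig_lengths)


@dataclass
class FilterPolicy:
    """The study's SNP filter: per-sample ``QUAL < 20 || DP < 10 || DP > 400``
    masking followed by site-level MAF 0.02 / missingness 0.5 / biallelic."""

    min_qual: float = 20.0
    min_dp: int = 10
    max_dp: int = 400
    min_maf: float = 0.02
    max_missing_fraction: float = 0.5
    biallelic_only: bool = True

    def validate(self) -> None:
        if self.min_dp >= self.max_dp:
            raise ParameterError("min_dp must be < max_dp")
        if not 0 <= self.min_maf <= 0.5:
            raise ParameterError("min_maf must lie in [0, 0.5]")
        if not 0 <= self.max_missing_fraction <= 1:
            raise ParameterError("max_missing_fraction must lie in [0, 1]")


def filter_variants(table: VariantTable, policy: FilterPolicy = FilterPolicy()
                    ) -> VariantTable:
    """Apply the per-sample mask then the site filters; order preserved.

    Per sample: genotype set to missing where the site QUAL < ``min_qual`` or
    the sample DP falls outside [min_dp, max_dp].  Sites are then dropped
    when not biallelic (if flagged), when the missing fraction exceeds
    ``max_missing_fraction``, or when the minor-allele frequency over the
    remaining called alleles is below ``min_maf``.  Idempotent.
    """
    policy.validate()
    if table.n_sites == 0:
        return table
    gt = table.gt.copy()
    qual = table.sites["qual"].to_numpy()
    for i in range(table.n_sites):
        for s in range(len(table.samples)):
            if gt[i, s] is None:
                continue
            if qual[i] < policy.min_qual or not policy.min_dp <= table.dp[i, s] <= policy.max_dp:
                gt[i, s] = None

    keep = np.ones(table.n_sites, dtype=bool)
    alts = table.sites["alts"]
    for i in range(table.n_sites):
        if policy.biallelic_only and len(alts.iat[i]) != 1:
            keep[i] = False
            continue
        called = [g for g in gt[i] if g is not None]
        missing_frac = 1 - len(called) / len(table.samples)
        if missing_frac > policy.max_missing_fraction:
            keep[i] = False
            continue
        alleles = [a for g in called for a in g]
        if not alleles:
            # MAF undefined with no called alleles; only a positive MAF
            # requirement can reject here (missingness already passed)
            keep[i] = policy.min_maf == 0
            continue
        counts = np.bincount(alleles, minlength=table.n_alleles(i))
        # non-major-allele fraction; equals the classical MAF at biallelic sites
        maf = 1.0 - counts.max() / len(alleles)
        if maf < policy.min_maf:
            keep[i] = False
    out = replace(table, gt=gt).subset_sites(keep)
    return out


# ---------------------------------------------------------------------------
# heterozygosity windows
# ---------------------------------------------------------------------------

def heterozygosity_windows(table: VariantTable, window_bp: int = 100_000,
                           mode: str = "per_snp") -> pd.DataFrame:
    """Heterozygosity in non-overlapping tiling windows.

    Returns a BED-like frame (chrom, start, end, sample, n_snps, n_het,
    value) with 0-based half-open windows.  ``per_snp``: value =
    n_het / n_snps (NaN when the window holds no SNPs); ``per_bp``: value =
    n_het / window_bp.  Chromosome lengths come from the table's contig
    metadata (falling back to the last SNP position).
    """
    if window_bp <= 0:
        raise ParameterError("window_bp must be positive")
    if mode not in ("per_snp", "per_bp"):
        raise ParameterError(f"unknown mode {mode!r}")
    rows = []
    for chrom, grp in table.sites.groupby("chrom", sort=False):
        length = table.contig_lengths.get(chrom, int(grp["pos"].max()))
        pos0 = grp["pos"].to_numpy() - 1
        idx = grp.index.to_numpy()
        win = pos0 // window_bp
        n_windows = max(int(np.ceil(length / window_bp)), int(win.max()) + 1 if len(win) else 1)
        for s, sample in enumerate(table.samples):
            called = np.array([table.gt[i, s] is not None for i in idx])
            het = np.array([table.is_het(i, s) for i in idx])
            n_snps = np.bincount(win[called], minlength=n_windows)
            n_het = np.bincount(win[het], minlength=n_windows)
            for w in range(n_windows):
                start = w * window_bp
                if mode == "per_snp":
                    value = n_het[w] / n_snps[w] if n_snps[w] else np.nan
                else:
                    value = n_het[w] / window_bp
                rows.append((chrom, start, min(start + window_bp, length), sample,
                             int(n_snps[w]), int(n_het[w]), value))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "sample",
                                       "n_snps", "n_het", "value"])


# ---------------------------------------------------------------------------
# allele-frequency profiles
# ---------------------------------------------------------------------------

@dataclass
class AlleleFrequencyProfile:
    """Per-site alternative-allele read fractions and their histogram.

    Bins are centered on multiples of ``bin_width`` (0.00, 0.02, ..., 1.00 by
    default) so that the haploid and diploid signatures land exactly on 1.0
    and 0.5.  ``modal_frequency`` is the center of the highest-mass bin.
    """

    sample: str
    fractions: np.ndarray
    bin_width: float
    bin_centers: np.ndarray
    histogram: np.ndarray
    modal_frequency: float
    n_skipped: int


def allele_frequency_profile(table: VariantTable, sample: str,
                             bin_width: float = 0.02,
                             sites: str = "auto") -> AlleleFrequencyProfile:
    """Alternative-allele read-fraction profile of one sample.

    ``sites``: ``"het"`` uses heterozygous genotypes (the diploid signature),
    ``"nonref"`` any genotype carrying an alternative allele (the haploid
    signature), ``"auto"`` picks by the sample's ploidy.  Per site the
    fraction is AD[alt] / sum(AD); zero-depth sites are skipped and counted.
    """
    s = table.sample_index(sample)
    if sites == "auto":
        sites = "het" if table.ploidy.get(sample, 2) >= 2 else "nonref"
    fracs = []
    n_skipped = 0
    for i in range(table.n_sites):
        g = table.gt[i, s]
        if g is None:
            continue
        if sites == "het" and len(set(g)) < 2:
            continue
        if sites == "nonref" and not any(a > 0 for a in g):
            continue
        advals = table.ad[i, s]
        total = sum(advals)
        if total == 0:
            n_skipped += 1
            continue
        alt_depth = sum(d for ai, d in enumerate(advals) if ai > 0)
        fracs.append(alt_depth / total)
    if n_skipped:
        logger.info("allele_frequency_profile(%s): skipped %d zero-depth sites",
                    sample, n_skipped)
    fracs = np.asarray(fracs)
    n_bins = int(round(1.0 / bin_width)) + 1
    centers = np.arange(n_bins) * bin_width
    edges = np.concatenate([centers - bin_width / 2, [centers[-1] + bin_width / 2]])
    hist, _ = np.histogram(fracs, bins=edges)
    modal = float(centers[int(np.argmax(hist))]) if len(fracs) else float("nan")
    return AlleleFrequencyProfile(sample=sample, fractions=fracs,
                                  bin_width=bin_width, bin_centers=centers,
                                  histogram=hist, modal_frequency=modal,
                                  n_skipped=n_skipped)


# ---------------------------------------------------------------------------
# IUPAC encoding and p-distances
# ---------------------------------------------------------------------------

def encode_iupac_matrix(table: VariantTable) -> pd.DataFrame:
    """Samples x sites character matrix with heterozygotes as IUPAC degenerate
    bases (e.g. K = G or T) and missing genotypes as N.

    Sites whose alleles are not single bases (indels) are skipped and the
    count logged.
    """
    cols, data = [], {s: [] for s in table.samples}
    n_skipped = 0
    for i, row in enumerate(table.sites.itertuples(index=False)):
        alleles = (row.ref,) + tuple(row.alts)
        if any(len(a) != 1 for a in alleles):
            n_skipped += 1
            continue
        cols.append(f"{row.chrom}:{row.pos}")
        for s, sample in enumerate(table.samples):
            g = table.gt[i, s]
            if g is None:
                data[sample].append("N")
                continue
            bases = {alleles[a] for a in g}
            if len(bases) == 1:
                data[sample].append(next(iter(bases)))
            else:
                data[sample].append(IUPAC_CODES[frozenset(bases)])
    if n_skipped:
        logger.info("encode_iupac_matrix: skipped %d non-SNP sites", n_skipped)
    return pd.DataFrame.from_dict(data, orient="index", columns=cols)


def p_distance_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pairwise p-distance: mismatching / compared sites, sites with N in
    either sample excluded, degenerate codes compared as literal symbols.
    A pair with zero comparable sites gets NaN (NJ then refuses the matrix).
    """
    if matrix.empty:
        raise ParameterError("empty character matrix")
    arr = matrix.to_numpy(dtype="U1")
    n = arr.shape[0]
    d = np.zeros((n, n))
    valid = arr != "N"
    for i in range(n):
        for j in range(i + 1, n):
            comp = valid[i] & valid[j]
            m = comp.sum()
            d[i, j] = d[j, i] = (arr[i, comp] != arr[j, comp]).sum() / m if m else np.nan
    return pd.DataFrame(d, index=matrix.index, columns=matrix.index)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def neighbor_joining(matrix: pd.DataFrame) -> str:
    """Classic neighbor joining; returns a newick string.

    At each step the pair minimising the Q-criterion is joined (ties broken
    toward the lexicographically smallest taxon-index pair); branch lengths
    follow the standard two-point formulas with negative lengths clamped to 0
    (clamp count logged).  Requires a complete matrix over >= 3 taxa.
    """
    labels = list(matrix.index)
    d = matrix.to_numpy(dtype=float).copy()
    if len(labels) < 3:
        raise ParameterError("neighbor joining needs >= 3 taxa")
    bad = np.argwhere(np.isnan(d))
    if len(bad):
        i, j = bad[0]
        raise ParameterError(f"incomplete distance matrix: ({labels[i]}, {labels[j]})")
    nodes = [str(l) for l in labels]
    active = list(range(len(labels)))
    n_clamped = 0
    while len(active) > 2:
        n = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (n - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # lexicographically smallest (i, j) among minima
        flat = np.argwhere(q == q.min())
        ii, jj = min((min(a, b), max(a, b)) for a, b in flat)
        i, j = active[ii], active[jj]
        dij = d[i, j]
        li = 0.5 * dij + (r[ii] - r[jj]) / (2 * (n - 2))
        lj = dij - li
        if li < 0 or lj < 0:
            n_clamped += 1
            li, lj = max(li, 0.0), max(lj, 0.0)
        new = f"({nodes[i]}:{li:.10g},{nodes[j]}:{lj:.10g})"
        # distances from the new node
        dnew = 0.5 * (d[i, :] + d[j, :] - dij)
        d = np.vstack([d, dnew])
        d = np.hstack([d, np.append(dnew, 0.0)[:, None]])
        nodes.append(new)
        active = [a for a in active if a not in (i, j)] + [len(nodes) - 1]
    i, j = active
    if n_clamped:
        logger.info("neighbor_joining: clamped %d negative branch lengths", n_clamped)
    final = max(d[i, j], 0.0)
    if "(" in nodes[j]:
        inner = nodes[j][1:-1]
        return f"({nodes[i]}:{final:.10g},{inner});"
    inner = nodes[i][1:-1] if "(" in nodes[i] else nodes[i]
    if "(" in nodes[i]:
        return f"({inner},{nodes[j]}:{final:.10g});"
    return f"({nodes[i]}:{final:.10g},{nodes[j]}:0);"


def tree_path_lengths(newick: str) -> pd.DataFrame:
    """Tip-to-tip path lengths of a newick tree (convenience for testing NJ
    against additive matrices)."""
    from io import StringIO
    from Bio import Phylo
    tree = Phylo.read(StringIO(newick), "newick")
    tips = tree.get_terminals()
    names = [t.name for t in tips]
    out = pd.DataFrame(0.0, index=names, columns=names)
    for a in tips:
        for b in tips:
            if a is not b:
                out.loc[a.name, b.name] = tree.distance(a, b)
    return out
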