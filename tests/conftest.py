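import numpy as np
import pandas as pd
import pytest

from hybridtriad import synthetic_data as sd


@pytest.fixture(scope="session")
def two_lineages():
    """Two haploid lineages, 2% diverged, one 100-kb chromosome."""
    cfg = sd.LineageSimConfig(n_chromosomes=1, chrom_length=100_000,
                              divergence_matrix=[[0, 0.02], [0.02, 0]], seed=1)
    return sd.simulate_lineages(cfg)


@pytest.fixture(scope="session")
def hybrid(two_lineages):
    return sd.make_hybrid(two_lineages,
                          sd.HybridSimConfig("L1", "L2", novel_mutation_rate=0.0,
                                             seed=2))


@pytest.fixture(scope="session")
def variant_table(two_lineages, hybrid):
    """Haploids L1/L2 plus the diploid hybrid, depth 50."""
    return sd.simulate_variant_table(
        two_lineages, {"L1": "L1", "L2": "L2", "hybrid": hybrid},
        depth=50, seed=3)


@pytest.fixture(scope="session")
def four_lineage_panel():
    """Two clades (within 0.5%, between 2%) of two lineages each."""
    w, d = 0.005, 0.02
    cfg = sd.LineageSimConfig(
        n_chromosomes=2, chrom_length=100_000,
        divergence_matrix=[[0, w, d, d], [w, 0, d, d],
                           [d, d, 0, w], [d, d, w, 0]], seed=7)
    return sd.simulate_lineages(cfg)


@pytest.fixture(scope="session")
def triad_sim():
    cfg = sd.TriadSimConfig(n_genes=2000, seed=11)
    tcm, ase, truth = sd.simulate_triad_counts(cfg)
    return cfg, tcm, ase, truth


def lineage_allele(lineages, lid, chrom, pos):
    return lineages.truth.lineage_mutations[lid].get(
        (chrom, pos), lineages.ancestor[chrom][pos])


def candidate_table(lineages, het):
    """Per-candidate allele table aligned to a het-site frame."""
    return pd.DataFrame({
        lid: [lineage_allele(lineages, lid, r.chrom, r.pos)
              for r in het.itertuples(index=False)]
        for lid in lineages.genomes})
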