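import numpy as np
import pandas as pd
import pytest

from tevland import simulate


SMALL_TREE = "(((A:0.3,B:0.3):0.4,(C:0.35,D:0.35):0.35):0.3,(REF:0.6,E:0.6):0.4);"


@pytest.fixture(scope="session")
def small_config():
    return simulate.SimulationConfig(
        seed=2, tree_spec=SMALL_TREE, reference_strain="REF",
        n_autosomes=2, autosome_length=10_000_000, x_length=10_000_000,
        n_genes=100, noise_pair_rate=0.0, read_depth=30,
    )


@pytest.fixture(scope="session")
def small_genome(small_config):
    return simulate.build_genome(small_config)


@pytest.fixture(scope="session")
def small_simulation(small_config, small_genome):
    events, presence = simulate.simulate_insertions(small_genome, small_config)
    return events, presence


def make_anchor_frame(rows):
    """rows: (strain, chrom, pos, orientation, mapq, mate_family)"""
    df = pd.DataFrame(rows, columns=[
        "strain", "chrom", "pos", "anchor_orientation", "mapq",
        "mate_family"])
    df["mate_mapped"] = 1
    return df.sort_values(["strain", "chrom", "pos"], ignore_index=True)


def clean_breakpoint_anchors(strain="s1", chrom="chr1", bp=10_000,
                             n_f=15, n_r=15, mapq=60, family="IAP",
                             spread=100):
    """A well-behaved anchor cluster around a breakpoint."""
    rows = []
    for i in range(n_f):
        rows.append((strain, chrom, bp - 1 - (i * spread) // max(n_f, 1),
                     "F", mapq, family))
    for i in range(n_r):
        rows.append((strain, chrom, bp + (i * spread) // max(n_r, 1),
                     "R", mapq, family))
    return make_anchor_frame(rows)
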