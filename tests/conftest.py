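import numpy as np
import pandas as pd
import pytest

from chromacross.fragment_io import FragmentSet, SampleMeta
from chromacross.synthetic_data import GenomeConfig, build_genome_model


def make_fs(intervals, genotype="WT", antibody="H3K4me3", replicate=1):
    """Build a FragmentSet from (chrom, start, end) tuples."""
    df = pd.DataFrame(intervals, columns=["chrom", "start", "end"])
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    return FragmentSet(df, SampleMeta(genotype, antibody, replicate))


@pytest.fixture(scope="session")
def default_genome():
    """The stock synthetic genome: 400 kb autosome + 80 kb X + 20 kb Y."""
    return build_genome_model(GenomeConfig(seed=7))


@pytest.fixture(scope="session")
def chrom_sizes(default_genome):
    return default_genome.chrom_sizes
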