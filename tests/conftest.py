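import numpy as np
import pandas as pd
import pytest

import drmeth
from drmeth import binning, io_formats
from drmeth.io_formats import GROUPS, CpGTable


def build_table(positions, counts, chrom="chr1", sample_groups=None):
    """Construct a CpGTable from explicit per-sample (meth, unmeth) lists.

    ``counts`` maps sample name -> list of (meth, unmeth) tuples aligned with
    ``positions``.
    """
    cols = {}
    for sample, pairs in counts.items():
        m, u = zip(*pairs)
        cols[(sample, "meth")] = np.asarray(m, dtype=np.int64)
        cols[(sample, "unmeth")] = np.asarray(u, dtype=np.int64)
    idx = pd.MultiIndex.from_arrays(
        [[chrom] * len(positions), list(positions)], names=["chrom", "pos"]
    )
    df = pd.DataFrame(cols, index=idx)
    df.columns = pd.MultiIndex.from_tuples(df.columns)
    if sample_groups is None:
        sample_groups = {s: GROUPS[i % 4] for i, s in enumerate(counts)}
    return CpGTable(df, sample_groups)


def group_table(positions, group_counts, chrom="chr1"):
    """CpGTable whose samples are the four groups themselves."""
    return build_table(positions, group_counts, chrom=chrom,
                       sample_groups={g: g for g in group_counts})


def prepare_bins(cfg):
    """Simulate + filter + bin, the standard desk-scale pipeline front end."""
    table, truth = drmeth.simdata.simulate_methylome(cfg)
    filtered = binning.filter_high_observation_regions(table)
    groups = binning.filter_min_coverage(io_formats.merge_replicates(filtered))
    return binning.make_bins(groups), truth, groups


@pytest.fixture(scope="session")
def default_sim():
    """One full default simulation shared by read-only tests."""
    cfg = drmeth.SimConfig(seed=1)
    table, truth = drmeth.simdata.simulate_methylome(cfg)
    filtered = binning.filter_high_observation_regions(table)
    groups = binning.filter_min_coverage(io_formats.merge_replicates(filtered))
    bins = binning.make_bins(groups)
    ann = drmeth.simdata.simulate_annotations(cfg)
    return {"config": cfg, "table": table, "truth": truth, "groups": groups,
            "bins": bins, "annotations": ann}
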