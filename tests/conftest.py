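import numpy as np
import pandas as pd
import pytest

from methylshift.cohort import CohortConfig, generate_cohort
from methylshift.io import SampleMethylome, common_sites, filter_min_coverage


def site_index(rows):
    """Build a (chrom, pos, strand) MultiIndex from (chrom, pos, strand) tuples."""
    return pd.MultiIndex.from_tuples(rows, names=("chrom", "pos", "strand"))


def make_sample(site_rows, sample_id="s", group="XX", age="PN4", region="STR", replicate=1):
    """Sample from rows of (chrom, pos, strand, context, c_reads, t_reads)."""
    idx = site_index([(c, p, s) for c, p, s, *_ in site_rows])
    df = pd.DataFrame(
        {
            "context": pd.Series([r[3] for r in site_rows], dtype=object, index=idx),
            "c_reads": np.array([r[4] for r in site_rows], dtype=np.int64),
            "t_reads": np.array([r[5] for r in site_rows], dtype=np.int64),
        },
        index=idx,
    )
    return SampleMethylome(sample_id, group, age, region, replicate, df)


def sample_from_levels(positions, levels, coverage=100, chrom="chr1", **kw):
    """Sample whose observed levels are exactly ``levels`` (counts = level*coverage)."""
    rows = []
    for p, lv in zip(positions, levels):
        c = int(round(lv * coverage))
        rows.append((chrom, p, "+", "CG", c, coverage - c))
    return make_sample(rows, **kw)


def pick(samples, group, age, region, min_reads=4):
    return [
        filter_min_coverage(s, min_reads)
        for s in samples
        if (s.group, s.age, s.region) == (group, age, region)
    ]


@pytest.fixture(scope="session")
def small_cohort():
    """A 5,000-CpG cohort with the default implanted effects (seed 11)."""
    cfg = CohortConfig(n_cpg=5_000, n_noncpg=1_000, seed=11)
    samples, truth = generate_cohort(cfg)
    return cfg, samples, truth


@pytest.fixture(scope="session")
def null_cohort():
    """A pure-null 5,000-CpG cohort: no implanted effects of any kind."""
    cfg = CohortConfig(
        n_cpg=5_000, n_noncpg=500, seed=23,
        sex_autosomal_frac=0.0, sex_chrx_frac=0.0,
        t_pn4_frac=0.0, t_pn60_frac=0.0,
        masc_fraction=0.0, age_noncpg_shift=0.0,
    )
    samples, truth = generate_cohort(cfg)
    return cfg, samples, truth


def cg_keys(samples):
    keys = common_sites(samples)
    ctx = samples[0].sites["context"].reindex(keys)
    return keys[(ctx == "CG").to_numpy()]
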