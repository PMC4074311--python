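"""Global methylation summaries by sequence context.

Global level = unweighted mean of per-site methylation fractions within a
context (CG, CHG or CHH).  Unweighted averaging treats each cytosine's
cell-population average equally and avoids read-depth bias; a read-weighted
variant is available via ``weighted=True``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from methylshift.io import CONTEXTS, SampleMethylome, ValidationError, common_sites
from methylshift.stats import TTestResult, pearson_matrix, pooled_t


@dataclass
class GlobalLevel:
    sample_id: str
    context: str
    level: float
    n_sites: int


def global_level(m: SampleMethylome, context: str, weighted: bool = False) -> GlobalLevel:
    """Mean methylation over all of a sample's sites in one context."""
    if context not in CONTEXTS:
        raise ValueError(f"context must be one of {CONTEXTS}")
    mask = (m.sites["context"] == context).to_numpy()
    if not mask.any():
        raise ValidationError(f"sample {m.sample_id} has no {context} sites")
    c = m.sites["c_reads"].to_numpy()[mask]
    t = m.sites["t_reads"].to_numpy()[mask]
    if weighted:
        level = c.sum() / (c.sum() + t.sum())
    else:
        level = float(np.mean(c / (c + t)))
    return GlobalLevel(m.sample_id, context, float(level), int(mask.sum()))


def global_table(samples: Sequence[SampleMethylome], weighted: bool = False) -> pd.DataFrame:
    """Tidy per-sample global levels for every context present."""
    rows = []
    for m in samples:
        for ctx in CONTEXTS:
            if (m.sites["context"] == ctx).any():
                gl = global_level(m, ctx, weighted=weighted)
                rows.append({
                    "sample_id": m.sample_id, "group": m.group, "age": m.age,
                    "region": m.region, "context": ctx, "level": gl.level,
                    "n_sites": gl.n_sites,
                })
    return pd.DataFrame(rows)


def compare_global(
    group_a: Sequence[GlobalLevel], group_b: Sequence[GlobalLevel]
) -> TTestResult:
    """Pooled t-test on two groups of per-sample global levels."""
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("compare_global needs >=2 samples per group")
    return pooled_t([g.level for g in group_a], [g.level for g in group_b])


def correlation_matrix(
    samples: Sequence[SampleMethylome],
    keys: pd.MultiIndex | None = None,
    context: str = "CG",
) -> pd.DataFrame:
    """Pearson correlation of per-site levels over the samples' common sites."""
    if keys is None:
        keys = common_sites(samples)
    ctx = samples[0].sites["context"].reindex(keys)
    keys = keys[(ctx == context).to_numpy()]
    X = np.vstack([s.levels().reindex(keys).to_numpy() for s in samples])
    R = pearson_matrix(X)
    ids = [s.sample_id for s in samples]
    return pd.DataFrame(R, index=ids, columns=ids)
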