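"""Masculinization of the methylome at sexually dimorphic CpGs.

A CpG is *sexually dimorphic* when control females (XX) and control males
(XY) differ by at least 15% in mean methylation with a per-site pooled-t
p ≤ 0.05 (both boundaries inclusive).  At each such site the male mean is
mapped to 0 and the female mean to 100; the hormone-treated group's (XX+T)
mean is linearly rescaled onto this axis:

    score = 100 · (mean_XXT − mean_XY) / (mean_XX − mean_XY)

Sites scoring ≤ 50 are *masculinized*.  Scores are clipped to [0, 100] for
summaries and histograms; the raw value is kept alongside.  A two-sample
Kolmogorov–Smirnov test compares score distributions between ages.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from methylshift.dmr import site_tests
from methylshift.io import SampleMethylome
from methylshift.stats import KsResult, ks_two_sample


def dimorphic_sites(
    xx_samples: Sequence[SampleMethylome],
    xy_samples: Sequence[SampleMethylome],
    keys: pd.MultiIndex | None = None,
    min_delta: float = 0.15,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Sites with |mean_XX − mean_XY| ≥ min_delta and p ≤ alpha.

    Returns a site-indexed table with columns ``mean_xx, mean_xy, delta_sex,
    p_sex``.  delta_sex = mean_XX − mean_XY.
    """
    tests = site_tests(xx_samples, xy_samples, keys)
    keep = (tests["delta"].abs() >= min_delta) & (tests["p"] <= alpha)
    out = tests.loc[keep, ["mean_a", "mean_b", "delta", "p"]].rename(
        columns={"mean_a": "mean_xx", "mean_b": "mean_xy",
                 "delta": "delta_sex", "p": "p_sex"}
    )
    return out


def masc_scores(
    dimorphic: pd.DataFrame, xxt_samples: Sequence[SampleMethylome]
) -> pd.DataFrame:
    """Score XX+T methylation on the male(0)–female(100) axis per dimorphic site.

    Sites missing from any XX+T sample are dropped.  ``score_raw`` is the
    unclipped value; ``score`` is clipped to [0, 100].
    """
    keys = dimorphic.index
    for s in xxt_samples:
        keys = keys.intersection(s.site_keys())
    out = dimorphic.loc[keys.sort_values()].copy()
    lv = np.column_stack([s.levels().reindex(out.index).to_numpy() for s in xxt_samples])
    out["mean_xxt"] = lv.mean(axis=1)
    denom = out["mean_xx"] - out["mean_xy"]
    if (denom == 0).any():
        raise RuntimeError("degenerate site with mean_xx == mean_xy passed the filter")
    out["score_raw"] = 100.0 * (out["mean_xxt"] - out["mean_xy"]) / denom
    out["score"] = out["score_raw"].clip(0.0, 100.0)
    return out


def masc_score(mean_xx: float, mean_xy: float, mean_xxt: float) -> float:
    """Scalar masculinization score (clipped to [0, 100])."""
    if mean_xx == mean_xy:
        raise ValueError("mean_xx == mean_xy: site is not dimorphic")
    raw = 100.0 * (mean_xxt - mean_xy) / (mean_xx - mean_xy)
    return float(np.clip(raw, 0.0, 100.0))


def masc_summary(
    scores: Sequence[float], bin_width: float = 5.0
) -> tuple[int, int, pd.DataFrame]:
    """(n_masculinized, n_total, histogram) for a set of clipped scores.

    Masculinized = score ≤ 50, boundary inclusive.  The histogram covers
    [0, 100] with ``bin_width``-wide bins (right-closed last bin).
    """
    s = np.asarray(list(scores), dtype=float)
    n_total = s.size
    n_masc = int((s <= 50.0).sum())
    edges = np.arange(0.0, 100.0 + bin_width / 2, bin_width)
    counts, _ = np.histogram(s, bins=edges)
    hist = pd.DataFrame({"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts})
    return n_masc, n_total, hist


def shift_test(scores_a: Sequence[float], scores_b: Sequence[float]) -> KsResult:
    """KS test for a distribution shift between two score sets (e.g. PN4 vs PN60)."""
    return ks_two_sample(scores_a, scores_b)
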