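"""Fragment-level DMR calling with simulated-null FDR calibration.

The procedure, per pairwise group comparison:

1. at every common cytosine (covered by ≥4 reads in all samples of both
   groups), a pooled two-sample t-test on the per-sample methylation levels
   yields a t-score and a level difference (delta = mean(A) − mean(B));
2. t-scores of the sites in each fragment are averaged into a fragment
   **z-score**; the fragment delta is the unweighted mean of site deltas;
3. a fragment is a DMR when |delta| ≥ 10%, at least three of its cytosines
   were observed in all relevant samples, and |z| exceeds a threshold.

The threshold is calibrated against a **simulated null methylome**: at each
site the across-sample mean level Pm becomes the success probability of a
binomial draw at the real per-sample coverage, so the simulated cohort keeps
the real methylation landscape and statistical power but carries no group
differences.  For each candidate threshold, FDR = (DMRs called in the
simulation) / (DMRs called in the real data); the most lenient threshold
with FDR below the target (default 10%) is selected.

Tables are pandas DataFrames: site tests are indexed by site key with
columns ``mean_a, mean_b, delta, t, p``; fragment tests and DMRs are indexed
by ``frag_id`` with columns ``chrom, start, end, n_obs_sites, z, delta,
mean_a, mean_b`` (DMRs add ``direction``).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from methylshift._rng import child_rng
from methylshift.fragments import assign_sites
from methylshift.io import SampleMethylome, common_sites
from methylshift.stats import pooled_t_arrays

DEFAULT_Z_GRID = tuple(np.arange(1.0, 5.0 + 1e-9, 0.25))
DEFAULT_MIN_DELTA = 0.10
DEFAULT_MIN_SITES = 3


class ThresholdSelectionError(RuntimeError):
    """No threshold on the grid met the FDR target."""


@dataclass
class FdrCurve:
    """Estimated FDR as a function of the |z| cutoff.

    ``thresholds`` runs from lenient (small |z|) to strict; ``n_sim`` may be
    fractional when averaged over several simulated cohorts.
    """

    thresholds: np.ndarray
    n_real: np.ndarray
    n_sim: np.ndarray
    fdr: np.ndarray
    target_fdr: float = 0.10
    selected_threshold: float | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "threshold": self.thresholds,
            "n_real": self.n_real,
            "n_sim": self.n_sim,
            "fdr": self.fdr,
        })


# ---------------------------------------------------------------------------
# Per-site testing
# ---------------------------------------------------------------------------

def _level_matrix(samples: Sequence[SampleMethylome], keys: pd.MultiIndex) -> np.ndarray:
    cols = [s.levels().reindex(keys).to_numpy() for s in samples]
    return np.column_stack(cols)


def site_tests(
    samples_a: Sequence[SampleMethylome],
    samples_b: Sequence[SampleMethylome],
    keys: pd.MultiIndex | None = None,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Pooled t-test at every site observed in all samples of both groups.

    ``keys`` defaults to the common sites of the two groups; keys missing
    from any sample are excluded and recorded in ``result.attrs["dropped"]``.
    """
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise ValueError("site_tests needs >=2 samples per group")
    everyone = list(samples_a) + list(samples_b)
    observed = common_sites(everyone)
    if keys is None:
        keys, dropped = observed, observed[:0]
    else:
        tested = keys.intersection(observed)
        dropped = keys.difference(tested)
        keys = tested.sort_values()

    la = _level_matrix(samples_a, keys)
    lb = _level_matrix(samples_b, keys)
    t, p, delta = pooled_t_arrays(la, lb, equal_var=equal_var)
    out = pd.DataFrame(
        {
            "mean_a": la.mean(axis=1),
            "mean_b": lb.mean(axis=1),
            "delta": delta,
            "t": t,
            "p": p,
        },
        index=keys,
    )
    out.attrs["dropped"] = dropped
    return out


# ---------------------------------------------------------------------------
# Fragment aggregation and calling
# ---------------------------------------------------------------------------

def fragment_z(fragments: pd.DataFrame, tests: pd.DataFrame) -> pd.DataFrame:
    """Average per-site t-scores (and deltas) into fragment z-scores.

    Fragments with zero tested sites are omitted.  ``n_obs_sites`` counts
    member sites present in the site-test table, i.e. observed in all
    relevant samples.
    """
    frag_of = assign_sites(tests.index, fragments)
    tab = tests[["t", "delta", "mean_a", "mean_b"]].copy()
    tab["frag_id"] = frag_of.to_numpy()
    tab = tab[tab["frag_id"] >= 0]
    if len(tab) == 0:
        out = fragments.iloc[:0].copy()
        for c in ("n_obs_sites", "z", "delta", "mean_a", "mean_b"):
            out[c] = []
        return out
    g = tab.groupby("frag_id")
    agg = g.agg(
        n_obs_sites=("t", "size"),
        z=("t", "mean"),
        delta=("delta", "mean"),
        mean_a=("mean_a", "mean"),
        mean_b=("mean_b", "mean"),
    )
    out = fragments.loc[agg.index, ["chrom", "start", "end"]].join(agg)
    out.index.name = "frag_id"
    return out


def call_dmrs(
    frag_tests: pd.DataFrame,
    z_threshold: float,
    min_delta: float = DEFAULT_MIN_DELTA,
    min_sites: int = DEFAULT_MIN_SITES,
) -> pd.DataFrame:
    """Apply the three DMR filters to a fragment-test table.

    ``z_threshold`` is the magnitude cutoff: fragments with |z| ≥ threshold
    pass (both directions; the sign is recorded as ``direction``).  The
    delta filter is boundary-inclusive (|delta| ≥ ``min_delta``).
    """
    z = frag_tests["z"].to_numpy()
    keep = (
        (np.abs(frag_tests["delta"].to_numpy()) >= min_delta)
        & (frag_tests["n_obs_sites"].to_numpy() >= min_sites)
        & (np.abs(z) >= z_threshold)
    )
    out = frag_tests.loc[keep].copy()
    out["direction"] = np.where(out["delta"] > 0, "hyper_in_A", "hypo_in_A")
    return out


def select_extreme_dmrs(dmrs: pd.DataFrame) -> pd.DataFrame:
    """Extremely differentiated DMRs: length > 50 bp, |delta| ≥ 25%, |z| ≥ 3.5."""
    length = dmrs["end"] - dmrs["start"]
    keep = (length > 50) & (dmrs["delta"].abs() >= 0.25) & (dmrs["z"].abs() >= 3.5)
    return dmrs.loc[keep].copy()


# ---------------------------------------------------------------------------
# Simulated null and FDR
# ---------------------------------------------------------------------------

def simulate_null(
    samples: Sequence[SampleMethylome],
    keys: pd.MultiIndex | None = None,
    seed: int = 0,
) -> list[SampleMethylome]:
    """Coverage-matched binomial null methylomes for a comparison.

    Pm at each site is the average methylation level over **all** real
    samples in the comparison; each simulated sample keeps its real per-site
    coverage n and draws c_reads ~ Binomial(n, Pm) independently.  Group
    structure therefore vanishes while the methylation landscape (genes,
    repeats, promoters) and statistical power are preserved.
    """
    if len(samples) == 0:
        raise ValueError("simulate_null needs at least one sample")
    if keys is None:
        keys = common_sites(samples)
    pm = np.mean([s.levels().reindex(keys).to_numpy() for s in samples], axis=0)
    pm = np.clip(pm, 0.0, 1.0)
    rng = np.random.default_rng(seed)
    out = []
    context = samples[0].sites["context"].reindex(keys).to_numpy()
    for s in samples:
        cov = s.coverage().reindex(keys).to_numpy().astype(np.int64)
        c = rng.binomial(cov, pm)
        sites = pd.DataFrame(
            {"context": context, "c_reads": c, "t_reads": cov - c}, index=keys
        )
        out.append(dataclasses.replace(s, sample_id=s.sample_id + "_sim", sites=sites))
    return out


def _counts_by_threshold(
    frag_tests: pd.DataFrame,
    thresholds: np.ndarray,
    min_delta: float,
    min_sites: int,
) -> np.ndarray:
    """DMR count at each |z| cutoff (vectorized; non-increasing in the cutoff)."""
    ok = (
        (frag_tests["delta"].abs().to_numpy() >= min_delta)
        & (frag_tests["n_obs_sites"].to_numpy() >= min_sites)
    )
    z = np.abs(frag_tests["z"].to_numpy()[ok])
    z = z[~np.isnan(z)]
    return np.array([(z >= th).sum() for th in thresholds], dtype=float)


def fdr_curve(
    samples_a: Sequence[SampleMethylome],
    samples_b: Sequence[SampleMethylome],
    fragments: pd.DataFrame,
    keys: pd.MultiIndex | None = None,
    thresholds: Sequence[float] = DEFAULT_Z_GRID,
    min_delta: float = DEFAULT_MIN_DELTA,
    min_sites: int = DEFAULT_MIN_SITES,
    seed: int = 0,
    n_sim_reps: int = 1,
    equal_var: bool = True,
    real_tests: pd.DataFrame | None = None,
) -> FdrCurve:
    """Estimate the FDR curve by re-running the full caller on simulated nulls.

    One simulated cohort per rep (default 1) undergoes the identical
    site-test → fragment-z → three-filter procedure as the real data;
    FDR(threshold) = n_sim / n_real, with the conventions FDR = 1 when
    n_real = 0 but n_sim > 0, and FDR = 0 when both are 0.
    """
    thresholds = np.asarray(list(thresholds), dtype=float)
    if thresholds.size == 0:
        raise ValueError("empty threshold grid")
    if np.any(np.diff(thresholds) <= 0):
        raise ValueError("thresholds must increase from lenient to strict")
    if n_sim_reps < 1:
        raise ValueError("n_sim_reps must be >= 1")

    everyone = list(samples_a) + list(samples_b)
    if keys is None:
        keys = common_sites(everyone)
    if real_tests is None:
        tests = site_tests(samples_a, samples_b, keys, equal_var=equal_var)
    else:
        tests = real_tests
    real_frag = fragment_z(fragments, tests)
    n_real = _counts_by_threshold(real_frag, thresholds, min_delta, min_sites)

    n_a = len(samples_a)
    n_sim = np.zeros_like(n_real)
    for rep in range(n_sim_reps):
        rng = child_rng(seed, "null_rep", rep)
        sim = simulate_null(everyone, keys, seed=int(rng.integers(2**31)))
        sim_tests = site_tests(sim[:n_a], sim[n_a:], keys, equal_var=equal_var)
        sim_frag = fragment_z(fragments, sim_tests)
        n_sim += _counts_by_threshold(sim_frag, thresholds, min_delta, min_sites)
    n_sim /= n_sim_reps

    with np.errstate(divide="ignore", invalid="ignore"):
        fdr = n_sim / n_real
    fdr = np.where(n_real > 0, fdr, np.where(n_sim > 0, 1.0, 0.0))
    return FdrCurve(thresholds, n_real, n_sim, fdr)


def select_threshold(curve: FdrCurve, target_fdr: float = 0.10) -> float:
    """Most lenient grid threshold with estimated FDR strictly below target."""
    below = np.nonzero(curve.fdr < target_fdr)[0]
    if below.size == 0:
        raise ThresholdSelectionError(
            f"no threshold on the grid reaches FDR < {target_fdr:g} "
            f"(min estimated FDR {np.nanmin(curve.fdr):.3g})"
        )
    th = float(curve.thresholds[below[0]])
    curve.target_fdr = target_fdr
    curve.selected_threshold = th
    return th


# ---------------------------------------------------------------------------
# Output helpers
# ---------------------------------------------------------------------------

def dmrs_to_bed(dmrs: pd.DataFrame, gene_names: dict[int, list[str]] | None = None) -> str:
    """BED6 text: name = ';'-joined associated genes, score = 1000·|delta| capped."""
    lines = []
    for frag_id, row in dmrs.iterrows():
        name = ";".join(gene_names.get(frag_id, [])) if gene_names else "."
        score = int(min(1000, round(1000 * abs(row["delta"]))))
        strand = "+" if row["delta"] >= 0 else "-"
        lines.append(
            f"{row['chrom']}\t{int(row['start'])}\t{int(row['end'])}\t{name or '.'}"
            f"\t{score}\t{strand}"
        )
    return "\n".join(lines) + ("\n" if lines else "")
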