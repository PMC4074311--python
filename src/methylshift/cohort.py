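"""Synthetic RRBS cohorts with implanted effects and known ground truth.

The generator emulates the statistical structure of a three-group
(XX / XY / XX+T), two-age (PN4 / PN60), two-region (striatum, BNST/POA)
methylome study with two biological replicates per group:

* CpG sites laid out in MspI-fragment-like clusters (default 5 sites per
  fragment, 40 bp apart, fragments 1 kb apart) across named autosomes and
  chrX;
* per-site baseline methylation from a bimodal beta mixture (unmethylated
  island-like mode near 0.05, methylated mode near 0.85);
* read coverage per site and sample from a negative binomial with mean 58;
* methylated-read counts from Binomial(coverage, true mean) — the same
  sampling model the null simulation assumes;
* implanted effects: autosomal sex differences (male-hyper biased), X-linked
  sex differences (female-hyper biased, mimicking X inactivation),
  testosterone effects that are rare at PN4 and abundant at PN60
  (hyper-in-XX+T biased), per-site masculinization of dimorphic CpGs at
  PN60 (XX+T true mean set to the XY mean with probability f), and an
  age-driven increase of non-CpG (CHG/CHH) methylation.

Effects are drawn independently per brain region.  Every random draw flows
from ``config.seed`` through named substreams, so the same config yields a
byte-identical cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from methylshift._rng import child_rng
from methylshift.io import (
    AGES,
    GROUPS,
    REGIONS,
    GeneModel,
    IntervalTrack,
    SampleMethylome,
    ValidationError,
    write_site_calls,
)

_MU_LO, _MU_HI = 0.02, 0.98  # clip true means away from 0/1


@dataclass
class CohortConfig:
    """Study-design and effect parameters of a synthetic cohort."""

    n_cpg: int = 50_000
    n_noncpg: int = 6_000
    chromosomes: tuple[str, ...] = ("chr1", "chr2", "chr3", "chr4", "chrX")
    chrx_fraction: float = 0.15
    sites_per_fragment: int = 5
    site_spacing: int = 40
    fragment_gap: int = 1000
    # baseline methylation mixture
    weight_low: float = 0.5
    low_mode_mean: float = 0.05
    high_mode_mean: float = 0.85
    mode_concentration: float = 60.0
    # sequencing
    coverage_mean: float = 58.0
    coverage_dispersion: float = 10.0
    replicates: int = 2
    # sex effects (stable across ages)
    sex_autosomal_frac: float = 0.03
    male_hyper_bias: float = 0.92
    sex_chrx_frac: float = 0.15
    female_hyper_bias: float = 0.85
    sex_delta: float = 0.30
    # testosterone effects (late-emerging: rare at PN4, abundant at PN60)
    t_pn4_frac: float = 0.002
    t_pn60_frac: float = 0.04
    t_delta: float = 0.30
    xxt_hyper_bias: float = 0.96
    # share of PN60 testosterone fragments drawn on sex-affected fragments.
    # Defaults to 0: overlap between called testosterone- and sex-affected
    # gene sets then emerges from masculinization alone, instead of being
    # implanted a second time on top of it.
    t_sex_overlap: float = 0.0
    # masculinization of dimorphic sites at PN60
    masc_fraction: float = 0.7
    # non-CpG context
    noncpg_level: float = 0.02
    age_noncpg_shift: float = 0.02
    seed: int = 0
    # optional explicit effect placement (region -> fragment ids); overrides draws
    sex_fragments: dict | None = None
    t_pn60_fragments: dict | None = None

    def validate(self) -> None:
        bad = []
        for name in ("chrx_fraction", "weight_low", "sex_autosomal_frac",
                     "male_hyper_bias", "sex_chrx_frac", "female_hyper_bias",
                     "t_pn4_frac", "t_pn60_frac", "xxt_hyper_bias",
                     "t_sex_overlap", "masc_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                bad.append(f"{name}={v} not in [0,1]")
        for name in ("sex_delta", "t_delta"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                bad.append(f"{name}={v} not in (0,1)")
        if self.n_cpg < self.sites_per_fragment:
            bad.append("n_cpg smaller than one fragment")
        if self.replicates < 2:
            bad.append("replicates must be >= 2 for group testing")
        if bad:
            raise ValidationError("invalid CohortConfig: " + "; ".join(bad))


@dataclass
class GroundTruth:
    """Generating quantities of a cohort, for parameter-recovery tests.

    ``fragments`` is the global fragment layout; ``effects[region]`` holds
    per-fragment effect directions (0 = none) and a combined label;
    ``masc[region]`` labels each dimorphic (sex-affected) CpG as masculinized
    or not at PN60; ``true_means[(group, age, region)]`` are the per-site
    generating means aligned to ``site_index``.
    """

    site_index: pd.MultiIndex
    frag_of_site: np.ndarray           # frag_id per CpG site, -1 for non-CpG
    fragments: pd.DataFrame            # frag_id -> chrom, start, end
    baseline: np.ndarray               # per-site baseline mean (all contexts)
    effects: dict[str, pd.DataFrame] = field(default_factory=dict)
    masc: dict[str, pd.Series] = field(default_factory=dict)
    true_means: dict[tuple[str, str, str], np.ndarray] = field(default_factory=dict)

    def effect_fragments(self, region: str, kind: str) -> np.ndarray:
        """Fragment ids carrying a given effect ('sex', 't_pn4', 't_pn60')."""
        eff = self.effects[region]
        col = {"sex": "sex_dir", "t_pn4": "t4_dir", "t_pn60": "t60_dir"}[kind]
        return eff.index.to_numpy()[eff[col].to_numpy() != 0]


def _layout(config: CohortConfig) -> tuple[pd.DataFrame, pd.MultiIndex, np.ndarray, np.ndarray]:
    """Fragment layout and the full site index (CpG clusters + non-CpG tail)."""
    n_frag = int(np.ceil(config.n_cpg / config.sites_per_fragment))
    n_x = int(round(config.chrx_fraction * n_frag))
    autosomes = [c for c in config.chromosomes if c != "chrX"]
    has_x = "chrX" in config.chromosomes
    if not has_x:
        n_x = 0
    per_auto = (n_frag - n_x) // max(len(autosomes), 1)
    counts = {c: per_auto for c in autosomes}
    if autosomes:
        counts[autosomes[0]] += (n_frag - n_x) - per_auto * len(autosomes)
    if has_x:
        counts["chrX"] = n_x

    span = (config.sites_per_fragment - 1) * config.site_spacing
    step = span + 1 + config.fragment_gap
    frag_rows, chroms, poss, frag_ids, ctxs = [], [], [], [], []
    fid = 0
    for chrom in config.chromosomes:
        for j in range(counts.get(chrom, 0)):
            start = 1000 + j * step
            sites = [start + i * config.site_spacing
                     for i in range(config.sites_per_fragment)]
            frag_rows.append((chrom, sites[0], sites[-1] + 1))
            chroms.extend([chrom] * len(sites))
            poss.extend(sites)
            frag_ids.extend([fid] * len(sites))
            ctxs.extend(["CG"] * len(sites))
            fid += 1
    # non-CpG sites: past the CpG block of each chromosome, far from fragments
    n_nc = config.n_noncpg
    if n_nc:
        chrom0 = config.chromosomes[0]
        base = 1000 + max(counts.get(chrom0, 0), *counts.values()) * step + 100_000
        for i in range(n_nc):
            chroms.append(chrom0)
            poss.append(base + i * 50)
            frag_ids.append(-1)
            ctxs.append("CHG" if i % 2 == 0 else "CHH")

    fragments = pd.DataFrame(frag_rows, columns=["chrom", "start", "end"])
    fragments.index.name = "frag_id"
    idx = pd.MultiIndex.from_arrays(
        [np.array(chroms, dtype=object), np.array(poss, dtype=np.int64),
         np.array(["+"] * len(poss), dtype=object)],
        names=("chrom", "pos", "strand"),
    )
    return fragments, idx, np.array(frag_ids, dtype=np.int64), np.array(ctxs, dtype=object)


def _beta_mixture(rng: np.random.Generator, n: int, config: CohortConfig) -> np.ndarray:
    low = rng.random(n) < config.weight_low
    c = config.mode_concentration
    mu = np.where(low, config.low_mode_mean, config.high_mode_mean)
    return np.clip(rng.beta(mu * c, (1 - mu) * c), _MU_LO, _MU_HI)


def _draw_effect_dirs(
    rng: np.random.Generator, n_frag: int, chosen: np.ndarray, hyper_bias: float
) -> np.ndarray:
    dirs = np.zeros(n_frag, dtype=np.int64)
    signs = np.where(rng.random(chosen.size) < hyper_bias, 1, -1)
    dirs[chosen] = signs
    return dirs


def _region_effects(config: CohortConfig, fragments: pd.DataFrame, region: str) -> pd.DataFrame:
    n_frag = len(fragments)
    is_x = (fragments["chrom"] == "chrX").to_numpy()
    rng = child_rng(config.seed, "effects", region)

    if config.sex_fragments is not None and region in config.sex_fragments:
        sex_chosen = np.asarray(sorted(config.sex_fragments[region]), dtype=np.int64)
        sex_dir = _draw_effect_dirs(rng, n_frag, sex_chosen, config.male_hyper_bias)
    else:
        auto_ids = np.nonzero(~is_x)[0]
        x_ids = np.nonzero(is_x)[0]
        n_auto = int(round(config.sex_autosomal_frac * auto_ids.size))
        n_x = int(round(config.sex_chrx_frac * x_ids.size))
        a_chosen = rng.choice(auto_ids, size=n_auto, replace=False) if n_auto else np.empty(0, int)
        x_chosen = rng.choice(x_ids, size=n_x, replace=False) if n_x else np.empty(0, int)
        sex_dir = np.zeros(n_frag, dtype=np.int64)
        # autosomal: +1 means XY-hyper; X-linked: biased toward XX-hyper (-1)
        sex_dir[a_chosen] = np.where(rng.random(a_chosen.size) < config.male_hyper_bias, 1, -1)
        sex_dir[x_chosen] = np.where(rng.random(x_chosen.size) < config.female_hyper_bias, -1, 1)
        sex_chosen = np.sort(np.concatenate([a_chosen, x_chosen]))

    # testosterone PN4: rare, drawn anywhere
    n_t4 = int(round(config.t_pn4_frac * n_frag))
    t4_chosen = rng.choice(n_frag, size=n_t4, replace=False) if n_t4 else np.empty(0, int)
    t4_dir = _draw_effect_dirs(rng, n_frag, t4_chosen, config.xxt_hyper_bias)

    # testosterone PN60: abundant, a configurable share overlapping sex fragments
    if config.t_pn60_fragments is not None and region in config.t_pn60_fragments:
        t60_chosen = np.asarray(sorted(config.t_pn60_fragments[region]), dtype=np.int64)
    else:
        n_t60 = int(round(config.t_pn60_frac * n_frag))
        n_ov = min(int(round(config.t_sex_overlap * n_t60)), sex_chosen.size)
        ov = rng.choice(sex_chosen, size=n_ov, replace=False) if n_ov else np.empty(0, int)
        rest_pool = np.setdiff1d(np.arange(n_frag), sex_chosen)
        n_rest = min(n_t60 - n_ov, rest_pool.size)
        rest = rng.choice(rest_pool, size=n_rest, replace=False) if n_rest else np.empty(0, int)
        t60_chosen = np.sort(np.concatenate([ov, rest]))
    t60_dir = _draw_effect_dirs(rng, n_frag, t60_chosen, config.xxt_hyper_bias)

    label = np.full(n_frag, "none", dtype=object)
    label[t4_dir != 0] = "testosterone"
    label[t60_dir != 0] = "testosterone"
    label[sex_dir != 0] = "sex"
    label[(sex_dir != 0) & ((t4_dir != 0) | (t60_dir != 0))] = "both"
    return pd.DataFrame(
        {"sex_dir": sex_dir, "t4_dir": t4_dir, "t60_dir": t60_dir, "label": label},
        index=fragments.index,
    )


def generate_cohort(config: CohortConfig) -> tuple[list[SampleMethylome], GroundTruth]:
    """Generate the full 12-group factorial cohort plus its ground truth.

    Returns 3 groups × 2 ages × 2 regions × ``replicates`` samples.  With all
    effect fractions at zero the cohort is a pure null: every group shares
    the same true mean at every site.
    """
    config.validate()
    fragments, idx, frag_of, ctx = _layout(config)
    n_sites = len(idx)
    is_cpg = ctx == "CG"

    rng_base = child_rng(config.seed, "baseline")
    baseline = np.empty(n_sites)
    baseline[is_cpg] = _beta_mixture(rng_base, int(is_cpg.sum()), config)
    baseline[~is_cpg] = np.clip(config.noncpg_level, _MU_LO, _MU_HI)

    truth = GroundTruth(idx, frag_of, fragments, baseline)
    samples: list[SampleMethylome] = []

    for region in REGIONS:
        eff = _region_effects(config, fragments, region)
        truth.effects[region] = eff
        sex_dir_site = np.where(frag_of >= 0, eff["sex_dir"].to_numpy()[np.clip(frag_of, 0, None)], 0)
        t4_dir_site = np.where(frag_of >= 0, eff["t4_dir"].to_numpy()[np.clip(frag_of, 0, None)], 0)
        t60_dir_site = np.where(frag_of >= 0, eff["t60_dir"].to_numpy()[np.clip(frag_of, 0, None)], 0)

        # per-site masculinization labels for the dimorphic (sex-affected) CpGs
        dim_mask = sex_dir_site != 0
        rng_m = child_rng(config.seed, "masc", region)
        masc_site = np.zeros(n_sites, dtype=bool)
        masc_site[dim_mask] = rng_m.random(int(dim_mask.sum())) < config.masc_fraction
        truth.masc[region] = pd.Series(masc_site[dim_mask], index=idx[dim_mask],
                                       name="is_masculinized")

        for age in AGES:
            age_shift = config.age_noncpg_shift if age == "PN60" else 0.0
            mu_xx = baseline.copy()
            mu_xx[~is_cpg] = np.clip(mu_xx[~is_cpg] + age_shift, _MU_LO, _MU_HI)
            mu_xy = np.clip(mu_xx + sex_dir_site * config.sex_delta, _MU_LO, _MU_HI)
            mu_xxt = mu_xx.copy()
            if age == "PN4":
                mu_xxt = np.clip(mu_xxt + t4_dir_site * config.t_delta, _MU_LO, _MU_HI)
            else:
                mu_xxt = np.clip(mu_xxt + t60_dir_site * config.t_delta, _MU_LO, _MU_HI)
                mu_xxt = np.where(masc_site, mu_xy, mu_xxt)
            mus = {"XX": mu_xx, "XY": mu_xy, "XXT": mu_xxt}
            for group in GROUPS:
                truth.true_means[(group, age, region)] = mus[group]
                for rep in range(1, config.replicates + 1):
                    rng = child_rng(config.seed, "sample", group, age, region, rep)
                    k = config.coverage_dispersion
                    p_nb = k / (k + config.coverage_mean)
                    cov = rng.negative_binomial(k, p_nb, size=n_sites)
                    c = rng.binomial(cov, mus[group])
                    sites = pd.DataFrame(
                        {"context": ctx, "c_reads": c, "t_reads": cov - c}, index=idx
                    )
                    samples.append(SampleMethylome(
                        sample_id=f"{group}_{age}_{region}_{rep}",
                        group=group, age=age, region=region, replicate=rep,
                        sites=sites,
                    ))
    return samples, truth


# ---------------------------------------------------------------------------
# Toy annotation
# ---------------------------------------------------------------------------

def generate_annotation(
    config: CohortConfig,
    truth: GroundTruth,
    fragments_per_gene: int = 4,
    cgi_threshold: float = 0.3,
) -> tuple[list[GeneModel], list[IntervalTrack]]:
    """Toy gene models and interval tracks consistent with the cohort layout.

    Genes tile each chromosome over ``fragments_per_gene`` consecutive
    fragments; odd-numbered member fragments become exons, the remainder
    introns.  CpG islands cover fragments whose mean baseline methylation is
    below ``cgi_threshold`` (island-like low-methylation clusters).  SINE,
    LINE and simple-repeat tracks are placed deterministically in the
    inter-fragment gaps.
    """
    frags = truth.fragments
    # mean baseline per fragment
    cpg = truth.frag_of_site >= 0
    base_by_frag = pd.Series(truth.baseline[cpg]).groupby(
        pd.Series(truth.frag_of_site[cpg])).mean()

    genes: list[GeneModel] = []
    cgi_pairs: list[tuple[str, int, int]] = []
    rep_pairs: dict[str, list[tuple[str, int, int]]] = {
        "sine": [], "line": [], "simple_repeat": []}
    rep_names = ("sine", "line", "simple_repeat")
    rng = child_rng(config.seed, "annotation")

    for chrom, sub in frags.groupby("chrom", sort=False):
        ids = sub.index.to_numpy()
        for gi in range(len(ids) // fragments_per_gene):
            member = ids[gi * fragments_per_gene:(gi + 1) * fragments_per_gene]
            gstart = int(frags.loc[member[0], "start"]) - 200
            gend = int(frags.loc[member[-1], "end"]) + 200
            exons = [(int(frags.loc[m, "start"]), int(frags.loc[m, "end"]))
                     for k, m in enumerate(member) if k % 2 == 0]
            exons = [(gstart, exons[0][1])] + exons[1:]  # first exon reaches TSS
            genes.append(GeneModel(f"g_{chrom}_{gi}", str(chrom), "+", gstart, gend, exons))
        for fid in ids:
            if base_by_frag.get(fid, 1.0) < cgi_threshold:
                cgi_pairs.append((str(chrom),
                                  int(frags.loc[fid, "start"]) - 20,
                                  int(frags.loc[fid, "end"]) + 20))
            # one short repeat per fragment gap, rotating class
            gap_start = int(frags.loc[fid, "end"]) + 300
            name = rep_names[int(fid) % 3]
            length = int(rng.integers(100, 300))
            rep_pairs[name].append((str(chrom), gap_start, gap_start + length))

    tracks = [IntervalTrack.from_pairs("cpg_island", cgi_pairs)]
    for name in rep_names:
        tracks.append(IntervalTrack.from_pairs(name, rep_pairs[name]))
    return genes, tracks


# ---------------------------------------------------------------------------
# On-disk cohort
# ---------------------------------------------------------------------------

def write_cohort(
    samples: Sequence[SampleMethylome],
    truth: GroundTruth,
    out_dir: str | Path,
    dialect: str = "cgmap",
) -> Path:
    """Write per-sample call tables, a sample sheet, and fragment-level truth."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for m in samples:
        fname = f"{m.sample_id}.{ 'cgmap' if dialect == 'cgmap' else 'bedgraph' }.tsv"
        write_site_calls(m, out / fname, dialect)
        rows.append({"sample_id": m.sample_id, "group": m.group, "age": m.age,
                     "region": m.region, "replicate": m.replicate, "path": fname})
    pd.DataFrame(rows).to_csv(out / "sample_sheet.tsv", sep="\t", index=False)
    truth_rows = []
    for region, eff in truth.effects.items():
        t = truth.fragments.join(eff)
        t.insert(0, "region", region)
        truth_rows.append(t.reset_index())
    if truth_rows:
        pd.concat(truth_rows).to_csv(out / "truth.tsv", sep="\t", index=False)
    return out


def config_to_dict(config: CohortConfig) -> dict:
    return asdict(config)
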