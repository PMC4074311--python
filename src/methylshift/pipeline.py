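"""End-to-end orchestration: filters → DMR calling → genes → masculinization.

``run`` executes a configured set of pairwise comparisons on a sample sheet,
calibrates the z threshold per comparison via the simulated null, associates
DMRs with genes when annotation is supplied, runs the masculinization
analysis whenever XX, XY and XX+T are all present at an age/region, and
writes a manifest with per-stage counts and output hashes so identical
config + seed reproduce byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from methylshift import __version__
from methylshift._rng import child_seed
from methylshift.cohort import CohortConfig
from methylshift.dmr import (
    DEFAULT_MIN_DELTA,
    DEFAULT_MIN_SITES,
    DEFAULT_Z_GRID,
    ThresholdSelectionError,
    call_dmrs,
    fdr_curve,
    fragment_z,
    select_threshold,
    site_tests,
    dmrs_to_bed,
)
from methylshift.fragments import fragments_from_digest, fragments_from_gaps
from methylshift.genes import associate, partition
from methylshift.io import (
    SampleMethylome,
    common_sites,
    filter_min_coverage,
    load_samples,
    read_annotation,
    read_sample_sheet,
)
from methylshift.masc import dimorphic_sites, masc_scores, masc_summary, shift_test

log = logging.getLogger("methylshift")


@dataclass
class RunConfig:
    sample_sheet: str
    comparisons: list[tuple[str, str, str, str]]  # (group_a, group_b, age, region)
    out_dir: str = "methylshift_out"
    dialect: str = "cgmap"
    min_reads: int = 4
    min_delta: float = DEFAULT_MIN_DELTA
    min_sites: int = DEFAULT_MIN_SITES
    target_fdr: float = 0.10
    tss_window: int = 5000
    masc_min_delta: float = 0.15
    masc_alpha: float = 0.05
    n_sim_reps: int = 1
    z_grid: Sequence[float] = DEFAULT_Z_GRID
    genome: str | None = None
    genes: str | None = None
    tracks: list[tuple[str, str]] = field(default_factory=list)
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        d["comparisons"] = [tuple(c) for c in d.get("comparisons", [])]
        d["tracks"] = [tuple(t) for t in d.get("tracks", [])]
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


def _pick(samples: Sequence[SampleMethylome], group: str, age: str, region: str):
    return [s for s in samples if s.group == group and s.age == age and s.region == region]


def _cg_keys(samples: Sequence[SampleMethylome]) -> pd.MultiIndex:
    keys = common_sites(samples)
    ctx = samples[0].sites["context"].reindex(keys)
    return keys[(ctx == "CG").to_numpy()]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_comparison(
    samples: Sequence[SampleMethylome],
    group_a: str,
    group_b: str,
    age: str,
    region: str,
    config: RunConfig,
    fragments: pd.DataFrame | None = None,
    out_dir: Path | None = None,
) -> dict:
    """One pairwise DMR comparison; returns stage counts and result tables."""
    name = f"{group_a}vs{group_b}_{age}_{region}"
    sa = _pick(samples, group_a, age, region)
    sb = _pick(samples, group_b, age, region)
    if len(sa) < 2 or len(sb) < 2:
        raise ValueError(f"{name}: need >=2 replicates per group")
    keys = _cg_keys(list(sa) + list(sb))
    if fragments is None:
        fragments = fragments_from_gaps(keys)
    tests = site_tests(sa, sb, keys)
    seed = child_seed(config.seed, "fdr_sim", region, age, f"{group_a}vs{group_b}")
    curve = fdr_curve(
        sa, sb, fragments, keys, thresholds=config.z_grid,
        min_delta=config.min_delta, min_sites=config.min_sites,
        seed=seed, n_sim_reps=config.n_sim_reps, real_tests=tests,
    )
    frag_tests = fragment_z(fragments, tests)
    result = {
        "name": name,
        "n_common_sites": int(len(keys)),
        "n_fragments": int(len(fragments)),
        "n_tested_fragments": int(len(frag_tests)),
    }
    try:
        threshold = select_threshold(curve, config.target_fdr)
        dmrs = call_dmrs(frag_tests, threshold, config.min_delta, config.min_sites)
        result["threshold"] = threshold
        result["fdr_at_threshold"] = float(
            curve.fdr[list(curve.thresholds).index(threshold)])
        result["n_dmrs"] = int(len(dmrs))
    except ThresholdSelectionError as exc:
        log.warning("%s: %s", name, exc)
        dmrs = frag_tests.iloc[:0].copy()
        dmrs["direction"] = []
        result["threshold"] = None
        result["error"] = str(exc)
        result["n_dmrs"] = 0
    result["tables"] = {"dmrs": dmrs, "fdr_curve": curve.to_frame(), "site_tests": tests}

    if out_dir is not None:
        cdir = out_dir / name
        cdir.mkdir(parents=True, exist_ok=True)
        dmrs.to_csv(cdir / "dmrs.tsv", sep="\t")
        (cdir / "dmrs.bed").write_text(dmrs_to_bed(dmrs))
        curve.to_frame().to_csv(cdir / "fdr_curve.tsv", sep="\t", index=False)
        dropped = tests.attrs.get("dropped")
        pd.DataFrame(index=dropped if dropped is not None else []).to_csv(
            cdir / "drop_log.tsv", sep="\t")
    return result


def run(config: RunConfig) -> dict:
    """Execute all configured comparisons plus gene and masculinization stages."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sheet = read_sample_sheet(config.sample_sheet)
    base = Path(config.sample_sheet).parent
    samples = load_samples(sheet, base, config.dialect)
    n_raw = {s.sample_id: s.n_sites for s in samples}
    samples = [filter_min_coverage(s, config.min_reads) for s in samples]

    genes = tracks = None
    if config.genes:
        genes, tracks = read_annotation(config.genes, config.tracks)

    fragments = None
    if config.genome:
        fragments = fragments_from_digest(config.genome)

    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "n_samples": len(samples),
        "sites_raw": n_raw,
        "sites_after_filter": {s.sample_id: s.n_sites for s in samples},
        "comparisons": [],
    }

    dmg_sets = {}
    for (ga, gb, age, region) in config.comparisons:
        res = run_comparison(samples, ga, gb, age, region, config, fragments, out_dir)
        tables = res.pop("tables")
        if genes is not None and len(tables["dmrs"]):
            dmgs = associate(tables["dmrs"], genes, config.tss_window)
            dmg_sets[res["name"]] = dmgs
            res["n_dmgs"] = len(dmgs)
            part = partition(dmgs)
            part.to_csv(out_dir / res["name"] / "dmg_partition.tsv", sep="\t", index=False)
            pd.DataFrame({
                "gene_id": [d.gene_id for d in dmgs],
                "chrom": [d.chrom for d in dmgs],
                "chrom_class": [d.chrom_class for d in dmgs],
                "direction": [d.direction for d in dmgs],
                "n_dmrs": [len(d.dmr_ids) for d in dmgs],
                "max_delta": [d.max_delta for d in dmgs],
            }).to_csv(out_dir / res["name"] / "dmgs.tsv", sep="\t", index=False)
        manifest["comparisons"].append(res)

    # masculinization wherever the three groups coexist
    manifest["masculinization"] = []
    combos = {(s.age, s.region) for s in samples}
    for age, region in sorted(combos):
        xx = _pick(samples, "XX", age, region)
        xy = _pick(samples, "XY", age, region)
        xxt = _pick(samples, "XXT", age, region)
        if min(len(xx), len(xy)) < 2 or not xxt:
            continue
        keys = _cg_keys(xx + xy + xxt)
        dim = dimorphic_sites(xx, xy, keys, config.masc_min_delta, config.masc_alpha)
        scored = masc_scores(dim, xxt)
        n_masc, n_total, hist = masc_summary(scored["score"])
        mdir = out_dir / f"masc_{age}_{region}"
        mdir.mkdir(parents=True, exist_ok=True)
        scored.to_csv(mdir / "masc_sites.tsv", sep="\t")
        (mdir / "masc_summary.json").write_text(json.dumps(
            {"age": age, "region": region, "n_masculinized": n_masc,
             "n_total": n_total}, indent=2))
        manifest["masculinization"].append(
            {"age": age, "region": region, "n_dimorphic": int(len(dim)),
             "n_masculinized": n_masc, "n_total": n_total})

    # cross-age KS shift where both ages were scored in a region
    for region in {r for (_, r) in combos}:
        scores = {}
        for age in ("PN4", "PN60"):
            p = out_dir / f"masc_{age}_{region}" / "masc_sites.tsv"
            if p.exists():
                scores[age] = pd.read_csv(p, sep="\t")["score"]
        if len(scores) == 2:
            ks = shift_test(scores["PN4"], scores["PN60"])
            for m in manifest["masculinization"]:
                if m["region"] == region:
                    m["ks_d_pn4_vs_pn60"] = ks.d
                    m["ks_p_pn4_vs_pn60"] = ks.p

    # manifest with output hashes
    hashes = {str(p.relative_to(out_dir)): _sha256(p)
              for p in sorted(out_dir.rglob("*")) if p.is_file() and p.name != "manifest.json"}
    manifest["output_sha256"] = hashes
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
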