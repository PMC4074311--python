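"""DMR-to-gene association, gene-set logic and genomic-feature enrichment.

A DMR supports a gene when the gene's transcription start site lies within
5 kb of the DMR interval or the DMR overlaps the gene body.  Downstream set
logic works on the resulting differentially methylated genes (DMGs):
direction/chromosome partitions, cross-region sharing (same chromosomal
location, same direction), cross-age stability (gene-level intersection),
overlap enrichment between gene sets, and 2×2 Fisher tests of DMR-CpG
placement in genomic features against the assayed-CpG background.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from methylshift.io import GeneModel, IntervalTrack, ValidationError, promoter_track
from methylshift.stats import OverlapEnrichment, fisher_exact_2x2, hypergeom_overlap


@dataclass
class DMG:
    """A gene supported by one or more DMRs from a single comparison."""

    gene_id: str
    chrom: str
    chrom_class: str  # "autosome" | "chrX"
    direction: str    # "hyper_in_A" | "hypo_in_A" | "mixed"
    dmr_ids: list[int] = field(default_factory=list)
    intervals: list[tuple[int, int]] = field(default_factory=list)
    deltas: list[float] = field(default_factory=list)

    @property
    def max_delta(self) -> float:
        """Delta of the strongest supporting DMR (sign preserved)."""
        i = int(np.argmax(np.abs(self.deltas)))
        return self.deltas[i]

    @property
    def max_interval(self) -> tuple[int, int]:
        i = int(np.argmax(np.abs(self.deltas)))
        return self.intervals[i]


def _interval_tss_distance(start: int, end: int, tss: int) -> int:
    """Minimal genomic distance from any base of [start, end) to the TSS base."""
    if start <= tss < end:
        return 0
    return min(abs(tss - start), abs(tss - (end - 1)))


def associate(
    dmrs: pd.DataFrame, genes: Sequence[GeneModel], tss_window: int = 5000
) -> list[DMG]:
    """Associate called DMRs with genes (TSS within ``tss_window`` or body overlap).

    One DMR may support several genes; each gene appears once, with all its
    supporting DMRs.  Association is pure interval geometry and deterministic.
    """
    if tss_window < 0:
        raise ValueError("tss_window must be >= 0")
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)

    hits: dict[str, DMG] = {}
    for frag_id, row in dmrs.iterrows():
        s, e = int(row["start"]), int(row["end"])
        for g in by_chrom.get(row["chrom"], ()):
            overlaps = s < g.end and g.start < e
            near_tss = _interval_tss_distance(s, e, g.tss) <= tss_window
            if not (overlaps or near_tss):
                continue
            dmg = hits.get(g.gene_id)
            if dmg is None:
                cls = "chrX" if g.chrom == "chrX" else "autosome"
                dmg = DMG(g.gene_id, g.chrom, cls, "hyper_in_A")
                hits[g.gene_id] = dmg
            dmg.dmr_ids.append(int(frag_id))
            dmg.intervals.append((s, e))
            dmg.deltas.append(float(row["delta"]))

    out = list(hits.values())
    for dmg in out:
        signs = {np.sign(d) for d in dmg.deltas}
        if signs <= {1.0}:
            dmg.direction = "hyper_in_A"
        elif signs <= {-1.0}:
            dmg.direction = "hypo_in_A"
        else:
            dmg.direction = "mixed"
    return out


def partition(dmgs: Sequence[DMG]) -> pd.DataFrame:
    """Counts and percentages of DMGs by chromosome class and direction.

    Percentages are of the chromosome-class total, rounded to 2 d.p.
    An empty input yields all-zero rows.
    """
    rows = []
    for cls in ("autosome", "chrX"):
        sub = [d for d in dmgs if d.chrom_class == cls]
        total = len(sub)
        for direction in ("hyper_in_A", "hypo_in_A", "mixed"):
            n = sum(1 for d in sub if d.direction == direction)
            pct = round(100.0 * n / total, 2) if total else 0.0
            rows.append({"chrom_class": cls, "direction": direction,
                         "count": n, "total": total, "percent": pct})
    return pd.DataFrame(rows)


def _overlapping_same_sign(a: DMG, b: DMG) -> bool:
    for (sa, ea), da in zip(a.intervals, a.deltas):
        for (sb, eb), db in zip(b.intervals, b.deltas):
            if sa < eb and sb < ea and np.sign(da) == np.sign(db):
                return True
    return False


def shared_genes(set_a: Sequence[DMG], set_b: Sequence[DMG]) -> list[str]:
    """Genes differentially methylated in both comparisons, at the same
    chromosomal location (supporting DMR intervals overlap) and in the same
    direction.  Symmetric in its arguments."""
    bmap = {d.gene_id: d for d in set_b}
    out = []
    for a in set_a:
        b = bmap.get(a.gene_id)
        if b is not None and a.chrom == b.chrom and _overlapping_same_sign(a, b):
            out.append(a.gene_id)
    return sorted(out)


def stable_genes(
    dmgs_early: Sequence[DMG],
    dmgs_late: Sequence[DMG],
    genes: Sequence[GeneModel] | None = None,
    cpg_islands: IntervalTrack | None = None,
    promoter_half_width: int = 500,
) -> pd.DataFrame:
    """Genes differentially methylated at both ages (gene-level intersection).

    No location requirement: a stable gene may be supported by different
    fragments at the two ages.  Each age contributes its strongest
    supporting DMR (coordinates and delta); ``same_direction`` flags
    agreement of the two deltas.  When annotation is supplied, promoter /
    gene-body / CpG-island flags are derived from the two representative
    fragments.
    """
    late = {d.gene_id: d for d in dmgs_late}
    gmap = {g.gene_id: g for g in (genes or [])}
    prom = promoter_track(list(genes), promoter_half_width) if genes else None
    rows = []
    for a in dmgs_early:
        b = late.get(a.gene_id)
        if b is None:
            continue
        (sa, ea), (sb, eb) = a.max_interval, b.max_interval
        da, db = a.max_delta, b.max_delta
        row = {
            "gene_id": a.gene_id,
            "delta_early": da,
            "coord_early": f"{a.chrom}:{sa}-{ea}",
            "delta_late": db,
            "coord_late": f"{b.chrom}:{sb}-{eb}",
            "same_direction": bool(np.sign(da) == np.sign(db)),
        }
        g = gmap.get(a.gene_id)
        ivs = [(a.chrom, sa, ea), (b.chrom, sb, eb)]
        if g is not None:
            ps, pe = g.promoter(promoter_half_width)
            row["promoter"] = any(c == g.chrom and s < pe and ps < e for c, s, e in ivs)
            row["gene_body"] = any(c == g.chrom and s < g.end and g.start < e
                                   for c, s, e in ivs)
        elif prom is not None:
            row["promoter"] = False
            row["gene_body"] = False
        if cpg_islands is not None:
            def _in_cgi(c, s, e):
                arr = cpg_islands.intervals.get(c)
                return arr is not None and bool(np.any((arr[:, 0] < e) & (s < arr[:, 1])))
            row["cpg_island"] = any(_in_cgi(*iv) for iv in ivs)
        rows.append(row)
    return pd.DataFrame(rows)


def feature_enrichment(
    dmr_sites: pd.MultiIndex,
    background_sites: pd.MultiIndex,
    tracks: Sequence[IntervalTrack] = (),
    genes: Sequence[GeneModel] | None = None,
) -> pd.DataFrame:
    """Per-feature 2×2 Fisher's exact test of DMR-CpG placement.

    Rows are features (supplied tracks plus gene body / exon / intron
    derived from the gene models); the 2×2 table is [DMR CpGs in/out of the
    feature] vs [background CpGs in/out].  The background is the assayed
    common-CpG set — RRBS coverage is CpG-island biased, so enrichment
    against the genome at large would be meaningless.
    """
    if len(dmr_sites.difference(background_sites)) > 0:
        raise ValidationError("dmr_sites must be a subset of background_sites")
    feats: list[IntervalTrack] = list(tracks)
    if genes:
        feats.append(IntervalTrack.from_pairs(
            "gene_body", [(g.chrom, g.start, g.end) for g in genes]))
        exon_pairs = [(g.chrom, s, e) for g in genes for (s, e) in g.exons]
        intron_pairs = [(g.chrom, s, e) for g in genes for (s, e) in g.introns]
        if exon_pairs:
            feats.append(IntervalTrack.from_pairs("exon", exon_pairs))
        if intron_pairs:
            feats.append(IntervalTrack.from_pairs("intron", intron_pairs))

    d_chrom = np.asarray(dmr_sites.get_level_values("chrom"), dtype=object)
    d_pos = np.asarray(dmr_sites.get_level_values("pos"), dtype=np.int64)
    b_chrom = np.asarray(background_sites.get_level_values("chrom"), dtype=object)
    b_pos = np.asarray(background_sites.get_level_values("pos"), dtype=np.int64)

    rows = []
    for tr in feats:
        if not tr.intervals:
            warnings.warn(f"feature track {tr.name!r} is empty; skipped")
            continue
        a = int(tr.contains(d_chrom, d_pos).sum())
        b = len(dmr_sites) - a
        c = int(tr.contains(b_chrom, b_pos).sum())
        d = len(background_sites) - c
        odds, p = fisher_exact_2x2([[a, b], [c, d]])
        rows.append({"feature": tr.name, "a": a, "b": b, "c": c, "d": d,
                     "odds_ratio": odds, "p": p})
    return pd.DataFrame(rows)


def intersect_with_expression(
    dmgs: Sequence[DMG], de_genes: pd.DataFrame
) -> pd.DataFrame:
    """Inner join of DMGs with an external differential-expression gene list.

    ``de_genes`` needs columns gene_id, log2fc, p; duplicate gene_ids are
    deduplicated (first kept) with a warning.  Each row carries the DMG's
    strongest delta and the expression effect size.
    """
    required = {"gene_id", "log2fc", "p"}
    if not required <= set(de_genes.columns):
        raise ValueError(f"de_genes needs columns {sorted(required)}")
    if de_genes["gene_id"].duplicated().any():
        warnings.warn("duplicate gene_ids in expression list; keeping first")
        de_genes = de_genes.drop_duplicates("gene_id", keep="first")
    dm = pd.DataFrame({
        "gene_id": [d.gene_id for d in dmgs],
        "delta_me": [d.max_delta for d in dmgs],
        "direction": [d.direction for d in dmgs],
    })
    return dm.merge(de_genes, on="gene_id", how="inner")


def overlap_enrichment_sets(
    set_a: Sequence[str], set_b: Sequence[str], universe_size: int
) -> OverlapEnrichment:
    """Hypergeometric overlap enrichment between two gene-id sets.

    ``universe_size`` is the number of genes that could have entered either
    set (e.g. genes with ≥1 assayed CpG within association reach); it must
    be at least as large as the union.
    """
    a, b = set(set_a), set(set_b)
    if universe_size < len(a | b):
        raise ValidationError("universe smaller than the union of the sets")
    return hypergeom_overlap(len(a & b), len(a), len(b), universe_size)
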