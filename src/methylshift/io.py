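"""Site-level methylation call tables, annotation tracks, and filters.

Coordinate conventions
----------------------
All coordinates are **0-based, half-open** internally.  The ``cgmap`` dialect
stores 1-based positions and is converted on read/write; ``bedgraph_counts``
stores 0-based half-open single-base intervals.  A *site key* is the tuple
``(chrom, pos, strand)``; CpGs on opposite strands are kept as distinct sites
(per-cytosine counting), with an optional merge left to the caller.

Dialects
--------
``cgmap``
    TSV columns: chrom, nucleotide (C for + strand, G for −), 1-based
    position, context (CG/CHG/CHH), dinucleotide context, methylation level,
    methylated read count, total read count.
``bedgraph_counts``
    TSV columns: chrom, start, end, level, c_reads, total_reads.  Strand and
    context are not encoded; sites are taken as + strand CG.

The methylation level of a site is ``#C/(#C + #T)`` — the fraction of
bisulfite-unconverted (methylated) reads among all reads covering it.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

GROUPS = ("XX", "XY", "XXT")
AGES = ("PN4", "PN60")
REGIONS = ("STR", "BNSTPOA")
CONTEXTS = ("CG", "CHG", "CHH")

SITE_INDEX_NAMES = ("chrom", "pos", "strand")


class ParseError(ValueError):
    """A call-table or annotation record could not be parsed."""


class ValidationError(ValueError):
    """Parsed data violated an invariant (duplicate site, negative count, ...)."""


# ---------------------------------------------------------------------------
# Core containers
# ---------------------------------------------------------------------------

@dataclass
class SiteCall:
    """One cytosine's methylation call.

    ``level`` is defined only when the site has coverage; it is the fraction
    of methylated reads #C/(#C+#T).
    """

    chrom: str
    pos: int
    strand: str
    context: str
    c_reads: int
    t_reads: int

    def __post_init__(self) -> None:
        if self.c_reads < 0 or self.t_reads < 0:
            raise ValidationError(f"negative read count at {self.chrom}:{self.pos}")
        if self.strand not in ("+", "-"):
            raise ValidationError(f"bad strand {self.strand!r}")
        if self.context not in CONTEXTS:
            raise ValidationError(f"bad context {self.context!r}")

    @property
    def coverage(self) -> int:
        return self.c_reads + self.t_reads

    @property
    def level(self) -> float:
        if self.coverage == 0:
            raise ValidationError("level undefined at zero coverage")
        return self.c_reads / self.coverage

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chrom, self.pos, self.strand)


def _empty_sites() -> pd.DataFrame:
    idx = pd.MultiIndex.from_arrays([[], [], []], names=SITE_INDEX_NAMES)
    return pd.DataFrame(
        {"context": pd.Series([], dtype=object),
         "c_reads": pd.Series([], dtype=np.int64),
         "t_reads": pd.Series([], dtype=np.int64)},
        index=idx,
    )


@dataclass
class SampleMethylome:
    """All site calls of one sample plus its design labels.

    ``sites`` is a DataFrame indexed by (chrom, pos, strand) with columns
    ``context``, ``c_reads``, ``t_reads``.  The index is unique and sorted.
    """

    sample_id: str
    group: str
    age: str
    region: str
    replicate: int
    sites: pd.DataFrame = field(default_factory=_empty_sites)

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValidationError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.age not in AGES:
            raise ValidationError(f"age must be one of {AGES}, got {self.age!r}")
        if self.region not in REGIONS:
            raise ValidationError(f"region must be one of {REGIONS}, got {self.region!r}")
        if not self.sites.index.is_unique:
            dup = self.sites.index[self.sites.index.duplicated()][0]
            raise ValidationError(f"duplicate site {dup} in sample {self.sample_id}")
        if len(self.sites) and (
            (self.sites["c_reads"] < 0).any() or (self.sites["t_reads"] < 0).any()
        ):
            raise ValidationError(f"negative read counts in sample {self.sample_id}")
        if not self.sites.index.is_monotonic_increasing:
            self.sites = self.sites.sort_index()

    # -- derived views ------------------------------------------------------

    def levels(self) -> pd.Series:
        """Per-site methylation fraction #C/(#C+#T); NaN at zero coverage."""
        cov = self.coverage()
        with np.errstate(invalid="ignore", divide="ignore"):
            lv = self.sites["c_reads"] / cov
        return lv.where(cov > 0)

    def coverage(self) -> pd.Series:
        return self.sites["c_reads"] + self.sites["t_reads"]

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def site_keys(self) -> pd.MultiIndex:
        return self.sites.index

    def subset(self, keys: pd.MultiIndex) -> "SampleMethylome":
        """A copy restricted to ``keys`` (which must all be present)."""
        return dataclasses.replace(self, sites=self.sites.loc[keys])

    def with_sites(self, sites: pd.DataFrame) -> "SampleMethylome":
        return dataclasses.replace(self, sites=sites)


# ---------------------------------------------------------------------------
# Call-table I/O
# ---------------------------------------------------------------------------

_CGMAP_COLS = ["chrom", "nuc", "pos1", "context", "dinuc", "level", "c_reads", "total"]
_BEDGRAPH_COLS = ["chrom", "start", "end", "level", "c_reads", "total"]


def read_site_calls(
    path: str | Path,
    dialect: str = "cgmap",
    *,
    sample_id: str = "sample",
    group: str = "XX",
    age: str = "PN4",
    region: str = "STR",
    replicate: int = 1,
) -> SampleMethylome:
    """Read a site-level call table into a :class:`SampleMethylome`.

    Design labels (group/age/region/replicate) come from the caller — usually
    a sample sheet — never from the file itself.
    """
    path = Path(path)
    if dialect == "cgmap":
        names = _CGMAP_COLS
    elif dialect == "bedgraph_counts":
        names = _BEDGRAPH_COLS
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    try:
        df = pd.read_csv(path, sep="\t", header=None, names=names, comment="#",
                         dtype={"chrom": str})
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=names)
    except (pd.errors.ParserError, ValueError) as exc:
        raise ParseError(f"{path}: {exc}") from exc

    required = [c for c in names if c != "level"]  # level may be NA at zero coverage
    if df[required].isna().any().any():
        bad = int(df.index[df[required].isna().any(axis=1)][0]) + 1
        raise ParseError(f"{path}: malformed row at line {bad}")

    if dialect == "cgmap":
        try:
            pos = df["pos1"].astype(np.int64) - 1  # 1-based -> 0-based
            c = df["c_reads"].astype(np.int64)
            total = df["total"].astype(np.int64)
        except (ValueError, TypeError) as exc:
            raise ParseError(f"{path}: non-integer field ({exc})") from exc
        strand = np.where(df["nuc"].astype(str).str.upper() == "G", "-", "+")
        context = df["context"].astype(str)
        if len(df) and not context.isin(CONTEXTS).all():
            bad = int(df.index[~context.isin(CONTEXTS)][0]) + 1
            raise ParseError(f"{path}: unknown context at line {bad}")
    else:
        try:
            start = df["start"].astype(np.int64)
            end = df["end"].astype(np.int64)
            c = df["c_reads"].astype(np.int64)
            total = df["total"].astype(np.int64)
        except (ValueError, TypeError) as exc:
            raise ParseError(f"{path}: non-integer field ({exc})") from exc
        if len(df) and ((end - start) != 1).any():
            bad = int(df.index[(end - start) != 1][0]) + 1
            raise ParseError(f"{path}: interval is not single-base at line {bad}")
        pos = start
        strand = np.full(len(df), "+")
        context = pd.Series(["CG"] * len(df))

    t = total - c
    if len(df) and ((c < 0).any() or (t < 0).any()):
        bad = int(df.index[(c < 0) | (t < 0)][0]) + 1
        raise ValidationError(f"{path}: negative count at line {bad}")

    idx = pd.MultiIndex.from_arrays(
        [df["chrom"].to_numpy(), pos.to_numpy(), np.asarray(strand, dtype=object)],
        names=SITE_INDEX_NAMES,
    )
    if not idx.is_unique:
        dup = idx[idx.duplicated()][0]
        raise ValidationError(f"{path}: duplicate site {dup}")

    sites = pd.DataFrame(
        {"context": context.to_numpy(), "c_reads": c.to_numpy(), "t_reads": t.to_numpy()},
        index=idx,
    )
    return SampleMethylome(sample_id, group, age, region, replicate, sites)


def write_site_calls(m: SampleMethylome, path: str | Path, dialect: str = "cgmap") -> None:
    """Write a sample's calls; round-trips exactly through :func:`read_site_calls`."""
    path = Path(path)
    s = m.sites
    chrom = s.index.get_level_values("chrom")
    pos = s.index.get_level_values("pos").to_numpy()
    strand = s.index.get_level_values("strand").to_numpy()
    total = (s["c_reads"] + s["t_reads"]).to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        level = np.where(total > 0, s["c_reads"].to_numpy() / np.maximum(total, 1), np.nan)

    if dialect == "cgmap":
        out = pd.DataFrame({
            "chrom": chrom,
            "nuc": np.where(strand == "-", "G", "C"),
            "pos1": pos + 1,
            "context": s["context"].to_numpy(),
            "dinuc": s["context"].to_numpy(),
            "level": np.round(level, 6),
            "c_reads": s["c_reads"].to_numpy(),
            "total": total,
        })
    elif dialect == "bedgraph_counts":
        out = pd.DataFrame({
            "chrom": chrom,
            "start": pos,
            "end": pos + 1,
            "level": np.round(level, 6),
            "c_reads": s["c_reads"].to_numpy(),
            "total": total,
        })
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    out.to_csv(path, sep="\t", header=False, index=False)


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Sample sheet TSV: sample_id, group, age, region, replicate, path."""
    sheet = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "path": str})
    required = {"sample_id", "group", "age", "region", "replicate", "path"}
    missing = required - set(sheet.columns)
    if missing:
        raise ParseError(f"sample sheet missing columns: {sorted(missing)}")
    return sheet


def load_samples(
    sheet: pd.DataFrame, base_dir: str | Path = ".", dialect: str = "cgmap"
) -> list[SampleMethylome]:
    base = Path(base_dir)
    out = []
    for row in sheet.itertuples(index=False):
        p = Path(row.path)
        if not p.is_absolute():
            p = base / p
        out.append(read_site_calls(
            p, dialect, sample_id=row.sample_id, group=row.group,
            age=row.age, region=row.region, replicate=int(row.replicate)))
    return out


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def filter_min_coverage(m: SampleMethylome, min_reads: int = 4) -> SampleMethylome:
    """Keep sites covered by at least ``min_reads`` reads (boundary inclusive).

    The default of 4 reflects the standard RRBS practice of only analysing
    cytosines covered by at least four reads.
    """
    if min_reads < 1:
        raise ValueError("min_reads must be >= 1")
    keep = (m.sites["c_reads"] + m.sites["t_reads"]) >= min_reads
    return m.with_sites(m.sites.loc[keep])


def common_sites(samples: Sequence[SampleMethylome]) -> pd.MultiIndex:
    """Intersection of site keys present in every sample.

    Sites not observed in all comparison groups carry no usable contrast and
    are excluded from every downstream test.
    """
    if len(samples) == 0:
        raise ValidationError("common_sites requires at least one sample")
    keys = samples[0].site_keys()
    for s in samples[1:]:
        keys = keys.intersection(s.site_keys())
    return keys.sort_values()


# ---------------------------------------------------------------------------
# Gene models and interval tracks
# ---------------------------------------------------------------------------

@dataclass
class GeneModel:
    """A gene body with exon structure; all coordinates 0-based half-open.

    The TSS is ``start`` for + strand genes and ``end - 1`` for − strand.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(f"{self.gene_id}: empty gene body")
        for (s, e) in self.exons:
            if s < self.start or e > self.end or s >= e:
                raise ValidationError(f"{self.gene_id}: exon ({s},{e}) outside gene body")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def introns(self) -> list[tuple[int, int]]:
        """Gene-body complement of the exons."""
        if not self.exons:
            return []
        ex = sorted(self.exons)
        out = []
        cur = self.start
        for (s, e) in ex:
            if s > cur:
                out.append((cur, s))
            cur = max(cur, e)
        if cur < self.end:
            out.append((cur, self.end))
        return out

    def promoter(self, half_width: int = 500) -> tuple[int, int]:
        """TSS-centred window [tss - w, tss + w)."""
        return (max(0, self.tss - half_width), self.tss + half_width)


@dataclass
class IntervalTrack:
    """A named set of half-open genomic intervals, sorted per chromosome."""

    name: str
    intervals: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.name:
            raise ValidationError("track name must be nonempty")
        for chrom, arr in list(self.intervals.items()):
            arr = np.asarray(arr, dtype=np.int64).reshape(-1, 2)
            order = np.argsort(arr[:, 0], kind="stable")
            self.intervals[chrom] = arr[order]

    @classmethod
    def from_pairs(cls, name: str, pairs: Iterable[tuple[str, int, int]]) -> "IntervalTrack":
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, s, e in pairs:
            by_chrom.setdefault(chrom, []).append((s, e))
        return cls(name, {c: np.array(v, dtype=np.int64) for c, v in by_chrom.items()})

    def contains(self, chrom: np.ndarray, pos: np.ndarray) -> np.ndarray:
        """Boolean membership of positions (vectorized per chromosome).

        Overlapping intervals within the track are handled by interval-sweep
        rather than assuming disjointness.
        """
        chrom = np.asarray(chrom, dtype=object)
        pos = np.asarray(pos, dtype=np.int64)
        out = np.zeros(len(pos), dtype=bool)
        for c in np.unique(chrom):
            arr = self.intervals.get(str(c))
            if arr is None or len(arr) == 0:
                continue
            mask = chrom == c
            p = pos[mask]
            # event sweep: +1 at starts, -1 at ends; position covered if depth>0
            edges = np.concatenate([arr[:, 0], arr[:, 1]])
            deltas = np.concatenate([np.ones(len(arr)), -np.ones(len(arr))])
            order = np.argsort(edges, kind="stable")
            edges, deltas = edges[order], deltas[order]
            depth = np.cumsum(deltas)
            idx = np.searchsorted(edges, p, side="right") - 1
            cov = np.zeros(len(p), dtype=bool)
            valid = idx >= 0
            cov[valid] = depth[idx[valid]] > 0
            out[mask] = cov
        return out


def _read_bed12_genes(path: Path) -> list[GeneModel]:
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ParseError(f"{path}:{lineno}: BED12 needs 12 columns, got {len(f)}")
            chrom, start, end = f[0], int(f[1]), int(f[2])
            name, strand = f[3], f[5]
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            if len(sizes) != len(offsets):
                raise ParseError(f"{path}:{lineno}: blockSizes/blockStarts mismatch")
            exons = [(start + o, start + o + s) for o, s in zip(offsets, sizes)]
            try:
                genes.append(GeneModel(name, chrom, strand, start, end, exons))
            except ValidationError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    return genes


def _read_gff3_genes(path: Path) -> list[GeneModel]:
    """Minimal GFF3 reader for gene + exon features keyed by ID/Parent."""
    bodies: dict[str, GeneModel] = {}
    exons: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) != 9:
                raise ParseError(f"{path}:{lineno}: GFF3 needs 9 columns")
            chrom, _, ftype, start1, end, _, strand, _, attrs = f
            attr = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
            if ftype == "gene":
                gid = attr.get("ID") or attr.get("Name")
                if gid is None:
                    raise ParseError(f"{path}:{lineno}: gene without ID")
                bodies[gid] = GeneModel(gid, chrom, strand, int(start1) - 1, int(end))
            elif ftype == "exon":
                parent = attr.get("Parent")
                if parent:
                    exons.setdefault(parent, []).append((int(start1) - 1, int(end)))
    out = []
    for gid, g in bodies.items():
        ex = sorted(exons.get(gid, []))
        out.append(GeneModel(gid, g.chrom, g.strand, g.start, g.end, ex))
    return out


def _read_bed3_track(name: str, path: Path) -> IntervalTrack:
    pairs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ParseError(f"{path}:{lineno}: BED needs >=3 columns")
            s, e = int(f[1]), int(f[2])
            if s >= e:
                raise ValidationError(f"{path}:{lineno}: empty interval")
            pairs.append((f[0], s, e))
    return IntervalTrack.from_pairs(name, pairs)


def read_annotation(
    genes_path: str | Path,
    tracks: Sequence[tuple[str, str | Path]] = (),
    promoter_half_width: int = 500,
) -> tuple[list[GeneModel], list[IntervalTrack]]:
    """Load gene models (BED12 or GFF3) and BED3 interval tracks.

    A ``promoter`` track (TSS ± ``promoter_half_width``) is derived
    automatically from the gene models and appended to the returned tracks.
    """
    genes_path = Path(genes_path)
    if genes_path.suffix.lower() in (".gff", ".gff3"):
        genes = _read_gff3_genes(genes_path)
    else:
        genes = _read_bed12_genes(genes_path)
    out_tracks = [_read_bed3_track(name, Path(p)) for name, p in tracks]
    out_tracks.append(promoter_track(genes, promoter_half_width))
    return genes, out_tracks


def promoter_track(genes: Sequence[GeneModel], half_width: int = 500) -> IntervalTrack:
    return IntervalTrack.from_pairs(
        "promoter", [(g.chrom, *g.promoter(half_width)) for g in genes]
    )
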