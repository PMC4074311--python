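"""Fragment construction: in-silico MspI digestion and gap-based grouping.

RRBS libraries are built from MspI fragments (the enzyme cuts C^CGG), size
selected to CpG-rich fragments.  When a genome FASTA is available, fragments
are reconstructed by digesting every chromosome at each CCGG occurrence and
keeping internal fragments whose length falls in the selected size window.
Without a genome, nearby assayed cytosines are grouped greedily
(``fragments_from_gaps``); both paths yield the same fragment table.

Fragment tables are DataFrames indexed by ``frag_id`` with columns
``chrom``, ``start``, ``end`` (0-based half-open, non-overlapping).
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd

from methylshift.io import ValidationError

_MSPI = re.compile("CCGG", re.IGNORECASE)


def _frame(records: list[tuple[str, int, int]]) -> pd.DataFrame:
    df = pd.DataFrame(records, columns=["chrom", "start", "end"])
    df.index.name = "frag_id"
    return df


def fragments_from_digest(
    genome: str | Path, size_min: int = 100, size_max: int = 300
) -> pd.DataFrame:
    """In-silico MspI digestion of a genome FASTA.

    Cuts are placed between the first C and the CGG of every CCGG site; only
    internal fragments (bounded by two cuts) with length in
    [``size_min``, ``size_max``] are retained — terminal pieces have no
    defined second cut and are never part of the size-selected library.
    """
    if not (0 < size_min <= size_max):
        raise ValueError("need 0 < size_min <= size_max")
    from pyfaidx import Fasta

    records: list[tuple[str, int, int]] = []
    fa = Fasta(str(genome), rebuild=False)
    for chrom in fa.keys():
        seq = str(fa[chrom][:])
        cuts = [m.start() + 1 for m in _MSPI.finditer(seq)]
        for s, e in zip(cuts, cuts[1:]):
            if size_min <= e - s <= size_max:
                records.append((chrom, s, e))
    return _frame(records)


def fragments_from_gaps(
    keys: pd.MultiIndex, max_gap: int = 100, max_span: int = 300
) -> pd.DataFrame:
    """Greedy left-to-right grouping of assayed sites into fragments.

    The current fragment is extended while the next site on the same
    chromosome is within ``max_gap`` of the previous one and the fragment
    span stays within ``max_span``.  Genome-free fallback for cohorts without
    a FASTA; sites on both strands share fragments.
    """
    if max_gap <= 0 or max_span <= 0:
        raise ValueError("max_gap and max_span must be positive")
    if len(keys) == 0:
        return _frame([])
    chrom = np.asarray(keys.get_level_values("chrom"), dtype=object)
    pos = np.asarray(keys.get_level_values("pos"), dtype=np.int64)
    order = np.lexsort((pos, chrom))
    chrom, pos = chrom[order], pos[order]
    # unique positions only: opposite-strand calls at one position stay together
    records: list[tuple[str, int, int]] = []
    cur_chrom, cur_start, cur_last = chrom[0], pos[0], pos[0]
    for c, p in zip(chrom[1:], pos[1:]):
        same = c == cur_chrom
        if same and p == cur_last:
            continue
        if same and p - cur_last <= max_gap and p - cur_start + 1 <= max_span:
            cur_last = p
        else:
            records.append((cur_chrom, int(cur_start), int(cur_last) + 1))
            cur_chrom, cur_start, cur_last = c, p, p
    records.append((cur_chrom, int(cur_start), int(cur_last) + 1))
    return _frame(records)


def assign_sites(keys: pd.MultiIndex, fragments: pd.DataFrame) -> pd.Series:
    """Map each site key to its containing fragment id (−1 when unassigned).

    Fragments must be non-overlapping; assignment is by binary search on the
    per-chromosome fragment starts.
    """
    out = np.full(len(keys), -1, dtype=np.int64)
    if len(keys) == 0 or len(fragments) == 0:
        return pd.Series(out, index=keys, name="frag_id")
    chrom = np.asarray(keys.get_level_values("chrom"), dtype=object)
    pos = np.asarray(keys.get_level_values("pos"), dtype=np.int64)
    for c, sub in fragments.groupby("chrom", sort=False):
        starts = sub["start"].to_numpy()
        order = np.argsort(starts, kind="stable")
        starts = starts[order]
        ends = sub["end"].to_numpy()[order]
        ids = sub.index.to_numpy()[order]
        if np.any(starts[1:] < ends[:-1]):
            raise ValidationError(f"overlapping fragments on {c}")
        mask = chrom == c
        if not mask.any():
            continue
        p = pos[mask]
        i = np.searchsorted(starts, p, side="right") - 1
        ok = (i >= 0) & (p < ends[np.clip(i, 0, len(ends) - 1)])
        res = np.full(p.shape, -1, dtype=np.int64)
        res[ok] = ids[i[ok]]
        out[mask] = res
    return pd.Series(out, index=keys, name="frag_id")
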