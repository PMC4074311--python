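"""Deterministic seed derivation for named random substreams.

Every stage that consumes randomness derives its own child seed from the
master seed and a human-readable stream name (e.g.
``"fdr_sim/STR/PN60/XXvsXXT"``).  The derivation is a SHA-256 hash truncated
to 31 bits, so any comparison is independently reproducible from the master
seed alone and child seeds stay below 2**31.
"""

from __future__ import annotations

import hashlib

import numpy as np


def child_seed(master: int, *names: object) -> int:
    """Derive a deterministic 31-bit child seed from ``master`` and a path of names."""
    tag = "/".join(str(n) for n in names) + f"#{int(master)}"
    digest = hashlib.sha256(tag.encode("utf-8")).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def child_rng(master: int, *names: object) -> np.random.Generator:
    """A ``numpy`` Generator for the named substream."""
    return np.random.default_rng(child_seed(master, *names))
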