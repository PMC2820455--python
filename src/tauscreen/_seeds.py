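"""Deterministic per-well random substreams.

One root seed drives the whole screen; every well draws from its own
substream keyed by stable string identifiers (plate id, well name), so the
simulated content of a well does not depend on the order in which wells are
generated.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["substream"]


def _digest_words(*tokens: object) -> list[int]:
    h = hashlib.sha256()
    for t in tokens:
        h.update(repr(t).encode())
        h.update(b"\x1f")
    d = h.digest()
    # four 32-bit words are plenty of entropy for SeedSequence
    return [int.from_bytes(d[i : i + 4], "little") for i in (0, 4, 8, 12)]


def substream(seed: int, *tokens: object) -> np.random.Generator:
    """Generator for the substream identified by ``tokens`` under ``seed``.

    Identical (seed, tokens) always yield an identical stream; distinct
    tokens yield independent streams.
    """
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, *_digest_words(*tokens)]))
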