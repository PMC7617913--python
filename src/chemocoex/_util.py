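"""Shared helpers: seeded random substreams and numeric formatting."""

from __future__ import annotations

import zlib

import numpy as np


def substream(seed: int, name: str) -> np.random.Generator:
    """Return an RNG for a named substream of a global seed.

    Every stochastic stage draws from its own substream keyed by a stable
    string (``"generator"``, ``"clara"``, ``"fits"``, ...), so reseeding or
    re-ordering one stage never perturbs the draws of another.
    """
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(key,)))


def fmt6(x: float) -> str:
    """Format a float with 6 significant digits (TSV output convention)."""
    if isinstance(x, (int, np.integer)):
        return str(int(x))
    return format(float(x), ".6g")
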