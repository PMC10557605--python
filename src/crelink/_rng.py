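"""Named child RNG streams.

A single integer seed fans out to independent per-component streams keyed by
name, so adding a component to a simulation never perturbs the draws of the
others.
"""

from __future__ import annotations

import zlib

import numpy as np


def child_rng(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for the named substream of ``seed``.

    The child seed is derived from ``(seed, crc32(name))`` so each component
    name maps to a fixed, order-independent stream.
    """
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, key]))
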