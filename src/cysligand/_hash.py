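"""Stable hashing helpers.

Python's builtin ``hash`` is salted per process, so anything that must be
reproducible across runs (synthetic embeddings, archetype assignment,
derived RNG streams) goes through SHA-256 here.
"""

from __future__ import annotations

import hashlib

import numpy as np

_U31 = 2**31


def stable_u31(*parts) -> int:
    """Deterministically map the reprs of ``parts`` to an int in [0, 2**31)."""
    h = hashlib.sha256()
    for p in parts:
        h.update(repr(p).encode("utf-8"))
        h.update(b"\x1f")
    return int.from_bytes(h.digest()[:8], "big") % _U31


def rng_for(*parts) -> np.random.Generator:
    """A ``numpy`` Generator seeded from a stable hash of ``parts``."""
    return np.random.default_rng(stable_u31(*parts))
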