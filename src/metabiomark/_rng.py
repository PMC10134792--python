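"""Deterministic seed splitting.

All randomness in the package flows from one integer seed.  Sub-generators
for independent stages are derived by hashing a scope path (e.g.
``("study", "matson")``) together with the root seed, so any stage can be
re-run in isolation and still produce the same stream.
"""

import hashlib

import numpy as np


def child_seed_sequence(seed: int, *scope: str) -> np.random.SeedSequence:
    """Build a :class:`numpy.random.SeedSequence` for ``seed`` within ``scope``.

    The scope path is hashed with SHA-256 so that distinct paths give
    statistically independent streams, and the mapping is stable across
    processes and platforms.
    """
    digest = hashlib.sha256("/".join(scope).encode("utf-8")).digest()
    words = [int.from_bytes(digest[i : i + 4], "little") for i in (0, 4, 8, 12)]
    return np.random.SeedSequence([int(seed) & 0xFFFFFFFF, *words])


def child_rng(seed: int, *scope: str) -> np.random.Generator:
    """Return a generator seeded deterministically from ``seed`` and ``scope``."""
    return np.random.default_rng(child_seed_sequence(seed, *scope))


def child_int_seed(seed: int, *scope: str) -> int:
    """Return a plain integer seed derived from ``seed`` and ``scope``."""
    return int(child_seed_sequence(seed, *scope).generate_state(1)[0])
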