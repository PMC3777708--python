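"""Deterministic seed management.

All randomness in the package flows from a single master seed which is split
into named sub-streams, so every stage (cohort generation, rewiring nulls,
Louvain iterations, simulations) is independently reproducible.
"""

from __future__ import annotations

import random
import zlib

import numpy as np

__all__ = ["child_seed_sequence", "child_rng", "child_int_seed", "igraph_rng"]


def _name_key(name: str) -> int:
    # stable across processes (unlike hash())
    return zlib.crc32(name.encode("utf-8"))


def child_seed_sequence(master: int, name: str) -> np.random.SeedSequence:
    """A named, reproducible child seed sequence of ``master``."""
    return np.random.SeedSequence(entropy=[int(master) & 0x7FFFFFFF, _name_key(name)])


def child_rng(master: int, name: str) -> np.random.Generator:
    """A numpy Generator for the named sub-stream."""
    return np.random.default_rng(child_seed_sequence(master, name))


def child_int_seed(master: int, name: str) -> int:
    """A small positive integer seed (for libraries that want one)."""
    return int(child_seed_sequence(master, name).generate_state(1)[0] % (2**31 - 1))


# igraph draws its randomness from a generator registered globally; we keep a
# dedicated instance so seeding it never disturbs Python's global `random`.
_IGRAPH_RANDOM = random.Random()
_REGISTERED = False


def igraph_rng(seed: int) -> random.Random:
    """Seed and return the Random instance that backs igraph's RNG."""
    global _REGISTERED
    if not _REGISTERED:
        import igraph

        igraph.set_random_number_generator(_IGRAPH_RANDOM)
        _REGISTERED = True
    _IGRAPH_RANDOM.seed(int(seed))
    return _IGRAPH_RANDOM
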