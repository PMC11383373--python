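"""Deterministic per-entity random streams.

All randomness in the package flows through :func:`rng_for`: a master
seed plus string tokens (e.g. a sample id) are hashed into a
``SeedSequence``, so each sample's stream is a pure function of
``(master_seed, tokens)`` and adding samples to a cohort never perturbs
the draws of existing ones.
"""

from __future__ import annotations

import hashlib

import numpy as np


def _token_words(token: object) -> list[int]:
    digest = hashlib.sha256(str(token).encode("utf-8")).digest()
    return [int.from_bytes(digest[i : i + 4], "little") for i in (0, 4, 8, 12)]


def seed_sequence(master_seed: int, *tokens: object) -> np.random.SeedSequence:
    entropy = [int(master_seed) & 0x7FFFFFFF]
    for t in tokens:
        entropy.extend(_token_words(t))
    return np.random.SeedSequence(entropy)


def rng_for(master_seed: int, *tokens: object) -> np.random.Generator:
    """A PCG64 generator keyed by the master seed and arbitrary tokens."""
    return np.random.default_rng(seed_sequence(master_seed, *tokens))
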