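"""Shared constants and helpers."""

from __future__ import annotations

import zlib

import numpy as np

#: Sentinel for a missing genotype in a dosage matrix. Dosage values are
#: therefore restricted to {-1, 0, 1, 2}; -1 never enters any arithmetic.
MISSING = -1


def derive_seed(master_seed: int, *tokens: object) -> int:
    """Derive a stable child seed from a master seed and a label.

    The derivation hashes the string forms of ``tokens`` with CRC-32 so the
    same (seed, label) pair always maps to the same child seed, independent
    of execution order. The result is kept below 2**31.
    """
    h = zlib.crc32(repr(tuple(str(t) for t in tokens)).encode())
    return int((master_seed * 1_000_003 + h) % (2**31 - 1))


def rng_from(master_seed: int, *tokens: object) -> np.random.Generator:
    return np.random.default_rng(derive_seed(master_seed, *tokens))
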