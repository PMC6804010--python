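"""Seed-splitting helpers.

All randomness in the package flows from a single integer seed.  Child
streams are derived with :class:`numpy.random.SeedSequence` spawn keys so
that every module draws from a statistically independent stream that is a
pure function of (root seed, stream label).
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["child_rng", "child_seed"]


def _key(label: str | int) -> int:
    if isinstance(label, int):
        return label
    return zlib.crc32(label.encode("utf-8"))


def child_rng(seed: int, *labels: str | int) -> np.random.Generator:
    """Deterministic child generator for ``(seed, labels...)``."""
    ss = np.random.SeedSequence(int(seed), spawn_key=tuple(_key(l) for l in labels))
    return np.random.default_rng(ss)


def child_seed(seed: int, *labels: str | int) -> int:
    """A plain integer child seed (< 2**31), e.g. for scikit-learn."""
    ss = np.random.SeedSequence(int(seed), spawn_key=tuple(_key(l) for l in labels))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))
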