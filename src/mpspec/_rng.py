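"""Deterministic named substreams derived from one top-level seed."""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(seed: int, *keys: str | int) -> np.random.Generator:
    """A generator for the substream named by ``keys`` under ``seed``.

    Distinct key paths give statistically independent streams; the same
    path is bit-reproducible.  String keys are hashed with CRC32 so the
    mapping is stable across processes and platforms.
    """
    entropy = [int(seed) & 0x7FFFFFFF]
    for k in keys:
        if isinstance(k, str):
            entropy.append(zlib.crc32(k.encode("utf-8")))
        else:
            entropy.append(int(k) & 0xFFFFFFFF)
    return np.random.default_rng(np.random.SeedSequence(entropy))
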