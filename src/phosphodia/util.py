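"""Seed plumbing: one master seed, stable per-stage substreams."""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream_seed", "substream"]


def substream_seed(master_seed: int, stage: str) -> int:
    """Deterministic sub-seed for a named stage.

    Derived by hashing the stage name (CRC32) into a SeedSequence with the
    master seed, so inserting a new stage never scrambles the streams of
    unrelated stages.  The result is kept below 2**31.
    """
    ss = np.random.SeedSequence(
        [int(master_seed) & 0x7FFFFFFF, zlib.crc32(stage.encode())]
    )
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def substream(master_seed: int, stage: str) -> np.random.Generator:
    """Generator seeded from the stage substream."""
    return np.random.default_rng(substream_seed(master_seed, stage))
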