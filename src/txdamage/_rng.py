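"""Deterministic per-stage random streams derived from one root seed."""
from __future__ import annotations

import zlib

import numpy as np


def child_rng(seed: int, stage: str) -> np.random.Generator:
    """Generator for a named stage, reproducible independently of other stages.

    The child stream is keyed on (root seed, CRC32 of the stage name) so each
    stage can be re-run in isolation with identical output.
    """
    root = int(seed) & 0xFFFFFFFF
    offset = zlib.crc32(stage.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([root, offset]))
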