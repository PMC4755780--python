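"""Deterministic derivation of independent random streams from one seed.

A global integer seed expands into named child streams via
``SeedSequence([seed, crc32(label), index])``, so adding an analysis stream
never perturbs the draws of the dynamics stream, and replicate ``i`` of a
protocol has its own stream regardless of how many replicates run.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["stream", "child_seed"]


def child_seed(seed: int, label: str, index: int = 0) -> np.random.SeedSequence:
    return np.random.SeedSequence([int(seed), zlib.crc32(label.encode()), int(index)])


def stream(seed: int, label: str, index: int = 0) -> np.random.Generator:
    """Named child generator of the global seed."""
    return np.random.default_rng(child_seed(seed, label, index))
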