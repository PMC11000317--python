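"""Named random substreams derived from a single pipeline seed.

Every stochastic step (synthetic data, bootstrap resampling, CV fold
assignment) draws from its own named stream so that changing the number of
draws in one step never perturbs another.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for the named substream of ``seed``.

    The stream key is a CRC32 of the name, so streams are stable across
    sessions and independent of call order.
    """
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))
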