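"""Named, reproducible random streams derived from one master seed."""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["child_rng"]


def child_rng(master_seed: int, name: str) -> np.random.Generator:
    """Return a Generator for a named child stream of ``master_seed``.

    Distinct names yield statistically independent streams; the same
    (seed, name) pair always yields the same stream.
    """
    tag = zlib.crc32(name.encode("utf-8"))
    seq = np.random.SeedSequence(entropy=int(master_seed) % (2**31), spawn_key=(tag,))
    return np.random.default_rng(seq)
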