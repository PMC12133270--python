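"""Named random substreams derived from a single master seed.

Every source of randomness in the package draws from a stream keyed by the
master seed plus a tuple of stage/model names, so adding or reordering models
never perturbs another model's draws.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["substream"]


def _name_key(name: str) -> int:
    return int.from_bytes(hashlib.sha256(name.encode("utf-8")).digest()[:4], "little")


def substream(seed: int, *names: str) -> np.random.Generator:
    """Return a Generator for the stream identified by ``(seed, *names)``.

    Identical arguments always yield an identical stream; distinct name
    tuples yield independent streams.
    """
    keys = [int(seed) & 0x7FFFFFFF] + [_name_key(n) for n in names]
    return np.random.default_rng(np.random.SeedSequence(keys))
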