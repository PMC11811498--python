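"""Named random substreams derived from a single top-level seed.

Every stochastic stage draws from ``substream(seed, "stage-name")`` so that
adding or reordering stages never perturbs the randomness of the others, and
a run is fully reproducible from one integer.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["substream"]


def _name_key(name: str) -> int:
    digest = hashlib.blake2b(name.encode("utf-8"), digest_size=4).digest()
    return int.from_bytes(digest, "big")


def substream(seed: int, *names: str) -> np.random.Generator:
    """Return a Generator for the substream identified by ``names``.

    The same (seed, names) pair always yields an identically-seeded
    generator; distinct names yield statistically independent streams.
    """
    entropy = [int(seed) & 0x7FFFFFFF] + [_name_key(n) for n in names]
    return np.random.default_rng(np.random.SeedSequence(entropy))
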