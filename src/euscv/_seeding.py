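"""Stable derivation of per-stage random seeds.

Every stochastic stage of the pipeline draws its seed from the global run
seed plus a tuple of string tags naming the stage (and, where relevant, the
fold / patient it concerns).  Adding a new stage therefore never perturbs
the random streams of existing stages.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["derive_seed", "derive_rng"]


def derive_seed(seed: int, *tags: object) -> int:
    """Return a deterministic 31-bit seed from ``seed`` and string tags."""
    payload = repr(int(seed)) + "|" + "/".join(str(t) for t in tags)
    digest = hashlib.sha256(payload.encode("utf-8")).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def derive_rng(seed: int, *tags: object) -> np.random.Generator:
    """A ``numpy`` Generator seeded via :func:`derive_seed`."""
    return np.random.default_rng(derive_seed(seed, *tags))
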