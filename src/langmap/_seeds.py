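"""Deterministic derivation of per-stage random seeds from a master seed.

Every stochastic stage of the pipeline draws its randomness from a
``numpy.random.Generator`` obtained here, so that a single master seed fixes
the whole run while stages and subjects remain statistically independent.
"""

from __future__ import annotations

import hashlib

import numpy as np

_MOD = 2**31 - 1


def stage_seed(master_seed: int, *names: object) -> int:
    """Derive a reproducible integer seed (< 2^31) for a named stage.

    Parameters
    ----------
    master_seed
        The run-level seed.
    names
        Stage identifiers (strings or integers), e.g. ``("rest", subject_id, run)``.
    """
    h = hashlib.sha256()
    h.update(str(int(master_seed)).encode())
    for name in names:
        h.update(b"\x1f")
        h.update(str(name).encode())
    return int.from_bytes(h.digest()[:8], "big") % _MOD


def stage_rng(master_seed: int, *names: object) -> np.random.Generator:
    """A fresh ``Generator`` seeded for the named stage."""
    return np.random.default_rng(stage_seed(master_seed, *names))
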