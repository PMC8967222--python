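"""Seed plumbing.

Every public operation that consumes randomness derives its generator from
one user-facing integer seed plus a stage tag, via NumPy's ``SeedSequence``
spawn-key mechanism. Stages can therefore be re-run independently (e.g. the
control-dwell generator does not perturb the trajectory simulator's stream)
while the whole pipeline stays bit-reproducible under one seed.
"""
from __future__ import annotations

import zlib

import numpy as np


def stage_seed_sequence(seed: int, stage: str) -> np.random.SeedSequence:
    """A ``SeedSequence`` keyed by ``(seed, crc32(stage))``."""
    tag = zlib.crc32(stage.encode("utf-8")) & 0x7FFFFFFF
    return np.random.SeedSequence(entropy=int(seed), spawn_key=(tag,))


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Deterministic per-stage generator derived from one integer seed."""
    return np.random.default_rng(stage_seed_sequence(seed, stage))
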