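"""Small shared helpers."""

from __future__ import annotations

import numpy as np

_RC = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return seq.translate(_RC)[::-1]


def child_rng(seed: int | None, *salt: int) -> np.random.Generator:
    """Derive an independent generator from a base seed and integer salt.

    Keeps derived seeds below 2**31 so they survive round-trips through
    config files and command lines.
    """
    if seed is None:
        return np.random.default_rng()
    ss = np.random.SeedSequence(int(seed) % (2**31), spawn_key=tuple(int(s) for s in salt))
    return np.random.default_rng(ss)
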