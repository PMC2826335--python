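"""Small shared helpers: deterministic RNG sub-streams and half-up rounding."""

from __future__ import annotations

import math

import numpy as np


def round_half_up(x: float) -> int:
    """Round to the nearest integer with exact halves rounding up.

    Printed percentage tables in marker surveys conventionally use half-up
    rounding (87.5 -> 88), unlike Python's banker's rounding.
    """
    if not math.isfinite(x):
        raise ValueError(f"cannot round non-finite value {x!r}")
    return int(math.floor(x + 0.5))


def substream(seed: int, *keys: int) -> np.random.Generator:
    """Independent RNG stream keyed by (seed, *keys).

    Counter-style keyed streams make draws for one (marker, accession) cell
    independent of how many other markers or accessions exist, so enlarging a
    simulated panel never perturbs earlier draws.
    """
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, *map(int, keys)])
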