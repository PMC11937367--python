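"""Shared helpers: gene-symbol normalization, seed splitting, rounding."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import numpy as np

EV = "EV"
SF = "SF"
FRACTIONS = (EV, SF)


def normalize_symbol(symbol: str) -> str:
    """Uppercase and strip a gene symbol; no alias resolution."""
    s = str(symbol).strip().upper()
    if not s:
        raise ValueError("empty gene symbol")
    return s


def normalize_symbols(symbols) -> set[str]:
    return {normalize_symbol(s) for s in symbols}


def round_half_up(x: float, decimals: int) -> float:
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def child_seed(master_seed: int, stream: str) -> int:
    """Deterministic per-module substream seed derived from one master seed.

    Keeps every derived seed in [0, 2**31) so it is portable as an int32.
    """
    ss = np.random.SeedSequence(
        [int(master_seed) % (2**31), *(ord(c) for c in stream)]
    )
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def rng_for(master_seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(child_seed(master_seed, stream))
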