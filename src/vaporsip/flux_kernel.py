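"""Shared tracer-flux kernel.

Both tracer equations — 2H into fatty acids and 18O into DNA — reduce to the
same mass-balance kernel: the newly produced amount of a pool equals its size
times the excess heavy-isotope enrichment relative to the enrichment of the
assimilated source,

    produced = pool * (at%_labelled - at%_natural) / denominator_at%

where the denominator is the (assimilation-weighted) soil-water enrichment.
Negative excess — labelled below natural abundance, expected from instrument
noise at near-zero growth — optionally clamps to zero with a flag instead of
propagating negative production.
"""
from __future__ import annotations

from dataclasses import dataclass

from .errors import DomainError

__all__ = ["KernelResult", "excess_fraction_production"]


@dataclass(frozen=True)
class KernelResult:
    produced: float
    fraction_new: float
    clamped: bool


def excess_fraction_production(
    atpct_labelled: float,
    atpct_natural: float,
    denominator_atpct: float,
    pool: float,
    clamp_negative: bool = True,
) -> KernelResult:
    """Apply the excess-enrichment kernel to one pool.

    Raises
    ------
    DomainError
        Non-positive denominator enrichment or negative pool.
    """
    if denominator_atpct <= 0:
        raise DomainError(f"denominator enrichment must be > 0 at%, got {denominator_atpct}")
    if pool < 0:
        raise DomainError("pool size must be >= 0")
    fraction_new = (atpct_labelled - atpct_natural) / denominator_atpct
    if fraction_new < 0 and clamp_negative:
        return KernelResult(produced=0.0, fraction_new=0.0, clamped=True)
    return KernelResult(produced=fraction_new * pool, fraction_new=fraction_new, clamped=False)
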