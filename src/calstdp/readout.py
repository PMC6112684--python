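"""Macroscopic readout: map per-pathway switch fractions to synaptic strength.

For each pathway the ensemble yields U (fraction of depressed-start synapses
that ended potentiated) and D (fraction of potentiated-start synapses that
ended depressed).  The relative change in macroscopic synaptic strength
contributed by a pathway is a sigmoid H of the ratio r = U/D, pinned by

    H(1) = 1         (balanced switching: no net change)
    H(0) = LTD*      (no potentiation: maximal depression)
    H(inf) = LTP*    (no depression: maximal potentiation)

and the total change is the product of the per-pathway factors.  Pathway
blockade (pharmacological inactivation) corresponds to restricting the
product to a subset of pathways.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

from .params import ReadoutParams

__all__ = [
    "h_coefficients",
    "h_map",
    "pathway_factor",
    "total_change",
    "PlasticityOutcome",
]


def h_coefficients(readout: ReadoutParams) -> tuple[float, float, float, float]:
    """Coefficients (a, b, d, Delta) of H(r) = a + b / (1 + exp(-s (r - d))).

    With Delta = (LTP* - LTD*)/(LTP* - 1), the three pinning conditions give

        d = (1/s) * log((Delta - e^s) / (1 - Delta))
        b = (LTP* - LTD*) / (1 - 1/(1 + e^{s d}))
        a = LTP* - b

    which requires exp(s) > Delta (enforced by ReadoutParams).
    """
    s = readout.slope_s
    delta = readout.delta
    if not math.exp(s) > delta:
        raise ValueError(
            f"h_coefficients requires exp(slope_s) > Delta, got exp({s})={math.exp(s):.4g}"
            f" <= {delta:.4g}"
        )
    d = math.log((delta - math.exp(s)) / (1.0 - delta)) / s
    b = (readout.ltp_star - readout.ltd_star) / (1.0 - 1.0 / (1.0 + math.exp(s * d)))
    a = readout.ltp_star - b
    return a, b, d, delta


def h_map(r: float, readout: ReadoutParams) -> float:
    """Evaluate the sigmoid readout H at ratio ``r`` (r >= 0 or r = inf)."""
    if r < 0:
        raise ValueError(f"ratio must be >= 0, got {r}")
    if math.isinf(r):
        return readout.ltp_star
    a, b, d, _ = h_coefficients(readout)
    x = -readout.slope_s * (r - d)
    if x > 700:  # deep depression tail; avoid overflow
        return a
    return a + b / (1.0 + math.exp(x))


def pathway_factor(
    u: float, d: float, readout: ReadoutParams, *, min_fraction: float = 0.0
) -> float:
    """H factor of one pathway from its switch fractions.

    Fractions below ``min_fraction`` are treated as zero (used by the analytic
    engine, where Gaussian tails are never exactly 0 but a finite ensemble of
    N synapses cannot register probabilities below ~1/N).  The degenerate
    cases are fixed by the pinning conditions: U = D = 0 -> factor 1 (no
    plasticity evidence), D = 0 < U -> LTP*.
    """
    if not (0.0 <= u <= 1.0) or not (0.0 <= d <= 1.0):
        raise ValueError(f"switch fractions must lie in [0,1], got U={u}, D={d}")
    if u < min_fraction:
        u = 0.0
    if d < min_fraction:
        d = 0.0
    if u == 0.0 and d == 0.0:
        return 1.0
    if d == 0.0:
        return readout.ltp_star
    return h_map(u / d, readout)


def total_change(
    uds: Mapping[str, tuple[float, float]],
    readout: ReadoutParams,
    included: Iterable[str] | None = None,
    *,
    min_fraction: float = 0.0,
) -> float:
    """Product of H factors over the included pathways.

    ``uds`` maps pathway name -> (U, D).  ``included=None`` means all
    pathways; an explicit subset models pathway blockade.
    """
    names = list(uds) if included is None else list(included)
    if not names:
        raise ValueError("included pathway set must be non-empty")
    out = 1.0
    for name in names:
        u, d = uds[name]
        out *= pathway_factor(u, d, readout, min_fraction=min_fraction)
    return out


@dataclass(frozen=True)
class PlasticityOutcome:
    """Per-pathway switch fractions, H factors, and the total change."""

    u: dict
    d: dict
    h: dict
    total: float

    @classmethod
    def from_fractions(
        cls,
        uds: Mapping[str, tuple[float, float]],
        readout: ReadoutParams,
        included: Iterable[str] | None = None,
        *,
        min_fraction: float = 0.0,
    ) -> "PlasticityOutcome":
        names = list(uds) if included is None else list(included)
        h = {
            name: pathway_factor(*uds[name], readout, min_fraction=min_fraction)
            for name in names
        }
        tot = total_change(uds, readout, names, min_fraction=min_fraction)
        return cls(
            u={n: uds[n][0] for n in names},
            d={n: uds[n][1] for n in names},
            h=h,
            total=tot,
        )
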