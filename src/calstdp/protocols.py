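"""Deterministic stimulation protocols: spike pairs, triplets, repetitions.

A protocol repeats a fixed pre/post spike pattern ``n_pairings`` times at
frequency ``freq``.  Spike timing follows the convention
``dt = t_post - t_pre``: negative for post-before-pre ("post-pre"), positive
for pre-before-post ("pre-post").  For triplets, ``dt_i = t_post - t_pre,i``
(two pre, one post) or ``dt_i = t_post,i - t_pre`` (one pre, two post).

Anchor convention: pre spike #1 of pairing ``k`` sits at ``k / freq``; all
other spikes are offsets from it.  Any consistent anchor only shifts the
global time origin.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "PATTERNS",
    "StimulationProtocol",
    "SpikeSchedule",
    "build_schedule",
    "fold_dt",
]

PATTERNS = ("pair", "pre_post_pre", "post_pre_post")


@dataclass(frozen=True)
class StimulationProtocol:
    """A repeated pre/post spike pattern.

    For ``pattern="pair"`` give ``dt``; for the triplet patterns give ``dt1``
    and ``dt2`` with the ordering invariants ``dt1 < dt2`` (pre_post_pre: two
    pre, one post) or ``dt1 > dt2`` (post_pre_post: one pre, two post).
    """

    pattern: str
    freq: float
    n_pairings: int
    dt: float | None = None
    dt1: float | None = None
    dt2: float | None = None

    def __post_init__(self) -> None:
        if self.pattern not in PATTERNS:
            raise ValueError(f"pattern must be one of {PATTERNS}, got {self.pattern!r}")
        if not self.freq > 0:
            raise ValueError(f"freq must be > 0, got {self.freq}")
        if self.n_pairings < 1:
            raise ValueError(f"n_pairings must be >= 1, got {self.n_pairings}")
        if self.pattern == "pair":
            if self.dt is None:
                raise ValueError("pair pattern requires dt")
            if self.dt1 is not None or self.dt2 is not None:
                raise ValueError("pair pattern takes dt, not dt1/dt2")
        else:
            if self.dt1 is None or self.dt2 is None:
                raise ValueError(f"{self.pattern} requires dt1 and dt2")
            if self.dt is not None:
                raise ValueError(f"{self.pattern} takes dt1/dt2, not dt")
            if self.pattern == "pre_post_pre" and not self.dt1 < self.dt2:
                raise ValueError("pre_post_pre requires dt1 < dt2 (distinct pre spikes)")
            if self.pattern == "post_pre_post" and not self.dt1 > self.dt2:
                raise ValueError("post_pre_post requires dt1 > dt2 (distinct post spikes)")

    @property
    def period(self) -> float:
        return 1.0 / self.freq

    def spike_offsets(self) -> tuple[tuple[float, ...], tuple[float, ...]]:
        """(pre offsets, post offsets) of one pattern relative to its anchor."""
        if self.pattern == "pair":
            return (0.0,), (self.dt,)
        if self.pattern == "pre_post_pre":
            # dt_i = t_post - t_pre,i; pre #1 anchors at 0, so t_post = dt1.
            return (0.0, self.dt1 - self.dt2), (self.dt1,)
        # post_pre_post: dt_i = t_post,i - t_pre; single pre anchors at 0.
        return (0.0,), (self.dt2, self.dt1)


@dataclass(frozen=True)
class SpikeSchedule:
    """Realized pre- and postsynaptic spike times, sorted ascending."""

    pre_times: tuple[float, ...]
    post_times: tuple[float, ...]

    def __post_init__(self) -> None:
        for name, times in (("pre_times", self.pre_times), ("post_times", self.post_times)):
            if any(b < a for a, b in zip(times, times[1:])):
                raise ValueError(f"{name} must be sorted ascending")

    @property
    def span(self) -> tuple[float, float]:
        allt = self.pre_times + self.post_times
        return (min(allt), max(allt))


def build_schedule(protocol: StimulationProtocol) -> SpikeSchedule:
    """Realize the protocol as explicit spike-time lists.

    Pairing ``k`` (k = 0 .. n_pairings-1) is anchored at ``k / freq``.
    """
    pre_off, post_off = protocol.spike_offsets()
    T = protocol.period
    pre = sorted(k * T + o for k in range(protocol.n_pairings) for o in pre_off)
    post = sorted(k * T + o for k in range(protocol.n_pairings) for o in post_off)
    return SpikeSchedule(pre_times=tuple(pre), post_times=tuple(post))


def fold_dt(dt: float, freq: float) -> float:
    """Reduce a spike timing modulo the pairing period into (-T/2, T/2].

    At pairing frequency ``F`` the protocol is periodic with period
    ``T = 1/F``, so only timings in ``(-1/(2F), +1/(2F)]`` are distinct.
    """
    T = 1.0 / freq
    folded = dt - round(dt / T) * T
    if folded <= -T / 2:
        folded += T
    return folded
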