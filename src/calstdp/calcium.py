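"""Closed-form calcium trace: values, running integral, threshold crossings.

The postsynaptic calcium concentration is a sum of decaying exponentials: each
spike deposits an instantaneous impulse (``c_post`` at the postsynaptic spike
time, ``c_pre`` at the presynaptic spike time shifted by the influx delay
``delay_d``) which then relaxes with time constant ``tau_ca`` towards the
resting level 0.  All quantities here are evaluated exactly from the event
list — no time grid is involved.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .params import CalciumParams
from .protocols import SpikeSchedule, StimulationProtocol, build_schedule

__all__ = [
    "CalciumTrace",
    "trace_from_schedule",
    "single_repetition_trace",
    "inactivation_pairing",
    "repetition_calcium_integral",
]


@dataclass(frozen=True)
class CalciumTrace:
    """An impulse-response calcium trace: sorted events and a decay constant."""

    times: tuple[float, ...]
    amplitudes: tuple[float, ...]
    tau_ca: float

    def __post_init__(self) -> None:
        if len(self.times) != len(self.amplitudes):
            raise ValueError("times and amplitudes must have equal length")
        if any(b < a for a, b in zip(self.times, self.times[1:])):
            raise ValueError("events must be sorted by time")
        if any(a <= 0 for a in self.amplitudes):
            raise ValueError("amplitudes must be > 0")
        if not self.tau_ca > 0:
            raise ValueError("tau_ca must be > 0")

    # -- evaluation ----------------------------------------------------------

    def value_at(self, t):
        """c(t); right-continuous (the jump at an event time is included)."""
        t = np.asarray(t, dtype=float)
        ts = np.array(self.times)
        amps = np.array(self.amplitudes)
        out = np.zeros_like(t, dtype=float)
        for te, a in zip(ts, amps):
            m = t >= te
            out = out + np.where(m, a * np.exp(np.minimum((te - t), 0.0) / self.tau_ca), 0.0)
        return out if out.ndim else float(out)

    def integral_to(self, t):
        """∫_{-inf}^{t} c(s) ds, exactly.

        Each event contributes ``a * tau_ca * (1 - exp(-(t - t_e)/tau_ca))``
        once passed; the result is non-decreasing in ``t``.
        """
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t, dtype=float)
        for te, a in zip(self.times, self.amplitudes):
            m = t >= te
            out = out + np.where(
                m, a * self.tau_ca * (1.0 - np.exp(np.minimum((te - t), 0.0) / self.tau_ca)), 0.0
            )
        return out if out.ndim else float(out)

    def crossing_intervals(
        self, theta: float, window: tuple[float, float]
    ) -> list[tuple[float, float]]:
        """Maximal sub-intervals of ``window`` where c(t) >= theta, exactly.

        Between events the trace decays monotonically, so each inter-event
        segment contributes at most one downward crossing, solved in closed
        form: a segment starting at level C stays above theta for
        ``tau_ca * log(C / theta)``.
        """
        if not theta > 0:
            raise ValueError("theta must be > 0")
        t0, t1 = window
        if not t0 < t1:
            raise ValueError("window must satisfy t0 < t1")
        bounds = [t0] + [te for te in self.times if t0 < te < t1] + [t1]
        out: list[tuple[float, float]] = []
        for a, b in zip(bounds, bounds[1:]):
            c_a = self.value_at(a)
            if c_a >= theta:
                end = min(a + self.tau_ca * math.log(c_a / theta), b)
                if out and out[-1][1] == a:  # continues across an event
                    out[-1] = (out[-1][0], end)
                else:
                    out.append((a, end))
        return [(s, e) for s, e in out if e > s]

    def time_above(self, theta: float, window: tuple[float, float]) -> float:
        """Lebesgue measure of {t in [t0, t1] : c(t) >= theta}."""
        return sum(e - s for s, e in self.crossing_intervals(theta, window))

    def integral_crossing_time(self, mu: float, window: tuple[float, float]) -> float | None:
        """Exact time at which the running calcium integral reaches ``mu``.

        Returns None if the integral never reaches ``mu`` within the window.
        """
        from scipy.optimize import brentq

        t0, t1 = window
        if math.isinf(mu) or self.integral_to(t1) < mu:
            return None
        if self.integral_to(t0) >= mu:
            return t0
        return float(brentq(lambda t: self.integral_to(t) - mu, t0, t1, xtol=1e-12))


def trace_from_schedule(schedule: SpikeSchedule, cp: CalciumParams) -> CalciumTrace:
    """Build the calcium event list for a spike schedule.

    Presynaptic events are shifted by the influx delay ``delay_d``; zero
    amplitudes are dropped so the trace invariant (amplitudes > 0) holds.
    """
    events: list[tuple[float, float]] = []
    if cp.c_pre > 0:
        events += [(t + cp.delay_d, cp.c_pre) for t in schedule.pre_times]
    if cp.c_post > 0:
        events += [(t, cp.c_post) for t in schedule.post_times]
    events.sort()
    return CalciumTrace(
        times=tuple(t for t, _ in events),
        amplitudes=tuple(a for _, a in events),
        tau_ca=cp.tau_ca,
    )


def single_repetition_trace(protocol: StimulationProtocol, cp: CalciumParams) -> CalciumTrace:
    """Calcium trace of one isolated repetition of the protocol's pattern."""
    one = StimulationProtocol(
        pattern=protocol.pattern,
        freq=protocol.freq,
        n_pairings=1,
        dt=protocol.dt,
        dt1=protocol.dt1,
        dt2=protocol.dt2,
    )
    return trace_from_schedule(build_schedule(one), cp)


def repetition_calcium_integral(protocol: StimulationProtocol, cp: CalciumParams) -> float:
    """Total calcium integral contributed by one full repetition.

    In the fully-relaxing (low-frequency) regime each event contributes its
    complete ``amplitude * tau_ca``.
    """
    pre_off, post_off = protocol.spike_offsets()
    return (len(pre_off) * cp.c_pre + len(post_off) * cp.c_post) * cp.tau_ca


def inactivation_pairing(
    mu: float, protocol: StimulationProtocol, cp: CalciumParams
) -> int | None:
    """Pairing count at which a cumulative-calcium level ``mu`` is reached.

    Returns the smallest ``n >= 1`` with ``n * (per-repetition calcium
    integral) >= mu`` — e.g. with the cortico-striatal calcium parameters,
    one pairing deposits (7 + 17.1) * 0.018 = 0.4338, so mu = 6 is reached at
    pairing 14 and mu = 32 at pairing 74.  Returns None if ``mu`` is infinite
    or not reached within the protocol.
    """
    if math.isinf(mu):
        return None
    per = repetition_calcium_integral(protocol, cp)
    if per <= 0:
        return None
    n = math.ceil(mu / per)
    n = max(n, 1)
    if n > protocol.n_pairings:
        return None
    return n
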