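"""Ensemble simulation of the per-pathway bistable efficacy SDE.

Each pathway's individual synaptic efficacy follows

    tau drho = [ -rho(1-rho)(rho_star-rho)
                 + gamma_p (1-rho) A_p(t) - gamma_d rho A_d(t) ] dt
               + sigma sqrt(A_p(t) + A_d(t)) dW

where ``A_x(t) = 1`` while the calcium concentration exceeds the pathway's
LTP/LTD threshold and that threshold is not inactivated, else 0.  The noise
intensity ``sigma`` enters the tau-scaled equation on the same footing as the
rates ``gamma`` (so the efficacy increment per step carries a factor
``sigma/tau``); the noise is gated — fluctuations act only while a plasticity
mechanism is engaged.

Two ensembles of ``n_synapses`` efficacies are integrated per pathway, one
started depressed (rho = 0) and one potentiated (rho = 1).  They share the
deterministic calcium trace (and hence the gate functions) but have
independent noise.  The switch fractions are

    U = fraction of the depressed-start ensemble with rho > rho_star
    D = fraction of the potentiated-start ensemble with rho < rho_star

classified after the protocol (the post-protocol dynamics are deterministic
and preserve the side of rho_star, so this equals the steady-state fraction).

The gate functions are deterministic and shared by all synapses.  For the
piecewise threshold model they are computed exactly: the closed-form
threshold-crossing intervals of the calcium trace (cut at the exact time the
cumulative calcium reaches the inactivation level) are converted to a
fractional occupancy of each Euler step, so the integrated drive per pairing
carries no step-quantisation bias.  For the exponential threshold model the
time-varying threshold is sampled at step midpoints.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
import numpy as np

from .calcium import CalciumTrace, trace_from_schedule
from .params import PathwayParams, SynapseModel
from .protocols import StimulationProtocol, build_schedule

try:  # optional acceleration; the numpy fallback is bit-identical
    import numba

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

__all__ = [
    "SimulationSettings",
    "PathwayEnsemble",
    "EnsembleResult",
    "gate_masks",
    "simulate",
    "per_pairing_outcomes",
]

_EXP_CLIP = 700.0  # exp overflow guard for the exponential threshold model


@dataclass(frozen=True)
class SimulationSettings:
    """Euler-Maruyama ensemble settings."""

    n_synapses: int = 1000
    t_start: float = -1.0
    t_end: float = 101.0
    n_iter: int = 102000
    seed: int = 0
    record_per_pairing: bool = False

    def __post_init__(self) -> None:
        if self.n_synapses < 1:
            raise ValueError("n_synapses must be >= 1")
        if not self.t_start < self.t_end:
            raise ValueError("t_start must be < t_end")
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")

    @classmethod
    def for_model(cls, model: SynapseModel, **overrides) -> "SimulationSettings":
        """Settings from the model's preset defaults (N, window, N_iter)."""
        base = cls(
            n_synapses=model.default_n_synapses,
            t_start=model.default_window[0],
            t_end=model.default_window[1],
            n_iter=model.default_n_iter,
        )
        return replace(base, **overrides) if overrides else base

    @property
    def dt(self) -> float:
        return (self.t_end - self.t_start) / self.n_iter


@dataclass
class PathwayEnsemble:
    """One pathway's simulated ensembles and switch fractions."""

    u: float
    d: float
    rho_depressed: np.ndarray
    rho_potentiated: np.ndarray
    u_per_pairing: np.ndarray | None = None
    d_per_pairing: np.ndarray | None = None


@dataclass
class EnsembleResult:
    """Simulation output: per-pathway ensembles plus run metadata."""

    pathways: dict[str, PathwayEnsemble]
    protocol: StimulationProtocol
    settings: SimulationSettings

    def uds(self) -> dict[str, tuple[float, float]]:
        """Final (U, D) per pathway, for the readout module."""
        return {name: (pe.u, pe.d) for name, pe in self.pathways.items()}

    def uds_at(self, n: int) -> dict[str, tuple[float, float]]:
        """(U, D) per pathway after ``n`` completed pairings (needs recording)."""
        out = {}
        for name, pe in self.pathways.items():
            if pe.u_per_pairing is None:
                raise ValueError("per-pairing outcomes were not recorded")
            out[name] = (float(pe.u_per_pairing[n]), float(pe.d_per_pairing[n]))
        return out


# --- gate precomputation -----------------------------------------------------


def _midpoints(settings: SimulationSettings) -> np.ndarray:
    return settings.t_start + (np.arange(settings.n_iter) + 0.5) * settings.dt


def _interval_weights(
    intervals: list[tuple[float, float]], settings: SimulationSettings
) -> np.ndarray:
    """Per-step occupancy in [0, 1] of a union of time intervals."""
    w = np.zeros(settings.n_iter)
    dt = settings.dt
    t0 = settings.t_start
    for s, e in intervals:
        s = max(s, t0)
        e = min(e, settings.t_end)
        if e <= s:
            continue
        j0 = int((s - t0) // dt)
        j1 = min(int((e - t0) // dt), settings.n_iter - 1)
        if j0 == j1:
            w[j0] += (e - s) / dt
        else:
            w[j0] += (t0 + (j0 + 1) * dt - s) / dt
            w[j1] += (e - (t0 + j1 * dt)) / dt
            w[j0 + 1 : j1] += 1.0
    return np.clip(w, 0.0, 1.0)


def _pathway_gates(
    model: SynapseModel,
    p: PathwayParams,
    trace: CalciumTrace,
    settings: SimulationSettings,
    c: np.ndarray,
    integral: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """(LTP, LTD) gate occupancy per Euler step.

    Piecewise threshold model: exact within-step occupancy from the
    closed-form crossing intervals, cut at the exact time the cumulative
    calcium reaches mu.  Exponential model: the time-varying threshold is
    sampled at step midpoints (0/1 occupancy).
    """
    window = (settings.t_start, settings.t_end)
    gates = []
    for theta0, mu in ((p.theta0_p, p.mu_p), (p.theta0_d, p.mu_d)):
        if math.isinf(theta0):
            gates.append(np.zeros(settings.n_iter))
            continue
        if model.threshold_model == "piecewise":
            intervals = trace.crossing_intervals(theta0, window)
            t_mu = trace.integral_crossing_time(mu, window)
            if t_mu is not None:
                intervals = [
                    (s, min(e, t_mu)) for s, e in intervals if s < t_mu
                ]
            gates.append(_interval_weights(intervals, settings))
        else:  # exponential inactivation with sharpness epsilon
            if math.isinf(mu):
                theta = np.full_like(c, theta0)
            else:
                expo = (integral - mu) / model.epsilon
                bump = np.where(expo > _EXP_CLIP, np.inf, np.exp(np.minimum(expo, _EXP_CLIP)))
                theta = theta0 + bump
            gates.append((c >= theta).astype(float))
    return gates[0], gates[1]


def gate_masks(
    model: SynapseModel, protocol: StimulationProtocol, settings: SimulationSettings
) -> tuple[dict[str, tuple[np.ndarray, np.ndarray]], CalciumTrace]:
    """Per-pathway (LTP gate, LTD gate) occupancy arrays over the Euler steps."""
    schedule = build_schedule(protocol)
    trace = trace_from_schedule(schedule, model.calcium)
    tmid = _midpoints(settings)
    c = trace.value_at(tmid)
    integral = trace.integral_to(tmid)
    masks = {
        p.name: _pathway_gates(model, p, trace, settings, c, integral)
        for p in model.pathways
    }
    return masks, trace


# --- stepping kernels --------------------------------------------------------

if _HAVE_NUMBA:

    @numba.njit(cache=False)
    def _euler_kernel(
        rho, gp, gd, gamma_p, gamma_d, rho_star, dt_over_tau, noise_scale,
        noise, open_row, snap_steps, snaps, with_cubic,
    ):  # pragma: no cover - exercised via simulate()
        niter = gp.shape[0]
        m_tot = rho.shape[0]
        k = 0
        for i in range(niter):
            while k < snap_steps.shape[0] and snap_steps[k] == i:
                for m in range(m_tot):
                    snaps[k, m] = rho[m]
                k += 1
            ap = gp[i]
            ad = gd[i]
            for m in range(m_tot):  # two ensembles flattened into one vector
                r = rho[m]
                dr = gamma_p * (1.0 - r) * ap - gamma_d * r * ad
                if with_cubic:
                    dr -= r * (1.0 - r) * (rho_star - r)
                rho[m] = r + dr * dt_over_tau
            ng = ap + ad
            if ng > 0:
                row = open_row[i]
                f = noise_scale * math.sqrt(ng)
                for m in range(m_tot):
                    rho[m] += f * noise[row, m]
        while k < snap_steps.shape[0]:
            for m in range(m_tot):
                snaps[k, m] = rho[m]
            k += 1


def _euler_numpy(
    rho, gp, gd, gamma_p, gamma_d, rho_star, dt_over_tau, noise_scale,
    noise, open_row, snap_steps, snaps, with_cubic,
):
    niter = gp.shape[0]
    k = 0
    for i in range(niter):
        while k < snap_steps.shape[0] and snap_steps[k] == i:
            snaps[k] = rho
            k += 1
        ap = float(gp[i])
        ad = float(gd[i])
        dr = gamma_p * (1.0 - rho) * ap - gamma_d * rho * ad
        if with_cubic:
            dr -= rho * (1.0 - rho) * (rho_star - rho)
        rho += dr * dt_over_tau
        ng = ap + ad
        if ng > 0:
            rho += noise_scale * math.sqrt(ng) * noise[open_row[i]]
    while k < snap_steps.shape[0]:
        snaps[k] = rho
        k += 1


# --- snapshot placement ------------------------------------------------------


def _earliest_event_offset(protocol: StimulationProtocol, delay_d: float) -> float:
    pre_off, post_off = protocol.spike_offsets()
    return min([o + delay_d for o in pre_off] + list(post_off))


def _snapshot_steps(
    protocol: StimulationProtocol, settings: SimulationSettings, delay_d: float
) -> np.ndarray:
    """Step index for the state 'after n pairings', n = 0 .. n_pairings.

    The snapshot for pairing count n is taken just before the first calcium
    event of pairing n (states are classified against rho_star; between
    pairings the drift is the deterministic bistable relaxation, which
    preserves the side of rho_star, so this matches the basin endpoint).
    """
    e_min = _earliest_event_offset(protocol, delay_d)
    T = protocol.period
    steps = []
    for n in range(protocol.n_pairings + 1):
        s_n = n * T + e_min
        x = (s_n - settings.t_start) / settings.dt
        j = int(math.ceil(x - 0.5 - 1e-12))
        steps.append(min(max(j, 0), settings.n_iter))
    return np.asarray(steps, dtype=np.int64)


# --- driver ------------------------------------------------------------------


def simulate(
    model: SynapseModel,
    protocol: StimulationProtocol,
    settings: SimulationSettings | None = None,
    *,
    _with_cubic: bool = True,
) -> EnsembleResult:
    """Integrate the full nonlinear ensemble and classify switch fractions."""
    if settings is None:
        settings = SimulationSettings.for_model(model)
    schedule = build_schedule(protocol)
    trace = trace_from_schedule(schedule, model.calcium)
    if trace.times and (
        trace.times[0] < settings.t_start or trace.times[-1] > settings.t_end
    ):
        raise ValueError(
            f"protocol events span [{trace.times[0]:.4g}, {trace.times[-1]:.4g}] s, "
            f"outside the simulation window [{settings.t_start}, {settings.t_end}] s"
        )

    masks, _ = gate_masks(model, protocol, settings)
    dt = settings.dt
    n_syn = settings.n_synapses
    m_tot = 2 * n_syn
    snap_steps = (
        _snapshot_steps(protocol, settings, model.calcium.delay_d)
        if settings.record_per_pairing
        else np.empty(0, dtype=np.int64)
    )

    root = np.random.SeedSequence(settings.seed)
    children = root.spawn(len(model.pathways))

    pathways: dict[str, PathwayEnsemble] = {}
    for child, p in zip(children, model.pathways):
        gp, gd = masks[p.name]
        open_steps = np.flatnonzero((gp + gd) > 0)
        open_row = np.full(settings.n_iter, -1, dtype=np.int64)
        open_row[open_steps] = np.arange(open_steps.size)

        rng = np.random.default_rng(child)
        noise = (
            rng.standard_normal((open_steps.size, m_tot))
            if open_steps.size
            else np.zeros((1, m_tot))
        )

        rho = np.zeros(m_tot)
        rho[n_syn:] = 1.0
        snaps = np.empty((snap_steps.size, m_tot))

        kernel = _euler_kernel if _HAVE_NUMBA else _euler_numpy
        kernel(
            rho, gp, gd, p.gamma_p, p.gamma_d, model.rho_star, dt / model.tau,
            model.sigma / model.tau * math.sqrt(dt),
            noise, open_row, snap_steps, snaps, _with_cubic,
        )

        if not np.all(np.isfinite(rho)):
            raise FloatingPointError(
                f"non-finite efficacy in pathway {p.name} at the end of the run"
            )

        dep = rho[:n_syn]
        pot = rho[n_syn:]
        pe = PathwayEnsemble(
            u=float(np.mean(dep > model.rho_star)),
            d=float(np.mean(pot < model.rho_star)),
            rho_depressed=dep,
            rho_potentiated=pot,
        )
        if settings.record_per_pairing:
            pe.u_per_pairing = np.mean(snaps[:, :n_syn] > model.rho_star, axis=1)
            pe.d_per_pairing = np.mean(snaps[:, n_syn:] < model.rho_star, axis=1)
        pathways[p.name] = pe

    return EnsembleResult(pathways=pathways, protocol=protocol, settings=settings)


def per_pairing_outcomes(
    model: SynapseModel,
    protocol: StimulationProtocol,
    settings: SimulationSettings,
) -> list[dict[str, tuple[float, float]]]:
    """(U, D) per pathway after each pairing count 0 .. n_pairings.

    Snapshots along one realization are statistically dependent across
    pairing counts — they follow the same synapses through the protocol.
    """
    if not settings.record_per_pairing:
        raise ValueError("settings.record_per_pairing must be True")
    res = simulate(model, protocol, settings)
    return [res.uds_at(n) for n in range(protocol.n_pairings + 1)]
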