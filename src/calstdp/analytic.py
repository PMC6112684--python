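"""Closed-form Ornstein-Uhlenbeck mean-field solution at low pairing frequency.

When the calcium trace fully relaxes between pairings, the gated drift and
noise of the efficacy SDE can be homogenized over one pairing period ``T``:
with ``eta_x`` the time spent above threshold ``theta_x`` per pairing and
``Gamma_x = gamma_x * eta_x / T``, each pathway's linearized efficacy follows
an OU process

    drho = (alpha rho + beta) dt + sqrt(s2) dW
    alpha = -(Gamma_p + Gamma_d)/tau,  beta = Gamma_p/tau,
    s2    = sigma^2 (eta_p + eta_d) / (T tau^2)

with piecewise-constant coefficients: a threshold's contribution drops out at
its inactivation time ``t_x = n_x T`` (``n_x`` the pairing count at which the
cumulative calcium reaches ``mu_x``).  The mean and variance propagate in
closed form across phases, and the switch probabilities are Gaussian tails

    U(nT) = P(rho(nT) > rho_* | rho(0) = 0)
    D(nT) = P(rho(nT) < rho_* | rho(0) = 1).

The cubic bistable term is neglected (valid while single-pairing increments
are small), and thresholds are taken piecewise constant; the exponential
threshold model is approximated by its sharp (small-epsilon) limit here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.special import erf

from .calcium import inactivation_pairing, single_repetition_trace
from .params import PathwayParams, SynapseModel
from .protocols import StimulationProtocol

__all__ = [
    "OUPhase",
    "OUValidityError",
    "check_ou_validity",
    "homogenize",
    "ou_mean_var",
    "switch_probs",
    "switch_prob_curves",
]

_RELAX_TOL = 1e-6  # required fractional calcium relaxation between pairings


class OUValidityError(ValueError):
    """The pairing frequency is too high for the homogenized OU solution."""


@dataclass(frozen=True)
class OUPhase:
    """One phase of piecewise-constant OU coefficients.

    ``alpha`` (1/s) linear drift, ``beta`` (1/s) constant drift,
    ``diffusion_var`` (1/s) the variance production rate s2.
    """

    t_start: float
    t_end: float
    alpha: float
    beta: float
    diffusion_var: float

    def __post_init__(self) -> None:
        if not self.t_start < self.t_end:
            raise ValueError("phase must have t_start < t_end")

    @property
    def stationary_mean(self) -> float:
        """-beta/alpha, the level the mean relaxes towards (nan if alpha=0)."""
        if self.alpha == 0.0:
            return math.nan
        return -self.beta / self.alpha


def check_ou_validity(model: SynapseModel, protocol: StimulationProtocol) -> None:
    """Verify calcium relaxes (to < 1e-6 of one pattern) between pairings."""
    trace = single_repetition_trace(protocol, model.calcium)
    if not trace.times:
        return
    span = trace.times[-1] - trace.times[0]
    rest = protocol.period - span
    total_amp = sum(trace.amplitudes)
    residual = total_amp * math.exp(-max(rest, 0.0) / model.calcium.tau_ca)
    if rest <= 0 or residual > _RELAX_TOL * total_amp:
        raise OUValidityError(
            f"pairing frequency {protocol.freq} Hz leaves a calcium residual of "
            f"{residual:.3g} (> {_RELAX_TOL:g} of one pattern) between pairings; "
            "the homogenized solution does not apply - use the simulator"
        )


def homogenize(
    model: SynapseModel,
    pathway: PathwayParams,
    protocol: StimulationProtocol,
) -> list[OUPhase]:
    """Piecewise-constant OU phases for one pathway over the protocol."""
    check_ou_validity(model, protocol)
    T = protocol.period
    trace = single_repetition_trace(protocol, model.calcium)

    def eta(theta0: float) -> float:
        if math.isinf(theta0) or not trace.times:
            return 0.0
        lo = trace.times[0]
        return trace.time_above(theta0, (lo, lo + T))

    eta_p = eta(pathway.theta0_p)
    eta_d = eta(pathway.theta0_d)
    n_p = inactivation_pairing(pathway.mu_p, protocol, model.calcium)
    n_d = inactivation_pairing(pathway.mu_d, protocol, model.calcium)
    t_end = protocol.n_pairings * T

    cuts = {0.0, t_end}
    for n in (n_p, n_d):
        if n is not None and 0 < n * T < t_end:
            cuts.add(n * T)
    bounds = sorted(cuts)

    phases = []
    for a, b in zip(bounds, bounds[1:]):
        ep = eta_p if (n_p is None or a < n_p * T) else 0.0
        ed = eta_d if (n_d is None or a < n_d * T) else 0.0
        gamma_p = pathway.gamma_p * ep / T
        gamma_d = pathway.gamma_d * ed / T
        # noise gates follow the threshold crossings whether or not the rate
        # is zero, but a gamma=0 mechanism with an infinite threshold has
        # eta=0 so contributes nothing either way
        phases.append(
            OUPhase(
                t_start=a,
                t_end=b,
                alpha=-(gamma_p + gamma_d) / model.tau,
                beta=gamma_p / model.tau,
                diffusion_var=model.sigma**2 * (ep + ed) / (T * model.tau**2),
            )
        )
    return phases


def ou_mean_var(phases: list[OUPhase], rho0: float, t: float) -> tuple[float, float]:
    """Exact (mean, variance) of the piecewise OU process at time ``t``.

    Within a phase with coefficients (alpha, beta, s2):

        m(t) = m0 e^{alpha dt} + (beta/-alpha)(1 - e^{alpha dt})
        v(t) = v0 e^{2 alpha dt} + (s2 / -2 alpha)(1 - e^{2 alpha dt})

    (linear-in-dt limits when alpha = 0).  Variance starts at 0 at t = 0.
    """
    if not phases:
        raise ValueError("no phases given")
    if not phases[0].t_start <= t <= phases[-1].t_end + 1e-12:
        raise ValueError(
            f"t={t} outside the tiled phases [{phases[0].t_start}, {phases[-1].t_end}]"
        )
    m, v = float(rho0), 0.0
    for ph in phases:
        if t <= ph.t_start:
            break
        dt = min(t, ph.t_end) - ph.t_start
        if ph.alpha == 0.0:
            m = m + ph.beta * dt
            v = v + ph.diffusion_var * dt
        else:
            ea = math.exp(ph.alpha * dt)
            m = m * ea + (ph.beta / -ph.alpha) * (1.0 - ea)
            e2a = math.exp(2.0 * ph.alpha * dt)
            v = v * e2a + (ph.diffusion_var / (-2.0 * ph.alpha)) * (1.0 - e2a)
    return m, v


def _gauss_tail_above(x: float, mean: float, var: float) -> float:
    """P(X > x) for X ~ N(mean, var); point mass when var = 0."""
    if var <= 0.0:
        return 1.0 if mean > x else 0.0
    z = (mean - x) / math.sqrt(2.0 * var)
    return 0.5 * (1.0 + erf(z))


def _gauss_tail_below(x: float, mean: float, var: float) -> float:
    """P(X < x) for X ~ N(mean, var); point mass when var = 0."""
    if var <= 0.0:
        return 1.0 if mean < x else 0.0
    z = (x - mean) / math.sqrt(2.0 * var)
    return 0.5 * (1.0 + erf(z))


def switch_probs(
    phases: list[OUPhase], rho_star: float, T: float, n: int
) -> tuple[float, float]:
    """(U, D) after ``n`` pairings from the Gaussian law at t = n T."""
    if n < 1:
        raise ValueError("n must be >= 1")
    t = n * T
    m0, v0 = ou_mean_var(phases, 0.0, t)
    m1, v1 = ou_mean_var(phases, 1.0, t)
    u = _gauss_tail_above(rho_star, m0, v0)
    d = _gauss_tail_below(rho_star, m1, v1)
    return float(u), float(d)


def switch_prob_curves(
    model: SynapseModel, protocol: StimulationProtocol
) -> dict[str, tuple[list[float], list[float]]]:
    """Per-pathway (U, D) lists indexed by pairing count 0 .. n_pairings."""
    out = {}
    for p in model.pathways:
        phases = homogenize(model, p, protocol)
        us, ds = [0.0], [0.0]
        for n in range(1, protocol.n_pairings + 1):
            u, d = switch_probs(phases, model.rho_star, protocol.period, n)
            us.append(u)
            ds.append(d)
        out[p.name] = (us, ds)
    return out
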