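"""Model parameters, presets and configuration I/O.

The synapse model couples a shared postsynaptic calcium trace to ``P``
independent signalling pathways (e.g. endocannabinoid and NMDA-receptor
signalling at the cortico-striatal synapse).  Each pathway has its own LTP/LTD
rates and calcium thresholds, and the thresholds inactivate once the
cumulative calcium concentration exceeds a pathway-specific level, modelling
receptor desensitisation and resource depletion.

All times are stored internally in seconds.  Configuration files and preset
files may write time-like quantities either as plain numbers (seconds) or as
strings with an ``ms``/``s`` suffix (``"18 ms"``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from importlib import resources
from typing import Iterable, Mapping, Sequence

import yaml

__all__ = [
    "CalciumParams",
    "PathwayParams",
    "ReadoutParams",
    "SynapseModel",
    "PRESET_NAMES",
    "load_preset",
    "read_config",
    "write_config",
    "parse_time",
]


class ConfigError(ValueError):
    """Raised for malformed configuration data or invariant violations."""


def parse_time(value: object, *, name: str = "value") -> float:
    """Convert a time-like config value to seconds.

    Accepts plain numbers (interpreted as seconds) or strings with an optional
    ``ms`` or ``s`` suffix, e.g. ``"18 ms"`` -> ``0.018``.
    """
    if isinstance(value, (int, float)):
        return float(value)
    if isinstance(value, str):
        text = value.strip().lower().replace(",", ".")
        for suffix, scale in (("ms", 1e-3), ("s", 1.0)):
            if text.endswith(suffix):
                num = text[: -len(suffix)].strip()
                try:
                    return float(num) * scale
                except ValueError:
                    break
        else:
            try:
                return float(text)
            except ValueError:
                pass
    raise ConfigError(f"cannot parse {name} = {value!r} as a time in seconds")


def _parse_number(value: object, *, name: str = "value") -> float:
    if isinstance(value, (int, float)):
        return float(value)
    if isinstance(value, str):
        text = value.strip().lower()
        if text in {"inf", "+inf", ".inf", "infinity"}:
            return math.inf
        try:
            return float(text)
        except ValueError:
            pass
    raise ConfigError(f"cannot parse {name} = {value!r} as a number")


@dataclass(frozen=True)
class CalciumParams:
    """Spike-evoked calcium transients.

    Each presynaptic spike at ``t_pre`` adds a calcium impulse of amplitude
    ``c_pre`` at ``t_pre + delay_d``; each postsynaptic spike adds ``c_post``
    immediately.  Between spikes the concentration decays exponentially with
    time constant ``tau_ca`` towards the resting level (taken as 0).
    """

    c_pre: float
    c_post: float
    tau_ca: float
    delay_d: float = 0.0

    def __post_init__(self) -> None:
        if self.c_pre < 0:
            raise ConfigError(f"c_pre must be >= 0, got {self.c_pre}")
        if self.c_post < 0:
            raise ConfigError(f"c_post must be >= 0, got {self.c_post}")
        if not self.tau_ca > 0:
            raise ConfigError(f"tau_ca must be > 0, got {self.tau_ca}")


@dataclass(frozen=True)
class PathwayParams:
    """One signalling pathway's plasticity machinery.

    ``gamma_p``/``gamma_d`` are the LTP/LTD rates (dimensionless intensities
    acting at rate gamma/tau while the corresponding calcium gate is open);
    ``theta0_p``/``theta0_d`` the base calcium thresholds; ``mu_p``/``mu_d``
    the cumulative-calcium levels (concentration * seconds) beyond which the
    corresponding mechanism inactivates (+inf = never).  A pathway without an
    LTD mechanism is encoded with ``gamma_d = 0``.
    """

    name: str
    gamma_p: float
    gamma_d: float
    theta0_p: float
    theta0_d: float
    mu_p: float = math.inf
    mu_d: float = math.inf

    def __post_init__(self) -> None:
        if self.gamma_p < 0 or self.gamma_d < 0:
            raise ConfigError(f"pathway {self.name}: rates must be >= 0")
        if not self.theta0_p > 0 or not self.theta0_d > 0:
            raise ConfigError(f"pathway {self.name}: thresholds must be > 0")
        if not self.mu_p > 0 or not self.mu_d > 0:
            raise ConfigError(
                f"pathway {self.name}: inactivation levels must be > 0 or inf"
            )


@dataclass(frozen=True)
class ReadoutParams:
    """Parameters of the sigmoid map H from the U/D ratio to synaptic strength.

    ``ltp_star`` (> 1) and ``ltd_star`` (in (0, 1)) are the maximal relative
    potentiation and depression; ``slope_s`` the sigmoid slope.  The derived
    coefficients (a, b, d) are computed, not stored; see
    :func:`calstdp.readout.h_coefficients`.
    """

    ltp_star: float
    ltd_star: float
    slope_s: float

    def __post_init__(self) -> None:
        if not (0 < self.ltd_star < 1 < self.ltp_star):
            raise ConfigError(
                "readout requires 0 < ltd_star < 1 < ltp_star, got "
                f"ltd_star={self.ltd_star}, ltp_star={self.ltp_star}"
            )
        if not self.slope_s > 0:
            raise ConfigError(f"slope_s must be > 0, got {self.slope_s}")
        if not math.exp(self.slope_s) > self.delta:
            raise ConfigError(
                f"exp(slope_s)={math.exp(self.slope_s):.4g} must exceed "
                f"Delta={self.delta:.4g} for the H coefficients to exist"
            )

    @property
    def delta(self) -> float:
        """Delta = (LTP* - LTD*) / (LTP* - 1)."""
        return (self.ltp_star - self.ltd_star) / (self.ltp_star - 1.0)


THRESHOLD_MODELS = ("piecewise", "exponential")


@dataclass(frozen=True)
class SynapseModel:
    """Full synapse model: calcium dynamics, pathways, bistable SDE, readout.

    ``tau`` is the efficacy time constant (seconds, minutes-scale),
    ``rho_star`` the unstable midpoint of the bistable potential, ``sigma``
    the gated noise intensity.  ``threshold_model`` selects piecewise-constant
    or exponential (sharpness ``epsilon``) threshold inactivation.

    ``default_*`` fields carry the preset's simulation defaults (ensemble
    size, Euler steps, time window); they are consumed by
    :meth:`calstdp.dynamics.SimulationSettings.for_model`.
    """

    calcium: CalciumParams
    pathways: tuple[PathwayParams, ...]
    tau: float
    rho_star: float
    sigma: float
    readout: ReadoutParams
    threshold_model: str = "piecewise"
    epsilon: float = 1.0
    default_n_synapses: int = 1000
    default_n_iter: int = 102000
    default_window: tuple[float, float] = (-1.0, 101.0)

    def __post_init__(self) -> None:
        if len(self.pathways) < 1:
            raise ConfigError("model needs at least one pathway")
        names = [p.name for p in self.pathways]
        if len(set(names)) != len(names):
            raise ConfigError(f"duplicate pathway names: {names}")
        if not self.tau > 0:
            raise ConfigError(f"tau must be > 0, got {self.tau}")
        if not 0 < self.rho_star < 1:
            raise ConfigError(f"rho_star must be in (0,1), got {self.rho_star}")
        if self.sigma < 0:
            raise ConfigError(f"sigma must be >= 0, got {self.sigma}")
        if self.threshold_model not in THRESHOLD_MODELS:
            raise ConfigError(
                f"threshold_model must be one of {THRESHOLD_MODELS}, "
                f"got {self.threshold_model!r}"
            )
        if not self.epsilon > 0:
            raise ConfigError(f"epsilon must be > 0, got {self.epsilon}")

    @property
    def pathway_names(self) -> tuple[str, ...]:
        return tuple(p.name for p in self.pathways)

    def pathway(self, name: str) -> PathwayParams:
        for p in self.pathways:
            if p.name == name:
                return p
        raise KeyError(f"no pathway named {name!r}; have {self.pathway_names}")

    def with_threshold_model(self, model: str, epsilon: float | None = None) -> "SynapseModel":
        kwargs = {"threshold_model": model}
        if epsilon is not None:
            kwargs["epsilon"] = epsilon
        return replace(self, **kwargs)


PRESET_NAMES = (
    "corticostriatal",
    "scenario1",
    "scenario2",
    "scenario3",
    "hebbian_asymmetric",
    "hebbian_symmetric",
)


def load_preset(preset_name: str) -> SynapseModel:
    """Load one of the shipped parameter presets.

    ``corticostriatal``: two-pathway (eCB, NMDAR) cortico-striatal synapse.
    ``scenario1``..``scenario3``: one- and two-pathway mechanisms producing
    symmetric anti-Hebbian LTD at 100 pairings / 1 Hz.
    ``hebbian_asymmetric`` / ``hebbian_symmetric``: classical single-pathway
    Hebbian STDP parameter sets.
    """
    if preset_name not in PRESET_NAMES:
        raise ConfigError(
            f"unknown preset {preset_name!r}; available presets: "
            + ", ".join(PRESET_NAMES)
        )
    ref = resources.files("calstdp") / "presets" / f"{preset_name}.yaml"
    with ref.open("r", encoding="utf-8") as fh:
        return _model_from_mapping(yaml.safe_load(fh), source=str(ref))


def read_config(path) -> SynapseModel:
    """Read a model from a YAML (or JSON, a YAML subset) config file."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, Mapping):
        raise ConfigError(f"{path}: config must be a mapping")
    return _model_from_mapping(data, source=str(path))


def write_config(model: SynapseModel, path) -> None:
    """Write a model to a YAML config file (round-trips with read_config)."""
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(_model_to_mapping(model), fh, sort_keys=False)


# --- config schema -----------------------------------------------------------

_CALCIUM_KEYS = {"c_pre", "c_post", "tau_ca", "delay"}
_PATHWAY_KEYS = {"name", "gamma_p", "gamma_d", "theta0_p", "theta0_d", "mu_p", "mu_d"}
_DYNAMICS_KEYS = {"tau", "rho_star", "sigma"}
_READOUT_KEYS = {"ltp_star", "ltd_star", "slope"}
_THRESHOLD_KEYS = {"model", "epsilon"}
_SETTINGS_KEYS = {"n_synapses", "n_iter", "t_start", "t_end"}
_TOP_KEYS = {"calcium", "pathways", "dynamics", "readout", "thresholds", "settings"}


def _check_keys(section: Mapping, allowed: set, where: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ConfigError(f"{where}: unknown keys {sorted(unknown)}; allowed: {sorted(allowed)}")


def _require(section: Mapping, keys: Iterable[str], where: str) -> None:
    missing = [k for k in keys if k not in section]
    if missing:
        raise ConfigError(f"{where}: missing required keys {missing}")


def _model_from_mapping(data: Mapping, *, source: str = "config") -> SynapseModel:
    _check_keys(data, _TOP_KEYS, source)
    _require(data, ["calcium", "pathways", "dynamics", "readout"], source)

    cal = data["calcium"]
    _check_keys(cal, _CALCIUM_KEYS, f"{source}:calcium")
    _require(cal, ["c_pre", "c_post", "tau_ca"], f"{source}:calcium")
    calcium = CalciumParams(
        c_pre=_parse_number(cal["c_pre"], name="c_pre"),
        c_post=_parse_number(cal["c_post"], name="c_post"),
        tau_ca=parse_time(cal["tau_ca"], name="tau_ca"),
        delay_d=parse_time(cal.get("delay", 0.0), name="delay"),
    )

    raw_paths = data["pathways"]
    if not isinstance(raw_paths, Sequence) or isinstance(raw_paths, (str, bytes)):
        raise ConfigError(f"{source}: pathways must be a list")
    pathways = []
    for i, p in enumerate(raw_paths):
        where = f"{source}:pathways[{i}]"
        _check_keys(p, _PATHWAY_KEYS, where)
        _require(p, ["name", "gamma_p", "gamma_d", "theta0_p", "theta0_d"], where)
        pathways.append(
            PathwayParams(
                name=str(p["name"]),
                gamma_p=_parse_number(p["gamma_p"], name="gamma_p"),
                gamma_d=_parse_number(p["gamma_d"], name="gamma_d"),
                theta0_p=_parse_number(p["theta0_p"], name="theta0_p"),
                theta0_d=_parse_number(p["theta0_d"], name="theta0_d"),
                mu_p=_parse_number(p.get("mu_p", math.inf), name="mu_p"),
                mu_d=_parse_number(p.get("mu_d", math.inf), name="mu_d"),
            )
        )

    dyn = data["dynamics"]
    _check_keys(dyn, _DYNAMICS_KEYS, f"{source}:dynamics")
    _require(dyn, ["tau", "rho_star", "sigma"], f"{source}:dynamics")

    ro = data["readout"]
    _check_keys(ro, _READOUT_KEYS, f"{source}:readout")
    _require(ro, ["ltp_star", "ltd_star", "slope"], f"{source}:readout")
    readout = ReadoutParams(
        ltp_star=_parse_number(ro["ltp_star"], name="ltp_star"),
        ltd_star=_parse_number(ro["ltd_star"], name="ltd_star"),
        slope_s=_parse_number(ro["slope"], name="slope"),
    )

    thr = data.get("thresholds", {})
    _check_keys(thr, _THRESHOLD_KEYS, f"{source}:thresholds")

    st = data.get("settings", {})
    _check_keys(st, _SETTINGS_KEYS, f"{source}:settings")
    window = (
        parse_time(st.get("t_start", -1.0), name="t_start"),
        parse_time(st.get("t_end", 101.0), name="t_end"),
    )

    return SynapseModel(
        calcium=calcium,
        pathways=tuple(pathways),
        tau=parse_time(dyn["tau"], name="tau"),
        rho_star=_parse_number(dyn["rho_star"], name="rho_star"),
        sigma=_parse_number(dyn["sigma"], name="sigma"),
        readout=readout,
        threshold_model=str(thr.get("model", "piecewise")),
        epsilon=_parse_number(thr.get("epsilon", 1.0), name="epsilon"),
        default_n_synapses=int(st.get("n_synapses", 1000)),
        default_n_iter=int(st.get("n_iter", 102000)),
        default_window=window,
    )


def _num(x: float):
    return ".inf" if math.isinf(x) else x


def _model_to_mapping(model: SynapseModel) -> dict:
    return {
        "calcium": {
            "c_pre": model.calcium.c_pre,
            "c_post": model.calcium.c_post,
            "tau_ca": model.calcium.tau_ca,
            "delay": model.calcium.delay_d,
        },
        "pathways": [
            {
                "name": p.name,
                "gamma_p": p.gamma_p,
                "gamma_d": p.gamma_d,
                "theta0_p": _num(p.theta0_p),
                "theta0_d": _num(p.theta0_d),
                "mu_p": _num(p.mu_p),
                "mu_d": _num(p.mu_d),
            }
            for p in model.pathways
        ],
        "dynamics": {
            "tau": model.tau,
            "rho_star": model.rho_star,
            "sigma": model.sigma,
        },
        "readout": {
            "ltp_star": model.readout.ltp_star,
            "ltd_star": model.readout.ltd_star,
            "slope": model.readout.slope_s,
        },
        "thresholds": {"model": model.threshold_model, "epsilon": model.epsilon},
        "settings": {
            "n_synapses": model.default_n_synapses,
            "n_iter": model.default_n_iter,
            "t_start": model.default_window[0],
            "t_end": model.default_window[1],
        },
    }
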