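"""In-silico plasticity experiments: timing/pairing sweeps, blockade,
frequency dependence, triplet maps, and phase classification.

Results come back as :class:`SweepResult` holding a long-format
:class:`pandas.DataFrame` plus run metadata.  Qualitative significance bands
(what counts as "LTP", "LTD", "no plasticity" when reading a curve) are module
constants, not buried literals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import analytic, dynamics, readout
from .params import SynapseModel
from .protocols import StimulationProtocol, fold_dt

__all__ = [
    "LTP_THRESHOLD",
    "LTD_THRESHOLD",
    "NO_PLASTICITY_BAND",
    "MAX_BIOLOGICAL_FREQ",
    "SweepResult",
    "PhaseLabel",
    "run_protocol",
    "stdp_heatmap",
    "blockade_heatmap",
    "frequency_sweep",
    "triplet_map",
    "classify_phases",
]

# qualitative bands used when reading total-change curves against the
# descriptive statements ("LTP", "LTD", "no significant plasticity")
LTP_THRESHOLD = 1.15
LTD_THRESHOLD = 0.90
NO_PLASTICITY_BAND = (0.90, 1.10)
# beyond this pairing frequency the calcium model loses biological relevance
MAX_BIOLOGICAL_FREQ = 40.0

ENGINES = ("simulate", "analytic")


@dataclass
class SweepResult:
    """Long-format sweep output plus metadata describing how it was made."""

    data: pd.DataFrame
    metadata: dict = field(default_factory=dict)


@dataclass(frozen=True)
class PhaseLabel:
    """Polarity phases of a total-change curve vs pairing count.

    ``label`` concatenates the polarities of the surviving runs in order of
    appearance ('P' potentiation, 'D' depression); ``boundaries`` holds the
    first pairing count of each surviving run.
    """

    label: str
    boundaries: tuple[int, ...] = ()


def _analytic_floor(n_synapses: int) -> float:
    # a finite ensemble of N synapses cannot register switch probabilities
    # below ~1/N; flooring keeps the analytic engine comparable to an
    # N-synapse experiment
    return 1.0 / (2.0 * n_synapses)


def _check_engine_freq(engine: str, freq: float) -> None:
    if engine not in ENGINES:
        raise ValueError(f"engine must be one of {ENGINES}, got {engine!r}")
    if freq > MAX_BIOLOGICAL_FREQ:
        warnings.warn(
            f"pairing frequency {freq} Hz exceeds {MAX_BIOLOGICAL_FREQ} Hz; "
            "the calcium model starts losing biological relevance",
            stacklevel=3,
        )


def run_protocol(
    model: SynapseModel,
    protocol: StimulationProtocol,
    settings: dynamics.SimulationSettings | None = None,
    *,
    engine: str = "simulate",
    included: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Total change (and per-pathway U, D, H) after each pairing count.

    Returns one row per pairing count 1 .. n_pairings with columns
    ``n_pairings``, ``U_<pathway>``, ``D_<pathway>``, ``H_<pathway>`` and
    ``total_change``.
    """
    _check_engine_freq(engine, protocol.freq)
    if settings is None:
        settings = dynamics.SimulationSettings.for_model(model)
    included = list(included) if included is not None else list(model.pathway_names)

    if engine == "simulate":
        settings = dynamics.SimulationSettings(
            n_synapses=settings.n_synapses,
            t_start=settings.t_start,
            t_end=settings.t_end,
            n_iter=settings.n_iter,
            seed=settings.seed,
            record_per_pairing=True,
        )
        res = dynamics.simulate(model, protocol, settings)
        uds_at = res.uds_at
        floor = 0.0
    else:
        curves = analytic.switch_prob_curves(model, protocol)

        def uds_at(n: int) -> dict[str, tuple[float, float]]:
            return {name: (us[n], ds[n]) for name, (us, ds) in curves.items()}

        floor = _analytic_floor(settings.n_synapses)

    rows = []
    for n in range(1, protocol.n_pairings + 1):
        uds = uds_at(n)
        out = readout.PlasticityOutcome.from_fractions(
            uds, model.readout, included, min_fraction=floor
        )
        row: dict = {"n_pairings": n}
        for name in included:
            row[f"U_{name}"] = out.u[name]
            row[f"D_{name}"] = out.d[name]
            row[f"H_{name}"] = out.h[name]
        row["total_change"] = out.total
        rows.append(row)
    return pd.DataFrame(rows)


def stdp_heatmap(
    model: SynapseModel,
    dt_grid: Sequence[float],
    n_pairings_max: int,
    freq: float = 1.0,
    settings: dynamics.SimulationSettings | None = None,
    *,
    engine: str = "simulate",
    included: Iterable[str] | None = None,
) -> SweepResult:
    """Total change over a (spike timing x pairing count) grid.

    For each timing one trajectory is recorded at every pairing count, so
    cells along the pairing axis are correlated (they follow the same
    synapses through the protocol).
    """
    frames = []
    for dt in dt_grid:
        protocol = StimulationProtocol(
            pattern="pair", dt=float(dt), freq=freq, n_pairings=n_pairings_max
        )
        df = run_protocol(model, protocol, settings, engine=engine, included=included)
        df.insert(0, "dt", float(dt))
        frames.append(df)
    data = pd.concat(frames, ignore_index=True)
    meta = {
        "kind": "stdp_heatmap",
        "engine": engine,
        "freq": freq,
        "n_pairings_max": n_pairings_max,
        "included": list(included) if included is not None else list(model.pathway_names),
    }
    return SweepResult(data=data, metadata=meta)


def blockade_heatmap(
    model: SynapseModel,
    included_pathways: Iterable[str],
    dt_grid: Sequence[float],
    n_pairings_max: int,
    freq: float = 1.0,
    settings: dynamics.SimulationSettings | None = None,
    *,
    engine: str = "simulate",
) -> SweepResult:
    """As stdp_heatmap with the readout restricted to a pathway subset.

    Restricting the included set models pharmacological blockade of the
    complementary pathways: the synaptic change is then computed through the
    remaining efficacies only.
    """
    included = list(included_pathways)
    if not included:
        raise ValueError("included_pathways must be non-empty")
    for name in included:
        model.pathway(name)  # raises KeyError for unknown names
    res = stdp_heatmap(
        model, dt_grid, n_pairings_max, freq, settings, engine=engine, included=included
    )
    res.metadata["kind"] = "blockade_heatmap"
    return res


def frequency_sweep(
    model: SynapseModel,
    freqs: Sequence[float],
    dt_grid: Sequence[float],
    n_pairings: int,
    settings: dynamics.SimulationSettings | None = None,
    *,
    replicates: int = 30,
) -> SweepResult:
    """Mean/sd of the total change over replicates, per (frequency, timing).

    Spike timings are folded into ``(-1/(2F), 1/(2F)]`` — at frequency F the
    protocol is periodic in dt with period 1/F.  Uses the simulator engine
    (the homogenized solution is a low-frequency approximation).
    """
    if settings is None:
        settings = dynamics.SimulationSettings.for_model(model)
    rows = []
    for freq in freqs:
        _check_engine_freq("simulate", freq)
        for dt in dt_grid:
            dtf = fold_dt(float(dt), freq)
            totals = []
            for rep in range(replicates):
                seed = int(
                    np.random.SeedSequence([settings.seed, rep, abs(hash((freq, dt))) % 2**31])
                    .generate_state(1)[0] % 2**31
                )
                s = dynamics.SimulationSettings(
                    n_synapses=settings.n_synapses,
                    t_start=settings.t_start,
                    t_end=settings.t_end,
                    n_iter=settings.n_iter,
                    seed=seed,
                )
                protocol = StimulationProtocol(
                    pattern="pair", dt=dtf, freq=freq, n_pairings=n_pairings
                )
                res = dynamics.simulate(model, protocol, s)
                totals.append(
                    readout.total_change(res.uds(), model.readout)
                )
            rows.append(
                {
                    "freq": freq,
                    "dt": float(dt),
                    "dt_folded": dtf,
                    "total_change": float(np.mean(totals)),
                    "total_change_sd": float(np.std(totals, ddof=1)) if replicates > 1 else 0.0,
                }
            )
    meta = {
        "kind": "frequency_sweep",
        "n_pairings": n_pairings,
        "replicates": replicates,
    }
    return SweepResult(data=pd.DataFrame(rows), metadata=meta)


def triplet_map(
    model: SynapseModel,
    dt1_grid: Sequence[float],
    dt2_grid: Sequence[float],
    n_pairings: int,
    settings: dynamics.SimulationSettings | None = None,
    freq: float = 1.0,
    *,
    engine: str = "simulate",
    record_counts: Sequence[int] | None = None,
) -> SweepResult:
    """Total change over a (dt1 x dt2) triplet grid.

    Grid points with ``dt1 < dt2`` run the two-pre/one-post pattern
    (pre-post-pre family), points with ``dt1 > dt2`` the one-pre/two-post
    pattern (post-pre-post family); coincident-spike diagonals are skipped.
    ``record_counts`` selects which pairing counts to report (default: the
    final count only).
    """
    counts = sorted(record_counts) if record_counts else [n_pairings]
    if counts[-1] > n_pairings:
        raise ValueError("record_counts may not exceed n_pairings")
    rows = []
    for dt1 in dt1_grid:
        for dt2 in dt2_grid:
            if dt1 == dt2:
                continue
            pattern = "pre_post_pre" if dt1 < dt2 else "post_pre_post"
            protocol = StimulationProtocol(
                pattern=pattern,
                dt1=float(dt1),
                dt2=float(dt2),
                freq=freq,
                n_pairings=n_pairings,
            )
            df = run_protocol(model, protocol, settings, engine=engine)
            sub = df[df["n_pairings"].isin(counts)]
            for _, r in sub.iterrows():
                rows.append(
                    {
                        "dt1": float(dt1),
                        "dt2": float(dt2),
                        "pattern": pattern,
                        "n_pairings": int(r["n_pairings"]),
                        "total_change": float(r["total_change"]),
                    }
                )
    meta = {"kind": "triplet_map", "engine": engine, "freq": freq, "n_pairings": n_pairings}
    return SweepResult(data=pd.DataFrame(rows), metadata=meta)


def classify_phases(
    curve: Sequence[float], delta: float = 0.1, min_run: int = 5
) -> PhaseLabel:
    """Deterministic polarity-phase classification of a total-change curve.

    ``curve[i]`` is the total change after ``i + 1`` pairings.  Counts with
    change > 1 + delta are marked 'P', < 1 - delta 'D', else neutral; runs of
    P/D shorter than ``min_run`` are absorbed into neutral, and same-polarity
    runs separated by a neutral gap shorter than ``min_run`` are merged.  The
    label concatenates the surviving polarities ('PP' = potentiation, a
    silent stretch, then potentiation again).
    """
    if not delta > 0:
        raise ValueError("delta must be > 0")
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    values = np.asarray(curve, dtype=float)
    pol = np.zeros(values.size, dtype=int)
    pol[values > 1.0 + delta] = 1
    pol[values < 1.0 - delta] = -1

    def runs_of(p: np.ndarray) -> list[list[int]]:
        out: list[list[int]] = []  # [polarity, start, length]
        for i, v in enumerate(p):
            if out and out[-1][0] == v:
                out[-1][2] += 1
            else:
                out.append([int(v), i, 1])
        return out

    # absorb short non-neutral runs
    runs = runs_of(pol)
    for r in runs:
        if r[0] != 0 and r[2] < min_run:
            pol[r[1] : r[1] + r[2]] = 0
    # merge same-polarity runs across short neutral gaps
    runs = runs_of(pol)
    changed = True
    while changed:
        changed = False
        for i in range(1, len(runs) - 1):
            prev, gap, nxt = runs[i - 1], runs[i], runs[i + 1]
            if gap[0] == 0 and gap[2] < min_run and prev[0] == nxt[0] != 0:
                pol[gap[1] : gap[1] + gap[2]] = prev[0]
                runs = runs_of(pol)
                changed = True
                break

    phases = [(r[0], r[1]) for r in runs_of(pol) if r[0] != 0]
    label = "".join("P" if p > 0 else "D" for p, _ in phases)
    if not label:
        return PhaseLabel(label="none")
    if label not in {"D", "P", "PD", "PP", "PPD", "PDP"}:
        return PhaseLabel(label="other", boundaries=tuple(s + 1 for _, s in phases))
    return PhaseLabel(label=label, boundaries=tuple(s + 1 for _, s in phases))
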