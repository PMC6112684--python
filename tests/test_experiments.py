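"""Experiment orchestration: sweeps, blockade, folding, triplets, phases."""

import numpy as np
import pytest

from calstdp import load_preset
from calstdp.dynamics import SimulationSettings
from calstdp.experiments import (
    PhaseLabel,
    blockade_heatmap,
    classify_phases,
    frequency_sweep,
    stdp_heatmap,
    triplet_map,
)
from calstdp.protocols import StimulationProtocol, fold_dt


def small_settings(model, **kw):
    return SimulationSettings.for_model(model, n_synapses=100, seed=3, **kw)


# --- phase classification (pure function) -----------------------------------


def test_classify_flat_curve_is_none():
    assert classify_phases(np.ones(100)).label == "none"


def test_classify_biphasic_potentiation_depression():
    curve = np.concatenate([np.full(20, 1.5), np.full(20, 1.0), np.full(60, 0.6)])
    res = classify_phases(curve)
    assert res.label == "PD"
    assert res.boundaries == (1, 41)


def test_classify_absorbs_short_blips():
    curve = np.ones(100)
    curve[50:53] = 1.5  # 3-pairing blip, shorter than min_run
    assert classify_phases(curve, min_run=5).label == "none"


def test_classify_merges_across_short_gaps():
    curve = np.concatenate([np.full(20, 1.5), np.full(3, 1.0), np.full(20, 1.5)])
    assert classify_phases(curve, min_run=5).label == "P"
    gap = np.concatenate([np.full(20, 1.5), np.full(10, 1.0), np.full(20, 1.5)])
    assert classify_phases(gap, min_run=5).label == "PP"


def test_classify_triphasic_and_other():
    ppd = np.concatenate([np.full(15, 2.0), np.full(10, 1.0), np.full(15, 1.6),
                          np.full(30, 0.6)])
    assert classify_phases(ppd).label == "PPD"
    alternating = np.concatenate([np.full(10, 0.6), np.full(10, 1.6)] * 3)
    assert classify_phases(alternating).label == "other"


def test_classify_validates_arguments():
    with pytest.raises(ValueError):
        classify_phases(np.ones(10), delta=0.0)
    with pytest.raises(ValueError):
        classify_phases(np.ones(10), min_run=0)


def test_corticostriatal_post_pre_curve_is_pp(cortico):
    """Post-pre pairings: early eCB-LTP, a silent stretch, late NMDAR-LTP."""
    settings = SimulationSettings.for_model(cortico, n_synapses=300, seed=3)
    res = stdp_heatmap(cortico, [-0.010], 100, 1.0, settings)
    curve = res.data.sort_values("n_pairings")["total_change"].to_numpy()
    assert classify_phases(curve).label == "PP"


# --- sweeps ------------------------------------------------------------------


def test_heatmap_shape_and_positivity(cortico):
    settings = small_settings(cortico)
    res = stdp_heatmap(cortico, [-0.010, 0.010], 20, 1.0, settings)
    assert len(res.data) == 2 * 20
    assert (res.data["total_change"] > 0).all()
    assert res.metadata["engine"] == "simulate"


def test_blockade_with_all_pathways_matches_heatmap(cortico):
    settings = small_settings(cortico)
    full = stdp_heatmap(cortico, [-0.010], 20, 1.0, settings)
    both = blockade_heatmap(cortico, ["eCB", "NMDAR"], [-0.010], 20, 1.0, settings)
    assert np.allclose(
        full.data["total_change"].to_numpy(), both.data["total_change"].to_numpy()
    )


def test_blockade_rejects_unknown_pathway(cortico):
    with pytest.raises(KeyError):
        blockade_heatmap(cortico, ["AMPA"], [-0.010], 10, 1.0, small_settings(cortico))


def test_frequency_sweep_folds_and_reports_stats(cortico):
    settings = small_settings(cortico)
    res = frequency_sweep(
        cortico, [10.0], [-0.010, -0.010 + 0.1], 10, settings, replicates=2
    )
    df = res.data
    # dt and dt + 1/F fold to the same protocol: identical statistics
    assert df.iloc[0]["dt_folded"] == pytest.approx(df.iloc[1]["dt_folded"])
    assert df.iloc[0]["total_change"] == pytest.approx(df.iloc[1]["total_change"])
    assert {"total_change", "total_change_sd"} <= set(df.columns)


def test_folding_identity_at_low_frequency():
    assert fold_dt(-0.010, 1.0) == -0.010


# --- triplets ----------------------------------------------------------------


def test_triplet_map_patterns_and_diagonal(cortico):
    settings = small_settings(cortico)
    res = triplet_map(cortico, [-0.010, 0.010], [-0.010, 0.010], 10, settings)
    df = res.data
    assert set(df["pattern"]) == {"pre_post_pre", "post_pre_post"}
    assert len(df) == 2  # the two diagonal (coincident) cells are skipped
    assert (df["total_change"] > 0).all()


def test_triplet_timing_families_shape_plasticity(cortico):
    """Post-pre-pre triplets recruit eCB-LTP by ~10 presentations; pre-post-post
    triplets reveal eCB-LTD by 25 presentations (earlier than spike pairs)."""
    settings = SimulationSettings.for_model(cortico, n_synapses=300, seed=3)
    res = triplet_map(
        cortico,
        [-0.030, 0.030],
        [-0.010, 0.010],
        25,
        settings,
        record_counts=[10, 25],
    )
    df = res.data
    post_pre_pre = df.query("dt1 == -0.030 and dt2 == -0.010")
    assert post_pre_pre.query("n_pairings == 10").total_change.iloc[0] > 1.15
    pre_post_post = df.query("dt1 == 0.030 and dt2 == 0.010")
    assert pre_post_post.query("n_pairings == 25").total_change.iloc[0] < 0.9


def test_biologically_implausible_frequency_warns(cortico):
    settings = SimulationSettings(n_synapses=10, t_start=-0.2, t_end=1.0, n_iter=1200)
    protocol = StimulationProtocol(pattern="pair", dt=-0.005, freq=45.0, n_pairings=2)
    from calstdp.experiments import run_protocol

    with pytest.warns(UserWarning, match="biological relevance"):
        run_protocol(cortico, protocol, settings)


def test_triplet_reduces_to_pair_when_one_spike_is_remote():
    """Hebbian single-pathway preset: pushing the second presynaptic spike far
    outside the plasticity window recovers the spike-pair rule."""
    model = load_preset("hebbian_asymmetric")
    settings = SimulationSettings.for_model(
        model, n_synapses=400, seed=9, record_per_pairing=True
    )
    from calstdp.dynamics import simulate

    pair = simulate(
        model,
        StimulationProtocol(pattern="pair", dt=-0.020, freq=1.0, n_pairings=100),
        settings,
    )
    triplet = simulate(
        model,
        StimulationProtocol(
            pattern="pre_post_pre", dt1=-0.020, dt2=0.500, freq=1.0, n_pairings=100
        ),
        settings,
    )
    d_pair = np.asarray(pair.pathways["ca"].d_per_pairing)
    d_trip = np.asarray(triplet.pathways["ca"].d_per_pairing)
    # robust counts agree exactly; the stochastic transition shifts by at
    # most a few pairings
    assert d_pair[25] < 0.05 and d_trip[25] < 0.05
    assert d_pair[100] > 0.95 and d_trip[100] > 0.95
    cross_pair = int(np.argmax(d_pair >= 0.5))
    cross_trip = int(np.argmax(d_trip >= 0.5))
    assert abs(cross_pair - cross_trip) <= 4
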