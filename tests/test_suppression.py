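"""Binomial cluster suppression rule and activity sweeps."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from isletcrit.lattice import build_cubic_lattice, label_clusters, sample_bonds
from isletcrit.suppression import (
    ClusterSet,
    SuppressionParams,
    cluster_active_probability,
    network_activity,
    network_activity_sampled,
    node_activity_probability_map,
    suppression_count_threshold,
    sweep_activity,
)


def make_clusters(sizes):
    sizes = np.asarray(sizes, dtype=np.int64)
    assignment = np.repeat(np.arange(len(sizes)), sizes)
    return ClusterSet(assignment=assignment, sizes=sizes)


@pytest.mark.parametrize(
    "n,sp,k", [(10, 0.15, 2), (1, 0.15, 1), (20, 0.15, 4), (10, 0.0, 1), (3, 0.66, 2)]
)
def test_suppression_count_threshold_strict(n, sp, k):
    got = suppression_count_threshold(n, sp)
    assert got == k
    # defining property: smallest integer whose fraction strictly exceeds sp
    assert got / n > sp and (got - 1) / n <= sp


def test_suppression_count_threshold_gte_convention():
    # with the >= rule an integer n*Sp itself suppresses: 3/20 = 0.15
    assert suppression_count_threshold(20, 0.15, rule="gte") == 3
    assert suppression_count_threshold(10, 0.15, rule="gte") == 2


def test_suppression_threshold_sp_one_never_suppressed():
    with pytest.raises(ValueError):
        suppression_count_threshold(10, 1.0)
    assert cluster_active_probability(10, 0.9, 1.0) == 1.0


def _enumeration_oracle(n, q, sp, rule="strict"):
    """Exhaustive enumeration over all 2**n excitability assignments."""
    k = suppression_count_threshold(n, sp, rule)
    total = 0.0
    for bits in itertools.product([0, 1], repeat=n):
        m = sum(bits)  # number of inexcitable cells
        if m < k:
            total += q**m * (1 - q) ** (n - m)
    return total


@pytest.mark.parametrize("q", [0.05, 0.2, 0.5])
@pytest.mark.parametrize("sp", [0.0, 0.15, 0.5])
def test_cluster_active_probability_matches_enumeration(q, sp):
    for n in (1, 2, 3, 5, 8):
        assert cluster_active_probability(n, q, sp) == pytest.approx(
            _enumeration_oracle(n, q, sp), abs=1e-12
        )


def test_cluster_active_probability_examples():
    assert cluster_active_probability(1, 0.3, 0.15) == pytest.approx(0.7)
    # closed form: 0.8**10 + 10 * 0.2 * 0.8**9
    assert cluster_active_probability(10, 0.2, 0.15) == pytest.approx(0.375810, abs=1e-6)
    assert cluster_active_probability(123, 0.0, 0.15) == 1.0


@settings(max_examples=60, derandomize=True, deadline=None)
@given(
    n=st.integers(1, 200),
    q=st.floats(0.0, 1.0),
    sp=st.floats(0.0, 0.99),
)
def test_cluster_active_probability_properties(n, q, sp):
    pr = cluster_active_probability(n, q, sp)
    assert 0.0 <= pr <= 1.0
    # fewer inexcitable cells can only increase the activity probability
    assert cluster_active_probability(n, max(q - 0.1, 0.0), sp) >= pr - 1e-12
    # a looser threshold can only increase the activity probability
    assert cluster_active_probability(n, q, min(sp + 0.1, 0.99)) >= pr - 1e-12


def test_network_activity_hand_example():
    cs = make_clusters([9, 1])
    params = SuppressionParams(p_exc=0.8, sp=0.15)
    # cluster of 9: k = floor(9*0.15)+1 = 2, so Pr = P(X <= 1) with
    # X ~ Bin(9, 0.2): 0.8**9 + 9*0.2*0.8**8 = 0.436207616 exactly;
    # singleton: 0.8 -> (9*0.436207616 + 0.8) / 10
    assert network_activity(cs, params) == pytest.approx(0.4725868544, abs=1e-9)


def test_network_activity_extremes(spec11):
    cs = label_clusters(sample_bonds(spec11, 0.35, 3))
    assert network_activity(cs, SuppressionParams(1.0, 0.15)) == 1.0
    assert network_activity(cs, SuppressionParams(0.0, 0.15)) == 0.0


def test_network_activity_uncoupled_is_pexc(spec11):
    cs = label_clusters(sample_bonds(spec11, 0.0, 3))
    for pexc in (0.3, 0.62, 0.9):
        assert network_activity(cs, SuppressionParams(pexc, 0.15)) == pytest.approx(pexc)


def test_network_activity_label_sampling_cross_check(spec11, rng):
    cs = label_clusters(sample_bonds(spec11, 0.25, 5))
    params = SuppressionParams(0.85, 0.15)
    analytic = network_activity(cs, params)
    sampled = network_activity_sampled(cs, params, rng, n_draws=3000)
    assert sampled == pytest.approx(analytic, abs=0.01)


def test_suppression_params_validation():
    with pytest.raises(ValueError):
        SuppressionParams(1.2, 0.15)
    with pytest.raises(ValueError):
        SuppressionParams(0.5, -0.1)
    assert SuppressionParams(0.3, 0.15).q == pytest.approx(0.7)


def test_node_activity_map_uncoupled_equals_pexc(spec2):
    params = SuppressionParams(0.8, 0.15)
    m = node_activity_probability_map(spec2, 0.0, params, reps=3, seed=1)
    np.testing.assert_allclose(m, 0.8)
    m1 = node_activity_probability_map(spec2, 0.5, SuppressionParams(1.0, 0.15), reps=3, seed=1)
    np.testing.assert_allclose(m1, 1.0)


def test_node_activity_map_consistent_with_sweep():
    """The node-mean of the probability map equals the network-level mean
    activity at the same parameters (within Monte-Carlo error)."""
    spec = build_cubic_lattice(11)
    params = SuppressionParams(0.95, 0.15)
    m = node_activity_probability_map(spec, 0.30, params, reps=100, seed=9)
    surf = sweep_activity([0.30], [0.95], sp=0.15, L=11, reps=100, seed=42)
    se = max(surf.se_pct[0, 0], 1e-9)
    assert m.mean() * 100 == pytest.approx(surf.mean_pct[0, 0], abs=4 * se + 0.2)


def test_sweep_uncoupled_slice_is_identity():
    pexc = np.round(np.arange(0.0, 1.001, 0.1), 3)
    surf = sweep_activity([0.0], pexc, sp=0.15, L=5, reps=10, seed=0)
    np.testing.assert_allclose(surf.mean_pct[0], pexc * 100, atol=1e-9)
    np.testing.assert_allclose(surf.se_pct[0], 0.0, atol=1e-9)


def test_sweep_monotone_in_pexc_and_decreasing_in_p():
    pexc = np.round(np.arange(0.0, 1.001, 0.05), 3)
    surf = sweep_activity([0.1, 0.4], pexc, sp=0.15, L=8, reps=60, seed=3)
    for row in surf.mean_pct:
        assert np.all(np.diff(row) >= -1e-9)  # analytic in P_exc: exact
    # for P_exc < 1 - Sp coupling suppresses: higher p -> lower activity
    j = np.searchsorted(pexc, 0.7)
    assert surf.mean_pct[1, j] < surf.mean_pct[0, j]


def test_sweep_activity_validation():
    with pytest.raises(ValueError):
        sweep_activity([1.2], [0.5], L=3, reps=5, seed=0)
    with pytest.raises(ValueError):
        sweep_activity([0.5], [0.5], L=3, reps=0, seed=0)


def test_activity_curve_serialization_roundtrip():
    surf = sweep_activity([0.3], np.round(np.arange(0, 1.01, 0.25), 3), sp=0.15, L=4, reps=10, seed=1)
    curve = surf.curve_vs_pexc(0.3)
    df = curve.to_frame()
    assert list(df.columns[:5]) == [
        "control_name", "control_value", "mean_pct_active", "se_pct_active", "reps",
    ]
    assert df["control_name"].unique().tolist() == ["P_exc"]
    import json
    blob = json.loads(curve.to_json())
    assert blob["meta"]["Sp"] == 0.15 and blob["reps"] == 10
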