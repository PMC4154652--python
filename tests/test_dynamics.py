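"""Coupled islet integration: coupling currents, glucose behavior,
symmetry, convergence and the scan machinery."""

import numpy as np
import pytest

from isletcrit.architecture import (
    IsletArchitecture,
    assign_coupling,
    generate_sphere_packing,
)
from isletcrit.cellmodel import CellParams, params_table
from isletcrit.dynamics import (
    IntegrationError,
    SimConfig,
    coupling_current,
    glucose_to_p_open,
    integrate_islet,
    phase_transition_scan,
    silent_reference_trace,
)
from isletcrit.metrics import classify_active, plateau_fraction


def single_cell_arch():
    return IsletArchitecture(
        positions=np.zeros((1, 3)), edges=np.zeros((0, 2), dtype=np.int64)
    )


def all_to_all_arch(n, g=120.0):
    edges = np.array([(i, j) for i in range(n) for j in range(i + 1, n)], dtype=np.int64)
    return IsletArchitecture(
        positions=np.zeros((n, 3)), edges=edges, conductances=np.full(len(edges), g)
    )


def test_coupling_current_values_and_antisymmetry():
    assert coupling_current(-60.0, [-60.0, -60.0], [120.0, 80.0]) == 0.0
    # 120 pS across 40 mV -> 4.8 pA
    assert coupling_current(-20.0, [-60.0], [120.0]) == pytest.approx(4.8)
    ij = coupling_current(-20.0, [-60.0], [120.0])
    ji = coupling_current(-60.0, [-20.0], [120.0])
    assert ij == pytest.approx(-ji)
    with pytest.raises(ValueError):
        coupling_current(0.0, [1.0], [1.0, 2.0])


def test_pairwise_coupling_conservation():
    """Summed over both endpoints of every edge the gap-junction current
    cancels exactly."""
    arch = assign_coupling(generate_sphere_packing(80, seed=1), 120.0, 0.7, seed=2)
    rng = np.random.default_rng(3)
    v = rng.uniform(-75, -20, arch.n_cells)
    total = 0.0
    indptr, indices, eidx = arch.adjacency_csr()
    g = arch.conductances[eidx]
    for i in range(arch.n_cells):
        sl = slice(indptr[i], indptr[i + 1])
        total += np.sum(g[sl] * (v[i] - v[indices[sl]]))
    assert abs(total) < 1e-9 * arch.n_edges


def test_glucose_interpolation():
    assert glucose_to_p_open(2.0) == pytest.approx(0.040)
    assert glucose_to_p_open(20.0) == pytest.approx(0.024)
    assert 0.024 < glucose_to_p_open(15.0) < 0.029


def test_single_cell_silent_at_low_glucose():
    cfg = SimConfig(duration_ms=40000, glucose_mM=2.0, seed=1)
    tr = integrate_islet(single_cell_arch(), params_table(CellParams(), 1), cfg).after(10.0)
    assert np.ptp(tr.ca_uM[0]) < 0.02
    ref = silent_reference_trace(cfg)
    cls = classify_active(tr.ca_uM, reference=ref, variance_floor=1e-4, elevation_floor=0.06)
    assert not cls.active[0]


def test_single_cell_bursts_with_ordered_plateau_fractions():
    """20 mM drive bursts with plateau fraction in the 50-70% band; 11 mM
    bursts more sparsely."""
    pf = {}
    for glu in (11.0, 20.0):
        cfg = SimConfig(duration_ms=70000, glucose_mM=glu, seed=1)
        tr = integrate_islet(single_cell_arch(), params_table(CellParams(), 1), cfg).after(10.0)
        assert np.ptp(tr.ca_uM[0]) > 0.02
        pf[glu] = plateau_fraction(tr.ca_uM[0])
    assert 0.50 <= pf[20.0] <= 0.70
    assert pf[11.0] < pf[20.0]


def test_identical_cells_stay_identical_under_symmetric_coupling():
    arch = all_to_all_arch(4, g=120.0)
    cells = params_table(CellParams(), 4)
    cfg = SimConfig(duration_ms=20000, glucose_mM=20.0, v_jitter_mV=0.0, seed=2)
    tr = integrate_islet(arch, cells, cfg)
    for k in range(1, 4):
        np.testing.assert_allclose(tr.v_mV[k], tr.v_mV[0], atol=1e-9)
        np.testing.assert_allclose(tr.ca_uM[k], tr.ca_uM[0], atol=1e-12)


def test_silent_cell_timestep_convergence():
    """On a quiescent trajectory halving the Euler step moves the sampled
    potential by far less than a millivolt."""
    cells = params_table(CellParams(), 1)
    a = integrate_islet(single_cell_arch(), cells, SimConfig(duration_ms=30000, glucose_mM=2.0, dt_ms=0.1, seed=3))
    b = integrate_islet(single_cell_arch(), cells, SimConfig(duration_ms=30000, glucose_mM=2.0, dt_ms=0.05, seed=3))
    rms = np.sqrt(np.mean((a.v_mV - b.v_mV) ** 2))
    assert rms < 1.0


def test_integration_failure_reports_step():
    def blowup(v, n, c, cells):
        return np.full_like(v, 1e9), np.zeros_like(n), np.zeros_like(c)

    with pytest.raises(IntegrationError) as err:
        integrate_islet(
            single_cell_arch(), params_table(CellParams(), 1),
            SimConfig(duration_ms=1000, seed=1), custom_rhs=blowup,
        )
    assert err.value.step >= 0


def test_custom_rhs_reproduces_builtin_kernel():
    """The pluggable cell-model path integrates the same equations as the
    compiled kernel: a re-implementation of the default currents must give
    bitwise-comparable trajectories."""
    from isletcrit.dynamics import effective_katp_conductance

    arch = assign_coupling(generate_sphere_packing(12, seed=5), 120.0, 0.7, seed=6)
    cells = params_table(CellParams(), 12)
    cfg = SimConfig(duration_ms=5000, glucose_mM=20.0, seed=7)
    base = CellParams()
    gkatp = effective_katp_conductance(cells, cfg.glucose_mM)

    def rhs(v, n, c, tab):
        minf = 1 / (1 + np.exp((base.vm - v) / base.sm))
        ninf = 1 / (1 + np.exp((base.vn - v) / base.sn))
        ica = tab["g_ca"].to_numpy() * minf * (v - base.v_ca)
        ik = tab["g_k"].to_numpy() * n * (v - base.v_k)
        ikca = tab["g_kca"].to_numpy() * c**2 / (c**2 + base.kd**2) * (v - base.v_k)
        ikatp = gkatp * (v - base.v_k)
        dv = -(ica + ik + ikca + ikatp) / base.cm
        dn = (ninf - n) / base.tau_n
        dc = base.f_ca * (-base.alpha_ca * ica - tab["k_pmca"].to_numpy() * c)
        return dv, dn, dc

    fast = integrate_islet(arch, cells, cfg)
    slow = integrate_islet(arch, cells, cfg, custom_rhs=rhs)
    np.testing.assert_allclose(slow.v_mV, fast.v_mV, atol=1e-6)
    np.testing.assert_allclose(slow.ca_uM, fast.ca_uM, atol=1e-9)


def test_sim_config_validation():
    with pytest.raises(ValueError):
        SimConfig(dt_ms=200.0, sample_ms=100.0)
    with pytest.raises(ValueError):
        SimConfig(duration_ms=10.0, sample_ms=100.0)


def test_trace_set_table_and_transient_removal():
    cfg = SimConfig(duration_ms=3000, glucose_mM=20.0, seed=1)
    tr = integrate_islet(single_cell_arch(), params_table(CellParams(), 1), cfg)
    df = tr.to_frame("ca")
    assert list(df.columns) == ["time_s", "cell_0"] and len(df) == 30
    cut = tr.after(1.0)
    assert cut.time_s.min() >= 1.0 and cut.v_mV.shape[1] < tr.v_mV.shape[1]


def test_phase_scan_endpoints():
    """0% mutants at 20 mM and 120 pS: the whole islet is active; 100%
    mutants: silent."""
    cfg = SimConfig(duration_ms=20000, glucose_mM=20.0, seed=8)
    res = phase_transition_scan(
        60, cfg, "mutant_fraction", [0.0, 1.0], mean_g_list=[120.0],
        transient_s=8.0, seed=8,
    )
    curve = res[120.0]
    assert curve.mean_pct[0] > 90.0
    assert curve.mean_pct[1] < 10.0


def test_phase_scan_rejects_unknown_kind():
    cfg = SimConfig(duration_ms=1000, seed=1)
    with pytest.raises(ValueError):
        phase_transition_scan(10, cfg, "nonsense", [0.1])
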