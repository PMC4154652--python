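"""Coupled multicellular islet simulation.

Every cell follows the reduced β-cell model; neighboring cells exchange an
Ohmic gap-junction current I_coup,i = Σ_j g_ij (V_i − V_j) added to the
membrane equation, so Cm dV_i/dt = −(I_ion,i + I_coup,i).  Integration is
forward Euler at a fixed 100 µs step with states recorded every 100 ms.
Phase-transition scans sweep either the fraction of mutant (over-active
K_ATP) cells or the uniform channel-opener scaling α, classify activity
from the calcium-like traces, and return percent-active curves per mean
coupling conductance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

from .architecture import IsletArchitecture, assign_coupling, generate_sphere_packing
from .cellmodel import (
    GLUCOSE_P_OPEN,
    CellParams,
    assign_cell_heterogeneity,
    katp_effective_open_probability,
)
from .metrics import classify_active, percent_active
from .suppression import ActivityCurve

__all__ = [
    "SimConfig",
    "TraceSet",
    "IntegrationError",
    "coupling_current",
    "glucose_to_p_open",
    "integrate_islet",
    "silent_reference_trace",
    "phase_transition_scan",
]


class IntegrationError(RuntimeError):
    """Non-finite state encountered; carries the failing step index."""

    def __init__(self, step: int):
        super().__init__(f"integration diverged at step {step}")
        self.step = step


@dataclass(frozen=True)
class SimConfig:
    """Integration configuration: 100 µs Euler step, 100 ms sampling."""

    duration_ms: float = 60000.0
    dt_ms: float = 0.1
    sample_ms: float = 100.0
    glucose_mM: float = 11.0
    v_jitter_mV: float = 0.5  # initial per-cell voltage jitter (symmetry breaking)
    seed: int = 0

    def __post_init__(self):
        if self.dt_ms > self.sample_ms:
            raise ValueError("time step must not exceed the sampling interval")
        if self.duration_ms < self.sample_ms:
            raise ValueError("duration must cover at least one sampling interval")


@dataclass(frozen=True)
class TraceSet:
    """Per-cell membrane potential and calcium traces on the sampling grid."""

    time_s: np.ndarray = field(repr=False)
    v_mV: np.ndarray = field(repr=False)  # (cells, samples)
    ca_uM: np.ndarray = field(repr=False)
    config: SimConfig | None = None

    @property
    def n_cells(self) -> int:
        return self.v_mV.shape[0]

    def after(self, t_s: float) -> "TraceSet":
        """Drop samples before ``t_s`` (transient removal)."""
        keep = self.time_s >= t_s
        return TraceSet(
            time_s=self.time_s[keep],
            v_mV=self.v_mV[:, keep],
            ca_uM=self.ca_uM[:, keep],
            config=self.config,
        )

    def to_frame(self, which: str = "ca") -> pd.DataFrame:
        data = self.ca_uM if which == "ca" else self.v_mV
        df = pd.DataFrame(data.T, columns=[f"cell_{i}" for i in range(self.n_cells)])
        df.insert(0, "time_s", self.time_s)
        return df


def glucose_to_p_open(glucose_mM: float) -> float:
    """Baseline K_ATP open probability at a glucose level, interpolated
    linearly between the shipped calibration points."""
    from . import cellmodel

    table = cellmodel.GLUCOSE_P_OPEN
    g = np.array(sorted(table))
    p = np.array([table[k] for k in g])
    return float(np.interp(glucose_mM, g, p))


def coupling_current(v_i: float, neighbor_vs, conductances) -> float:
    """Gap-junction current on cell i in pA (positive = outward):
    I = Σ_j g_ij (V_i − V_j) with g in pS and V in mV."""
    nv = np.asarray(neighbor_vs, dtype=float)
    g = np.asarray(conductances, dtype=float)
    if nv.shape != g.shape:
        raise ValueError("neighbor potentials and conductances must have equal length")
    return float(np.sum(g * (v_i - nv)) / 1000.0)


@njit(cache=True)
def _euler_kernel(
    indptr,
    indices,
    gvals,
    gca,
    gk,
    gkca,
    gkatp,
    kpmca,
    cm,
    vca,
    vk,
    vm,
    sm,
    vn,
    sn,
    taun,
    kd,
    fca,
    aca,
    v,
    n,
    c,
    dt,
    n_steps,
    sample_every,
    vout,
    cout,
):
    ncell = v.shape[0]
    dv = np.empty(ncell)
    s = 0
    for step in range(n_steps):
        for i in range(ncell):
            vi = v[i]
            icoup = 0.0
            for k in range(indptr[i], indptr[i + 1]):
                icoup += gvals[k] * (vi - v[indices[k]])
            minf = 1.0 / (1.0 + np.exp((vm - vi) / sm))
            ninf = 1.0 / (1.0 + np.exp((vn - vi) / sn))
            ica = gca[i] * minf * (vi - vca)
            ik = gk[i] * n[i] * (vi - vk)
            ci = c[i]
            ikca = gkca[i] * ci * ci / (ci * ci + kd * kd) * (vi - vk)
            ikatp = gkatp[i] * (vi - vk)
            dv[i] = -(ica + ik + ikca + ikatp + icoup) / cm
            n[i] += dt * (ninf - n[i]) / taun
            c[i] += dt * fca * (-aca * ica - kpmca[i] * ci)
        for i in range(ncell):
            v[i] += dt * dv[i]
        if (step + 1) % sample_every == 0:
            for i in range(ncell):
                vout[i, s] = v[i]
                cout[i, s] = c[i]
                if not np.isfinite(v[i]) or np.abs(v[i]) > 500.0:
                    return step
            s += 1
    return -1


def effective_katp_conductance(cells: pd.DataFrame, glucose_mM: float) -> np.ndarray:
    """Per-cell effective K_ATP conductance g_bar · p_eff (pS), combining the
    glucose drive, per-cell metabolic heterogeneity, the mutant mix and the
    uniform opener scaling."""
    p_base = np.clip(glucose_to_p_open(glucose_mM) * cells["drive"].to_numpy(), 0.0, 1.0)
    p_eff = katp_effective_open_probability(
        p_base,
        mutant=cells["mutant"].to_numpy(dtype=bool),
        gamma=float(cells["gamma"].iloc[0]),
        alpha=float(cells["alpha"].iloc[0]),
    )
    return cells["g_katp_bar"].to_numpy() * p_eff


def integrate_islet(
    arch: IsletArchitecture,
    cells: pd.DataFrame,
    config: SimConfig,
    custom_rhs=None,
) -> TraceSet:
    """Forward-Euler integration of the coupled islet.

    ``cells`` is a per-cell parameter table (one row per cell, columns as in
    :class:`~isletcrit.cellmodel.CellParams`).  The default cell model runs
    in a compiled kernel; a ``custom_rhs(v, n, c, cells) -> (dv_ion_per_cm,
    dn, dc)`` callable substitutes the single-cell dynamics (the coupling
    current is always added by the integrator).
    """
    ncell = arch.n_cells
    if len(cells) != ncell:
        raise ValueError("parameter table size must match the architecture")
    rng = np.random.default_rng(config.seed)
    base = CellParams()
    v = np.full(ncell, -65.0) + config.v_jitter_mV * rng.normal(size=ncell)
    n = np.zeros(ncell)
    c = np.full(ncell, 0.1)

    indptr, indices, eidx = arch.adjacency_csr()
    g_edge = (
        arch.conductances if arch.conductances is not None else np.zeros(arch.n_edges)
    )
    gvals = g_edge[eidx] if arch.n_edges else np.zeros(0)

    dt = config.dt_ms
    sample_every = int(round(config.sample_ms / dt))
    n_steps = int(round(config.duration_ms / dt))
    n_samples = n_steps // sample_every
    vout = np.empty((ncell, n_samples))
    cout = np.empty((ncell, n_samples))

    if custom_rhs is None:
        gkatp = effective_katp_conductance(cells, config.glucose_mM)
        bad = _euler_kernel(
            indptr,
            indices,
            np.ascontiguousarray(gvals, dtype=np.float64),
            cells["g_ca"].to_numpy(dtype=np.float64),
            cells["g_k"].to_numpy(dtype=np.float64),
            cells["g_kca"].to_numpy(dtype=np.float64),
            gkatp.astype(np.float64),
            cells["k_pmca"].to_numpy(dtype=np.float64),
            base.cm,
            base.v_ca,
            base.v_k,
            base.vm,
            base.sm,
            base.vn,
            base.sn,
            base.tau_n,
            base.kd,
            base.f_ca,
            base.alpha_ca,
            v,
            n,
            c,
            dt,
            n_steps,
            sample_every,
            vout,
            cout,
        )
        if bad >= 0:
            raise IntegrationError(bad)
    else:
        cm = cells["cm"].to_numpy() if "cm" in cells else np.full(ncell, base.cm)
        s = 0
        for step in range(n_steps):
            icoup = np.zeros(ncell)
            if arch.n_edges:
                i0, j0 = arch.edges[:, 0], arch.edges[:, 1]
                flow = g_edge * (v[i0] - v[j0])
                np.add.at(icoup, i0, flow)
                np.add.at(icoup, j0, -flow)
            dv, dn, dc = custom_rhs(v, n, c, cells)
            v = v + dt * (dv - icoup / cm)
            n = n + dt * dn
            c = c + dt * dc
            if (step + 1) % sample_every == 0:
                if not np.all(np.isfinite(v)) or np.any(np.abs(v) > 500):
                    raise IntegrationError(step)
                vout[:, s] = v
                cout[:, s] = c
                s += 1

    time_s = (np.arange(1, n_samples + 1) * sample_every * dt) / 1000.0
    return TraceSet(time_s=time_s, v_mV=vout, ca_uM=cout, config=config)


def silent_reference_trace(
    config: SimConfig, base: CellParams | None = None
) -> np.ndarray:
    """Calcium trace of a single uncoupled, fully suppressed cell (maximal
    K_ATP opening), the quiescent reference for activity classification."""
    from .cellmodel import params_table

    base = base or CellParams()
    cells = params_table(base, 1)
    cells["mutant"] = True
    cells["gamma"] = 1.0  # fully ATP-insensitive: K_ATP wide open, silent
    arch = IsletArchitecture(
        positions=np.zeros((1, 3)), edges=np.zeros((0, 2), dtype=np.int64), kind="ref"
    )
    traces = integrate_islet(arch, cells, config)
    return traces.ca_uM[0]


def phase_transition_scan(
    arch: IsletArchitecture | int,
    config: SimConfig,
    kind: str,
    scan_values,
    mean_g_list=(120.0,),
    coupling_cv: float = 0.70,
    heterogeneity_mode: str = "all",
    transient_s: float = 10.0,
    base: CellParams | None = None,
    seed: int = 0,
    variance_floor: float = 1e-4,
    elevation_floor: float = 0.06,
) -> dict[float, ActivityCurve]:
    """Scan the mutant-cell fraction or the uniform opener scaling α and
    return percent-active curves, one per mean coupling conductance.

    ``arch`` may be an integer cell count (a sphere packing is generated) or
    a prebuilt architecture.  Cells are classified on their post-transient
    calcium traces against a simulated quiescent reference with a variance
    floor guarding against sub-threshold ripple transmitted through the
    coupling (see docs).  Integration failures are annotated per point
    (NaN activity) rather than aborting the scan.
    """
    if kind not in ("mutant_fraction", "alpha"):
        raise ValueError(f"unknown scan kind {kind!r}")
    scan_values = np.atleast_1d(np.asarray(scan_values, dtype=float))
    base = base or CellParams()
    if isinstance(arch, (int, np.integer)):
        arch = generate_sphere_packing(int(arch), seed=seed)
    ncell = arch.n_cells
    cells0 = assign_cell_heterogeneity(
        base, ncell, seed=seed + 1, mode=heterogeneity_mode
    )
    ref = silent_reference_trace(config, base)
    ref = ref[-max(1, int(len(ref) * (1 - transient_s * 1000 / config.duration_ms))):]
    out = {}
    for gi, mean_g in enumerate(mean_g_list):
        arch_g = (
            assign_coupling(arch, mean_g, coupling_cv, seed=seed + 100 + gi)
            if mean_g > 0
            else assign_coupling(arch, 0.0, 0.0, seed=seed)
        )
        means = np.empty(scan_values.size)
        for si, val in enumerate(scan_values):
            cells = cells0.copy()
            if kind == "mutant_fraction":
                n_mut = int(round(val * ncell))
                rng = np.random.default_rng(
                    np.random.SeedSequence(seed, spawn_key=(gi, si))
                )
                mut = rng.choice(ncell, size=n_mut, replace=False)
                flags = np.zeros(ncell, dtype=bool)
                flags[mut] = True
                cells["mutant"] = flags
            else:
                cells["alpha"] = val
            try:
                traces = integrate_islet(arch_g, cells, config).after(transient_s)
            except IntegrationError:
                means[si] = np.nan
                continue
            cls = classify_active(
                traces.ca_uM,
                reference=ref,
                variance_floor=variance_floor,
                elevation_floor=elevation_floor,
            )
            means[si] = percent_active(cls)
        order = np.argsort(scan_values)
        out[float(mean_g)] = ActivityCurve(
            control_name=kind,
            control=scan_values[order],
            mean_pct=means[order],
            se_pct=np.zeros(scan_values.size),
            reps=1,
            meta={
                "mean_g_pS": float(mean_g),
                "glucose_mM": config.glucose_mM,
                "n_cells": ncell,
                "seed": seed,
            },
        )
    return out
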