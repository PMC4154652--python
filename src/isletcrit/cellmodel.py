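"""Reduced β-cell electrophysiology model and per-cell parameter tables.

The single β-cell is a Chay-Keizer-class burster with three state
variables: membrane potential V (mV), delayed-rectifier activation n, and a
cytosolic calcium-like variable c (µM).  Currents (fA; conductances in pS,
potentials in mV):

* voltage-gated Ca²⁺ current, instantaneous activation m∞(V);
* delayed-rectifier K⁺ current gated by n;
* Ca²⁺-activated K⁺ current (Hill coefficient 2 in c);
* ATP-sensitive K⁺ (K_ATP) current  I = g_KATP_bar · p_open · (V − V_K),
  where g_KATP_bar is the open-channel conductance and p_open the mean open
  probability set by the glucose/metabolic drive.

Glucose acts through a calibration table mapping glucose level to the
baseline K_ATP open probability (higher glucose → more channel closure).
Two K_ATP perturbations are modeled as affine mixes of the open probability:

* over-active mutant channels in a chosen subset of cells:
  p' = γ + (1 − γ)·p_open  with γ the ATP-insensitive fraction (default 0.5);
* a uniform channel opener (diazoxide-like) applied to every cell:
  p' = (1 − α) + α·p_open, with α = 1 untreated; α = 0.5 acts identically to
  100% mutant expression at γ = 0.5.

These are the unique affine forms satisfying both boundary conditions; the
mutant mix composes after the opener scaling.

All cell constants are package calibration (chosen so that an uncoupled
default cell is silent at the 2 mM drive and bursts at 11 and 20 mM with the
plateau fraction at 20 mM in the 50–70% range and a lower one at 11 mM).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd

__all__ = [
    "CellParams",
    "GLUCOSE_P_OPEN",
    "katp_effective_open_probability",
    "assign_cell_heterogeneity",
    "params_table",
]

# glucose (mM) -> baseline K_ATP mean open probability (calibration table;
# with the default open-channel conductance this puts the effective K_ATP
# conductance at 240 pS / 174 pS / 144 pS, i.e. silent / sparse bursting /
# bursting with a 50-70% plateau fraction).  The open-channel conductance is
# far larger than the active-state effective conductance: K_ATP carries a
# large spare conductance, which is what makes over-active mutant channels
# (gamma = 0.5) such strong hyperpolarizing sinks.
GLUCOSE_P_OPEN = {2.0: 0.040, 11.0: 0.029, 20.0: 0.024}


@dataclass(frozen=True)
class CellParams:
    """Per-cell parameters of the reduced β-cell model (units in comments)."""

    cm: float = 5300.0  # membrane capacitance, fF
    g_ca: float = 1000.0  # Ca2+ conductance, pS
    v_ca: float = 25.0  # Ca2+ reversal, mV
    vm: float = -20.0  # Ca2+ activation midpoint, mV
    sm: float = 12.0  # Ca2+ activation slope, mV
    g_k: float = 2700.0  # delayed-rectifier conductance, pS
    v_k: float = -75.0  # K+ reversal, mV
    vn: float = -16.0  # n activation midpoint, mV
    sn: float = 5.0  # n activation slope, mV
    tau_n: float = 20.0  # n time constant, ms
    g_kca: float = 800.0  # Ca2+-activated K+ conductance, pS
    kd: float = 0.5  # K(Ca) half-activation, µM
    g_katp_bar: float = 6000.0  # K_ATP open-channel conductance, pS
    f_ca: float = 0.001  # fraction of free cytosolic Ca2+
    alpha_ca: float = 4.5e-6  # current-to-flux conversion, µM/(fA·ms)
    k_pmca: float = 0.2  # Ca2+ removal rate, 1/ms
    drive: float = 1.0  # metabolic-drive multiplier on p_open (dimensionless)
    mutant: bool = False  # over-active (ATP-insensitive) K_ATP subunit
    gamma: float = 0.5  # ATP-insensitive current fraction in mutant cells
    alpha: float = 1.0  # uniform opener scaling (1 = untreated)


def katp_effective_open_probability(
    p_open_base: float, mutant: bool = False, gamma: float = 0.5, alpha: float = 1.0
):
    """Effective K_ATP open probability after the uniform opener scaling and
    (for mutant cells) the ATP-insensitive mix; the mutant mix is applied
    after the opener scaling so the two perturbations compose."""
    p = np.asarray(p_open_base, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("open probability must lie in [0, 1]")
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must lie in (0, 1]")
    if not 0.0 <= gamma <= 1.0:
        raise ValueError("gamma must lie in [0, 1]")
    out = (1.0 - alpha) + alpha * p
    out = np.where(mutant, gamma + (1.0 - gamma) * out, out)
    return float(out) if out.ndim == 0 else out


# parameters receiving the general 10% heterogeneity; g_katp_bar carries its
# own, larger, coefficient of variation (25%); "drive" stands for
# glycolytic/metabolic flux
_GENERAL_HET = ("g_ca", "g_k", "g_kca", "k_pmca", "drive")
_KATP_HET = ("g_katp_bar",)


def params_table(base: CellParams, n_cells: int) -> pd.DataFrame:
    """Homogeneous per-cell parameter table from a base parameter set."""
    cols = {f.name: np.full(n_cells, getattr(base, f.name)) for f in fields(base)}
    cols["mutant"] = np.full(n_cells, bool(base.mutant))
    return pd.DataFrame(cols)


def assign_cell_heterogeneity(
    base: CellParams,
    n_cells: int,
    cv_general: float = 0.10,
    cv_gkatp: float = 0.25,
    seed: int = 0,
    mode: str = "all",
) -> pd.DataFrame:
    """Per-cell parameter table with Gaussian multiplicative heterogeneity.

    ``mode`` reproduces the heterogeneity ablations: "all" (default),
    "katp_only" (heterogeneity solely in K_ATP open-channel conductance),
    "metabolic_only" (solely in the metabolic drive), or "none".  Draws are
    truncated at zero by resampling.
    """
    if cv_general < 0 or cv_gkatp < 0:
        raise ValueError("coefficients of variation must be >= 0")
    if mode not in ("all", "katp_only", "metabolic_only", "none"):
        raise ValueError(f"unknown heterogeneity mode {mode!r}")
    rng = np.random.default_rng(seed)
    table = params_table(base, n_cells)

    def scatter(col: str, cv: float):
        if cv == 0:
            return
        mult = rng.normal(1.0, cv, size=n_cells)
        bad = mult <= 0
        while bad.any():
            mult[bad] = rng.normal(1.0, cv, size=int(bad.sum()))
            bad = mult <= 0
        table[col] = table[col] * mult

    if mode == "all":
        for col in _GENERAL_HET:
            scatter(col, cv_general)
        for col in _KATP_HET:
            scatter(col, cv_gkatp)
    elif mode == "katp_only":
        for col in _KATP_HET:
            scatter(col, cv_gkatp)
    elif mode == "metabolic_only":
        scatter("drive", cv_general)
    return table
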