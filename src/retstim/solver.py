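"""Backward-Euler integration of the multicompartment cable equation.

Each compartment n obeys

    C_n dV_n/dt = −I_ion,n + Σ_j [ (V_j − V_n) + (V_e,j − V_e,n) ] / (R_j/2 + R_n/2)

where the sum runs over all neighbors (branch points may have more than
two).  The extracellular potential enters through the axial difference
terms (activating-function coupling).  Each time step solves the sparse
symmetric positive-definite system

    (C/dt + G_ion + L) V' = (C/dt)·V + b_ion − L·V_e

with Rush–Larsen (exact exponential) gating updates and linearized ionic
conductances (gates and calcium-dependent reversals lagged one step), a
scheme that is unconditionally stable at the default dt = 0.025 ms.
The system is solved by banded Cholesky after ordering compartments
parent-before-child; morphologies whose bandwidth is too large fall back
to sparse LU.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import scipy.linalg
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .errors import ConfigError, SolverDivergenceError
from .morphology import CompartmentGraph
from .units import DT_MS


@dataclass
class SimConfig:
    """Integration settings.

    ``settle_ms`` of stimulus-free integration are run and discarded
    before t = 0 so gates and calcium sit on their fixed point.
    ``v_bounds_mv`` is a divergence guard, not a physical clamp.
    """

    dt_ms: float = DT_MS
    total_ms: float = 100.0
    settle_ms: float = 50.0
    record_stride: int = 1
    record_indices: np.ndarray | None = None
    v_bounds_mv: tuple[float, float] = (-200.0, 300.0)
    max_bandwidth: int = 128

    def __post_init__(self):
        if self.dt_ms <= 0 or self.total_ms < 0:
            raise ConfigError("dt_ms must be > 0 and total_ms >= 0")


@dataclass
class Clamp:
    """Voltage clamp of selected compartments.

    ``v_mv`` is a scalar or a callable t_ms -> mV applied to every
    clamped compartment (implemented as a 1e9 µS series conductance to
    the command potential).
    """

    indices: np.ndarray
    v_mv: float | Callable[[float], float]

    def command(self, t_ms: float) -> float:
        return self.v_mv(t_ms) if callable(self.v_mv) else self.v_mv


@dataclass
class SimTrace:
    """Recorded simulation output (time in ms, potentials in mV,
    calcium in µM, calcium current density in mA/cm²)."""

    t_ms: np.ndarray
    v_mv: np.ndarray                   # (n_samples, n_recorded)
    record_indices: np.ndarray
    ca_um: np.ndarray | None
    i_ca_ma_cm2: np.ndarray | None
    current_ua: np.ndarray
    first_crossing_ms: np.ndarray      # per compartment, NaN if no spike
    dt_ms: float

    def v_of(self, compartment: int) -> np.ndarray:
        pos = np.flatnonzero(self.record_indices == compartment)
        if pos.size == 0:
            raise KeyError(f"compartment {compartment} was not recorded")
        return self.v_mv[:, pos[0]]

    def ca_of(self, compartment: int) -> np.ndarray:
        if self.ca_um is None:
            raise KeyError("calcium was not recorded")
        pos = np.flatnonzero(self.record_indices == compartment)
        if pos.size == 0:
            raise KeyError(f"compartment {compartment} was not recorded")
        return self.ca_um[:, pos[0]]

    def export_tsv(self, path, decimate: int = 1) -> None:
        """Long-format delimited export: (time, compartment, V[, Ca])."""
        with open(path, "w") as fh:
            cols = "t_ms\tcompartment\tv_mv"
            if self.ca_um is not None:
                cols += "\tca_um"
            fh.write(cols + "\n")
            for k in range(0, len(self.t_ms), decimate):
                for c, idx in enumerate(self.record_indices):
                    row = f"{self.t_ms[k]:.4f}\t{idx}\t{self.v_mv[k, c]:.6f}"
                    if self.ca_um is not None:
                        row += f"\t{self.ca_um[k, c]:.6f}"
                    fh.write(row + "\n")


class _LinearSystem:
    """Holds the fixed axial structure; solves (diag(d) + L) x = rhs."""

    def __init__(self, graph: CompartmentGraph, max_bandwidth: int):
        n = graph.n_compartments
        self.n = n
        g_edge = graph.edge_conductances_us()
        ei = np.array([e[0] for e in graph.edges], dtype=int)
        ej = np.array([e[1] for e in graph.edges], dtype=int)
        self.ei, self.ej, self.g_edge = ei, ej, g_edge
        # graph Laplacian L: (L v)_n = sum_j g_nj (v_n - v_j)
        lap_diag = np.zeros(n)
        np.add.at(lap_diag, ei, g_edge)
        np.add.at(lap_diag, ej, g_edge)
        self.lap_diag = lap_diag
        bw = int(np.max(np.abs(ei - ej))) if len(ei) else 0
        self.banded = bw <= max_bandwidth
        if self.banded:
            self.bw = bw
            ab = np.zeros((bw + 1, n))
            lower = np.minimum(ei, ej)
            upper = np.maximum(ei, ej)
            ab[upper - lower, lower] = -g_edge
            self._ab_template = ab
        else:
            off = sp.coo_matrix((-g_edge, (ei, ej)), shape=(n, n))
            self._off = (off + off.T).tocsc()

    def apply_lap(self, x: np.ndarray) -> np.ndarray:
        out = self.lap_diag * x
        if len(self.ei):
            np.subtract.at(out, self.ei, self.g_edge * x[self.ej])
            np.subtract.at(out, self.ej, self.g_edge * x[self.ei])
        return out

    def solve(self, diag: np.ndarray, rhs: np.ndarray) -> np.ndarray:
        d = diag + self.lap_diag
        if self.banded:
            ab = self._ab_template.copy()
            ab[0, :] = d
            return scipy.linalg.solveh_banded(ab, rhs, lower=True,
                                              check_finite=False)
        m = self._off + sp.diags(d)
        return spla.spsolve(m.tocsc(), rhs)


def simulate(graph: CompartmentGraph, mechanism, field=None, waveform=None,
             config: SimConfig | None = None, v_init=None,
             clamp: Clamp | None = None) -> SimTrace:
    """Integrate the cable equation and return recorded traces.

    ``field`` provides the extracellular potential per µA;
    ``waveform.current_ua(t)`` modulates it.  The solver is fully
    deterministic (no RNG).  Raises :class:`SolverDivergenceError`
    naming the first offending compartment if any membrane potential
    leaves ``config.v_bounds_mv``.
    """
    cfg = config or SimConfig()
    dt = cfg.dt_ms
    n = graph.n_compartments
    sys_ = _LinearSystem(graph, cfg.max_bandwidth)

    areas = graph.areas_cm2
    c_over_dt = graph.capacitances_nf / dt          # nF/ms
    unit_ve = (np.asarray(field.potential_at(1.0, graph.centers), dtype=float)
               if field is not None else np.zeros(n))
    drive_unit = -sys_.apply_lap(unit_ve)           # nA per µA of stimulus

    state = mechanism.init_state()
    v = state["v"].copy()
    if v_init is not None:
        v = np.full(n, float(v_init)) if np.isscalar(v_init) \
            else np.asarray(v_init, dtype=float).copy()

    rec_idx = (np.arange(n) if cfg.record_indices is None
               else np.asarray(cfg.record_indices, dtype=int))
    n_steps = int(round(cfg.total_ms / dt))
    n_settle = int(round(cfg.settle_ms / dt))
    sample_steps = np.arange(0, n_steps + 1, cfg.record_stride)
    n_samp = len(sample_steps)

    v_rec = np.empty((n_samp, len(rec_idx)))
    has_ca = "ca" in state
    ca_rec = np.empty((n_samp, len(rec_idx))) if has_ca else None
    ica_rec = np.empty((n_samp, len(rec_idx))) if has_ca else None
    cur_rec = np.empty(n_samp)
    first_crossing = np.full(n, np.nan)

    clamp_idx = (np.asarray(clamp.indices, dtype=int)
                 if clamp is not None else None)
    big_g = 1e9

    def step(v, t_ms, i_ua):
        mechanism.advance_gates(state, v, dt)
        g_density, b_density = mechanism.linearized(state)
        g_us = g_density * areas * 1e3
        b_na = b_density * areas * 1e3
        diag = c_over_dt + g_us
        rhs = c_over_dt * v + b_na + drive_unit * i_ua
        if clamp_idx is not None:
            diag = diag.copy()
            diag[clamp_idx] += big_g
            rhs[clamp_idx] += big_g * clamp.command(t_ms)
        v_new = sys_.solve(diag, rhs)
        if has_ca:
            mechanism.advance_calcium(state, v_new, dt)
        return v_new

    lo, hi = cfg.v_bounds_mv
    for k in range(n_settle):
        v = step(v, -(n_settle - k) * dt, 0.0)
    state["v"] = v

    t_grid = np.arange(n_steps + 1) * dt
    currents = (waveform.current_ua(t_grid) if waveform is not None
                else np.zeros(n_steps + 1))

    sample_pos = 0
    if sample_steps[0] == 0:
        v_rec[0] = v[rec_idx]
        if has_ca:
            ca_rec[0] = state["ca"][rec_idx]
            ica_rec[0] = state["i_ca"][rec_idx]
        cur_rec[0] = currents[0]
        sample_pos = 1

    for k in range(n_steps):
        t_new = (k + 1) * dt
        v_prev = v
        v = step(v, t_new, float(currents[k]))
        if np.any(v < lo) or np.any(v > hi):
            bad = int(np.argmax(np.abs(v)))
            raise SolverDivergenceError(
                f"membrane potential {v[bad]:.1f} mV outside "
                f"[{lo}, {hi}] mV at compartment {bad}, t = {t_new:.3f} ms",
                compartment=bad, time_ms=t_new)
        crossed = (v >= 0.0) & (v_prev < 0.0) & np.isnan(first_crossing)
        if crossed.any():
            first_crossing[crossed] = t_new
        if sample_pos < n_samp and sample_steps[sample_pos] == k + 1:
            v_rec[sample_pos] = v[rec_idx]
            if has_ca:
                ca_rec[sample_pos] = state["ca"][rec_idx]
                ica_rec[sample_pos] = state["i_ca"][rec_idx]
            cur_rec[sample_pos] = currents[k]
            sample_pos += 1
    state["v"] = v

    return SimTrace(t_ms=sample_steps * dt, v_mv=v_rec,
                    record_indices=rec_idx, ca_um=ca_rec,
                    i_ca_ma_cm2=ica_rec, current_ua=cur_rec,
                    first_crossing_ms=first_crossing, dt_ms=dt)


class PassiveMechanism:
    """Leak-only membrane (no gates, no calcium) — used for polarization
    analyses and for analytic solver checks."""

    def __init__(self, graph: CompartmentGraph, g_l_ms_cm2: float = 0.5,
                 e_l_mv: float = -60.0):
        self.graph = graph
        self.g_l = np.full(graph.n_compartments, g_l_ms_cm2)
        self.e_l = e_l_mv
        self.v_rest = e_l_mv

    def init_state(self) -> dict:
        return {"v": np.full(self.graph.n_compartments, self.v_rest)}

    def advance_gates(self, state, v, dt_ms):
        pass

    def linearized(self, state):
        return self.g_l, self.g_l * self.e_l


def polarization_profile(graph: CompartmentGraph, field, current_ua: float,
                         g_l_ms_cm2: float = 0.5) -> np.ndarray:
    """Steady-state passive membrane polarization (mV, relative to rest)
    for a static extracellular field.

    Solves (G_leak + L) ΔV = −L·V_e directly — the t → ∞ limit of the
    leak-only cable equation.  Linear in the stimulus current.
    """
    sys_ = _LinearSystem(graph, max_bandwidth=10 ** 9)
    ve = np.asarray(field.potential_at(current_ua, graph.centers), dtype=float)
    g_us = g_l_ms_cm2 * graph.areas_cm2 * 1e3
    rhs = -sys_.apply_lap(ve)
    return sys_.solve(g_us, rhs)


def fit_membrane_time_constant(t_ms: np.ndarray, v_mv: np.ndarray,
                               t_on_ms: float, window_ms: float = 1.0):
    """Fit V(t) = V0 + ΔV·(1 − exp(−(t−t_on)/τ)) to the polarization rise
    after a pulse edge; returns (tau_ms, dv_mv)."""
    from scipy.optimize import curve_fit

    mask = (t_ms >= t_on_ms) & (t_ms <= t_on_ms + window_ms)
    tt = t_ms[mask] - t_on_ms
    vv = v_mv[mask]
    v0 = vv[0]

    def model(t, dv, tau):
        return v0 + dv * (1.0 - np.exp(-t / tau))

    p0 = (vv[-1] - v0, 0.2)
    popt, _ = curve_fit(model, tt, vv, p0=p0, maxfev=10000)
    return float(popt[1]), float(popt[0])
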