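"""Ionic membrane mechanisms.

Two membrane models are provided:

* **Bipolar cell (BC)** — an ohmic leak over the whole membrane plus an
  L-type calcium channel confined to the synaptic terminals
  (i_CaL = g_Ca·m²·h·(V − E_Ca)), with the calcium reversal potential
  recomputed every step as a divalent Nernst potential from the
  submembrane calcium concentration, and a single-shell intracellular
  calcium balance (influx through the channel, first-order extrusion).

* **Retinal ganglion cell (RGC)** — the classic five-channel
  Fohlmeister–Coleman–Miller repertoire (Na, K, Ca, Ca-activated K,
  leak) with section-wise channel densities (dendrite, soma, axon
  hillock, AIS, axon).

Channel densities are shipped as editable CSV tables under
``retstim/data`` and resolved per compartment through the morphology's
section labels.  All rates are taken at 23 °C, matching the
room-temperature experiments the model is compared against; no Q10
scaling is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .errors import StateError, ConfigError
from .morphology import CompartmentGraph
from .units import NERNST_CA_MV, ca_flux_factor


def load_density_table(cell_kind: str, path=None) -> pd.DataFrame:
    """Channel density table (mS/cm²), indexed by section label."""
    if path is None:
        name = "bc_densities.csv" if cell_kind == "BC" else "rgc_densities.csv"
        src = resources.files("retstim.data").joinpath(name)
        with resources.as_file(src) as p:
            table = pd.read_csv(p)
    else:
        table = pd.read_csv(path)
    return table.set_index("section")


def _vtrap(x: np.ndarray) -> np.ndarray:
    """x / (1 - exp(-x)) with the removable singularity at x = 0 handled
    by a 3-term Taylor expansion for |x| < 1e-4."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    small = np.abs(x) < 1e-4
    xs = x[small]
    out[small] = 1.0 + xs / 2.0 + xs * xs / 12.0
    xb = x[~small]
    out[~small] = xb / (1.0 - np.exp(-xb))
    return out


def nernst_eca(ca_i_um, ca_e_um: float = 1800.0) -> np.ndarray | float:
    """Divalent Nernst potential for calcium, in mV.

    E_Ca = (RT/2F)·ln([Ca]_e/[Ca]_i) with R = 8.31 J/(K·mol),
    T = 296.15 K, F = 9.6485e4 C/mol.  Strictly decreasing in [Ca]_i.
    """
    ca = np.asarray(ca_i_um, dtype=float)
    if np.any(ca <= 0):
        raise StateError("E_Ca undefined for non-positive [Ca]_i")
    e = NERNST_CA_MV * np.log(ca_e_um / ca)
    return float(e) if np.isscalar(ca_i_um) else e


# ----------------------------------------------------------------------
# Bipolar cell
# ----------------------------------------------------------------------

@dataclass
class BCParams:
    """Bipolar-cell membrane parameters (densities in mS/cm²)."""

    e_l_mv: float = -60.0           # leak reversal = resting potential
    ca_e_um: float = 1800.0
    ca_res_um: float = 0.1          # residual (resting) calcium
    shell_depth_nm: float = 50.0    # submembrane shell for [Ca]_i
    tau_ca_ms: float = 50.0         # calcium extrusion time constant
    tau_h_ms: float = 292.0         # L-type inactivation time constant
    act_tau_scale: float = 1.0      # multiplies tau_m pointwise
    density_table_path: str | None = None

    def densities(self) -> pd.DataFrame:
        return load_density_table("BC", self.density_table_path)


def bc_gating_rates(v_mv, act_tau_scale: float = 1.0):
    """L-type calcium channel gating: (α_m, β_m, h∞, τ_h).

    α_m = 0.21(V+5)/(1 − exp(−(V+5)/10.5)) ms⁻¹,
    β_m = 0.02·exp((12 − V)/12) ms⁻¹,
    h∞ = 1/(1 + exp((V+55)/66.4)),  τ_h = 292 ms.

    ``act_tau_scale`` scales the activation time constant
    τ_m = 1/(α_m+β_m) pointwise (both rates divided by the scale),
    leaving m∞ unchanged — used for the chronaxie sensitivity analysis.
    """
    v = np.asarray(v_mv, dtype=float)
    alpha_m = 0.21 * 10.5 * _vtrap((v + 5.0) / 10.5)
    beta_m = 0.02 * np.exp((12.0 - v) / 12.0)
    h_inf = 1.0 / (1.0 + np.exp((v + 55.0) / 66.4))
    tau_h = np.full_like(v, 292.0)
    return (alpha_m / act_tau_scale, beta_m / act_tau_scale, h_inf, tau_h)


def bc_ionic_current(v_mv, m, h, ca_i_um, section: str,
                     params: BCParams | None = None) -> dict:
    """Per-species current densities in mA/cm² for one section label."""
    p = params or BCParams()
    table = p.densities()
    if section not in table.index:
        raise ConfigError(f"unknown BC section {section!r}")
    g_ca = float(table.loc[section, "g_ca"])
    g_l = float(table.loc[section, "g_l"])
    i_l = g_l * (np.asarray(v_mv) - p.e_l_mv) * 1e-3
    if g_ca > 0:
        e_ca = nernst_eca(ca_i_um, p.ca_e_um)
        i_cal = g_ca * np.asarray(m) ** 2 * np.asarray(h) \
            * (np.asarray(v_mv) - e_ca) * 1e-3
    else:
        i_cal = np.zeros_like(np.asarray(v_mv, dtype=float))
    return {"i_cal": i_cal, "i_l": i_l, "i_total": i_cal + i_l}


def step_bc_calcium(ca_i_um, i_ca_ma_cm2, dt_ms, params: BCParams | None = None):
    """Advance the submembrane calcium concentration by one step.

    d[Ca]/dt = −i_Ca/(2F·d) − ([Ca] − [Ca]_res)/τ.  The update is the
    exact exponential solution for a piecewise-constant current, so with
    i_Ca = 0 the concentration relaxes to [Ca]_res with τ exactly, and a
    constant current settles at [Ca]_res − i_Ca·τ/(2F·d).
    """
    p = params or BCParams()
    factor = ca_flux_factor(p.shell_depth_nm)
    ca_inf = p.ca_res_um - np.asarray(i_ca_ma_cm2) * p.tau_ca_ms * factor
    decay = np.exp(-dt_ms / p.tau_ca_ms)
    return ca_inf + (np.asarray(ca_i_um) - ca_inf) * decay


class BCMechanism:
    """Stateful BC membrane model bound to a morphology.

    State arrays (per compartment): activation gate ``m``, inactivation
    gate ``h``, submembrane calcium ``ca`` (µM).  Gates use exact
    exponential (Rush–Larsen) updates; calcium uses the closed-form
    update of :func:`step_bc_calcium`.
    """

    cell_kind = "BC"

    def __init__(self, graph: CompartmentGraph, params: BCParams | None = None):
        self.params = params or BCParams()
        self.graph = graph
        table = self.params.densities()
        try:
            self.g_ca = np.array([float(table.loc[s, "g_ca"])
                                  for s in graph.sections])
            self.g_l = np.array([float(table.loc[s, "g_l"])
                                 for s in graph.sections])
        except KeyError as exc:
            raise ConfigError(f"section {exc} missing from density table")
        self.v_rest = self.params.e_l_mv

    def init_state(self) -> dict:
        p = self.params
        v = np.full(self.graph.n_compartments, self.v_rest)
        am, bm, h_inf, _ = bc_gating_rates(v, p.act_tau_scale)
        m = am / (am + bm)
        h = h_inf.copy()
        # resting calcium: fixed point of influx vs extrusion
        ca = np.full(self.graph.n_compartments, p.ca_res_um)
        factor = ca_flux_factor(p.shell_depth_nm)
        for _ in range(50):
            i_ca = self.g_ca * m ** 2 * h * (v - nernst_eca(ca, p.ca_e_um)) * 1e-3
            ca_new = p.ca_res_um - i_ca * p.tau_ca_ms * factor
            if np.max(np.abs(ca_new - ca)) < 1e-12:
                ca = ca_new
                break
            ca = ca_new
        return {"v": v, "m": m, "h": h, "ca": ca,
                "i_ca": np.zeros_like(v)}

    def advance_gates(self, state: dict, v: np.ndarray, dt_ms: float) -> None:
        p = self.params
        am, bm, h_inf, tau_h = bc_gating_rates(v, p.act_tau_scale)
        tau_m = 1.0 / (am + bm)
        m_inf = am * tau_m
        state["m"] = m_inf + (state["m"] - m_inf) * np.exp(-dt_ms / tau_m)
        state["h"] = h_inf + (state["h"] - h_inf) * np.exp(-dt_ms / tau_h)

    def linearized(self, state: dict):
        """Return (G, b) densities such that I_ion ≈ G·V − b, with G in
        mS/cm² and b in mS/cm²·mV (gates and E_Ca lagged one step)."""
        p = self.params
        e_ca = nernst_eca(state["ca"], p.ca_e_um)
        g_cal = self.g_ca * state["m"] ** 2 * state["h"]
        g_total = g_cal + self.g_l
        b = g_cal * e_ca + self.g_l * p.e_l_mv
        return g_total, b

    def advance_calcium(self, state: dict, v_new: np.ndarray,
                        dt_ms: float) -> None:
        p = self.params
        e_ca = nernst_eca(state["ca"], p.ca_e_um)
        i_ca = self.g_ca * state["m"] ** 2 * state["h"] * (v_new - e_ca) * 1e-3
        state["i_ca"] = i_ca
        # positivity floor: the continuous equation self-limits through the
        # diverging Nernst potential, but the discrete update can overshoot
        # when V far exceeds E_Ca (outward calcium current)
        state["ca"] = np.maximum(step_bc_calcium(state["ca"], i_ca, dt_ms, p),
                                 1e-4)


# ----------------------------------------------------------------------
# Retinal ganglion cell
# ----------------------------------------------------------------------

@dataclass
class RGCParams:
    """RGC membrane parameters (Fohlmeister-type kinetics).

    The rate functions below are the standard published forms; the
    source only cites them, so they are exposed here explicitly.  E_L is
    solved per section at initialization so that every section rests at
    ``v_rest_mv`` exactly.
    """

    v_rest_mv: float = -65.0
    e_na_mv: float = 35.0
    e_k_mv: float = -75.0
    ca_e_um: float = 1800.0
    ca_res_um: float = 0.1
    ca_diss_um: float = 1.0         # K_Ca half-activation
    shell_depth_nm: float = 50.0
    tau_ca_ms: float = 50.0
    density_table_path: str | None = None

    def densities(self) -> pd.DataFrame:
        return load_density_table("RGC", self.density_table_path)


def rgc_gating_rates(v_mv) -> dict:
    """α/β for the Na (m, h), K (n) and Ca (c) gates, ms⁻¹."""
    v = np.asarray(v_mv, dtype=float)
    return {
        "m": (6.0 * _vtrap(0.1 * (v + 30.0)),
              20.0 * np.exp(-(v + 55.0) / 18.0)),
        "h": (0.4 * np.exp(-(v + 50.0) / 20.0),
              6.0 / (1.0 + np.exp(-0.1 * (v + 20.0)))),
        "n": (0.2 * _vtrap(0.1 * (v + 40.0)),
              0.4 * np.exp(-(v + 50.0) / 80.0)),
        "c": (3.0 * _vtrap(0.1 * (v + 13.0)),
              10.0 * np.exp(-(v + 38.0) / 18.0)),
    }


def rgc_rates_and_currents(v_mv, gates: dict, ca_i_um, section: str,
                           params: RGCParams | None = None,
                           e_l_mv: float | None = None) -> tuple[dict, dict]:
    """Gate time derivatives and per-species current densities (mA/cm²)
    for one section label.

    i_Na = g_Na·m³·h·(V−E_Na); i_K = g_K·n⁴·(V−E_K);
    i_Ca = g_Ca·c³·(V−E_Ca); i_KCa = g_KCa·x²/(1+x²)·(V−E_K) with
    x = [Ca]_i/Ca_diss; i_L = g_L·(V−E_L).
    """
    p = params or RGCParams()
    table = p.densities()
    if section not in table.index:
        raise ConfigError(f"unknown RGC section {section!r}")
    row = table.loc[section]
    v = np.asarray(v_mv, dtype=float)
    rates = rgc_gating_rates(v)
    derivs = {g: a * (1.0 - gates[g]) - b * gates[g]
              for g, (a, b) in rates.items()}
    m, h, n, c = (np.asarray(gates[g]) for g in "mhnc")
    x2 = (np.asarray(ca_i_um) / p.ca_diss_um) ** 2
    e_ca = nernst_eca(ca_i_um, p.ca_e_um)
    e_l = p.v_rest_mv if e_l_mv is None else e_l_mv
    cur = {
        "i_na": row["g_na"] * m ** 3 * h * (v - p.e_na_mv) * 1e-3,
        "i_k": row["g_k"] * n ** 4 * (v - p.e_k_mv) * 1e-3,
        "i_ca": row["g_ca"] * c ** 3 * (v - e_ca) * 1e-3,
        "i_kca": row["g_kca"] * x2 / (1.0 + x2) * (v - p.e_k_mv) * 1e-3,
        "i_l": row["g_l"] * (v - e_l) * 1e-3,
    }
    cur["i_total"] = sum(cur.values())
    return derivs, cur


class RGCMechanism:
    """Stateful five-channel RGC membrane model bound to a morphology."""

    cell_kind = "RGC"

    def __init__(self, graph: CompartmentGraph,
                 params: RGCParams | None = None):
        self.params = params or RGCParams()
        self.graph = graph
        table = self.params.densities()
        try:
            dens = {c: np.array([float(table.loc[s, c])
                                 for s in graph.sections])
                    for c in ("g_na", "g_k", "g_ca", "g_kca", "g_l")}
        except KeyError as exc:
            raise ConfigError(f"section {exc} missing from density table")
        self.dens = dens
        self.v_rest = self.params.v_rest_mv
        self.e_l = self._solve_leak_reversal()

    def _steady_gates(self, v: np.ndarray) -> dict:
        rates = rgc_gating_rates(v)
        return {g: a / (a + b) for g, (a, b) in rates.items()}

    def _solve_leak_reversal(self) -> np.ndarray:
        """Per-compartment E_L such that the whole cell rests exactly at
        v_rest (uniform rest ⇒ no axial currents ⇒ true steady state)."""
        p = self.params
        v = np.full(self.graph.n_compartments, p.v_rest_mv)
        g = self._steady_gates(v)
        ca = np.full_like(v, p.ca_res_um)
        e_ca = nernst_eca(ca, p.ca_e_um)
        x2 = (ca / p.ca_diss_um) ** 2
        i_other = (self.dens["g_na"] * g["m"] ** 3 * g["h"] * (v - p.e_na_mv)
                   + self.dens["g_k"] * g["n"] ** 4 * (v - p.e_k_mv)
                   + self.dens["g_ca"] * g["c"] ** 3 * (v - e_ca)
                   + self.dens["g_kca"] * x2 / (1 + x2) * (v - p.e_k_mv))
        return v + i_other / self.dens["g_l"]

    def init_state(self) -> dict:
        v = np.full(self.graph.n_compartments, self.v_rest)
        state = {"v": v.copy(), "ca": np.full_like(v, self.params.ca_res_um),
                 "i_ca": np.zeros_like(v)}
        state.update(self._steady_gates(v))
        return state

    def advance_gates(self, state: dict, v: np.ndarray, dt_ms: float) -> None:
        rates = rgc_gating_rates(v)
        for gname, (a, b) in rates.items():
            tau = 1.0 / (a + b)
            inf = a * tau
            state[gname] = inf + (state[gname] - inf) * np.exp(-dt_ms / tau)

    def linearized(self, state: dict):
        p = self.params
        e_ca = nernst_eca(state["ca"], p.ca_e_um)
        x2 = (state["ca"] / p.ca_diss_um) ** 2
        g_na = self.dens["g_na"] * state["m"] ** 3 * state["h"]
        g_k = self.dens["g_k"] * state["n"] ** 4
        g_ca = self.dens["g_ca"] * state["c"] ** 3
        g_kca = self.dens["g_kca"] * x2 / (1.0 + x2)
        g_l = self.dens["g_l"]
        g_total = g_na + g_k + g_ca + g_kca + g_l
        b = (g_na * p.e_na_mv + (g_k + g_kca) * p.e_k_mv + g_ca * e_ca
             + g_l * self.e_l)
        return g_total, b

    def advance_calcium(self, state: dict, v_new: np.ndarray,
                        dt_ms: float) -> None:
        p = self.params
        e_ca = nernst_eca(state["ca"], p.ca_e_um)
        i_ca = self.dens["g_ca"] * state["c"] ** 3 * (v_new - e_ca) * 1e-3
        state["i_ca"] = i_ca
        factor = ca_flux_factor(p.shell_depth_nm)
        ca_inf = p.ca_res_um - i_ca * p.tau_ca_ms * factor
        decay = np.exp(-dt_ms / p.tau_ca_ms)
        state["ca"] = np.maximum(ca_inf + (state["ca"] - ca_inf) * decay, 1e-4)


def voltage_clamp_ca_trace(params: BCParams | None = None,
                           v_hold_mv: float = -60.0, v_step_mv: float = -10.0,
                           total_ms: float = 2000.0, dt_ms: float = 0.025,
                           g_ca_ms_cm2: float | None = None):
    """Terminal calcium trajectory under a somatic-independent voltage
    clamp of the synaptic terminals (hold → step at t = 0).

    Because the terminals are clamped, the cable plays no role and the
    L-type gating + calcium shell can be integrated directly.  Returns
    (t_ms, ca_um, i_ca_ma_cm2) on the solver grid — the drive for the
    ribbon-synapse calibration protocol.
    """
    p = params or BCParams()
    if g_ca_ms_cm2 is None:
        g_ca_ms_cm2 = float(p.densities().loc["terminal", "g_ca"])
    n = int(round(total_ms / dt_ms))
    t = np.arange(n + 1) * dt_ms

    am, bm, h_inf, tau_h = bc_gating_rates(v_hold_mv, p.act_tau_scale)
    m = float(am / (am + bm))
    h = float(h_inf)
    ca = p.ca_res_um
    factor = ca_flux_factor(p.shell_depth_nm)
    for _ in range(50):  # resting fixed point at the holding potential
        i_ca = g_ca_ms_cm2 * m ** 2 * h * (v_hold_mv - nernst_eca(ca, p.ca_e_um)) * 1e-3
        ca_new = p.ca_res_um - i_ca * p.tau_ca_ms * factor
        if abs(ca_new - ca) < 1e-12:
            break
        ca = ca_new

    am, bm, h_inf, tau_h = bc_gating_rates(v_step_mv, p.act_tau_scale)
    tau_m = 1.0 / (am + bm)
    m_inf = float(am * tau_m)
    em = float(np.exp(-dt_ms / tau_m))
    eh = float(np.exp(-dt_ms / tau_h))
    h_inf = float(h_inf)
    decay = np.exp(-dt_ms / p.tau_ca_ms)

    ca_out = np.empty(n + 1)
    ica_out = np.empty(n + 1)
    ca_out[0] = ca
    ica_out[0] = 0.0
    for k in range(n):
        m = m_inf + (m - m_inf) * em
        h = h_inf + (h - h_inf) * eh
        i_ca = g_ca_ms_cm2 * m ** 2 * h * (v_step_mv - nernst_eca(ca, p.ca_e_um)) * 1e-3
        ca_inf = p.ca_res_um - i_ca * p.tau_ca_ms * factor
        ca = max(ca_inf + (ca - ca_inf) * decay, 1e-4)
        ca_out[k + 1] = ca
        ica_out[k + 1] = i_ca
    return t, ca_out, ica_out


def make_mechanism(graph: CompartmentGraph, params=None):
    """Mechanism factory keyed on the morphology's cell kind."""
    if graph.cell_kind == "BC":
        return BCMechanism(graph, params)
    return RGCMechanism(graph, params)
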