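"""Stochastic two-pool ribbon-synapse vesicle release.

Each bipolar cell carries 8 synaptic terminals with 10 ribbon synapses
each (80 synapses); every synapse has 6 release sites of 5 vesicle rows
(30 releasable vesicles).  Row 1 holds the docked/primed vesicles (the
*fast pool*, 6 per synapse); rows 2–5 hold the *slow pool* (24 per
synapse).  The terminal's submembrane calcium concentration is converted
to instantaneous release rate constants through a cooperative (Hill)
sensor; the fast-pool rate exceeds the slow-pool rate by a fixed factor
of 40 at every calcium level (the two pools share one calcium sensor at
one shell depth and differ only in rate amplitude).  Release is applied
independently and stochastically to every occupied site each solver
step; vacant slots refill from an unlimited reserve with a 1 s time
constant (0.5 s in the grating protocols), and a vacated docked slot is
re-primed by row advance from the nearest occupied row at the same
refill time constant.

Release is rectified by construction — the rate is never negative — and
vesicle bookkeeping is exactly conservative per synapse.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.optimize import brentq

from .errors import CalibrationError, ConfigError
from .mechanisms import BCParams, voltage_clamp_ca_trace
from .units import DT_MS


@dataclass
class ReleaseParams:
    """Ribbon-synapse population geometry and rate parameters.

    ``a_fast_per_ms`` is the saturating fast-pool rate constant produced
    by :func:`calibrate` (factory calibration against the depolarization
    clamp anchors); ``kd_um``/``hill_n`` define the calcium sensor.
    ``advance`` selects how a vacated docked slot is re-primed from the
    upper rows: at the refill time constant (default) or instantly.
    """

    a_fast_per_ms: float = 0.7596
    kd_um: float = 60.0
    hill_n: float = 2.0
    slow_sensor: str = "independent"   # "independent" | "shared"
    a_slow_per_ms: float = 0.008
    slow_kd_um: float = 300.0
    slow_hill_n: float = 2.0
    fast_slow_ratio: float = 40.0      # k_fast/k_slow in "shared" mode
    refill_tau_ms: float = 1000.0
    advance: str = "refill"            # "refill" | "instant"
    n_terminals: int = 8
    synapses_per_terminal: int = 10
    release_sites: int = 6
    rows: int = 5

    def __post_init__(self):
        if self.advance not in ("refill", "instant"):
            raise ConfigError("advance must be 'refill' or 'instant'")
        if self.slow_sensor not in ("independent", "shared"):
            raise ConfigError("slow_sensor must be 'independent' or 'shared'")
        if min(self.a_fast_per_ms, self.kd_um, self.hill_n,
               self.a_slow_per_ms, self.slow_kd_um, self.slow_hill_n,
               self.fast_slow_ratio, self.refill_tau_ms) <= 0:
            raise ConfigError("rate parameters must be positive")

    @property
    def n_synapses(self) -> int:
        return self.n_terminals * self.synapses_per_terminal

    @property
    def vesicles_per_synapse(self) -> int:
        return self.release_sites * self.rows


def release_rate_constants(ca_um, params: ReleaseParams | None = None):
    """(k_fast, k_slow) in ms⁻¹ for a calcium concentration in µM.

    Each pool has a saturating (Hill) calcium sensor
    k = A·Ca^n/(K_d^n + Ca^n).  By default the docked pool uses a
    cooperative high-affinity sensor (n = 4, K_d = 20 µM) and the slow
    pool a shallow low-affinity one (n = 2, K_d = 300 µM), so the slow
    pool stays nearly inert at pulse-train calcium levels while the
    docked pool already responds near threshold.  With
    ``slow_sensor="shared"`` both pools share the fast sensor and
    k_slow = k_fast/40 at every calcium level.  Both rates are monotone
    nondecreasing in calcium and negligible (< 1e-4 ms⁻¹) at the 0.1 µM
    resting level.
    """
    p = params or ReleaseParams()
    ca = np.asarray(ca_um, dtype=float)
    if np.any(ca < 0):
        raise ConfigError("calcium concentration must be >= 0")
    x = (ca / p.kd_um) ** p.hill_n
    k_fast = p.a_fast_per_ms * x / (1.0 + x)
    if p.slow_sensor == "shared":
        return k_fast, k_fast / p.fast_slow_ratio
    xs = (ca / p.slow_kd_um) ** p.slow_hill_n
    return k_fast, p.a_slow_per_ms * xs / (1.0 + xs)


class SynapsePopulation:
    """State of the 80-ribbon-synapse population (optionally batched
    over independent repetitions for Monte-Carlo averaging).

    All slots start occupied unless ``start_empty``.  One vectorized RNG
    stream (spawned from ``seed``) drives the whole population; runs are
    bit-reproducible for a fixed seed.

    Sampling is event-driven and exact for piecewise-constant rates:
    each occupied slot carries a release threshold on the integrated
    fast-pool hazard H(t) = ∫ k_fast dt (slow-pool slots scale their
    unit-rate exponential by the fixed fast/slow ratio), and each vacant
    slot carries an absolute reserve-refill time.  Per-synapse minima of
    both schedules let quiet steps cost O(n_synapses) instead of
    O(n_slots).
    """

    def __init__(self, params: ReleaseParams | None = None, seed: int = 0,
                 n_reps: int = 1, record_events: bool = False,
                 start_empty: bool = False):
        self.params = params or ReleaseParams()
        p = self.params
        self.n_reps = n_reps
        self.rng = np.random.default_rng(np.random.SeedSequence(seed))
        shape = (n_reps, p.n_synapses, p.release_sites, p.rows)
        self.occ = np.full(shape, not start_empty, dtype=bool)
        self.t_ms = 0.0
        self._h_fast = np.zeros(p.n_synapses)
        self._h_slow = np.zeros(p.n_synapses)
        self._release_h = np.full(shape, np.inf)
        self.refill_at = np.full(shape, np.inf)
        if start_empty:
            self.refill_at[:] = self.rng.exponential(
                p.refill_tau_ms, size=shape)
        else:
            self._release_h[:] = self.rng.exponential(1.0, size=shape)
        self._min_rel0 = self._release_h[..., 0].min(axis=2)
        self._min_rel1 = self._release_h[..., 1:].min(axis=(2, 3))
        self._min_ref = self.refill_at.min(axis=(2, 3))
        self.syn_terminal = np.repeat(np.arange(p.n_terminals),
                                      p.synapses_per_terminal)
        self.released = np.zeros((n_reps, p.n_synapses), dtype=np.int64)
        self.refilled = np.zeros((n_reps, p.n_synapses), dtype=np.int64)
        slots = p.n_synapses * p.release_sites * p.rows
        self._n_occ = self.occ.sum(axis=(1, 2, 3)).astype(np.int64)
        self._n_fast = self.occ[..., 0].sum(axis=(1, 2)).astype(np.int64)
        self._slots = slots
        self._fast_slots = p.n_synapses * p.release_sites
        self.record_events = record_events and n_reps == 1
        self.events: list[tuple[float, int, str]] = []

    # -- observables -----------------------------------------------------

    @property
    def occupancy_fraction(self) -> np.ndarray:
        """Mean slot occupancy per repetition."""
        return self._n_occ / self._slots

    @property
    def fast_pool_occupancy(self) -> np.ndarray:
        """Mean docked-row occupancy per repetition."""
        return self._n_fast / self._fast_slots

    # -- dynamics --------------------------------------------------------

    def _advance_rows(self, ri, si, t_new):
        """Row advance for the selected synapses: any vacant docked slot
        takes the nearest occupied upper-row vesicle."""
        p = self.params
        occ = self.occ[ri, si]                       # (K, sites, rows) copy
        adv = (~occ[..., 0]) & occ[..., 1:].any(axis=-1)
        if not adv.any():
            return
        nearest = np.argmax(occ[..., 1:], axis=-1)
        one_hot = (np.arange(p.rows - 1) == nearest[..., None]) & adv[..., None]
        occ[..., 1:] &= ~one_hot
        occ[..., 0] |= adv
        self.occ[ri, si] = occ
        rel_h = self._release_h[ri, si]
        ref_at = self.refill_at[ri, si]
        rel_h[..., 1:][one_hot] = np.inf
        ref_at[..., 1:][one_hot] = t_new + self.rng.exponential(
            p.refill_tau_ms, size=int(one_hot.sum()))
        hs = np.broadcast_to(self._h_fast[si][:, None], adv.shape)[adv]
        rel_h[..., 0][adv] = hs + self.rng.exponential(1.0, size=int(adv.sum()))
        ref_at[..., 0][adv] = np.inf
        self._release_h[ri, si] = rel_h
        self.refill_at[ri, si] = ref_at
        np.add.at(self._n_fast, ri, adv.sum(axis=(1, 2))
                  if adv.ndim == 3 else adv.sum(axis=1))

    def step(self, ca_per_terminal, dt_ms: float):
        """Advance one time step; returns (n_fast, n_slow) released per
        repetition.  ``ca_per_terminal`` is scalar or (n_terminals,) µM."""
        p = self.params
        ca = np.broadcast_to(np.asarray(ca_per_terminal, dtype=float),
                             (p.n_terminals,))
        k_f, k_s = release_rate_constants(ca[self.syn_terminal], p)
        t_new = self.t_ms + dt_ms
        self._h_fast = self._h_fast + k_f * dt_ms
        self._h_slow = self._h_slow + k_s * dt_ms
        h_f, h_s = self._h_fast, self._h_slow
        n_fast = np.zeros(self.n_reps, dtype=np.int64)
        n_slow = np.zeros(self.n_reps, dtype=np.int64)
        touched = None

        ri, si = np.nonzero((self._min_rel0 <= h_f[None, :])
                            | (self._min_rel1 <= h_s[None, :]))
        if ri.size:
            rel = self._release_h[ri, si] <= h_s[si][:, None, None]
            rel[..., 0] = self._release_h[ri, si, :, 0] <= h_f[si][:, None]
            occ = self.occ[ri, si]
            rel &= occ
            occ &= ~rel
            self.occ[ri, si] = occ
            rel_h = self._release_h[ri, si]
            ref_at = self.refill_at[ri, si]
            rel_h[rel] = np.inf
            ref_at[rel] = t_new + self.rng.exponential(
                p.refill_tau_ms, size=int(rel.sum()))
            self._release_h[ri, si] = rel_h
            self.refill_at[ri, si] = ref_at
            nf = rel[..., 0].sum(axis=1)
            nt = rel.sum(axis=(1, 2))
            np.add.at(n_fast, ri, nf)
            np.add.at(n_slow, ri, nt - nf)
            np.add.at(self.released, (ri, si), nt)
            self._n_occ -= np.bincount(ri, weights=nt,
                                       minlength=self.n_reps).astype(np.int64)
            self._n_fast -= np.bincount(ri, weights=nf,
                                        minlength=self.n_reps).astype(np.int64)
            if self.record_events:
                for j, site, row in np.argwhere(rel):
                    self.events.append((t_new, int(si[j]),
                                        "fast" if row == 0 else "slow"))
            touched = (ri, si)

        di, dj = np.nonzero(self._min_ref <= t_new)
        if di.size:
            ref_at = self.refill_at[di, dj]
            due = ref_at <= t_new
            occ = self.occ[di, dj]
            rel_h = self._release_h[di, dj]
            n_due = due.sum(axis=(1, 2))
            reserve = n_due.copy()
            if p.advance == "refill":
                # a due docked slot takes the nearest occupied upper-row
                # vesicle (row advance) and spares the reserve
                adv = due[..., 0] & occ[..., 1:].any(axis=-1)
                if adv.any():
                    nearest = np.argmax(occ[..., 1:], axis=-1)
                    one_hot = ((np.arange(p.rows - 1) == nearest[..., None])
                               & adv[..., None])
                    occ[..., 1:] &= ~one_hot
                    rel_h[..., 1:][one_hot] = np.inf
                    ref_at[..., 1:][one_hot] = t_new + self.rng.exponential(
                        p.refill_tau_ms, size=int(one_hot.sum()))
                    reserve = reserve - adv.sum(axis=(1, 2)).astype(np.int64) \
                        if adv.ndim == 3 else reserve - adv.sum(axis=1)
            occ |= due
            ref_at[due] = np.inf
            rows = np.broadcast_to(np.arange(p.rows), due.shape)[due]
            hf = np.broadcast_to(h_f[dj][:, None, None], due.shape)[due]
            hsl = np.broadcast_to(h_s[dj][:, None, None], due.shape)[due]
            base = np.where(rows == 0, hf, hsl)
            rel_h[due] = base + self.rng.exponential(1.0, size=int(due.sum()))
            self.occ[di, dj] = occ
            self.refill_at[di, dj] = ref_at
            self._release_h[di, dj] = rel_h
            np.add.at(self.refilled, (di, dj), reserve)
            # net occupancy gain excludes row-advance moves (they vacate
            # an upper slot for every docked slot they fill)
            self._n_occ += np.bincount(di, weights=reserve,
                                       minlength=self.n_reps).astype(np.int64)
            nf_due = due[..., 0].sum(axis=1)
            self._n_fast += np.bincount(di, weights=nf_due,
                                        minlength=self.n_reps).astype(np.int64)
            if touched is None:
                touched = (di, dj)
            else:
                touched = (np.concatenate([touched[0], di]),
                           np.concatenate([touched[1], dj]))

        if touched is not None:
            lin = np.unique(touched[0] * p.n_synapses + touched[1])
            ri, si = np.divmod(lin, p.n_synapses)
            if p.advance == "instant":
                self._advance_rows(ri, si, t_new)
            self._min_rel0[ri, si] = self._release_h[ri, si, :, 0].min(axis=1)
            self._min_rel1[ri, si] = self._release_h[ri, si][..., 1:].min(
                axis=(1, 2))
            self._min_ref[ri, si] = self.refill_at[ri, si].min(axis=(1, 2))

        self.t_ms = t_new
        return n_fast, n_slow


@dataclass
class ReleaseRecord:
    """Logged release time series (per repetition).

    ``counts_fast``/``counts_slow`` hold population release counts per
    solver step; occupancy series are population means.  Rates derived
    here are per terminal (vesicles/ms/terminal) unless noted.
    """

    dt_ms: float
    counts_fast: np.ndarray        # (n_reps, n_steps)
    counts_slow: np.ndarray
    occupancy: np.ndarray          # (n_reps, n_steps)
    fast_occupancy: np.ndarray
    n_terminals: int
    events: list = field(default_factory=list)

    @property
    def t_ms(self) -> np.ndarray:
        return (np.arange(self.counts_fast.shape[1]) + 1) * self.dt_ms

    @property
    def counts(self) -> np.ndarray:
        return self.counts_fast + self.counts_slow

    def binned_rate(self, bin_ms: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
        """Boxcar-binned mean release rate (vesicles/ms/terminal),
        averaged across repetitions: (bin_centers, rate)."""
        c = self.counts.mean(axis=0)
        per_bin = max(1, int(round(bin_ms / self.dt_ms)))
        n_bins = c.size // per_bin
        binned = c[:n_bins * per_bin].reshape(n_bins, per_bin).sum(axis=1)
        rate = binned / (per_bin * self.dt_ms) / self.n_terminals
        centers = (np.arange(n_bins) + 0.5) * per_bin * self.dt_ms
        return centers, rate

    def mean_rate(self, t0_ms: float, t1_ms: float) -> float:
        """Mean release rate (vesicles/ms/terminal) over a window,
        averaged across repetitions."""
        t = self.t_ms
        mask = (t > t0_ms) & (t <= t1_ms)
        total = self.counts[:, mask].sum(axis=1).mean()
        return float(total / (t1_ms - t0_ms) / self.n_terminals)

    def total_released(self, t0_ms: float = 0.0,
                       t1_ms: float | None = None) -> np.ndarray:
        """Vesicles released per repetition in [t0, t1] (whole cell)."""
        t = self.t_ms
        t1 = t[-1] if t1_ms is None else t1_ms
        mask = (t > t0_ms) & (t <= t1)
        return self.counts[:, mask].sum(axis=1)

    def export_events_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("time_ms\tterminal\tsynapse\tpool\n")
            for t, syn, pool in self.events:
                fh.write(f"{t:.3f}\t{syn // 10}\t{syn}\t{pool}\n")


def run_release(ca_trace, dt_ms: float = DT_MS,
                params: ReleaseParams | None = None, n_reps: int = 20,
                seed: int = 0, record_events: bool = False,
                start_empty: bool = False) -> ReleaseRecord:
    """Drive the stochastic release model with a calcium trajectory.

    ``ca_trace``: (n_steps, n_terminals) or (n_steps,) µM — the calcium
    level during each solver step.
    """
    p = params or ReleaseParams()
    ca = np.asarray(ca_trace, dtype=float)
    if ca.ndim == 1:
        ca = ca[:, None]
    n_steps = ca.shape[0]
    pop = SynapsePopulation(p, seed=seed, n_reps=n_reps,
                            record_events=record_events,
                            start_empty=start_empty)
    cf = np.empty((n_reps, n_steps), dtype=np.int64)
    cs = np.empty((n_reps, n_steps), dtype=np.int64)
    occ = np.empty((n_reps, n_steps))
    focc = np.empty((n_reps, n_steps))
    for k in range(n_steps):
        nf, ns = pop.step(ca[k, :] if ca.shape[1] > 1 else float(ca[k, 0]),
                          dt_ms)
        cf[:, k] = nf
        cs[:, k] = ns
        occ[:, k] = pop.occupancy_fraction
        focc[:, k] = pop.fast_pool_occupancy
    return ReleaseRecord(dt_ms=dt_ms, counts_fast=cf, counts_slow=cs,
                         occupancy=occ, fast_occupancy=focc,
                         n_terminals=p.n_terminals, events=pop.events)


# ----------------------------------------------------------------------
# calibration against the depolarization-clamp anchors
# ----------------------------------------------------------------------

@dataclass
class CalibrationResult:
    params: ReleaseParams
    achieved: dict
    targets: dict
    converged: bool

    def to_json(self, path=None) -> str:
        payload = {"params": asdict(self.params), "achieved": self.achieved,
                   "targets": self.targets, "converged": self.converged}
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def clamp_release_metrics(params: ReleaseParams, n_seeds: int = 20,
                          seed: int = 0, total_ms: float = 2000.0,
                          dt_ms: float = DT_MS,
                          sustained_window_ms=(500.0, 2000.0),
                          bc_params: BCParams | None = None,
                          ca_trace: np.ndarray | None = None) -> dict:
    """Run the −60 → −10 mV terminal-clamp protocol and summarize it.

    Returns sustained rate (vesicles/ms/terminal over the window),
    fast-pool depletion time (ms to < 10 % docked occupancy, averaged
    over synapses and seeds) and the peak(1 ms bins, first 20 ms) to
    sustained release-rate ratio.
    """
    if ca_trace is None:
        _, ca_trace, _ = voltage_clamp_ca_trace(bc_params, total_ms=total_ms,
                                                dt_ms=dt_ms)
    rec = run_release(ca_trace[1:], dt_ms, params, n_reps=n_seeds, seed=seed)
    sustained = rec.mean_rate(*sustained_window_ms)
    focc = rec.fast_occupancy.mean(axis=0)
    below = np.flatnonzero(focc < 0.10)
    depletion = float((below[0] + 1) * dt_ms) if below.size else float("inf")
    centers, rate = rec.binned_rate(1.0)
    peak = float(rate[centers <= 20.0].max())
    ratio = peak / sustained if sustained > 0 else float("inf")
    return {"sustained_per_ms_per_terminal": float(sustained),
            "depletion_ms": depletion,
            "peak_rate_per_ms_per_terminal": peak,
            "peak_to_sustained_ratio": float(ratio)}


def calibrate(target_sustained: float = 0.5,
              target_depletion_ms: float = 20.0,
              target_peak_ratio: float = 50.0,
              base_params: ReleaseParams | None = None,
              bc_params: BCParams | None = None,
              n_seeds: int = 20, search_seeds: int = 6, seed: int = 0,
              total_ms: float = 2000.0,
              raise_on_miss: bool = False) -> CalibrationResult:
    """Fit the fast-pool rate amplitude to the depolarization-clamp
    anchors (−60 → −10 mV step).

    The anchors are: the fast pool empties within ``target_depletion_ms``
    (a bound), the transient/sustained release ratio is
    ``target_peak_ratio`` (~50×), and the sustained rate approaches
    ``target_sustained``.  Because the sustained rate is capped by the
    reserve refill (30 slots/τ ≈ 0.3 vesicles/ms/terminal) and is nearly
    flat in the rate amplitude, A_fast is solved by root-finding on the
    peak/sustained ratio, then checked against the depletion bound; the
    achieved sustained rate is reported.  With ``raise_on_miss`` a
    :class:`CalibrationError` (carrying the achieved values) is raised
    when any anchor is out of tolerance; by default the result records
    ``converged=False`` instead.
    """
    base = base_params or ReleaseParams()
    _, ca_trace, _ = voltage_clamp_ca_trace(bc_params, total_ms=total_ms)

    def with_a(a):
        kw = asdict(base)
        kw["a_fast_per_ms"] = a
        return ReleaseParams(**kw)

    def ratio_err(a):
        m = clamp_release_metrics(with_a(a), n_seeds=search_seeds, seed=seed,
                                  total_ms=total_ms, ca_trace=ca_trace)
        return m["peak_to_sustained_ratio"] - target_peak_ratio

    try:
        a_fit = brentq(ratio_err, 0.02, 2.0, xtol=2e-3, rtol=1e-3)
    except ValueError as exc:
        raise CalibrationError(f"no rate amplitude in [0.02, 2] /ms "
                               f"reaches ratio {target_peak_ratio}: {exc}")

    params = with_a(float(a_fit))
    achieved = clamp_release_metrics(params, n_seeds=n_seeds, seed=seed,
                                     total_ms=total_ms, ca_trace=ca_trace)
    if achieved["depletion_ms"] > target_depletion_ms:
        # depletion bound binds: solve it directly instead
        def depl_err(a):
            m = clamp_release_metrics(with_a(a), n_seeds=search_seeds,
                                      seed=seed, total_ms=total_ms,
                                      ca_trace=ca_trace)
            d = m["depletion_ms"]
            return (d if np.isfinite(d) else 10 * total_ms) - target_depletion_ms
        a_fit = brentq(depl_err, 0.02, 2.0, xtol=2e-3, rtol=1e-3)
        params = with_a(float(a_fit))
        achieved = clamp_release_metrics(params, n_seeds=n_seeds, seed=seed,
                                         total_ms=total_ms, ca_trace=ca_trace)

    targets = {"sustained_per_ms_per_terminal": target_sustained,
               "depletion_ms": target_depletion_ms,
               "peak_to_sustained_ratio": target_peak_ratio}
    ok = (achieved["depletion_ms"] <= target_depletion_ms
          and abs(achieved["sustained_per_ms_per_terminal"]
                  - target_sustained) <= 0.1)
    if not ok and raise_on_miss:
        raise CalibrationError(
            "calibration missed tolerance (sustained rate is structurally "
            f"refill-capped): {achieved}", achieved=achieved)
    return CalibrationResult(params=params, achieved=achieved,
                             targets=targets, converged=ok)
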