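"""Extracellular potentials and stimulus waveforms.

A point source in an unbounded homogeneous medium follows
V_e = I·ρ_ext/(4πr); a uniform field is a linear potential ramp.  Fields
report the potential at every compartment center, and a
:class:`StimulusWaveform` modulates the source current over time
(piecewise-constant on the solver grid, pulse edges aligned to steps).
Only the anodic phase of stimulation is modeled; the much longer, lower
amplitude cathodic phase of a charge-balanced photovoltaic pulse has a
~4x higher threshold and is omitted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, SingularityError
from .morphology import CompartmentGraph
from .units import RHO_EXT_OHM_CM


@dataclass
class PointSourceField:
    """Ideal point-source electrode in a homogeneous medium.

    ``rho_ext_ohm_cm`` defaults to 1000 Ω·cm, mid-range for retinal
    tissue.  Points closer than ``r_min_um`` to the source raise a
    :class:`SingularityError` (the clamp is explicit, never silent).
    """

    position_um: np.ndarray
    rho_ext_ohm_cm: float = RHO_EXT_OHM_CM
    r_min_um: float = 0.5

    def __post_init__(self):
        self.position_um = np.asarray(self.position_um, dtype=float)
        if self.rho_ext_ohm_cm <= 0:
            raise ConfigError("rho_ext_ohm_cm must be positive")

    def potential_at(self, current_ua: float, points_um) -> np.ndarray:
        """V_e in mV at each point for the given source current (µA)."""
        pts = np.atleast_2d(np.asarray(points_um, dtype=float))
        r = np.linalg.norm(pts - self.position_um, axis=1)
        if np.any(r < self.r_min_um):
            bad = int(np.argmin(r))
            raise SingularityError(
                f"point {bad} is {r[bad]:.3g} µm from the source "
                f"(r_min = {self.r_min_um} µm)")
        return 10.0 * current_ua * self.rho_ext_ohm_cm / (4.0 * np.pi * r)


@dataclass
class UniformField:
    """Uniform electric field: linear potential ramp along ``direction``.

    ``gradient_mv_um`` is the potential drop per µm along the direction
    vector; V_e(p) = offset − gradient·(p·direction).
    """

    direction: np.ndarray
    gradient_mv_um: float
    offset_mv: float = 0.0

    def __post_init__(self):
        d = np.asarray(self.direction, dtype=float)
        norm = np.linalg.norm(d)
        if not np.isclose(norm, 1.0, atol=1e-9):
            raise ConfigError("direction must be a unit vector")
        self.direction = d

    def potential_at(self, scale: float, points_um) -> np.ndarray:
        """V_e in mV; ``scale`` multiplies the field linearly (use the
        stimulus current in µA relative to the matching current)."""
        pts = np.atleast_2d(np.asarray(points_um, dtype=float))
        proj = pts @ self.direction
        return scale * (self.offset_mv - self.gradient_mv_um * proj)


def potential_at(field, current_ua: float, points_um) -> np.ndarray:
    """Potential of any field type at the given points, in mV."""
    return field.potential_at(current_ua, points_um)


def superpose(fields, currents_ua, points_um) -> np.ndarray:
    """Linear superposition of several point sources.

    The medium is linear, so multi-electrode potentials are the sum of
    the individual source potentials.
    """
    fields = list(fields)
    currents = list(currents_ua)
    if len(fields) != len(currents):
        raise ConfigError("fields and currents must have equal length")
    pts = np.atleast_2d(np.asarray(points_um, dtype=float))
    total = np.zeros(pts.shape[0])
    for f, i in zip(fields, currents):
        total += f.potential_at(i, pts)
    return total


def matched_uniform_field(field: PointSourceField, current_ua: float,
                          graph: CompartmentGraph) -> UniformField:
    """Uniform field with the same top-to-bottom voltage drop as the
    point source, evaluated on the soma's vertical axis across the cell's
    z-extent.  Used to compare polarization by field shape alone."""
    z_min, z_max = graph.z_extent
    extent = z_max - z_min
    if extent <= 0:
        raise ConfigError("degenerate z-extent")
    axis_xy = graph.soma_position[:2]
    p_bottom = np.array([axis_xy[0], axis_xy[1], z_min])
    p_top = np.array([axis_xy[0], axis_xy[1], z_max])
    v = field.potential_at(current_ua, np.vstack([p_bottom, p_top]))
    gradient = (v[0] - v[1]) / extent
    # offset chosen so the on-axis potential at z_min matches the source
    offset = v[0] + gradient * z_min
    return UniformField(direction=np.array([0.0, 0.0, 1.0]),
                        gradient_mv_um=gradient, offset_mv=offset)


@dataclass
class StimulusWaveform:
    """Pulsatile current time course (monophasic, anodic).

    shape: ``pulse`` (single monophasic anodic pulse), ``pulse_train``
    (regular train at ``frequency_hz``), ``cw`` (continuous), or
    ``schedule`` (explicit pulse onsets, e.g. a grating half-cycle gate).
    """

    shape: str = "pulse"
    amplitude_ua: float = 1.0
    pulse_duration_ms: float = 4.0
    frequency_hz: float = 0.0
    total_duration_ms: float = 100.0
    onsets_ms: list = field(default_factory=list)
    delay_ms: float = 0.0   # onset of the first (or only) pulse

    def __post_init__(self):
        if self.shape not in ("pulse", "pulse_train", "cw", "schedule"):
            raise ConfigError(f"unknown waveform shape {self.shape!r}")
        if self.amplitude_ua < 0:
            raise ConfigError("anodic amplitude must be >= 0")
        if self.shape in ("pulse", "pulse_train") and self.pulse_duration_ms <= 0:
            raise ConfigError("pulse_duration_ms must be positive")
        if self.shape == "pulse_train":
            if self.frequency_hz <= 0:
                raise ConfigError("pulse_train requires frequency_hz > 0")
            if 1000.0 / self.frequency_hz < self.pulse_duration_ms:
                raise ConfigError("pulse period shorter than pulse duration")
        if self.shape == "schedule":
            onsets = np.asarray(self.onsets_ms, dtype=float)
            if onsets.size and np.any(np.diff(onsets) <= 0):
                raise ConfigError("onsets must be strictly increasing")

    def pulse_onsets(self) -> np.ndarray:
        if self.shape == "pulse":
            return np.array([self.delay_ms])
        if self.shape == "pulse_train":
            period = 1000.0 / self.frequency_hz
            return np.arange(self.delay_ms, self.total_duration_ms,
                             period)
        if self.shape == "schedule":
            return np.asarray(self.onsets_ms, dtype=float)
        return np.array([])  # cw

    def current_ua(self, t_ms: np.ndarray) -> np.ndarray:
        """Instantaneous current on a time grid (piecewise constant;
        samples are interpreted as the value on [t, t+dt))."""
        t = np.asarray(t_ms, dtype=float)
        if self.shape == "cw":
            out = np.full(t.shape, self.amplitude_ua)
            out[t < self.delay_ms] = 0.0
            return out
        out = np.zeros(t.shape)
        for onset in self.pulse_onsets():
            mask = (t >= onset - 1e-9) & (t < onset + self.pulse_duration_ms - 1e-9)
            out[mask] = self.amplitude_ua
        return out

    def export_tsv(self, path, dt_ms: float) -> None:
        """Two-column delimited export: time (ms), current (µA)."""
        t = np.arange(0.0, self.total_duration_ms + dt_ms / 2, dt_ms)
        i = self.current_ua(t)
        np.savetxt(path, np.column_stack([t, i]), fmt="%.6f",
                   delimiter="\t", header="t_ms\tI_uA", comments="")
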