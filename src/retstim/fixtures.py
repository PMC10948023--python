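"""Programmatic test fixtures.

Everything here is generated, deterministic for a given seed, and tiny:
stylized SWC morphologies, a 3-point toy cable, canned calcium
trajectories for synapse unit tests, and a 2-synapse release-model
configuration for exact-expectation oracle tests.
"""

from __future__ import annotations

from dataclasses import replace
from pathlib import Path

import numpy as np

from .morphology import build_stylized_bc, build_stylized_rgc, save_swc
from .synapse import ReleaseParams

TOY_CABLE_SWC = """# three-point straight cable, 10 µm total
1 3 0.0 0.0 0.0 0.5 -1
2 3 0.0 0.0 5.0 0.5 1
3 3 0.0 0.0 10.0 0.5 2
"""


def tiny_release_params(**overrides) -> ReleaseParams:
    """A 2-synapse, 1-terminal release model for enumeration oracles."""
    base = ReleaseParams(n_terminals=1, synapses_per_terminal=2)
    return replace(base, **overrides)


def canned_ca_step(total_ms: float = 200.0, dt_ms: float = 0.025,
                   level_um: float = 50.0, onset_ms: float = 20.0):
    """Step calcium trajectory: resting 0.1 µM, step to ``level_um``."""
    n = int(round(total_ms / dt_ms))
    t = (np.arange(n) + 1) * dt_ms
    ca = np.where(t >= onset_ms, level_um, 0.1)
    return t, ca


def canned_ca_pulses(total_ms: float = 500.0, dt_ms: float = 0.025,
                     peak_um: float = 30.0, period_ms: float = 100.0,
                     decay_ms: float = 50.0):
    """Pulsatile calcium trajectory: instantaneous rises at each period
    onset with exponential decay — the canonical train-driving shape."""
    n = int(round(total_ms / dt_ms))
    t = (np.arange(n) + 1) * dt_ms
    phase = t % period_ms
    ca = 0.1 + peak_um * np.exp(-phase / decay_ms)
    return t, ca


def make_fixtures(seed: int, out_dir) -> dict[str, Path]:
    """Write the fixture set to ``out_dir``; byte-identical per seed."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    p = out / "toy_cable.swc"
    p.write_text(TOY_CABLE_SWC)
    paths["toy_cable"] = p

    bc = build_stylized_bc()
    p = out / "stylized_bc.swc"
    save_swc(bc, p)
    paths["bc"] = p

    rgc = build_stylized_rgc()
    p = out / "stylized_rgc.swc"
    save_swc(rgc, p)
    paths["rgc"] = p

    rng = np.random.default_rng(seed)
    for name, (t, ca) in (("ca_step", canned_ca_step()),
                          ("ca_pulses", canned_ca_pulses())):
        noisy = ca * (1.0 + 0.01 * rng.standard_normal(ca.size))
        p = out / f"{name}.tsv"
        np.savetxt(p, np.column_stack([t, noisy]), fmt="%.6f",
                   delimiter="\t", header="t_ms\tca_um", comments="")
        paths[name] = p
    return paths
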