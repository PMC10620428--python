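"""Shared builders for the test suite."""

import numpy as np

from dtmr.harmonize import HarmonizedInstrument, harmonize, \
    orient_exposure_increasing
from dtmr.simulate import SimulationConfig, simulate_two_sample


def make_instruments(bx, by, sy, sx=None, rsids=None):
    """Build a harmonized instrument list straight from effect arrays."""
    bx = np.asarray(bx, dtype=float)
    by = np.asarray(by, dtype=float)
    sy = np.broadcast_to(np.asarray(sy, dtype=float), bx.shape)
    sx = np.broadcast_to(np.asarray(sx if sx is not None else 1e-6,
                                    dtype=float), bx.shape)
    rsids = rsids or [f"rs{i + 1}" for i in range(bx.size)]
    return [
        HarmonizedInstrument(
            rsid=r, effect_allele="A", other_allele="G",
            beta_exposure=float(x), se_exposure=float(s_x),
            beta_outcome=float(y), se_outcome=float(s_y),
            chrom="1", pos=1_000_000 + 1000 * i)
        for i, (r, x, s_x, y, s_y) in enumerate(zip(rsids, bx, sx, by, sy))
    ]


def simulate_instruments(seed, **overrides):
    """Simulated, harmonized, exposure-oriented instruments plus truth."""
    cfg = SimulationConfig(seed=seed, **overrides)
    exposure, outcome, truth = simulate_two_sample(cfg)
    instruments, _ = harmonize(exposure, outcome)
    return orient_exposure_increasing(instruments), truth
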