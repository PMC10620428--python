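"""Run every applicable estimator on one instrument set.

Each method appears in the output either as its result object or as a
``NotApplicable`` marker carrying the reason (e.g. a single-variant
proxy only supports the Wald ratio) — never silently absent.
"""

from __future__ import annotations

from dataclasses import dataclass

from .estimators import (
    ivw_random_effects,
    mr_egger,
    mr_raps,
    wald_ratio,
    weighted_median,
    weighted_mode,
)
from .exceptions import DtmrError
from .harmonize import HarmonizedInstrument
from .presso import mr_presso

METHODS = ("wald", "ivw_re", "weighted_median", "weighted_mode", "egger",
           "raps", "presso")


@dataclass(frozen=True)
class NotApplicable:
    method: str
    reason: str


def estimate_all(instruments: list[HarmonizedInstrument],
                 n_boot: int = 1000,
                 seed: int | None = None,
                 phi: float = 1.0,
                 loss: str = "huber",
                 n_sim: int = 1000,
                 presso_alpha: float = 0.05,
                 include_presso: bool = True) -> dict:
    """Full battery with per-method applicability guards."""
    k = len(instruments)
    out: dict = {}

    def run(name, min_k, fn):
        if k < min_k:
            out[name] = NotApplicable(
                name, f"needs ≥ {min_k} instruments, have {k}")
            return
        try:
            out[name] = fn()
        except DtmrError as e:
            out[name] = NotApplicable(name, str(e))

    if k == 1:
        run("wald", 1, lambda: wald_ratio(instruments[0]))
    else:
        out["wald"] = NotApplicable(
            "wald", f"single-instrument method, have {k}")
    run("ivw_re", 2, lambda: ivw_random_effects(instruments))
    run("weighted_median", 3,
        lambda: weighted_median(instruments, n_boot=n_boot, seed=seed))
    run("weighted_mode", 3,
        lambda: weighted_mode(instruments, phi=phi, n_boot=n_boot, seed=seed))
    run("egger", 3, lambda: mr_egger(instruments))
    run("raps", 3, lambda: mr_raps(instruments, loss=loss, seed=seed))
    if include_presso:
        run("presso", 4,
            lambda: mr_presso(instruments, n_sim=n_sim, seed=seed,
                              alpha=presso_alpha))
    return out
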