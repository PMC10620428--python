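"""End-to-end analysis: selection → harmonisation → estimation →
diagnostics for every target × outcome pair in a config.

Pairs are isolated: an error in one target/outcome analysis is
recorded in the report and the batch continues.  Reports are
deterministic given config + seeds (stable key order, no timestamps),
so re-running a config reproduces the output files byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .battery import METHODS, NotApplicable, estimate_all
from .diagnostics import cochran_q, cooks_outliers
from .estimators import EggerResult, MREstimate, RapsResult
from .exceptions import ConfigurationError, DtmrError
from .harmonize import harmonize, orient_exposure_increasing
from .instruments import SelectionConfig, select_instruments
from .io import read_ld_matrix, read_regions, read_sumstats
from .presso import PressoResult

logger = logging.getLogger(__name__)


@dataclass
class AnalysisConfig:
    exposure_path: str
    outcome_paths: dict
    region_catalog_path: str
    ld_path: str
    targets: list
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    seed: int = 0
    n_boot: int = 1000
    n_sim: int = 1000
    phi: float = 1.0
    loss: str = "huber"
    genome_build: str = "unspecified"  # metadata only, never converted
    output_dir: str = "dtmr_output"

    def __post_init__(self):
        if not self.targets:
            raise ConfigurationError("at least one target gene is required")
        if not self.outcome_paths:
            raise ConfigurationError("at least one outcome GWAS is required")
        if isinstance(self.selection, dict):
            self.selection = SelectionConfig(**self.selection)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        try:
            return cls(**raw)
        except TypeError as e:
            raise ConfigurationError(f"bad analysis config: {e}") from None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class PairResult:
    target: str
    outcome: str
    error: str | None = None
    selection: object = None
    drop_log: list = field(default_factory=list)
    n_instruments: int = 0
    estimates: dict = field(default_factory=dict)
    heterogeneity: object = None
    influence: object = None


@dataclass
class AnalysisReport:
    pairs: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    @property
    def failed_pairs(self) -> list:
        return [k for k, p in self.pairs.items() if p.error]


def analyse_pair(exposure, outcome, regions, ld, target, config
                 ) -> PairResult:
    result = PairResult(target=target, outcome="")
    report = select_instruments(exposure, regions, target, ld,
                                config.selection)
    result.selection = report
    harmonized, drop_log = harmonize(report.instruments, outcome)
    result.drop_log = drop_log
    instruments = orient_exposure_increasing(harmonized)
    result.n_instruments = len(instruments)
    if not instruments:
        raise DtmrError(
            f"no instruments remain for {target} after harmonisation")
    result.estimates = estimate_all(
        instruments, n_boot=config.n_boot, seed=config.seed, phi=config.phi,
        loss=config.loss, n_sim=config.n_sim)
    if len(instruments) >= 2:
        result.heterogeneity = cochran_q(instruments)
    else:
        result.heterogeneity = NotApplicable(
            "cochran_q", "single instrument")
    if len(instruments) >= 4:
        result.influence = cooks_outliers(
            instruments, n_boot=config.n_boot, seed=config.seed,
            phi=config.phi, loss=config.loss, n_sim=config.n_sim)
    else:
        result.influence = NotApplicable(
            "cooks_outliers", f"needs ≥ 4 instruments, "
            f"have {len(instruments)}")
    return result


def run_analysis(config: AnalysisConfig) -> AnalysisReport:
    exposure = read_sumstats(config.exposure_path)
    regions = read_regions(config.region_catalog_path)
    ld = read_ld_matrix(config.ld_path)
    outcomes = {name: read_sumstats(path)
                for name, path in config.outcome_paths.items()}
    report = AnalysisReport(provenance={
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "dtmr_version": __version__,
        "config": config.to_dict(),
    })
    for target in config.targets:
        for oname, outcome in outcomes.items():
            key = f"{target}|{oname}"
            try:
                pair = analyse_pair(exposure, outcome, regions, ld,
                                    target, config)
                pair.outcome = oname
            except DtmrError as e:
                logger.error("pair %s failed: %s", key, e)
                pair = PairResult(target=target, outcome=oname,
                                  error=str(e))
            report.pairs[key] = pair
    return report


def _estimate_of(method: str, obj) -> MREstimate | None:
    if isinstance(obj, MREstimate):
        return obj
    if isinstance(obj, EggerResult):
        return obj.slope
    if isinstance(obj, RapsResult):
        return obj.estimate
    if isinstance(obj, PressoResult):
        return obj.corrected_estimate  # None when no outliers (NA row)
    return None


def render_forest_table(report: AnalysisReport) -> pd.DataFrame:
    """Tidy per-method OR table mirroring a forest plot's rows."""
    rows = []
    for pair in report.pairs.values():
        for method in METHODS:
            obj = pair.estimates.get(method)
            est = _estimate_of(method, obj)
            row = {"target": pair.target, "outcome": pair.outcome,
                   "method": method}
            if est is not None:
                row.update(
                    or_per_decrease=est.or_per_decrease,
                    or_ci_low=est.or_ci_low, or_ci_high=est.or_ci_high,
                    pval=est.pval, n_snps=est.n_snps, note="")
            else:
                reason = obj.reason if isinstance(obj, NotApplicable) else (
                    "no outliers detected"
                    if isinstance(obj, PressoResult)
                    else pair.error or "not available")
                row.update(or_per_decrease=np.nan, or_ci_low=np.nan,
                           or_ci_high=np.nan, pval=np.nan, n_snps=0,
                           note=f"NA: {reason}")
            rows.append(row)
    df = pd.DataFrame(rows)
    return df.sort_values(["target", "outcome", "method"],
                          kind="stable").reset_index(drop=True)


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        d = {f.name: _jsonable(getattr(obj, f.name))
             for f in dataclasses.fields(obj)
             if not f.name.startswith("_") and f.name != "instruments"}
        d["__type__"] = type(obj).__name__
        return d
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def write_report(report: AnalysisReport, outdir) -> dict:
    """Write report.json, forest.csv, diagnostics and drop-log CSVs.

    Returns the paths written.  Output is deterministic for a given
    config + seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    blob = _jsonable({"provenance": report.provenance,
                      "pairs": report.pairs})
    if report.failed_pairs:
        blob["failures"] = {k: report.pairs[k].error
                            for k in report.failed_pairs}
    paths["report"] = outdir / "report.json"
    with open(paths["report"], "w") as fh:
        json.dump(blob, fh, indent=2, sort_keys=True)

    paths["forest"] = outdir / "forest.csv"
    render_forest_table(report).to_csv(paths["forest"], index=False,
                                       float_format="%.6g")

    diag_rows, drop_rows = [], []
    for key, pair in report.pairs.items():
        if pair.heterogeneity is not None and not isinstance(
                pair.heterogeneity, NotApplicable):
            h = pair.heterogeneity
            diag_rows.append({"pair": key, "statistic": "cochran_q",
                              "value": h.q, "df": h.df, "pval": h.pval})
        egger = pair.estimates.get("egger")
        if isinstance(egger, EggerResult):
            diag_rows.append({"pair": key, "statistic": "egger_intercept",
                              "value": egger.intercept, "df": np.nan,
                              "pval": egger.intercept_pval})
        presso = pair.estimates.get("presso")
        if isinstance(presso, PressoResult):
            diag_rows.append({"pair": key, "statistic": "presso_global",
                              "value": presso.rss_observed, "df": np.nan,
                              "pval": presso.global_pval})
        for rec in pair.drop_log:
            drop_rows.append({"pair": key, **rec})
    paths["diagnostics"] = outdir / "diagnostics.csv"
    pd.DataFrame(diag_rows, columns=["pair", "statistic", "value", "df",
                                     "pval"]).to_csv(
        paths["diagnostics"], index=False, float_format="%.6g")
    paths["drop_log"] = outdir / "drop_log.csv"
    pd.DataFrame(drop_rows, columns=["pair", "rsid", "reason"]).to_csv(
        paths["drop_log"], index=False)

    paths["log"] = outdir / "run.log"
    with open(paths["log"], "w") as fh:
        fh.write(f"dtmr {__version__}\n")
        fh.write(f"config_hash: {report.provenance['config_hash']}\n")
        fh.write(f"seed: {report.provenance['seed']}\n")
        for key, pair in report.pairs.items():
            if pair.selection is not None:
                s = pair.selection
                fh.write(f"{key}: n={s.n_region_snps} "
                         f"p_threshold={s.p_threshold:.6g} "
                         f"significant={s.n_significant} "
                         f"post_clump={s.n_post_clump} "
                         f"kept={s.n_post_palindrome}\n")
            if pair.error:
                fh.write(f"{key}: ERROR {pair.error}\n")
    return paths
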