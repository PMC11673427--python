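"""End-to-end orchestration from a declarative run config.

A run config (YAML or dict) names the exposure and outcome summary-
statistics files with their column maps, the instrument-selection
thresholds, the methods to run, and the seeds of every stochastic step
(median bootstrap, SIMEX, MR-PRESSO).  ``run_univariable`` executes
select -> clump -> harmonise -> orient -> estimators -> diagnostics for
every exposure-outcome pair and writes, per pair, a forest-plot results
table, the per-SNP scatter data (with outlier flags), and a diagnostics
table; ``run_multivariable`` produces the adjusted-effects table.  A
run-manifest JSON records config, seeds and output files so identical
configs reproduce identical outputs byte for byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import pleiotropy as pl
from . import univariable_mr as uni
from .instruments import LDReference, instrument_strength, ld_clump, select_instruments
from .mvmr import build_mvmr_input, mvmr_egger, mvmr_ivw
from .sumstats_io import harmonise, orient_positive_exposure, read_summary_stats

__all__ = ["RunConfig", "run_univariable", "run_multivariable"]

logger = logging.getLogger("mrkit")

_DEFAULT_METHODS = ["IVW", "weighted_median", "MR_Egger", "MR_Egger_SIMEX", "MR_PRESSO"]


@dataclass
class RunConfig:
    exposures: dict
    outcomes: dict
    output_dir: str
    ld_reference: dict | None = None
    thresholds: dict = field(
        default_factory=lambda: {"p": 5.0e-8, "r2": 0.001, "window_kb": 10_000}
    )
    methods: list[str] = field(default_factory=lambda: list(_DEFAULT_METHODS))
    seeds: dict = field(
        default_factory=lambda: {"median_bootstrap": 1, "simex": 2, "presso": 3}
    )
    n_boot: int = 1000
    simex_B: int = 1000
    presso_n_sim: int = 1000
    simex_always: bool = False  # by default SIMEX only when I2_GX < 90%

    @classmethod
    def load(cls, source: "RunConfig | dict | str | Path") -> "RunConfig":
        if isinstance(source, RunConfig):
            return source
        if isinstance(source, (str, Path)):
            source = yaml.safe_load(Path(source).read_text())
        return cls(**source)


def _load_ld(cfg: RunConfig) -> LDReference | None:
    if cfg.ld_reference is None:
        return None
    spec = cfg.ld_reference
    if "square_tsv" in spec:
        return LDReference.from_square_tsv(spec["square_tsv"])
    if "pairs" in spec:
        return LDReference.from_pairs(spec["pairs"])
    raise ValueError("ld_reference must give 'square_tsv' or 'pairs'")


def _read(entry: dict) -> pd.DataFrame:
    return read_summary_stats(
        entry["path"],
        column_map=entry.get("column_map"),
        trait_type=entry.get("trait_type", "continuous"),
    )


def run_univariable(config: RunConfig | dict | str | Path) -> dict:
    """Run the full univariable pipeline for every exposure-outcome pair.

    Returns a bundle mapping (exposure, outcome) to the estimates,
    diagnostics report and output paths; everything is also written under
    ``output_dir``.
    """
    cfg = RunConfig.load(config)
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    ld = _load_ld(cfg)
    thr = cfg.thresholds

    bundle: dict = {"pairs": {}, "files": []}
    for exp_label, exp_entry in cfg.exposures.items():
        exposure = _read(exp_entry)
        instruments = select_instruments(exposure, thr.get("p", 5.0e-8))
        if ld is not None:
            instruments = ld_clump(
                instruments, ld, thr.get("r2", 0.001), thr.get("window_kb", 10_000)
            )
        strength = instrument_strength(instruments)
        for out_label, out_entry in cfg.outcomes.items():
            logger.info("pair %s -> %s", exp_label, out_label)
            outcome = _read(out_entry)
            try:
                h, report = harmonise(instruments, outcome, exp_label, out_label)
                h = orient_positive_exposure(h)
                result = _analyse_pair(cfg, h, mean_f=strength.mean_f)
            except ValueError as err:
                raise ValueError(f"pair {exp_label}->{out_label}: {err}") from err

            stem = outdir / f"{exp_label}__{out_label}"
            rows = [est.as_row() for est in result["estimates"]]
            forest = pd.DataFrame(rows)
            forest.insert(0, "outcome", out_label)
            forest.insert(0, "exposure", exp_label)
            forest.to_csv(f"{stem}_forest.tsv", sep="\t", index=False)

            scatter = h.to_frame()
            scatter["outlier"] = [
                v in set(result["diagnostics"].presso_outlier_ids)
                for v in h.variant_id
            ]
            scatter.to_csv(f"{stem}_scatter.tsv", sep="\t", index=False)
            report.to_json(f"{stem}_harmonisation.json")
            pl.diagnostics_to_tsv(
                {(exp_label, out_label): result["diagnostics"]},
                f"{stem}_diagnostics.tsv",
            )
            bundle["files"] += [
                f"{stem}_forest.tsv",
                f"{stem}_scatter.tsv",
                f"{stem}_diagnostics.tsv",
            ]
            result["harmonisation"] = report
            result["strength"] = strength
            bundle["pairs"][(exp_label, out_label)] = result

    manifest = {
        "kind": "univariable",
        "methods": cfg.methods,
        "seeds": cfg.seeds,
        "thresholds": cfg.thresholds,
        "outputs": [str(f) for f in bundle["files"]],
    }
    (outdir / "run_manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return bundle


def _analyse_pair(cfg: RunConfig, h, mean_f: float | None = None) -> dict:
    estimates: list[uni.MREstimate] = []
    ivw_est, _ = uni.ivw(h)
    egger = uni.mr_egger(h)
    if "IVW" in cfg.methods:
        estimates.append(ivw_est)
    if "weighted_median" in cfg.methods:
        estimates.append(
            uni.weighted_median(h, cfg.n_boot, cfg.seeds.get("median_bootstrap", 1))
        )
    if "MR_Egger" in cfg.methods:
        estimates.append(egger.slope)
    simex = None
    run_simex = "MR_Egger_SIMEX" in cfg.methods and (
        cfg.simex_always or (egger.i2_gx is not None and egger.i2_gx < 90.0)
    )
    if run_simex:
        simex = uni.egger_simex(h, B=cfg.simex_B, seed=cfg.seeds.get("simex", 2))
        estimates.append(simex.slope)
    diagnostics = pl.diagnostics_report(
        h,
        egger,
        simex=simex,
        mean_f=mean_f,
        n_sim=cfg.presso_n_sim,
        seed=cfg.seeds.get("presso", 3),
    )
    if "MR_PRESSO" in cfg.methods and diagnostics.presso_corrected is not None:
        estimates.append(diagnostics.presso_corrected)
    return {"estimates": estimates, "egger": egger, "simex": simex, "diagnostics": diagnostics}


def run_multivariable(config: RunConfig | dict | str | Path) -> dict:
    """Multivariable MR over all exposures jointly, per outcome.

    Emits one TSV with IVW and Egger adjusted effects side by side for
    every (outcome, exposure) combination.
    """
    cfg = RunConfig.load(config)
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    ld = _load_ld(cfg)
    thr = cfg.thresholds

    exposure_tables = {label: _read(e) for label, e in cfg.exposures.items()}
    bundle: dict = {"outcomes": {}, "files": []}
    rows = []
    for out_label, out_entry in cfg.outcomes.items():
        outcome = _read(out_entry)
        m = build_mvmr_input(
            exposure_tables,
            outcome,
            ld=ld,
            p_threshold=thr.get("p", 5.0e-8),
            r2_threshold=thr.get("r2", 0.001),
            window_kb=thr.get("window_kb", 10_000),
            outcome_label=out_label,
        )
        ivw_est = mvmr_ivw(m)
        egger_est, intercept = mvmr_egger(m, orient_on=0)
        bundle["outcomes"][out_label] = {
            "input": m,
            "ivw": ivw_est,
            "egger": egger_est,
            "egger_intercept": intercept,
        }
        for k, label in enumerate(m.exposure_labels):
            for est in (ivw_est[k], egger_est[k]):
                row = {"outcome": out_label, "exposure": label}
                row.update(est.as_row())
                rows.append(row)

    table = pd.DataFrame(rows)
    path = outdir / "mvmr_results.tsv"
    table.to_csv(path, sep="\t", index=False)
    bundle["files"].append(str(path))
    manifest = {
        "kind": "multivariable",
        "thresholds": cfg.thresholds,
        "outputs": bundle["files"],
    }
    (outdir / "run_manifest_mvmr.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return bundle
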