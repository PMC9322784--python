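"""End-to-end runs driven by a single config: ingest or simulate, fit,
write tables, manifest and (optionally) figures.

This is the layer behind the command line; library users normally work
with :class:`~stepvar.model.ActivityVariabilityModel` directly.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .exceptions import ConfigurationError
from .io import parse_fitbit_export, read_canonical_csv
from .data import records_to_frame
from .model import ActivityVariabilityModel, VariabilityResults
from .poincare import PoincareConfig

logger = logging.getLogger("stepvar.pipeline")

INPUT_MODES = ("fitbit_export_dir", "canonical_csv", "simulate")


@dataclass
class AnalysisConfig:
    """One end-to-end run.

    Exactly one input mode is active: ``fitbit_export_dir`` (a directory of
    per-subject account exports, subject id = filename stem),
    ``canonical_csv`` (a canonical-long activity file), or ``simulate``
    (a synthetic cohort; ``seed`` and the ``simulation`` sub-config apply).
    """

    input_mode: str = "simulate"
    activity_path: str | None = None
    outcomes_path: str | None = None
    output_dir: str = "stepvar_out"
    seed: int = 0
    simulation: dict = field(default_factory=dict)
    lag_days: int = 1
    pairing_mode: str = "calendar"
    min_pairs: int = 10
    block_days: int = 30
    alpha: float = 0.05
    correlation_policy: str = "auto"
    bh_adjust: bool = False
    figures: bool = False
    distance_unit: str = "km"
    log_level: str = "INFO"

    def __post_init__(self):
        if self.input_mode not in INPUT_MODES:
            raise ConfigurationError(f"input_mode must be one of {INPUT_MODES}")
        if self.input_mode != "simulate" and not self.activity_path:
            raise ConfigurationError(f"input_mode {self.input_mode!r} needs activity_path")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def poincare(self) -> PoincareConfig:
        return PoincareConfig(self.lag_days, self.pairing_mode, self.min_pairs)


def _simulation_config(config: AnalysisConfig):
    from .simulate import SyntheticCohortConfig

    kwargs = dict(config.simulation)
    kwargs.setdefault("seed", config.seed)
    return SyntheticCohortConfig(**kwargs)


def _stage(name: str):
    logger.info("stage=%s", name)


def load_inputs(config: AnalysisConfig):
    """Resolve the configured input mode to (activity frame, outcomes frame)."""
    if config.input_mode == "simulate":
        from .simulate import simulate_cohort

        bundle = simulate_cohort(_simulation_config(config))
        return bundle.activity, bundle.outcomes
    outcomes = pd.read_csv(config.outcomes_path) if config.outcomes_path else None
    if config.input_mode == "canonical_csv":
        return read_canonical_csv(config.activity_path), outcomes
    # fitbit_export_dir: one export file per subject, id from the filename stem
    records = []
    export_dir = Path(config.activity_path)
    files = sorted(export_dir.glob("*.csv"))
    if not files:
        raise ConfigurationError(f"no CSV exports found in {export_dir}")
    for path in files:
        with open(path, "r", encoding="utf-8") as fh:
            records.extend(
                parse_fitbit_export(
                    fh,
                    dialect="fitbit_activities",
                    subject_id=path.stem,
                    distance_unit=config.distance_unit,
                )
            )
    return records_to_frame(records), outcomes


def run_analysis(config: AnalysisConfig) -> VariabilityResults:
    """Execute every stage and write all outputs to ``config.output_dir``.

    Deterministic given the config (including the seed in simulate mode).
    Tables computed before a late-stage failure are still written.
    """
    logging.basicConfig(
        stream=sys.stderr,
        level=getattr(logging, config.log_level.upper(), logging.INFO),
        format="%(levelname)s %(name)s %(message)s",
    )
    _stage("ingest")
    try:
        activity, outcomes = load_inputs(config)
    except Exception as err:
        raise ConfigurationError(f"stage ingest failed: {err}") from err

    _stage("fit")
    model = ActivityVariabilityModel(
        activity,
        outcomes,
        poincare=config.poincare(),
        block_days=config.block_days,
        alpha=config.alpha,
        correlation_policy=config.correlation_policy,
        bh_adjust=config.bh_adjust,
    )
    results = model.fit()
    results.manifest["seed"] = config.seed
    results.manifest["input_mode"] = config.input_mode

    _stage("write")
    outdir = Path(config.output_dir)
    results.save_tables(outdir)

    if config.figures:
        _stage("figures")
        _write_figures(results, outdir / "figures")
    return results


def _write_figures(results: VariabilityResults, figdir: Path):
    """Per-subject Poincaré plots and delta-vs-descriptor scatters.

    Point coordinates are written as CSV next to each image so figures can
    be tested without image comparison.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    figdir.mkdir(parents=True, exist_ok=True)
    for subject_id in results.descriptors["subject_id"].unique():
        sub = results.descriptors[results.descriptors["subject_id"] == subject_id]
        if "steps" not in set(sub["metric"]):
            continue
        points = results.poincare_points(subject_id, "steps")
        points.to_csv(figdir / f"poincare_{subject_id}_steps.csv", index=False)
        ax = results.plot_poincare(subject_id, "steps")
        ax.figure.savefig(figdir / f"poincare_{subject_id}_steps.png", dpi=100)
        plt.close(ax.figure)
    if len(results.correlations):
        defined = results.correlations[results.correlations["defined"]]
        if len(defined):
            best = defined.loc[defined["p_value"].idxmin()]
            ax = results.plot_delta_scatter(best["outcome_delta"], best["descriptor"])
            ax.figure.savefig(
                figdir / f"delta_{best['outcome_delta']}_vs_{best['descriptor']}.png",
                dpi=100,
            )
            plt.close(ax.figure)
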