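"""Model/Results interface tying the pipeline together.

:class:`ActivityVariabilityModel` holds a cohort's daily activity (and
optionally its clinical outcomes) plus the analysis settings;
:meth:`~ActivityVariabilityModel.fit` runs the full pipeline —
validation → Poincaré descriptors per subject × metric → monthly summaries
→ normality-gated paired comparisons → delta-vs-descriptor correlations —
and returns a :class:`VariabilityResults` carrying the four tables, a
machine-readable manifest, a text :meth:`~VariabilityResults.summary`, and
plotting/serialisation helpers.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .data import ACTIVITY_METRICS, frame_to_records, records_to_frame, series_from_frame
from .exceptions import ValidationError
from .io import read_canonical_csv, validate_records
from .poincare import PoincareConfig, PoincareDescriptors, descriptor_table, ellipse_outline, lagged_pairs
from .stats import compare_outcomes, delta_correlations, monthly_summary


class ActivityVariabilityModel:
    """Variability analysis of a cohort's daily activity-tracker data.

    Parameters
    ----------
    activity
        Canonical long DataFrame (subject_id, date, steps, distance_km and
        the four minute channels) or a list of
        :class:`~stepvar.data.DailyActivityRecord`.
    outcomes
        Optional flat clinical table (subject_id, outcome, baseline,
        followup); enables the comparison and correlation stages.
    poincare
        Poincaré settings (lag, pairing mode, minimum pairs).
    block_days
        Window length for "monthly" summaries, counted from each subject's
        first record (subjects enrol on different dates).
    alpha
        Normality-gate threshold for the Shapiro–Wilk test.
    correlation_policy
        ``auto`` (gated Pearson/Spearman), ``pearson``, or ``spearman``.
    bh_adjust
        Append Benjamini–Hochberg adjusted p-values to the correlation
        table.
    """

    def __init__(
        self,
        activity,
        outcomes: Optional[pd.DataFrame] = None,
        *,
        poincare: PoincareConfig = PoincareConfig(),
        block_days: int = 30,
        alpha: float = 0.05,
        correlation_policy: str = "auto",
        bh_adjust: bool = False,
    ):
        if isinstance(activity, pd.DataFrame):
            missing = set(("subject_id", "date") + ACTIVITY_METRICS) - set(activity.columns)
            if missing:
                raise ValidationError(f"activity frame missing columns {sorted(missing)}")
            self.activity = activity.reset_index(drop=True)
        else:
            self.activity = records_to_frame(activity)
        if outcomes is not None:
            required = {"subject_id", "outcome", "baseline", "followup"}
            missing = required - set(outcomes.columns)
            if missing:
                raise ValidationError(f"outcomes frame missing columns {sorted(missing)}")
        self.outcomes = outcomes
        self.poincare = poincare
        self.block_days = block_days
        self.alpha = alpha
        self.correlation_policy = correlation_policy
        self.bh_adjust = bh_adjust

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_csv(cls, activity_path, outcomes_path=None, **kwargs):
        """Build from a canonical-long activity CSV (and optional outcomes CSV)."""
        activity = read_canonical_csv(activity_path)
        outcomes = pd.read_csv(outcomes_path) if outcomes_path else None
        return cls(activity, outcomes, **kwargs)

    @classmethod
    def from_simulation(cls, config_or_bundle, **kwargs):
        """Build from a :class:`~stepvar.simulate.SyntheticCohortConfig` or bundle."""
        from .simulate import CohortBundle, SyntheticCohortConfig, simulate_cohort

        if isinstance(config_or_bundle, SyntheticCohortConfig):
            bundle = simulate_cohort(config_or_bundle)
        elif isinstance(config_or_bundle, CohortBundle):
            bundle = config_or_bundle
        else:
            raise ValidationError("expected SyntheticCohortConfig or CohortBundle")
        model = cls(bundle.activity, bundle.outcomes, **kwargs)
        model.ground_truth = bundle.ground_truth
        return model

    # -- fitting ------------------------------------------------------------

    def fit(self) -> "VariabilityResults":
        """Run every pipeline stage and return the results object."""
        notes: list[str] = []
        report = validate_records(frame_to_records(self.activity))
        if not report.ok:
            notes.extend(f"validation: {m}" for m in report.messages)

        descriptors, skip_notes = descriptor_table(
            series_from_frame(self.activity), self.poincare
        )
        notes.extend(f"descriptors: {m}" for m in skip_notes)

        monthly_parts = []
        for metric in ACTIVITY_METRICS:
            series_list = list(series_from_frame(self.activity, metric))
            if series_list:
                monthly_parts.append(monthly_summary(series_list, self.block_days))
        monthly = (
            pd.concat(monthly_parts, ignore_index=True)
            if monthly_parts
            else pd.DataFrame(columns=["metric", "month_index", "n_days", "mean", "sd", "cv"])
        )

        if self.outcomes is not None and len(self.outcomes):
            comparisons = compare_outcomes(self.outcomes, alpha=self.alpha)
            n_subjects = self.outcomes["subject_id"].nunique()
            if n_subjects >= 3 and len(descriptors):
                correlations = delta_correlations(
                    self.outcomes,
                    descriptors,
                    policy=self.correlation_policy,
                    alpha=self.alpha,
                    bh_adjust=self.bh_adjust,
                )
            else:
                correlations = pd.DataFrame()
                notes.append(
                    "correlations: stage skipped "
                    f"(need >= 3 subjects with descriptors, have {n_subjects})"
                )
        else:
            comparisons = pd.DataFrame()
            correlations = pd.DataFrame()
            notes.append("comparisons: stage skipped (no outcomes provided)")
            notes.append("correlations: stage skipped (no outcomes provided)")

        manifest = {
            "stepvar_version": __version__,
            "n_subjects": int(self.activity["subject_id"].nunique()),
            "n_records": int(len(self.activity)),
            "config": {
                "poincare": asdict(self.poincare),
                "block_days": self.block_days,
                "alpha": self.alpha,
                "correlation_policy": self.correlation_policy,
                "bh_adjust": self.bh_adjust,
            },
            "validation": {
                "n_duplicate_dates": report.n_duplicate_dates,
                "n_out_of_range": report.n_out_of_range,
                "n_gaps": len(report.date_gaps),
            },
            "notes": notes,
        }
        return VariabilityResults(self, descriptors, monthly, comparisons, correlations, manifest)


@dataclass
class VariabilityResults:
    """Fitted tables and diagnostics of an :class:`ActivityVariabilityModel`."""

    model: ActivityVariabilityModel
    descriptors: pd.DataFrame
    monthly: pd.DataFrame
    comparisons: pd.DataFrame
    correlations: pd.DataFrame
    manifest: dict = field(default_factory=dict)

    # -- reporting ----------------------------------------------------------

    def summary(self) -> str:
        """Human-readable multi-table summary."""
        parts = [
            "Activity variability analysis",
            "=" * 64,
            f"subjects: {self.manifest.get('n_subjects')}   "
            f"records: {self.manifest.get('n_records')}   "
            f"stepvar {self.manifest.get('stepvar_version')}",
        ]

        def block(title, frame, floatfmt="%.4g"):
            parts.append("")
            parts.append(title)
            parts.append("-" * len(title))
            if frame is None or not len(frame):
                parts.append("(empty)")
            else:
                parts.append(frame.to_string(index=False, float_format=lambda v: floatfmt % v))

        block("Poincaré descriptors (per subject × metric)", self.descriptors)
        block("Monthly activity summaries", self.monthly)
        block("Paired baseline vs follow-up comparisons", self.comparisons)
        block("Outcome-change vs descriptor correlations", self.correlations)
        if self.manifest.get("notes"):
            parts.append("")
            parts.append("Notes")
            parts.append("-----")
            parts.extend(f"- {n}" for n in self.manifest["notes"])
        return "\n".join(parts)

    def save_tables(self, outdir) -> dict:
        """Write the four tables (CSV) and the manifest (YAML); returns paths.

        Table bytes depend only on the model inputs and configuration, so
        identical config + seed reproduces them byte for byte; run metadata
        (timestamp, versions) lives in the manifest only.
        """
        import yaml

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, frame in [
            ("descriptors", self.descriptors),
            ("monthly", self.monthly),
            ("comparisons", self.comparisons),
            ("correlations", self.correlations),
        ]:
            path = outdir / f"{name}.csv"
            frame.to_csv(path, index=False)
            paths[name] = path
        manifest = dict(self.manifest)
        manifest["written_at"] = dt.datetime.now().isoformat(timespec="seconds")
        manifest["empty_tables"] = {
            name: "empty-with-reason: see notes" if not len(frame) else "populated"
            for name, frame in [
                ("descriptors", self.descriptors),
                ("monthly", self.monthly),
                ("comparisons", self.comparisons),
                ("correlations", self.correlations),
            ]
        }
        path = outdir / "manifest.yaml"
        path.write_text(yaml.safe_dump(manifest, sort_keys=True))
        paths["manifest"] = path
        return paths

    # -- figure data --------------------------------------------------------

    def _subject_descriptors(self, subject_id: str, metric: str) -> PoincareDescriptors:
        row = self.descriptors[
            (self.descriptors["subject_id"] == subject_id)
            & (self.descriptors["metric"] == metric)
        ]
        if not len(row):
            raise ValidationError(f"no descriptor row for {subject_id}/{metric}")
        r = row.iloc[0]
        return PoincareDescriptors(
            avg=r["avg"], sd=r["sd"], sd1=r["sd1"], sd2=r["sd2"],
            sd12=r["sd12"], afe=r["afe"], n_pairs=int(r["n_pairs"]),
        )

    def poincare_points(self, subject_id: str, metric: str) -> pd.DataFrame:
        """Scatter (xₙ, xₙ₊ᵢ) and fitted-ellipse coordinates for one subject.

        Columns: kind ("pair" or "ellipse"), x, y — the plottable data
        behind :meth:`plot_poincare`, emitted so figures are testable
        without image comparison.
        """
        series = next(
            s
            for s in series_from_frame(
                self.model.activity[self.model.activity["subject_id"] == subject_id],
                metric,
            )
        )
        pairs = lagged_pairs(series, self.model.poincare)
        desc = self._subject_descriptors(subject_id, metric)
        outline = ellipse_outline(desc)
        frames = [
            pd.DataFrame({"kind": "pair", "x": pairs[:, 0], "y": pairs[:, 1]}),
            pd.DataFrame({"kind": "ellipse", "x": outline[:, 0], "y": outline[:, 1]}),
        ]
        return pd.concat(frames, ignore_index=True)

    def plot_poincare(self, subject_id: str, metric: str = "steps", ax=None):
        """Poincaré scatter with the fitted ellipse for one subject × metric."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        points = self.poincare_points(subject_id, metric)
        pairs = points[points["kind"] == "pair"]
        outline = points[points["kind"] == "ellipse"]
        ax.scatter(pairs["x"], pairs["y"], s=12, alpha=0.6, label="daily pairs")
        ax.plot(outline["x"], outline["y"], color="C3", label="fitting ellipse")
        lo = min(pairs["x"].min(), pairs["y"].min())
        hi = max(pairs["x"].max(), pairs["y"].max())
        ax.plot([lo, hi], [lo, hi], color="grey", lw=0.8, ls="--")
        ax.set_xlabel(r"$x_n$")
        ax.set_ylabel(r"$x_{n+i}$")
        ax.set_title(f"{subject_id} — {metric}")
        ax.legend()
        return ax

    def plot_delta_scatter(self, outcome: str, descriptor: str, ax=None):
        """Outcome change vs a descriptor column (e.g. ``steps.sd2``)."""
        import matplotlib.pyplot as plt

        from .stats import descriptor_wide

        if ax is None:
            _, ax = plt.subplots()
        wide = descriptor_wide(self.descriptors)
        outcomes = self.model.outcomes
        deltas = (
            outcomes.assign(delta=outcomes["followup"] - outcomes["baseline"])
            .pivot(index="subject_id", columns="outcome", values="delta")
        )
        joined = deltas[[outcome]].join(wide[[descriptor]], how="inner").dropna()
        ax.scatter(joined[descriptor], joined[outcome], s=18)
        ax.set_xlabel(descriptor)
        ax.set_ylabel(f"Δ {outcome}")
        if len(joined) >= 2 and joined[descriptor].std() > 0:
            slope, intercept = np.polyfit(joined[descriptor], joined[outcome], 1)
            xs = np.linspace(joined[descriptor].min(), joined[descriptor].max(), 50)
            ax.plot(xs, slope * xs + intercept, color="C3", lw=1)
        return ax
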