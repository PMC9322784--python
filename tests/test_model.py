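"""End-to-end tests for the Model/Results layer, the pipeline and the CLI."""

import numpy as np
import pandas as pd
import yaml
from click.testing import CliRunner

from stepvar.cli import main
from stepvar.model import ActivityVariabilityModel
from stepvar.pipeline import AnalysisConfig, run_analysis
from stepvar.simulate import (
    Ar1Params,
    OutcomeSpec,
    SyntheticCohortConfig,
    simulate_cohort,
)


def small_config(**kw):
    base = dict(n_subjects=6, n_days=70, seed=31)
    base.update(kw)
    return SyntheticCohortConfig(**base)


class TestModelFit:
    def test_tables_populated_for_default_cohort(self, default_cohort):
        results = ActivityVariabilityModel.from_simulation(default_cohort).fit()
        assert len(results.descriptors) > 0
        assert set(results.descriptors.columns) >= {
            "subject_id", "metric", "n_days", "n_pairs", "avg", "sd", "sd1", "sd2", "sd12", "afe",
        }
        assert results.monthly["month_index"].max() >= 6
        assert len(results.comparisons) == 3
        assert len(results.correlations) > 0
        assert "n_subjects" in results.manifest

    def test_summary_text_mentions_every_stage(self, default_cohort):
        text = ActivityVariabilityModel.from_simulation(default_cohort).fit().summary()
        for fragment in ("Poincaré descriptors", "Monthly", "Paired", "correlations"):
            assert fragment in text

    def test_no_outcomes_skips_late_stages_with_notes(self):
        bundle = simulate_cohort(small_config())
        results = ActivityVariabilityModel(bundle.activity).fit()
        assert not len(results.comparisons)
        assert not len(results.correlations)
        notes = "\n".join(results.manifest["notes"])
        assert "comparisons: stage skipped" in notes
        assert "correlations: stage skipped" in notes

    def test_constant_subject_degenerate_descriptors(self):
        dates = pd.date_range("2020-08-01", periods=60).date
        frame = pd.DataFrame(
            {
                "subject_id": "S01",
                "date": dates,
                "steps": 5000,
                "distance_km": 3.5,
                "minutes_sedentary": 800,
                "minutes_lightly_active": 300,
                "minutes_fairly_active": 20,
                "minutes_very_active": 10,
            }
        )
        results = ActivityVariabilityModel(frame).fit()
        row = results.descriptors.query("metric == 'steps'").iloc[0]
        assert row["sd1"] == 0 and row["sd2"] == 0 and row["afe"] == 0
        assert np.isnan(row["sd12"])
        notes = "\n".join(results.manifest["notes"])
        assert "stage skipped" in notes

    def test_strong_coupling_recovered_end_to_end(self):
        # strong long-term-variability -> lipid-delta coupling survives the
        # full pipeline (simulation, records, descriptors, correlation)
        from stepvar.simulate import OutcomeCoupling

        cfg = SyntheticCohortConfig(
            n_subjects=60,
            n_days=120,
            seed=13,
            activity_params={"steps": Ar1Params(2800, 0.3, 9900)},
            outcomes=(OutcomeSpec("tc", 5.7, 1.14),),
            couplings=(OutcomeCoupling("steps", "SD2", "tc", 3e-3, noise_sd=0.5),),
        )
        results = ActivityVariabilityModel.from_simulation(
            cfg, correlation_policy="pearson"
        ).fit()
        row = results.correlations.query(
            "outcome_delta == 'tc' and descriptor == 'steps.sd2'"
        ).iloc[0]
        assert row["r"] > 0.7
        assert row["p_value"] < 1e-6


class TestPipelineRuns:
    def test_simulate_mode_byte_identical_tables(self, tmp_path):
        paths = []
        for name in ("a", "b"):
            cfg = AnalysisConfig(
                input_mode="simulate",
                seed=42,
                simulation=dict(n_subjects=6, n_days=70),
                output_dir=str(tmp_path / name),
            )
            run_analysis(cfg)
            paths.append(tmp_path / name)
        for table in ("descriptors", "monthly", "comparisons", "correlations"):
            assert (paths[0] / f"{table}.csv").read_bytes() == (
                paths[1] / f"{table}.csv"
            ).read_bytes()

    def test_canonical_csv_mode(self, tmp_path):
        from stepvar.data import frame_to_records
        from stepvar.io import write_canonical

        bundle = simulate_cohort(small_config())
        activity_path = tmp_path / "activity.csv"
        activity_path.write_text(write_canonical(frame_to_records(bundle.activity)))
        outcomes_path = tmp_path / "outcomes.csv"
        bundle.outcomes.to_csv(outcomes_path, index=False)
        cfg = AnalysisConfig(
            input_mode="canonical_csv",
            activity_path=str(activity_path),
            outcomes_path=str(outcomes_path),
            output_dir=str(tmp_path / "out"),
        )
        results = run_analysis(cfg)
        assert len(results.descriptors)
        assert (tmp_path / "out" / "manifest.yaml").exists()
        manifest = yaml.safe_load((tmp_path / "out" / "manifest.yaml").read_text())
        assert manifest["input_mode"] == "canonical_csv"

    def test_null_couplings_rarely_bh_significant(self):
        # with no true couplings, BH-adjusted correlation tables should be
        # clean for (almost) all seeds; fixed seed list keeps this exact
        hits = 0
        for seed in range(20):
            cfg = SyntheticCohortConfig(
                n_subjects=12,
                n_days=60,
                seed=1000 + seed,
                activity_params={"steps": Ar1Params(2800, 0.3, 9900)},
                outcomes=(OutcomeSpec("y", 0.0, 1.0, delta_noise_sd=1.0),),
                couplings=(),
            )
            results = ActivityVariabilityModel.from_simulation(
                cfg, bh_adjust=True, correlation_policy="pearson"
            ).fit()
            table = results.correlations
            if (table.loc[table["defined"], "p_adj_bh"] < 0.05).any():
                hits += 1
        assert hits <= 1  # >= 95% of the 20 seeds are clean

    def test_figure_data_emitted_with_figures_flag(self, tmp_path):
        import matplotlib

        matplotlib.use("Agg")
        cfg = AnalysisConfig(
            input_mode="simulate",
            seed=3,
            simulation=dict(n_subjects=3, n_days=70),
            output_dir=str(tmp_path / "out"),
            figures=True,
        )
        results = run_analysis(cfg)
        figdir = tmp_path / "out" / "figures"
        data_files = list(figdir.glob("poincare_*_steps.csv"))
        assert data_files
        points = pd.read_csv(data_files[0])
        assert set(points["kind"]) == {"pair", "ellipse"}
        sid = data_files[0].stem.split("_")[1]
        n_pairs = int(
            results.descriptors.query(
                "subject_id == @sid and metric == 'steps'"
            ).iloc[0]["n_pairs"]
        )
        assert (points["kind"] == "pair").sum() == n_pairs


class TestCli:
    def test_descriptors_command(self, tmp_path):
        from stepvar.data import frame_to_records
        from stepvar.io import write_canonical

        bundle = simulate_cohort(small_config())
        src = tmp_path / "activity.csv"
        src.write_text(write_canonical(frame_to_records(bundle.activity)))
        out = tmp_path / "desc.csv"
        result = CliRunner().invoke(
            main, ["descriptors", "--in", str(src), "--lag", "1",
                   "--mode", "calendar", "--out", str(out)]
        )
        assert result.exit_code == 0, result.output
        table = pd.read_csv(out)
        assert {"subject_id", "metric", "sd1", "sd2"} <= set(table.columns)

    def test_simulate_and_run_commands(self, tmp_path):
        sim_cfg = tmp_path / "sim.yaml"
        sim_cfg.write_text(yaml.safe_dump(dict(n_subjects=4, n_days=70)))
        outdir = tmp_path / "cohort"
        result = CliRunner().invoke(
            main, ["simulate", "--config", str(sim_cfg), "--out", str(outdir), "--seed", "5"]
        )
        assert result.exit_code == 0, result.output
        assert (outdir / "activity.csv").exists()
        assert (outdir / "outcomes.csv").exists()

        run_cfg = tmp_path / "run.yaml"
        run_cfg.write_text(
            yaml.safe_dump(
                dict(
                    input_mode="canonical_csv",
                    activity_path=str(outdir / "activity.csv"),
                    outcomes_path=str(outdir / "outcomes.csv"),
                    output_dir=str(tmp_path / "report"),
                )
            )
        )
        result = CliRunner().invoke(main, ["run", "--config", str(run_cfg)])
        assert result.exit_code == 0, result.output
        assert (tmp_path / "report" / "descriptors.csv").exists()

    def test_run_fails_cleanly_on_missing_input(self, tmp_path):
        run_cfg = tmp_path / "run.yaml"
        run_cfg.write_text(
            yaml.safe_dump(dict(input_mode="canonical_csv", activity_path="/nonexistent.csv",
                                output_dir=str(tmp_path / "o")))
        )
        result = CliRunner().invoke(main, ["run", "--config", str(run_cfg)])
        assert result.exit_code != 0
        assert "ingest" in result.output
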