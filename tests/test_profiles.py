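"""End-to-end depth profiling, CSV round-trips and the CLI."""

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from groovescreen import (
    ImageStack,
    RunConfig,
    SynthConfig,
    evaluate_against_truth,
    generate_stack,
    profile_stack,
    read_profile,
    write_profile,
)
from groovescreen.cli import main as cli_main
from groovescreen.profiles import SliceMetrics


def run_config(**kw):
    defaults = dict(groove_angle_deg=30.0, pixel_size_xy=0.5, z_step_um=0.3)
    defaults.update(kw)
    return RunConfig(**defaults)


class TestProfileStack:
    def test_background_only_stack_all_rows_empty(self, rng):
        vox = rng.poisson(40.0, size=(13, 128, 128)).astype(np.uint16)
        stack = ImageStack(vox, 0.5, 0.3)
        rows = profile_stack(stack, run_config(stop_after_empty=None))
        assert len(rows) == 3
        for m in rows:
            assert m.n_cells == 0
            assert m.total_outgrowth_um == 0.0
            assert m.alignment_pct is None
            assert m.support_px == 0

    def test_default_cutoff_stops_after_two_empty_slices(self, rng):
        vox = rng.poisson(40.0, size=(31, 128, 128)).astype(np.uint16)
        stack = ImageStack(vox, 0.5, 0.3)
        rows = profile_stack(stack, run_config())
        assert len(rows) == 2  # truncated by the zero-outgrowth cutoff

    def test_surface_only_aligned_limit_case(self):
        """Somas on slice 0 only, all neurites on the groove axis, noise off."""
        cfg = SynthConfig(
            shape=(13, 256, 256), n_cells_surface=8.0, max_cell_depth_um=0.1,
            kappa_surface=1e9, kappa_decay_length_um=1e9, avoid_soma_overlap=True,
            noise_sd=0.0, poisson_gain=0.0, seed=11,
        )
        stack, truth = generate_stack(cfg)
        rows = profile_stack(stack, run_config(groove_angle_deg=cfg.groove.angle_deg))
        assert rows[0].n_cells == truth.true_n_cells[0]
        assert rows[0].alignment_pct == pytest.approx(100.0)
        for m in rows[1:]:
            assert m.n_cells == 0
            assert m.total_outgrowth_um == 0.0

    def test_deterministic_across_runs(self):
        cfg = SynthConfig(shape=(7, 192, 192), n_cells_surface=10.0, seed=13)
        stack, _ = generate_stack(cfg)
        a = profile_stack(stack, run_config())
        b = profile_stack(stack, run_config())
        assert a == b

    def test_agrees_with_depth_truncated_stack(self):
        cfg = SynthConfig(shape=(13, 192, 192), n_cells_surface=10.0, seed=17)
        stack, _ = generate_stack(cfg)
        cut = ImageStack(stack.voxels[:7], stack.pixel_size_xy, stack.z_step_um)
        full_rows = profile_stack(stack, run_config(stop_after_empty=None))
        cut_rows = profile_stack(cut, run_config(stop_after_empty=None))
        shared = {m.slice_index: m for m in full_rows}
        for m in cut_rows:
            assert shared[m.slice_index] == m

    def test_isotropic_regime_near_baseline(self):
        """kappa = 0 stacks: mean alignment over populated slices ~ 33%."""
        pcts = []
        for seed in range(10):
            cfg = SynthConfig(
                shape=(7, 192, 192), n_cells_surface=12.0, kappa_surface=0.0, seed=400 + seed
            )
            stack, _ = generate_stack(cfg)
            for m in profile_stack(stack, run_config(groove_angle_deg=cfg.groove.angle_deg)):
                if m.alignment_pct is not None:
                    pcts.append(m.alignment_pct)
        assert np.mean(pcts) == pytest.approx(33.3, abs=2.0)


class TestProfileCsv:
    def metrics(self):
        return [
            SliceMetrics(0, 0.0, 5, 123.456789, 58.51234, 300),
            SliceMetrics(6, 1.8, 3, 0.0, None, 0),
        ]

    def test_single_row_file_has_header_and_row(self, tmp_path):
        path = tmp_path / "p.csv"
        write_profile(self.metrics()[:1], path)
        assert len(path.read_text().strip().splitlines()) == 2

    def test_roundtrip_to_written_precision(self, tmp_path):
        path = tmp_path / "p.csv"
        write_profile(self.metrics(), path)
        back = read_profile(path)
        assert list(back.columns) == [
            "slice_index", "z_um", "n_cells", "total_outgrowth_um", "alignment_pct", "support_px",
        ]
        assert back.loc[0, "total_outgrowth_um"] == pytest.approx(123.457)
        assert back.loc[0, "alignment_pct"] == pytest.approx(58.512)

    def test_missing_alignment_serializes_empty_and_parses_nan(self, tmp_path):
        path = tmp_path / "p.csv"
        write_profile(self.metrics(), path)
        row = path.read_text().strip().splitlines()[2]
        assert ",," in row  # empty alignment field
        back = read_profile(path)
        assert np.isnan(back.loc[1, "alignment_pct"])

    def test_empty_metrics_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            write_profile([], tmp_path / "p.csv")


class TestEvaluate:
    def test_error_columns(self):
        profile = pd.DataFrame(
            {"slice_index": [0], "z_um": [0.0], "n_cells": [5],
             "total_outgrowth_um": [100.0], "alignment_pct": [60.0], "support_px": [100]}
        )
        truth = pd.DataFrame(
            {"slice_index": [0], "true_n_cells": [6],
             "true_outgrowth_um": [110.0], "true_aligned_fraction": [0.55]}
        )
        out = evaluate_against_truth(profile, truth)
        assert out.loc[0, "cells_abs_err"] == 1
        assert out.loc[0, "outgrowth_abs_err_um"] == pytest.approx(10.0)
        assert out.loc[0, "alignment_abs_err_pct"] == pytest.approx(5.0)


class TestRunConfig:
    def test_from_yaml_with_overrides(self, tmp_path):
        cfg_path = tmp_path / "cfg.yaml"
        cfg_path.write_text(
            "groove_angle_deg: 10.0\npixel_size_xy: 0.4\n"
            "soma:\n  min_soma_area_px: 40\n  max_soma_area_px: 900\n"
        )
        cfg = RunConfig.from_yaml(cfg_path, groove_angle_deg=77.0)
        assert cfg.groove_angle_deg == 77.0
        assert cfg.pixel_size_xy == 0.4
        assert cfg.soma.min_soma_area_px == 40

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError):
            RunConfig(groove_angle_deg=0.0, threshold_deg=120.0)


class TestCli:
    def test_simulate_analyze_evaluate_pipeline(self, tmp_path):
        runner = CliRunner()
        synth_yaml = tmp_path / "synth.yaml"
        synth_yaml.write_text(
            "shape: [7, 192, 192]\nn_cells_surface: 10.0\nseed: 5\n"
            "groove:\n  angle_deg: 30.0\n"
        )
        res = runner.invoke(
            cli_main,
            ["simulate", "--config", str(synth_yaml), "--out-dir", str(tmp_path)],
        )
        assert res.exit_code == 0, res.output
        tif = tmp_path / "synthetic_seed5.tif"
        assert tif.exists()

        res = runner.invoke(
            cli_main,
            ["analyze", "--input", str(tif), "--pixel-size", "0.5", "--z-step", "0.3",
             "--groove-angle", "30.0", "--out-dir", str(tmp_path)],
        )
        assert res.exit_code == 0, res.output
        profile_csv = tmp_path / "synthetic_seed5_profile.csv"
        assert profile_csv.exists()

        res = runner.invoke(
            cli_main,
            ["evaluate", "--profile", str(profile_csv),
             "--truth", str(tmp_path / "synthetic_seed5_truth.csv")],
        )
        assert res.exit_code == 0, res.output
        assert "mean_alignment_abs_err_pct" in res.output
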