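"""Synthetic-data generators: determinism, truth sidecars, study structure."""

import json

import numpy as np
import pandas as pd
import pytest

from sterolflux.config import ScenarioConfig, SpeciesScenario, paper_like_scenario
from sterolflux.extraction import read_run
from sterolflux.qpcr import analyze_expression
from sterolflux.simulate import (
    generate_cq_table,
    generate_labelled_run,
    generate_viability_table,
    simulate_run_spectra,
)


def small_scenario(seed=0, **overrides):
    cfg = paper_like_scenario(seed=seed)
    return cfg.model_copy(update={"n_ms_replicates": 2, **overrides})


class TestLabelledRuns:
    def test_sidecar_records_truth_and_files_exist(self, tmp_path):
        cfg = small_scenario()
        sidecar = generate_labelled_run(cfg, tmp_path)
        truth = json.loads(sidecar.read_text())
        assert truth["seed"] == cfg.seed
        assert truth["enrichment_p"] == 0.30
        assert truth["species"]["lanosterol"]["fraction_new"]["CEM_R2"] == 0.30
        for run in truth["runs"]:
            assert (tmp_path / run["file"]).exists()

    def test_unlabelled_and_labelled_identical_when_p_zero(self, tmp_path):
        cfg = small_scenario(enrichment_p=0.0, envelope_cv=0.0, n_ms_replicates=1)
        rng = np.random.default_rng(0)
        plain = simulate_run_spectra(cfg, labelled=False, cell_line="CEM", rng=rng)
        heavy = simulate_run_spectra(cfg, labelled=True, cell_line="CEM", rng=rng)
        for a, b in zip(plain, heavy):
            assert np.allclose(a.mz, b.mz)
            assert np.allclose(a.intensity, b.intensity)

    def test_only_lanosterol_shifts_in_heavy_water(self):
        """Cholesterol (f=0) keeps its envelope; lanosterol's shifts up."""
        cfg = small_scenario(envelope_cv=0.0)

        def envelope_mean_shift(labelled, mz0, k):
            spectra = simulate_run_spectra(
                cfg, labelled=labelled, cell_line="CEM_R2",
                rng=np.random.default_rng(0),
            )
            total = np.zeros(k + 1)
            for s in spectra:
                for i in range(k + 1):
                    sel = np.abs(s.mz - (mz0 + i * 1.00336)) < 0.01
                    total[i] += s.intensity[sel].sum()
            total /= total.sum()
            return float(np.arange(k + 1) @ total)

        lan_shift = envelope_mean_shift(True, 409.3829, 8) - envelope_mean_shift(
            False, 409.3829, 8
        )
        chol_shift = envelope_mean_shift(True, 369.3516, 8) - envelope_mean_shift(
            False, 369.3516, 8
        )
        assert lan_shift > 1.0
        assert abs(chol_shift) < 1e-9

    def test_mzml_outputs_deterministic(self, tmp_path):
        cfg = small_scenario(n_ms_replicates=1)
        generate_labelled_run(cfg, tmp_path / "a")
        generate_labelled_run(cfg, tmp_path / "b")
        name = "CEM_d2o_rep1.mzML"
        assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()

    def test_out_of_range_species_rejected(self):
        with pytest.raises(ValueError, match="outside acquisition range"):
            ScenarioConfig(
                species=[SpeciesScenario(
                    name="tiny", formula="CH4", ion_species="[M+H]+",
                    rt_min=1.0, n_exch=0, fraction_new={"CEM": 0.0},
                )],
                mz_range=(70.0, 1700.0),
            )

    def test_runs_readable_and_centroided(self, tmp_path):
        cfg = small_scenario(n_ms_replicates=1)
        generate_labelled_run(cfg, tmp_path)
        spectra = read_run(tmp_path / "CEM_h2o_rep1.mzML")
        assert len(spectra) > 10
        assert all(np.all(np.diff(s.mz) > 0) for s in spectra)


class TestCqTables:
    def test_noiseless_folds_exact(self, tmp_path):
        from sterolflux.qpcr import relative_expression

        cfg = small_scenario(cq_sd=0.0)
        sidecar = generate_cq_table(cfg, tmp_path / "cq.csv")
        truth = json.loads(sidecar.read_text())
        table = pd.read_csv(tmp_path / "cq.csv", comment="#")
        for gene, fold in truth["gene_folds"].items():
            rel = relative_expression(table, gene)
            means = rel.groupby("condition")["relative_expression"].mean()
            # exact up to the 6-decimal Cq serialization in the CSV
            assert means[truth["comparison"]] / means[truth["baseline"]] == pytest.approx(
                fold, rel=1e-5
            )

    def test_default_scenario_recovers_study_pattern(self, tmp_path):
        cfg = small_scenario()
        sidecar = generate_cq_table(cfg, tmp_path / "cq.csv")
        truth = json.loads(sidecar.read_text())
        table = pd.read_csv(tmp_path / "cq.csv", comment="#")
        result = analyze_expression(
            table, sorted(truth["gene_folds"]), truth["baseline"], truth["comparison"]
        ).set_index("gene")
        assert 2 ** result.loc["CYP51A1", "log2_fold"] == pytest.approx(5.0, rel=0.25)
        assert 2 ** result.loc["SQLE", "log2_fold"] == pytest.approx(3.0, rel=0.25)
        assert result.loc["HMGCR", "log2_fold"] < 0

    def test_seed_reproducibility(self, tmp_path):
        cfg = small_scenario(seed=42)
        generate_cq_table(cfg, tmp_path / "a.csv")
        generate_cq_table(cfg, tmp_path / "b.csv")
        assert (tmp_path / "a.csv").read_bytes() == (tmp_path / "b.csv").read_bytes()
        header = (tmp_path / "a.csv").read_text().splitlines()[0]
        assert "seed=42" in header


class TestViabilityTables:
    def test_truth_effects_recovered(self, tmp_path):
        from sterolflux.viability import aggregate_experiments, normalize_viability

        cfg = small_scenario(n_experiments=8)
        sidecar = generate_viability_table(cfg, tmp_path / "v.csv")
        truth = json.loads(sidecar.read_text())
        table = pd.read_csv(tmp_path / "v.csv", comment="#")
        out = aggregate_experiments(normalize_viability(table))
        for line, effects in truth["effects"].items():
            chunk = out[out.cell_line == line]
            for treatment, effect in effects.items():
                observed = chunk.loc[chunk.treatment == treatment, "viability"].mean()
                assert observed == pytest.approx(effect, abs=0.12)

    def test_null_effect_rejects_at_alpha(self, tmp_path, rng):
        """With every effect 1.0 the Dunnett comparisons reject at ~alpha."""
        from sterolflux.viability import (
            aggregate_experiments, anova_dunnett, normalize_viability,
        )

        rejections, total = 0, 0
        for seed in range(40):
            cfg = small_scenario(
                seed=seed,
                viability_effects={
                    "CEM": {"vehicle": 1.0, "a": 1.0, "b": 1.0, "c": 1.0}
                },
                n_experiments=4,
            )
            generate_viability_table(cfg, tmp_path / f"null{seed}.csv")
            table = pd.read_csv(tmp_path / f"null{seed}.csv", comment="#")
            out = aggregate_experiments(normalize_viability(table))
            control = out.loc[out.treatment == "vehicle", "viability"].to_numpy()
            groups = {t: g["viability"].to_numpy()
                      for t, g in out.groupby("treatment") if t != "vehicle"}
            result = anova_dunnett(groups, control)
            rejections += sum(c.p_adjusted < 0.05 for c in result.comparisons) > 0
            total += 1
        assert rejections / total <= 0.20  # small-sample binomial slack around 0.05

    def test_strong_effect_detected(self, tmp_path):
        """Effect 0.5 at 10% CV and n=4 experiments is reliably detected."""
        from sterolflux.viability import (
            aggregate_experiments, anova_dunnett, normalize_viability,
        )

        hits, total = 0, 20
        for seed in range(total):
            cfg = small_scenario(
                seed=seed,
                viability_effects={"CEM": {"vehicle": 1.0, "drug": 0.5}},
                n_experiments=4,
            )
            generate_viability_table(cfg, tmp_path / f"eff{seed}.csv")
            table = pd.read_csv(tmp_path / f"eff{seed}.csv", comment="#")
            out = aggregate_experiments(normalize_viability(table))
            control = out.loc[out.treatment == "vehicle", "viability"].to_numpy()
            drug = out.loc[out.treatment == "drug", "viability"].to_numpy()
            result = anova_dunnett({"drug": drug}, control)
            hits += result.comparisons[0].p_adjusted < 0.05
        assert hits / total >= 0.9
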