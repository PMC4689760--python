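"""End-to-end orchestration: simulate -> extract -> fit -> qpcr -> viability.

Stages run in dependency order; a stage failure stops everything downstream
and is attributed to the stage by name. Every output file is hashed into a
run manifest together with the config snapshot and seed, so deterministic
stages can be verified to reproduce byte-identically.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import ScenarioConfig
from .enrichment import fit_fraction_new, mass_shift_index
from .extraction import read_run, integrate_isotopologues
from .isotopes import IsotopologueDistribution
from .labeling import build_correction_matrix, correct_mid
from .qpcr import analyze_expression
from .simulate import generate_all
from .viability import (
    aggregate_experiments,
    anova_dunnett,
    normalize_viability,
    significance_stars,
)

__all__ = ["PipelineError", "run_pipeline", "report", "extract_runs", "fit_flux"]


class PipelineError(RuntimeError):
    """A stage failed; ``stage`` names the culprit."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class _Bundle:
    out_dir: Path
    manifest: dict


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def extract_runs(ms_sidecar: Path, tol_ppm: float = 20.0) -> pd.DataFrame:
    """Integrate isotopologue envelopes for every run listed in a sidecar."""
    truth = json.loads(Path(ms_sidecar).read_text())
    ms_dir = Path(ms_sidecar).parent
    from .extraction import MolecularSpecies

    species = [
        MolecularSpecies(
            name=name, formula=meta["formula"], ion_species=meta["ion_species"],
            rt_min=meta["rt_min"], rt_halfwidth=meta["rt_halfwidth"],
            n_exch=meta["n_exch"], k_max=meta["k_max"],
        )
        for name, meta in truth["species"].items()
    ]
    rows = []
    for run in truth["runs"]:
        spectra = read_run(ms_dir / run["file"])
        for sp in species:
            result = integrate_isotopologues(spectra, sp, tol_ppm, sample=run["file"])
            record = {
                "species": sp.name,
                "cell_line": run["cell_line"],
                "labelled": run["labelled"],
                "replicate": run["replicate"],
                "detected": result.detected,
                "rt_apex": result.rt_apex,
            }
            for i, value in enumerate(result.intensities):
                record[f"I{i}"] = value
            rows.append(record)
    return pd.DataFrame(rows)


def fit_flux(intensities: pd.DataFrame, cfg: ScenarioConfig) -> pd.DataFrame:
    """Fit fraction-new and the corrected-envelope shift index per replicate.

    The fraction new comes from the raw-envelope mixture fit (exactly the
    inverse of the forward model, so it carries no deconvolution error);
    the natural-abundance-corrected envelope feeds the model-free mass
    shift index.
    """
    species_meta = {sp.name: sp for sp in cfg.species}
    out = []
    for (name, line, labelled), chunk in intensities.groupby(
        ["species", "cell_line", "labelled"]
    ):
        if not labelled:
            continue
        sp = species_meta[name]
        ion = sp.to_species().ion_counts
        correction = build_correction_matrix(ion, k_max=sp.k_max)
        raw_reps, corrected_reps = [], []
        for _, row in chunk.iterrows():
            if not row["detected"]:
                continue
            raw = IsotopologueDistribution(
                [row[f"I{i}"] for i in range(sp.k_max + 1)], species=name
            )
            raw_reps.append(raw)
            corrected_reps.append(correct_mid(raw, correction))
        if not raw_reps:
            continue
        estimate = fit_fraction_new(
            raw_reps, ion, p=cfg.enrichment_p,
            n_exch=sp.n_exch, k_max=sp.k_max, species=name, condition=line,
        )
        delta0 = IsotopologueDistribution(
            np.eye(sp.k_max + 1)[0] + 0.0, species=name
        )
        for rep_index, (mid, f_rep) in enumerate(
            zip(corrected_reps, estimate.replicate_f), start=1
        ):
            out.append(
                {
                    "species": name,
                    "condition": line,
                    "replicate": rep_index,
                    "f_hat": f_rep,
                    "ci_lo": estimate.ci_lo,
                    "ci_hi": estimate.ci_hi,
                    "shift_index": mass_shift_index(mid, delta0),
                    "residual": estimate.residual,
                    "f_hat_group": estimate.f_hat,
                    "at_boundary": estimate.at_boundary,
                }
            )
    return pd.DataFrame(out)


def run_pipeline(cfg: ScenarioConfig, out_dir, tol_ppm: float = 20.0) -> dict:
    """Run every stage under ``out_dir``; returns the manifest dict."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": cfg.model_dump(mode="json"),
        "seed": cfg.seed,
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": {},
        "outputs": {},
    }

    def run_stage(name: str, fn):
        try:
            result = fn()
        except Exception as err:  # noqa: BLE001 - stage attribution is the point
            manifest["stages"][name] = {"status": "failed", "error": str(err)}
            _write_manifest(out_dir, manifest)
            raise PipelineError(name, err) from err
        manifest["stages"][name] = {"status": "ok"}
        return result

    sidecars = run_stage("simulate", lambda: generate_all(cfg, out_dir / "inputs"))

    intensities = run_stage(
        "extract", lambda: extract_runs(sidecars["ms"], tol_ppm=tol_ppm)
    )
    intensities_path = out_dir / "isotopologue_intensities.csv"
    intensities.to_csv(intensities_path, index=False, float_format="%.6f")

    flux = run_stage("fit", lambda: fit_flux(intensities, cfg))
    flux_path = out_dir / "flux_estimates.csv"
    flux.to_csv(flux_path, index=False, float_format="%.6f")

    def qpcr_stage():
        table = pd.read_csv(out_dir / "inputs" / "qpcr" / "cq_table.csv", comment="#")
        baseline, comparison = cfg.cell_lines
        result = analyze_expression(
            table, sorted(cfg.gene_folds), baseline=baseline, comparison=comparison
        )
        result["stars"] = result["p_value"].map(significance_stars)
        return result

    expression = run_stage("qpcr", qpcr_stage)
    expression_path = out_dir / "expression_folds.csv"
    expression.to_csv(expression_path, index=False, float_format="%.6f")

    def viability_stage():
        table = pd.read_csv(
            out_dir / "inputs" / "viability" / "viability.csv", comment="#"
        )
        normalized = normalize_viability(table)
        per_experiment = aggregate_experiments(normalized)
        rows = []
        for line, chunk in per_experiment.groupby("cell_line"):
            control = chunk.loc[chunk["treatment"] == "vehicle", "viability"].to_numpy()
            treatments = {
                t: g["viability"].to_numpy()
                for t, g in chunk.groupby("treatment")
                if t != "vehicle"
            }
            result = anova_dunnett(treatments, control)
            for comp in result.comparisons:
                rows.append(
                    {
                        "cell_line": line,
                        "treatment": comp.treatment,
                        "mean_viability": comp.mean_difference + control.mean(),
                        "difference_vs_vehicle": comp.mean_difference,
                        "ci_lo": comp.ci_lo,
                        "ci_hi": comp.ci_hi,
                        "p_adjusted": comp.p_adjusted,
                        "stars": significance_stars(comp.p_adjusted),
                        "anova_f": result.f_statistic,
                        "anova_p": result.anova_p,
                    }
                )
        return pd.DataFrame(rows)

    viability_results = run_stage("viability", viability_stage)
    viability_path = out_dir / "viability_results.csv"
    viability_results.to_csv(viability_path, index=False, float_format="%.6f")

    run_stage("figures", lambda: _figures(out_dir, flux, expression, viability_results))

    for path in (intensities_path, flux_path, expression_path, viability_path):
        manifest["outputs"][path.name] = _sha256(path)
    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    _write_manifest(out_dir, manifest)
    return manifest


def _write_manifest(out_dir: Path, manifest: dict) -> None:
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")


def _figures(out_dir: Path, flux, expression, viability_results) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 3, figsize=(13, 4))
    if not flux.empty:
        for i, (label, chunk) in enumerate(flux.groupby(["species", "condition"])):
            axes[0].scatter([i] * len(chunk), chunk["f_hat"], s=12)
            axes[0].annotate("/".join(label), (i, chunk["f_hat"].max()), fontsize=6,
                             rotation=45)
    axes[0].set_ylabel("fraction newly synthesized")
    if not expression.empty:
        axes[1].bar(expression["gene"], expression["log2_fold"])
        axes[1].axhline(0, color="k", lw=0.5)
        axes[1].set_ylabel("log2 fold change")
        axes[1].tick_params(axis="x", rotation=45)
    if not viability_results.empty:
        for line, chunk in viability_results.groupby("cell_line"):
            axes[2].plot(chunk["treatment"], chunk["mean_viability"], "o-", label=line)
        axes[2].legend(fontsize=6)
        axes[2].set_ylabel("viability vs vehicle")
        axes[2].tick_params(axis="x", rotation=90)
    fig.tight_layout()
    fig.savefig(out_dir / "summary.png", dpi=120)
    plt.close(fig)


def report(out_dir) -> str:
    """Human-readable summary of a completed results bundle."""
    out_dir = Path(out_dir)
    manifest_path = out_dir / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest in {out_dir}; incomplete bundle")
    manifest = json.loads(manifest_path.read_text())
    failed = [s for s, meta in manifest["stages"].items() if meta["status"] != "ok"]
    lines = [f"sterolflux run (seed {manifest['seed']})", "=" * 40]
    if failed:
        lines.append(f"FAILED stages: {', '.join(failed)}")

    def table_or_placeholder(name: str, title: str) -> None:
        lines.append("")
        lines.append(title)
        lines.append("-" * len(title))
        path = out_dir / name
        if not path.exists():
            lines.append("(no data)")
            return
        frame = pd.read_csv(path)
        if frame.empty:
            lines.append("(no data)")
            return
        lines.append(frame.to_string(index=False, float_format=lambda v: f"{v:.4f}"))

    table_or_placeholder(
        "flux_estimates.csv", "De novo synthesis (fraction new and shift index)"
    )
    table_or_placeholder("expression_folds.csv", "qPCR log2 fold changes")
    table_or_placeholder("viability_results.csv", "Viability vs vehicle (Dunnett)")
    lines.append("")
    lines.append("stars: # p<=0.1, * p<=0.05, ** p<=0.01, *** p<=0.001")
    return "\n".join(lines)
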