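"""Synthetic-data generators with ground-truth sidecars.

Every generator emulates one of the study's raw-data modalities — centroided
LC-MS runs, long-format Cq tables, viability plate tables — under a
:class:`~sterolflux.config.ScenarioConfig` whose parameters are the truth.
Each artifact gets a JSON sidecar recording the seed and every true value,
so downstream checks read truth from the sidecar rather than re-hardcoding
it. Identical config + seed produce byte-identical outputs.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from ._mzml import write_mzml
from .config import ScenarioConfig
from .extraction import CentroidSpectrum
from .isotopes import natural_mid
from .labeling import LabelingModelParams, labeled_mid, mixture_mid
from .qpcr import DEFAULT_REFERENCE_GENES

__all__ = [
    "generate_labelled_run",
    "generate_cq_table",
    "generate_viability_table",
    "generate_all",
]


def _write_sidecar(path: Path, payload: dict) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def simulate_run_spectra(
    cfg: ScenarioConfig, labelled: bool, cell_line: str, rng: np.random.Generator
) -> list[CentroidSpectrum]:
    """Build centroided MS1 scans for one sample (one injection).

    Each species contributes Gaussian elution peaks on its isotopologue m/z
    grid with envelope mixture_mid(f_true) in the heavy-water run and the
    natural envelope in the plain-water run, plus multiplicative
    (log-normal, CV ``envelope_cv``) and additive-floor noise.
    """
    if not cfg.species:
        raise ValueError("scenario has no species")
    rt_lo = min(sp.rt_min - 3 * sp.rt_halfwidth for sp in cfg.species)
    rt_hi = max(sp.rt_min + 3 * sp.rt_halfwidth for sp in cfg.species)
    dt = cfg.scan_interval_s / 60.0
    rt_grid = np.arange(max(rt_lo, 0.0), rt_hi + dt, dt)
    sigma_min = cfg.peak_sigma_s / 60.0

    per_species = []
    for sp in cfg.species:
        mspec = sp.to_species()
        ion = mspec.ion_counts
        natural = natural_mid(ion, k_max=sp.k_max, species=sp.name)
        f_true = sp.fraction_new.get(cell_line, 0.0) if labelled else 0.0
        p_true = cfg.enrichment_p if labelled else 0.0
        lab = labeled_mid(
            ion, LabelingModelParams(p=p_true, n_exch=sp.n_exch), k_max=sp.k_max,
            species=sp.name,
        )
        envelope = mixture_mid(f_true, natural, lab).abundances
        per_species.append((mspec.mz_grid(), envelope * sp.apex_intensity, sp))

    spectra = []
    for rt in rt_grid:
        mz_list, int_list = [], []
        for grid, heights, sp in per_species:
            elution = np.exp(-0.5 * ((rt - sp.rt_min) / sigma_min) ** 2)
            intensity = heights * elution
            if cfg.envelope_cv > 0:
                sd = np.sqrt(np.log1p(cfg.envelope_cv**2))
                intensity = intensity * rng.lognormal(-0.5 * sd**2, sd, size=intensity.size)
            if cfg.noise_floor > 0:
                intensity = intensity + rng.uniform(0, cfg.noise_floor, size=intensity.size)
            keep = intensity > 1e-9
            mz_list.append(grid[keep])
            int_list.append(intensity[keep])
        mz = np.concatenate(mz_list)
        intensity = np.concatenate(int_list)
        order = np.argsort(mz)
        spectra.append(CentroidSpectrum(rt_min=float(rt), mz=mz[order], intensity=intensity[order]))
    return spectra


def generate_labelled_run(cfg: ScenarioConfig, out_dir) -> Path:
    """Write paired plain-water / heavy-water mzML runs plus a truth sidecar.

    One mzML per (cell line, media, replicate); returns the sidecar path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    truth: dict = {
        "seed": cfg.seed,
        "enrichment_p": cfg.enrichment_p,
        "species": {
            sp.name: {
                "formula": sp.formula,
                "ion_species": sp.ion_species,
                "n_exch": sp.n_exch,
                "k_max": sp.k_max,
                "rt_min": sp.rt_min,
                "rt_halfwidth": sp.rt_halfwidth,
                "fraction_new": sp.fraction_new,
            }
            for sp in cfg.species
        },
        "runs": [],
    }
    for line_index, cell_line in enumerate(cfg.cell_lines):
        for labelled in (False, True):
            for replicate in range(1, cfg.n_ms_replicates + 1):
                rng = np.random.default_rng(
                    [cfg.seed, line_index, int(labelled), replicate]
                )
                spectra = simulate_run_spectra(cfg, labelled, cell_line, rng)
                media = "d2o" if labelled else "h2o"
                name = f"{cell_line}_{media}_rep{replicate}.mzML"
                write_mzml(out_dir / name, spectra)
                truth["runs"].append(
                    {
                        "file": name,
                        "cell_line": cell_line,
                        "labelled": labelled,
                        "replicate": replicate,
                        "enrichment_p": cfg.enrichment_p if labelled else 0.0,
                    }
                )
    sidecar = out_dir / "runs_truth.json"
    _write_sidecar(sidecar, truth)
    return sidecar


def generate_cq_table(cfg: ScenarioConfig, out_path) -> Path:
    """Write a long-format Cq CSV emulating the two-line qPCR comparison.

    Reference genes are constant across conditions up to Gaussian Cq noise;
    each target gene is offset by -log2(true fold) cycles in the comparison
    line. Returns the truth sidecar path.
    """
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng([cfg.seed, 101])
    baseline, comparison = cfg.cell_lines
    rows = []
    for condition in (baseline, comparison):
        for replicate in range(1, cfg.n_qpcr_replicates + 1):
            sample = f"{condition}_r{replicate}"
            for gene, cq0 in cfg.reference_cq.items():
                rows.append((gene, sample, condition, replicate,
                             cq0 + rng.normal(0, cfg.cq_sd), 2.0))
            for gene, fold in cfg.gene_folds.items():
                cq = cfg.target_baseline_cq
                if condition == comparison:
                    cq -= np.log2(fold)
                rows.append((gene, sample, condition, replicate,
                             cq + rng.normal(0, cfg.cq_sd), 2.0))
    table = pd.DataFrame(
        rows, columns=["gene", "sample", "condition", "replicate", "cq", "efficiency"]
    )
    with out_path.open("w") as fh:
        fh.write(f"# seed={cfg.seed}\n")
        table.to_csv(fh, index=False, float_format="%.6f")
    sidecar = out_path.with_suffix(".truth.json")
    _write_sidecar(
        sidecar,
        {
            "seed": cfg.seed,
            "baseline": baseline,
            "comparison": comparison,
            "gene_folds": cfg.gene_folds,
            "cq_sd": cfg.cq_sd,
            "n_replicates": cfg.n_qpcr_replicates,
            "reference_genes": list(DEFAULT_REFERENCE_GENES),
        },
    )
    return sidecar


def generate_viability_table(cfg: ScenarioConfig, out_path) -> Path:
    """Write a viability plate CSV: log-normal counts around truth effects.

    Raw luminescence is log-normal around baseline x effect with CV
    ``viability_cv``; the vehicle effect is 1 by definition. Returns the
    truth sidecar path.
    """
    if not cfg.viability_effects:
        raise ValueError("scenario has no viability effects")
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng([cfg.seed, 202])
    sd = np.sqrt(np.log1p(cfg.viability_cv**2))
    rows = []
    for cell_line, effects in cfg.viability_effects.items():
        if "vehicle" not in effects:
            raise ValueError(f"no vehicle effect for {cell_line!r}")
        for experiment in range(1, cfg.n_experiments + 1):
            # per-experiment plate factor: experiments vary in absolute scale
            plate = cfg.baseline_signal * rng.lognormal(0, 0.05)
            for treatment, effect in effects.items():
                for technical in range(1, cfg.n_technical + 1):
                    signal = plate * effect * rng.lognormal(-0.5 * sd**2, sd)
                    rows.append((cell_line, treatment, technical, experiment, signal))
    table = pd.DataFrame(
        rows, columns=["cell_line", "treatment", "replicate", "experiment", "signal"]
    )
    with out_path.open("w") as fh:
        fh.write(f"# seed={cfg.seed}\n")
        table.to_csv(fh, index=False, float_format="%.4f")
    sidecar = out_path.with_suffix(".truth.json")
    _write_sidecar(
        sidecar,
        {
            "seed": cfg.seed,
            "effects": cfg.viability_effects,
            "cv": cfg.viability_cv,
            "n_experiments": cfg.n_experiments,
            "n_technical": cfg.n_technical,
        },
    )
    return sidecar


def generate_all(cfg: ScenarioConfig, out_dir) -> dict:
    """Generate every pipeline input under ``out_dir``; returns sidecar paths."""
    out_dir = Path(out_dir)
    return {
        "ms": generate_labelled_run(cfg, out_dir / "ms"),
        "qpcr": generate_cq_table(cfg, out_dir / "qpcr" / "cq_table.csv"),
        "viability": generate_viability_table(cfg, out_dir / "viability" / "viability.csv"),
    }
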