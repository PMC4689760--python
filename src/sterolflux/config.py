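"""Validated configuration for species, scenarios and pipeline runs."""

from __future__ import annotations

from pydantic import BaseModel, Field, field_validator, model_validator

from .isotopes import ADDUCTS, parse_formula
from .extraction import MolecularSpecies

__all__ = ["SpeciesScenario", "ScenarioConfig", "paper_like_scenario"]


class SpeciesScenario(BaseModel):
    """One targeted sterol: how it is monitored and its labelling truth."""

    name: str
    formula: str
    ion_species: str = "[M+H-H2O]+"
    charge: int = 1
    rt_min: float = Field(gt=0)
    rt_halfwidth: float = Field(default=0.25, gt=0)
    n_exch: int = Field(ge=0)
    k_max: int = Field(default=8, ge=1)
    fraction_new: dict[str, float]  # cell line / condition -> true f
    apex_intensity: float = Field(default=1e6, gt=0)

    @field_validator("formula")
    @classmethod
    def _formula_parses(cls, v: str) -> str:
        parse_formula(v)
        return v

    @field_validator("ion_species")
    @classmethod
    def _known_adduct(cls, v: str) -> str:
        if v not in ADDUCTS:
            raise ValueError(f"unknown ion species {v!r}")
        return v

    @field_validator("fraction_new")
    @classmethod
    def _fractions(cls, v: dict) -> dict:
        for condition, f in v.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"fraction new {f} for {condition!r} outside [0, 1]")
        return v

    @model_validator(mode="after")
    def _n_exch_fits(self):
        hydrogens = parse_formula(self.formula).get("H", 0)
        if self.n_exch > hydrogens:
            raise ValueError(f"n_exch={self.n_exch} exceeds {hydrogens} hydrogens")
        return self

    def to_species(self) -> MolecularSpecies:
        return MolecularSpecies(
            name=self.name, formula=self.formula, ion_species=self.ion_species,
            charge=self.charge, rt_min=self.rt_min, rt_halfwidth=self.rt_halfwidth,
            n_exch=self.n_exch, k_max=self.k_max,
        )


class ScenarioConfig(BaseModel):
    """Ground-truth scenario driving every synthetic input of the pipeline."""

    seed: int = 0
    cell_lines: tuple[str, str] = ("CEM", "CEM_R2")

    # LC-MS labelling block
    enrichment_p: float = Field(default=0.30, ge=0.0, le=1.0)
    species: list[SpeciesScenario] = Field(default_factory=list)
    envelope_cv: float = Field(default=0.01, ge=0)      # multiplicative noise
    noise_floor: float = Field(default=0.0, ge=0)       # additive counts
    n_ms_replicates: int = Field(default=5, ge=1)
    scan_interval_s: float = Field(default=0.5, gt=0)
    peak_sigma_s: float = Field(default=2.0, gt=0)
    mz_range: tuple[float, float] = (70.0, 1700.0)

    # qPCR block: gene -> true fold change (comparison line over baseline)
    gene_folds: dict[str, float] = Field(
        default_factory=lambda: {"HMGCR": 0.5, "CYP51A1": 5.0, "ABCA1": 5.0, "SQLE": 3.0}
    )
    reference_cq: dict[str, float] = Field(
        default_factory=lambda: {"RPL13A": 20.0, "RPS18": 16.0, "ACTB": 18.0, "GAPDH": 19.0}
    )
    target_baseline_cq: float = Field(default=24.0, gt=0, lt=45)
    cq_sd: float = Field(default=0.2, ge=0)
    n_qpcr_replicates: int = Field(default=6, ge=2)

    # viability block: cell line -> treatment -> true viability fraction
    viability_effects: dict[str, dict[str, float]] = Field(default_factory=dict)
    viability_cv: float = Field(default=0.10, ge=0)
    n_experiments: int = Field(default=4, ge=2)
    n_technical: int = Field(default=3, ge=1)
    baseline_signal: float = Field(default=1e5, gt=0)

    @model_validator(mode="after")
    def _species_in_range(self):
        for sp in self.species:
            mz0 = sp.to_species().mz0
            if not (self.mz_range[0] <= mz0 <= self.mz_range[1]):
                raise ValueError(
                    f"{sp.name} ion m/z {mz0:.3f} outside acquisition range {self.mz_range}"
                )
        return self


def paper_like_scenario(seed: int = 0) -> ScenarioConfig:
    """Default scenario emulating the study's observed structure.

    Lanosterol turns over substantially, more in the resistant line;
    cholesterol shows essentially no label uptake; water enrichment is 30 %.
    The qPCR block encodes HMGCR down and CYP51A1/ABCA1 ~5x, SQLE ~3x up.
    Viability effects follow the reported qualitative sensitivity pattern;
    the exact values are scenario parameters, not reported measurements.
    """
    inhibitor_effects_cem = {
        "hymeglusin": 0.55, "atorvastatin": 0.60, "YM-53601": 0.70,
        "terbinafine": 0.80, "BIBB-515": 0.90, "ketoconazole": 0.65,
        "triparanol": 0.85, "CI976": 0.80,
    }
    inhibitor_effects_r2 = {
        "hymeglusin": 0.75, "atorvastatin": 0.80, "YM-53601": 0.70,
        "terbinafine": 0.60, "BIBB-515": 0.90, "ketoconazole": 0.85,
        "triparanol": 0.65, "CI976": 0.60,
    }
    return ScenarioConfig(
        seed=seed,
        species=[
            SpeciesScenario(
                name="lanosterol", formula="C30H50O", rt_min=8.8, n_exch=25,
                fraction_new={"CEM": 0.15, "CEM_R2": 0.30},
            ),
            SpeciesScenario(
                name="cholesterol", formula="C27H46O", rt_min=8.2, n_exch=26,
                fraction_new={"CEM": 0.0, "CEM_R2": 0.0},
            ),
        ],
        viability_effects={
            "CEM": {"vehicle": 1.0, **inhibitor_effects_cem},
            "CEM_R2": {"vehicle": 1.0, **inhibitor_effects_r2},
        },
    )
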