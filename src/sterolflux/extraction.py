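"""Targeted isotopologue extraction from centroided LC-MS runs.

Species are located by accurate mass (ppm tolerance) and retention time; the
isotopologue m/z grid is the monoisotopic ion m/z plus multiples of the
averaged neutron-equivalent spacing (1.00336 Th per charge), adequate at
unit-mass bin aggregation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .isotopes import (
    ADDUCTS,
    ISOTOPOLOGUE_SPACING,
    ElementCounts,
    IsotopologueDistribution,
    ion_composition,
    ion_mz,
    parse_formula,
)

__all__ = [
    "CentroidSpectrum",
    "MolecularSpecies",
    "IsotopologueIntensities",
    "read_run",
    "read_spectra_csv",
    "extract_xic",
    "integrate_isotopologues",
]

DEFAULT_TOL_PPM = 20.0


@dataclass
class CentroidSpectrum:
    """One centroided scan: retention time plus (m/z, intensity) arrays."""

    rt_min: float
    mz: np.ndarray
    intensity: np.ndarray
    ms_level: int = 1

    def __post_init__(self):
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("m/z and intensity arrays differ in length")
        if self.mz.size > 1 and np.any(np.diff(self.mz) <= 0):
            raise ValueError("m/z values must be strictly increasing")
        if np.any(self.intensity < 0):
            raise ValueError("negative intensities")


@dataclass
class MolecularSpecies:
    """A targeted metabolite and how it is monitored."""

    name: str
    formula: str
    ion_species: str = "[M+H-H2O]+"
    charge: int = 1
    rt_min: float = 5.0           # expected apex, minutes
    rt_halfwidth: float = 0.5     # window half-width, minutes
    n_exch: int = 0
    k_max: int = 8

    def __post_init__(self):
        if self.rt_halfwidth <= 0:
            raise ValueError("RT window half-width must be positive")
        if self.ion_species not in ADDUCTS:
            raise ValueError(f"unknown ion species {self.ion_species!r}")
        self.counts: ElementCounts = parse_formula(self.formula)

    @property
    def mz0(self) -> float:
        return ion_mz(self.counts, self.ion_species, self.charge)

    @property
    def ion_counts(self) -> ElementCounts:
        return ion_composition(self.counts, self.ion_species, self.charge)

    def mz_grid(self) -> np.ndarray:
        """Theoretical m/z of M+0..M+K for this ion."""
        return self.mz0 + np.arange(self.k_max + 1) * ISOTOPOLOGUE_SPACING / self.charge


@dataclass
class IsotopologueIntensities:
    """Integrated per-isotopologue areas for one species in one run."""

    species: str
    sample: str
    intensities: np.ndarray
    ppm_deviation: np.ndarray
    rt_apex: float
    detected: bool = True

    def to_mid(self) -> IsotopologueDistribution:
        if not self.detected or self.intensities[0] <= 0:
            raise ValueError(f"{self.species} not detected; no valid envelope")
        return IsotopologueDistribution(self.intensities, species=self.species)


def read_run(path) -> list[CentroidSpectrum]:
    """Read centroided MS1 spectra from an mzML file, in RT order.

    Profile-mode spectra are rejected; a run without MS1 scans is an error.
    """
    from ._mzml import iter_spectra

    spectra: list[CentroidSpectrum] = []
    for entry in iter_spectra(path):
        if entry["ms_level"] != 1:
            continue
        if entry["centroided"] is False:
            raise ValueError(
                f"{path}: profile-mode spectra are not supported; centroid first"
            )
        spectra.append(
            CentroidSpectrum(
                rt_min=entry["rt_min"],
                mz=entry["mz"],
                intensity=entry["intensity"],
            )
        )
    if not spectra:
        raise ValueError(f"{path}: no MS1 scans")
    spectra.sort(key=lambda s: s.rt_min)
    return spectra


def read_spectra_csv(path) -> list[CentroidSpectrum]:
    """Read the plain-text alternative: columns rt_min, mz, intensity."""
    table = pd.read_csv(path, comment="#")
    required = {"rt_min", "mz", "intensity"}
    if not required.issubset(table.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    spectra = []
    for rt, group in table.groupby("rt_min", sort=True):
        group = group.sort_values("mz")
        spectra.append(
            CentroidSpectrum(rt_min=float(rt), mz=group["mz"].to_numpy(),
                             intensity=group["intensity"].to_numpy())
        )
    if not spectra:
        raise ValueError(f"{path}: no spectra")
    return spectra


def load_spectra(path) -> list[CentroidSpectrum]:
    """Dispatch on extension: .mzML or spectrum-table CSV."""
    path = Path(path)
    if path.suffix.lower() == ".mzml":
        return read_run(path)
    return read_spectra_csv(path)


def extract_xic(
    spectra, mz: float, tol_ppm: float = DEFAULT_TOL_PPM, rt_window: tuple | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Extracted ion chromatogram: per-scan summed intensity near one m/z.

    The RT window is half-open [start, end) in minutes; an empty XIC (all
    zeros) is a legitimate result, not an error.
    """
    if tol_ppm <= 0:
        raise ValueError("tolerance must be positive")
    half = tol_ppm * mz * 1e-6
    rts, sums = [], []
    for spectrum in spectra:
        if rt_window is not None and not (rt_window[0] <= spectrum.rt_min < rt_window[1]):
            continue
        lo = np.searchsorted(spectrum.mz, mz - half, side="left")
        hi = np.searchsorted(spectrum.mz, mz + half, side="right")
        rts.append(spectrum.rt_min)
        sums.append(float(spectrum.intensity[lo:hi].sum()))
    return np.asarray(rts), np.asarray(sums)


def _apex_rt(rts: np.ndarray, xic: np.ndarray) -> float | None:
    """Apex = maximum of the 3-point moving average; earliest RT wins ties."""
    if rts.size == 0 or xic.sum() <= 0:
        return None
    if rts.size < 3:
        return float(rts[int(np.argmax(xic))])
    smooth = np.convolve(xic, np.ones(3) / 3.0, mode="same")
    return float(rts[int(np.argmax(smooth))])  # argmax returns first maximum


def integrate_isotopologues(
    spectra, species: MolecularSpecies, tol_ppm: float = DEFAULT_TOL_PPM,
    sample: str = "",
) -> IsotopologueIntensities:
    """Integrate M+0..M+K areas for one species around its elution apex.

    The apex is located on the summed M+0..M+2 XIC inside the configured RT
    window; the integration window is then re-anchored at the apex so an
    off-center elution yields the same areas as a centered one. Bin areas
    are trapezoid integrals over retention time.
    """
    window = (species.rt_min - species.rt_halfwidth, species.rt_min + species.rt_halfwidth)
    grid = species.mz_grid()
    rts, summed = extract_xic(spectra, grid[0], tol_ppm, window)
    for i in (1, 2):
        if i <= species.k_max:
            _, extra = extract_xic(spectra, grid[i], tol_ppm, window)
            summed = summed + extra
    apex = _apex_rt(rts, summed)
    if apex is None:
        return IsotopologueIntensities(
            species=species.name, sample=sample,
            intensities=np.zeros(species.k_max + 1),
            ppm_deviation=np.full(species.k_max + 1, np.nan),
            rt_apex=np.nan, detected=False,
        )
    window = (apex - species.rt_halfwidth, apex + species.rt_halfwidth)
    areas = np.zeros(species.k_max + 1)
    ppm_dev = np.full(species.k_max + 1, np.nan)
    for i, mz in enumerate(grid):
        rts_i, xic = extract_xic(spectra, mz, tol_ppm, window)
        if rts_i.size >= 2 and xic.sum() > 0:
            areas[i] = np.trapezoid(xic, rts_i)
        elif xic.size:
            areas[i] = float(xic.sum())
        ppm_dev[i] = _weighted_ppm_deviation(spectra, mz, tol_ppm, window)
    return IsotopologueIntensities(
        species=species.name, sample=sample, intensities=areas,
        ppm_deviation=ppm_dev, rt_apex=apex, detected=bool(areas[0] > 0),
    )


def _weighted_ppm_deviation(spectra, mz: float, tol_ppm: float, window) -> float:
    half = tol_ppm * mz * 1e-6
    total, weighted = 0.0, 0.0
    for spectrum in spectra:
        if not (window[0] <= spectrum.rt_min < window[1]):
            continue
        lo = np.searchsorted(spectrum.mz, mz - half, side="left")
        hi = np.searchsorted(spectrum.mz, mz + half, side="right")
        w = spectrum.intensity[lo:hi]
        total += w.sum()
        weighted += float((spectrum.mz[lo:hi] * w).sum())
    if total <= 0:
        return float("nan")
    return (weighted / total - mz) / mz * 1e6
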