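"""Molecular-formula arithmetic and natural-abundance isotopologue envelopes.

Isotopologues are aggregated by *nominal* mass shift above the monoisotopic
species (unit-mass bins), which is the resolution at which Q-TOF sterol
envelopes are read out; isotope fine structure is deliberately out of scope.
"""

from __future__ import annotations

import logging
import re
from importlib import resources

import numpy as np

__all__ = [
    "ElementCounts",
    "IsotopologueDistribution",
    "load_isotope_table",
    "parse_formula",
    "formula_to_string",
    "combine_formulas",
    "monoisotopic_mass",
    "ion_mz",
    "ion_composition",
    "natural_mid",
    "convolve_mids",
    "PROTON_MASS",
    "ISOTOPOLOGUE_SPACING",
    "ADDUCTS",
]

logger = logging.getLogger(__name__)

#: Mass of a proton in Da (CODATA). Ion m/z uses proton-mass bookkeeping;
#: electron-mass refinements are out of scope.
PROTON_MASS = 1.007276466621

#: Averaged 13C/2H unit spacing used for isotopologue m/z grids (Th at z=1).
ISOTOPOLOGUE_SPACING = 1.00336

# Adduct registry: name -> (neutral loss formula or None, charge).
# m/z = (M - loss + z * proton) / z.
ADDUCTS = {
    "[M+H]+": None,
    "[M+H-H2O]+": "H2O",
}

ElementCounts = dict  # element symbol -> non-negative atom count

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def load_isotope_table() -> dict[str, list[tuple[float, float]]]:
    """Load the pinned isotope table: element -> [(mass Da, abundance), ...].

    Masses are strictly increasing per element and abundances sum to 1;
    both invariants are checked on load so a corrupted override fails fast.
    """
    table: dict[str, list[tuple[float, float]]] = {}
    text = (
        resources.files("sterolflux.data")
        .joinpath("isotope_abundances.tsv")
        .read_text()
    )
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        element, mass, abundance = line.split("\t")
        table.setdefault(element, []).append((float(mass), float(abundance)))
    for element, rows in table.items():
        masses = [m for m, _ in rows]
        total = sum(a for _, a in rows)
        if masses != sorted(masses):
            raise ValueError(f"isotope masses for {element} not increasing")
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"abundances for {element} sum to {total}, not 1")
    return table


ISOTOPES = load_isotope_table()


class IsotopologueDistribution:
    """Normalized fractional abundances a0..aK of M+0..M+K for one species.

    Index i is the nominal mass shift above the monoisotopic isotopologue.
    """

    def __init__(self, abundances, species: str = ""):
        a = np.asarray(abundances, dtype=float)
        if a.ndim != 1 or a.size < 2:
            raise ValueError("need a 1-D vector covering at least M+0 and M+1")
        if np.any(a < -1e-12):
            raise ValueError("negative isotopologue abundance")
        a = np.clip(a, 0.0, None)
        total = a.sum()
        if total <= 0:
            raise ValueError("all-zero isotopologue vector")
        self.abundances = a / total
        self.species = species

    @property
    def k_max(self) -> int:
        return self.abundances.size - 1

    def mean_shift(self) -> float:
        """Expected nominal mass shift, Σ i·a_i (Da-equivalents)."""
        return float(np.dot(np.arange(self.abundances.size), self.abundances))

    def __len__(self) -> int:
        return self.abundances.size

    def __getitem__(self, i):
        return self.abundances[i]

    def __repr__(self) -> str:  # pragma: no cover
        body = ", ".join(f"{x:.4g}" for x in self.abundances)
        return f"IsotopologueDistribution({self.species!r}, [{body}])"


def parse_formula(text: str) -> ElementCounts:
    """Parse a molecular formula string such as ``"C30H50O"``.

    Raises ValueError on empty input, unknown element symbols, or an
    explicit zero count. Round-trips through :func:`formula_to_string`.
    """
    if not text or not text.strip():
        raise ValueError("empty formula")
    text = text.strip()
    counts: ElementCounts = {}
    pos = 0
    for match in _FORMULA_TOKEN.finditer(text):
        if not match.group(0):
            continue
        if match.start() != pos:
            raise ValueError(f"unparseable formula {text!r} at position {pos}")
        pos = match.end()
        element, digits = match.groups()
        if element not in ISOTOPES:
            raise ValueError(f"unknown element symbol {element!r} in {text!r}")
        n = int(digits) if digits else 1
        if n <= 0:
            raise ValueError(f"non-positive count for {element} in {text!r}")
        counts[element] = counts.get(element, 0) + n
    if pos != len(text):
        raise ValueError(f"unparseable formula {text!r} at position {pos}")
    if not counts:
        raise ValueError(f"formula {text!r} contains no atoms")
    return counts


def formula_to_string(counts: ElementCounts) -> str:
    """Canonical (Hill-order) writer: C, H first, then alphabetical."""
    _validate_counts(counts)
    order = [e for e in ("C", "H") if e in counts]
    order += sorted(e for e in counts if e not in ("C", "H"))
    return "".join(
        f"{e}{counts[e]}" if counts[e] != 1 else e for e in order if counts[e]
    )


def combine_formulas(a: ElementCounts, b: ElementCounts, sign: int = 1) -> ElementCounts:
    """Element-wise a + sign*b; rejects negative resulting counts."""
    out = dict(a)
    for element, n in b.items():
        out[element] = out.get(element, 0) + sign * n
        if out[element] < 0:
            raise ValueError(f"negative {element} count in combined formula")
        if out[element] == 0:
            del out[element]
    if not out:
        raise ValueError("combined formula is empty")
    return out


def _validate_counts(counts: ElementCounts) -> None:
    if not counts:
        raise ValueError("empty element counts")
    for element, n in counts.items():
        if element not in ISOTOPES:
            raise ValueError(f"unknown element symbol {element!r}")
        if not isinstance(n, (int, np.integer)) or n < 0:
            raise ValueError(f"invalid count {n!r} for {element}")
    if not any(n > 0 for n in counts.values()):
        raise ValueError("formula contains no atoms")


def monoisotopic_mass(counts: ElementCounts) -> float:
    """Sum of count x lightest-isotope mass over all elements, in Da."""
    _validate_counts(counts)
    return sum(n * ISOTOPES[e][0][0] for e, n in counts.items())


def ion_mz(neutral: ElementCounts, ion_species: str, charge: int = 1) -> float:
    """Monoisotopic m/z (Th) of the given adduct of a neutral formula.

    Supported adducts are registered in :data:`ADDUCTS`; APCI sterols are
    typically observed as the dehydrated protonated ion [M+H-H2O]+.
    """
    if ion_species not in ADDUCTS:
        raise ValueError(f"unknown ion species {ion_species!r}; known: {sorted(ADDUCTS)}")
    if charge < 1:
        raise ValueError("charge must be a positive integer")
    mass = monoisotopic_mass(neutral)
    loss = ADDUCTS[ion_species]
    if loss is not None:
        mass -= monoisotopic_mass(parse_formula(loss))
        # validate the loss is chemically possible for this formula
        ion_composition(neutral, ion_species, charge)
    return (mass + charge * PROTON_MASS) / charge


def ion_composition(neutral: ElementCounts, ion_species: str, charge: int = 1) -> ElementCounts:
    """Elemental composition of the monitored ion (protons counted as H).

    This is the composition whose natural envelope underlies the observed
    isotopologue pattern, e.g. lanosterol [M+H-H2O]+ -> C30H49.
    """
    if ion_species not in ADDUCTS:
        raise ValueError(f"unknown ion species {ion_species!r}")
    comp = combine_formulas(neutral, {"H": charge})
    loss = ADDUCTS[ion_species]
    if loss is not None:
        try:
            comp = combine_formulas(comp, parse_formula(loss), sign=-1)
        except ValueError as err:
            raise ValueError(
                f"adduct {ion_species} removes atoms that "
                f"{formula_to_string(neutral)} lacks"
            ) from err
    return comp


def _element_shift_distribution(element: str) -> np.ndarray:
    """Single-atom distribution over nominal mass shifts (index = shift)."""
    rows = ISOTOPES[element]
    base = rows[0][0]
    max_shift = round(rows[-1][0] - base)
    dist = np.zeros(max_shift + 1)
    for mass, abundance in rows:
        dist[round(mass - base)] += abundance
    return dist


def _power_convolve(dist: np.ndarray, n: int) -> np.ndarray:
    """dist convolved with itself n times (exponentiation by squaring)."""
    result = np.array([1.0])
    power = dist
    while n:
        if n & 1:
            result = np.convolve(result, power)
        n >>= 1
        if n:
            power = np.convolve(power, power)
    return result


def natural_mid(
    counts: ElementCounts, k_max: int = 8, species: str = ""
) -> IsotopologueDistribution:
    """Theoretical natural-abundance envelope of a formula, truncated at M+K.

    Per-element multinomial expansions are combined by discrete convolution
    over nominal mass shifts; the full envelope is computed first, then
    truncated at ``k_max`` and renormalized. The discarded tail mass is
    logged when it exceeds 1e-6.
    """
    _validate_counts(counts)
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    full = np.array([1.0])
    for element, n in counts.items():
        if n == 0:
            continue
        full = np.convolve(full, _power_convolve(_element_shift_distribution(element), n))
    truncated = np.zeros(k_max + 1)
    upto = min(full.size, k_max + 1)
    truncated[:upto] = full[:upto]
    tail = 1.0 - truncated.sum()
    if tail > 1e-6:
        logger.warning(
            "natural_mid(%s, K=%d): discarding tail mass %.3g",
            formula_to_string(counts), k_max, tail,
        )
    return IsotopologueDistribution(truncated, species=species)


def convolve_mids(
    a: IsotopologueDistribution, b: IsotopologueDistribution, k_max: int | None = None
) -> IsotopologueDistribution:
    """Discrete convolution of two envelopes, truncated at K and renormalized.

    Commutative, associative within floating tolerance; the delta at shift 0
    is the identity element.
    """
    if k_max is None:
        k_max = max(a.k_max, b.k_max)
    full = np.convolve(a.abundances, b.abundances)
    out = np.zeros(k_max + 1)
    upto = min(full.size, k_max + 1)
    out[:upto] = full[:upto]
    return IsotopologueDistribution(out, species=a.species or b.species)
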