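"""Independent brute-force oracles shared across test modules."""

import itertools

import numpy as np

from sterolflux.isotopes import ISOTOPES


def enumerate_envelope(formula):
    """Exhaustively enumerate every isotope assignment of every atom.

    Exact (to float arithmetic) reference for natural isotopologue
    envelopes of small formulas; independent of the convolution code path.
    """
    atoms = [element for element, n in formula.items() for _ in range(n)]
    base = {e: ISOTOPES[e][0][0] for e in ISOTOPES}
    max_shift = sum(round(ISOTOPES[a][-1][0] - base[a]) for a in atoms)
    dist = np.zeros(max_shift + 1)
    for assignment in itertools.product(*[ISOTOPES[a] for a in atoms]):
        prob = np.prod([abundance for _, abundance in assignment])
        shift = sum(round(mass - base[a]) for a, (mass, _) in zip(atoms, assignment))
        dist[shift] += prob
    return dist
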