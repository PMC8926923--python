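"""Molecular formulas and subformula decomposition.

A fragment peak in a tandem mass spectrum is "explainable" if some
subformula of the precursor's molecular formula (optionally offset by the
ionisation adduct mass) has a monoisotopic mass within a ppm tolerance of
the observed peak mass. Peaks without such a decomposition are candidate
noise peaks.

Formula parsing and monoisotopic element masses come from pyteomics; the
bounded subformula enumeration (exact, with mass pruning) is implemented
here.
"""

from __future__ import annotations

from functools import lru_cache
from typing import Dict, Iterator, Mapping

from pyteomics import mass as _pt_mass

#: Monoisotopic mass of a proton; the default adduct offset models [M+H]+.
PROTON_MASS = 1.00727646688

# Elements supported by the enumerator: CHNOPS plus the common halogens.
SUPPORTED_ELEMENTS = ("C", "H", "N", "O", "P", "S", "F", "Cl", "Br", "I")


@lru_cache(maxsize=None)
def element_mass(symbol: str) -> float:
    """Monoisotopic mass of an element, from the pyteomics NIST table."""
    try:
        return _pt_mass.nist_mass[symbol][0][0]
    except KeyError:
        raise ValueError(f"unknown element symbol: {symbol!r}") from None


def parse_formula(formula: str | Mapping[str, int]) -> Dict[str, int]:
    """Parse a molecular formula string (e.g. ``"C6H12O6"``) into counts.

    Counts must be non-negative; unknown element symbols raise ValueError.
    """
    if isinstance(formula, Mapping):
        counts = dict(formula)
    else:
        try:
            counts = dict(_pt_mass.Composition(formula=formula))
        except Exception as exc:  # pyteomics raises its own error types
            raise ValueError(f"cannot parse formula {formula!r}: {exc}") from exc
    for el, n in counts.items():
        element_mass(el)
        if n < 0:
            raise ValueError(f"negative count for element {el} in {formula!r}")
    return counts


def formula_mass(formula: str | Mapping[str, int]) -> float:
    """Monoisotopic (neutral) mass of a molecular formula in Da."""
    counts = parse_formula(formula)
    return sum(element_mass(el) * n for el, n in counts.items())


def iter_subformulas(precursor: str | Mapping[str, int]) -> Iterator[Dict[str, int]]:
    """Yield every subformula of ``precursor`` (element-wise counts ≤ precursor).

    Includes the empty formula and the full precursor. The number of
    subformulas is prod(count_e + 1); callers should prefer
    :func:`subformula_decomposable`, which prunes by mass.
    """
    counts = parse_formula(precursor)
    elements = sorted(counts)

    def rec(i: int, current: Dict[str, int]) -> Iterator[Dict[str, int]]:
        if i == len(elements):
            yield dict(current)
            return
        el = elements[i]
        for n in range(counts[el] + 1):
            current[el] = n
            yield from rec(i + 1, current)
        del current[el]

    yield from rec(0, {})


def subformula_decomposable(
    peak_mz: float,
    precursor_formula: str | Mapping[str, int],
    tol_ppm: float = 10.0,
    adduct_mass: float = PROTON_MASS,
) -> bool:
    """Whether a peak mass decomposes as a subformula of the precursor.

    Tests if some subformula F of ``precursor_formula`` satisfies
    ``|mass(F) + adduct_mass - peak_mz| <= tol_ppm * 1e-6 * peak_mz``.
    The full precursor counts as an (improper) subformula of itself.
    Exact bounded search over element-count vectors, pruned by the
    residual-mass window, so it stays fast for typical small molecules.
    """
    counts = parse_formula(precursor_formula)
    elements = sorted(counts, key=element_mass, reverse=True)  # heavy first
    masses = [element_mass(el) for el in elements]
    max_counts = [counts[el] for el in elements]
    target = peak_mz - adduct_mass
    tol = tol_ppm * 1e-6 * peak_mz
    if target < -tol:
        return False
    # max residual mass attainable from elements i..end
    suffix_max = [0.0] * (len(elements) + 1)
    for i in range(len(elements) - 1, -1, -1):
        suffix_max[i] = suffix_max[i + 1] + masses[i] * max_counts[i]

    def rec(i: int, remaining: float) -> bool:
        if abs(remaining) <= tol:
            return True
        if remaining < -tol or remaining > suffix_max[i] + tol:
            return False
        if i == len(elements):
            return False
        m = masses[i]
        # count of element i bounded above by both formula and mass window
        n_hi = min(max_counts[i], int((remaining + tol) // m))
        for n in range(n_hi, -1, -1):
            if rec(i + 1, remaining - n * m):
                return True
        return False

    return rec(0, target)
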