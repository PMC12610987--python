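"""Chemical hypothesis generation for aligned breath features.

All ions are assumed singly protonated ([M+H]+, PTR soft ionization), so the
neutral mass of a feature is its m/z minus the proton mass 1.00728 Da (electron
mass neglected; below m/z 80 this costs < 8 ppm, well inside the library
tolerance). Annotation proceeds by (i) matching against a compound library at
+/-200 ppm, (ii) exhaustively enumerating elemental compositions over
C/H/N/O/P/S (optionally F, Cl, Na, Br) at +/-5-10 ppm with chemical-plausibility
filtering, and (iii) flagging likely 13C isotopologue features by exact-mass
shift and abundance ratio. Annotations are hypotheses: structural confirmation
would require targeted MS/MS, which is out of scope here.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

PROTON_MASS = 1.00728  # Da, [M+H]+ convention
C13_DELTA = 1.00336    # Da, 13C - 12C
C13_ABUNDANCE = 0.0107  # natural 13C fraction per carbon

#: monoisotopic atomic masses, Da
ATOMIC_MASS = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "P": 30.97376163,
    "S": 31.97207100,
    "F": 18.99840322,
    "Cl": 34.96885268,
    "Na": 22.9897692809,
    "Br": 78.9183371,
}


class AnnotationError(ValueError):
    pass


@dataclass
class AnnotationCandidate:
    """One chemical hypothesis for a feature."""

    feature_mz: float
    neutral_mass: float
    kind: str                 # library_match | formula | isotopologue
    name_or_formula: str
    theoretical_mz: float
    error_ppm: float


def formula_mass(formula: dict[str, int] | str) -> float:
    """Monoisotopic mass of an elemental composition like ``"C5H8"``."""
    if isinstance(formula, str):
        formula = parse_formula(formula)
    return sum(ATOMIC_MASS[el] * n for el, n in formula.items())


def parse_formula(text: str) -> dict[str, int]:
    import re
    counts: dict[str, int] = {}
    for el, num in re.findall(r"([A-Z][a-z]?)(\d*)", text):
        if el:
            counts[el] = counts.get(el, 0) + (int(num) if num else 1)
    if formula_to_str(counts) == "" or not counts:
        raise AnnotationError(f"cannot parse formula {text!r}")
    return counts


def formula_to_str(counts: dict[str, int]) -> str:
    order = ["C", "H"] + sorted(el for el in counts if el not in ("C", "H"))
    return "".join(
        f"{el}{counts[el] if counts[el] != 1 else ''}"
        for el in order if counts.get(el, 0) > 0
    )


# Small curated library of compounds named in the breathomics literature for the
# ions this pipeline targets; neutral monoisotopic masses computed from atomic
# masses. The formic-acid fragment CHO2+ is represented as protonated CO2.
BUNDLED_LIBRARY = tuple(
    (name, formula_mass(f))
    for name, f in [
        ("isoprene", "C5H8"),
        ("dimethyl sulfide", "C2H6S"),
        ("1,2-butadiene", "C4H6"),
        ("formic acid fragment (CO2H+)", "CO2"),
        ("formic acid", "CH2O2"),
        ("acetaldehyde", "C2H4O"),
        ("acetone", "C3H6O"),
        ("propylene glycol", "C3H8O2"),
        ("phenol", "C6H6O"),
        ("toluene", "C7H8"),
        ("cresol (hydroxytoluene)", "C7H8O"),
        ("indole", "C8H7N"),
        ("methanol", "CH4O"),
        ("ethanol", "C2H6O"),
        ("2-pentanone", "C5H10O"),
    ]
)


def neutral_mass(mz: float) -> float:
    """Neutral monoisotopic mass of a protonated ion: m/z - 1.00728 Da."""
    if mz <= PROTON_MASS:
        raise AnnotationError(f"m/z {mz} is not above the proton mass")
    return mz - PROTON_MASS


def _ppm(theoretical: float, measured: float) -> float:
    return (theoretical - measured) / theoretical * 1e6


def match_library(mz: float, library=BUNDLED_LIBRARY, tol_ppm: float = 200.0
                  ) -> list[AnnotationCandidate]:
    """Library entries whose protonated mass lies within ``tol_ppm`` of ``mz``.

    Results are sorted by absolute ppm error, ascending. The library is a
    sequence of (name, neutral monoisotopic mass) pairs.
    """
    if not library:
        raise AnnotationError("library is empty")
    out = []
    for name, neutral in library:
        theo = neutral + PROTON_MASS
        err = _ppm(theo, mz)
        if abs(err) <= tol_ppm:
            out.append(AnnotationCandidate(
                feature_mz=mz, neutral_mass=neutral_mass(mz), kind="library_match",
                name_or_formula=name, theoretical_mz=theo, error_ppm=err))
    out.sort(key=lambda c: abs(c.error_ppm))
    return out


def _rdbe(c: dict[str, int]) -> float:
    """Ring-plus-double-bond equivalents; O and S contribute 0, Na counted as a
    monovalent substituent."""
    return (c.get("C", 0) + 1
            + 0.5 * (c.get("N", 0) + c.get("P", 0))
            - 0.5 * (c.get("H", 0) + c.get("F", 0) + c.get("Cl", 0)
                     + c.get("Br", 0) + c.get("Na", 0)))


def is_plausible(counts: dict[str, int]) -> bool:
    """Heuristic plausibility for a neutral molecule.

    Requires integer, nonnegative RDBE and a hydrogen (plus other monovalent)
    count not exceeding 2C + 2 + N.
    """
    if sum(counts.values()) == 0:
        return False
    rdbe = _rdbe(counts)
    if rdbe < 0 or abs(rdbe - round(rdbe)) > 1e-9:
        return False
    monovalent = (counts.get("H", 0) + counts.get("F", 0) + counts.get("Cl", 0)
                  + counts.get("Br", 0) + counts.get("Na", 0))
    if monovalent > 2 * counts.get("C", 0) + 2 + counts.get("N", 0):
        return False
    return True


DEFAULT_ELEMENTS = ("C", "H", "N", "O", "P", "S")


def default_max_counts(mass: float, elements=DEFAULT_ELEMENTS) -> dict[str, int]:
    """Per-element ceilings implied by the target mass itself."""
    return {el: int(mass // ATOMIC_MASS[el]) + 1 for el in elements}


def enumerate_formulas(target_neutral_mass: float, elements=DEFAULT_ELEMENTS,
                       tol_ppm: float = 10.0, max_counts: dict[str, int] | None = None,
                       plausibility: bool = True) -> list[AnnotationCandidate]:
    """All elemental compositions within ``tol_ppm`` of a neutral mass.

    Depth-first search over element counts with mass-bound pruning; candidates
    failing :func:`is_plausible` are dropped unless ``plausibility`` is False.
    Sorted by absolute ppm error.
    """
    if target_neutral_mass <= 0:
        raise AnnotationError("neutral mass must be positive")
    if max_counts is None:
        raise AnnotationError(
            "max_counts must be given to bound the search "
            "(default_max_counts(mass) provides mass-implied ceilings)")
    tol_da = target_neutral_mass * tol_ppm * 1e-6 * 1.01  # pruning bound only
    # heavy elements first, hydrogen last: tightest pruning
    order = sorted(elements, key=lambda el: -ATOMIC_MASS[el])
    results: list[AnnotationCandidate] = []

    def search(i: int, counts: dict[str, int], remaining: float) -> None:
        if i == len(order):
            theo = target_neutral_mass - remaining
            if theo <= 0:
                return
            err = _ppm(theo, target_neutral_mass)
            if abs(err) <= tol_ppm:
                c = {el: n for el, n in counts.items() if n > 0}
                if not plausibility or is_plausible(c):
                    results.append(AnnotationCandidate(
                        feature_mz=target_neutral_mass + PROTON_MASS,
                        neutral_mass=target_neutral_mass,
                        kind="formula",
                        name_or_formula=formula_to_str(c),
                        theoretical_mz=theo,
                        error_ppm=err,
                    ))
            return
        el = order[i]
        m = ATOMIC_MASS[el]
        if i == len(order) - 1:
            # last (lightest) element: only counts landing inside the tolerance
            n_lo = max(0, int(np.ceil((remaining - tol_da) / m)))
            n_hi = min(max_counts.get(el, 0), int(np.floor((remaining + tol_da) / m)))
            for n in range(n_lo, n_hi + 1):
                counts[el] = n
                search(i + 1, counts, remaining - n * m)
            counts[el] = 0
            return
        n_max = min(max_counts.get(el, 0), int((remaining + tol_da) // m))
        lighter_max = sum(ATOMIC_MASS[e] * max_counts.get(e, 0) for e in order[i + 1:])
        for n in range(n_max + 1):
            rem = remaining - n * m
            if rem < -tol_da:
                break
            if rem - tol_da > lighter_max:
                continue  # remaining mass unreachable with lighter elements
            counts[el] = n
            search(i + 1, counts, rem)
        counts[el] = 0

    search(0, dict.fromkeys(order, 0), target_neutral_mass)
    results.sort(key=lambda c: (abs(c.error_ppm), c.name_or_formula))
    return results


def flag_isotopologues(matrix, shift_tol: float = 0.01, ratio_slack: float = 0.5
                       ) -> list[AnnotationCandidate]:
    """Flag features that look like 13C isotopologues of a lighter feature.

    Feature B is flagged as the 13C satellite of A iff its m/z exceeds A's by
    1.00336 Da (within ``shift_tol``) and the median intensity ratio B/A falls
    inside the abundance band expected for 1..floor(mass/12) carbons, widened by
    ``ratio_slack`` on each side.
    """
    if not matrix.normalized:
        raise AnnotationError("isotopologue flagging expects a normalized matrix")
    mzs = matrix.feature_mzs
    out = []
    for i, j in itertools.permutations(range(len(mzs)), 2):
        delta = mzs[j] - mzs[i]
        if abs(delta - C13_DELTA) > shift_tol:
            continue
        a = matrix.values.iloc[:, i].to_numpy(dtype=float)
        b = matrix.values.iloc[:, j].to_numpy(dtype=float)
        ok = a > 0
        if not ok.any():
            continue
        ratio = float(np.median(b[ok] / a[ok]))
        n_c_max = max(1, int(neutral_mass(mzs[i]) // ATOMIC_MASS["C"]))
        lo = C13_ABUNDANCE * 1 * (1 - ratio_slack)
        hi = C13_ABUNDANCE * n_c_max * (1 + ratio_slack)
        if lo <= ratio <= hi:
            theo = mzs[i] + C13_DELTA
            out.append(AnnotationCandidate(
                feature_mz=float(mzs[j]), neutral_mass=neutral_mass(float(mzs[j])),
                kind="isotopologue",
                name_or_formula=f"13C isotopologue of m/z {mzs[i]:.3f} (ratio {ratio:.3f})",
                theoretical_mz=theo, error_ppm=_ppm(theo, mzs[j])))
    return out
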