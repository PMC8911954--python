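"""Elemental monoisotopic masses and molecular-formula arithmetic.

Masses are neutral monoisotopic masses in Da. Electron mass is ignored:
fragment m/z values in this package are treated as neutral-fragment masses,
which is consistent throughout generator, deconvolution and identification
(errors cancel in every ppm comparison).
"""

from __future__ import annotations

import re

# CODATA/IUPAC 2021 monoisotopic masses, Da
MONOISOTOPIC_MASS: dict[str, float] = {
    "C": 12.0,
    "H": 1.0078250319,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "S": 31.97207069,
    "P": 30.97376151,
    "Cl": 34.96885271,
    "F": 18.99840320,
    "Br": 78.9183376,
    "Si": 27.9769265327,
    "Na": 22.98976928,
    "K": 38.9637069,
}

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Raised for formulas that cannot be parsed or contain unknown elements."""


def parse_formula(formula: str) -> dict[str, int]:
    """Parse a Hill-notation molecular formula into element counts.

    >>> parse_formula("C11H22O2")
    {'C': 11, 'H': 22, 'O': 2}
    """
    if not formula or not formula.strip():
        raise FormulaError("empty formula")
    counts: dict[str, int] = {}
    pos = 0
    s = formula.strip()
    for m in _FORMULA_RE.finditer(s):
        if m.start() != pos:
            raise FormulaError(f"cannot parse formula {formula!r} at position {pos}")
        pos = m.end()
        elem, num = m.group(1), m.group(2)
        if elem not in MONOISOTOPIC_MASS:
            raise FormulaError(f"unsupported element {elem!r} in {formula!r}")
        counts[elem] = counts.get(elem, 0) + (int(num) if num else 1)
    if pos != len(s):
        raise FormulaError(f"cannot parse formula {formula!r} at position {pos}")
    return counts


def formula_to_string(counts: dict[str, int]) -> str:
    """Render element counts in Hill order (C, H, then alphabetical)."""
    order = sorted(counts, key=lambda e: (e != "C", e != "H", e))
    out = []
    for e in order:
        n = counts[e]
        if n <= 0:
            continue
        out.append(e if n == 1 else f"{e}{n}")
    return "".join(out)


def monoisotopic_mass(formula: str | dict[str, int]) -> float:
    """Neutral monoisotopic mass in Da of a formula string or count dict."""
    counts = parse_formula(formula) if isinstance(formula, str) else formula
    return float(sum(MONOISOTOPIC_MASS[e] * n for e, n in counts.items()))


def ppm_error(observed: float, reference: float) -> float:
    """Signed relative mass error of `observed` vs `reference`, in ppm."""
    if reference <= 0:
        raise ValueError("reference mass must be positive")
    return (observed - reference) / reference * 1e6
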