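"""Library identification of deconvolved components.

A component is scored against library entries with a weighted-cosine match
factor (MF, 0-100), then gated on accurate fragment mass (< 20 ppm starting
at 30 m/z), retention-index agreement (|dRI| < 30 when both sides carry an
RI) and, for retention-aware libraries, a trapezoidal retention-time penalty
(penalty-free within 12 s, full exclusion beyond 18 s). Components that pass
no gate become *Unknowns* named by their retention time in minutes, carrying
the base-peak exact mass and candidate molecular formulas.

The MF is a NIST-style weighted cosine: each peak is weighted
``w = sqrt(intensity) * mz`` and the score is ``100 * cos^2`` between the
weighted spectra, with peaks aligned by m/z. The vendor score this mirrors is
unpublished; this variant reproduces the qualitative behaviour (self-match
100, unrelated spectra near 0, >80 for clean rediscovery).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .chem import MONOISOTOPIC_MASS, formula_to_string

__all__ = [
    "LibraryEntry",
    "MatchResult",
    "match_factor",
    "fragment_ppm",
    "rt_penalty_weight",
    "identify",
    "formula_candidates",
    "make_unknown_name",
]


@dataclass
class LibraryEntry:
    """A named library compound with spectrum and optional retention data."""

    name: str
    spectrum: np.ndarray  # (n, 2): m/z [Th], relative intensity (base = 100)
    cas: str = ""
    formula: str = ""
    exact_mass: float | None = None
    rt_min: float | None = None  # retention time, minutes
    ri: float | None = None  # retention index
    id_level: int = 2  # 1 standard-confirmed .. 4 unknown

    def __post_init__(self) -> None:
        self.spectrum = np.asarray(self.spectrum, dtype=float).reshape(-1, 2)
        if self.spectrum.shape[0] == 0:
            raise ValueError(f"library entry {self.name!r} has an empty spectrum")
        order = np.argsort(self.spectrum[:, 0])
        self.spectrum = self.spectrum[order]
        base = self.spectrum[:, 1].max()
        if base <= 0:
            raise ValueError(f"library entry {self.name!r} has no positive peak")
        self.spectrum[:, 1] *= 100.0 / base
        if self.id_level not in (1, 2, 3, 4):
            raise ValueError("id_level must be 1..4")


@dataclass
class MatchResult:
    """Outcome of scoring one component against libraries."""

    name: str
    entry: LibraryEntry | None
    match_factor: float = 0.0
    penalized_mf: float = 0.0
    delta_ri: float | None = None
    delta_rt_s: float | None = None
    max_fragment_ppm: float | None = None
    passed: bool = False
    id_level: int = 4
    is_unknown: bool = False
    exact_mass: float | None = None
    formulas: list[tuple[str, float]] = field(default_factory=list)


def _align(spec_a: np.ndarray, spec_b: np.ndarray, tol_ppm: float) -> list[tuple[int, int]]:
    """Greedy one-to-one peak alignment by m/z within ``tol_ppm``.

    Candidate pairs are considered in order of increasing ppm distance so a
    peak pairs with its nearest partner.
    """
    mza, mzb = spec_a[:, 0], spec_b[:, 0]
    cand: list[tuple[float, int, int]] = []
    j0 = np.searchsorted(mzb, mza)
    for i, mz in enumerate(mza):
        tol = tol_ppm * 1e-6 * mz
        for j in range(int(j0[i]) - 1, int(j0[i]) + 1):
            if 0 <= j < len(mzb) and abs(mzb[j] - mz) <= tol:
                cand.append((abs(mzb[j] - mz) / mz, i, j))
    cand.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs = []
    for _, i, j in cand:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        pairs.append((i, j))
    return pairs


def match_factor(spec_a: np.ndarray, spec_b: np.ndarray, tol_ppm: float = 10.0) -> float:
    """Weighted-cosine spectral match factor in [0, 100].

    Symmetric; 100 for identical spectra, 0 when no peak pair aligns within
    ``tol_ppm``. Unmatched peaks dilute the score through the norms.
    """
    a = np.asarray(spec_a, dtype=float).reshape(-1, 2)
    b = np.asarray(spec_b, dtype=float).reshape(-1, 2)
    if a.shape[0] == 0 or b.shape[0] == 0:
        raise ValueError("match_factor requires non-empty spectra")
    a = a[np.argsort(a[:, 0])]
    b = b[np.argsort(b[:, 0])]
    wa = np.sqrt(np.clip(a[:, 1], 0, None)) * a[:, 0]
    wb = np.sqrt(np.clip(b[:, 1], 0, None)) * b[:, 0]
    dot = sum(wa[i] * wb[j] for i, j in _align(a, b, tol_ppm))
    denom = float(np.sum(wa**2)) * float(np.sum(wb**2))
    if denom <= 0:
        raise ValueError("spectra must contain positive intensities")
    return float(100.0 * dot * dot / denom)


def fragment_ppm(
    spec_obs: np.ndarray,
    spec_lib: np.ndarray,
    min_mz: float = 30.0,
    match_window_ppm: float = 40.0,
) -> float | None:
    """Maximum absolute fragment mass error (ppm) over aligned peaks >= min_mz.

    Returns None when no observed fragment at or above ``min_mz`` aligns with
    a library fragment — the accurate-mass gate then fails with that reason.
    Alignment for this check uses a window wider than the gate threshold so a
    20-40 ppm discrepancy is *measured* (and rejected) rather than silently
    treated as two different fragments.
    """
    a = np.asarray(spec_obs, dtype=float).reshape(-1, 2)
    b = np.asarray(spec_lib, dtype=float).reshape(-1, 2)
    a = a[np.argsort(a[:, 0])]
    b = b[np.argsort(b[:, 0])]
    pairs = _align(a, b, match_window_ppm)
    errs = [
        abs(a[i, 0] - b[j, 0]) / b[j, 0] * 1e6
        for i, j in pairs
        if a[i, 0] >= min_mz and b[j, 0] >= min_mz
    ]
    if not errs:
        return None
    return float(max(errs))


def rt_penalty_weight(delta_rt_s: float, free_s: float = 12.0, range_s: float = 18.0) -> float:
    """Trapezoidal retention-time weight in [0, 1].

    No penalty for |dRT| <= ``free_s``; linear decay to zero at ``range_s``;
    zero beyond. ``free_s`` and ``range_s`` are half-widths of the trapezoid's
    top and base.
    """
    if delta_rt_s < 0:
        raise ValueError("delta_rt_s must be non-negative")
    if range_s <= free_s:
        raise ValueError("range_s must exceed free_s")
    if delta_rt_s <= free_s:
        return 1.0
    if delta_rt_s >= range_s:
        return 0.0
    return float((range_s - delta_rt_s) / (range_s - free_s))


def make_unknown_name(rt_min: float) -> str:
    return f"Unknown {rt_min:.4f}"


def identify(
    component,
    libraries: Sequence[Iterable[LibraryEntry]],
    component_ri: float | None = None,
    mf_min: float = 70.0,
    dri_max: float = 30.0,
    ppm_max: float = 20.0,
    use_rt_penalty: bool = True,
    penalty_free_s: float = 12.0,
    penalty_range_s: float = 18.0,
    penalty_mode: str = "multiplicative",
    standards: set[str] | frozenset[str] = frozenset(),
    unknown_formula_ppm: float = 10.0,
) -> MatchResult:
    """Score ``component`` against one or more libraries and pick the best hit.

    ``component`` needs ``spectrum`` ((n,2) m/z, abundance base-100) and
    ``apex_rt`` (seconds). Candidates must clear the penalized-MF floor, the
    fragment accurate-mass gate, and the dRI gate when both RIs are known.
    The RT penalty applies only to entries that carry a retention time and
    only when ``use_rt_penalty`` is set (internal, retention-aware libraries);
    external libraries are searched with ``use_rt_penalty=False``.

    Ties: highest penalized MF, then smallest dRI, then smallest dRT, then
    lexicographic name. No hit -> an Unknown named by RT in minutes (4
    decimals), identification level 4, with base-peak exact mass and formula
    candidates attached.
    """
    spec = np.asarray(component.spectrum, dtype=float).reshape(-1, 2)
    rt_min_obs = component.apex_rt / 60.0
    best: MatchResult | None = None
    best_key: tuple = ()
    for lib in libraries:
        for entry in lib:
            mf = match_factor(spec, entry.spectrum)
            drt = None
            weight = 1.0
            if use_rt_penalty and entry.rt_min is not None:
                drt = abs(component.apex_rt - entry.rt_min * 60.0)
                weight = rt_penalty_weight(drt, penalty_free_s, penalty_range_s)
            if penalty_mode == "multiplicative":
                pmf = mf * weight
            elif penalty_mode == "subtractive":
                pmf = max(0.0, mf - 100.0 * (1.0 - weight))
            else:
                raise ValueError(f"unknown penalty_mode {penalty_mode!r}")
            dri = None
            if component_ri is not None and entry.ri is not None:
                dri = abs(component_ri - entry.ri)
            max_ppm = fragment_ppm(spec, entry.spectrum)
            ok = (
                pmf >= mf_min
                and max_ppm is not None
                and max_ppm < ppm_max
                and (dri is None or dri < dri_max)
            )
            if not ok:
                continue
            key = (
                -pmf,
                dri if dri is not None else math.inf,
                drt if drt is not None else math.inf,
                entry.name,
            )
            if best is None or key < best_key:
                if entry.name in standards and drt is not None:
                    level = 1
                else:
                    level = entry.id_level
                best = MatchResult(
                    name=entry.name,
                    entry=entry,
                    match_factor=mf,
                    penalized_mf=pmf,
                    delta_ri=dri,
                    delta_rt_s=drt,
                    max_fragment_ppm=max_ppm,
                    passed=True,
                    id_level=level,
                    is_unknown=entry.name.startswith("Unknown "),
                )
                best_key = key
    if best is not None:
        return best
    base_mz = float(spec[np.argmax(spec[:, 1]), 0])
    return MatchResult(
        name=make_unknown_name(rt_min_obs),
        entry=None,
        passed=False,
        id_level=4,
        is_unknown=True,
        exact_mass=base_mz,
        formulas=formula_candidates(base_mz, ppm=unknown_formula_ppm),
    )


# element bounds for the exhaustive formula search
_FORMULA_BOUNDS = {"C": 30, "H": 60, "N": 3, "O": 6, "S": 1, "Cl": 2, "F": 3}


def formula_candidates(
    exact_mass: float, ppm: float = 10.0, bounds: dict[str, int] | None = None
) -> list[tuple[str, float]]:
    """Exhaustive CHNOS(Cl,F) formula search within a ppm tolerance.

    Returns ``(formula, ppm_error)`` pairs ranked by |ppm error|. Candidates
    must have a non-negative ring-and-double-bond equivalent
    ``RDBE = C + 1 + N/2 - (H + Cl + F)/2``. Valid for masses 30-500 Da.
    """
    if not (30.0 <= exact_mass <= 500.0):
        raise ValueError("formula search supports masses between 30 and 500 Da")
    b = dict(_FORMULA_BOUNDS)
    if bounds:
        b.update(bounds)
    mH = MONOISOTOPIC_MASS["H"]
    tol = ppm * 1e-6 * exact_mass
    out: list[tuple[float, str]] = []
    for n in range(b.get("N", 0) + 1):
        for o in range(b.get("O", 0) + 1):
            for s in range(b.get("S", 0) + 1):
                for cl in range(b.get("Cl", 0) + 1):
                    for f in range(b.get("F", 0) + 1):
                        hetero = (
                            n * MONOISOTOPIC_MASS["N"]
                            + o * MONOISOTOPIC_MASS["O"]
                            + s * MONOISOTOPIC_MASS["S"]
                            + cl * MONOISOTOPIC_MASS["Cl"]
                            + f * MONOISOTOPIC_MASS["F"]
                        )
                        if hetero - tol > exact_mass:
                            break
                        for c in range(b.get("C", 0) + 1):
                            rem = exact_mass - hetero - 12.0 * c
                            if rem < -tol:
                                break
                            h_guess = int(round(rem / mH))
                            for h in (h_guess - 1, h_guess, h_guess + 1):
                                if h < 0 or h > b.get("H", 0):
                                    continue
                                rdbe = c + 1 + n / 2.0 - (h + cl + f) / 2.0
                                if rdbe < 0:
                                    continue
                                mass = 12.0 * c + h * mH + hetero
                                err = (mass - exact_mass) / exact_mass * 1e6
                                if abs(err) <= ppm:
                                    counts = {
                                        "C": c, "H": h, "N": n, "O": o,
                                        "S": s, "Cl": cl, "F": f,
                                    }
                                    if c == 0 and h == 0:
                                        continue
                                    out.append((abs(err), formula_to_string(counts)))
    seen: set[str] = set()
    ranked: list[tuple[str, float]] = []
    for err, formula in sorted(out):
        if formula in seen:
            continue
        seen.add(formula)
        ranked.append((formula, err))
    return ranked
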