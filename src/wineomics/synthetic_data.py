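"""Synthetic GC-QTOF runs with known ground truth.

The generator emulates the study design this pipeline targets: Cabernet
Sauvignon wines from 2 vineyards x 2 vintages x 3 replicates, a pooled-wine
QC (PW) and a spiked pool (PWS), five-level calibration curves of four
volatile standards (alpha-/beta-pinene at 1.56-25 ng/L, p-cymene and
2-undecanone at 0.31-5 ng/L, 1:1 dilution steps), a C8-C40 n-alkane ladder
and a blank — all as time-ordered centroid scans over a 63-min acquisition
at 2.5 spectra/s, mass range 30-400 Th.

Peaks are Gaussian (exponentially-modified Gaussian when ``tailing_tau`` >
0) per fragment ion, co-apexed at the compound's retention time, sampled on
the scan grid with ppm-perturbed m/z and additive positive baseline noise
emitted in a window around each peak (real centroiding drops near-zero
points, so scans far from any signal are empty).

Fragment spectra are *invented*: deterministic seeded draws of sub-formula
masses of each compound (real EI spectra are library-copyrighted). They are
chemically plausible in mass but not in physics; tests that pass on them
validate the processing chain, not EI fragmentation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .chem import monoisotopic_mass, parse_formula
from .io_formats import RawRun, RunMetadata, Scan, load_table1_fixture
from .retention_index import RICalibration, ri_to_rt

__all__ = [
    "CompoundSpec",
    "NoiseModel",
    "RunTruth",
    "SimulatedStudy",
    "ALKANE_LADDER",
    "AREA_PER_NG_L",
    "STANDARD_LEVELS_NG_L",
    "make_catalog",
    "make_standards_catalog",
    "catalog_to_library",
    "simulate_run",
    "simulate_alkane_run",
    "simulate_validation_runs",
    "simulate_study",
]

#: scan grid: 63 min at 2.5 spectra/s
SCAN_PERIOD_S = 0.4
RUN_LENGTH_S = 63.0 * 60.0
N_SCANS = int(round(RUN_LENGTH_S / SCAN_PERIOD_S))  # 9450
MASS_RANGE = (30.0, 400.0)

#: canonical alkane ladder: C8 elutes at 320 s, C40 at 3680 s, linear in n.
ALKANE_LADDER = RICalibration(
    carbon_numbers=np.arange(8, 41, dtype=float),
    rt_s=320.0 + 105.0 * np.arange(0, 33, dtype=float),
)

#: instrument response: component area counts per ng/L of standard.
#: No measured response factor is available for this instrument class, so a
#: single arbitrary-but-fixed slope keeps LOD/LOQ arithmetic verifiable.
AREA_PER_NG_L = 1.65e5

#: five-level calibration concentrations (ng/L), 1:1 dilution factor
STANDARD_LEVELS_NG_L = {
    "alpha-Pinene": [25.0 / 2**k for k in (4, 3, 2, 1, 0)],
    "beta-Pinene": [25.0 / 2**k for k in (4, 3, 2, 1, 0)],
    "p-Cymene": [5.0 / 2**k for k in (4, 3, 2, 1, 0)],
    "2-Undecanone": [5.0 / 2**k for k in (4, 3, 2, 1, 0)],
}

_STANDARD_FORMULAS = {
    "alpha-Pinene": ("C10H16", "80-56-8", 1025.0),
    "beta-Pinene": ("C10H16", "127-91-3", 1112.0),
    "p-Cymene": ("C10H14", "99-87-6", 1268.0),
    "2-Undecanone": ("C11H22O", "112-12-9", 1600.0),
}


@dataclass
class CompoundSpec:
    """A planted compound: identity, invented spectrum, retention target and
    per-group expected areas."""

    name: str
    formula: dict[str, int]
    monoisotopic_mass: float
    fragments: np.ndarray  # (n, 2): m/z, relative intensity (base = 100)
    target_ri: float
    group_abundances: dict[str, float] = field(default_factory=dict)
    cas: str = ""
    id_level: int = 2

    def __post_init__(self) -> None:
        self.fragments = np.asarray(self.fragments, dtype=float).reshape(-1, 2)
        calc = monoisotopic_mass(self.formula)
        if abs(calc - self.monoisotopic_mass) > 1e-4:
            raise ValueError(
                f"{self.name}: formula mass {calc:.5f} != stated {self.monoisotopic_mass:.5f}"
            )
        if abs(self.fragments[:, 1].max() - 100.0) > 1e-9:
            raise ValueError(f"{self.name}: base fragment must have intensity 100")
        lo, hi = MASS_RANGE
        if np.any((self.fragments[:, 0] < lo) | (self.fragments[:, 0] > hi)):
            raise ValueError(f"{self.name}: fragment m/z outside instrument mass range")

    @property
    def target_rt_s(self) -> float:
        return ri_to_rt(self.target_ri, ALKANE_LADDER)


@dataclass
class NoiseModel:
    """Instrument imperfections; defaults are calibrated so the printed
    validation envelope (area %RSD < 20, RT %RSD < 0.5, mass error < 5 ppm)
    is achievable end-to-end."""

    area_cv: float = 0.08  # multiplicative area scatter, fraction
    rt_jitter_sd: float = 1.5  # s
    mass_error_sd: float = 1.5  # ppm, per centroid point
    baseline_sd: float = 20.0  # counts
    baseline_level: float = 100.0  # counts, mean of the positive baseline
    peak_sigma: float = 2.5  # s, Gaussian width
    tailing_tau: float = 0.0  # s; > 0 switches to exponentially-modified Gaussian
    peak_window_s: float = 25.0  # emit centroid points within +/- this of apex
    saturation_counts: float | None = None  # clip intensities (ion saturation); off

    def __post_init__(self) -> None:
        for name in ("area_cv", "rt_jitter_sd", "mass_error_sd", "baseline_sd",
                     "baseline_level", "peak_sigma", "tailing_tau", "peak_window_s"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @classmethod
    def noiseless(cls) -> "NoiseModel":
        return cls(area_cv=0.0, rt_jitter_sd=0.0, mass_error_sd=0.0,
                   baseline_sd=0.0, baseline_level=0.0)


@dataclass
class RunTruth:
    """Planted ground truth for one run."""

    compounds: pd.DataFrame  # name, true_rt_s, area, n_fragments
    fragments: pd.DataFrame  # name, mz, area


@dataclass
class SimulatedStudy:
    """A materialised study: runs, manifest and planted design."""

    runs: dict[str, RawRun]
    truths: dict[str, RunTruth]
    manifest: pd.DataFrame  # run_id, role, group, vineyard, vintage, replicate, day, level
    catalog: list[CompoundSpec]
    standards: list[CompoundSpec]
    presence: pd.DataFrame  # planted entity x group booleans (wine groups)


# --------------------------------------------------------------------------
# catalog construction
# --------------------------------------------------------------------------

def _subformula_masses(counts: dict[str, int], lo: float, hi: float) -> np.ndarray:
    """Masses of all sub-formulas (with >= 1 heavy atom) within [lo, hi]."""
    elems = [e for e, n in counts.items() if n > 0]
    ranges = [range(counts[e] + 1) for e in elems]
    masses = []
    for combo in itertools.product(*ranges):
        if sum(combo) == 0:
            continue
        sub = dict(zip(elems, combo))
        if sum(n for e, n in sub.items() if e != "H") == 0:
            continue
        m = monoisotopic_mass(sub)
        if lo <= m <= hi:
            masses.append(m)
    return np.unique(np.round(masses, 6))


def _invent_fragments(
    formula: dict[str, int],
    rng: np.random.Generator,
    n_min: int = 4,
    n_max: int = 8,
    exclude: np.ndarray | None = None,
) -> np.ndarray:
    """Draw 4-8 distinct sub-formula masses as a synthetic EI spectrum.

    Small molecules whose sub-formula pool is too shallow draw from the
    doubled formula (cluster-ion-like masses above the molecular mass) —
    synthetic, flagged in the module docstring. ``exclude`` masses (within
    50 ppm) are avoided so that designed pairs (e.g. the pinene isomers)
    stay spectrally distinct.
    """
    lo = MASS_RANGE[0] + 1.0
    hi = min(MASS_RANGE[1], max(monoisotopic_mass(formula), lo + 5.0))
    pool = _subformula_masses(formula, lo, hi)
    if pool.size < n_max + 2:
        doubled = {e: 2 * n for e, n in formula.items()}
        pool = _subformula_masses(doubled, lo, min(MASS_RANGE[1], 2 * monoisotopic_mass(formula)))
    if exclude is not None and exclude.size:
        keep = np.ones(pool.size, dtype=bool)
        for m in exclude:
            keep &= np.abs(pool - m) / m > 50e-6
        pool = pool[keep]
    # thin the pool so chosen masses are >= 0.05 Da apart
    chosen: list[float] = []
    for m in rng.permutation(pool):
        if all(abs(m - c) > 0.05 for c in chosen):
            chosen.append(float(m))
    n = int(rng.integers(n_min, min(n_max, len(chosen)) + 1)) if len(chosen) >= n_min else len(chosen)
    if n < n_min:
        raise ValueError(f"cannot invent {n_min} fragments for formula {formula}")
    masses = sorted(chosen[:n])
    rels = rng.uniform(20.0, 95.0, size=n)
    rels[int(rng.integers(0, n))] = 100.0
    # exactly one base peak
    rels = np.where(rels == 100.0, rels, np.minimum(rels, 95.0))
    return np.column_stack([masses, rels])


#: formulas for catalog rows whose source annotation lacks one (invented,
#: mass-consistent placeholders so every planted compound has a spectrum)
_FALLBACK_FORMULAS = {"Unknown 34.9582": "C9H18O"}

#: minimum spacing imposed on planted retention indices. Adjacent catalog
#: entries closer than this are nudged apart so that every planted compound
#: is chromatographically resolvable at the generator's peak width —
#: deconvolution resolution limits are exercised by dedicated stress tests,
#: not by the study-design scenarios.
MIN_RI_SPACING = 7.5


def make_catalog(
    n_compounds: int | None = None,
    seed: int = 0,
    min_ri_spacing: float = MIN_RI_SPACING,
) -> list[CompoundSpec]:
    """Build the default compound catalog from the bundled 101-compound wine
    table (names, formulas, retention indices, per-group abundances), with
    deterministic invented spectra.

    ``n_compounds`` keeps the first n entries in elution order. Retention
    indices are nudged to at least ``min_ri_spacing`` apart (see
    :data:`MIN_RI_SPACING`).
    """
    table = load_table1_fixture()
    rows = table.entities.reset_index()
    if n_compounds is not None:
        if n_compounds < 1:
            raise ValueError("n_compounds must be >= 1")
        rows = rows.iloc[:n_compounds]
    ris = rows["ri"].to_numpy(dtype=float).copy()
    for i in range(1, len(ris)):
        ris[i] = max(ris[i], ris[i - 1] + min_ri_spacing)
    standards = {c.name: c for c in make_standards_catalog(seed=0)}
    catalog: list[CompoundSpec] = []
    for i, (_, row) in enumerate(rows.iterrows()):
        formula_s = row["formula"] or _FALLBACK_FORMULAS.get(row["entity"], "C10H20O")
        formula = parse_formula(formula_s)
        rng = np.random.default_rng([seed, 7, i])
        rt_i = ri_to_rt(float(ris[i]), ALKANE_LADDER)
        # near-eluting catalog entries must not share accurate fragment
        # masses: co-eluting *and* isobaric-to-ppm is a resolution stress
        # case, exercised separately, not part of the study design
        nearby = [
            m
            for c in catalog
            if abs(c.target_rt_s - rt_i) < 30.0
            for m in c.fragments[:, 0]
        ]
        nearby += [
            m
            for c in standards.values()
            if abs(c.target_rt_s - rt_i) < 30.0
            for m in c.fragments[:, 0]
        ]
        exclude = np.asarray(nearby) if nearby else None
        if row["entity"] in standards:
            # spiked validation standards occur in wines too; one spectrum
            # per physical compound keeps pool + spike coherent
            fragments = standards[row["entity"]].fragments.copy()
        else:
            try:
                fragments = _invent_fragments(formula, rng, exclude=exclude)
            except ValueError:
                fragments = _invent_fragments(formula, rng)
        abundances = {
            g: float(v)
            for g, v in table.abundance.loc[row["entity"]].items()
            if pd.notna(v)
        }
        catalog.append(
            CompoundSpec(
                name=row["entity"],
                formula=formula,
                monoisotopic_mass=monoisotopic_mass(formula),
                fragments=fragments,
                target_ri=float(ris[i]),
                group_abundances=abundances,
                cas=row["cas"] or "",
                id_level=int(row["id_level"]),
            )
        )
    return catalog


def make_standards_catalog(seed: int = 0) -> list[CompoundSpec]:
    """The four validation standards with deterministic invented spectra.

    The pinene isomers share formula C10H16 (136.1252 Da) but are given
    disjoint fragment sets and distinct retention indices, so the method's
    selectivity between them is testable by construction.
    """
    out: list[CompoundSpec] = []
    exclude: np.ndarray | None = None
    for i, (name, (formula_s, cas, ri)) in enumerate(_STANDARD_FORMULAS.items()):
        formula = parse_formula(formula_s)
        rng = np.random.default_rng([seed, 11, i])
        fragments = _invent_fragments(formula, rng, exclude=exclude if name == "beta-Pinene" else None)
        if name == "alpha-Pinene":
            exclude = fragments[:, 0]
        out.append(
            CompoundSpec(
                name=name,
                formula=formula,
                monoisotopic_mass=monoisotopic_mass(formula),
                fragments=fragments,
                target_ri=ri,
                cas=cas,
                id_level=1,
            )
        )
    return out


def catalog_to_library(
    catalog: list[CompoundSpec], name: str = "catalog", with_rt: bool = True
):
    """Render a catalog as a spectral library (the generator's entries are
    exact, so this is the idealised external/internal library)."""
    from .identification import LibraryEntry
    from .io_formats import LibraryFile

    entries = [
        LibraryEntry(
            name=c.name,
            spectrum=c.fragments.copy(),
            cas=c.cas,
            formula="".join(f"{e}{n}" for e, n in c.formula.items() if n),
            exact_mass=c.monoisotopic_mass,
            rt_min=c.target_rt_s / 60.0 if with_rt else None,
            ri=c.target_ri,
            id_level=c.id_level,
        )
        for c in catalog
    ]
    return LibraryFile(entries=entries, name=name)


# --------------------------------------------------------------------------
# run simulation
# --------------------------------------------------------------------------

def _emg_profile(t: np.ndarray, rt: float, sigma: float, tau: float) -> np.ndarray:
    """Unit-area peak profile: Gaussian, or EMG when tau > 0."""
    if tau <= 0:
        return np.exp(-0.5 * ((t - rt) / sigma) ** 2) / (sigma * np.sqrt(2 * np.pi))
    from scipy.stats import exponnorm

    return exponnorm.pdf(t, K=tau / sigma, loc=rt, scale=sigma)


def simulate_run(
    compound_areas: list[tuple[CompoundSpec, float]],
    metadata: RunMetadata,
    noise: NoiseModel | None = None,
    seed: int | list[int] = 0,
) -> tuple[RawRun, RunTruth]:
    """Emit one run: every planted compound contributes one co-apexed peak
    per fragment ion, with areas proportional to compound area x relative
    intensity, on the canonical 63-min / 2.5 Hz scan grid.

    Retention-time collisions between planted compounds are permitted — they
    are a deconvolution stress case, not an error.
    """
    noise = noise or NoiseModel()
    rng = np.random.default_rng(seed)
    times = np.arange(N_SCANS) * SCAN_PERIOD_S
    scan_mz: list[list[float]] = [[] for _ in range(N_SCANS)]
    scan_int: list[list[float]] = [[] for _ in range(N_SCANS)]
    comp_rows = []
    frag_rows = []
    window = noise.peak_window_s + 5.0 * noise.tailing_tau
    for spec, area in compound_areas:
        if area <= 0:
            continue
        rt = spec.target_rt_s + rng.normal(0.0, noise.rt_jitter_sd) if noise.rt_jitter_sd else spec.target_rt_s
        area_run = area * max(rng.normal(1.0, noise.area_cv), 0.05) if noise.area_cv else area
        rel = spec.fragments[:, 1]
        frac = rel / rel.sum()
        lo = np.searchsorted(times, rt - window)
        hi = np.searchsorted(times, rt + window)
        if hi <= lo:
            continue
        t_win = times[lo:hi]
        profile = _emg_profile(t_win, rt, noise.peak_sigma, noise.tailing_tau)
        for (mz0, _), f in zip(spec.fragments, frac):
            frag_area = area_run * f
            y = frag_area * profile
            if noise.baseline_level or noise.baseline_sd:
                y = y + np.clip(
                    rng.normal(noise.baseline_level, noise.baseline_sd, size=y.size), 0.0, None
                )
            if noise.saturation_counts:
                y = np.minimum(y, noise.saturation_counts)
            if noise.mass_error_sd:
                mzs = mz0 * (1.0 + rng.normal(0.0, noise.mass_error_sd, size=y.size) * 1e-6)
            else:
                mzs = np.full(y.size, mz0)
            for k in range(y.size):
                scan_mz[lo + k].append(float(mzs[k]))
                scan_int[lo + k].append(float(y[k]))
            frag_rows.append({"name": spec.name, "mz": mz0, "area": frag_area})
        comp_rows.append(
            {"name": spec.name, "true_rt_s": rt, "area": area_run,
             "n_fragments": len(spec.fragments)}
        )
    scans = []
    for i in range(N_SCANS):
        mz = np.asarray(scan_mz[i])
        inten = np.asarray(scan_int[i])
        order = np.argsort(mz)
        mz, inten = mz[order], inten[order]
        if mz.size > 1:
            # centroiding: co-channel points (< 10 ppm apart, e.g. a shared
            # fragment of two nearby compounds) merge into one centroid —
            # the instrument's extraction window cannot resolve them anyway
            close = np.diff(mz) / mz[:-1] < 10e-6
            if close.any():
                group = np.concatenate([[0], np.cumsum(~close)])
                w = np.clip(inten, 1e-12, None)
                sums = np.bincount(group, weights=w)
                mz = np.bincount(group, weights=mz * w) / sums
                inten = np.bincount(group, weights=inten)
        scans.append(Scan(time=float(times[i]), mz=mz, intensity=inten))
    run = RawRun(scans=scans, metadata=metadata)
    truth = RunTruth(
        compounds=pd.DataFrame(comp_rows, columns=["name", "true_rt_s", "area", "n_fragments"]),
        fragments=pd.DataFrame(frag_rows, columns=["name", "mz", "area"]),
    )
    return run, truth


_ALKANE_FRAGMENT_FORMULAS = ["C3H7", "C4H9", "C5H11", "C6H13"]


def alkane_catalog() -> list[CompoundSpec]:
    """C8..C40 n-alkanes with their shared acylium-series fragment ions."""
    frag_mz = [monoisotopic_mass(f) for f in _ALKANE_FRAGMENT_FORMULAS]
    rels = [100.0, 80.0, 55.0, 35.0]
    out = []
    for n, rt in zip(ALKANE_LADDER.carbon_numbers.astype(int), ALKANE_LADDER.rt_s):
        formula = {"C": int(n), "H": 2 * int(n) + 2}
        out.append(
            CompoundSpec(
                name=f"C{n} alkane",
                formula=formula,
                monoisotopic_mass=monoisotopic_mass(formula),
                fragments=np.column_stack([frag_mz, rels]),
                target_ri=100.0 * n,
                id_level=1,
            )
        )
    return out


def simulate_alkane_run(seed: int = 0, noise: NoiseModel | None = None) -> RawRun:
    """The 50 ng/L C8-C40 ladder run used for retention-index calibration."""
    noise = noise or NoiseModel(rt_jitter_sd=0.5)
    md = RunMetadata(run_id=f"alkane_s{seed}", sample_role="alkane")
    run, _ = simulate_run(
        [(c, 5.0e6) for c in alkane_catalog()], md, noise, seed=[seed, 101]
    )
    return run


def _standard_areas(level: int, rng: np.random.Generator | None = None) -> dict[str, float]:
    return {
        name: AREA_PER_NG_L * STANDARD_LEVELS_NG_L[name][level - 1]
        for name in STANDARD_LEVELS_NG_L
    }


def simulate_validation_runs(
    seed: int = 0,
    noise: NoiseModel | None = None,
    standards: list[CompoundSpec] | None = None,
) -> tuple[dict[str, RawRun], dict[str, RunTruth], pd.DataFrame]:
    """The method-validation injection set.

    Day 1: five-level curve in triplicate (repeatability). Day 2: levels
    L1/L3/L5 in triplicate (reproducibility). Day 3: four further L1
    injections, completing ten L1 injections across three days (LOD/LOQ).
    """
    noise = noise or NoiseModel()
    standards = standards or make_standards_catalog(seed=0)
    by_name = {c.name: c for c in standards}
    plan: list[tuple[int, int, int]] = []  # (day, level, replicate)
    plan += [(1, lvl, rep) for lvl in range(1, 6) for rep in range(1, 4)]
    plan += [(2, lvl, rep) for lvl in (1, 3, 5) for rep in range(1, 4)]
    plan += [(3, 1, rep) for rep in range(1, 5)]
    runs: dict[str, RawRun] = {}
    truths: dict[str, RunTruth] = {}
    rows = []
    for i, (day, lvl, rep) in enumerate(plan):
        run_id = f"std_d{day}_L{lvl}_r{rep}"
        md = RunMetadata(
            run_id=run_id, sample_role="standard_level", day=day, level=lvl, replicate=rep
        )
        areas = _standard_areas(lvl)
        compound_areas = [(by_name[name], areas[name]) for name in sorted(areas)]
        run, truth = simulate_run(compound_areas, md, noise, seed=[seed, 201, i])
        runs[run_id] = run
        truths[run_id] = truth
        rows.append(
            {"run_id": run_id, "role": "standard_level", "group": "", "vineyard": "",
             "vintage": "", "replicate": rep, "day": day, "level": lvl}
        )
    return runs, truths, pd.DataFrame(rows)


_WINE_GROUPS = [
    ("LaChanga", "2017"),
    ("LaChanga", "2018"),
    ("LosDolores", "2017"),
    ("LosDolores", "2018"),
]


def simulate_study(
    seed: int = 0,
    noise: NoiseModel | None = None,
    catalog: list[CompoundSpec] | None = None,
    n_qc: int = 3,
    include_standards: bool = False,
    include_spiked_qc: bool = True,
    include_blank: bool = True,
) -> SimulatedStudy:
    """Materialise the full study: 4 wine groups x 3 replicates, PW/PWS QC
    pools, the alkane ladder, optionally the validation set and a blank.

    The planted per-group presence/abundance design is the catalog's
    ``group_abundances`` (by default the bundled wine table), so the study's
    Venn structure is known ground truth. The PW pool contains every
    compound present in any wine at the mean of its present-group areas; PWS
    adds the four standards at level-4 concentration.
    """
    noise = noise or NoiseModel()
    catalog = catalog if catalog is not None else make_catalog(seed=seed)
    standards = make_standards_catalog(seed=0)
    runs: dict[str, RawRun] = {}
    truths: dict[str, RunTruth] = {}
    rows = []
    idx = 0

    def add(run_id: str, md: RunMetadata, compound_areas, day=1, level=None):
        nonlocal idx
        run, truth = simulate_run(compound_areas, md, noise, seed=[seed, 301, idx])
        idx += 1
        runs[run_id] = run
        truths[run_id] = truth
        rows.append(
            {"run_id": run_id, "role": md.sample_role, "group": md.group or "",
             "vineyard": md.vineyard or "", "vintage": md.vintage or "",
             "replicate": md.replicate, "day": day, "level": level}
        )

    for vineyard, vintage in _WINE_GROUPS:
        group = f"{vineyard}{vintage}"
        planted = [
            (c, c.group_abundances[group]) for c in catalog if group in c.group_abundances
        ]
        for rep in range(1, 4):
            md = RunMetadata(
                run_id=f"{group}_r{rep}", sample_role="sample",
                vineyard=vineyard, vintage=vintage, replicate=rep,
            )
            add(md.run_id, md, planted)

    pool = [
        (c, float(np.mean(list(c.group_abundances.values()))))
        for c in catalog
        if c.group_abundances
    ]
    for rep in range(1, n_qc + 1):
        md = RunMetadata(run_id=f"PW_r{rep}", sample_role="qc_pool", replicate=rep)
        add(md.run_id, md, pool)
    if include_spiked_qc:
        l4 = _standard_areas(4)
        pooled_names = {c.name for c, _ in pool}
        spiked = [
            (c, a + l4.get(c.name, 0.0)) for c, a in pool
        ] + [(c, l4[c.name]) for c in standards if c.name not in pooled_names]
        for rep in range(1, n_qc + 1):
            md = RunMetadata(run_id=f"PWS_r{rep}", sample_role="qc_spiked", replicate=rep)
            add(md.run_id, md, spiked)

    alk_md = RunMetadata(run_id="alkane", sample_role="alkane")
    add("alkane", alk_md, [(c, 5.0e6) for c in alkane_catalog()])
    if include_blank:
        add("blank", RunMetadata(run_id="blank", sample_role="blank"), [])
    if include_standards:
        vruns, vtruths, vman = simulate_validation_runs(seed=seed, noise=noise)
        runs.update(vruns)
        truths.update(vtruths)
        rows.extend(vman.to_dict("records"))

    groups = [f"{v}{y}" for v, y in _WINE_GROUPS]
    presence = pd.DataFrame(
        {g: [g in c.group_abundances for c in catalog] for g in groups},
        index=pd.Index([c.name for c in catalog], name="entity"),
    )
    return SimulatedStudy(
        runs=runs,
        truths=truths,
        manifest=pd.DataFrame(rows),
        catalog=catalog,
        standards=standards,
        presence=presence,
    )
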