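"""Method-validation statistics and batch quality control.

Validation follows targeted-method practice applied to an untargeted
workflow: repeatability and reproducibility as %RSD of extracted component
areas, retention-time and match-factor %RSD, linearity of five-level
standard curves (Pearson r), LOD/LOQ from replicate low-level injections via
the ICH sigma/slope convention (LOD = 3.3 s/m, LOQ = 10 s/m), fragment mass
accuracy, and a carryover rule (blank signal < 20% of LOQ).

Quality control monitors pooled samples (PW, spiked PWS) injected through
every batch: a PCA over all runs should show the QC pool clustering tightly
relative to the biological spread of the samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .entities import EntityTable

__all__ = [
    "rsd",
    "CalibrationSeries",
    "linearity",
    "lod_loq",
    "carryover_check",
    "ValidationThresholds",
    "ValidationReport",
    "compute_validation_report",
    "QCReport",
    "qc_pca_report",
]


def rsd(values) -> float:
    """Percent relative standard deviation: 100 * sample SD / mean."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("%RSD needs at least two values")
    mean = x.mean()
    if mean == 0:
        raise ValueError("%RSD undefined for zero mean")
    return float(100.0 * x.std(ddof=1) / mean)


@dataclass
class CalibrationSeries:
    """Replicate areas per concentration level for one standard."""

    standard: str
    levels: list[tuple[float, list[float]]]  # (concentration ng/L, areas)
    days: list[int] | None = None

    def __post_init__(self) -> None:
        concs = [c for c, _ in self.levels]
        if len(set(concs)) < 2:
            raise ValueError("calibration needs at least two distinct concentrations")
        # 1:1 dilution design: each step doubles the concentration
        ratios = np.diff(np.log2(sorted(set(concs))))
        if not np.allclose(ratios, 1.0, atol=0.05):
            raise ValueError(
                f"{self.standard}: concentrations do not follow a 1:1 dilution design"
            )

    def level_means(self) -> tuple[np.ndarray, np.ndarray]:
        concs = np.array([c for c, _ in self.levels])
        means = np.array([float(np.mean(a)) for _, a in self.levels])
        order = np.argsort(concs)
        return concs[order], means[order]

    def slope(self) -> float:
        """Least-squares response slope (area counts per ng/L)."""
        concs, means = self.level_means()
        return float(np.polyfit(concs, means, 1)[0])


def linearity(series: CalibrationSeries) -> float:
    """Pearson r between concentration and mean area per level (signed)."""
    concs, means = series.level_means()
    if len(concs) < 3:
        raise ValueError("linearity needs at least three distinct levels")
    if np.ptp(means) == 0:
        raise ValueError("constant areas: correlation undefined")
    return float(np.corrcoef(concs, means)[0, 1])


def lod_loq(l1_areas, slope: float) -> tuple[float, float]:
    """Detection/quantification limits (ng/L) from replicate L1 injections.

    sigma is the sample SD of the L1 areas; LOD = 3.3 sigma/slope,
    LOQ = 10 sigma/slope.
    """
    x = np.asarray(l1_areas, dtype=float)
    if x.size < 6:
        raise ValueError("LOD/LOQ need at least six L1 measurements")
    if slope <= 0:
        raise ValueError("slope must be positive")
    sigma = float(x.std(ddof=1))
    return 3.3 * sigma / slope, 10.0 * sigma / slope


def carryover_check(blank_concentration: float, loq: float) -> bool:
    """Pass iff the blank signal is below 20% of LOQ (boundary excluded)."""
    if loq <= 0:
        raise ValueError("LOQ must be positive")
    return bool(blank_concentration < 0.20 * loq)


@dataclass
class ValidationThresholds:
    area_rsd_max: float = 20.0  # %
    rt_rsd_max: float = 0.5  # %
    mf_rsd_max: float = 2.0  # %
    linearity_min: float = 0.99
    fragment_ppm_max: float = 5.0


@dataclass
class ValidationReport:
    """Aggregated validation outcome across standards."""

    repeatability: pd.DataFrame  # standard x level %RSD (day 1 triplicates)
    reproducibility: pd.DataFrame  # standard x level %RSD (days pooled)
    rt_rsd: pd.Series  # per standard, %
    mf_rsd: pd.Series  # per standard, %
    linearity_r: pd.Series  # per standard (|r|)
    lod: pd.Series  # ng/L
    loq: pd.Series  # ng/L
    max_fragment_ppm: pd.Series  # per standard, over 5 most abundant fragments
    thresholds: ValidationThresholds = field(default_factory=ValidationThresholds)

    @property
    def max_area_rsd(self) -> float:
        return float(
            np.nanmax(
                np.concatenate(
                    [self.repeatability.to_numpy().ravel(),
                     self.reproducibility.to_numpy().ravel()]
                )
            )
        )

    @property
    def max_rt_rsd(self) -> float:
        return float(self.rt_rsd.max())

    def passes(self) -> dict[str, bool]:
        t = self.thresholds
        return {
            "area_rsd": self.max_area_rsd < t.area_rsd_max,
            "rt_rsd": self.max_rt_rsd < t.rt_rsd_max,
            "mf_rsd": float(self.mf_rsd.max()) < t.mf_rsd_max,
            "linearity": float(self.linearity_r.min()) > t.linearity_min,
            "mass_accuracy": float(self.max_fragment_ppm.max()) < t.fragment_ppm_max,
        }

    def all_pass(self) -> bool:
        return all(self.passes().values())


def compute_validation_report(
    measurements: pd.DataFrame,
    concentrations: dict[str, list[float]],
    thresholds: ValidationThresholds | None = None,
) -> ValidationReport:
    """Build a :class:`ValidationReport` from per-injection measurements.

    ``measurements`` is a long table with one row per (run, standard):
    columns ``standard``, ``day``, ``level``, ``replicate``, ``area``,
    ``rt_s``, ``mf``, ``max_ppm5``. ``concentrations`` maps each standard to
    its level concentrations (ng/L, level 1..n).

    Repeatability: per-level %RSD of the day-1 triplicates. Reproducibility:
    per-level %RSD pooling day 1 with the day-2 injections at the levels
    repeated on day 2 (the two-day design leaves pooling unspecified;
    pooling matching levels across days is this package's reading).
    LOD/LOQ: every L1 injection across days against the day-1 response
    slope.
    """
    thresholds = thresholds or ValidationThresholds()
    standards = sorted(measurements["standard"].unique())
    levels = sorted(measurements["level"].unique())
    rep = pd.DataFrame(index=standards, columns=levels, dtype=float)
    rpro = pd.DataFrame(index=standards, columns=levels, dtype=float)
    rt_rsd: dict[str, float] = {}
    mf_rsd: dict[str, float] = {}
    lin: dict[str, float] = {}
    lods: dict[str, float] = {}
    loqs: dict[str, float] = {}
    ppm5: dict[str, float] = {}
    for std in standards:
        m = measurements[measurements["standard"] == std]
        day1 = m[m["day"] == 1]
        day2_levels = sorted(m.loc[m["day"] == 2, "level"].unique())
        for lvl in levels:
            a1 = day1.loc[day1["level"] == lvl, "area"]
            if len(a1) >= 2:
                rep.loc[std, lvl] = rsd(a1)
            if lvl in day2_levels:
                pooled = m[(m["level"] == lvl) & (m["day"].isin([1, 2]))]["area"]
                if len(pooled) >= 2:
                    rpro.loc[std, lvl] = rsd(pooled)
        rt_rsd[std] = rsd(m["rt_s"])
        mf_rsd[std] = rsd(m["mf"])
        series = CalibrationSeries(
            standard=std,
            levels=[
                (concentrations[std][lvl - 1],
                 day1.loc[day1["level"] == lvl, "area"].tolist())
                for lvl in sorted(day1["level"].unique())
            ],
        )
        lin[std] = abs(linearity(series))
        l1 = m.loc[m["level"] == 1, "area"]
        lod, loq = lod_loq(l1, series.slope())
        lods[std], loqs[std] = lod, loq
        ppm5[std] = float(m["max_ppm5"].max())
    return ValidationReport(
        repeatability=rep,
        reproducibility=rpro,
        rt_rsd=pd.Series(rt_rsd),
        mf_rsd=pd.Series(mf_rsd),
        linearity_r=pd.Series(lin),
        lod=pd.Series(lods),
        loq=pd.Series(loqs),
        max_fragment_ppm=pd.Series(ppm5),
        thresholds=thresholds,
    )


@dataclass
class QCReport:
    scores: pd.DataFrame  # samples x PC1..PC2 (+ group column)
    ratio: float | None  # QC spread / overall spread on PC1-2
    high_quality: bool
    degenerate: bool = False


def qc_pca_report(
    table: EntityTable,
    qc_groups: tuple[str, ...] = ("qc_pool", "qc_spiked"),
    ratio_max: float = 0.5,
) -> QCReport:
    """PCA-based QC clustering diagnostic.

    Runs the covariance-method PCA on the median-baseline-transformed
    entity table (all runs: QC + samples) and compares the RMS distance of
    QC scores about the QC centroid to the RMS distance of all runs about
    the overall centroid, in the PC1-PC2 plane. A ratio below ``ratio_max``
    grants the *high quality* flag: the pool re-injections vary much less
    than the biological samples do.
    """
    from .differential_analysis import median_baseline_transform, pca

    qc_samples = [s for s in table.samples if table.sample_groups[s] in qc_groups]
    if len(qc_samples) < 3:
        raise ValueError("QC diagnostic needs at least three QC observations")
    mat = median_baseline_transform(table)
    if mat.shape[0] < 2 or mat.shape[1] < 3:
        raise ValueError("need at least 2 entities and 3 runs for 2 PCs")
    res = pca(mat)
    if res.scores.shape[1] < 2:
        raise ValueError("fewer than 2 principal components available")
    sc = res.scores.iloc[:, :2]
    overall = sc - sc.mean(axis=0)
    denom = float(np.sqrt((overall**2).to_numpy().sum() / len(sc)))
    qc = sc.loc[qc_samples]
    qc_centred = qc - qc.mean(axis=0)
    num = float(np.sqrt((qc_centred**2).to_numpy().sum() / len(qc)))
    scores = sc.copy()
    scores["group"] = [table.sample_groups[s] for s in sc.index]
    if denom == 0:
        return QCReport(scores=scores, ratio=None, high_quality=False, degenerate=True)
    ratio = num / denom
    return QCReport(scores=scores, ratio=ratio, high_quality=ratio < ratio_max)
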