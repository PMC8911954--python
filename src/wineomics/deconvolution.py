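"""Spectral deconvolution: from raw scans to co-eluting components.

The extraction chain mirrors classic untargeted GC-MS processing:

1. **Ion traces** — centroid points are chained scan-to-scan into extracted
   ion chromatograms using a +/-10 ppm linkage window.
2. **Ion peaks** — local maxima with signal-to-noise >= 5, where noise is a
   robust (MAD-based) estimate from the trace's signal-free residue; areas
   are trapezoidal integrals between valley bounds above local baseline.
3. **Components** — ion peaks are clustered around the tallest unassigned
   peak within a co-elution apex window and admitted only when their peak
   shape correlates with the base peak (score >= 25 on a 0-100 Pearson
   scale). Components keep 4-10 ions (fewer than 4 is discarded as
   unreliable, more than 10 is trimmed to the largest areas) and carry a
   spectrum of ion *areas* normalised to base peak = 100.

The co-elution window default (1.2 s = 3 scans at 2.5 spectra/s) and the
shape threshold are configuration, not physical constants: the vendor
parameters they stand in for ("RT window factor", "component shape
threshold") are not publicly documented.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks as _find_peaks

from .io_formats import RawRun

__all__ = [
    "IonTrace",
    "IonPeak",
    "Component",
    "build_ion_traces",
    "detect_peaks",
    "group_components",
    "deconvolve",
]


@dataclass
class IonTrace:
    """An extracted ion chromatogram: one m/z channel over time."""

    mz_center: float
    times: np.ndarray  # s, strictly increasing
    intensities: np.ndarray  # counts
    tolerance_ppm: float = 10.0

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class IonPeak:
    """A chromatographic peak within one ion trace."""

    mz_center: float
    apex_rt: float  # s
    height: float  # counts, above local baseline
    area: float  # counts*s
    snr: float
    shape_t: np.ndarray = field(repr=False, default=None)
    shape_y: np.ndarray = field(repr=False, default=None)


@dataclass
class Component:
    """A deconvolved feature: co-eluting ion peaks with a composite spectrum."""

    apex_rt: float  # s, base-peak apex
    ions: list[IonPeak]
    spectrum: np.ndarray  # (n, 2): m/z, area normalised to base = 100
    total_area: float
    height: float

    @property
    def apex_rt_min(self) -> float:
        return self.apex_rt / 60.0

    @property
    def base_mz(self) -> float:
        return float(self.spectrum[np.argmax(self.spectrum[:, 1]), 0])


class _TraceBuilder:
    __slots__ = ("wsum_mz", "wsum", "last_scan", "times", "intens")

    def __init__(self, scan: int, time: float, mz: float, inten: float) -> None:
        w = max(inten, 1e-9)
        self.wsum_mz = mz * w
        self.wsum = w
        self.last_scan = scan
        self.times = [time]
        self.intens = [inten]

    @property
    def center(self) -> float:
        return self.wsum_mz / self.wsum

    def add(self, scan: int, time: float, mz: float, inten: float) -> None:
        w = max(inten, 1e-9)
        self.wsum_mz += mz * w
        self.wsum += w
        if scan == self.last_scan:
            # second centroid of the same channel in one scan: merge
            self.intens[-1] += inten
        else:
            self.times.append(time)
            self.intens.append(inten)
        self.last_scan = scan


def build_ion_traces(
    run: RawRun,
    ppm: float = 10.0,
    max_gap_scans: int = 25,
    min_points: int = 5,
) -> list[IonTrace]:
    """Chain centroid points scan-to-scan into ion traces.

    Each point joins the nearest open trace whose intensity-weighted m/z
    centre lies within ``+/-ppm``; otherwise it opens a new trace. Traces
    idle for more than ``max_gap_scans`` scans are closed, so a recurring
    fragment m/z produces separate traces per chromatographic region (which
    keeps the local noise estimate local). Traces shorter than
    ``min_points`` are dropped.
    """
    if run.n_scans == 0:
        raise ValueError("run has no scans")
    tol = ppm * 1e-6
    active: list[_TraceBuilder] = []
    done: list[IonTrace] = []

    def close(tr: _TraceBuilder) -> None:
        if len(tr.times) >= min_points:
            done.append(
                IonTrace(
                    mz_center=tr.center,
                    times=np.asarray(tr.times),
                    intensities=np.asarray(tr.intens),
                    tolerance_ppm=ppm,
                )
            )

    for i, scan in enumerate(run.scans):
        if active:
            still: list[_TraceBuilder] = []
            for tr in active:
                if i - tr.last_scan > max_gap_scans:
                    close(tr)
                else:
                    still.append(tr)
            active = still
        n_pts = scan.mz.size
        if n_pts == 0:
            continue
        if active:
            active.sort(key=lambda tr: tr.center)
            centers = np.array([tr.center for tr in active])
            n_open = len(centers)
            pos = np.searchsorted(centers, scan.mz)
            claimed: set[int] = set()
            for k in range(n_pts):
                mz, inten = float(scan.mz[k]), float(scan.intensity[k])
                best_j, best_d = -1, np.inf
                fallback_j, fallback_d = -1, np.inf
                for j in (int(pos[k]) - 1, int(pos[k])):
                    if 0 <= j < n_open:
                        d = abs(centers[j] - mz)
                        if d > tol * mz:
                            continue
                        if j not in claimed and d < best_d:
                            best_j, best_d = j, d
                        if d < fallback_d:
                            fallback_j, fallback_d = j, d
                if best_j < 0 and fallback_j >= 0:
                    # a second in-window point in the same scan merges into
                    # the claimed trace rather than opening a duplicate
                    best_j = fallback_j
                if best_j >= 0:
                    active[best_j].add(i, scan.time, mz, inten)
                    claimed.add(best_j)
                else:
                    active.append(_TraceBuilder(i, scan.time, mz, inten))
        else:
            for k in range(n_pts):
                active.append(
                    _TraceBuilder(i, scan.time, float(scan.mz[k]), float(scan.intensity[k]))
                )
    for tr in active:
        close(tr)
    done.sort(key=lambda t: t.mz_center)
    return done


def _noise_estimate(y: np.ndarray) -> tuple[float, float]:
    """(baseline level, noise sigma) of the trace's signal-free residue.

    Median/MAD of the whole trace: robust as long as peaks occupy fewer
    than half of the trace's points, and unbiased on pure baseline
    (1.4826 x MAD estimates a Gaussian sigma)."""
    baseline = float(np.median(y))
    mad = float(np.median(np.abs(y - baseline)))
    return baseline, 1.4826 * mad


def detect_peaks(trace: IonTrace, snr_min: float = 5.0) -> list[IonPeak]:
    """Local maxima with height/noise >= ``snr_min``.

    Height is measured above the local baseline; the area is the trapezoidal
    integral of the baseline-subtracted trace between valley bounds.
    """
    y = trace.intensities
    t = trace.times
    if y.size < 5:
        raise ValueError("trace too short for peak detection (need >= 5 points)")
    baseline, noise = _noise_estimate(y)
    floor = max(noise, 1e-6)
    # prominence on the noise scale suppresses sub-peaks carved out of a
    # single peak's flank by baseline noise
    idx, _ = _find_peaks(y, distance=3, prominence=snr_min * floor)
    # plateau apexes (e.g. saturated or perfectly flat tops) are not local
    # maxima for find_peaks with default args; the global max covers them
    if y.max() > baseline and idx.size == 0:
        idx = np.array([int(np.argmax(y))])
    peaks: list[IonPeak] = []
    thr = baseline + floor

    def bound(apex: int, limit: int, step: int) -> int:
        """Integration bound towards ``limit``: the first threshold crossing,
        else the minimum between this apex and the neighbouring one."""
        lo, hi = (limit, apex) if step < 0 else (apex, limit)
        seg = y[lo : hi + 1]
        below = np.nonzero(seg <= thr)[0]
        if below.size:
            return lo + (below[-1] if step < 0 else below[0])
        return lo + int(np.argmin(seg))

    for k, apex in enumerate(idx):
        height = float(y[apex] - baseline)
        snr = height / floor
        if snr < snr_min:
            continue
        left_limit = int(idx[k - 1]) if k > 0 else 0
        right_limit = int(idx[k + 1]) if k + 1 < idx.size else y.size - 1
        left = bound(int(apex), left_limit, -1)
        right = bound(int(apex), right_limit, +1)
        area = float(np.trapezoid(np.clip(y[left : right + 1] - baseline, 0, None),
                                  t[left : right + 1]))
        if area <= 0 or height <= 0:
            continue
        lo = max(left, apex - 12)
        hi = min(right, apex + 12)
        # sub-scan apex: intensity-weighted centroid of the upper half of the
        # peak — far more stable against baseline noise than the max sample
        seg_t = t[lo : hi + 1]
        seg_y = np.clip(y[lo : hi + 1] - baseline, 0.0, None)
        top = seg_y >= 0.5 * height
        apex_rt = float(np.sum(seg_t[top] * seg_y[top]) / np.sum(seg_y[top])) if top.any() else float(t[apex])
        peaks.append(
            IonPeak(
                mz_center=trace.mz_center,
                apex_rt=apex_rt,
                height=height,
                area=area,
                snr=snr,
                shape_t=t[lo : hi + 1],
                shape_y=np.clip(y[lo : hi + 1] - baseline, 0, None),
            )
        )
    return peaks


def _shape_score(seed: IonPeak, other: IonPeak) -> float:
    """0-100 shape-similarity: rescaled Pearson r of the two peak shapes on
    the seed's time grid (non-overlapping or degenerate shapes score 0)."""
    t0, t1 = other.shape_t[0], other.shape_t[-1]
    mask = (seed.shape_t >= t0) & (seed.shape_t <= t1)
    if mask.sum() < 3:
        return 0.0
    a = seed.shape_y[mask]
    b = np.interp(seed.shape_t[mask], other.shape_t, other.shape_y)
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return 0.0
    r = float(np.corrcoef(a, b)[0, 1])
    return 100.0 * max(0.0, r)


def group_components(
    peaks: list[IonPeak],
    coelute_window_s: float = 1.2,
    shape_min: float = 25.0,
    min_ions: int = 4,
    max_ions: int = 10,
) -> list[Component]:
    """Cluster ion peaks into components around successive base peaks.

    Iteratively seeds on the tallest unassigned peak, gathers peaks whose
    apexes fall within ``coelute_window_s`` and whose shapes correlate with
    the seed (score >= ``shape_min``), and emits a component when at least
    ``min_ions`` ions survive (trimmed to the ``max_ions`` largest areas).
    """
    order = sorted(range(len(peaks)), key=lambda i: -peaks[i].height)
    assigned = [False] * len(peaks)
    apexes = np.array([p.apex_rt for p in peaks])
    components: list[Component] = []
    for seed_i in order:
        if assigned[seed_i]:
            continue
        seed = peaks[seed_i]
        near = [
            i
            for i in range(len(peaks))
            if not assigned[i] and abs(apexes[i] - seed.apex_rt) <= coelute_window_s
        ]
        members = [i for i in near if i == seed_i or _shape_score(seed, peaks[i]) >= shape_min]
        for i in members:
            assigned[i] = True
        if len(members) < min_ions:
            continue
        members.sort(key=lambda i: -peaks[i].area)
        members = members[:max_ions]
        ions = sorted((peaks[i] for i in members), key=lambda p: p.mz_center)
        areas = np.array([p.area for p in ions])
        spectrum = np.column_stack(
            [[p.mz_center for p in ions], 100.0 * areas / areas.max()]
        )
        components.append(
            Component(
                apex_rt=seed.apex_rt,
                ions=ions,
                spectrum=spectrum,
                total_area=float(areas.sum()),
                height=seed.height,
            )
        )
    components.sort(key=lambda c: c.apex_rt)
    return components


def deconvolve(
    run: RawRun,
    ppm: float = 10.0,
    snr_min: float = 5.0,
    coelute_window_s: float = 1.2,
    shape_min: float = 25.0,
    min_ions: int = 4,
    max_ions: int = 10,
) -> list[Component]:
    """Full extraction: traces -> ion peaks -> components, by retention time.

    No area or height floor is applied beyond the SNR gate, so minor
    compounds survive extraction.
    """
    peaks: list[IonPeak] = []
    for trace in build_ion_traces(run, ppm=ppm):
        if len(trace) >= 5:
            peaks.extend(detect_peaks(trace, snr_min=snr_min))
    return group_components(
        peaks,
        coelute_window_s=coelute_window_s,
        shape_min=shape_min,
        min_ions=min_ions,
        max_ions=max_ions,
    )
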