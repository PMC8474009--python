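"""Chromatogram integration and light/heavy peak-area ratios.

The heavy internal standard defines the elution window: integration bounds
are placed around the apex of the summed heavy signal and the same bounds are
applied to the light traces, replacing manual equal-boundary inspection with
a deterministic rule.  Areas use the trapezoidal rule with no baseline
subtraction; apex heights are read off the raw, unsmoothed traces.

Detection follows the assay's two-threshold rule: an endogenous (light)
peptide is confidently detected (category 1) when every monitored transition
shows signal inside the window and the reporting transition's light apex
exceeds 250 counts (pY-antibody route) or 300 counts (IMAC route).  Signal
present but under the threshold is category 2; any transition with no light
signal at all is category 3.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .constants import HEIGHT_THRESHOLD


class QuantError(ValueError):
    pass


@dataclass
class ChromTrace:
    """Time/intensity series for one transition of one isotope label."""

    peptide: str
    transition: tuple[str, int, int]  # (series, index, charge)
    label: str  # "light" | "heavy"
    times: np.ndarray  # minutes, strictly increasing
    intensities: np.ndarray  # counts, >= 0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.times.shape != self.intensities.shape:
            raise QuantError("time and intensity vectors differ in length")
        if self.times.size < 5:
            raise QuantError("trace needs >= 5 points")
        if np.any(np.diff(self.times) <= 0):
            raise QuantError("times must be strictly increasing")
        if np.any(self.intensities < 0):
            raise QuantError("negative intensity")


@dataclass
class PeakIntegration:
    boundary_start: float
    boundary_end: float
    area: float
    apex_height: float


@dataclass
class QuantRecord:
    """Per peptide x sample quantification result."""

    peptide: str
    sample: str
    route: str
    light_areas: dict[tuple[str, int, int], float] = field(default_factory=dict)
    heavy_areas: dict[tuple[str, int, int], float] = field(default_factory=dict)
    reporting_transition: tuple[str, int, int] | None = None
    light_height: float = 0.0
    par: float = float("nan")
    detected: bool = False
    category: int = 3


def integrate_peak(trace: ChromTrace, bounds: tuple[float, float]) -> PeakIntegration:
    """Trapezoidal area and apex height within ``bounds`` (inclusive)."""
    start, end = bounds
    if start >= end:
        raise QuantError("boundary_start must precede boundary_end")
    if start < trace.times[0] - 1e-9 or end > trace.times[-1] + 1e-9:
        raise QuantError("integration bounds outside trace time range")
    mask = (trace.times >= start) & (trace.times <= end)
    if mask.sum() < 2:
        return PeakIntegration(start, end, 0.0, float(trace.intensities[mask].max(initial=0.0)))
    t = trace.times[mask]
    y = trace.intensities[mask]
    return PeakIntegration(start, end, float(np.trapezoid(y, t)), float(y.max()))


def pick_boundaries(
    heavy_traces: list[ChromTrace], k: float = 1.5
) -> tuple[float, float]:
    """Elution window from the heavy internal standard.

    Sums the heavy traces, finds the apex, measures the FWHM by linear
    interpolation at half the apex height, and returns apex +/- k * FWHM,
    clipped to the trace time range.  A flat nonzero profile (no half-max
    crossing) falls back to the full window with a warning.
    """
    if not heavy_traces:
        raise QuantError("no heavy traces")
    times = heavy_traces[0].times
    total = np.zeros_like(times)
    for tr in heavy_traces:
        if not np.array_equal(tr.times, times):
            raise QuantError("heavy traces must share a common time grid")
        total = total + tr.intensities
    if not np.any(total > 0):
        raise QuantError("internal standard not detected")
    i_apex = int(np.argmax(total))
    apex_t = float(times[i_apex])
    half = total[i_apex] / 2.0

    def crossing(idx_range, forward: bool) -> float | None:
        prev = i_apex
        for i in idx_range:
            if total[i] < half:
                t0, t1 = times[i], times[prev]
                y0, y1 = total[i], total[prev]
                frac = (half - y0) / (y1 - y0)
                return float(t0 + frac * (t1 - t0))
            prev = i
        return None

    left = crossing(range(i_apex - 1, -1, -1), forward=False)
    right = crossing(range(i_apex + 1, len(total)), forward=True)
    if left is None or right is None:
        warnings.warn(
            "heavy profile has no half-max crossing; using full window",
            stacklevel=2,
        )
        return float(times[0]), float(times[-1])
    fwhm = right - left
    lo = max(float(times[0]), apex_t - k * fwhm)
    hi = min(float(times[-1]), apex_t + k * fwhm)
    return lo, hi


def select_reporting_transition(
    light_areas: dict[tuple[str, int, int], float],
    heavy_areas: dict[tuple[str, int, int], float],
    interference_cutoff: float = 0.2,
) -> tuple[str, int, int]:
    """Most abundant interference-free transition.

    Compares each transition's relative contribution in the light vs the
    heavy pattern; a deviation above ``interference_cutoff`` flags
    interference.  Among clean transitions the largest heavy area wins; if
    all are flagged, the least-deviating one is used with a warning.
    """
    keys = sorted(set(light_areas) & set(heavy_areas))
    if not keys:
        raise QuantError("no transitions integrated for both labels")
    light_sum = sum(light_areas[k] for k in keys)
    heavy_sum = sum(heavy_areas[k] for k in keys)
    if heavy_sum <= 0:
        raise QuantError("internal standard not detected")
    deviations = {}
    for key in keys:
        lf = light_areas[key] / light_sum if light_sum > 0 else 0.0
        hf = heavy_areas[key] / heavy_sum
        deviations[key] = abs(lf - hf)
    clean = [k for k in keys if deviations[k] <= interference_cutoff]
    if clean:
        return max(clean, key=lambda k: heavy_areas[k])
    warnings.warn(
        "all transitions interference-flagged; using least deviating",
        stacklevel=2,
    )
    return min(keys, key=lambda k: deviations[k])


def detect_endogenous(
    record: QuantRecord, threshold_override: float | None = None
) -> QuantRecord:
    """Apply the detection rule and assign the data category in place."""
    if record.route not in HEIGHT_THRESHOLD:
        raise QuantError(f"unknown route {record.route!r}")
    threshold = (
        threshold_override
        if threshold_override is not None
        else HEIGHT_THRESHOLD[record.route]
    )
    all_present = bool(record.light_areas) and all(
        a > 0 for a in record.light_areas.values()
    )
    if not all_present:
        record.detected = False
        record.category = 3
    elif record.light_height > threshold:
        record.detected = True
        record.category = 1
    else:
        record.detected = False
        record.category = 2
    return record


def compute_par(record: QuantRecord) -> float:
    """Light/heavy peak-area ratio on the reporting transition."""
    if record.reporting_transition is None:
        raise QuantError("reporting transition not selected")
    heavy = record.heavy_areas[record.reporting_transition]
    if heavy <= 0:
        raise QuantError("internal standard not detected (zero heavy area)")
    record.par = record.light_areas[record.reporting_transition] / heavy
    return record.par


def quantify_peptide(
    sample: str,
    peptide: str,
    route: str,
    light_traces: list[ChromTrace],
    heavy_traces: list[ChromTrace],
    interference_cutoff: float = 0.2,
    threshold_override: float | None = None,
) -> QuantRecord:
    """Full per-peptide quantification: window, integrate, report, detect."""
    bounds = pick_boundaries(heavy_traces)
    record = QuantRecord(peptide=peptide, sample=sample, route=route)
    for tr in heavy_traces:
        record.heavy_areas[tr.transition] = integrate_peak(tr, bounds).area
    light_heights = {}
    for tr in light_traces:
        peak = integrate_peak(tr, bounds)
        record.light_areas[tr.transition] = peak.area
        light_heights[tr.transition] = peak.apex_height
    record.reporting_transition = select_reporting_transition(
        record.light_areas, record.heavy_areas, interference_cutoff
    )
    record.light_height = light_heights.get(record.reporting_transition, 0.0)
    detect_endogenous(record, threshold_override)
    if record.heavy_areas[record.reporting_transition] > 0:
        compute_par(record)
    return record


def percent_cv(values) -> float:
    """100 * sample standard deviation / mean."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size < 2:
        raise QuantError("percent_cv needs >= 2 values")
    mean = arr.mean()
    if mean == 0:
        raise QuantError("percent_cv undefined for zero mean")
    return float(100.0 * arr.std(ddof=1) / mean)
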