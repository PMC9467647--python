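"""Measurement pipeline: force-distance curve -> friction parameters.

The pipeline mirrors how sled-test traces are read out by eye and then
automated: find the first force peak (the static friction force), take
the 15 mm of trace that follows it (the sliding phase), average it (the
sliding friction force), locate every stick-slip peak after removing the
baseline drift, and summarise the peaks as a frequency (peaks per mm)
and as the mean of the 10 highest raw peak forces (the maximum sliding
force).

Stages
------
1. ``detect_static_peak``  - first prominent local maximum of the trace.
2. ``sliding_window``      - the half-open 15 mm interval after the peak.
3. ``sliding_mean``        - mean raw force in that window.
4. ``detect_extrema``      - alternating maxima/minima from the sign of
   successive differences (plateaus collapse to their last sample).
5. ``detrend``             - least-squares line through those extrema,
   subtracted from the signal.
6. ``identify_peaks``      - prominence- and separation-filtered local
   maxima of the detrended signal.
7. ``max_sliding_force``   - mean of the k highest raw forces at the
   identified peak positions.
8. ``extract_features``    - composition of the above into a
   :class:`~sledfriction.io.FrictionFeatures` record.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import (
    FLAG_FEWER_THAN_K_PEAKS,
    FLAG_NO_PEAKS,
    FLAG_SHORT_WINDOW,
    FLAG_TRUNCATED_WINDOW,
    ForceCurve,
    FrictionFeatures,
    SledTestConfig,
    log,
)

__all__ = [
    "NoStaticPeakError",
    "WindowTooShortError",
    "Segment",
    "detect_static_peak",
    "sliding_window",
    "sliding_mean",
    "detect_extrema",
    "detrend",
    "identify_peaks",
    "peak_frequency",
    "max_sliding_force",
    "extract_features",
]

#: A truncated sliding window shorter than this is flagged SHORT_WINDOW
#: and excluded by default from top-k peak statistics downstream.
MIN_RELIABLE_WINDOW_MM = 10.0

#: Hard floor on window size: fewer samples than this is unanalysable.
MIN_WINDOW_SAMPLES = 10


class NoStaticPeakError(ValueError):
    """The trace has no qualifying first peak (e.g. monotone loading)."""


class WindowTooShortError(ValueError):
    """The sliding window holds too few samples to analyse."""


@dataclass(frozen=True)
class Segment:
    """A slice of a curve: the sliding-phase window."""

    distance: np.ndarray  # mm
    force: np.ndarray  # mN
    start: float  # mm, window start (exclusive bound = static peak)
    end: float  # mm
    truncated: bool

    @property
    def length_mm(self) -> float:
        return self.end - self.start

    def __len__(self) -> int:
        return len(self.distance)


# ---------------------------------------------------------------------------
# Static peak
# ---------------------------------------------------------------------------


def noise_scale(force: np.ndarray) -> float:
    """Robust noise estimate: median absolute successive difference."""
    d = np.abs(np.diff(force))
    return float(np.median(d)) if len(d) else 0.0


def default_static_prominence(force: np.ndarray) -> float:
    """Default prominence for the static peak: 5% of the global maximum
    with a floor of 3x the noise estimate, so noise blips on the loading
    ramp are not mistaken for the slip point."""
    return max(0.05 * float(np.max(force)), 3.0 * noise_scale(force))


def detect_static_peak(
    curve: ForceCurve, min_prominence: float | None = None
) -> tuple[float, float]:
    """Locate the static friction peak: the first local maximum whose
    topographic prominence reaches ``min_prominence``.

    Returns ``(distance_mm, force_mN)`` of the raw recorded maximum of
    that peak.  Raises :class:`NoStaticPeakError` if no local maximum
    qualifies (a monotonically rising trace never slipped).
    """
    if min_prominence is None:
        min_prominence = default_static_prominence(curve.force)
    if min_prominence < 0:
        raise ValueError("min_prominence must be >= 0")
    maxima = [i for i, kind in _alternating_extrema(curve.force) if kind > 0]
    for i in maxima:
        if _prominence(curve.force, i) >= min_prominence:
            return float(curve.distance[i]), float(curve.force[i])
    raise NoStaticPeakError(
        f"NO_STATIC_PEAK: no local maximum with prominence >= "
        f"{min_prominence:.3g} mN (test {curve.test_id}, {curve.direction})"
    )


# ---------------------------------------------------------------------------
# Sliding window
# ---------------------------------------------------------------------------


def sliding_window(
    curve: ForceCurve,
    static_peak_distance: float,
    config: SledTestConfig | None = None,
) -> Segment:
    """Cut the sliding-phase analysis window ``(d_peak, d_peak + w]``.

    ``w`` is ``config.sliding_window`` (15 mm by default).  If the
    recorded travel ends earlier, the segment is truncated to the
    available data and marked so that downstream code can flag it.
    """
    config = config or SledTestConfig()
    d0 = static_peak_distance
    d1 = static_peak_distance + config.sliding_window
    end_of_data = float(curve.distance[-1])
    truncated = d1 > end_of_data + 1e-12
    d1 = min(d1, end_of_data)
    mask = (curve.distance > d0) & (curve.distance <= d1 + 1e-12)
    if int(mask.sum()) < MIN_WINDOW_SAMPLES:
        raise WindowTooShortError(
            f"WINDOW_TOO_SHORT: {int(mask.sum())} sample(s) in sliding window "
            f"(test {curve.test_id}, {curve.direction})"
        )
    return Segment(
        distance=curve.distance[mask],
        force=curve.force[mask],
        start=d0,
        end=d1,
        truncated=truncated,
    )


def sliding_mean(segment: Segment) -> float:
    """Mean raw force over the sliding window (the sliding friction
    force)."""
    return float(np.mean(segment.force))


# ---------------------------------------------------------------------------
# Extrema, detrending, peak identification
# ---------------------------------------------------------------------------


def _alternating_extrema(y: np.ndarray) -> list[tuple[int, int]]:
    """Indices where the sign of the first difference flips.

    Returns ``(index, kind)`` pairs with kind +1 for maxima and -1 for
    minima, strictly alternating.  Zero differences inherit the previous
    nonzero sign, so a plateau yields a single extremum at its last
    sample.  Leading/trailing monotone runs produce no extremum.
    """
    d = np.diff(y)
    out: list[tuple[int, int]] = []
    prev_sign = 0
    for i, di in enumerate(d):
        s = 0 if di == 0 else (1 if di > 0 else -1)
        if s == 0:
            continue  # plateau: carry previous sign forward
        if prev_sign == 1 and s == -1:
            out.append((i, +1))  # rise -> fall: maximum at plateau end
        elif prev_sign == -1 and s == 1:
            out.append((i, -1))
        prev_sign = s
    return out


def detect_extrema(segment: Segment | np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Alternating positive/negative peaks of the sliding signal.

    Implements successive-difference sign-change detection.  Returns
    ``(indices, forces, kinds)`` with kind +1 for maxima, -1 for minima;
    the sequence strictly alternates.  Monotone segments return empty
    arrays.
    """
    y = segment.force if isinstance(segment, Segment) else np.asarray(segment, float)
    if len(y) < 3:
        raise ValueError("need >= 3 samples to detect extrema")
    pairs = _alternating_extrema(y)
    idx = np.array([i for i, _ in pairs], dtype=int)
    kinds = np.array([k for _, k in pairs], dtype=int)
    return idx, y[idx] if len(idx) else np.empty(0), kinds


def detrend(
    segment: Segment, extrema_idx: np.ndarray | None = None
) -> tuple[np.ndarray, tuple[float, float]]:
    """Remove the baseline drift of the sliding signal.

    The trend is the least-squares straight line through the alternating
    extrema (maxima and minima jointly), which tracks the midline of the
    stick-slip envelope; with fewer than two extrema it falls back to a
    horizontal line at the segment mean.  Returns the detrended force
    and ``(slope mN/mm, intercept mN)`` of the trend.
    """
    if extrema_idx is None:
        extrema_idx, _, _ = detect_extrema(segment)
    x, y = segment.distance, segment.force
    if len(extrema_idx) >= 2:
        slope, intercept = np.polyfit(x[extrema_idx], y[extrema_idx], 1)
    else:
        slope, intercept = 0.0, float(np.mean(y))
    trend = slope * x + intercept
    return y - trend, (float(slope), float(intercept))


def _prominence(y: np.ndarray, i: int) -> float:
    """Topographic prominence of a local maximum at index ``i``: its
    height above the higher of the two lowest valleys separating it from
    higher ground (or from the signal edge)."""
    h = y[i]
    left_min = h
    for j in range(i - 1, -1, -1):
        if y[j] > h:
            break
        left_min = min(left_min, y[j])
    else:
        j = -1
    right_min = h
    for j in range(i + 1, len(y)):
        if y[j] > h:
            break
        right_min = min(right_min, y[j])
    return float(h - max(left_min, right_min))


def identify_peaks(
    detrended: np.ndarray,
    distance: np.ndarray,
    prominence_threshold: float | None = None,
    min_separation_mm: float | None = None,
) -> np.ndarray:
    """Indices of stick-slip peaks in the detrended sliding signal.

    Candidates are the alternating maxima; they must have topographic
    prominence >= ``prominence_threshold`` (default 1.5x the median
    absolute deviation of the detrended signal, floored at 3x the robust
    noise sd so pure-noise blips are rejected) and pairwise separation
    >= ``min_separation_mm`` (default 3 sample spacings).  When two
    candidates conflict the higher one wins; on a tie, the earlier one.
    """
    y = np.asarray(detrended, float)
    x = np.asarray(distance, float)
    if prominence_threshold is None:
        mad = float(np.median(np.abs(y - np.median(y))))
        d = np.diff(y)
        sigma = 1.4826 * float(np.median(np.abs(d - np.median(d)))) / np.sqrt(2.0)
        prominence_threshold = max(1.5 * mad, 3.0 * sigma)
    if min_separation_mm is None:
        spacing = float(np.median(np.diff(x))) if len(x) > 1 else 0.0
        min_separation_mm = 3.0 * spacing
    if prominence_threshold < 0 or min_separation_mm < 0:
        raise ValueError("thresholds must be >= 0")

    candidates = [i for i, kind in _alternating_extrema(y) if kind > 0]
    candidates = [i for i in candidates if _prominence(y, i) >= prominence_threshold]
    # Greedy separation filter: height-descending, earlier index wins ties.
    order = sorted(candidates, key=lambda i: (-y[i], i))
    kept: list[int] = []
    for i in order:
        if all(abs(x[i] - x[j]) >= min_separation_mm * (1 - 1e-9) for j in kept):
            kept.append(i)
    return np.array(sorted(kept), dtype=int)


def peak_frequency(n_peaks: int, window_length_mm: float) -> float:
    """Peaks per millimetre of sliding."""
    if window_length_mm <= 0:
        raise ValueError("window_length_mm must be positive")
    return n_peaks / window_length_mm


def max_sliding_force(
    peak_idx: np.ndarray, segment: Segment, k: int = 10
) -> tuple[float, set[str]]:
    """Mean of the ``k`` highest RAW forces at identified peak positions.

    Peak positions come from the detrended signal but the forces are
    read off the measured trace.  With fewer than ``k`` peaks the mean
    of all of them is returned with a ``FEWER_THAN_K_PEAKS`` flag; with
    none, the sliding mean is returned with ``NO_PEAKS``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    flags: set[str] = set()
    if len(peak_idx) == 0:
        flags.add(FLAG_NO_PEAKS)
        return sliding_mean(segment), flags
    raw = np.sort(segment.force[peak_idx])[::-1]
    if len(raw) < k:
        flags.add(FLAG_FEWER_THAN_K_PEAKS)
    return float(np.mean(raw[:k])), flags


# ---------------------------------------------------------------------------
# Composition
# ---------------------------------------------------------------------------


def extract_features(
    curve: ForceCurve,
    config: SledTestConfig | None = None,
    static_prominence: float | None = None,
    peak_prominence: float | None = None,
    min_separation_mm: float | None = None,
) -> FrictionFeatures:
    """Run the full measurement pipeline on one curve."""
    config = config or SledTestConfig()
    d_peak, f_static = detect_static_peak(curve, static_prominence)
    seg = sliding_window(curve, d_peak, config)
    flags: set[str] = set()
    if seg.truncated:
        flags.add(FLAG_TRUNCATED_WINDOW)
        if seg.length_mm < MIN_RELIABLE_WINDOW_MM:
            flags.add(FLAG_SHORT_WINDOW)

    mean_force = sliding_mean(seg)
    ext_idx, _, _ = detect_extrema(seg)
    detrended, _trend = detrend(seg, ext_idx)
    peaks = identify_peaks(
        detrended, seg.distance, peak_prominence, min_separation_mm
    )
    freq = peak_frequency(len(peaks), seg.length_mm)
    f_max, k_flags = max_sliding_force(peaks, seg, config.top_k_peaks)
    flags |= k_flags

    with np.errstate(invalid="ignore"):
        cv = float(np.std(seg.force, ddof=1) / mean_force) if mean_force > 0 else float("nan")

    feats = FrictionFeatures(
        test_id=curve.test_id,
        species=curve.species,
        direction=curve.direction,
        static_force=f_static,
        sliding_mean_force=mean_force,
        max_sliding_force=f_max,
        peak_frequency=freq,
        n_peaks=len(peaks),
        peak_positions=tuple(float(v) for v in seg.distance[peaks]),
        peak_forces=tuple(float(v) for v in seg.force[peaks]),
        static_peak_distance=d_peak,
        window_start=seg.start,
        window_end=seg.end,
        cv_sliding=cv,
        flags=frozenset(flags),
    )
    log.info(
        "extracted %s/%s: F_static=%.3g F_slide=%.3g F_max=%.3g f_p=%.3g flags=%s",
        curve.test_id,
        curve.direction,
        f_static,
        mean_force,
        f_max,
        freq,
        ",".join(sorted(flags)) or "-",
    )
    return feats
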