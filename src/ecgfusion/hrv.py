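"""QRS detection on lead II and the seven heart-rate-variability features.

The detector is a Pan-Tompkins-style pipeline: 5-15 Hz band-pass ->
five-point derivative -> squaring -> 150 ms moving-window integration ->
adaptive dual thresholds with a 200 ms refractory period and RR-gap
search-back, with each detection refined to the local R-peak maximum of
the band-passed signal.

The HRV summary computed from the resulting RR series is

1. SDRR        standard deviation of RR intervals (ms)
2. longest RR  (ms)
3. shortest RR (ms)
4. mean RR     (ms)
5. pNN50       count of successive differences > 50 ms divided by the
               total number of RR intervals (note: the divisor is the
               interval count, not the difference count; switchable)
6. RMSSD       root mean square of successive differences (ms)
7. SampEn      sample entropy of the RR series (m=2, r=0.2*SDRR)
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, fields

import numpy as np
from scipy import signal as sps

logger = logging.getLogger(__name__)

REFRACTORY_S = 0.200


class InsufficientBeatsError(ValueError):
    """Too few detected beats to derive the requested quantity."""


@dataclass
class RRSeries:
    """R-peak sample indices on lead II and the derived RR intervals."""

    beat_samples: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.beat_samples = np.asarray(self.beat_samples, dtype=int)
        if len(self.beat_samples) < 2:
            raise InsufficientBeatsError(
                f"need >= 2 beats for an RR series, got {len(self.beat_samples)}")
        if np.any(np.diff(self.beat_samples) <= 0):
            raise ValueError("beat samples must be strictly increasing")

    @property
    def rr_ms(self) -> np.ndarray:
        return np.diff(self.beat_samples) * 1000.0 / self.fs


@dataclass(frozen=True)
class HRVFeatures:
    """The seven RR-derived statistics, in frozen fusion-vector order."""

    sdrr: float
    rr_longest: float
    rr_shortest: float
    rr_mean: float
    pnn50: float
    rmssd: float
    sampen: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f.name) for f in fields(self)])

    @classmethod
    def field_names(cls) -> tuple[str, ...]:
        return tuple(f.name for f in fields(cls))


# ---------------------------------------------------------------------------
# QRS detection
# ---------------------------------------------------------------------------

def detect_qrs(lead_ii: np.ndarray, fs: float) -> np.ndarray:
    """Detect R peaks on a single lead; returns sorted sample indices.

    Deterministic; returns an empty array (with a warning) for flat or
    sub-threshold input.  Requires at least two seconds of signal.
    """
    x = np.asarray(lead_ii, dtype=float)
    if x.ndim != 1:
        raise ValueError("detect_qrs expects a 1-D signal")
    if len(x) < 2 * fs:
        raise ValueError("need at least 2 s of signal for QRS detection")
    if np.ptp(x) < 1e-9:
        logger.warning("flat signal: no QRS detected")
        return np.array([], dtype=int)

    sos = sps.butter(2, [5.0, 15.0], btype="bandpass", fs=fs, output="sos")
    band = sps.sosfiltfilt(sos, x)
    deriv = np.gradient(band)
    squared = deriv ** 2
    win = max(1, int(round(0.150 * fs)))
    integrated = np.convolve(squared, np.ones(win) / win, mode="same")

    refr = int(round(REFRACTORY_S * fs))
    peaks, _ = sps.find_peaks(integrated, distance=refr)
    if peaks.size == 0:
        logger.warning("no candidate peaks found")
        return np.array([], dtype=int)

    # adaptive dual thresholds (running signal / noise level estimates)
    spki = float(np.max(integrated[: int(2 * fs)]) * 0.5)
    npki = float(np.mean(integrated[: int(2 * fs)]) * 0.5)
    accepted: list[int] = []
    maybe: list[tuple[int, float]] = []   # sub-threshold candidates, for search-back
    rr_recent: list[float] = []
    for p in peaks:
        level = integrated[p]
        thr1 = npki + 0.25 * (spki - npki)
        if level > thr1:
            accepted.append(p)
            spki = 0.125 * level + 0.875 * spki
            if len(accepted) > 1:
                rr_recent.append(accepted[-1] - accepted[-2])
                rr_recent = rr_recent[-8:]
        else:
            maybe.append((p, level))
            npki = 0.125 * level + 0.875 * npki
        # search-back: a long RR gap re-examines skipped peaks at thr1/2
        if len(rr_recent) >= 2 and accepted and maybe:
            rr_avg = float(np.mean(rr_recent))
            if p - accepted[-1] > 1.66 * rr_avg:
                thr2 = 0.5 * (npki + 0.25 * (spki - npki))
                back = [(q, lv) for q, lv in maybe
                        if accepted[-1] + refr <= q <= p - refr and lv > thr2]
                if back:
                    q, lv = max(back, key=lambda t: t[1])
                    accepted.append(q)
                    accepted.sort()
                    spki = 0.25 * lv + 0.75 * spki
            maybe = [m for m in maybe if m[0] > accepted[-1]]

    if not accepted:
        logger.warning("all candidate peaks below threshold")
        return np.array([], dtype=int)

    # refine each detection to the R maximum of the band-passed signal
    half = int(round(0.10 * fs))
    refined = []
    for p in accepted:
        lo, hi = max(0, p - half), min(len(x), p + half + 1)
        refined.append(lo + int(np.argmax(np.abs(band[lo:hi]))))
    refined = np.unique(refined)
    keep = [int(refined[0])]
    for r in refined[1:]:
        if r - keep[-1] >= refr:
            keep.append(int(r))
    return np.asarray(keep, dtype=int)


def rr_intervals(beats: np.ndarray, fs: float) -> RRSeries:
    """Wrap detected beat indices as an :class:`RRSeries` (validated)."""
    return RRSeries(beat_samples=np.asarray(beats), fs=fs)


def write_beat_annotations(path, beats: np.ndarray) -> None:
    """Export beats in annotation style: one ``<sample> N`` line per beat."""
    with open(path, "w") as fh:
        for b in np.asarray(beats, dtype=int):
            fh.write(f"{b} N\n")


# ---------------------------------------------------------------------------
# features
# ---------------------------------------------------------------------------

def sample_entropy(series: np.ndarray, m: int = 2,
                   r: float | None = None) -> float:
    """Sample entropy of a 1-D series: ``-ln(A/B)``.

    ``B`` counts pairs of length-``m`` templates within Chebyshev
    distance ``r`` (self-matches excluded), ``A`` the same for length
    ``m+1``.  ``r`` defaults to ``0.2 * SD(series)``.  If every template
    pair matches the entropy is exactly 0; if no pair matches (or the
    tolerance degenerates to 0) a flagged ceiling value
    ``-ln(2 / ((n-m-1)(n-m)))`` is returned.
    """
    x = np.asarray(series, dtype=float)
    n = len(x)
    if n < m + 2:
        raise InsufficientBeatsError(
            f"sample entropy needs >= {m + 2} points, got {n}")
    if r is None:
        r = 0.2 * x.std()
    ceiling = -math.log(2.0 / ((n - m - 1) * (n - m)))
    if r <= 0:
        logger.warning("degenerate SampEn tolerance r=%g: returning 0", r)
        return 0.0

    def count(mm: int) -> int:
        # both template lengths use the same n-m template count (the
        # standard convention), so a strictly periodic series in which
        # every m-match extends to an (m+1)-match scores exactly 0
        templ = np.lib.stride_tricks.sliding_window_view(x, mm)[: n - m]
        d = np.max(np.abs(templ[:, None, :] - templ[None, :, :]), axis=2)
        within = d <= r
        return int((within.sum() - len(templ)) // 2)   # exclude self-pairs

    b = count(m)
    a = count(m + 1)
    if b == 0 or a == 0:
        # common for short, highly irregular RR series: flag at the
        # theoretical ceiling rather than returning infinity
        logger.debug("no template matches: SampEn flagged at ceiling %.4f",
                     ceiling)
        return ceiling
    return -math.log(a / b)


def hrv_features(rr: RRSeries,
                 pnn50_denominator: str = "intervals",
                 sampen_m: int = 2,
                 sampen_r_factor: float = 0.2) -> HRVFeatures:
    """Compute the seven HRV statistics from an RR series.

    ``pnn50_denominator`` selects the divisor of the NN50 count:
    ``"intervals"`` (number of RR intervals, the default) or
    ``"differences"`` (number of successive differences, the common
    convention elsewhere).
    """
    rr_ms = rr.rr_ms
    if len(rr_ms) < 3:
        raise InsufficientBeatsError(
            f"need >= 3 RR intervals for HRV features, got {len(rr_ms)}")
    diffs = np.diff(rr_ms)
    if pnn50_denominator == "intervals":
        denom = len(rr_ms)
    elif pnn50_denominator == "differences":
        denom = len(diffs)
    else:
        raise ValueError("pnn50_denominator must be 'intervals' or 'differences'")
    sd = float(rr_ms.std())
    if len(rr_ms) < sampen_m + 2:
        logger.warning("only %d RR intervals: SampEn needs %d, set to 0",
                       len(rr_ms), sampen_m + 2)
        sampen = 0.0
    elif sd > 0:
        sampen = sample_entropy(rr_ms, m=sampen_m, r=sampen_r_factor * sd)
    else:
        logger.warning("constant RR series: SampEn set to 0")
        sampen = 0.0
    return HRVFeatures(
        sdrr=sd,
        rr_longest=float(rr_ms.max()),
        rr_shortest=float(rr_ms.min()),
        rr_mean=float(rr_ms.mean()),
        pnn50=float(np.sum(np.abs(diffs) > 50.0) / denom),
        rmssd=float(np.sqrt(np.mean(diffs ** 2))),
        sampen=float(sampen),
    )


def hrv_from_lead_ii(lead_ii: np.ndarray, fs: float) -> HRVFeatures | None:
    """Detector + features in one step; ``None`` if detection fails.

    Callers impute missing features (training-set median) and flag the
    record; see the fusion module.
    """
    beats = detect_qrs(lead_ii, fs)
    if len(beats) < 4:
        logger.warning("QRS detection found %d beats: HRV undefined",
                       len(beats))
        return None
    try:
        return hrv_features(rr_intervals(beats, fs))
    except InsufficientBeatsError:
        return None
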