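"""Signal conditioning: downsampling, wavelet denoising, slicing, z-scoring,
and the class-balancing oversampler that prepares cross-validation folds.

The chain applied to every record is

    downsample (-> 250 Hz) -> 9-level DB6 wavelet denoise per lead
    -> slice into 10 overlapping 6-s segments -> per-segment z-score

Denoising keeps only detail sub-bands D3..D9 of a 9-level Daubechies-6
decomposition: the deepest approximation (A9) carries baseline wander
and the two finest detail bands (D1, D2) carry high-frequency noise
above the ECG's informative band, so all three are zeroed before
reconstruction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pywt
from scipy import signal as sps

from .labels import ClassLabel
from .record_io import ECGRecord

logger = logging.getLogger(__name__)

#: Default analysis sampling rate (Hz) after downsampling.
TARGET_FS = 250.0

#: Number of slices taken from every record, and slice length in seconds.
N_SEGMENTS = 10
SEGMENT_SECONDS = 6.0

WAVELET = "db6"
DWT_LEVELS = 9
_MIN_DENOISE_LEN = 2 ** DWT_LEVELS


@dataclass
class SegmentStack:
    """Ten standardized slices of one lead: a (10, L) matrix.

    ``start_indices`` are the sample offsets of each slice into the
    (downsampled, denoised) source lead; identical across all 12 leads
    of a record.
    """

    lead_index: int
    segments: np.ndarray
    start_indices: np.ndarray

    def __post_init__(self) -> None:
        self.segments = np.asarray(self.segments, dtype=float)
        self.start_indices = np.asarray(self.start_indices, dtype=int)
        if self.segments.shape[0] != N_SEGMENTS:
            raise ValueError(
                f"expected {N_SEGMENTS} segments, got {self.segments.shape[0]}")
        if np.any(np.diff(self.start_indices) < 0):
            raise ValueError("start indices must be non-decreasing")


def downsample(record: ECGRecord, target_fs: float = TARGET_FS) -> ECGRecord:
    """Anti-aliased downsampling of all 12 leads to *target_fs*.

    Integer ratios use FIR decimation (zero-phase); non-integer ratios
    fall back to polyphase resampling with a logged note.
    """
    if record.fs < target_fs:
        raise ValueError(
            f"record fs {record.fs} is below target {target_fs}")
    if record.fs == target_fs:
        return record
    ratio = record.fs / target_fs
    if abs(ratio - round(ratio)) < 1e-9:
        up, down = 1, int(round(ratio))
    else:
        from fractions import Fraction

        frac = Fraction(target_fs / record.fs).limit_denominator(1000)
        logger.info("non-integer downsample ratio %.4f: polyphase %s",
                    ratio, frac)
        up, down = frac.numerator, frac.denominator
    # polyphase FIR with linear-extension padding: no edge transients on
    # slowly varying signals, and a constant input stays constant
    out = sps.resample_poly(record.signals, up, down, axis=1,
                            padtype="line")
    return record.with_signals(out, fs=target_fs)


def wavelet_denoise(x: np.ndarray, fs: float | None = None) -> np.ndarray:
    """9-level DB6 sub-band denoising of a single lead.

    Zeroes the level-9 approximation (baseline wander) and the two
    finest detail bands (high-frequency noise), reconstructing from
    D3..D9 only.  Symmetric boundary extension; output has the input's
    length.  The transform is linear, so denoising commutes with
    scaling and addition.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("wavelet_denoise expects a 1-D signal")
    if len(x) < _MIN_DENOISE_LEN:
        raise ValueError(
            f"signal too short for a {DWT_LEVELS}-level transform: "
            f"need >= {_MIN_DENOISE_LEN} samples, got {len(x)}")
    with warnings.catch_warnings():
        # a 9-level transform of a short record touches the boundary in the
        # deepest bands; acceptable here since A9 is discarded anyway
        warnings.filterwarnings("ignore", message="Level value of .* is too high")
        coeffs = pywt.wavedec(x, WAVELET, mode="symmetric", level=DWT_LEVELS)
    coeffs[0] = np.zeros_like(coeffs[0])    # A9: baseline wander
    coeffs[-1] = np.zeros_like(coeffs[-1])  # D1
    coeffs[-2] = np.zeros_like(coeffs[-2])  # D2
    out = pywt.waverec(coeffs, WAVELET, mode="symmetric")
    return out[: len(x)]


def denoise_record(record: ECGRecord) -> ECGRecord:
    """Apply :func:`wavelet_denoise` to every lead."""
    out = np.vstack([wavelet_denoise(row, record.fs) for row in record.signals])
    return record.with_signals(out)


def segment_starts(n_samples: int, seg_len: int,
                   n_segments: int = N_SEGMENTS) -> np.ndarray:
    """Evenly spaced slice starts: ``s_i = round(i * (N - L) / (n - 1))``.

    Reproduces both boundary behaviours: a record exactly one slice long
    yields ten identical copies (all starts 0), and a record ten slices
    long yields ten disjoint slices; intermediate lengths overlap evenly.
    """
    if n_samples <= seg_len:
        return np.zeros(n_segments, dtype=int)
    i = np.arange(n_segments)
    return np.rint(i * (n_samples - seg_len) / (n_segments - 1)).astype(int)


def zscore(segment: np.ndarray, eps: float = 1e-12) -> np.ndarray:
    """Standardize to zero mean, unit (population) standard deviation.

    A constant segment has no scale; it is returned as all zeros with a
    logged warning rather than dividing by ~0.
    """
    segment = np.asarray(segment, dtype=float)
    if segment.size < 2:
        raise ValueError("z-score needs at least 2 samples")
    mu = segment.mean()
    sd = segment.std()  # population SD (ddof=0), frozen for reproducibility
    if sd < eps:
        logger.warning("degenerate (constant) segment: returning zeros")
        return np.zeros_like(segment)
    return (segment - mu) / sd


def slice_record(record: ECGRecord,
                 fs_target: float = TARGET_FS,
                 segment_seconds: float = SEGMENT_SECONDS,
                 standardize: bool = True) -> list[SegmentStack]:
    """Slice all 12 leads into 10 standardized segments each.

    Expects the record already at the analysis rate.  Records shorter
    than one segment are right-padded with zeros (warned).  Start
    indices are identical across leads, preserving inter-lead timing.
    """
    if abs(record.fs - fs_target) > 1e-6:
        raise ValueError(
            f"record must be at {fs_target} Hz before slicing "
            f"(got {record.fs}); run downsample first")
    seg_len = int(round(segment_seconds * fs_target))
    signals = record.signals
    if signals.shape[1] < seg_len:
        logger.warning("record %s shorter than one segment: zero-padding "
                       "%d -> %d samples", record.record_id,
                       signals.shape[1], seg_len)
        pad = seg_len - signals.shape[1]
        signals = np.pad(signals, ((0, 0), (0, pad)))
    starts = segment_starts(signals.shape[1], seg_len)
    stacks = []
    for lead in range(signals.shape[0]):
        rows = np.stack([signals[lead, s:s + seg_len] for s in starts])
        if standardize:
            rows = np.stack([zscore(r) for r in rows])
        stacks.append(SegmentStack(lead_index=lead, segments=rows,
                                   start_indices=starts))
    return stacks


def preprocess_record(record: ECGRecord,
                      target_fs: float = TARGET_FS,
                      segment_seconds: float = SEGMENT_SECONDS,
                      ) -> tuple[np.ndarray, ECGRecord]:
    """Full conditioning chain for one record.

    Returns ``(segments, conditioned)`` where ``segments`` has shape
    ``(12, 10, L)`` (z-scored model inputs) and ``conditioned`` is the
    downsampled, denoised record (the signal HRV analysis runs on).
    """
    ds = downsample(record, target_fs)
    dn = denoise_record(ds)
    stacks = slice_record(dn, fs_target=target_fs,
                          segment_seconds=segment_seconds)
    segments = np.stack([s.segments for s in stacks])
    return segments, dn


# ---------------------------------------------------------------------------
# class-balancing oversampler / fold builder
# ---------------------------------------------------------------------------

@dataclass
class FoldAssignment:
    """One (possibly replicated) record placed in one CV fold."""

    record_id: str
    cls: ClassLabel
    fold: int
    replica_of: str | None = None   # None for original records

    @property
    def source_id(self) -> str:
        return self.replica_of if self.replica_of is not None else self.record_id


def balance_subsets(records: Sequence[tuple[str, ClassLabel]],
                    n_folds: int = 5,
                    seed: int = 0) -> list[FoldAssignment]:
    """Stratified fold split plus per-fold oversampling to the largest class.

    Each class is shuffled and split into *n_folds* subsets.  Within each
    subset the largest class count is the reference ``n_ref``; a class
    whose count ``n_c`` satisfies ``2 * n_c <= n_ref`` is first replicated
    whole ``floor(n_ref / n_c)`` times, then topped up with random
    duplicate draws to ``n_ref``; a class with more than half the
    reference receives only ``n_ref - n_c`` random duplicates.  Replicas
    never leave their source subset, so no record (original or copy)
    spans two folds.
    """
    rng = np.random.default_rng(seed)
    by_class: dict[ClassLabel, list[str]] = {}
    for rid, cls in records:
        by_class.setdefault(cls, []).append(rid)
    for cls, ids in by_class.items():
        if not ids:
            raise ValueError(f"class {cls.code} has no records")
        if len(ids) < n_folds:
            raise ValueError(
                f"class {cls.code} has {len(ids)} records; "
                f"needs at least {n_folds} for {n_folds}-fold CV")

    # stratified split: shuffle within class, deal into folds
    fold_members: list[dict[ClassLabel, list[str]]] = [
        {} for _ in range(n_folds)]
    for cls in sorted(by_class, key=lambda c: c.index):
        ids = sorted(by_class[cls])
        rng.shuffle(ids)
        for fold, chunk in enumerate(np.array_split(ids, n_folds)):
            fold_members[fold][cls] = list(chunk)

    out: list[FoldAssignment] = []
    for fold, members in enumerate(fold_members):
        n_ref = max(len(ids) for ids in members.values())
        for cls in sorted(members, key=lambda c: c.index):
            ids = members[cls]
            n_c = len(ids)
            for rid in ids:
                out.append(FoldAssignment(rid, cls, fold))
            replicas: list[str] = []
            if 2 * n_c <= n_ref:
                whole = n_ref // n_c          # total copies incl. original
                for _ in range(whole - 1):
                    replicas.extend(ids)
                short = n_ref - whole * n_c
            else:
                short = n_ref - n_c
            if short > 0:
                replicas.extend(rng.choice(ids, size=short, replace=True))
            for k, rid in enumerate(replicas):
                out.append(FoldAssignment(f"{rid}#r{k}", cls, fold,
                                          replica_of=rid))
    return out


def assignments_table(assignments: Sequence[FoldAssignment]) -> "pd.DataFrame":
    """Fold assignments as a table (record_id, class, fold, replica_of)."""
    import pandas as pd

    return pd.DataFrame([
        {"record_id": a.record_id, "class": a.cls.code, "fold": a.fold,
         "replica_of": "" if a.replica_of is None else a.replica_of}
        for a in assignments
    ], columns=["record_id", "class", "fold", "replica_of"])
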