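"""Synthetic 12-lead ECG generator with class-conditional rhythm and morphology.

Every beat is a sum of Gaussian-shaped P/Q/R/S/T bumps plus a smooth ST
plateau, projected onto the 12 leads by fixed per-lead gains, with an RR
process drawn per rhythm class.  The emulation is a deliberate caricature:
classes differ in the features a cardiologist would name —

* ``N``      regular RR, full PQRST;
* ``AF``     highly irregular RR, suppressed P wave;
* ``I-AVB``  long PR interval (P wave displaced early);
* ``LBBB``   widened QRS, negative polarity in V1-V3, tall lateral leads;
* ``RBBB``   widened QRS, extra positive deflection in V1-V2;
* ``PAC``    occasional early beats with normal (narrow) QRS;
* ``PVC``    occasional early wide-QRS beats without a P wave;
* ``STD``    negative ST-segment offset on lateral leads;
* ``STE``    positive ST-segment offset on anterior leads —

and the generator records ground-truth beat times, so signal-processing
and classification stages can be tested without any external data.  It
does not attempt clinical realism (no respiration, electrode artefacts,
inter-subject morphology variation, or vectorcardiographic projection).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path


import numpy as np

from .labels import ClassLabel
from .record_io import ECGRecord, LEAD_NAMES, write_record

__all__ = [
    "ClassParams", "SynthSpec", "SynthTruth",
    "generate_record", "generate_records", "generate_dataset",
]

# fixed per-lead projection gains for the (P, T) waves and the QRS complex;
# aVR is the classic inverted lead, chest leads ramp up towards V5
_LEAD_GAIN = np.array(
    [0.6, 1.0, 0.5, -0.8, 0.35, 0.7, -0.3, 0.25, 0.55, 0.8, 1.0, 0.9]
)

_V1, _V2, _V3 = (LEAD_NAMES.index(n) for n in ("V1", "V2", "V3"))
_LATERAL = tuple(LEAD_NAMES.index(n) for n in ("I", "aVL", "V4", "V5", "V6"))
_ANTERIOR = tuple(LEAD_NAMES.index(n) for n in ("V1", "V2", "V3", "V4"))


@dataclass(frozen=True)
class ClassParams:
    """Rhythm/morphology knobs for one class.

    Times in milliseconds, amplitudes/offsets in millivolts,
    probabilities per beat.
    """

    mean_rr_ms: float = 850.0
    rr_jitter_sd_ms: float = 30.0
    ectopic_prob: float = 0.0
    qrs_width_ms: float = 90.0
    p_amp_mv: float = 0.15
    pr_ms: float = 160.0
    st_offset_mv: float = 0.0
    st_leads: tuple[int, ...] = ()
    ectopic_wide: bool = False     # PVC-like ectopics: wide QRS, no P
    qrs_gain_override: tuple[float, ...] | None = None


def _lbbb_gains() -> tuple[float, ...]:
    g = _LEAD_GAIN.copy()
    g[[_V1, _V2, _V3]] = [-0.9, -0.8, -0.5]   # deep negative anterior QRS
    for i in _LATERAL:
        g[i] *= 1.2
    return tuple(float(v) for v in g)


def _rbbb_gains() -> tuple[float, ...]:
    g = _LEAD_GAIN.copy()
    g[[_V1, _V2]] = [0.9, 0.8]                # dominant positive rsR'-like V1/V2
    return tuple(float(v) for v in g)


#: Default per-class generator parameters (the study conditions).
CLASS_DEFAULTS: dict[ClassLabel, ClassParams] = {
    ClassLabel.N: ClassParams(),
    ClassLabel.AF: ClassParams(rr_jitter_sd_ms=150.0, p_amp_mv=0.0),
    ClassLabel.I_AVB: ClassParams(pr_ms=260.0),
    ClassLabel.LBBB: ClassParams(qrs_width_ms=150.0,
                                 qrs_gain_override=_lbbb_gains()),
    ClassLabel.RBBB: ClassParams(qrs_width_ms=135.0,
                                 qrs_gain_override=_rbbb_gains()),
    ClassLabel.PAC: ClassParams(ectopic_prob=0.15),
    ClassLabel.PVC: ClassParams(ectopic_prob=0.15, ectopic_wide=True),
    ClassLabel.STD: ClassParams(st_offset_mv=-0.15, st_leads=_LATERAL),
    ClassLabel.STE: ClassParams(st_offset_mv=0.20, st_leads=_ANTERIOR),
}


@dataclass
class SynthSpec:
    """Configuration of a synthetic dataset.

    ``seed`` fully determines the output; each record uses an independent
    substream keyed by ``(seed, record_index)`` so records are
    reproducible in isolation.
    """

    n_records: int = 90
    class_mix: dict[ClassLabel, float] = field(
        default_factory=lambda: {c: 1 / 9 for c in ClassLabel})
    fs: float = 500.0
    duration_range: tuple[float, float] = (6.0, 60.0)
    noise_sd_mv: float = 0.02
    seed: int = 0
    class_params: dict[ClassLabel, ClassParams] = field(
        default_factory=lambda: dict(CLASS_DEFAULTS))

    def __post_init__(self) -> None:
        self.class_mix = {
            (c if isinstance(c, ClassLabel) else ClassLabel.from_code(c)): p
            for c, p in self.class_mix.items()
        }
        total = sum(self.class_mix.values())
        if not np.isclose(total, 1.0):
            raise ValueError(f"class_mix must sum to 1, sums to {total}")
        if not self.fs > 0:
            raise ValueError("fs must be positive")
        lo, hi = self.duration_range
        if not (6.0 <= lo <= hi <= 60.0):
            raise ValueError("duration_range must lie within [6, 60] seconds")

    def params_for(self, cls: ClassLabel) -> ClassParams:
        return self.class_params.get(cls, CLASS_DEFAULTS[cls])


@dataclass
class SynthTruth:
    """Ground truth attached to one generated record."""

    beat_times_s: np.ndarray          # strictly increasing, seconds
    ectopic_mask: np.ndarray          # bool per beat
    true_class: ClassLabel
    params: ClassParams

    def __post_init__(self) -> None:
        self.beat_times_s = np.asarray(self.beat_times_s, dtype=float)
        if np.any(np.diff(self.beat_times_s) <= 0):
            raise ValueError("beat times must be strictly increasing")


def _draw_duration(spec: SynthSpec, rng: np.random.Generator) -> float:
    """Record length in seconds: short records dominate, tail to the max.

    Offset-exponential (6 s floor, 10 s mean excess) clipped to the upper
    bound, giving a median near 13 s — the length profile typical of
    clinical arrhythmia snapshot recordings.
    """
    lo, hi = spec.duration_range
    if hi - lo < 1e-9:
        return lo
    return float(min(hi, lo + rng.exponential(10.0)))


def _draw_rhythm(params: ClassParams, duration_s: float,
                 rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Beat times and ectopic flags for one record."""
    mean = params.mean_rr_ms / 1000.0
    sd = params.rr_jitter_sd_ms / 1000.0
    times: list[float] = []
    ectopic: list[bool] = []
    t = rng.uniform(0.25, 0.25 + mean)
    compensate = False
    while t < duration_s:
        is_ect = (not compensate) and (rng.uniform() < params.ectopic_prob)
        times.append(t)
        ectopic.append(is_ect and len(times) > 1)
        rr = max(0.30, rng.normal(mean, sd))
        if is_ect:
            rr *= 0.65                 # premature beat arrives early
            compensate = True
        elif compensate:
            rr *= 1.35                 # compensatory pause after the ectopic
            compensate = False
        t += rr
    return np.asarray(times), np.asarray(ectopic, dtype=bool)


def _gauss(t: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - mu) / sigma) ** 2)


def _st_plateau(t: np.ndarray, lo: float, hi: float, edge: float) -> np.ndarray:
    """Smooth boxcar between *lo* and *hi* seconds after the R peak."""
    from scipy.special import expit

    return expit((t - lo) / edge) * expit((hi - t) / edge)


def generate_record(spec: SynthSpec, cls: ClassLabel,
                    rng: np.random.Generator,
                    record_id: str = "synth",
                    duration_s: float | None = None,
                    ) -> tuple[ECGRecord, SynthTruth]:
    """Generate one 12-lead record of class *cls*.

    Demographics are drawn too (age ~ N(60, 15) clipped to [18, 95],
    sex uniform) so the full fusion vector can be exercised.
    """
    params = spec.params_for(cls)
    if duration_s is None:
        duration_s = _draw_duration(spec, rng)
    n = int(round(duration_s * spec.fs))
    t = np.arange(n) / spec.fs
    beat_times, ectopic = _draw_rhythm(params, duration_s, rng)

    signals = np.zeros((len(LEAD_NAMES), n))
    qrs_gain = (np.asarray(params.qrs_gain_override)
                if params.qrs_gain_override is not None else _LEAD_GAIN)
    pt_gain = _LEAD_GAIN
    st_mask = np.zeros(len(LEAD_NAMES))
    st_mask[list(params.st_leads)] = params.st_offset_mv

    w = params.qrs_width_ms / 1000.0
    for bt, is_ect in zip(beat_times, ectopic):
        wide = is_ect and params.ectopic_wide
        bw = max(w, 0.14) if wide else w
        sigma_r = bw / 5.0
        lo = max(0, int((bt - 0.45) * spec.fs))
        hi = min(n, int((bt + 0.55) * spec.fs))
        if hi <= lo:
            continue
        tw = t[lo:hi] - bt
        qrs = (_gauss(tw, 0.0, sigma_r)
               - 0.12 * _gauss(tw, -0.55 * bw, 0.4 * sigma_r)
               - 0.25 * _gauss(tw, 0.55 * bw, 0.4 * sigma_r))
        p_amp = 0.0 if wide else params.p_amp_mv
        pt = (p_amp * _gauss(tw, -params.pr_ms / 1000.0, 0.025)
              + (-0.25 if wide else 0.35) * _gauss(tw, 0.30, 0.06))
        st = _st_plateau(tw, 0.06 + 0.5 * bw, 0.24, 0.01)
        amp = 1.45 if wide else 1.0
        signals[:, lo:hi] += (amp * qrs_gain[:, None] * qrs
                              + pt_gain[:, None] * pt
                              + st_mask[:, None] * st)

    signals += rng.normal(0.0, spec.noise_sd_mv, size=signals.shape)

    age = float(np.clip(rng.normal(60.0, 15.0), 18.0, 95.0))
    sex = "female" if rng.uniform() < 0.5 else "male"
    record = ECGRecord(signals=signals, fs=spec.fs, labels=[cls],
                       age=round(age), sex=sex, record_id=record_id)
    truth = SynthTruth(beat_times_s=beat_times, ectopic_mask=ectopic,
                       true_class=cls, params=params)
    return record, truth


def _class_counts(spec: SynthSpec) -> dict[ClassLabel, int]:
    """Largest-remainder apportionment of n_records over class_mix."""
    classes = list(spec.class_mix)
    exact = np.array([spec.class_mix[c] * spec.n_records for c in classes])
    counts = np.floor(exact).astype(int)
    rem = exact - counts
    for i in np.argsort(-rem, kind="stable")[: spec.n_records - counts.sum()]:
        counts[i] += 1
    return dict(zip(classes, counts))


def generate_records(spec: SynthSpec) -> list[tuple[ECGRecord, SynthTruth]]:
    """Generate the full dataset in memory, deterministically from the seed."""
    counts = _class_counts(spec)
    out: list[tuple[ECGRecord, SynthTruth]] = []
    idx = 0
    for cls in counts:
        for _ in range(counts[cls]):
            rng = np.random.default_rng([spec.seed, idx])
            rid = f"rec{idx:05d}"
            out.append(generate_record(spec, cls, rng, record_id=rid))
            idx += 1
    return out


def generate_dataset(spec: SynthSpec, out_dir: str | Path) -> "pd.DataFrame":
    """Write the dataset to *out_dir* in the csvmat dialect.

    Produces one record pair per entry, a ``manifest.csv`` with columns
    ``record_id, true_class, n_beats``, and ``truth.json`` mapping each
    record id to its ground-truth beat times (seconds).
    """
    import pandas as pd

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    truth_map = {}
    for record, truth in generate_records(spec):
        write_record(record, out_dir / record.record_id, format="csvmat")
        rows.append({
            "record_id": record.record_id,
            "true_class": truth.true_class.code,
            "n_beats": len(truth.beat_times_s),
        })
        truth_map[record.record_id] = [round(t, 6) for t in truth.beat_times_s]
    manifest = pd.DataFrame(rows, columns=["record_id", "true_class", "n_beats"])
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    with open(out_dir / "truth.json", "w") as fh:
        json.dump(truth_map, fh)
    return manifest
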