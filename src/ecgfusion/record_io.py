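"""Reading and writing multichannel ECG records.

Two interchange dialects are supported:

``csvmat``
    A human-inspectable pair ``<base>.csv`` + ``<base>.json``.  The CSV
    holds the signal matrix as N rows x 12 columns (header = lead names,
    full-precision floats, millivolts); the JSON sidecar holds
    ``{record_id, fs, age, sex, labels}`` with missing age/sex encoded
    as explicit ``null``.

``wfdb``
    A minimal WFDB-compatible ``<base>.hea`` / ``<base>.dat`` pair
    (formats 16 and 32, sample-interleaved little-endian integers).
    Age, sex and labels travel in ``#`` comment lines of the header.
    Writing quantizes physical millivolts to integers at the stated ADC
    gain (default 1000 adu/mV), so a float round trip is accurate to
    0.5/gain; write-read is exactly idempotent thereafter.

Lead order is fixed as the standard 12-lead layout
(I, II, III, aVR, aVL, aVF, V1..V6) and normalized on read.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .labels import ClassLabel

logger = logging.getLogger(__name__)

#: Fixed lead order of a standard 12-lead ECG.
LEAD_NAMES: tuple[str, ...] = (
    "I", "II", "III", "aVR", "aVL", "aVF",
    "V1", "V2", "V3", "V4", "V5", "V6",
)

N_LEADS = len(LEAD_NAMES)

#: Index of lead II, the conventional rhythm lead used for HRV analysis.
LEAD_II = LEAD_NAMES.index("II")


class RecordFormatError(ValueError):
    """A record file does not conform to its dialect."""


@dataclass
class ECGRecord:
    """One 12-lead ECG record: signals plus demographics and labels.

    Parameters
    ----------
    signals : ndarray, shape (12, n_samples)
        Voltages in millivolts, rows in :data:`LEAD_NAMES` order.
    fs : float
        Sampling rate in Hz, > 0.
    labels : sequence of ClassLabel
        One to three rhythm labels.  Order matters: the first label is
        the record's primary diagnosis (see :func:`primary_label`).
    age : float or None
        Age in years; ``None`` when unknown (never silently zero).
    sex : str or None
        ``'female'`` or ``'male'``; ``None`` when unknown.
    """

    signals: np.ndarray
    fs: float
    labels: list[ClassLabel]
    age: float | None = None
    sex: str | None = None
    record_id: str = "record"

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=float)
        if self.signals.ndim != 2 or self.signals.shape[0] != N_LEADS:
            raise RecordFormatError(
                f"signals must be (12, N); got shape {self.signals.shape}"
            )
        if self.signals.shape[1] < 1:
            raise RecordFormatError("record must contain at least one sample")
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        self.labels = [
            lab if isinstance(lab, ClassLabel) else ClassLabel.from_code(lab)
            for lab in self.labels
        ]
        if not 1 <= len(self.labels) <= 3:
            raise ValueError(f"need 1..3 labels, got {len(self.labels)}")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate labels are not allowed")
        if self.sex is not None and self.sex not in ("female", "male"):
            raise ValueError(f"sex must be 'female', 'male' or None, got {self.sex!r}")

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def with_signals(self, signals: np.ndarray, fs: float | None = None) -> "ECGRecord":
        """Copy of this record with new signal data (metadata preserved)."""
        return replace(self, signals=signals, fs=self.fs if fs is None else fs)


def primary_label(record: ECGRecord) -> ClassLabel:
    """The record's primary diagnosis: the first label.

    Records with multiple concurrent diagnoses keep an ordered label
    list; all training targets use the first entry.
    """
    if not record.labels:
        raise ValueError("record has no labels")
    return record.labels[0]


# ---------------------------------------------------------------------------
# csvmat dialect
# ---------------------------------------------------------------------------

def _csvmat_paths(path: Path) -> tuple[Path, Path]:
    base = path.with_suffix("") if path.suffix in (".csv", ".json") else path
    return base.with_suffix(".csv"), base.with_suffix(".json")


def _write_csvmat(record: ECGRecord, path: Path) -> None:
    csv_path, json_path = _csvmat_paths(path)
    with open(csv_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(LEAD_NAMES)
        for row in record.signals.T:
            writer.writerow([repr(float(v)) for v in row])
    meta = {
        "record_id": record.record_id,
        "fs": record.fs,
        "age": record.age,
        "sex": record.sex,
        "labels": [lab.code for lab in record.labels],
    }
    with open(json_path, "w") as fh:
        json.dump(meta, fh, indent=1)
        fh.write("\n")


def _read_csvmat(path: Path) -> ECGRecord:
    csv_path, json_path = _csvmat_paths(path)
    if not csv_path.exists():
        raise FileNotFoundError(csv_path)
    if not json_path.exists():
        raise RecordFormatError(f"missing JSON sidecar {json_path}")
    with open(json_path) as fh:
        meta = json.load(fh)
    with open(csv_path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None:
            raise RecordFormatError(f"{csv_path}: empty file")
        missing = [name for name in LEAD_NAMES if name not in header]
        if missing:
            raise RecordFormatError(
                f"{csv_path}: missing lead column(s) {missing}"
            )
        order = [header.index(name) for name in LEAD_NAMES]
        rows = []
        for lineno, row in enumerate(reader, start=2):
            try:
                rows.append([float(row[j]) for j in order])
            except (ValueError, IndexError) as exc:
                raise RecordFormatError(
                    f"{csv_path}:{lineno}: non-numeric or short row"
                ) from exc
    if not rows:
        raise RecordFormatError(f"{csv_path}: no samples")
    signals = np.asarray(rows, dtype=float).T
    return ECGRecord(
        signals=signals,
        fs=float(meta["fs"]),
        labels=[ClassLabel.from_code(c) for c in meta["labels"]],
        age=None if meta.get("age") is None else float(meta["age"]),
        sex=meta.get("sex"),
        record_id=str(meta.get("record_id", csv_path.stem)),
    )


# ---------------------------------------------------------------------------
# WFDB dialect (formats 16 / 32)
# ---------------------------------------------------------------------------

_WFDB_DTYPES = {16: "<i2", 32: "<i4"}


def _wfdb_base(path: Path) -> Path:
    return path.with_suffix("") if path.suffix in (".hea", ".dat") else path


def _write_wfdb(record: ECGRecord, path: Path, gain: float = 1000.0,
                fmt: int = 16) -> None:
    if fmt not in _WFDB_DTYPES:
        raise ValueError(f"unsupported WFDB format {fmt}; use 16 or 32")
    base = _wfdb_base(path)
    dtype = np.dtype(_WFDB_DTYPES[fmt])
    digital = np.rint(record.signals * gain)
    lim = np.iinfo(np.int16 if fmt == 16 else np.int32)
    if digital.min() < lim.min or digital.max() > lim.max:
        raise ValueError(
            f"signal exceeds format-{fmt} range at gain {gain}; "
            "lower the gain or use format 32"
        )
    digital = digital.astype(dtype.base if fmt == 16 else np.int32)
    # sample-interleaved: s0 of all leads, then s1, ...
    digital.T.astype(_WFDB_DTYPES[fmt]).tofile(base.with_suffix(".dat"))
    checksums = (digital.astype(np.int64).sum(axis=1) & 0xFFFF).astype(np.int16)
    lines = [f"{base.name} {N_LEADS} {_fmt_num(record.fs)} {record.n_samples}"]
    for i, name in enumerate(LEAD_NAMES):
        first = int(digital[i, 0])
        lines.append(
            f"{base.name}.dat {fmt} {_fmt_num(gain)}/mV 16 0 "
            f"{first} {int(checksums[i])} 0 {name}"
        )
    lines.append(f"# Age: {'' if record.age is None else _fmt_num(record.age)}")
    lines.append(f"# Sex: {'' if record.sex is None else record.sex}")
    lines.append("# Labels: " + "|".join(lab.code for lab in record.labels))
    base.with_suffix(".hea").write_text("\n".join(lines) + "\n")


def _fmt_num(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else repr(float(x))


def _read_wfdb(path: Path) -> ECGRecord:
    base = _wfdb_base(path)
    hea = base.with_suffix(".hea")
    if not hea.exists():
        raise FileNotFoundError(hea)
    lines = hea.read_text().splitlines()
    head = lines[0].split()
    n_sig, fs, n_samp = int(head[1]), float(head[2]), int(head[3])
    if n_sig != N_LEADS:
        raise RecordFormatError(
            f"{hea}: expected 12 signals, found {n_sig}"
        )
    sig_lines = [ln.split() for ln in lines[1 : 1 + n_sig]]
    fmts = {int(ln[1]) for ln in sig_lines}
    if len(fmts) != 1 or fmts.pop() not in _WFDB_DTYPES:
        raise RecordFormatError(f"{hea}: unsupported or mixed sample formats")
    fmt = int(sig_lines[0][1])
    gains = [float(ln[2].split("/")[0]) for ln in sig_lines]
    names = [ln[-1] for ln in sig_lines]
    missing = [name for name in LEAD_NAMES if name not in names]
    if missing:
        raise RecordFormatError(f"{hea}: missing lead(s) {missing}")
    raw = np.fromfile(base.with_suffix(".dat"), dtype=_WFDB_DTYPES[fmt])
    if raw.size != n_sig * n_samp:
        raise RecordFormatError(
            f"{base}.dat: expected {n_sig * n_samp} samples, found {raw.size}"
        )
    digital = raw.reshape(n_samp, n_sig).T.astype(float)
    physical = digital / np.asarray(gains)[:, None]
    order = [names.index(name) for name in LEAD_NAMES]
    physical = physical[order]

    age: float | None = None
    sex: str | None = None
    labels: list[ClassLabel] = []
    for ln in lines[1 + n_sig:]:
        if not ln.startswith("#"):
            continue
        body = ln[1:].strip()
        if body.lower().startswith("age:"):
            val = body[4:].strip()
            age = float(val) if val else None
        elif body.lower().startswith("sex:"):
            val = body[4:].strip()
            sex = val if val else None
        elif body.lower().startswith("labels:"):
            val = body[7:].strip()
            labels = [ClassLabel.from_code(c) for c in val.split("|") if c]
    if not labels:
        raise RecordFormatError(f"{hea}: no '# Labels:' comment found")
    return ECGRecord(
        signals=physical, fs=fs, labels=labels, age=age, sex=sex,
        record_id=base.name,
    )


# ---------------------------------------------------------------------------
# public entry points
# ---------------------------------------------------------------------------

def write_record(record: ECGRecord, path: str | Path,
                 format: str = "csvmat", **kwargs) -> None:
    """Write *record* to *path* in the named dialect (``csvmat``/``wfdb``)."""
    path = Path(path)
    if format == "csvmat":
        _write_csvmat(record, path)
    elif format == "wfdb":
        _write_wfdb(record, path, **kwargs)
    else:
        raise ValueError(f"unknown format {format!r}")


def read_record(path: str | Path, format: str = "csvmat") -> ECGRecord:
    """Read a validated :class:`ECGRecord`; lead order is normalized."""
    path = Path(path)
    if format == "csvmat":
        return _read_csvmat(path)
    if format == "wfdb":
        return _read_wfdb(path)
    raise ValueError(f"unknown format {format!r}")


def separate_metadata(dataset_dir: str | Path,
                      out_csv: str | Path | None = None) -> "pd.DataFrame":
    """Extract per-record demographics into a metadata table.

    Scans *dataset_dir* for csvmat sidecars and WFDB headers, and returns
    (optionally writing to *out_csv*) a table with columns
    ``record_id, age, sex, labels`` (labels pipe-separated), sorted by
    record_id so repeated runs are byte-identical.  Unreadable records
    are skipped with a logged warning.
    """
    import pandas as pd

    dataset_dir = Path(dataset_dir)
    rows = []
    candidates = sorted(
        set(p.with_suffix("") for p in dataset_dir.glob("*.json"))
        | set(p.with_suffix("") for p in dataset_dir.glob("*.hea"))
    )
    for base in candidates:
        fmt = "csvmat" if base.with_suffix(".json").exists() else "wfdb"
        try:
            rec = read_record(base, format=fmt)
        except Exception as exc:  # noqa: BLE001 - skip-and-log contract
            logger.warning("skipping unreadable record %s: %s", base, exc)
            continue
        rows.append({
            "record_id": rec.record_id,
            "age": "" if rec.age is None else _fmt_num(rec.age),
            "sex": "" if rec.sex is None else rec.sex,
            "labels": "|".join(lab.code for lab in rec.labels),
        })
    table = pd.DataFrame(rows, columns=["record_id", "age", "sex", "labels"])
    table = table.sort_values("record_id", kind="stable").reset_index(drop=True)
    if out_csv is not None:
        table.to_csv(out_csv, index=False)
    return table
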