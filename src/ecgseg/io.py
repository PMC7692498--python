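"""Reading and writing ECG records, resampling, and subject-disjoint splits.

Two on-disk dialects are supported:

* ``csv`` — a pair of plain-text files, ``<id>.csv`` holding one amplitude
  per line and ``<id>.ann`` holding one 0-based R-peak sample index per
  line.  This suits raw-signal databases shipped without a standard
  annotation format (CYBHi-style, typically 1000 Hz).
* ``wfdb`` — a minimal read-only implementation of the WFDB record format
  used by MIT-BIH-style databases: ``.hea`` header, ``.dat`` signal in
  format 212 or 16, and ``.atr`` beat annotations.  Beat annotation codes
  are mapped to R-peak indices; non-beat annotations are ignored.

Indices are 0-based throughout and windows are half-open.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import numpy as np
import yaml
from scipy.interpolate import interp1d

from .records import ECGRecord

__all__ = [
    "read_record",
    "write_record",
    "resample_to_length",
    "make_subject_split",
    "load_record_config",
]

# WFDB annotation codes that denote a beat (NORMAL, LBBB, RBBB, PVC, ...)
_BEAT_CODES = frozenset({1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12, 13, 25, 34, 35, 38})


# ---------------------------------------------------------------------------
# CSV / ANN dialect
# ---------------------------------------------------------------------------

def _read_csv_record(stem: Path, fs: float) -> ECGRecord:
    sig_path = stem.with_suffix(".csv")
    ann_path = stem.with_suffix(".ann")
    if not sig_path.exists():
        raise FileNotFoundError(f"signal file not found: {sig_path}")
    if not ann_path.exists():
        raise FileNotFoundError(
            f"annotation file not found: {ann_path} "
            "(ground-truth R-peaks are required to label samples)"
        )
    samples = np.loadtxt(sig_path, dtype=np.float64, ndmin=1)
    text = ann_path.read_text().split()
    r_peaks = np.asarray([int(v) for v in text], dtype=np.int64)
    for idx in r_peaks:
        if idx < 0 or idx >= samples.size:
            raise ValueError(
                f"annotation index {idx} out of range for signal of length {samples.size}"
            )
    return ECGRecord(samples=samples, fs=fs, r_peaks=np.sort(r_peaks),
                     record_id=stem.name)


def write_record(record: ECGRecord, stem: str | Path) -> tuple[Path, Path]:
    """Write a record in the CSV/ANN dialect; returns the two paths."""
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    sig_path = stem.with_suffix(".csv")
    ann_path = stem.with_suffix(".ann")
    np.savetxt(sig_path, record.samples, fmt="%.10g")
    ann_path.write_text("\n".join(str(int(i)) for i in record.r_peaks) + "\n")
    return sig_path, ann_path


# ---------------------------------------------------------------------------
# Minimal WFDB reader (header + format 212/16 signal + .atr annotations)
# ---------------------------------------------------------------------------

def _parse_header(hea_path: Path) -> dict:
    lines = [ln.strip() for ln in hea_path.read_text().splitlines()
             if ln.strip() and not ln.startswith("#")]
    head = lines[0].split()
    name = head[0].split("/")[0]
    nsig = int(head[1])
    fs = float(head[2].split("/")[0]) if len(head) > 2 else 250.0
    nsamp = int(head[3]) if len(head) > 3 else 0
    signals = []
    for ln in lines[1 : 1 + nsig]:
        f = ln.split()
        fmt = int(re.match(r"\d+", f[1]).group())
        gain_field = f[2] if len(f) > 2 else "200"
        m = re.match(r"([-+0-9.eE]+)(?:\(([-+0-9]+)\))?", gain_field)
        gain = float(m.group(1)) if m else 200.0
        if gain == 0:
            gain = 200.0
        baseline = int(m.group(2)) if m and m.group(2) else (int(f[4]) if len(f) > 4 else 0)
        signals.append({"file": f[0], "fmt": fmt, "gain": gain, "baseline": baseline})
    return {"name": name, "nsig": nsig, "fs": fs, "nsamp": nsamp, "signals": signals}


def _read_dat(dat_path: Path, fmt: int, nsig: int, nsamp: int) -> np.ndarray:
    """Return digital samples, shape (nsamp, nsig)."""
    raw = dat_path.read_bytes()
    if fmt == 16:
        data = np.frombuffer(raw, dtype="<i2")
        total = (data.size // nsig) * nsig
        return data[:total].reshape(-1, nsig).astype(np.int32)
    if fmt == 212:
        b = np.frombuffer(raw, dtype=np.uint8)
        n_triplets = b.size // 3
        b = b[: n_triplets * 3].reshape(-1, 3).astype(np.int32)
        s1 = ((b[:, 1] & 0x0F) << 8) | b[:, 0]
        s2 = ((b[:, 1] & 0xF0) << 4) | b[:, 2]
        s1 = np.where(s1 > 2047, s1 - 4096, s1)
        s2 = np.where(s2 > 2047, s2 - 4096, s2)
        flat = np.empty(2 * n_triplets, dtype=np.int32)
        flat[0::2], flat[1::2] = s1, s2
        total = (flat.size // nsig) * nsig
        return flat[:total].reshape(-1, nsig)
    raise ValueError(f"unsupported WFDB signal format {fmt} (only 212 and 16 are supported)")


def _read_atr(atr_path: Path) -> np.ndarray:
    """Return sample indices of beat annotations from a MIT-format file."""
    data = atr_path.read_bytes()
    times: list[int] = []
    t = 0
    i = 0
    while i + 1 < len(data):
        word = data[i] | (data[i + 1] << 8)
        i += 2
        code = word >> 10
        delta = word & 0x3FF
        if code == 0 and delta == 0:  # EOF
            break
        if code == 59:  # SKIP: 4-byte interval, high word first
            if i + 3 >= len(data):
                break
            hi = data[i] | (data[i + 1] << 8)
            lo = data[i + 2] | (data[i + 3] << 8)
            i += 4
            skip = (hi << 16) | lo
            if skip >= 1 << 31:
                skip -= 1 << 32
            t += skip
        elif code in (60, 61, 62):  # NUM / SUB / CHN: no time advance
            continue
        elif code == 63:  # AUX: delta is the byte count (padded to even)
            i += delta + (delta & 1)
        else:
            t += delta
            if code in _BEAT_CODES:
                times.append(t)
    return np.asarray(sorted(set(times)), dtype=np.int64)


def _read_wfdb_record(stem: Path, channel: int = 0) -> ECGRecord:
    hea_path = stem.with_suffix(".hea")
    if not hea_path.exists():
        raise FileNotFoundError(f"WFDB header not found: {hea_path}")
    hdr = _parse_header(hea_path)
    sig = hdr["signals"][channel]
    dat_path = stem.parent / sig["file"]
    if not dat_path.exists():
        raise FileNotFoundError(f"WFDB signal file not found: {dat_path}")
    digital = _read_dat(dat_path, sig["fmt"], hdr["nsig"], hdr["nsamp"])
    physical = (digital[:, channel] - sig["baseline"]) / sig["gain"]
    if hdr["nsamp"]:
        physical = physical[: hdr["nsamp"]]

    atr_path = stem.with_suffix(".atr")
    if not atr_path.exists():
        raise FileNotFoundError(
            f"annotation file not found: {atr_path} "
            "(ground-truth beat annotations are required)"
        )
    r_peaks = _read_atr(atr_path)
    for idx in r_peaks:
        if idx >= physical.size:
            raise ValueError(
                f"annotation index {idx} out of range for signal of length {physical.size}"
            )
    return ECGRecord(samples=physical.astype(np.float64), fs=hdr["fs"],
                     r_peaks=r_peaks, record_id=stem.name)


def read_record(path: str | Path, format: str = "csv", fs: float = 1000.0,
                channel: int = 0) -> ECGRecord:
    """Read a record with its beat annotations.

    Parameters
    ----------
    path : path-like
        Record stem (extension optional): ``rec`` reads ``rec.csv`` +
        ``rec.ann`` or ``rec.hea`` + ``rec.dat`` + ``rec.atr``.
    format : {"csv", "wfdb"}
    fs : float
        Sampling rate for the CSV dialect, which does not store one
        (WFDB takes fs from the header).
    channel : int
        Signal channel for multi-signal WFDB records (single-lead method;
        one channel is read).
    """
    stem = Path(path)
    if stem.suffix in (".csv", ".ann", ".hea", ".dat", ".atr"):
        stem = stem.with_suffix("")
    if format == "csv":
        return _read_csv_record(stem, fs=fs)
    if format == "wfdb":
        return _read_wfdb_record(stem, channel=channel)
    raise ValueError(f"unknown format {format!r}; expected 'csv' or 'wfdb'")


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

def resample_to_length(values: np.ndarray, n_out: int) -> np.ndarray:
    """Resample a segment to exactly ``n_out`` samples over the same extent.

    Piecewise cubic polynomial interpolation on the uniform sample grid
    (linear when the input is too short for a cubic).  Endpoints are
    preserved exactly, and the operation is the identity when
    ``n_out == len(values)``.
    """
    values = np.asarray(values, dtype=np.float64)
    n_in = values.size
    if n_in < 2:
        raise ValueError("input must have at least 2 samples")
    if n_out < 2:
        raise ValueError("n_out must be >= 2")
    if n_out == n_in:
        return values.copy()
    x_in = np.linspace(0.0, 1.0, n_in)
    x_out = np.linspace(0.0, 1.0, n_out)
    kind = "cubic" if n_in >= 4 else "linear"
    return interp1d(x_in, values, kind=kind, assume_sorted=True)(x_out)


# ---------------------------------------------------------------------------
# Subject-disjoint splits
# ---------------------------------------------------------------------------

def _check_subject_disjoint(records: list[ECGRecord], train: set[str],
                            test: set[str]) -> None:
    by_subject: dict[str, set[str]] = {}
    for r in records:
        by_subject.setdefault(r.subject_id, set()).add(
            "train" if r.record_id in train else "test")
    for subj, sides in by_subject.items():
        if len(sides) > 1:
            raise ValueError(
                f"subject {subj!r} has records on both sides of the split; "
                "refusing to build a subject-overlapping split"
            )


def make_subject_split(records: list[ECGRecord], scheme: str = "odd_even",
                       seed: int = 0) -> tuple[list[str], list[str]]:
    """Partition records into train/test ids with no subject overlap.

    ``odd_even`` puts odd-numbered record ids in train and even-numbered
    in test (the convention for numerically-identified records);
    ``random_half`` splits the *subjects* in half at random.  Either way
    a subject whose records would straddle the split raises an error —
    records are never silently reassigned.
    """
    if len(records) < 2:
        raise ValueError("need at least 2 records to split")
    ids = [r.record_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("record ids must be unique")

    if scheme == "odd_even":
        train, test = [], []
        for r in records:
            m = re.search(r"(\d+)$", r.record_id)
            if m is None:
                raise ValueError(
                    f"record id {r.record_id!r} does not end in digits; "
                    "odd_even scheme needs numeric ids"
                )
            (train if int(m.group(1)) % 2 == 1 else test).append(r.record_id)
    elif scheme == "random_half":
        subjects = sorted({r.subject_id for r in records})
        if len(subjects) < 2:
            raise ValueError(
                "random_half needs >= 2 subjects to produce two non-empty, "
                "subject-disjoint sides"
            )
        rng = np.random.default_rng(seed)
        order = [subjects[i] for i in rng.permutation(len(subjects))]
        train_subj = set(order[: len(order) // 2])
        train = [r.record_id for r in records if r.subject_id in train_subj]
        test = [r.record_id for r in records if r.subject_id not in train_subj]
    else:
        raise ValueError(f"unknown scheme {scheme!r}; expected 'odd_even' or 'random_half'")

    if not train or not test:
        raise ValueError("split produced an empty side")
    _check_subject_disjoint(records, set(train), set(test))
    return train, test


def load_record_config(path: str | Path) -> dict:
    """Load a YAML/JSON config naming train/test record lists.

    Recognised keys: ``train``, ``test`` (lists of record ids) and
    ``exclude`` (ids to drop, e.g. records too noisy to annotate).
    """
    path = Path(path)
    text = path.read_text()
    cfg = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ValueError("record config must be a mapping")
    cfg.setdefault("train", [])
    cfg.setdefault("test", [])
    cfg.setdefault("exclude", [])
    return cfg
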