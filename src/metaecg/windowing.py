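"""ECG records, resampling, dynamic-stride windowing and leakage-safe splits.

Protocol
--------
Recordings are resampled to 200 Hz by linear interpolation and cut into 2-s
windows (400 samples).  Windowing walks left to right: after emitting the
window at position ``p``, the walker advances by 20 samples (0.1 s) if that
window's label is 1, else by 400 samples — oversampling the rare VA class.
A window is labeled 1 iff it overlaps any VA annotation interval by at least
one sample; the final partial window is discarded.

Per-subject splits are temporal-disjoint: a support set (K windows per class)
is drawn first; every window that overlaps a support window or lies within a
safety gap of one window length of it is masked out; the validation set
(K per class) is drawn from the remainder under the same non-overlap rule,
and whatever does not overlap support or validation becomes the test set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ECGRecord", "Segment", "SubjectSplit", "SubjectTooShortError",
    "resample_linear", "resample_record", "segment_record",
    "make_subject_split", "read_text", "write_text",
    "WINDOW_SAMPLES", "TARGET_FS", "STRIDE_VA", "STRIDE_NONVA",
]

TARGET_FS = 200.0
WINDOW_SAMPLES = 400
STRIDE_VA = 20
STRIDE_NONVA = 400


class SubjectTooShortError(ValueError):
    """Raised when a subject cannot supply the required windows per class."""


@dataclass
class ECGRecord:
    """One subject's continuous single-lead signal with VA annotations.

    ``va_intervals`` are half-open, 0-based sample-index intervals
    ``[start, end)`` flagged as ventricular arrhythmia; they must be sorted
    and non-overlapping.
    """
    subject_id: str
    signal: np.ndarray
    fs: float
    va_intervals: list[tuple[int, int]] = field(default_factory=list)
    source_channel: str = ""

    def __post_init__(self):
        self.signal = np.asarray(self.signal, dtype=np.float64)
        ivs = sorted((int(a), int(b)) for a, b in self.va_intervals)
        n = len(self.signal)
        prev_end = 0
        for a, b in ivs:
            if a < 0 or b > n or a >= b:
                raise ValueError(f"interval [{a}, {b}) outside signal of "
                                 f"length {n}")
            if a < prev_end:
                raise ValueError("VA intervals overlap")
            prev_end = b
        self.va_intervals = ivs


@dataclass(frozen=True)
class Segment:
    """A fixed-length labeled window with provenance."""
    subject_id: str
    samples: np.ndarray
    label: int
    start_index: int

    def __post_init__(self):
        if len(self.samples) != WINDOW_SAMPLES:
            raise ValueError(f"segment must be {WINDOW_SAMPLES} samples")
        if self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")

    @property
    def end_index(self) -> int:
        return self.start_index + WINDOW_SAMPLES


@dataclass
class SubjectSplit:
    """Temporal-disjoint support / validation / test partition."""
    support: list[Segment]
    validation: list[Segment]
    test: list[Segment]
    K: int
    gap: int = WINDOW_SAMPLES


def resample_linear(signal: np.ndarray, fs_in: float, fs_out: float = TARGET_FS
                    ) -> np.ndarray:
    """Linear-interpolation resampling preserving record duration."""
    signal = np.asarray(signal, dtype=np.float64)
    if signal.size < 2:
        raise ValueError("resample_linear needs at least 2 samples")
    if fs_in <= 0 or fs_out <= 0:
        raise ValueError("sampling rates must be positive")
    n_out = int(round(signal.size * fs_out / fs_in))
    t_out = np.arange(n_out) * (fs_in / fs_out)
    return np.interp(t_out, np.arange(signal.size), signal)


def rescale_intervals(intervals, fs_in: float, fs_out: float, n_out: int
                      ) -> list[tuple[int, int]]:
    """Rescale annotation intervals by fs_out/fs_in with floor(start) /
    ceil(end) rounding, so a VA interval never shrinks."""
    r = fs_out / fs_in
    out = []
    for a, b in intervals:
        a2 = int(np.floor(a * r))
        b2 = min(int(np.ceil(b * r)), n_out)
        if a2 < b2:
            out.append((a2, b2))
    return out


def resample_record(record: ECGRecord, fs_out: float = TARGET_FS) -> ECGRecord:
    if record.fs == fs_out:
        return record
    sig = resample_linear(record.signal, record.fs, fs_out)
    ivs = rescale_intervals(record.va_intervals, record.fs, fs_out, sig.size)
    return ECGRecord(record.subject_id, sig, fs_out, ivs,
                     record.source_channel)


def _window_label(start: int, intervals) -> int:
    end = start + WINDOW_SAMPLES
    for a, b in intervals:
        if a < end and start < b:     # >= 1 shared sample
            return 1
        if a >= end:
            break
    return 0


def segment_record(record: ECGRecord,
                   stride_va: int = STRIDE_VA,
                   stride_nonva: int = STRIDE_NONVA) -> list[Segment]:
    """Cut a 200-Hz record into labeled windows with the dynamic stride.

    The stride after each emitted window is chosen by that window's own
    label: ``stride_va`` (default 20 samples = 0.1 s) after VA windows,
    ``stride_nonva`` (a full window) after non-VA windows.
    """
    if record.fs != TARGET_FS:
        raise ValueError(f"segment_record expects a {TARGET_FS:.0f}-Hz record; "
                         "call resample_record first")
    n = record.signal.size
    if n < WINDOW_SAMPLES:
        warnings.warn(f"record {record.subject_id} shorter than one window; "
                      "no segments produced")
        return []
    segments = []
    p = 0
    while p + WINDOW_SAMPLES <= n:
        label = _window_label(p, record.va_intervals)
        segments.append(Segment(record.subject_id,
                                record.signal[p:p + WINDOW_SAMPLES],
                                label, p))
        p += stride_va if label == 1 else stride_nonva
    return segments


def _overlaps(seg: Segment, others: list[Segment], margin: int = 0) -> bool:
    for o in others:
        if seg.start_index < o.end_index + margin and \
           o.start_index - margin < seg.end_index:
            return True
    return False


def make_subject_split(segments: list[Segment], K: int, seed: int,
                       gap: int = WINDOW_SAMPLES) -> SubjectSplit:
    """Draw the temporal-disjoint support/validation/test split.

    Support (K per class) is drawn uniformly first; all windows overlapping
    support or within ``gap`` samples of it are masked; validation (K per
    class) is drawn from the remainder; windows overlapping validation are
    dropped and the rest form the test set.
    """
    rng = np.random.default_rng(seed)
    by_class = {0: [s for s in segments if s.label == 0],
                1: [s for s in segments if s.label == 1]}
    for cls, pool in by_class.items():
        if len(pool) < 4 * K:
            raise SubjectTooShortError(
                f"class {cls}: only {len(pool)} windows, need >= {4 * K} "
                f"for a K={K} split")

    support = []
    for cls in (0, 1):
        idx = rng.choice(len(by_class[cls]), size=K, replace=False)
        support.extend(by_class[cls][i] for i in sorted(idx))

    remainder = [s for s in segments
                 if not _overlaps(s, support, margin=gap)]
    rem_by_class = {c: [s for s in remainder if s.label == c] for c in (0, 1)}
    for cls in (0, 1):
        if len(rem_by_class[cls]) < K:
            raise SubjectTooShortError(
                f"class {cls}: only {len(rem_by_class[cls])} windows left "
                f"after masking the support neighbourhood, need >= {K}")

    validation = []
    for cls in (0, 1):
        idx = rng.choice(len(rem_by_class[cls]), size=K, replace=False)
        validation.extend(rem_by_class[cls][i] for i in sorted(idx))

    val_ids = {id(s) for s in validation}
    test = [s for s in remainder
            if id(s) not in val_ids and not _overlaps(s, validation)]
    if not test:
        raise SubjectTooShortError("no test windows remain after masking")
    return SubjectSplit(support, validation, test, K=K, gap=gap)


# ---------------------------------------------------------------------------
# plain-text record dialect: one sample per line + interval CSV
# ---------------------------------------------------------------------------

def write_text(record: ECGRecord, signal_path, intervals_path):
    """Write the delimited-text dialect: one sample value per line, plus an
    interval file with ``start_s,end_s,label`` rows."""
    np.savetxt(signal_path, record.signal, fmt="%.9g")
    with open(intervals_path, "w") as fh:
        fh.write("start_s,end_s,label\n")
        for a, b in record.va_intervals:
            fh.write(f"{a / record.fs:.6f},{b / record.fs:.6f},VA\n")


def read_text(signal_path, intervals_path, fs: float,
              subject_id: str = "") -> ECGRecord:
    signal = np.loadtxt(signal_path, ndmin=1)
    intervals = []
    with open(intervals_path) as fh:
        header = fh.readline()
        if not header.lower().startswith("start_s"):
            raise ValueError(f"{intervals_path}: expected 'start_s,end_s,label'"
                             " header")
        for line in fh:
            line = line.strip()
            if not line:
                continue
            start_s, end_s, label = line.split(",")
            if label.strip().upper() != "VA":
                continue
            intervals.append((int(np.floor(float(start_s) * fs)),
                              min(int(np.ceil(float(end_s) * fs)),
                                  signal.size)))
    sid = subject_id or str(signal_path)
    return ECGRecord(sid, signal, fs, intervals, source_channel="0")
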