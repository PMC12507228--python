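"""Minimal native reader/writer for the PhysioNet WFDB format.

Supports the subset of the format family that VA-detection work actually
touches: ``.hea`` headers, ``.dat`` signal files in formats 16 (little-endian
int16) and 212 (packed 12-bit pairs), and MIT ``.atr`` annotation files with
beat symbols and rhythm-change ('+') annotations carrying aux strings such as
``(VT`` / ``(VFIB``.

VA intervals are built from the annotation stream under a configurable symbol
set: entries beginning with ``(`` are rhythm labels — a matching rhythm
annotation opens a VA interval that runs until the next rhythm change (or the
end of the record); the bracket pair ``[`` / ``]`` (VF on/off) is honoured;
any single-character beat symbol in the set marks just its own sample.
"""

from __future__ import annotations

import os
import struct
from dataclasses import dataclass

import numpy as np

from .windowing import ECGRecord

__all__ = ["read_wfdb", "write_wfdb", "read_annotations", "write_annotations",
           "DEFAULT_VA_SYMBOLS"]

DEFAULT_VA_SYMBOLS = ("(VT", "(VF", "(VFL", "(VFIB", "[")

# MIT annotation type codes used here
_CODE_FOR_SYMBOL = {"N": 1, "V": 5, "+": 28, "[": 32, "]": 33}
_SYMBOL_FOR_CODE = {v: k for k, v in _CODE_FOR_SYMBOL.items()}
_SKIP, _NUM, _SUB, _CHN, _AUX = 59, 60, 61, 62, 63


@dataclass
class _HeaderSignal:
    file_name: str
    fmt: int
    gain: float
    baseline: int
    description: str


def _parse_header(hea_path):
    with open(hea_path) as fh:
        lines = [ln.strip() for ln in fh
                 if ln.strip() and not ln.startswith("#")]
    rec = lines[0].split()
    name, n_sig = rec[0], int(rec[1])
    fs = float(rec[2]) if len(rec) > 2 else 250.0
    n_samples = int(rec[3]) if len(rec) > 3 else 0
    signals = []
    for ln in lines[1:1 + n_sig]:
        tok = ln.split()
        fmt = int(tok[1].split("x")[0].split(":")[0].split("+")[0])
        gain, baseline = 200.0, 0
        if len(tok) > 2:
            gfield = tok[2].split("/")[0]
            if "(" in gfield:
                gpart, bpart = gfield.split("(")
                gain = float(gpart)
                baseline = int(bpart.rstrip(")"))
            else:
                gain = float(gfield)
        if gain == 0:
            gain = 200.0
        desc = " ".join(tok[8:]) if len(tok) > 8 else ""
        signals.append(_HeaderSignal(tok[0], fmt, gain, baseline, desc))
    return name, fs, n_samples, signals


def _read_dat(path, fmt: int, n_sig: int) -> np.ndarray:
    raw = np.fromfile(path, dtype=np.uint8)
    if fmt == 16:
        adc = raw.view("<i2").astype(np.int64)
    elif fmt == 212:
        raw = raw[: (len(raw) // 3) * 3].reshape(-1, 3).astype(np.int64)
        first = raw[:, 0] | ((raw[:, 1] & 0x0F) << 8)
        second = raw[:, 2] | ((raw[:, 1] & 0xF0) << 4)
        first = np.where(first > 2047, first - 4096, first)
        second = np.where(second > 2047, second - 4096, second)
        adc = np.column_stack([first, second]).ravel()
    else:
        raise ValueError(f"unsupported WFDB signal format {fmt}")
    n_frames = adc.size // n_sig
    return adc[: n_frames * n_sig].reshape(n_frames, n_sig)


def read_annotations(atr_path) -> list[tuple[int, str, str]]:
    """Decode an MIT annotation file into (sample, symbol, aux) triples."""
    data = np.fromfile(atr_path, dtype="<u2")
    out = []
    sample = 0
    i = 0
    while i < len(data):
        word = int(data[i])
        code, delta = word >> 10, word & 0x3FF
        i += 1
        if word == 0:                       # EOF
            break
        if code == _SKIP:
            # 4-byte interval in PDP-11 order: high 16-bit word first
            hi, lo = int(data[i]), int(data[i + 1])
            interval = (hi << 16) | lo
            if interval >= 1 << 31:
                interval -= 1 << 32
            sample += interval
            i += 2
        elif code == _AUX:
            n_bytes = delta
            raw = data[i: i + (n_bytes + 1) // 2].tobytes()[:n_bytes]
            aux = raw.rstrip(b"\x00").decode("ascii", errors="replace")
            if out:
                s, sym, _ = out[-1]
                out[-1] = (s, sym, aux)
            i += (n_bytes + 1) // 2
        elif code in (_NUM, _SUB, _CHN):
            continue
        else:
            sample += delta
            out.append((sample, _SYMBOL_FOR_CODE.get(code, f"#{code}"), ""))
    return out


def intervals_from_annotations(annotations, n_samples: int,
                               va_symbols=DEFAULT_VA_SYMBOLS
                               ) -> list[tuple[int, int]]:
    va_symbols = tuple(va_symbols)
    rhythm_labels = {s for s in va_symbols if s.startswith("(")}
    beat_symbols = {s for s in va_symbols if not s.startswith("(") and s != "["}
    use_brackets = "[" in va_symbols

    raw: list[tuple[int, int]] = []
    open_start = None
    for sample, symbol, aux in annotations:
        if symbol == "+":
            if open_start is not None:
                raw.append((open_start, sample))
                open_start = None
            if aux in rhythm_labels:
                open_start = sample
        elif use_brackets and symbol == "[":
            if open_start is None:
                open_start = sample
        elif use_brackets and symbol == "]":
            if open_start is not None:
                raw.append((open_start, sample))
                open_start = None
        elif symbol in beat_symbols:
            raw.append((sample, min(sample + 1, n_samples)))
    if open_start is not None:
        raw.append((open_start, n_samples))

    merged: list[tuple[int, int]] = []
    for a, b in sorted((max(0, a), min(b, n_samples)) for a, b in raw if a < b):
        if merged and a <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], b))
        else:
            merged.append((a, b))
    return merged


def read_wfdb(record_path, channel: int | str = 0,
              va_symbols=DEFAULT_VA_SYMBOLS) -> ECGRecord:
    """Read a WFDB record (``.hea`` + ``.dat`` [+ ``.atr``]) into an
    :class:`ECGRecord` with the configured channel extracted.

    ``channel`` is a 0-based index or a signal-description string.
    """
    base, _ = os.path.splitext(str(record_path))
    name, fs, _, signals = _parse_header(base + ".hea")
    if isinstance(channel, str) and not channel.isdigit():
        matches = [i for i, s in enumerate(signals)
                   if s.description == channel]
        if not matches:
            raise ValueError(
                f"channel {channel!r} not found in {base}.hea; available: "
                f"{[s.description for s in signals]}")
        ch = matches[0]
    else:
        ch = int(channel)
        if ch >= len(signals):
            raise ValueError(f"channel index {ch} out of range "
                             f"({len(signals)} signals)")
    dat_files = {s.file_name for s in signals}
    if len(dat_files) != 1:
        raise ValueError("multi-file WFDB records are not supported")
    adc = _read_dat(base + ".dat", signals[0].fmt, len(signals))
    sig = signals[ch]
    physical = (adc[:, ch] - sig.baseline) / sig.gain

    intervals: list[tuple[int, int]] = []
    if os.path.exists(base + ".atr"):
        ann = read_annotations(base + ".atr")
        intervals = intervals_from_annotations(ann, len(physical), va_symbols)
    return ECGRecord(subject_id=name, signal=physical, fs=fs,
                     va_intervals=intervals, source_channel=str(channel))


# ---------------------------------------------------------------------------
# writer (format 16), used by the synthetic cohort exporter and round-trips
# ---------------------------------------------------------------------------

def write_annotations(atr_path, annotations):
    """Write (sample, symbol, aux) triples as an MIT annotation file."""
    words = bytearray()
    prev = 0
    for sample, symbol, aux in annotations:
        delta = sample - prev
        prev = sample
        code = _CODE_FOR_SYMBOL[symbol]
        if delta > 1023 or delta < 0:
            words += struct.pack("<H", _SKIP << 10)
            words += struct.pack("<i", delta)[2:] + struct.pack("<i", delta)[:2]
            delta = 0
        words += struct.pack("<H", (code << 10) | delta)
        if aux:
            raw = aux.encode("ascii")
            words += struct.pack("<H", (_AUX << 10) | len(raw))
            if len(raw) % 2:
                raw += b"\x00"
            words += raw
    words += struct.pack("<H", 0)
    with open(atr_path, "wb") as fh:
        fh.write(bytes(words))


def write_wfdb(record: ECGRecord, directory, gain: float = 200.0,
               va_label: str = "(VT"):
    """Write an ECGRecord as a single-channel format-16 WFDB record with
    rhythm-change annotations delimiting the VA intervals."""
    os.makedirs(directory, exist_ok=True)
    name = record.subject_id
    base = os.path.join(str(directory), name)
    adc = np.clip(np.round(record.signal * gain), -32768, 32767).astype("<i2")
    adc.tofile(base + ".dat")
    with open(base + ".hea", "w") as fh:
        fs = record.fs
        fs_str = f"{fs:g}"
        fh.write(f"{name} 1 {fs_str} {adc.size}\n")
        first = int(adc[0]) if adc.size else 0
        fh.write(f"{name}.dat 16 {gain:g}(0)/mV 16 0 {first} 0 0 ECG\n")
    ann = []
    for a, b in record.va_intervals:
        ann.append((a, "+", va_label))
        ann.append((b, "+", "(N"))
    write_annotations(base + ".atr", sorted(ann))
    return base
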