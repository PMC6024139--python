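"""File formats: EDF for EEG, CSV for logs and metadata.

EDF files are read through mne's native reader. Writing uses a minimal EDF
encoder (16-bit samples, physical units µV, 1-s data records), sufficient for
lossless round-trips within one quantization step.
"""

from __future__ import annotations

import datetime as _dt
from pathlib import Path

import numpy as np
import pandas as pd

from .records import (
    CHANNELS, FS, AnesthesiaLog, DrugEvent, DrugKind, EEGRecord, Group, Sex,
    SubjectMeta,
)

_UNITS = {
    DrugKind.PROPOFOL_RATE_SET: "mcg/kg/min",
    DrugKind.PROPOFOL_BOLUS: "mg/kg",
    DrugKind.MIDAZOLAM: "mg/kg",
    DrugKind.FENTANYL: "mcg/kg",
    DrugKind.INHALED_ON: "",
    DrugKind.INHALED_OFF: "",
}


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii")[:width]
    return b + b" " * (width - len(b))


def write_edf(record: EEGRecord, path: str | Path) -> None:
    """Write a 4-channel record as EDF (16-bit, physical units µV)."""
    path = Path(path)
    fs = record.fs
    spr = int(round(fs))                      # samples per 1-s data record
    n_full = record.samples.shape[1] // spr
    data = record.samples[:, : n_full * spr]
    n_ch = len(record.channels)

    phys_max = float(np.max(np.abs(data))) * 1.0001 + 1e-6
    phys_min = -phys_max
    dig_max, dig_min = 32767, -32768

    now = _dt.datetime(2000, 1, 1)
    header = b"".join([
        _pad("0", 8),
        _pad(record.subject_id, 80),
        _pad("synthetic propofol EEG", 80),
        _pad(now.strftime("%d.%m.%y"), 8),
        _pad(now.strftime("%H.%M.%S"), 8),
        _pad(str(256 * (1 + n_ch)), 8),
        _pad("", 44),
        _pad(str(n_full), 8),
        _pad("1", 8),                          # record duration, s
        _pad(str(n_ch), 4),
    ])
    sig = b"".join([
        b"".join(_pad(f"EEG {ch}", 16) for ch in record.channels),
        b"".join(_pad("AgAgCl electrode", 80) for _ in record.channels),
        b"".join(_pad("uV", 8) for _ in record.channels),
        b"".join(_pad(f"{phys_min:.4f}"[:8], 8) for _ in record.channels),
        b"".join(_pad(f"{phys_max:.4f}"[:8], 8) for _ in record.channels),
        b"".join(_pad(str(dig_min), 8) for _ in record.channels),
        b"".join(_pad(str(dig_max), 8) for _ in record.channels),
        b"".join(_pad("", 80) for _ in record.channels),
        b"".join(_pad(str(spr), 8) for _ in record.channels),
        b"".join(_pad("", 32) for _ in record.channels),
    ])
    # re-derive the gain from the truncated header fields so that reading
    # back reproduces samples to within one digitization step
    pmin = float(f"{phys_min:.4f}"[:8])
    pmax = float(f"{phys_max:.4f}"[:8])
    gain = (pmax - pmin) / (dig_max - dig_min)
    digital = np.clip(np.round((data - pmin) / gain) + dig_min,
                      dig_min, dig_max).astype("<i2")
    with open(path, "wb") as fh:
        fh.write(header + sig)
        for r in range(n_full):
            fh.write(digital[:, r * spr:(r + 1) * spr].tobytes())


def read_edf(path: str | Path, subject_id: str | None = None) -> EEGRecord:
    """Read a 4-channel frontal EDF record; channel labels must match."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    labels = [ch.removeprefix("EEG ").strip() for ch in raw.ch_names]
    for want in CHANNELS:
        if want not in labels:
            raise ValueError(f"EDF missing channel {want}")
    order = [labels.index(want) for want in CHANNELS]
    data_uv = raw.get_data()[order] * 1e6
    fs = float(raw.info["sfreq"])
    if abs(fs - FS) > 1e-6:
        raise ValueError(f"expected {FS} Hz sampling, got {fs}")
    if subject_id is None:
        subject_id = raw.info.get("subject_info", {}).get("his_id") or Path(path).stem
    return EEGRecord(subject_id, data_uv, fs, CHANNELS)


def write_log_csv(log: AnesthesiaLog, path: str | Path) -> None:
    pd.DataFrame(
        [{"time_s": e.time, "kind": e.kind.value, "value": e.value,
          "units": _UNITS[e.kind]} for e in log.events]
    ).to_csv(path, index=False)


def read_log_csv(path: str | Path) -> AnesthesiaLog:
    df = pd.read_csv(path)
    for col in ("time_s", "kind", "value"):
        if col not in df.columns:
            raise ValueError(f"log CSV missing column {col}")
    if (df["value"] < 0).any():
        raise ValueError("negative dose/rate in log CSV")
    return AnesthesiaLog(
        [DrugEvent(float(r.time_s), DrugKind(r.kind), float(r.value))
         for r in df.itertuples()]
    )


def write_meta_csv(metas: list[SubjectMeta], path: str | Path) -> None:
    pd.DataFrame(
        [{"subject_id": m.subject_id, "group": m.group.value,
          "age_years": m.age, "sex": m.sex.value,
          "epilepsy": int(m.epilepsy), "weight_kg": m.weight}
         for m in metas]
    ).to_csv(path, index=False)


def read_meta_csv(path: str | Path) -> list[SubjectMeta]:
    df = pd.read_csv(path)
    need = {"subject_id", "group", "age_years", "sex", "epilepsy", "weight_kg"}
    if not need <= set(df.columns):
        raise ValueError(f"metadata CSV missing columns {need - set(df.columns)}")
    return [
        SubjectMeta(str(r.subject_id), Group(r.group), float(r.age_years),
                    Sex(r.sex), bool(r.epilepsy), float(r.weight_kg))
        for r in df.itertuples()
    ]
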