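"""Selection of the per-case 120-s analysis epoch.

An epoch qualifies when the propofol infusion rate is constant over the epoch
and the preceding 5 minutes, no other anesthetic drug (bolus, midazolam,
fentanyl) was given in that same lookback, the epoch starts ≥5 min after any
inhaled-agent discontinuation, and the EEG segment is free of large-amplitude
artifacts and suppression events. The earliest qualifying start is selected.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .records import AnesthesiaLog, DrugKind, EEGRecord, WASHOUT_KINDS
from .suppression import detect_suppression_events

EPOCH_S = 120.0
WASHOUT_S = 300.0

#: Automated stand-ins for visual artifact screening (configurable).
AMPLITUDE_CEILING_UV = 500.0
VARIANCE_RATIO_CEILING = 10.0


class RejectionReason(str, Enum):
    NONE = "none"
    DRUG_WITHIN_5MIN = "drug_within_5min"
    INHALED_WITHIN_5MIN = "inhaled_within_5min"
    ARTIFACT = "artifact"
    SUPPRESSION = "suppression"
    NO_STABLE_INFUSION = "no_stable_infusion"


@dataclass(frozen=True)
class EpochSelection:
    subject_id: str
    start: float
    duration: float
    qualifying: bool
    rejection_reason: RejectionReason

    def __post_init__(self) -> None:
        if self.duration != EPOCH_S:
            raise ValueError("epoch duration fixed at 120 s")
        if self.qualifying != (self.rejection_reason is RejectionReason.NONE):
            raise ValueError("qualifying flag inconsistent with reason")


def _log_rule_violation(
    log: AnesthesiaLog, start: float,
    epoch_s: float = EPOCH_S, washout_s: float = WASHOUT_S,
) -> RejectionReason:
    """First log rule violated by an epoch at ``start``, or NONE.

    Lookback intervals are open on the left: a drug given exactly 5 min before
    the epoch satisfies "at least 5 min prior".
    """
    lo, hi = start - washout_s, start + epoch_s
    rate_changes = [e for e in log.of_kind(DrugKind.PROPOFOL_RATE_SET)
                    if lo < e.time < hi]
    if rate_changes or log.infusion_rate_at(lo) is None:
        return RejectionReason.NO_STABLE_INFUSION
    if any(lo < e.time < hi for e in log.events if e.kind in WASHOUT_KINDS):
        return RejectionReason.DRUG_WITHIN_5MIN
    inhaled_off = log.of_kind(DrugKind.INHALED_OFF)
    if inhaled_off and start < max(e.time for e in inhaled_off) + washout_s:
        return RejectionReason.INHALED_WITHIN_5MIN
    if any(e.time >= lo for e in log.of_kind(DrugKind.INHALED_ON)):
        return RejectionReason.INHALED_WITHIN_5MIN
    return RejectionReason.NONE


def find_stable_epochs(
    log: AnesthesiaLog,
    record: EEGRecord,
    grid_s: float = 1.0,
    epoch_s: float = EPOCH_S,
    washout_s: float = WASHOUT_S,
) -> list[EpochSelection]:
    """Candidate epochs satisfying the drug-log rules, earliest first.

    Candidate starts are scanned on a ``grid_s`` grid plus the boundary starts
    implied by each event time (event + washout), so the earliest feasible
    start is found exactly even off-grid.
    """
    if not log.events:
        raise ValueError("empty anesthesia log")
    if any(e.time > record.duration for e in log.events):
        raise ValueError("log events beyond record duration")
    last_start = record.duration - epoch_s
    candidates = set(np.arange(0.0, last_start + 1e-9, grid_s))
    for e in log.events:
        t = e.time + washout_s
        if 0.0 <= t <= last_start:
            candidates.add(t)
    out = []
    for start in sorted(candidates):
        if _log_rule_violation(log, start, epoch_s, washout_s) is RejectionReason.NONE:
            out.append(EpochSelection(record.subject_id, float(start), epoch_s,
                                      True, RejectionReason.NONE))
    return out


def artifact_check(
    segment: EEGRecord,
    amplitude_ceiling_uv: float = AMPLITUDE_CEILING_UV,
    variance_ratio_ceiling: float = VARIANCE_RATIO_CEILING,
) -> tuple[bool, RejectionReason]:
    """Automated screen of a 120-s segment for artifacts and suppression.

    Fails when any sample exceeds the amplitude ceiling, any 1-s window's
    variance exceeds ``variance_ratio_ceiling``× the epoch's median 1-s
    variance, or the suppression detector reports any event.
    """
    x = segment.samples
    if np.abs(x).max() >= amplitude_ceiling_uv:
        return False, RejectionReason.ARTIFACT
    n_per_s = int(round(segment.fs))
    n_windows = x.shape[1] // n_per_s
    win = x[:, : n_windows * n_per_s].reshape(x.shape[0], n_windows, n_per_s)
    var = win.var(axis=2).mean(axis=0)
    if np.any(var > variance_ratio_ceiling * np.median(var)):
        return False, RejectionReason.ARTIFACT
    if detect_suppression_events(segment):
        return False, RejectionReason.SUPPRESSION
    return True, RejectionReason.NONE


def select_epoch(
    log: AnesthesiaLog, record: EEGRecord, **kwargs
) -> EpochSelection | None:
    """Earliest epoch passing both the log rules and the artifact screen."""
    for cand in find_stable_epochs(log, record, **kwargs):
        ok, reason = artifact_check(record.slice(cand.start, cand.duration))
        if ok:
            return cand
    return None
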