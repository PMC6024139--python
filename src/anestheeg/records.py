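"""Core domain records shared across the pipeline.

A subject is described by :class:`SubjectMeta`, their anesthetic history by an
:class:`AnesthesiaLog` of timestamped :class:`DrugEvent` entries, and the raw
signal by a 4-channel frontal :class:`EEGRecord` sampled at 250 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np

#: Frontal montage used throughout: prefrontal and lateral-frontal electrodes.
CHANNELS = ("Fp1", "Fp2", "F7", "F8")

#: Sampling rate of the acquisition system, Hz.
FS = 250.0


class Group(str, Enum):
    ASD = "ASD"
    NT = "NT"


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"


class DrugKind(str, Enum):
    PROPOFOL_RATE_SET = "propofol_rate_set"   # value: infusion rate, mcg/kg/min
    PROPOFOL_BOLUS = "propofol_bolus"         # value: dose, mg/kg
    MIDAZOLAM = "midazolam"                   # value: dose, mg/kg
    FENTANYL = "fentanyl"                     # value: dose, mcg/kg
    INHALED_ON = "inhaled_on"                 # value unused (0)
    INHALED_OFF = "inhaled_off"               # value unused (0)


#: Drug kinds that reset the 5-minute washout clock for epoch selection.
WASHOUT_KINDS = frozenset(
    {DrugKind.PROPOFOL_BOLUS, DrugKind.MIDAZOLAM, DrugKind.FENTANYL}
)


@dataclass(frozen=True)
class SubjectMeta:
    """Demographics and comorbidity for one subject.

    Ages are in years and restricted to the study range [2, 30]; weight in kg.
    """

    subject_id: str
    group: Group
    age: float
    sex: Sex
    epilepsy: bool
    weight: float

    def __post_init__(self) -> None:
        if not (2.0 <= self.age <= 30.0):
            raise ValueError(f"age {self.age} outside study range [2, 30]")
        if self.weight <= 0:
            raise ValueError("weight must be positive")


@dataclass(frozen=True, order=True)
class DrugEvent:
    """One timestamped entry of the anesthesia record.

    ``time`` is seconds from the start of the EEG record; ``value`` carries the
    infusion rate (mcg/kg/min) for rate changes, the per-kg dose for boluses
    (mg/kg for propofol/midazolam, mcg/kg for fentanyl), and 0 for inhaled-agent
    on/off markers.
    """

    time: float
    kind: DrugKind = field(compare=False)
    value: float = field(compare=False, default=0.0)

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError(f"negative dose/rate at t={self.time}")


@dataclass
class AnesthesiaLog:
    """Ordered drug events for one case; times nondecreasing."""

    events: list[DrugEvent]

    def __post_init__(self) -> None:
        times = [e.time for e in self.events]
        if any(b < a for a, b in zip(times, times[1:])):
            raise ValueError("log event times must be nondecreasing")

    def of_kind(self, *kinds: DrugKind) -> list[DrugEvent]:
        want = set(kinds)
        return [e for e in self.events if e.kind in want]

    def infusion_rate_at(self, t: float) -> float | None:
        """Propofol infusion rate in effect at time ``t`` (None before any set)."""
        rate = None
        for e in self.events:
            if e.kind is DrugKind.PROPOFOL_RATE_SET and e.time <= t:
                rate = e.value
        return rate

    def shifted(self, offset: float) -> "AnesthesiaLog":
        return AnesthesiaLog(
            [replace(e, time=e.time + offset) for e in self.events]
        )


@dataclass
class EEGRecord:
    """A 4-channel frontal EEG time series in microvolts.

    ``samples`` has shape (4, n_samples); channel order follows ``channels``.
    """

    subject_id: str
    samples: np.ndarray
    fs: float = FS
    channels: tuple[str, ...] = CHANNELS

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[0] != len(self.channels):
            raise ValueError(
                f"samples must be ({len(self.channels)}, n); got {self.samples.shape}"
            )
        if len(self.channels) != 4:
            raise ValueError("exactly 4 channels expected")
        if not np.isfinite(self.samples).all():
            raise ValueError("non-finite samples")

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.samples.shape[1] / self.fs

    def slice(self, start: float, duration: float) -> "EEGRecord":
        """Extract [start, start+duration) as a new record (half-open, 0-based)."""
        i0 = int(round(start * self.fs))
        i1 = i0 + int(round(duration * self.fs))
        if i0 < 0 or i1 > self.samples.shape[1]:
            raise ValueError("slice outside record")
        return EEGRecord(self.subject_id, self.samples[:, i0:i1].copy(),
                         self.fs, self.channels)
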