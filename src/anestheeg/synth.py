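"""Synthetic cohort generation.

Produces subject metadata, anesthesia drug logs and 4-channel frontal EEG with
the statistical structure the downstream analysis assumes:

* cohort demographics and dosing drawn from the study's published group
  means/SDs/proportions (truncated normals and Bernoullis);
* EEG = 1/f (pink) background + narrowband slow (centered 0.5 Hz) and alpha
  (centered 10 Hz, ~2 Hz bandwidth) oscillations, calibrated per record so the
  multitaper band power of the clean analysis epoch hits an age- and
  group-dependent dB target;
* the dB targets follow cubic-in-age trajectories anchored at the published
  posterior-mean powers, peaking in the 6–8 year range and declining
  monotonically thereafter;
* burst-suppression episodes injected per case as Bernoulli draws at the
  group incidences (ASD 0.230, NT 0.122).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .records import (
    CHANNELS,
    FS,
    AnesthesiaLog,
    DrugEvent,
    DrugKind,
    EEGRecord,
    Group,
    Sex,
    SubjectMeta,
)
from .spectral import band_power, epoch_spectrum, multitaper_spectrum

#: Group incidences of burst suppression used for Bernoulli injection.
SUPPRESSION_RATES = {Group.ASD: 0.230, Group.NT: 0.122}

#: Center used for the trajectory cubics' centered-age coordinate, years.
TRAJECTORY_AGE_CENTER = 12.0

#: Ages over which the trajectories are defined; outside, targets are clamped.
TRAJECTORY_AGE_RANGE = (2.0, 23.0)

# Published cohort parameters: mean/SD pairs and proportions per group.
COHORT_PARAMS = {
    Group.ASD: dict(
        age=(10.88, 5.25), male_frac=0.857, epilepsy_frac=0.095,
        infusion=(239.88, 32.69), bolus=(1.34, 1.13),
        midazolam_p=0.20, midazolam_dose=0.05, fentanyl=(0.71, 0.62),
    ),
    Group.NT: dict(
        age=(13.29, 5.27), male_frac=0.555, epilepsy_frac=0.0,
        infusion=(256.11, 37.15), bolus=(2.03, 1.52),
        midazolam_p=0.04, midazolam_dose=0.05, fentanyl=(0.74, 0.58),
    ),
}


@dataclass(frozen=True)
class TrajectoryModel:
    """Cubic-in-centered-age dB power trajectory through fixed anchor points."""

    band: str
    group: Group
    anchor_points: tuple[tuple[float, float], ...]
    coeffs: tuple[float, float, float, float] = field(init=False)

    def __post_init__(self) -> None:
        pts = np.asarray(self.anchor_points, dtype=float)
        c = np.polyfit(pts[:, 0] - TRAJECTORY_AGE_CENTER, pts[:, 1], 3)
        object.__setattr__(self, "coeffs", tuple(c))
        for age, power in self.anchor_points:
            if abs(self(age) - power) > 0.01:
                raise ValueError("anchor not reproduced within 0.01 dB")

    def __call__(self, age: float) -> float:
        return float(np.polyval(self.coeffs, age - TRAJECTORY_AGE_CENTER))


# Anchors at the published posterior-mean powers (alpha: 5.42 y and 22.5 y;
# slow: 2.33, 10.8 and 22.5 y) plus interior anchors chosen once so each cubic
# peaks in the 6-8 y range implied by total-power development and declines
# monotonically afterwards.
TRAJECTORIES: dict[tuple[str, Group], TrajectoryModel] = {
    ("alpha", Group.NT): TrajectoryModel(
        "alpha", Group.NT,
        ((2.0, 18.08), (5.42, 18.86), (13.0, 17.80), (22.5, 11.89))),
    ("alpha", Group.ASD): TrajectoryModel(
        "alpha", Group.ASD,
        ((2.0, 16.39), (5.42, 17.65), (13.0, 15.43), (22.5, 6.37))),
    ("slow", Group.NT): TrajectoryModel(
        "slow", Group.NT,
        ((2.33, 14.20), (6.0, 17.03), (10.8, 18.99), (22.5, 13.95))),
    ("slow", Group.ASD): TrajectoryModel(
        "slow", Group.ASD,
        ((2.33, 17.05), (6.0, 17.35), (10.8, 16.93), (22.5, 11.56))),
}


def power_trajectory(
    age: float, group: Group | str, band: str, clamp: bool = False
) -> float:
    """Target band power (dB re µV²/Hz) for a subject of given age and group.

    Valid for ages 2–23; with ``clamp=True`` out-of-range ages are clamped to
    the boundary instead of raising (used for the secondary cohort's 23–30 y
    subjects, whose spectra are not analyzed for trajectories).
    """
    lo, hi = TRAJECTORY_AGE_RANGE
    if not lo <= age <= hi:
        if not clamp:
            raise ValueError(f"age {age} outside trajectory range [{lo}, {hi}]")
        age = min(max(age, lo), hi)
    return TRAJECTORIES[(band, Group(group))](age)


def _truncnorm(rng: np.random.Generator, mean: float, sd: float,
               lo: float, hi: float, size: int) -> np.ndarray:
    """Truncated normal by rejection; fine for the mild truncations used here."""
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.normal(mean, sd, size=2 * (size - filled))
        keep = draw[(draw >= lo) & (draw <= hi)][: size - filled]
        out[filled:filled + keep.size] = keep
        filled += keep.size
    return out


@dataclass
class SyntheticSubject:
    """One sampled subject: metadata, drug log, and injection bookkeeping."""

    meta: SubjectMeta
    log: AnesthesiaLog
    infusion_rate: float          # mcg/kg/min, the epoch's stable rate
    propofol_bolus: float         # mg/kg
    midazolam: float              # mg/kg
    fentanyl: float               # mcg/kg
    suppressed: bool              # Bernoulli draw at the group incidence


def sample_cohort(
    n_asd: int,
    n_nt: int,
    seed: int,
    age_range: tuple[float, float] = (2.0, 23.0),
    suppression: bool = True,
) -> list[SyntheticSubject]:
    """Sample a two-group cohort with the published baseline distributions.

    Ages are truncated normals on ``age_range`` with the published group
    means/SDs; sex, epilepsy and burst-suppression status are Bernoulli;
    dosing covariates are zero-truncated normals. Identical seeds yield
    identical cohorts.
    """
    if n_asd < 1 or n_nt < 1:
        raise ValueError("both group sizes must be >= 1")
    rng = np.random.default_rng(seed)
    subjects: list[SyntheticSubject] = []
    for group, n in ((Group.ASD, n_asd), (Group.NT, n_nt)):
        p = COHORT_PARAMS[group]
        ages = _truncnorm(rng, *p["age"], *age_range, n)
        males = rng.random(n) < p["male_frac"]
        epilepsy = rng.random(n) < p["epilepsy_frac"]
        infusion = _truncnorm(rng, *p["infusion"], 0.0, np.inf, n)
        bolus = _truncnorm(rng, *p["bolus"], 0.0, np.inf, n)
        mida = np.where(rng.random(n) < p["midazolam_p"],
                        rng.exponential(p["midazolam_dose"], n), 0.0)
        fenta = _truncnorm(rng, *p["fentanyl"], 0.0, np.inf, n)
        supp = rng.random(n) < (SUPPRESSION_RATES[group] if suppression else 0.0)
        for i in range(n):
            age = float(ages[i])
            weight = float(np.clip(min(2.0 * (age + 4.0), 60.0)
                                   + rng.normal(0.0, 3.0), 10.0, 100.0))
            meta = SubjectMeta(
                subject_id=f"{group.value}-{i:04d}",
                group=group,
                age=age,
                sex=Sex.MALE if males[i] else Sex.FEMALE,
                epilepsy=bool(epilepsy[i]),
                weight=weight,
            )
            log = _make_log(float(infusion[i]), float(bolus[i]),
                            float(mida[i]), float(fenta[i]))
            subjects.append(SyntheticSubject(
                meta=meta, log=log,
                infusion_rate=float(infusion[i]),
                propofol_bolus=float(bolus[i]),
                midazolam=float(mida[i]),
                fentanyl=float(fenta[i]),
                suppressed=bool(supp[i]),
            ))
    return subjects


def _make_log(infusion: float, bolus: float, midazolam: float,
              fentanyl: float, mask_induction: bool = False) -> AnesthesiaLog:
    """Induction drug sequence followed by a stable infusion.

    Fentanyl (and midazolam, if given) at induction only, one propofol bolus,
    one intermediate rate change, and the final stable rate at t=60 s — so the
    earliest log-qualifying 120-s epoch starts at t=360 s (5-min washout).
    """
    events = []
    if mask_induction:
        events += [DrugEvent(0.0, DrugKind.INHALED_ON),
                   DrugEvent(5.0, DrugKind.INHALED_OFF)]
    if midazolam > 0:
        events.append(DrugEvent(5.0, DrugKind.MIDAZOLAM, midazolam))
    if fentanyl > 0:
        events.append(DrugEvent(10.0, DrugKind.FENTANYL, fentanyl))
    if bolus > 0:
        events.append(DrugEvent(20.0, DrugKind.PROPOFOL_BOLUS, bolus))
    events.append(DrugEvent(30.0, DrugKind.PROPOFOL_RATE_SET,
                            max(infusion * 0.6, 1.0)))
    events.append(DrugEvent(60.0, DrugKind.PROPOFOL_RATE_SET, infusion))
    return AnesthesiaLog(events)


def _pink_noise(rng: np.random.Generator, n: int, fs: float,
                rms: float, f_lo: float = 2.0) -> np.ndarray:
    """1/f-power noise, flat below ``f_lo``, scaled to the requested RMS.

    Flattening below ``f_lo`` keeps the background's slow-band density several
    dB under the lowest trajectory target, so the calibrated oscillations
    always have headroom.
    """
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    shaping = 1.0 / np.sqrt(np.maximum(freqs, f_lo))
    shaping[0] = 0.0
    x = np.fft.irfft(spec * shaping, n=n)
    return x * (rms / np.std(x))


def _narrowband(rng: np.random.Generator, n: int, fs: float,
                lo: float, hi: float) -> np.ndarray:
    """Unit-RMS band-limited noise (4th-order zero-phase Butterworth)."""
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, rng.standard_normal(n))
    return x / np.std(x)


#: Default placement of the 120-s calibration/analysis epoch, seconds.
EPOCH_START = 360.0
EPOCH_DURATION = 120.0

#: Background pink-noise RMS (µV). High enough that the clean-EEG envelope in
#: the suppression detector's band stays well above its 5 µV threshold even
#: for the lowest-power (oldest ASD) subjects, while in-band background
#: density stays below every trajectory target.
BACKGROUND_RMS = 8.0


def synthesize_eeg(
    meta: SubjectMeta,
    duration: float = 600.0,
    suppression: list[tuple[float, float]] | None = None,
    seed: int = 0,
    log: AnesthesiaLog | None = None,
    slow_db: float | None = None,
    alpha_db: float | None = None,
) -> tuple[EEGRecord, AnesthesiaLog]:
    """Synthesize one case: stationary propofol-like EEG plus drug log.

    The slow and alpha components are narrowband noise scaled so that the
    channel-averaged multitaper band power of the clean analysis epoch
    (t = 360–480 s) matches the trajectory target (or explicit ``slow_db`` /
    ``alpha_db`` overrides) to well within ±1 dB. Channels share the
    oscillations and differ by independent background and sensor noise.
    ``suppression`` is an optional list of (start, duration) silences to
    inject after construction.
    """
    if duration < 600.0:
        raise ValueError("duration must be >= 600 s so a washed-out epoch exists")
    rng = np.random.default_rng(seed)
    n = int(round(duration * FS))
    if slow_db is None:
        slow_db = power_trajectory(meta.age, meta.group, "slow", clamp=True)
    if alpha_db is None:
        alpha_db = power_trajectory(meta.age, meta.group, "alpha", clamp=True)

    backgrounds = np.stack(
        [_pink_noise(rng, n, FS, BACKGROUND_RMS) for _ in CHANNELS]
    )
    slow_u = _narrowband(rng, n, FS, 0.1, 1.0)
    alpha_u = _narrowband(rng, n, FS, 9.0, 11.0)
    sensor = 0.5 * rng.standard_normal((len(CHANNELS), n))

    # Calibrate on the epoch the analysis will select: solve
    # amp^2 * P_component + P_background = P_target in linear band density.
    i0 = int(EPOCH_START * FS)
    i1 = i0 + int(EPOCH_DURATION * FS)
    bg_rec = EEGRecord(meta.subject_id, backgrounds[:, i0:i1] + sensor[:, i0:i1])
    bg_spec = epoch_spectrum(bg_rec)
    amps = {}
    for name, unit, target in (("slow", slow_u, slow_db),
                               ("alpha", alpha_u, alpha_db)):
        # channels share the oscillation, so one channel's spectrum suffices
        unit_spec = multitaper_spectrum(unit[i0:i1], FS)
        p_unit = 10.0 ** (band_power(unit_spec, name) / 10.0)
        p_bg = 10.0 ** (band_power(bg_spec, name) / 10.0)
        p_target = 10.0 ** (target / 10.0)
        amps[name] = np.sqrt(max(p_target - p_bg, 0.01 * p_target) / p_unit)

    samples = (backgrounds + sensor
               + amps["slow"] * slow_u[None, :]
               + amps["alpha"] * alpha_u[None, :])
    record = EEGRecord(meta.subject_id, samples)
    if suppression:
        record = inject_suppression(record, suppression)
    return record, (log if log is not None else _make_log(200.0, 2.0, 0.0, 1.0))


def inject_suppression(
    record: EEGRecord,
    events: list[tuple[float, float]],
    floor_uv: float = 2.0,
) -> EEGRecord:
    """Attenuate all channels during each (start, duration) event.

    Within an event the signal is scaled so its RMS sits safely below
    ``floor_uv`` (an isoelectric-like silence); outside events the record is
    unchanged. Events must lie within the record and not overlap.
    """
    ordered = sorted(events)
    for (s1, d1), (s2, _d2) in zip(ordered, ordered[1:]):
        if s1 + d1 > s2:
            raise ValueError("suppression events overlap")
    samples = record.samples.copy()
    n = samples.shape[1]
    for start, dur in ordered:
        if start < 0 or dur <= 0 or (start + dur) * record.fs > n:
            raise ValueError("event outside record")
        i0, i1 = int(round(start * record.fs)), int(round((start + dur) * record.fs))
        seg = samples[:, i0:i1]
        rms = max(float(np.sqrt(np.mean(seg ** 2))), 1e-9)
        samples[:, i0:i1] = seg * (0.25 * floor_uv / rms)
    return EEGRecord(record.subject_id, samples, record.fs, record.channels)


def sample_suppression_events(
    rng: np.random.Generator,
    record_duration: float,
    kind: str = "burst",
) -> list[tuple[float, float]]:
    """A suppression episode late in the case.

    ``burst``: 4 silences of 1.5–4 s spread over ~50 s (≥3 onsets within any
    60-s window, so the case grades positive); ``prolonged``: one ≥10 s
    silence.
    """
    t0 = record_duration - 90.0
    if kind == "prolonged":
        return [(t0 + float(rng.uniform(0, 20)), float(rng.uniform(10.5, 20)))]
    events, t = [], t0 + float(rng.uniform(0, 5))
    for _ in range(4):
        dur = float(rng.uniform(1.5, 4.0))
        events.append((t, dur))
        t += dur + float(rng.uniform(5.0, 10.0))
    return events
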