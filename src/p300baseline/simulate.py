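"""Seeded generator of oddball-paradigm EEG with ground truth.

The generator emulates the continuous-stimulation design the detection
pipeline is built for: nine stimuli flash pseudo-randomly at 400 ms intervals
with no immediate repeats, 100 presentations each, and a 10 s rest after
every 36 flashes.  The single synthetic channel is the sum of

* a narrowband background rhythm — a continuous-phase sinusoid whose phase
  performs a slow random walk (Wiener phase noise), giving a Lorentzian line
  of configurable width around the alpha peak.  Phase is continuous through
  the whole recording, so epoch-to-epoch phase follows the stimulus schedule
  instead of being redrawn per epoch: exactly the structured pre-stimulus
  activity that makes baseline correction hard under continuous stimulation.
* 1/f-shaped ("pink") broadband noise of configurable RMS;
* a Gaussian P300 bump after every attended (target) flash;
* optionally: a slow high-amplitude drift (period longer than the 200 ms
  baseline window — the regime that breaks range-averaged baselines),
  blink-like ±150 µV transients, and mains interference.

A clean photosensor channel pulses for the flash duration at every onset, and
a ground-truth sidecar records every injected bump so recovery can be checked.
Everything is reproducible from the seed.
"""

from __future__ import annotations

import json
import pathlib
from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import ParameterError
from .io import EEGRecording, EventList

_TWO_PI = 2.0 * np.pi
_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class SessionSpec:
    """Stimulus schedule of one recording session."""

    n_stimulus_types: int = 9
    isi_ms: float = 400.0
    flash_ms: float = 200.0
    presentations_per_stimulus: int = 100
    rest_every: int = 36
    rest_ms: float = 10000.0
    target_label: int = 3
    sampling_rate: float = 1000.0
    lead_in_ms: float = 2000.0
    lead_out_ms: float = 2000.0

    def __post_init__(self) -> None:
        if self.n_stimulus_types < 1:
            raise ParameterError("need at least one stimulus type")
        if not 1 <= self.target_label <= self.n_stimulus_types:
            raise ParameterError("target_label must be one of the stimulus ids")
        if not self.isi_ms >= self.flash_ms > 0:
            raise ParameterError("need isi_ms >= flash_ms > 0")
        if self.rest_every < 1 or self.rest_ms < 0:
            raise ParameterError("invalid rest configuration")
        if self.lead_in_ms < 0 or self.lead_out_ms < 0:
            raise ParameterError("lead times must be non-negative")

    @property
    def n_flashes(self) -> int:
        return self.n_stimulus_types * self.presentations_per_stimulus


@dataclass(frozen=True)
class NoiseModel:
    """Amplitude model of the synthetic channel (all amplitudes in µV).

    ``rhythm_bandwidth_hz`` is the Lorentzian full width of the background
    rhythm's spectral line; 2 Hz is a typical eyes-open alpha width and makes
    epochs 400 ms apart essentially phase-independent, so the rhythm cancels
    through averaging the way real alpha does.  ``p300_width_ms`` is the full
    width at half maximum of the Gaussian bump.
    """

    rhythm_freq_hz: float = 10.0
    rhythm_amp_uv: float = 8.0
    rhythm_bandwidth_hz: float = 2.0
    broadband_rms_uv: float = 8.0
    p300_amp_uv: float = 5.0
    p300_latency_ms: float = 330.0
    p300_width_ms: float = 80.0
    drift_amp_uv: float = 0.0
    drift_freq_hz: float = 2.0
    drift_bandwidth_hz: float = 0.1
    blink_rate_per_min: float = 0.0
    blink_amp_uv: float = 150.0
    blink_width_ms: float = 120.0
    line_freq_hz: float | None = None
    line_amp_uv: float = 1.0

    def __post_init__(self) -> None:
        for name in ("rhythm_amp_uv", "broadband_rms_uv", "p300_amp_uv",
                     "drift_amp_uv", "blink_rate_per_min", "blink_amp_uv",
                     "line_amp_uv"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if self.p300_amp_uv > 0:
            lo = self.p300_latency_ms - self.p300_width_ms
            hi = self.p300_latency_ms + self.p300_width_ms
            if lo < 0 or hi > 500:
                raise ParameterError(
                    "p300 bump support must lie inside the 0…+500 ms post extent"
                )


@dataclass
class GroundTruth:
    """What was injected: the answer key for recovery tests."""

    target_label: int
    p300_amp_uv: float
    p300_latency_ms: float
    bump_onset_samples: list[int]
    blink_samples: list[int]
    rhythm_amp_uv: float
    rhythm_freq_hz: float

    def to_dict(self) -> dict:
        return {
            "target_label": self.target_label,
            "p300_amp_uv": self.p300_amp_uv,
            "p300_latency_ms": self.p300_latency_ms,
            "bump_onset_samples": list(map(int, self.bump_onset_samples)),
            "blink_samples": list(map(int, self.blink_samples)),
            "rhythm_amp_uv": self.rhythm_amp_uv,
            "rhythm_freq_hz": self.rhythm_freq_hz,
        }

    def to_json(self, path: str | pathlib.Path | None = None, **kwargs) -> str:
        text = json.dumps(self.to_dict(), **kwargs)
        if path is not None:
            pathlib.Path(path).write_text(text)
        return text


# ---------------------------------------------------------------------------
# schedule


def _balanced_no_repeat_sequence(
    n_types: int, per_type: int, rng: np.random.Generator
) -> list[int]:
    """Random label order: each label exactly ``per_type`` times, no immediate repeats.

    Greedy draw weighted by remaining counts, forcing the dominant label
    whenever its remaining count exceeds half the remaining slots (the
    feasibility boundary), which guarantees completion when one exists.
    """
    total = n_types * per_type
    if per_type * 2 > total + 1:  # a single label would have to repeat
        raise ParameterError(
            f"no balanced no-repeat sequence exists for {n_types} labels "
            f"x {per_type} presentations"
        )
    counts = np.full(n_types, per_type, dtype=int)
    labels = np.arange(1, n_types + 1)
    seq: list[int] = []
    prev = -1
    for k in range(total):
        remaining = total - k
        forced = np.flatnonzero(2 * counts > remaining)
        if len(forced) and labels[forced[0]] != prev:
            choice = forced[0]
        else:
            cand = np.flatnonzero((counts > 0) & (labels != prev))
            if len(cand) == 0:
                raise ParameterError("stimulus schedule infeasible")  # pragma: no cover
            w = counts[cand] / counts[cand].sum()
            choice = rng.choice(cand, p=w)
        seq.append(int(labels[choice]))
        counts[choice] -= 1
        prev = labels[choice]
    return seq


def generate_schedule(
    spec: SessionSpec = SessionSpec(),
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> EventList:
    """Pseudo-random balanced oddball schedule with rests.

    Flash k starts at ``lead_in + k*isi + (k // rest_every)*rest_ms``; with
    defaults the first rest therefore begins 36 × 400 ms = 14 400 ms into the
    flash timeline, and nine consecutive flashes span 3.6 s.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    labels = _balanced_no_repeat_sequence(
        spec.n_stimulus_types, spec.presentations_per_stimulus, rng
    )
    k = np.arange(spec.n_flashes)
    t_ms = spec.lead_in_ms + k * spec.isi_ms + (k // spec.rest_every) * spec.rest_ms
    onsets = np.round(t_ms * spec.sampling_rate / 1000.0).astype(np.int64)
    return EventList(
        onsets=onsets,
        labels=np.array(labels),
        target_label=spec.target_label,
        n_stimulus_types=spec.n_stimulus_types,
    )


# ---------------------------------------------------------------------------
# signal components


def _narrowband(
    rng: np.random.Generator, n: int, fs: float, freq: float, amp: float, bandwidth: float
) -> np.ndarray:
    """Constant-amplitude oscillation with Wiener phase noise.

    The phase increment per sample is 2πf/fs plus Gaussian jitter whose
    variance rate D = 2π·bandwidth gives a Lorentzian line of FWHM
    ``bandwidth`` Hz.  Phase is continuous over the whole record.
    """
    if amp == 0:
        return np.zeros(n)
    dphi = _TWO_PI * freq / fs + rng.standard_normal(n) * np.sqrt(_TWO_PI * bandwidth / fs)
    phase = np.cumsum(dphi) + rng.uniform(0, _TWO_PI)
    return amp * np.sin(phase)


def _pink(rng: np.random.Generator, n: int, fs: float, rms: float) -> np.ndarray:
    """1/f-power broadband noise, flat below 1 Hz, normalised to ``rms`` µV."""
    if rms == 0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    spectrum = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shaping = 1.0 / np.sqrt(np.maximum(freqs, 1.0))
    shaping[0] = 0.0  # no DC
    x = np.fft.irfft(spectrum * shaping, n=n)
    return x * (rms / x.std())


def _gaussian_bump(n: int, center: float, sigma: float, amp: float) -> np.ndarray:
    """Additive Gaussian transient truncated at ±4σ (returned as index/value pairs)."""
    lo = max(0, int(np.floor(center - 4 * sigma)))
    hi = min(n, int(np.ceil(center + 4 * sigma)) + 1)
    k = np.arange(lo, hi)
    out = np.zeros(n)
    out[lo:hi] = amp * np.exp(-0.5 * ((k - center) / sigma) ** 2)
    return out


def generate_recording(
    events: EventList,
    noise: NoiseModel = NoiseModel(),
    *,
    sampling_rate: float = 1000.0,
    flash_ms: float = 200.0,
    lead_out_ms: float = 2000.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[EEGRecording, GroundTruth]:
    """Synthesize one channel of oddball EEG plus a clean photosensor.

    Returns the recording and a :class:`GroundTruth` sidecar listing every
    injected P300 bump and blink.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    fs = sampling_rate
    n = int(events.onsets[-1] + round(lead_out_ms * fs / 1000.0)) + 1
    if events.onsets[0] < 0 or events.onsets[-1] >= n:
        raise ParameterError("events do not fit in the recording duration")

    x = _narrowband(rng, n, fs, noise.rhythm_freq_hz, noise.rhythm_amp_uv,
                    noise.rhythm_bandwidth_hz)
    x += _pink(rng, n, fs, noise.broadband_rms_uv)
    if noise.drift_amp_uv > 0:
        x += _narrowband(rng, n, fs, noise.drift_freq_hz, noise.drift_amp_uv,
                         noise.drift_bandwidth_hz)
    if noise.line_freq_hz:
        t = np.arange(n) / fs
        x += noise.line_amp_uv * np.sin(_TWO_PI * noise.line_freq_hz * t + rng.uniform(0, _TWO_PI))

    sigma = noise.p300_width_ms * _FWHM_TO_SIGMA * fs / 1000.0
    lat = noise.p300_latency_ms * fs / 1000.0
    bump_onsets: list[int] = []
    if noise.p300_amp_uv > 0:
        for onset, label in events.events:
            if label == events.target_label:
                x += _gaussian_bump(n, onset + lat, sigma, noise.p300_amp_uv)
                bump_onsets.append(int(onset))

    blink_samples: list[int] = []
    if noise.blink_rate_per_min > 0:
        n_blinks = rng.poisson(noise.blink_rate_per_min * n / fs / 60.0)
        sigma_b = noise.blink_width_ms * _FWHM_TO_SIGMA * fs / 1000.0
        for c in np.sort(rng.uniform(0, n, size=n_blinks)):
            x += _gaussian_bump(n, c, sigma_b, noise.blink_amp_uv)
            blink_samples.append(int(c))

    photo = np.zeros(n)
    flash_samples = int(round(flash_ms * fs / 1000.0))
    for onset in events.onsets:
        photo[onset : min(n, onset + flash_samples)] = 5000.0

    rec = EEGRecording(
        channel_labels=["Cz"],
        sampling_rate=fs,
        data=x[None, :],
        photosensor=photo,
        meta="synthetic oddball session",
    )
    gt = GroundTruth(
        target_label=int(events.target_label),
        p300_amp_uv=noise.p300_amp_uv,
        p300_latency_ms=noise.p300_latency_ms,
        bump_onset_samples=bump_onsets,
        blink_samples=blink_samples,
        rhythm_amp_uv=noise.rhythm_amp_uv,
        rhythm_freq_hz=noise.rhythm_freq_hz,
    )
    return rec, gt


def generate_session(
    spec: SessionSpec = SessionSpec(),
    noise: NoiseModel = NoiseModel(),
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[EEGRecording, EventList, GroundTruth]:
    """Schedule + recording in one call, from a single seed."""
    rng = rng if rng is not None else np.random.default_rng(seed)
    events = generate_schedule(spec, rng=rng)
    rec, gt = generate_recording(
        events,
        noise,
        sampling_rate=spec.sampling_rate,
        flash_ms=spec.flash_ms,
        lead_out_ms=spec.lead_out_ms,
        rng=rng,
    )
    return rec, events, gt


def recover_bump(
    erp,
    noise: NoiseModel,
    label: int | None = None,
    search_ms: tuple[float, float] = (250.0, 450.0),
    baseline_range_ms: tuple[float, float] = (-200.0, 0.0),
) -> tuple[float, float]:
    """Least-squares fit of the injected Gaussian template to an averaged ERP.

    Returns ``(latency_ms, amplitude_uv)`` of the best-fitting bump of the
    known width.  The template fit recovers the injected amplitude without
    the upward bias of a max-over-window statistic (the maximum of signal
    plus noise exceeds the signal's peak in expectation) and its latency
    estimate is far less sensitive to narrowband residuals than a raw argmax.
    """
    from .preprocess import ms_to_samples  # local import: avoids a cycle at import time

    label = erp.target_label if label is None else label
    fs = erp.sampling_rate
    pre = erp.window.pre_samples(fs)
    w = erp.waveforms[label]
    i0 = pre + ms_to_samples(baseline_range_ms[0], fs)
    i1 = pre + ms_to_samples(baseline_range_ms[1], fs)
    c = w - w[i0:i1].mean()
    sigma = noise.p300_width_ms * _FWHM_TO_SIGMA * fs / 1000.0
    k = np.arange(len(c), dtype=float)
    taus = np.arange(
        pre + ms_to_samples(search_ms[0], fs),
        pre + ms_to_samples(search_ms[1], fs) + 1,
    )
    best = (-np.inf, 0.0, 0.0)
    for tau in taus:
        g = np.exp(-0.5 * ((k - tau) / sigma) ** 2)
        amp = float(g @ c) / float(g @ g)
        explained = amp * float(g @ c)
        if explained > best[0]:
            best = (explained, (tau - pre) * 1000.0 / fs, amp)
    return best[1], best[2]


# ---------------------------------------------------------------------------
# cohort


@dataclass
class SubjectRun:
    run_index: int
    target_label: int
    recording: EEGRecording
    events: EventList
    ground_truth: GroundTruth


@dataclass
class Subject:
    subject_id: int
    rhythm_amp_uv: float
    rhythm_freq_hz: float
    p300_latency_ms: float
    runs: list[SubjectRun]


def generate_cohort(
    n_subjects: int = 22,
    spec: SessionSpec = SessionSpec(),
    noise: NoiseModel = NoiseModel(),
    seed: int = 0,
    targets: tuple[int, ...] = (3, 5),
    rhythm_amp_range_uv: tuple[float, float] = (6.5, 9.5),
    rhythm_freq_range_hz: tuple[float, float] = (9.0, 11.0),
    latency_range_ms: tuple[float, float] = (315.0, 345.0),
) -> list[Subject]:
    """Independent subjects, each with one run per entry of ``targets``.

    Per-subject rhythm amplitude/frequency and P300 latency are drawn
    uniformly from the stated ranges; runs within a subject share those
    traits but have independent noise realisations.  Bit-identical given the
    same seed.
    """
    root = np.random.SeedSequence(seed)
    subjects: list[Subject] = []
    for sid, ss in enumerate(root.spawn(n_subjects), start=1):
        jitter_rng = np.random.default_rng(ss)
        amp = jitter_rng.uniform(*rhythm_amp_range_uv)
        freq = jitter_rng.uniform(*rhythm_freq_range_hz)
        lat = jitter_rng.uniform(*latency_range_ms)
        subj_noise = replace(
            noise, rhythm_amp_uv=amp, rhythm_freq_hz=freq, p300_latency_ms=lat
        )
        runs = []
        for ridx, (target, run_ss) in enumerate(zip(targets, ss.spawn(len(targets))), start=1):
            run_spec = replace(spec, target_label=int(target))
            rec, events, gt = generate_session(
                run_spec, subj_noise, rng=np.random.default_rng(run_ss)
            )
            runs.append(SubjectRun(ridx, int(target), rec, events, gt))
        subjects.append(Subject(sid, amp, freq, lat, runs))
    return subjects
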