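"""Synthetic participants, sessions, stories and embeddings with known ground truth.

The generator emulates the three study designs end to end so every analysis
stage is testable without a physical slider device or any downloaded data:

* a **participant** is a small set of latent parameters — a sigmoid
  comprehension-vs-speech-rate profile (asymptote, slope, center), a
  gamma-shaped motor delay kernel, motor noise, and a linear clock-drift rate
  for the device's microcontroller;
* a **trial** turns the participant's latent comprehension into a device log:
  the latent target (0 before stimulus onset, then the comprehension level,
  pushed down during high-surprisal passages) is convolved with the delay
  kernel, perturbed by motor noise, clipped to [0, 1], quantized to 8 bits,
  and timestamped on a drifting device clock at 250 Hz;
* a **session plan** reproduces the design arithmetic of the three
  experiments: 125 segments (25 per speed-up factor 1-5) with the observed
  mean durations; 10-minute blocks of 16 x 5 x 7.5-s chunks; and stories that
  alternate ~30-word low- and high-surprisal passages at speeds x1 and x2.5;
* **summaries** are sampled from segment words with inclusion weights that
  rise across word pentiles, emulating the recency bias seen in written
  recall;
* **TRF subjects** are traces generated exactly as known lag kernels
  convolved with the six annotation channels plus Gaussian noise, so kernel
  recovery has an objective ground truth.

Everything is deterministic given its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from . import trf as _trf
from .semantics import EmbeddingTable
from .slider import (
    RawSliderLog,
    SliderTrace,
    TrialRecord,
    expected_sample_count,
    median_score,
    to_trace,
)

SPEECH_RATES = (1, 2, 3, 4, 5)

#: Observed mean segment durations (s) per speed-up factor in the short-segment design.
SEGMENT_DURATION_MEAN_S: Mapping[int, float] = {1: 29.0, 2: 14.55, 3: 10.93, 4: 7.28, 5: 5.81}
SEGMENT_DURATION_SD_S: Mapping[int, float] = {1: 1.33, 2: 0.57, 3: 0.31, 4: 0.26, 5: 0.26}

#: ~195.76 words per minute at the original speed.
WORDS_PER_MINUTE_X1 = 195.76
MEAN_IWI_X1_S = 60.0 / WORDS_PER_MINUTE_X1

#: Surprisal targets (dimensionless language-model surprisal) for the
#: alternating low/high information-load passages.
SURPRISAL_MEAN_LOW = 4.91
SURPRISAL_MEAN_HIGH = 5.90
SURPRISAL_SD = 0.5


class ProfileValidationError(ValueError):
    """Raised when a participant-profile override violates an invariant."""


@dataclass(frozen=True)
class ParticipantProfile:
    """Latent parameters of one simulated participant.

    ``comp_max`` in (0, 1] is the asymptotic comprehension level, ``comp_slope``
    (> 0) the steepness of the decline and ``comp_center`` the speech rate at
    which comprehension halves.  ``delay_shape``/``delay_scale`` parameterize a
    gamma-density motor response kernel (seconds); ``motor_noise_sd`` is in
    normalized slider units; ``drift_ppm`` is the device clock's linear rate
    offset in parts per million (bounded at 500 ppm = 0.05%, the measured
    worst case over a trial).
    """

    participant_id: str
    comp_max: float
    comp_slope: float
    comp_center: float
    delay_shape: float
    delay_scale: float
    motor_noise_sd: float
    drift_ppm: float
    digit_span: int
    digit_in_noise: float
    rng_seed: int

    def __post_init__(self) -> None:
        checks = {
            "comp_max": 0 < self.comp_max <= 1,
            "comp_slope": self.comp_slope > 0,
            "comp_center": self.comp_center > 0,
            "delay_shape": self.delay_shape > 0,
            "delay_scale": self.delay_scale > 0,
            "motor_noise_sd": self.motor_noise_sd >= 0,
            "drift_ppm": 0 <= self.drift_ppm <= 500,
            "digit_span": 3 <= self.digit_span <= 9,
            "digit_in_noise": 0 <= self.digit_in_noise <= 100,
        }
        bad = [name for name, ok in checks.items() if not ok]
        if bad:
            raise ProfileValidationError(
                f"invalid profile field(s) {bad}: "
                + ", ".join(f"{b}={getattr(self, b)!r}" for b in bad)
            )

    @property
    def delay_peak_s(self) -> float:
        """Mode of the gamma delay kernel: (shape - 1) * scale for shape > 1."""
        return max(self.delay_shape - 1.0, 0.0) * self.delay_scale

    def delay_kernel(self, fs: float, tmax_s: float = 5.0) -> tuple[np.ndarray, np.ndarray]:
        """Discretized delay kernel on [0, tmax_s].

        Returns (lags_s, weights); the weights are gamma-density masses
        normalized so the kernel integrates to one, i.e. convolving a constant
        signal leaves its level unchanged.
        """
        lags = np.arange(int(round(tmax_s * fs)) + 1) / fs
        dens = stats.gamma.pdf(lags, a=self.delay_shape, scale=self.delay_scale)
        total = dens.sum()
        if total == 0:
            raise ProfileValidationError("delay kernel has no mass within the window")
        return lags, dens / total


def make_participant(seed: int, overrides: Mapping[str, object] | None = None) -> ParticipantProfile:
    """Draw a random participant profile, deterministic given the seed.

    Distributions span the between-subject variation seen in the slider
    cohorts: asymptotes 0.7-1.0, decline centered between rates 2.5 and 3.5,
    motor delays peaking around 0.5-1.5 s.
    """
    if seed < 0:
        raise ValueError("seed must be non-negative")
    rng = np.random.default_rng(seed)
    fields = {
        "participant_id": f"sub-{seed:04d}",
        "comp_max": float(rng.uniform(0.7, 1.0)),
        "comp_slope": float(rng.uniform(1.5, 3.0)),
        "comp_center": float(rng.uniform(2.5, 3.5)),
        "delay_shape": float(rng.uniform(2.5, 4.5)),
        "delay_scale": float(rng.uniform(0.25, 0.45)),
        "motor_noise_sd": 0.05,
        "drift_ppm": float(rng.uniform(50, 500)),
        "digit_span": int(rng.integers(3, 10)),
        "digit_in_noise": float(rng.uniform(50, 100)),
        "rng_seed": int(seed),
    }
    if overrides:
        fields.update(overrides)
    return ParticipantProfile(**fields)


def latent_comprehension(profile: ParticipantProfile, rate) -> float | np.ndarray:
    """Latent comprehension at a speech rate: a declining sigmoid.

    ``comp_max / (1 + exp(comp_slope * (rate - comp_center)))`` — the value is
    comp_max/2 at the center and falls toward 0 as the rate grows.
    """
    rate = np.asarray(rate, dtype=float)
    if np.any(rate <= 0):
        raise ValueError("speech rate must be positive")
    z = np.clip(profile.comp_slope * (rate - profile.comp_center), -700.0, 700.0)
    out = profile.comp_max / (1.0 + np.exp(z))
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Word events and stories
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WordEvent:
    """One word of a stimulus: string, onset (s), surprisal, and its passage."""

    word: str
    onset_s: float
    surprisal: float
    chunk_index: int = 0
    chunk_level: str = ""  # "low" / "high" for alternating-surprisal stories


def simulate_surprisal_story(
    n_chunks: int,
    words_per_chunk: int = 30,
    mean_low: float = SURPRISAL_MEAN_LOW,
    mean_high: float = SURPRISAL_MEAN_HIGH,
    rate: float = 1.0,
    seed: int = 0,
    jitter_words: bool = False,
    start_level: str = "low",
    lead_in_s: float = 0.0,
    chunk_gap_s: float = 0.0,
) -> list[WordEvent]:
    """A story alternating low- and high-surprisal passages of ~30 words.

    Word onsets are spaced by a jittered inter-word interval scaled by the
    speed-up factor (the same seed at rate 2.5 gives onsets exactly 2.5x
    compressed relative to rate 1).  Per-word surprisal is normal around the
    passage mean (sd 0.5), truncated at zero.  With ``jitter_words`` the
    passage lengths vary around ``words_per_chunk``; ``start_level``,
    ``lead_in_s`` (silence before the first word, in x1 audio seconds) and
    ``chunk_gap_s`` (maximum random pause between passages) produce richer,
    less periodic designs when wanted.
    """
    if n_chunks % 2 != 0:
        raise ValueError("n_chunks must be even so low/high passages alternate in pairs")
    if not mean_high > mean_low:
        raise ValueError("mean_high must exceed mean_low")
    if start_level not in ("low", "high"):
        raise ValueError("start_level must be 'low' or 'high'")
    rng = np.random.default_rng(seed)
    events: list[WordEvent] = []
    t = lead_in_s / rate
    w = 0
    for chunk in range(n_chunks):
        parity = 0 if start_level == "low" else 1
        level = "low" if chunk % 2 == parity else "high"
        if chunk > 0 and chunk_gap_s > 0:
            t += rng.uniform(0.0, chunk_gap_s) / rate
        mean = mean_low if level == "low" else mean_high
        n_words = words_per_chunk
        if jitter_words:
            n_words = int(rng.integers(max(2, words_per_chunk - 10), words_per_chunk + 11))
        a = (0.0 - mean) / SURPRISAL_SD
        surprisals = stats.truncnorm.rvs(
            a, np.inf, loc=mean, scale=SURPRISAL_SD, size=n_words, random_state=rng
        )
        # lognormal IWI with mean ~= the x1 inter-word interval, scaled by rate
        iwis = rng.lognormal(math.log(MEAN_IWI_X1_S), 0.25, size=n_words) / rate
        for surp, iwi in zip(surprisals, iwis):
            events.append(
                WordEvent(
                    word=f"w{w:04d}",
                    onset_s=round(t, 9),
                    surprisal=float(surp),
                    chunk_index=chunk,
                    chunk_level=level,
                )
            )
            t += iwi
            w += 1
    return events


def chunk_surprisal_means(events: Sequence[WordEvent]) -> tuple[float, float]:
    """Realized mean surprisal of the low and high passages of a story."""
    low = [e.surprisal for e in events if e.chunk_level == "low"]
    high = [e.surprisal for e in events if e.chunk_level == "high"]
    return float(np.mean(low)), float(np.mean(high))


# ---------------------------------------------------------------------------
# Trials and sessions
# ---------------------------------------------------------------------------

def simulate_trial(
    profile: ParticipantProfile,
    rate: float,
    duration_s: float,
    word_events: Sequence[WordEvent] = (),
    fs: float = 250.0,
    seed: int | None = None,
    surprisal_gain: float = 0.08,
    usb_jitter: bool = False,
) -> tuple[RawSliderLog, np.ndarray]:
    """One trial's device log plus the noiseless latent trace.

    The latent target starts at 0 (the device origin), steps to the
    participant's latent comprehension at stimulus onset and, when word events
    are given, is pushed down in proportion to the local surprisal excess over
    the stimulus mean (``surprisal_gain`` units of slider per surprisal unit).
    The target is convolved with the participant's delay kernel, perturbed by
    motor noise, clipped to [0, 1], quantized to 0..255 and logged with device
    timestamps scaled by (1 + drift_ppm * 1e-6).  ``usb_jitter`` adds i.i.d.
    uniform +-2 ms jitter to the host timestamps only.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if fs <= 0:
        raise ValueError("fs must be positive")
    rng = np.random.default_rng(profile.rng_seed if seed is None else seed)
    n = expected_sample_count(duration_s, fs)
    t = np.arange(n) / fs
    level = latent_comprehension(profile, rate)
    target = np.full(n, level)
    if word_events:
        onsets = np.array([e.onset_s for e in word_events])
        surps = np.array([e.surprisal for e in word_events])
        idx = np.clip(np.searchsorted(onsets, t, side="right") - 1, 0, len(surps) - 1)
        local = surps[idx]
        target = np.clip(level - surprisal_gain * (local - surps.mean()), 0.0, 1.0)
    _, kernel = profile.delay_kernel(fs)
    latent = np.convolve(target, kernel)[:n]
    noisy = latent + rng.normal(0.0, profile.motor_noise_sd, n)
    adc = np.rint(np.clip(noisy, 0.0, 1.0) * 255).astype(int)
    host = t.copy()
    if usb_jitter:
        host = host + rng.uniform(-0.002, 0.002, n)
    device_ms = t * (1.0 + profile.drift_ppm * 1e-6) * 1000.0
    log = RawSliderLog(device_time_ms=device_ms, host_time_s=host, value=adc)
    return log, latent


@dataclass(frozen=True)
class PlannedTrial:
    speech_rate: float
    duration_s: float
    has_summary: bool = False
    word_events: tuple[WordEvent, ...] = ()


@dataclass(frozen=True)
class SessionPlan:
    """Ordered trial list plus the design constants of one experiment."""

    experiment: str  # "exp1" | "exp2" | "exp3"
    trials: tuple[PlannedTrial, ...]
    chunk_s: float | None = None
    words_per_chunk: int | None = None

    def __post_init__(self) -> None:
        rates = [t.speech_rate for t in self.trials]
        if self.experiment == "exp1":
            for r in SPEECH_RATES:
                if rates.count(r) != 25:
                    raise ValueError(f"exp1 needs 25 trials at rate {r}, got {rates.count(r)}")
        elif self.experiment == "exp2":
            per_rate = {r: rates.count(r) for r in set(rates)}
            if len(set(per_rate.values())) != 1:
                raise ValueError("exp2 blocks need equal chunk counts per rate")


def exp1_plan(seed: int = 0, summary_fraction: float = 0.6) -> SessionPlan:
    """125 short segments: 25 per speed-up factor, randomly ordered, with the
    observed per-rate duration means; summaries required on 60% of trials."""
    rng = np.random.default_rng(seed)
    trials = []
    for r in SPEECH_RATES:
        durs = rng.normal(SEGMENT_DURATION_MEAN_S[r], SEGMENT_DURATION_SD_S[r], 25)
        trials += [PlannedTrial(speech_rate=r, duration_s=float(max(d, 1.0))) for d in durs]
    order = rng.permutation(len(trials))
    has_summary = rng.random(len(trials)) < summary_fraction
    trials = [replace(trials[i], has_summary=bool(h)) for i, h in zip(order, has_summary)]
    return SessionPlan(experiment="exp1", trials=tuple(trials))


def exp2_plan(n_blocks: int = 2, chunks_per_condition: int = 16, chunk_s: float = 7.5) -> SessionPlan:
    """Continuous-listening blocks: 16 chunks per rate per 10-minute block.

    Each 7.5-s chunk is one trial-equivalent; rates are pseudo-randomized with
    no immediate repetition of the same rate.
    """
    trials = []
    for block in range(n_blocks):
        seq: list[int] = []
        rng = np.random.default_rng(block)
        pool = [r for r in SPEECH_RATES for _ in range(chunks_per_condition)]
        while pool:
            options = [r for r in set(pool) if not seq or r != seq[-1]]
            if not options:  # dead end: restart the block shuffle
                seq, pool = [], [r for r in SPEECH_RATES for _ in range(chunks_per_condition)]
                continue
            pick = int(rng.choice(sorted(options)))
            pool.remove(pick)
            seq.append(pick)
        trials += [PlannedTrial(speech_rate=r, duration_s=chunk_s) for r in seq]
    return SessionPlan(experiment="exp2", trials=tuple(trials), chunk_s=chunk_s)


def exp3_plan(seed: int = 0, n_stories: int = 4, words_per_chunk: int = 30) -> SessionPlan:
    """Alternating-surprisal stories, each presented at x1 and x2.5."""
    rng = np.random.default_rng(seed)
    trials = []
    for story in range(n_stories):
        n_chunks = int(rng.choice([4, 6]))
        for rate in (1.0, 2.5):
            events = simulate_surprisal_story(
                n_chunks=n_chunks,
                words_per_chunk=words_per_chunk,
                rate=rate,
                seed=seed * 1000 + story,
            )
            duration = events[-1].onset_s + 3.0
            trials.append(
                PlannedTrial(speech_rate=rate, duration_s=duration, word_events=tuple(events))
            )
    order = rng.permutation(len(trials))
    return SessionPlan(
        experiment="exp3",
        trials=tuple(trials[i] for i in order),
        words_per_chunk=words_per_chunk,
    )


@dataclass
class SimulatedSession:
    """Generator output for one participant: logs, parsed records, ground truth."""

    profile: ParticipantProfile
    plan: SessionPlan
    records: list[TrialRecord]
    logs: dict[str, RawSliderLog]
    latents: dict[str, np.ndarray]
    segments: dict[str, list[str]]  # trial_id -> heard words (summary trials)

    def __len__(self) -> int:
        return len(self.records)


def simulate_session(
    plan: SessionPlan,
    profile: ParticipantProfile,
    fs: float = 250.0,
    recency_bias: float = 1.0,
    vocabulary_size: int = 300,
) -> SimulatedSession:
    """Run a full session: logs, parsed traces, post hoc scores and summaries.

    The 10-point rating is ``round(10 * median latent)``; the multiple-choice
    response is correct with probability ``0.25 + 0.75 * median latent``
    (chance mixing with comprehension, keeping accuracy above the 25% chance
    line even when comprehension collapses).  Summary trials draw a synthetic
    segment word list and sample a recency-biased summary from it.
    """
    root = np.random.default_rng(profile.rng_seed)
    seeds = root.spawn(len(plan.trials))
    vocab = [f"tok{i:04d}" for i in range(vocabulary_size)]
    records, logs, latents, segments = [], {}, {}, {}
    for i, (planned, ss) in enumerate(zip(plan.trials, seeds)):
        trial_id = f"{profile.participant_id}_t{i:03d}"
        trial_seed = int(ss.integers(0, 2**31 - 1))
        log, latent = simulate_trial(
            profile,
            planned.speech_rate,
            planned.duration_s,
            word_events=planned.word_events,
            fs=fs,
            seed=trial_seed,
        )
        trace = to_trace(
            log,
            fs=fs,
            condition=planned.speech_rate,
            participant_id=profile.participant_id,
            trial_id=trial_id,
        )
        rng = np.random.default_rng(trial_seed + 1)
        med = float(np.median(latent))
        summary_text = None
        if planned.has_summary:
            # same text at every rate: word count reflects the x1 duration
            n_words = max(int(round(planned.duration_s * planned.speech_rate
                                    / MEAN_IWI_X1_S)), 20)
            segment_words = list(rng.choice(vocab, size=n_words, replace=True))
            summary_words = simulate_summary(
                segment_words, med, recency_bias, seed=int(rng.integers(0, 2**31 - 1))
            )
            summary_text = " ".join(summary_words)
            segments[trial_id] = segment_words
        records.append(
            TrialRecord(
                trace=trace,
                speech_rate=planned.speech_rate,
                duration_s=trace.duration_s,
                participant_id=profile.participant_id,
                trial_id=trial_id,
                scale_10=int(round(10 * med)),
                mc_correct=int(rng.random() < 0.25 + 0.75 * med),
                summary_text=summary_text,
                digit_span=profile.digit_span,
                digit_in_noise=profile.digit_in_noise,
            )
        )
        logs[trial_id] = log
        latents[trial_id] = latent
    return SimulatedSession(
        profile=profile, plan=plan, records=records, logs=logs,
        latents=latents, segments=segments,
    )


def simulate_summary(
    segment_words: Sequence[str],
    comprehension: float,
    recency_bias: float = 1.0,
    seed: int = 0,
) -> list[str]:
    """Sample a written summary from the heard words.

    ``ceil(comprehension * len(segment))`` words are drawn without replacement
    with inclusion weights ``1 + recency_bias * pentile_index`` (pentiles 1-5
    across the segment), so later material is over-represented when
    ``recency_bias > 0``.  Sampled words keep their segment order.
    """
    if not segment_words:
        raise ValueError("segment must be non-empty")
    if not 0 <= comprehension <= 1:
        raise ValueError("comprehension must lie in [0, 1]")
    if recency_bias < 0:
        raise ValueError("recency_bias must be non-negative")
    k = math.ceil(comprehension * len(segment_words))
    if k == 0:
        return []
    n = len(segment_words)
    pentile = np.minimum((np.arange(n) * 5) // n, 4) + 1  # 1..5, earliest bins larger
    weights = 1.0 + recency_bias * pentile
    rng = np.random.default_rng(seed)
    chosen = rng.choice(n, size=k, replace=False, p=weights / weights.sum())
    return [segment_words[i] for i in sorted(chosen)]


def make_toy_embeddings(vocab: Sequence[str], dim: int = 16, seed: int = 0) -> EmbeddingTable:
    """Deterministic unit-norm random vectors, one per unique word."""
    if not vocab:
        raise ValueError("vocabulary must be non-empty")
    if dim < 2:
        raise ValueError("dim must be at least 2")
    rng = np.random.default_rng(seed)
    vectors = {}
    for word in sorted(set(vocab)):  # sorted: identical tables regardless of input order
        v = rng.standard_normal(dim)
        vectors[word] = v / np.linalg.norm(v)
    return EmbeddingTable(vectors)


# ---------------------------------------------------------------------------
# TRF ground-truth generator
# ---------------------------------------------------------------------------

#: Kernel amplitudes (slider units per impulse unit) used by the TRF generator.
#: Signs encode the expected behavior: low-surprisal passages push
#: comprehension up, high-surprisal passages and per-word surprisal push it
#: down, story onsets produce a rate-dependent positive deflection.  Because
#: every story onset is also a rate onset, the segment channel is exactly the
#: sum of the two rate channels and only the minimum-norm decomposition of
#: the onset response is identifiable; the ground truth is therefore stated
#: in that form (segment amplitude = sum of the rate amplitudes), so perfect
#: estimation would recover these values exactly.
TRF_TRUE_AMPLITUDES: Mapping[str, float] = {
    "low_surprisal_onset": 0.3,
    "high_surprisal_onset": -0.3,
    "word_surprisal": -0.03,
    "segment_onset": 0.85,
    "rate_x1_onset": 0.45,
    "rate_x2p5_onset": 0.4,
}


@dataclass
class TRFSubject:
    """A simulated continuous-listening subject with known TRF ground truth."""

    profile: ParticipantProfile
    trace: np.ndarray
    annotations: _trf.AnnotationSet
    window: _trf.LagWindow
    true_kernels: np.ndarray  # (6, n_lags), FEATURES order
    noise_sd: float

    def true_kernel(self, feature: str) -> np.ndarray:
        return self.true_kernels[_trf.FEATURES.index(feature)]


def simulate_trf_subject(
    seed: int,
    fs: float = 20.0,
    n_stories: int = 32,
    snr: float = 5.0,
    surprisal_effect: bool = True,
    amplitudes: Mapping[str, float] | None = None,
    tmin: float = -0.2,
    tmax: float = 5.0,
    drift_fraction: float = 0.5,
    drift_tau_s: float = 10.0,
) -> TRFSubject:
    """Generate one subject's concatenated trace as kernels (x) annotations + noise.

    Half the stories play at x1 and half at x2.5, with jittered passage
    lengths so the design is not periodic.  Every true feature kernel is the
    participant's gamma delay kernel scaled by its feature amplitude (zero at
    negative lags); the clean trace is built through the very same lagged
    design used for estimation, and noise is added to reach the requested
    signal-to-noise variance ratio.  The noise budget is split between white
    motor noise and a slow endogenous drift (an AR(1) wander with time
    constant ``drift_tau_s``, ``drift_fraction`` of the noise variance):
    real slider traces wander with attention and posture in ways no stimulus
    channel predicts, and that wander — not quantization white noise — is
    what limits held-out prediction accuracy.  With
    ``surprisal_effect=False`` the three surprisal-feature amplitudes are
    zero (the null generator for ablation checks).
    """
    if n_stories % 2 != 0:
        raise ValueError("n_stories must be even (half at each rate)")
    profile = make_participant(seed, overrides={"drift_ppm": 0.0})
    rng = np.random.default_rng(seed + 2**20)
    window = _trf.LagWindow(tmin=tmin, tmax=tmax, fs=fs)

    amps = dict(TRF_TRUE_AMPLITUDES if amplitudes is None else amplitudes)
    if not surprisal_effect:
        for name in _trf.SURPRISAL_FEATURES:
            amps[name] = 0.0

    rates = [1.0, 2.5] * (n_stories // 2)
    rng.shuffle(rates)
    pairs = []
    for story, rate in enumerate(rates):
        n_chunks = int(rng.choice([4, 6]))
        events = simulate_surprisal_story(
            n_chunks=n_chunks,
            words_per_chunk=30,
            rate=rate,
            seed=seed * 10000 + story,
            jitter_words=True,
            start_level=str(rng.choice(["low", "high"])),
            # lead-in longer than the lag window (in presented time), so the
            # story-onset response never overlaps the first passage onset
            lead_in_s=float(rng.uniform(tmax + 0.5, tmax + 3.0)) * rate,
            chunk_gap_s=2.0,
        )
        duration = events[-1].onset_s + 3.0
        n_samples = expected_sample_count(duration, fs)
        ann = _trf.build_annotation_vectors(events, n_samples, fs, rate=rate)
        pairs.append((np.zeros(n_samples), ann))
    _, ann_all = _trf.concatenate_sessions(pairs)

    # true kernels: shared gamma delay shape, per-feature amplitude, causal
    lags = window.lags_s
    shape = stats.gamma.pdf(np.clip(lags, 0.0, None), a=profile.delay_shape,
                            scale=profile.delay_scale)
    shape[lags < 0] = 0.0
    true_kernels = np.array([amps[f] * shape for f in _trf.FEATURES])

    design = _trf.build_lagged_design(ann_all, window)
    clean = 0.5 + design @ true_kernels.ravel()
    signal_sd = float(np.std(clean))
    noise_sd = signal_sd / math.sqrt(snr)
    n = len(clean)
    white = rng.normal(0.0, 1.0, n)
    phi = math.exp(-1.0 / (drift_tau_s * fs))  # AR(1) with time constant drift_tau_s
    drift = np.empty(n)
    drift[0] = rng.normal(0.0, 1.0)
    innov = rng.normal(0.0, math.sqrt(1.0 - phi**2), n)
    for i in range(1, n):
        drift[i] = phi * drift[i - 1] + innov[i]
    noise = (
        math.sqrt(drift_fraction) * drift + math.sqrt(1.0 - drift_fraction) * white
    ) * noise_sd
    trace = clean + noise
    return TRFSubject(
        profile=profile,
        trace=trace,
        annotations=ann_all,
        window=window,
        true_kernels=true_kernels,
        noise_sd=noise_sd,
    )


# ---------------------------------------------------------------------------
# Design arithmetic
# ---------------------------------------------------------------------------

def exp2_block_duration_min(
    chunks_per_condition: int = 16, n_conditions: int = 5, chunk_s: float = 7.5
) -> float:
    """Block length in minutes: (16 chunks x 5 rates x 7.5 s) / 60 = 10."""
    return chunks_per_condition * n_conditions * chunk_s / 60.0


def exp2_presentations_per_condition(n_blocks: int = 2, chunks_per_condition: int = 16) -> int:
    """Presentations of each rate across the session: 2 blocks x 16 = 32."""
    return n_blocks * chunks_per_condition


def compressed_clip_duration_s(chunk_s: float = 7.5, rate: float = 2.0) -> float:
    """Duration of one time-compressed clip inside a fixed-length chunk (x2 -> 3.75 s)."""
    return chunk_s / rate


def snr_db_from_rms_factor(factor: float = 1.5) -> float:
    """Speech-to-noise ratio in dB for a speech/noise RMS ratio (1.5 -> +3.5 dB)."""
    if factor <= 0:
        raise ValueError("RMS factor must be positive")
    return 20.0 * math.log10(factor)
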