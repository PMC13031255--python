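"""Slider-device log handling: parsing, clock-drift correction, traces, trial summaries.

The slider device streams 8-bit readings (0-255) at a nominal 250 Hz over USB.
Each row carries two timestamps: the microcontroller's own clock (which drifts
relative to the host by a small linear rate offset) and the host clock, which
is aligned with audio playback and therefore serves as the reference.  This
module turns those logs into uniform-rate, normalized comprehension traces and
computes the per-trial summaries used downstream (median score, initial-movement
cropping, pentile medians, movement-based outlier screening).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import IO, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

ADC_MAX = 255
DEFAULT_FS = 250.0

#: Per-rate initial-movement cutoffs (seconds): the time participants spend
#: moving the slider away from the 0 origin at trial start, removed before
#: time-course analyses.  Keyed by speed-up factor.
INITIAL_MOVEMENT_CUTOFFS_S: Mapping[int, float] = {1: 5.0, 2: 4.0, 3: 2.5, 4: 2.0, 5: 1.5}

LOG_COLUMNS = ("device_time_ms", "host_time_s", "value")


class SliderFormatError(ValueError):
    """Raised when a device log violates the log format contract."""


class InsufficientDataError(ValueError):
    """Raised when an operation receives fewer rows/participants than it needs."""


@dataclass(frozen=True)
class RawSliderLog:
    """Timestamp-paired 8-bit readings as emitted by the device.

    Attributes
    ----------
    device_time_ms : device-clock timestamps, milliseconds, strictly increasing.
    host_time_s : host-clock timestamps, seconds.
    value : integer ADC readings in 0..255.
    """

    device_time_ms: np.ndarray
    host_time_s: np.ndarray
    value: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.device_time_ms, dtype=float)
        h = np.asarray(self.host_time_s, dtype=float)
        v = np.asarray(self.value)
        if not (len(d) == len(h) == len(v)):
            raise SliderFormatError("log columns have unequal lengths")
        if len(d) and np.any(np.diff(d) <= 0):
            row = int(np.argmax(np.diff(d) <= 0)) + 1
            raise SliderFormatError(f"device_time_ms not strictly increasing at row {row}")
        if len(v) and (v.min() < 0 or v.max() > ADC_MAX):
            row = int(np.argmax((v < 0) | (v > ADC_MAX)))
            raise SliderFormatError(f"value outside 0..{ADC_MAX} at row {row}")
        object.__setattr__(self, "device_time_ms", d)
        object.__setattr__(self, "host_time_s", h)
        object.__setattr__(self, "value", np.asarray(v, dtype=int))

    def __len__(self) -> int:
        return len(self.value)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "device_time_ms": self.device_time_ms,
                "host_time_s": self.host_time_s,
                "value": self.value,
            }
        )

    def to_csv(self, path_or_buf) -> None:
        self.to_frame().to_csv(path_or_buf, index=False)


@dataclass
class SliderTrace:
    """Uniform-rate, normalized comprehension time series for one trial.

    ``values`` live in [0, 1] (ADC counts divided by 255) on a uniform grid at
    ``fs`` Hz starting at ``t0`` seconds on the host clock.
    """

    values: np.ndarray
    fs: float = DEFAULT_FS
    t0: float = 0.0
    condition: object = None
    participant_id: str = ""
    trial_id: str = ""
    quality: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("trace values must be one-dimensional")
        if len(self.values) and (self.values.min() < -1e-12 or self.values.max() > 1 + 1e-12):
            raise ValueError("trace values must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(len(self.values)) / self.fs

    @property
    def duration_s(self) -> float:
        return len(self.values) / self.fs

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t": self.times, "value": self.values})


@dataclass
class TrialRecord:
    """One trial: trace plus condition, covariates and post hoc scores."""

    trace: SliderTrace
    speech_rate: float
    duration_s: float
    participant_id: str = ""
    trial_id: str = ""
    scale_10: int | None = None
    mc_correct: int | None = None
    summary_text: str | None = None
    digit_span: int | None = None
    digit_in_noise: float | None = None

    def __post_init__(self) -> None:
        # duration must agree with the trace length to within one sample
        if abs(self.duration_s - self.trace.duration_s) > 1.0 / self.trace.fs + 1e-9:
            raise ValueError(
                f"duration_s={self.duration_s} inconsistent with trace length "
                f"{self.trace.duration_s:.4f}s at fs={self.trace.fs}"
            )


# ---------------------------------------------------------------------------
# Parsing and drift correction
# ---------------------------------------------------------------------------

def parse_slider_log(path_or_buf: str | IO) -> RawSliderLog:
    """Read a device-log CSV (columns device_time_ms, host_time_s, value).

    Raises :class:`SliderFormatError` (naming the offending row) on
    non-monotone device timestamps or out-of-range ADC values.
    """
    df = pd.read_csv(path_or_buf)
    missing = [c for c in LOG_COLUMNS if c not in df.columns]
    if missing:
        raise SliderFormatError(f"log is missing columns {missing}")
    return RawSliderLog(
        device_time_ms=df["device_time_ms"].to_numpy(float),
        host_time_s=df["host_time_s"].to_numpy(float),
        value=df["value"].to_numpy(),
    )


def estimate_clock_drift(log: RawSliderLog) -> tuple[float, float, float]:
    """Least-squares linear fit relating device and host clocks.

    Elapsed device time is regressed on elapsed host time, so that
    ``rate_ratio`` is the device clock rate expressed in host-clock units:
    a device running fast by 400 ppm yields ``rate_ratio`` = 1.0004, and
    ``abs(rate_ratio - 1)`` is the drift fraction.  ``offset`` (seconds,
    device scale) absorbs the clock origin difference.

    Returns
    -------
    (rate_ratio, offset_s, max_residual_s) where residuals are measured on the
    host-time scale after mapping device times through the fit.
    """
    if len(log) < 2:
        raise InsufficientDataError("clock-drift estimation needs at least 2 rows")
    host = log.host_time_s
    dev = log.device_time_ms / 1000.0
    rate_ratio, offset = np.polyfit(host, dev, 1)
    corrected = (dev - offset) / rate_ratio
    max_residual = float(np.max(np.abs(corrected - host)))
    return float(rate_ratio), float(offset), max_residual


def _round_half_up(x: float) -> int:
    # counteract binary representation error before the .5 tie-break
    return int(math.floor(round(x, 9) + 0.5))


def expected_sample_count(duration_s: float, fs: float = DEFAULT_FS) -> int:
    """Number of samples in a trial of the given duration: round-half-up(duration * fs)."""
    if duration_s < 0:
        raise ValueError("duration_s must be non-negative")
    return _round_half_up(duration_s * fs)


def to_trace(
    log: RawSliderLog,
    fs: float = DEFAULT_FS,
    correct_drift: bool = True,
    normalization: str = "device",
    hold: str = "previous",
    gap_fill_limit: int = 5,
    **trace_meta,
) -> SliderTrace:
    """Convert a raw log to a uniform-rate normalized trace.

    Timestamps are taken from the device clock mapped onto the host clock when
    ``correct_drift`` (the host clock is aligned with audio playback and is the
    reference), or from the host column directly otherwise.  Values are divided
    by 255 (``normalization='device'``) or min-max scaled within the trial
    (``normalization='trial'``).  Resampling onto the uniform grid uses
    zero-order hold by default — the slider reports a held physical position,
    not samples of a band-limited signal — with ``hold='linear'`` as an option.

    Gaps longer than ``gap_fill_limit`` sample periods are filled by the hold
    but flagged in ``trace.quality['gaps']``.
    """
    if len(log) == 0:
        raise InsufficientDataError("cannot build a trace from an empty log")
    if correct_drift and len(log) >= 2:
        rate_ratio, offset, _ = estimate_clock_drift(log)
        t = (log.device_time_ms / 1000.0 - offset) / rate_ratio
    else:
        t = log.host_time_s
    t = t - t[0]

    if normalization == "device":
        v = log.value / ADC_MAX
    elif normalization == "trial":
        lo, hi = log.value.min(), log.value.max()
        v = (log.value - lo) / (hi - lo) if hi > lo else np.zeros(len(log))
    else:
        raise ValueError(f"unknown normalization {normalization!r}")

    n = expected_sample_count(t[-1], fs) + 1
    grid = np.arange(n) / fs
    if hold == "previous":
        idx = np.searchsorted(t, grid + 1e-12, side="right") - 1
        out = v[np.clip(idx, 0, len(v) - 1)]
    elif hold == "linear":
        out = np.interp(grid, t, v)
    else:
        raise ValueError(f"unknown hold {hold!r}")

    gaps = []
    dt = np.diff(t)
    long_gaps = np.nonzero(dt > gap_fill_limit / fs)[0]
    for i in long_gaps:
        gaps.append((float(t[i]), float(t[i + 1])))
    quality = {"gaps": gaps, "n_raw": len(log)}
    return SliderTrace(values=out, fs=fs, t0=0.0, quality=quality, **trace_meta)


# ---------------------------------------------------------------------------
# Trial-level summaries
# ---------------------------------------------------------------------------

def median_score(trace: SliderTrace | np.ndarray) -> float:
    """Median of the trace samples: the single comprehension score for a trial."""
    values = trace.values if isinstance(trace, SliderTrace) else np.asarray(trace, float)
    if len(values) == 0:
        raise InsufficientDataError("median of an empty trace is undefined")
    return float(np.median(values))


def crop_initial_movement(
    trace: SliderTrace,
    rate: int | float,
    cutoffs_s: Mapping[int, float] | None = None,
) -> SliderTrace:
    """Drop the initial slider travel from the 0 origin.

    Cutoffs default to 5/4/2.5/2/1.5 s for speed-up factors 1..5 and can be
    overridden per experiment via ``cutoffs_s``.
    """
    cutoffs = INITIAL_MOVEMENT_CUTOFFS_S if cutoffs_s is None else cutoffs_s
    key = int(rate) if float(rate).is_integer() else rate
    if key not in cutoffs:
        raise KeyError(f"no initial-movement cutoff configured for rate {rate}")
    cutoff = cutoffs[key]
    n_drop = _round_half_up(cutoff * trace.fs)
    if n_drop >= len(trace):
        raise InsufficientDataError(
            f"trace of {trace.duration_s:.2f}s is shorter than the {cutoff}s cutoff"
        )
    return replace(
        trace,
        values=trace.values[n_drop:],
        t0=trace.t0 + n_drop / trace.fs,
        quality=dict(trace.quality, cropped_s=cutoff),
    )


def differential(trace: SliderTrace | np.ndarray) -> np.ndarray:
    """First differences of the trace (change between consecutive slider values)."""
    values = trace.values if isinstance(trace, SliderTrace) else np.asarray(trace, float)
    if len(values) < 2:
        raise InsufficientDataError("differential needs at least 2 samples")
    return np.diff(values)


def pentile_split(values: Sequence) -> list[np.ndarray]:
    """Split a sequence into five contiguous near-equal bins.

    Bin sizes differ by at most one, with the remainder going to the earliest
    bins (length 13 -> sizes 3, 3, 3, 2, 2).  The bins partition the input:
    concatenating them restores it exactly.
    """
    arr = np.asarray(values)
    if len(arr) < 5:
        raise InsufficientDataError("pentile split needs at least 5 elements")
    return list(np.array_split(arr, 5))


def pentile_trace_scores(trace: SliderTrace | np.ndarray) -> np.ndarray:
    """Median slider score within each pentile of the trace."""
    values = trace.values if isinstance(trace, SliderTrace) else np.asarray(trace, float)
    return np.array([np.median(b) for b in pentile_split(values)])


def trial_displacement(trace: SliderTrace | np.ndarray) -> float:
    """Total absolute slider displacement over a trial (sum of |first differences|)."""
    return float(np.sum(np.abs(differential(trace))))


def movement_outlier_check(
    records: Iterable[TrialRecord],
    n_sd: float = 3.5,
) -> pd.DataFrame:
    """Attention check: flag participants whose slider movement is extreme.

    The movement statistic is each participant's mean total absolute trace
    displacement per trial; participants beyond ``n_sd`` standard deviations
    from the group mean are flagged.  Returns a frame indexed by participant
    with columns ``movement`` and ``outlier``.
    """
    per_trial: dict[str, list[float]] = {}
    for rec in records:
        per_trial.setdefault(rec.participant_id, []).append(trial_displacement(rec.trace))
    if len(per_trial) < 2:
        raise InsufficientDataError("outlier screening needs at least 2 participants")
    stat = pd.Series({p: float(np.mean(v)) for p, v in per_trial.items()}, name="movement")
    mu, sd = stat.mean(), stat.std(ddof=1)
    if sd == 0:
        outlier = pd.Series(False, index=stat.index)
    else:
        outlier = (stat - mu).abs() > n_sd * sd
    return pd.DataFrame({"movement": stat, "outlier": outlier})
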