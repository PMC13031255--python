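"""Temporal response functions for continuous behavioral traces.

A temporal response function (TRF) is a set of lagged linear coefficients
mapping stimulus feature impulses to a continuous response signal.  Here the
response is the comprehension slider trace and the stimulus features are six
annotation channels: low- and high-surprisal passage onsets, word-by-word
surprisal impulses, segment onset, and the onsets of the two speech-rate
conditions.  The TRF is estimated by time-lagged ridge regression over a lag
window of -0.2 to +5 s (the small negative-lag band is retained as an
artifact-detection region: a true response cannot precede its stimulus, so
substantial negative-lag mass flags a modeling problem).

The module follows the estimator/results convention: build a
:class:`TemporalResponseModel` from a trace and an :class:`AnnotationSet`,
call :meth:`~TemporalResponseModel.fit` or
:meth:`~TemporalResponseModel.fit_cv`, and read coefficients, per-fold
Spearman accuracies and peak latencies off the returned :class:`TRFResults`.
Thin module-level functions (``build_lagged_design``, ``ridge_fit``,
``crossval_trf``, ``ablation_compare``) expose the same steps functionally.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.linalg
from scipy import stats

from .slider import SliderTrace

logger = logging.getLogger(__name__)

#: Fixed channel order of an annotation set.
FEATURES = (
    "low_surprisal_onset",
    "high_surprisal_onset",
    "word_surprisal",
    "segment_onset",
    "rate_x1_onset",
    "rate_x2p5_onset",
)
SURPRISAL_FEATURES = ("low_surprisal_onset", "high_surprisal_onset", "word_surprisal")


class DegenerateDataError(ValueError):
    """Raised when a trace or fold has no variation to fit or score against."""


@dataclass(frozen=True)
class LagWindow:
    """Lag window of the TRF kernel, -0.2 to +5 s by default."""

    tmin: float = -0.2
    tmax: float = 5.0
    fs: float = 250.0

    def __post_init__(self) -> None:
        if not self.tmin < self.tmax:
            raise ValueError("tmin must be < tmax")

    @property
    def n_lags(self) -> int:
        return int(round((self.tmax - self.tmin) * self.fs)) + 1

    @property
    def lag_samples(self) -> np.ndarray:
        return np.arange(int(round(self.tmin * self.fs)), int(round(self.tmax * self.fs)) + 1)

    @property
    def lags_s(self) -> np.ndarray:
        return self.lag_samples / self.fs


@dataclass
class AnnotationSet:
    """Six aligned stimulus-feature impulse channels at the trace rate.

    ``channels`` is a (6, n_samples) array in :data:`FEATURES` order.  Onset
    channels are 0/1 impulses; ``word_surprisal`` is zero except at word-onset
    samples, where it carries the word's surprisal (summed on the rare
    occasions two words round to the same sample).
    """

    channels: np.ndarray
    fs: float
    story_bounds: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        self.channels = np.atleast_2d(np.asarray(self.channels, dtype=float))
        if self.channels.shape[0] != len(FEATURES):
            raise ValueError(f"expected {len(FEATURES)} channels, got {self.channels.shape[0]}")
        if not self.story_bounds:
            self.story_bounds = (0, self.n_samples)

    @property
    def n_samples(self) -> int:
        return self.channels.shape[1]

    def channel(self, name: str) -> np.ndarray:
        return self.channels[FEATURES.index(name)]

    def drop(self, names: Iterable[str]) -> "AnnotationSet":
        """Zero out the named channels (ablation keeps the matrix shape fixed)."""
        out = self.channels.copy()
        for name in names:
            out[FEATURES.index(name)] = 0.0
        return replace(self, channels=out)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.channels.T, columns=list(FEATURES))


def build_annotation_vectors(
    events: Sequence,
    n_samples: int,
    fs: float,
    rate: float = 1.0,
    low_onsets_s: Sequence[float] | None = None,
    high_onsets_s: Sequence[float] | None = None,
) -> AnnotationSet:
    """Place feature impulses into six zero-initialized channels.

    ``events`` are word events with ``onset_s`` and ``surprisal`` attributes
    (and optionally ``chunk_level``/``chunk_index``, from which the low/high
    passage onsets are derived when not given explicitly: the passage onset is
    the onset of its first word).  ``segment_onset`` gets an impulse at sample
    0, and the speech-rate channel matching ``rate`` (1 or 2.5) gets an
    impulse at sample 0 while the other stays zero.
    """
    chan = np.zeros((len(FEATURES), n_samples))

    def _sample(t: float, what: str) -> int:
        s = int(round(t * fs))
        if not 0 <= s < n_samples:
            raise IndexError(f"{what} at {t:.3f}s falls outside the {n_samples / fs:.3f}s trace")
        return s

    word_idx = FEATURES.index("word_surprisal")
    collisions = 0
    for ev in events:
        s = _sample(ev.onset_s, f"word {getattr(ev, 'word', '?')!r}")
        if chan[word_idx, s] != 0.0:
            collisions += 1
        chan[word_idx, s] += ev.surprisal
    if collisions:
        logger.warning("%d word onsets rounded to an already-occupied sample; "
                       "surprisal values were summed", collisions)

    if low_onsets_s is None or high_onsets_s is None:
        lows, highs, seen = [], [], set()
        for ev in events:
            key = getattr(ev, "chunk_index", None)
            level = getattr(ev, "chunk_level", "")
            if key is None or key in seen or level not in ("low", "high"):
                continue
            seen.add(key)
            (lows if level == "low" else highs).append(ev.onset_s)
        low_onsets_s = lows if low_onsets_s is None else low_onsets_s
        high_onsets_s = highs if high_onsets_s is None else high_onsets_s
    for t in low_onsets_s:
        chan[FEATURES.index("low_surprisal_onset"), _sample(t, "low-surprisal onset")] = 1.0
    for t in high_onsets_s:
        chan[FEATURES.index("high_surprisal_onset"), _sample(t, "high-surprisal onset")] = 1.0

    chan[FEATURES.index("segment_onset"), 0] = 1.0
    if float(rate) == 1.0:
        chan[FEATURES.index("rate_x1_onset"), 0] = 1.0
    elif float(rate) == 2.5:
        chan[FEATURES.index("rate_x2p5_onset"), 0] = 1.0
    else:
        raise ValueError(f"rate must be 1 or 2.5 for the rate-onset channels, got {rate}")
    return AnnotationSet(channels=chan, fs=fs)


def concatenate_sessions(
    pairs: Sequence[tuple[SliderTrace | np.ndarray, AnnotationSet]],
) -> tuple[np.ndarray, AnnotationSet]:
    """Concatenate per-story traces and annotation sets in presentation order.

    Story-boundary sample indices are retained on the returned annotation set
    so cross-validation folds can respect story edges.
    """
    if not pairs:
        raise ValueError("nothing to concatenate")
    fs = pairs[0][1].fs
    traces, channels, bounds = [], [], [0]
    for trace, ann in pairs:
        y = trace.values if isinstance(trace, SliderTrace) else np.asarray(trace, float)
        if ann.fs != fs:
            raise ValueError(f"annotation fs {ann.fs} != {fs}")
        if len(y) != ann.n_samples:
            raise ValueError(f"trace length {len(y)} != annotation length {ann.n_samples}")
        traces.append(y)
        channels.append(ann.channels)
        bounds.append(bounds[-1] + len(y))
    out = AnnotationSet(
        channels=np.concatenate(channels, axis=1), fs=fs, story_bounds=tuple(bounds)
    )
    return np.concatenate(traces), out


def build_lagged_design(ann: AnnotationSet, window: LagWindow) -> np.ndarray:
    """Time-lagged design matrix, shape (n_samples, n_features * n_lags).

    Column (f, lag) holds channel f delayed by ``lag`` samples (zero-padded at
    the edges): row t of that column is ``channel[f][t - lag]``.  Lags run from
    ``tmin`` to ``tmax`` inclusive; at 250 Hz the default -0.2..+5 s window
    gives 1301 lags per feature.
    """
    if window.fs != ann.fs:
        raise ValueError(f"window fs {window.fs} != annotation fs {ann.fs}")
    n = ann.n_samples
    lags = window.lag_samples
    if len(lags) > n:
        raise ValueError("lag window longer than the signal")
    X = np.zeros((n, len(FEATURES) * len(lags)))
    for f in range(len(FEATURES)):
        x = ann.channels[f]
        for j, lag in enumerate(lags):
            col = X[:, f * len(lags) + j]
            if lag >= 0:
                col[lag:] = x[: n - lag] if lag else x
            else:
                col[:lag] = x[-lag:]
    return X


@dataclass
class TRFResults:
    """Fitted TRF: per-feature lag-coefficient matrix plus CV accuracy.

    ``coefficients`` has shape (6, n_lags) in :data:`FEATURES` order;
    ``cv_rho`` holds the per-fold Spearman correlations between predicted and
    observed held-out traces (empty when the kernel was fit without CV).
    """

    coefficients: np.ndarray
    intercept: float
    window: LagWindow
    cv_rho: list[float] = field(default_factory=list)
    k_used: int | None = None
    alpha: float = 1.0

    @property
    def mean_rho(self) -> float:
        return float(np.mean(self.cv_rho)) if self.cv_rho else float("nan")

    def kernel(self, feature: str) -> np.ndarray:
        return self.coefficients[FEATURES.index(feature)]

    def peak_latency(self, feature: str) -> float:
        return kernel_peak_latency(self, feature)

    def predict(self, ann: AnnotationSet) -> np.ndarray:
        X = build_lagged_design(ann, self.window)
        return self.intercept + X @ self.coefficients.ravel()

    def negative_lag_mass(self, feature: str) -> float:
        """Fraction of a kernel's absolute mass at negative lags (artifact band)."""
        k = np.abs(self.kernel(feature))
        if k.sum() == 0:
            return 0.0
        return float(k[self.window.lags_s < 0].sum() / k.sum())

    def to_frame(self) -> pd.DataFrame:
        lags = self.window.lags_s
        rows = [
            {"feature": f, "lag_s": float(lag), "coef": float(c)}
            for f, kern in zip(FEATURES, self.coefficients)
            for lag, c in zip(lags, kern)
        ]
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            "Temporal response function (ridge, alpha=%g)" % self.alpha,
            f"  window: {self.window.tmin:+.2f}..{self.window.tmax:+.2f} s "
            f"at {self.window.fs:g} Hz ({self.window.n_lags} lags/feature)",
        ]
        if self.cv_rho:
            lines.append(
                f"  CV Spearman rho: mean {self.mean_rho:.3f} over {self.k_used} folds "
                f"({', '.join(f'{r:.3f}' for r in self.cv_rho)})"
            )
        lines.append(f"  {'feature':<22} {'peak lag (s)':>12} {'peak coef':>10} {'neg-lag mass':>13}")
        for f in FEATURES:
            k = self.kernel(f)
            if np.any(k != 0):
                lines.append(
                    f"  {f:<22} {self.peak_latency(f):>12.3f} "
                    f"{k[np.argmax(np.abs(k))]:>10.4f} {self.negative_lag_mass(f):>13.3f}"
                )
            else:
                lines.append(f"  {f:<22} {'—':>12} {0.0:>10.4f} {'—':>13}")
        return "\n".join(lines)

    def plot(self, ax=None, features: Sequence[str] = FEATURES):
        """Plot per-feature kernels over lag (one line per feature)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for f in features:
            ax.plot(self.window.lags_s, self.kernel(f), label=f)
        ax.axvline(0.0, color="k", lw=0.5)
        ax.set_xlabel("lag (s)")
        ax.set_ylabel("TRF coefficient")
        ax.legend(fontsize="x-small")
        return ax


class TemporalResponseModel:
    """Time-lagged ridge regression from annotation impulses to a slider trace.

    Parameters
    ----------
    trace : the continuous response (SliderTrace or 1-D array).
    ann : AnnotationSet with six channels at the same sampling rate.
    window : lag window; defaults to -0.2..+5 s at the annotation rate.
    alpha : ridge penalty (identity penalty matrix, intercept unpenalized).
    """

    def __init__(
        self,
        trace: SliderTrace | np.ndarray,
        ann: AnnotationSet,
        window: LagWindow | None = None,
        alpha: float = 1.0,
    ):
        self.y = trace.values if isinstance(trace, SliderTrace) else np.asarray(trace, float)
        if len(self.y) != ann.n_samples:
            raise ValueError("trace and annotations have different lengths")
        if not np.all(np.isfinite(self.y)) or not np.all(np.isfinite(ann.channels)):
            raise ValueError("non-finite values in trace or annotations")
        self.ann = ann
        self.window = window or LagWindow(fs=ann.fs)
        self.alpha = float(alpha)
        self._X: np.ndarray | None = None

    @property
    def design(self) -> np.ndarray:
        if self._X is None:
            self._X = build_lagged_design(self.ann, self.window)
        return self._X

    def _solve(self, rows: np.ndarray | slice) -> tuple[np.ndarray, float]:
        # centered ridge: projecting out the mean of y AND of each column keeps
        # the unpenalized intercept from leaking a DC offset into the kernels
        X = self.design[rows]
        y = self.y[rows]
        ybar = float(np.mean(y))
        mu = X.mean(axis=0)
        Xc = X - mu
        G = Xc.T @ Xc
        G[np.diag_indices_from(G)] += self.alpha
        beta = scipy.linalg.solve(G, Xc.T @ (y - ybar), assume_a="pos")
        intercept = ybar - float(mu @ beta)
        return beta, intercept

    def fit(self) -> TRFResults:
        """Fit the kernel on all samples (no cross-validation)."""
        beta, intercept = self._solve(slice(None))
        return TRFResults(
            coefficients=beta.reshape(len(FEATURES), self.window.n_lags),
            intercept=intercept,
            window=self.window,
            alpha=self.alpha,
        )

    # -- cross-validation --------------------------------------------------

    def _fold_slices(self, k: int) -> list[tuple[int, int]]:
        """Contiguous-block folds aligned to story boundaries."""
        bounds = np.asarray(self.ann.story_bounds)
        n_stories = len(bounds) - 1
        if n_stories >= k:
            # assign contiguous groups of stories to folds, sizes differing <= 1
            story_groups = np.array_split(np.arange(n_stories), k)
            return [(int(bounds[g[0]]), int(bounds[g[-1] + 1])) for g in story_groups]
        # single story: contiguous sample blocks
        edges = np.linspace(0, len(self.y), k + 1).astype(int)
        return [(int(a), int(b)) for a, b in zip(edges[:-1], edges[1:])]

    def _fold_degenerate(self, folds: list[tuple[int, int]]) -> bool:
        """True when any fold lacks variation: a constant test trace, or an
        annotation channel that varies overall but is constant within the
        fold's training rows (globally flat channels — e.g. ablated ones —
        carry no information either way and are exempt)."""
        varies = np.ptp(self.ann.channels, axis=1) > 0
        for a, b in folds:
            if np.ptp(self.y[a:b]) == 0:
                return True
            train = np.concatenate([self.ann.channels[:, :a], self.ann.channels[:, b:]], axis=1)
            if train.shape[1] and np.any(np.ptp(train[varies], axis=1) == 0):
                return True
        return False

    def fit_cv(self, k: int = 3, seed: int | None = None) -> TRFResults:
        """k-fold cross-validated fit; final kernel refit on all data.

        Folds are contiguous blocks respecting story boundaries (shuffled
        sample-level folds would leak through the strong autocorrelation of
        slider traces, so they are never used).  If any fold lacks variation
        under k=3 — a constant held-out trace, or a regressor channel constant
        within a training fold — the model falls back to k=2.  Accuracy is the
        Spearman correlation (average ranks on ties) between predicted and
        observed held-out samples.  ``seed`` is accepted for interface
        uniformity; fold construction is deterministic.
        """
        if k not in (2, 3):
            raise ValueError("k must be 2 or 3")
        if np.ptp(self.y) == 0:
            raise DegenerateDataError("slider trace is constant; nothing to cross-validate")
        folds = self._fold_slices(k)
        if k == 3 and self._fold_degenerate(folds):
            logger.info("insufficient variation within a fold; falling back to 2-fold CV")
            k = 2
            folds = self._fold_slices(k)
        if self._fold_degenerate(folds):
            raise DegenerateDataError("folds lack variation even under 2-fold CV")

        n = len(self.y)
        rhos = []
        for a, b in folds:
            train = np.concatenate([np.arange(0, a), np.arange(b, n)])
            beta, intercept = self._solve(train)
            pred = intercept + self.design[a:b] @ beta
            rho = stats.spearmanr(pred, self.y[a:b]).statistic
            rhos.append(float(rho))
        final = self.fit()
        final.cv_rho = rhos
        final.k_used = k
        return final


# ---------------------------------------------------------------------------
# Functional wrappers and group-level comparisons
# ---------------------------------------------------------------------------

def ridge_fit(
    design: np.ndarray,
    y: np.ndarray,
    alpha: float = 1.0,
    window: LagWindow | None = None,
) -> TRFResults:
    """Ridge solution on an explicit lagged design matrix.

    Coefficients are ``(X'X + aI)^-1 X'(y - ybar)`` with intercept ``ybar``
    (the penalty never touches the intercept), solved by a positive-definite
    decomposition.
    """
    X = np.asarray(design, float)
    y = np.asarray(y, float)
    if X.shape[0] != len(y):
        raise ValueError("design rows and trace length differ")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in design or trace")
    ybar = float(np.mean(y))
    mu = X.mean(axis=0)
    Xc = X - mu
    G = Xc.T @ Xc
    G[np.diag_indices_from(G)] += alpha
    beta = scipy.linalg.solve(G, Xc.T @ (y - ybar), assume_a="pos")
    intercept = ybar - float(mu @ beta)
    n_feat = len(FEATURES) if X.shape[1] % len(FEATURES) == 0 else 1
    if window is None:
        window = LagWindow(tmin=0.0, tmax=float(X.shape[1] // n_feat - 1), fs=1.0)
    return TRFResults(
        coefficients=beta.reshape(n_feat, -1),
        intercept=intercept,
        window=window,
        alpha=alpha,
    )


def crossval_trf(
    trace: SliderTrace | np.ndarray,
    ann: AnnotationSet,
    window: LagWindow | None = None,
    alpha: float = 1.0,
    k: int = 3,
    seed: int | None = None,
) -> TRFResults:
    """Cross-validated TRF fit (see :meth:`TemporalResponseModel.fit_cv`)."""
    return TemporalResponseModel(trace, ann, window=window, alpha=alpha).fit_cv(k=k, seed=seed)


@dataclass
class AblationResult:
    """Per-subject accuracy with and without a feature subset, plus the group test."""

    rho_full: np.ndarray
    rho_reduced: np.ndarray
    dropped: tuple[str, ...]
    t_stat: float
    p_value: float

    @property
    def delta_rho(self) -> np.ndarray:
        return self.rho_full - self.rho_reduced

    @property
    def mean_delta(self) -> float:
        return float(np.mean(self.delta_rho))

    def summary(self) -> str:
        n = len(self.rho_full)
        return (
            f"Ablation of {', '.join(self.dropped)} over {n} subjects\n"
            f"  mean rho full    = {np.mean(self.rho_full):.3f}\n"
            f"  mean rho reduced = {np.mean(self.rho_reduced):.3f}\n"
            f"  mean delta rho   = {self.mean_delta:.3f}  "
            f"(one-sample t({n - 1}) = {self.t_stat:.2f}, p = {self.p_value:.4f})"
        )


def ablation_compare(
    subjects: Sequence[tuple[SliderTrace | np.ndarray, AnnotationSet]],
    window: LagWindow | None = None,
    alpha: float = 1.0,
    k: int = 3,
    features_to_drop: Sequence[str] = SURPRISAL_FEATURES,
) -> AblationResult:
    """Refit TRFs with a feature subset removed and test the accuracy drop.

    For each subject the full and reduced models are cross-validated on the
    same folds; the group-level one-sample t-test asks whether the mean
    per-subject difference in held-out Spearman rho differs from zero.
    Dropping an empty feature set gives a delta of exactly zero.
    """
    if len(subjects) < 2:
        raise ValueError("group ablation test needs at least 2 subjects")
    full, reduced = [], []
    for trace, ann in subjects:
        model = TemporalResponseModel(trace, ann, window=window, alpha=alpha)
        res_full = model.fit_cv(k=k)
        if features_to_drop:
            model_red = TemporalResponseModel(
                trace, ann.drop(features_to_drop), window=window, alpha=alpha
            )
            res_red = model_red.fit_cv(k=res_full.k_used)
            reduced.append(res_red.mean_rho)
        else:
            reduced.append(res_full.mean_rho)
        full.append(res_full.mean_rho)
    full_arr, red_arr = np.asarray(full), np.asarray(reduced)
    diffs = full_arr - red_arr
    if np.all(diffs == 0):
        t_stat, p = 0.0, 1.0
    else:
        t = stats.ttest_1samp(diffs, 0.0)
        t_stat, p = float(t.statistic), float(t.pvalue)
    return AblationResult(
        rho_full=full_arr,
        rho_reduced=red_arr,
        dropped=tuple(features_to_drop),
        t_stat=t_stat,
        p_value=p,
    )


def kernel_peak_latency(result: TRFResults, feature: str) -> float:
    """Lag (s) of the maximum absolute coefficient within [0, tmax].

    Ties resolve to the earlier lag; an all-zero kernel is an error rather
    than a spurious latency of 0.
    """
    if feature not in FEATURES:
        raise KeyError(f"unknown feature {feature!r}")
    kern = np.abs(result.kernel(feature))
    lags = result.window.lags_s
    mask = lags >= 0
    seg = kern[mask]
    if np.all(seg == 0):
        raise DegenerateDataError(f"kernel for {feature!r} is all zero; latency undefined")
    return float(lags[mask][np.argmax(seg)])
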