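"""Linear vs. sigmoidal models of comprehension decline with speech rate.

Median slider scores fall as speech is time-compressed.  Whether they fall
*linearly* (consistent with a purely sensory limit) or *sigmoidally*
(consistent with an information-integration bottleneck that holds up to a
point and then collapses) is decided by comparing

    linear:   y = b0 + b1 * x
    sigmoid:  y = b0 / (1 + exp(-b1 * (x - b2)))

under speech-rate-stratified k-fold cross-validation: both models are fit on
the training folds and scored by the Pearson correlation (and MSE) between
predicted and observed held-out medians; per-subject accuracies are compared
with a Wilcoxon signed-rank test.  In the sigmoid, b0 is the maximum
asymptote, b1 the growth rate (negative for a decline) and b2 the center,
where the main drop occurs.

The module follows the estimator/results convention: build a
:class:`ComprehensionDecline` model from (rate, score) data, call
:meth:`~ComprehensionDecline.fit` or :meth:`~ComprehensionDecline.fit_cv`,
and read parameters, fold metrics and a ``summary()`` table off the results.
Group statistics used alongside (paired t with Cohen's d, two-way ANOVA) and
the long-format analysis-table builder live here too.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .semantics import ScoredSummary
from .slider import TrialRecord, median_score

PARAM_NAMES = {"linear": ("b0", "b1"), "sigmoid": ("b0", "b1", "b2")}


class FitError(RuntimeError):
    """Raised when the nonlinear fit fails to converge after restarts."""


def sigmoid(x, b0, b1, b2):
    return b0 / (1.0 + np.exp(-b1 * (np.asarray(x, float) - b2)))


@dataclass
class RateFitResults:
    """Fitted comprehension-decline model with optional CV metrics.

    ``params`` is (b0, b1) for the linear model and (b0, b1, b2) for the
    sigmoid; ``param_se`` holds the asymptotic standard errors.  ``per_fold``
    carries (pearson_r, mse) pairs when the fit was cross-validated.
    """

    kind: str
    params: np.ndarray
    param_se: np.ndarray
    n_obs: int
    per_fold: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.params) != len(PARAM_NAMES[self.kind]):
            raise ValueError(f"{self.kind} model takes {len(PARAM_NAMES[self.kind])} parameters")

    @property
    def param_names(self) -> tuple[str, ...]:
        return PARAM_NAMES[self.kind]

    @property
    def mean_r(self) -> float:
        return float(np.mean([r for r, _ in self.per_fold])) if self.per_fold else float("nan")

    @property
    def mean_mse(self) -> float:
        return float(np.mean([m for _, m in self.per_fold])) if self.per_fold else float("nan")

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, float)
        if self.kind == "linear":
            return self.params[0] + self.params[1] * x
        return sigmoid(x, *self.params)

    def summary(self) -> str:
        lines = [f"Comprehension-decline model ({self.kind}), n = {self.n_obs}"]
        lines.append(f"  {'param':<6} {'estimate':>10} {'std err':>10}")
        for name, p, se in zip(self.param_names, self.params, self.param_se):
            lines.append(f"  {name:<6} {p:>10.4f} {se:>10.4f}")
        if self.per_fold:
            lines.append(
                f"  CV ({len(self.per_fold)} folds): mean r = {self.mean_r:.4f}, "
                f"mean MSE = {self.mean_mse:.4f}"
            )
        return "\n".join(lines)

    def plot(self, x=None, y=None, ax=None):
        """Plot the fitted curve (and the data when given)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if x is not None and y is not None:
            ax.scatter(x, y, s=8, alpha=0.4, label="trials")
            grid = np.linspace(np.min(x), np.max(x), 200)
        else:
            grid = np.linspace(1, 5, 200)
        ax.plot(grid, self.predict(grid), label=self.kind)
        ax.set_xlabel("speech rate (speed-up factor)")
        ax.set_ylabel("median slider score")
        ax.legend()
        return ax


class ComprehensionDecline:
    """Median comprehension score as a function of speech rate for one subject."""

    def __init__(self, rates: Sequence[float], scores: Sequence[float]):
        self.x = np.asarray(rates, float)
        self.y = np.asarray(scores, float)
        if len(self.x) != len(self.y):
            raise ValueError("rates and scores have different lengths")

    @classmethod
    def from_records(cls, records: Iterable[TrialRecord]) -> "ComprehensionDecline":
        recs = list(records)
        return cls(
            [r.speech_rate for r in recs],
            [median_score(r.trace) for r in recs],
        )

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, rate_col: str = "speech_rate",
        score_col: str = "median_slider_score",
    ) -> "ComprehensionDecline":
        return cls(df[rate_col].to_numpy(float), df[score_col].to_numpy(float))

    def fit(self, kind: str = "sigmoid", **kwargs) -> RateFitResults:
        if kind == "linear":
            return fit_linear(self.x, self.y)
        if kind == "sigmoid":
            return fit_sigmoid(self.x, self.y, **kwargs)
        raise ValueError(f"unknown model kind {kind!r}")

    def fit_cv(self, kind: str = "sigmoid", k: int = 5, seed: int = 0) -> RateFitResults:
        """Rate-stratified k-fold CV; the returned fit is on all data with
        per-fold held-out (pearson_r, mse) attached."""
        folds = stratified_folds(self.x, k=k, seed=seed)
        per_fold = []
        for test_idx in folds:
            train = np.setdiff1d(np.arange(len(self.x)), test_idx)
            res = ComprehensionDecline(self.x[train], self.y[train]).fit(kind)
            pred = res.predict(self.x[test_idx])
            r = stats.pearsonr(pred, self.y[test_idx]).statistic if np.ptp(pred) > 0 else 0.0
            per_fold.append((float(r), float(np.mean((pred - self.y[test_idx]) ** 2))))
        full = self.fit(kind)
        full.per_fold = per_fold
        return full


def fit_linear(x: Sequence[float], y: Sequence[float]) -> RateFitResults:
    """Ordinary least squares for y = b0 + b1 * x."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(np.unique(x)) < 2:
        raise np.linalg.LinAlgError("linear fit needs at least 2 distinct rates")
    X = np.column_stack([np.ones_like(x), x])
    beta, res_ss, *_ = np.linalg.lstsq(X, y, rcond=None)
    dof = max(len(x) - 2, 1)
    sigma2 = float(np.sum((y - X @ beta) ** 2)) / dof
    cov = sigma2 * np.linalg.inv(X.T @ X)
    return RateFitResults(
        kind="linear", params=beta, param_se=np.sqrt(np.diag(cov)), n_obs=len(x)
    )


def fit_sigmoid(
    x: Sequence[float],
    y: Sequence[float],
    init: Sequence[float] | None = None,
    bounds: tuple | None = None,
    n_restarts: int = 10,
    seed: int = 0,
) -> RateFitResults:
    """Nonlinear least squares for y = b0 / (1 + exp(-b1 (x - b2))).

    Default initialization is (max(y), -1, median(x)) — a declining curve
    centered mid-range — with bounds b0 in (0, 1.5], b2 within the observed
    rate range, b1 free within +-50.  On non-convergence, up to ``n_restarts``
    seeded random restarts are drawn within the bounds before a
    :class:`FitError` carrying the diagnostics is raised.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 4 or len(np.unique(x)) < 3:
        raise ValueError("sigmoid fit needs >= 4 points spanning >= 3 distinct rates")
    lo = np.array([1e-9, -50.0, float(np.min(x))])
    hi = np.array([1.5, 50.0, float(np.max(x))])
    if bounds is not None:
        lo, hi = np.asarray(bounds[0], float), np.asarray(bounds[1], float)
    p0 = np.array([max(float(np.max(y)), 1e-3), -1.0, float(np.median(x))])
    if init is not None:
        p0 = np.asarray(init, float)
    p0 = np.clip(p0, lo, hi)

    rng = np.random.default_rng(seed)
    attempts = [p0] + [rng.uniform(lo, hi) for _ in range(n_restarts)]
    errors = []
    for start in attempts:
        try:
            popt, pcov = optimize.curve_fit(
                sigmoid, x, y, p0=start, bounds=(lo, hi), maxfev=20000
            )
            se = np.sqrt(np.diag(pcov))
            return RateFitResults(kind="sigmoid", params=popt, param_se=se, n_obs=len(x))
        except (RuntimeError, optimize.OptimizeWarning) as exc:  # pragma: no cover
            errors.append(f"start {np.round(start, 3)}: {exc}")
    raise FitError(
        "sigmoid fit did not converge after "
        f"{len(attempts)} starts:\n  " + "\n  ".join(errors)
    )


def stratified_folds(rates: Sequence[float], k: int = 5, seed: int = 0) -> list[np.ndarray]:
    """k folds with an equal number of trials of each speech rate per fold.

    Within each rate, trial indices are shuffled by ``seed`` and dealt
    round-robin; any remainder also goes round-robin, so fold counts per rate
    differ by at most one.  Raises when some rate has fewer than k trials.
    """
    rates = np.asarray(rates)
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    for r in np.unique(rates):
        idx = np.nonzero(rates == r)[0]
        if len(idx) < k:
            raise ValueError(f"stratification impossible: only {len(idx)} trials at rate {r} < k={k}")
        idx = rng.permutation(idx)
        for j, i in enumerate(idx):
            folds[j % k].append(int(i))
    return [np.sort(np.array(f)) for f in folds]


@dataclass
class ModelComparisonResults:
    """Per-subject CV accuracies of both models plus the group Wilcoxon test."""

    per_subject_r: list[tuple[float, float]]  # (r_linear, r_sigmoid)
    wilcoxon_stat: float
    p_value: float
    winner: str | None

    @property
    def mean_r_linear(self) -> float:
        return float(np.mean([r for r, _ in self.per_subject_r]))

    @property
    def mean_r_sigmoid(self) -> float:
        return float(np.mean([r for _, r in self.per_subject_r]))

    def summary(self) -> str:
        n = len(self.per_subject_r)
        return (
            f"Linear vs. sigmoid over {n} subjects (rate-stratified CV)\n"
            f"  mean r linear  = {self.mean_r_linear:.4f}\n"
            f"  mean r sigmoid = {self.mean_r_sigmoid:.4f}\n"
            f"  Wilcoxon signed-rank (sigmoid > linear): W = {self.wilcoxon_stat:.1f}, "
            f"p = {self.p_value:.4f}\n"
            f"  winner: {self.winner or 'undecided'}"
        )


def _wilcoxon_onesided_greater(diffs: np.ndarray) -> tuple[float, float]:
    nz = diffs[diffs != 0]  # zero differences dropped (Wilcoxon's rule)
    if len(nz) == 0:
        return 0.0, 1.0
    method = "exact" if len(nz) <= 25 else "approx"
    try:
        res = stats.wilcoxon(nz, alternative="greater", zero_method="wilcox", method=method)
    except ValueError:  # ties prevent the exact distribution
        res = stats.wilcoxon(nz, alternative="greater", zero_method="wilcox", method="approx")
    return float(res.statistic), float(res.pvalue)


def crossval_compare(
    subjects: Sequence[tuple[Sequence[float], Sequence[float]]],
    k: int = 5,
    seed: int = 0,
    alpha_level: float = 0.05,
) -> ModelComparisonResults:
    """Fit both models per subject under rate-stratified k-fold CV and compare.

    Each subject contributes its across-fold mean Pearson r per model; the
    paired per-subject r values go into a one-sided Wilcoxon signed-rank test
    of the directional hypothesis r_sigmoid > r_linear (exact distribution up
    to n = 25 non-zero differences).  ``winner`` is the better model when
    either direction reaches ``alpha_level``, else None.
    """
    pairs = []
    for i, (x, y) in enumerate(subjects):
        model = ComprehensionDecline(x, y)
        r_lin = model.fit_cv("linear", k=k, seed=seed + i).mean_r
        r_sig = model.fit_cv("sigmoid", k=k, seed=seed + i).mean_r
        pairs.append((r_lin, r_sig))
    diffs = np.array([s - l for l, s in pairs])
    w_stat, p = _wilcoxon_onesided_greater(diffs)
    winner = None
    if p < alpha_level:
        winner = "sigmoid"
    else:
        _, p_rev = _wilcoxon_onesided_greater(-diffs)
        if p_rev < alpha_level:
            winner = "linear"
    return ModelComparisonResults(
        per_subject_r=pairs, wilcoxon_stat=w_stat, p_value=p, winner=winner
    )


# ---------------------------------------------------------------------------
# Simple group statistics
# ---------------------------------------------------------------------------

def paired_cohens_d(a: Sequence[float], b: Sequence[float]) -> tuple[float, int, float]:
    """Paired-samples t-test with Cohen's d on the differences.

    Returns (t, df, d) where d = mean(diff) / sd(diff) = t / sqrt(n).
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) != len(b) or len(a) < 2:
        raise ValueError("paired test needs two equal-length samples of n >= 2")
    diff = a - b
    sd = diff.std(ddof=1)
    if sd == 0:
        raise ZeroDivisionError("zero-variance differences: t undefined")
    n = len(diff)
    t = float(diff.mean() / (sd / np.sqrt(n)))
    return t, n - 1, t / np.sqrt(n)


def two_way_anova(
    values: Sequence[float],
    factor_a: Sequence,
    factor_b: Sequence,
    names: tuple[str, str] = ("speech_rate", "pentile"),
) -> pd.DataFrame:
    """Fixed-effects two-way ANOVA with interaction.

    Returns a frame indexed by effect (the two factors and their interaction)
    with columns F and p.  Empty design cells are an error; a constant
    response returns F = 0, p = 1 for every effect.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = pd.DataFrame({"value": np.asarray(values, float),
                       "a": list(factor_a), "b": list(factor_b)})
    if df["a"].nunique() < 2 or df["b"].nunique() < 2:
        raise ValueError("each factor needs at least 2 levels")
    cells = df.groupby(["a", "b"]).size().unstack()
    if cells.isna().any().any():
        raise ValueError("empty design cell(s); the two-way decomposition is undefined")
    index = [names[0], names[1], f"{names[0]}:{names[1]}"]
    if np.ptp(df["value"].to_numpy()) == 0:
        return pd.DataFrame({"F": [0.0] * 3, "p": [1.0] * 3}, index=index)
    model = smf.ols("value ~ C(a) * C(b)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    out = table.loc[["C(a)", "C(b)", "C(a):C(b)"], ["F", "PR(>F)"]]
    out.index = index
    out.columns = ["F", "p"]
    return out


# ---------------------------------------------------------------------------
# Analysis table
# ---------------------------------------------------------------------------

#: The mixed-effects specification the analysis table feeds; fitting such
#: models is routine statistics delegated to the user's preferred package.
MIXED_MODEL_FORMULA = (
    "median_slider_score ~ speech_rate + (1 | digit_span) + (1 | digit_in_noise)"
)


def _minmax(s: pd.Series) -> pd.Series:
    lo, hi = s.min(), s.max()
    if pd.isna(lo) or hi == lo:
        return s * 0.0
    return (s - lo) / (hi - lo)


def build_trial_table(
    records: Sequence[TrialRecord],
    scores: Sequence[ScoredSummary] = (),
) -> pd.DataFrame:
    """Long-format analysis table: one row per trial, all variables in 0-1.

    Slider medians are already 0-1; the 10-point rating divides by 10, the
    speech-rate factor and digit-span map through their design ranges, the
    digit-in-noise percentage divides by 100, and the semantic scores are
    min-max scaled over the observed trials.  Trials without a summary carry
    missing semantic scores (never zeros).
    """
    rows = []
    for rec in records:
        rows.append(
            {
                "trial_id": rec.trial_id,
                "participant_id": rec.participant_id,
                "speech_rate_raw": rec.speech_rate,
                "median_slider_score": median_score(rec.trace),
                "scale_10": np.nan if rec.scale_10 is None else rec.scale_10 / 10.0,
                "mc_correct": np.nan if rec.mc_correct is None else float(rec.mc_correct),
                "digit_span": np.nan if rec.digit_span is None else (rec.digit_span - 3) / 6.0,
                "digit_in_noise": (
                    np.nan if rec.digit_in_noise is None else rec.digit_in_noise / 100.0
                ),
            }
        )
    df = pd.DataFrame(rows)
    if df["trial_id"].duplicated().any():
        dupes = df.loc[df["trial_id"].duplicated(), "trial_id"].tolist()
        raise ValueError(f"duplicate trial keys: {dupes}")
    df["speech_rate"] = _minmax(df["speech_rate_raw"])
    if len(scores):
        sdf = pd.DataFrame(
            {
                "trial_id": [s.trial_id for s in scores],
                "written_summary_score": [s.written_summary_score for s in scores],
                "heard_segment_score": [s.heard_segment_score for s in scores],
                "contextual_score": [s.contextual_score for s in scores],
            }
        )
        if sdf["trial_id"].duplicated().any():
            raise ValueError("duplicate trial keys in semantic scores")
        df = df.merge(sdf, on="trial_id", how="left")
        for col in ("written_summary_score", "heard_segment_score", "contextual_score"):
            df[col] = _minmax(df[col])
    else:
        for col in ("written_summary_score", "heard_segment_score", "contextual_score"):
            df[col] = np.nan
    return df
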