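"""End-to-end orchestration: simulate -> preprocess -> score -> model -> report.

A :class:`RunConfig` (loadable from YAML) fixes the experiment, cohort size,
seeds and model options; :func:`run_pipeline` executes the stages in order,
writes every tabular artifact as CSV/JSON under the output directory, and
returns a :class:`RunReport` whose counts reconcile stage by stage and whose
file manifest carries SHA-256 checksums.  Runs are idempotent: the same
config and seed produce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import ratemodel, semantics, simulate, slider, trf

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Raised for invalid or incomplete run configuration."""


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    ``mc_accuracy_threshold`` (the multiple-choice exclusion cutoff) has no
    default on purpose: it is a study-level analysis decision and must be
    stated explicitly whenever the accuracy criterion is applied.
    """

    experiment: str = "exp1"
    participants: int = 3
    seed: int = 0
    fs: float = 250.0
    out_dir: str = "compslide_run"
    embeddings: str = "toy"  # "toy" or a word2vec text file path
    crop: bool = False
    crop_cutoffs_s: Mapping[int, float] | None = None
    k_folds: int = 5
    trf_alpha: float = 1.0
    trf_k: int = 3
    trf_tmin: float = -0.2
    trf_tmax: float = 5.0
    mc_accuracy_threshold: float | None = None
    movement_sd: float = 3.5
    write_logs: bool = True
    recency_bias: float = 1.0

    def __post_init__(self) -> None:
        if self.experiment not in ("exp1", "exp2", "exp3"):
            raise ConfigError(f"unknown experiment {self.experiment!r}")
        if self.participants < 1:
            raise ConfigError("participants must be >= 1")
        if self.crop_cutoffs_s is not None and any(v <= 0 for v in self.crop_cutoffs_s.values()):
            raise ConfigError("crop cutoffs must be positive")
        if self.embeddings != "toy" and not Path(self.embeddings).exists():
            raise ConfigError(f"embeddings path {self.embeddings!r} does not exist")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


@dataclass
class StageCount:
    stage: str
    n_in: int
    n_retained: int
    n_excluded: int


@dataclass
class RunReport:
    """Machine-readable record of a pipeline run."""

    config: dict
    stages: list[StageCount] = field(default_factory=list)
    exclusions: list[dict] = field(default_factory=list)
    fitted: dict = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)

    def add_stage(self, stage: str, n_in: int, n_retained: int) -> None:
        self.stages.append(StageCount(stage, n_in, n_retained, n_in - n_retained))

    def to_json(self) -> str:
        payload = {
            "config": self.config,
            "stages": [asdict(s) for s in self.stages],
            "exclusions": self.exclusions,
            "fitted": self.fitted,
            "manifest": self.manifest,
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def exclusion_report(
    records: Sequence[slider.TrialRecord],
    criteria: Mapping[str, Mapping],
) -> tuple[pd.DataFrame, list[str]]:
    """Apply named participant-exclusion criteria.

    Supported criteria: ``mc_accuracy`` (params: ``threshold`` — mean
    multiple-choice accuracy must reach it) and ``movement`` (params:
    ``n_sd`` — mean per-trial slider displacement must stay within n_sd group
    standard deviations of the group mean).  Returns the per-participant
    pass/fail table (with the statistic values) and the retained participant
    list.
    """
    frame = pd.DataFrame(
        {
            "participant_id": [r.participant_id for r in records],
            "mc_correct": [r.mc_correct for r in records],
        }
    )
    participants = sorted(frame["participant_id"].unique())
    out = pd.DataFrame(index=pd.Index(participants, name="participant_id"))
    excluded = pd.Series(False, index=out.index)
    for name, params in criteria.items():
        if name == "mc_accuracy":
            if "threshold" not in params:
                raise ConfigError("mc_accuracy criterion requires an explicit 'threshold'")
            acc = frame.dropna(subset=["mc_correct"]).groupby("participant_id")["mc_correct"].mean()
            out["mc_accuracy"] = acc
            out["fail_mc_accuracy"] = acc < float(params["threshold"])
            excluded |= out["fail_mc_accuracy"]
        elif name == "movement":
            mv = slider.movement_outlier_check(records, n_sd=float(params.get("n_sd", 3.5)))
            out["movement"] = mv["movement"]
            out["fail_movement"] = mv["outlier"]
            excluded |= out["fail_movement"]
        else:
            raise ConfigError(f"unknown exclusion criterion {name!r}")
    out["excluded"] = excluded
    retained = [p for p in participants if not excluded.loc[p]]
    return out, retained


def _write(df_or_text, path: Path, report: RunReport) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(df_or_text, pd.DataFrame):
        df_or_text.to_csv(path, index=False)
    else:
        path.write_text(df_or_text)
    report.manifest[str(path.name)] = _sha256(path)


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the full pipeline for one simulated cohort.

    Stages: simulate the cohort; preprocess logs into traces; score summaries
    (when the design collects them); fit rate models (or the TRF with the
    surprisal ablation for the alternating-surprisal design); apply exclusion
    criteria; write artifacts + report.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(config={**asdict(config), "crop_cutoffs_s":
                               dict(config.crop_cutoffs_s or {})})
    t_start = time.perf_counter()

    # -- stage 1: simulate -------------------------------------------------
    sessions = []
    for i in range(config.participants):
        profile = simulate.make_participant(config.seed + i)
        if config.experiment == "exp1":
            plan = simulate.exp1_plan(seed=config.seed + i)
        elif config.experiment == "exp2":
            plan = simulate.exp2_plan()
        else:
            plan = simulate.exp3_plan(seed=config.seed + i)
        sessions.append(simulate.simulate_session(
            plan, profile, fs=config.fs, recency_bias=config.recency_bias))
    records = [r for s in sessions for r in s.records]
    report.add_stage("simulate", len(records), len(records))
    logger.info("simulate: %d trials in %.1fs", len(records), time.perf_counter() - t_start)

    if config.write_logs:
        log_dir = out / "logs"
        log_dir.mkdir(exist_ok=True)
        for s in sessions:
            for trial_id, log in s.logs.items():
                log.to_csv(log_dir / f"{trial_id}.csv")
    meta = pd.DataFrame(
        [
            {
                "trial_id": r.trial_id,
                "participant_id": r.participant_id,
                "speech_rate": r.speech_rate,
                "duration_s": r.duration_s,
                "scale_10": r.scale_10,
                "mc_correct": r.mc_correct,
                "summary_text": r.summary_text,
                "digit_span": r.digit_span,
                "digit_in_noise": r.digit_in_noise,
            }
            for r in records
        ]
    )
    _write(meta, out / "trials.csv", report)

    # -- stage 2: exclusions ----------------------------------------------
    criteria: dict[str, dict] = {"movement": {"n_sd": config.movement_sd}}
    if config.mc_accuracy_threshold is not None:
        criteria["mc_accuracy"] = {"threshold": config.mc_accuracy_threshold}
    if config.participants >= 2:
        excl_table, retained = exclusion_report(records, criteria)
        report.exclusions = (
            excl_table.reset_index().replace({np.nan: None}).to_dict(orient="records")
        )
    else:
        retained = [sessions[0].profile.participant_id]
    records = [r for r in records if r.participant_id in retained]
    sessions = [s for s in sessions if s.profile.participant_id in retained]
    report.add_stage("exclusions", len(meta), len(records))

    # -- stage 3: preprocess (crop) ----------------------------------------
    analyzed = []
    n_before = len(records)
    for rec in records:
        trace = rec.trace
        if config.crop:
            try:
                trace = slider.crop_initial_movement(
                    trace, rec.speech_rate, cutoffs_s=config.crop_cutoffs_s
                )
            except (KeyError, slider.InsufficientDataError):
                continue
        analyzed.append((rec, trace))
    report.add_stage("preprocess", n_before, len(analyzed))

    # -- stage 4: summary scoring ------------------------------------------
    scored: list[semantics.ScoredSummary] = []
    segments = {tid: words for s in sessions for tid, words in s.segments.items()}
    if segments:
        if config.embeddings == "toy":
            vocab = sorted({w for words in segments.values() for w in words})
            emb = simulate.make_toy_embeddings(vocab, dim=16, seed=config.seed)
            emb.to_word2vec(out / "embeddings.txt")
            report.manifest["embeddings.txt"] = _sha256(out / "embeddings.txt")
        else:
            emb = semantics.EmbeddingTable.from_word2vec(config.embeddings)
        for rec, _ in analyzed:
            if rec.summary_text is not None and rec.trial_id in segments:
                scored.append(
                    semantics.score_summary(
                        rec.trial_id, rec.summary_text,
                        " ".join(segments[rec.trial_id]), emb,
                    )
                )
        _write(semantics.scores_to_frame(scored), out / "semantic_scores.csv", report)
    report.add_stage("score", len(analyzed), len(analyzed))

    # -- stage 5: models ----------------------------------------------------
    table = ratemodel.build_trial_table([rec for rec, _ in analyzed], scored)
    _write(table, out / "trial_table.csv", report)

    if config.experiment in ("exp1", "exp2"):
        subjects = []
        for s in sessions:
            recs = [rec for rec, _ in analyzed if rec.participant_id == s.profile.participant_id]
            if recs:
                subjects.append(
                    (
                        [r.speech_rate for r in recs],
                        [slider.median_score(r.trace) for r in recs],
                    )
                )
        comparison = ratemodel.crossval_compare(subjects, k=config.k_folds, seed=config.seed)
        report.fitted["model_comparison"] = {
            "mean_r_linear": comparison.mean_r_linear,
            "mean_r_sigmoid": comparison.mean_r_sigmoid,
            "wilcoxon_p": comparison.p_value,
            "winner": comparison.winner,
        }
        fits = {}
        for (x, y), s in zip(subjects, sessions):
            res = ratemodel.ComprehensionDecline(x, y).fit("sigmoid")
            fits[s.profile.participant_id] = dict(zip(res.param_names, map(float, res.params)))
        report.fitted["sigmoid_params"] = fits
        _write(json.dumps(report.fitted, indent=2, sort_keys=True),
               out / "ratefit.json", report)
    else:  # exp3: TRF with surprisal ablation
        window = trf.LagWindow(tmin=config.trf_tmin, tmax=config.trf_tmax, fs=config.fs)
        subject_pairs = []
        for s in sessions:
            pairs = []
            for rec, planned in zip(s.records, s.plan.trials):
                ann = trf.build_annotation_vectors(
                    planned.word_events, len(rec.trace), config.fs, rate=planned.speech_rate
                )
                pairs.append((rec.trace, ann))
            subject_pairs.append(trf.concatenate_sessions(pairs))
        kernels = []
        for (y, ann), s in zip(subject_pairs, sessions):
            res = trf.crossval_trf(y, ann, window=window, alpha=config.trf_alpha, k=config.trf_k)
            kernels.append((s.profile.participant_id, res))
        ablation = trf.ablation_compare(
            subject_pairs, window=window, alpha=config.trf_alpha, k=config.trf_k
        )
        report.fitted["trf"] = {
            pid: {"mean_rho": res.mean_rho, "k_used": res.k_used} for pid, res in kernels
        }
        report.fitted["ablation"] = {
            "mean_rho_full": float(np.mean(ablation.rho_full)),
            "mean_rho_reduced": float(np.mean(ablation.rho_reduced)),
            "mean_delta_rho": ablation.mean_delta,
            "t": ablation.t_stat,
            "p": ablation.p_value,
        }
        kern_frames = []
        for pid, res in kernels:
            f = res.to_frame()
            f.insert(0, "participant_id", pid)
            kern_frames.append(f)
        _write(pd.concat(kern_frames, ignore_index=True), out / "trf_kernels.csv", report)
    report.add_stage("model", len(analyzed), len(analyzed))

    report_path = out / "report.json"
    report_path.write_text(report.to_json())
    logger.info("pipeline finished in %.1fs", time.perf_counter() - t_start)
    return report
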