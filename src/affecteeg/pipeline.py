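"""End-to-end orchestration of the two-group EEG affect study.

The full workflow mirrors the study design: train an emotion recognizer on
a benchmark-style corpus, record a two-group cohort viewing a 100 s
stimulus clip, score every participant's EEG per 10 s stimulus epoch,
aggregate to one (valence, arousal) point per participant, and run the
between-group / between-method statistics.  Each stage reads and writes
files inside one run directory, so any stage can be rerun in isolation,
and every table carries the configuration hash it was produced under.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .ensemble import (
    ColumnConfig,
    EnsembleModel,
    split_subjects,
    train_ensemble,
    windows_from_corpus,
    predict_trial,
    evaluate,
    save_model,
    load_model,
)
from .preprocess import PreprocessConfig, preprocess_trial
from .scoring import score_participant
from .stats import AnalysisReport, analyze_experiment
from .storage import load_cohort, load_corpus, save_cohort, save_corpus
from .synthetic import (
    CohortRecording,
    GeneratorParams,
    generate_cohort,
    generate_deap_like,
    load_table2,
    simulate_cohort_scores,
    strong_coupling_params,
)

logger = logging.getLogger("affecteeg")

ALL_STAGES = ("simulate-deap", "train", "simulate-cohort", "score", "analyze")


class PipelineStageError(RuntimeError):
    """A stage failed; partial outputs up to that stage are preserved."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Everything a run needs, serializable and hashable.

    ``stages`` selects which stages execute; omitted stages must find their
    inputs already present in the run directory (or, for ``analyze``, fall
    back to the packaged experiment table when no scores exist).
    """

    out_dir: str
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    schema_version: int = 1
    # corpus / training scale (desk-scale defaults)
    n_subjects: int = 8
    n_train: int = 4
    n_val: int = 2
    n_test: int = 2
    strong_coupling: bool = True
    trial_seconds: float = 12.0
    # cohort
    n_per_group: int = 20
    clip_seconds: float = 100.0
    epoch_seconds: float = 10.0
    #: score straight from cohort latents instead of running the classifier
    stats_only_scores: bool = False
    # stats
    alpha: float = 0.05
    d_denominator: str = "n"
    equal_var: bool = True
    # nested parameter blocks
    generator: Optional[GeneratorParams] = None
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    column: ColumnConfig = field(default_factory=ColumnConfig)

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stage(s) {sorted(unknown)}; valid: {ALL_STAGES}")
        if self.generator is None:
            base = {"trial_seconds": self.trial_seconds}
            self.generator = (
                strong_coupling_params(**base) if self.strong_coupling
                else GeneratorParams(**base)
            )

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, indent=2, sort_keys=True, default=str)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        d = json.loads(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        for key, sub in (("generator", GeneratorParams),
                         ("preprocess", PreprocessConfig),
                         ("column", ColumnConfig)):
            if isinstance(d.get(key), dict):
                sd = d[key]
                for k, v in sd.items():
                    if isinstance(v, list):
                        sd[k] = tuple(tuple(e) if isinstance(e, list) else e for e in v)
                d[key] = sub(**sd)
        if "stages" in d:
            d["stages"] = tuple(d["stages"])
        return cls(**d)

    @property
    def config_hash(self) -> str:
        """Hash of the scientific configuration.

        The output location is excluded, so two runs of the same experiment
        written to different directories carry the same hash (and produce
        byte-identical tables).
        """
        d = dataclasses.asdict(self)
        d.pop("out_dir")
        blob = json.dumps(d, indent=2, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _write_table(df: pd.DataFrame, path: Path, config_hash: str) -> None:
    """CSV with a provenance comment line; read back with ``comment='#'``."""
    with open(path, "w") as fh:
        fh.write(f"# config_hash: {config_hash}\n")
        df.to_csv(fh, index=False)


def _seed_for(config: PipelineConfig, stage: str) -> int:
    h = hashlib.sha256(f"{config.seed}/{stage}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2 ** 31)


# ---------------------------------------------------------------------------
# stages


def stage_simulate_deap(config: PipelineConfig, run: Path) -> Path:
    path = run / "corpus.h5"
    corpus = generate_deap_like(config.n_subjects, config.generator,
                                seed=_seed_for(config, "deap"))
    save_corpus(corpus, path)
    logger.info("wrote corpus with %d subjects to %s", config.n_subjects, path)
    return path


def stage_train(config: PipelineConfig, run: Path) -> Path:
    corpus = load_corpus(run / "corpus.h5")
    split = split_subjects(corpus, config.n_train, config.n_val, config.n_test,
                           seed=_seed_for(config, "split"))
    tr = windows_from_corpus(corpus, split.train, config.preprocess)
    va = windows_from_corpus(corpus, split.val, config.preprocess)
    te = windows_from_corpus(corpus, split.test, config.preprocess)
    col = dataclasses.replace(config.column, seed=_seed_for(config, "train"))
    model = train_ensemble(tr, va, col)
    acc = evaluate(model, te)
    model.manifest["test_accuracy"] = acc
    model.manifest["split"] = dataclasses.asdict(split)
    out = run / "model"
    save_model(model, out)
    logger.info("trained ensemble; test accuracy %s", acc)
    return out


def stage_simulate_cohort(config: PipelineConfig, run: Path) -> Path:
    path = run / "cohort.h5"
    cohort = generate_cohort(
        n_per_group=config.n_per_group,
        seed=_seed_for(config, "cohort"),
        params=config.generator,
        clip_seconds=config.clip_seconds,
        epoch_seconds=config.epoch_seconds,
        with_signals=not config.stats_only_scores,
    )
    save_cohort(cohort, path)
    logger.info("wrote cohort of %d participants to %s", len(cohort), path)
    return path


def score_cohort_with_model(
    cohort: Sequence[CohortRecording],
    model: EnsembleModel,
    pconfig: PreprocessConfig,
    annotation_seed: int,
    annotation_sd: float = 0.15,
) -> pd.DataFrame:
    """Score every participant: classifier per stimulus epoch, mean over epochs.

    The questionnaire round is simulated from the participant's latent state
    with annotation noise, mirroring the second (self-assessment) round of
    the experiment.
    """
    rng = np.random.default_rng(np.random.SeedSequence(annotation_seed))
    rows = []
    for rec in cohort:
        if rec.signal is None:
            raise ValueError(f"participant {rec.participant_id} has no signal")
        epoch_scores = []
        for (a, b) in rec.epoch_bounds:
            tws = preprocess_trial(rec.signal[:, a:b], config=pconfig,
                                   trial_id=f"{rec.participant_id}/{a}")
            _, _, sv, sa = predict_trial(model, tws)
            epoch_scores.append((sv, sa))
        es = score_participant(epoch_scores, participant=rec.participant_id)
        uv = int(np.clip(round(5 + 4 * (rec.latent_valence + rng.normal(0, annotation_sd))), 1, 9))
        ua = int(np.clip(round(5 + 4 * (rec.latent_arousal + rng.normal(0, annotation_sd))), 1, 9))
        rows.append(dict(
            participant=rec.participant_id, group=rec.group,
            eeg_valence=es.valence, eeg_arousal=es.arousal,
            user_valence=uv, user_arousal=ua,
        ))
    return pd.DataFrame(rows)


def stage_score(config: PipelineConfig, run: Path) -> Path:
    cohort = load_cohort(run / "cohort.h5")
    if config.stats_only_scores:
        scores = simulate_cohort_scores(cohort, seed=_seed_for(config, "score"))
    else:
        model = load_model(run / "model")
        scores = score_cohort_with_model(
            cohort, model, config.preprocess,
            annotation_seed=_seed_for(config, "annotation"),
        )
    path = run / "scores.csv"
    _write_table(scores, path, config.config_hash)
    logger.info("wrote %d participant scores to %s", len(scores), path)
    return path


def stage_analyze(config: PipelineConfig, run: Path,
                  scores: Optional[pd.DataFrame] = None) -> AnalysisReport:
    if scores is None:
        path = run / "scores.csv"
        if path.exists():
            scores = pd.read_csv(path, comment="#", dtype={"participant": str})
        else:
            logger.info("no scores.csv in run dir; analyzing the packaged table")
            scores = load_table2()
    report = analyze_experiment(
        scores, alpha=config.alpha,
        d_denominator=config.d_denominator,  # type: ignore[arg-type]
        equal_var=config.equal_var,
    )
    out = run / "report"
    out.mkdir(parents=True, exist_ok=True)
    for name, frame in report.to_frames().items():
        _write_table(frame, out / f"{name}.csv", config.config_hash)
    (out / "report.json").write_text(report.to_json())
    logger.info("wrote analysis report to %s", out)
    return report


# ---------------------------------------------------------------------------


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the configured stages in order inside the run directory.

    Writes ``manifest.json`` (config, hash, package version, per-stage
    timings) last, so its presence marks a completed run.  Rerunning with
    the same configuration reproduces all deterministic artifacts bit for
    bit.
    """
    run = Path(config.out_dir)
    run.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(run / "run.log")
    handler.setFormatter(logging.Formatter(
        "%(asctime)s %(levelname)s %(name)s: %(message)s", "%Y-%m-%dT%H:%M:%S"))
    logger.addHandler(handler)
    (run / "config.json").write_text(config.to_json())

    funcs = {
        "simulate-deap": stage_simulate_deap,
        "train": stage_train,
        "simulate-cohort": stage_simulate_cohort,
        "score": stage_score,
        "analyze": stage_analyze,
    }
    timings: dict[str, float] = {}
    try:
        for stage in ALL_STAGES:
            if stage not in config.stages:
                continue
            t0 = time.perf_counter()
            logger.info("stage %s: start", stage)
            try:
                funcs[stage](config, run)
            except Exception as exc:
                logger.error("stage %s failed: %s", stage, exc)
                raise PipelineStageError(stage, exc) from exc
            timings[stage] = round(time.perf_counter() - t0, 3)
            logger.info("stage %s: done in %.1f s", stage, timings[stage])
        manifest = {
            "config_hash": config.config_hash,
            "package_version": __version__,
            "seed": config.seed,
            "stages_run": [s for s in ALL_STAGES if s in config.stages],
            "timings_s": timings,
        }
        (run / "manifest.json").write_text(json.dumps(manifest, indent=2))
    finally:
        logger.removeHandler(handler)
        handler.close()
    return run
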