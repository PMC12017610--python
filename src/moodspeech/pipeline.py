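"""End-to-end orchestration: manifest -> features -> associations -> models.

A run consumes a manifest CSV linking each participant's WAV recording,
word-timestamped transcript JSON, sex and MADRS/YMRS totals, plus the
reference story text and a word-embedding table. It produces a run
directory with the per-participant feature table, correlation outputs
(overall and sex-stratified), severity group tests, nested-CV model
evaluations with Shapley summaries, and a QC report. Runs are
deterministic given the config seed; every output carries the resolved
config hash, and per-participant failures are isolated — one unreadable
recording flags one row, never the run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import associations as assoc
from . import models as models_mod
from .audio import AudioRecording, read_wav
from .langfeatures import (
    EmbeddingTable,
    LanguageFeatureExtractor,
    ReferenceStory,
    TimedTranscript,
)
from .segmentation import SilenceSegmenter, conversational_features
from .voicequality import VoiceQualityExtractor

MANIFEST_REQUIRED = ["id", "wav", "transcript", "sex", "madrs_total", "ymrs_total"]
SCORE_RANGE = (0, 60)


# --------------------------------------------------------------------------
# config
# --------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Resolved run configuration; serializable and re-runnable."""

    manifest: str
    story: str
    embeddings: str
    output_dir: str
    seed: int = 0
    segmentation: dict[str, Any] = field(default_factory=dict)
    pitch: dict[str, Any] = field(default_factory=dict)
    intraword_convention: str = "onset"
    subgroups: bool = True
    severity_tests: bool = True
    multiple_testing: bool = False
    plots: bool = True
    run_models: bool = True
    targets: tuple[str, ...] = ("madrs", "ymrs")
    min_rows_for_models: int = 10

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        cfg = cls(**{k: v for k, v in raw.items()})
        if isinstance(cfg.targets, list):
            cfg.targets = tuple(cfg.targets)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["targets"] = list(self.targets)
        return d

    def content_hash(self) -> str:
        """Hash of the resolved analysis parameters. File locations are
        excluded so a rerun into a different directory (or from a moved
        tree) hashes identically."""
        d = {k: v for k, v in self.to_dict().items()
             if k not in ("manifest", "story", "embeddings", "output_dir")}
        return hashlib.sha256(
            json.dumps(d, sort_keys=True).encode()
        ).hexdigest()[:16]

    def validate_paths(self) -> None:
        for name in ("manifest", "story", "embeddings"):
            p = Path(getattr(self, name))
            if not p.exists():
                raise FileNotFoundError(f"{name} path does not exist: {p}")
        if not isinstance(self.seed, (int, np.integer)):
            raise TypeError("seed must be an integer")


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Manifest CSV with required columns id, wav, transcript, sex,
    madrs_total, ymrs_total; wav/transcript paths resolve relative to the
    manifest location. Extra columns (e.g. per-item scores) pass through."""
    path = Path(path)
    table = pd.read_csv(path, comment="#")
    missing = [c for c in MANIFEST_REQUIRED if c not in table.columns]
    if missing:
        raise ValueError(f"manifest is missing required columns: {missing}")
    if table.empty:
        raise ValueError("manifest contains no rows")
    if table["id"].duplicated().any():
        dupes = table.loc[table["id"].duplicated(), "id"].tolist()
        raise ValueError(f"duplicate participant ids: {dupes}")
    base = path.parent
    for col in ("wav", "transcript"):
        table[col] = [str((base / p)) if not Path(p).is_absolute() else p
                      for p in table[col]]
    return table


# --------------------------------------------------------------------------
# validation
# --------------------------------------------------------------------------

def _check_row(row: pd.Series) -> list[str]:
    problems = []
    if row["sex"] not in ("female", "male"):
        problems.append(f"sex must be female/male, got {row['sex']!r}")
    for col in ("madrs_total", "ymrs_total"):
        v = row[col]
        if pd.isna(v):
            problems.append(f"{col} missing")
        elif not SCORE_RANGE[0] <= v <= SCORE_RANGE[1]:
            problems.append(f"{col}={v} outside [0, 60]")
    if not Path(row["wav"]).exists():
        problems.append(f"wav not found: {row['wav']}")
    else:
        try:
            audio = read_wav(row["wav"])
            clipped = float(np.mean(np.abs(audio.samples) >= 0.999))
            if clipped > 0.001:
                problems.append(f"audio clipping on {clipped:.1%} of samples")
        except Exception as exc:
            problems.append(f"unreadable wav: {exc}")
    if not Path(row["transcript"]).exists():
        problems.append(f"transcript not found: {row['transcript']}")
    else:
        try:
            TimedTranscript.read_json(row["transcript"])
        except Exception as exc:
            problems.append(f"invalid transcript: {exc}")
    return problems


def validate_inputs(manifest: pd.DataFrame | str | Path) -> pd.DataFrame:
    """Report-only validation: one row per participant with pass/fail and
    the reasons for failure."""
    if not isinstance(manifest, pd.DataFrame):
        manifest = read_manifest(manifest)
    records = []
    for _, row in manifest.iterrows():
        problems = _check_row(row)
        records.append(
            {"id": row["id"], "passed": not problems, "reasons": "; ".join(problems)}
        )
    return pd.DataFrame(records)


# --------------------------------------------------------------------------
# the run
# --------------------------------------------------------------------------

@dataclass
class RunResult:
    run_dir: Path
    feature_table: pd.DataFrame
    n_participants: int
    n_failed: int
    config_hash: str

    @property
    def complete(self) -> bool:
        return self.n_failed == 0


def _write_csv(df: pd.DataFrame, path: Path, config_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, index=False, float_format="%.10g", lineterminator="\n")


def _extract_participant(
    row: pd.Series,
    segmenter: SilenceSegmenter,
    vq: VoiceQualityExtractor,
    lang: LanguageFeatureExtractor,
) -> tuple[dict[str, float], dict[str, float]]:
    audio = read_wav(row["wav"])
    transcript = TimedTranscript.read_json(row["transcript"])
    seg = segmenter.segment(audio)
    conv = conversational_features(seg, transcript.n_words)
    acoustic, qc = vq.extract(audio)
    features: dict[str, float] = {}
    features.update(lang.extract(transcript))
    features.update(conv.as_dict())
    features.update(acoustic.as_dict())
    return features, qc


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute the full analysis; returns a summary of the run directory."""
    config.validate_paths()
    run_dir = Path(config.output_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    chash = config.content_hash()

    manifest = read_manifest(config.manifest)
    story = ReferenceStory.read_text(config.story)
    embeddings = EmbeddingTable.read_text(config.embeddings)
    segmenter = SilenceSegmenter(**config.segmentation)
    vq = VoiceQualityExtractor(**config.pitch)
    lang = LanguageFeatureExtractor(
        story=story, embeddings=embeddings,
        intraword_convention=config.intraword_convention,
    )

    rows = []
    failures = []
    participant_qc: dict[str, dict] = {}
    for _, mrow in manifest.iterrows():
        record: dict[str, Any] = {
            "id": mrow["id"],
            "sex": mrow["sex"],
            "madrs_total": mrow["madrs_total"],
            "ymrs_total": mrow["ymrs_total"],
        }
        for col in manifest.columns:
            if col not in MANIFEST_REQUIRED:
                record[col] = mrow[col]
        try:
            features, qc = _extract_participant(mrow, segmenter, vq, lang)
            record.update(features)
            participant_qc[str(mrow["id"])] = qc
            record["extraction_failed"] = False
        except Exception as exc:
            record["extraction_failed"] = True
            failures.append({"id": str(mrow["id"]), "error": str(exc)})
        rows.append(record)
    table = pd.DataFrame(rows)

    severe = table.apply(
        lambda r: assoc.dichotomize_severity(r["madrs_total"], r["ymrs_total"]),
        axis=1, result_type="expand",
    )
    table["depr_severe"] = severe[0]
    table["manic_severe"] = severe[1]
    _write_csv(table, run_dir / "features.csv", chash)

    feature_cols = [
        c for c in table.columns
        if c in models_mod.standard_feature_sets().get(
            "combined", models_mod.FeatureSetSpec("x", ("_",))
        ).columns
    ]
    targets = [f"{t}_total" for t in config.targets]
    complete = table[~table["extraction_failed"]]

    # associations ---------------------------------------------------------
    long_frames = []
    if len(complete) >= assoc.MIN_PAIRS and feature_cols:
        strata = (
            assoc.subgroup_analysis(complete, feature_cols, targets)
            if config.subgroups
            else {"overall": assoc.correlation_matrix(complete, feature_cols, targets)}
        )
        for name, corr in sorted(strata.items()):
            long_frames.append(corr.to_long(stratum=name))
            if config.plots:
                assoc.correlation_heatmap(
                    corr, run_dir / f"correlations_{name}.png",
                    title=f"{name} (spearman)",
                )
            if config.multiple_testing:
                adj = assoc.adjust_p_values(corr)
                _write_csv(
                    adj.reset_index(names="feature"),
                    run_dir / f"p_adjusted_{name}.csv", chash,
                )
    if long_frames:
        _write_csv(pd.concat(long_frames, ignore_index=True),
                   run_dir / "correlations.csv", chash)

    if config.severity_tests and feature_cols:
        tests = []
        for flag, label in (("depr_severe", "depressive"), ("manic_severe", "manic")):
            for feat in feature_cols:
                res = assoc.group_difference(complete, feat, flag)
                if res is not None:
                    tests.append({
                        "feature": feat, "severity": label,
                        "u": res.u_statistic, "p": res.p_value,
                        "median_severe": res.median_group1,
                        "median_not_severe": res.median_group2,
                        "n_severe": res.n_group1, "n_not_severe": res.n_group2,
                        "method": res.method,
                    })
        if tests:
            _write_csv(pd.DataFrame(tests), run_dir / "severity_tests.csv", chash)

    # models ---------------------------------------------------------------
    evaluations = []
    if config.run_models and len(complete) >= config.min_rows_for_models:
        evaluator = models_mod.NestedForestEvaluator(random_state=config.seed)
        specs = models_mod.standard_feature_sets(available=complete.columns)
        attr_rows = []
        for spec in specs.values():
            for target in config.targets:
                for adjust in (False, True):
                    ev = evaluator.evaluate(complete, spec.with_sex(adjust), target)
                    evaluations.append(ev)
                if len(spec.columns) <= 20:
                    model, X, _y = evaluator.fit_full(
                        complete, spec.with_sex(True), target
                    )
                    att = models_mod.shapley_attribution(
                        model.model_, X, random_state=config.seed
                    )
                    for feat, val in att.mean_abs().items():
                        attr_rows.append({
                            "feature_set": spec.name, "target": target,
                            "feature": feat, "mean_abs_shapley": val,
                        })
        report = models_mod.report_table(evaluations)
        (run_dir / "model_report.txt").write_text(
            f"# config_hash={chash}\n" + models_mod.format_report(report) + "\n"
        )
        (run_dir / "model_evaluations.json").write_text(json.dumps(
            {"config_hash": chash,
             "evaluations": [ev.to_dict() for ev in evaluations]},
            indent=2, allow_nan=True,
        ))
        if attr_rows:
            _write_csv(pd.DataFrame(attr_rows),
                       run_dir / "shapley_summary.csv", chash)

    # QC -------------------------------------------------------------------
    qc = {
        "config_hash": chash,
        # analysis parameters only: file locations are left out so reruns
        # into different directories produce identical reports
        "config": {k: v for k, v in config.to_dict().items()
                   if k not in ("manifest", "story", "embeddings", "output_dir")},
        "n_participants": int(len(table)),
        "n_failed": len(failures),
        "failures": failures,
        "n_models_evaluated": len(evaluations),
        "feature_missingness": {
            c: int(table[c].isna().sum()) for c in feature_cols
        },
        "participants": participant_qc,
    }
    (run_dir / "qc_report.json").write_text(json.dumps(qc, indent=2))

    return RunResult(
        run_dir=run_dir,
        feature_table=table,
        n_participants=len(table),
        n_failed=len(failures),
        config_hash=chash,
    )
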