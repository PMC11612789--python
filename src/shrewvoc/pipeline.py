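"""Configuration-driven orchestration of the full repertoire analysis.

Synthesize (or ingest) recordings -> detect call units -> extract the
22-parameter feature table -> standardize / embed / soft-cluster ->
typicality and call-type assignment -> behavioural context and call-rate
statistics.  Every run is reproducible from its seed; every written table
carries the config hash and seed in a comment header.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .audio import AudioRecording, read_wav
from .context import (DEFAULT_PRIORITY, align_calls, behavior_shares,
                      call_rates, proximity_shares)
from .context import ETHOGRAM
from .features import FeatureConfig, extract_feature_table
from .repertoire import RepertoireModel, RepertoireResults
from .segmentation import SegmentationConfig, segment_calls
from .stats import LmeFit, backward_eliminate, cohens_kappa
from .synth import ExperimentConfig, SyntheticExperiment, generate_experiment
from .textgrid import read_textgrid

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "read_annotations"]


@dataclass
class PipelineConfig:
    """Everything one analysis run needs.

    ``input_mode`` is ``"synthetic"`` (generate recordings from
    ``experiment``) or ``"recordings"`` (read WAV/annotation files from
    ``input_dir``).
    """

    input_mode: str = "synthetic"
    seed: int = 0
    input_dir: str | None = None
    output_dir: str | None = None
    experiment: ExperimentConfig = field(default_factory=ExperimentConfig)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    n_clusters: int = 3
    fuzzifier: float = 2.0
    max_iter: int = 100
    tol: float = 1e-6
    n_neighbors: int = 15
    min_dist: float = 0.1
    cluster_space: str = "features"
    typicality_method: str = "tercile"
    fixed_thresholds: tuple[float, float] | None = None
    behavior_priority: tuple[str, ...] = DEFAULT_PRIORITY
    fit_rate_models: bool = True

    def config_hash(self) -> str:
        def _default(o):
            if hasattr(o, "__dict__"):
                return o.__dict__
            return str(o)
        blob = json.dumps(asdict(self), sort_keys=True, default=_default)
        return hashlib.sha1(blob.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = dict(raw)
        if "experiment" in kwargs:
            kwargs["experiment"] = ExperimentConfig(**kwargs["experiment"])
        if "segmentation" in kwargs:
            kwargs["segmentation"] = SegmentationConfig(**kwargs["segmentation"])
        if "features" in kwargs:
            kwargs["features"] = FeatureConfig(**kwargs["features"])
        return cls(**kwargs)


@dataclass
class PipelineResult:
    """Bundle of all artifacts of one pipeline run."""

    config: PipelineConfig
    experiment: SyntheticExperiment | None
    features: pd.DataFrame
    repertoire: RepertoireResults
    annotated_calls: pd.DataFrame | None
    behavior_share_table: pd.DataFrame | None
    proximity_table: pd.DataFrame | None
    rate_table: pd.DataFrame | None
    rate_models: dict[str, LmeFit]
    log: list[str]

    @property
    def per_call(self) -> pd.DataFrame:
        return self.repertoire.per_call

    def kappa_vs_truth(self) -> float | None:
        """Agreement between assigned call types and generator ground truth
        (synthetic mode only)."""
        pc = self.per_call
        if "true_type" not in pc.columns:
            return None
        ok = pc["true_type"].notna()
        return cohens_kappa(pc.loc[ok, "call_type"], pc.loc[ok, "true_type"])

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        header = (f"# shrewvoc run  config_hash={self.config.config_hash()}  "
                  f"seed={self.config.seed}\n")

        def _write(df: pd.DataFrame | None, name: str) -> None:
            if df is None:
                return
            with open(outdir / name, "w") as fh:
                fh.write(header)
                df.to_csv(fh, index=False, float_format="%.6f")

        _write(self.features, "features.csv")
        _write(self.per_call[["call_id", "umap1", "umap2"]], "embedding.csv")
        mem_cols = ["call_id"] + [c for c in self.per_call.columns
                                  if c.startswith("u") and c[1:].isdigit()] \
            + ["hard_label"]
        _write(self.per_call[mem_cols], "membership.csv")
        _write(self.per_call[["call_id", "hard_label", "typicality_coefficient",
                              "typicality_category", "call_type"]],
               "call_types.csv")
        _write(self.behavior_share_table, "behavior_shares.csv")
        _write(self.proximity_table, "proximity_shares.csv")
        _write(self.rate_table, "call_rates.csv")
        with open(outdir / "report.txt", "w") as fh:
            fh.write(header + "\n" + self.repertoire.summary() + "\n\n")
            for name, fit in self.rate_models.items():
                fh.write(f"--- call-rate model: {name}\n{fit.summary()}\n\n")
            fh.write("run log:\n" + "\n".join(self.log) + "\n")


def read_annotations(path: str | Path, dialect: str = "auto") -> pd.DataFrame:
    """Read behaviour annotations from TextGrid (long/short) or CSV.

    Returns a DataFrame with columns experiment_id, category, onset, offset,
    phase.  Unknown ethogram categories are rejected with their location.
    """
    path = Path(path)
    if dialect == "auto":
        dialect = "csv" if path.suffix.lower() == ".csv" else "textgrid"
    if dialect == "csv":
        df = pd.read_csv(path, comment="#")
        required = {"category", "onset", "offset"}
        if not required <= set(df.columns):
            raise ValueError(f"{path}: annotation CSV needs columns {sorted(required)}")
        for i, cat in enumerate(df["category"]):
            if cat not in ETHOGRAM:
                raise ValueError(f"{path}: unknown behaviour category {cat!r} "
                                 f"(row {i + 2})")
        if "experiment_id" not in df.columns:
            df["experiment_id"] = path.stem
        if "phase" not in df.columns:
            df["phase"] = "open_door"
        return df[["experiment_id", "category", "onset", "offset", "phase"]]
    tiers = read_textgrid(path)
    tier_name = "behavior" if "behavior" in tiers else next(iter(tiers))
    rows = []
    for i, (a, b, text) in enumerate(tiers[tier_name]):
        if not text:
            continue
        if text not in ETHOGRAM:
            raise ValueError(f"{path}: unknown behaviour category {text!r} "
                             f"(tier {tier_name!r}, interval {i + 1})")
        rows.append({"experiment_id": path.stem, "category": text,
                     "onset": a, "offset": b, "phase": "open_door"})
    return pd.DataFrame(rows)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _match_ground_truth(features: pd.DataFrame,
                        truth: pd.DataFrame) -> pd.DataFrame:
    """Attach the overlapping ground-truth call (if any) to each detected
    call, matching within a recording by maximal interval overlap."""
    cols = ["true_type", "true_voiced_fraction", "coarse_class",
            "individual_id", "experiment_id", "context_label", "age_group"]
    out = features.copy()
    for c in cols:
        out[c] = pd.NA
    for rid, grp in out.groupby("recording_id"):
        t = truth[truth.recording_id == rid]
        if not len(t):
            continue
        for idx, row in grp.iterrows():
            ov = (np.minimum(row["offset"], t["offset"])
                  - np.maximum(row["onset"], t["onset"]))
            j = int(np.argmax(ov.to_numpy()))
            if ov.iloc[j] > 0:
                for c in cols:
                    out.loc[idx, c] = t.iloc[j][c]
    return out


def run_pipeline(config: PipelineConfig | None = None) -> PipelineResult:
    """Execute the full analysis described by ``config``."""
    cfg = config or PipelineConfig()
    log: list[str] = [f"config_hash={cfg.config_hash()} seed={cfg.seed}"]

    # --- stage: input
    stage = "input"
    try:
        if cfg.input_mode == "synthetic":
            exp = generate_experiment(cfg.experiment, seed=cfg.seed)
            truth = exp.ground_truth
            behavior = exp.behavior
            dyads = exp.dyads
            recording_ids = exp.recording_ids
        elif cfg.input_mode == "recordings":
            if not cfg.input_dir:
                raise ValueError("recordings mode requires input_dir")
            indir = Path(cfg.input_dir)
            wavs = sorted(indir.glob("*.wav"))
            if not wavs:
                raise FileNotFoundError(f"no WAV files found in {indir}")
            exp = None
            recording_ids = [w.stem for w in wavs]
            truth = None
            gt_path = indir / "ground_truth.csv"
            if gt_path.exists():
                truth = pd.read_csv(gt_path, comment="#")
            behavior = None
            beh_csv = indir / "behavior.csv"
            if beh_csv.exists():
                behavior = pd.read_csv(beh_csv, comment="#")
            dyads = None
            dyad_csv = indir / "dyads.csv"
            if dyad_csv.exists():
                dyads = pd.read_csv(dyad_csv, comment="#")
        else:
            raise ValueError(f"unknown input_mode {cfg.input_mode!r}")
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # --- stage: segmentation + features (one recording at a time)
    stage = "features"
    try:
        tables = []
        for rid in recording_ids:
            if cfg.input_mode == "synthetic":
                rec = AudioRecording(samples=exp.recording_audio(rid),
                                     sample_rate=cfg.experiment.sample_rate,
                                     source_path=rid)
                age_mode = "pup" if rid.startswith("pup") else "adult"
            else:
                rec = read_wav(Path(cfg.input_dir) / f"{rid}.wav")
                rec.source_path = rid
                age_mode = "pup" if rid.startswith("pup") else "adult"
            segments = segment_calls(rec, age_mode=age_mode,
                                     config=cfg.segmentation)
            log.append(f"{rid}: {len(segments)} call unit(s) detected")
            if segments:
                tables.append(extract_feature_table(
                    segments, {rid: rec}, cfg.features))
        if not tables:
            raise ValueError("no call units detected in any recording")
        features = pd.concat(tables, ignore_index=True)
        if truth is not None:
            features = _match_ground_truth(features, truth)
            features["age_group"] = features["age_group"].fillna(
                features["recording_id"].str.startswith("pup").map(
                    {True: "pup", False: "adult"}))
    except StageError:
        raise
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # --- stage: clustering + typicality + call types
    stage = "clustering"
    try:
        model = RepertoireModel(
            features, n_clusters=cfg.n_clusters, fuzzifier=cfg.fuzzifier,
            max_iter=cfg.max_iter, tol=cfg.tol, n_neighbors=cfg.n_neighbors,
            min_dist=cfg.min_dist, cluster_space=cfg.cluster_space,
            typicality_method=cfg.typicality_method,
            fixed_thresholds=cfg.fixed_thresholds)
        repertoire = model.fit(seed=cfg.seed)
        log.append("clustering: " + ", ".join(
            f"c{i}:{r}" for i, r in repertoire.cluster_roles.items()))
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # --- stage: behavioural context + rates
    stage = "context"
    annotated = share_table = prox_table = rate_table = None
    rate_models: dict[str, LmeFit] = {}
    try:
        pc = repertoire.per_call
        if behavior is not None and "experiment_id" in pc.columns:
            adult = pc[(pc["recording_id"].astype(str).str.startswith("exp"))
                       & pc["experiment_id"].notna()].copy()
            if len(adult):
                annotated = align_calls(adult, behavior,
                                        priority=cfg.behavior_priority)
                share_table = behavior_shares(annotated)
                prox = behavior[["experiment_id", "onset", "offset"]]
                prox_table = proximity_shares(annotated, prox)
        if dyads is not None and annotated is not None:
            rate_table = call_rates(annotated, dyads, phase="open_door")
            if cfg.fit_rate_models:
                for ct, sub in rate_table.groupby("call_type"):
                    if sub["rate_per_min"].nunique() < 3:
                        log.append(f"rate model for {ct}: skipped (too few "
                                   "distinct rates)")
                        continue
                    try:
                        fit, steps = backward_eliminate(
                            sub, "rate_per_min",
                            ["sex_composition", "familiarity", "housing_type"],
                            ["sex_composition:housing_type",
                             "familiarity:housing_type"],
                            ["individual_1", "individual_2"])
                    except np.linalg.LinAlgError as exc:
                        log.append(f"rate model for {ct}: singular design "
                                   f"({exc}); skipped")
                        continue
                    rate_models[str(ct)] = fit
                    log.append(f"rate model for {ct}: dropped "
                               f"{[s.dropped for s in steps]}")
    except Exception as exc:
        raise StageError(stage, exc) from exc

    result = PipelineResult(
        config=cfg, experiment=exp, features=features, repertoire=repertoire,
        annotated_calls=annotated, behavior_share_table=share_table,
        proximity_table=prox_table, rate_table=rate_table,
        rate_models=rate_models, log=log)
    if cfg.output_dir:
        result.write(cfg.output_dir)
    return result
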