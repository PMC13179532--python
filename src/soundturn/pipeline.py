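"""End-to-end orchestration: sessions -> features -> clustering -> reports.

For each of the four 2-D feature sets the pipeline fits the 3-component
mixture on the toddler training split (80% of valid toddler trials by
default), predicts on the held-out toddler trials and on all infant trials
(infants are never used for training — enforced structurally), and emits
contingency tables, validation statistics, serialized models, the head-yaw
timecourse and a run log.  Everything is reproducible from (config, seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import decisions as dec
from . import em, features, synth

log = logging.getLogger(__name__)

SPLITS = ("training", "validation_toddler", "validation_infant")


@dataclass
class PipelineConfig:
    mode: str = "simulate"                  # "simulate" | "ingest"
    # simulate mode
    n_infants: int = 28
    n_toddlers: int = 30
    infant_params: synth.ResponseModelParams = field(
        default_factory=lambda: synth.ResponseModelParams.for_group("infant"))
    toddler_params: synth.ResponseModelParams = field(
        default_factory=lambda: synth.ResponseModelParams.for_group("toddler"))
    write_sessions: bool = False            # also write the raw session CSVs
    # ingest mode
    features_path: str | None = None
    stimulus_log: str | None = None
    flip_yaw: bool = False
    # analysis
    split_unit: str = "trial"               # "trial" | "participant"
    split_fraction: float = 0.8
    offset_s: float = 2.0
    tol_s: float | None = None
    em_config: em.EMConfig = field(default_factory=em.EMConfig)
    conflict_policy: str = "gaze"
    pca_standardize: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.mode not in ("simulate", "ingest"):
            raise ValueError("mode must be 'simulate' or 'ingest'")
        if not 0.0 < self.split_fraction < 1.0:
            raise ValueError("split_fraction must lie in (0, 1)")
        if self.split_unit not in ("trial", "participant"):
            raise ValueError("split_unit must be 'trial' or 'participant'")
        if self.mode == "ingest":
            for p in (self.features_path, self.stimulus_log):
                if p is None or not Path(p).exists():
                    raise ValueError(f"ingest mode path missing: {p}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        for key, typ in (("infant_params", synth.ResponseModelParams),
                         ("toddler_params", synth.ResponseModelParams),
                         ("em_config", em.EMConfig)):
            if key in d and isinstance(d[key], dict):
                d[key] = typ(**d[key])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def split_toddler_trials(vectors: list[features.TrialFeatureVector],
                         fraction: float, unit: str, seed: int
                         ) -> tuple[list, list, list]:
    """Split valid trials into toddler-training / toddler-validation / infant.

    Infant trials always go to validation.  The toddler split is seeded and
    either trial-level (default) or participant-level.
    """
    valid = [v for v in vectors if v.valid]
    toddler = [v for v in valid if v.trial.group == "toddler"]
    infant = [v for v in valid if v.trial.group == "infant"]
    rng = np.random.default_rng(seed)
    if unit == "trial":
        idx = rng.permutation(len(toddler))
        n_train = int(round(fraction * len(toddler)))
        train = [toddler[i] for i in sorted(idx[:n_train])]
        val = [toddler[i] for i in sorted(idx[n_train:])]
    else:
        pids = sorted({v.trial.participant_id for v in toddler})
        idx = rng.permutation(len(pids))
        n_train = int(round(fraction * len(pids)))
        train_pids = {pids[i] for i in idx[:n_train]}
        train = [v for v in toddler if v.trial.participant_id in train_pids]
        val = [v for v in toddler if v.trial.participant_id not in train_pids]
    return train, val, infant


def _fs_em_config(base: em.EMConfig, feature_set: str, seed: int) -> em.EMConfig:
    cfg = dataclasses.replace(base, seed=seed)
    if feature_set == "pca2":
        cfg.apply_sign_criterion = False
    return cfg


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Run the full analysis; writes reports under ``out_dir`` and returns
    the report dict."""
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("soundturn")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        report = _run(config, out)
    finally:
        root.removeHandler(handler)
        handler.close()
    return report


def _stage(name):
    def deco(fn):
        def wrapped(*a, **kw):
            try:
                return fn(*a, **kw)
            except Exception as e:
                raise RuntimeError(f"pipeline stage '{name}' failed: {e}") from e
        return wrapped
    return deco


def _run(config: PipelineConfig, out: Path) -> dict:
    log.info("config hash %s, seed %d", config_hash(config), config.seed)

    # --- data -------------------------------------------------------------
    if config.mode == "simulate":
        schedule, frames = synth.simulate_cohort(
            config.n_infants, config.n_toddlers, config.seed,
            {"infant": config.infant_params, "toddler": config.toddler_params})
        if config.write_sessions:
            synth.write_session(schedule, frames, out / "sessions")
    else:
        frames, schedule = features.read_session(
            config.features_path, config.stimulus_log, flip_yaw=config.flip_yaw)
        for pid, df in frames.items():
            log.info("input %s: %d frames, sha %s", pid, len(df),
                     hashlib.sha256(df.to_csv(index=False).encode()).hexdigest()[:12])

    # --- extraction & timecourse -----------------------------------------
    vectors = features.extract_all(frames, schedule, config.offset_s, config.tol_s)
    features.vectors_to_frame(vectors).to_csv(out / "trial_features.csv", index=False)
    curve = features.mean_abs_yaw_timecourse(frames, schedule)
    curve.to_csv(out / "timecourse.csv", index=False)

    train, val_tod, val_inf = split_toddler_trials(
        vectors, config.split_fraction, config.split_unit, config.seed)
    split_vectors = {"training": train, "validation_toddler": val_tod,
                     "validation_infant": val_inf}
    n_valid = sum(v.valid for v in vectors)
    log.info("trials: %d total, %d valid (train %d / tod-val %d / infant %d)",
             len(vectors), n_valid, len(train), len(val_tod), len(val_inf))

    # --- per-feature-set fits ---------------------------------------------
    pca = features.fit_pca(train, standardize=config.pca_standardize)
    report: dict = {
        "seed": config.seed,
        "config_hash": config_hash(config),
        "config": config.to_dict(),
        "n_trials": len(vectors),
        "n_valid_trials": int(n_valid),
        "split_sizes": {k: len(v) for k, v in split_vectors.items()},
        "feature_sets": {},
    }
    predictions: dict[str, dict[str, np.ndarray]] = {}
    for fs in features.FEATURE_SETS:
        fs_pca = pca if fs == "pca2" else None
        X = {s: features.select_features_matrix(v, fs, fs_pca)
             for s, v in split_vectors.items()}
        sides = {s: np.asarray([v.trial.side for v in vecs])
                 for s, vecs in split_vectors.items()}
        cfg = _fs_em_config(config.em_config, fs, config.seed)
        model = em.fit(X["training"], cfg)
        log.info("%s: loglik %.3f, restarts %d, criterion %s", fs, model.loglik,
                 model.n_restarts_used, model.criterion_satisfied)
        labelling = dec.label_clusters(model, X["training"], sides["training"])
        em.save_model(model, out / f"model_{fs}.json", cfg)
        fs_rep = {
            "n_restarts_used": model.n_restarts_used,
            "criterion_satisfied": model.criterion_satisfied,
            "labelling": list(labelling.mapping),
            "decision_axis": labelling.decision_axis,
            "splits": {},
        }
        predictions[fs] = {}
        for s in SPLITS:
            pred = (predict_empty if len(X[s]) == 0 else dec.predict)(
                model, labelling, X[s])
            predictions[fs][s] = pred
            table = dec.contingency(pred, sides[s], s, fs)
            fs_rep["splits"][s] = dec.table_report(table)
        report["feature_sets"][fs] = fs_rep

    # --- combination & averages -------------------------------------------
    report["combination"] = {}
    for s in ("validation_toddler", "validation_infant"):
        combined, cstats = dec.combine_decisions(
            predictions["head_rot"][s], predictions["gaze_angle"][s],
            config.conflict_policy)
        sides_s = np.asarray([v.trial.side for v in split_vectors[s]])
        ctab = dec.contingency(combined, sides_s, s, "head+gaze")
        cstats.update(dec.table_report(ctab))
        report["combination"][s] = cstats
    report["averages"] = {}
    for s in SPLITS:
        tables = [dec.DirectionTable(
            np.asarray(report["feature_sets"][fs]["splits"][s]["counts"]), s, fs)
            for fs in features.FEATURE_SETS]
        report["averages"][s] = dec.average_correct_rate(tables)

    with open(out / "report.json", "w") as fh:
        json.dump(_jsonable(report), fh, indent=1, sort_keys=True)
    make_paper_tables(report, out / "prediction_tables.tsv")
    return report


def predict_empty(model, labelling, X):
    return np.asarray([], dtype=object)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        return round(float(obj), 12)
    return obj


def make_paper_tables(report: dict, path) -> pd.DataFrame:
    """Write the prediction-count table: rows feature set x class, columns
    split x speaker side."""
    rows = []
    fss = report.get("feature_sets", {})
    if report.get("n_trials", 0):
        missing = [fs for fs in features.FEATURE_SETS if fs not in fss]
        if missing:
            raise ValueError("report incomplete: missing feature set(s) "
                             + ", ".join(missing))
    for fs in features.FEATURE_SETS:
        if fs not in fss:
            continue
        for ci, cls in enumerate(dec.CLASSES):
            row = {"feature_set": fs, "class": cls}
            for s in SPLITS:
                counts = fss[fs]["splits"][s]["counts"]
                row[f"{s}_left_speaker"] = counts[ci][0]
                row[f"{s}_right_speaker"] = counts[ci][1]
            rows.append(row)
    cols = (["feature_set", "class"]
            + [f"{s}_{side}_speaker" for s in SPLITS for side in ("left", "right")])
    df = pd.DataFrame(rows, columns=cols)
    df.to_csv(path, sep="\t", index=False)
    return df
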