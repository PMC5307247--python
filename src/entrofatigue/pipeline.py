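"""End-to-end pipeline: simulate -> preprocess -> features -> evaluate -> report.

Stages communicate through on-disk TSV artifacts inside a run directory, so
any stage can be rerun or inspected independently:

    run_dir/
      raw/            one TSV recording per (subject, state)
      proc/           filtered recordings
      features.tsv    tidy feature table (raw values)
      features_norm.tsv  per-subject [-1, 1]-normalized values
      results.tsv     one row per (subject, channel, feature, classifier)
      report/         summary tables
      manifest.json   full configuration, library versions, decision flags

Identical :class:`RunConfig` (including the seed) reproduces bit-identical
artifacts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .classify import CLASSIFIER_NAMES, ClassifierSpec
from .entropy import FEATURE_NAMES, EntropyParams, extract_features
from .evaluate import evaluate_grid
from .io import write_recording
from .preprocess import FilterSpec, apply_filters, epoch_recording, normalize_features, \
    stack_epochsets
from .report import best_combination_per_subject, feature_classifier_table, \
    format_mean_sd, global_best, rank_channels
from .synth import STATES, Recording, SynthConfig, generate_dataset

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid or incomplete run configuration."""


@dataclass(frozen=True)
class RunConfig:
    """Fully serializable description of one benchmark run."""

    synth: SynthConfig = field(default_factory=SynthConfig)
    filter: FilterSpec = field(default_factory=FilterSpec)
    entropy: EntropyParams = field(default_factory=EntropyParams)
    features: tuple[str, ...] = FEATURE_NAMES
    classifiers: tuple[str, ...] = CLASSIFIER_NAMES
    fold_normalize: bool = False
    cv: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        bad = set(self.features) - set(FEATURE_NAMES)
        if bad:
            raise ConfigError(f"unknown features {sorted(bad)}")
        bad = set(self.classifiers) - set(CLASSIFIER_NAMES)
        if bad:
            raise ConfigError(f"unknown classifiers {sorted(bad)}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["synth"]["channel_names"] = list(self.synth.channel_names)
        return d

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)

        def sub(name, klass, required=()):
            block = raw.pop(name, None)
            if block is None:
                return klass()
            if not isinstance(block, dict):
                raise ConfigError(f"config section {name!r} must be a mapping")
            for key in required:
                if key not in block:
                    raise ConfigError(f"config section {name!r} is missing required "
                                      f"field {name}.{key}")
            known = {f.name for f in dataclasses.fields(klass)}
            unknown = set(block) - known
            if unknown:
                raise ConfigError(f"unknown keys in {name!r}: {sorted(unknown)}")
            if name == "synth" and "channel_names" in block:
                block["channel_names"] = tuple(block["channel_names"])
            try:
                return klass(**block)
            except (TypeError, ValueError) as exc:
                raise ConfigError(f"invalid {name} config: {exc}") from exc

        synth = sub("synth", SynthConfig, required=("fs",))
        filt = sub("filter", FilterSpec)
        entropy = sub("entropy", EntropyParams)
        kwargs = {}
        for key in ("features", "classifiers"):
            if key in raw:
                kwargs[key] = tuple(raw.pop(key))
        for key in ("fold_normalize", "cv", "seed"):
            if key in raw:
                kwargs[key] = raw.pop(key)
        if raw:
            raise ConfigError(f"unknown top-level config keys: {sorted(raw)}")
        try:
            return cls(synth=synth, filter=filt, entropy=entropy, **kwargs)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config must be a YAML mapping")
        return cls.from_dict(raw)


def _manifest(cfg: RunConfig) -> dict:
    import numpy
    import scipy
    import sklearn

    return {
        "package": {"name": "entrofatigue", "version": __version__},
        "versions": {"numpy": numpy.__version__, "scipy": scipy.__version__,
                     "sklearn": sklearn.__version__, "pandas": pd.__version__},
        "config": cfg.to_dict(),
        "decisions": {
            "template_distance": "chebyshev",
            "fuzzy_membership": "exp(-(d/r)^n), n from entropy.fuzzy_n, baseline-removed",
            "tolerance_sd_scope": "per-epoch population SD",
            "sampen_zero_match_policy": "inf sentinel imputed with column max",
            "loo_unit": "epoch within subject",
            "normalization": ("train-fold only" if cfg.fold_normalize
                              else "pooled per subject (fit before cross-validation)"),
            "cv": "leave-one-out" if cfg.cv is None else f"stratified {cfg.cv}-fold (non-protocol)",
            "sd_convention": "sample SD (ddof=1)",
        },
    }


def simulate_stage(cfg: RunConfig, out_dir: Path) -> list[Path]:
    """Generate the synthetic dataset and write one TSV per recording."""
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for rec in generate_dataset(cfg.synth):
        path = out_dir / f"sub{rec.subject_id:02d}_{rec.state}.tsv"
        write_recording(rec, path)
        paths.append(path)
    return paths


def features_stage(recordings: list[Recording], cfg: RunConfig) -> pd.DataFrame:
    """Filter, epoch and extract features from a list of recordings."""
    by_subject: dict[int, dict[str, Recording]] = {}
    for rec in recordings:
        by_subject.setdefault(rec.subject_id, {})[rec.state] = rec

    tables = []
    for subject in sorted(by_subject):
        pair = by_subject[subject]
        missing = set(STATES) - set(pair)
        if missing:
            raise ValueError(f"subject {subject} lacks state(s) {sorted(missing)}")
        epochsets = {state: epoch_recording(apply_filters(pair[state], cfg.filter),
                                            cfg.synth.epoch_len_s)
                     for state in STATES}
        for channel in pair[STATES[0]].channels:
            combined = stack_epochsets(epochsets[STATES[0]][channel],
                                       epochsets[STATES[1]][channel])
            tables.append(extract_features(combined, cfg.features, cfg.entropy))
    return pd.concat(tables, ignore_index=True)


def report_stage(results: pd.DataFrame, out_dir: Path) -> dict:
    """Write summary tables and return the headline numbers."""
    out_dir.mkdir(parents=True, exist_ok=True)
    tables = feature_classifier_table(results)
    format_mean_sd(tables.acc_mean.drop(index="Mean", columns="Mean"),
                   tables.acc_sd).to_csv(out_dir / "table_acc.tsv", sep="\t")
    format_mean_sd(tables.auc_mean.drop(index="Mean", columns="Mean"),
                   tables.auc_sd, decimals=3).to_csv(out_dir / "table_auc.tsv", sep="\t")
    best = best_combination_per_subject(results)
    best.to_csv(out_dir / "best_per_subject.tsv", sep="\t", index=False)
    top = global_best(results)
    channel_rank = rank_channels(results, top["feature"], top["classifier"])
    channel_rank.to_csv(out_dir / "channel_ranking.tsv", sep="\t", index=False)

    summary = {
        "best_cell": {k: (float(top[k]) if k in ("acc", "auc") else
                          int(top[k]) if k == "subject" else str(top[k]))
                      for k in ("subject", "channel", "feature", "classifier", "acc", "auc")},
        "best_channel": str(channel_rank.iloc[0]["key"]),
        "n_no_signal_subjects": int(best["no_signal"].sum()),
    }
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary


def run_pipeline(cfg: RunConfig, run_dir: str | Path, write_raw: bool = True) -> dict:
    """Execute all stages into ``run_dir``; returns the summary dict."""
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    with open(run_dir / "manifest.json", "w") as fh:
        json.dump(_manifest(cfg), fh, indent=2, sort_keys=True)

    recordings = generate_dataset(cfg.synth)
    if write_raw:
        raw_dir = run_dir / "raw"
        raw_dir.mkdir(exist_ok=True)
        for rec in recordings:
            write_recording(rec, raw_dir / f"sub{rec.subject_id:02d}_{rec.state}.tsv")

    features = features_stage(recordings, cfg)
    features.to_csv(run_dir / "features.tsv", sep="\t", index=False)
    normalized = features if cfg.fold_normalize else normalize_features(features)
    normalized.to_csv(run_dir / "features_norm.tsv", sep="\t", index=False)

    specs = [ClassifierSpec(name=n, seed=cfg.seed) for n in cfg.classifiers]
    results = evaluate_grid(normalized, specs,
                            fold_normalize=cfg.fold_normalize, cv=cfg.cv)
    results.to_csv(run_dir / "results.tsv", sep="\t", index=False)

    summary = report_stage(results, run_dir / "report")
    logger.info("pipeline complete: best cell %s", summary["best_cell"])
    return summary
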