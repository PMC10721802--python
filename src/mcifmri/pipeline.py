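"""End-to-end orchestration of the experiment grid.

Runs simulate -> (extract -> parcellate) -> select -> evaluate over the grid
(metric sets) x (selectors) x (classifiers) and writes a JSON report with a
cross-method feature-frequency table and a provenance block.

Two evaluation modes:

* ``faithful`` — feature selection and the reported metrics use the same
  tenfold CV. This mirrors the original analysis protocol and is known to be
  optimistically biased (the selection has seen every fold's test data).
* ``honest`` — an outer CV wraps the whole selection: masks are chosen on the
  outer-training portion only and scored on the held-out outer fold, so the
  reported accuracy is selection-bias free.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import pathlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .evalkit import CLASSIFIERS, ConfusionMatrix, cross_validate, metrics_from_confusion, stratified_folds
from .featsel import METHODS, ObjectiveSpec, SearchBudget, run_feature_selection
from .parcellate import METRICS, FeatureTable, assemble_feature_table, region_of_feature
from .synthgen import CohortConfig, generate_feature_table, generate_image_cohort
from .voxmetrics import Band, bandpass_filter, compute_falff, compute_icc, compute_lcor

logger = logging.getLogger("mcifmri")

DEFAULT_METRIC_SETS: tuple[tuple[str, ...], ...] = (
    ("fALFF",),
    ("LCOR",),
    ("ICC",),
    ("fALFF", "LCOR", "ICC"),
)

__all__ = [
    "ExperimentConfig",
    "ExperimentReport",
    "run_experiment",
    "feature_frequency",
    "region_frequency",
    "extract_feature_table",
    "honest_cv_accuracy",
]


@dataclass(frozen=True)
class ExperimentConfig:
    """Full experiment description; everything derives from ``seed``."""

    cohort: CohortConfig = CohortConfig()
    image_level: bool = False  # False: plant effects directly at feature level
    metric_sets: tuple[tuple[str, ...], ...] = DEFAULT_METRIC_SETS
    selectors: tuple[str, ...] = METHODS
    classifiers: tuple[str, ...] = CLASSIFIERS
    alpha: float = 0.9
    cv_folds: int = 10
    mode: str = "faithful"
    outer_folds: int = 5
    budget: SearchBudget = SearchBudget()
    rf_trees: int = 128  # forest size for grid runs (config-exposed)
    seed: int = 0
    output_dir: str | None = None

    def __post_init__(self) -> None:
        for s in self.selectors:
            if s not in METHODS:
                raise ValueError(f"unknown selector {s!r}")
        for c in self.classifiers:
            if c not in CLASSIFIERS:
                raise ValueError(f"unknown classifier {c!r}")
        for ms in self.metric_sets:
            unknown = set(ms) - set(METRICS)
            if unknown:
                raise ValueError(f"unknown metric(s) {sorted(unknown)}")
        if self.mode not in ("faithful", "honest"):
            raise ValueError("mode must be 'faithful' or 'honest'")

    def to_jsonable(self) -> dict:
        out = dataclasses.asdict(self)
        out.pop("output_dir")  # where a report lands is not part of the experiment
        out["cohort"]["grid_shape"] = (
            list(out["cohort"]["grid_shape"]) if out["cohort"]["grid_shape"] else None
        )
        return out


@dataclass
class ExperimentReport:
    cells: list[dict]
    feature_frequency: pd.DataFrame
    region_frequency: pd.DataFrame
    provenance: dict
    truth_regions: list[int] = field(default_factory=list)

    @property
    def report_hash(self) -> str:
        return self.provenance["report_hash"]

    def to_json(self, path=None) -> str:
        payload = {
            "provenance": self.provenance,
            "truth_regions": self.truth_regions,
            "cells": self.cells,
            "feature_frequency": self.feature_frequency.to_dict(orient="records"),
            "region_frequency": self.region_frequency.to_dict(orient="records"),
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            pathlib.Path(path).write_text(text)
        return text


def extract_feature_table(cohort, band: Band = Band()) -> FeatureTable:
    """Image-level cohorts: denoise, compute the three metric maps, parcellate."""
    subject_maps = {}
    for sid, _group, series in cohort.subjects:
        filtered = bandpass_filter(series, band)
        subject_maps[sid] = {
            "fALFF": compute_falff(series, band),  # full-spectrum input by design
            "LCOR": compute_lcor(filtered),
            "ICC": compute_icc(filtered),
        }
    return assemble_feature_table(subject_maps, cohort.atlas, cohort.labels)


def _cohort_table(config: ExperimentConfig) -> tuple[FeatureTable, np.ndarray]:
    if config.image_level:
        cohort = generate_image_cohort(config.cohort)
        table = extract_feature_table(cohort)
        return table, cohort.truth_mask
    return generate_feature_table(config.cohort)


def _subtable(table: FeatureTable, metric_set: tuple[str, ...]) -> FeatureTable:
    cols = [c for c in table.data.columns for m in metric_set if str(c).startswith(f"{m}__")]
    return FeatureTable(data=table.data[cols], labels=table.labels)


def _cell_seed(base: int, index: int) -> int:
    return (base * 1000 + index * 7 + 1) % (2**31 - 1)


def _clf_params(config: ExperimentConfig, classifier: str) -> dict | None:
    if classifier == "RF":
        return {"n_estimators": config.rf_trees}
    return None


def honest_cv_accuracy(
    table: FeatureTable,
    selector: str,
    classifier: str,
    config: ExperimentConfig,
    seed: int,
) -> tuple[float, ConfusionMatrix]:
    """Outer-CV accuracy with feature selection nested inside each outer fold."""
    y = table.y
    outer = stratified_folds(y, k=config.outer_folds, seed=seed)
    pooled = ConfusionMatrix(0, 0, 0, 0)
    for fold in range(outer.k):
        tr = outer.train_indices(fold)
        te = outer.test_indices(fold)
        train_tab = FeatureTable(data=table.data.iloc[tr], labels=table.labels.iloc[tr])
        spec = ObjectiveSpec(
            alpha=config.alpha,
            classifier=classifier,
            cv_folds=config.cv_folds,
            seed=_cell_seed(seed, fold),
            clf_params=_clf_params(config, classifier),
        )
        sel = run_feature_selection(selector, train_tab, spec, config.budget)
        # fit once on the whole outer-training split, score the held-out fold
        from .evalkit import make_classifier
        from sklearn.preprocessing import StandardScaler

        scaler = StandardScaler().fit(table.x[np.ix_(tr, sel.mask)])
        clf = make_classifier(classifier, seed=spec.seed, params=spec.clf_params)
        clf.fit(scaler.transform(table.x[np.ix_(tr, sel.mask)]), y[tr])
        pred = clf.predict(scaler.transform(table.x[np.ix_(te, sel.mask)]))
        pooled = pooled + ConfusionMatrix.from_predictions(y[te], pred)
    return (pooled.tp + pooled.tn) / pooled.total, pooled


def run_experiment(config: ExperimentConfig) -> ExperimentReport:
    """Execute the (metric set) x (selector) x (classifier) grid."""
    table, truth_mask = _cohort_table(config)
    truth_regions = sorted(
        {region_of_feature(c) for c, t in zip(table.feature_names, truth_mask) if t}
    )
    cells: list[dict] = []
    selected_lists: list[list[str]] = []
    index = 0
    for metric_set in config.metric_sets:
        sub = _subtable(table, metric_set)
        for selector in config.selectors:
            for classifier in config.classifiers:
                cell_seed = _cell_seed(config.seed, index)
                index += 1
                logger.info(
                    "cell %d: metrics=%s selector=%s classifier=%s",
                    index, "+".join(metric_set), selector, classifier,
                )
                try:
                    cell = _run_cell(sub, metric_set, selector, classifier, config, cell_seed)
                except Exception as exc:  # annotate the failing grid cell
                    raise RuntimeError(
                        f"grid cell (metrics={'+'.join(metric_set)}, selector={selector}, "
                        f"classifier={classifier}) failed during selection/evaluation: {exc}"
                    ) from exc
                cells.append(cell)
                selected_lists.append(cell["selected_features"])
    freq = feature_frequency(selected_lists)
    rfreq = region_frequency(selected_lists)
    config_json = json.dumps(config.to_jsonable(), sort_keys=True)
    provenance = {
        "package_version": __version__,
        "seed": config.seed,
        "config": config.to_jsonable(),
        "config_hash": hashlib.sha256(config_json.encode()).hexdigest(),
    }
    body = json.dumps(
        {"cells": cells, "frequency": freq.to_dict(orient="records")}, sort_keys=True
    )
    provenance["report_hash"] = hashlib.sha256((config_json + body).encode()).hexdigest()
    report = ExperimentReport(
        cells=cells,
        feature_frequency=freq,
        region_frequency=rfreq,
        provenance=provenance,
        truth_regions=truth_regions,
    )
    if config.output_dir:
        outdir = pathlib.Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        report.to_json(outdir / "report.json")
        freq.to_csv(outdir / "feature_frequency.csv", index=False)
        rfreq.to_csv(outdir / "region_frequency.csv", index=False)
    return report


def _run_cell(
    sub: FeatureTable,
    metric_set: tuple[str, ...],
    selector: str,
    classifier: str,
    config: ExperimentConfig,
    cell_seed: int,
) -> dict:
    spec = ObjectiveSpec(
        alpha=config.alpha,
        classifier=classifier,
        cv_folds=config.cv_folds,
        seed=cell_seed,
        clf_params=_clf_params(config, classifier),
    )
    sel = run_feature_selection(selector, sub, spec, config.budget)
    names = sub.feature_names
    cell = {
        "metric_set": list(metric_set),
        "selector": selector,
        "classifier": classifier,
        "seed": cell_seed,
        "n_selected": sel.fitness.n_selected,
        "selected_features": sel.selected_features(names),
        "selection_P": sel.fitness.p,
        "selection_f": sel.fitness.f,
    }
    if config.mode == "faithful":
        cv = cross_validate(
            sub.x, sub.y, mask=sel.mask, classifier=classifier,
            k=config.cv_folds, seed=cell_seed, clf_params=spec.clf_params,
        )
        cell["confusion"] = {
            "tn": cv.confusion.tn, "fp": cv.confusion.fp,
            "fn": cv.confusion.fn, "tp": cv.confusion.tp,
        }
        cell["metrics"] = cv.report.as_dict()
    else:
        acc, pooled = honest_cv_accuracy(sub, selector, classifier, config, cell_seed)
        cell["confusion"] = {
            "tn": pooled.tn, "fp": pooled.fp, "fn": pooled.fn, "tp": pooled.tp,
        }
        cell["metrics"] = metrics_from_confusion(pooled).as_dict()
    return cell


def feature_frequency(selected_lists: list[list[str]]) -> pd.DataFrame:
    """Count, per feature, how many selector runs included it.

    Sorted by descending count; ties broken by region index, then name.
    """
    if not selected_lists:
        raise ValueError("need at least one selection result")
    counts: dict[str, int] = {}
    for run in selected_lists:
        for name in set(run):
            counts[name] = counts.get(name, 0) + 1
    rows = [
        {"feature": name, "region": region_of_feature(name), "count": count}
        for name, count in counts.items()
    ]
    frame = pd.DataFrame(rows, columns=["feature", "region", "count"])
    return frame.sort_values(
        ["count", "region", "feature"], ascending=[False, True, True]
    ).reset_index(drop=True)


def region_frequency(selected_lists: list[list[str]]) -> pd.DataFrame:
    """Count, per atlas region, how many runs selected any of its columns."""
    if not selected_lists:
        raise ValueError("need at least one selection result")
    counts: dict[int, int] = {}
    for run in selected_lists:
        for region in {region_of_feature(n) for n in run}:
            counts[region] = counts.get(region, 0) + 1
    frame = pd.DataFrame(
        [{"region": r, "count": c} for r, c in counts.items()],
        columns=["region", "count"],
    )
    return frame.sort_values(["count", "region"], ascending=[False, True]).reset_index(drop=True)
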