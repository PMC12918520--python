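"""Sample-type driver analysis across laboratories.

Annotated features are merged by identical library ID (summing peak areas),
each laboratory's TIC-normalized subset is classified by a random forest,
importances are normalized per lab and averaged into a cross-laboratory
driver ranking, and the per-lab top-importance sets are intersected
UpSet-style to ask whether the same metabolites drive the sample-type
distinction everywhere.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.metrics import accuracy_score
from sklearn.model_selection import StratifiedKFold

from .stats import OverlapSummary, intersection_counts
from .tables import AlignedFeatureTable


@dataclass
class DriverResult:
    per_lab_accuracy: dict  # lab -> CV accuracy
    importance: pd.DataFrame  # labs x merged features, rows sum to 1
    ranking: pd.DataFrame  # mean importance and rank per feature
    top_driver_overlap: OverlapSummary
    errors: dict  # lab -> reason it was skipped


def merge_by_annotation(
    aligned: AlignedFeatureTable,
    annotations: dict | None = None,
    keep_unannotated: bool = False,
) -> AlignedFeatureTable:
    """Sum intensities of features sharing an identical library annotation.

    ``annotations`` (feature id -> library ID) overrides the table's own
    annotation column and may be partial.  Unannotated features are dropped
    by default (the driver path works on putatively identified metabolites)
    or passed through unchanged with ``keep_unannotated=True``.  Total
    intensity per sample column is conserved over the merged subset.
    """
    if annotations is not None:
        ann = pd.Series(
            [annotations.get(fid) for fid in aligned.intensities.index],
            index=aligned.intensities.index,
        )
    else:
        ann = aligned.features["annotation"]
    annotated = ann.notna()

    groups: dict[str, list[str]] = {}
    for fid in aligned.intensities.index[annotated]:
        groups.setdefault(str(ann[fid]), []).append(fid)

    rows, meta, provenance, index = [], [], {}, []
    for name in sorted(groups):
        members = groups[name]
        rows.append(aligned.intensities.loc[members].sum(axis=0))
        meta.append(
            {
                "mz": float(aligned.features.loc[members, "mz"].mean()),
                "rt": float(aligned.features.loc[members, "rt"].mean()),
                "annotation": name,
                "n_labs": np.nan,
            }
        )
        prov: list = []
        for m in members:
            prov.extend(aligned.provenance.get(m, [(None, m)]))
        provenance[name] = prov
        index.append(name)
    if keep_unannotated:
        for fid in aligned.intensities.index[~annotated]:
            rows.append(aligned.intensities.loc[fid])
            meta.append(dict(aligned.features.loc[fid, ["mz", "rt", "annotation"]]) | {"n_labs": np.nan})
            provenance[str(fid)] = list(aligned.provenance.get(fid, []))
            index.append(str(fid))

    intensities = pd.DataFrame(rows, index=index, columns=aligned.intensities.columns)
    features = pd.DataFrame(meta, index=index, columns=["mz", "rt", "annotation", "n_labs"])
    return dataclasses.replace(
        aligned, intensities=intensities, features=features, provenance=provenance
    )


def classify_per_lab(
    merged: AlignedFeatureTable,
    seed: int,
    n_estimators: int = 300,
    cv_folds: int = 5,
    importance: str = "impurity",
):
    """Random-forest sample-type classification, one model per laboratory.

    Expects a TIC-normalized table.  Accuracy is stratified k-fold
    cross-validation (k capped at the smallest class size); importances are
    impurity-based (default) or permutation-based, normalized to sum 1 per
    lab.  Laboratories whose subset has fewer than two classes with two
    samples each are recorded as errors and skipped.

    Returns ``(accuracies, importance_frame, errors)``.
    """
    if importance not in ("impurity", "permutation"):
        raise ValueError("importance must be 'impurity' or 'permutation'")
    feature_ids = list(merged.intensities.index)
    if not feature_ids:
        raise ValueError("merged table has no features")
    accuracies: dict[str, float] = {}
    errors: dict[str, str] = {}
    rows = {}
    non_blank = ~merged.samples["is_blank"].astype(bool)
    for lab in merged.labs:
        lab_mask = (merged.samples.index.get_level_values(0) == lab) & non_blank.to_numpy()
        cols = merged.samples.index[lab_mask]
        y = merged.samples.loc[cols, "sample_type"].to_numpy()
        counts = pd.Series(y).value_counts()
        if len(counts) < 2 or counts.min() < 2:
            errors[lab] = "needs >= 2 classes with >= 2 samples each"
            continue
        x = merged.intensities[cols].T.to_numpy()
        k = min(cv_folds, int(counts.min()))
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        correct, total = 0, 0
        for train, test in skf.split(x, y):
            clf = RandomForestClassifier(n_estimators=n_estimators, random_state=seed)
            clf.fit(x[train], y[train])
            correct += accuracy_score(y[test], clf.predict(x[test]), normalize=False)
            total += len(test)
        accuracies[lab] = correct / total

        clf = RandomForestClassifier(n_estimators=n_estimators, random_state=seed)
        clf.fit(x, y)
        if importance == "impurity":
            imp = clf.feature_importances_
        else:
            imp = permutation_importance(
                clf, x, y, n_repeats=10, random_state=seed
            ).importances_mean
            imp = np.clip(imp, 0.0, None)
        s = imp.sum()
        rows[lab] = imp / s if s > 0 else np.full(len(imp), 1.0 / len(imp))
    importance_frame = pd.DataFrame(rows, index=feature_ids).T
    return accuracies, importance_frame, errors


def rank_mean_importance(importance: pd.DataFrame) -> pd.DataFrame:
    """Rank features by unweighted mean importance across laboratories.

    Ties are broken by feature ID.  Returns a frame sorted best-first with
    ``mean_importance`` and 1-based ``rank`` columns.
    """
    if importance.size == 0:
        raise ValueError("importance matrix is empty")
    mean_imp = importance.mean(axis=0)
    order = sorted(mean_imp.index, key=lambda fid: (-mean_imp[fid], str(fid)))
    out = pd.DataFrame(
        {"mean_importance": mean_imp.loc[order], "rank": np.arange(1, len(order) + 1)}
    )
    return out


def driver_overlap(importance: pd.DataFrame, top_fraction: float = 0.05) -> OverlapSummary:
    """UpSet intersection of each laboratory's top-importance feature set.

    Per lab, the top ``ceil(top_fraction * n_features)`` features by
    importance (ties broken by feature ID) form the lab's driver set.
    """
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must be in (0, 1]")
    if importance.size == 0:
        raise ValueError("importance matrix is empty")
    n_top = math.ceil(top_fraction * importance.shape[1])
    presence = {}
    for lab in importance.index:
        row = importance.loc[lab]
        order = sorted(row.index, key=lambda fid: (-row[fid], str(fid)))
        presence[lab] = set(order[:n_top])
    return intersection_counts(presence)


def analyze_drivers(
    merged: AlignedFeatureTable,
    seed: int,
    top_fraction: float = 0.05,
    n_estimators: int = 300,
    cv_folds: int = 5,
    importance: str = "impurity",
) -> DriverResult:
    """End-to-end driver battery on an annotation-merged, TIC-normalized table."""
    accuracies, imp, errors = classify_per_lab(
        merged, seed, n_estimators=n_estimators, cv_folds=cv_folds, importance=importance
    )
    if imp.size == 0:
        raise ValueError("no laboratory produced a usable model")
    ranking = rank_mean_importance(imp)
    overlap = driver_overlap(imp, top_fraction)
    return DriverResult(accuracies, imp, ranking, overlap, errors)


def abundance_trends(merged: AlignedFeatureTable, feature_ids) -> pd.DataFrame:
    """Sample-centric normalized abundance per sample type for selected drivers.

    For each feature, the mean intensity per sample type (non-blank) is
    scaled to its maximum across types, giving the 0-1 trend curves used to
    read gradient direction.
    """
    cols = merged.sample_columns
    types = merged.samples.loc[cols, "sample_type"]
    out = {}
    for fid in feature_ids:
        means = merged.intensities.loc[fid, cols].groupby(types).mean()
        top = means.max()
        out[fid] = means / top if top > 0 else means
    return pd.DataFrame(out).T
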