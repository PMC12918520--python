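"""Per-laboratory quality gating and dataset metrics.

A laboratory enters the unified analysis when at least ``min_standards`` of
the eight spiked internal standards are matched in its dataset (default 6).
Dataset metrics mirror the usual molecular-networking summary: cluster and
library-ID counts, annotation rate, the median retention-time deviation of
the matched standards, and the chimeric-spectrum rate (fraction of MS/MS
events whose precursor purity falls below a threshold, default 0.9).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .align import cosine_similarity
from .standards import standard_library


@dataclass
class QcReport:
    lab_id: str
    standards_matched: int
    included: bool
    n_clusters: int
    n_library_ids: int
    annotation_rate: float | None  # None when no clusters (undefined, not divided)
    median_rt_deviation: float
    mean_purity: float
    chimera_rate: float

    def __post_init__(self) -> None:
        if not 0 <= self.standards_matched <= 8:
            raise ValueError("standards_matched must be in 0..8")
        for name in ("annotation_rate", "chimera_rate"):
            v = getattr(self, name)
            if v is not None and not np.isnan(v) and not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")


def match_standards(
    table,
    library: list[dict] | None = None,
    mz_tol_ppm: float = 10.0,
    rt_tol: float = 1.7,
    cosine_min: float = 0.7,
    spectra: dict | None = None,
    return_detail: bool = False,
):
    """Count internal standards matched in a laboratory dataset.

    A standard matches a feature when the m/z agrees within ``mz_tol_ppm``,
    the retention time within ``rt_tol`` minutes, and — when ``spectra``
    supplies a fragment list for the feature — the cosine against the library
    fragments is at least ``cosine_min``.  Each feature is assigned to at
    most one standard (best candidate by smallest ppm error).
    """
    if library is None:
        library = standard_library()
    if not library:
        raise ValueError("standard library is empty")
    if mz_tol_ppm <= 0 or rt_tol <= 0:
        raise ValueError("tolerances must be positive")
    if table is None or table.n_features == 0:
        return (0, pd.DataFrame(columns=["standard", "feature", "ppm_error", "rt_deviation"])) if return_detail else 0

    feats = table.features
    candidates = []  # (ppm_err, std_idx, feature_id, rt_dev)
    for si, std in enumerate(library):
        ppm_err = (feats["mz"] - std["mz"]).abs() / std["mz"] * 1e6
        rt_dev = (feats["rt"] - std["rt"]).abs()
        ok = (ppm_err <= mz_tol_ppm) & (rt_dev <= rt_tol)
        for fid in feats.index[ok]:
            if spectra is not None and fid in spectra:
                if cosine_similarity(spectra[fid], std["fragments"]) < cosine_min:
                    continue
            candidates.append((float(ppm_err[fid]), si, str(fid), float(rt_dev[fid])))

    candidates.sort()
    used_std: set[int] = set()
    used_feat: set[str] = set()
    rows = []
    for ppm_err, si, fid, rt_dev in candidates:
        if si in used_std or fid in used_feat:
            continue
        used_std.add(si)
        used_feat.add(fid)
        rows.append(
            {
                "standard": library[si]["name"],
                "feature": fid,
                "ppm_error": ppm_err,
                "rt_deviation": rt_dev,
            }
        )
    detail = pd.DataFrame(rows, columns=["standard", "feature", "ppm_error", "rt_deviation"])
    return (len(rows), detail) if return_detail else len(rows)


def select_labs(reports: list[QcReport], min_standards: int = 6) -> list[str]:
    """Labs passing the standards gate, in input order."""
    ids = [r.lab_id for r in reports]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate lab ids in QC reports")
    return [r.lab_id for r in reports if r.standards_matched >= min_standards]


def precursor_purity(precursor_mz: float, ms1_scan, isolation_width: float = 1.0) -> float:
    """Precursor share of summed MS1 intensity inside the isolation window.

    The window is ``[mz - w/2, mz + w/2)`` — closed lower, open upper edge.
    The scan must contain the precursor peak itself.
    """
    if isolation_width <= 0:
        raise ValueError("isolation_width must be positive")
    peaks = [(float(m), float(i)) for m, i in ms1_scan]
    if not peaks:
        raise ValueError("empty MS1 scan")
    mz = np.array([p[0] for p in peaks])
    inten = np.array([p[1] for p in peaks])
    matches = np.isclose(mz, precursor_mz, rtol=0, atol=1e-6)
    if not matches.any():
        raise ValueError(f"precursor {precursor_mz} not found in MS1 scan")
    prec_intensity = float(inten[matches].max())
    half = isolation_width / 2.0
    window = (mz >= precursor_mz - half) & (mz < precursor_mz + half)
    total = float(inten[window].sum())
    if total <= 0:
        raise ValueError("isolation window has no intensity")
    return min(prec_intensity / total, 1.0)


def dataset_metrics(
    table,
    events,
    annotations: dict | None = None,
    purity_threshold: float = 0.9,
    library: list[dict] | None = None,
    mz_tol_ppm: float = 10.0,
    rt_tol: float = 1.7,
    min_standards: int = 6,
) -> QcReport:
    """Assemble the per-laboratory QC report.

    ``annotations`` overrides the table's own annotation column (feature id
    -> library ID).  ``annotation_rate = n_library_ids / n_clusters`` is left
    undefined (None) when the table has no features.
    """
    if not 0 < purity_threshold <= 1:
        raise ValueError("purity_threshold must be in (0, 1]")
    n_clusters = table.n_features
    if annotations is not None:
        ann = pd.Series(
            [annotations.get(fid) for fid in table.features.index], index=table.features.index
        )
    else:
        ann = table.features["annotation"]
    n_ids = int(ann.notna().sum())
    rate = n_ids / n_clusters if n_clusters else None

    purities = np.array([ev.purity for ev in events]) if events else np.array([])
    mean_purity = float(purities.mean()) if purities.size else float("nan")
    chimera_rate = float((purities < purity_threshold).mean()) if purities.size else float("nan")

    matched, detail = match_standards(
        table, library, mz_tol_ppm=mz_tol_ppm, rt_tol=rt_tol, return_detail=True
    )
    median_rt_dev = float(detail["rt_deviation"].median()) if len(detail) else float("nan")

    return QcReport(
        lab_id=table.lab_id or "lab",
        standards_matched=matched,
        included=matched >= min_standards,
        n_clusters=n_clusters,
        n_library_ids=n_ids,
        annotation_rate=rate,
        median_rt_deviation=median_rt_dev,
        mean_purity=mean_purity,
        chimera_rate=chimera_rate,
    )


def qc_summary_table(reports: list[QcReport]) -> pd.DataFrame:
    """One row per laboratory, mirroring the usual networking-metrics table."""
    return pd.DataFrame(
        [
            {
                "lab_id": r.lab_id,
                "standards_matched": r.standards_matched,
                "included": r.included,
                "n_clusters": r.n_clusters,
                "n_library_ids": r.n_library_ids,
                "annotation_rate": r.annotation_rate,
                "median_rt_deviation": r.median_rt_deviation,
                "mean_purity": r.mean_purity,
                "chimera_rate": r.chimera_rate,
            }
            for r in reports
        ]
    ).set_index("lab_id")
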