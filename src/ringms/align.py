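"""Cross-laboratory feature alignment.

Two modes mirror the two molecular-networking conventions for unifying
non-targeted LC-MS/MS datasets:

* ``align_mz_rt`` (FBMN-style): features are merged across laboratories when
  their MS1 m/z agree within a ppm (or Da) tolerance and their retention
  times within an absolute tolerance.  Clustering is greedy-centroid on
  features sorted by descending mean intensity, which is deterministic and
  independent of input lab order.
* ``align_spectral`` (CMN-style): MS/MS spectra are single-linkage clustered
  by precursor m/z proximity and cosine similarity; retention time is
  ignored and cluster abundance per (lab, sample) is the maximum precursor
  intensity among member spectra.
"""

from __future__ import annotations

import math
from collections import Counter

import numpy as np
import pandas as pd

from .simulate import MsmsEvent
from .tables import AlignedFeatureTable, FeatureTable


# ---------------------------------------------------------------------------
# Cosine similarity
# ---------------------------------------------------------------------------

def cosine_similarity(spec_a, spec_b, frag_tol: float = 0.02, weighting: str = "sqrt") -> float:
    """Greedy-matched cosine between two peak lists.

    Peaks are paired within ``frag_tol`` Da, best pairs (largest weighted
    intensity product) first, each peak used at most once; the score is the
    dot product of the matched weighted intensities over the product of the
    full-spectrum norms, hence in [0, 1] and symmetric.  ``weighting`` is
    ``"sqrt"`` (square-root intensity, the spectral-networking convention) or
    ``"raw"``.
    """
    a = _as_peaks(spec_a, "spec_a")
    b = _as_peaks(spec_b, "spec_b")
    if weighting == "sqrt":
        wa, wb = np.sqrt(a[1]), np.sqrt(b[1])
    elif weighting == "raw":
        wa, wb = a[1], b[1]
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    norm = math.sqrt(float(wa @ wa)) * math.sqrt(float(wb @ wb))
    if norm == 0:
        return 0.0
    ia, ib = np.nonzero(np.abs(a[0][:, None] - b[0][None, :]) <= frag_tol)
    if ia.size == 0:
        return 0.0
    products = wa[ia] * wb[ib]
    order = np.argsort(-products, kind="stable")
    used_a: set[int] = set()
    used_b: set[int] = set()
    score = 0.0
    for k in order:
        i, j = int(ia[k]), int(ib[k])
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        score += float(products[k])
    return min(score / norm, 1.0)


def _as_peaks(spec, name: str):
    peaks = list(spec)
    if not peaks:
        raise ValueError(f"{name} is empty")
    mz = np.array([p[0] for p in peaks], dtype=float)
    inten = np.array([p[1] for p in peaks], dtype=float)
    if np.any(inten < 0):
        raise ValueError(f"{name} has negative intensities")
    return mz, inten


# ---------------------------------------------------------------------------
# FBMN-style m/z + RT alignment
# ---------------------------------------------------------------------------

def align_mz_rt(
    tables: list[FeatureTable],
    mz_tol_ppm: float = 10.0,
    rt_tol: float = 1.7,
    mz_tol_da: float | None = None,
) -> AlignedFeatureTable:
    """Merge per-laboratory feature tables on MS1 m/z and retention time.

    Pooled features are processed in descending mean-intensity order; each
    joins the nearest existing cluster lying within both tolerances that does
    not already contain a feature from the same laboratory, else it seeds a
    new cluster.  Cluster centroids are intensity-weighted means.  The m/z
    tolerance is in ppm by default; pass ``mz_tol_da`` for an absolute
    window.
    """
    if not tables:
        raise ValueError("need at least one feature table")
    if mz_tol_ppm <= 0 or rt_tol <= 0 or (mz_tol_da is not None and mz_tol_da <= 0):
        raise ValueError("tolerances must be positive")
    labs = [t.lab_id or f"lab{i}" for i, t in enumerate(tables)]
    if len(set(labs)) != len(labs):
        raise ValueError("duplicate lab ids across input tables")

    # pooled records in canonical order (input lab order must not matter)
    records = []
    for lab, table in zip(labs, tables):
        means = table.intensities.mean(axis=1)
        for fid in table.intensities.index:
            row = table.features.loc[fid]
            records.append(
                (
                    -float(means[fid]),
                    lab,
                    str(fid),
                    float(row["mz"]),
                    float(row["rt"]),
                    row["annotation"],
                    float(means[fid]),
                )
            )
    records.sort(key=lambda r: (r[0], r[1], r[2]))

    def tol_of(mz: float) -> float:
        return mz_tol_da if mz_tol_da is not None else mz * mz_tol_ppm * 1e-6

    bin_width = max(0.05, 2.0 * (mz_tol_da or 0.0))
    clusters: list[dict] = []
    bins: dict[int, list[int]] = {}
    for _, lab, fid, mz, rt, annotation, weight in records:
        tol = tol_of(mz)
        b = int(mz // bin_width)
        best, best_dist = None, None
        for bb in (b - 1, b, b + 1):
            for ci in bins.get(bb, ()):
                c = clusters[ci]
                if lab in c["labs"]:
                    continue
                dmz = abs(c["mz"] - mz)
                drt = abs(c["rt"] - rt)
                if dmz > tol or drt > rt_tol:
                    continue
                dist = math.hypot(dmz / tol, drt / rt_tol)
                if best_dist is None or dist < best_dist:
                    best, best_dist = ci, dist
        if best is None:
            ci = len(clusters)
            clusters.append(
                {
                    "mz": mz,
                    "rt": rt,
                    "w": max(weight, 1e-12),
                    "labs": {lab},
                    "members": [(lab, fid)],
                    "annotations": [annotation] if pd.notna(annotation) else [],
                }
            )
            bins.setdefault(b, []).append(ci)
        else:
            c = clusters[best]
            w_new = max(weight, 1e-12)
            w_tot = c["w"] + w_new
            old_bin = int(c["mz"] // bin_width)
            c["mz"] = (c["mz"] * c["w"] + mz * w_new) / w_tot
            c["rt"] = (c["rt"] * c["w"] + rt * w_new) / w_tot
            c["w"] = w_tot
            c["labs"].add(lab)
            c["members"].append((lab, fid))
            if pd.notna(annotation):
                c["annotations"].append(annotation)
            new_bin = int(c["mz"] // bin_width)
            if new_bin != old_bin:
                bins[old_bin].remove(best)
                bins.setdefault(new_bin, []).append(best)

    return _build_aligned(clusters, dict(zip(labs, tables)), mode="mz_rt")


def _consensus_annotation(annotations: list) -> object:
    if not annotations:
        return np.nan
    counts = Counter(annotations)
    top = max(counts.values())
    return sorted(a for a, c in counts.items() if c == top)[0]


def _build_aligned(clusters, tables_by_lab, mode: str) -> AlignedFeatureTable:
    order = sorted(range(len(clusters)), key=lambda i: (clusters[i]["mz"], clusters[i].get("rt", 0.0)))
    gids = [f"G{k:06d}" for k in range(len(order))]

    columns = []
    sample_type, is_blank = [], []
    for lab, table in tables_by_lab.items():
        for s in table.intensities.columns:
            columns.append((lab, s))
            sample_type.append(table.samples.loc[s, "sample_type"])
            is_blank.append(bool(table.samples.loc[s, "is_blank"]))
    col_index = pd.MultiIndex.from_tuples(columns, names=("lab", "sample"))
    if col_index.has_duplicates:
        raise ValueError("conflicting duplicate (lab, sample) columns")
    col_pos = {c: i for i, c in enumerate(columns)}

    matrix = np.zeros((len(order), len(columns)))
    meta_rows = []
    provenance = {}
    for k, ci in enumerate(order):
        c = clusters[ci]
        for lab, fid in c["members"]:
            row = tables_by_lab[lab].intensities.loc[fid]
            for s, v in row.items():
                if v:
                    matrix[k, col_pos[(lab, s)]] = v
        meta_rows.append(
            {
                "mz": c["mz"],
                "rt": c.get("rt", np.nan),
                "annotation": _consensus_annotation(c["annotations"]),
                "n_labs": len(c["labs"]),
            }
        )
        provenance[gids[k]] = list(c["members"])

    intensities = pd.DataFrame(matrix, index=gids, columns=col_index)
    features = pd.DataFrame(meta_rows, index=gids)
    samples = pd.DataFrame(
        {"sample_type": sample_type, "is_blank": is_blank}, index=col_index
    )
    return AlignedFeatureTable(intensities, features, samples, provenance, mode)


# ---------------------------------------------------------------------------
# CMN-style spectral alignment
# ---------------------------------------------------------------------------

def _spectrum_records(spectra_by_lab) -> list[dict]:
    records = []
    for lab, spectra in spectra_by_lab.items():
        for i, s in enumerate(spectra):
            if isinstance(s, MsmsEvent):
                rec = {
                    "lab": lab,
                    "sample": s.sample_id or "sample",
                    "precursor_mz": s.precursor_mz,
                    "precursor_intensity": s.precursor_intensity,
                    "peaks": s.fragments,
                    "source": s.source_compound or f"scan{i}",
                }
            else:
                params = s.get("params", {})
                pepmass = params.get("pepmass", (None, None))
                rec = {
                    "lab": lab,
                    "sample": s.get("sample") or params.get("sample", "sample"),
                    "precursor_mz": float(pepmass[0]),
                    "precursor_intensity": float(pepmass[1] if len(pepmass) > 1 and pepmass[1] else 0.0),
                    "peaks": list(zip(s["m/z array"], s["intensity array"])),
                    "source": params.get("title", f"scan{i}"),
                }
            if rec["precursor_mz"] is None or rec["precursor_mz"] <= 0:
                raise ValueError(f"spectrum {i} of lab {lab!r} lacks a precursor m/z")
            if rec["peaks"]:
                records.append(rec)
    records.sort(key=lambda r: (r["precursor_mz"], r["lab"], r["sample"], -r["precursor_intensity"]))
    return records


def align_spectral(
    spectra_by_lab: dict,
    cosine_min: float = 0.7,
    precursor_tol: float = 0.01,
    frag_tol: float = 0.02,
    samples_by_lab: dict | None = None,
) -> AlignedFeatureTable:
    """Single-linkage clustering of MS/MS spectra across laboratories.

    ``spectra_by_lab`` maps lab id to a list of :class:`MsmsEvent` or
    MGF-style spectrum dicts.  Spectra join the same cluster when linked by a
    chain of pairs with precursor m/z within ``precursor_tol`` Da and cosine
    >= ``cosine_min``.  Cluster abundance per (lab, sample) is the maximum
    precursor intensity among members; consensus RT is undefined (NaN).
    ``samples_by_lab`` optionally maps lab id to a sample-metadata DataFrame
    (index sample id, columns sample_type / is_blank); otherwise sample type
    is parsed from sample ids of the form ``<type>_<replicate>``.
    """
    if not 0 < cosine_min <= 1:
        raise ValueError("cosine_min must be in (0, 1]")
    if precursor_tol <= 0:
        raise ValueError("precursor_tol must be positive")
    records = _spectrum_records(spectra_by_lab)
    n = len(records)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: int, y: int) -> None:
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[max(rx, ry)] = min(rx, ry)

    mzs = np.array([r["precursor_mz"] for r in records])
    cos_cache: dict[tuple[int, int], float] = {}
    for i in range(n):
        j = i + 1
        while j < n and mzs[j] - mzs[i] <= precursor_tol:
            if find(i) != find(j):
                score = cos_cache.get((i, j))
                if score is None:
                    score = cosine_similarity(records[i]["peaks"], records[j]["peaks"], frag_tol)
                    cos_cache[(i, j)] = score
                if score >= cosine_min:
                    union(i, j)
            j += 1

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)

    clusters = []
    for root in sorted(groups):
        members = groups[root]
        weights = np.array([records[i]["precursor_intensity"] for i in members])
        w = weights if weights.sum() > 0 else np.ones(len(members))
        clusters.append(
            {
                "mz": float(np.average(mzs[members], weights=w)),
                "rt": np.nan,
                "labs": {records[i]["lab"] for i in members},
                "member_idx": members,
                "annotations": [],
            }
        )

    # columns and pseudo-tables for matrix assembly
    labs = list(spectra_by_lab)
    columns: list[tuple] = []
    sample_type, is_blank = [], []
    seen = set()
    for lab in labs:
        lab_samples = sorted({r["sample"] for r in records if r["lab"] == lab})
        meta = samples_by_lab.get(lab) if samples_by_lab else None
        for s in lab_samples:
            if (lab, s) in seen:
                continue
            seen.add((lab, s))
            columns.append((lab, s))
            if meta is not None and s in meta.index:
                sample_type.append(meta.loc[s, "sample_type"])
                is_blank.append(bool(meta.loc[s, "is_blank"]))
            else:
                stype = str(s).rsplit("_", 1)[0]
                sample_type.append(stype)
                is_blank.append(stype == "blank")
    col_index = pd.MultiIndex.from_tuples(columns, names=("lab", "sample")) if columns else pd.MultiIndex.from_arrays([[], []], names=("lab", "sample"))
    col_pos = {c: i for i, c in enumerate(columns)}

    order = sorted(range(len(clusters)), key=lambda i: clusters[i]["mz"])
    gids = [f"S{k:06d}" for k in range(len(order))]
    matrix = np.zeros((len(order), len(columns)))
    meta_rows = []
    provenance = {}
    for k, ci in enumerate(order):
        c = clusters[ci]
        for i in c["member_idx"]:
            r = records[i]
            pos = col_pos[(r["lab"], r["sample"])]
            matrix[k, pos] = max(matrix[k, pos], r["precursor_intensity"])
        meta_rows.append({"mz": c["mz"], "rt": np.nan, "annotation": np.nan, "n_labs": len(c["labs"])})
        provenance[gids[k]] = [(records[i]["lab"], records[i]["source"]) for i in c["member_idx"]]

    intensities = pd.DataFrame(matrix, index=gids, columns=col_index)
    features = pd.DataFrame(meta_rows, index=gids, columns=["mz", "rt", "annotation", "n_labs"])
    samples = pd.DataFrame({"sample_type": sample_type, "is_blank": is_blank}, index=col_index)
    return AlignedFeatureTable(intensities, features, samples, provenance, "spectral")
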