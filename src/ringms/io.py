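"""Delimited-text and MGF exchange formats.

Per-laboratory feature tables are tab-separated with one header row
(``feature_id, mz, rt, annotation`` then sample columns); sample types are
encoded in the column names as ``<type>_<replicate>`` and blanks as
``blank_<n>``.  Aligned matrices flatten the (lab, sample) column index as
``lab|sample`` and ship a provenance sidecar.  Spectra travel as MGF via
pyteomics.  Round-trips are lossless: floats are written with 17 significant
digits and parsed with the correctly-rounded reader.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from pyteomics import mgf as _mgf

from .tables import AlignedFeatureTable, FeatureTable

_META_COLS = ["feature_id", "mz", "rt", "annotation"]


def _sample_meta_from_names(names) -> pd.DataFrame:
    types = [str(s).rsplit("_", 1)[0] for s in names]
    return pd.DataFrame(
        {"sample_type": types, "is_blank": [t == "blank" for t in types]},
        index=pd.Index(names, name="sample"),
    )


def write_feature_table(table: FeatureTable, path, config_hash: str | None = None) -> None:
    path = Path(path)
    out = pd.concat(
        [table.features[["mz", "rt", "annotation"]], table.intensities], axis=1
    )
    out.index.name = "feature_id"
    with path.open("w") as fh:
        if config_hash:
            fh.write(f"# config_hash={config_hash}\n")
        if table.lab_id:
            fh.write(f"# lab_id={table.lab_id}\n")
        out.to_csv(fh, sep="\t", float_format="%.17g")


def read_feature_table(path, lab_id: str | None = None) -> FeatureTable:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    header_lab = None
    with path.open() as fh:
        first = fh.readline()
        while first.startswith("#"):
            if first.startswith("# lab_id="):
                header_lab = first.split("=", 1)[1].strip()
            first = fh.readline()
    if not first.strip():
        raise ValueError(f"{path}: empty feature table file")
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"feature_id": str}, float_precision="round_trip")
    missing = [c for c in _META_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing header column(s) {missing}")
    df = df.set_index("feature_id")
    sample_cols = [c for c in df.columns if c not in ("mz", "rt", "annotation")]
    if not sample_cols:
        raise ValueError(f"{path}: no sample columns")
    intensities = df[sample_cols].astype(float)
    features = df[["mz", "rt", "annotation"]].copy()
    samples = _sample_meta_from_names(sample_cols)
    return FeatureTable(intensities, features, samples, lab_id=lab_id or header_lab)


def write_aligned_table(aligned: AlignedFeatureTable, prefix, config_hash: str | None = None) -> tuple[Path, Path]:
    """Write the aligned matrix and its provenance sidecar; returns both paths."""
    prefix = Path(prefix)
    matrix_path = prefix.with_suffix(".tsv")
    prov_path = Path(str(prefix) + ".provenance.tsv")
    flat = aligned.intensities.copy()
    flat.columns = [f"{lab}|{sample}" for lab, sample in aligned.intensities.columns]
    out = pd.concat(
        [aligned.features[["mz", "rt", "annotation"]], flat], axis=1
    )
    out.index.name = "feature_id"
    with matrix_path.open("w") as fh:
        if config_hash:
            fh.write(f"# config_hash={config_hash}\n")
        fh.write(f"# mode={aligned.mode}\n")
        out.to_csv(fh, sep="\t", float_format="%.17g")
    with prov_path.open("w") as fh:
        fh.write("global_feature_id\tsources\n")
        for gid in aligned.intensities.index:
            pairs = aligned.provenance.get(gid, [])
            fh.write(f"{gid}\t" + ";".join(f"{lab}:{fid}" for lab, fid in pairs) + "\n")
    return matrix_path, prov_path


def read_aligned_table(matrix_path, provenance_path=None) -> AlignedFeatureTable:
    matrix_path = Path(matrix_path)
    mode = "mz_rt"
    with matrix_path.open() as fh:
        line = fh.readline()
        while line.startswith("#"):
            if line.startswith("# mode="):
                mode = line.split("=", 1)[1].strip()
            line = fh.readline()
    if not line.strip():
        raise ValueError(f"{matrix_path}: empty aligned table file")
    df = pd.read_csv(matrix_path, sep="\t", comment="#", dtype={"feature_id": str}, float_precision="round_trip").set_index(
        "feature_id"
    )
    missing = [c for c in ("mz", "rt", "annotation") if c not in df.columns]
    if missing:
        raise ValueError(f"{matrix_path}: missing header column(s) {missing}")
    sample_cols = [c for c in df.columns if c not in ("mz", "rt", "annotation")]
    pairs = []
    for c in sample_cols:
        if "|" not in c:
            raise ValueError(f"{matrix_path}: column {c!r} is not of the form lab|sample")
        pairs.append(tuple(c.split("|", 1)))
    col_index = pd.MultiIndex.from_tuples(pairs, names=("lab", "sample"))
    intensities = df[sample_cols].astype(float)
    intensities.columns = col_index
    features = df[["mz", "rt", "annotation"]].copy()
    features["n_labs"] = np.nan
    types = [s.rsplit("_", 1)[0] for _, s in pairs]
    samples = pd.DataFrame(
        {"sample_type": types, "is_blank": [t == "blank" for t in types]}, index=col_index
    )
    provenance = {}
    if provenance_path is not None and Path(provenance_path).exists():
        with Path(provenance_path).open() as fh:
            fh.readline()
            for line in fh:
                gid, _, src = line.rstrip("\n").partition("\t")
                provenance[gid] = [
                    tuple(item.split(":", 1)) for item in src.split(";") if item
                ]
    return AlignedFeatureTable(intensities, features, samples, provenance, mode)


def write_mgf(spectra: list[dict], path) -> None:
    with Path(path).open("w") as fh:
        _mgf.write(spectra, fh)


def read_mgf(path) -> list[dict]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    spectra = []
    with _mgf.read(str(path)) as reader:
        for i, spec in enumerate(reader):
            params = spec.get("params", {})
            if "pepmass" not in params or params["pepmass"] is None:
                raise ValueError(f"{path}: spectrum {i} is missing PEPMASS")
            spectra.append(spec)
    return spectra


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=str) + "\n")
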