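"""Feature-table preprocessing: blank filtering, zero imputation, total-ion-
current normalization, and top-N intensity restriction.

The canonical order of operations is blank_filter -> impute_zeros ->
tic_normalize -> (optional top_n_subset).  All functions are pure: they
return new tables and never mutate their inputs.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd


def _replace_intensities(table, intensities: pd.DataFrame):
    return dataclasses.replace(table, intensities=intensities)


def blank_filter(table, blank_ratio: float = 0.3, aggregate: str = "mean"):
    """Remove features whose blank signal exceeds ``blank_ratio`` of the
    sample signal.

    A feature is removed iff ``agg(blank intensities) > blank_ratio *
    agg(sample intensities)`` with a strictly-greater comparison, so a
    feature sitting exactly at the threshold (e.g. blank mean 30 vs sample
    mean 100 at ratio 0.3) is retained.  ``aggregate`` is ``"mean"``
    (default) or ``"max"``.

    Returns ``(filtered_table, removed_ids, log)`` where ``log`` is a
    per-feature DataFrame with blank/sample aggregates, their ratio and the
    decision.
    """
    if blank_ratio < 0:
        raise ValueError("blank_ratio must be >= 0")
    if aggregate not in ("mean", "max"):
        raise ValueError("aggregate must be 'mean' or 'max'")
    blanks = table.blank_columns
    samples = table.sample_columns
    if not blanks:
        raise ValueError("table has no blank columns; blank filtering cannot be applied")
    if not samples:
        raise ValueError("table has no non-blank sample columns")
    agg = getattr(table.intensities[blanks], aggregate)(axis=1)
    sample_agg = getattr(table.intensities[samples], aggregate)(axis=1)
    removed_mask = agg > blank_ratio * sample_agg
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = agg / sample_agg
    log = pd.DataFrame(
        {
            "blank_" + aggregate: agg,
            "sample_" + aggregate: sample_agg,
            "ratio": ratio,
            "removed": removed_mask,
        }
    )
    kept = table.intensities.index[~removed_mask]
    removed = list(table.intensities.index[removed_mask])
    return table.subset_features(kept), removed, log


def drop_blanks(table):
    """Drop blank columns (used after blank filtering, before statistics)."""
    keep = ~table.samples["is_blank"].astype(bool)
    intensities = table.intensities.loc[:, keep.to_numpy()]
    out = dataclasses.replace(table, intensities=intensities, samples=table.samples[keep])
    return out


def impute_zeros(table):
    """Replace zeros by half the smallest nonzero value of the whole matrix."""
    values = table.intensities.to_numpy()
    if values.size == 0:
        raise ValueError("table is empty")
    nonzero = values[values > 0]
    if nonzero.size == 0:
        raise ValueError("all-zero matrix cannot be imputed")
    if (values > 0).all():
        return _replace_intensities(table, table.intensities.copy())
    fill = float(nonzero.min()) / 2.0
    imputed = table.intensities.where(table.intensities > 0, fill)
    return _replace_intensities(table, imputed)


def tic_normalize(table):
    """Divide each sample column by its total so columns sum to 1."""
    sums = table.intensities.sum(axis=0)
    zero = sums[sums <= 0]
    if len(zero):
        raise ValueError(f"zero-sum column(s): {list(zero.index)}")
    return _replace_intensities(table, table.intensities / sums)


def top_n_subset(table, n: int, rank_by: str = "mean"):
    """Keep the ``n`` features with the highest mean intensity across samples.

    Ties are broken by feature id (lexicographically smaller first); the
    output is in rank order.  Requesting more features than available returns
    the whole table with a warning.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if rank_by != "mean":
        raise ValueError("only rank_by='mean' is supported")
    means = table.intensities.mean(axis=1)
    order = sorted(means.index, key=lambda fid: (-means[fid], str(fid)))
    if n > len(order):
        warnings.warn(
            f"requested top {n} of {len(order)} features; returning all", stacklevel=2
        )
        n = len(order)
    return table.subset_features(order[:n])
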