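"""Ratiometric normalization, fold-change classification and transforms.

For each comparison the raw ratiometric value of a protein is its
case-pool intensity divided by its control-pool intensity.  Dividing all
ratios of a comparison by their median ("1/median" loading correction)
makes the median ratio exactly 1, removing pool-level loading
differences.  Proteins are then called UP when the normalized ratio is
>= 1.2 and DOWN when it is <= 0.8 — the +/-20% change criterion.  Note
the thresholds are not reciprocal (1/1.2 ~ 0.833 > 0.8), so the
classifier is deliberately asymmetric around 1.

Row z-scores and a Euclidean-distance hierarchical ordering support
heatmap-style displays of the log2 ratios.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

from .design import ComparisonDesign
from .errors import ConfigError, SchemaError

__all__ = [
    "UP",
    "DOWN",
    "UNCHANGED",
    "classify_change",
    "ratiometric_normalize",
    "zscore_rows",
    "hierarchical_order",
]

UP = "UP"
DOWN = "DOWN"
UNCHANGED = "UNCHANGED"

RATIO_COLUMNS = [
    "accession",
    "symbol",
    "comparison",
    "raw_ratio",
    "norm_ratio",
    "log2_ratio",
    "change_class",
]


def classify_change(
    norm_ratio, up_threshold: float = 1.2, down_threshold: float = 0.8
):
    """Classify a normalized ratio (scalar or array) as UP/DOWN/UNCHANGED.

    UP iff ratio >= ``up_threshold``; DOWN iff ratio <= ``down_threshold``;
    UNCHANGED otherwise.  Thresholds are inclusive.

    Raises
    ------
    ConfigError
        If thresholds are inverted (``down >= up``) or ``up <= 1``/
        ``down >= 1`` in a way that makes every ratio altered.
    ValueError
        For non-positive ratios.
    """
    if not (0 < down_threshold < up_threshold):
        raise ConfigError(
            f"need 0 < down_threshold < up_threshold, got {down_threshold}/{up_threshold}"
        )
    arr = np.asarray(norm_ratio, dtype=float)
    if np.any(~(arr > 0)):
        raise ValueError("ratios must be strictly positive and finite")
    out = np.where(arr >= up_threshold, UP, np.where(arr <= down_threshold, DOWN, UNCHANGED))
    return out.item() if np.isscalar(norm_ratio) else out


def ratiometric_normalize(
    table: pd.DataFrame,
    design: ComparisonDesign,
    up_threshold: float = 1.2,
    down_threshold: float = 0.8,
) -> pd.DataFrame:
    """Compute raw, median-normalized and log2 ratios for every comparison.

    Parameters
    ----------
    table
        Analysis-ready quantification table (no missing intensities in
        any pool referenced by the design).
    design
        The case/control comparisons to evaluate.

    Returns
    -------
    pandas.DataFrame
        Tidy ratio table with one row per protein per comparison and
        columns ``accession, symbol, comparison, raw_ratio, norm_ratio,
        log2_ratio, change_class``.  Within each comparison the median
        ``norm_ratio`` is exactly 1.

    Raises
    ------
    SchemaError
        On an empty table, missing pool columns, or residual missing
        intensities (the table must be filtered first).
    """
    if len(table) == 0:
        raise SchemaError("cannot normalize an empty protein table")
    missing_pools = [p for p in design.pool_ids if p not in table.columns]
    if missing_pools:
        raise SchemaError(f"table lacks pool column(s) {missing_pools}")
    block = table[list(design.pool_ids)]
    if block.isna().any().any():
        raise SchemaError(
            "table contains missing intensities; apply filter_analysis_ready first"
        )

    frames = []
    for comp in design:
        raw = (table[comp.case_pool] / table[comp.control_pool]).astype(float)
        norm = raw / np.median(raw.to_numpy())
        frames.append(
            pd.DataFrame(
                {
                    "accession": table.index,
                    "symbol": table["symbol"].to_numpy(),
                    "comparison": comp.name,
                    "raw_ratio": raw.to_numpy(),
                    "norm_ratio": norm.to_numpy(),
                    "log2_ratio": np.log2(norm.to_numpy()),
                    "change_class": classify_change(
                        norm.to_numpy(), up_threshold, down_threshold
                    ),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)[RATIO_COLUMNS]


def zscore_rows(values: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Row-wise z-scores: (value - row mean) / row sample SD (ddof=1).

    Rows with zero spread are degenerate: their z-scores are all zero and
    they are flagged in the returned boolean Series.

    Raises
    ------
    ValueError
        If rows have fewer than two values or any value is non-finite.
    """
    if values.shape[1] < 2:
        raise ValueError("z-scores need at least two values per row")
    arr = values.to_numpy(dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite values in z-score input")
    mean = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, ddof=1, keepdims=True)
    degenerate = (sd == 0).ravel()
    safe_sd = np.where(sd == 0, 1.0, sd)
    z = (arr - mean) / safe_sd
    z[degenerate, :] = 0.0
    return (
        pd.DataFrame(z, index=values.index, columns=values.columns),
        pd.Series(degenerate, index=values.index, name="degenerate"),
    )


def hierarchical_order(
    matrix: pd.DataFrame, method: str = "complete"
) -> tuple[list, np.ndarray]:
    """Agglomerative clustering of rows on Euclidean distance.

    Returns the dendrogram leaf order (row labels) and the scipy linkage
    matrix (merge pairs and heights).  Complete linkage by default.
    """
    if len(matrix) < 2:
        raise ValueError("clustering needs at least two rows")
    arr = matrix.to_numpy(dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite values in clustering input")
    Z = linkage(pdist(arr, metric="euclidean"), method=method)
    order = leaves_list(Z)
    return [matrix.index[i] for i in order], Z
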