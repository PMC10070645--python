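"""Preprocessing: outlier-based exclusion, ordinal recoding, standardization.

Order of operations matters and is fixed: subjects are excluded on raw
in-model numeric values first; zero-inflated counts are then recoded to
3-level ordinals; finally each block is standardized according to its role
(range/Gower scaling for the mixed block, z-scoring for numeric-only blocks),
with standardization statistics computed on the retained subjects only.
All steps are deterministic and preserve subject order.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .blocks import FeatureBlock, check_aligned

__all__ = [
    "OrdinalRecode",
    "exclude_outliers",
    "categorize_zero_inflated",
    "gower_standardize",
    "z_standardize",
    "preprocess_blocks",
]


@dataclass
class OrdinalRecode:
    """Result of recoding a zero-inflated count to a 3-level ordinal.

    Level 0 <=> raw value equals zero; level 2 <=> raw value at or above the
    top-quintile cutpoint (80th percentile, linear interpolation); level 1
    otherwise.
    """

    variable: str
    zero_boundary: float
    top_quintile_cutpoint: float
    levels: np.ndarray


def _tukey_fences(col: np.ndarray, factor: float) -> tuple[float, float]:
    q1, q3 = np.percentile(col, [25, 75])  # linear interpolation
    iqr = q3 - q1
    return q1 - factor * iqr, q3 + factor * iqr


def exclude_outliers(
    blocks: list[FeatureBlock],
    factor: float = 3.0,
    mode: str = "tukey",
) -> tuple[list[FeatureBlock], pd.DataFrame]:
    """Drop subjects with extreme in-model numeric values in any block.

    A subject is excluded when, for any in-model numeric variable, its value
    falls outside the per-variable fences. Two fence modes are provided:

    - ``"tukey"`` (default): [Q1 - factor*IQR, Q3 + factor*IQR], fences
      anchored at the quartiles (quartiles by linear interpolation);
    - ``"median"``: [median - factor*IQR, median + factor*IQR].

    Boundary values sit *inside* the fence (equality is not an outlier), so a
    zero-IQR variable excludes nobody.

    Returns the identically-subset blocks and an exclusion log with columns
    ``subject``, ``block``, ``variable``, ``value``, ``lower_fence``,
    ``upper_fence`` (one row per triggering variable).
    """
    if factor <= 0:
        raise ValueError("factor must be positive")
    if mode not in ("tukey", "median"):
        raise ValueError(f"unknown outlier mode {mode!r}")
    ids = check_aligned(blocks)

    records = []
    excluded = set()
    for b in blocks:
        for var in b.numeric_variables():
            col = np.asarray(b.values[var], dtype=float)
            if mode == "tukey":
                lo, hi = _tukey_fences(col, factor)
            else:
                med = np.median(col)
                q1, q3 = np.percentile(col, [25, 75])
                iqr = q3 - q1
                lo, hi = med - factor * iqr, med + factor * iqr
            out = (col < lo) | (col > hi)
            for i in np.flatnonzero(out):
                records.append(
                    {
                        "subject": ids[i],
                        "block": b.name,
                        "variable": var,
                        "value": col[i],
                        "lower_fence": lo,
                        "upper_fence": hi,
                    }
                )
                excluded.add(ids[i])

    keep = [s for s in ids if s not in excluded]
    if not keep:
        raise ValueError("outlier exclusion removed every subject")
    log = pd.DataFrame(
        records,
        columns=["subject", "block", "variable", "value", "lower_fence", "upper_fence"],
    )
    return [b.subset(keep) for b in blocks], log


def categorize_zero_inflated(
    raw_counts, variable: str = "", include_zeros_in_quintile: bool = True
) -> OrdinalRecode:
    """Recode a zero-inflated count into a 3-level ordinal.

    Level 0: zero; Level 2: within the top quintile (>= the 80th percentile,
    linear interpolation — ties at the cutpoint are level 2); Level 1:
    positive but below the cutpoint. By default the quintile is computed over
    all subjects' values including zeros; ``include_zeros_in_quintile=False``
    computes it over the positive values only.
    """
    raw = np.asarray(raw_counts, dtype=float)
    if raw.size == 0:
        raise ValueError("empty count vector")
    if (raw < 0).any():
        raise ValueError(f"negative counts in zero-inflated variable {variable!r}")
    pool = raw if include_zeros_in_quintile else raw[raw > 0]
    cut = float(np.percentile(pool, 80)) if pool.size else 0.0
    levels = np.ones(raw.shape, dtype=int)
    levels[raw == 0] = 0
    levels[(raw > 0) & (raw >= cut)] = 2
    return OrdinalRecode(
        variable=variable, zero_boundary=0.0, top_quintile_cutpoint=cut, levels=levels
    )


def gower_standardize(block: FeatureBlock) -> FeatureBlock:
    """Range-scale a mixed block so per-variable Gower contributions lie in [0,1].

    Numeric variables are shifted/scaled by their observed range. Ordinal
    3-level variables are treated as ordered with rank scores 0,1,2 and
    likewise range-normalized (Gower's ordinal treatment); after recoding they
    are plain columns in [0,1] and the downstream Gower distance is the
    equal-weight mean of absolute differences.
    """
    if block.block_role != "mixed":
        raise ValueError("gower_standardize applies to mixed blocks only")
    values = block.values.copy().astype(float)
    kinds = dict(block.kinds)
    for var, kind in block.kinds.items():
        if kind == "zero_inflated_count":
            raise ValueError(
                f"variable {var!r} must be recoded to ordinal3 before standardization"
            )
        col = np.asarray(values[var], dtype=float)
        rng = col.max() - col.min()
        if kind == "numeric" and rng == 0:
            raise ValueError(f"numeric variable {var!r} has zero range")
        if rng == 0:  # single-level ordinal: constant contribution 0
            values[var] = 0.0
        else:
            values[var] = (col - col.min()) / rng
        kinds[var] = "numeric"
    return replace(block, values=values, kinds=kinds)


def z_standardize(block: FeatureBlock) -> FeatureBlock:
    """Z-score every column of a numeric-only block (sample SD, n-1)."""
    if block.block_role != "numeric_only":
        raise ValueError("z_standardize applies to numeric_only blocks only")
    values = block.values.copy().astype(float)
    for var in values.columns:
        col = np.asarray(values[var], dtype=float)
        sd = col.std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            raise ValueError(f"variable {var!r} has zero variance")
        values[var] = (col - col.mean()) / sd
    return replace(block, values=values)


def preprocess_blocks(
    blocks: list[FeatureBlock],
    outlier_factor: float = 3.0,
    outlier_mode: str = "tukey",
    exclude: bool = True,
    include_zeros_in_quintile: bool = True,
) -> tuple[list[FeatureBlock], pd.DataFrame]:
    """Full preprocessing chain: exclusion -> ordinal recoding -> standardization.

    Set ``exclude=False`` to skip the outlier step (used when re-standardizing
    bootstrap subsamples of an already-screened cohort).
    """
    if exclude:
        blocks, log = exclude_outliers(blocks, factor=outlier_factor, mode=outlier_mode)
    else:
        check_aligned(blocks)
        log = pd.DataFrame(
            columns=["subject", "block", "variable", "value", "lower_fence", "upper_fence"]
        )

    out = []
    for b in blocks:
        b = b.copy()
        for var, kind in list(b.kinds.items()):
            if kind == "zero_inflated_count":
                rec = categorize_zero_inflated(
                    b.values[var], var, include_zeros_in_quintile
                )
                b.values[var] = rec.levels
                b.kinds[var] = "ordinal3"
        out.append(gower_standardize(b) if b.block_role == "mixed" else z_standardize(b))
    return out, log
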