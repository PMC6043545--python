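"""Shannon-Wiener spatial-spread indices of harmonized fishing effort.

For a fleet (tRFMO x stock x year x gear) whose days fished are spread
over grid cells a = 1..A with shares p_a = E_a / sum(E), the index is
the entropy

    H = -sum_a p_a log p_a

(natural log by default).  H = 0 means all effort sat in a single cell;
H = log(A) means effort was spread perfectly evenly over the A occupied
cells.  An increasing index therefore tracks spatial expansion /
evening-out of a fleet's operations, a proxy for information sharing
and fleet development used alongside the economic drivers.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .errors import UndefinedIndexError, ValidationError

GROUP_KEYS = ["org", "stock", "year", "gear"]


def shannon_index(efforts, base: float | None = None) -> float:
    """Entropy of an effort vector's cell shares, in nats by default.

    Zero cells contribute nothing (0 * log 0 := 0).  ``base`` switches
    the logarithm (e.g. 2 for bits); the default is the natural log.

    Raises
    ------
    UndefinedIndexError
        If the vector is empty or sums to zero.
    """
    e = np.asarray(efforts, dtype=float)
    if e.size == 0 or not np.any(e > 0):
        raise UndefinedIndexError("Shannon index undefined for empty or all-zero effort")
    if np.any(e < 0):
        raise ValidationError("effort values must be non-negative")
    p = e[e > 0]
    p = p / p.sum()
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= math.log(base)
    # guard against -0.0 from single-cell vectors
    return abs(h) if h == 0 else h


def compute_indices(
    harmonized: pd.DataFrame,
    base: float | None = None,
) -> pd.DataFrame:
    """Shannon-Wiener index per (org, stock, year, gear) fleet.

    Parameters
    ----------
    harmonized
        Output of :func:`tunadrivers.effort.harmonize_table`: one row
        per occupied grid cell with a ``days_fished`` column.

    Returns
    -------
    DataFrame with columns org, stock, year, gear, shannon_wiener,
    n_cells.  Groups whose total effort is zero are emitted with NaN
    and counted in ``result.attrs["n_undefined"]``.
    """
    required = set(GROUP_KEYS + ["days_fished"])
    missing = required - set(harmonized.columns)
    if missing:
        raise ValidationError(f"harmonized table missing columns: {sorted(missing)}")

    rows = []
    n_undefined = 0
    for key, grp in harmonized.groupby(GROUP_KEYS, sort=True):
        e = grp["days_fished"].to_numpy()
        try:
            h = shannon_index(e, base=base)
            n_cells = int((e > 0).sum())
        except UndefinedIndexError:
            h, n_cells = np.nan, 0
            n_undefined += 1
        rows.append(dict(zip(GROUP_KEYS, key)) | {"shannon_wiener": h, "n_cells": n_cells})
    out = pd.DataFrame(rows, columns=GROUP_KEYS + ["shannon_wiener", "n_cells"])
    out.attrs["n_undefined"] = n_undefined
    return out
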