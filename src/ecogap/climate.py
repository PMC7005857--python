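"""Climate extraction at record locations, collinearity pruning, and the
per-taxon climate summaries used by the ecogeographic classification.

``AMEANT``/``TWETQ``/``AP``/``PWETQ`` (annual mean temperature, temperature of
the wettest quarter, annual precipitation, precipitation of the wettest
quarter) map to BIO1/BIO8/BIO12/BIO16 under the standard bioclim semantics.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .types import BIO_NAMES, CLIMATE_VARS, ClimateStack


def extract_values(records, stack: ClimateStack):
    """Record-level climate matrix -> (DataFrame, excluded).

    The DataFrame is indexed by record_id with a ``taxon_id`` column and one
    column per bioclim variable (the value of the cell containing the point).
    Records outside the extent or on nodata cells land in ``excluded`` as
    ``(record_id, reason)``.
    """
    vals = stack.values_at([r.lon for r in records], [r.lat for r in records])
    rows, excluded = [], []
    row_idx, _ = stack.grid.cell_of([r.lon for r in records],
                                    [r.lat for r in records])
    row_idx = np.atleast_1d(row_idx)
    for i, rec in enumerate(records):
        if row_idx[i] < 0:
            excluded.append((rec.record_id, "outside raster extent"))
        elif np.isnan(vals[i]).any():
            excluded.append((rec.record_id, "no climate data"))
        else:
            rows.append((rec.record_id, rec.taxon_id, *vals[i]))
    df = pd.DataFrame(rows, columns=["record_id", "taxon_id", *BIO_NAMES])
    return df.set_index("record_id"), excluded


def prune_correlated(matrix: pd.DataFrame, r_max: float = 0.7,
                     preferred_order=None) -> list[str]:
    """Greedy collinearity pruning at the |Pearson r| <= ``r_max`` threshold.

    Variables are visited in ``preferred_order`` (default BIO1..BIO19); one is
    retained iff its absolute correlation with every already-retained variable
    stays at or below the threshold. Constant columns have no defined
    correlation and are dropped with a warning.
    """
    if not 0.0 < r_max < 1.0:
        raise ValueError("r_max must be in (0, 1)")
    order = list(preferred_order) if preferred_order else \
        [v for v in BIO_NAMES if v in matrix.columns]
    if len(matrix) < 2:
        raise ValueError("need at least 2 rows to compute correlations")
    retained = []
    for var in order:
        col = matrix[var].to_numpy(dtype=float)
        if np.std(col) == 0:
            warnings.warn(f"variable {var} is constant; correlation undefined, dropped")
            continue
        ok = all(abs(np.corrcoef(col, matrix[kept].to_numpy(dtype=float))[0, 1])
                 <= r_max for kept in retained)
        if ok:
            retained.append(var)
    return retained


def taxon_climate_summary(records, stack: ClimateStack) -> pd.DataFrame:
    """Per-taxon means of AMEANT, TWETQ, AP, PWETQ plus record counts.

    Taxa with no valid record are omitted (returned in the ``omitted`` attr of
    the frame is avoided; they simply do not appear).
    """
    matrix, _ = extract_values(records, stack)
    if matrix.empty:
        return pd.DataFrame(columns=["taxon_id", *CLIMATE_VARS, "n_records"]
                            ).set_index("taxon_id")
    agg = matrix.groupby("taxon_id").agg(
        **{name: (bio, "mean") for name, bio in CLIMATE_VARS.items()},
        n_records=("BIO1", "size"))
    return agg
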