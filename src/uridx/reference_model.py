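"""Normal reference intervals and per-sample outlier calls.

A healthy urine cohort defines, per protein, a 95% reference interval
(2.5th-97.5th percentiles of iFOT) and an interquartile range.  A protein
is called an *outlier* in a disease sample when its abundance exceeds the
reference interval's upper bound plus twice the IQR — or, for proteins
never seen in healthy urine, when it is detected at all.  Only
over-expression is screened; loss of expression is out of scope.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .io_preprocess import AbundanceMatrix

logger = logging.getLogger(__name__)

RI_COLUMNS = ("ri_low", "ri_high", "iqr", "outlier_cutoff", "expressed_in_normal", "n_normal")

#: Minimum cohort size below which the 2.5/97.5 percentiles are degenerate
#: (they collapse onto the extremes of the sample).
MIN_COHORT = 8


def build_reference_intervals(normal_matrix: AbundanceMatrix,
                              percentile_method: str = "linear",
                              iqr_multiplier: float = 2.0) -> pd.DataFrame:
    """Per-protein reference statistics from a healthy cohort.

    Returns a DataFrame indexed by protein id with columns ``ri_low``
    (2.5th percentile), ``ri_high`` (97.5th), ``iqr`` (Q3 - Q1),
    ``outlier_cutoff`` (ri_high + iqr_multiplier * iqr),
    ``expressed_in_normal`` and ``n_normal``.  Undetected cells count as
    0 in the percentiles.  Proteins never detected in the cohort get the
    ``expressed_in_normal=False`` flag and all-zero statistics.

    ``percentile_method`` is any quantile-interpolation convention that
    :func:`numpy.percentile` accepts (default: linear interpolation
    between order statistics).
    """
    n = len(normal_matrix.sample_ids)
    if n == 0:
        raise ValueError("empty normal cohort")
    if n < MIN_COHORT:
        warnings.warn(
            f"normal cohort of {n} samples: 2.5/97.5 percentiles are degenerate",
            UserWarning, stacklevel=2,
        )
    if normal_matrix.stage not in ("ifot", "quantile"):
        raise ValueError("reference intervals are built on iFOT or quantile-normalized data")
    values = normal_matrix.values
    q = np.percentile(values, [2.5, 25.0, 75.0, 97.5], axis=1, method=percentile_method)
    ri_low, q1, q3, ri_high = q
    iqr = q3 - q1
    cutoff = ri_high + iqr_multiplier * iqr
    expressed = (values > 0).any(axis=1)
    for arr in (ri_low, ri_high, iqr, cutoff):
        arr[~expressed] = 0.0
    table = pd.DataFrame(
        {
            "ri_low": ri_low,
            "ri_high": ri_high,
            "iqr": iqr,
            "outlier_cutoff": cutoff,
            "expressed_in_normal": expressed,
            "n_normal": n,
        },
        index=pd.Index(normal_matrix.protein_ids, name="protein_id"),
    )
    return table


def call_outliers(disease_matrix: AbundanceMatrix,
                  ri_table: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Boolean outlier calls for every (protein, sample) cell.

    A call is made when the cell exceeds the protein's ``outlier_cutoff``
    strictly, or when the protein is not expressed in the healthy cohort
    and the cell is detected (> 0).  Proteins absent from ``ri_table``
    are treated as never expressed in healthy urine and logged.

    Returns the call matrix plus per-sample outlier counts.
    """
    if disease_matrix.stage not in ("ifot", "quantile"):
        raise ValueError("outlier calls are made on iFOT or quantile-normalized data")
    proteins = disease_matrix.data.index
    known = proteins.isin(ri_table.index)
    if not known.all():
        unknown = proteins[~known].tolist()
        logger.warning(
            "%d proteins absent from the reference table; treating as not expressed "
            "in healthy urine: %s%s",
            len(unknown), unknown[:10], "..." if len(unknown) > 10 else "",
        )
    cutoff = ri_table["outlier_cutoff"].reindex(proteins, fill_value=0.0).to_numpy(float)
    expressed = ri_table["expressed_in_normal"].reindex(proteins, fill_value=False).to_numpy(bool)
    values = disease_matrix.values
    # for never-expressed proteins cutoff == 0, so a single strict
    # comparison implements both branches of the criterion
    calls = np.where(expressed[:, None], values > cutoff[:, None], values > 0.0)
    call_df = pd.DataFrame(calls, index=proteins, columns=disease_matrix.data.columns)
    per_sample = call_df.sum(axis=0)
    return call_df, per_sample
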