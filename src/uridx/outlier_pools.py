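"""Disease-group outlier pools.

Per-sample outlier calls are screened into a per-group pool of
disease-related proteins by two percentile standards evaluated over the
group's outlier-called proteins:

(1) proteins expressed in healthy urine enter the pool when their own
    outlier cutoff exceeds the ``cutoff_pctl``-th percentile of all the
    group's outlier cutoff values (selecting high-abundance outliers)
    AND their outlier frequency is at least the ``freq_pctl``-th
    percentile of the group's outlier-frequency distribution;

(2) proteins never expressed in healthy urine enter when their outlier
    frequency is at least the ``absent_freq_pctl``-th percentile of that
    same frequency distribution.

A percentile threshold set to 0 (or below) disables the corresponding
constraint, so ``cutoff_pctl=freq_pctl=absent_freq_pctl=0`` yields every
protein with at least one call.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_preprocess import group_samples

logger = logging.getLogger(__name__)


@dataclass
class OutlierPool:
    """Outlier proteins of one disease group.

    ``entries`` is indexed by protein id with columns
    ``outlier_frequency`` (fraction of group samples calling the protein,
    in (0, 1]), ``cutoff_value`` (the protein's outlier cutoff from the
    reference table) and ``expressed_in_normal``.
    """

    group: str
    entries: pd.DataFrame

    @property
    def protein_ids(self) -> list[str]:
        return list(self.entries.index)

    def __len__(self) -> int:
        return len(self.entries)


def build_outlier_pool(calls: pd.DataFrame, metadata: pd.DataFrame,
                       ri_table: pd.DataFrame, group: str,
                       cutoff_pctl: float = 75.0, freq_pctl: float = 90.0,
                       absent_freq_pctl: float = 95.0,
                       percentile_method: str = "linear",
                       compare_observed_ifot: pd.DataFrame | None = None) -> OutlierPool:
    """Screen a group's outlier calls into an :class:`OutlierPool`.

    ``calls`` is the boolean call matrix (proteins x samples); only the
    group's samples are used.  ``compare_observed_ifot``, when given,
    switches standard (1) to compare each protein's *maximum observed*
    abundance in the group (from the supplied matrix) against the
    cutoff-value percentile, instead of the protein's own cutoff — an
    alternative reading of the abundance standard.
    """
    samples = [s for s in group_samples(metadata, group) if s in calls.columns]
    if len(samples) < 2:
        raise ValueError(f"group {group!r} needs >= 2 samples with calls, found {len(samples)}")
    group_calls = calls.loc[:, samples]
    freq = group_calls.mean(axis=1)
    called = freq > 0
    if not called.any():
        warnings.warn(f"no outlier calls in group {group!r}: empty pool", UserWarning,
                      stacklevel=2)
        empty = pd.DataFrame(
            columns=["outlier_frequency", "cutoff_value", "expressed_in_normal"],
            index=pd.Index([], name="protein_id"),
        )
        return OutlierPool(group, empty)

    sel = calls.index[called]
    freqs = freq[called].to_numpy()
    cutoffs = ri_table["outlier_cutoff"].reindex(sel, fill_value=0.0).to_numpy(float)
    expressed = ri_table["expressed_in_normal"].reindex(sel, fill_value=False).to_numpy(bool)

    if compare_observed_ifot is not None:
        abundance = compare_observed_ifot.loc[sel, samples].max(axis=1).to_numpy()
    else:
        abundance = cutoffs

    freq_thr = np.percentile(freqs, freq_pctl, method=percentile_method) if freq_pctl > 0 else None
    absent_thr = (np.percentile(freqs, absent_freq_pctl, method=percentile_method)
                  if absent_freq_pctl > 0 else None)
    cut_thr = (np.percentile(cutoffs, cutoff_pctl, method=percentile_method)
               if cutoff_pctl > 0 else None)

    std1 = expressed.copy()
    if cut_thr is not None:
        std1 &= abundance > cut_thr
    if freq_thr is not None:
        std1 &= freqs >= freq_thr
    std2 = ~expressed
    if absent_thr is not None:
        std2 &= freqs >= absent_thr
    keep = std1 | std2

    entries = pd.DataFrame(
        {
            "outlier_frequency": freqs[keep],
            "cutoff_value": cutoffs[keep],
            "expressed_in_normal": expressed[keep],
        },
        index=pd.Index(sel[keep], name="protein_id"),
    )
    logger.info("group %s: %d called proteins -> pool of %d", group, called.sum(), len(entries))
    return OutlierPool(group, entries)


def pool_intersection_report(pool_a: OutlierPool, pool_b: OutlierPool) -> dict:
    """Partition the union of two pools into shared / a-only / b-only."""
    a, b = set(pool_a.protein_ids), set(pool_b.protein_ids)
    shared = a & b
    return {
        "groups": (pool_a.group, pool_b.group),
        "shared": sorted(shared),
        "a_only": sorted(a - shared),
        "b_only": sorted(b - shared),
        "n_shared": len(shared),
        "n_a_only": len(a - shared),
        "n_b_only": len(b - shared),
        "n_union": len(a | b),
    }


def pool_union(pool_a: OutlierPool, pool_b: OutlierPool) -> list[str]:
    """Sorted union of two pools' proteins (the differential-test candidates)."""
    return sorted(set(pool_a.protein_ids) | set(pool_b.protein_ids))
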