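"""Differential screening and diagnostic-panel selection.

Candidate proteins (the union of the AA and CON outlier pools) are first
screened with a two-sided unpaired Wilcoxon rank-sum (Mann-Whitney U)
test between the two disease groups on log2-imputed abundances; proteins
with p < 0.05 (raw, uncorrected — a Benjamini-Hochberg option exists but
is off by default) proceed to feature selection, which reduces them to a
k-protein panel (default k = 10).

The default selector is seeded random-forest permutation importance with
backward elimination, halving the candidate set each round until k
proteins remain.  Cheaper alternatives: top-k by p-value and
L1-regularized logistic ranking.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.linear_model import LogisticRegression
from statsmodels.stats.multitest import multipletests

from .io_preprocess import AbundanceMatrix, group_samples

logger = logging.getLogger(__name__)

#: The 10-protein urinary panel reported for distinguishing acute
#: appendicitis from other acute abdomens; shipped so downstream models
#: can be run on the published panel directly.
PUBLISHED_PANEL = (
    "LYVE1", "AHCYL1", "APOC1", "SECTM1", "SLC31A1",
    "ITGA6", "SLC35F2", "GPX3", "TMEM14C", "SLC47A2",
)

#: Largest per-arm size for which the exact rank-sum null is enumerated.
EXACT_MAX_N = 10


@dataclass
class FeaturePanel:
    """An ordered k-protein diagnostic panel with selection scores."""

    protein_ids: tuple[str, ...]
    selection_scores: tuple[float, ...]
    seed: int
    method: str

    def __len__(self) -> int:
        return len(self.protein_ids)

    def __iter__(self):
        return iter(self.protein_ids)


def rank_sum_pvalues(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Row-wise two-sided Mann-Whitney p-values for x (rows x n_a) vs y.

    The exact null distribution is enumerated when both arms have at most
    :data:`EXACT_MAX_N` observations and the row is tie-free; otherwise
    the normal approximation with midrank tie correction is used.
    Constant rows (every value identical) get p = 1.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.atleast_2d(np.asarray(y, dtype=float))
    n_rows = x.shape[0]
    pvals = np.ones(n_rows)
    combined = np.concatenate([x, y], axis=1)
    constant = np.ptp(combined, axis=1) == 0
    small = x.shape[1] <= EXACT_MAX_N and y.shape[1] <= EXACT_MAX_N
    asym_rows = []
    for i in range(n_rows):
        if constant[i]:
            continue
        tied = np.unique(combined[i]).size < combined.shape[1]
        if small and not tied:
            pvals[i] = stats.mannwhitneyu(x[i], y[i], alternative="two-sided",
                                          method="exact").pvalue
        else:
            asym_rows.append(i)
    if asym_rows:
        idx = np.array(asym_rows)
        res = stats.mannwhitneyu(x[idx], y[idx], alternative="two-sided",
                                 method="asymptotic", axis=1)
        pvals[idx] = np.atleast_1d(res.pvalue)
    return pvals


def rank_sum_table(matrix: AbundanceMatrix, metadata: pd.DataFrame,
                   candidates) -> pd.DataFrame:
    """Wilcoxon rank-sum statistics for every candidate, AA vs CON.

    Returns a DataFrame indexed by protein id with ``p_value``,
    ``median_log2_diff`` (AA median - CON median) and ``direction``,
    sorted by ascending p.
    """
    candidates = list(candidates)
    missing = [c for c in candidates if c not in matrix.data.index]
    if missing:
        raise KeyError(f"candidates absent from matrix: {missing}")
    aa = [s for s in group_samples(metadata, "AA") if s in matrix.data.columns]
    con = [s for s in group_samples(metadata, "CON") if s in matrix.data.columns]
    if not aa or not con:
        raise ValueError("both AA and CON groups must be nonempty")
    x = matrix.data.loc[candidates, aa].to_numpy()
    y = matrix.data.loc[candidates, con].to_numpy()
    pvals = rank_sum_pvalues(x, y)
    diff = np.median(x, axis=1) - np.median(y, axis=1)
    table = pd.DataFrame(
        {
            "p_value": pvals,
            "median_log2_diff": diff,
            "direction": np.where(diff >= 0, "up_in_AA", "up_in_CON"),
        },
        index=pd.Index(candidates, name="protein_id"),
    )
    return table.sort_values("p_value", kind="mergesort")


def wilcoxon_screen(matrix: AbundanceMatrix, metadata: pd.DataFrame, candidates,
                    alpha: float = 0.05, fdr_correct: bool = False) -> pd.DataFrame:
    """Candidates passing the rank-sum screen at ``alpha``, sorted by p.

    With ``fdr_correct`` the Benjamini-Hochberg adjusted p-values are
    thresholded instead of the raw ones (off by default).
    """
    if matrix.stage != "log2_imputed":
        raise ValueError("the differential screen runs on log2-imputed abundances")
    table = rank_sum_table(matrix, metadata, candidates)
    if fdr_correct and len(table):
        _, adj, _, _ = multipletests(table["p_value"].to_numpy(), method="fdr_bh")
        table = table.assign(p_adjusted=adj)
        passing = table[table["p_adjusted"] < alpha]
    else:
        passing = table[table["p_value"] < alpha]
    logger.info("rank-sum screen: %d of %d candidates pass at alpha=%g",
                len(passing), len(table), alpha)
    return passing


def _design(matrix: AbundanceMatrix, metadata: pd.DataFrame, proteins):
    meta = metadata[metadata["sample_id"].isin(matrix.data.columns)]
    ids = sorted(meta["sample_id"])
    X = matrix.data.loc[list(proteins), ids].T.to_numpy()
    labels = meta.set_index("sample_id").loc[ids, "group"]
    y = (labels == "AA").to_numpy(int)
    return X, y


def select_features(matrix: AbundanceMatrix, metadata: pd.DataFrame,
                    candidates: pd.DataFrame, k: int = 10, seed: int = 0,
                    method: str = "rf_backward", n_estimators: int = 300,
                    n_repeats: int = 5) -> FeaturePanel:
    """Reduce screened candidates to an ordered k-protein panel.

    ``candidates`` is the screen output (indexed by protein id, sorted by
    p).  Methods:

    ``rf_backward`` (default)
        Seeded random forest + permutation importance; each round keeps
        the better-scoring half of the candidates until k remain, and the
        final panel is ordered by importance on the survivors.
    ``top_p``
        The k smallest screen p-values.
    ``l1_logistic``
        Rank by absolute coefficient of an L1-regularized logistic fit.
    """
    names = list(candidates.index)
    if not names:
        warnings.warn("no candidates passed the screen; empty panel", UserWarning, stacklevel=2)
        return FeaturePanel((), (), seed, method)
    if len(names) < k:
        warnings.warn(f"only {len(names)} candidates for a panel of {k}; returning all",
                      UserWarning, stacklevel=2)
        k = len(names)
    if method == "top_p":
        chosen = names[:k]
        scores = -np.log10(candidates.loc[chosen, "p_value"].to_numpy())
        return FeaturePanel(tuple(chosen), tuple(scores), seed, method)

    X, y = _design(matrix, metadata, names)
    if method == "l1_logistic":
        model = LogisticRegression(penalty="l1", solver="liblinear", C=1.0,
                                   random_state=seed, max_iter=2000)
        model.fit(X, y)
        coef = np.abs(model.coef_.ravel())
        order = np.argsort(-coef, kind="mergesort")[:k]
        return FeaturePanel(tuple(names[i] for i in order),
                            tuple(coef[order]), seed, method)
    if method != "rf_backward":
        raise ValueError(f"unknown selection method {method!r}")

    current = list(range(len(names)))
    importances = np.zeros(len(names))
    while True:
        rf = RandomForestClassifier(n_estimators=n_estimators, max_features="sqrt",
                                    random_state=seed, n_jobs=1)
        rf.fit(X[:, current], y)
        imp = permutation_importance(rf, X[:, current], y, n_repeats=n_repeats,
                                     random_state=seed, n_jobs=1)
        scores = imp.importances_mean
        order = np.argsort(-scores, kind="mergesort")  # stable: p-value order breaks ties
        if len(current) <= k:
            final = [current[i] for i in order]
            importances = scores[order]
            break
        keep = max(k, len(current) // 2)
        current = [current[i] for i in sorted(order[:keep])]
    panel = tuple(names[i] for i in final)
    logger.info("rf_backward selection: panel of %d from %d candidates", len(panel), len(names))
    return FeaturePanel(panel, tuple(float(s) for s in importances), seed, "rf_backward")


def panel_to_frame(panel: FeaturePanel) -> pd.DataFrame:
    """Panel as a TSV-ready table (protein, score, rank)."""
    return pd.DataFrame(
        {
            "protein_id": panel.protein_ids,
            "selection_score": panel.selection_scores,
            "rank": np.arange(1, len(panel) + 1),
        }
    )
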