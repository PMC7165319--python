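"""End-to-end orchestration of the discovery and validation workflow.

Chains the individual stages: iFOT conversion and quantile normalization
(applied separately within each dataset split, since the splits come
from different instruments and must not share normalization
information), reference-interval construction on the healthy cohort,
outlier calling and pooling per disease group, the rank-sum screen over
the pool union, feature selection, and classifier training/evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .classify_evaluate import (ClassificationMetrics, FittedModel, evaluate, loocv,
                                train_classifier)
from .io_preprocess import AbundanceMatrix, log2_impute, quantile_normalize, to_ifot
from .outlier_pools import OutlierPool, build_outlier_pool, pool_union
from .panel_selection import FeaturePanel, select_features, wilcoxon_screen
from .reference_model import build_reference_intervals, call_outliers


def normalize_chain(raw: AbundanceMatrix) -> tuple[AbundanceMatrix, AbundanceMatrix]:
    """raw iBAQ -> (iFOT, quantile-normalized iFOT)."""
    ifot = to_ifot(raw)
    return ifot, quantile_normalize(ifot)


@dataclass
class DiscoveryResult:
    """Everything the discovery workflow produces."""

    panel: FeaturePanel
    screen: pd.DataFrame
    pool_aa: OutlierPool
    pool_con: OutlierPool
    ri_table: pd.DataFrame
    calls: pd.DataFrame
    quantile_matrix: AbundanceMatrix
    log2_matrix: AbundanceMatrix
    metadata: pd.DataFrame


def run_discovery(disease_raw: AbundanceMatrix, normal_raw: AbundanceMatrix,
                  metadata: pd.DataFrame, k: int = 10, seed: int = 0,
                  alpha: float = 0.05, select_method: str = "rf_backward",
                  cutoff_pctl: float = 75.0, freq_pctl: float = 90.0,
                  absent_freq_pctl: float = 95.0,
                  **select_kwargs) -> DiscoveryResult:
    """Run the full discovery workflow from raw iBAQ tables to a panel.

    Outlier screening runs on the iFOT stage (the outlier criterion is
    stated on iFOT values; quantile normalization pins extreme ranks to
    identical values across samples, which collapses reference-interval
    dispersion for the most abundant proteins).  The differential screen
    and the classifiers run on quantile-normalized, log2-imputed data.
    """
    disease_ifot, disease_q = normalize_chain(disease_raw)
    normal_ifot, _ = normalize_chain(normal_raw)
    ri = build_reference_intervals(normal_ifot)
    calls, _ = call_outliers(disease_ifot, ri)
    pools = {
        g: build_outlier_pool(calls, metadata, ri, g, cutoff_pctl=cutoff_pctl,
                              freq_pctl=freq_pctl, absent_freq_pctl=absent_freq_pctl)
        for g in ("AA", "CON")
    }
    candidates = pool_union(pools["AA"], pools["CON"])
    log2_matrix = log2_impute(disease_q)
    screen = wilcoxon_screen(log2_matrix, metadata, candidates, alpha=alpha)
    panel = select_features(log2_matrix, metadata, screen, k=k, seed=seed,
                            method=select_method, **select_kwargs)
    return DiscoveryResult(panel=panel, screen=screen, pool_aa=pools["AA"],
                           pool_con=pools["CON"], ri_table=ri, calls=calls,
                           quantile_matrix=disease_q, log2_matrix=log2_matrix,
                           metadata=metadata)


def run_validation(result: DiscoveryResult, validation_raw: AbundanceMatrix,
                   validation_metadata: pd.DataFrame, algo: str = "rf",
                   seed: int = 0) -> tuple[FittedModel, ClassificationMetrics]:
    """Train on the discovery cohort, evaluate on an independent cohort.

    The validation matrix is normalized separately (its own iFOT and
    quantile pass), mirroring the instrument split.
    """
    model = train_classifier(result.log2_matrix, result.metadata, result.panel,
                             algo=algo, seed=seed)
    _, vq = normalize_chain(validation_raw)
    v_log2 = log2_impute(vq)
    metrics = evaluate(model, v_log2, validation_metadata)
    return model, metrics


def discovery_loocv(result: DiscoveryResult, algo: str = "rf",
                    seed: int = 0) -> tuple[ClassificationMetrics, pd.Series]:
    """LOOCV of the fixed selected panel on the discovery cohort.

    The panel is the one selected once on the full discovery set, held
    fixed across folds (the study's apparent procedure).  This is
    optimistically biased because selection saw every sample; see
    :func:`honest_loocv` for the leakage-free variant.
    """
    return loocv(result.log2_matrix, result.metadata, panel=result.panel,
                 algo=algo, seed=seed)


def honest_loocv(log2_matrix: AbundanceMatrix, metadata: pd.DataFrame,
                 k: int = 10, algo: str = "rf", seed: int = 0,
                 alpha: float = 0.05, select_method: str = "top_p",
                 **select_kwargs) -> tuple[ClassificationMetrics, pd.Series]:
    """LOOCV re-running screening and selection inside every fold.

    Candidates are all proteins detected in the training fold; the
    rank-sum screen and feature selection see only the n-1 training
    samples, so the held-out prediction is free of selection leakage.
    The default in-fold selector is ``top_p`` (cheap and deterministic).
    """

    def panel_fn(fold_matrix: AbundanceMatrix, fold_meta: pd.DataFrame):
        detected = fold_matrix.data.index[
            (fold_matrix.data.to_numpy() > fold_matrix.imputation_value).any(axis=1)
        ]
        screen = wilcoxon_screen(fold_matrix, fold_meta, detected, alpha=alpha)
        return select_features(fold_matrix, fold_meta, screen, k=k, seed=seed,
                               method=select_method, **select_kwargs)

    return loocv(log2_matrix, metadata, algo=algo, seed=seed, panel_fn=panel_fn)
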