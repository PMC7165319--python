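"""Abundance-matrix containers, I/O and label-free normalization.

The pipeline starts from protein-level iBAQ tables (proteins x samples).
Undetected proteins are encoded as 0 throughout; they are treated as
*missing* only at the final log2/imputation step, where model input is
prepared.  The normalization chain is

    raw iBAQ  ->  iFOT (per-sample fraction of total, x 1e5)
              ->  quantile-normalized iFOT
              ->  log2 with minimal-value imputation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Processing stages, in pipeline order.
STAGES = ("raw_ibaq", "ifot", "quantile", "log2_imputed")

#: iFOT values are scaled to parts-per-1e5 (a convenient display range for
#: urinary proteins whose fractional abundance spans ~5 orders of magnitude).
IFOT_SCALE = 1.0e5

GROUPS = ("AA", "CON")
SUBGROUPS = ("AA", "CHO", "PAN", "GP", "IO", "OTH")
SPLITS = ("discovery", "validation")

METADATA_COLUMNS = ("sample_id", "group", "subgroup", "split", "instrument")


@dataclass
class AbundanceMatrix:
    """A proteins x samples abundance matrix with a processing-stage tag.

    Parameters
    ----------
    data
        DataFrame with protein identifiers as the index and sample
        identifiers as columns.  Cells are abundances in the units implied
        by ``stage``; 0 means "not detected" for pre-log stages.
    stage
        One of :data:`STAGES`.
    imputation_value
        The log2 value used to fill undetected cells; set by
        :func:`log2_impute`, ``None`` for other stages.
    """

    data: pd.DataFrame
    stage: str
    imputation_value: float | None = field(default=None)

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}; expected one of {STAGES}")
        self.data = self.data.rename_axis(index="protein_id")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate protein ids: {dups}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        values = self.data.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            raise ValueError("abundance matrix contains non-finite values")
        if self.stage != "log2_imputed" and (values < 0).any():
            raise ValueError(f"negative abundance at stage {self.stage!r}")
        if self.stage == "ifot" and values.size:
            sums = values.sum(axis=0)
            if not np.allclose(sums, IFOT_SCALE, rtol=1e-9, atol=0.0):
                raise ValueError("iFOT columns must each sum to 1e5")

    @property
    def protein_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def select_samples(self, sample_ids: Sequence[str]) -> "AbundanceMatrix":
        """Column subset preserving stage (order follows ``sample_ids``)."""
        missing = [s for s in sample_ids if s not in self.data.columns]
        if missing:
            raise KeyError(f"samples not in matrix: {missing}")
        sub = self.data.loc[:, list(sample_ids)]
        if self.stage == "ifot":
            # column subsetting preserves per-column sums, so stage survives
            return AbundanceMatrix(sub, "ifot")
        return replace(self, data=sub)


def read_abundance_matrix(path, stage: str) -> AbundanceMatrix:
    """Read a TSV abundance matrix (proteins as rows, samples as columns).

    Blank and NA cells become 0 (undetected).  Duplicate identifiers or
    negative abundances are hard errors.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    df = df.fillna(0.0).astype(float)
    return AbundanceMatrix(df, stage)


def write_abundance_matrix(matrix: AbundanceMatrix, path) -> None:
    """Write a matrix as TSV; values round-trip at full float precision."""
    matrix.data.to_csv(path, sep="\t", index_label="protein_id", float_format="%.17g")


def read_metadata(path) -> pd.DataFrame:
    """Read a sample-metadata TSV and validate it."""
    meta = pd.read_csv(path, sep="\t", dtype=str)
    return validate_metadata(meta)


def write_metadata(metadata: pd.DataFrame, path) -> None:
    metadata.to_csv(path, sep="\t", index=False)


def validate_metadata(metadata: pd.DataFrame) -> pd.DataFrame:
    """Check the metadata contract: unique ids, known labels, AA <-> AA."""
    missing = [c for c in METADATA_COLUMNS if c not in metadata.columns]
    if missing:
        raise ValueError(f"metadata missing columns: {missing}")
    if metadata["sample_id"].duplicated().any():
        dups = metadata.loc[metadata["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample ids in metadata: {dups}")
    bad_group = set(metadata["group"]) - set(GROUPS)
    if bad_group:
        raise ValueError(f"unknown groups: {sorted(bad_group)}")
    bad_sub = set(metadata["subgroup"]) - set(SUBGROUPS)
    if bad_sub:
        raise ValueError(f"unknown subgroups: {sorted(bad_sub)}")
    bad_split = set(metadata["split"]) - set(SPLITS)
    if bad_split:
        raise ValueError(f"unknown splits: {sorted(bad_split)}")
    aa_mismatch = (metadata["group"] == "AA") != (metadata["subgroup"] == "AA")
    if aa_mismatch.any():
        raise ValueError("subgroup 'AA' must be used exactly for group 'AA'")
    return metadata


def group_samples(metadata: pd.DataFrame, group: str) -> list[str]:
    """Sample ids belonging to a disease group, in metadata order."""
    return metadata.loc[metadata["group"] == group, "sample_id"].tolist()


def filter_quantifiable(evidence: pd.DataFrame, min_peptides: int = 2,
                        min_ion_score: float = 20.0) -> set[str]:
    """Proteins quantifiable from peptide evidence.

    A protein is kept when it has at least ``min_peptides`` *distinct*
    strict peptides: peptide-spectrum matches passing 1% FDR with ion
    score strictly greater than ``min_ion_score``.

    ``evidence`` needs columns ``protein_id``, ``peptide_sequence``,
    ``passes_fdr`` and ``ion_score``; rows may repeat per protein.
    """
    required = {"protein_id", "peptide_sequence", "passes_fdr", "ion_score"}
    missing = required - set(evidence.columns)
    if missing:
        raise ValueError(f"evidence table missing columns: {sorted(missing)}")
    if evidence.empty:
        return set()
    scores = evidence["ion_score"].to_numpy(dtype=float)
    if not np.isfinite(scores).all():
        raise ValueError("non-finite ion scores in evidence table")
    strict = evidence[evidence["passes_fdr"].astype(bool) & (scores > min_ion_score)]
    counts = strict.groupby("protein_id")["peptide_sequence"].nunique()
    return set(counts.index[counts >= min_peptides])


def to_ifot(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """Convert raw iBAQ to iFOT: each column scaled to sum to 1e5.

    iFOT (fraction of total) divides each protein's iBAQ by the sample's
    summed iBAQ, removing loading-amount differences between samples; the
    fractions are multiplied by 1e5 for readability.
    """
    if matrix.stage != "raw_ibaq":
        raise ValueError(f"to_ifot expects stage 'raw_ibaq', got {matrix.stage!r}")
    sums = matrix.data.sum(axis=0)
    zero_cols = sums.index[sums.to_numpy() == 0.0].tolist()
    if zero_cols:
        raise ValueError(f"all-zero sample columns cannot be iFOT-normalized: {zero_cols}")
    out = matrix.data.div(sums, axis=1) * IFOT_SCALE
    logger.debug("iFOT conversion: %d samples, iBAQ column sums %s", len(sums), sums.to_dict())
    return AbundanceMatrix(out, "ifot")


def quantile_normalize(matrix: AbundanceMatrix, preserve_zeros: bool = True) -> AbundanceMatrix:
    """Classic quantile normalization across sample columns.

    Every column is ranked and rank *r* is replaced by the mean of the
    *r*-th order statistics over all columns, so all columns end up with
    one common value distribution.  Ties within a column receive the mean
    of the normalized values they span.

    With ``preserve_zeros`` (default), cells that were exactly 0 on input
    stay 0 on output, keeping the detected/undetected distinction intact
    for downstream detection-frequency and reference-interval logic; the
    target distribution is still computed from the full columns.
    """
    if matrix.stage not in ("ifot", "raw_ibaq", "quantile"):
        raise ValueError(f"quantile_normalize expects pre-log stage, got {matrix.stage!r}")
    values = matrix.values
    n_prot, n_samp = values.shape
    if n_samp < 1:
        raise ValueError("quantile normalization needs at least one sample")
    target = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(n_samp):
        col = values[:, j]
        order = np.argsort(col, kind="mergesort")
        assigned = np.empty(n_prot)
        assigned[order] = target
        # ties span a block of ranks -> mean of the spanned target values
        out[:, j] = pd.Series(assigned).groupby(col, sort=False).transform("mean").to_numpy()
    if preserve_zeros:
        out[values == 0.0] = 0.0
    df = pd.DataFrame(out, index=matrix.data.index, columns=matrix.data.columns)
    return AbundanceMatrix(df, "quantile")


def log2_impute(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """log2-transform, imputing undetected cells with the minimal value.

    Zeros are replaced by the global minimum nonzero value of the matrix
    before taking log2, so imputed cells carry the matrix's minimum log2
    value.  The imputation value (log2 scale) is recorded on the result.
    """
    if matrix.stage not in ("ifot", "quantile"):
        raise ValueError(f"log2_impute expects stage 'ifot' or 'quantile', got {matrix.stage!r}")
    values = matrix.values
    nonzero = values[values > 0]
    if nonzero.size == 0:
        raise ValueError("cannot log2-transform an all-zero matrix")
    floor = float(nonzero.min())
    filled = np.where(values == 0.0, floor, values)
    out = np.log2(filled)
    logger.info("log2_impute: %d undetected cells imputed at %g (log2 %.4f)",
                int((values == 0.0).sum()), floor, np.log2(floor))
    df = pd.DataFrame(out, index=matrix.data.index, columns=matrix.data.columns)
    return AbundanceMatrix(df, "log2_imputed", imputation_value=float(np.log2(floor)))


def detection_frequency(matrix: AbundanceMatrix, metadata: pd.DataFrame,
                        groups: Sequence[str] = GROUPS) -> tuple[pd.DataFrame, dict]:
    """Per-group detection frequencies plus group overlap counts.

    For each group, the fraction of its samples in which each protein is
    detected (abundance > 0).  The overlap report partitions the detected
    universe into shared and group-unique proteins.
    """
    if matrix.stage not in ("ifot", "quantile", "raw_ibaq"):
        raise ValueError("detection frequencies are defined on pre-log stages")
    freq = {}
    detected_sets: dict[str, set[str]] = {}
    for g in groups:
        ids = [s for s in group_samples(metadata, g) if s in matrix.data.columns]
        if not ids:
            raise ValueError(f"group {g!r} has no samples in the matrix")
        sub = matrix.data.loc[:, ids]
        detected = sub.gt(0.0)
        freq[g] = detected.mean(axis=1)
        detected_sets[g] = set(sub.index[detected.any(axis=1)])
    freq_df = pd.DataFrame(freq)
    report: dict = {"detected": {g: len(s) for g, s in detected_sets.items()}}
    if len(groups) == 2:
        a, b = groups
        shared = detected_sets[a] & detected_sets[b]
        report.update(
            shared=len(shared),
            unique={a: len(detected_sets[a] - shared), b: len(detected_sets[b] - shared)},
            total_detected=len(detected_sets[a] | detected_sets[b]),
            shared_ids=sorted(shared),
        )
    return freq_df, report
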