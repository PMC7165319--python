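"""Synthetic urinary-proteome cohorts with known ground truth.

The study's raw tables are request-only, so the pipeline is exercised on
simulated cohorts that reproduce the statistical structure the analysis
assumes:

* a protein universe whose baseline log2 abundance is drawn from a wide
  hyperprior (several orders of magnitude of dynamic range, as is
  typical of urinary iFOT data);
* abundance-dependent detection (probit link on log2 abundance), i.e.
  detection-limit censoring rather than missing-completely-at-random,
  calibrated so the number of proteins detected per sample matches a
  target mean and standard deviation — the defaults emulate the
  reported 1561 +/- 432 detected out of 5335, scaled to the simulated
  universe size;
* a per-sample multiplicative loading-depth factor (removed by iFOT
  conversion);
* spiked marker proteins with chosen log2 fold-changes in one disease
  group, optionally absent from healthy urine entirely.

Undetected cells are exactly 0.  All randomness flows from a single
integer seed; the same seed reproduces the matrices bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import ndtr, ndtri

from .io_preprocess import AbundanceMatrix, validate_metadata
from .panel_selection import FeaturePanel

#: Reported profiling scale the detection defaults are scaled from:
#: 1561 +/- 432 proteins detected per sample out of a 5335-protein universe.
REFERENCE_UNIVERSE = 5335
REFERENCE_DETECTED_MEAN = 1561.0
REFERENCE_DETECTED_SD = 432.0

#: Control subgroup composition (discovery cohort case counts):
#: cholecystitis/gallstones, pancreatitis, GI perforation, obstruction, other.
CON_SUBGROUP_WEIGHTS = {"CHO": 17, "PAN": 5, "GP": 6, "IO": 9, "OTH": 4}


@dataclass(frozen=True)
class Marker:
    """A spiked disease marker.

    ``log2_fc`` is added to the protein's log2 abundance in samples of
    ``group`` ("AA" or "CON").  With ``absent_in_normal`` the protein is
    additionally zeroed in the healthy cohort and in the unaffected
    disease group (a protein only ever seen under that pathology); such
    markers must be up-regulated (positive fold-change).
    ``baseline_quantile``, when set, pins the protein's baseline location
    to that quantile of the abundance hyperprior instead of a random
    draw, so marker detectability is controlled.
    """

    protein_index: int
    log2_fc: float
    group: str
    absent_in_normal: bool = False
    baseline_quantile: float | None = None


@dataclass
class SyntheticCohortSpec:
    """Study conditions for one simulated cohort.

    Defaults follow the emulated study: 32 AA and 41 control acute
    abdomens in the discovery cohort against a healthy reference cohort
    (scaled to 100 samples; the reported reference used 495), over a
    2000-protein universe (scaled from 5335 so default test runs stay
    fast; :func:`full_scale_spec` gives the full-size configuration).
    """

    n_proteins: int = 2000
    n_aa: int = 32
    n_con: int = 41
    n_normal: int = 100
    detected_mean: float | None = None
    detected_sd: float | None = None
    baseline_log2_mean: float = 10.0
    baseline_log2_sd: float = 4.0
    within_protein_sd: float = 0.5
    depth_sd: float = 0.25
    detection_sd: float = 1.5
    markers: tuple[Marker, ...] = field(default_factory=tuple)
    split: str = "discovery"
    instrument: str = "synthetic-orbitrap"

    def __post_init__(self) -> None:
        if min(self.n_proteins, self.n_aa, self.n_con, self.n_normal) < 0:
            raise ValueError("sizes must be nonnegative")
        mean, _ = self.detection_targets()
        if not 0 < mean < self.n_proteins:
            raise ValueError(
                f"infeasible detection target: mean {mean} per sample with "
                f"{self.n_proteins} proteins"
            )
        idx = [m.protein_index for m in self.markers]
        if len(set(idx)) != len(idx):
            raise ValueError("marker protein indices must be unique")
        for m in self.markers:
            if not 0 <= m.protein_index < self.n_proteins:
                raise ValueError(f"marker index {m.protein_index} out of range")
            if not np.isfinite(m.log2_fc):
                raise ValueError("marker fold-changes must be finite")
            if m.group not in ("AA", "CON"):
                raise ValueError(f"marker group must be AA or CON, got {m.group!r}")
            if m.absent_in_normal and m.log2_fc <= 0:
                raise ValueError("absent-in-normal markers must be up-regulated")

    def detection_targets(self) -> tuple[float, float]:
        """(mean, sd) of detected proteins per sample, scaled to the universe."""
        scale = self.n_proteins / REFERENCE_UNIVERSE
        mean = self.detected_mean if self.detected_mean is not None \
            else REFERENCE_DETECTED_MEAN * scale
        sd = self.detected_sd if self.detected_sd is not None \
            else REFERENCE_DETECTED_SD * scale
        return float(mean), float(sd)


@dataclass
class GroundTruth:
    """What the generator injected: marker identities and sample labels."""

    markers: tuple[Marker, ...]
    marker_ids: tuple[str, ...]
    labels: pd.Series  # sample_id -> AA/CON (disease cohort only)


def protein_id(i: int) -> str:
    return f"P{i:05d}"


def _con_subgroups(n_con: int) -> list[str]:
    """Assign control subgroups by largest-remainder apportionment."""
    if n_con == 0:
        return []
    names = list(CON_SUBGROUP_WEIGHTS)
    weights = np.array([CON_SUBGROUP_WEIGHTS[k] for k in names], dtype=float)
    quotas = weights / weights.sum() * n_con
    counts = np.floor(quotas).astype(int)
    remainder = n_con - counts.sum()
    for i in np.argsort(-(quotas - counts), kind="mergesort")[:remainder]:
        counts[i] += 1
    out: list[str] = []
    for name, c in zip(names, counts):
        out.extend([name] * c)
    return out


def _calibrate_detection(mu: np.ndarray, spec: SyntheticCohortSpec) -> tuple[float, float]:
    """Solve for the detection threshold and the per-sample threshold jitter.

    Detection of cell x is Bernoulli(Phi((x - c - t_j) / detection_sd))
    with t_j ~ N(0, tau).  Integrating the within-protein noise, the
    expected count per sample at jitter t is
    g(t) = sum_i Phi((mu_i - c - t) / s_eff); c is solved so g(0) hits
    the target mean, and tau is set from the target sd after removing
    the Bernoulli sampling variance, via the local slope g'(0).
    """
    target_mean, target_sd = spec.detection_targets()
    s_eff = float(np.hypot(spec.detection_sd, spec.within_protein_sd))

    def g(c: float) -> float:
        return float(ndtr((mu - c) / s_eff).sum())

    lo = float(mu.min() - 12 * s_eff)
    hi = float(mu.max() + 12 * s_eff)
    c = brentq(lambda v: g(v) - target_mean, lo, hi, xtol=1e-9)
    p = ndtr((mu - c) / s_eff)
    var_bernoulli = float((p * (1 - p)).sum())
    z = (mu - c) / s_eff
    slope = float((np.exp(-0.5 * z**2) / np.sqrt(2 * np.pi) / s_eff).sum())
    excess = max(target_sd**2 - var_bernoulli, 0.0)
    tau = float(np.sqrt(excess) / slope) if slope > 0 else 0.0
    return float(c), tau


def _simulate_block(rng: np.random.Generator, mu: np.ndarray, n_samples: int,
                    spec: SyntheticCohortSpec, c: float, tau: float,
                    effect: np.ndarray | None = None) -> np.ndarray:
    """One cohort block of raw iBAQ values (proteins x samples)."""
    n_prot = mu.size
    if n_samples == 0:
        return np.zeros((n_prot, 0))
    eps = rng.normal(0.0, spec.within_protein_sd, size=(n_prot, n_samples))
    x = mu[:, None] + eps
    if effect is not None:
        x = x + effect
    depth = rng.normal(0.0, spec.depth_sd, size=n_samples)
    t = rng.normal(0.0, tau, size=n_samples)
    p_detect = ndtr((x - c - t[None, :]) / spec.detection_sd)
    detected = rng.random(size=x.shape) < p_detect
    values = np.exp2(x + depth[None, :])
    values[~detected] = 0.0
    return values


def generate_cohort(spec: SyntheticCohortSpec, seed: int, universe_seed: int | None = None
                    ) -> tuple[AbundanceMatrix, AbundanceMatrix, pd.DataFrame, GroundTruth]:
    """Simulate one disease cohort plus a matched healthy reference cohort.

    Returns ``(disease_raw, normal_raw, metadata, ground_truth)`` where
    both matrices are at stage ``raw_ibaq``.  Reproducible: the same
    (spec, seed) pair yields bit-identical output.

    ``universe_seed`` fixes the protein universe (per-protein baseline
    abundances) independently of the sampling noise; pass the discovery
    cohort's value when simulating an independent validation cohort of
    the *same* biological universe.  Defaults to ``seed``.
    """
    # separate streams so the universe draw and the sampling noise never
    # alias even when the two seeds coincide
    rng = np.random.default_rng([seed, 1])
    universe_rng = np.random.default_rng([seed if universe_seed is None else universe_seed, 0])
    mu = universe_rng.normal(spec.baseline_log2_mean, spec.baseline_log2_sd,
                             size=spec.n_proteins)
    for m in spec.markers:
        if m.baseline_quantile is not None:
            mu[m.protein_index] = (spec.baseline_log2_mean
                                   + spec.baseline_log2_sd * ndtri(m.baseline_quantile))
    c, tau = _calibrate_detection(mu, spec)

    aa_ids = [f"{spec.split}_AA_{i:03d}" for i in range(spec.n_aa)]
    con_ids = [f"{spec.split}_CON_{i:03d}" for i in range(spec.n_con)]
    normal_ids = [f"normal_{i:03d}" for i in range(spec.n_normal)]

    effect = np.zeros((spec.n_proteins, spec.n_aa + spec.n_con))
    aa_cols = np.arange(spec.n_aa)
    con_cols = np.arange(spec.n_aa, spec.n_aa + spec.n_con)
    for m in spec.markers:
        cols = aa_cols if m.group == "AA" else con_cols
        effect[m.protein_index, cols] += m.log2_fc

    disease = _simulate_block(rng, mu, spec.n_aa + spec.n_con, spec, c, tau, effect)
    normal = _simulate_block(rng, mu, spec.n_normal, spec, c, tau)

    for m in spec.markers:
        if m.absent_in_normal:
            normal[m.protein_index, :] = 0.0
            off = con_cols if m.group == "AA" else aa_cols
            disease[m.protein_index, off] = 0.0

    proteins = pd.Index([protein_id(i) for i in range(spec.n_proteins)], name="protein_id")
    disease_mat = AbundanceMatrix(
        pd.DataFrame(disease, index=proteins, columns=aa_ids + con_ids), "raw_ibaq")
    normal_mat = AbundanceMatrix(
        pd.DataFrame(normal, index=proteins, columns=normal_ids), "raw_ibaq")

    metadata = pd.DataFrame(
        {
            "sample_id": aa_ids + con_ids,
            "group": ["AA"] * spec.n_aa + ["CON"] * spec.n_con,
            "subgroup": ["AA"] * spec.n_aa + _con_subgroups(spec.n_con),
            "split": spec.split,
            "instrument": spec.instrument,
        }
    )
    validate_metadata(metadata)

    truth = GroundTruth(
        markers=spec.markers,
        marker_ids=tuple(protein_id(m.protein_index) for m in spec.markers),
        labels=metadata.set_index("sample_id")["group"],
    )
    return disease_mat, normal_mat, metadata, truth


def null_spec(n_aa: int = 30, n_con: int = 30, n_proteins: int = 2000,
              n_normal: int = 100, **kwargs) -> SyntheticCohortSpec:
    """A no-effect cohort: identical group distributions, zero markers."""
    return SyntheticCohortSpec(n_proteins=n_proteins, n_aa=n_aa, n_con=n_con,
                               n_normal=n_normal, markers=(), **kwargs)


def strong_effect_spec(n_aa: int = 30, n_con: int = 30, n_proteins: int = 2000,
                       n_normal: int = 100, n_markers: int = 10,
                       log2_fc: float = 2.5, **kwargs) -> SyntheticCohortSpec:
    """A cohort with ``n_markers`` strong markers (default |log2 FC| = 2.5).

    Markers alternate between the AA and CON groups, sit at baseline
    quantiles 0.55-0.95 of the abundance hyperprior (detectable but not
    dominating), and the last two are absent from healthy urine (one per
    group), exercising selection standard (2).
    """
    markers = []
    for i in range(n_markers):
        q = 0.55 + 0.40 * (i / max(n_markers - 1, 1))
        markers.append(
            Marker(
                protein_index=(i + 1) * (n_proteins // (n_markers + 1)),
                log2_fc=log2_fc,
                group="AA" if i % 2 == 0 else "CON",
                absent_in_normal=i >= n_markers - 2,
                baseline_quantile=q,
            )
        )
    return SyntheticCohortSpec(n_proteins=n_proteins, n_aa=n_aa, n_con=n_con,
                               n_normal=n_normal, markers=tuple(markers), **kwargs)


def full_scale_spec(**kwargs) -> SyntheticCohortSpec:
    """The full-size configuration: 5335 proteins, 32/41 disease samples,
    495 healthy reference samples, detection 1561 +/- 432 per sample."""
    defaults = dict(n_proteins=REFERENCE_UNIVERSE, n_aa=32, n_con=41, n_normal=495)
    defaults.update(kwargs)
    return SyntheticCohortSpec(**defaults)


def validation_spec(base: SyntheticCohortSpec, n_aa: int = 16, n_con: int = 45
                    ) -> SyntheticCohortSpec:
    """An independent validation cohort drawn from the same universe model."""
    return replace(base, n_aa=n_aa, n_con=n_con, n_normal=0, split="validation")


def spike_summary(ground_truth: GroundTruth, panel: FeaturePanel | tuple) -> dict:
    """How much of the injected marker set a selected panel recovered."""
    panel_ids = set(panel.protein_ids if isinstance(panel, FeaturePanel) else panel)
    markers = set(ground_truth.marker_ids)
    hits = sorted(panel_ids & markers)
    recall = len(hits) / len(markers) if markers else float("nan")
    return {"n_markers": len(markers), "true_positives": hits, "recall": recall}
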