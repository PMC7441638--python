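"""Synthetic spermathecal LFQ datasets with known ground truth.

The generator emulates the statistical structure of a label-free
quantification (LFQ) experiment on queen honey bee spermathecae so that every
downstream stage — filtering, differential expression, enrichment, marker
selection and the blind-trial classifier — can be exercised and its parameter
recovery measured without any raw mass-spectrometry data.

Generative model
----------------
* Each protein group gets a baseline log2 abundance drawn uniformly from
  ``baseline_log2_mean_range`` (default [20, 32], a typical LFQ dynamic
  range); per-sample values add independent Gaussian noise with standard
  deviation ``baseline_log2_sd`` (default 0.4 log2 units).
* Stress markers add their injected log2 fold change to samples of their
  stressor group.  Marker baselines are drawn from the quantifiable
  mid-to-upper range (default [24, 30]): a protein can only ever be
  nominated as a candidate biomarker if it survives the minimum-valid-values
  filter, so useful markers are reliably quantified by construction.
* One designated housekeeping protein (default accession ``HK_REF_1``) sits
  at a fixed, high baseline with a much smaller noise sd (default 0.02), so
  reference-protein selection has a known answer.
* Missingness is left-censoring (missing-not-at-random): the probability a
  cell is unobserved follows a logistic curve in its log2 intensity anchored
  at the ``censor_quantile`` of all generated values — low-abundance values
  vanish preferentially, as in real LFQ data.
* Decoy (reversed-sequence) and contaminant rows are appended with
  ``REV__``/``CON__`` accession prefixes, matching the MaxQuant dialect.

Heat time-course effects follow a hinge ramp: no effect below ``onset_h``
(default 1 h, matching the observation that marker induction needs about an
hour of heat), linear up to ``saturation_h``, and multiplied by
``rh_multiplier_at_80`` at 80 % relative humidity (high humidity amplifies
the heat-shock response).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .containers import GroundTruth, LfqMatrix, SealedLabels

DECOY_PREFIX = "REV__"
CONTAMINANT_PREFIX = "CON__"


@dataclass
class SimulationConfig:
    """Parameters of the synthetic LFQ generator (defaults = study-like)."""

    n_proteins: int = 300
    groups: Sequence[tuple[str, int]] = (("control", 7), ("heatshock", 7))
    #: accession -> (stressor group label, injected log2 fold change)
    marker_effects: Mapping[str, tuple[str, float]] = field(default_factory=dict)
    baseline_log2_mean_range: tuple[float, float] = (20.0, 32.0)
    #: markers emulate reliably quantified candidate biomarkers: their
    #: baselines stay clear of the left-censoring floor
    marker_baseline_log2_range: tuple[float, float] = (24.0, 30.0)
    baseline_log2_sd: float = 0.4
    #: (censor_quantile in [0, 1], logistic steepness per log2 unit)
    missingness: tuple[float, float] = (0.1, 3.0)
    n_decoys: int = 10
    n_contaminants: int = 5
    housekeeping_accession: str = "HK_REF_1"
    housekeeping_sd: float = 0.02
    housekeeping_baseline_log2: float = 28.0
    #: (onset_h, saturation_h, rh_multiplier_at_80)
    time_course: tuple[float, float, float] = (1.0, 2.0, 1.5)
    seed: int = 0

    def validate(self) -> None:
        if self.n_proteins <= 0:
            raise ValueError("n_proteins must be positive")
        if self.n_decoys < 0 or self.n_contaminants < 0:
            raise ValueError("decoy/contaminant counts must be >= 0")
        if not self.groups:
            raise ValueError("at least one sample group is required")
        for label, n in self.groups:
            if n < 0:
                raise ValueError(f"group {label!r} has negative size")
        q, steep = self.missingness
        if not 0.0 <= q <= 1.0:
            raise ValueError("censor_quantile must lie in [0, 1]")
        if steep <= 0:
            raise ValueError("logistic steepness must be positive")
        if self.baseline_log2_sd <= 0 or self.housekeeping_sd <= 0:
            raise ValueError("noise standard deviations must be positive")
        onset, sat, mult = self.time_course
        if sat <= onset:
            raise ValueError("saturation_h must exceed onset_h")
        if mult <= 1.0:
            raise ValueError("rh_multiplier_at_80 must exceed 1")
        for acc, (stressor, lfc) in self.marker_effects.items():
            if not np.isfinite(lfc):
                raise ValueError(f"marker {acc}: fold change must be finite")
            if acc.startswith((DECOY_PREFIX, CONTAMINANT_PREFIX)):
                raise ValueError(
                    f"marker accession {acc!r} collides with decoy/contaminant naming"
                )
        n_named = len(self.marker_effects) + 1  # + housekeeping
        if self.n_proteins < n_named:
            raise ValueError(
                f"n_proteins={self.n_proteins} too small for "
                f"{len(self.marker_effects)} markers plus the housekeeping protein"
            )


def time_course_effect(
    lfc: float,
    duration_h: float,
    onset_h: float,
    saturation_h: float,
    rh_percent: float,
    rh_multiplier_at_80: float,
) -> float:
    """Expected log2 effect of a heat marker after *duration_h* at *rh_percent*.

    A hinge ramp in time — zero below the onset, saturating at the plateau —
    scaled linearly in relative humidity from 1× at 40 % RH to
    ``rh_multiplier_at_80`` at 80 % RH.
    """
    ramp = np.clip((duration_h - onset_h) / (saturation_h - onset_h), 0.0, 1.0)
    rh_factor = 1.0 + (rh_percent - 40.0) / 40.0 * (rh_multiplier_at_80 - 1.0)
    return float(lfc * ramp * rh_factor)


def _accession_roster(config: SimulationConfig) -> tuple[list[str], list[str], list[str]]:
    markers = sorted(config.marker_effects)
    n_fill = config.n_proteins - len(markers) - 1
    fillers = [f"PROT_{i + 1:05d}" for i in range(n_fill)]
    real = markers + [config.housekeeping_accession] + fillers
    decoys = [f"{DECOY_PREFIX}DECOY_{i + 1:03d}" for i in range(config.n_decoys)]
    contams = [f"{CONTAMINANT_PREFIX}CONTAM_{i + 1:03d}" for i in range(config.n_contaminants)]
    return real, decoys, contams


def _build_matrix(
    config: SimulationConfig,
    sample_ids: list[str],
    sample_groups: list[str],
    effect_fn,
    rng: np.random.Generator,
    metadata_extra: pd.DataFrame | None = None,
    marker_baseline_log2: float | None = None,
) -> tuple[LfqMatrix, np.ndarray]:
    """Shared core: draw log2 values, apply effects, censor, exponentiate.

    *effect_fn(accession, group_label) -> log2 shift* supplies the injected
    marker effects.  Returns the matrix and the pre-censoring log2 array.
    """
    real, decoys, contams = _accession_roster(config)
    accessions = real + decoys + contams
    n_rows, n_cols = len(accessions), len(sample_ids)

    lo, hi = config.baseline_log2_mean_range
    baselines = rng.uniform(lo, hi, size=n_rows)
    sds = np.full(n_rows, config.baseline_log2_sd)
    hk_idx = accessions.index(config.housekeeping_accession)
    baselines[hk_idx] = config.housekeeping_baseline_log2
    sds[hk_idx] = config.housekeeping_sd
    m_lo, m_hi = config.marker_baseline_log2_range
    for acc in sorted(config.marker_effects):
        baselines[accessions.index(acc)] = (
            marker_baseline_log2
            if marker_baseline_log2 is not None
            else rng.uniform(m_lo, m_hi)
        )

    log2_vals = baselines[:, None] + rng.normal(size=(n_rows, n_cols)) * sds[:, None]
    for i, acc in enumerate(real):
        if acc in config.marker_effects:
            for j, grp in enumerate(sample_groups):
                log2_vals[i, j] += effect_fn(acc, grp)

    q, steep = config.missingness
    mask = np.zeros_like(log2_vals, dtype=bool)
    if q > 0.0:
        anchor = np.quantile(log2_vals, q)
        p_missing = expit(-(log2_vals - anchor) * steep)
        mask = rng.random(size=log2_vals.shape) < p_missing

    intensities = np.power(2.0, log2_vals)
    intensities[mask] = np.nan

    flags = pd.DataFrame(
        {
            "reverse": [a.startswith(DECOY_PREFIX) for a in accessions],
            "contaminant": [a.startswith(CONTAMINANT_PREFIX) for a in accessions],
            "site_only": [False] * n_rows,
        },
        index=accessions,
    )
    metadata = pd.DataFrame({"group": sample_groups}, index=sample_ids)
    metadata["duration_h"] = np.nan
    metadata["rh_percent"] = np.nan
    metadata["age"] = np.nan
    if metadata_extra is not None:
        for col in metadata_extra.columns:
            metadata[col] = metadata_extra[col].to_numpy()

    matrix = LfqMatrix(
        intensities=pd.DataFrame(intensities, index=accessions, columns=sample_ids),
        flags=flags,
        metadata=metadata,
    )
    return matrix, log2_vals


def generate_dataset(config: SimulationConfig) -> tuple[LfqMatrix, GroundTruth]:
    """Generate one multi-group LFQ dataset.

    The matrix has ``n_proteins + n_decoys + n_contaminants`` rows; marker
    rows differ between their stressor group and all other groups by the
    injected log2 fold change in expectation.  Identical configs (including
    the seed) give bit-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    group_of_marker = {acc: grp for acc, (grp, _) in config.marker_effects.items()}
    known_groups = {label for label, _ in config.groups}
    for acc, grp in group_of_marker.items():
        if grp not in known_groups:
            raise ValueError(f"marker {acc}: stressor group {grp!r} not among groups")

    sample_ids, sample_groups = [], []
    for label, n in config.groups:
        for i in range(n):
            sample_ids.append(f"{label}_{i + 1}")
            sample_groups.append(label)

    def effect(acc: str, grp: str) -> float:
        stressor, lfc = config.marker_effects[acc]
        return lfc if grp == stressor else 0.0

    matrix, _ = _build_matrix(config, sample_ids, sample_groups, effect, rng)

    true_markers: dict[str, set[str]] = {}
    for acc, (stressor, _) in config.marker_effects.items():
        true_markers.setdefault(stressor, set()).add(acc)
    truth = GroundTruth(
        true_markers=true_markers,
        sample_labels=dict(zip(sample_ids, sample_groups)),
        injected_lfc={acc: lfc for acc, (_, lfc) in config.marker_effects.items()},
        housekeeping_accession=config.housekeeping_accession,
    )
    return matrix, truth


def generate_time_course(
    config: SimulationConfig,
    durations_h: Sequence[float],
    rh_levels: Sequence[float],
    n_per_condition: int = 7,
) -> tuple[LfqMatrix, GroundTruth]:
    """Generate a heat-exposure time-course across durations × RH levels.

    One group per (duration, RH) cell, labelled ``t{d}h_rh{rh}``.  Marker
    effects follow :func:`time_course_effect`: zero below the onset (default
    1 h), saturating, and amplified at high relative humidity.
    """
    config.validate()
    if len(durations_h) == 0:
        raise ValueError("durations_h must be non-empty")
    if any(d < 0 for d in durations_h):
        raise ValueError("durations must be non-negative")
    if n_per_condition <= 0:
        raise ValueError("n_per_condition must be positive")

    onset, sat, mult = config.time_course
    conditions = [(float(d), float(rh)) for d in durations_h for rh in rh_levels]
    labels = [f"t{d:g}h_rh{rh:g}" for d, rh in conditions]
    cfg = replace(config, groups=tuple((lab, n_per_condition) for lab in labels))

    sample_ids, sample_groups, durs, rhs = [], [], [], []
    for (d, rh), lab in zip(conditions, labels):
        for i in range(n_per_condition):
            sample_ids.append(f"{lab}_{i + 1}")
            sample_groups.append(lab)
            durs.append(d)
            rhs.append(rh)

    cond_of_label = dict(zip(labels, conditions))

    def effect(acc: str, grp: str) -> float:
        _, lfc = config.marker_effects[acc]
        d, rh = cond_of_label[grp]
        return time_course_effect(lfc, d, onset, sat, rh, mult)

    extra = pd.DataFrame({"duration_h": durs, "rh_percent": rhs}, index=sample_ids)
    rng = np.random.default_rng(config.seed)
    matrix, _ = _build_matrix(cfg, sample_ids, sample_groups, effect, rng, metadata_extra=extra)

    group_effects = {
        (acc, lab): effect(acc, lab) for acc in config.marker_effects for lab in labels
    }
    truth = GroundTruth(
        true_markers={"heat": set(config.marker_effects)},
        sample_labels=dict(zip(sample_ids, sample_groups)),
        injected_lfc={acc: lfc for acc, (_, lfc) in config.marker_effects.items()},
        group_effects=group_effects,
        housekeeping_accession=config.housekeeping_accession,
    )
    return matrix, truth


def generate_blind_trial(
    config: SimulationConfig,
    n_total: int = 16,
    n_stressed: int = 8,
    marker_ratio: float = 0.02,
) -> tuple[LfqMatrix, GroundTruth]:
    """Generate a blind trial: *n_stressed* of *n_total* queens carry effects.

    True assignments are shuffled by the seed and hidden in
    ``GroundTruth.sealed_labels``; the metadata group is uniformly ``blind``.
    Marker baselines are tied to the housekeeping reference at linear ratio
    *marker_ratio* (default 0.02), placing unstressed queens below and
    stressed queens above the 0.05 elevation-ratio threshold regime the
    published trial operated in.
    """
    config.validate()
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_stressed <= n_total:
        raise ValueError("n_stressed must lie in [0, n_total]")
    if marker_ratio <= 0:
        raise ValueError("marker_ratio must be positive")

    rng = np.random.default_rng(config.seed)
    stressed = np.zeros(n_total, dtype=bool)
    stressed[:n_stressed] = True
    stressed = rng.permutation(stressed)

    sample_ids = [f"BLIND_{i + 1:02d}" for i in range(n_total)]
    # internal per-sample pseudo-groups drive the effect injection; public
    # metadata shows only the uninformative label "blind"
    hidden_groups = ["stressed" if s else "unstressed" for s in stressed]
    cfg = replace(config, groups=(("stressed", int(n_stressed)), ("unstressed", n_total - int(n_stressed))))

    def effect(acc: str, grp: str) -> float:
        _, lfc = config.marker_effects[acc]
        return lfc if grp == "stressed" else 0.0

    marker_baseline = config.housekeeping_baseline_log2 + float(np.log2(marker_ratio))
    matrix, _ = _build_matrix(
        cfg, sample_ids, hidden_groups, effect, rng, marker_baseline_log2=marker_baseline
    )
    matrix.metadata["group"] = "blind"

    truth = GroundTruth(
        true_markers={"heat": set(config.marker_effects)},
        sample_labels=None,
        injected_lfc={acc: lfc for acc, (_, lfc) in config.marker_effects.items()},
        sealed_labels=SealedLabels(dict(zip(sample_ids, (bool(s) for s in stressed)))),
        housekeeping_accession=config.housekeeping_accession,
    )
    return matrix, truth


def generate_annotations(
    accessions: Sequence[str],
    n_terms: int = 40,
    size_range: tuple[int, int] = (5, 40),
    seed: int = 0,
) -> list:
    """Random synthetic GO-like annotation sets over *accessions*.

    Purely synthetic term memberships (term ids ``SYN:0000001`` ...) for
    exercising the enrichment stage; sizes drawn uniformly from
    *size_range*.
    """
    from .containers import AnnotationSet

    rng = np.random.default_rng(seed)
    pool = [a for a in accessions if not a.startswith((DECOY_PREFIX, CONTAMINANT_PREFIX))]
    lo, hi = size_range
    hi = min(hi, len(pool))
    lo = min(lo, hi)
    out = []
    for t in range(n_terms):
        k = int(rng.integers(lo, hi + 1))
        members = rng.choice(len(pool), size=k, replace=False)
        out.append(
            AnnotationSet(
                term_id=f"SYN:{t + 1:07d}",
                term_name=f"synthetic term {t + 1}",
                members=frozenset(pool[i] for i in members),
            )
        )
    return out
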