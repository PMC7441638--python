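"""Candidate-marker selection and the blind-trial threshold classifier.

The diagnostic procedure: take the top two most significantly upregulated
proteins of a stress comparison as candidate markers; normalise each
sample's marker LFQ intensity to the most stable (lowest log2-variance,
fully observed) protein in the dataset; flag a sample as stressed when the
linear-scale marker/reference ratio exceeds an elevation threshold (0.05 in
the published heat-shock trial, where only heat-shocked queens exceeded it
unblinded).  In a blind trial the true group assignments stay sealed until
after every prediction is made, and unsealing yields sensitivity-style
confusion metrics (TPR = correctly flagged stressed queens / all truly
stressed queens).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import LfqMatrix, SealedLabels


@dataclass
class MarkerPanel:
    """Candidate biomarkers chosen from one differential-expression table."""

    markers: list[tuple[str, str]]  # (accession, stressor label)
    selection_rule: str
    k: int
    warning: bool = False

    @property
    def accessions(self) -> list[str]:
        return [acc for acc, _ in self.markers]


@dataclass
class ClassificationOutcome:
    """Per-sample threshold calls plus the confusion summary."""

    reference_accession: str
    threshold: float
    samples: pd.DataFrame  # columns: normalized_value, flagged, true_label
    tp: int
    fp: int
    tn: int
    fn: int
    tpr: float
    fpr: float
    ppv: float


@dataclass
class BlindTrialResult:
    """Outcome of a blind trial: one confusion per marker plus the joint rule."""

    reference_accession: str
    threshold: float
    per_marker: dict[str, ClassificationOutcome] = field(default_factory=dict)
    joint: ClassificationOutcome | None = None


def select_candidate_markers(
    de_table: pd.DataFrame, k: int = 2, stressor: str = ""
) -> MarkerPanel:
    """The *k* most significantly upregulated proteins of one comparison.

    Ranking is by adjusted p ascending, then larger |t|, then accession.
    If fewer than *k* proteins are both significant and upregulated, the
    panel is padded with the best remaining upregulated proteins and the
    ``warning`` flag is set; with no upregulated proteins at all the panel
    is empty (warned).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    up = de_table[de_table["direction"] == "up"].copy()
    up["_abs_t"] = up["t_stat"].abs()
    up = up.sort_values(["adj_p", "_abs_t", "accession"], ascending=[True, False, True])
    strict = up[up["significant"]] if "significant" in up.columns else up[up["adj_p"] <= 0.05]
    chosen = list(strict["accession"].head(k))
    warning = len(chosen) < k
    if warning:
        pad = [a for a in up["accession"] if a not in chosen]
        chosen += pad[: k - len(chosen)]
    return MarkerPanel(
        markers=[(acc, stressor) for acc in chosen],
        selection_rule=f"top-{k} upregulated by adjusted p",
        k=k,
        warning=warning,
    )


def select_reference_protein(matrix: LfqMatrix) -> str:
    """The fully observed protein with the lowest log2-intensity variance.

    Candidates must be quantified in every sample.  Variance is computed on
    the log2 scale (linear-scale variance is dominated by abundance); ties
    at machine precision resolve to the lexicographically smaller accession.
    """
    vals = matrix.intensities.to_numpy(dtype=float)
    if not matrix.log2:
        with np.errstate(divide="ignore"):
            vals = np.log2(np.where(vals > 0, vals, np.nan))
    complete = ~np.isnan(vals).any(axis=1)
    if not complete.any():
        raise ValueError(
            "no protein is observed in every sample; relax completeness or "
            "filter samples before selecting a reference"
        )
    variances = np.var(vals[complete], axis=1, ddof=1)
    accs = np.asarray(matrix.accessions, dtype=object)[complete]
    vmin = variances.min()
    tied = variances - vmin <= 1e-12 * max(vmin, 1.0)
    return min(accs[tied])


def normalize_to_reference(
    matrix: LfqMatrix, marker: str, reference: str
) -> pd.Series:
    """Per-sample linear-scale ratio of *marker* to *reference* LFQ intensity.

    The reference must be observed in every sample; a missing marker value
    is treated as no elevation (ratio 0).
    """
    for acc in (marker, reference):
        if acc not in matrix.intensities.index:
            raise KeyError(f"accession {acc!r} not in matrix")
    m = matrix.intensities.loc[marker].to_numpy(dtype=float)
    r = matrix.intensities.loc[reference].to_numpy(dtype=float)
    if matrix.log2:
        m, r = np.power(2.0, m), np.power(2.0, r)
    if np.isnan(r).any():
        missing = [s for s, v in zip(matrix.sample_ids, r) if np.isnan(v)]
        raise ValueError(f"reference {reference!r} missing in samples: {missing}")
    vals = np.where(np.isnan(m), 0.0, m / r)
    return pd.Series(vals, index=matrix.sample_ids, name=marker)


def classify_by_threshold(values: pd.Series, threshold: float = 0.05) -> pd.Series:
    """Flag samples whose normalised value strictly exceeds *threshold*."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    return values > threshold


def evaluate_confusion(
    flags,
    true_labels,
    normalized_values=None,
    reference_accession: str = "",
    threshold: float = np.nan,
) -> ClassificationOutcome:
    """Confusion counts and rates for threshold calls against known labels.

    ``tpr`` is sensitivity: correctly flagged stressed samples over all
    truly stressed samples.  Rates with empty denominators are NaN.
    """
    f = np.asarray(flags, dtype=bool)
    y = np.asarray(true_labels, dtype=bool)
    if f.shape != y.shape:
        raise ValueError(f"length mismatch: {f.shape} flags vs {y.shape} labels")
    tp = int(np.sum(f & y))
    fp = int(np.sum(f & ~y))
    tn = int(np.sum(~f & ~y))
    fn = int(np.sum(~f & y))
    tpr = tp / (tp + fn) if tp + fn else float("nan")
    fpr = fp / (fp + tn) if fp + tn else float("nan")
    ppv = tp / (tp + fp) if tp + fp else float("nan")
    index = flags.index if isinstance(flags, pd.Series) else pd.RangeIndex(len(f))
    samples = pd.DataFrame(
        {
            "normalized_value": (
                np.asarray(normalized_values, dtype=float)
                if normalized_values is not None
                else np.full(len(f), np.nan)
            ),
            "flagged": f,
            "true_label": y,
        },
        index=index,
    )
    return ClassificationOutcome(
        reference_accession=reference_accession,
        threshold=threshold,
        samples=samples,
        tp=tp, fp=fp, tn=tn, fn=fn,
        tpr=tpr, fpr=fpr, ppv=ppv,
    )


def blind_trial(
    matrix: LfqMatrix,
    panel: MarkerPanel,
    sealed_labels: SealedLabels,
    reference: str | None = None,
    threshold: float = 0.05,
) -> BlindTrialResult:
    """Run the blind classification protocol end to end.

    All per-marker flags (and the both-markers-elevated joint rule) are
    computed *before* the sealed labels are opened; attempting to rerun on
    an already-unsealed label set raises.  Returns one confusion per marker
    plus the joint AND rule, which in the published trial performed worse
    than the best single marker.
    """
    if sealed_labels.opened:
        raise RuntimeError("labels were unsealed before prediction; trial is not blind")
    if not panel.markers:
        raise ValueError("empty marker panel")
    ref = reference if reference is not None else select_reference_protein(matrix)

    values: dict[str, pd.Series] = {}
    flags: dict[str, pd.Series] = {}
    for acc in panel.accessions:
        v = normalize_to_reference(matrix, acc, ref)
        values[acc] = v
        flags[acc] = classify_by_threshold(v, threshold)
    joint_flags = np.logical_and.reduce([flags[a].to_numpy() for a in panel.accessions])

    labels = sealed_labels.unseal()  # predictions fixed; reveal the groups
    y = pd.Series({s: labels[s] for s in matrix.sample_ids})

    result = BlindTrialResult(reference_accession=ref, threshold=threshold)
    for acc in panel.accessions:
        result.per_marker[acc] = evaluate_confusion(
            flags[acc], y, normalized_values=values[acc],
            reference_accession=ref, threshold=threshold,
        )
    result.joint = evaluate_confusion(
        pd.Series(joint_flags, index=matrix.sample_ids), y,
        reference_accession=ref, threshold=threshold,
    )
    return result
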