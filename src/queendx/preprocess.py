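"""Standard LFQ preprocessing: log2 transform and quality filters.

The filtering rules mirror Perseus-style practice on MaxQuant output:
reverse (decoy) hits, potential contaminants and proteins only identified by
site are removed, along with any protein quantified in fewer than
``min_valid`` samples (default 6) across the whole experiment.  When several
flags apply to one row it is counted once, with precedence
reverse > contaminant > site-only, so the report always reconciles.
No imputation is performed anywhere; downstream tests use pairwise-complete
observations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import LfqMatrix


@dataclass(frozen=True)
class FilterReport:
    """Accounting of rows removed by :func:`apply_standard_filters`."""

    n_input: int
    n_removed_reverse: int
    n_removed_contaminant: int
    n_removed_site_only: int
    n_removed_min_valid: int
    n_retained: int

    def __post_init__(self) -> None:
        removed = (
            self.n_removed_reverse
            + self.n_removed_contaminant
            + self.n_removed_site_only
            + self.n_removed_min_valid
        )
        if self.n_input != self.n_retained + removed:
            raise ValueError("filter report does not reconcile with input count")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])


def log2_transform(matrix: LfqMatrix) -> LfqMatrix:
    """Return a copy with present intensities replaced by their log2.

    Missing cells stay missing.  Zeros (non-detections that escaped the
    reader's missing-value convention) become missing; negative intensities
    raise.
    """
    if matrix.log2:
        return matrix.copy()
    vals = matrix.intensities.to_numpy(dtype=float).copy()
    if np.nanmin(vals, initial=np.inf) < 0:
        raise ValueError("negative intensities cannot be log2-transformed")
    vals[vals == 0.0] = np.nan
    with np.errstate(divide="ignore"):
        out = np.log2(vals)
    return LfqMatrix(
        intensities=pd.DataFrame(out, index=matrix.intensities.index, columns=matrix.intensities.columns),
        flags=matrix.flags.copy(),
        metadata=matrix.metadata.copy(),
        log2=True,
    )


def apply_standard_filters(
    matrix: LfqMatrix,
    min_valid: int = 6,
    per_group: bool = False,
) -> tuple[LfqMatrix, FilterReport]:
    """Remove flagged rows and rows with too few quantified values.

    With ``per_group=False`` (default) a row needs at least *min_valid*
    non-missing values across all samples of the experiment; with
    ``per_group=True`` it needs *min_valid* valid values in at least one
    metadata group (the Perseus per-group alternative).  Filtering is
    idempotent.
    """
    if min_valid < 0:
        raise ValueError("min_valid must be >= 0")
    if min_valid > matrix.n_samples:
        raise ValueError(
            f"min_valid={min_valid} exceeds the number of samples ({matrix.n_samples})"
        )

    flags = matrix.flags
    reverse = flags["reverse"].to_numpy()
    contaminant = flags["contaminant"].to_numpy() & ~reverse
    site_only = flags["site_only"].to_numpy() & ~reverse & ~flags["contaminant"].to_numpy()
    flagged = reverse | contaminant | site_only

    present = ~matrix.intensities.isna()
    if per_group:
        groups = matrix.metadata["group"]
        ok = np.zeros(matrix.n_proteins, dtype=bool)
        for label in groups.dropna().unique():
            cols = matrix.metadata.index[groups == label]
            ok |= present[cols].sum(axis=1).to_numpy() >= min_valid
    else:
        ok = present.sum(axis=1).to_numpy() >= min_valid
    too_sparse = ~ok & ~flagged

    keep = ~flagged & ~too_sparse
    report = FilterReport(
        n_input=matrix.n_proteins,
        n_removed_reverse=int(reverse.sum()),
        n_removed_contaminant=int(contaminant.sum()),
        n_removed_site_only=int(site_only.sum()),
        n_removed_min_valid=int(too_sparse.sum()),
        n_retained=int(keep.sum()),
    )
    kept = [a for a, k in zip(matrix.accessions, keep) if k]
    return matrix.subset(kept), report
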