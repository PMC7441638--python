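"""Core in-memory containers shared across the pipeline.

The central object is :class:`LfqMatrix`, a protein-group × sample table of
label-free quantification (LFQ) intensities together with the MaxQuant-style
quality flags (reverse/decoy hits, contaminants, proteins only identified by
site) and per-sample metadata (treatment group, exposure duration, relative
humidity, age, free covariates).  Missing values are ``NaN``; an LFQ intensity
of zero in the source file means non-detection and is converted to missing on
read.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

FLAG_COLUMNS = ("reverse", "contaminant", "site_only")

#: Metadata columns every LfqMatrix carries (missing entries are NaN).
METADATA_COLUMNS = ("group", "duration_h", "rh_percent", "age")


@dataclass
class LfqMatrix:
    """Protein-group × sample LFQ intensity matrix with flags and metadata.

    Parameters
    ----------
    intensities : pandas.DataFrame
        Rows indexed by protein-group accession, columns by sample id.
        Values are LFQ intensities (linear scale unless ``log2`` is True);
        ``NaN`` marks a missing (non-detected) value.
    flags : pandas.DataFrame
        Boolean columns ``reverse``, ``contaminant``, ``site_only`` aligned
        to the protein index.
    metadata : pandas.DataFrame
        One row per sample (aligned to the intensity columns).  Must contain
        a ``group`` column; other covariates are free.
    log2 : bool
        Whether intensities are on the log2 scale.
    """

    intensities: pd.DataFrame
    flags: pd.DataFrame | None = None
    metadata: pd.DataFrame | None = None
    log2: bool = False

    def __post_init__(self) -> None:
        if not isinstance(self.intensities, pd.DataFrame):
            raise TypeError("intensities must be a pandas DataFrame")
        if self.intensities.index.has_duplicates:
            dups = self.intensities.index[self.intensities.index.duplicated()]
            raise ValueError(f"duplicate accessions: {sorted(set(dups))}")
        if self.flags is None:
            self.flags = pd.DataFrame(
                False, index=self.intensities.index, columns=list(FLAG_COLUMNS)
            )
        else:
            self.flags = self.flags.reindex(self.intensities.index)
            for col in FLAG_COLUMNS:
                if col not in self.flags.columns:
                    self.flags[col] = False
            self.flags = self.flags[list(FLAG_COLUMNS)].fillna(False).astype(bool)
        if self.metadata is None:
            self.metadata = pd.DataFrame(index=self.intensities.columns)
        if "group" not in self.metadata.columns:
            self.metadata = self.metadata.copy()
            self.metadata["group"] = np.nan
        missing = [s for s in self.intensities.columns if s not in self.metadata.index]
        if missing:
            raise ValueError(f"samples missing from metadata: {missing}")
        self.metadata = self.metadata.loc[self.intensities.columns]
        if not self.log2:
            vals = self.intensities.to_numpy(dtype=float)
            if np.nanmin(vals, initial=np.inf) < 0:
                raise ValueError("linear-scale intensities must be non-negative")

    # -- basic accessors -------------------------------------------------
    @property
    def accessions(self) -> list[str]:
        return list(self.intensities.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.intensities.columns)

    @property
    def n_proteins(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[1]

    def samples_in_group(self, label: str) -> list[str]:
        """Sample ids whose metadata ``group`` equals *label*."""
        mask = self.metadata["group"] == label
        return list(self.metadata.index[mask])

    def group_labels(self) -> list[str]:
        labels = self.metadata["group"].dropna().unique()
        return sorted(str(x) for x in labels)

    def copy(self) -> "LfqMatrix":
        return LfqMatrix(
            intensities=self.intensities.copy(),
            flags=self.flags.copy(),
            metadata=self.metadata.copy(),
            log2=self.log2,
        )

    def subset(self, accessions: Iterable[str]) -> "LfqMatrix":
        acc = list(accessions)
        return LfqMatrix(
            intensities=self.intensities.loc[acc],
            flags=self.flags.loc[acc],
            metadata=self.metadata.copy(),
            log2=self.log2,
        )

    def equals(self, other: "LfqMatrix") -> bool:
        return (
            self.log2 == other.log2
            and self.intensities.equals(other.intensities)
            and self.flags.equals(other.flags)
        )


@dataclass(frozen=True)
class AnnotationSet:
    """One GO term and the protein accessions annotated to it."""

    term_id: str
    term_name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"annotation term {self.term_id} has no members")

    @property
    def size(self) -> int:
        return len(self.members)


class SealedLabels:
    """Write-once container hiding blind-trial group assignments.

    The true heat-shock/control labels of a blind trial are stored sealed;
    they can be read exactly once, via :meth:`unseal`, after predictions have
    been made.  Attempting to re-seal or peek raises.
    """

    def __init__(self, labels: Mapping[str, bool]):
        self._labels = dict(labels)
        self._opened = False

    @property
    def opened(self) -> bool:
        return self._opened

    def unseal(self) -> dict[str, bool]:
        """Reveal the labels (marks the seal as broken)."""
        self._opened = True
        return dict(self._labels)

    def __repr__(self) -> str:  # labels never leak through repr
        state = "opened" if self._opened else "sealed"
        return f"SealedLabels(n={len(self._labels)}, {state})"


@dataclass
class GroundTruth:
    """What the synthetic-data generator actually injected.

    Used by parameter-recovery tests: which accessions carry true stressor
    effects, which sample belongs to which group, and the injected log2 fold
    changes.  Blind trials carry their labels in ``sealed_labels`` instead of
    ``sample_labels``.
    """

    true_markers: dict[str, set[str]] = field(default_factory=dict)
    sample_labels: dict[str, str] | None = None
    injected_lfc: dict[str, float] = field(default_factory=dict)
    group_effects: dict[tuple[str, str], float] | None = None
    sealed_labels: SealedLabels | None = None
    housekeeping_accession: str | None = None
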