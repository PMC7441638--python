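"""Readers and writers for the tabular formats the pipeline touches.

Two LFQ dialects are supported:

``maxquant``
    A MaxQuant ``proteinGroups.txt``-style TSV: one row per protein group,
    samples in ``LFQ intensity <sample>`` columns, ``+``-marked ``Reverse``,
    ``Potential contaminant`` and ``Only identified by site`` columns.  A
    zero LFQ intensity means non-detection and is read as missing.

``plain``
    A bare accession × sample matrix (first column = accession); empty cells
    are missing.

Sample metadata travels in a sidecar TSV keyed by sample id, because
proteinGroups files carry none.  Annotations are a two/three-column
(accession, term[, name]) TSV or a GAF-like file.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .containers import AnnotationSet, LfqMatrix, METADATA_COLUMNS

LFQ_PREFIX = "LFQ intensity "

_MAXQUANT_FLAGS = {
    "Reverse": "reverse",
    "Potential contaminant": "contaminant",
    "Only identified by site": "site_only",
}

_ACCESSION_CANDIDATES = ("Majority protein IDs", "Protein IDs", "Accession")


class FormatError(ValueError):
    """Raised when an input file does not match the expected dialect."""


def _first_accession(value: str) -> str:
    # protein groups list members ';'-separated; the first majority id names the group
    return str(value).split(";")[0].strip()


def read_lfq_table(
    path: str | Path,
    dialect: str = "maxquant",
    metadata_path: str | Path | None = None,
) -> LfqMatrix:
    """Read an LFQ intensity table into an :class:`LfqMatrix`.

    Zero intensities (maxquant dialect) and empty cells (plain dialect)
    become missing values.  ``+`` marks in the MaxQuant flag columns set the
    corresponding boolean flags.  Rows are never silently dropped; duplicate
    accessions raise, naming the duplicates.
    """
    if dialect not in ("maxquant", "plain"):
        raise ValueError(f"unknown dialect: {dialect!r}")
    raw = pd.read_csv(path, sep="\t", dtype=str)
    if raw.shape[1] < 2:
        raise FormatError(f"{path}: expected a tab-separated table with >=2 columns")

    if dialect == "maxquant":
        acc_col = next((c for c in _ACCESSION_CANDIDATES if c in raw.columns), None)
        if acc_col is None:
            acc_col = raw.columns[0]
        accessions = raw[acc_col].map(_first_accession)
        lfq_cols = [c for c in raw.columns if c.startswith(LFQ_PREFIX)]
        if not lfq_cols:
            raise FormatError(
                f"{path}: no '{LFQ_PREFIX}<sample>' columns found (maxquant dialect)"
            )
        sample_ids = [c[len(LFQ_PREFIX):] for c in lfq_cols]
        values = raw[lfq_cols].astype(float).to_numpy()
        values[values == 0.0] = np.nan
        flags = pd.DataFrame(index=range(len(raw)))
        for col, name in _MAXQUANT_FLAGS.items():
            if col in raw.columns:
                flags[name] = raw[col].fillna("").str.strip().eq("+").to_numpy()
            else:
                flags[name] = False
    else:  # plain
        accessions = raw.iloc[:, 0].map(_first_accession)
        sample_ids = list(raw.columns[1:])
        values = raw.iloc[:, 1:].astype(float).to_numpy()
        flags = pd.DataFrame(
            False, index=range(len(raw)), columns=["reverse", "contaminant", "site_only"]
        )

    dup = accessions[accessions.duplicated()]
    if len(dup):
        raise FormatError(f"{path}: duplicate accessions: {sorted(set(dup))}")

    intensities = pd.DataFrame(values, index=list(accessions), columns=sample_ids)
    flags.index = intensities.index
    metadata = None
    if metadata_path is not None:
        metadata = read_sample_metadata(metadata_path)
    return LfqMatrix(intensities=intensities, flags=flags, metadata=metadata)


def write_lfq_table(matrix: LfqMatrix, path: str | Path, dialect: str = "maxquant") -> None:
    """Write *matrix* as TSV; lossless under the same dialect.

    In the maxquant dialect missing values are written as 0 (the MaxQuant
    non-detection convention) and flags as ``+`` marks; the plain dialect
    keeps missing cells empty and carries no flags.
    """
    if dialect == "maxquant":
        out = pd.DataFrame({"Majority protein IDs": matrix.accessions})
        for col, name in _MAXQUANT_FLAGS.items():
            out[col] = np.where(matrix.flags[name].to_numpy(), "+", "")
        vals = matrix.intensities.to_numpy(dtype=float).copy()
        vals[np.isnan(vals)] = 0.0
        for j, sid in enumerate(matrix.sample_ids):
            out[LFQ_PREFIX + sid] = vals[:, j]
        out.to_csv(path, sep="\t", index=False)
    elif dialect == "plain":
        out = matrix.intensities.copy()
        out.index.name = "accession"
        out.to_csv(path, sep="\t")
    else:
        raise ValueError(f"unknown dialect: {dialect!r}")


def read_sample_metadata(path: str | Path) -> pd.DataFrame:
    """Read the sidecar sample-metadata TSV (first column = sample id)."""
    meta = pd.read_csv(path, sep="\t", index_col=0)
    meta.index = meta.index.astype(str)
    for col in METADATA_COLUMNS:
        if col not in meta.columns:
            meta[col] = np.nan
    return meta


def write_sample_metadata(metadata: pd.DataFrame, path: str | Path) -> None:
    out = metadata.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def read_annotations(path: str | Path) -> list[AnnotationSet]:
    """Read protein→GO annotations into a list of :class:`AnnotationSet`.

    Accepts a two/three-column TSV ``accession<TAB>term_id[<TAB>term_name]``
    or a GAF-like file (>=5 tab-separated columns; accession in column 2,
    term in column 5).  Lines starting with ``!`` or ``#`` are comments.
    Duplicated (protein, term) pairs count once.  A malformed line raises
    with its line number.
    """
    members: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("!", "#")):
                continue
            fields = line.split("\t")
            if len(fields) >= 5:  # GAF-like
                acc, term = fields[1].strip(), fields[4].strip()
                name = ""
            elif len(fields) >= 2:
                acc, term = fields[0].strip(), fields[1].strip()
                name = fields[2].strip() if len(fields) >= 3 else ""
            else:
                raise FormatError(f"{path}:{lineno}: malformed annotation line: {line!r}")
            if not acc or not term:
                raise FormatError(f"{path}:{lineno}: empty accession or term")
            members.setdefault(term, set()).add(acc)
            if name:
                names.setdefault(term, name)
    return [
        AnnotationSet(term_id=t, term_name=names.get(t, ""), members=frozenset(m))
        for t, m in sorted(members.items())
    ]


def write_annotations(annotations: list[AnnotationSet], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for ann in annotations:
            for acc in sorted(ann.members):
                fh.write(f"{acc}\t{ann.term_id}\t{ann.term_name}\n")


def read_mixture_table(path: str | Path) -> pd.DataFrame:
    """Read a pesticide-mixture table (CSV or TSV by extension).

    Required columns: ``name`` (or ``pesticide``), ``concentration_ppb``,
    ``ld50_ug_per_bee``; optional ``mode_of_action`` and ``group``.
    """
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    tab = pd.read_csv(path, sep=sep)
    if "name" not in tab.columns and "pesticide" in tab.columns:
        tab = tab.rename(columns={"pesticide": "name"})
    required = {"name", "concentration_ppb", "ld50_ug_per_bee"}
    missing = required - set(tab.columns)
    if missing:
        raise FormatError(f"{path}: missing mixture columns: {sorted(missing)}")
    return tab
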