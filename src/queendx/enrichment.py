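"""Gene-score-resampling (GSR) GO-term enrichment.

GSR, the ErmineJ-style threshold-free enrichment method, asks whether the
proteins annotated to a GO term have systematically better differential-
expression scores than randomly drawn proteins.  Each protein's score is
-log10 of its raw (unadjusted) p-value, restricted to one direction of
change at a time (up- and downregulation are analysed separately; proteins
moving the other way score 0).  A term's group score is the mean of its
members' scores, and its p-value is the probability that an equally sized
set drawn without replacement from the realised score list does at least as
well.  Small terms are enumerated exhaustively; larger ones use Monte Carlo
with add-one smoothing, p = (b + 1) / (B + 1).  Term p-values are BH
adjusted within the direction.

A descriptive multifunctionality (MF) score is attached to each term: the
mean over members of the gene-level normalised rank of annotation counts,
oriented so that higher values mean *less* multifunctional genes.  It is
reported only; no multifunctionality correction is applied.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import comb
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats as st

from .containers import AnnotationSet
from .de import benjamini_hochberg

P_FLOOR = 1e-300

ENRICHMENT_COLUMNS = (
    "term_id", "term_name", "n_members_scored", "group_score",
    "resampling_p", "adj_p", "direction", "mf_score",
)


@dataclass
class GeneScoreSet:
    """Per-protein enrichment scores for one direction of change."""

    scores: dict[str, float]
    direction: str  # 'up' or 'down'

    def __post_init__(self) -> None:
        if self.direction not in ("up", "down"):
            raise ValueError("direction must be 'up' or 'down'")
        for acc, s in self.scores.items():
            if not np.isfinite(s) or s < 0:
                raise ValueError(f"score for {acc} must be finite and >= 0")


def compute_gene_scores(de_table: pd.DataFrame, direction: str) -> GeneScoreSet:
    """Scores = -log10(raw p) for proteins changing in *direction*, else 0.

    P-values are floored at 1e-300 so scores stay finite.
    """
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    if len(de_table) == 0:
        raise ValueError("de_table is empty")
    sign_match = de_table["direction"] == direction
    p = np.clip(de_table["p_value"].to_numpy(dtype=float), P_FLOOR, 1.0)
    scores = np.where(sign_match, -np.log10(p), 0.0)
    return GeneScoreSet(
        scores=dict(zip(de_table["accession"], scores.astype(float))),
        direction=direction,
    )


def multifunctionality_score(
    annotations: Sequence[AnnotationSet],
    universe: Sequence[str] | None = None,
) -> dict[str, float]:
    """Gene-level multifunctionality, oriented so higher = less multifunctional.

    Each gene's raw multifunctionality is the number of terms annotating it;
    the reported score is the normalised (average-tie) rank of genes ordered
    from most to least annotated, scaled to [0, 1]: the most promiscuously
    annotated gene scores 0, the least scores 1, and full ties all share one
    value.
    """
    if not annotations:
        raise ValueError("annotations must be non-empty")
    counts: dict[str, int] = {}
    keep = set(universe) if universe is not None else None
    for ann in annotations:
        for acc in ann.members:
            if keep is None or acc in keep:
                counts[acc] = counts.get(acc, 0) + 1
    if not counts:
        return {}
    genes = sorted(counts)
    c = np.array([counts[g] for g in genes], dtype=float)
    if len(genes) == 1:
        return {genes[0]: 0.0}
    ranks = st.rankdata(-c, method="average")  # 1 = most multifunctional
    mf = (ranks - 1.0) / (len(genes) - 1.0)
    return dict(zip(genes, mf))


def _exact_tail(scores: np.ndarray, k: int, observed: float, tol: float) -> float:
    total = comb(len(scores), k)
    hits = sum(
        1
        for combo in itertools.combinations(scores, k)
        if sum(combo) / k >= observed - tol
    )
    return hits / total


def _null_means_by_size(
    scores: np.ndarray, sizes: set[int], n_iterations: int, rng: np.random.Generator
) -> dict[int, np.ndarray]:
    """Monte-Carlo null group-score distributions, one permutation pass.

    Each iteration permutes the realised score list once; the first k
    entries of a permutation are a size-k draw without replacement, so a
    single cumulative sum serves every term size.
    """
    n = len(scores)
    out: dict[int, np.ndarray] = {}
    max_chunk = max(1, int(2e7 // max(n, 1)))
    means = {k: [] for k in sizes}
    done = 0
    while done < n_iterations:
        b = min(max_chunk, n_iterations - done)
        order = np.argsort(rng.random((b, n)), axis=1)
        perm = scores[order]
        csum = np.cumsum(perm, axis=1)
        for k in sizes:
            means[k].append(csum[:, k - 1] / k)
        done += b
    for k in sizes:
        out[k] = np.concatenate(means[k])
    return out


def gsr_enrichment(
    scores: GeneScoreSet | Mapping[str, float],
    annotations: Sequence[AnnotationSet],
    min_size: int = 5,
    max_size: int = 200,
    n_iterations: int = 10_000,
    seed: int | None = None,
    method: str = "auto",
    exact_limit: int = 10_000,
    stat: str = "mean",
) -> pd.DataFrame:
    """Gene-score-resampling enrichment over *annotations*.

    For each term (membership intersected with the scored universe, size
    filtered to [*min_size*, *max_size*]) the group score is the mean (or
    median, ``stat='median'``) of member scores, and ``resampling_p`` is the
    probability that an equal-size draw without replacement from all scores
    matches or beats it.  ``method='auto'`` enumerates exhaustively whenever
    C(n, k) <= *exact_limit* and falls back to Monte Carlo with add-one
    smoothing otherwise.  Adjusted p-values are BH across the returned
    terms (one direction per call).
    """
    if isinstance(scores, GeneScoreSet):
        score_map, direction = scores.scores, scores.direction
    else:
        score_map, direction = dict(scores), "up"
    if not score_map:
        raise ValueError("empty score set")
    if method not in ("auto", "exact", "monte-carlo"):
        raise ValueError(f"unknown method: {method!r}")
    if stat not in ("mean", "median"):
        raise ValueError(f"unknown group statistic: {stat!r}")
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")

    universe = sorted(score_map)
    values = np.array([score_map[a] for a in universe], dtype=float)
    n = len(universe)
    uset = set(universe)

    agg = np.mean if stat == "mean" else np.median
    rows = []
    for ann in annotations:
        if len(ann.members) > n:
            raise ValueError(
                f"term {ann.term_id} ({len(ann.members)} members) exceeds the "
                f"gene universe ({n})"
            )
        member_scores = np.array(
            [score_map[a] for a in sorted(ann.members & uset)], dtype=float
        )
        k = len(member_scores)
        if not min_size <= k <= max_size:
            continue
        rows.append((ann, k, float(agg(member_scores))))
    if not rows:
        return pd.DataFrame(columns=list(ENRICHMENT_COLUMNS))

    need_mc = {
        k
        for _, k, _ in rows
        if method == "monte-carlo" or (method == "auto" and (stat == "median" or comb(n, k) > exact_limit))
    }
    mc_null: dict[int, np.ndarray] = {}
    if need_mc:
        rng = np.random.default_rng(seed)
        if stat == "mean":
            mc_null = _null_means_by_size(values, need_mc, n_iterations, rng)
        else:  # medians do not reduce to cumulative sums; draw directly
            for k in sorted(need_mc):
                draws = np.array(
                    [agg(rng.choice(values, size=k, replace=False)) for _ in range(n_iterations)]
                )
                mc_null[k] = draws

    mf_gene = multifunctionality_score(annotations, universe=universe)

    records = []
    for ann, k, observed in rows:
        tol = 1e-9 * max(1.0, abs(observed))
        if k in mc_null:
            b = int(np.sum(mc_null[k] >= observed - tol))
            p = (b + 1) / (len(mc_null[k]) + 1)
        else:
            p = _exact_tail(values, k, observed, tol)
        member_mf = [mf_gene[a] for a in ann.members & uset if a in mf_gene]
        records.append(
            {
                "term_id": ann.term_id,
                "term_name": ann.term_name,
                "n_members_scored": k,
                "group_score": observed,
                "resampling_p": min(p, 1.0),
                "direction": direction,
                "mf_score": float(np.mean(member_mf)) if member_mf else np.nan,
            }
        )
    out = pd.DataFrame.from_records(records)
    out["adj_p"] = benjamini_hochberg(out["resampling_p"])
    out = (
        out.sort_values(["adj_p", "resampling_p", "term_id"])
        .reset_index(drop=True)[list(ENRICHMENT_COLUMNS)]
    )
    return out
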