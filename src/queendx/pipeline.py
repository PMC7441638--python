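"""End-to-end orchestration: presets, stages, manifest, report.

A pipeline run goes simulate/load → preprocess → pairwise differential
expression per comparison → directional GSR enrichment → candidate-marker
selection → (blind-trial presets) threshold classification → (pesticide
preset) hazard-quotient summary, with every stage's table written as TSV
and a JSON manifest recording the seed, parameters and library versions so
a run can be reproduced exactly.  Identical config + seed gives
byte-identical tables.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .biomarkers import (
    blind_trial,
    select_candidate_markers,
)
from .de import fit_linear_model, run_pairwise_de
from .enrichment import compute_gene_scores, gsr_enrichment
from .hazard import load_cocktail_fixture
from .io import read_lfq_table, read_annotations, write_lfq_table
from .preprocess import apply_standard_filters, log2_transform
from .simulate import (
    SimulationConfig,
    generate_annotations,
    generate_blind_trial,
    generate_dataset,
    generate_time_course,
)

logger = logging.getLogger("queendx")

HEAT_MARKERS = {"XP_001120006.2": ("heatshock", 3.0), "XP_395659.1": ("heatshock", 2.5)}
COLD_MARKERS = {"XP_026296654.1": ("coldshock", 2.5), "XP_395122.1": ("coldshock", 2.2)}
PESTICIDE_MARKERS = {"XP_026296889.1": ("pesticide", 2.0), "XP_392368.1": ("pesticide", 1.8)}

PRESETS = ("coldshock", "heatshock-timecourse", "pesticide", "blind-trial", "survey")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run (file inputs or a simulation preset)."""

    preset: str | None = None
    lfq_path: str | None = None
    metadata_path: str | None = None
    annotation_path: str | None = None
    lfq_dialect: str = "maxquant"
    comparisons: list[dict[str, Any]] = field(default_factory=list)
    min_valid: int = 6
    n_proteins: int = 400
    enrichment_iterations: int = 2000
    enrichment_min_size: int = 5
    enrichment_max_size: int = 100
    k_markers: int = 2
    threshold: float = 0.05
    out_dir: str | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.preset is None and self.lfq_path is None:
            raise ValueError("either a preset or an input LFQ table is required")
        if self.preset is not None and self.preset not in PRESETS:
            raise ValueError(f"unknown preset {self.preset!r}; choose from {PRESETS}")
        for comp in self.comparisons:
            fdr = comp.get("fdr", 0.05)
            if not 0 < fdr < 1:
                raise ValueError(f"comparison {comp}: fdr must lie in (0, 1)")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _child_seed(seed: int, stage: int) -> int:
    return int(np.random.SeedSequence([seed, stage]).generate_state(1)[0] % (2**31))


def _preset_inputs(config: PipelineConfig):
    """Build (matrix, truth, comparisons, stressor) for a simulation preset."""
    seed = _child_seed(config.seed, 0)
    if config.preset == "coldshock":
        sim = SimulationConfig(
            n_proteins=config.n_proteins,
            groups=(("control", 7), ("coldshock", 5)),
            marker_effects=COLD_MARKERS,
            seed=seed,
        )
        matrix, truth = generate_dataset(sim)
        comps = [{"group_a": "coldshock", "group_b": "control", "fdr": 0.05}]
        return matrix, truth, comps, "cold"
    if config.preset == "pesticide":
        sim = SimulationConfig(
            n_proteins=config.n_proteins,
            groups=(("acetone", 8), ("pesticide", 7)),
            marker_effects=PESTICIDE_MARKERS,
            seed=seed,
        )
        matrix, truth = generate_dataset(sim)
        comps = [{"group_a": "pesticide", "group_b": "acetone", "fdr": 0.10}]
        return matrix, truth, comps, "pesticide"
    if config.preset == "heatshock-timecourse":
        sim = SimulationConfig(
            n_proteins=config.n_proteins,
            groups=(("control", 7), ("heatshock", 7)),
            marker_effects=HEAT_MARKERS,
            seed=seed,
        )
        matrix, truth = generate_time_course(
            sim, durations_h=[0.0, 0.25, 0.5, 1.0, 2.0, 4.0], rh_levels=[40.0, 80.0],
            n_per_condition=3,
        )
        comps = [{"group_a": "t2h_rh40", "group_b": "t0h_rh40", "fdr": 0.05}]
        return matrix, truth, comps, "heat"
    if config.preset == "blind-trial":
        sim = SimulationConfig(
            n_proteins=config.n_proteins,
            groups=(("control", 7), ("heatshock", 7)),
            marker_effects=HEAT_MARKERS,
            seed=seed,
        )
        matrix, truth = generate_blind_trial(sim, n_total=16, n_stressed=8)
        return matrix, truth, [], "heat"
    if config.preset == "survey":
        markers = {**HEAT_MARKERS, **PESTICIDE_MARKERS}
        markers = {acc: ("failed", 1.5) for acc in markers}
        sim = SimulationConfig(
            n_proteins=config.n_proteins,
            groups=(("healthy", 45), ("failed", 60)),
            marker_effects=markers,
            seed=seed,
        )
        matrix, truth = generate_dataset(sim)
        rng = np.random.default_rng(_child_seed(config.seed, 9))
        matrix.metadata["age"] = rng.integers(0, 4, size=matrix.n_samples)
        comps = [{"group_a": "failed", "group_b": "healthy", "fdr": 0.05}]
        return matrix, truth, comps, "survey"
    raise ValueError(f"unknown preset {config.preset!r}")


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:  # re-raise with the stage name
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            logger.info("stage %s finished in %.2f s", name, time.perf_counter() - t0)
            return out
        return wrapped
    return deco


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute every applicable stage; return (and optionally write) the bundle."""
    config.validate()
    bundle: dict[str, Any] = {}
    truth = None
    stressor = ""

    if config.preset is not None:
        matrix, truth, comparisons, stressor = _stage("simulate")(_preset_inputs)(config)
        bundle["ground_truth"] = truth
    else:
        matrix = _stage("load")(read_lfq_table)(
            config.lfq_path, dialect=config.lfq_dialect, metadata_path=config.metadata_path
        )
        comparisons = config.comparisons
    bundle["raw_matrix"] = matrix

    @_stage("preprocess")
    def _preprocess():
        filtered, report = apply_standard_filters(matrix, min_valid=config.min_valid)
        return log2_transform(filtered), report

    log_matrix, report = _preprocess()
    bundle["filter_report"] = report
    bundle["matrix"] = log_matrix

    if config.annotation_path is not None:
        annotations = _stage("annotations")(read_annotations)(config.annotation_path)
    else:
        annotations = generate_annotations(
            log_matrix.accessions, seed=_child_seed(config.seed, 1)
        )
    bundle["annotations"] = annotations

    bundle["de"] = {}
    bundle["enrichment"] = {}
    panel = None
    for i, comp in enumerate(comparisons):
        key = f"{comp['group_a']}_vs_{comp['group_b']}"
        fdr = comp.get("fdr", 0.05)
        de = _stage(f"de:{key}")(run_pairwise_de)(
            log_matrix, comp["group_a"], comp["group_b"], fdr=fdr,
            test=comp.get("test", "student"),
        )
        bundle["de"][key] = de
        enr = {}
        for direction in ("up", "down"):
            scores = compute_gene_scores(de, direction)
            enr[direction] = _stage(f"enrich:{key}:{direction}")(gsr_enrichment)(
                scores,
                annotations,
                min_size=config.enrichment_min_size,
                max_size=config.enrichment_max_size,
                n_iterations=config.enrichment_iterations,
                seed=_child_seed(config.seed, 100 + i),
            )
        bundle["enrichment"][key] = enr
        if panel is None:
            panel = _stage(f"markers:{key}")(select_candidate_markers)(
                de, k=config.k_markers, stressor=stressor
            )
    if panel is not None:
        bundle["panel"] = panel

    if config.preset == "blind-trial" and truth is not None:
        from .biomarkers import MarkerPanel

        panel = MarkerPanel(
            markers=[(acc, "heat") for acc in sorted(truth.true_markers["heat"])],
            selection_rule="pre-established heat-shock markers",
            k=len(truth.true_markers["heat"]),
        )
        bundle["panel"] = panel
        bundle["classification"] = _stage("classify")(blind_trial)(
            log_matrix, panel, truth.sealed_labels, threshold=config.threshold
        )

    if config.preset == "survey":
        @_stage("survey-models")
        def _survey_models():
            out = {}
            groups = (log_matrix.metadata["group"] == "failed").astype(float)
            design = pd.DataFrame(
                {"failed": groups, "age": log_matrix.metadata["age"].astype(float)},
                index=log_matrix.metadata.index,
            )
            for acc in sorted(truth.true_markers.get("failed", [])):
                y = log_matrix.intensities.loc[acc]
                ok = ~y.isna()
                out[acc] = fit_linear_model(y[ok], design.loc[ok.index[ok]], accession=acc)
            return out

        bundle["survey_models"] = _survey_models()

    if config.preset == "pesticide":
        mixture, table = _stage("hazard")(load_cocktail_fixture)()
        bundle["hazard"] = {"mixture": mixture, "table": table}

    bundle["manifest"] = _manifest(config)
    if config.out_dir is not None:
        _stage("write")(_write_bundle)(bundle, config)
    return bundle


def _manifest(config: PipelineConfig) -> dict[str, Any]:
    import scipy
    import statsmodels

    return {
        "queendx_version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "library_versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scipy": scipy.__version__,
            "statsmodels": statsmodels.__version__,
        },
    }


def _write_bundle(bundle: dict[str, Any], config: PipelineConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_lfq_table(bundle["raw_matrix"], out / "lfq_raw.tsv", dialect="maxquant")
    bundle["filter_report"].to_frame().to_csv(out / "filter_report.tsv", sep="\t", index=False)
    for key, de in bundle.get("de", {}).items():
        de.to_csv(out / f"de_{key}.tsv", sep="\t", index=False)
    for key, enr in bundle.get("enrichment", {}).items():
        for direction, table in enr.items():
            table.to_csv(out / f"enrichment_{key}_{direction}.tsv", sep="\t", index=False)
    if "panel" in bundle:
        pd.DataFrame(bundle["panel"].markers, columns=["accession", "stressor"]).to_csv(
            out / "marker_panel.tsv", sep="\t", index=False
        )
    if "classification" in bundle:
        res = bundle["classification"]
        rows = []
        for acc, oc in res.per_marker.items():
            df = oc.samples.copy()
            df.insert(0, "marker", acc)
            rows.append(df.reset_index(names="sample_id"))
        pd.concat(rows).to_csv(out / "classification.tsv", sep="\t", index=False)
    if "hazard" in bundle:
        bundle["hazard"]["mixture"].to_frame().to_csv(
            out / "hazard_quotients.tsv", sep="\t", index=False
        )
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(bundle["manifest"], fh, indent=2, sort_keys=True)


def make_report(bundle: dict[str, Any]) -> str:
    """Human-readable run summary (pure; does not mutate the bundle)."""
    lines = ["queendx run summary", "==================="]
    if "filter_report" in bundle:
        r = bundle["filter_report"]
        lines.append(
            f"filtering: {r.n_input} input rows -> {r.n_retained} retained "
            f"(reverse {r.n_removed_reverse}, contaminant {r.n_removed_contaminant}, "
            f"site-only {r.n_removed_site_only}, <min valid {r.n_removed_min_valid})"
        )
    for key, de in bundle.get("de", {}).items():
        n_sig = int(de["significant"].sum())
        if n_sig == 0:
            lines.append(f"DE {key}: zero discoveries among {len(de)} tested proteins")
        else:
            lines.append(f"DE {key}: {n_sig} significant of {len(de)} tested proteins")
    for key, enr in bundle.get("enrichment", {}).items():
        for direction, table in enr.items():
            n_sig = int((table["adj_p"] <= 0.05).sum()) if len(table) else 0
            lines.append(f"enrichment {key} [{direction}]: {n_sig} terms at 5% FDR")
            for _, row in table.head(3).iterrows():
                lines.append(
                    f"  {row['term_id']} {row['term_name']}: "
                    f"adj p = {row['adj_p']:.3g}"
                )
    if "panel" in bundle:
        panel = bundle["panel"]
        flag = " (padded: fewer significant hits than requested)" if panel.warning else ""
        lines.append("marker panel: " + ", ".join(panel.accessions) + flag)
    if "classification" in bundle:
        res = bundle["classification"]
        lines.append(f"blind trial (reference {res.reference_accession}, "
                     f"threshold {res.threshold}):")
        for acc, oc in res.per_marker.items():
            lines.append(
                f"  {acc}: TP={oc.tp} FP={oc.fp} TN={oc.tn} FN={oc.fn} "
                f"TPR={oc.tpr:.2f}"
            )
        if res.joint is not None:
            oc = res.joint
            lines.append(
                f"  joint AND rule: TP={oc.tp} FP={oc.fp} TN={oc.tn} FN={oc.fn} "
                f"TPR={oc.tpr:.2f}"
            )
    if "hazard" in bundle:
        mixture = bundle["hazard"]["mixture"]
        lines.append(
            f"pesticide cocktail: {len(mixture.components)} components, "
            f"cumulative HQ = {round(mixture.total_hq)}"
        )
    return "\n".join(lines)
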