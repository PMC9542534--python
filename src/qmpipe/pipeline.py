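"""End-to-end pipeline: profiling -> cohort -> DA -> ordination -> mediation.

Every run writes into its own output directory with a provenance sidecar
(input hashes, configuration, package version); input files are never
mutated.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from qmpipe import da, io, mediation, ordination, profiling
from qmpipe.cohort import antibiotic_class, assign_study_groups, censor_postnatal_antibiotics

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    counts: str = ""
    taxonomy: str = ""
    qpcr: str = ""
    copy_numbers: str = ""
    metadata: str = ""
    wellbeing: str = ""
    blanks: str = ""
    blank_runs: str = ""
    treatments: str = ""
    out_dir: str = "qmpipe_run"
    cohort_cutoffs: dict = field(default_factory=lambda: {"HELMi": 2000, "Jorvi": 120})
    min_read_count: int = 10
    prevalence: float = 0.30
    fdr: float = 0.10
    alpha: float = 0.05
    log10_fc_cap: float = 5.0
    pseudocount: float = 1.0
    scale: str = "absolute"  # or "relative"
    rank: str = "family"
    mediation_outcomes: tuple = ("crying", "defecation_rate")
    mediation_timepoints: tuple = (4.0,)
    seed: int = 0
    stages: tuple = ("profile", "cohort", "da", "ordinate", "mediate")

    def validate(self) -> None:
        if not (0 < self.prevalence < 1):
            raise ValueError("prevalence threshold must be in (0, 1)")
        if not (0 < self.fdr <= 1) or not (0 < self.alpha <= 1):
            raise ValueError("alpha/FDR thresholds must be in (0, 1]")
        if self.log10_fc_cap <= 0 or self.pseudocount < 0:
            raise ValueError("cap must be positive and pseudo-count non-negative")
        if self.scale not in ("absolute", "relative"):
            raise ValueError("scale must be 'absolute' or 'relative'")

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for k in ("mediation_outcomes", "mediation_timepoints", "stages"):
            if k in raw and isinstance(raw[k], list):
                raw[k] = tuple(raw[k])
        return cls(**raw)


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the configured stages; returns the run directory."""
    config.validate()
    run_dir = Path(config.out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)

    counts = io.read_counts(config.counts)
    taxonomy = io.read_taxonomy(config.taxonomy)
    metadata = io.read_table(config.metadata, index_col="sample_id")

    # cohort stage: study groups, antibiotic classes, censoring
    if "cohort" in config.stages:
        if "group" not in metadata.columns:
            metadata["group"] = assign_study_groups(metadata)
        metadata["antibiotic_class"] = metadata["antibiotic"].map(antibiotic_class)
        if config.treatments and Path(config.treatments).exists():
            treatments = io.read_table(config.treatments)
            metadata = censor_postnatal_antibiotics(metadata, treatments)
        else:
            metadata["censored"] = False
        io.write_table(metadata, run_dir / "cohort.tsv", index_name="sample_id")

    # profiling stage
    if config.blanks and Path(config.blanks).exists():
        blanks = io.read_counts(config.blanks)
        blank_runs = io.read_table(config.blank_runs, index_col="sample_id")["run_id"]
        counts = profiling.subtract_blank_contaminants(
            counts, blanks, metadata["run_id"], blank_runs)
    counts = profiling.filter_rare_reads(counts, config.min_read_count,
                                         runs=metadata["run_id"])
    counts, removed = profiling.apply_coverage_cutoff(
        counts, config.cohort_cutoffs, metadata["cohort"])
    io.write_table(removed, run_dir / "removed_samples.tsv", index_name="sample_id")
    metadata = metadata.loc[counts.index]

    rel = profiling.relative_abundance(counts)
    if config.scale == "absolute":
        if not config.qpcr or not Path(config.qpcr).exists():
            raise FileNotFoundError(
                f"absolute-scale stages requested but qPCR file missing: "
                f"{config.qpcr!r}")
        qpcr = io.read_qpcr(config.qpcr)
        cn = io.read_copy_numbers(config.copy_numbers)
        prof = profiling.absolute_profile(counts, qpcr, cn, taxonomy)
        matrix = prof.cells
        io.write_table(prof.copies, run_dir / "profile_copies.tsv",
                       index_name="sample_id")
        io.write_table(prof.cells, run_dir / "profile_cells.tsv",
                       index_name="sample_id")
    else:
        logger.warning("relative-only mode: downstream stages run on proportions")
        matrix = rel * rel.attrs.get("common_depth", 10000)
        io.write_table(rel, run_dir / "profile_relative.tsv", index_name="sample_id")
    metadata = metadata.loc[matrix.index]

    if "da" in config.stages:
        fam = profiling.aggregate_rank(matrix, taxonomy, config.rank)
        results = da.run_differential_abundance(fam, metadata,
                                                prevalence=config.prevalence)
        io.write_table(results, run_dir / "da_results.tsv", index_name="row")
        if len(results):
            mat = da.fold_change_matrix(results)
            mat.to_csv(run_dir / "da_fold_change_matrix.tsv", sep="\t")

    if "ordinate" in config.stages:
        ord_res = ordination.pcoa_pearson(matrix, config.pseudocount)
        io.write_table(ord_res.coordinates, run_dir / "pcoa_coordinates.tsv",
                       index_name="sample_id")
        ord_res.eigenvalues.rename("eigenvalue").to_csv(
            run_dir / "pcoa_eigenvalues.tsv", sep="\t")
        med = ordination.group_median_trajectories(ord_res, metadata)
        med.to_csv(run_dir / "pcoa_group_medians.tsv", sep="\t")

    if "mediate" in config.stages and config.wellbeing and Path(config.wellbeing).exists():
        if config.scale == "relative":
            logger.warning("mediation on proportions: absolute effects may be masked")
        wellbeing = io.read_table(config.wellbeing, index_col="sample_id")
        for outcome in config.mediation_outcomes:
            for tp in config.mediation_timepoints:
                try:
                    res = mediation.run_mediation(matrix, metadata, wellbeing,
                                                  outcome, tp,
                                                  prevalence=config.prevalence)
                except ValueError as exc:
                    logger.warning("mediation %s@%s skipped: %s", outcome, tp, exc)
                    continue
                with open(run_dir / f"path_{outcome}_w{tp:g}.json", "w") as fh:
                    fh.write(res.to_json())

    inputs = {k: getattr(config, k) for k in
              ("counts", "taxonomy", "qpcr", "copy_numbers", "metadata",
               "wellbeing", "blanks") if getattr(config, k)}
    io.write_provenance(run_dir, dataclasses.asdict(config), inputs)
    return run_dir


def write_simulation(sim, out_dir: str | Path) -> Path:
    """Write a simulated cohort to disk in the pipeline's interchange formats."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    io.write_counts(sim.counts, out / "counts.tsv")
    io.write_counts(sim.blanks, out / "blanks.tsv")
    sim.blank_runs.rename_axis("sample_id").to_frame().to_csv(
        out / "blank_runs.tsv", sep="\t")
    io.write_qpcr(sim.qpcr, out / "qpcr.tsv")
    io.write_copy_numbers(sim.copy_numbers, out / "copy_numbers.tsv")
    io.write_taxonomy(sim.taxonomy, out / "taxonomy.tsv")
    io.write_table(sim.metadata, out / "metadata.tsv", index_name="sample_id")
    io.write_table(sim.wellbeing, out / "wellbeing.tsv", index_name="sample_id")
    truth = {
        "group_effects": [dataclasses.asdict(e) for e in sim.truth.group_effects],
        "mediators": {k: [dataclasses.asdict(m) for m in v]
                      for k, v in sim.truth.mediators.items()},
    }
    import json

    with open(out / "ground_truth.json", "w") as fh:
        json.dump(truth, fh, indent=2)
    return out
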