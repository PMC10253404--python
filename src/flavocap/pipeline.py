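"""End-to-end orchestration: inputs -> quantification -> significance ->
comparison -> annotation screen -> similarity shortlist -> report bundle.

Runs either on real input files (peptide report, design, annotations,
homologue map, FASTA, optional BLAST tabular) or in fixture mode on a
simulated experiment. Identical configuration and seed produce a
byte-identical bundle.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import annotate, compare, quantify, shortlist as shortlist_mod, significance, simulate
from .errors import ConfigurationError
from .io import (
    read_annotations, read_design, read_fasta, read_homologue_map,
    read_peptide_report, validate_design, write_table,
)

logger = logging.getLogger("flavocap")

ALL_STAGES = ("quantify", "classify", "compare", "screen", "shortlist")


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs.

    Exactly one of ``simulation`` (fixture mode) or ``peptide_report_path``
    (real-input mode) must be set. Quantification switches mirror the
    processing rules: log2 transform before ANOVA, replicate mean for
    grouped abundances, minimum two peptides per protein.
    """

    peptide_report_path: str | None = None
    design_path: str | None = None
    annotations_path: str | None = None
    homologue_map_path: str | None = None
    fasta_path: str | None = None
    query_fasta_path: str | None = None
    blast_tabular_path: str | None = None
    simulation: simulate.SimulationConfig | None = None
    thresholds: significance.SignificanceThresholds = field(
        default_factory=significance.SignificanceThresholds
    )
    min_peptides: int = 2
    center: str = "mean"
    log_transform: bool = True
    selectivity_probes: tuple[str, str] = ("Q8", "Q6")
    outdir: str = "flavocap_out"
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES

    def validate(self) -> "PipelineConfig":
        if (self.simulation is None) == (self.peptide_report_path is None):
            raise ConfigurationError(
                "exactly one of a simulation block or a peptide_report_path must be configured"
            )
        if self.min_peptides < 1:
            raise ConfigurationError("min_peptides must be >= 1")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ConfigurationError(f"unknown stage(s): {sorted(unknown)}")
        return self

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulation", None)
        thr = raw.pop("thresholds", None)
        cfg = cls(**raw)
        if sim is not None:
            cfg.simulation = simulate.SimulationConfig(**sim)
        if thr is not None:
            cfg.thresholds = significance.SignificanceThresholds(**thr)
        if isinstance(cfg.stages, list):
            cfg.stages = tuple(cfg.stages)
        if isinstance(cfg.selectivity_probes, list):
            cfg.selectivity_probes = tuple(cfg.selectivity_probes)
        return cfg


@dataclass
class ReportBundle:
    """Output tables of one run, in memory and on disk."""

    outdir: Path
    matrix: quantify.AbundanceMatrix | None = None
    classified: dict[tuple[str, str, str], pd.DataFrame] = field(default_factory=dict)
    counts: pd.DataFrame | None = None
    venn: pd.DataFrame | None = None
    selectivity: pd.DataFrame | None = None
    heatmap: pd.DataFrame | None = None
    enrichment: pd.DataFrame | None = None
    shortlist: pd.DataFrame | None = None
    manifest: dict = field(default_factory=dict)


def _assay_groups(design: pd.DataFrame) -> dict[tuple[str, str, str], list[str]]:
    groups: dict[tuple[str, str, str], list[str]] = {}
    for (species, probe, method), sub in design.groupby(["species", "probe", "method"]):
        groups[(species, probe, method)] = sorted(sub["sample_id"])
    return groups


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Execute the configured stages in order and write the report bundle."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle = ReportBundle(outdir=outdir)
    manifest: dict = {"seed": config.seed, "stages": list(config.stages), "rows": {},
                      "skipped": []}

    # ------------------------------------------------------------- inputs
    annotations = homologue_map = None
    sequences: dict[str, str] = {}
    queries: dict[str, str] = {}
    if config.simulation is not None:
        sim_cfg = config.simulation
        truth = simulate.generate_ground_truth(sim_cfg)
        design = validate_design(
            simulate.default_design(n_replicates=sim_cfg.n_replicates)
        )
        report = simulate.simulate_peptide_report(truth, design, sim_cfg)
        report["multi_mapped"] = report["protein_accession"].str.contains(";", regex=False)
        annotations = truth.catalog[["accession", "description", "go_terms", "ipr_terms"]]
        sequences = dict(zip(truth.catalog["accession"], truth.catalog["sequence"]))
        queries = dict(truth.query_sequences)
        catalog = set(truth.catalog["accession"]) | set(truth.duplicate_map)
    else:
        report = read_peptide_report(config.peptide_report_path)
        design = read_design(config.design_path)
        if config.annotations_path:
            annotations = read_annotations(config.annotations_path)
        if config.homologue_map_path:
            homologue_map = read_homologue_map(config.homologue_map_path)
        if config.fasta_path:
            sequences = read_fasta(config.fasta_path)
        if config.query_fasta_path:
            queries = read_fasta(config.query_fasta_path)
        catalog = set(sequences) if sequences else set()
        for acc_field in report["protein_accession"].unique():
            catalog.update(str(acc_field).split(";"))
    manifest["rows"]["peptide_report"] = len(report)
    manifest["rows"]["design"] = len(design)

    # ------------------------------------------------------- quantification
    matrix = quantify.aggregate_abundance(report, catalog)
    matrix = quantify.normalize_abundance(matrix)
    matrix = quantify.filter_min_peptides(matrix, k=config.min_peptides)
    matrix = quantify.AbundanceMatrix(
        abundance=matrix.abundance.sort_index(),
        peptide_counts=matrix.peptide_counts.sort_index(),
    )
    bundle.matrix = matrix
    out = matrix.abundance.copy()
    out.insert(0, "accession", out.index)
    manifest["rows"]["abundance_matrix"] = write_table(
        out, outdir / "abundance_matrix.tsv", index=False
    )
    logger.info("quantify: %d proteins x %d samples", *matrix.abundance.shape)
    if "classify" not in config.stages:
        _finish(bundle, manifest, config)
        return bundle

    # --------------------------------------------------------- significance
    assays = _assay_groups(design)
    controls = {sp: ids for (sp, probe, _m), ids in assays.items() if probe == "none"}
    classified: dict[tuple[str, str, str], pd.DataFrame] = {}
    for (species, probe, method), sample_ids in assays.items():
        if probe == "none":
            continue
        contrast = quantify.Contrast(
            numerator=sample_ids, denominator=controls[species],
            label=f"{species}/{probe}/{method} vs control",
        )
        stats = quantify.contrast_statistics(
            matrix, contrast, center=config.center, log_transform=config.log_transform
        )
        classified[(species, probe, method)] = significance.classify_table(
            stats, config.thresholds
        )
    bundle.classified = classified
    long = pd.concat(
        [t.assign(species=k[0], probe=k[1], method=k[2]) for k, t in classified.items()]
    )
    long.index.name = "accession"
    manifest["rows"]["classification"] = write_table(
        long.reset_index(), outdir / "classification.tsv"
    )
    bundle.counts = significance.summarize_assay(classified)
    manifest["rows"]["counts_summary"] = write_table(bundle.counts, outdir / "counts_summary.tsv")
    if "compare" not in config.stages:
        _finish(bundle, manifest, config)
        return bundle

    # ----------------------------------------------------------- comparison
    hs_sets = {
        key: significance.highly_significant_set(table) for key, table in classified.items()
    }
    venn_frames = []
    by_probe = {k[1]: v for k, v in hs_sets.items() if k[2] == "O"}
    if len(by_probe) >= 2:
        probe_sets = dict(list(by_probe.items())[:3])
        vc = compare.set_overlap(probe_sets)
        venn_frames.append(vc.to_frame().assign(comparison="probes"))
    by_method: dict[str, set] = {}
    for (sp, probe, method), s in hs_sets.items():
        if probe == config.selectivity_probes[0]:
            by_method[method] = s
    if len(by_method) >= 2:
        vc = compare.set_overlap(by_method)
        venn_frames.append(vc.to_frame().assign(comparison="methods"))
    if venn_frames:
        bundle.venn = pd.concat(venn_frames, ignore_index=True)
        manifest["rows"]["venn"] = write_table(bundle.venn, outdir / "venn.tsv")
    else:
        manifest["skipped"].append("venn (fewer than two comparable assays)")

    probe_a, probe_b = config.selectivity_probes
    sel_keys = {k[1]: k for k in classified if k[1] in (probe_a, probe_b) and k[2] == "O"}
    if len(sel_keys) == 2:
        key_a, key_b = sel_keys[probe_a], sel_keys[probe_b]
        absent_ctrl_a = classified[key_a]["n_detected_control"] <= config.thresholds.max_control_detected
        absent_ctrl_b = classified[key_b]["n_detected_control"] <= config.thresholds.max_control_detected
        eligible = (
            hs_sets[key_a] & hs_sets[key_b]
            & set(classified[key_a].index[absent_ctrl_a])
            & set(classified[key_b].index[absent_ctrl_b])
        )
        records, excluded = compare.probe_selectivity(
            matrix, _assay_groups(design)[key_a], _assay_groups(design)[key_b], eligible
        )
        bundle.selectivity = records
        manifest["rows"]["selectivity"] = write_table(
            records.reset_index(), outdir / "selectivity.tsv"
        )
        manifest["rows"]["selectivity_excluded"] = write_table(
            excluded.reset_index(), outdir / "selectivity_excluded.tsv"
        )
    else:
        manifest["skipped"].append(
            f"selectivity (need both probes {probe_a} and {probe_b} under method O)"
        )
    if "screen" not in config.stages:
        _finish(bundle, manifest, config)
        return bundle

    # ---------------------------------------------------- annotation screen
    if annotations is not None:
        categories = annotate.categorize_candidates(annotations)
        bundle.heatmap = annotate.build_heatmap_table(classified, categories, homologue_map)
        manifest["rows"]["heatmap"] = write_table(bundle.heatmap, outdir / "heatmap.tsv")
        background = set(matrix.proteins)
        main_key = next(
            (k for k in classified if k[1] == probe_a and k[2] == "O"), next(iter(classified))
        )
        target = hs_sets[main_key] | {
            a for a in classified[main_key].index[classified[main_key]["capture_class"] == "significant"]
        }
        target &= background
        bundle.enrichment = annotate.go_enrichment(target, background, annotations)
        manifest["rows"]["enrichment"] = write_table(bundle.enrichment, outdir / "enrichment.tsv")
    else:
        manifest["skipped"].append("screen (no annotation table configured)")
    if "shortlist" not in config.stages:
        _finish(bundle, manifest, config)
        return bundle

    # ------------------------------------------------- similarity shortlist
    main_key = next(
        (k for k in classified if k[1] == probe_a and k[2] == "O"), next(iter(classified))
    )
    if config.blast_tabular_path:
        hits = shortlist_mod.parse_blast_tabular(config.blast_tabular_path)
    elif queries and sequences:
        hits = shortlist_mod.search_database(queries, sequences)
    else:
        hits = None
        manifest["skipped"].append("shortlist (no queries/database or BLAST table configured)")
    if hits is not None:
        ranked, hits_only, capture_only = shortlist_mod.crossref_shortlist(
            hits, classified[main_key]
        )
        bundle.shortlist = ranked
        manifest["rows"]["shortlist"] = write_table(ranked, outdir / "shortlist.tsv")
        manifest["rows"]["shortlist_hits_only"] = write_table(
            hits_only, outdir / "shortlist_hits_only.tsv"
        )
        manifest["rows"]["shortlist_capture_only"] = write_table(
            capture_only.reset_index(), outdir / "shortlist_capture_only.tsv"
        )

    _finish(bundle, manifest, config)
    return bundle


def _finish(bundle: ReportBundle, manifest: dict, config: PipelineConfig) -> None:
    manifest["config"] = {
        "min_peptides": config.min_peptides,
        "center": config.center,
        "log_transform": config.log_transform,
        "thresholds": vars(config.thresholds).copy(),
        "selectivity_probes": list(config.selectivity_probes),
        "mode": "simulation" if config.simulation is not None else "files",
    }
    bundle.manifest = manifest
    with open(bundle.outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
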