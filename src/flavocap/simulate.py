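"""Ground-truthed simulation of affinity-capture chemoproteomics experiments.

The generator emulates the statistical structure of probe-capture LFQ data:
triplicate capture and probe-less control samples, a minority of true probe
binders enriched in capture samples with probe-specific affinities, log-normal
peptide intensities with multiplicative replicate noise, left-censored
missingness (low-intensity peptides drop out of the report), and an optional
redundant database variant in which some proteins appear under a second
accession.

True binders are drawn as low-abundance proteins: the enzymes such probes are
designed to fish out (cytochrome P450s, transferases bound to membranes) sit
near the detection limit of an unenriched extract, which is what makes the
"absent from the negative control" capture signature possible at all.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: default per-category protein-name pools used to annotate simulated binders;
#: keys are screen categories, values are (description, GO term, IPR term)
BINDER_ANNOTATION_POOL: dict[str, tuple[tuple[str, str, str], ...]] = {
    "A_oxidase": (
        ("cytochrome P450 monooxygenase", "GO:0016491|oxidoreductase activity", "IPR001128|Cytochrome P450"),
        ("peroxidase 12-like", "GO:0016491|oxidoreductase activity", "IPR002016|Haem peroxidase"),
        ("flavonol hydroxylase", "GO:0016491|oxidoreductase activity", "IPR001128|Cytochrome P450"),
        ("polyphenol oxidase", "GO:0016491|oxidoreductase activity", "IPR002227|Tyrosinase"),
    ),
    "B_methyltransferase": (
        ("probable methyltransferase", "GO:0008168|methyltransferase activity", "IPR029063|SAM-dependent MTase"),
        ("caffeic acid 3-O-methyltransferase", "GO:0008168|methyltransferase activity", "IPR001077|O-methyltransferase"),
    ),
    "C_glycosyltransferase": (
        ("UDP-glycosyltransferase", "GO:0016757|glycosyltransferase activity", "IPR002213|UDP-glucuronosyl transferase"),
        ("anthocyanidin 3-O-glucosyltransferase", "GO:0016757|glycosyltransferase activity", "IPR002213|UDP-glucuronosyl transferase"),
    ),
}

#: shared functional term carried by every simulated binder
BINDER_SHARED_GO = "GO:0003824|catalytic activity"

_BACKGROUND_GO = (
    "GO:0005524|ATP binding",
    "GO:0006412|translation",
    "GO:0016020|membrane",
    "GO:0005737|cytoplasm",
    "GO:0006457|protein folding",
    "GO:0005975|carbohydrate metabolic process",
    "GO:0015031|protein transport",
    "GO:0006096|glycolytic process",
)
_BACKGROUND_NAMES = (
    "elongation factor", "heat shock protein 70", "ATP synthase subunit",
    "ribosomal protein", "tubulin alpha chain", "aquaporin", "V-type proton ATPase",
    "14-3-3-like protein", "aminoacyl-tRNA synthetase", "translation initiation factor",
)


@dataclass
class SimulationConfig:
    """Parameters of one simulated capture experiment.

    Intensity parameters are on the natural-log scale of arbitrary LFQ
    intensity units. ``probe_affinity`` multiplies ``enrichment_fold`` per
    binder and probe, modelling the observed Q8 > Q6 > K8 selectivity ladder.
    """

    n_proteins: int = 500
    binder_fraction: float = 0.10
    enrichment_fold: float = 16.0
    probe_affinity: Mapping[str, float] = field(
        default_factory=lambda: {"Q8": 1.0, "Q6": 0.25, "K8": 0.0625}
    )
    peptides_per_protein_mean: float = 8.0
    intensity_location: float = 14.0
    intensity_scale: float = 1.2
    peptide_scale: float = 0.35
    binder_intensity_shift: float = -1.8
    cv_replicate: float = 0.20
    detection_midpoint: float = 12.5
    detection_slope: float = 12.0
    method_n_efficiency: float = 0.5
    n_replicates: int = 3
    redundancy_rate: float = 0.10
    sequence_length: int = 240
    similarity_identity_levels: Sequence[float] = (0.9, 0.6, 0.3)
    seed: int = 0

    def validate(self) -> "SimulationConfig":
        if self.n_proteins < 1:
            raise ConfigurationError("n_proteins must be >= 1")
        if not 0.0 <= self.binder_fraction <= 1.0:
            raise ConfigurationError("binder_fraction must lie in [0, 1]")
        if self.enrichment_fold <= 1.0:
            raise ConfigurationError("enrichment_fold must be > 1")
        if self.n_replicates < 2:
            raise ConfigurationError("n_replicates must be >= 2")
        for name in ("intensity_scale", "peptide_scale", "detection_slope",
                     "peptides_per_protein_mean", "cv_replicate"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        if not 0.0 < self.method_n_efficiency <= 1.0:
            raise ConfigurationError("method_n_efficiency must lie in (0, 1]")
        if not 0.0 <= self.redundancy_rate <= 1.0:
            raise ConfigurationError("redundancy_rate must lie in [0, 1]")
        for probe, aff in self.probe_affinity.items():
            if aff < 0:
                raise ConfigurationError(f"probe_affinity[{probe}] must be >= 0")
        return self


@dataclass
class GroundTruth:
    """Simulated protein catalog with all latent variables known.

    ``catalog`` has one row per canonical protein (accession, sequence,
    is_binder, screen category, annotation strings, base log-intensity);
    ``peptides`` one row per theoretical peptide; ``duplicate_map`` maps each
    redundant alternative accession to its canonical accession;
    ``query_sequences`` holds the bait-like query used to seed similarity
    tiers among binder sequences.
    """

    catalog: pd.DataFrame
    peptides: pd.DataFrame
    duplicate_map: dict[str, str]
    query_sequences: dict[str, str]

    @property
    def binders(self) -> list[str]:
        return list(self.catalog.loc[self.catalog["is_binder"], "accession"])


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def mutate_sequence(rng: np.random.Generator, seed_seq: str, identity: float) -> str:
    """Point-mutate ``seed_seq`` so the result keeps about ``identity`` of its
    residues, creating graded similarity tiers for alignment tests."""
    seq = list(seed_seq)
    n_mut = int(round((1.0 - identity) * len(seq)))
    positions = rng.choice(len(seq), size=n_mut, replace=False)
    for pos in positions:
        choices = [a for a in AMINO_ACIDS if a != seq[pos]]
        seq[pos] = choices[rng.integers(len(choices))]
    return "".join(seq)


def _random_peptide(rng: np.random.Generator) -> str:
    length = int(rng.integers(8, 21))
    body = _random_sequence(rng, length - 1)
    return body + ("K" if rng.random() < 0.5 else "R")


def generate_ground_truth(config: SimulationConfig) -> GroundTruth:
    """Draw the latent protein catalog for one simulated experiment.

    Deterministic for a fixed ``config.seed``: the same config yields a
    bit-identical catalog. Binder count is ``round(binder_fraction *
    n_proteins)``; binders receive category annotations from the keyword pool
    and, for the first ``len(similarity_identity_levels)`` of them, sequences
    mutated from the bait query at the configured identities.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 0])

    n = config.n_proteins
    n_binders = int(round(config.binder_fraction * n))
    accessions = [f"RH_{i:05d}" for i in range(1, n + 1)]
    binder_idx = rng.choice(n, size=n_binders, replace=False)
    is_binder = np.zeros(n, dtype=bool)
    is_binder[binder_idx] = True

    query_seq = _random_sequence(rng, config.sequence_length)
    categories = list(BINDER_ANNOTATION_POOL)

    sequences: list[str] = []
    descriptions: list[str] = []
    go_terms: list[str] = []
    ipr_terms: list[str] = []
    category_col: list[str] = []
    binder_rank = 0
    for i in range(n):
        if is_binder[i]:
            cat = categories[binder_rank % len(categories)]
            pool = BINDER_ANNOTATION_POOL[cat]
            desc, go, ipr = pool[binder_rank % len(pool)]
            descriptions.append(f"{desc} {binder_rank + 1}")
            go_terms.append(f"{BINDER_SHARED_GO};{go}")
            ipr_terms.append(ipr)
            category_col.append(cat)
            levels = config.similarity_identity_levels
            if binder_rank < len(levels):
                sequences.append(mutate_sequence(rng, query_seq, levels[binder_rank]))
            else:
                sequences.append(_random_sequence(rng, config.sequence_length))
            binder_rank += 1
        else:
            sequences.append(_random_sequence(rng, config.sequence_length))
            category_col.append("D_other")
            if rng.random() < 0.3:
                descriptions.append(f"uncharacterized protein LOC{rng.integers(10 ** 8, 10 ** 9)}")
                go_terms.append("")
                ipr_terms.append("")
            else:
                descriptions.append(str(rng.choice(_BACKGROUND_NAMES)))
                terms = list(rng.choice(_BACKGROUND_GO, size=2, replace=False))
                if rng.random() < 0.1:
                    terms.append(BINDER_SHARED_GO)
                go_terms.append(";".join(terms))
                ipr_terms.append("")

    base_log = config.intensity_location + config.intensity_scale * rng.standard_normal(n)
    base_log[is_binder] += config.binder_intensity_shift

    n_peptides = 1 + rng.poisson(config.peptides_per_protein_mean - 1.0, size=n)

    catalog = pd.DataFrame(
        {
            "accession": accessions,
            "sequence": sequences,
            "is_binder": is_binder,
            "category": category_col,
            "description": descriptions,
            "go_terms": go_terms,
            "ipr_terms": ipr_terms,
            "base_log_intensity": base_log,
            "n_peptides": n_peptides,
        }
    )

    pep_rows = []
    for acc, base, k in zip(accessions, base_log, n_peptides):
        offsets = config.peptide_scale * rng.standard_normal(k)
        for j in range(k):
            pep_rows.append(
                (f"{acc}_pep{j + 1}", _random_peptide(rng), acc, base + offsets[j])
            )
    peptides = pd.DataFrame(
        pep_rows, columns=["peptide_id", "peptide_sequence", "protein_accession", "base_log_intensity"]
    )

    n_dup = int(round(config.redundancy_rate * n))
    dup_idx = rng.choice(n, size=n_dup, replace=False)
    duplicate_map = {f"{accessions[i]}_r": accessions[i] for i in sorted(dup_idx)}

    return GroundTruth(
        catalog=catalog,
        peptides=peptides,
        duplicate_map=duplicate_map,
        query_sequences={"F6H_QUERY": query_seq},
    )


def default_design(
    species: str = "Rudbeckia",
    probes: Sequence[str] = ("Q8", "Q6", "K8"),
    methods: Sequence[str] = ("O",),
    n_replicates: int = 3,
    include_method_n_for: Sequence[str] = (),
) -> pd.DataFrame:
    """Sample-design table: each probe under each method, plus a probe-less
    DMSO control per species, everything in ``n_replicates`` replicates."""
    rows = []
    combos = [(p, m) for p in probes for m in methods]
    combos += [(p, "N") for p in include_method_n_for if ("N" not in methods)]
    combos.append(("none", "O"))
    for probe, method in combos:
        for rep in range(1, n_replicates + 1):
            sid = f"{species[:3]}_{probe}_{method}_{rep}"
            rows.append((species, probe, method, rep, sid))
    return pd.DataFrame(rows, columns=["species", "probe", "method", "replicate", "sample_id"])


def detection_probability(log_intensity: np.ndarray, midpoint: float, slope: float) -> np.ndarray:
    """Logistic probability that a peptide of the given ln-intensity is
    observed; midpoint -inf means no censoring."""
    if math.isinf(midpoint) and midpoint < 0:
        return np.ones_like(np.asarray(log_intensity, dtype=float))
    z = slope * (np.asarray(log_intensity, dtype=float) - midpoint)
    return 1.0 / (1.0 + np.exp(-z))


def expected_log2_ratio(config: SimulationConfig, probe: str, method: str = "O") -> float:
    """Analytic expected log2 capture/control intensity ratio for a binder,
    before censoring and normalization."""
    mult = 1.0 if method == "O" else config.method_n_efficiency
    return math.log2(config.enrichment_fold * config.probe_affinity[probe] * mult)


def simulate_peptide_report(
    truth: GroundTruth,
    design: pd.DataFrame,
    config: SimulationConfig,
    redundant: bool = False,
) -> pd.DataFrame:
    """Simulate the peptide-level LFQ report for every sample in ``design``.

    Each row is one observed peptide in one sample. Binder peptide intensities
    in capture samples carry ``enrichment_fold x probe_affinity x method
    multiplier``; all peptides get multiplicative log-normal replicate noise
    at the configured CV and are then thinned by the logistic detection
    process (censored rows are simply absent). With ``redundant=True``,
    peptides of duplicated proteins report both accessions (";"-separated),
    emulating an uncurated database with identical entries.
    """
    config.validate()
    for probe in design["probe"].unique():
        if probe != "none" and probe not in config.probe_affinity:
            raise ConfigurationError(
                f"probe_affinity has no entry for probe {probe!r} referenced by the design"
            )

    rng = np.random.default_rng([config.seed, 1])
    is_binder = dict(zip(truth.catalog["accession"], truth.catalog["is_binder"]))
    pep = truth.peptides
    pep_binder = pep["protein_accession"].map(is_binder).to_numpy()
    base = pep["base_log_intensity"].to_numpy()
    noise_sd = math.sqrt(math.log1p(config.cv_replicate ** 2))

    if redundant and truth.duplicate_map:
        canonical_to_dup = {v: k for k, v in truth.duplicate_map.items()}
        acc_field = np.array(
            [
                f"{a};{canonical_to_dup[a]}" if a in canonical_to_dup else a
                for a in pep["protein_accession"]
            ]
        )
    else:
        acc_field = pep["protein_accession"].to_numpy()

    frames = []
    for row in design.itertuples(index=False):
        if row.probe == "none":
            log_mult = 0.0
            binder_boost = 0.0
        else:
            method_mult = 1.0 if row.method == "O" else config.method_n_efficiency
            log_mult = math.log(method_mult)
            binder_boost = math.log(config.enrichment_fold * config.probe_affinity[row.probe])
        log_i = base + log_mult + np.where(pep_binder, binder_boost, 0.0)
        log_i = log_i + noise_sd * rng.standard_normal(len(base))
        p_det = detection_probability(log_i, config.detection_midpoint, config.detection_slope)
        keep = rng.random(len(base)) < p_det
        frames.append(
            pd.DataFrame(
                {
                    "peptide_id": pep["peptide_id"].to_numpy()[keep],
                    "peptide_sequence": pep["peptide_sequence"].to_numpy()[keep],
                    "protein_accession": acc_field[keep],
                    "sample_id": row.sample_id,
                    "intensity": np.exp(log_i[keep]),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def write_fixture_bundle(
    truth: GroundTruth,
    report: pd.DataFrame,
    design: pd.DataFrame,
    outdir: str | Path,
) -> dict[str, Path]:
    """Write the simulated experiment as the plain-text files the pipeline
    readers consume: peptide report, design, annotations, canonical and
    redundant FASTA, homologue map (local -> reference accessions) and the
    ground-truth table. Returns the path of each file by role."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "peptide_report": outdir / "peptide_report.tsv",
        "design": outdir / "design.tsv",
        "annotations": outdir / "annotations.tsv",
        "fasta": outdir / "proteins.fasta",
        "fasta_redundant": outdir / "proteins_redundant.fasta",
        "homologue_map": outdir / "homologue_map.tsv",
        "truth": outdir / "truth.tsv",
    }
    report.to_csv(paths["peptide_report"], sep="\t", index=False)
    design.to_csv(paths["design"], sep="\t", index=False)
    truth.catalog[["accession", "description", "go_terms", "ipr_terms"]].to_csv(
        paths["annotations"], sep="\t", index=False
    )
    seqs = dict(zip(truth.catalog["accession"], truth.catalog["sequence"]))
    with open(paths["fasta"], "w") as fh:
        for acc, seq in seqs.items():
            fh.write(f">{acc}\n{seq}\n")
    with open(paths["fasta_redundant"], "w") as fh:
        for acc, seq in seqs.items():
            fh.write(f">{acc}\n{seq}\n")
        for dup, canon in truth.duplicate_map.items():
            fh.write(f">{dup}\n{seqs[canon]}\n")
    hmap = pd.DataFrame(
        {
            "local_accession": truth.catalog["accession"],
            "reference_accession": [a.replace("RH_", "REF_") for a in truth.catalog["accession"]],
        }
    )
    hmap.to_csv(paths["homologue_map"], sep="\t", index=False)
    truth.catalog.drop(columns=["sequence"]).to_csv(paths["truth"], sep="\t", index=False)
    return paths
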