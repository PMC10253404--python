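import math

import numpy as np
import pandas as pd
import pytest

from flavocap import (
    ConfigurationError,
    SimulationConfig,
    default_design,
    detection_probability,
    generate_ground_truth,
    simulate_peptide_report,
    write_fixture_bundle,
)
from flavocap.io import read_peptide_report
from flavocap.simulate import GroundTruth, mutate_sequence


class TestGroundTruth:
    def test_binder_count_follows_rounding_rule(self):
        truth = generate_ground_truth(SimulationConfig(n_proteins=100, binder_fraction=0.1, seed=7))
        assert truth.catalog["is_binder"].sum() == 10

    def test_same_seed_gives_identical_catalogs(self):
        cfg = SimulationConfig(n_proteins=50, seed=3)
        t1, t2 = generate_ground_truth(cfg), generate_ground_truth(cfg)
        pd.testing.assert_frame_equal(t1.catalog, t2.catalog)
        pd.testing.assert_frame_equal(t1.peptides, t2.peptides)
        assert t1.duplicate_map == t2.duplicate_map

    def test_redundancy_rate_forces_duplicate_count(self):
        cfg = SimulationConfig(n_proteins=100, redundancy_rate=0.2, seed=1)
        truth = generate_ground_truth(cfg)
        assert len(truth.duplicate_map) == 20
        # every duplicate maps to exactly one existing canonical accession
        canon = set(truth.catalog["accession"])
        assert all(v in canon for v in truth.duplicate_map.values())

    def test_similarity_tiers_exist_among_binder_sequences(self):
        truth = generate_ground_truth(SimulationConfig(n_proteins=60, seed=5))
        query = truth.query_sequences["F6H_QUERY"]
        binders = truth.catalog[truth.catalog["is_binder"]]
        identities = [
            np.mean([a == b for a, b in zip(query, seq)]) for seq in binders["sequence"][:3]
        ]
        assert identities[0] > identities[1] > identities[2]

    @pytest.mark.parametrize(
        "field,value",
        [
            ("binder_fraction", 1.5),
            ("enrichment_fold", 0.5),
            ("n_replicates", 1),
            ("cv_replicate", -0.1),
            ("method_n_efficiency", 0.0),
        ],
    )
    def test_invalid_config_names_field(self, field, value):
        cfg = SimulationConfig(**{field: value})
        with pytest.raises(ConfigurationError, match=field.split("_")[0]):
            cfg.validate()

    def test_mutate_sequence_hits_requested_identity(self):
        rng = np.random.default_rng(0)
        seed_seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=200))
        mutant = mutate_sequence(rng, seed_seq, 0.9)
        identity = np.mean([a == b for a, b in zip(seed_seq, mutant)])
        assert identity == pytest.approx(0.9, abs=0.01)


class TestPeptideReport:
    def test_no_censoring_when_midpoint_minus_inf(self, small_truth, small_design, small_config):
        from dataclasses import replace

        cfg = replace(small_config, detection_midpoint=-math.inf)
        report = simulate_peptide_report(small_truth, small_design, cfg)
        assert len(report) == len(small_truth.peptides) * len(small_design)

    def test_unconfigured_probe_raises(self, small_truth, small_config):
        design = default_design(probes=("Z9",))
        with pytest.raises(ConfigurationError, match="Z9"):
            simulate_peptide_report(small_truth, design, small_config)

    def test_detection_probability_monotone_in_intensity(self):
        x = np.linspace(5, 20, 200)
        p = detection_probability(x, midpoint=12.5, slope=12.0)
        assert (np.diff(p) >= 0).all()
        assert detection_probability(x, midpoint=-math.inf, slope=12.0).min() == 1.0

    def test_binder_log2_ratio_matches_analytic_expectation(self):
        """Mean realized log2 capture/control ratio of binder peptides equals
        log2(enrichment_fold x affinity) without censoring, within MC error."""
        ratios = []
        for seed in range(12):
            cfg = SimulationConfig(n_proteins=120, seed=seed, detection_midpoint=-math.inf)
            truth = generate_ground_truth(cfg)
            design = default_design(probes=("Q8",))
            rep = simulate_peptide_report(truth, design, cfg)
            binder_pep = rep["protein_accession"].isin(truth.binders)
            cap = rep["sample_id"].str.contains("_Q8_")
            logi = np.log2(rep["intensity"])
            ratios.append(logi[binder_pep & cap].mean() - logi[binder_pep & ~cap].mean())
        assert np.mean(ratios) == pytest.approx(math.log2(16.0), abs=0.05)

    def test_nonbinder_ratio_is_method_multiplier_only(self):
        cfg = SimulationConfig(n_proteins=120, binder_fraction=0.0, seed=4,
                               detection_midpoint=-math.inf)
        truth = generate_ground_truth(cfg)
        design = default_design(probes=("Q8",), include_method_n_for=("Q8",))
        rep = simulate_peptide_report(truth, design, cfg)
        logi = np.log2(rep["intensity"])
        n_mask = rep["sample_id"].str.contains("_Q8_N_")
        o_mask = rep["sample_id"].str.contains("_Q8_O_")
        ctrl = rep["sample_id"].str.contains("_none_")
        assert logi[o_mask].mean() - logi[ctrl].mean() == pytest.approx(0.0, abs=0.05)
        assert logi[n_mask].mean() - logi[ctrl].mean() == pytest.approx(
            math.log2(cfg.method_n_efficiency), abs=0.05
        )

    def test_redundant_variant_reports_shared_accessions(self, small_truth, small_design, small_config):
        rep = simulate_peptide_report(small_truth, small_design, small_config, redundant=True)
        shared = rep["protein_accession"].str.contains(";")
        dup_canon = set(small_truth.duplicate_map.values())
        assert shared.any()
        assert set(rep.loc[shared, "protein_accession"].str.split(";").str[0]) <= dup_canon


class TestFixtureBundle:
    def test_round_trip_and_redundant_fasta_count(self, tmp_path, small_truth, small_design,
                                                  small_report, small_config):
        paths = write_fixture_bundle(small_truth, small_report, small_design, tmp_path)
        back = read_peptide_report(paths["peptide_report"])
        pd.testing.assert_frame_equal(
            back.drop(columns="multi_mapped"), small_report, check_dtype=False
        )
        n_entries = sum(1 for line in open(paths["fasta_redundant"]) if line.startswith(">"))
        assert n_entries == small_config.n_proteins + len(small_truth.duplicate_map)

    def test_fixed_seed_gives_bit_identical_bundles(self, tmp_path, small_config, small_design):
        import hashlib

        digests = []
        for sub in ("a", "b"):
            truth = generate_ground_truth(small_config)
            rep = simulate_peptide_report(truth, small_design, small_config)
            paths = write_fixture_bundle(truth, rep, small_design, tmp_path / sub)
            digests.append(
                {k: hashlib.sha256(p.read_bytes()).hexdigest() for k, p in paths.items()}
            )
        assert digests[0] == digests[1]

    def test_empty_truth_writes_headers(self, tmp_path):
        cols = ["accession", "sequence", "is_binder", "category", "description",
                "go_terms", "ipr_terms", "base_log_intensity", "n_peptides"]
        truth = GroundTruth(
            catalog=pd.DataFrame(columns=cols),
            peptides=pd.DataFrame(columns=["peptide_id", "peptide_sequence",
                                           "protein_accession", "base_log_intensity"]),
            duplicate_map={},
            query_sequences={},
        )
        report = pd.DataFrame(columns=["peptide_id", "peptide_sequence",
                                       "protein_accession", "sample_id", "intensity"])
        design = default_design()
        paths = write_fixture_bundle(truth, report, design, tmp_path)
        header = open(paths["peptide_report"]).readline().strip().split("\t")
        assert header == ["peptide_id", "peptide_sequence", "protein_accession",
                          "sample_id", "intensity"]
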