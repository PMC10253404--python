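"""Simulate a probe-capture experiment with known ground truth.

Builds a 200-protein proteome with 10% true probe binders, triplicate Q8/Q6/K8
captures plus probe-less DMSO controls, and prints what the generator spiked
in versus what survived detection censoring in the peptide report.
"""

from flavocap import SimulationConfig, default_design, generate_ground_truth, simulate_peptide_report

cfg = SimulationConfig(n_proteins=200, seed=42)
truth = generate_ground_truth(cfg)
design = default_design(n_replicates=cfg.n_replicates)
report = simulate_peptide_report(truth, design, cfg)

print(f"proteins: {cfg.n_proteins}, true binders: {len(truth.binders)}")
print(f"samples: {len(design)} ({design['probe'].nunique() - 1} probes + control, triplicate)")
print(f"observed peptide rows: {len(report)} "
      f"(of {len(truth.peptides) * len(design)} possible before censoring)")
ctrl = report["sample_id"].str.contains("_none_")
binder_rows = report["protein_accession"].isin(truth.binders)
print(f"binder peptide rows in controls: {(binder_rows & ctrl).sum()} — "
      "low-abundance binders are largely invisible without enrichment")
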