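"""From a peptide report to tiered capture-significance calls.

Quantifies protein abundance (sum of unique peptide intensities, total-amount
normalization, minimum two peptides), contrasts the Q8 capture against the
probe-less control, and classifies each protein. The two highly-significant
tiers — absent from every control replicate, or log2(r) > 2 with
-log10(p) > 2.5 — are the capture calls worth following up.
"""

from flavocap import (
    Contrast, SimulationConfig, aggregate_abundance, classify_table,
    contrast_statistics, default_design, filter_min_peptides,
    generate_ground_truth, normalize_abundance, simulate_peptide_report,
    summarize_assay,
)

cfg = SimulationConfig(n_proteins=200, seed=42)
truth = generate_ground_truth(cfg)
design = default_design()
report = simulate_peptide_report(truth, design, cfg)

matrix = aggregate_abundance(report, set(truth.catalog["accession"]))
matrix = filter_min_peptides(normalize_abundance(matrix), k=2)

captures = sorted(design.loc[(design.probe == "Q8") & (design.method == "O"), "sample_id"])
controls = sorted(design.loc[design.probe == "none", "sample_id"])
stats = contrast_statistics(matrix, Contrast(captures, controls, "Q8/O vs control"))
classified = classify_table(stats)

print(summarize_assay({("Rudbeckia", "Q8", "O"): classified}).to_string(index=False))
hs = classified[classified.capture_class.str.startswith("highly")]
binders = set(truth.binders)
print(f"\nhighly significant: {len(hs)}, of which true binders: {len(set(hs.index) & binders)}"
      f" (spiked: {len(binders)})")
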