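"""Screen captured proteins by annotation and test GO-term enrichment.

Captured candidates are binned into oxidase (A), methyltransferase (B),
glycosyltransferase (C) and other (D) classes by keyword matching, and the
highly-significant capture set is tested for GO over-representation against
the detected proteome (hypergeometric test, Benjamini-Hochberg).
"""

from flavocap import (
    Contrast, SimulationConfig, aggregate_abundance, categorize_candidates,
    classify_table, contrast_statistics, default_design, filter_min_peptides,
    generate_ground_truth, go_enrichment, highly_significant_set,
    normalize_abundance, simulate_peptide_report,
)

cfg = SimulationConfig(n_proteins=300, seed=7)
truth = generate_ground_truth(cfg)
design = default_design()
report = simulate_peptide_report(truth, design, cfg)
matrix = filter_min_peptides(
    normalize_abundance(aggregate_abundance(report, set(truth.catalog["accession"])))
)
controls = sorted(design.loc[design.probe == "none", "sample_id"])
captures = sorted(design.loc[(design.probe == "Q8") & (design.method == "O"), "sample_id"])
classified = classify_table(
    contrast_statistics(matrix, Contrast(captures, controls, "Q8/O"))
)
hs = highly_significant_set(classified)

annotations = truth.catalog[["accession", "description", "go_terms", "ipr_terms"]]
categories = categorize_candidates(annotations)
print("screen categories among highly-significant captures:")
print(categories.loc[sorted(hs)].value_counts().to_string())

enrichment = go_enrichment(hs & set(matrix.proteins), set(matrix.proteins), annotations)
print("\ntop enriched GO terms (capture set vs detected proteome):")
print(enrichment.head(3)[["term", "name", "target_count", "background_count", "p_adjusted"]]
      .to_string(index=False))
print("\ncatalytic-activity terms dominate: the probes fish out enzymes, as designed")
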