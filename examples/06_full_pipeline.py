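"""Run the whole pipeline in fixture mode and inspect the report bundle.

One call executes quantification, significance classification, probe
comparison, annotation screening and similarity shortlisting, and writes the
full set of TSV outputs plus a manifest. The same config and seed always
reproduce a byte-identical bundle.
"""

from flavocap import PipelineConfig, SimulationConfig, run_pipeline

cfg = PipelineConfig(
    simulation=SimulationConfig(n_proteins=200, seed=9),
    outdir="scratch/example_bundle",
    seed=9,
)
bundle = run_pipeline(cfg)

print(f"bundle written to {bundle.outdir}")
print(bundle.counts.to_string(index=False))
print("\nrows per output:")
for name, n in bundle.manifest["rows"].items():
    print(f"  {name}: {n}")
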