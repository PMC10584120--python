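# Demo pipeline configuration: simulate the year-1 design, rank the ten
# survival models, run the morphometric permutation analyses, the clutch
# ANOVAs and the carbonate solve, writing all report tables + manifest.
# Run with:  opilio run --config examples/demo_config.yaml --out results/demo
seed: 42
year: 1
n_perm: 999
n_females: 10
salinity: 32.0
out_dir: results/demo
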