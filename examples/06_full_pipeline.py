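"""Run the whole pipeline end to end and inspect the manifest.

Equivalent to `tilscore run-all` on the command line: simulate a cohort,
score it at the published cutoffs, export Kaplan-Meier curves and Cox
tables for both endpoints, compare NAC responders, run the expression
stage, and record every output with a checksum in the manifest.
"""

from pathlib import Path

from tilscore import (ExpressionSimConfig, PipelineConfig, SimulationConfig,
                      run_pipeline)

out = Path("scratch/example_run")
cfg = PipelineConfig(
    seed=7,
    output_dir=out,
    simulation=SimulationConfig(n_patients=200),
    expression=ExpressionSimConfig(),
)
manifest = run_pipeline(cfg)

print(f"{len(manifest['files'])} files written under {out}\n")
print("log-rank p-values (OS):")
for key, entry in sorted(manifest["logrank"].items()):
    if key.endswith("_OS") and "p" in entry:
        print(f"  {key:12s} p = {entry['p']:.3g}")
resp = manifest["responders"].get("cd8_im_by_nac_response", {})
if resp:
    print(f"\nCD8_IM by NAC response: p = {resp['p']:.3g} "
          f"(medians {resp['median_responder']:.0f} vs "
          f"{resp['median_nonresponder']:.0f} cells/mm²)")
de = manifest["de_summary"]
print(f"DE stage: {de['n_significant']}/{de['n_tested']} cytotoxicity genes "
      f"significant at q < 0.05")
print("\nSame seed + config reproduces every file byte-identically "
      "(compare manifest checksums).")
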