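"""One-command reproducible run: simulate -> score -> PRT -> RL -> associate.

Equivalent to `grsanhedonia run-all --seed 11 --outdir scratch/demo_run`.
Every output is a TSV plus a manifest of SHA-256 digests; identical
config + seed reproduces identical digests.
"""

from grsanhedonia import pipeline

cfg = pipeline.PipelineConfig(seed=11, rl_subjects=8)
manifest = pipeline.run_pipeline(cfg, "scratch/demo_run")

print(f"{len(manifest.digests)} outputs written; stage log:")
for stage, log in manifest.stage_log.items():
    print(f"  {stage}: {log}")
print()
print(open("scratch/demo_run/report.txt").read())
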