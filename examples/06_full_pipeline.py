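"""The whole analysis end to end through the pipeline runner.

Equivalent to `protfnet all --seed 0 --outdir protfnet_demo`; stages are
cached, so re-running this script is a no-op unless the config changes
or an output file is deleted or modified.
"""

from protfnet.pipeline import Pipeline, RunConfig

config = RunConfig(seed=0, outdir="protfnet_demo")
manifest = Pipeline(config).run_all()
print(manifest[["stage", "output", "wall_time_s"]]
      .groupby("stage", sort=False)
      .agg(outputs=("output", "count"), seconds=("wall_time_s", "first"))
      .to_string())
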