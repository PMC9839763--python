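"""Generate a synthetic four-date series and run the whole pipeline on it.

Uses a quarter-scale grid so the example runs in a few seconds; prints
the per-stage directional signature and the rapidity stage averages the
pipeline derives from its own multi-way factor analysis.
"""

import tempfile
from pathlib import Path

import pandas as pd

from morphoscape import SynthConfig, generate_series, stage_signature
from morphoscape.pipeline import PipelineConfig, run_pipeline

config = SynthConfig.scaled(grid_size=128, seed=0)
series = generate_series(config)
print("urban pixels per date:", [int((g.values == 1).sum()) for g in series])

print("\ndirectional stage signature (computed with the real pipeline):")
print(stage_signature(series).round(2).to_string(index=False))

with tempfile.TemporaryDirectory() as td:
    out = run_pipeline(PipelineConfig(synth=config, out_dir=str(Path(td) / "run")))
    rap = pd.read_csv(out / "rapidity.csv")
    means = rap.groupby(["dimension", "window"], sort=False)["rprime"].mean()
    print("\nmean R' per dimension and window from the synthetic run:")
    print(means.round(4).to_string())
    print(f"\n{len(list(out.iterdir()))} artifacts written (segmentations, tables,")
    print("factor results, rapidity values, report) — all reproducible from seed 0.")
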