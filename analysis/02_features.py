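"""Build the Fisher-z functional-connectivity feature table.

Each subject's series is detrended, band-pass filtered to 0.01-0.08 Hz
and correlated ROI-by-ROI; the strict lower triangle (190 edges at 20
ROIs) is Fisher z-transformed into one feature row per subject,
written to results/study/features.csv.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from study import RESULTS, base_block

from csmfc.pipeline import PipelineConfig, run_pipeline

report = run_pipeline(
    PipelineConfig.from_dict(base_block(stages=["simulate", "features"]))
)
f = report["features"]
print(f"feature table: {f['n_subjects']} subjects x {f['n_edges']} edges "
      f"-> {RESULTS / 'features.csv'}")
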