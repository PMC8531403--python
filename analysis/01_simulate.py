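"""Generate the synthetic two-site cohort and write it to disk.

Produces results/study/cohort/: the phenotype CSV (100 subjects, two
sites, JOA scores for patients only), one ROI-by-time series file per
subject, and the ground-truth JSON naming the planted discriminative
and score-linked edges that later stages try to recover.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from study import RESULTS, base_block

from csmfc.pipeline import PipelineConfig, run_pipeline

report = run_pipeline(PipelineConfig.from_dict(base_block(stages=["simulate"])))
truth = json.loads((RESULTS / "cohort" / "ground_truth.json").read_text())
print(f"wrote cohort of {report['simulate']['n_subjects']} subjects "
      f"({report['simulate']['n_rois']} ROIs) under {RESULTS / 'cohort'}")
print(f"planted discriminative edges: {truth['disc_edges']}")
print(f"planted score-linked edges:   {truth['score_edges']}")
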