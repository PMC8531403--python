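"""Bland-Altman agreement between predicted and actual scores.

For every prediction analysis: bias, 95% limits of agreement
(bias +/- 1.96 SD of the differences) and the share of points inside
the LOA (~95% expected for Gaussian errors).
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from study import RESULTS, base_block

from csmfc.pipeline import PipelineConfig, run_pipeline

report = run_pipeline(
    PipelineConfig.from_dict(
        base_block(stages=["simulate", "features", "predict", "agreement"])
    )
)
for name, r in report["agreement"].items():
    print(f"{name}: bias {r['bias']:+.3f}, LOA [{r['loa_low']:.3f}, {r['loa_high']:.3f}], "
          f"{100 * r['within_loa_fraction']:.0f}% of {r['n']} points within LOA")
print(f"table -> {RESULTS / 'bland_altman.csv'}")
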