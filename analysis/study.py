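"""Shared study configuration for the numbered analysis drivers.

One synthetic two-site cohort shaped like the study design: site 1 has
27 patients and 11 controls scanned at 170 usable volumes (TR 2.0 s),
site 2 has 26 patients and 36 controls at 440 volumes (TR 0.8 s) with a
higher noise level. The parcellation is scaled to 20 ROIs (190 edges)
so every stage runs in minutes on one CPU; subjects remain far fewer
than edges, preserving the regime the methods are designed for.
"""

from pathlib import Path

RESULTS = Path(__file__).resolve().parent.parent / "results" / "study"

SEED = 1

SYNTHETIC = {
    "n_rois": 20,
    "sites": [
        {"n_patients": 27, "n_controls": 11, "n_timepoints": 170, "tr": 2.0},
        {"n_patients": 26, "n_controls": 36, "n_timepoints": 440, "tr": 0.8, "noise_scale": 1.3},
    ],
    "n_disc_edges": 10,
    "disc_effect": 0.4,
    "n_score_edges": 8,
    "score_edge_sd": 0.3,
    "score_gain": 2.0,
    "score_noise_sd": 0.6,
}


def base_block(**overrides):
    block = {
        "out_dir": str(RESULTS),
        "seed": SEED,
        "synthetic": SYNTHETIC,
        "fractions": [0.05, 0.15, 0.25, 0.5, 0.75, 1.0],
        "n_perm": 99,
        "clean": True,
    }
    block.update(overrides)
    return block
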