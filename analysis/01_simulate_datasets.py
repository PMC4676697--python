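#!/usr/bin/env python
"""Simulate the three ground-truth contrast-variation series.

Generates time-of-flight-like reflectivity (3% relative noise, 1e-7
background, 8% dQ/Q, Q = 0.005–0.3 Å⁻¹) for the hydrogenated 50 °C structure
(four contrasts), the per-deuterated 50 °C structure (four contrasts, vesicles
in H₂O only) and the per-deuterated 25 °C structure (three contrasts, vesicles
throughout). Data files and the truth sidecars land under results/data/.
"""

import json
from pathlib import Path

from slbnr.io import write_reflectivity
from slbnr.simulate import InstrumentSpec, ground_truth_presets, simulate_contrast_series

SEED = 20151211
OUT = Path(__file__).resolve().parent.parent / "results" / "data"


def main() -> None:
    instrument = InstrumentSpec(q_min=0.005, q_max=0.3)
    for i, (name, gt) in enumerate(ground_truth_presets().items()):
        outdir = OUT / name
        outdir.mkdir(parents=True, exist_ok=True)
        datasets = simulate_contrast_series(
            gt.model, gt.contrasts, instrument, SEED + i
        )
        files = []
        for curve, contrast in datasets:
            path = outdir / f"{name}_{round(100 * contrast.d2o_fraction):03d}pctD2O.dat"
            write_reflectivity(
                path, curve, header=f"{gt.description}\nd2o_fraction {contrast.d2o_fraction}"
            )
            files.append(path.name)
        truth = {
            "preset": name,
            "seed": SEED + i,
            "truth": gt.truth_values(),
            "derived": gt.model.derived(gt.truth_values()),
            "files": files,
        }
        (outdir / "truth.json").write_text(json.dumps(truth, indent=1) + "\n")
        print(f"{name}: {len(files)} contrasts -> {outdir}")


if __name__ == "__main__":
    main()
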