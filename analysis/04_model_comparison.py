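#!/usr/bin/env python
"""Is the sparse vesicle layer a necessary part of the model?

Re-enacts the model choice for the per-deuterated 50 °C series: fit the
one-layer model with and without the vesicle extension to data that contain a
4%-coverage vesicle layer in the H₂O contrast, then repeat on vesicle-free
data as a null control. Writes results/model_comparison.json.
"""

import copy
import json
from pathlib import Path

from slbnr.fitting import co_refine, compare_models
from slbnr.simulate import InstrumentSpec, ground_truth_presets, simulate_contrast_series

SEED = 20151211
ROOT = Path(__file__).resolve().parent.parent / "results"


def plain_variant(model):
    plain = copy.deepcopy(model)
    plain.vesicle_contrasts = ()
    plain.params["coverage"].vary = False
    plain.params["d_vesicle_gap"].vary = False
    return plain


def run(tag, truth_model, contrasts, instrument, data_seed):
    data = simulate_contrast_series(truth_model, contrasts, instrument, data_seed)
    base = ground_truth_presets()["dEcoli_50C"].model
    fit_ext = co_refine(copy.deepcopy(base), data, n_starts=8, seed=SEED)
    fit_plain = co_refine(plain_variant(base), data, n_starts=8, seed=SEED)
    cmp = compare_models(fit_ext, fit_plain, data)
    print(f"\n{tag}:")
    print(f"  with vesicle layer:    reduced chi2 {cmp.reduced_chisq_a:.3f} "
          f"(coverage {100 * fit_ext.params['coverage']:.2f} % v/v)")
    print(f"  without vesicle layer: reduced chi2 {cmp.reduced_chisq_b:.3f}")
    print(f"  improvement factor {cmp.improvement:.2f} -> "
          f"{'necessary' if cmp.necessary else 'not necessary'}")
    return {
        "reduced_chisq_with_vesicles": cmp.reduced_chisq_a,
        "reduced_chisq_without": cmp.reduced_chisq_b,
        "improvement": cmp.improvement,
        "necessary": cmp.necessary,
        "recovered_coverage_pct": 100 * fit_ext.params["coverage"],
    }


def main() -> None:
    instrument = InstrumentSpec(q_min=0.005, q_max=0.3)
    gt = ground_truth_presets()["dEcoli_50C"]
    out = {
        "vesicle_truth": run(
            "data WITH a 4% vesicle layer", gt.model, gt.contrasts, instrument, SEED + 1
        )
    }
    no_vesicles = copy.deepcopy(gt.model)
    no_vesicles.params["coverage"].value = 0.0
    out["vesicle_free_truth"] = run(
        "vesicle-free control data", no_vesicles, gt.contrasts, instrument, SEED + 2
    )
    ROOT.mkdir(exist_ok=True)
    (ROOT / "model_comparison.json").write_text(json.dumps(out, indent=1) + "\n")


if __name__ == "__main__":
    main()
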