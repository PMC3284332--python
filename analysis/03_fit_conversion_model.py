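"""Jointly estimate the conversion DSB rate and tract-length parameter
from the detected events, with profile intervals, derived rates and the
likelihood-ratio test of a fixed genome-wide event total.

Reads results/dataset/, writes results/fit.json.
"""

import json
import pathlib

from meiorec import detect, io, mle
from meiorec import reference_events as ref

ROOT = pathlib.Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    data = io.load_dataset(ROOT / "dataset")
    # default detection (>= 2 converted markers) keeps the conformation set
    # free of isolated false calls at the cost of missing short tracts
    res = detect.detect_dataset(data["marker_map"], data["calls"])
    confs = mle.conformations_from_events(res["conversions"])
    fit = mle.fit(res["span_histogram"], confs)
    fit = mle.profile_ci(fit, res["span_histogram"], confs)
    rates = mle.derived_rates(fit.params)
    total_true = (ref.CO_PER_MEIOSIS
                  + 4.0 * ref.ML_DSB_RATE * ref.GENOME_EUCHROMATIC_LENGTH)
    lrt = mle.likelihood_ratio_test(res["span_histogram"], confs,
                                    total_true, free_fit=fit)
    out = {
        "n_conformations": len(confs),
        "dsb_rate": fit.dsb_rate,
        "tract_p": fit.tract_p,
        "dsb_rate_ci": list(fit.dsb_rate_ci),
        "one_sided_tract_ci": list(fit.one_sided_tract_ci),
        "max_lnl": fit.max_lnl,
        "one_sided_mean_tract": rates.one_sided_mean_tract,
        "total_mean_tract": rates.total_mean_tract,
        "per_bp_conversion_rate": rates.per_bp_conversion_rate,
        "per_arm_rate": rates.per_arm_rate,
        "genome_haploid_rate": rates.genome_haploid_rate,
        "per_meiosis_rate": rates.per_meiosis_rate,
        "gc_co_ratio": rates.gc_co_ratio,
        "lrt": lrt,
    }
    with open(ROOT / "fit.json", "w") as fh:
        json.dump(out, fh, indent=2)
        fh.write("\n")
    print(json.dumps(out, indent=2))


if __name__ == "__main__":
    main()
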