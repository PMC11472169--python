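"""Calibrate the Gini-coefficient threshold at a 1% false-discovery rate.

For each anchor set in a small collection, candidate patterns are discovered
on the real flanks and on mononucleotide-shuffled flanks (which keep base
composition but destroy positional structure).  The Gini threshold is the
smallest cut at which shuffled candidates pass at <= 1% of the real rate.
"""

import numpy as np

from comotif import (
    FIXTURE_MOTIF_W8,
    RunConfig,
    calibrate_datasets,
    generate_dataset,
    run_dataset,
)


def main() -> None:
    # a small collection: two sets with genuine co-binding signal, two without
    datasets = {
        "signal_a": generate_dataset(1000, 0.10, FIXTURE_MOTIF_W8, offset=6,
                                     seed=1, id_prefix="a_").records,
        "signal_b": generate_dataset(1000, 0.10, FIXTURE_MOTIF_W8, offset=2,
                                     seed=2, id_prefix="b_").records,
        "background_a": generate_dataset(1000, 0.0, FIXTURE_MOTIF_W8,
                                         seed=3, id_prefix="c_").records,
        "background_b": generate_dataset(1000, 0.0, FIXTURE_MOTIF_W8,
                                         seed=4, id_prefix="d_").records,
    }
    cal = calibrate_datasets(datasets, RunConfig(seed=5), fdr_target=0.01)
    print(f"candidate Gini scores: {len(cal.real_ginis)} real, {len(cal.null_ginis)} null")
    print(f"real Gini:  median {np.median(cal.real_ginis):.3f}  max {max(cal.real_ginis):.3f}")
    print(f"null Gini:  median {np.median(cal.null_ginis):.3f}  max {max(cal.null_ginis):.3f}")
    print(f"calibrated threshold: {cal.threshold:.3f} "
          f"(target FDR {cal.fdr_target}, achieved {cal.achieved_fdr:.4f})")

    config = RunConfig(seed=5, gini_min=cal.threshold)
    for name, records in datasets.items():
        result = run_dataset(records, config, dataset=name)
        print(f"  {name}: {len(result.patterns)} pattern(s) at the calibrated threshold")
    print("\nSignal sets retain their co-binding pattern; pure-background sets")
    print("report nothing, which is what the 1% FDR calibration guarantees.")


if __name__ == "__main__":
    main()
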