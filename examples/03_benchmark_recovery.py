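"""Benchmark motif recovery across injection prevalences and motif widths.

Reproduces a slice of the synthetic benchmark protocol: datasets of 1000
random sequences with a known motif injected in 1, 3, 5 or 10% of them; for
each condition the pipeline runs and recovery is scored (permutation match
p < 0.05 against the injected PFM; F1/MCC over the true carriers).
"""

from comotif import (
    FIXTURE_MOTIF_W3,
    FIXTURE_MOTIF_W8,
    RunConfig,
    evaluate_recovery,
    generate_dataset,
    run_dataset,
)

MOTIFS = {"width-8 (TGACGTCA)": FIXTURE_MOTIF_W8, "width-3 (GAT)": FIXTURE_MOTIF_W3}


def main() -> None:
    print(f"{'motif':>20} {'prevalence':>10} {'matched':>8} {'F1':>6} {'MCC':>6} {'incorrect':>9}")
    for label, motif in MOTIFS.items():
        for prevalence in (0.01, 0.03, 0.05, 0.10):
            ds = generate_dataset(1000, prevalence, motif, side="downstream",
                                  offset=6, seed=17)
            result = run_dataset(ds.records, RunConfig(seed=17))
            rec = evaluate_recovery(result.archetypes, ds, n_perm=499, seed=17)
            print(f"{label:>20} {prevalence:>10.0%} {str(rec.matched):>8} "
                  f"{rec.f1:>6.2f} {rec.mcc:>6.2f} {rec.n_incorrect:>9}")
    print("\nRecovery switches on around 3% prevalence at this dataset size.")
    print("The width-3 motif is a known hard case: a 3-column matrix admits only")
    print("six column orders, so the column-permutation match test cannot reach")
    print("p < 0.05 and short discovered patterns land in the 'incorrect' column")
    print("even when they resemble the injection — inspect them before dismissing.")


if __name__ == "__main__":
    main()
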