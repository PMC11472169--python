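"""Discover a co-binding motif injected at a fixed spacing downstream of an anchor.

Builds a synthetic anchor set of 1000 sequences in which 10% carry an
instance of a width-8 bZIP-like motif (consensus TGACGTCA) starting 6 nt
downstream of the anchor, runs the full discovery pipeline and prints the
resulting co-binding patterns.
"""

import numpy as np

from comotif import (
    FIXTURE_MOTIF_W8,
    RunConfig,
    evaluate_recovery,
    generate_dataset,
    run_dataset,
)


def consensus(counts: np.ndarray) -> str:
    return "".join("ACGT"[i] for i in np.argmax(counts, axis=0))


def main() -> None:
    dataset = generate_dataset(
        num_sequences=1000, prevalence=0.10, motif=FIXTURE_MOTIF_W8,
        side="downstream", offset=6, seed=11,
    )
    print(f"dataset: {dataset.num_sequences} sequences, "
          f"{len(dataset.truth_ids)} carriers of {consensus(dataset.injected_motif)} "
          f"at downstream offset {dataset.injection_offset}")

    result = run_dataset(dataset.records, RunConfig(seed=11))
    disc = result.discoveries["anchors"]
    print(f"candidates: {len(disc.candidates)} from NMF, "
          f"{len(disc.kept)} pass IC/Gini filters, "
          f"{len(result.archetypes)} archetypes after clustering")

    for pattern in result.patterns:
        print(f"  {pattern.archetype_id}: consensus {consensus(pattern.archetype.counts)}"
              f" | side={pattern.side} spacing={pattern.spacing}"
              f" orientation={pattern.orientation} prevalence={pattern.prevalence:.3f}")

    recovery = evaluate_recovery(result.archetypes, dataset, n_perm=499, seed=11)
    print(f"recovery: matched={recovery.matched} "
          f"F1={recovery.f1:.3f} MCC={recovery.mcc:.3f} "
          f"incorrect motifs={recovery.n_incorrect}")
    print("\nThe reported spacing equals the injected offset (6 nt), and the")
    print("prevalence approximates the injected carrier fraction; F1/MCC score")
    print("how precisely the assigned sequences coincide with the true carriers.")


if __name__ == "__main__":
    main()
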