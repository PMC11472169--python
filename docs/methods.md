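# Methods

## Problem and model

Transcription factors (TFs) often bind DNA cooperatively: a partner TF binds
at a short, nearly fixed distance from an anchor TF's binding site (TFBS),
producing a recurrent motif at a constant offset in the flanking sequence of
many anchor sites. `comotif` discovers such fixed-spacing co-binding
patterns de novo, without a motif library.

Given a set of anchor TFBSs, the pipeline:

1. **Flank extraction.** Takes the `n` nucleotides (default 30) immediately
   upstream and downstream of each anchor, oriented to the anchor's reading
   strand (minus-strand anchors are reverse-complemented, so "upstream" is
   always 5' of the anchor motif).
2. **One-hot encoding.** Each flank becomes a 4-bit-per-base vector
   (A=1000, C=0100, G=0010, T=0001; anything else = 1111), giving one
   `(num_sequences x 4n)` binary matrix per side.
3. **NMF.** Each matrix `X` is factorized as `X ≈ W H` with `W, H >= 0`
   under the squared Frobenius objective, for every `k` in a range (default
   3–6). Each basis row of `H` is a candidate flank pattern; each sequence
   is assigned to the component with its maximal coefficient in `W`
   (argmax clustering; ties to the lowest index, all-zero rows unassigned).
   Running several `k` deliberately rediscovers the same pattern at several
   resolutions; redundancy is resolved later by clustering.
4. **Candidate scoring.** Per component, a full-flank positional frequency
   matrix (PFM) is counted from the assigned sequences (ambiguous bases add
   0.25 per row, so column sums stay equal to the component size). Per
   column, information content `IC = 2 + Σ_b f_b log2 f_b` (bits, no
   pseudocount). Candidates are kept when total IC >= 2 bits **and** the
   Gini coefficient of the per-position IC vector is >= a threshold
   (default 0.5, or calibrated — below). The Gini coefficient
   `g = Σ_ij |x_i − x_j| / (2 m² x̄)` separates localized patterns (IC
   concentrated in few adjacent positions, high g) from dispersed or flat
   IC profiles (low g).
5. **Core trimming.** The smallest contiguous window holding at least half
   the flank's total IC is found (ties: maximal IC sum, then leftmost) and
   expanded by `floor(width/2)` positions per side, clipped to the flank.
6. **Clustering into archetypes.** Core motifs from all runs (and all
   datasets, when several are pooled) are compared by Pearson correlation
   of column frequencies, maximized over all offsets with >= 3 overlapping
   columns and both orientations; the normalized score scales by
   `overlap / max(widths)`. Average-linkage agglomeration merges while the
   best pair keeps correlation >= 0.6 and normalized correlation >= 0.4.
   Each cluster's archetype is the per-position mean of the member count
   matrices aligned to the cluster seed (widest member, ties by total IC),
   with successive edge positions of IC < 0.1 discarded.
7. **Spacing summary.** Each pattern is reported per dataset with its side,
   spacing to the anchor, orientation relative to the anchor strand, and
   prevalence (fraction of the dataset's sequences assigned to it, unioned
   across the member motifs so a sequence found at several `k` counts
   once). Members of one archetype at different spacings yield distinct
   rows, as on a spacing heatmap.

## Spacing readout

Spacing is **not** measured to the edge of the step-5 window. That window
floats inside the informative block (any half-IC sub-window qualifies), so
its expanded edge is biased by 1–2 nt relative to the injected offset in
simulations. Instead, the core window is grown over adjacent full-flank
positions with IC >= 0.1 and then stripped of edges below 0.1
(`effective_span`); spacing runs from the anchor edge to the nearest edge of
that informative extent. With this readout a motif injected `s` nt
downstream is reported at exactly `s` in simulation (all seeds tested, `s`
in {0, 1, 4, 6}); the raw window convention remains available as
`spacing_of`.

## Gini threshold calibration

The default Gini cutoff 0.5 is a convention; the distribution of candidate
Gini scores depends on dataset size and composition. `calibrate_datasets`
re-derives the cutoff for a collection at a target false-discovery rate
(default 1%): every dataset is re-analyzed with each flank independently
shuffled at the mononucleotide level (exactly preserving per-sequence base
composition while destroying positional structure), and the threshold is the
smallest observed Gini value `t` with
`(fraction of null candidates >= t) / (fraction of real candidates >= t) <= FDR`.
If no cut qualifies (real and null indistinguishable — e.g. a pure-noise
collection), the threshold is set above all observed values with a warning,
disabling discovery; that behaviour is what bounds the false-positive rate
on background-only collections.

## Synthetic benchmark

`generate_dataset` emulates the evaluation protocol: `N` records with
i.i.d. uniform-ACGT anchors (default 10 nt) and flanks (30 nt); a fraction
`p` of records (carriers, chosen without replacement) receives one motif
instance, sampled column-wise from a source PFM, overwriting one flank at a
fixed offset. Defaults follow the stated benchmark world: sizes
{800, 1000, 4000, 8000, 10000, 40000, 80000}, prevalences
{0.5, 1, 3, 5, 10}%, motif widths 3–19 (three fixture PFMs are bundled:
width-8 bZIP-like TGACGTCA at 0.94 consensus dominance, width-3 GATA-half
GAT, width-19 zinc-finger-like at 0.80 dominance). What the generator does
**not** emulate: genomic base composition and repeats, soft-masking,
anchor-motif information (anchors are random), overlapping or variably
spaced partner sites, and multiple distinct co-binders per dataset. A green
recovery test therefore establishes sensitivity under clean fixed-spacing
signal, not robustness to genomic confounders (low-complexity A/T stretches
are a known false-positive mode on real data).

`evaluate_recovery` declares the injection recovered when any archetype
matches the injected PFM with permutation p < 0.05: the null permutes the
candidate's columns and re-scores the best-offset/orientation normalized
similarity, `p = (1 + #better) / (n_perm + 1)`. Carrier recovery is scored
with F1 and Matthews correlation over assigned-vs-true carrier ids,
reporting the best-F1 matching archetype; non-matching archetypes count as
incorrect predictions.

**Limitation of the permutation match:** a width-`w` candidate has only
`w!` column orders, so for `w = 3` the attainable minimum p is ~1/6 and no
short motif can be certified at α = 0.05. The very-short-motif benchmark
rows report `matched=False` for this reason; the discovered short patterns
themselves are still emitted and can be inspected.

## Numerical and procedural choices

| choice | value | why |
|---|---|---|
| NMF solver | sklearn cd, Frobenius, `init=nndsvdar`, `max_iter=200`, `tol=1e-4`, seeded | deterministic given a seed; the double-SVD init with seeded perturbation avoids the zero-locking of plain NNDSVD |
| flank length `n` | 30 nt | physical-interaction range: cooperative TFs sit ~9–10 bp apart on average and the longest anchor motifs are ~20 bp; longer flanks dilute the signal |
| `k` range | 3–6 | chosen from synthetic sweeps; the union over `k` is used, never a single "best" k |
| IC filter | total IC >= 2 bits, full-flank PFM, no pseudocount | per-column reading would reject everything; components summarize dozens of sequences so zero counts are meaningful |
| assignment ties | lowest component index | argmax needs a deterministic rule; ties occur on degenerate coefficients |
| ambiguous bases | 0.25 per PFM row | keeps column sums constant so IC and Gini are comparable across columns |
| trim window sums | direct per-window summation | a cumulative-sum shortcut breaks exact leftmost tie-breaking on constant vectors via rounding noise |
| window tie-break | smallest width, then max IC, then leftmost | full order for determinism |
| cluster thresholds | cor >= 0.6, normalized cor >= 0.4, average linkage | documented defaults of the standard matrix-clustering tool this stage replaces |
| similarity degenerate case | Pearson of a zero-variance window = 0 | avoids NaN on uniform columns |
| permutation test | add-one estimator, >= 99 permutations, seeded | p is never 0; deterministic given the seed |
| seed fan-out | `SeedSequence(seed, spawn_key=(stage, indices...))` | every stage reproducible independently of execution order |
| dataset gate | < 1000 sites skipped (overridable) | below this the factorization lacks recurrence to separate pattern from background |

## Known limitations

- Components are impure: background sequences argmax-assign into motif
  components, so prevalence overestimates the true carrier fraction
  (≈ carrier fraction + background/k) and F1 saturates well below 1 even
  for perfect motif recovery. The motif match itself is unaffected.
- Overlapping anchor/partner motifs are out of reach by construction (the
  anchor is excluded from factorization).
- Motifs shorter than ~4 columns cannot pass the permutation match test
  (above).
- Published species-scale results — thresholds calibrated on thousands of
  TFBS datasets (0.46–0.54 across seven species), the catalogue of
  hundreds of co-binding patterns, and conservation/open-chromatin/
  single-molecule validations — require external data collections and are
  not reproduced here; the synthetic-recovery, spacing and FDR properties
  tested in `tests/` substitute at desk scale.
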