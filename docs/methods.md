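# Methods

## Fusion model

Two peak-caller outputs are treated as scoring systems over genomic
regions, the score being the caller-reported ChIP tag count. Fusion
operates on the *union* U(x, y) (all regions, cross-overlapping ones
merged) or the *intersection* I(x, y) (only regions with contributions
from both systems). Per-system scores on fused regions are the sum of the
contributing member tag counts (0 for an absent system), min–max
normalized within the fusion set at hand, and ranked descending. The score
combination is the unweighted mean of the two normalized scores; the rank
combination is the unweighted mean of the two ranks. Weights are fixed at
½/½; weighted or k-way (k > 2) variants are out of scope — the batch
driver composes pairs.

### Merging semantics

Overlap means ≥ 1 shared bp under BED-style 0-based half-open coordinates;
there is no distance tolerance. Merging is *transitive*: the fused regions
are the connected components of the pairwise-overlap graph, so a chain
x₁–y₁–x₂ collapses into one region spanning [min start, max end). Any
non-transitive rule would emit overlapping output regions and make
per-locus scoring ambiguous. Within-system overlap chains that never touch
the other system also merge by default (callers rarely emit overlapping
peaks, and leaving them stacked would double-score a locus); passing
`intra_merge=False` / `--no-intra-merge` restores pass-through for those.
The implementation is a per-chromosome sort-by-start linear sweep tracking
the running maximum end — for intervals this recovers exactly the
overlap-graph components, which the test suite verifies against a
brute-force O(n²) graph oracle.

### Ties and degenerate scales

The rank function cannot be a bijection onto {1..p} under tied scores, and
ties are ubiquitous (every union single scores 0 on the other system).
Midranks are used: symmetric, order-independent, and rank-sum preserving.
When a score column is constant (including single-region sets) min–max
normalization is undefined; all values are set to 0.5 so the constant
column contributes neutrally to the ½-weighted combination rather than
claiming full or zero evidence. Final orderings break remaining ties by
(chrom, start, end) ascending so outputs are identical across runs and
platforms.

## Evaluation

A region is relevant if it overlaps the closed window
[pos − flank, pos + flank] of at least one TSS; the default flank is 0
(point containment, start ≤ pos < end), configurable because TSS-proximity
windows are a reporting choice, not part of the metric. Average precision
uses denominator n, the full region count — AP(n) = Σ p(r)·o(r)/n —
deliberately different from standard IR average precision (denominator =
number of relevant items): appending an irrelevant region strictly
decreases it, so long noisy tails are penalized. The conventional variant
is available behind an explicit `standard_ap` flag for comparison only.
Coverage counts distinct TSS by (chrom, pos, strand): transcript isoforms
sharing a start count once; the same position on opposite strands counts
twice. Regions on chromosomes absent from the annotation are kept and
scored irrelevant, not dropped.

Two facts are consequences of the construction, and are enforced as hard
invariants: every input region is contained in some union region, so
Coverage(U) ≥ max of the single coverages on *every* input; and
I(x, y) ⊆ U(x, y), so Coverage(I) ≤ Coverage(U).

## Synthetic data generator

The generator emulates peak calling for TSS-proximal marks. Per caller,
`frac_true` of the peaks are centred near a TSS with Gaussian displacement
(`offset_sd`) and high tag counts; the rest are uniform background with
low counts. Tag counts are Poisson(λ)+1 — a called peak has at least one
tag. Correlation between two callers is induced *only* through a shared
subset of true-peak TSS targets (`shared_frac` of targets drawn from a
common pool of round(shared_frac · n_tss) sites); tag counts are
independent. That single mechanism spans the diversity axis that governs
how much fusion can add.

Defaults (one experiment): 2 Mb genome over 2 chromosomes, 200 TSS at
≥ 2 kb spacing, 300 peaks per caller, frac_true = 0.7, shared_frac = 0.6,
widths uniform in 200–800 bp (point-source peaks are a few hundred bases
wide), offset_sd = 100 bp, λ_true = 50, λ_bg = 5 (10× ratio). With
offset_sd = 100 roughly a tenth of true peaks miss their TSS — intended
relevance noise. These sizes keep a 100-replicate two-caller experiment
in seconds while leaving all the qualitative structure intact.

What passing tests on this generator do **not** show: real callers differ
in peak-boundary conventions, width distributions, systematic score
biases, and correlated errors from the shared read data — none of which
the generator models. The synthetic experiments demonstrate that the
fusion and evaluation machinery behave as specified and that the expected
qualitative pattern (intersection improves precision, union improves
coverage) emerges under controlled diversity; they say nothing
quantitative about any particular real dataset.

## Numerical choices

- All RNG streams derive from one seed via numpy `SeedSequence`; caller
  identity salts its stream (CRC32 of the label) so identical configs give
  distinct but reproducible callers.
- Normalized/combined scores are serialized at 6 significant digits;
  report tables at 4 decimals.
- Empty fusion sets are legal (disjoint inputs under intersection) and
  serialize as header-only files; average precision is undefined (an
  error) for an empty list, while coverage of an empty set is 0.
- TSS positions from gene records: start for `+` strand, end − 1 for `-`
  (the transcript 5′ end); point-mode records default to `+`. Strand never
  affects overlap testing.

## Known limitations

- Only pairwise fusion in the core; k-way fusion is composed, not native.
- Tag counts are taken as given per region; there is no read-level
  recounting, and no p-value or fold-enrichment scoring.
- Chromosome names are exact strings (optional `chr`-prefix stripping);
  no assembly-aware liftover or alias table.
- The TSS annotation is user-supplied ground truth; the package does not
  fetch or validate reference annotations.
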