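# Methods

## The Monte Carlo–Wilcoxon test family

The package's central statistic is a signed-rank bias index computed under
three data structures (unmatched sets, matched pairs, and sets of
per-element bias measures), each with a rearrangement null. The shared
ranking rules are: differences of exactly zero receive rank 0; nonzero
differences are ranked ascending by absolute value starting at 1 among the
nonzeros; tied magnitudes all receive the lowest of their would-be ranks
(`scipy.stats.rankdata(method="min")` after shifting out the zeros); signs
follow the differences.

### Normalisers

The bias index is a ratio of the signed-rank sum to its most extreme
achievable value *given the observed rank magnitudes*:

- uMCW: `BI = Σr / Σ|r|` over all n_a × n_b cross-set differences. The
  denominator is what the numerator would be if every first-set measure
  exceeded every second-set one with the observed tie structure. With
  completely tied (constant, identical) sets both sums are zero and BI is
  defined as 0, with both p-values 1.
- mbMCW: per-pair differences from both sets are ranked jointly;
  `BI = (S_x − S_y)/M`. The extreme configuration — all of x's ranks
  positive and all of y's negative — makes `S_x − S_y` equal the total
  rank mass, so `M = Σ|r|`. Joint ranking is assignment-invariant, so the
  null only re-partitions precomputed signed ranks.
- bMCW: `wBI = Σr / Σ|r|`; `sBI = Σ_{i∈S} r_i / (sum of the |S| largest
  rank magnitudes)`, i.e. 1 exactly when the subset occupies the top |S|
  ranks all positively. Only one subtraction direction is computed; the
  reverse direction is the negated statistic and carries no extra
  information.

These normaliser choices are pinned by the worked examples the test suite
freezes (BI = 5/7 for a=[3,1] vs b=[2,0]; mbMCW BI = 1/3 for (4,1) vs
(2,1); sBI = (2+3)/(3+2) = 1) and by the symmetry properties enforced in
tests: BI flips sign under set swap, and |BI| = 1 exactly under complete
bias.

### Rearrangement nulls and p-values

`P_upper` / `P_lower` are the proportions of null BIs ≥ / ≤ the observed
one; ties count toward both, so `P_upper + P_lower ≥ 1`. The comparison
uses a 1e-12 float guard so exact-path ties are never lost to rounding.

`max_rearrangements` (default 10,000) separates the exact path — full
enumeration when the number of distinct rearrangements is *strictly*
smaller — from the Monte-Carlo path, which draws exactly
`max_rearrangements` uniform rearrangements with replacement from a seeded
`numpy` generator. Monte-Carlo p-values are raw proportions (no +1
smoothing); a zero proportion is logged as "< 1/max_rearrangements".
uMCW/mbMCW rearrangement spaces are C(n_a+n_b, n_a) set assortments; bMCW
uses 2^N sign configurations for the whole set and C(N, |S|) memberships
per subset. Monte-Carlo membership draws share one seeded permutation
matrix across subsets (a slice of a uniform permutation is a uniform
same-size membership), so cost does not grow with the number of subsets;
exact paths are enumerated per subset.

With the 5-vs-5 replicate layout used throughout the expression analyses,
C(10,5) = 252 < 10,000, so every per-gene test is exact. The vectorised
per-gene path (`umcw_test_many`) evaluates all genes of a contrast against
the same enumerated assortment index, chunked to bound the working array
at ~2×10⁷ elements.

## Isochore segmentation

Non-overlapping 100-kb windows; GC computed over non-N bases; five classes
with lower-inclusive half-open boundaries at 37/41/46/53% GC; juxtaposed
same-class windows merged into isochores. Conventions that the underlying
definition leaves open, fixed here:

- Boundary membership: [0.37, 0.41) etc. Any consistent convention
  preserves downstream analyses; windows rarely sit exactly on a boundary.
- Windows with > 50% N bases are assembly-gap windows: unclassified,
  excluded, and run-breaking (the threshold is an argument). Classified
  isochores plus gap runs exactly tile each chromosome — a tested
  invariant.
- Terminal sub-100-kb windows are classified normally.
- Coordinates are 0-based half-open internally and in BED output; GTF is
  converted on read. Gene span is the annotated gene interval, introns
  included.

Genes are assigned to the single overlapping isochore with the largest
base-pair overlap; ties go to the lower start coordinate; non-overlapping
genes stay unassigned (a valid state — they still enter whole-transcriptome
tests). Relative gene fractions per class are `log10((x/n)/(X/N))`; an
empty subset class yields −inf as a sentinel rather than an error.

## Expression contrasts

Per contrast (sex × tissue × exposure group vs the shared control), the
order of operations is: select the contrast's samples → drop genes without
≥ 2 reads in ≥ 2 of those samples → drop mitochondrial / Y / unassembled
genes (label-pattern match; unrecognised labels are treated as unassembled)
→ cpm-normalise the surviving table (per-sample totals equal 10⁶ over the
genes present at that stage) → one exact uMCW per gene, positive BI
meaning higher in exposure. 0–1 rescaling of cpm values is provided for
visualisation matrices; constant genes map to all-zero to avoid a 0/0.

## Pre-ranked enrichment

Genes are ordered by BI descending, ties broken by gene id so ranked lists
are deterministic. The running sum uses weight exponent 1 (hits add
|stat|/Σ_set|stat|, misses subtract 1/(N − N_set)); ES is the
maximal-magnitude excursion with its sign. Sets are intersected with the
ranked universe first, then filtered to 15 ≤ size < 500 (both bounds are
arguments). The null permutes set membership — equivalent to permuting
gene ranks for a fixed set — with p the proportion of same-sign null ES at
least as extreme, and NES = ES / mean |same-sign null ES|. Null
distributions are shared across sets of equal size. If no same-sign null
values exist, p is floored at 1/n_perm and NES flagged NaN. No
multiple-testing adjustment is applied across sets; raw p-values are
reported.

## Compartment bias and the dichotomy call

For one contrast, the per-gene BIs feed a single bMCW test whose subsets
are each isochore class, each isochore holding at least
`isochore_min_genes` scored genes (or explicitly listed isochores of
interest, e.g. those housing a gene family), and each chromosome.
Isochore-unassigned genes stay in the whole set but not in class/isochore
subsets. Per-isochore subsets contain all scored genes in the isochore,
not only family members.

The heterochromatin/euchromatin dichotomy is qualitative in origin, so the
caller formalises it: present iff mean sBI over {L1, L2} and mean sBI over
{H2, H3} have opposite signs and each side carries ≥ 1 class with
min(P_upper, P_lower) < α (default 0.05); the label records which side is
up. H1 is deliberately unconstrained — it is the intermediate class in the
AT-rich/GC-rich framing. Missing classes yield "absent" with a warning.

## Phenotype analyses

Traits are normalised to the units the comparisons use: body weight by
days of age (g/day); fasting glucose, tissue weights and plasma
metabolites additionally by body weight. Matched pairs are oriented
(later − earlier): post-fasting minus pre-fasting, exit minus entry, so
negative paired differences mean loss/consumption, and an exposure group
losing more than controls gives mbMCW BI < 0. Plasma values flagged
outside the standard curve (or non-extrapolable) are set to zero; PCA then
uses only metabolites that are positive and present in every mouse of a
sex, centred and — by default — scaled to unit variance (metabolite
concentrations span orders of magnitude; the unscaled mode is exposed as
an argument since the convention is not universal). Component signs are
fixed by making each component's largest-magnitude loading positive.

Drinking-water dose: dose [mg/kg/day] = concentration [mol/L] × MW [g/mol]
× 10³ × intake [L/day] / body weight [kg]. The tributyltin molecular
weight defaults to the cation (290.06 g/mol; the chloride salt, 325.5, is
an override — both round to the same one-significant-figure dose at the
reference conditions of 50 nM, 30 g, 10 mL/day). The NOAEL ratio divides
the 0.025 mg/kg/day reference level by the dose.

## Synthetic data

The generator emulates the study *structure*, not real mouse data:

- Genome: blocks of prescribed length and GC target (defaults 30/39/43/50/
  60%, 500 kb each, cycled over 3 × 5 Mb chromosomes with one 100-kb all-N
  gap per chromosome). Bases are i.i.d. within a block, so 100-kb windows
  hit the target with ~0.2% binomial fluctuation — far inside the 1%
  tolerance asserted in tests. Real isochore structure (gradients,
  long-range correlation, repeats) is not modelled.
- Annotation: non-overlapping intron-free gene spans (2–10 kb) placed
  uniformly within non-gap blocks, so each gene's true class is
  unambiguous. Real gene structure and clustering are not modelled.
- Counts: negative binomial with dispersion 0.1 (typical bulk RNA-seq)
  around log-normal gene baselines (σ = 1 around a mean of 100); exposure
  samples shift the mean by 2^log2fc of the gene's class. A shift planted
  in *every* class is invisible after cpm normalisation (library totals
  scale with it) — the dichotomy scenarios therefore plant opposite shifts
  in AT-rich and GC-rich classes, which is also the structure under study.
  Library-size variation, sample covariance and batch effects are not
  modelled, so passing recovery tests demonstrates the statistics, not
  robustness to those artefacts.
- Phenotypes: Gaussian traits with standardised group effects; log-normal
  plasma panel with a configurable out-of-range fraction (default 5%)
  exercising the zeroing rule; Poisson litters.

All randomness derives from the design seed through crc32-named
substreams, making every artifact byte-identical across runs and
processes.

## Problem sizes and numerical choices

The test suite and the worked examples run at desk scale by design: 2–3
chromosomes of 2.6–5 Mb, 80–300 genes, 5 replicates per cell. Calibration
suites use 500 null per-gene tests / 500 random gene sets (type-I error
within three binomial standard errors of α = 0.05), and recovery suites
100 seeded replicates with |log2FC| = 1 planted shifts (≥ 95% recovery,
≤ 5% false calls). Tie comparisons between observed and null statistics
use a 1e-12 absolute guard; BI denominators of zero (all-tied data) define
the statistic as 0 rather than erroring.

## Known limitations

- The dichotomy caller tests sign opposition plus per-side significance;
  it does not model between-class correlation of sBIs (classes share the
  whole-set ranking), so its α is nominal, controlled empirically in the
  specificity tests.
- Unweighted (exponent-0) and multi-level weighting variants of the
  enrichment score are not implemented.
- The per-isochore test list is bounded by a minimum gene count rather
  than a multiple-testing correction, matching the exploratory,
  raw-p-value reporting style of the analyses this package supports.
- GTF ingestion reads gene features only; transcript-level records are out
  of scope.
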