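# Methods

This note records the models, conventions and numerical choices behind
`hgtsignal`, and what its synthetic benchmarks do and do not demonstrate.

## Trait model and likelihood machinery

Categorical niche traits are modelled with the equal-rates (ER) Mk process:
k observed states, one transition rate r per ordered state pair, diagonal
−(k−1)r. The transition probabilities have the closed form

    P_same(t) = 1/k + (k−1)/k · exp(−k r t)
    P_diff(t) = 1/k −   1/k  · exp(−k r t)

k is always the number of *observed* categories on the tree at hand, never
the size of the seven-category niche vocabulary; a constant trait is
rejected (the signal statistic is undefined for it). The root prior is
uniform 1/k. The likelihood uses Felsenstein pruning with per-node
rescaling; polytomies are supported natively, because published δ analyses
run on consensus trees whose weakly supported nodes may be collapsed.
Zero-length branches are legal (identity transition); negative lengths are
rejected rather than clamped. A tip configuration that is impossible under
the model (conflicting states across zero-length branches) yields −∞
log-likelihood rather than an exception from the optimizer's path.

The rate is fitted by bounded scalar maximization of the log-likelihood on
r ∈ [1e-8, 100] with absolute tolerance 1e-6. The bounds are wide enough
that on unit-height trees the optimum is interior in all but pathological
cases.

Marginal ancestral probabilities use up–down message passing: upward
partials from pruning, a downward pass that combines the parent's
downward message with sibling upward messages, both normalized per node.
Correctness of both the likelihood and the marginals is asserted against
exhaustive enumeration over all internal-state assignments on trees of up
to 6 tips (the enumeration oracle lives in `synthetic_data` and is guarded
to ≤ 8 internal nodes).

Equal-rates Mk with a uniform root prior and ML rate matches the common
reference implementation of the δ method; the model choice matters little
for δ because only the *relative* confidence of ancestral reconstructions
enters the statistic.

## The δ statistic

Per internal node, the normalized Shannon entropy of the marginal ancestral
distribution, h_i = −Σ p ln p / ln k, is clamped into the open interval by
a deterministic ε = 1e-9 (the reference implementation jitters zeros
randomly; a deterministic clamp makes runs reproducible bit-for-bit and
changes δ negligibly). The entropies are treated as i.i.d. Beta(α, β) with
independent Exponential(λ₀) priors. Sampling is by alternating
Metropolis–Hastings: Normal proposals with sd `proposal_sd`, non-positive
proposals rejected outright (not reflected), initialization α = β = 1. The
log-posterior for α given β is

    (α−1) Σ ln h_i − m·ln B(α, β) − λ₀ α        (m = number of internal nodes)

and symmetrically for β with Σ ln(1−h_i). Samples are retained at
iterations i with burn·thin < i ≤ n_iter and i ≡ 0 (mod thin) — at the
defaults (λ₀ = 0.1, sd = 0.5, n_iter = 10,000, thin = 10, burn = 100) that
is exactly 900 samples. δ is the posterior mean of β/α, the estimator used
by the method's reference implementation; the alternative
mean(β)/mean(α) is exposed as a diagnostic on the result object. At the
default settings two independent chains agree to within a few percent on
typical inputs; the test suite asserts 5% agreement at 50,000 iterations.

Intuition for the direction: strongly tree-structured traits give confident
ancestral reconstructions, i.e. small h_i, which concentrates the Beta fit
at α < β and inflates β/α.

### Permutation test

Significance is assessed against trait *shuffles* (uniform random
permutations of the observed values over the tips — category counts exactly
preserved), not resampling: shuffling yields a higher null δ and is
therefore the conservative choice. The default is 100 shuffles;
p = (# shuffled δ ≥ observed δ)/100, with ties counted against the observed
signal ("≥" is the conservative reading where conventions differ). Each
shuffle gets an independent RNG stream derived from the master seed by a
fixed offset, so shuffles can be evaluated in any order or in parallel
without changing results. The whole shuffled distribution is returned so
reports can quote its mean and standard deviation; a zero count is rendered
as "<0.01" in tabular output.

## Tree reduction

`collapse_low_support` contracts internal edges whose child has bootstrap
support below 50% (absent support is *unknown*, never zero, and is left
alone); promoted children keep their own branch lengths.

`trim_to_hgt_only` iteratively removes same-genus paralog tips so the
congeners that remain imply transfer rather than vertical descent. Genus
groups are the first token of the binomial, except that configured
cecidomyiid species collapse into a single family-level pseudo-group. Per
pass, genus groups and tip pairs are visited in lexicographic order and
rule A (pair's MRCA support strictly > 75%: drop one tip) is evaluated
before rule B (one tip is a lone outgroup — no sister of its own — to the
clade holding the other: drop the lone tip). Which congener of a rule-A
pair (or of a two-tip cherry, where both are "lone") is dropped is not
determined by the rules themselves; the lexicographically later label goes,
a documented deterministic convention. Passes repeat to a fixed point; each
removal requires a surviving partner, so no genus group is ever lost
entirely, and the terminal state — no congeneric sister pair — is asserted
exactly in tests. Trimming takes no trait input, so it is blind to niche by
construction.

## Screening cascade and contamination triage

Stage order (each hit's first failure is final and logged):
E-value < 0.01 → canonical-insect top-hit exclusion (< 2 insect top
matches, consumed as a precomputed count to keep the package offline) →
aligned length ≥ 50 aa → redundancy collapse → scaffold ≥ 1 kb → fragment
≥ 10% of the canonical protein length → removal of candidates on scaffolds
< 10 kb with no bona fide eukaryotic gene. "Aligned length" stands in for
predicted protein length in the canonical-fraction rule: the package
consumes tabular hits and does not predict ORFs. A missing canonical length
marks that stage NA and retains the candidate with a warning.

Redundant hits ("the same gene recovered from different donor strains at
the same coordinates") are grouped on a scaffold by reciprocal coordinate
overlap ≥ 50% with single-linkage, keeping the lowest-E-value
(ties: highest bitscore, then lexicographic query) representative. The 50%
reciprocal threshold is this package's tolerance for "same coordinate";
coordinates are 1-based inclusive throughout, with strand carried
separately from normalized start ≤ end.

Intron counts and transcription status are ledger annotations, not removal
stages — they are evidence columns of the final candidate table, mirroring
how such screens report them.

Duplicate-vs-misassembly classification: two copies are a misassembly
artifact if their scaffolds align at > 90% nucleotide identity; a genuine
duplication if ≥ 2 ranges on the same scaffold share > 90% amino-acid
identity; otherwise independent.

Read-depth triage uses the two-sided single-outlier Grubbs test
(G = max|dᵢ − mean|/sd with the n−1 sd; t-based critical value at
α = 0.05). The core operation is deliberately non-iterative — one test, at
most one flagged value — because sidedness and iteration conventions vary;
the screening pipeline applies it iteratively (remove, retest) to flag
multiple anomalous scaffolds. The single-outlier statistic is vulnerable to
masking: when a large fraction of the sample is anomalous, the inflated sd
can hide all outliers. Depth screens should therefore include the genome's
ordinary scaffolds, not just candidates.

The Shine–Dalgarno scan looks for AGGAGG with at most one mismatch
anywhere within 3–15 nt upstream of the start codon (window truncated at
the sequence start; N counts as a mismatch). Published screens assert the
motif's absence without defining the scan; this motif/window/mismatch
triple is this package's documented convention.

Micro-synteny: a candidate has synteny evidence in another species iff at
least one flanking gene's homolog lands on the same scaffold as the
candidate's own homolog there; missing placements are ignored.

## Acquisition timing

Per gene, with carriers = species having ≥ 1 copy on bona fide eukaryotic
scaffolds: (1) any micro-synteny between carriers ⇒ one solid gain at the
MRCA of the syntenic carriers, with one loss per maximal non-carrier clade
below it (losses at maximal clades, not per terminal — one event explains a
whole missing subtree); (2) otherwise, carriers resolved monophyletic ⇒ one
dashed gain at their MRCA plus losses; (3) otherwise one dashed gain per
carrier terminal. When a single-gain-plus-losses scenario and independent
gains tie on event count without synteny support, independent gains win —
the more cautious claim. When monophyly is simply untested, the scenario is
additionally flagged `ambiguous` with an explanatory note instead of
pretending the multi-gain history is established. Node ages on the species
tree are pass-through annotations, never computed. A consistency check
(presence implied by the events equals the input presence row) and a
brute-force minimal-event enumeration back these rules in the tests.

## Synthetic data: what it emulates, and what it does not

Trees are pure-birth (Yule): exponential waiting times at rate
birth_rate × lineages, uniform choice of the splitting lineage, rescaled to
unit height by default (δ is invariant to overall scale once the rate is
refit, so units are arbitrary). Traits evolve by exact simulation — one
closed-form transition-matrix draw per branch — with a uniform (or pinned)
root state, reported in the seven-category niche vocabulary.

Two rate parameterizations are provided. `expected_changes_rate` fixes the
expected number of changes over the whole tree; on a 60-tip tree a budget
of 2 changes usually lands on pendant branches and produces
single-deviant-tip traits whose real and shuffled entropies are equally
degenerate — such draws carry almost no recoverable signal, a genuine
property of the statistic, not an implementation artifact.
`conserved_trait_rate` instead fixes the expected changes per root-to-tip
lineage ((k−1)·r·height); at ≤ 2 changes per lineage the trait forms
clade-sized blocks and is the package's definition of a "strong-signal"
simulation. The benchmark suite uses the per-lineage version for power
studies and i.i.d.-uniform tip states for calibration studies.

The screening fixture plants 12 true HTGs (multi-kilobase scaffolds, ≥ 1
eukaryotic neighbor gene, genome-typical read depth drawn N(50, 5), 0–3
introns, a pyrimidine-only ribosome-binding window so no AGGAGG-like motif
can precede the start codon) and 8 removal-fated records, cycled across the
seven cascade stages so each stage fires at least once; contaminant
scaffolds get 10× depth and a planted AGGAGG motif 8 nt upstream of the
start codon. Scaffold lengths are exponential with a 200 kb mean over a
30-scaffold background. Fixture sequences are ORF-centered upstream windows
(start codon at position 61), not whole scaffolds. Every generator is a
pure function of its seed.

What passing these benchmarks shows: the machinery is numerically correct
(oracle agreement at 1e-9), calibrated (type-I error near the nominal
6/101 of a 100-shuffle test with the ≥ tie rule), powerful on genuinely
conserved traits, and exact on planted screening truth. What it does not
show: robustness to real-data pathologies — misestimated branch lengths,
rogue taxa, niche misassignment, correlated sampling of related donors,
assemblies whose contamination does not follow the planted contrasts — and
the fixture's clean separation of contaminant properties is far sharper
than real assemblies provide.

## Benchmark scales and tolerances

The replicated simulation studies run at a reduced chain length of
n_iter = 2,000 (thin 10, burn 100 → 100 retained samples): δ point
estimates are noisier there, but rank-based permutation p-values are
insensitive to symmetric estimator noise, and calibration confirms this
empirically. The test suite uses 200 replicates for calibration (accepting
a [0.015, 0.10] rejection-rate band at nominal 5%) and 50 for power
(requiring ≥ 80% detection, and δ above the shuffled mean in ≥ 95%);
`scripts/acceptance.py` reports the same quantities at 100 and 30
replicates, sizes chosen so the full script completes in minutes on a
single CPU. MCMC agreement tolerances: 5% between independent long chains,
10% for scale-invariance at short chains.

## Known limitations

* δ's Beta model treats node entropies as i.i.d.; they are in fact
  correlated along the tree, so δ is a useful index, not a calibrated
  effect size. The permutation test, not δ's magnitude, carries the
  inference.
* The α chain mixes slowly when all entropies are near 0 (very strong
  signal): acceptance rates below 10% are common there. Long chains or
  multiple seeds are advisable when the point value of δ matters.
* The canonical-fraction rule uses aligned length, which understates the
  predicted protein when the alignment is partial.
* Iterative Grubbs screening inherits the masking caveat above.
* The trimming drop-choice convention (lexicographic) can, on symmetric
  trees, retain a different congener than a human curator would; the
  retained *topology* is the same.
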