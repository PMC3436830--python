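# Methods

`trnadecode` infers which codons each tRNA isoacceptor decodes — the binary
anticodon–codon *reading* of an amino-acid family — from nothing but coding
sequences and tRNA gene copy numbers. The premise is that translation leaves
a detectable imprint in codon usage bias: codons decoded by the same tRNA
are used in a correlated way, and codon frequencies track the abundance of
the tRNAs that read them. Three methods exploit different facets of that
imprint; this note records the models, their assumptions, the tunable
parameters, and the design choices that were genuinely open.

## Problem setup

A family is one codon box: the synonymous codons sharing their first two
positions (six-codon amino acids split into a four-box and a two-box, which
are analyzed independently; cross-box reading is excluded). For a family
with *t* tRNAs and *k* codons, a reading is a binary *t × k* matrix with no
all-zero row (every tRNA reads something) and no all-zero column (every
codon is decodable). The full solution space is enumerated exactly up to a
configurable size cap; a *plausible* subset is generated from per-wobble-base
option sets (`data/wobble_options.yaml`) encoding decodings with
experimental precedent: C pairs only with G, G constitutively reads {C, U},
while A (via inosine and related modifications) admits {U}, {U,C}, {U,C,A}
and U (via its many modifications) admits {A} through {A,C,G,U}. These
option sets are data, not code, because the experimental compendium they
summarize is revisable; any same-shaped YAML overrides them. Implausible
readings are retained: they estimate the score distribution against which
the plausible subset is ranked.

Two rule-based baselines are provided for comparison: Crick's wobble rules
(`original`, with wobble-A treated as inosine I:{A,C,U}; `restricted`
removes I:A) and wobble parsimony (canonical decoding where a cognate tRNA
exists, then restricted wobble G:U and A:C for orphan codons, then extended
A:A and U:G). Parsimony is refused outside eukaryote mode, since bacterial
tRNAs typically read more broadly than its rules assume.

## HMM method

The primary method scores a reading by the likelihood of the observed runs
of synonymous codons (per gene, in order, regardless of spacing) under a
hidden Markov model whose hidden states are the tRNAs.

- **Emissions** are fixed by the candidate reading: uniform over the codons
  a tRNA reads (a tRNA reading two of four codons has row
  [0.5, 0.5, 0, 0]). This is the binary-interaction assumption: the method
  asks *whether* a tRNA reads a codon, not how efficiently.
- **Transitions** are shared by all candidates: row *i* is the relative
  gene-copy-number vector *w* with a reuse boost max(0, α + β·w<sub>i</sub>)
  added on the diagonal, then renormalized. Defaults α = 0.065,
  β = −0.087 (units: transition probability per step); the negative
  gradient makes reuse strongest for rare tRNAs. Copy number is used as
  the abundance proxy throughout.
- **Start vector** is the stationary distribution of T (eigendecomposition),
  i.e. the limiting tRNA usage; the abundance vector is available as a
  fallback for reducible chains. The choice has little numerical effect.
- **Scoring** is the scaled forward recursion in log space (stable for runs
  of arbitrary length; a codon unreadable by every state yields −∞). No
  parameter is optimized during evaluation; the candidate with the highest
  total log-likelihood over all runs wins. Scoring is vectorized across
  runs and across candidate readings (T and π are shared; only E differs).

The reuse parameters can be re-estimated from data by iterating: build T
from the current (α, β) → Viterbi-decode all runs (ties break to the lower
state index, deterministically) → convert each state's self-transition
frequency f<sub>i</sub> to the implied diagonal excess
r<sub>i</sub> = (f<sub>i</sub> − w<sub>i</sub>)/(1 − f<sub>i</sub>) → refit
r ~ α + β·w by count-weighted least squares. Convergence returns the
pre-update iterate, so an infinite tolerance returns the initial guess
after one diagnostic pass. Emissions during estimation come from a fixed
reference reading (the restricted wobble rules), which is neutral with
respect to the hypotheses later scored; the covariate is relative frequency
rather than absolute copies, and estimation is global rather than
per-family (both configurable by calling per family). On simulated data
with the default parameters the estimator recovers them within ±0.02 at
2000 genes, because plausible readings are near-partitions and the hidden
state is then almost observable, making Viterbi counting consistent.

## Regression method (REG)

Empirically, tRNA abundance grows with the square of the usage of the
codons it reads. For a candidate reading, each tRNA receives a share of
every codon it reads via the normalization n<sub>c</sub>: a tRNA reading
k<sub>i</sub> codons claims 1/k<sub>i</sub>, and claims over a codon are
renormalized to sum to one (a codon contested by a four-codon and a
three-codon reader splits 3/7 : 4/7). The shares are summed into
x<sub>i</sub> (mass-conserving: Σx<sub>i</sub> equals the family total),
and the one-parameter model copies<sub>i</sub> = γ·x<sub>i</sub>² + ε is
fit through the origin, γ̂ = Σx²y / Σx⁴ in closed form. Because a
no-intercept model makes the conventional R² ill-defined (it can go
negative), the default coefficient of determination is the uncentered
1 − Σε²/Σy², which stays in [0, 1]; the centered variant is behind a flag.
tRNAs with zero annotated copies are excluded from the fit; at least two
tRNAs with copies are required. Raw counts (not frequencies) are used —
the ranking is scale-invariant, and counts match the natural axis of the
worked example (58 952 + 35 580 → 94 532 against 11 copies).

## Codon-correlation method (CC)

Consecutive synonymous codons are not independent; codons read by the same
tRNA show positive cross-correlation, visible as block structure in the
matrix X of consecutive-pair counts. Under independence with corpus-wide
within-family frequencies p, each cell is binomial:
E = N·p<sub>i</sub>p<sub>j</sub>, V = N·p<sub>i</sub>p<sub>j</sub>(1 −
p<sub>i</sub>p<sub>j</sub>), and Z = (X − E)/√V. A candidate reading is
scored by s = Σ<sub>i≠j</sub> C<sub>ij</sub>X<sub>ij</sub> with
C<sub>ij</sub> = +1 if codons i and j share at least one reading tRNA and
−1 otherwise; the diagonal (plain codon-repetition bias) is excluded. The
total z-score is (s<sub>obs</sub> − s<sub>exp</sub>)/√(Σ<sub>i≠j</sub>V),
summing cell variances under an independence approximation — the simplest
estimator consistent with the per-cell binomial model, and approximate by
construction. Corpus-wide (not per-gene) frequencies define the
expectation. Choosing "+1 if *any* shared tRNA" (rather than all) means
ties favor broader readings. Degenerate cases — a reading whose blocks
cover every pair, or an empty pair matrix — are flagged rather than
trusted; the method is also structurally weak for two-codon families and
cannot distinguish the hypothetical everything-reads-everything case.

## Significance and consensus

Scores live on incomparable scales, so each family's solution space is
min-max normalized, s<sub>n</sub> = (s − min s)/(max s − min s) (all-equal
spaces map to 0.5 and are flagged). Significance is a Monte-Carlo rank
test: the best plausible score on the real corpus against the best
plausible scores of n randomized corpora (default n = 99), with
p = (r + 1)/(n + 1), ties counted in r. This p is distribution-free and
uniform on its support under an exchangeable null. Randomization preserves
gene structure and run lengths but redraws synonymous codons i.i.d. from
the corpus frequencies (HMM, CC), or redraws family codon counts from a
skew normal moment-matched to the observed count distribution, skewness
clamped to |γ₁| ≤ 0.995, negative draws clamped to zero (REG; the clamping
is needed because moment matching is only defined inside the skew-normal's
admissible skewness range). Cross-method agreement is tallied as a Venn
partition over {HMM, REG, CC} with exact reading identity as the
agreement criterion; expected region counts and two one-sided p-values
per region come from null prediction replicates.

## Synthetic corpora

The simulator is the scoring model run forward: i.i.d. amino acids per
gene (Poisson lengths, floor 50 aa so the default filters pass), and per
family a tRNA Markov chain started from the stationary distribution,
emitting codons uniformly over each state's reading set. The null variant
draws codons i.i.d. from the implied marginal. Corpora are written as DNA
FASTA with terminal stops to exercise the ingestion path. Two presets:
`alanine_example` (two tRNAs, 11 and 5 copies, the exclusive reading
AGC→{GCU,GCC}, UGC→{GCA,GCG}, pure-alanine genes of mean length 60 — the
within-family methods only ever see the family's runs, so single-family
genes lose nothing) and `yeast_like_example` (three families with
yeast-like isoacceptor structure and copy numbers, mean length 150).

What the generator emulates: reuse-correlated synonymous runs, abundance-
linked codon frequencies, filterable FASTA. What it does not: expression-
level heterogeneity, GC gradients, protein-like amino-acid order, and —
deliberately — the quadratic abundance–usage law. The chain ties usage
*linearly* to copy numbers, so REG (which assumes the quadratic law) does
not recover the generator's truth on these corpora: on the 20-replicate
recovery suite HMM and CC recover the true alanine reading in 20/20
corpora while REG prefers a broader overlapping reading in all 20 (its
pinned recovery rate is 0/20). REG's correctness is instead established on
counts constructed from the inverted quadratic model, where the true
reading attains R² = 1. Passing tests therefore show that each method
recovers the structure it models, not that any method is robust to the
full heterogeneity of real genomes.

Problem sizes used by the shipped checks, chosen to give stable margins:
recovery and robustness use 20 (respectively 10) corpora of 1000 genes;
reuse re-estimation uses 2000 genes; the Monte-Carlo significance
recomputation (`scripts/acceptance.py`) uses a 4000-gene corpus scored
with CC, where the real block z (≈12) clears the 99 null maxima (≈3.5) by
a wide margin. The CC statistic is used there because it is standardized:
its real-versus-null separation grows as √N, whereas the HMM's
unstandardized log-likelihood margin at desk scale is smaller than the
spread of the null maximum.

## Numerical and edge-case choices

- Forward/Viterbi in scaled or log space; zero-probability steps yield −∞
  without NaN contamination. Forward agrees with exhaustive path
  enumeration to 1e-12 relative and with an independent HMM library.
- Viterbi ties break toward the lower state index (deterministic).
- Stationary vectors: eigenvector nearest eigenvalue 1, clipped of
  sub-1e-9 negative round-off; reducible chains fall back to the abundance
  vector with a warning.
- Terminal stop codons are stripped before the length check; the 50-aa
  threshold applies to the stop-free amino-acid length. Frameshifts are
  detected as non-triplet length — the only observable proxy in plain
  FASTA. The ≥3-instances rule applies to runs (HMM, CC); REG uses counts
  from all retained genes.
- Duplicate (amino acid, anticodon) rows in tRNA tables are summed;
  modified wobble bases are represented by their unmodified parent, with
  modification identity treated as metadata only, never inferred.
- All randomized procedures are reproducible from (config, seed); outputs
  carry the seed and a config hash.

## Known limitations

The methods detect a *weak* signal: at a few hundred genes the HMM's
Monte-Carlo p-values are unremarkable even when its ranking is correct,
and reliable significance needs corpora in the thousands of genes.
Agreement between HMM and CC is expected — both read the same pair
signal — so their consensus is weaker evidence of correctness than
HMM–REG agreement. Binary readings cannot express unequal decoding
efficiency; abundance is proxied by gene copy number, which ignores
condition-dependent tRNA expression.
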