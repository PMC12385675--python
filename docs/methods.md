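# Methods

## The model

`mdlseq` computes sequence-specific lossless-compression bounds. A string
over a finite alphabet of α symbols is parsed into words by a *parsing
model* — non-overlapping k-mers starting at offset ("phase") p, codon
translation into amino acids, or incremental LZ78 phrases. Each parsing
induces a dictionary Φ of the m *observed* distinct words, with word count
n and empirical frequencies p̂_k = n_k/n, and hence a fitted multinomial of
dimension d = m − 1.

The total description length under Φ is the normalized-maximum-likelihood
(NML, Shtarkov) code length. Exactly,

    L_NML = −log₂ p(x; θ̂(x)) + log₂ C(n, m),
    C(n, m) = Σ_y p(y; θ̂(y))   (the Shtarkov sum),

and asymptotically, for any exponential family with finite root-Fisher
integral,

    L_NML = n·H(θ̂) + (d/2)·log₂(n/2π) + log₂ ∫_Θ |I(θ)|^{1/2} dθ + o(1).

For the multinomial, |I(p)| = 1/Π_k p_k and the Jeffreys integral is
π^{(d+1)/2}/Γ((d+1)/2) (the Dirichlet(½,…,½) normalizer), which collapses
the expansion to the closed form implemented in
`multinomial_complexity_bits`:

    L_NML@Φ = n·H(θ̂) + (d/2)·log₂ n − d/2 − log₂ Γ((d+1)/2) + (1/2)·log₂ π.

All logarithms are base 2; all code lengths are real-valued bits (the
generalized Kraft view — no integer rounding, no actual encoder). The
Bayesian-predictive (mixture) code with a Dirichlet prior has the exact
closed form

    L_mixture = −log₂ [ Γ(A)/Γ(n+A) · Π_k Γ(n_k+α_k)/Γ(α_k) ],  A = Σα_k,

equal word-for-word to one-pass posterior-predictive coding
(`predictive_codelength_sequential`), and the expansion
n·H(θ̂) + (d/2)·log₂(n/2π) + log₂ |I(θ̂)|^{1/2}/w(θ̂); with the Jeffreys
prior it reproduces the NML expansion exactly. The LZ78 bound is
c·log₂ c + c·log₂ α for c phrases.

A model's *compression rate* is L/L_RAW with L_RAW = (symbols actually
covered by the parsing) × log₂ α; phased parsings drop 1–3 symbols, and
the denominator shrinks accordingly. A translated (amino-acid) word stands
for 3 nucleotides, so its denominator is 6 bits per word. Rates ≥ 1 under
every dictionary tried are the operational signature of incompressibility
(randomness); the minimum-rate model is the MDL selection, and for
protein-coding DNA it is the in-frame codon parsing.

## Assumptions and conventions

- Words are modeled as i.i.d. multinomial draws within each parsing; no
  Markov structure. Longer words absorb local dependence at the cost of a
  larger dictionary — exactly the trade-off the bound arbitrates.
- The dictionary is the set of observed words, not all α^k possibilities;
  d = m − 1 throughout. Unseen words carry no parameters.
- Incomplete leading/trailing fragments are dropped, never padded.
- Coordinates are 0-based; phase is an offset; no reverse-complement scan.
- Stop codons are ordinary words ('*') in the amino-acid dictionary, so a
  full-length coding gene yields up to 21 distinct amino-acid words.
- FASTA input is uppercased; any symbol outside the declared alphabet
  (including ambiguity codes such as N) is a hard error with its position.
  There is no principled imputation for N under a counting model, so we
  refuse rather than guess.
- Degenerate cases: a single-word dictionary (d = 0) has entropy 0 and
  complexity exactly 0, reported with a warning — the asymptotic expansion
  is uninformative there. An MLE on the simplex boundary (declared
  super-dictionary with unobserved words) makes the Laplace-type expansion
  invalid; `bayes_expansion` refuses with `BoundaryMLEError` instead of
  extrapolating. The exact closed forms have no such restriction.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| word length k | scan 1–4 (+a.a.) for DNA, 1–9 for binary | dictionary granularity |
| phase p | all phases scanned | reading-frame offset, 0 ≤ p < k |
| Dirichlet concentration | ½ (Jeffreys / KT) | mixture-code prior |
| permutation replicates R | 1000 (CLI), smaller in tests | randomization reference |
| verdict rule | min rate ≥ 1 over scanned lossless models | incompressibility call |

The translated model participates in scans but is excluded from the
randomness verdict by default: translation is many-to-one and therefore
not a lossless description of the nucleotide string. "Min over all
dictionaries" is operationalized as min over the user's scan list.

## Numerical choices

- Every Γ is evaluated through `scipy.special.gammaln`; dictionaries of
  10⁴ words and sequences of 10⁶ words stay finite.
- The exact Shtarkov sum enumerates count vectors (compositions of n into
  m parts) with multinomial weights in log space (`logsumexp`), guarded at
  10⁶ compositions — it is a test oracle, not a production path. Its
  equivalence to full m^n sequence enumeration is itself tested at n ≤ 6.
- Permutation statistics use the sample SD (ddof = 1) and type-1
  (inverted-CDF) empirical quantiles; when a model is permutation-invariant
  (k = 1: counts are order-free) the statistics are returned exactly, with
  SD 0 rather than accumulated float noise.
- The asymptotic and BIC bounds are compared per row: their difference is
  d/2 + log₂ Γ((d+1)/2) − ½·log₂ π, negative at d = 1 and positive from
  d = 2 on, so "BIC overestimates NML" holds only beyond dimension one.
- Verdicts compare the computed real rate with 1; display rounding (tables
  print 4 decimals, with full precision in the JSON companions) never
  affects a verdict.

## Synthetic sources

`simulate` draws i.i.d. categorical strings from numpy's PCG64 generator.
The benchmark condition is a Bernoulli(0.5) binary string of 3000 symbols
scanned at word lengths 1–9 (`replicate_table1`), the regime in which the
NML rate stays just above 1 through word length 8 and may legitimately dip
below 1 at word length 9, where the number of distinct words approaches
the number of words and the o(1) expansion degrades. External reference
values for this benchmark come from a different generator stream, so they
are matched in distribution: a printed single-draw value is compared
against the Monte-Carlo spread of this generator (4 per-draw SDs), never
bit-for-bit.

What the generator does *not* emulate: real coding DNA's codon usage bias,
GC skew, repeats, or any long-range dependence. Passing tests on synthetic
uniform sequences therefore demonstrate the calibration of the bounds
under the null (incompressibility of i.i.d. strings) and the machinery of
frame detection on periodic composites — not performance on genomic data.
Gene-scale tests use synthetic stand-ins of the same length (2907 / 2352
nt, labelled synthetic in fixtures); the entropy columns of real genes are
reproducible only from the actual sequences, which the pipeline accepts as
ordinary FASTA input.

## Problem sizes

Test and benchmark sizes are chosen to keep every exact-oracle comparison
well inside the composition guard: Shtarkov convergence is checked at
n ≤ 500 with m ∈ {2, 3}; Kraft sums at n ≤ 6, m ≤ 3; permutation suites at
20–30 replicates on 600–2352 nt sequences; the fair-coin benchmark at its
native 3000 symbols with 20-seed replicate averages.

## Known limitations

- Only code *lengths* are computed; there is no arithmetic or Huffman
  encoder, so round-trip compression is out of scope by design.
- The o(1) remainder at small n is uncharacterized beyond its empirically
  monotone decay; word lengths where m ≈ n are outside the expansion's
  regime and are reported as such, not corrected.
- Conjugate-mixture expansions are exercised for Dirichlet priors (and the
  Gaussian-mean-on-interval family as a second instance) only.
- No Markov or context-tree sources, no overlapping k-mers, no
  reverse-strand models, no p-values for the randomness verdict —
  permutation quantiles are the inferential summary.
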