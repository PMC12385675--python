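# mdlseq

Sequence-specific lossless-compression bounds for symbol strings, with
applications to randomness testing and reading-frame discovery in DNA.

## The problem

How many bits does it take to describe *this particular* sequence — not a
hypothetical source it came from? Kolmogorov complexity answers that in
principle but is uncomputable; the plug-in entropy n·H(θ̂) of the observed
word frequencies systematically *under*-states the cost because it charges
nothing for describing the fitted model. `mdlseq` computes the
normalized-maximum-likelihood (NML) code length, which is minimax-optimal
over all coding distributions and adds the exact model cost:

    L_NML@Φ = n·H(θ̂) + (d/2)·log₂ n − d/2 − log₂ Γ((d+1)/2) + (½)·log₂ π

for a dictionary Φ of m observed words (d = m − 1, all logs base 2). This
is the multinomial instance of the general exponential-family expansion

    L_NML = n·H(θ̂) + (d/2)·log₂(n/2π) + log₂ ∫_Θ |I(θ)|^{1/2} dθ + o(1),

and it is attained in one pass by Bayesian predictive coding with the
Jeffreys (Dirichlet-½, Krichevsky–Trofimov) prior — both routes are
implemented and agree to 10⁻⁹ bits.

Dividing by the raw length (symbols × log₂ alphabet) gives a compression
rate per parsing model. Rates ≥ 1 under every dictionary tried mean the
sequence is incompressible — consistent with randomness. A rate well below
1 under one dictionary is discovered structure, and the minimum-rate model
is the MDL (minimum-description-length) selection: for protein-coding DNA
it is the in-frame codon parsing, so the scan rediscovers the reading
frame from a single gene.

Intended users: anyone asking "is this sequence random?" or "which
word-level description of this sequence is most economical?" — from
bioinformatics (codon structure, ORF phase) to RNG auditing.

## Worked example: rediscovering the reading frame

```python
import numpy as np
from mdlseq import (SymbolSequence, model_scan, randomness_verdict,
                    standard_dna_models)

rng = np.random.default_rng(55)
codons = ["ATG", "GCA", "GAA", "AAA", "CTG", "GAT", "CGT", "TTT"]
seq = SymbolSequence.dna("".join(rng.choice(codons, size=969)))  # 2907 nt

reports = model_scan(seq, standard_dna_models())
for r in reports:
    print(f"{r.label}\t{r.n}\t{r.m}\t{r.total_bits:.2f}\t{r.rate:.4f}"
          + ("\t<- MDL" if r.minimum else ""))
print(randomness_verdict(reports))
```

Output (columns: model, words n, dictionary m, total bits, rate):

```
1       2907    4     5650.49   0.9719
2.0     1453    15    5436.22   0.9353
2.1     1453    15    5435.17   0.9352
3.0     969     8     2931.79   0.5043  <- MDL
3.1     968     24    4315.47   0.7430
3.2     968     21    4246.73   0.7312
4.0     726     83    4646.49   0.8000
4.1     726     85    4680.86   0.8059
4.2     726     85    4679.44   0.8057
4.3     726     85    4681.91   0.8061
a.a.    969     8     2931.79   0.5043
RandomnessVerdict(min_rate=0.504..., model_label='3.0',
                  consistent_with_random=False)
```

The sequence was built from in-frame codons, and only model 3.0 — triplets
at phase 0 — sees that structure: its rate drops to 0.50 while every
mis-phased or wrong-length parsing stays near or above the single-symbol
baseline. The verdict is "not random", with the codon model as the MDL
selection. On a genuinely random uniform DNA string the same scan returns
rates clustered just around 1.

The same workflow runs from the shell:

```sh
mdlseq rates gene.fa --out rates.tsv          # model scan table
mdlseq verdict gene.fa                        # incompressibility call
mdlseq permute gene.fa -R 1000 --seed 3 --out perm.tsv   # permutation reference
mdlseq simulate --seed 7 --out coin.tsv       # fair-coin benchmark
```

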