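"""Seeded synthetic sources: i.i.d. categorical strings and the
fair-coin benchmark scan.

The default conditions mirror the randomness benchmark the package is
calibrated against: a Bernoulli(0.5) binary string of 3000 symbols scanned
at word lengths 1-9.  Generation uses numpy's PCG64 generator, so results
are reproducible given a seed but are matched to any external run only in
distribution, never stream-for-stream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .parsing import ParsingModel, SymbolSequence
from .randomness import evaluate_model

TABLE1_LENGTH = 3000
TABLE1_P = (0.5, 0.5)


@dataclass(frozen=True)
class SourceSpec:
    """An i.i.d. categorical source: alphabet, probabilities, length, seed."""

    alphabet: tuple[str, ...]
    p: tuple[float, ...]
    length: int
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.alphabet) != len(self.p):
            raise ValueError("alphabet and probability vector differ in length")
        p = np.asarray(self.p, dtype=float)
        if np.any(p < 0) or not np.isclose(p.sum(), 1.0, atol=1e-9):
            raise ValueError("probabilities must be non-negative and sum to 1")
        if self.length < 0:
            raise ValueError("length must be >= 0")

    @classmethod
    def fair_coin(cls, length: int = TABLE1_LENGTH, seed: int = 0) -> "SourceSpec":
        return cls(("0", "1"), TABLE1_P, length, seed)

    @classmethod
    def uniform_dna(cls, length: int, seed: int = 0) -> "SourceSpec":
        return cls(tuple("ACGT"), (0.25,) * 4, length, seed)


def iid_string(spec: SourceSpec) -> SymbolSequence:
    """Draw spec.length i.i.d. symbols; deterministic given spec.seed."""
    rng = np.random.default_rng(spec.seed)
    draws = rng.choice(list(spec.alphabet), size=spec.length, p=list(spec.p))
    return SymbolSequence("".join(draws), frozenset(spec.alphabet))


def replicate_table1(
    seed: int,
    length: int = TABLE1_LENGTH,
    max_word_length: int = 9,
) -> pd.DataFrame:
    """Scan one fair-coin string at word lengths 1..max_word_length.

    Returns a frame with, per word length, the word count n, dictionary
    size m, and the compression rate under the three nested bounds: bare
    plug-in entropy, entropy + (d/2)log2 n (BIC), and the full NML bound.
    """
    seq = iid_string(SourceSpec.fair_coin(length, seed))
    rows = []
    for k in range(1, max_word_length + 1):
        model = ParsingModel(kind="fixed", k=k, phase=0, label=str(k))
        by_method = {
            meth: evaluate_model(seq, model, method=meth)
            for meth in ("entropy", "bic", "nml")
        }
        r = by_method["nml"]
        rows.append(
            {
                "word_length": k,
                "n": r.n,
                "m": r.m,
                "rate_entropy": by_method["entropy"].rate,
                "rate_bic": by_method["bic"].rate,
                "rate_nml": r.rate,
            }
        )
    return pd.DataFrame(rows)


def write_fasta(seq: SymbolSequence, path, record_id: str = "synthetic") -> None:
    """Emit a sequence as single-record FASTA (fixture writer for round trips)."""
    with open(path, "w") as fh:
        fh.write(f">{record_id}\n")
        s = seq.symbols
        for i in range(0, len(s), 70):
            fh.write(s[i : i + 70] + "\n")
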