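"""Parsing of symbol strings into word sequences and word counts.

A compression model is induced by the way a string is parsed: fixed-length
non-overlapping k-mers at a chosen phase, codon translation into amino
acids, or incremental LZ78 phrases.  The resulting dictionary holds the
*observed* words only; its size m (and the model dimension d = m - 1) is
what the code-length machinery downstream consumes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from Bio.Seq import Seq

DNA_ALPHABET = frozenset("ACGT")
BINARY_ALPHABET = frozenset("01")


@dataclass(frozen=True)
class SymbolSequence:
    """A validated string over a declared finite alphabet.

    Symbols are normalized to uppercase.  Any symbol outside the declared
    alphabet is a hard error naming its (0-based) position: ambiguity codes
    such as N are rejected rather than guessed at.
    """

    symbols: str
    alphabet: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "symbols", self.symbols.upper())
        object.__setattr__(
            self, "alphabet", frozenset(a.upper() for a in self.alphabet)
        )
        if len(self.alphabet) < 2:
            raise ValueError("alphabet must contain at least 2 symbols")
        for i, s in enumerate(self.symbols):
            if s not in self.alphabet:
                raise ValueError(
                    f"symbol {s!r} at position {i} not in declared alphabet"
                )

    @classmethod
    def dna(cls, symbols: str) -> "SymbolSequence":
        return cls(symbols, DNA_ALPHABET)

    @classmethod
    def binary(cls, symbols: str) -> "SymbolSequence":
        return cls(symbols, BINARY_ALPHABET)

    @property
    def alphabet_size(self) -> int:
        return len(self.alphabet)

    def __len__(self) -> int:
        return len(self.symbols)

    def is_dna(self) -> bool:
        return self.alphabet <= DNA_ALPHABET


@dataclass(frozen=True)
class ParsingModel:
    """How a sequence becomes words.

    ``kind`` is one of ``fixed`` (non-overlapping k-mers), ``translate``
    (codons to amino acids; forces k = 3) or ``lz78``.  ``phase`` is the
    0-based offset at which parsing starts; for DNA triplets it is the
    reading frame.  Labels follow the ``k.phase`` convention ("2.0", "3.1");
    "1" is single-symbol parsing and "aa" selects translation.
    """

    kind: str
    k: int = 1
    phase: int = 0
    label: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("fixed", "translate", "lz78"):
            raise ValueError(f"unknown parsing kind {self.kind!r}")
        if self.kind == "translate" and self.k != 3:
            raise ValueError("translation parses triplets: k must be 3")
        if self.kind != "lz78":
            if self.k < 1:
                raise ValueError("word length k must be positive")
            if not 0 <= self.phase < self.k:
                raise ValueError(f"phase {self.phase} must lie in [0, {self.k})")
        if not self.label:
            object.__setattr__(self, "label", self._default_label())

    def _default_label(self) -> str:
        if self.kind == "lz78":
            return "lz78"
        if self.kind == "translate":
            return "a.a." if self.phase == 0 else f"a.a.{self.phase}"
        if self.k == 1:
            return "1"
        return f"{self.k}.{self.phase}"

    @classmethod
    def from_label(cls, label: str) -> "ParsingModel":
        """Parse a model label like "1", "3.1", "aa", "a.a.", "lz78"."""
        text = label.strip().lower().replace(" ", "")
        if text == "lz78":
            return cls(kind="lz78", label=label.strip())
        if text in ("aa", "a.a.", "a.a"):
            return cls(kind="translate", k=3, phase=0, label="a.a.")
        if text.startswith("aa."):
            return cls(kind="translate", k=3, phase=int(text[3:]), label=label.strip())
        parts = text.split(".")
        k = int(parts[0])
        phase = int(parts[1]) if len(parts) > 1 else 0
        return cls(kind="fixed", k=k, phase=phase, label=label.strip())


@dataclass(frozen=True)
class WordSequence:
    """An ordered list of words plus the raw-symbol span they describe."""

    words: tuple[str, ...]
    encoded_symbols: int

    def __len__(self) -> int:
        return len(self.words)


@dataclass(frozen=True)
class WordCounts:
    """Observed word frequencies: word -> count, in lexicographic order.

    n is the total number of words, m the number of distinct words, and
    d = m - 1 the dimension of the induced multinomial model.
    """

    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ordered = {w: self.counts[w] for w in sorted(self.counts)}
        if any(c < 1 for c in ordered.values()):
            raise ValueError("only observed words (count >= 1) are stored")
        object.__setattr__(self, "counts", ordered)

    @classmethod
    def from_vector(cls, counts, prefix: str = "w") -> "WordCounts":
        """Build counts from a bare count vector with synthetic word labels."""
        width = len(str(len(counts)))
        return cls({f"{prefix}{i:0{width}d}": int(c) for i, c in enumerate(counts)})

    @property
    def n(self) -> int:
        return sum(self.counts.values())

    @property
    def m(self) -> int:
        return len(self.counts)

    @property
    def d(self) -> int:
        return max(self.m - 1, 0)


def parse_fixed_length(seq: SymbolSequence, k: int, phase: int = 0) -> WordSequence:
    """Split ``seq`` into consecutive non-overlapping k-mers from ``phase``.

    The leading ``phase`` symbols and any trailing fragment shorter than k
    are dropped, so the number of words is floor((S - phase) / k).
    """
    if k < 1:
        raise ValueError("word length k must be positive")
    if not 0 <= phase < k:
        raise ValueError(f"phase {phase} must lie in [0, {k})")
    s = seq.symbols
    n_words = max((len(s) - phase) // k, 0)
    words = tuple(s[phase + i * k : phase + (i + 1) * k] for i in range(n_words))
    return WordSequence(words=words, encoded_symbols=k * n_words)


def translate_codons(seq: SymbolSequence, phase: int = 0) -> WordSequence:
    """Translate complete DNA triplets from ``phase`` into amino-acid words.

    Uses the standard genetic code; stop codons become the distinct word
    '*'.  Each amino-acid word stands for 3 nucleotides of the original
    string, which is what ``encoded_symbols`` records.
    """
    if not seq.is_dna():
        raise ValueError("codon translation requires a DNA (ACGT) alphabet")
    if not 0 <= phase < 3:
        raise ValueError(f"phase {phase} must lie in [0, 3)")
    n_cod = (len(seq) - phase) // 3
    region = seq.symbols[phase : phase + 3 * n_cod]
    aa = str(Seq(region).translate())
    return WordSequence(words=tuple(aa), encoded_symbols=3 * n_cod)


def lz78_phrases(seq: SymbolSequence) -> list[str]:
    """Incremental LZ78 parsing into phrases.

    Each phrase is the shortest prefix of the remaining input not yet in
    the dictionary, i.e. a previously seen phrase extended by one symbol.
    A final incomplete phrase (a duplicate of an earlier one) still counts.
    """
    phrases: list[str] = []
    seen: set[str] = set()
    s = seq.symbols
    i = 0
    while i < len(s):
        j = i + 1
        while j <= len(s) and s[i:j] in seen:
            j += 1
        phrase = s[i:j]  # if we ran off the end this duplicates an entry
        phrases.append(phrase)
        seen.add(phrase)
        i = j
    return phrases


def count_words(ws: WordSequence) -> WordCounts:
    """Tally observed word frequencies; empty input yields n = m = 0."""
    if not ws.words:
        warnings.warn("empty word sequence: n = 0, downstream code lengths "
                      "will reject it", stacklevel=2)
        return WordCounts({})
    counts: dict[str, int] = {}
    for w in ws.words:
        counts[w] = counts.get(w, 0) + 1
    return WordCounts(counts)
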