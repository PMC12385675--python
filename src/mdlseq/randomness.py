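"""Compression rates, dictionary scans, permutation references, verdicts.

A sequence is judged against its own raw description length: rate =
total_bits / raw_bits with raw_bits = encoded_symbols * log2(alphabet).
Rates at or above 1 under every dictionary tried are the operational
signature of randomness (incompressibility); a rate well below 1 under one
dictionary — e.g. the in-frame codon parsing of a protein-coding gene — is
discovered structure, and the minimum-rate model is the MDL selection.
Permuting the symbols and re-scanning yields the reference distribution
against which an observed rate is judged.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .codelength import (
    CodeLengthBreakdown,
    DirichletPrior,
    bic_codelength,
    empirical_entropy,
    entropy_codelength,
    lz78_codelength,
    mixture_codelength_dirichlet,
    nml_codelength_multinomial,
)
from .parsing import (
    ParsingModel,
    SymbolSequence,
    count_words,
    lz78_phrases,
    parse_fixed_length,
    translate_codons,
)

METHODS = ("nml", "bic", "entropy", "mixture", "lz78")


@dataclass(frozen=True)
class RateReport:
    """One row of a dictionary scan: code-length breakdown and rate."""

    label: str
    kind: str
    n: int
    m: int
    entropy_per_word: float
    entropy_bits: float
    complexity_bits: float
    total_bits: float
    raw_bits: float
    rate: float
    minimum: bool = False


@dataclass(frozen=True)
class ModelPermStats:
    """Permutation statistics of the compression rate for one model."""

    mean: float
    sd: float
    q01: float
    q99: float


@dataclass(frozen=True)
class PermutationSummary:
    """Per-method, per-model rate statistics over R symbol permutations."""

    replicates: int
    seed: int
    stats: dict[str, dict[str, ModelPermStats]] = field(default_factory=dict)


@dataclass(frozen=True)
class RandomnessVerdict:
    min_rate: float
    model_label: str
    consistent_with_random: bool


def raw_bits(encoded_symbols: int, alphabet_size: int) -> float:
    """Theoretical raw length of the covered symbols: count * log2(alpha)."""
    if alphabet_size < 2:
        raise ValueError("alphabet size must be >= 2")
    return encoded_symbols * math.log2(alphabet_size)


def compression_rate(total_bits: float, raw: float) -> float:
    if raw <= 0:
        raise ValueError("raw bit length must be positive")
    return total_bits / raw


def _breakdown(wc, method: str, prior_concentration: float) -> CodeLengthBreakdown:
    if method == "nml":
        return nml_codelength_multinomial(wc)
    if method == "bic":
        return bic_codelength(wc)
    if method == "entropy":
        return entropy_codelength(wc)
    if method == "mixture":
        prior = DirichletPrior.symmetric(wc.m, prior_concentration)
        return mixture_codelength_dirichlet(wc, prior)
    raise ValueError(f"unknown code-length method {method!r}")


def evaluate_model(
    seq: SymbolSequence,
    model: ParsingModel,
    method: str = "nml",
    prior_concentration: float = 0.5,
) -> RateReport:
    """Parse under one model, compute the chosen bound and its rate.

    The rate denominator covers only the symbols the model actually
    describes (phased parsings drop a leading/trailing fragment); for the
    translated model each amino-acid word stands for 3 nucleotides.
    """
    if model.kind == "lz78":
        phrases = lz78_phrases(seq)
        c = len(phrases)
        bits = lz78_codelength(c, seq.alphabet_size)
        raw = raw_bits(len(seq), seq.alphabet_size)
        return RateReport(
            label=model.label, kind="lz78", n=c, m=len(set(phrases)),
            entropy_per_word=float("nan"), entropy_bits=0.0,
            complexity_bits=bits, total_bits=bits, raw_bits=raw,
            rate=compression_rate(bits, raw),
        )
    if model.kind == "translate":
        ws = translate_codons(seq, model.phase)
        alpha = 4
    else:
        ws = parse_fixed_length(seq, model.k, model.phase)
        alpha = seq.alphabet_size
    wc = count_words(ws)
    bd = _breakdown(wc, method, prior_concentration)
    raw = raw_bits(ws.encoded_symbols, alpha)
    return RateReport(
        label=model.label, kind=model.kind, n=wc.n, m=wc.m,
        entropy_per_word=empirical_entropy(wc),
        entropy_bits=bd.entropy_bits, complexity_bits=bd.complexity_bits,
        total_bits=bd.total_bits, raw_bits=raw,
        rate=compression_rate(bd.total_bits, raw),
    )


def model_scan(
    seq: SymbolSequence,
    models: list[ParsingModel],
    method: str = "nml",
    prior_concentration: float = 0.5,
) -> list[RateReport]:
    """One RateReport per applicable model, sorted by label; the
    minimum-rate row (the MDL selection) is flagged."""
    if not models:
        raise ValueError("model list must be non-empty")
    reports: list[RateReport] = []
    for model in models:
        if model.kind == "translate" and not seq.is_dna():
            warnings.warn(
                f"model {model.label!r} needs a DNA alphabet; skipped",
                stacklevel=2,
            )
            continue
        reports.append(evaluate_model(seq, model, method, prior_concentration))
    reports.sort(key=lambda r: r.label)
    if reports:
        i_min = min(range(len(reports)), key=lambda i: reports[i].rate)
        reports[i_min] = replace(reports[i_min], minimum=True)
    return reports


def permutation_test(
    seq: SymbolSequence,
    models: list[ParsingModel],
    replicates: int = 1000,
    seed: int = 0,
    methods: tuple[str, ...] = ("nml", "entropy", "bic"),
) -> PermutationSummary:
    """Randomization reference: permute the symbols R times and re-scan.

    For each method and model, reports mean, sample SD and the empirical
    1%/99% quantiles (type-1 order statistics) of the compression rate.
    Single-symbol parsing is permutation-invariant, so its SD is exactly 0.
    """
    if replicates < 1:
        raise ValueError("need at least one permutation replicate")
    rng = np.random.default_rng(seed)
    symbols = np.array(list(seq.symbols))
    rates: dict[str, dict[str, list[float]]] = {
        meth: {m.label: [] for m in models} for meth in methods
    }
    for _ in range(replicates):
        perm = SymbolSequence("".join(rng.permutation(symbols)), seq.alphabet)
        for meth in methods:
            for model in models:
                r = evaluate_model(perm, model, meth)
                rates[meth][model.label].append(r.rate)
    stats: dict[str, dict[str, ModelPermStats]] = {}
    for meth in methods:
        stats[meth] = {}
        for model in models:
            x = np.array(rates[meth][model.label])
            if np.all(x == x[0]):
                # permutation-invariant model (e.g. k = 1): exact statistics
                st = ModelPermStats(mean=float(x[0]), sd=0.0,
                                    q01=float(x[0]), q99=float(x[0]))
            else:
                st = ModelPermStats(
                    mean=float(x.mean()),
                    sd=float(x.std(ddof=1)),
                    q01=float(np.quantile(x, 0.01, method="inverted_cdf")),
                    q99=float(np.quantile(x, 0.99, method="inverted_cdf")),
                )
            stats[meth][model.label] = st
    return PermutationSummary(replicates=replicates, seed=seed, stats=stats)


def randomness_verdict(
    reports: list[RateReport], include_translated: bool = False
) -> RandomnessVerdict:
    """Incompressibility verdict over the scanned dictionaries.

    consistent-with-random iff the minimum rate is >= 1 (on the computed
    real value, not its display rounding).  Translated (amino-acid) rows
    are excluded by default: translation is not a lossless description of
    the nucleotide sequence.
    """
    if not reports:
        raise ValueError("need at least one rate report")
    eligible = [
        r for r in reports if include_translated or r.kind != "translate"
    ]
    if not eligible:
        raise ValueError("no lossless models among the reports")
    best = min(eligible, key=lambda r: r.rate)
    return RandomnessVerdict(
        min_rate=float(best.rate),
        model_label=best.label,
        consistent_with_random=bool(best.rate >= 1.0),
    )


def standard_dna_models(max_k: int = 4, include_translate: bool = True) -> list[ParsingModel]:
    """The usual scan list: every phase of word lengths 1..max_k, plus the
    amino-acid translation model."""
    models = [
        ParsingModel.from_label("1" if k == 1 else f"{k}.{p}")
        for k in range(1, max_k + 1)
        for p in range(k if k > 1 else 1)
    ]
    if include_translate:
        models.append(ParsingModel.from_label("a.a."))
    return models
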