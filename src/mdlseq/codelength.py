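"""Code-length mathematics for lossless compression bounds.

All quantities are in bits (base-2 logarithms throughout).  The central
object is the multinomial normalized-maximum-likelihood (NML) code length

    L_NML = n H(theta_hat) + (d/2) log2 n - d/2 - log2 Gamma((d+1)/2)
            + (1/2) log2 pi,

where n is the word count, d = m - 1 the dimension of the multinomial over
the m observed words, and H(theta_hat) the empirical (plug-in) entropy per
word.  This is the Jeffreys-prior instance of the generic exponential-family
expansion

    L_NML = n H(theta_hat) + (d/2) log2(n / 2 pi)
            + log2 integral |I(theta)|^(1/2) dtheta + o(1),

whose Bayesian-predictive counterpart replaces the Fisher integral by
log2 |I(theta_hat)|^(1/2) / w(theta_hat) for a conjugate prior w.  The
exact Shtarkov normalizer is provided as a brute-force oracle at small
problem sizes, and the LZ78 phrase-count length closes the set of bounds.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.special import comb, gammaln, logsumexp

from .parsing import WordCounts, WordSequence

LN2 = math.log(2.0)
LOG2_PI = math.log2(math.pi)
LOG2_2PI = math.log2(2.0 * math.pi)

#: guard for the exact Shtarkov enumeration (number of count vectors)
_SHTARKOV_MAX_COMPOSITIONS = 1_000_000


class BoundaryMLEError(ValueError):
    """The MLE sits on the simplex boundary; the Laplace-type expansion of
    the Bayesian predictive code length is not valid there."""


@dataclass(frozen=True)
class CodeLengthBreakdown:
    """A code length split into its data term and its model-cost term.

    entropy_bits is n.H(theta_hat); complexity_bits collects every other
    term of the bound (the parametric / stochastic complexity).
    """

    entropy_bits: float
    complexity_bits: float
    method: str

    @property
    def total_bits(self) -> float:
        return self.entropy_bits + self.complexity_bits


@dataclass(frozen=True)
class DirichletPrior:
    """Dirichlet(alpha_1, ..., alpha_m) prior on the word-probability simplex.

    The Jeffreys prior for the multinomial is the symmetric case with all
    concentrations 1/2 (the Krichevsky-Trofimov assignment).
    """

    alphas: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "alphas", tuple(float(a) for a in self.alphas))
        if any(a <= 0 for a in self.alphas):
            raise ValueError("all Dirichlet concentrations must be positive")

    @classmethod
    def jeffreys(cls, m: int) -> "DirichletPrior":
        return cls((0.5,) * m)

    @classmethod
    def symmetric(cls, m: int, alpha: float) -> "DirichletPrior":
        return cls((alpha,) * m)

    @property
    def m(self) -> int:
        return len(self.alphas)

    @property
    def total(self) -> float:
        return sum(self.alphas)

    def log2_pdf(self, p: Sequence[float]) -> float:
        """log2 of the Dirichlet density at a point of the open simplex."""
        p = np.asarray(p, dtype=float)
        if p.shape != (self.m,):
            raise ValueError("point dimension must match prior dimension")
        if np.any(p <= 0):
            raise BoundaryMLEError("Dirichlet density requested on the boundary")
        a = np.asarray(self.alphas)
        ln = gammaln(self.total) - gammaln(a).sum() + ((a - 1.0) * np.log(p)).sum()
        return ln / LN2


@dataclass(frozen=True)
class ExponentialFamilySpec:
    """Ingredients of the NML / Bayes expansions for one exponential family.

    dimension d; the per-word entropy at the MLE; the (finite) base-2 log
    of the integrated root-Fisher determinant over the parameter space; the
    local root-Fisher determinant at the MLE; and optionally a prior density
    at the MLE, all on the log2 scale.
    """

    dimension: int
    entropy_at_mle: Callable[[WordCounts], float]
    log2_fisher_sqrt_integral: float
    log2_fisher_sqrt_at: Callable[[Sequence[float]], float]
    log2_prior_at: Optional[Callable[[Sequence[float]], float]] = None

    def __post_init__(self) -> None:
        if self.dimension < 1:
            raise ValueError("dimension must be >= 1")
        if not math.isfinite(self.log2_fisher_sqrt_integral):
            raise ValueError(
                "integrated root-Fisher term must be finite; restrict the "
                "parameter space to a compact subset"
            )


def empirical_entropy(wc: WordCounts) -> float:
    """Plug-in entropy H(theta_hat) = -sum p_k log2 p_k in bits per word."""
    if wc.n == 0:
        raise ValueError("entropy of an empty word sequence is undefined")
    counts = np.fromiter(wc.counts.values(), dtype=float)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def multinomial_complexity_bits(n: int, m: int) -> float:
    """Complexity (non-entropy) terms of the multinomial NML code length.

    (d/2) log2 n - d/2 - log2 Gamma((d+1)/2) + (1/2) log2 pi with d = m-1,
    evaluated via log-gamma so large dictionaries do not overflow.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if m < 1:
        raise ValueError("m must be >= 1")
    d = m - 1
    if d == 0:
        warnings.warn(
            "single-word dictionary (d = 0): complexity is exactly 0 and the "
            "asymptotic expansion is uninformative",
            stacklevel=2,
        )
        return 0.0
    return (
        0.5 * d * math.log2(n)
        - 0.5 * d
        - gammaln((d + 1) / 2.0) / LN2
        + 0.5 * LOG2_PI
    )


def nml_codelength_multinomial(wc: WordCounts) -> CodeLengthBreakdown:
    """Multinomial NML (stochastic-complexity) code length of the counts."""
    h = empirical_entropy(wc)
    return CodeLengthBreakdown(
        entropy_bits=wc.n * h,
        complexity_bits=multinomial_complexity_bits(wc.n, wc.m),
        method="nml_asym",
    )


def bic_codelength(wc: WordCounts) -> CodeLengthBreakdown:
    """Two-part / BIC-style bound: n.H(theta_hat) + (d/2) log2 n."""
    h = empirical_entropy(wc)
    return CodeLengthBreakdown(
        entropy_bits=wc.n * h,
        complexity_bits=0.5 * wc.d * math.log2(wc.n),
        method="bic",
    )


def entropy_codelength(wc: WordCounts) -> CodeLengthBreakdown:
    """Bare plug-in bound n.H(theta_hat) with no model cost."""
    return CodeLengthBreakdown(
        entropy_bits=wc.n * empirical_entropy(wc),
        complexity_bits=0.0,
        method="entropy_only",
    )


def fisher_det_multinomial(p: Sequence[float]) -> float:
    """Determinant of the multinomial Fisher information: 1 / prod_k p_k."""
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0):
        raise ValueError("all probabilities must be strictly positive")
    if not math.isclose(float(p.sum()), 1.0, rel_tol=0, abs_tol=1e-9):
        raise ValueError("probabilities must sum to 1")
    return float(np.exp(-np.log(p).sum()))


def jeffreys_log_integral_multinomial(d: int) -> float:
    """log2 of the root-Fisher integral over the d-simplex.

    Equals log2( pi^((d+1)/2) / Gamma((d+1)/2) ), the normalizer of the
    Dirichlet(1/2, ..., 1/2) distribution on d+1 categories.
    """
    if d < 1:
        raise ValueError("d must be >= 1")
    return 0.5 * (d + 1) * LOG2_PI - gammaln((d + 1) / 2.0) / LN2


def multinomial_family(m: int) -> ExponentialFamilySpec:
    """The multinomial exponential-family spec on m observed categories."""
    d = m - 1

    def _fisher_sqrt_at(p: Sequence[float]) -> float:
        return 0.5 * math.log2(fisher_det_multinomial(p))

    def _jeffreys_at(p: Sequence[float]) -> float:
        return DirichletPrior.jeffreys(m).log2_pdf(p)

    return ExponentialFamilySpec(
        dimension=d,
        entropy_at_mle=empirical_entropy,
        log2_fisher_sqrt_integral=jeffreys_log_integral_multinomial(d),
        log2_fisher_sqrt_at=_fisher_sqrt_at,
        log2_prior_at=_jeffreys_at,
    )


def gaussian_mean_family(half_width: float, sigma: float = 1.0) -> ExponentialFamilySpec:
    """Gaussian mean on the compact interval [-a, a] with known sigma.

    |I(mu)| = 1/sigma^2, so the root-Fisher integral is 2a/sigma.  The
    per-word term is the differential entropy (1/2) log2(2 pi e sigma^2),
    independent of the fitted mean.
    """
    if half_width <= 0 or sigma <= 0:
        raise ValueError("half_width and sigma must be positive")
    h = 0.5 * math.log2(2.0 * math.pi * math.e * sigma**2)
    return ExponentialFamilySpec(
        dimension=1,
        entropy_at_mle=lambda wc: h,
        log2_fisher_sqrt_integral=math.log2(2.0 * half_width / sigma),
        log2_fisher_sqrt_at=lambda theta: -math.log2(sigma),
        log2_prior_at=lambda theta: -math.log2(2.0 * half_width),  # uniform
    )


def nml_parametric_expansion(
    spec: ExponentialFamilySpec, wc: WordCounts
) -> CodeLengthBreakdown:
    """Generic asymptotic NML length for any exponential-family spec.

    complexity = (d/2) log2(n / 2 pi) + log2 integral |I|^(1/2).
    """
    if wc.n < 1:
        raise ValueError("n must be >= 1")
    complexity = (
        0.5 * spec.dimension * (math.log2(wc.n) - LOG2_2PI)
        + spec.log2_fisher_sqrt_integral
    )
    return CodeLengthBreakdown(
        entropy_bits=wc.n * spec.entropy_at_mle(wc),
        complexity_bits=complexity,
        method="nml_asym",
    )


def mixture_codelength_dirichlet(
    wc: WordCounts,
    prior: DirichletPrior,
    support: Optional[Sequence[str]] = None,
) -> CodeLengthBreakdown:
    """Closed-form Dirichlet-multinomial mixture code length.

    total = -log2[ Gamma(A)/Gamma(n+A) * prod_k Gamma(n_k+a_k)/Gamma(a_k) ],
    the marginal probability of the observed word sequence (any order) under
    the prior.  ``support`` may declare a super-dictionary containing all
    observed words; by default the prior lives on the observed words in
    lexicographic order.
    """
    if wc.n == 0:
        raise ValueError("cannot encode an empty word sequence")
    if support is None:
        support = list(wc.counts)
    if len(support) != prior.m:
        raise ValueError("prior dimension must match the (super-)dictionary")
    missing = set(wc.counts) - set(support)
    if missing:
        raise ValueError(f"observed words outside prior support: {sorted(missing)}")
    counts = np.array([wc.counts.get(w, 0) for w in support], dtype=float)
    a = np.asarray(prior.alphas)
    ln_marginal = (
        gammaln(prior.total)
        - gammaln(wc.n + prior.total)
        + (gammaln(counts + a) - gammaln(a)).sum()
    )
    total = -ln_marginal / LN2
    h = empirical_entropy(wc)
    return CodeLengthBreakdown(
        entropy_bits=wc.n * h,
        complexity_bits=total - wc.n * h,
        method="mixture",
    )


def predictive_codelength_sequential(
    ws: WordSequence,
    prior: DirichletPrior,
    support: Optional[Sequence[str]] = None,
) -> float:
    """One-pass Bayesian predictive code length in bits.

    Each word is encoded with the current posterior-predictive probability
    (count_so_far + alpha) / (i + A), then the posterior is updated.  By
    exchangeability this equals the closed-form mixture length exactly.
    """
    if not ws.words:
        raise ValueError("cannot encode an empty word sequence")
    if support is None:
        support = sorted(set(ws.words))
    if len(support) != prior.m:
        raise ValueError("prior dimension must match the (super-)dictionary")
    index = {w: i for i, w in enumerate(support)}
    counts = np.zeros(prior.m)
    a = np.asarray(prior.alphas)
    total_bits = 0.0
    for i, w in enumerate(ws.words):
        try:
            k = index[w]
        except KeyError:
            raise ValueError(f"word {w!r} outside prior support") from None
        q = (counts[k] + a[k]) / (i + prior.total)
        total_bits -= math.log2(q)
        counts[k] += 1
    return total_bits


def bayes_expansion(
    spec: ExponentialFamilySpec,
    wc: WordCounts,
    log2_prior_at_mle: Optional[float] = None,
    support_size: Optional[int] = None,
) -> CodeLengthBreakdown:
    """Asymptotic Bayesian-predictive (mixture) code length.

    complexity = (d/2) log2(n / 2 pi) + log2 |I(theta_hat)|^(1/2)
                 - log2 w(theta_hat).

    Requires an interior MLE: if the declared super-dictionary has more
    categories than were observed, some frequency is 0 and the expansion is
    refused rather than extrapolated.
    """
    if wc.n < 1:
        raise ValueError("n must be >= 1")
    if support_size is not None and support_size > wc.m:
        raise BoundaryMLEError(
            f"{support_size - wc.m} categories of the declared dictionary are "
            "unobserved: the MLE is on the boundary"
        )
    p_hat = np.fromiter(wc.counts.values(), dtype=float)
    p_hat /= p_hat.sum()
    if log2_prior_at_mle is None:
        if spec.log2_prior_at is None:
            raise ValueError("no prior supplied and spec has no default prior")
        log2_prior_at_mle = spec.log2_prior_at(p_hat)
    complexity = (
        0.5 * spec.dimension * (math.log2(wc.n) - LOG2_2PI)
        + spec.log2_fisher_sqrt_at(p_hat)
        - log2_prior_at_mle
    )
    return CodeLengthBreakdown(
        entropy_bits=wc.n * spec.entropy_at_mle(wc),
        complexity_bits=complexity,
        method="mixture",
    )


def shtarkov_normalizer_exact(n: int, m: int) -> float:
    """log2 of the exact Shtarkov sum C(n, m) for the multinomial family.

    C(n, m) = sum over count vectors (n_1..n_m) summing to n of
    multinomial(n; n_1..n_m) * prod_k (n_k/n)^(n_k).  Enumeration over
    compositions (not over the m^n sequences) with a hard size guard; this
    is a test oracle, not a production code length.
    """
    if n < 1 or m < 1:
        raise ValueError("n and m must be >= 1")
    n_comp = comb(n + m - 1, m - 1, exact=True)
    if n_comp > _SHTARKOV_MAX_COMPOSITIONS:
        raise ValueError(
            f"{n_comp} compositions exceeds the exact-enumeration guard "
            f"({_SHTARKOV_MAX_COMPOSITIONS}); this oracle is for small n, m"
        )
    lg = gammaln(np.arange(n + 2) + 1.0)  # lg[i] = ln Gamma(i+1) = ln i!
    with np.errstate(divide="ignore", invalid="ignore"):
        xlx = np.arange(n + 1) * np.log(np.arange(n + 1) / n)
    xlx[0] = 0.0
    log_terms: list[np.ndarray] = []

    def recurse(cats_left: int, remaining: int, prefix: float) -> None:
        if cats_left == 1:
            log_terms.append(np.atleast_1d(prefix - lg[remaining] + xlx[remaining]))
            return
        j = np.arange(remaining + 1)
        if cats_left == 2:
            log_terms.append(prefix - lg[j] + xlx[j] - lg[remaining - j] + xlx[remaining - j])
            return
        for jj in range(remaining + 1):
            recurse(cats_left - 1, remaining - jj, prefix - lg[jj] + xlx[jj])

    recurse(m, n, float(lg[n]))
    return float(logsumexp(np.concatenate(log_terms)) / LN2)


def nml_codelength_exact(wc: WordCounts, m: Optional[int] = None) -> float:
    """Exact (non-asymptotic) NML code length, in bits, for small problems.

    -log2 p(x; theta_hat(x)) + log2 C(n, m); by default m is the number of
    observed words, but a larger declared dictionary may be passed.
    """
    if m is None:
        m = wc.m
    return wc.n * empirical_entropy(wc) + shtarkov_normalizer_exact(wc.n, m)


def lz78_codelength(phrase_count: int, alphabet_size: int) -> float:
    """LZ78 length: c log2 c bits of prefix addresses + c log2 alpha bits of
    final symbols, for c phrases (0 for an empty parse)."""
    if phrase_count < 0:
        raise ValueError("phrase count must be >= 0")
    if phrase_count == 0:
        return 0.0
    address_bits = phrase_count * math.log2(phrase_count) if phrase_count > 1 else 0.0
    return address_bits + phrase_count * math.log2(alphabet_size)
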