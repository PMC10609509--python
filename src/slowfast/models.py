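"""Reversible amino-acid substitution models and discrete-gamma rate classes.

The continuous-time Markov chain is parameterised the standard way: a
symmetric exchangeability matrix ``S`` and equilibrium frequencies ``pi``
give the generator ``Q_ij = S_ij * pi_j`` (i != j), with the diagonal set so
rows sum to zero and the whole matrix rescaled so that the expected number
of substitutions per site per unit time, ``-sum_i pi_i Q_ii``, equals one.
Branch lengths are therefore in expected substitutions per site.

Among-site rate variation uses the discrete-gamma approximation with k
equal-probability categories; each category carries the conditional mean of
a mean-1 Gamma(alpha, alpha) distribution within its quantile bin (the
"mean" variant of Yang's discretisation).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy.stats import gamma as _gamma_dist

from ._aa import AA_ORDER, N_AA

SUPPORTED_MODELS = ("LG", "WAG", "Dayhoff", "JTT")


class UnsupportedModelError(ValueError):
    """Raised for a substitution-model name this package does not bundle."""


@dataclass(frozen=True)
class RateModel:
    """A reversible 20-state amino-acid substitution model.

    Attributes
    ----------
    name : str
        Model identifier (e.g. ``"LG"``); ``+F`` is appended when the
        bundled frequencies have been replaced by empirical ones.
    exchangeabilities : (20, 20) ndarray
        Symmetric, non-negative, zero diagonal.
    frequencies : (20,) ndarray
        Equilibrium amino-acid frequencies, summing to one.
    generator : (20, 20) ndarray
        Rate matrix Q, rows summing to zero, scaled to unit mean rate.
    """

    name: str
    exchangeabilities: np.ndarray
    frequencies: np.ndarray
    generator: np.ndarray = field(repr=False)

    @classmethod
    def from_exchangeabilities(
        cls, name: str, exchangeabilities: np.ndarray, frequencies: np.ndarray
    ) -> "RateModel":
        S = np.asarray(exchangeabilities, dtype=float)
        pi = np.asarray(frequencies, dtype=float)
        if S.shape != (N_AA, N_AA):
            raise ValueError(f"exchangeabilities must be 20x20, got {S.shape}")
        if pi.shape != (N_AA,) or np.any(pi < 0):
            raise ValueError("frequencies must be 20 non-negative values")
        pi = pi / pi.sum()
        Q = S * pi[np.newaxis, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mu = -np.dot(pi, np.diag(Q))  # expected substitutions per unit time
        if mu <= 0:
            raise ValueError("degenerate model: zero mean substitution rate")
        return cls(name=name, exchangeabilities=S, frequencies=pi, generator=Q / mu)

    def with_frequencies(self, frequencies: np.ndarray) -> "RateModel":
        """Return the same exchangeabilities fit with new (+F) frequencies."""
        base = self.name.removesuffix("+F")
        return RateModel.from_exchangeabilities(
            base + "+F", self.exchangeabilities, frequencies
        )

    # -- spectral decomposition (cached) ------------------------------------
    def _eigen(self):
        """Eigendecomposition of the similarity-transformed generator.

        Reversibility makes ``B = diag(sqrt(pi)) Q diag(1/sqrt(pi))``
        symmetric, so the spectrum is real and the matrix exponential is
        cheap: P(t) = diag(1/sqrt(pi)) U exp(L t) U' diag(sqrt(pi)).
        """
        cached = getattr(self, "_eigen_cache", None)
        if cached is None:
            sp = np.sqrt(self.frequencies)
            B = (sp[:, None] * self.generator) / sp[None, :]
            B = 0.5 * (B + B.T)  # symmetrise away rounding noise
            lam, U = np.linalg.eigh(B)
            left = U.T * sp[None, :]
            right = U / sp[:, None]
            object.__setattr__(self, "_eigen_cache", (lam, right, left))
            cached = (lam, right, left)
        return cached


def _parse_paml_dat(text: str) -> tuple[np.ndarray, np.ndarray]:
    """Parse a PAML-layout .dat file: lower-triangle exchangeabilities
    (19 rows) followed by the 20 equilibrium frequencies."""
    values = [float(tok) for tok in text.split()]
    if len(values) < 190 + 20:
        raise ValueError("model file too short for a 20-state PAML table")
    S = np.zeros((N_AA, N_AA))
    pos = 0
    for i in range(1, N_AA):
        for j in range(i):
            S[i, j] = S[j, i] = values[pos]
            pos += 1
    pi = np.array(values[pos : pos + N_AA])
    return S, pi


def load_model(name: str) -> RateModel:
    """Load a bundled empirical model (LG, WAG, Dayhoff or JTT).

    The parameter tables ship as PAML-layout ``.dat`` files (lower-triangle
    exchangeabilities then frequencies, amino acids in the order
    ``{order}``).
    """
    canonical = {m.lower(): m for m in SUPPORTED_MODELS}.get(name.strip().lower())
    if canonical is None:
        raise UnsupportedModelError(
            f"unsupported model {name!r}; choose one of {SUPPORTED_MODELS}"
        )
    text = (
        resources.files("slowfast.data").joinpath(f"{canonical.lower()}.dat").read_text()
    )
    S, pi = _parse_paml_dat(text)
    return RateModel.from_exchangeabilities(canonical, S, pi)


load_model.__doc__ = load_model.__doc__.format(order=" ".join(AA_ORDER))


@dataclass(frozen=True)
class GammaRateCategories:
    """Discrete-gamma rate heterogeneity: k equiprobable categories."""

    alpha: float
    n_categories: int
    rates: np.ndarray

    @property
    def category_probability(self) -> float:
        return 1.0 / self.n_categories


def discretize_gamma(alpha: float, k: int) -> GammaRateCategories:
    """Discretise a mean-1 Gamma(alpha, alpha) into k equal-probability
    categories, each carrying its bin's conditional mean rate.

    The bin boundaries are the i/k quantiles; the conditional mean over
    ``[a, b]`` follows from the partial-expectation identity
    ``int_a^b x f_alpha(x) dx = F_{alpha+1}(b) - F_{alpha+1}(a)`` for a
    mean-1 gamma, so each rate is k times that increment. The k rates
    average to exactly one.
    """
    if not alpha > 0:
        raise ValueError(f"alpha must be positive, got {alpha}")
    k = int(k)
    if k < 1:
        raise ValueError(f"need at least one category, got {k}")
    bounds = _gamma_dist.ppf(np.arange(k + 1) / k, alpha, scale=1.0 / alpha)
    bounds[0], bounds[-1] = 0.0, np.inf
    upper_cdf = _gamma_dist.cdf(bounds, alpha + 1.0, scale=1.0 / alpha)
    rates = k * np.diff(upper_cdf)
    rates = rates / rates.mean()  # remove last-digit drift; exact mean 1
    return GammaRateCategories(alpha=float(alpha), n_categories=k, rates=rates)


def transition_probabilities(
    model: RateModel, branch_length: float, rate: float = 1.0
) -> np.ndarray:
    """P(t) = exp(Q * rate * branch_length) via the cached spectral form."""
    if branch_length < 0:
        raise ValueError(f"branch length must be non-negative, got {branch_length}")
    if not rate > 0:
        raise ValueError(f"rate multiplier must be positive, got {rate}")
    lam, right, left = model._eigen()
    P = (right * np.exp(lam * rate * branch_length)[None, :]) @ left
    np.maximum(P, 0.0, out=P)
    P /= P.sum(axis=1, keepdims=True)
    return P


def transition_probability_stack(
    model: RateModel, branch_length: float, rates: np.ndarray
) -> np.ndarray:
    """P(t) for several rate multipliers at once; shape (len(rates), 20, 20)."""
    if branch_length < 0:
        raise ValueError(f"branch length must be non-negative, got {branch_length}")
    lam, right, left = model._eigen()
    expd = np.exp(np.multiply.outer(np.asarray(rates) * branch_length, lam))
    P = np.einsum("ik,ck,kj->cij", right, expd, left)
    np.maximum(P, 0.0, out=P)
    P /= P.sum(axis=2, keepdims=True)
    return P


def expected_substitutions(
    branch_length: float,
    alignment_length: float,
    n_categories: int,
    category_rate: float,
) -> tuple[float, float]:
    """Expected substitutions contributed by one rate category along a branch.

    With k equiprobable categories, a category holds ``alignment_length/k``
    sites, each accumulating ``branch_length * category_rate`` expected
    substitutions, so its count is ``(L/k) * t * r`` and its share of the
    branch total ``L * t`` is simply ``r/k`` — independent of branch length.

    Returns
    -------
    (count, fraction)
        Expected substitution count for the category, and its fraction of
        the branch-wide total (in [0, 1] for rates below k).
    """
    if branch_length <= 0 or alignment_length <= 0:
        raise ValueError("branch length and alignment length must be positive")
    if n_categories < 1 or category_rate <= 0:
        raise ValueError("need n_categories >= 1 and a positive category rate")
    count = (alignment_length / n_categories) * branch_length * category_rate
    fraction = count / (alignment_length * branch_length)
    return count, fraction
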