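"""GTR+Γ nucleotide substitution model.

The general time-reversible (GTR) model is parameterized by six symmetric
exchangeabilities s_ij (G↔T fixed to 1 for identifiability) and stationary
base frequencies π. The instantaneous rate matrix Q_ij = s_ij π_j (i≠j) is
scaled so the expected substitution rate at stationarity is one, making
branch lengths expected substitutions per site. Among-site rate variation
uses the discrete-gamma approximation: K equal-probability categories whose
rates are the category-median gamma(α, α) quantiles, normalized to mean 1
(so K=1 reduces exactly to the rate-homogeneous model).

Bases are indexed A=0, C=1, G=2, T=3; exchangeability order is
(AC, AG, AT, CG, CT, GT).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import gamma as _gamma_dist

__all__ = ["GTRGammaParams", "gtr_rate_matrix", "GTREigen", "discrete_gamma_rates",
           "BASES", "BASE_INDEX"]

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

# (i, j) pairs for the exchangeability vector order
_PAIRS = ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))


@dataclass
class GTRGammaParams:
    """GTR+Γ parameter bundle.

    ``exchangeabilities``: 6 nonnegative rates (AC, AG, AT, CG, CT, GT),
    interpreted relative to GT which optimizers keep fixed at 1.
    ``alpha``: gamma shape; large α approaches rate homogeneity.
    """

    exchangeabilities: np.ndarray = field(
        default_factory=lambda: np.ones(6))
    base_freqs: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25))
    alpha: float = 1.0
    n_categories: int = 4

    def __post_init__(self):
        self.exchangeabilities = np.asarray(self.exchangeabilities, dtype=float)
        self.base_freqs = np.asarray(self.base_freqs, dtype=float)
        if self.exchangeabilities.shape != (6,):
            raise ValueError("need 6 exchangeabilities (AC, AG, AT, CG, CT, GT)")
        if np.any(self.exchangeabilities < 0):
            raise ValueError("exchangeabilities must be nonnegative")
        if self.base_freqs.shape != (4,):
            raise ValueError("need 4 base frequencies")
        if abs(self.base_freqs.sum() - 1.0) > 1e-9:
            raise ValueError("base frequencies must sum to 1")
        if self.alpha <= 0:
            raise ValueError("gamma shape must be positive")
        if self.n_categories < 1:
            raise ValueError("need at least one rate category")

    def copy(self) -> "GTRGammaParams":
        return GTRGammaParams(self.exchangeabilities.copy(),
                              self.base_freqs.copy(),
                              self.alpha, self.n_categories)

    @classmethod
    def jc(cls, n_categories: int = 1, alpha: float = 1.0) -> "GTRGammaParams":
        """Jukes–Cantor special case (equal rates, uniform frequencies)."""
        return cls(np.ones(6), np.full(4, 0.25), alpha, n_categories)

    def category_rates(self) -> np.ndarray:
        return discrete_gamma_rates(self.alpha, self.n_categories)


def discrete_gamma_rates(alpha: float, k: int) -> np.ndarray:
    """Median rates of K equal-probability gamma(α, α) slices, scaled to
    mean exactly 1."""
    if k == 1:
        return np.ones(1)
    quantiles = (2.0 * np.arange(k) + 1.0) / (2.0 * k)
    rates = _gamma_dist.ppf(quantiles, a=alpha, scale=1.0 / alpha)
    return rates / rates.mean()


def gtr_rate_matrix(exchangeabilities, base_freqs) -> np.ndarray:
    """Scaled GTR rate matrix (rows sum to 0, mean rate 1 at stationarity)."""
    s = np.asarray(exchangeabilities, dtype=float)
    pi = np.asarray(base_freqs, dtype=float)
    Q = np.zeros((4, 4))
    for rate, (i, j) in zip(s, _PAIRS):
        Q[i, j] = rate * pi[j]
        Q[j, i] = rate * pi[i]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mu = -np.dot(pi, np.diag(Q))
    if mu <= 0:
        raise ValueError("degenerate rate matrix (zero overall rate)")
    return Q / mu


class GTREigen:
    """Eigendecomposition of the scaled GTR generator for fast P(t).

    Time-reversibility makes diag(√π) Q diag(1/√π) symmetric, so the
    decomposition is done with a stable symmetric solver.
    """

    def __init__(self, params: GTRGammaParams):
        self.params = params
        pi = params.base_freqs
        Q = gtr_rate_matrix(params.exchangeabilities, pi)
        sq = np.sqrt(pi)
        B = (Q * sq[:, None]) / sq[None, :]
        B = 0.5 * (B + B.T)  # symmetrize away rounding noise
        lam, V = np.linalg.eigh(B)
        self.eigenvalues = lam
        self.U = V / sq[:, None]          # right eigenvectors of Q
        self.U_inv = (V * sq[:, None]).T  # left eigenvectors

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt); rows sum to 1."""
        if t < 0:
            raise ValueError("negative branch length")
        P = (self.U * np.exp(self.eigenvalues * t)) @ self.U_inv
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P

    def transition_matrices(self, t: float, rates: np.ndarray) -> np.ndarray:
        """Stacked P(t·r_k) for each rate category, shape (K, 4, 4)."""
        out = np.empty((len(rates), 4, 4))
        for k, r in enumerate(rates):
            out[k] = self.transition_matrix(t * r)
        return out
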