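"""Reversible substitution models with invariant sites and discrete-gamma rates.

The general time-reversible rate matrix is Q_ij = s_ij * pi_j (i != j), with
symmetric exchangeabilities s and stationary frequencies pi, scaled so that
the expected number of substitutions per site per unit branch length is one.
Across-site rate heterogeneity uses the standard discrete-gamma approximation
(equal-probability categories represented by their conditional means, mean
rate 1) mixed with a proportion p_inv of invariant sites.

Amino-acid analyses draw exchangeabilities from the published empirical
matrices LG, WAG and JTT (packaged in ``data/aa_models.json``); a uniform
prior over this fixed set plays the role of a mixed amino-acid model.
"""

from __future__ import annotations

import functools
import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

from .alignment import AA_ALPHABET, BINARY_ALPHABET, NT_ALPHABET

AA_MODEL_NAMES = ("LG", "WAG", "JTT")


def discrete_gamma_rates(alpha: float, ncat: int = 4) -> np.ndarray:
    """Equal-probability discrete-gamma category rates with mean exactly 1."""
    if alpha <= 0:
        raise ValueError("gamma shape must be positive")
    if ncat == 1:
        return np.ones(1)
    # category boundaries at quantiles i/ncat of Gamma(alpha, scale=1/alpha)
    edges = gamma_dist.ppf(np.arange(1, ncat) / ncat, alpha, scale=1.0 / alpha)
    edges = np.concatenate([[0.0], edges, [np.inf]])
    # E[X | a<X<b] for Gamma(alpha, 1/alpha) via the shape+1 identity
    upper = np.where(np.isinf(edges[1:]), 1.0, gammainc(alpha + 1, alpha * edges[1:]))
    lower = gammainc(alpha + 1, alpha * edges[:-1])
    rates = (upper - lower) * ncat
    return rates / rates.mean()


@functools.cache
def _aa_data() -> dict:
    with resources.files("picoevo.data").joinpath("aa_models.json").open() as fh:
        return json.load(fh)


def aa_exchangeabilities(name: str) -> tuple[np.ndarray, np.ndarray]:
    """Published lower-triangle exchangeabilities and frequencies for LG/WAG/JTT."""
    data = _aa_data()
    if name not in data:
        raise KeyError(f"unknown amino acid model {name!r}")
    tri = np.asarray(data[name]["exchangeabilities_lower_triangle"], dtype=float)
    freqs = np.asarray(data[name]["frequencies"], dtype=float)
    K = 20
    S = np.zeros((K, K))
    idx = 0
    for i in range(1, K):  # PAML dat ordering: row-wise lower triangle
        for j in range(i):
            S[i, j] = S[j, i] = tri[idx]
            idx += 1
    return S, freqs / freqs.sum()


@dataclass
class SubstitutionModel:
    """GTR-family model: exchangeabilities + frequencies + p_inv + Gamma(4)."""

    alphabet: str = NT_ALPHABET
    exchangeabilities: np.ndarray | None = None
    frequencies: np.ndarray | None = None
    p_inv: float = 0.0
    alpha: float = np.inf  # inf => rate homogeneity
    ncat: int = 4
    model_id: str = "custom"
    _eig: tuple = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        K = len(self.alphabet)
        if self.exchangeabilities is None:
            self.exchangeabilities = np.ones((K, K)) - np.eye(K)
        self.exchangeabilities = np.asarray(self.exchangeabilities, dtype=float)
        if self.frequencies is None:
            self.frequencies = np.full(K, 1.0 / K)
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if self.frequencies.shape != (K,) or np.any(self.frequencies < 0):
            raise ValueError("invalid frequency vector")
        if abs(self.frequencies.sum() - 1.0) > 1e-8:
            raise ValueError("frequencies must sum to 1")
        if not 0.0 <= self.p_inv < 1.0:
            raise ValueError("p_inv must lie in [0, 1)")
        if self.alpha <= 0:
            raise ValueError("gamma shape must be positive")
        self._eig = None

    @property
    def K(self) -> int:
        return len(self.alphabet)

    def rate_matrix(self) -> np.ndarray:
        """Q scaled to one expected substitution per site at rate 1."""
        pi = self.frequencies
        Q = self.exchangeabilities * pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mu = -np.dot(pi, np.diag(Q))
        if mu <= 0:
            raise ValueError("degenerate rate matrix")
        return Q / mu

    def _eigen(self):
        if self._eig is None:
            pi = self.frequencies
            Q = self.rate_matrix()
            sq = np.sqrt(pi)
            B = (Q * sq[None, :]) / sq[:, None]  # symmetric similarity transform
            w, U = np.linalg.eigh((B + B.T) / 2.0)
            left = U.T / sq[None, :]
            right = U * sq[:, None]
            # fix: B = D^1/2 Q D^-1/2 => Q = right @ diag(w) @ left with
            # right = D^-1/2 U, left = U.T D^1/2
            right = U / sq[:, None]
            left = U.T * sq[None, :]
            self._eig = (w, right, left)
        return self._eig

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt)."""
        if t < 0:
            raise ValueError("negative branch length")
        w, right, left = self._eigen()
        P = (right * np.exp(w * t)[None, :]) @ left
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P

    def category_rates(self) -> np.ndarray:
        key = (self.alpha, self.ncat)
        cached = getattr(self, "_rates_cache", None)
        if cached is None or cached[0] != key:
            rates = (
                np.ones(1)
                if np.isinf(self.alpha)
                else discrete_gamma_rates(self.alpha, self.ncat)
            )
            object.__setattr__(self, "_rates_cache", (key, rates))
            cached = (key, rates)
        return cached[1]

    def transition_matrices(self, ts: np.ndarray) -> np.ndarray:
        """P(t) for a batch of branch lengths; shape (len(ts), K, K)."""
        w, right, left = self._eigen()
        expwt = np.exp(np.asarray(ts)[:, None] * w[None, :])
        P = np.einsum("ik,ek,kj->eij", right, expwt, left, optimize=True)
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=2, keepdims=True)
        return P

    def with_params(self, **kw) -> "SubstitutionModel":
        fields = dict(
            alphabet=self.alphabet,
            exchangeabilities=self.exchangeabilities,
            frequencies=self.frequencies,
            p_inv=self.p_inv,
            alpha=self.alpha,
            ncat=self.ncat,
            model_id=self.model_id,
        )
        fields.update(kw)
        return SubstitutionModel(**fields)


def jc_like(alphabet: str = NT_ALPHABET, **kw) -> SubstitutionModel:
    """Equal-exchangeability, equal-frequency model (Jukes-Cantor analogue)."""
    return SubstitutionModel(alphabet=alphabet, model_id=f"poisson{len(alphabet)}", **kw)


def gtr(
    exchangeabilities, frequencies, alphabet: str = NT_ALPHABET, **kw
) -> SubstitutionModel:
    return SubstitutionModel(
        alphabet=alphabet,
        exchangeabilities=np.asarray(exchangeabilities, dtype=float),
        frequencies=np.asarray(frequencies, dtype=float),
        model_id="GTR",
        **kw,
    )


def empirical_aa(name: str, **kw) -> SubstitutionModel:
    S, freqs = aa_exchangeabilities(name)
    return SubstitutionModel(
        alphabet=AA_ALPHABET,
        exchangeabilities=S,
        frequencies=freqs,
        model_id=name,
        **kw,
    )


def binary_model(**kw) -> SubstitutionModel:
    return SubstitutionModel(alphabet=BINARY_ALPHABET, model_id="binary", **kw)
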