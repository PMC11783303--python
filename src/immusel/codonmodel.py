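"""Mixture codon substitution models.

The model is a Muse–Gaut-style codon model extended with

* a discrete mixture of dN/dS classes (omega_k, weight p_k) shared across
  all branches,
* a discrete mean-one mixture of synonymous-rate classes (s_m, weight q_m)
  capturing site-to-site synonymous rate variation, and
* instantaneous multinucleotide (multi-hit) substitutions: codon changes at
  two positions with rate factor delta and at three positions with rate
  factor psi.

For codons i != j differing at d positions the instantaneous rate is

    d=1:  pi_j * (kappa if transition) * (s if synonymous else omega)
    d=2:  delta * pi_j * (omega if nonsynonymous else s)
    d=3:  psi   * pi_j * (omega if nonsynonymous else s)

One unit of branch length equals one expected substitution per codon under
the base model (omega = 1, s = 1, current delta/psi), so the normalization
constant is computed once from the base model and shared across mixture
components.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import genetics as G


@dataclass
class MixtureCodonModel:
    kappa: float
    pi: np.ndarray  # 61 sense-codon frequencies
    omegas: np.ndarray  # K omega classes, ascending
    omega_weights: np.ndarray  # K weights, simplex
    syn_rates: np.ndarray = field(default_factory=lambda: np.array([1.0]))
    syn_weights: np.ndarray = field(default_factory=lambda: np.array([1.0]))
    delta: float = 0.0  # double-hit rate
    psi: float = 0.0  # triple-hit rate
    # set by the optimizer's parameter mapping, whose construction already
    # guarantees validity; skips per-evaluation re-validation
    trusted: bool = False

    def __post_init__(self):
        self.pi = np.asarray(self.pi, dtype=float)
        self.omegas = np.asarray(self.omegas, dtype=float)
        self.omega_weights = np.asarray(self.omega_weights, dtype=float)
        self.syn_rates = np.asarray(self.syn_rates, dtype=float)
        self.syn_weights = np.asarray(self.syn_weights, dtype=float)
        if not self.trusted:
            self.validate()

    def validate(self) -> None:
        if not self.kappa > 0:
            raise ValueError("kappa must be > 0")
        if self.pi.shape != (G.N_STATES,) or np.any(self.pi < 0):
            raise ValueError("pi must be 61 nonnegative frequencies")
        if abs(self.pi.sum() - 1.0) > 1e-6:
            raise ValueError("pi must sum to 1")
        if np.any(self.omegas < 0) or np.any(self.syn_rates < 0):
            raise ValueError("rate classes must be nonnegative")
        if np.any(np.diff(self.omegas) < -1e-12):
            raise ValueError("omega classes must be ascending")
        for w, name in ((self.omega_weights, "omega"), (self.syn_weights, "syn")):
            if np.any(w < -1e-12) or abs(w.sum() - 1.0) > 1e-6:
                raise ValueError(f"{name} weights must lie in the simplex")
        if len(self.omegas) != len(self.omega_weights):
            raise ValueError("omega classes/weights length mismatch")
        if len(self.syn_rates) != len(self.syn_weights):
            raise ValueError("syn classes/weights length mismatch")
        mean_s = float(self.syn_weights @ self.syn_rates)
        if abs(mean_s - 1.0) > 1e-9:
            raise ValueError("synonymous rates must have mixture mean 1")
        if self.delta < 0 or self.psi < 0:
            raise ValueError("delta and psi must be nonnegative")

    @property
    def has_positive_class(self) -> bool:
        return bool(
            np.any((self.omegas > 1.0) & (self.omega_weights > 0.0))
        )

    def components(self):
        """Iterate (omega, syn_rate, weight) over the K x M mixture."""
        for k, (w, pw) in enumerate(zip(self.omegas, self.omega_weights)):
            for m, (s, qw) in enumerate(zip(self.syn_rates, self.syn_weights)):
                yield w, s, pw * qw


def normalize_syn_rates(rates, weights):
    """Rescale synonymous-rate classes so the mixture mean is exactly 1."""
    rates = np.asarray(rates, dtype=float)
    weights = np.asarray(weights, dtype=float)
    mean = float(weights @ rates)
    if mean <= 0:
        raise ValueError("synonymous-rate mixture mean must be positive")
    return rates / mean


class RateMatrixBuilder:
    """Caches the parts of Q that depend only on (pi, kappa, delta, psi) so
    that Q(omega, s) for each mixture component is a cheap elementwise
    product. Also provides eigendecomposition-based transition matrices
    exploiting reversibility."""

    def __init__(self, pi: np.ndarray, kappa: float, delta: float, psi: float):
        self.pi = np.asarray(pi, dtype=float)
        # baseline pair factor: target frequency, kappa on transitions,
        # delta/psi damping on double/triple-hit changes
        fac = np.where(G.IS_TRANSITION, kappa, 1.0) * self.pi[None, :]
        fac = np.where(G.NDIFF == 1, fac, 0.0)
        fac = fac + np.where(G.NDIFF == 2, delta * self.pi[None, :], 0.0)
        fac = fac + np.where(G.NDIFF == 3, psi * self.pi[None, :], 0.0)
        self._base = fac
        # normalization from the base model (omega = 1, s = 1): expected
        # substitution rate per codon
        rowsum = self._base.sum(axis=1)
        self._norm = float(self.pi @ rowsum)
        sqrt_pi = np.sqrt(np.maximum(self.pi, 1e-300))
        self._sqrt_pi = sqrt_pi
        self._inv_sqrt_pi = 1.0 / sqrt_pi

    def build(self, omega: float, syn_rate: float) -> np.ndarray:
        """61x61 generator for one (omega, s) mixture component."""
        Q = self._base * np.where(G.IS_SYNONYMOUS, syn_rate, omega)
        Q[np.diag_indices_from(Q)] = 0.0
        Q[np.diag_indices_from(Q)] = -Q.sum(axis=1)
        return Q / self._norm

    def spectral(self, omega: float, syn_rate: float):
        """Eigendecomposition of Q via the pi-symmetrized form; returns
        (eigenvalues, A, B) with P(t) = (A * exp(lam t)) @ B."""
        Q = self.build(omega, syn_rate)
        S = (self._sqrt_pi[:, None] * Q) * self._inv_sqrt_pi[None, :]
        lam, V = np.linalg.eigh((S + S.T) / 2.0)
        A = self._inv_sqrt_pi[:, None] * V
        B = V.T * self._sqrt_pi[None, :]
        return lam, A, B

    @staticmethod
    def transition_matrix(lam, A, B, t: float) -> np.ndarray:
        P = (A * np.exp(lam * t)) @ B
        np.clip(P, 0.0, None, out=P)
        return P


def build_rate_matrix(model: MixtureCodonModel, omega: float, syn_rate: float):
    """Normalized 61x61 generator for one (omega, s) component of ``model``.

    The normalization constant comes from the base model (omega = 1, s = 1,
    current delta/psi) so one unit of branch length is one expected
    substitution per codon under the base model.
    """
    model.validate()
    return RateMatrixBuilder(
        model.pi, model.kappa, model.delta, model.psi
    ).build(omega, syn_rate)
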