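"""Felsenstein pruning for mixture codon models.

The engine compresses alignment columns into unique site patterns, then for
each mixture component (omega_k, s_m) computes per-pattern likelihoods with
a single post-order pass, batching the components in the leading axis of
the matrix products. Gap (``---``), ``NNN`` and partially ambiguous codons
are missing data (partial likelihood of all ones). The total site
likelihood is the weighted sum over components,

    L(site) = sum_k sum_m p_k q_m L(site | Q(omega_k, s_m)).

Per-pattern rescaling guards against underflow on deep trees.
"""

from __future__ import annotations

import numpy as np

from .alignment import CodonAlignment
from .codonmodel import MixtureCodonModel, RateMatrixBuilder
from .trees import Phylogeny


class PruningEngine:
    """Reusable likelihood machine for one (alignment, tree) pair.

    The engine is built once per gene; ``log_likelihood`` is then called
    many times during optimization with different model parameters.
    """

    def __init__(self, aln: CodonAlignment, tree: Phylogeny):
        extra = set(aln.taxon_names) - set(tree.taxon_names)
        if extra:
            raise ValueError(f"alignment taxa missing from tree: {sorted(extra)}")
        if set(tree.taxon_names) != set(aln.taxon_names):
            tree = tree.prune_to(aln.taxon_names)
        self.tree = tree
        self.aln = aln

        order = [aln.taxon_names.index(t) for t in tree.taxon_names]
        states = aln.state_matrix()[order]  # rows follow tree tip indexing

        patterns, inverse, counts = np.unique(
            states.T, axis=0, return_inverse=True, return_counts=True
        )
        self.tip_states = patterns.T  # (n_tips, n_patterns)
        self.pattern_of_site = inverse
        self.counts = counts.astype(float)
        self.n_patterns = patterns.shape[0]
        self.n_tips = tree.n_tips

        self._missing = self.tip_states < 0
        self._clipped = np.where(self._missing, 0, self.tip_states)

        # flat branch arrays (child node id, branch length) for batched
        # transition-matrix construction
        child_nodes, child_lens = [], []
        for k in tree.postorder:
            for child, bl in tree.children[k - tree.n_tips]:
                child_nodes.append(child)
                child_lens.append(bl)
        self._branch_nodes = np.array(child_nodes, dtype=np.intp)
        self._branch_lens = np.array(child_lens, dtype=float)

        # mixture weights only mix already-computed per-component pattern
        # likelihoods, so those are cached on the structural parameters
        # (kappa, classes, delta/psi, scale); finite-difference steps on
        # weight logits then cost almost nothing
        self._cache: dict = {}
        self._cache_max = 8
        # eigendecompositions per (pi, kappa, delta, psi, omega, s): most
        # finite-difference steps perturb one parameter, leaving the other
        # mixture components' spectra reusable
        self._spectra: dict = {}
        self._spectra_max = 64

    # ------------------------------------------------------------------ core
    def _component_pattern_likelihoods(
        self, model: MixtureCodonModel, scale: float
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-component, per-pattern likelihoods.

        Returns (comp_weights, pattern_likelihoods (ncomp, npat) on the
        rescaled scale, log_rescalers (npat,))."""
        comps = list(model.components())
        ncomp = len(comps)
        pi_key = hash(model.pi.tobytes())
        builder = None
        spectra = []
        for (w, s, _) in comps:
            key = (pi_key, model.kappa, model.delta, model.psi, w, s)
            spec = self._spectra.get(key)
            if spec is None:
                if builder is None:
                    builder = RateMatrixBuilder(
                        model.pi, model.kappa, model.delta, model.psi
                    )
                lam, A, B = builder.spectral(w, s)
                spec = (
                    lam,
                    np.ascontiguousarray(B.T),
                    np.ascontiguousarray(A.T),
                )
                if len(self._spectra) >= self._spectra_max:
                    self._spectra.pop(next(iter(self._spectra)))
                self._spectra[key] = spec
            spectra.append(spec)
        weights = np.array([wt for (_, _, wt) in comps])

        tree = self.tree
        npat = self.n_patterns
        # transposed transition matrices per (component, child-node),
        # batched over branches: P(t)^T = (B^T * exp(lam t)) @ A^T; storing
        # the transpose makes tip lookups row gathers and internal-node
        # updates plain matmuls on contiguous arrays
        T = self._branch_lens * scale
        PT = np.empty((ncomp, tree.n_nodes, 61, 61))
        for c, (lam, Bt, At) in enumerate(spectra):
            expl = np.exp(T[:, None] * lam[None, :])  # (n_branch, 61)
            Pc = (Bt[None, :, :] * expl[:, None, :]) @ At
            np.clip(Pc, 0.0, None, out=Pc)
            PT[c, self._branch_nodes] = Pc

        partial: dict[int, np.ndarray] = {}
        log_rescale = np.zeros(npat)
        since_rescale = 0
        for k in tree.postorder:
            res = None
            for child, _bl in tree.children[k - tree.n_tips]:
                Pc = PT[:, child]  # (ncomp, 61, 61), transposed P
                if child < self.n_tips:
                    # advanced indexing copies, so in-place accumulation on
                    # the result is safe
                    contrib = Pc[:, self._clipped[child], :]
                    if self._missing[child].any():
                        contrib[:, self._missing[child], :] = 1.0
                else:
                    contrib = partial.pop(child) @ Pc
                if res is None:
                    res = contrib
                else:
                    res *= contrib
            # rescale periodically (and at the root) to prevent underflow
            since_rescale += 1
            if since_rescale >= 8 or k == tree.root_index:
                m = res.max(axis=(0, 2))
                m = np.where(m > 0, m, 1.0)
                res /= m[None, :, None]
                log_rescale += np.log(m)
                since_rescale = 0
            partial[k] = res

        root = partial[self.tree.root_index]
        pat_like = root @ model.pi  # (ncomp, npat)
        return weights, pat_like, log_rescale

    def log_likelihood(self, model: MixtureCodonModel, scale: float = 1.0) -> float:
        """Total log-likelihood of the alignment under the mixture model,
        with branch lengths multiplied by ``scale``."""
        key = (
            model.kappa, tuple(model.omegas), tuple(model.syn_rates),
            model.delta, model.psi, scale,
        )
        cached = self._cache.get(key)
        if cached is None:
            _, pat_like, log_rescale = self._component_pattern_likelihoods(
                model, scale
            )
            if len(self._cache) >= self._cache_max:
                self._cache.pop(next(iter(self._cache)))
            self._cache[key] = (pat_like, log_rescale)
        else:
            pat_like, log_rescale = cached
        weights = np.array([wt for (_, _, wt) in model.components()])
        site = weights @ pat_like
        site = np.maximum(site, 1e-300)
        return float(self.counts @ (np.log(site) + log_rescale))

    def site_log_likelihoods(
        self, model: MixtureCodonModel, scale: float = 1.0
    ) -> np.ndarray:
        """Per-codon-column log-likelihoods (in original site order)."""
        weights, pat_like, log_rescale = self._component_pattern_likelihoods(
            model, scale
        )
        site = np.maximum(weights @ pat_like, 1e-300)
        per_pattern = np.log(site) + log_rescale
        return per_pattern[self.pattern_of_site]


def mixture_log_likelihood(
    aln: CodonAlignment, tree: Phylogeny, model: MixtureCodonModel, scale: float = 1.0
) -> float:
    """One-shot total log-likelihood (builds a fresh engine)."""
    return PruningEngine(aln, tree).log_likelihood(model, scale)


def site_log_likelihood(
    column: CodonAlignment, tree: Phylogeny, model: MixtureCodonModel
) -> float:
    """Log-likelihood of a single codon column under the full mixture.

    The column is given as a one-codon alignment; at least two non-missing
    states are required for an informative value (an all-missing column has
    likelihood one, contributing zero)."""
    if column.n_codons != 1:
        raise ValueError("site_log_likelihood expects a single codon column")
    return mixture_log_likelihood(column, tree, model)
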