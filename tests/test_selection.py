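"""Codon-model machinery: rate matrices, QC filters, model fits, LRTs,
model averaging, FDR."""

import numpy as np
import pytest
from scipy import stats as sps

import immusel as im
from immusel import genetics as G
from immusel.codonmodel import build_rate_matrix, normalize_syn_rates
from immusel.likelihood import PruningEngine
from immusel.selection import FitSettings, bh_fdr, model_averaged_p


def _model(pi, **kw):
    defaults = dict(
        kappa=2.0, pi=pi,
        omegas=np.array([0.5]), omega_weights=np.array([1.0]),
    )
    defaults.update(kw)
    return im.MixtureCodonModel(**defaults)


# ------------------------------------------------------------ rate matrix
class TestRateMatrix:
    def test_rows_sum_to_zero(self, uniform_pi):
        rng = np.random.default_rng(0)
        for _ in range(3):
            pi = rng.dirichlet(np.full(61, 3.0))
            m = _model(pi, kappa=float(rng.uniform(1, 5)),
                       delta=float(rng.uniform(0, 0.5)),
                       psi=float(rng.uniform(0, 0.2)))
            Q = build_rate_matrix(m, omega=1.3, syn_rate=0.8)
            assert np.allclose(Q.sum(axis=1), 0.0, atol=1e-10)

    def test_no_multi_hit_entries_without_delta_psi(self, uniform_pi):
        Q = build_rate_matrix(_model(uniform_pi), omega=2.0, syn_rate=1.0)
        assert np.all(Q[G.NDIFF >= 2] == 0.0)

    def test_omega_zero_kills_nonsynonymous_rates(self, uniform_pi):
        Q = build_rate_matrix(
            _model(uniform_pi, delta=0.3, psi=0.1), omega=0.0, syn_rate=1.0
        )
        nonsyn_offdiag = (~G.IS_SYNONYMOUS) & (G.NDIFF >= 1)
        assert np.all(Q[nonsyn_offdiag] == 0.0)

    def test_base_model_unit_substitution_rate(self, uniform_pi):
        # one unit of branch length = one expected substitution per codon
        # under the base model (omega = s = 1)
        m = _model(uniform_pi, delta=0.2, psi=0.05)
        Q = build_rate_matrix(m, omega=1.0, syn_rate=1.0)
        rate = -float(uniform_pi @ np.diag(Q))
        assert rate == pytest.approx(1.0, abs=1e-10)

    def test_reversibility(self, uniform_pi):
        rng = np.random.default_rng(1)
        pi = rng.dirichlet(np.full(61, 3.0))
        Q = build_rate_matrix(_model(pi, delta=0.1), omega=0.7, syn_rate=1.2)
        flux = pi[:, None] * Q
        assert np.allclose(flux, flux.T, atol=1e-12)

    def test_syn_rate_normalization(self):
        rates = normalize_syn_rates([0.5, 1.0, 3.0], [0.2, 0.5, 0.3])
        assert np.array([0.2, 0.5, 0.3]) @ rates == pytest.approx(1.0)


# -------------------------------------------------------------- QC filters
class TestAlignmentFilters:
    @pytest.mark.parametrize(
        "trimmed,original,keep",
        [(80, 100, True), (79, 100, False), (100, 100, True)],
    )
    def test_length_fraction_boundary(self, trimmed, original, keep):
        assert im.filter_alignment_length(trimmed, original) is keep

    def test_trimmed_longer_than_original_errors(self):
        with pytest.raises(ValueError):
            im.filter_alignment_length(101, 100)

    def test_min_taxa_per_clade(self):
        def aln_with(n_a, n_b):
            names = [f"A{i}" for i in range(n_a)] + [f"B{i}" for i in range(n_b)]
            return im.CodonAlignment(names, ["ATG"] * (n_a + n_b))

        clades = {f"A{i}": "one" for i in range(20)}
        clades.update({f"B{i}": "two" for i in range(20)})
        assert im.filter_min_taxa(aln_with(7, 7), clades)
        assert not im.filter_min_taxa(aln_with(6, 15), clades)

    def test_min_taxa_survivor_enumeration(self):
        rng = np.random.default_rng(3)
        clades = {f"A{i}": "one" for i in range(20)}
        clades.update({f"B{i}": "two" for i in range(20)})
        kept = 0
        expected = 0
        for _ in range(10):
            n_a, n_b = rng.integers(4, 12, size=2)
            names = [f"A{i}" for i in range(n_a)] + [
                f"B{i}" for i in range(n_b)
            ]
            aln = im.CodonAlignment(names, ["ATG"] * (n_a + n_b))
            kept += im.filter_min_taxa(aln, clades)
            expected += (n_a >= 7) and (n_b >= 7)
        assert kept == expected

    def test_unknown_taxon_errors(self):
        aln = im.CodonAlignment(["X1", "X2"], ["ATG", "ATG"])
        with pytest.raises(ValueError):
            im.filter_min_taxa(aln, {"X1": "one"})


# ------------------------------------------------------------------- fits
class TestFitting:
    def test_constrained_never_beats_unconstrained(self, tiny_tree, uniform_pi):
        model = _model(
            uniform_pi, omegas=np.array([0.2, 2.0]),
            omega_weights=np.array([0.8, 0.2]),
        )
        aln, _ = im.simulate_codon_alignment(tiny_tree, model, 120, seed=31)
        st = FitSettings(n_omega_classes=2, n_restarts=1, maxfun=80)
        eng = PruningEngine(aln, tiny_tree)
        res = im.busted_like_test(aln, tiny_tree, "base", seed=0,
                                  settings=st, engine=eng)
        assert res["null"].log_likelihood <= res["alt"].log_likelihood + 1e-6
        assert res["lrt"] >= 0.0

    def test_aic_consistency(self, tiny_tree, uniform_pi):
        model = _model(uniform_pi)
        aln, _ = im.simulate_codon_alignment(tiny_tree, model, 60, seed=32)
        fit = im.fit_model(aln, tiny_tree, "base",
                           settings=FitSettings(n_restarts=1, maxfun=60))
        assert fit.aic == pytest.approx(
            2 * fit.n_free_params - 2 * fit.log_likelihood
        )

    def test_identical_sequences_lrt_zero(self, uniform_pi):
        tree = im.Phylogeny.from_newick("(A:0.1,B:0.1,(C:0.1,D:0.1):0.1);")
        aln = im.CodonAlignment(list("ABCD"), ["ATGAAGGGCTTT"] * 4)
        st = FitSettings(n_omega_classes=2, n_restarts=1, maxfun=60)
        res = im.busted_like_test(aln, tree, "base", seed=0, settings=st)
        assert res["lrt"] == pytest.approx(0.0, abs=0.02)
        assert res["p"] > 0.95

    def test_chi2_reference_value(self):
        # LRT = 5.99 on 2 df sits at the 5% tail
        assert sps.chi2.sf(5.99, 2) == pytest.approx(0.050, abs=5e-4)

    def test_m2a_nests_m1a(self, tiny_tree, uniform_pi):
        model = _model(
            uniform_pi, omegas=np.array([0.1, 1.0]),
            omega_weights=np.array([0.6, 0.4]),
        )
        aln, _ = im.simulate_codon_alignment(tiny_tree, model, 120, seed=33)
        res = im.m1a_m2a_test(
            aln, tiny_tree, seed=0,
            settings=FitSettings(n_restarts=1, maxfun=80),
        )
        assert res["M2a"].log_likelihood >= res["M1a"].log_likelihood - 1e-6
        assert 0.0 <= res["p"] <= 1.0

    def test_global_omega_unidentifiable_without_variation(self, uniform_pi):
        tree = im.Phylogeny.from_newick("(A:0.1,B:0.1);")
        aln = im.CodonAlignment(["A", "B"], ["ATGATG", "ATGATG"])
        fit = im.fit_global_omega(aln, tree)
        assert not fit.converged
        assert "omega" not in fit.parameters

    def test_power_monotone_in_effect_size(self, small_tree, uniform_pi):
        # median LRT grows with the omega of the positive class
        st = FitSettings(n_omega_classes=2, n_restarts=1, maxfun=80)

        def median_lrt(omega3, weight, n=4):
            lrts = []
            for i in range(n):
                model = _model(
                    uniform_pi, omegas=np.array([0.2, omega3]),
                    omega_weights=np.array([1 - weight, weight]),
                )
                aln, _ = im.simulate_codon_alignment(
                    small_tree, model, 120, seed=600 + i
                )
                lrts.append(
                    im.busted_like_test(aln, small_tree, "base", seed=i,
                                        settings=st)["lrt"]
                )
            return np.median(lrts)

        null_lrt = median_lrt(1.0, 0.0)
        weak = median_lrt(2.0, 0.1)
        strong = median_lrt(5.0, 0.1)
        assert strong > weak
        assert strong > null_lrt


# -------------------------------------------------------- model averaging
class TestModelAveraging:
    @staticmethod
    def _variant(aic, p, converged=True):
        fit = im.FitResult(
            log_likelihood=-aic / 2.0, n_free_params=0, parameters={},
            model=None, scale=1.0, converged=converged,
        )
        return {"alt": fit, "p": p, "converged": converged}

    def test_equal_aic_is_plain_mean(self):
        p, w = model_averaged_p({
            "a": self._variant(10, 0.01),
            "b": self._variant(10, 0.02),
            "c": self._variant(10, 0.03),
        })
        assert p == pytest.approx(0.02)
        assert sum(w.values()) == pytest.approx(1.0)

    def test_dominant_model_takes_over(self):
        p, _ = model_averaged_p({
            "a": self._variant(0, 0.01),
            "b": self._variant(50, 0.02),
            "c": self._variant(50, 0.03),
        })
        assert p == pytest.approx(0.01, abs=1e-8)

    def test_single_converged_model(self):
        p, w = model_averaged_p({
            "a": self._variant(0, 0.4),
            "b": self._variant(0, 0.9, converged=False),
        })
        assert p == pytest.approx(0.4)
        assert list(w) == ["a"]

    def test_no_converged_model_is_missing(self):
        p, w = model_averaged_p({"a": self._variant(0, 0.5, converged=False)})
        assert np.isnan(p) and w == {}


# -------------------------------------------------------------------- FDR
class TestBhFdr:
    def test_step_up_by_hand(self):
        q, flags = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])
        assert flags.all()

    def test_all_ones(self):
        q, flags = bh_fdr([1.0, 1.0, 1.0])
        assert np.allclose(q, 1.0)
        assert not flags.any()

    def test_single_p(self):
        q, _ = bh_fdr([0.17])
        assert q[0] == pytest.approx(0.17)

    def test_empty(self):
        q, flags = bh_fdr([])
        assert len(q) == 0 and len(flags) == 0

    def test_rejects_invalid(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])
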