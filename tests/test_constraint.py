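"""Degeneracy, variant filters, coverage masks and pN/pS."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as hst

import immusel as im
from immusel import genetics as G
from immusel.constraint import (
    CoverageTrack,
    FilterThresholds,
    assign_sex_linked_scaffolds,
    classify_degeneracy,
    classify_snp,
    compute_pnps,
    count_sites,
    excessive_coverage_intervals,
    hwe_excess_het_pvalue,
    maf_filter,
    mean_ortholog_pnps,
    per_sample_coverage_mask,
    restrict_to_aligned_intervals,
    site_filters,
    subtract_repeats,
)


def brute_force_synonymous_mutants(cds):
    """Count synonymous single-nucleotide mutants over all positions."""
    total = 0
    for ci in range(len(cds) // 3):
        codon = cds[3 * ci : 3 * ci + 3]
        aa = G.translate_codon(codon)
        for pos in range(3):
            for nt in "ACGT":
                if nt == codon[pos]:
                    continue
                mut = codon[:pos] + nt + codon[pos + 1 :]
                if mut not in G.STOP_CODONS and G.translate_codon(mut) == aa:
                    total += 1
    return total


# ------------------------------------------------------------- degeneracy
class TestDegeneracy:
    @pytest.mark.parametrize(
        "codon,f,S,N",
        [
            ("GGG", (2, 0, 0, 1), 1.0, 2.0),  # Gly: third position 4-fold
            ("TGG", (3, 0, 0, 0), 0.0, 3.0),  # Trp: nothing synonymous
            ("ATA", (2, 0, 1, 0), 2 / 3, 7 / 3),  # Ile: third position 3-fold
        ],
    )
    def test_known_codons(self, codon, f, S, N):
        prof = classify_degeneracy(codon)
        assert (prof.f0, prof.f2, prof.f3, prof.f4) == f
        assert prof.S_sites == pytest.approx(S)
        assert prof.N_sites == pytest.approx(N)

    def test_site_formulas(self):
        from immusel.constraint import DegeneracyProfile

        assert count_sites(DegeneracyProfile(10, 0, 0, 5)) == (5.0, 10.0)
        S, N = count_sites(DegeneracyProfile(0, 3, 0, 0))
        assert (S, N) == (pytest.approx(1.0), pytest.approx(2.0))
        S, N = count_sites(DegeneracyProfile(0, 0, 3, 0))
        assert (S, N) == (pytest.approx(2.0), pytest.approx(1.0))

    @given(hst.integers(0, 2**31 - 1))
    def test_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 31))
        cds = "".join(rng.choice(G.SENSE_CODONS, size=n))
        prof = classify_degeneracy(cds)
        assert prof.S_sites == pytest.approx(
            brute_force_synonymous_mutants(cds) / 3.0, abs=1e-12
        )
        assert prof.S_sites + prof.N_sites == pytest.approx(3 * n)
        assert prof.f0 + prof.f2 + prof.f3 + prof.f4 == 3 * n

    def test_internal_stop_rejected(self):
        with pytest.raises(ValueError):
            classify_degeneracy("ATGTAAGGG")

    def test_terminal_stop_ignored_and_ambiguous_skipped(self):
        prof = classify_degeneracy("ATGANGGGGTAA")
        # ANG codon skipped; ATG + GGG counted
        assert prof.f0 + prof.f2 + prof.f3 + prof.f4 == 6


# ---------------------------------------------------------------- classify
class TestClassifySnp:
    def test_synonymous_third_position(self):
        assert classify_snp("AAA", 2, "A", "G") == "synonymous"  # Lys

    def test_nonsynonymous_first_position(self):
        assert classify_snp("AAA", 0, "A", "C") == "nonsynonymous"  # Gln

    def test_stop_gain_is_nonsynonymous(self):
        assert classify_snp("TGG", 1, "G", "A") == "nonsynonymous"  # TAG stop

    def test_minus_strand_matches_plus_oracle(self):
        cds = "ATGAAAGGCTTT"
        rc = G.reverse_complement(cds)
        for cds_pos in range(len(cds)):
            ref = cds[cds_pos]
            for alt in "ACGT":
                if alt == ref:
                    continue
                plus = classify_snp(cds, cds_pos, ref, alt, strand="+")
                comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
                minus = classify_snp(
                    cds, cds_pos, comp[ref], comp[alt], strand="-"
                )
                assert plus == minus

    def test_mismatching_reference_errors(self):
        with pytest.raises(ValueError):
            classify_snp("AAA", 0, "C", "G")


# ----------------------------------------------------------------- filters
def _record(**kw):
    base = dict(
        scaffold="s1", pos=10, ref="A", alt="G", qual=100.0,
        SAF=5, SAR=5, RPL=5, RPR=5, allele_balance=0.5,
        genotypes=np.array([0, 1, 1, 2, 0, 1, 0, 0]),
        biallelic_snp=True,
    )
    base.update(kw)
    return base


class TestSiteFilters:
    def test_qual_boundary(self):
        df = pd.DataFrame([_record(qual=29.0), _record(qual=31.0)])
        out = site_filters(df)
        assert list(out["qual"]) == [31.0]

    def test_passing_record_retained(self):
        df = pd.DataFrame([_record()])
        assert len(site_filters(df)) == 1

    def test_one_violation_each(self):
        # twelve records, one rule violated apiece (plus one clean)
        rows = [
            _record(),  # clean
            _record(qual=10.0),
            _record(SAF=0),
            _record(SAR=0),
            _record(RPL=1),
            _record(RPR=0),
            _record(allele_balance=0.1),
            _record(allele_balance=0.9),
            _record(biallelic_snp=False),
            _record(genotypes=np.array([-1, -1, -1, -1, -1, 0, 1, 2])),
            # all-het in 20 diploids: exact heterozygote-excess p ~ 8e-6
            # (small tables cannot reach p <= 1e-4, so use a larger one)
            _record(genotypes=np.array([1] * 20)),
            _record(qual=np.nan),  # missing annotation
        ]
        out = site_filters(pd.DataFrame(rows))
        assert len(out) == 1

    def test_hwe_excess_het_pvalue_extremes(self):
        # all heterozygotes: strong excess
        assert hwe_excess_het_pvalue(0, 30, 0) < 1e-4
        # HWE-ish data: no excess
        assert hwe_excess_het_pvalue(16, 8, 1) > 0.5


class TestMafFilter:
    def test_minor_count_three_of_62_removed(self):
        g = np.zeros(31, dtype=int)
        g[:3] = 1  # 3/62 ~ 0.048
        df = pd.DataFrame([_record(genotypes=g)])
        assert len(maf_filter(df, 0.0625)) == 0

    def test_minor_count_four_of_62_kept(self):
        g = np.zeros(31, dtype=int)
        g[:4] = 1  # 4/62 ~ 0.0645
        df = pd.DataFrame([_record(genotypes=g)])
        assert len(maf_filter(df, 0.0625)) == 1

    def test_zero_threshold_is_identity(self):
        df = pd.DataFrame([_record(), _record(pos=11)])
        assert len(maf_filter(df, 0.0)) == 2


class TestSubtractRepeats:
    def test_half_open_convention(self):
        # interval [9, 12) in 0-based = positions 10..12 in 1-based VCF
        repeats = pd.DataFrame(
            [{"scaffold": "s1", "start": 9, "end": 12}]
        )
        snps = pd.DataFrame([
            _record(pos=10),  # 0-based 9 = interval start -> dropped
            _record(pos=13),  # 0-based 12 = interval end -> kept
            _record(pos=5),
        ])
        out = subtract_repeats(snps, repeats)
        assert sorted(out["pos"]) == [5, 13]

    def test_malformed_interval_errors(self):
        repeats = pd.DataFrame([{"scaffold": "s1", "start": 9, "end": 5}])
        with pytest.raises(ValueError):
            subtract_repeats(pd.DataFrame([_record()]), repeats)


# ---------------------------------------------------------------- coverage
class TestCoverage:
    def test_excessive_coverage_hand_cases(self):
        assert excessive_coverage_intervals([10, 10, 25, 25, 10, 30]) == []
        assert excessive_coverage_intervals([10, 40, 40, 10]) == []
        assert excessive_coverage_intervals([10, 60, 60, 10]) == []
        assert excessive_coverage_intervals([0, 80, 80, 0]) == [(1, 3)]
        assert excessive_coverage_intervals([5] * 10) == []
        assert excessive_coverage_intervals([]) == []

    def test_single_spike(self):
        assert excessive_coverage_intervals([1, 1, 1, 1, 50, 1, 1, 1]) == [(4, 5)]

    def test_per_sample_mask_hand_case(self):
        depths = pd.DataFrame({
            "scaffold": ["a", "a", "a", "x", "x"],
            "pos": [1, 2, 3, 1, 2],
            "m1": [30.0, 5.0, 30.0, 15.0, 2.0],
            "f1": [30.0, 30.0, 80.0, 30.0, 30.0],
        })
        sex = {"m1": "male", "f1": "female"}
        removed = per_sample_coverage_mask(depths, sex, x_scaffolds={"x"})
        # m1 median 15 -> autosome bounds (5, 22.5), X bounds (2.5, 11.25)
        # f1 median 30 -> bounds (10, 45) everywhere
        # row0: m1=30 > 22.5 -> removed; row1: m1=5 at bound ok? 5 < 5 False,
        #   but f1=30 fine -> kept; row2: f1=80 > 45 -> removed
        # row3 (X): m1=15 > 11.25 -> removed; row4 (X): m1=2 < 2.5 -> removed
        assert list(removed) == [True, False, True, True, True]

    def test_sex_linked_assignment(self):
        track = im.simulate_coverage(
            {f"a{i}": 30_000 for i in range(9)} | {"x1": 30_000},
            ["x1"], 4, 4, 30.0, seed=9, spike_rate=0.0,
        )
        labels = assign_sex_linked_scaffolds(track)
        assert labels["x1"] == "X"
        assert all(labels[f"a{i}"] == "autosome" for i in range(9))

    def test_normalized_median_is_one(self):
        track = im.simulate_coverage(
            {"a": 50_000}, [], 2, 2, 25.0, seed=10, spike_rate=0.0
        )
        norm = track.normalized()
        for s in track.samples:
            assert norm[s].median() == pytest.approx(1.0)


# ------------------------------------------------------------------- pN/pS
class TestPnps:
    def test_zero_counts(self):
        s = compute_pnps(0, 0, 100.0, 300.0)
        assert s.pnps == 0.0
        assert s.pS_adj == pytest.approx(1 / 100)

    def test_pseudocount_arithmetic(self):
        s = compute_pnps(0, 5, 100.0, 300.0)
        assert s.pN == pytest.approx(5 / 300)
        assert s.pS_adj == pytest.approx(1 / 100)
        assert s.pnps == pytest.approx(5 / 3)

    def test_zero_sites_missing(self):
        s = compute_pnps(1, 1, 0.0, 10.0)
        assert np.isnan(s.pnps)

    def test_mean_ortholog_requires_both_by_default(self):
        a = pd.Series({"g1": 0.2, "g2": 0.5})
        b = pd.Series({"g1": 0.4, "g3": 0.3})
        both = mean_ortholog_pnps(a, b)
        assert both.to_dict() == {"g1": pytest.approx(0.3)}
        loose = mean_ortholog_pnps(a, b, require_both=False)
        assert loose["g2"] == pytest.approx(0.5)

    def test_shared_constraint_gives_positive_correlation(self):
        rng = np.random.default_rng(11)
        n = 120
        true = np.exp(rng.normal(np.log(0.2), 0.6, n))
        cds_pool = ["".join(rng.choice(G.SENSE_CODONS, size=100)) for _ in range(n)]
        vals = {}
        for sp, (ndip, seed0) in {"a": (8, 0), "b": (31, 5000)}.items():
            out = []
            for i, (cds, t) in enumerate(zip(cds_pool, true)):
                var = im.simulate_variants(cds, t, ndip, 0.15, seed=seed0 + i)
                prof = classify_degeneracy(cds)
                n_syn = (var["true_class"] == "synonymous").sum()
                n_non = (var["true_class"] == "nonsynonymous").sum()
                out.append(
                    compute_pnps(n_syn, n_non, prof.S_sites, prof.N_sites).pnps
                )
            vals[sp] = np.array(out)
        from scipy.stats import spearmanr

        r, _ = spearmanr(vals["a"], vals["b"])
        assert r > 0.2

    def test_restrict_to_aligned_intervals(self):
        cds = "ATGAAAGGCTTTCCCGAT"
        prof = classify_degeneracy(cds)
        snps = pd.DataFrame({"cds_pos": [2, 8, 15]})
        sub_prof, sub_snps = restrict_to_aligned_intervals(
            prof, snps, [(0, 9)]
        )
        assert sub_prof.f0 + sub_prof.f2 + sub_prof.f3 + sub_prof.f4 == 9
        assert list(sub_snps["cds_pos"]) == [2, 8]
        # full interval is the identity
        full_prof, full_snps = restrict_to_aligned_intervals(
            prof, snps, [(0, len(cds))]
        )
        assert full_prof.S_sites == pytest.approx(prof.S_sites)
        assert len(full_snps) == 3
        with pytest.raises(ValueError):
            restrict_to_aligned_intervals(prof, snps, [(100, 120)])
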