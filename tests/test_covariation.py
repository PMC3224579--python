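import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sdrcov import (
    DomainAlignment,
    chi2_pvalue,
    covariation_map,
    entropy,
    filter_sites,
    joint_distribution,
    msa_site_distribution,
    mutual_information,
    permutation_pvalue,
    pwm_site_distribution,
    rank_pairs,
    uncertainty_coefficient,
    uniform_weights,
)
from sdrcov.covariation import SiteDistribution
from sdrcov.errors import GapError, ParameterError
from sdrcov.weighting import SequenceWeights
from conftest import make_delta_profiles

AAS = "ACDEFGHIKLMNPQRSTVWY"


def mi_brute_force(msa_col, pwm_col, weights, base):
    """Independent MI oracle: direct summation of p log(p / (px py)) over
    all residue pairs from tallied joint counts."""
    total = sum(weights)
    pj, pk, pjk = {}, {}, {}
    for x, y, w in zip(msa_col, pwm_col, weights):
        pj[x] = pj.get(x, 0.0) + w / total
        pk[y] = pk.get(y, 0.0) + w / total
        pjk[(x, y)] = pjk.get((x, y), 0.0) + w / total
    mi = 0.0
    for (x, y), p in pjk.items():
        mi += p * math.log(p / (pj[x] * pk[y]), base)
    return mi


class TestEntropy:
    def test_conserved_site_is_zero(self):
        p = np.zeros(20)
        p[3] = 1.0
        for base in (2, 10, 20):
            assert entropy(SiteDistribution(p, "msa_site"), base) == 0.0

    def test_uniform_site_is_one_in_base20(self):
        p = np.full(20, 0.05)
        assert entropy(SiteDistribution(p, "msa_site"), 20) == pytest.approx(1.0, abs=1e-12)

    def test_toy_example_entropies_base2(self, table1_alignment):
        w = uniform_weights(4)
        # site 3: four distinct residues; site 4: C,D,E,C
        h3 = entropy(msa_site_distribution(table1_alignment, w, 3), 2)
        h4 = entropy(msa_site_distribution(table1_alignment, w, 4), 2)
        assert h3 == pytest.approx(2.0, abs=1e-12)
        assert h4 == pytest.approx(1.5, abs=1e-12)

    def test_bad_base_rejected(self):
        p = np.full(20, 0.05)
        with pytest.raises(ParameterError):
            entropy(SiteDistribution(p, "msa_site"), 1.0)


class TestDistributions:
    def test_msa_site_frequencies(self, table1_alignment):
        w = uniform_weights(4)
        d = msa_site_distribution(table1_alignment, w, 1)
        assert d.probs[AAS.index("A")] == pytest.approx(0.5)
        assert d.probs[AAS.index("T")] == pytest.approx(0.5)

    def test_zero_weight_rows_vanish(self, table1_alignment):
        w = SequenceWeights(np.array([1.0, 0.0, 0.0, 0.0]))
        d = msa_site_distribution(table1_alignment, w, 1)
        assert d.probs[AAS.index("A")] == pytest.approx(1.0)

    def test_gap_raises_gap_error(self):
        aln = DomainAlignment(ids=["a", "b"], rows=["A-", "AC"])
        with pytest.raises(GapError, match="filter"):
            msa_site_distribution(aln, uniform_weights(2), 2)

    def test_pwm_site_weighted_mean(self, table1_alignment):
        profiles = make_delta_profiles(table1_alignment.ids, ["VVYY"])
        w = SequenceWeights(np.array([0.75, 0.0, 0.25, 0.0]))
        d = pwm_site_distribution(profiles, w, 1)
        assert d.probs[AAS.index("V")] == pytest.approx(0.75)
        assert d.probs[AAS.index("Y")] == pytest.approx(0.25)

    def test_identical_pwms_reproduce_column(self, table1_alignment):
        rng = np.random.default_rng(0)
        col = rng.dirichlet(np.ones(20))
        mats = np.broadcast_to(col, (4, 1, 20)).copy()
        from sdrcov import ProfileSet

        profiles = ProfileSet(ids=table1_alignment.ids, matrices=mats)
        d = pwm_site_distribution(profiles, uniform_weights(4), 1)
        np.testing.assert_allclose(d.probs, col, atol=1e-12)

    def test_joint_perfect_covariation(self, table1_alignment):
        profiles = make_delta_profiles(table1_alignment.ids, ["VVYY"])
        jd = joint_distribution(table1_alignment, profiles, uniform_weights(4), 1, 1)
        assert jd.probs[AAS.index("A"), AAS.index("V")] == pytest.approx(0.5)
        assert jd.probs[AAS.index("T"), AAS.index("Y")] == pytest.approx(0.5)
        assert jd.probs.sum() == pytest.approx(1.0, abs=1e-12)

    def test_joint_marginals_match_site_distributions(self, table1_alignment):
        rng = np.random.default_rng(1)
        from sdrcov import ProfileSet

        mats = rng.dirichlet(np.ones(20), size=(4, 2))
        profiles = ProfileSet(ids=table1_alignment.ids, matrices=mats)
        w = SequenceWeights(rng.random(4) + 0.1)
        jd = joint_distribution(table1_alignment, profiles, w, 1, 2)
        np.testing.assert_allclose(
            jd.msa_marginal(),
            msa_site_distribution(table1_alignment, w, 1).probs,
            atol=1e-9,
        )
        np.testing.assert_allclose(
            jd.pwm_marginal(), pwm_site_distribution(profiles, w, 2).probs, atol=1e-9
        )

    def test_independent_joint_is_outer_product(self, table1_alignment):
        # identical PWMs for all sequences make the joint factorize
        rng = np.random.default_rng(2)
        col = rng.dirichlet(np.ones(20))
        from sdrcov import ProfileSet

        mats = np.broadcast_to(col, (4, 1, 20)).copy()
        profiles = ProfileSet(ids=table1_alignment.ids, matrices=mats)
        w = uniform_weights(4)
        jd = joint_distribution(table1_alignment, profiles, w, 1, 1)
        outer = np.outer(msa_site_distribution(table1_alignment, w, 1).probs, col)
        np.testing.assert_allclose(jd.probs, outer, atol=1e-12)


class TestMutualInformation:
    def test_toy_covarying_pair(self, table1_alignment):
        w = uniform_weights(4)
        profiles = make_delta_profiles(table1_alignment.ids, ["VVYY"])
        h1 = entropy(msa_site_distribution(table1_alignment, w, 1), 2)
        h2 = entropy(pwm_site_distribution(profiles, w, 1), 2)
        hj = entropy(joint_distribution(table1_alignment, profiles, w, 1, 1), 2)
        assert mutual_information(h1, h2, hj) == pytest.approx(1.0, abs=1e-12)

    def test_toy_diverse_pair_scores_higher_mi(self, table1_alignment):
        w = uniform_weights(4)
        profiles = make_delta_profiles(table1_alignment.ids, ["CDEC"])
        sub = DomainAlignment(
            ids=table1_alignment.ids, rows=[r[2] for r in table1_alignment.rows]
        )
        h3 = entropy(msa_site_distribution(sub, w, 1), 2)
        h4 = entropy(pwm_site_distribution(profiles, w, 1), 2)
        hj = entropy(joint_distribution(sub, profiles, w, 1, 1), 2)
        assert mutual_information(h3, h4, hj) == pytest.approx(1.5, abs=1e-12)

    def test_independent_is_zero(self, table1_alignment):
        rng = np.random.default_rng(3)
        col = rng.dirichlet(np.ones(20))
        from sdrcov import ProfileSet

        mats = np.broadcast_to(col, (4, 1, 20)).copy()
        profiles = ProfileSet(ids=table1_alignment.ids, matrices=mats)
        w = uniform_weights(4)
        h1 = entropy(msa_site_distribution(table1_alignment, w, 1))
        h2 = entropy(pwm_site_distribution(profiles, w, 1))
        hj = entropy(joint_distribution(table1_alignment, profiles, w, 1, 1))
        assert mutual_information(h1, h2, hj) == pytest.approx(0.0, abs=1e-12)

    @settings(derandomize=True, max_examples=100)
    @given(st.data())
    def test_brute_force_oracle_delta_pwms(self, data):
        """MI from the distribution pipeline equals direct summation over
        residue pairs for small alignments with delta PWMs."""
        n = data.draw(st.integers(2, 6))
        msa_col = data.draw(st.lists(st.sampled_from(AAS), min_size=n, max_size=n))
        pwm_col = data.draw(st.lists(st.sampled_from(AAS), min_size=n, max_size=n))
        ids = [f"s{i}" for i in range(n)]
        aln = DomainAlignment(ids=ids, rows=msa_col)
        profiles = make_delta_profiles(ids, ["".join(pwm_col)])
        w = uniform_weights(n)
        h1 = entropy(msa_site_distribution(aln, w, 1))
        h2 = entropy(pwm_site_distribution(profiles, w, 1))
        hj = entropy(joint_distribution(aln, profiles, w, 1, 1))
        mi = mutual_information(h1, h2, hj)
        expected = mi_brute_force(msa_col, pwm_col, [1.0] * n, 20)
        assert mi == pytest.approx(expected, abs=1e-12)
        assert -1e-9 <= mi <= min(h1, h2) + 1e-9

    @settings(derandomize=True, max_examples=50)
    @given(seed=st.integers(0, 10_000))
    def test_information_inequality_nondelta(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 7))
        from sdrcov import ProfileSet

        ids = [f"s{i}" for i in range(n)]
        aln = DomainAlignment(
            ids=ids, rows=["".join(rng.choice(list(AAS), 1)) for _ in range(n)]
        )
        mats = rng.dirichlet(np.ones(20) * 0.5, size=(n, 1))
        profiles = ProfileSet(ids=ids, matrices=mats)
        w = SequenceWeights(rng.random(n) + 0.05)
        h1 = entropy(msa_site_distribution(aln, w, 1))
        h2 = entropy(pwm_site_distribution(profiles, w, 1))
        hj = entropy(joint_distribution(aln, profiles, w, 1, 1))
        mi = mutual_information(h1, h2, hj)
        assert 0.0 <= mi <= min(h1, h2) + 1e-9

    def test_base_change_rescales_mi(self, table1_alignment):
        w = uniform_weights(4)
        profiles = make_delta_profiles(table1_alignment.ids, ["VVYY"])

        def mi_in_base(b):
            h1 = entropy(msa_site_distribution(table1_alignment, w, 1), b)
            h2 = entropy(pwm_site_distribution(profiles, w, 1), b)
            hj = entropy(joint_distribution(table1_alignment, profiles, w, 1, 1), b)
            return mutual_information(h1, h2, hj)

        assert mi_in_base(20) * math.log(20) / math.log(2) == pytest.approx(
            mi_in_base(2), rel=1e-9
        )


class TestUncertaintyCoefficient:
    def test_symmetric_toy_values(self):
        assert uncertainty_coefficient(1.0, 1.0, 1.0) == pytest.approx(1.0)
        # diverse unrelated pair drops below the covarying pair
        assert uncertainty_coefficient(1.5, 2.0, 1.5) == pytest.approx(
            2 * 1.5 / 3.5, abs=1e-12
        )
        assert uncertainty_coefficient(1.5, 2.0, 1.5) < 1.0

    def test_variants(self):
        assert uncertainty_coefficient(0.5, 1.0, 2.0, "msa") == pytest.approx(0.5)
        assert uncertainty_coefficient(0.5, 1.0, 2.0, "pwm") == pytest.approx(0.25)

    def test_zero_mi_gives_zero(self):
        for v in ("symmetric", "msa", "pwm"):
            assert uncertainty_coefficient(0.0, 1.0, 1.0, v) == 0.0

    def test_zero_denominator_gives_zero(self):
        assert uncertainty_coefficient(0.0, 0.0, 0.0) == 0.0

    def test_scale_free_in_log_base(self, table1_alignment):
        w = uniform_weights(4)
        profiles = make_delta_profiles(table1_alignment.ids, ["CDEC"])
        ucs = []
        for base in (2.0, 20.0):
            h1 = entropy(msa_site_distribution(table1_alignment, w, 3), base)
            h2 = entropy(pwm_site_distribution(profiles, w, 1), base)
            hj = entropy(
                joint_distribution(table1_alignment, profiles, w, 3, 1), base
            )
            mi = mutual_information(h1, h2, hj)
            ucs.append(uncertainty_coefficient(mi, h1, h2))
        assert ucs[0] == pytest.approx(ucs[1], abs=1e-9)


class TestSignificance:
    def test_chi2_zero_mi(self):
        assert chi2_pvalue(0.0, 100, 4, 4) == pytest.approx(1.0)

    def test_chi2_large_mi_small_p(self):
        assert chi2_pvalue(1.5, 100, 4, 4) < 1e-6

    def test_chi2_matches_reference_sf(self):
        from scipy.stats import chi2 as ref

        mi, n, ca, cb = 0.12, 40, 3, 5
        stat = 2 * math.log(2) * n * mi
        assert chi2_pvalue(mi, n, ca, cb) == pytest.approx(
            ref.sf(stat, (ca - 1) * (cb - 1)), abs=1e-12
        )

    def test_chi2_degenerate_cardinality(self):
        with pytest.raises(ParameterError):
            chi2_pvalue(0.1, 10, 1, 4)

    def test_permutation_constant_site_p_one(self):
        ids = [f"s{i}" for i in range(6)]
        aln = DomainAlignment(ids=ids, rows=["A"] * 6)
        profiles = make_delta_profiles(ids, ["VVVYYY"])
        p = permutation_pvalue(aln, profiles, uniform_weights(6), 1, 1, n_perm=50, seed=0)
        assert p == 1.0

    def test_permutation_detects_perfect_covariation(self):
        ids = [f"s{i}" for i in range(20)]
        col = "AT" * 10
        aln = DomainAlignment(ids=ids, rows=list(col))
        profiles = make_delta_profiles(ids, ["".join("V" if c == "A" else "Y" for c in col)])
        p = permutation_pvalue(aln, profiles, uniform_weights(20), 1, 1, n_perm=999, seed=1)
        assert p <= 0.01

    def test_permutation_deterministic(self, table1_alignment):
        profiles = make_delta_profiles(table1_alignment.ids, ["VVYY"])
        w = uniform_weights(4)
        p1 = permutation_pvalue(table1_alignment, profiles, w, 1, 1, n_perm=200, seed=42)
        p2 = permutation_pvalue(table1_alignment, profiles, w, 1, 1, n_perm=200, seed=42)
        assert p1 == p2


class TestFilter:
    def test_boundary_half_kept(self, table1_alignment):
        report = filter_sites(table1_alignment, uniform_weights(4))
        v = report.verdict(1)  # A,A,T,T: majority exactly half
        assert v.kept and v.majority_fraction == pytest.approx(0.5)

    def test_too_conserved_removed(self):
        aln = DomainAlignment(ids=list("abcd"), rows=["A", "A", "A", "T"])
        report = filter_sites(aln, uniform_weights(4))
        v = report.verdict(1)
        assert not v.kept and v.reasons == {"too_conserved"}

    def test_gap_removed(self):
        aln = DomainAlignment(ids=list("abcd"), rows=["A", "-", "T", "T"])
        report = filter_sites(aln, uniform_weights(4))
        assert report.verdict(1).reasons == {"has_gap"}

    def test_gap_monotonicity(self):
        # adding a gap can only remove a site from the kept set
        aln = DomainAlignment(ids=list("abcd"), rows=["A", "A", "T", "T"])
        kept_before = filter_sites(aln, uniform_weights(4)).verdict(1).kept
        gapped = DomainAlignment(ids=list("abcd"), rows=["A", "A", "T", "-"])
        v = filter_sites(gapped, uniform_weights(4)).verdict(1)
        assert kept_before and not v.kept


class TestCovariationMap:
    def test_toy_map_mi_values(self, table1_alignment):
        # sites 1-2 as the MSA, sites 3-4 wrapped as delta PWMs
        msa = DomainAlignment(
            ids=table1_alignment.ids, rows=[r[:2] for r in table1_alignment.rows]
        )
        profiles = make_delta_profiles(table1_alignment.ids, ["ACDE", "CDEC"])
        cmap = covariation_map(msa, profiles, uniform_weights(4), base=2.0)
        assert set(cmap.pairs) == {(1, 1), (1, 2), (2, 1), (2, 2)}
        # hand evaluation: H(site1)=H(site2)=1, H(ACDE)=2, H(CDEC)=1.5,
        # each joint has four equiprobable cells so H_joint=2
        assert cmap.pairs[(1, 1)].mi == pytest.approx(1.0, abs=1e-12)
        assert cmap.pairs[(2, 1)].mi == pytest.approx(1.0, abs=1e-12)
        assert cmap.pairs[(1, 2)].mi == pytest.approx(0.5, abs=1e-12)
        assert cmap.pairs[(2, 2)].mi == pytest.approx(0.5, abs=1e-12)
        for (j, k), pair in cmap.pairs.items():
            assert pair.mi == pytest.approx(
                pair.h_msa + pair.h_pwm - pair.h_joint, abs=1e-9
            )

    def test_all_conserved_empty_map(self):
        ids = list("abcd")
        aln = DomainAlignment(ids=ids, rows=["AA"] * 4)
        profiles = make_delta_profiles(ids, ["VVVV"])
        cmap = covariation_map(aln, profiles, uniform_weights(4))
        assert cmap.pairs == {}
        assert len(cmap.filter_report.verdicts) == 2
        assert not any(v.kept for v in cmap.filter_report.verdicts)

    def test_weighting_consistency_duplicate_row(self, table1_alignment):
        """Duplicating a sequence and its PWM while halving its weight
        leaves every entropy, MI and UC unchanged."""
        profiles = make_delta_profiles(table1_alignment.ids, ["VVYY", "CDEC"])
        w = uniform_weights(4)
        cmap = covariation_map(table1_alignment, profiles, w)

        dup_aln = DomainAlignment(
            ids=table1_alignment.ids + ["I_dup"],
            rows=table1_alignment.rows + [table1_alignment.rows[0]],
        )
        dup_prof = make_delta_profiles(dup_aln.ids, ["VVYYV", "CDECC"])
        dup_w = SequenceWeights(np.array([0.125, 0.25, 0.25, 0.25, 0.125]))
        dup_map = covariation_map(dup_aln, dup_prof, dup_w)
        for key, pair in cmap.pairs.items():
            other = dup_map.pairs[key]
            for attr in ("h_msa", "h_pwm", "h_joint", "mi", "uc"):
                assert getattr(pair, attr) == pytest.approx(
                    getattr(other, attr), abs=1e-9
                )

    def test_id_mismatch_rejected(self, table1_alignment):
        profiles = make_delta_profiles(["w", "x", "y", "z"], ["VVYY"])
        with pytest.raises(Exception, match="ids"):
            covariation_map(table1_alignment, profiles, uniform_weights(4))


class TestRankPairs:
    def test_single_pair(self, table1_alignment):
        profiles = make_delta_profiles(table1_alignment.ids, ["VVYY"])
        msa = DomainAlignment(
            ids=table1_alignment.ids, rows=[r[0] for r in table1_alignment.rows]
        )
        cmap = covariation_map(msa, profiles, uniform_weights(4))
        assert rank_pairs(cmap)[0][:2] == (1, 1)

    def test_tie_breaks_by_smaller_site(self, table1_alignment):
        msa = DomainAlignment(
            ids=table1_alignment.ids, rows=[r[0] * 2 for r in table1_alignment.rows]
        )
        profiles = make_delta_profiles(table1_alignment.ids, ["VVYY"])
        cmap = covariation_map(msa, profiles, uniform_weights(4))
        ranked = rank_pairs(cmap)
        assert ranked[0][:2] == (1, 1) and ranked[1][:2] == (2, 1)

    def test_per_msa_site_best_keeps_top_k(self, table1_alignment):
        msa = DomainAlignment(
            ids=table1_alignment.ids, rows=[r[0] for r in table1_alignment.rows]
        )
        profiles = make_delta_profiles(table1_alignment.ids, ["VYVY", "VVYY"])
        cmap = covariation_map(msa, profiles, uniform_weights(4))
        ranked = rank_pairs(cmap, per_msa_site_best=True)
        assert len(ranked) == 1
        assert ranked[0][:2] == (1, 2)  # the covarying PWM site wins
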