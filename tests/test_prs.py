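"""PRS computation, allele orientation, percentile and tertile scaling."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from prsgre.exceptions import DegenerateReferenceError, StrandAmbiguityWarning
from prsgre.prs import (GenotypeMatrix, PRSScorer, ReferencePercentiler,
                        TertileAssigner, VariantWeight, compute_prs,
                        percentile_transform, tertile_assign)


def _matrix(dosages, variant_ids=None, alleles=None):
    dosages = np.atleast_2d(np.asarray(dosages, float))
    n, m = dosages.shape
    vids = variant_ids or [f"v{j}" for j in range(m)]
    return GenotypeMatrix([f"p{i}" for i in range(n)], vids, dosages,
                          counted_alleles=alleles)


class TestComputePRS:
    def test_hand_summed_score(self):
        ws = [VariantWeight("v0", "A", "G", 0.1),
              VariantWeight("v1", "A", "G", -0.2),
              VariantWeight("v2", "A", "G", 0.05)]
        prs = compute_prs(_matrix([[1, 2, 0]]), ws)
        assert prs[0] == pytest.approx(-0.3)

    def test_zero_dosages_score_zero(self):
        ws = [VariantWeight("v0", "A", "G", 0.25)]
        assert compute_prs(_matrix([[0], [0]]), ws).tolist() == [0.0, 0.0]
        assert compute_prs(_matrix([[2]]), ws)[0] == pytest.approx(0.5)

    @given(st.permutations(range(5)))
    def test_invariant_to_variant_order(self, perm):
        rng = np.random.default_rng(0)
        dos = rng.integers(0, 3, size=(6, 5)).astype(float)
        ws = [VariantWeight(f"v{j}", "A", "G", w)
              for j, w in enumerate(rng.normal(size=5))]
        base = compute_prs(_matrix(dos), ws)
        shuffled = compute_prs(_matrix(dos[:, perm],
                                       variant_ids=[f"v{j}" for j in perm]), ws)
        np.testing.assert_allclose(shuffled, base, atol=1e-12)

    def test_invariant_to_orientation_flip(self):
        rng = np.random.default_rng(1)
        dos = rng.integers(0, 3, size=(8, 3)).astype(float)
        ws = [VariantWeight(f"v{j}", "A", "G", w)
              for j, w in enumerate([0.3, -0.1, 0.2])]
        eff = {f"v{j}": ("A", "G") for j in range(3)}
        flipped = {"v0": ("G", "A"), "v1": ("A", "G"), "v2": ("G", "A")}
        dos_f = dos.copy()
        dos_f[:, [0, 2]] = 2 - dos_f[:, [0, 2]]
        base = compute_prs(_matrix(dos, alleles=eff), ws)
        flip = compute_prs(_matrix(dos_f, alleles=flipped), ws)
        np.testing.assert_allclose(flip, base, atol=1e-12)

    def test_allele_mismatch_rejected(self):
        ws = [VariantWeight("v0", "A", "G", 0.1)]
        with pytest.raises(ValueError, match="do not match"):
            compute_prs(_matrix([[1]], alleles={"v0": ("C", "T")}), ws)

    def test_strand_ambiguous_variant_warns_but_scores(self):
        ws = [VariantWeight("v0", "A", "T", 0.1)]
        with pytest.warns(StrandAmbiguityWarning):
            prs = compute_prs(_matrix([[2]], alleles={"v0": ("A", "T")}), ws)
        assert prs[0] == pytest.approx(0.2)

    def test_missing_variant_policy(self):
        ws = [VariantWeight("v0", "A", "G", 0.1),
              VariantWeight("zzz", "A", "G", 5.0)]
        with pytest.raises(KeyError):
            compute_prs(_matrix([[1]]), ws)
        prs = compute_prs(_matrix([[1]]), ws, on_missing_variant="drop")
        assert prs[0] == pytest.approx(0.1)

    def test_missing_dosage_filled_with_twice_allele_frequency(self):
        dos = np.array([[0.0], [2.0], [1.0], [np.nan]])
        ws = [VariantWeight("v0", "A", "G", 1.0)]
        prs = compute_prs(_matrix(dos), ws)
        assert prs[3] == pytest.approx(1.0)  # mean observed dosage = 2 * AF
        with pytest.raises(ValueError, match="missing dosages"):
            compute_prs(_matrix(dos), ws, missing_dosage="error")


class TestPercentiles:
    def test_midrank_examples(self):
        assert percentile_transform([3], [1, 2, 3, 4, 5])[0] == pytest.approx(50.0)
        ref = np.arange(9)
        below = percentile_transform([-10], ref)[0]
        assert 0.0 < below < 100.0 / (len(ref) + 1)
        above = percentile_transform([99], ref)[0]
        assert 100.0 * len(ref) / (len(ref) + 1) < above < 100.0

    def test_median_of_reference_maps_to_fifty(self):
        rng = np.random.default_rng(2)
        ref = rng.normal(size=1001)
        assert percentile_transform([np.median(ref)], ref)[0] == pytest.approx(
            50.0, abs=0.2)

    @given(st.lists(st.floats(-50, 50), min_size=2, max_size=40))
    def test_monotone_in_the_score(self, values):
        ref = np.linspace(-10, 10, 31)
        pct = percentile_transform(sorted(values), ref)
        assert np.all(np.diff(pct) >= 0)

    def test_reference_self_transform_is_uniform(self):
        rng = np.random.default_rng(3)
        ref = rng.normal(size=2559)
        pct = percentile_transform(ref, ref)
        ks = stats.kstest(pct / 100.0, "uniform").statistic
        assert ks < 0.02

    def test_empty_reference_rejected(self):
        with pytest.raises(DegenerateReferenceError):
            ReferencePercentiler().fit([])


class TestTertiles:
    def test_distinct_reference_splits_evenly(self):
        rng = np.random.default_rng(4)
        ref = rng.normal(size=2559)
        assert len(np.unique(ref)) == 2559
        labels, counts = np.unique(tertile_assign(ref, ref), return_counts=True)
        assert list(labels) == ["T1", "T2", "T3"]
        assert counts.tolist() == [853, 853, 853]

    def test_boundary_value_closed_on_the_right(self):
        ta = TertileAssigner().fit(np.arange(1, 10))  # q33 = 3, q67 = 6
        assert ta.transform([ta.q33_])[0] == "T1"
        assert ta.transform([ta.q67_])[0] == "T2"
        assert ta.transform([ta.q67_ + 1e-9])[0] == "T3"

    def test_uniform_reference_center_is_t2(self):
        rng = np.random.default_rng(5)
        ref = rng.uniform(0, 1, size=3000)
        assert tertile_assign([0.5], ref)[0] == "T2"

    def test_degenerate_reference_rejected(self):
        with pytest.raises(DegenerateReferenceError):
            TertileAssigner().fit(np.ones(100))

    def test_agrees_with_percentile_thresholds_off_boundaries(self):
        rng = np.random.default_rng(6)
        ref = rng.normal(size=999)
        q = rng.normal(size=500)
        pct = percentile_transform(q, ref)
        tert = tertile_assign(q, ref)
        clear = (np.abs(pct - 100 / 3) > 0.5) & (np.abs(pct - 200 / 3) > 0.5)
        expected = np.where(pct < 100 / 3, "T1",
                            np.where(pct < 200 / 3, "T2", "T3"))
        assert (tert[clear] == expected[clear]).all()

    def test_ordinal_codes(self):
        ta = TertileAssigner().fit(np.arange(30))
        codes = ta.transform_codes([0, 15, 29])
        assert codes.tolist() == [1, 2, 3]
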