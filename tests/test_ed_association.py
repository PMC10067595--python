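import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bsaed.ed_association import (
    AssociationScore,
    call_regions,
    compute_ed,
    compute_threshold,
    ed_to_association,
    fit_local_polynomial,
    fit_scores,
    pool_frequencies,
    score_sites,
    select_candidates,
)
from bsaed.pool_io import AnnotationRecord, PooledSiteCounts


def ed_oracle(high, low):
    """Term-by-term evaluation of the distance, independent of numpy."""
    total = 0.0
    for h, l in zip(high, low):
        total += (h - l) * (h - l)
    return math.sqrt(total)


def random_freq_vector(rng):
    v = rng.random(4)
    return v / v.sum()


class TestPoolFrequencies:
    def test_basic(self):
        site = PooledSiteCounts(
            chrom="chr1", pos=100, ref="A", alt="G",
            high_counts=(12, 0, 8, 0), low_counts=(19, 0, 1, 0),
        )
        high, low = pool_frequencies(site)
        assert high == pytest.approx([0.6, 0.0, 0.4, 0.0])
        assert low == pytest.approx([0.95, 0.0, 0.05, 0.0])

    def test_all_one_base(self):
        site = PooledSiteCounts(
            chrom="chr1", pos=1, ref="A", alt="C",
            high_counts=(20, 0, 0, 0), low_counts=(10, 10, 0, 0),
        )
        high, _ = pool_frequencies(site)
        assert high == pytest.approx([1.0, 0, 0, 0])

    def test_sums_to_one(self, small_sim):
        sites, _ = small_sim
        for site in sites[:200]:
            if site.high_depth and site.low_depth:
                high, low = pool_frequencies(site)
                assert high.sum() == pytest.approx(1.0)
                assert low.sum() == pytest.approx(1.0)

    def test_zero_depth_rejected(self):
        site = PooledSiteCounts(
            chrom="chr1", pos=1, ref="A", alt="C",
            high_counts=(0, 0, 0, 0), low_counts=(10, 10, 0, 0),
        )
        with pytest.raises(ValueError):
            pool_frequencies(site)


class TestComputeEd:
    def test_identical_vectors_zero(self):
        v = [0.25, 0.25, 0.25, 0.25]
        assert compute_ed(v, v) == 0.0

    def test_complete_biallelic_divergence(self):
        assert compute_ed([1, 0, 0, 0], [0, 0, 0, 1]) == pytest.approx(math.sqrt(2))

    def test_hand_case(self):
        high = [0.75, 0.25, 0, 0]
        low = [0.25, 0.75, 0, 0]
        assert compute_ed(high, low) == pytest.approx(math.sqrt(0.5))

    def test_oracle_equivalence(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            h, l = random_freq_vector(rng), random_freq_vector(rng)
            ed = compute_ed(h, l)
            assert ed == pytest.approx(ed_oracle(h, l), abs=1e-12)
            assert ed_to_association(ed) == pytest.approx(ed_oracle(h, l) ** 4, abs=1e-12)

    @given(st.lists(st.floats(0.001, 1), min_size=4, max_size=4),
           st.lists(st.floats(0.001, 1), min_size=4, max_size=4))
    def test_symmetry_and_bounds(self, a, b):
        h = np.array(a) / sum(a)
        l = np.array(b) / sum(b)
        ed = compute_ed(h, l)
        assert ed == compute_ed(l, h)
        assert 0 <= ed <= 2

    def test_ed4_values(self):
        assert ed_to_association(0.0) == 0.0
        assert ed_to_association(math.sqrt(2)) == pytest.approx(4.0)
        assert ed_to_association(0.7071067811865476) == pytest.approx(0.25)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            ed_to_association(-0.1)


class TestLocalPolynomial:
    def test_constant_reproduction(self):
        x = np.arange(50, dtype=float)
        fitted = fit_local_polynomial(x, np.full(50, 3.25))
        assert fitted == pytest.approx(np.full(50, 3.25))

    @pytest.mark.parametrize("degree", [1, 2])
    def test_linear_reproduction(self, degree):
        x = np.sort(np.random.default_rng(3).uniform(0, 1e6, 300))
        y = 2e-6 * x + 0.3
        fitted = fit_local_polynomial(x, y, span=0.2, degree=degree)
        assert np.allclose(fitted, y, atol=1e-6)

    def test_noisy_step_track(self):
        """Plateau of 0.5 over 100 of 10,000 sites recovered within 0.1 at the center."""
        rng = np.random.default_rng(0)
        n = 10_000
        x = np.arange(n, dtype=float)
        y = rng.normal(0, 0.05, n)
        y[4950:5050] += 0.5
        fitted = fit_local_polynomial(x, y, span=0.02, degree=2)
        assert abs(fitted[5000] - 0.5) < 0.1
        # oracle: one independent weighted least-squares solve at the center
        i = 5000
        k = 200
        window = slice(i - k // 2, i + k // 2)
        d = np.abs(x[window] - x[i])
        w = (1 - (d / d.max()) ** 3) ** 3
        V = np.vander(x[window] - x[i], 3, increasing=True)
        beta, *_ = np.linalg.lstsq(V * np.sqrt(w)[:, None], y[window] * np.sqrt(w), rcond=None)
        assert fitted[i] == pytest.approx(beta[0], abs=0.02)

    def test_too_few_sites_falls_back_to_mean(self, caplog):
        fitted = fit_local_polynomial([1.0, 2.0], [1.0, 3.0], degree=2)
        assert fitted == pytest.approx([2.0, 2.0])

    def test_unsorted_rejected(self):
        with pytest.raises(ValueError):
            fit_local_polynomial([3.0, 1.0, 2.0, 4.0], [0.0, 0.0, 0.0, 0.0])

    def test_finite_output_on_fixture(self, small_sim):
        sites, _ = small_sim
        from bsaed.site_filtering import apply_pre_ed_filters

        retained, _ = apply_pre_ed_filters(sites)
        scores = fit_scores(score_sites(retained))
        assert all(np.isfinite(s.fitted) for s in scores)


class TestThreshold:
    def test_constant_values(self):
        thr = compute_threshold([0.3, 0.3, 0.3])
        assert thr.threshold == pytest.approx(0.3)

    def test_hand_case(self):
        thr = compute_threshold([0, 0, 0, 1])
        assert thr.median_fitted == 0.0
        assert thr.sd_fitted == pytest.approx(0.5)
        assert thr.threshold == pytest.approx(1.5)

    def test_step_fixture(self):
        vals = np.concatenate([np.zeros(9900), np.full(100, 0.5)])
        thr = compute_threshold(vals)
        assert thr.threshold == pytest.approx(0.1493, abs=5e-4)
        assert thr.threshold < 0.5

    def test_threshold_at_least_median(self):
        rng = np.random.default_rng(1)
        thr = compute_threshold(rng.random(100))
        assert thr.threshold >= thr.median_fitted

    def test_too_few_values(self):
        with pytest.raises(ValueError):
            compute_threshold([0.5])


def _scores(fitted, chrom="chr1", start_pos=1):
    return [
        AssociationScore(chrom=chrom, pos=start_pos + i * 10, ed=0.1, ed4=1e-4,
                         high_alt_freq=0.5, low_alt_freq=0.5, fitted=f)
        for i, f in enumerate(fitted)
    ]


class TestCallRegions:
    def test_nothing_above_threshold(self):
        assert call_regions(_scores([0.1, 0.1]), 0.15) == []

    def test_single_run(self):
        regions = call_regions(_scores([0.1, 0.2, 0.2, 0.1]), 0.15)
        assert len(regions) == 1
        reg = regions[0]
        assert (reg.start_pos, reg.end_pos) == (11, 21)
        assert len(reg.members) == 2

    def test_step_fixture_single_region(self):
        fitted = np.concatenate([np.zeros(4950), np.full(100, 0.5), np.zeros(4850)])
        thr = compute_threshold(fitted)
        regions = call_regions(_scores(fitted), thr)
        assert len(regions) == 1
        assert len(regions[0].members) == 100

    def test_gap_bridging(self):
        fitted = [0.2, 0.0, 0.2]
        assert len(call_regions(_scores(fitted), 0.1, max_gap_snps=0)) == 2
        bridged = call_regions(_scores(fitted), 0.1, max_gap_snps=1)
        assert len(bridged) == 1
        assert len(bridged[0].members) == 2  # gap site is not a member

    def test_min_region_snps(self):
        fitted = [0.2, 0.0, 0.2, 0.2]
        regions = call_regions(_scores(fitted), 0.1, min_region_snps=2)
        assert len(regions) == 1 and len(regions[0].members) == 2

    def test_strictly_greater(self):
        assert call_regions(_scores([0.15, 0.15]), 0.15) == []

    def test_chromosomes_independent(self):
        scores = _scores([0.2, 0.2], chrom="chr1") + _scores([0.2, 0.2], chrom="chr2")
        regions = call_regions(scores, 0.1)
        assert [r.chrom for r in regions] == ["chr1", "chr2"]


class TestSelectCandidates:
    def _setup(self, high_counts, ed_scale=1.0):
        site = PooledSiteCounts(
            chrom="chr1", pos=11, ref="A", alt="G",
            high_counts=high_counts, low_counts=(19, 0, 1, 0),
        )
        scores = score_sites([site])
        scores = [
            AssociationScore(**{**s.__dict__, "fitted": 1.0, "ed": s.ed * ed_scale,
                                "ed4": (s.ed * ed_scale) ** 4})
            for s in scores
        ]
        regions = call_regions(scores, 0.5)
        ann = AnnotationRecord(chrom="chr1", pos=11, ref="A", alt="G",
                               gene_id="ASMT", region_class="exonic",
                               mutation_class="non-synonymous", aa_change="E/Q")
        return regions, [site], [ann], scores

    def test_selected_with_annotation(self):
        regions, sites, anns, _ = self._setup((2, 0, 18, 0))  # alt freq 0.9, ed ~1.2
        cands = select_candidates(regions, sites, anns)
        assert len(cands) == 1
        assert cands[0].annotation.gene_id == "ASMT"
        assert cands[0].high_call.call == "hom_alt"

    def test_rejected_low_ed(self):
        regions, sites, anns, _ = self._setup((2, 0, 18, 0), ed_scale=0.3)
        assert select_candidates(regions, sites, anns) == []

    def test_rejected_low_freq(self):
        regions, sites, anns, _ = self._setup((8, 0, 12, 0))  # alt freq 0.6
        assert select_candidates(regions, sites, anns) == []

    def test_out_of_region_rejected(self):
        _, sites, anns, scores = self._setup((2, 0, 18, 0))
        assert select_candidates([], sites, anns) == []

    def test_unannotated_gets_null_link(self):
        regions, sites, _, _ = self._setup((2, 0, 18, 0))
        cands = select_candidates(regions, sites, [])
        assert cands[0].annotation is None
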