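"""Subsampling, depth profiles and CD4/CD8 whole-blood reconstitution."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from trbdyn.diversity import sequence_diversity, status_diversity
from trbdyn.repertoire import Compartment, Repertoire, Sex, collapse_clones
from trbdyn.resampling import (
    depth_profile,
    plan_merge,
    reconstitute_whole_blood,
    subsample_to_depth,
)
from trbdyn.synthetic import simulate_repertoire

from conftest import make_record


@pytest.fixture(scope="module")
def medium_repertoire():
    return collapse_clones(
        simulate_repertoire(depth=60_000, n_clones=300, seed=21, sample_id="med")
    )


class TestSubsample:
    def test_full_depth_is_identity(self, medium_repertoire):
        sub = subsample_to_depth(medium_repertoire, medium_repertoire.total_copies, 0)
        assert [r.copy_count for r in sub.records] == [
            r.copy_count for r in medium_repertoire.records
        ]

    def test_depth_one_single_copy(self, medium_repertoire):
        sub = subsample_to_depth(medium_repertoire, 1, 4)
        assert sub.total_copies == 1 and sub.n_records == 1

    def test_exceeding_depth_rejected(self, medium_repertoire):
        with pytest.raises(ValueError, match="pre-filter"):
            subsample_to_depth(medium_repertoire, medium_repertoire.total_copies + 1, 0)

    def test_exact_depth_and_no_clone_inflation(self, medium_repertoire):
        before = {r.nucleotide: r.copy_count for r in medium_repertoire.records}
        for seed in range(5):
            sub = subsample_to_depth(medium_repertoire, 5_000, seed)
            assert sub.total_copies == 5_000
            for rec in sub.records:
                assert rec.copy_count <= before[rec.nucleotide]

    def test_marginal_means_match_hypergeometric(self, medium_repertoire):
        """Expected per-clone draw is depth * p_clone; check the three
        largest clones against 3 SE of the hypergeometric marginal."""
        depth = 10_000
        total = medium_repertoire.total_copies
        counts = medium_repertoire.copy_counts()
        top = np.argsort(counts)[-3:]
        n_rep = 400
        rng = np.random.default_rng(8)
        sums = np.zeros(3)
        for _ in range(n_rep):
            drawn = rng.multivariate_hypergeometric(counts, depth, method="marginals")
            sums += drawn[top]
        means = sums / n_rep
        for k, idx in enumerate(top):
            K = counts[idx]
            mean = depth * K / total
            var = depth * (K / total) * (1 - K / total) * (total - depth) / (total - 1)
            assert abs(means[k] - mean) < 3 * np.sqrt(var / n_rep)

    def test_seed_reproducible(self, medium_repertoire):
        a = subsample_to_depth(medium_repertoire, 2_000, 99)
        b = subsample_to_depth(medium_repertoire, 2_000, 99)
        assert [r.copy_count for r in a.records] == [r.copy_count for r in b.records]

    def test_metadata_preserved(self):
        rep = Repertoire(
            "s", [make_record("A" * 12, 50), make_record("C" * 12, 50)],
            donor_id="d", age=7, sex=Sex.MALE, compartment=Compartment.CD4,
        )
        sub = subsample_to_depth(rep, 10, 0)
        assert (sub.donor_id, sub.age, sub.sex, sub.compartment) == ("d", 7, Sex.MALE, Compartment.CD4)


class TestDepthProfile:
    def test_unsorted_depths_rejected(self, medium_repertoire):
        with pytest.raises(ValueError, match="ascending"):
            depth_profile(medium_repertoire, depths=[100, 50])

    def test_skips_depths_beyond_total(self, medium_repertoire):
        prof = depth_profile(
            medium_repertoire, depths=[1_000, 10_000_000], n_replicates=5, seed=0
        )
        assert prof.skipped_depths == [10_000_000]
        assert list(prof.table.depth) == [1_000]

    def test_replicate_sd_shrinks_with_depth(self, medium_repertoire):
        prof = depth_profile(
            medium_repertoire, depths=[1_000, 16_000], n_replicates=60, seed=1
        )
        sd = prof.table.status_J_sd.to_numpy()
        # binomial noise scales ~ 1/sqrt(depth): expect roughly 4x shrinkage
        assert sd[1] < sd[0] / 2

    def test_status_stable_between_low_depth_and_full(self, medium_repertoire):
        prof = depth_profile(medium_repertoire, depths=[10_000], n_replicates=60, seed=2)
        full = status_diversity(medium_repertoire).J
        assert abs(prof.table.status_J_mean.iloc[0] - full) < 0.005


class TestPlanMerge:
    def test_balanced_ratio_three(self):
        plan = plan_merge(1000, 1000, 3.0)
        assert plan.draw_cd4 == 1000 and plan.draw_cd8 == 333
        assert plan.cd4_fraction == pytest.approx(0.750, abs=1e-3)

    def test_exact_ratio_draws_nothing(self):
        plan = plan_merge(300, 100, 3.0)
        assert plan.overrepresented == "balanced"
        assert (plan.draw_cd4, plan.draw_cd8) == (300, 100)

    def test_even_ratio_downsamples_cd4(self):
        plan = plan_merge(200, 100, 1.0)
        assert (plan.draw_cd4, plan.draw_cd8) == (100, 100)
        assert plan.cd4_fraction == pytest.approx(0.5)

    def test_nonpositive_ratio_rejected(self):
        with pytest.raises(ValueError):
            plan_merge(100, 100, 0.0)

    @given(
        n4=st.integers(min_value=50, max_value=200_000),
        n8=st.integers(min_value=50, max_value=200_000),
        r=st.floats(min_value=0.2, max_value=5.0),
    )
    def test_merged_fraction_matches_blood_ratio(self, n4, n8, r):
        plan = plan_merge(n4, n8, r)
        assert plan.draw_cd4 <= n4 and plan.draw_cd8 <= n8
        tol = 1.0 / min(plan.draw_cd4, plan.draw_cd8)
        assert abs(plan.cd4_fraction - r / (1 + r)) <= tol


@pytest.fixture(scope="module")
def donor_pair():
    kw = dict(donor_id="d1", age=30, sex=Sex.FEMALE, timepoint=0)
    cd4 = simulate_repertoire(
        depth=20_000, productive_fraction=0.90, n_clones=200, seed=31,
        sample_id="cd4", compartment=Compartment.CD4, **kw,
    )
    cd8 = simulate_repertoire(
        depth=10_000, productive_fraction=0.70, n_clones=200, seed=32,
        sample_id="cd8", compartment=Compartment.CD8, **kw,
    )
    return collapse_clones(cd4), collapse_clones(cd8)


class TestReconstitution:

    def test_mismatched_donors_rejected(self, donor_pair):
        cd4, cd8 = donor_pair
        other = Repertoire("x", list(cd8.records), donor_id="OTHER", timepoint=0)
        with pytest.raises(ValueError, match="not paired"):
            reconstitute_whole_blood(cd4, other, ratio=2.0, n_replicates=2, seed=0)

    def test_identical_compartments_at_unit_ratio_are_identity(self, donor_pair):
        cd4, _ = donor_pair
        twin = Repertoire(
            "twin", list(cd4.records), donor_id="d1", timepoint=0,
            compartment=Compartment.CD8, age=30, sex=Sex.FEMALE,
        )
        res = reconstitute_whole_blood(cd4, twin, ratio=1.0, n_replicates=20, seed=5)
        assert res.status_J == pytest.approx(status_diversity(cd4).J, abs=0.01)
        assert res.sequence_J == pytest.approx(sequence_diversity(cd4).J, abs=0.01)

    def test_merged_total_copies_exact_every_replicate(self, donor_pair):
        cd4, cd8 = donor_pair
        res = reconstitute_whole_blood(cd4, cd8, ratio=2.0, n_replicates=10, seed=7)
        assert res.representative.total_copies == res.plan.draw_cd4 + res.plan.draw_cd8

    def test_status_matches_mixture_prediction(self, donor_pair):
        """Merged productive fraction is the copy-weighted mixture of the
        compartment fractions; predict the merged status evenness from it."""
        from trbdyn.diversity import CountVector, pielou_index, status_counts

        cd4, cd8 = donor_pair
        ratio = 2.0
        res = reconstitute_whole_blood(cd4, cd8, ratio=ratio, n_replicates=50, seed=11)
        f = ratio / (1 + ratio)
        p4 = status_counts(cd4).counts[0] / cd4.total_copies
        p8 = status_counts(cd8).counts[0] / cd8.total_copies
        p_mix = f * p4 + (1 - f) * p8
        n = res.plan.draw_cd4 + res.plan.draw_cd8
        predicted = pielou_index(
            CountVector([round(p_mix * n), n - round(p_mix * n)], S=2)
        )
        assert abs(res.status_J - predicted) <= max(3 * res.status_J_sd / np.sqrt(50), 0.004)

    def test_extreme_ratio_recovers_cd4(self, donor_pair):
        # ratio so large that the expected CD8 draw rounds to zero: the
        # merged repertoire is exactly the CD4 compartment
        cd4, cd8 = donor_pair
        res = reconstitute_whole_blood(cd4, cd8, ratio=1e6, n_replicates=5, seed=3)
        assert res.plan.draw_cd8 == 0
        assert res.sequence_J == pytest.approx(sequence_diversity(cd4).J, abs=1e-12)
        assert res.status_J == pytest.approx(status_diversity(cd4).J, abs=1e-12)

    def test_bit_reproducible_with_fixed_seed(self, donor_pair):
        cd4, cd8 = donor_pair
        a = reconstitute_whole_blood(cd4, cd8, ratio=2.0, n_replicates=5, seed=42)
        b = reconstitute_whole_blood(cd4, cd8, ratio=2.0, n_replicates=5, seed=42)
        assert a.status_J == b.status_J and a.sequence_J == b.sequence_J
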