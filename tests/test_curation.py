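"""Curation filters, attribution order, conservation; outlier screening."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from trbdyn.curation import (
    SEQUENCE_FILTERS,
    classify_functionality,
    curate_cohort,
    curate_records,
    filter_metadata,
)
from trbdyn.genes import default_reference
from trbdyn.outliers import detect_outlier_samples, fit_generalized_boxplot
from trbdyn.repertoire import FrameStatus, Repertoire, Sex, UNRESOLVED
from trbdyn.synthetic import simulate_repertoire

from conftest import make_record


class TestFilterMetadata:
    def test_drops_exactly_missing_age_or_sex(self):
        cohort = [
            Repertoire("a", [make_record()], age=3, sex=Sex.MALE),
            Repertoire("b", [make_record()], age=5, sex=None),
            Repertoire("c", [make_record()], age=None, sex=Sex.FEMALE),
        ]
        kept, dropped = filter_metadata(cohort)
        assert [r.sample_id for r in kept] == ["a"]
        assert [r.sample_id for r in dropped] == ["b", "c"]

    def test_identity_when_all_present(self):
        cohort = [Repertoire(f"s{i}", [make_record()], age=i, sex=Sex.MALE) for i in range(4)]
        kept, dropped = filter_metadata(cohort)
        assert kept == cohort and dropped == []


class TestClassifyFunctionality:
    @pytest.mark.parametrize(
        "status,expected",
        [
            (FrameStatus.IN_FRAME, "productive"),
            (FrameStatus.OUT_OF_FRAME, "nonproductive"),
            (FrameStatus.STOP_CODON, "nonproductive"),
        ],
    )
    def test_open_reading_frame_rule(self, status, expected):
        assert classify_functionality(make_record(frame_status=status)) == expected

    def test_unknown_frame_is_an_error(self):
        with pytest.raises(ValueError, match="unknown"):
            classify_functionality(make_record(frame_status=FrameStatus.UNKNOWN))


class TestCurateRecords:
    def violating_records(self):
        return {
            "orphon_v": make_record("A" * 12, 2, v_call="TRBV21/OR9-2"),
            "unresolved_v": make_record("C" * 12, 3, v_call=UNRESOLVED),
            "unresolved_j": make_record("G" * 12, 4, j_call=UNRESOLVED),
            "indexing_error": make_record("T" * 12, 5, cdr3_start=10, n2_start=5),
            "nonfunctional_or_orf_gene": make_record("AC" * 6, 6, v_call="TRBV23-01"),
            "excluded_gene": make_record("AG" * 6, 7, v_call="TRBV03-01"),
        }

    def test_one_removal_per_category(self):
        bad = self.violating_records()
        clean = make_record("AT" * 6, 10)
        rep = Repertoire("s", list(bad.values()) + [clean], age=1, sex=Sex.MALE)
        curated, report = curate_records(rep)
        assert curated.n_records == 1
        for cat, rec in bad.items():
            assert report.removed_sequences[cat] == 1, cat
            assert report.removed_copies[cat] == rec.copy_count, cat
        assert report.retained_copies == 10
        assert report.conserved

    def test_n2_before_cdr3_is_indexing_error(self):
        rep = Repertoire("s", [make_record(cdr3_start=10, n2_start=5)])
        _, report = curate_records(rep)
        assert report.removed_sequences["indexing_error"] == 1

    def test_missing_indices_are_not_indexing_errors(self):
        rep = Repertoire("s", [make_record(cdr3_start=None, n2_start=5)])
        curated, report = curate_records(rep)
        assert curated.n_records == 1

    def test_excluded_gene_attribution_wins_over_functional(self):
        # TRBV03-01 is in the functional set but on the exclusion list
        ref = default_reference()
        assert ref.is_functional_v("TRBV03-01")
        rep = Repertoire("s", [make_record(v_call="TRBV03-01")])
        _, report = curate_records(rep)
        assert report.removed_sequences["excluded_gene"] == 1
        assert report.removed_sequences["nonfunctional_or_orf_gene"] == 0

    def test_first_violated_rule_attribution(self):
        # orphon call that also has an indexing error: attributed to orphon
        rec = make_record(v_call="TRBV21/OR9-2", cdr3_start=10, n2_start=5)
        _, report = curate_records(Repertoire("s", [rec]))
        assert report.removed_sequences["orphon_v"] == 1
        assert report.removed_sequences["indexing_error"] == 0

    def test_idempotence(self):
        rep = simulate_repertoire(
            depth=5000,
            n_clones=50,
            seed=3,
            contamination={"unresolved_v": 0.1, "excluded_gene": 0.02},
        )
        once, report1 = curate_records(rep)
        twice, report2 = curate_records(once)
        assert [r.nucleotide for r in twice.records] == [r.nucleotide for r in once.records]
        assert sum(report2.removed_copies.values()) == 0

    def test_empty_after_curation_flagged_not_raised(self):
        rep = Repertoire("s", [make_record(v_call=UNRESOLVED)])
        curated, report = curate_records(rep)
        assert curated.n_records == 0
        assert report.empty_after_curation

    def test_conservation_on_contaminated_repertoire(self):
        rep = simulate_repertoire(
            depth=20_000,
            n_clones=200,
            seed=9,
            contamination={cat: 0.01 for cat in SEQUENCE_FILTERS},
        )
        _, report = curate_records(rep)
        assert report.conserved


class TestCurateCohort:
    def test_bookkeeping_with_metadata_and_collapse(self):
        reps = [
            simulate_repertoire(depth=2000, n_clones=30, seed=i, sample_id=f"s{i}",
                                age=20 + i, sex=Sex.MALE)
            for i in range(3)
        ]
        reps.append(Repertoire("nometa", [make_record()], age=None, sex=None))
        curated, report = curate_cohort(reps, outlier_alpha=None)
        assert len(curated) == 3
        assert report.removed_sequences["missing_metadata"] == 1
        assert report.conserved


class TestOutlierScreen:
    def test_extreme_sample_flagged(self, rng):
        counts = np.concatenate([rng.uniform(8e5, 1.3e6, 20), [1e9]]).round()
        flags = detect_outlier_samples(counts)
        assert flags[-1]
        assert flags.sum() == 1

    def test_identical_counts_no_flags(self):
        assert detect_outlier_samples(np.full(20, 1e6)).sum() == 0

    def test_too_few_samples_advises_skipping(self):
        with pytest.raises(ValueError, match="skip outlier screening"):
            detect_outlier_samples(np.arange(1, 6))

    def test_fences_match_bruteforce_quantile_model(self, rng):
        """Oracle: recompute the fences from the fitted (g, h) by direct
        evaluation of the quantile transform at the tail probabilities."""
        from scipy import stats

        x = rng.lognormal(14, 0.6, 200)
        box = fit_generalized_boxplot(x, alpha=0.007)
        for z, fence in [
            (stats.norm.ppf(0.0035), box.lower),
            (stats.norm.ppf(0.9965), box.upper),
        ]:
            t = (np.expm1(box.g * z) / box.g if abs(box.g) > 1e-8 else z) * np.exp(
                box.h * z * z / 2.0
            )
            assert fence == pytest.approx(box.A + box.B * t, rel=1e-9)
        assert box.g > 0  # right-skew detected on lognormal data

    def test_symmetric_data_agrees_with_tukey_oracle(self, rng):
        """On well-behaved symmetric data the skew correction is inactive
        and the flags coincide with the classical 1.5-IQR boxplot."""
        bulk = np.clip(rng.normal(1e6, 1e4, 60), 1e6 - 2e4, 1e6 + 2e4)
        x = np.concatenate([bulk, [1e6 + 6e4, 1e6 - 6e4]])
        q1, q3 = np.percentile(x, [25, 75])
        iqr = q3 - q1
        tukey = (x < q1 - 1.5 * iqr) | (x > q3 + 1.5 * iqr)
        flags = detect_outlier_samples(x)
        assert (flags == tukey).all()
        assert flags.sum() == 2

    def test_deterministic(self, rng):
        x = rng.lognormal(14, 0.5, 50)
        f1 = detect_outlier_samples(x)
        f2 = detect_outlier_samples(x)
        assert (f1 == f2).all()


@given(
    counts=st.lists(st.integers(min_value=1, max_value=10_000), min_size=1, max_size=30)
)
def test_retained_set_independent_of_rule_order(counts):
    """Permuting filter attribution never changes which records survive:
    survival is 'violates no rule', independent of ordering."""
    rng = np.random.default_rng(7)
    recs = []
    for i, c in enumerate(counts):
        kind = i % 4
        kw = {}
        if kind == 1:
            kw["v_call"] = UNRESOLVED
        elif kind == 2:
            kw["v_call"] = "TRBV03-01"
        elif kind == 3:
            kw["cdr3_start"], kw["n2_start"] = 10, 4
        recs.append(make_record(f"A{i:03d}CGT{'A' * 8}", c, **kw))
    curated, report = curate_records(Repertoire("s", recs))
    # survivors are exactly the kind-0 records
    assert curated.n_records == sum(1 for i in range(len(counts)) if i % 4 == 0)
    assert report.conserved
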