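"""Cohort survey statistics: fractions, summaries, correlation, censuses."""

import numpy as np
import pytest
from scipy import stats

from mendqc.survey import (
    CensusPredicate,
    DatasetRecord,
    census,
    compute_fractions,
    mend_recommendation,
    read_survey_table,
    records_to_frame,
    spearman_rho,
    summarize,
)


def record(total=100, mapped=90, dup=30, mend=45, ds="d1", cohort="c1"):
    return DatasetRecord(
        dataset_id=ds, cohort=cohort, total_pairs=total, mapped_pairs=mapped,
        duplicate_pairs=dup, mend_pairs=mend,
    )


class TestComputeFractions:
    def test_hierarchy_arithmetic(self):
        r = compute_fractions(record())
        assert r.unmapped_frac == pytest.approx(0.10)
        assert r.dup_frac == pytest.approx(30 / 90)
        assert r.nonexonic_frac == pytest.approx(0.25)
        assert r.mend_frac == pytest.approx(0.45)

    def test_all_duplicate_boundary(self):
        r = compute_fractions(record(total=100, mapped=100, dup=100, mend=0))
        assert r.dup_frac == 1.0 and r.mend_frac == 0.0 and r.nonexonic_frac == 0.0

    def test_fully_exonic_boundary(self):
        r = compute_fractions(record(total=100, mapped=90, dup=30, mend=60))
        assert r.nonexonic_frac == pytest.approx(0.0)

    @pytest.mark.parametrize(
        "kw", [dict(mapped=110), dict(dup=95), dict(mend=70)]
    )
    def test_invariant_violations_rejected(self, kw):
        with pytest.raises(ValueError, match="d1"):
            compute_fractions(record(**kw))


class TestSummarize:
    def test_median_of_three(self):
        recs = [record(ds=f"d{i}", mend=m) for i, m in enumerate((9, 18, 27))]
        s = summarize(recs)
        assert s.stats.loc["mend_frac", "median"] == pytest.approx(0.18)
        assert s.n_datasets == 3

    def test_constant_column_has_zero_iqr(self):
        recs = [record(ds=f"d{i}") for i in range(5)]
        s = summarize(recs)
        row = s.stats.loc["dup_frac"]
        assert row["q3"] - row["q1"] == 0.0

    def test_permutation_invariant(self):
        rng = np.random.default_rng(5)
        recs = [record(ds=f"d{i}", mend=int(m)) for i, m in
                enumerate(rng.integers(0, 60, size=40))]
        s1 = summarize(recs)
        s2 = summarize(list(reversed(recs)))
        assert s1.stats.equals(s2.stats)

    def test_beta_sample_median_near_closed_form(self):
        """Sample medians of Beta-distributed fractions approach the
        distribution median (Monte-Carlo check at n=1000)."""
        rng = np.random.default_rng(12)
        a, b = 2.0, 5.0
        fracs = rng.beta(a, b, size=1000)
        recs = []
        for i, f in enumerate(fracs):
            mapped = 1000
            mend = int(round(mapped * (1 - f)))
            recs.append(record(ds=f"d{i}", total=1000, mapped=mapped, dup=0, mend=mend))
        s = summarize(recs)
        expected = 1 - stats.beta.median(a, b)
        assert s.stats.loc["mend_frac", "median"] == pytest.approx(expected, abs=0.03)

    def test_quantile_method_toggle(self):
        recs = [record(ds=f"d{i}", mend=m) for i, m in enumerate((10, 20, 30, 40))]
        lin = summarize(recs, quantile_method="linear")
        low = summarize(recs, quantile_method="lower")
        assert lin.stats.loc["mend_frac", "q1"] >= low.stats.loc["mend_frac", "q1"]

    def test_empty_table_is_an_error(self):
        with pytest.raises(ValueError):
            summarize([])


class TestSpearman:
    def test_monotone_limits(self):
        x = [1.0, 2.0, 3.0, 5.0]
        assert spearman_rho(x, [10, 20, 30, 50]) == pytest.approx(1.0)
        assert spearman_rho(x, [50, 30, 20, 10]) == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        assert spearman_rho([1, 2, 3, 4], [2, 1, 4, 3]) == pytest.approx(0.6)

    def test_zero_variance_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            spearman_rho([1, 1, 1], [1, 2, 3])

    def test_matches_brute_force_rank_pearson(self):
        """On tie-free inputs the result equals a quadratic rank-counting
        computation followed by Pearson on the ranks."""
        rng = np.random.default_rng(3)
        x = rng.permutation(40).astype(float)
        y = 0.5 * x + rng.normal(size=40) * 10

        def brute_ranks(v):
            return np.array([1 + sum(1 for w in v if w < vi) for vi in v], float)

        rx, ry = brute_ranks(x), brute_ranks(y)
        expected = np.corrcoef(rx, ry)[0, 1]
        assert spearman_rho(x, y) == pytest.approx(expected, abs=1e-12)


class TestCensus:
    def _records(self):
        dups = (60, 60, 20, 10, 5)
        return [record(ds=f"d{i}", mapped=100, total=100, dup=d, mend=20)
                for i, d in enumerate(dups)]

    def test_counts_strictly_above_threshold(self):
        counts = census(self._records(),
                        [CensusPredicate("hi_dup", "dup_frac", ">", 0.5)])
        assert counts == {"hi_dup": 2}

    def test_boundary_value_excluded_by_strictness(self):
        recs = [record(ds="x", mapped=100, total=100, dup=50, mend=20)]
        counts = census(recs, [CensusPredicate("hi_dup", "dup_frac", ">", 0.5)])
        assert counts == {"hi_dup": 0}

    def test_empty_predicate_set(self):
        assert census(self._records(), []) == {}

    def test_additive_over_disjoint_partitions(self):
        recs = self._records()
        pred = [CensusPredicate("hi_dup", "dup_frac", ">", 0.25)]
        whole = census(recs, pred)["hi_dup"]
        parts = census(recs[:2], pred)["hi_dup"] + census(recs[2:], pred)["hi_dup"]
        assert whole == parts

    def test_conditioned_predicate(self):
        deep = CensusPredicate("deep", "mapped_pairs", ">", 50)
        low_mend = CensusPredicate("deep_low_mend", "mend_frac", "<", 0.3, where=deep)
        recs = [record(ds="a", total=100, mapped=90, dup=0, mend=20),   # deep, low mend
                record(ds="b", total=100, mapped=90, dup=0, mend=80),   # deep, high mend
                record(ds="c", total=40, mapped=30, dup=0, mend=5)]     # shallow
        assert census(recs, [low_mend]) == {"deep_low_mend": 1}


class TestMendRecommendation:
    def test_encode_guideline_equivalent(self):
        """30M mapped reads with ~1M unmapped at a 50% MEND fraction
        corresponds to 15.5M MEND reads."""
        assert mend_recommendation(30e6, 1e6, 0.50) == pytest.approx(15.5e6)

    def test_identity_when_everything_is_mend(self):
        assert mend_recommendation(42e6, 0, 1.0) == pytest.approx(42e6)

    def test_scales_with_target(self):
        assert mend_recommendation(20e6, 1e6, 0.50) == pytest.approx(10.5e6)

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            mend_recommendation(30e6, 1e6, 0.0)


class TestTableIO:
    def _write(self, tmp_path, rows, header="dataset_id\tcohort\ttotal\tmapped\tduplicates\tmend"):
        p = tmp_path / "t.tsv"
        p.write_text(header + "\n" + "\n".join(rows) + ("\n" if rows else ""))
        return str(p)

    def test_reads_and_derives_fractions(self, tmp_path):
        path = self._write(tmp_path, ["d1\tc1\t100\t90\t30\t45"])
        (rec,) = read_survey_table(path)
        assert rec.mend_frac == pytest.approx(0.45)

    def test_extra_metadata_columns_tolerated(self, tmp_path):
        path = self._write(
            tmp_path, ["d1\tc1\t100\t90\t30\t45\tglioma"],
            header="dataset_id\tcohort\ttotal\tmapped\tduplicates\tmend\tdisease",
        )
        assert len(read_survey_table(path)) == 1

    def test_column_mapping(self, tmp_path):
        path = self._write(
            tmp_path, ["d1\tc1\t100\t90\t30\t45"],
            header="sample\tgroup\tn_total\tn_mapped\tn_dup\tn_mend",
        )
        recs = read_survey_table(path, column_map={
            "dataset_id": "sample", "cohort": "group", "total_pairs": "n_total",
            "mapped_pairs": "n_mapped", "duplicate_pairs": "n_dup", "mend_pairs": "n_mend",
        })
        assert recs[0].dataset_id == "d1"

    def test_missing_columns_reported_with_available_headers(self, tmp_path):
        path = self._write(tmp_path, ["d1\tc1\t100"], header="dataset_id\tcohort\ttotal")
        with pytest.raises(ValueError, match="available"):
            read_survey_table(path)

    def test_invalid_row_skipped_and_logged(self, tmp_path):
        path = self._write(tmp_path, ["d1\tc1\t100\t90\t30\t45",
                                      "d2\tc1\t100\t110\t30\t45"])
        messages = []
        recs = read_survey_table(path, log=messages.append)
        assert len(recs) == 1
        assert any("d2" in m for m in messages)
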