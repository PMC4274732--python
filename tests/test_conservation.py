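"""Consensus building, Wilcoxon rank-sum, conservation ratios, the
housekeeping reference band and candidate ranking."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import mannwhitneyu

from symsieve import conservation as cons


# ---------------------------------------------------------------------------
# Independent enumeration oracle: U statistic by direct pair comparison,
# null by exhaustive assignment of pooled values to the first group.
# ---------------------------------------------------------------------------

def _u_stat(x, y):
    return sum(
        1.0 if xi > yj else (0.5 if xi == yj else 0.0) for xi in x for yj in y
    )


def oracle_rank_sum_p(x, y):
    pooled = list(x) + list(y)
    n1 = len(x)
    mu = n1 * len(y) / 2.0
    dev = abs(_u_stat(x, y) - mu)
    total = extreme = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        rest = [pooled[i] for i in range(len(pooled)) if i not in combo]
        sub = [pooled[i] for i in combo]
        total += 1
        if abs(_u_stat(sub, rest) - mu) >= dev - 1e-9:
            extreme += 1
    return extreme / total


class TestConsensus:
    def test_majority_per_column(self):
        aln = cons.AlignedCluster("c", {"Mtr_a": "ACD", "Gma_b": "ACD", "Sly_c": "AGD"})
        assert cons.consensus_from_alignment(aln) == "ACD"

    def test_gap_majority_column_is_dropped(self):
        aln = cons.AlignedCluster("c", {"Mtr_a": "A-D", "Gma_b": "A-D", "Sly_c": "AGD"})
        assert cons.consensus_from_alignment(aln) == "AD"

    def test_single_row_returns_itself_minus_gaps(self):
        aln = cons.AlignedCluster("c", {"Mtr_a": "AC-D"})
        assert cons.consensus_from_alignment(aln) == "ACD"

    def test_residue_ties_break_alphabetically(self):
        aln = cons.AlignedCluster("c", {"Mtr_a": "W", "Gma_b": "C"})
        assert cons.consensus_from_alignment(aln) == "C"

    def test_species_restriction(self):
        aln = cons.AlignedCluster(
            "c", {"Mtr_a": "AAA", "Gma_b": "AAA", "Ath_x": "CCC"}
        )
        assert cons.consensus_from_alignment(aln, restrict_to=["Mtr", "Gma"]) == "AAA"
        with pytest.raises(ValueError):
            cons.consensus_from_alignment(aln, restrict_to=["Osa"])


class TestHitTable:
    def _write(self, path, lines):
        path.write_text("\n".join(lines) + "\n")
        return path

    def _line(self, query, subject, evalue):
        return "\t".join(
            [query, subject, "50.0", "100", "0", "0", "1", "100", "1", "100",
             evalue, "200.0"]
        )

    def test_parse_rows_and_species(self, tmp_path, toy_groups):
        path = self._write(
            tmp_path / "hits.tsv",
            [
                self._line("q1", "Mtr_P1", "1e-50"),
                self._line("q1", "Ath_P2", "1e-5"),
                self._line("q2", "Mtr_P3", "2.5"),
            ],
        )
        table = cons.ingest_hit_table(path, groups=toy_groups)
        assert len(table) == 3
        assert set(table["species"]) == {"Mtr", "Ath"}

    def test_extreme_evalue_parses_exactly(self, tmp_path, toy_groups):
        path = self._write(
            tmp_path / "h.tsv", [self._line("q", "Mtr_P", "1e-180")]
        )
        assert cons.ingest_hit_table(path, groups=toy_groups)["evalue"].iloc[0] == 1e-180

    def test_wrong_column_count_names_the_line(self, tmp_path, toy_groups):
        path = tmp_path / "h.tsv"
        path.write_text(self._line("q", "Mtr_P", "1e-5") + "\n" + "a\tb\tc\n")
        with pytest.raises(ValueError, match=":2"):
            cons.ingest_hit_table(path, groups=toy_groups)

    def test_non_numeric_evalue_names_the_line(self, tmp_path, toy_groups):
        path = self._write(tmp_path / "h.tsv", [self._line("q", "Mtr_P", "oops")])
        with pytest.raises(ValueError, match=":1"):
            cons.ingest_hit_table(path, groups=toy_groups)

    def test_best_hit_reduce_takes_the_minimum(self):
        hits = pd.DataFrame(
            [
                ("q", "s1", "Mtr", 1e-3),
                ("q", "s2", "Mtr", 1e-50),
                ("q", "s3", "Ath", 0.5),
            ],
            columns=cons.HIT_COLUMNS,
        )
        best = cons.best_hit_reduce(hits).set_index("species")["evalue"]
        assert best["Mtr"] == 1e-50
        assert best["Ath"] == 0.5


class TestGroupAverage:
    def test_mean_over_present_species(self):
        assert cons.group_average(
            {"Mtr": 1e-10, "Gma": 3e-10}, ["Mtr", "Gma"]
        ) == pytest.approx(2e-10)

    def test_missing_species_are_excluded_not_zero_filled(self):
        assert cons.group_average({"Mtr": 1e-5}, ["Mtr", "Gma", "Sly"]) == 1e-5

    def test_entirely_missing_group_is_undefined(self):
        assert math.isnan(cons.group_average({}, ["Ath", "Aly"]))


class TestWilcoxon:
    def test_identical_multisets_give_p_one(self):
        assert cons.wilcoxon_group_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 1.0

    def test_fully_separated_3_vs_6(self):
        p = cons.wilcoxon_group_test([10, 11, 12], [1, 2, 3, 4, 5, 6])
        assert p == pytest.approx(2 / 84)

    def test_fully_separated_3_vs_7(self):
        p = cons.wilcoxon_group_test([10, 11, 12], [1, 2, 3, 4, 5, 6, 7])
        assert p == pytest.approx(2 / 120)

    def test_exact_matches_enumeration_oracle_on_random_configs(self):
        rng = np.random.default_rng(13)
        for _ in range(25):
            n1 = int(rng.integers(1, 4))
            n2 = int(rng.integers(1, 8))
            x = list(rng.integers(0, 6, size=n1).astype(float))  # ties likely
            y = list(rng.integers(0, 6, size=n2).astype(float))
            assert cons.wilcoxon_group_test(x, y) == pytest.approx(
                oracle_rank_sum_p(x, y)
            )

    def test_invariant_under_monotone_log_transform(self):
        rng = np.random.default_rng(3)
        x = list(10.0 ** -rng.uniform(1, 150, size=3))
        y = list(10.0 ** -rng.uniform(1, 150, size=6))
        assert cons.wilcoxon_group_test(x, y) == pytest.approx(
            cons.wilcoxon_group_test([math.log10(v) for v in x],
                                     [math.log10(v) for v in y])
        )

    def test_large_sample_approximation_tracks_scipy(self):
        rng = np.random.default_rng(9)
        x = list(rng.normal(0, 1, size=10))
        y = list(rng.normal(0.8, 1, size=12))
        ours = cons.wilcoxon_group_test(x, y)
        ref = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue
        assert ours == pytest.approx(ref, rel=1e-6)

    def test_empty_side_is_undefined(self):
        assert math.isnan(cons.wilcoxon_group_test([], [1.0]))


class TestConservationRatio:
    def test_direct_evaluations(self):
        assert cons.conservation_ratio(1e-5, 1e-150) == pytest.approx(145.0)
        assert cons.conservation_ratio(1e-7, 1e-7) == 0.0
        assert cons.conservation_ratio(1e-120, 1e-100) == pytest.approx(-20.0)

    def test_floor_applies_before_log(self):
        assert cons.conservation_ratio(1e-5, 0.0) == pytest.approx(175.0)

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(
        st.floats(min_value=-170, max_value=0),
        st.floats(min_value=-170, max_value=0),
    )
    def test_antisymmetry(self, la, lb):
        a, b = 10.0**la, 10.0**lb
        assert cons.conservation_ratio(a, b) == pytest.approx(
            -cons.conservation_ratio(b, a), abs=1e-9
        )

    def test_monotonicity_in_both_arguments(self):
        assert cons.conservation_ratio(1e-5, 1e-50) > cons.conservation_ratio(
            1e-6, 1e-50
        )
        assert cons.conservation_ratio(1e-5, 1e-50) < cons.conservation_ratio(
            1e-5, 1e-60
        )


def _record(cid, e_a, e_b, e_c, ratio_ca, cls="nonsignificant", zero=False):
    return {
        "cluster_id": cid, "E_A": e_a, "E_B": e_b, "E_C": e_c,
        "p_CA": 0.5, "p_CB": 0.5, "q_CA": 0.5,
        "ratio_CA": ratio_ca, "ratio_CB": ratio_ca, "class": cls,
        "flag_CA": False, "flag_CB": False, "flag_both": False,
        "zero_E": zero, "n_A": 6, "n_B": 7, "n_C": 3,
    }


class TestReferenceBand:
    def test_median_centered_window(self):
        records = pd.DataFrame(
            [_record(f"c{i:03d}", 10.0 ** -(i / 2 + 1), 1e-5, 1e-5, float(i))
             for i in range(300)]
        )
        band = cons.select_reference_band(records, n=150)
        # ranked by E_A ascending = i descending; middle 150 are i = 75..224
        assert len(band.cluster_ids) == 150
        picked = {int(c[1:]) for c in band.cluster_ids}
        assert picked == set(range(75, 225))

    def test_exclusions(self):
        records = pd.DataFrame(
            [
                _record("ok", 1e-10, 1e-9, 1e-8, 1.0),
                _record("zero", 0.0, 1e-9, 1e-8, 1.0, zero=True),
                _record("no_monocot", 1e-10, float("nan"), 1e-8, 1.0),
            ]
        )
        band = cons.select_reference_band(records, n=3)
        assert band.cluster_ids == ["ok"]

    def test_fewer_than_n_takes_all_with_warning(self, caplog):
        records = pd.DataFrame(
            [_record(f"c{i}", 1e-10, 1e-9, 1e-8, float(i)) for i in range(5)]
        )
        with caplog.at_level("WARNING"):
            band = cons.select_reference_band(records, n=150)
        assert len(band.cluster_ids) == 5
        assert any("eligible" in m for m in caplog.messages)


class TestRanking:
    def test_nan_class_first_then_descending_ratio(self):
        records = pd.DataFrame(
            [
                _record("mid", 1e-50, 1e-50, 1e-30, 20.0),
                _record("nanc", 1e-50, 1e-50, float("nan"), float("nan"),
                        cls=cons.CLASS_NAN),
                _record("top", 1e-160, 1e-160, 1e-10, 150.0),
                _record("neg", 1e-30, 1e-30, 1e-35, -5.0),
            ]
        )
        ranked = cons.rank_candidates(records)
        assert list(ranked["cluster_id"]) == ["nanc", "top", "mid", "neg"]

    def test_both_ratios_above_threshold_flag(self, toy_groups):
        best = pd.DataFrame(
            [("q", c, 1e-150) for c in ("Mtr", "Gma", "Sly", "Stu", "Vvi", "Ptr")]
            + [("q", c, 1e-150) for c in ("Osa", "Zma")]
            + [("q", c, 1e-10) for c in ("Ath", "Aly", "Bra")],
            columns=["query", "species", "evalue"],
        )
        records = cons.build_conservation_records(best, toy_groups)
        assert bool(records["flag_both"].iloc[0]) is True
        assert records["class"].iloc[0] == cons.CLASS_RATIO

    def test_empty_input_gives_empty_report(self):
        ranked = cons.rank_candidates(pd.DataFrame(columns=cons.RECORD_COLUMNS))
        assert len(ranked) == 0


class TestBuildRecords:
    def test_no_negative_hits_yields_nan_class(self, toy_groups):
        best = pd.DataFrame(
            [("q", c, 1e-120) for c in ("Mtr", "Gma", "Sly")],
            columns=["query", "species", "evalue"],
        )
        records = cons.build_conservation_records(best, toy_groups)
        assert records["class"].iloc[0] == cons.CLASS_NAN
        assert math.isnan(records["ratio_CA"].iloc[0])

    def test_query_without_group_a_hits_is_dropped(self, toy_groups, caplog):
        best = pd.DataFrame(
            [("q", "Ath", 1e-5)], columns=["query", "species", "evalue"]
        )
        with caplog.at_level("WARNING"):
            records = cons.build_conservation_records(best, toy_groups)
        assert records.empty
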