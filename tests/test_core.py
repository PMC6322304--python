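import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pepdegradome import (
    FilteredPeptidome,
    ProteomeMap,
    fold_change_table,
    intensity_correlation,
    locate_peptides,
    new_precursor_fraction,
    replicate_filter,
    small_protein_flags,
    venn_counts,
)
from pepdegradome.core import (
    classify_cterminal,
    is_cterminal,
    log2_fold_change,
    percent_shared_by_repeat,
)

from conftest import make_peptide_row, make_table


class TestLocatePeptides:
    def test_single_exact_match(self, tiny_proteome):
        df = make_table([make_peptide_row("AAPLQ", None, np.nan, np.nan)])
        out = locate_peptides(df, tiny_proteome)
        assert out.loc[0, "matches"] == [("P1", 4, 8)]
        assert not out.loc[0, "ambiguous"]

    def test_multi_site_sets_ambiguity(self, tiny_proteome):
        df = make_table([make_peptide_row("MK", None, np.nan, np.nan)])
        out = locate_peptides(df, tiny_proteome)
        sites = set(out.loc[0, "matches"])
        # manual scan: MK at P1 1-2, P2 1-2 and 3-4
        assert sites == {("P1", 1, 2), ("P2", 1, 2), ("P2", 3, 4)}
        assert out.loc[0, "ambiguous"]

    def test_no_match_flags_unmapped(self, tiny_proteome):
        df = make_table([make_peptide_row("WWWW", None, np.nan, np.nan)])
        out = locate_peptides(df, tiny_proteome)
        assert out.loc[0, "unmapped"]
        assert out.loc[0, "matches"] == []


class TestReplicateFilter:
    def test_threshold_inclusion(self):
        rows = [
            make_peptide_row("AAAA", "P1", 1, 4, repeats=(1, 3)),
            make_peptide_row("CCCC", "P1", 1, 4, repeats=(2,)),
        ]
        filtered = replicate_filter(make_table(rows), 2, n_repeats_design=3)
        assert filtered.sequences("cell", "control") == {"AAAA"}

    def test_min_repeats_beyond_design_errors(self):
        rows = [make_peptide_row("AAAA", "P1", 1, 4, repeats=(1, 2))]
        with pytest.raises(ValueError, match="design"):
            replicate_filter(make_table(rows), 4, n_repeats_design=3)

    def test_duplicate_sequences_merged(self):
        rows = [
            make_peptide_row("AAAA", "P1", 1, 4, repeats=(1,), intensity_1=10.0),
            make_peptide_row("AAAA", "P1", 1, 4, repeats=(2,), intensity_1=30.0),
        ]
        filtered = replicate_filter(make_table(rows), 2, n_repeats_design=3)
        table = filtered.table("cell", "control")
        assert len(table) == 1
        assert table.loc[0, "repeats"] == frozenset({1, 2})
        assert table.loc[0, "intensity_1"] == 20.0

    @given(st.lists(st.frozensets(st.integers(1, 3), min_size=1), min_size=1,
                    max_size=20))
    @settings(max_examples=50, deadline=None)
    def test_retained_count_monotone_in_min_repeats(self, presence_sets):
        rows = [
            make_peptide_row(f"PEP{i}AAAA", "P1", 1, 4, repeats=reps)
            for i, reps in enumerate(presence_sets)
        ]
        table = make_table(rows)
        counts = [
            len(replicate_filter(table, k, n_repeats_design=3)
                .sequences("cell", "control"))
            for k in (1, 2, 3)
        ]
        assert counts == sorted(counts, reverse=True)


class TestVenn:
    def test_partition_example(self):
        v = venn_counts({"x", "y"}, {"y", "z"})
        assert (v.unique_a, v.shared, v.unique_b) == (1, 1, 1)

    def test_identical_sets(self):
        v = venn_counts({"a", "b"}, {"a", "b"})
        assert (v.unique_a, v.shared, v.unique_b) == (0, 2, 0)

    @given(st.sets(st.text("ACDG", min_size=1, max_size=5)),
           st.sets(st.text("ACDG", min_size=1, max_size=5)))
    @settings(max_examples=100, deadline=None)
    def test_additivity(self, a, b):
        v = venn_counts(a, b)
        assert v.unique_a + v.shared + v.unique_b == len(a | b)

    def test_percent_shared_dispersion_over_repeats(self):
        ta = make_table([
            make_peptide_row("AAAA", "P1", 1, 4, repeats=(1, 2)),
            make_peptide_row("CCCC", "P1", 1, 4, repeats=(1, 2)),
        ])
        tb = make_table([
            make_peptide_row("AAAA", "P1", 1, 4, condition="treated",
                             repeats=(1, 2)),
        ])
        mean, sd = percent_shared_by_repeat(ta, tb)
        assert mean == pytest.approx(50.0)
        assert sd == pytest.approx(0.0)


class TestNewPrecursors:
    def test_hand_count(self):
        unique = make_table([
            make_peptide_row("AAAA", "P1", 1, 4, condition="treated"),
            make_peptide_row("CCCC", "P2", 1, 4, condition="treated"),
        ])
        control = make_table([make_peptide_row("GGGG", "P1", 1, 4)])
        count, frac = new_precursor_fraction({"AAAA", "CCCC"}, unique, control)
        assert (count, frac) == (1, 0.5)

    def test_reference_superset_gives_zero(self):
        unique = make_table([make_peptide_row("AAAA", "P1", 1, 4)])
        control = make_table([
            make_peptide_row("GGGG", "P1", 1, 4),
            make_peptide_row("TTTT", "P2", 1, 4),
        ])
        assert new_precursor_fraction({"AAAA"}, unique, control) == (0, 0.0)

    def test_empty_unique_set_undefined(self):
        control = make_table([make_peptide_row("GGGG", "P1", 1, 4)])
        count, frac = new_precursor_fraction(set(), control.iloc[:0], control)
        assert count == 0 and frac is None


class TestCterminal:
    @pytest.mark.parametrize("L,start,window,expected", [
        (100, 60, 50, True),    # 60 >= 100-50+1
        (100, 51, 50, True),
        (100, 50, 50, False),
        (100, 1, 50, False),
        (40, 1, 50, True),      # whole protein inside the window
    ])
    def test_boundary_arithmetic(self, L, start, window, expected):
        assert is_cterminal(start, L, window) is expected

    def test_agrees_with_enumeration_oracle(self):
        """Brute force: the qualifying starts are exactly the last w positions."""
        for L in range(1, 121):
            for w in range(0, 61):
                qualifying = set(range(max(1, L - w + 1), L + 1)) if w else set()
                for s in range(1, L + 1):
                    assert is_cterminal(s, L, w) == (s in qualifying)

    def test_ambiguous_record_true_if_any_site_qualifies(self, tiny_proteome):
        row = make_table([make_peptide_row("MK", "P2", 1, 2)]).iloc[0].copy()
        row["matches"] = [("P2", 1, 2), ("P2", 3, 4)]
        assert classify_cterminal(row, tiny_proteome, window_aa=2)

    def test_unmapped_record_errors(self, tiny_proteome):
        row = make_table([make_peptide_row("WWWW", None, np.nan, np.nan)]).iloc[0]
        with pytest.raises(ValueError, match="unmapped"):
            classify_cterminal(row, tiny_proteome)


def _filtered_from(rows, min_repeats=2):
    return replicate_filter(make_table(rows), min_repeats, n_repeats_design=3)


class TestFoldChange:
    def test_doubling_gives_plus_one(self):
        assert log2_fold_change(100.0, 200.0) == pytest.approx(1.0)
        assert log2_fold_change(5.0, 5.0) == 0.0

    def test_table_statuses(self):
        rows = [
            make_peptide_row("AAAA", "P1", 1, 4, condition="control",
                             repeats=(1, 2), intensity_1=100.0, intensity_2=100.0),
            make_peptide_row("AAAA", "P1", 1, 4, condition="treated",
                             repeats=(1, 2), intensity_1=200.0, intensity_2=200.0),
            make_peptide_row("CCCC", "P1", 1, 4, condition="control",
                             repeats=(1, 2), intensity_1=50.0, intensity_2=50.0),
        ]
        fc = fold_change_table(_filtered_from(rows), "cell")
        fc = fc.set_index("sequence")
        assert fc.loc["AAAA", "status"] == "ok"
        assert fc.loc["AAAA", "log2fc"] == pytest.approx(1.0)
        assert fc.loc["CCCC", "status"] == "present_only_from"
        assert math.isnan(fc.loc["CCCC", "log2fc"])

    def test_antisymmetry(self):
        rows = [
            make_peptide_row("AAAA", "P1", 1, 4, condition="control",
                             repeats=(1, 2), intensity_1=80.0, intensity_2=120.0),
            make_peptide_row("AAAA", "P1", 1, 4, condition="treated",
                             repeats=(1, 2), intensity_1=260.0, intensity_2=240.0),
        ]
        filtered = _filtered_from(rows)
        fwd = fold_change_table(filtered, "cell", "control", "treated")
        rev = fold_change_table(filtered, "cell", "treated", "control")
        assert fwd.loc[0, "log2fc"] == pytest.approx(-rev.loc[0, "log2fc"])

    def test_known_effect_recovered_without_noise(self):
        """A simulated 2.5x treatment effect with no repeat noise."""
        rows = []
        for i in range(3):
            seq = "AAPL" + "ACDE"[i] * 4
            base = 1000.0 * (i + 1)
            rows.append(make_peptide_row(seq, "P1", 1, 8, condition="control",
                                         repeats=(1, 2, 3), intensity_1=base,
                                         intensity_2=base, intensity_3=base))
            rows.append(make_peptide_row(seq, "P1", 1, 8, condition="treated",
                                         repeats=(1, 2, 3), intensity_1=base * 2.5,
                                         intensity_2=base * 2.5,
                                         intensity_3=base * 2.5))
        fc = fold_change_table(_filtered_from(rows), "cell")
        assert np.allclose(fc["log2fc"], math.log2(2.5))


class TestIntensityCorrelation:
    @staticmethod
    def _fc_frame(x, y):
        return pd.DataFrame({
            "sequence": [f"S{i}" for i in range(len(x))],
            "mean_from": 10.0 ** np.asarray(x),
            "mean_to": 10.0 ** np.asarray(y),
            "n_from": 2, "n_to": 2,
            "log2fc": 0.0, "status": "ok",
        })

    def test_perfect_correlations(self):
        r, _, n = intensity_correlation(self._fc_frame([1, 2, 3], [1, 2, 3]))
        assert r == pytest.approx(1.0)
        r, _, _ = intensity_correlation(self._fc_frame([1, 2, 3], [3, 2, 1]))
        assert r == pytest.approx(-1.0)

    def test_too_few_pairs_errors(self):
        with pytest.raises(ValueError, match=">=3"):
            intensity_correlation(self._fc_frame([1, 2], [1, 2]))

    def test_monte_carlo_population_r(self):
        """Shared log-normal signal + noise with population r = 0.7.

        r = var(s)/(var(s)+var(e)) when x = s+e1, y = s+e2 with equal noise;
        the sample estimate over 100 pairs must sit within 0.7 +/- 0.15
        across seeds.
        """
        target = 0.7
        sd_noise = math.sqrt(1.0 * (1 / target - 1))
        for seed in range(10):
            rng = np.random.default_rng(seed)
            s = rng.normal(5, 1.0, 100)
            x = s + rng.normal(0, sd_noise, 100)
            y = s + rng.normal(0, sd_noise, 100)
            r, _, n = intensity_correlation(self._fc_frame(x, y))
            assert n == 100
            assert abs(r - target) < 0.15


class TestSmallProteins:
    def test_strict_inequality(self):
        prot = ProteomeMap({"P1": "A" * 199, "P2": "A" * 200})
        assert small_protein_flags(prot, 200) == {"P1"}

    def test_empty_and_zero_threshold(self):
        assert small_protein_flags(ProteomeMap({}), 200) == set()
        prot = ProteomeMap({"P1": "AAAA"})
        assert small_protein_flags(prot, 0) == set()
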