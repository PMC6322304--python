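import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from pepdegradome import (
    ProteomeMap,
    aa_frequencies,
    background_peptides,
    cluster_enrichment,
    cluster_indexes,
    compare_aaf,
    mannwhitney,
    peptide_property,
    property_matrix,
    property_screen,
    synthetic_aaindex,
    terminal_profile,
)
from pepdegradome.io import AA20
from pepdegradome.physchem import (
    IndexClustering,
    assign_tier,
    mannwhitney_exact,
)

from conftest import make_peptide_row, make_table

peptides_strategy = st.lists(
    st.text(alphabet=AA20, min_size=1, max_size=20), min_size=1, max_size=30
)


class TestAAFrequencies:
    def test_two_residue_example(self):
        f = aa_frequencies({"AA", "GG"})
        assert f["A"] == pytest.approx(0.5)
        assert f["G"] == pytest.approx(0.5)

    def test_nonstandard_excluded_from_both_sides(self):
        f = aa_frequencies({"AXAG"})
        assert f["A"] == pytest.approx(2 / 3)
        assert f["G"] == pytest.approx(1 / 3)
        assert f.attrs["total"] == 3

    def test_empty_set_errors(self):
        with pytest.raises(ValueError):
            aa_frequencies(set())

    @given(peptides_strategy)
    @settings(max_examples=50, deadline=None)
    def test_frequencies_sum_to_one(self, peps):
        f = aa_frequencies(peps)
        assert f.sum() == pytest.approx(1.0, abs=1e-9)
        assert (f >= 0).all()


class TestCompareAAF:
    def test_identical_sets_nothing_significant(self):
        peps = ["ACDKLM", "GGHWYV", "PQRST"]
        out = compare_aaf(peps, list(peps))
        assert not out["significant"].any()
        assert (out["p"] == 1.0).all()

    def test_perfect_separation_matches_hypergeometric(self):
        # counts A: [[10, 0], [0, 10]] -> two-sided Fisher p = 2/184756
        out = compare_aaf(["A"] * 10, ["G"] * 10)
        assert out.loc["A", "p"] == pytest.approx(2 / 184756)
        assert out.loc["G", "p"] == pytest.approx(2 / 184756)

    def test_doubled_residue_detected_at_scale(self):
        """Power check: an A-enriched set vs background, ~10,000 residues."""
        rng = np.random.default_rng(0)
        freqs = np.ones(20) / 20
        enriched = freqs.copy()
        enriched[0] *= 2
        enriched /= enriched.sum()
        draw = lambda p, n: [
            "".join(rng.choice(list(AA20), 10, p=p)) for _ in range(n)
        ]
        out = compare_aaf(draw(enriched, 1000), draw(freqs, 1000))
        assert out.loc["A", "significant"]


class TestBackgroundPeptides:
    def test_fully_covered_precursor_unusable(self):
        prot = ProteomeMap({"P1": "AAAAACCCCC"})
        observed = make_table([make_peptide_row("AAAAACCCCC", "P1", 1, 10)])
        with pytest.raises((ValueError, RuntimeError)):
            background_peptides(prot, observed, 5, np.random.default_rng(0))

    def test_samples_confined_to_unmasked_run(self):
        prot = ProteomeMap({"P1": "AAAAACCCCC"})
        observed = make_table([make_peptide_row("AAAAA", "P1", 1, 5)])
        peps = background_peptides(prot, observed, 50, np.random.default_rng(0))
        assert peps and all(set(p) == {"C"} for p in peps)

    def test_deterministic_given_seed(self, small_simulation):
        _cfg, proteome, _topo, peptides, _truth = small_simulation
        a = background_peptides(proteome, peptides, 30, np.random.default_rng(5))
        b = background_peptides(proteome, peptides, 30, np.random.default_rng(5))
        assert a == b

    def test_never_overlaps_observed_spans(self, small_simulation):
        _cfg, proteome, _topo, peptides, _truth = small_simulation
        peps = background_peptides(proteome, peptides, 100,
                                   np.random.default_rng(1))
        masks = {pid: np.zeros(L, bool) for pid, L in proteome.lengths.items()}
        for _, row in peptides.iterrows():
            for pid, s, e in row["matches"]:
                masks[pid][s - 1:e] = True
        for pep in peps:
            found_clean = False
            for pid, seq in proteome.items():
                pos = seq.find(pep)
                while pos != -1:
                    if not masks[pid][pos:pos + len(pep)].any():
                        found_clean = True
                    pos = seq.find(pep, pos + 1)
            assert found_clean


class TestTerminalProfile:
    def test_n_terminal_positions(self):
        prof = terminal_profile(["ACDEFGHIKL"], "N", 5)
        for pos, res in enumerate("ACDEF", start=1):
            assert prof.pfm.loc[pos, res] == 1.0

    def test_c_terminal_counts_inward(self):
        prof = terminal_profile(["ACDEFGHIKL"], "C", 5)
        for pos, res in enumerate("LKIHG", start=1):
            assert prof.pfm.loc[pos, res] == 1.0

    def test_short_peptides_excluded(self):
        prof = terminal_profile(["ACDEFGHIKL", "AC"], "N", 5)
        assert prof.n_used == 1 and prof.n_skipped == 1
        with pytest.raises(ValueError):
            terminal_profile(["AC"], "N", 5)

    def test_uniform_random_information_near_zero(self):
        rng = np.random.default_rng(0)
        peps = ["".join(rng.choice(list(AA20), 8)) for _ in range(20000)]
        prof = terminal_profile(peps, "N", 5)
        assert (prof.information.abs() < 0.05).all()

    @given(peptides_strategy)
    @settings(max_examples=50, deadline=None)
    def test_position_rows_normalised(self, peps):
        k = 3
        usable = [p for p in peps if len(p) >= k]
        if not usable:
            return
        prof = terminal_profile(usable, "N", k)
        assert np.allclose(prof.pfm.sum(axis=1), 1.0, atol=1e-9)


class TestPeptideProperty:
    def test_homopolymer_identity(self, aaindex_mini):
        idx = pd.Series(0.48, index=list(AA20))
        assert peptide_property("GGG", idx) == pytest.approx(0.48)

    def test_two_residue_mean(self):
        idx = pd.Series(0.0, index=list(AA20))
        idx["A"] = 1.0
        assert peptide_property("AG", idx) == pytest.approx(0.5)

    def test_net_charge_against_flat_file(self, aaindex_mini):
        # KLEP840101: K=+1, D=-1 straight from the bundled flat file
        vals = aaindex_mini["KLEP840101"]
        expected = (vals["K"] + vals["K"] + vals["D"] + vals["D"]) / 4
        assert peptide_property("KKDD", vals) == pytest.approx(expected)
        assert expected == 0.0

    def test_incomplete_index_rejected(self, aaindex_mini):
        with pytest.raises(ValueError, match="incomplete"):
            peptide_property("AAA", aaindex_mini["SYNNAX0001"])
        with pytest.raises(ValueError, match="non-standard"):
            peptide_property("AXA", aaindex_mini["KLEP840101"])

    @given(st.text(alphabet=AA20, min_size=1, max_size=12),
           st.text(alphabet=AA20, min_size=1, max_size=12))
    @settings(max_examples=100, deadline=None)
    def test_linear_under_concatenation(self, aaindex_mini, x, y):
        vals = aaindex_mini["KYTJ820101"]
        lhs = peptide_property(x + y, vals)
        rhs = (len(x) * peptide_property(x, vals)
               + len(y) * peptide_property(y, vals)) / (len(x) + len(y))
        assert lhs == pytest.approx(rhs, abs=1e-9)


def permutation_oracle(x, y):
    """Exhaustive label permutation over pooled observations (independent of
    the implementation's rank-based shortcut)."""
    pooled = list(x) + list(y)
    n1 = len(x)
    mu = n1 * len(y) / 2

    def u_stat(sample_a, sample_b):
        u = 0.0
        for a in sample_a:
            for b in sample_b:
                u += (a > b) + 0.5 * (a == b)
        return u

    u_obs = u_stat(x, y)
    hits = total = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        ga = [pooled[i] for i in combo]
        gb = [pooled[i] for i in range(len(pooled)) if i not in combo]
        total += 1
        if abs(u_stat(ga, gb) - mu) >= abs(u_obs - mu) - 1e-9:
            hits += 1
    return hits / total


class TestMannWhitney:
    def test_complete_separation_exact_p(self):
        _u, p = mannwhitney([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1)

    def test_identical_groups_p_one(self):
        _u, p = mannwhitney([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        assert p == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(4))
    def test_exact_matches_permutation_oracle_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        for n1, n2 in [(2, 3), (3, 3), (4, 5), (5, 5)]:
            x = rng.integers(0, 4, n1).astype(float)
            y = rng.integers(0, 4, n2).astype(float)
            _u, p = mannwhitney_exact(x, y)
            assert p == pytest.approx(permutation_oracle(x, y))

    def test_large_samples_use_normal_approximation(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 100)
        y = rng.normal(1, 1, 100)
        _u, p = mannwhitney(x, y)
        ref = stats.mannwhitneyu(x, y, alternative="two-sided",
                                 method="asymptotic")
        assert p == pytest.approx(float(ref.pvalue))

    def test_tiny_groups_rejected(self):
        with pytest.raises(ValueError):
            mannwhitney([1.0], [2.0, 3.0])


class TestTiers:
    def test_tier_assignment_nested(self):
        tiers = (1e-5, 1e-15, 1e-25)
        assert assign_tier(1e-3, tiers) == "ns"
        assert assign_tier(1e-6, tiers) == "sig"
        assert assign_tier(1e-16, tiers) == "sigAA"
        assert assign_tier(1e-26, tiers) == "top"


class TestPropertyScreen:
    def test_identical_sets_all_ns(self, aaindex_mini):
        peps = ["ACDKLMW", "GGHWYVA", "PQRSTCD", "KKLLMMA"]
        out = property_screen(peps, list(peps), aaindex_mini)
        assert (out["tier"] == "ns").all()
        assert (out["p"] > 0.5).all()

    def test_injected_hydrophobicity_shift_detected(self):
        """Secretome-style hydrophobic sampling must flag the hydropathy-family
        indexes with the secretome direction."""
        rng = np.random.default_rng(0)
        table, families = synthetic_aaindex(rng, n_families=2, per_family=5)
        hydrophobic = list("AVLIFMC")
        polar = list("RNDQEKH")
        cell = ["".join(rng.choice(polar + hydrophobic, 12)) for _ in range(300)]
        sec = ["".join(rng.choice(
            hydrophobic * 3 + polar, 12)) for _ in range(300)]
        out = property_screen(cell, sec, table, label_a="cell",
                              label_b="secretome")
        kd = out.loc["KYTJ820101"]
        assert kd["p"] < 1e-5
        assert kd["direction"] == "secretome"


class TestClustering:
    def test_identical_profiles_cocluster(self):
        rng = np.random.default_rng(0)
        base = rng.normal(0, 1, 40)
        pm = pd.DataFrame({
            "IDXA": base, "IDXB": base,
            "IDXC": rng.normal(5, 1, 40), "IDXD": rng.normal(-3, 1, 40),
        })
        cl = cluster_indexes(pm, 2)
        assert cl.labels["IDXA"] == cl.labels["IDXB"]

    def test_deterministic_and_order_independent(self):
        rng = np.random.default_rng(1)
        pm = pd.DataFrame(rng.normal(0, 1, (30, 8)),
                          columns=[f"I{k}" for k in range(8)])
        a = cluster_indexes(pm, 3).labels
        b = cluster_indexes(pm[list(reversed(pm.columns))], 3).labels
        assert a.sort_index().equals(b.sort_index())

    def test_constant_index_excluded(self):
        rng = np.random.default_rng(2)
        pm = pd.DataFrame(rng.normal(0, 1, (20, 6)),
                          columns=[f"I{k}" for k in range(6)])
        pm["FLAT"] = 1.0
        cl = cluster_indexes(pm, 3)
        assert "FLAT" in cl.excluded
        assert "FLAT" not in cl.labels.index

    def test_latent_families_recovered_exactly(self):
        """3 synthetic index families with distinct latent factors, k=3:
        adjusted Rand index against truth must be 1."""
        from sklearn.metrics import adjusted_rand_score

        rng = np.random.default_rng(3)
        table, families = synthetic_aaindex(
            rng, n_families=3, per_family=12, noise_sd=0.05,
            include_hydrophobicity_refs=False,
        )
        peps = ["".join(rng.choice(list(AA20), 12)) for _ in range(200)]
        pm = property_matrix(peps, table)
        cl = cluster_indexes(pm, 3)
        truth = families[cl.labels.index]
        assert adjusted_rand_score(truth, cl.labels) == 1.0


class TestClusterEnrichment:
    @staticmethod
    def _clustering(groups):
        labels = {}
        for c, members in enumerate(groups, start=1):
            for m in members:
                labels[m] = c
        return IndexClustering(pd.Series(labels, name="cluster"),
                               np.empty((0, 4)), [])

    def test_whole_cluster_significant_has_minimal_p(self):
        cl = self._clustering([[f"A{i}" for i in range(10)],
                               [f"B{i}" for i in range(10)],
                               [f"C{i}" for i in range(10)]])
        out = cluster_enrichment(cl, {f"A{i}" for i in range(10)})
        assert out.loc[1, "p"] == out["p"].min()
        # hypergeometric oracle for [[10, 0], [0, 20]]: drawing all 10
        # significant ids inside a 10-member cluster of a 30-id universe
        expected = stats.hypergeom(30, 10, 10).pmf(10)
        assert out.loc[1, "p"] == pytest.approx(expected)

    def test_perfect_split_matches_enumeration(self):
        cl = self._clustering([[f"A{i}" for i in range(10)],
                               [f"B{i}" for i in range(10)]])
        out = cluster_enrichment(cl, {f"A{i}" for i in range(10)})
        # [[10, 0], [0, 10]]: only the two extreme tables are as unlikely
        assert out.loc[1, "p"] == pytest.approx(2 / 184756)

    def test_empty_significant_set_all_p_one(self):
        cl = self._clustering([["A0", "A1"], ["B0", "B1"]])
        out = cluster_enrichment(cl, set())
        assert (out["p"] == 1.0).all()
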