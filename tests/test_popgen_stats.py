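import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from polyte import (aim_threshold_counts, allele_frequencies, delta_stat,
                    frequency_matrix, locus_stats_table, sharing_summary,
                    unfolded_sfs, weir_cockerham_fst)

from _oracles import all_two_pop_two_sample_configs, wc_theta
from conftest import make_matrix, make_panel

def two_pop_setup(d1, d2):
    """DosageMatrix + panel from two per-population dosage vectors."""
    n1, n2 = len(d1), len(d2)
    samples = [f"A{i}" for i in range(n1)] + [f"B{i}" for i in range(n2)]
    m = make_matrix(np.array(d1 + d2)[:, None], samples=samples)
    panel = make_panel(
        {s: ("P1" if s.startswith("A") else "P2") for s in samples},
        {"P1": "G1", "P2": "G2"},
    )
    return m, panel


class TestAlleleFrequencies:
    def test_te_count_over_2n(self):
        """Dosages [0,1,2,0] in one stratum: TEi=3, 2n=8, freq=0.375."""
        m = make_matrix(np.array([[0], [1], [2], [0]]))
        panel = make_panel({s: "P1" for s in m.samples}, {"P1": "G1"})
        fr = allele_frequencies(m, panel, level="population")
        row = fr.iloc[0]
        assert row["te_count"] == 3
        assert row["n_alleles"] == 8
        assert row["freq"] == 0.375

    def test_all_zero_locus_zero_everywhere(self, small_result):
        m, panel = small_result.matrix, small_result.panel
        z = np.flatnonzero(m.dosage.sum(axis=0) == 0)
        if z.size == 0:
            pytest.skip("no monomorphic-absent locus in this draw")
        fr = frequency_matrix(m, panel, level="population")
        assert (fr.iloc[z] == 0.0).all().all()

    def test_stratum_te_counts_sum_to_overall(self, small_result):
        """Conservation: per-group TEi sums to the overall TEi."""
        m, panel = small_result.matrix, small_result.panel
        per_group = allele_frequencies(m, panel, level="group")
        overall = allele_frequencies(m, level="overall")
        got = per_group.groupby("locus_id")["te_count"].sum()
        want = overall.set_index("locus_id")["te_count"]
        assert got.sort_index().equals(want.sort_index())


class TestUnfoldedSfs:
    def test_binning(self):
        fr = pd.DataFrame({"locus_id": list("abc"), "stratum": "ALL",
                           "freq": [0.01, 0.02, 0.5]})
        out = unfolded_sfs(fr, [0.0, 0.05, 1.0])
        assert out["count"].tolist() == [2, 1]

    def test_all_mass_in_first_bin_and_total_preserved(self):
        fr = pd.DataFrame({"locus_id": list("abcd"), "stratum": "ALL",
                           "freq": [0.0, 0.0, 0.0, 1.0]})
        out = unfolded_sfs(fr, [0.0, 0.05, 0.5, 1.0])
        assert out["count"].tolist() == [3, 0, 1]
        assert out["count"].sum() == 4

    def test_unsorted_edges_rejected(self):
        fr = pd.DataFrame({"locus_id": ["a"], "stratum": "ALL", "freq": [0.1]})
        with pytest.raises(ValueError):
            unfolded_sfs(fr, [0.5, 0.0, 1.0])

    def test_skewed_generator_spectrum(self):
        """At 10,000 loci the realized fraction of sub-5 % loci is within
        2 % of the configured target; oracle = direct count over the drawn
        ancestral frequencies."""
        from polyte import serial_founder_preset, simulate

        res = simulate(serial_founder_preset(seed=29, n_loci=10_000))
        f = res.truth.ancestral_freq
        target = res.config.frequency_law.target_rare_fraction
        assert abs((f < 0.05).mean() - target) < 0.02


class TestSharingSummary:
    def test_exclusive_single_group(self):
        fm = pd.DataFrame({"A": [0.1], "B": [0.0], "C": [0.0]})
        s = sharing_summary(fm, 0.05)
        assert s.exclusive == {"A": 1, "B": 0, "C": 0}
        assert s.combinations == {frozenset({"A"}): 1}

    def test_shared_not_exclusive(self):
        fm = pd.DataFrame({"A": [0.06], "B": [0.06]})
        s = sharing_summary(fm, 0.05)
        assert s.exclusive == {"A": 0, "B": 0}
        assert s.combinations == {frozenset({"A", "B"}): 1}

    def test_threshold_is_strict(self):
        fm = pd.DataFrame({"A": [0.05], "B": [0.0]})
        s = sharing_summary(fm, 0.05)
        assert s.above_threshold == {"A": 0, "B": 0}
        assert s.combinations == {}

    def test_combination_counts_sum_to_loci_above_anywhere(self, small_result):
        m, panel = small_result.matrix, small_result.panel
        fm = frequency_matrix(m, panel, level="group")
        s = sharing_summary(fm)
        anywhere = int((fm.to_numpy() > 0.05).any(axis=1).sum())
        assert s.total_above == anywhere
        for g in fm.columns:
            assert s.exclusive[g] <= s.above_threshold[g]


class TestDeltaStat:
    @pytest.mark.parametrize("freqs,expected", [
        ((0.6, 0.2), 0.4),
        ((0.3, 0.3, 0.3), 0.0),
        ((0.1, 0.5, 0.35), 0.4),
    ])
    def test_examples(self, freqs, expected):
        assert delta_stat(freqs) == pytest.approx(expected, abs=1e-15)

    def test_fewer_than_two_groups_rejected(self):
        with pytest.raises(ValueError):
            delta_stat([0.5])

    @given(st.lists(st.floats(0, 1), min_size=2, max_size=6),
           st.randoms(use_true_random=False))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_permutation_and_duplication_invariance(self, freqs, rnd):
        base = delta_stat(freqs)
        shuffled = list(freqs)
        rnd.shuffle(shuffled)
        assert delta_stat(shuffled) == base
        assert delta_stat(freqs + [freqs[0]]) == base
        assert 0.0 <= base <= 1.0


class TestWeirCockerhamFst:
    def test_identical_count_vectors_nonpositive(self):
        m, panel = two_pop_setup([2, 1, 0], [2, 1, 0])
        theta, defined = weir_cockerham_fst(m, panel)
        assert defined[0]
        assert theta[0] <= 0

    def test_complete_fixation_is_one(self):
        m, panel = two_pop_setup([2, 2, 2], [0, 0, 0])
        theta, _ = weir_cockerham_fst(m, panel)
        assert theta[0] == pytest.approx(1.0, abs=1e-15)

    def test_spec_example_matches_literal_oracle(self):
        """pop1 [2,2,1,1,0] vs pop2 [0,0,0,1,0]: theta-hat = 41/116,
        frozen from the hand-evaluated variance-component oracle."""
        m, panel = two_pop_setup([2, 2, 1, 1, 0], [0, 0, 0, 1, 0])
        theta, _ = weir_cockerham_fst(m, panel)
        assert theta[0] == pytest.approx(41 / 116, abs=1e-12)
        assert theta[0] == pytest.approx(
            wc_theta([[2, 2, 1, 1, 0], [0, 0, 0, 1, 0]]), abs=1e-14)

    def test_exhaustive_tiny_configs_match_oracle(self):
        """All 3^4 two-population, two-diploid-sample configurations agree
        with the literal Weir & Cockerham component formulas to 1e-12."""
        for pops in all_two_pop_two_sample_configs():
            m, panel = two_pop_setup(pops[0], pops[1])
            theta, defined = weir_cockerham_fst(m, panel)
            want = wc_theta(pops)
            if want is None:
                assert not defined[0]
                assert np.isnan(theta[0])
            else:
                assert theta[0] == pytest.approx(want, abs=1e-12)

    def test_monomorphic_everywhere_flagged_undefined(self):
        m, panel = two_pop_setup([0, 0], [0, 0])
        theta, defined = weir_cockerham_fst(m, panel)
        assert not defined[0] and np.isnan(theta[0])

    def test_group_exclusive_loci_outrank_uniform_loci(self, small_result):
        """Ranking by F_ST places group-private high-frequency loci above
        loci with uniform frequencies across groups."""
        m, panel, truth = (small_result.matrix, small_result.panel,
                           small_result.truth)
        groups = ["African", "Asian", "European"]
        theta, defined = weir_cockerham_fst(m, panel, strata=groups)
        gf = truth.group_freq[groups]
        owner = truth.exclusive_owner
        excl_hi = (owner.isin(groups) & (gf.max(axis=1) > 0.3)).to_numpy()
        uniform = ((gf.max(axis=1) - gf.min(axis=1)) < 0.02).to_numpy()
        if not excl_hi.any() or not uniform.any():
            pytest.skip("draw lacks one of the contrast classes")
        assert np.nanmean(theta[excl_hi]) > np.nanmean(theta[uniform])


class TestAimCounts:
    def test_counts_strictly_exceeding(self):
        t = pd.DataFrame({"delta": [0.31, 0.45, 0.55]})
        assert aim_threshold_counts(t, (0.3, 0.4, 0.5)) == \
            {0.3: 3, 0.4: 2, 0.5: 1}

    def test_empty_table(self):
        t = pd.DataFrame({"delta": []})
        assert aim_threshold_counts(t, (0.3, 0.4, 0.5)) == \
            {0.3: 0, 0.4: 0, 0.5: 0}

    def test_boundary_not_counted(self):
        t = pd.DataFrame({"delta": [0.3]})
        assert aim_threshold_counts(t, (0.3,)) == {0.3: 0}


class TestLocusStatsTable:
    def test_delta_consistent_with_frequencies(self, small_result):
        m, panel = small_result.matrix, small_result.panel
        tab = locus_stats_table(m, panel)
        groups = [c for c in tab.columns if c.startswith("freq_")]
        f = tab[groups].to_numpy()
        assert np.allclose(tab["delta"], f.max(axis=1) - f.min(axis=1))
        assert (tab["delta"] <= 1).all()
        assert (tab.loc[tab["fst_defined"], "fst"] <= 1).all()
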