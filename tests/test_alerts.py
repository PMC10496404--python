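import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from rdkit import Chem

from gutshield.alerts import (
    FragmentStats,
    class_frequency,
    compute_krfp,
    fragment_counts,
    identify_alerts,
    information_gain,
    krfp_matrix,
    score_fragments,
)
from gutshield.dataio import MoleculeDataset, MoleculeRecord
from gutshield.smartskeys import KRFP_SIZE, get_matcher, krfp_patterns
from gutshield.synthdata import SynthConfig, generate_dataset


def brute_force_mutual_information(m_pos, m_neg, n_pos, n_neg):
    """Independent oracle: MI from the explicit joint distribution (bits)."""
    n = n_pos + n_neg
    joint = {
        (1, 1): m_pos / n,
        (1, 0): m_neg / n,
        (0, 1): (n_pos - m_pos) / n,
        (0, 0): (n_neg - m_neg) / n,
    }
    p_frag = {1: (m_pos + m_neg) / n, 0: (n - m_pos - m_neg) / n}
    p_label = {1: n_pos / n, 0: n_neg / n}
    mi = 0.0
    for (f, l), p in joint.items():
        if p > 0:
            mi += p * math.log2(p / (p_frag[f] * p_label[l]))
    return mi


class TestDictionary:
    def test_cardinality_is_4860(self):
        assert len(krfp_patterns()) == KRFP_SIZE == 4860

    def test_all_patterns_compile(self):
        matcher = get_matcher("krfp")
        assert len(matcher) == 4860

    def test_patterns_unique(self):
        pats = krfp_patterns()
        assert len(set(pats)) == len(pats)


class TestKRFP:
    def test_methane_near_zero(self):
        bits = compute_krfp(Chem.MolFromSmiles("C"))
        assert bits.shape == (4860,)
        assert bits.sum() <= 2

    def test_substructure_monotonicity_via_benzene(self):
        benzene = compute_krfp(Chem.MolFromSmiles("c1ccccc1"))
        toluene = compute_krfp(Chem.MolFromSmiles("Cc1ccccc1"))
        ibuprofen = compute_krfp(Chem.MolFromSmiles("CC(C)Cc1ccc(C(C)C(=O)O)cc1"))
        for containing in (toluene, ibuprofen):
            assert np.all(containing[benzene == 1] == 1)

    def test_prescreen_agrees_with_direct_matching(self, sample_molecules):
        matcher = get_matcher("krfp")
        rng = np.random.default_rng(0)
        idx = rng.choice(len(matcher), size=300, replace=False)
        for mol in sample_molecules[:4]:
            bits = matcher.match(mol)
            for i in idx:
                direct = mol.HasSubstructMatch(Chem.MolFromSmarts(matcher.patterns[i]))
                assert bool(bits[i]) == direct


class TestInformationGain:
    def test_fragment_in_every_compound_zero(self):
        st_ = FragmentStats(0, "C", m_pos=4, m_neg=6, n_pos=4, n_neg=6)
        assert information_gain(st_) == pytest.approx(0.0, abs=1e-15)

    def test_perfect_split_one_bit(self):
        st_ = FragmentStats(0, "C", m_pos=5, m_neg=0, n_pos=5, n_neg=5)
        assert information_gain(st_) == pytest.approx(1.0)

    def test_worked_example(self):
        st_ = FragmentStats(0, "C", m_pos=3, m_neg=1, n_pos=4, n_neg=6)
        assert information_gain(st_) == pytest.approx(0.2564, abs=5e-5)

    @given(
        st.integers(1, 60),
        st.integers(1, 60),
        st.integers(0, 60),
        st.integers(0, 60),
    )
    @settings(max_examples=200, derandomize=True)
    def test_matches_brute_force_oracle(self, n_pos, n_neg, m_pos, m_neg):
        m_pos, m_neg = min(m_pos, n_pos), min(m_neg, n_neg)
        st_ = FragmentStats(0, "C", m_pos=m_pos, m_neg=m_neg, n_pos=n_pos, n_neg=n_neg)
        assert information_gain(st_) == pytest.approx(
            brute_force_mutual_information(m_pos, m_neg, n_pos, n_neg), abs=1e-12
        )

    @given(st.integers(1, 40), st.integers(1, 40), st.integers(0, 40), st.integers(0, 40))
    @settings(max_examples=100, derandomize=True)
    def test_invariant_under_class_swap(self, n_pos, n_neg, m_pos, m_neg):
        m_pos, m_neg = min(m_pos, n_pos), min(m_neg, n_neg)
        a = FragmentStats(0, "C", m_pos=m_pos, m_neg=m_neg, n_pos=n_pos, n_neg=n_neg)
        b = FragmentStats(0, "C", m_pos=m_neg, m_neg=m_pos, n_pos=n_neg, n_neg=n_pos)
        assert information_gain(a) == pytest.approx(information_gain(b), abs=1e-12)

    def test_bounded_by_label_entropy(self, rng):
        for _ in range(50):
            n_pos, n_neg = rng.integers(1, 50, size=2)
            m_pos = rng.integers(0, n_pos + 1)
            m_neg = rng.integers(0, n_neg + 1)
            st_ = FragmentStats(0, "C", m_pos=m_pos, m_neg=m_neg, n_pos=int(n_pos), n_neg=int(n_neg))
            n = n_pos + n_neg
            h_label = -sum(
                p * math.log2(p) for p in (n_pos / n, n_neg / n) if p > 0
            )
            assert information_gain(st_) <= h_label + 1e-12


class TestClassFrequency:
    def test_worked_example(self):
        st_ = FragmentStats(0, "C", m_pos=20, m_neg=5, n_pos=40, n_neg=60)
        freq_p, freq_n = class_frequency(st_)
        assert freq_p == pytest.approx(2.0)
        assert freq_n == pytest.approx((5 / 60) / 0.25)

    def test_proportional_fragment_null_enrichment(self):
        st_ = FragmentStats(0, "C", m_pos=10, m_neg=15, n_pos=20, n_neg=30)
        freq_p, freq_n = class_frequency(st_)
        assert freq_p == pytest.approx(1.0)
        assert freq_n == pytest.approx(1.0)

    def test_positive_only_fragment(self):
        st_ = FragmentStats(0, "C", m_pos=8, m_neg=0, n_pos=20, n_neg=30)
        _, freq_n = class_frequency(st_)
        assert freq_n == 0.0

    @given(st.integers(1, 50), st.integers(1, 50), st.integers(0, 50), st.integers(0, 50))
    @settings(max_examples=100, derandomize=True)
    def test_prevalence_weighted_mean_is_one(self, n_pos, n_neg, m_pos, m_neg):
        m_pos, m_neg = min(m_pos, n_pos), min(m_neg, n_neg)
        if m_pos + m_neg == 0:
            return
        st_ = FragmentStats(0, "C", m_pos=m_pos, m_neg=m_neg, n_pos=n_pos, n_neg=n_neg)
        freq_p, freq_n = class_frequency(st_)
        n = n_pos + n_neg
        assert (n_pos / n) * freq_p + (n_neg / n) * freq_n == pytest.approx(1.0, abs=1e-12)


class TestFragmentCounts:
    def _dataset(self, n=30):
        ds, _ = generate_dataset(SynthConfig(n_molecules=n, seed=13))
        return ds

    def test_occurrence_floor_strict(self):
        ds = self._dataset(30)
        presence = np.zeros((30, 4860), dtype=np.uint8)
        presence[:11, 7] = 1  # 11 occurrences: retained
        presence[:10, 8] = 1  # exactly 10: dropped
        stats = fragment_counts(ds, min_occurrence=10, presence=presence)
        kept = {s.fragment_id for s in stats}
        assert 7 in kept and 8 not in kept

    def test_counts_split_by_class(self):
        ds = self._dataset(30)
        y = np.asarray(ds.labels)
        presence = np.zeros((30, 4860), dtype=np.uint8)
        presence[:, 3] = 1
        stats = fragment_counts(ds, min_occurrence=10, presence=presence)
        st3 = next(s for s in stats if s.fragment_id == 3)
        assert st3.m_pos == int(y.sum())
        assert st3.m_neg == int((1 - y).sum())

    def test_empty_result_not_an_error(self):
        ds = self._dataset(12)
        presence = np.zeros((12, 4860), dtype=np.uint8)
        assert fragment_counts(ds, presence=presence) == []

    def test_unlabeled_rejected(self):
        ds = MoleculeDataset(records=[MoleculeRecord(id="a", smiles="CCO")])
        from gutshield.dataio import InputError

        with pytest.raises(InputError):
            fragment_counts(ds)


class TestIdentifyAlerts:
    def test_planted_fragment_ranks_first(self):
        ds, truth = generate_dataset(SynthConfig(n_molecules=400, seed=21, label_noise=0.0))
        alerts = identify_alerts(ds, top_k=7)
        assert alerts[0].stats.smarts == truth.alert_smarts[0]
        assert alerts[0].stats.freq_p > alerts[0].stats.freq_n

    def test_all_reported_alerts_positively_enriched(self):
        ds, _ = generate_dataset(SynthConfig(n_molecules=300, seed=22))
        for alert in identify_alerts(ds, top_k=20):
            assert alert.stats.freq_p > alert.stats.freq_n

    def test_equal_enrichment_excluded_even_at_high_ig(self):
        ds, _ = generate_dataset(SynthConfig(n_molecules=40, seed=23, pos_fraction=0.5))
        n = len(ds)
        presence = np.zeros((n, 4860), dtype=np.uint8)
        y = np.asarray(ds.labels)
        # fragment 5 present proportionally in both classes -> freq_p == freq_n
        pos_idx = np.flatnonzero(y == 1)[:6]
        neg_idx = np.flatnonzero(y == 0)[:6]
        presence[pos_idx, 5] = 1
        presence[neg_idx, 5] = 1
        alerts = identify_alerts(ds, top_k=10, presence=presence)
        assert all(a.stats.fragment_id != 5 for a in alerts)

    def test_representatives_are_positive_carriers(self):
        ds, truth = generate_dataset(SynthConfig(n_molecules=200, seed=24))
        label_of = dict(zip(ds.ids, ds.labels))
        alerts = identify_alerts(ds, top_k=3)
        presence = krfp_matrix(ds)
        id_index = {r: i for i, r in enumerate(ds.ids)}
        for alert in alerts:
            assert 0 < len(alert.representatives) <= 3
            for rid in alert.representatives:
                assert label_of[rid] == 1
                assert presence[id_index[rid], alert.stats.fragment_id] == 1
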