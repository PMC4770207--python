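"""Ensemble backends, stretch decomposition and the Q_f structure score."""

import itertools

import numpy as np
import pytest

from ribodesign.folding import (CORE_PENALTY, EnsembleStructure,
                                FixtureFoldingBackend, MockFoldingBackend,
                                ViennaFoldingBackend, core_intact,
                                double_stranded_stretches, fold_ensemble,
                                pairs_from_dotbracket, partner_array,
                                structure_quality, stretch_tm_kelvin)
from ribodesign.model import Candidate, CoreTemplate, CutSite
from ribodesign.synthetic import designed_candidate_fold


def _candidate(arm1="GGCC", arm3="CCGG"):
    core = CoreTemplate.for_model("minimal")
    return Candidate(cutsite=CutSite(10, "GUC"), arm1_len=len(arm1),
                     arm3_len=len(arm3),
                     ribozyme_seq=arm1 + core.core_seq + arm3, core=core)


def _ens(*pairs):
    return [EnsembleStructure(db, w) for db, w in pairs]


class TestDotBracket:
    def test_pairs_and_partner(self):
        pairs = pairs_from_dotbracket("((..))..")
        assert pairs == [(0, 5), (1, 4)]
        partner = partner_array("((..))..")
        assert partner[0] == 5 and partner[5] == 0 and partner[2] == -1

    @pytest.mark.parametrize("bad", ["((.)", ".))", "(.x)"])
    def test_invalid_rejected(self, bad):
        with pytest.raises(ValueError):
            pairs_from_dotbracket(bad)

    def test_ensemble_structure_weight_bounds(self):
        with pytest.raises(ValueError):
            EnsembleStructure("....", 1.5)


def _oracle_stretches(dotbracket):
    """Brute-force stretch enumeration directly from the partner table:
    walk 5'->3', growing a run while pairs stack, allowing one 1x1 internal
    loop per run."""
    partner = partner_array(dotbracket)
    pairs = sorted((i, int(j)) for i, j in enumerate(partner)
                   if j != -1 and i < j)
    runs = []
    for p in pairs:
        placed = False
        if runs:
            (li, lj) = runs[-1]["pairs"][-1]
            stacked = p == (li + 1, lj - 1)
            gap = (p == (li + 2, lj - 2) and partner[li + 1] == -1
                   and partner[lj - 1] == -1 and not runs[-1]["mm"])
            if stacked or gap:
                runs[-1]["pairs"].append(p)
                if gap:
                    runs[-1]["mm"] = True
                placed = True
        if not placed:
            runs.append({"pairs": [p], "mm": False})
    return [r["pairs"] for r in runs]


class TestStretchDecomposition:
    def test_simple_helix(self):
        assert double_stranded_stretches([(0, 9), (1, 8), (2, 7)]) == \
            [[(0, 9), (1, 8), (2, 7)]]

    def test_one_by_one_mismatch_merges(self):
        pairs = [(0, 11), (1, 10), (3, 8), (4, 7)]
        assert double_stranded_stretches(pairs) == [pairs]

    def test_second_mismatch_splits(self):
        pairs = [(0, 15), (2, 13), (4, 11)]
        stretches = double_stranded_stretches(pairs)
        assert stretches == [[(0, 15), (2, 13)], [(4, 11)]]

    def test_bulge_splits(self):
        # one-sided gap (bulge) is not a 1x1 internal loop
        pairs = [(0, 11), (2, 10)]
        assert len(double_stranded_stretches(pairs)) == 2

    def test_matches_oracle_on_random_structures(self):
        rng = np.random.default_rng(42)
        backend = MockFoldingBackend(n_samples=30)
        bases = np.array(list("ACGU"))
        for trial in range(25):
            seq = "".join(rng.choice(bases, size=int(rng.integers(15, 40))))
            for s in backend.fold(seq, seed=trial):
                pairs = pairs_from_dotbracket(s.dotbracket)
                assert double_stranded_stretches(pairs) == \
                    _oracle_stretches(s.dotbracket)


class TestMockBackend:
    def test_unpairable_sequence_single_open_structure(self):
        ens = fold_ensemble("AAAAAAA", MockFoldingBackend(), seed=3)
        assert ens == [EnsembleStructure(".......", 1.0)]

    def test_hairpin_ensemble_contains_designed_stem(self):
        """Exhaustively, the only 4-pair nested structure of GGGGAAAACCCC
        is the canonical hairpin; the sampler must find it."""
        ens = fold_ensemble("GGGGAAAACCCC", MockFoldingBackend(), seed=1)
        assert "((((....))))" in [s.dotbracket for s in ens]
        top = max(ens, key=lambda s: s.f_s)
        assert top.dotbracket == "((((....))))"

    def test_seed_reproducibility(self):
        be = MockFoldingBackend()
        seq = "GGCAGCUGAUGAGUCGCUGAAAUGCGACGAAACGCUGCC"
        assert be.fold(seq, 7) == be.fold(seq, 7)
        assert be.fold(seq, 7) != be.fold(seq, 8)

    def test_weights_sum_at_most_one(self):
        ens = fold_ensemble("GGCAGCAUGCUAGCUAGCGCGAUCGC",
                            MockFoldingBackend(), seed=0)
        total = sum(s.f_s for s in ens)
        assert 0 < total <= 1 + 1e-9

    def test_default_ensemble_size_is_ten(self):
        cand = _candidate()
        ens = fold_ensemble(cand.ribozyme_seq, MockFoldingBackend(), seed=5)
        assert MockFoldingBackend().n_structures == 10
        assert len(ens) == 10

    def test_min_loop_respected(self):
        for s in MockFoldingBackend(n_samples=50).fold("GCGCGCGCGCGC", 0):
            for i, j in pairs_from_dotbracket(s.dotbracket):
                assert j - i > 3


class TestViennaBackend:
    def test_hairpin_and_contract(self):
        be = ViennaFoldingBackend()
        ens = fold_ensemble("GGGGAAAACCCC", be, seed=0)
        assert "((((....))))" in [s.dotbracket for s in ens]
        assert sum(s.f_s for s in ens) <= 1 + 1e-6
        assert be.fold("GGGGAAAACCCC", 0) == be.fold("GGGGAAAACCCC", 99)


class TestFixtureBackend:
    def test_register_and_replay(self):
        be = FixtureFoldingBackend()
        be.register("GGGAAACCC", [("(((...)))", 0.6), ("." * 9, 0.4)])
        ens = be.fold("GGGAAACCC", 0)
        assert [s.f_s for s in ens] == [0.6, 0.4]

    def test_rejects_overweight_ensemble(self):
        be = FixtureFoldingBackend()
        with pytest.raises(ValueError):
            be.register("GGGAAACCC", [("(((...)))", 0.7), ("." * 9, 0.4)])

    def test_missing_sequence_raises(self):
        with pytest.raises(KeyError):
            FixtureFoldingBackend().fold("ACGU", 0)


class TestCoreIntact:
    def test_designed_fold_is_intact(self):
        cand = _candidate()
        s = EnsembleStructure(designed_candidate_fold(cand), 1.0)
        assert core_intact(cand, s)

    def test_fully_unpaired_lacks_helix_ii(self):
        cand = _candidate()
        s = EnsembleStructure("." * len(cand.ribozyme_seq), 1.0)
        assert not core_intact(cand, s)

    def test_paired_conserved_base_breaks_core(self):
        cand = _candidate()
        fold = list(designed_candidate_fold(cand))
        # pair arm1 position 0 with the first core base (the C of CUGAUGA)
        fold[0] = "("
        fold[cand.core_offset] = ")"
        assert not core_intact(cand, EnsembleStructure("".join(fold), 1.0))


class TestStructureQuality:
    def test_designed_fold_scores_zero(self, env):
        cand = _candidate()
        sq = structure_quality(
            cand, _ens((designed_candidate_fold(cand), 1.0)), env)
        assert sq.q_f == 0.0
        assert sq.core_intact == (True,)

    def test_core_disruption_adds_exact_penalty(self, env):
        cand = _candidate()
        fold = list(designed_candidate_fold(cand))
        fold[0] = "("
        fold[cand.core_offset] = ")"
        for f_s in (1.0, 0.25):
            sq = structure_quality(cand, _ens(("".join(fold), f_s)), env)
            assert sq.q_f == pytest.approx(CORE_PENALTY * f_s)

    def test_weighted_sum_of_structure_scores(self, env):
        """Q_f is the f_s-weighted sum of per-structure Q_s."""
        cand = _candidate(arm1="GGGGGAAAACCCCC", arm3="CCGG")
        open_fold = designed_candidate_fold(cand)
        hairpin = list(open_fold)
        for k in range(5):
            hairpin[k] = "("
            hairpin[13 - k] = ")"  # arm1 folds on itself
        hairpin = "".join(hairpin)
        q_hairpin = structure_quality(cand, _ens((hairpin, 1.0)), env).q_f
        assert q_hairpin > 0
        mixed = structure_quality(
            cand, _ens((open_fold, 0.6), (hairpin, 0.4)), env)
        assert mixed.q_f == pytest.approx(0.6 * 0.0 + 0.4 * q_hairpin)
        assert mixed.q_s == (0.0, q_hairpin)

    def test_permutation_invariance_and_weight_linearity(self, env):
        cand = _candidate(arm1="GGGGGAAAACCCCC", arm3="CCGG")
        open_fold = designed_candidate_fold(cand)
        unpaired = "." * len(cand.ribozyme_seq)
        a = structure_quality(cand, _ens((open_fold, 0.3), (unpaired, 0.7)),
                              env).q_f
        b = structure_quality(cand, _ens((unpaired, 0.7), (open_fold, 0.3)),
                              env).q_f
        assert a == pytest.approx(b)
        half = structure_quality(
            cand, _ens((open_fold, 0.15), (unpaired, 0.35)), env).q_f
        assert half == pytest.approx(a / 2)

    def test_helix_ii_pairs_not_counted(self, env):
        """The designed stem II is meant to be there: a structure holding
        only helix II scores 0 apart from the (absent) core penalty."""
        cand = _candidate()
        sq = structure_quality(
            cand, _ens((designed_candidate_fold(cand), 1.0)), env)
        assert sq.q_f == 0.0

    def test_removing_a_stretch_never_increases_qs(self, env):
        cand = _candidate(arm1="GGGGGAAAACCCCC", arm3="GGCAUGCC")
        fold = list(designed_candidate_fold(cand))
        for k in range(5):
            fold[k] = "("
            fold[13 - k] = ")"
        n = len(cand.ribozyme_seq)
        for k in range(3):
            fold[n - 8 + k] = "("
            fold[n - 1 - k] = ")"
        full = structure_quality(cand, _ens(("".join(fold), 1.0)), env).q_f
        for k in range(3):  # remove the arm3 hairpin stretch
            fold[n - 8 + k] = "."
            fold[n - 1 - k] = "."
        reduced = structure_quality(cand, _ens(("".join(fold), 1.0)), env).q_f
        assert reduced <= full
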