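"""Reindex expander, rate selection, splits, turns, label shuffling."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pispki import (
    Dataset,
    bootstrap_turn,
    choose_expansion_rates,
    expand_dataset,
    expand_pairs,
    load_dataset,
    mark_atom,
    reindex_pair,
    reindex_sample,
    save_dataset,
    shuffle_labels,
    split_dataset,
    SynthSpec,
    generate_dataset,
)
from conftest import canonical_form


def _labeled_dataset(n_pos, n_neg, seed=0):
    spec = SynthSpec(n_molecules=80, atom_range=(4, 10),
                     positive_fraction=0.3, noise=0.0)
    ds, _ = generate_dataset(spec, seed=seed)
    y = ds.labels()
    pos = [s for s, yi in zip(ds.samples, y) if yi == 1][:n_pos]
    neg = [s for s, yi in zip(ds.samples, y) if yi == 0][:n_neg]
    assert len(pos) == n_pos and len(neg) == n_neg
    return Dataset(pos + neg)


class TestReindex:
    def test_same_seed_same_permutation(self, path4):
        f, s = path4.F, path4.S
        a = reindex_pair(f, s, seed=7)
        b = reindex_pair(f, s, seed=7)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_two_atom_consistent_swap(self):
        # enumerate both permutations of a 2-atom molecule by seed search
        f = np.array([[1.0, 0.0], [0.0, 1.0]])
        s = np.array([[0, 2], [2, 0]])
        seen = set()
        for seed in range(20):
            f2, s2 = reindex_pair(f, s, seed)
            assert np.array_equal(s2, s)  # symmetric 2x2 is swap-invariant
            seen.add(tuple(f2[:, 0]))
        assert seen == {(1.0, 0.0), (0.0, 1.0)}

    def test_consistent_preserves_canonical_form(self, small_molecules):
        for mol in small_molecules:
            if mol.n_atoms > 6:
                continue
            ref = canonical_form(mol.colors, mol.S)
            for seed in range(5):
                f2, s2 = reindex_pair(mol.F, mol.S, seed)
                colors2 = f2.argmax(axis=1)
                assert canonical_form(colors2, s2) == ref

    def test_paper_literal_rows_only_on_s(self, path4):
        f, s = path4.F, path4.S
        for seed in range(5):
            pi = np.random.default_rng(seed).permutation(4)
            _, s2 = reindex_pair(f, s, seed, mode="paper_literal")
            assert np.array_equal(s2, s[pi])  # rows permuted, columns not

    def test_paper_literal_breaks_structure_generally(self, path4):
        # rows-only reindexing of an asymmetric path yields a non-symmetric
        # matrix for at least one permutation: the literal algorithm does
        # not preserve the graph
        broke = any(
            not np.array_equal(*(lambda m: (m, m.T))(
                reindex_pair(path4.F, path4.S, seed, mode="paper_literal")[1]))
            for seed in range(10)
        )
        assert broke

    def test_reindex_sample_tracks_mark_and_label(self, path4):
        sp = mark_atom(path4, 2)
        sp.label = 1
        sp2 = reindex_sample(sp, seed=3)
        assert sp2.label == 1
        # the marked atom keeps its color after relabeling
        i_old, i_new = sp.marked_atom - 1, sp2.marked_atom - 1
        assert np.array_equal(sp2.F_marked[i_new, :-1], sp.F_marked[i_old, :-1])
        assert sp2.F_marked[:, -1].sum() == 1

    def test_asymmetric_path_has_24_distinct_reindexings(self, path4):
        # N! upper bound is attained for a graph with trivial automorphism
        pairs = set()
        f, s = path4.F, path4.S
        for pi in itertools.permutations(range(4)):
            pi = list(pi)
            pairs.add((tuple(f[pi].ravel()), tuple(s[np.ix_(pi, pi)].ravel())))
        assert len(pairs) == 24


class TestExpand:
    def test_output_length_and_cycling(self):
        f_set = [np.full((2, 3), i, dtype=float) for i in range(4)]
        s_set = [np.zeros((2, 2), dtype=int)] * 4
        f_e, s_e = expand_pairs(f_set, s_set, rate=3, seed=0)
        assert len(f_e) == 12
        # sources cycle 1,2,3,4,1,2,... ; value identifies the source
        assert [int(f[0, 0]) for f in f_e] == [0, 1, 2, 3] * 3

    def test_rate_one_samples_graph_isomorphic(self, small_molecules):
        mols = [m for m in small_molecules if m.n_atoms <= 6][:3]
        f_set = [m.F for m in mols]
        s_set = [m.S for m in mols]
        f_e, s_e = expand_pairs(f_set, s_set, rate=1, seed=5)
        for m, f2, s2 in zip(mols, f_e, s_e):
            assert canonical_form(f2.argmax(axis=1), s2) == \
                canonical_form(m.colors, m.S)

    def test_zero_rate_rejected(self):
        with pytest.raises(ValueError):
            expand_pairs([np.eye(2)], [np.zeros((2, 2), dtype=int)], rate=0)

    def test_dataset_expansion_counts_exact(self):
        ds = _labeled_dataset(10, 30)
        big = expand_dataset(ds, rate=4, seed=1)
        assert len(big) == 160
        assert big.class_counts == (40, 120)

    def test_labels_copied_unchanged(self):
        ds = _labeled_dataset(5, 5)
        big = expand_dataset(ds, rate=2, seed=1)
        src = list(ds.labels()) * 2
        assert list(big.labels()) == src


class TestRates:
    @pytest.mark.parametrize("n,expected", [(2560, 1), (2561, 1), (300, 9),
                                            (1, 2560), (2559, 2)])
    def test_ceiling_arithmetic(self, n, expected):
        r_pos, _ = choose_expansion_rates(n, 5000)
        assert r_pos == expected
        assert n * r_pos >= 2560

    def test_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            choose_expansion_rates(0, 10)


class TestSplit:
    def test_stratified_tenths(self):
        ds = _labeled_dataset(100, 100)
        sp = split_dataset(ds, seed=0)
        assert sp.test.class_counts == (10, 10)
        assert sp.validation.class_counts == (10, 10)
        assert sp.train.class_counts == (80, 80)

    def test_partition_exact(self):
        ds = _labeled_dataset(40, 60)
        sp = split_dataset(ds, seed=3)
        ids = lambda d: sorted(id(s) for s in d.samples)
        all_ids = ids(sp.train) + ids(sp.validation) + ids(sp.test)
        assert sorted(all_ids) == ids(ds)
        assert len(set(all_ids)) == len(ds)

    def test_deterministic(self):
        ds = _labeled_dataset(40, 60)
        a = split_dataset(ds, seed=9)
        b = split_dataset(ds, seed=9)
        assert [s.marked_atom for s in a.test.samples] == \
            [s.marked_atom for s in b.test.samples]

    def test_too_few_rejected(self):
        ds = _labeled_dataset(5, 30)
        with pytest.raises(ValueError, match="class 1"):
            split_dataset(ds, seed=0)


class TestBootstrap:
    def test_turn_exactly_balanced(self):
        ds = _labeled_dataset(20, 80)
        turn = bootstrap_turn(ds, per_class=64, seed=0)
        assert len(turn) == 128
        assert turn.class_counts == (64, 64)

    def test_minimal_turn(self):
        ds = _labeled_dataset(10, 10)
        assert len(bootstrap_turn(ds, per_class=1, seed=0)) == 2

    def test_draws_uniform_with_replacement(self):
        # over many draws each positive sample appears ~ uniformly
        ds = _labeled_dataset(10, 10)
        counts = np.zeros(10)
        key = {id(s): i for i, s in enumerate(ds.samples[:10])}
        rng = np.random.default_rng(0)
        n_draws = 200
        for _ in range(n_draws):
            turn = bootstrap_turn(ds, per_class=50, seed=rng)
            for s in turn.samples:
                if id(s) in key:
                    counts[key[id(s)]] += 1
        freq = counts / counts.sum()
        assert np.all(np.abs(freq - 0.1) < 0.02)


class TestShuffleLabels:
    def test_histogram_conserved(self):
        ds = _labeled_dataset(30, 70)
        shuf = shuffle_labels(ds, seed=0)
        assert shuf.class_counts == ds.class_counts

    def test_features_untouched(self):
        ds = _labeled_dataset(10, 10)
        shuf = shuffle_labels(ds, seed=0)
        for a, b in zip(ds.samples, shuf.samples):
            assert a.F_marked is b.F_marked
            assert a.S is b.S

    def test_all_same_label_unchanged(self):
        ds = _labeled_dataset(10, 10)
        pos_only = Dataset(ds.samples[:10])
        shuf = shuffle_labels(pos_only, seed=1)
        assert list(shuf.labels()) == [1] * 10


class TestPersistence:
    def test_save_load_roundtrip(self, tmp_path):
        ds = _labeled_dataset(10, 20)
        p = tmp_path / "ds.npz"
        save_dataset(ds, p)
        back = load_dataset(p)
        assert len(back) == 30
        assert list(back.labels()) == list(ds.labels())
        for a, b in zip(ds.samples, back.samples):
            assert np.array_equal(a.F_marked, b.F_marked)
            assert np.array_equal(a.S, b.S)
            assert a.marked_atom == b.marked_atom


@settings(deadline=None, max_examples=25, derandomize=True)
@given(n_pos=st.integers(1, 400), n_neg=st.integers(1, 400),
       target=st.integers(1, 3000))
def test_rate_selection_always_reaches_target(n_pos, n_neg, target):
    r_pos, r_neg = choose_expansion_rates(n_pos, n_neg, target=target)
    assert n_pos * r_pos >= target
    assert n_neg * r_neg >= target
    # minimality: one less rate would miss the floor (when rate > 1)
    if r_pos > 1:
        assert n_pos * (r_pos - 1) < target
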