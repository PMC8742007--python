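"""Dataset containers, the reindex expander, splits, turns, shuffled labels.

The expander enlarges a small per-atom dataset by relabeling atom order with
seeded permutations: a graph-isomorphic relabeling produces a genuinely new
(F, S) input pair while leaving the molecule — and the sample's label —
unchanged.  Up to N! distinct pairs exist for an N-atom molecule with no
non-trivial automorphism.

Two reindex modes are provided.  ``consistent`` (default) permutes F rows
and S rows *and* columns with the same permutation, which is the structure-
preserving graph relabeling.  ``paper_literal`` reproduces the printed
batch-expander pseudocode exactly — S permuted by rows only, F by rows then
columns — which does not preserve the graph and is kept for fidelity
experiments only (with a ``paper_literal_rows`` sub-variant that permutes
F rows only, since the pseudocode's F orientation is ambiguous).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .mol2 import SamplePair

_SEED_CAP = 2**31


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass
class Dataset:
    """A bag of per-atom samples with binary labels."""

    samples: list[SamplePair] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.samples)

    def labels(self) -> np.ndarray:
        return np.array([int(s.label) for s in self.samples], dtype=np.int64)

    @property
    def class_counts(self) -> tuple[int, int]:
        """(n_pos, n_neg)."""
        y = self.labels()
        return int((y == 1).sum()), int((y == 0).sum())

    def subset(self, idx: Sequence[int]) -> "Dataset":
        return Dataset([self.samples[i] for i in idx])


@dataclass
class Split:
    train: Dataset
    validation: Dataset
    test: Dataset


# -- reindexing ------------------------------------------------------------

def reindex_pair(F: np.ndarray, S: np.ndarray, seed: int,
                 mode: str = "consistent") -> tuple[np.ndarray, np.ndarray]:
    """Relabel atom order with a permutation drawn deterministically from seed.

    ``consistent``: F' = F[pi], S' = S[pi][:, pi] (isomorphic relabeling).
    ``paper_literal``: F' rows permuted by pi then columns by an independent
    permutation from the same seed; S' rows only.
    ``paper_literal_rows``: F' and S' rows only.
    """
    F = np.asarray(F)
    S = np.asarray(S)
    n = S.shape[0]
    pi = np.random.default_rng(seed).permutation(n)
    if mode == "consistent":
        return F[pi], S[np.ix_(pi, pi)]
    if mode == "paper_literal":
        pc = np.random.default_rng(seed).permutation(F.shape[1])
        return F[pi][:, pc], S[pi]
    if mode == "paper_literal_rows":
        return F[pi], S[pi]
    raise ValueError(f"unknown reindex mode: {mode!r}")


def reindex_sample(sample: SamplePair, seed: int,
                   mode: str = "consistent") -> SamplePair:
    """Reindex one sample; the label travels unchanged (Y' = Y)."""
    f2, s2 = reindex_pair(sample.F_marked, sample.S, seed, mode=mode)
    mark_col = f2[:, -1]
    marked = int(mark_col.argmax()) + 1 if mark_col.max() == 1.0 else sample.marked_atom
    return SamplePair(F_marked=f2, S=s2, marked_atom=marked,
                      label=sample.label, molecule_id=sample.molecule_id)


def expand_pairs(F_set: Sequence[np.ndarray], S_set: Sequence[np.ndarray],
                 rate: int, seed=0, mode: str = "consistent",
                 ) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Batch expander: l inputs -> l * rate reindexed outputs.

    Sources cycle in order 1..l; the reindex seed is refreshed every 10
    outputs, so runs of up to 10 consecutive outputs share one permutation
    pattern.
    """
    if len(F_set) != len(S_set):
        raise ValueError("F_set and S_set must be aligned")
    if rate < 1:
        raise ValueError("expansion rate must be a positive integer")
    l = len(F_set)
    if l < 1:
        raise ValueError("need at least one input pair")
    rng = _rng(seed)
    cur = int(rng.integers(_SEED_CAP))
    F_e: list[np.ndarray] = []
    S_e: list[np.ndarray] = []
    for x in range(1, l * rate + 1):
        src = (x - 1) % l
        f2, s2 = reindex_pair(F_set[src], S_set[src], cur, mode=mode)
        F_e.append(f2)
        S_e.append(s2)
        if x % 10 == 0:
            cur = int(rng.integers(_SEED_CAP))
    return F_e, S_e


def expand_dataset(ds: Dataset, rate: int, seed=0,
                   mode: str = "consistent") -> Dataset:
    """Expander over samples; labels copied unchanged."""
    if rate < 1:
        raise ValueError("expansion rate must be a positive integer")
    l = len(ds)
    if l < 1:
        raise ValueError("cannot expand an empty dataset")
    rng = _rng(seed)
    cur = int(rng.integers(_SEED_CAP))
    out: list[SamplePair] = []
    for x in range(1, l * rate + 1):
        out.append(reindex_sample(ds.samples[(x - 1) % l], cur, mode=mode))
        if x % 10 == 0:
            cur = int(rng.integers(_SEED_CAP))
    return Dataset(out)


def choose_expansion_rates(n_pos: int, n_neg: int,
                           target: int = 2560) -> tuple[int, int]:
    """Smallest integer rates bringing each class to >= target samples."""
    if n_pos < 1 or n_neg < 1:
        raise ValueError("both classes need at least one sample")
    return math.ceil(target / n_pos), math.ceil(target / n_neg)


def expand_to_target(ds: Dataset, target: int = 2560, seed=0,
                     mode: str = "consistent") -> Dataset:
    """Expand each class with its own rate so both reach the target floor."""
    y = ds.labels()
    pos = Dataset([s for s, yi in zip(ds.samples, y) if yi == 1])
    neg = Dataset([s for s, yi in zip(ds.samples, y) if yi == 0])
    r_pos, r_neg = choose_expansion_rates(len(pos), len(neg), target=target)
    rng = _rng(seed)
    big_pos = expand_dataset(pos, r_pos, seed=rng, mode=mode)
    big_neg = expand_dataset(neg, r_neg, seed=rng, mode=mode)
    return Dataset(big_pos.samples + big_neg.samples)


# -- splitting, turns, shuffling ------------------------------------------

def split_dataset(ds: Dataset, seed=0) -> Split:
    """Class-stratified 10% test / 10% validation / 80% train partition."""
    y = ds.labels()
    rng = _rng(seed)
    test_idx: list[int] = []
    val_idx: list[int] = []
    train_idx: list[int] = []
    for cls in (1, 0):
        idx = np.flatnonzero(y == cls)
        if len(idx) < 10:
            raise ValueError(
                f"class {cls} has {len(idx)} samples; need >= 10 for a tenth split"
            )
        idx = rng.permutation(idx)
        tenth = len(idx) // 10
        test_idx.extend(idx[:tenth])
        val_idx.extend(idx[tenth : 2 * tenth])
        train_idx.extend(idx[2 * tenth :])
    return Split(train=ds.subset(train_idx), validation=ds.subset(val_idx),
                 test=ds.subset(test_idx))


def bootstrap_turn(ds: Dataset, per_class: int, seed=0) -> Dataset:
    """One turn: per_class positives + per_class negatives, drawn uniformly
    with replacement, so every epoch sees an exactly class-balanced resample."""
    y = ds.labels()
    rng = _rng(seed)
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("bootstrap_turn needs samples of both classes")
    pick = np.concatenate([rng.choice(pos, size=per_class, replace=True),
                           rng.choice(neg, size=per_class, replace=True)])
    pick = rng.permutation(pick)
    return ds.subset(pick)


def shuffle_labels(ds: Dataset, seed=0) -> Dataset:
    """Permute labels across samples; features untouched, multiset conserved."""
    rng = _rng(seed)
    y = ds.labels()
    perm = rng.permutation(len(y))
    out = []
    for s, yi in zip(ds.samples, y[perm]):
        out.append(SamplePair(F_marked=s.F_marked, S=s.S,
                              marked_atom=s.marked_atom, label=int(yi),
                              molecule_id=s.molecule_id))
    return Dataset(out)


# -- persistence -----------------------------------------------------------

def save_dataset(ds: Dataset, path: str | Path) -> None:
    """Serialize to a numpy archive (object arrays for the ragged matrices)."""
    np.savez_compressed(
        Path(path),
        F=np.array([s.F_marked for s in ds.samples], dtype=object),
        S=np.array([s.S for s in ds.samples], dtype=object),
        marked=np.array([s.marked_atom for s in ds.samples], dtype=np.int64),
        label=np.array([-1 if s.label is None else int(s.label)
                        for s in ds.samples], dtype=np.int64),
        mol_id=np.array([s.molecule_id for s in ds.samples], dtype=object),
    )


def load_dataset(path: str | Path) -> Dataset:
    with np.load(Path(path), allow_pickle=True) as z:
        samples = [
            SamplePair(F_marked=np.asarray(f, dtype=np.float64),
                       S=np.asarray(s, dtype=np.int64),
                       marked_atom=int(m),
                       label=None if lab < 0 else int(lab),
                       molecule_id=str(mid))
            for f, s, m, lab, mid in zip(z["F"], z["S"], z["marked"],
                                         z["label"], z["mol_id"])
        ]
    return Dataset(samples)
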