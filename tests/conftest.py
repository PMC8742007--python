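"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately use nothing from the production code paths
they check: nested Python loops for the WL aggregation and region pooling,
and exhaustive permutation search for graph canonical forms.
"""

from __future__ import annotations

import itertools
from math import ceil

import numpy as np
import pytest

from pispki import MoleculeGraph, SynthSpec, generate_molecule


# -- independent oracles ---------------------------------------------------

def wl_update_oracle(h: np.ndarray, S: np.ndarray, w_row: np.ndarray
                     ) -> np.ndarray:
    """Nested-loop switch-weighted WL update; w_row indexed by bond type 0..4
    with w_row[0] == 0."""
    n = h.shape[0]
    out = h.copy()
    for i in range(n):
        for j in range(n):
            out[i] = out[i] + w_row[S[i, j]] * h[j]
    return out


def wl_box_oracle(F: np.ndarray, S: np.ndarray, w: np.ndarray,
                  slope: float = 0.01) -> list[np.ndarray]:
    """Loop-based box: w has shape (T, L, 4); returns L activated blocks."""
    t_steps, layers, _ = w.shape
    blocks = []
    for l in range(layers):
        h = F.astype(float).copy()
        for t in range(t_steps):
            w_row = np.concatenate([[0.0], w[t, l]])
            h = wl_update_oracle(h, S, w_row)
        blocks.append(np.where(h >= 0, h, slope * h))
    return blocks


def pool_oracle(M: np.ndarray, k: int, mode: str) -> np.ndarray:
    """Region pooling by explicit loops, including the zero extension."""
    r, c = M.shape
    i_sz, j_sz = ceil(r / k), ceil(c / k)
    ext = np.zeros((k * i_sz, k * j_sz))
    ext[:r, :c] = M
    out = np.zeros((k, k))
    for x in range(k):
        for y in range(k):
            vals = []
            for i in range(i_sz):
                for j in range(j_sz):
                    vals.append(ext[x * i_sz + i, y * j_sz + j])
            out[x, y] = np.mean(vals) if mode == "average" else np.max(vals)
    return out


def canonical_form(colors: np.ndarray, S: np.ndarray) -> tuple:
    """Exact graph canonical form by minimising over all atom permutations.

    Only usable for small N (N! permutations); serves as the ground truth
    that structure-preserving reindexing must not change.
    """
    n = len(colors)
    best = None
    for pi in itertools.permutations(range(n)):
        pi = list(pi)
        key = (tuple(np.asarray(colors)[pi]),
               tuple(S[np.ix_(pi, pi)].ravel()))
        if best is None or key < best:
            best = key
    return best


def early_stop_oracle(accs, patience: int) -> int | None:
    """Brute-force scan: first epoch e such that none of the `patience`
    accuracies ending at e beat the best accuracy seen before them."""
    for e in range(patience + 1, len(accs) + 1):
        window = accs[e - patience : e]
        best_before = max(accs[: e - patience])
        if all(a <= best_before for a in window):
            return e
    return None


# -- fixtures --------------------------------------------------------------

@pytest.fixture
def path4() -> MoleculeGraph:
    """An asymmetric 4-atom path: distinct colors, distinct bond types."""
    s = np.zeros((4, 4), dtype=np.int64)
    s[0, 1] = s[1, 0] = 1
    s[1, 2] = s[2, 1] = 2
    s[2, 3] = s[3, 2] = 4
    return MoleculeGraph("path4", [0, 3, 8, 12], s)


@pytest.fixture
def small_molecules() -> list[MoleculeGraph]:
    rng = np.random.default_rng(42)
    spec = SynthSpec(atom_range=(4, 12))
    return [generate_molecule(spec, rng) for _ in range(10)]


SAMPLE_MOL2 = """\
# synthetic two-molecule fixture
@<TRIPOS>MOLECULE
ethanamide-like
4 3 0 0 0
SMALL
NO_CHARGES
@<TRIPOS>ATOM
1 C1 0.0 0.0 0.0 C.3 1 LIG 0.0
2 C2 1.5 0.0 0.0 C.2 1 LIG 0.0
3 O1 2.1 1.0 0.0 O.2 1 LIG 0.0
4 N1 2.1 -1.1 0.0 N.am 1 LIG 0.0
@<TRIPOS>BOND
1 1 2 1
2 2 3 2
3 2 4 am
@<TRIPOS>MOLECULE
benzene-fragment
3 3 0 0 0
SMALL
NO_CHARGES
@<TRIPOS>ATOM
1 C1 0.0 0.0 0.0 C.ar 1 LIG 0.0
2 C2 1.4 0.0 0.0 C.ar 1 LIG 0.0
3 C3 0.7 1.2 0.0 C.ar 1 LIG 0.0
@<TRIPOS>BOND
1 1 2 ar
2 2 3 ar
3 1 3 ar
"""


@pytest.fixture
def mol2_file(tmp_path):
    p = tmp_path / "fixture.mol2"
    p.write_text(SAMPLE_MOL2)
    return p
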