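"""TRIPOS MOL2 ligand parsing and the (F, S) graph encoding.

A ligand with N atoms becomes a :class:`MoleculeGraph`: a binary feature
matrix ``F`` (N x N_c, one-hot SYBYL atom-type "colors", N_c = 35) and a
symmetric structure adjacency matrix ``S`` (N x N) whose entries are bond
classes 0..4 (0 = not bonded).  Bond-type strings collapse to four classes:
single/triple/dummy/unknown/not-connected -> 1, double -> 2, amide -> 3,
aromatic -> 4; anything else -> 0.

The 35-entry SYBYL table and the 16-entry chemical-element merge table are
fixed, documented vocabularies; parsing fails loudly on an atom type outside
the table rather than guessing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

N_BOND_TYPES = 4  # N_e: bond classes 1..4; 0 means "not bonded"

#: SYBYL atom-type vocabulary: 35 types spanning 16 chemical-element groups.
#: Index order is the color index (0-based internally, 1-based in docs).
SYBYL_ATOM_TYPES: tuple[str, ...] = (
    # carbon
    "C.3", "C.2", "C.1", "C.ar", "C.cat",
    # nitrogen
    "N.3", "N.2", "N.1", "N.ar", "N.am", "N.pl3", "N.4",
    # oxygen
    "O.3", "O.2", "O.co2", "O.spc", "O.t3p",
    # sulfur
    "S.3", "S.2", "S.o", "S.o2",
    # phosphorus, halogens
    "P.3", "F", "Cl", "Br", "I",
    # hydrogen
    "H", "H.spc", "H.t3p",
    # other elements occasionally present in inhibitors
    "B", "Se", "Si", "Li", "Na", "Mg",
)

N_COLORS = len(SYBYL_ATOM_TYPES)  # 35

#: Merge of the 35 subtypes into 16 chemical elements (for the reduced-color
#: ablation): every subtype of one element maps to the same merged color.
ELEMENT_GROUPS: tuple[str, ...] = (
    "C", "N", "O", "S", "P", "F", "Cl", "Br", "I", "H",
    "B", "Se", "Si", "Li", "Na", "Mg",
)

N_MERGED_COLORS = len(ELEMENT_GROUPS)  # 16

MERGE_TABLE: Mapping[str, str] = {
    t: t.split(".")[0] for t in SYBYL_ATOM_TYPES
}

_BOND_CLASS: Mapping[str, int] = {
    "1": 1, "3": 1, "du": 1, "un": 1, "nc": 1,
    "2": 2,
    "am": 3,
    "ar": 4,
}


class Mol2ParseError(ValueError):
    """Raised for malformed MOL2 content; carries the offending line number."""


@dataclass
class MoleculeGraph:
    """A small-molecule graph: one-hot atom colors plus typed adjacency.

    ``colors`` holds 0-based color indices; ``F[i, colors[i]] == 1``;
    ``S`` is symmetric with a zero diagonal (no self-loops) and entries
    in 0..4.
    """

    molecule_id: str
    colors: np.ndarray  # (N,) int, 0-based color indices
    S: np.ndarray       # (N, N) int

    def __post_init__(self):
        self.colors = np.asarray(self.colors, dtype=np.int64)
        self.S = np.asarray(self.S, dtype=np.int64)
        n = self.colors.shape[0]
        if self.S.shape != (n, n):
            raise ValueError("S shape inconsistent with atom count")
        if not np.array_equal(self.S, self.S.T):
            raise ValueError("S must be symmetric")
        if np.any(np.diag(self.S) != 0):
            raise ValueError("S diagonal must be zero (no self-loops)")
        if self.S.min() < 0 or self.S.max() > N_BOND_TYPES:
            raise ValueError("bond classes must lie in 0..4")

    @property
    def n_atoms(self) -> int:
        return int(self.colors.shape[0])

    @property
    def n_colors(self) -> int:
        return N_COLORS

    @property
    def F(self) -> np.ndarray:
        """One-hot feature matrix, rows = atoms (N x 35)."""
        f = np.zeros((self.n_atoms, N_COLORS))
        f[np.arange(self.n_atoms), self.colors] = 1.0
        return f


@dataclass
class BindingRecord:
    """Binding-atom annotation from one crystal structure of a (K, I) pair.

    ``binding_atoms`` uses 1-based atom indices, matching common MOL2 and
    annotation-file conventions.
    """

    kinase_id: str
    inhibitor_id: str
    structure_index: int
    binding_atoms: frozenset[int] = field(default_factory=frozenset)


@dataclass
class SamplePair:
    """One per-atom sample: marked features, structure, binary label.

    ``F_marked`` is N x (width + 1); the last column is the mark channel and
    is 1 only at the marked atom's row, whose color entries are scaled by
    :data:`MARK_EMPHASIS` (see :func:`mark_atom` / :func:`strip_mark`).
    """

    F_marked: np.ndarray
    S: np.ndarray
    marked_atom: int  # 1-based
    label: int | None = None
    molecule_id: str = ""

    @property
    def n_atoms(self) -> int:
        return int(self.S.shape[0])


# -- parsing ---------------------------------------------------------------

def parse_mol2(path: str | Path) -> list[MoleculeGraph]:
    """Parse every molecule in a TRIPOS MOL2 file.

    Only the MOLECULE, ATOM, and BOND sections are consumed.  Unknown SYBYL
    atom types raise :class:`Mol2ParseError` naming the offending string and
    line number.
    """
    text = Path(path).read_text()
    return parse_mol2_text(text, source=str(path))


def parse_mol2_text(text: str, source: str = "<string>") -> list[MoleculeGraph]:
    molecules: list[MoleculeGraph] = []
    lines = text.splitlines()
    section = None
    mol_name: str | None = None
    mol_line = 0
    atom_types: list[str] = []
    atom_ids: dict[int, int] = {}
    bonds: list[tuple[int, int, str, int]] = []  # (atom a, atom b, type, line)

    def flush():
        if mol_name is None:
            return
        if not atom_types:
            raise Mol2ParseError(
                f"{source}:{mol_line}: molecule {mol_name!r} has no ATOM section"
            )
        molecules.append(_build_graph(mol_name, atom_types, atom_ids, bonds, source))

    for ln, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("@<TRIPOS>"):
            section = line[len("@<TRIPOS>"):].upper()
            if section == "MOLECULE":
                flush()
                mol_name, mol_line = None, ln
                atom_types, atom_ids, bonds = [], {}, []
            continue
        if section == "MOLECULE":
            if mol_name is None:
                mol_name = line
            continue
        if section == "ATOM":
            parts = line.split()
            if len(parts) < 6:
                raise Mol2ParseError(f"{source}:{ln}: malformed ATOM record: {raw!r}")
            try:
                atom_id = int(parts[0])
            except ValueError as e:
                raise Mol2ParseError(f"{source}:{ln}: bad atom id {parts[0]!r}") from e
            sybyl = parts[5]
            if sybyl not in _COLOR_INDEX:
                raise Mol2ParseError(
                    f"{source}:{ln}: unknown SYBYL atom type {sybyl!r}"
                )
            atom_ids[atom_id] = len(atom_types)
            atom_types.append(sybyl)
            continue
        if section == "BOND":
            parts = line.split()
            if len(parts) < 4:
                raise Mol2ParseError(f"{source}:{ln}: malformed BOND record: {raw!r}")
            try:
                a, b = int(parts[1]), int(parts[2])
            except ValueError as e:
                raise Mol2ParseError(f"{source}:{ln}: bad bond endpoints") from e
            bonds.append((a, b, parts[3].lower(), ln))
    flush()
    return molecules


_COLOR_INDEX = {t: i for i, t in enumerate(SYBYL_ATOM_TYPES)}


def bond_class(type_string: str) -> int:
    """Map a MOL2 bond-type string to its class 1..4 (unlisted -> 0)."""
    return _BOND_CLASS.get(type_string.lower(), 0)


def _build_graph(name, atom_types, atom_ids, bonds, source) -> MoleculeGraph:
    n = len(atom_types)
    colors = np.array([_COLOR_INDEX[t] for t in atom_types], dtype=np.int64)
    s = np.zeros((n, n), dtype=np.int64)
    for a, b, tstr, ln in bonds:
        if a not in atom_ids or b not in atom_ids:
            raise Mol2ParseError(f"{source}:{ln}: bond references unknown atom")
        if a == b:
            raise Mol2ParseError(f"{source}:{ln}: self-loop bond on atom {a}")
        i, j = atom_ids[a], atom_ids[b]
        s[i, j] = s[j, i] = bond_class(tstr)
    return MoleculeGraph(molecule_id=name, colors=colors, S=s)


def write_mol2(molecules: Iterable[MoleculeGraph], path: str | Path) -> None:
    """Write molecules as minimal TRIPOS MOL2 (zero coordinates).

    Bond classes are written back as representative type strings
    (1 -> "1", 2 -> "2", 3 -> "am", 4 -> "ar"), so parse -> write -> parse
    round-trips (colors, S) exactly.
    """
    rev = {1: "1", 2: "2", 3: "am", 4: "ar"}
    out = []
    for mol in molecules:
        n = mol.n_atoms
        pairs = [(i, j) for i in range(n) for j in range(i + 1, n) if mol.S[i, j] > 0]
        out.append("@<TRIPOS>MOLECULE")
        out.append(mol.molecule_id)
        out.append(f"{n} {len(pairs)} 0 0 0")
        out.append("SMALL")
        out.append("NO_CHARGES")
        out.append("@<TRIPOS>ATOM")
        for i in range(n):
            t = SYBYL_ATOM_TYPES[mol.colors[i]]
            el = t.split(".")[0]
            out.append(f"{i + 1} {el}{i + 1} 0.0 0.0 0.0 {t} 1 LIG 0.0")
        out.append("@<TRIPOS>BOND")
        for b_id, (i, j) in enumerate(pairs, start=1):
            out.append(f"{b_id} {i + 1} {j + 1} {rev[int(mol.S[i, j])]}")
    Path(path).write_text("\n".join(out) + "\n")


# -- per-atom samples and derived matrices ---------------------------------

#: The marked atom's color entries are scaled by this factor in addition to
#: the dedicated mark column.  The scaling writes the conjunction "the
#: marked atom has color c" directly into column c, where a single WL
#: aggregation step can combine it with bond-type information; a mark
#: confined to its own column would only meet the colors inside the dense
#: head, which learns that interaction far more slowly.
MARK_EMPHASIS = 3.0


def mark_atom(mol: MoleculeGraph, i: int) -> SamplePair:
    """Build the sample for atom ``i`` (1-based).

    The returned features are F with (a) a mark column appended that is 1
    only at row i and (b) row i's color entries scaled by
    :data:`MARK_EMPHASIS`.  :func:`strip_mark` inverts both.
    """
    if not 1 <= i <= mol.n_atoms:
        raise IndexError(f"atom index {i} out of range 1..{mol.n_atoms}")
    mark = np.zeros((mol.n_atoms, 1))
    mark[i - 1, 0] = 1.0
    f = mol.F
    f[i - 1] *= MARK_EMPHASIS
    return SamplePair(
        F_marked=np.hstack([f, mark]),
        S=mol.S.copy(),
        marked_atom=i,
        molecule_id=mol.molecule_id,
    )


def strip_mark(sample: SamplePair) -> np.ndarray:
    """Recover the plain one-hot F from a marked feature matrix."""
    f = np.array(sample.F_marked[:, :-1])
    i = int(np.asarray(sample.F_marked)[:, -1].argmax())
    f[i] /= MARK_EMPHASIS
    return f


def all_samples(mol: MoleculeGraph) -> list[SamplePair]:
    """One sample per atom (labels unset)."""
    return [mark_atom(mol, i) for i in range(1, mol.n_atoms + 1)]


def conv_input(mol: MoleculeGraph) -> np.ndarray:
    """Convolutional-branch input: S with -l_i on the diagonal.

    l_i is the 1-based color index of atom i, so the diagonal embeds atom
    identity into the otherwise purely structural matrix.
    """
    labels = mol.colors + 1  # 1-based label index l_i
    return mol.S.astype(np.float64) - np.diag(labels.astype(np.float64))


def conv_input_from_sample(sample: SamplePair) -> np.ndarray:
    """conv_input recovered from a marked sample (mark column ignored)."""
    f = sample.F_marked[:, :-1]
    labels = f.argmax(axis=1) + 1
    return sample.S.astype(np.float64) - np.diag(labels.astype(np.float64))


def resolve_labels(records: Sequence[BindingRecord], n_atoms: int) -> np.ndarray:
    """Union binding atoms over all crystal structures of one (K, I) pair.

    An atom is an interaction site (label 1) if it binds the kinase in ANY
    crystal structure; this removes the apparent contradiction of an atom
    bound in structure alpha but not in structure beta.  Returns a (N,)
    0/1 array indexed 0-based (atom i at position i-1).
    """
    if not records:
        raise ValueError("resolve_labels requires at least one BindingRecord")
    keys = {(r.kinase_id, r.inhibitor_id) for r in records}
    if len(keys) > 1:
        raise ValueError(f"records span multiple (kinase, inhibitor) pairs: {keys}")
    union: set[int] = set()
    for r in records:
        union |= set(r.binding_atoms)
    bad = [i for i in union if not 1 <= i <= n_atoms]
    if bad:
        raise ValueError(f"binding atom indices out of range 1..{n_atoms}: {sorted(bad)}")
    y = np.zeros(n_atoms, dtype=np.int64)
    for i in union:
        y[i - 1] = 1
    return y


def merge_colors(F: np.ndarray) -> np.ndarray:
    """Collapse 35 SYBYL-subtype columns to 16 chemical-element columns.

    Accepts either a plain F (N x 35) or a marked F (N x 36); a mark column,
    if present, is carried through unchanged as the last output column.
    """
    f = np.asarray(F, dtype=np.float64)
    if f.shape[1] in (N_MERGED_COLORS, N_MERGED_COLORS + 1):
        return f.copy()  # already on the element space: merge is idempotent
    has_mark = f.shape[1] == N_COLORS + 1
    if f.shape[1] not in (N_COLORS, N_COLORS + 1):
        raise ValueError(f"expected {N_COLORS} or {N_COLORS + 1} columns, got {f.shape[1]}")
    colors = f[:, :N_COLORS]
    el_index = {e: k for k, e in enumerate(ELEMENT_GROUPS)}
    proj = np.zeros((N_COLORS, N_MERGED_COLORS))
    for c, t in enumerate(SYBYL_ATOM_TYPES):
        proj[c, el_index[MERGE_TABLE[t]]] = 1.0
    merged = colors @ proj
    if has_mark:
        return np.hstack([merged, f[:, -1:]])
    return merged

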