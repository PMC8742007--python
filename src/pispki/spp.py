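"""Spatial pyramid pooling: variable-size matrices to a fixed-length vector.

Each pyramid stage k (k = 1..K) zero-extends the input to a multiple of k
in both dimensions, then pools non-overlapping ceil(R/k) x ceil(C/k)
regions into a k x k matrix.  Flattening all stages of all blocks row-major
and concatenating (feature blocks first) gives a vector whose length,
B_F * sum(k^2, k<=K_F) + B_S * sum(k^2, k<=K_S), depends only on the block
and stage counts — never on the number of atoms.

Average pooling divides the region sum by the full region area, padded
zeros included; max pooling takes the region maximum (a padded zero can win
in an all-negative region — this is the literal contract, documented).

The default mode assignment is feature branch = average, structure branch =
max, following the pooling formulas; the transposed "prose" assignment is
available via :class:`PyramidConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil

import numpy as np

from . import autodiff as ad


@dataclass
class PyramidConfig:
    """Stage counts and pooling modes for the two branches."""

    k_feature: int = 10
    k_structure: int = 3
    mode_feature: str = "average"
    mode_structure: str = "max"

    def __post_init__(self):
        if self.k_feature < 1 or self.k_structure < 1:
            raise ValueError("stage counts must be >= 1")
        for m in (self.mode_feature, self.mode_structure):
            if m not in ("average", "max"):
                raise ValueError(f"unknown pooling mode {m!r}")

    @classmethod
    def prose_mode(cls, k_feature: int = 10, k_structure: int = 3
                   ) -> "PyramidConfig":
        """The alternative assignment: feature = max, structure = average."""
        return cls(k_feature=k_feature, k_structure=k_structure,
                   mode_feature="max", mode_structure="average")


def extend_matrix(M: np.ndarray, k: int) -> np.ndarray:
    """Zero-extend an R x C matrix to k*ceil(R/k) x k*ceil(C/k);
    original entries stay top-left."""
    if k < 1:
        raise ValueError("stage coefficient k must be >= 1")
    M = np.asarray(M, dtype=np.float64)
    r, c = M.shape
    out = np.zeros((k * ceil(r / k), k * ceil(c / k)))
    out[:r, :c] = M
    return out


def pool_stage(M_ext: np.ndarray, k: int, mode: str) -> np.ndarray:
    """Pool an already-extended matrix into k x k regions."""
    M_ext = np.asarray(M_ext, dtype=np.float64)
    r, c = M_ext.shape
    if r % k or c % k:
        raise ValueError(f"extended shape {M_ext.shape} not divisible by k={k}")
    i_sz, j_sz = r // k, c // k
    resh = M_ext.reshape(k, i_sz, k, j_sz)
    if mode == "average":
        return resh.sum(axis=(1, 3)) / (i_sz * j_sz)
    if mode == "max":
        return resh.max(axis=(1, 3))
    raise ValueError(f"unknown pooling mode {mode!r}")


def pyramid_vector(M: np.ndarray, stages: int, mode: str) -> np.ndarray:
    """All stages k = 1..stages of one block, flattened row-major."""
    return np.concatenate([
        pool_stage(extend_matrix(M, k), k, mode).ravel()
        for k in range(1, stages + 1)
    ])


def stage_length(stages: int) -> int:
    """sum of k^2 for k = 1..stages."""
    return stages * (stages + 1) * (2 * stages + 1) // 6


def spp_length(n_feature_blocks: int, n_structure_blocks: int,
               cfg: PyramidConfig) -> int:
    """Output length as a pure function of block and stage counts."""
    return (n_feature_blocks * stage_length(cfg.k_feature)
            + n_structure_blocks * stage_length(cfg.k_structure))


def spp_vector(feature_blocks, structure_blocks, cfg: PyramidConfig):
    """Pool every block of both branches and concatenate, features first.

    Blocks may be ndarrays (returns an ndarray) or autodiff Tensors
    (returns a Tensor on the tape).
    """
    feature_blocks = list(feature_blocks)
    structure_blocks = list(structure_blocks)
    if not feature_blocks and not structure_blocks:
        raise ValueError("spp_vector needs at least one block")
    tensor_mode = any(isinstance(b, ad.Tensor)
                      for b in feature_blocks + structure_blocks)
    parts = []
    for blk in feature_blocks:
        if tensor_mode:
            blk = blk if isinstance(blk, ad.Tensor) else ad.Tensor(blk)
            parts.append(ad.pyramid_pool(blk, cfg.k_feature, cfg.mode_feature))
        else:
            parts.append(pyramid_vector(blk, cfg.k_feature, cfg.mode_feature))
    for blk in structure_blocks:
        if tensor_mode:
            blk = blk if isinstance(blk, ad.Tensor) else ad.Tensor(blk)
            parts.append(ad.pyramid_pool(blk, cfg.k_structure, cfg.mode_structure))
        else:
            parts.append(pyramid_vector(blk, cfg.k_structure, cfg.mode_structure))
    if tensor_mode:
        return ad.cat(parts)
    return np.concatenate(parts)
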