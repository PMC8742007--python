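"""The WL Box: switch-weighted Weisfeiler-Lehman feature refinement.

A WL Box is L independent layers, each a chain of T "wl-neurons".  Layer l
starts from the input feature matrix (h_l^0 = F) and each neuron updates
every atom row by mixing in its neighbors' rows, scaled by a trainable
*switch weight* w[t][l][e] selected by the bond type e of the connecting
edge:

    h_l^t(i) = h_l^(t-1)(i) + sum_j  w[t][l][S_ij] * h_l^(t-1)(j)

Bond type 0 means "not bonded" and its switch weight is structurally zero —
it is not a parameter and can never be trained away from zero.  After T
steps the layer output passes through the activation once; the L activated
matrices are the box's output blocks.  Chained boxes feed every block of the
previous box through the next box separately and concatenate, so block
counts multiply.

Functions here accept plain ndarrays (and return ndarrays) or autodiff
Tensors (and return Tensors), so the same code path serves tests and
training.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .mol2 import N_BOND_TYPES


@dataclass
class WLBoxConfig:
    """Shape of one box: L layers x T time steps."""

    layers: int = 3
    time_steps: int = 3

    def __post_init__(self):
        if self.layers < 1 or self.time_steps < 1:
            raise ValueError("a WL Box needs layers >= 1 and time_steps >= 1")


class SwitchWeights:
    """Trainable switch weights w[t][l][e] for one box.

    Stored as a (T, L, N_e) tensor over bond types e = 1..N_e; bond type 0
    is a hard-wired zero, not a parameter ("no bond" must contribute
    nothing regardless of training).  Initialised uniformly on
    [-init_scale, init_scale].
    """

    def __init__(self, cfg: WLBoxConfig, rng: np.random.Generator,
                 n_bond_types: int = N_BOND_TYPES, init_scale: float = 0.1):
        self.cfg = cfg
        self.n_bond_types = n_bond_types
        self.w = ad.Tensor(
            rng.uniform(-init_scale, init_scale,
                        size=(cfg.time_steps, cfg.layers, n_bond_types)),
            requires_grad=True,
        )

    def full(self) -> np.ndarray:
        """(T, L, N_e + 1) view with the bond-type-0 zero column prepended."""
        t, l, e = self.w.data.shape
        out = np.zeros((t, l, e + 1))
        out[:, :, 1:] = self.w.data
        return out

    @property
    def n_trainable(self) -> int:
        return int(self.w.data.size)

    def row(self, t: int, l: int):
        """Switch-weight vector for (time step t, layer l), 0-based."""
        return self.w[t, l]


def wl_neuron_update(h, S: np.ndarray, w_row):
    """One Eq.-style update: row i += sum_j w[S_ij] * row j (no activation).

    ``w_row`` indexes bond types 0..N_e with w_row[0] == 0, or equivalently
    types 1..N_e when it has length N_e.  ``h`` may be an ndarray or an
    autodiff Tensor.
    """
    S = np.asarray(S)
    if isinstance(w_row, ad.Tensor):
        wd = w_row.data
    else:
        wd = np.asarray(w_row, dtype=np.float64)
    if wd.shape[0] == N_BOND_TYPES + 1:
        if wd[0] != 0.0:
            raise ValueError("switch weight for bond type 0 must be zero")
        if isinstance(w_row, ad.Tensor):
            w_row = w_row[1:]
        else:
            w_row = wd[1:]
    elif wd.shape[0] != N_BOND_TYPES:
        raise ValueError("switch-weight row has wrong length")
    if isinstance(h, ad.Tensor) or isinstance(w_row, ad.Tensor):
        h_t = h if isinstance(h, ad.Tensor) else ad.Tensor(h)
        w_t = w_row if isinstance(w_row, ad.Tensor) else ad.Tensor(w_row)
        return ad.wl_step(h_t, S, w_t)
    h = np.asarray(h, dtype=np.float64)
    w_full = np.concatenate([[0.0], np.asarray(w_row, dtype=np.float64)])
    return h + w_full[S] @ h


def leaky_relu_array(x: np.ndarray, slope: float = 0.01) -> np.ndarray:
    return np.where(x >= 0, x, slope * x)


def wl_box_forward(F_in, S: np.ndarray, params: SwitchWeights,
                   cfg: WLBoxConfig | None = None, slope: float = 0.01) -> list:
    """Run one box: per layer, T chained updates, then the activation once.

    Returns the list of L output blocks (each N x width).  S itself is
    never modified; layers share nothing, so they refine the same input
    into L independent feature views.
    """
    cfg = cfg or params.cfg
    is_tensor = isinstance(F_in, ad.Tensor)
    S = np.asarray(S)
    blocks = []
    for l in range(cfg.layers):
        h = F_in if is_tensor else np.asarray(F_in, dtype=np.float64)
        for t in range(cfg.time_steps):
            if is_tensor:
                h = ad.wl_step(h, S, params.row(t, l))
            else:
                w_full = np.concatenate([[0.0], params.w.data[t, l]])
                h = h + w_full[S] @ h
        if is_tensor:
            blocks.append(ad.leaky_relu(h, slope))
        else:
            blocks.append(leaky_relu_array(h, slope))
    return blocks


def multi_box_forward(F_in, S: np.ndarray,
                      boxes: list[SwitchWeights], slope: float = 0.01) -> list:
    """Chain boxes: box 1 eats F; box m eats every block of box m-1
    separately; outputs concatenate in (outer block, inner layer) order.
    Final block count is the product of the boxes' layer counts."""
    if not boxes:
        raise ValueError("need at least one WL Box")
    blocks = [F_in]
    for box in boxes:
        blocks = [out for blk in blocks
                  for out in wl_box_forward(blk, S, box, slope=slope)]
    return blocks
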