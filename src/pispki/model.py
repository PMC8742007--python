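"""The full interaction-site predictor and its ablation variants.

Per sample (one marked atom of one molecule), the forward pass is:

* feature branch — the marked feature matrix runs through chained WL Boxes
  (two 3-layers-x-3-time-steps boxes by default, so 9 output blocks);
* structure branch — S with color indices subtracted on the diagonal runs
  through two convolution stages (1 -> 2 -> 5 channels, 3x3 kernels,
  stride 1, zero-padded to keep N x N, Leaky ReLU after each), giving 5
  blocks;
* both block lists pass through spatial pyramid pooling into one
  fixed-length vector (3535 under the defaults), independent of N — no
  zero-padding of inputs is ever needed;
* a dense head (5 hidden layers, width 2000, Leaky ReLU, dropout 0.05 in
  training) ends in a single sigmoid unit; prediction is probability >= 0.5.

Ablation variants: ``no_wl`` feeds the raw marked features to the feature
pyramid as a single block; ``one_box`` keeps a single WL Box; ``no_conv``
drops the structure branch; ``merged_colors`` collapses the 35 atom
subtypes to 16 chemical elements before everything else.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import autodiff as ad
from .mol2 import (N_COLORS, N_MERGED_COLORS, SamplePair,
                   conv_input_from_sample, merge_colors)
from .spp import PyramidConfig, spp_length, spp_vector
from .wl import SwitchWeights, WLBoxConfig, multi_box_forward

VARIANTS = ("full", "no_wl", "one_box", "no_conv", "merged_colors")


@dataclass
class ModelConfig:
    wl_boxes: list[WLBoxConfig] = field(
        default_factory=lambda: [WLBoxConfig(3, 3), WLBoxConfig(3, 3)])
    conv_channels: tuple[int, int, int] = (1, 2, 5)
    kernel: int = 3
    pyramid: PyramidConfig = field(default_factory=PyramidConfig)
    dense_width: int = 2000
    dense_depth: int = 5
    dropout: float = 0.05
    leaky_slope: float = 0.01
    variant: str = "full"

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.dense_depth < 1:
            raise ValueError("dense_depth must be >= 1")
        if self.conv_channels[0] != 1:
            raise ValueError("the structure branch has one input channel")

    # -- derived shapes ----------------------------------------------------
    @property
    def n_colors(self) -> int:
        return N_MERGED_COLORS if self.variant == "merged_colors" else N_COLORS

    @property
    def feature_width(self) -> int:
        return self.n_colors + 1  # one-hot colors + mark channel

    @property
    def n_feature_blocks(self) -> int:
        if self.variant == "no_wl":
            return 1
        n = 1
        for b in self.effective_boxes():
            n *= b.layers
        return n

    @property
    def n_structure_blocks(self) -> int:
        return 0 if self.variant == "no_conv" else self.conv_channels[-1]

    def effective_boxes(self) -> list[WLBoxConfig]:
        if self.variant == "no_wl":
            return []
        if self.variant == "one_box":
            return self.wl_boxes[:1]
        return list(self.wl_boxes)

    @property
    def spp_output_length(self) -> int:
        return spp_length(self.n_feature_blocks, self.n_structure_blocks,
                          self.pyramid)


def build_ablation(variant: str, base: ModelConfig | None = None,
                   seed: int | np.random.Generator = 0) -> "PISPKIModel":
    """Construct one of the five variants from a shared base configuration."""
    base = base or ModelConfig()
    cfg = ModelConfig(wl_boxes=[WLBoxConfig(b.layers, b.time_steps)
                                for b in base.wl_boxes],
                      conv_channels=base.conv_channels, kernel=base.kernel,
                      pyramid=base.pyramid, dense_width=base.dense_width,
                      dense_depth=base.dense_depth, dropout=base.dropout,
                      leaky_slope=base.leaky_slope, variant=variant)
    return PISPKIModel(cfg, seed=seed)


class PISPKIModel:
    """WL Boxes + convolutional branch + SPP + dense head."""

    def __init__(self, cfg: ModelConfig | None = None,
                 seed: int | np.random.Generator = 0):
        self.cfg = cfg or ModelConfig()
        rng = seed if isinstance(seed, np.random.Generator) \
            else np.random.default_rng(seed)
        c = self.cfg
        self.boxes = [SwitchWeights(b, rng) for b in c.effective_boxes()]
        self.conv_w: list[ad.Tensor] = []
        self.conv_b: list[ad.Tensor] = []
        if c.variant != "no_conv":
            chain = c.conv_channels
            for stage, (cin, cout) in enumerate(zip(chain[:-1], chain[1:])):
                # He fan-in scaling keeps activation variance stable under
                # the Leaky-ReLU stack; the first stage is additionally
                # divided by N_c because S_conv carries color indices up to
                # N_c on its diagonal — without this the structure branch
                # enters the pyramid pooling orders of magnitude louder
                # than the feature branch and drowns it out at the start
                # of training
                std = np.sqrt(2.0 / (cin * c.kernel * c.kernel))
                if stage == 0:
                    std /= c.n_colors
                self.conv_w.append(ad.Tensor(
                    rng.normal(0.0, std, (cout, cin, c.kernel, c.kernel)),
                    requires_grad=True))
                self.conv_b.append(ad.Tensor(np.zeros(cout), requires_grad=True))
        self.dense_W: list[ad.Tensor] = []
        self.dense_b: list[ad.Tensor] = []
        widths = [c.spp_output_length] + [c.dense_width] * c.dense_depth + [1]
        for fan_in, fan_out in zip(widths[:-1], widths[1:]):
            std = np.sqrt(2.0 / fan_in)
            self.dense_W.append(ad.Tensor(
                rng.normal(0.0, std, (fan_out, fan_in)), requires_grad=True))
            self.dense_b.append(ad.Tensor(np.zeros(fan_out), requires_grad=True))

    # -- parameters --------------------------------------------------------
    def parameters(self) -> list[ad.Tensor]:
        return ([b.w for b in self.boxes] + self.conv_w + self.conv_b
                + self.dense_W + self.dense_b)

    def parameter_count(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def audit(self) -> dict[str, int]:
        """Named parameter-count table (switch weights listed per box)."""
        table: dict[str, int] = {}
        for i, b in enumerate(self.boxes, start=1):
            table[f"wl_box_{i}_switch_weights"] = b.n_trainable
        for i, (w, bb) in enumerate(zip(self.conv_w, self.conv_b), start=1):
            table[f"conv{i}"] = w.data.size + bb.data.size
        for i, (w, bb) in enumerate(zip(self.dense_W, self.dense_b), start=1):
            table[f"dense{i}"] = w.data.size + bb.data.size
        table["total"] = self.parameter_count()
        return table

    # -- forward -----------------------------------------------------------
    def _features(self, sample: SamplePair) -> np.ndarray:
        f = sample.F_marked
        if self.cfg.variant == "merged_colors":
            f = merge_colors(f)
        if f.shape[1] != self.cfg.feature_width:
            raise ValueError(
                f"sample feature width {f.shape[1]} != model width "
                f"{self.cfg.feature_width}")
        return np.asarray(f, dtype=np.float64)

    def conv_branch(self, s_conv: np.ndarray) -> list[ad.Tensor]:
        """Two Leaky-ReLU convolution stages over the N x N structure input."""
        x = ad.Tensor(np.asarray(s_conv, dtype=np.float64)[None, :, :])
        for w, b in zip(self.conv_w, self.conv_b):
            x = ad.leaky_relu(ad.conv2d_same(x, w, b), self.cfg.leaky_slope)
        return [x[c] for c in range(x.shape[0])]

    def dense_head(self, p: ad.Tensor, train: bool = False,
                   rng: np.random.Generator | None = None) -> ad.Tensor:
        """Hidden stack then a single logit; dropout only in training mode."""
        h = p
        for w, b in zip(self.dense_W[:-1], self.dense_b[:-1]):
            h = ad.leaky_relu(w @ h + b, self.cfg.leaky_slope)
            if train and self.cfg.dropout > 0:
                if rng is None:
                    raise ValueError("training-mode dropout needs an rng")
                h = ad.dropout(h, self.cfg.dropout, rng)
        return self.dense_W[-1] @ h + self.dense_b[-1]  # (1,) logit

    def forward_logit(self, sample: SamplePair, train: bool = False,
                      rng: np.random.Generator | None = None) -> ad.Tensor:
        f = self._features(sample)
        if self.cfg.variant == "no_wl":
            feature_blocks: list = [ad.Tensor(f)]
        else:
            feature_blocks = multi_box_forward(ad.Tensor(f), sample.S,
                                               self.boxes,
                                               slope=self.cfg.leaky_slope)
        if self.cfg.variant == "no_conv":
            structure_blocks: list = []
        else:
            structure_blocks = self.conv_branch(conv_input_from_sample(sample))
        p = spp_vector(feature_blocks, structure_blocks, self.cfg.pyramid)
        return self.dense_head(p, train=train, rng=rng)

    def predict_proba(self, sample: SamplePair) -> float:
        with ad.no_grad():
            z = self.forward_logit(sample, train=False)
            return float(ad.sigmoid(z).data[0])

    def predict(self, sample: SamplePair) -> int:
        return int(self.predict_proba(sample) >= 0.5)

    # -- persistence -------------------------------------------------------
    def save(self, path: str | Path) -> None:
        arrays: dict[str, np.ndarray] = {}
        for i, b in enumerate(self.boxes):
            arrays[f"box{i}_w"] = b.w.data
        for i, (w, bb) in enumerate(zip(self.conv_w, self.conv_b)):
            arrays[f"conv{i}_w"] = w.data
            arrays[f"conv{i}_b"] = bb.data
        for i, (w, bb) in enumerate(zip(self.dense_W, self.dense_b)):
            arrays[f"dense{i}_W"] = w.data
            arrays[f"dense{i}_b"] = bb.data
        cfg = asdict(self.cfg)
        cfg["wl_boxes"] = [asdict(b) for b in self.cfg.wl_boxes]
        cfg["pyramid"] = asdict(self.cfg.pyramid)
        arrays["config_json"] = np.array(json.dumps(cfg))
        np.savez(Path(path), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "PISPKIModel":
        with np.load(Path(path), allow_pickle=False) as z:
            cfg_d = json.loads(str(z["config_json"]))
            cfg = ModelConfig(
                wl_boxes=[WLBoxConfig(**b) for b in cfg_d.pop("wl_boxes")],
                pyramid=PyramidConfig(**cfg_d.pop("pyramid")),
                conv_channels=tuple(cfg_d.pop("conv_channels")),
                **cfg_d)
            model = cls(cfg, seed=0)
            for i, b in enumerate(model.boxes):
                b.w.data[...] = z[f"box{i}_w"]
            for i in range(len(model.conv_w)):
                model.conv_w[i].data[...] = z[f"conv{i}_w"]
                model.conv_b[i].data[...] = z[f"conv{i}_b"]
            for i in range(len(model.dense_W)):
                model.dense_W[i].data[...] = z[f"dense{i}_W"]
                model.dense_b[i].data[...] = z[f"dense{i}_b"]
        return model
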