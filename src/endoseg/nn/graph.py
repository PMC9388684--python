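"""Declarative construction of DenseUNet backbones with fNLA/sNLA attention.

The network is described as an ordered list of :class:`LayerSpec` nodes
forming a DAG; parameters are countable from the specification alone, so a
graph can be audited (e.g. against published model sizes) without
instantiating any weights.

Architecture summary (five resolution stages):

* Dense nodes hold 4, 8, 12, 16 or 20 convolutional blocks depending on the
  resolution stage.  A convolutional block is a compression layer
  Conv(1x1, 4*GR) + BRN + ELU, a growth layer Conv(3x3, GR) + BRN + ELU,
  Dropout(20%), and concatenation with the block input.  The very first
  convolutional block of the network has no compression layer, and nodes at
  the first (full) resolution stage use no dropout.
* Transition layers are Conv(1x1, alpha) + BRN + ELU; downsampling is
  Conv(2x2, stride 2, alpha); upsampling is ConvTranspose(2x2, stride 2,
  alpha); alpha = (blocks in the previous dense node) * GR / 2.
* The multiscale variants ('plus'/'plusplus') fill the decoder triangle of
  nodes X^{a,b} (a + b <= 4).  Every node owns one transition conv; the
  'plusplus' variant aggregates, by feature addition, the transition outputs
  of *all* previous nodes of the same resolution row, while 'plus' uses only
  the immediately preceding one.
* Attention: each node attends on the output of the node one resolution
  stage deeper in the same column when it exists (feedback non-local
  attention, fNLA, keyed through 2x2 transpose convolutions) and on itself
  otherwise (self non-local attention, sNLA) — hence the deepest encoder
  node and the decoder nodes are sNLA.  Queries, keys and values are
  projected to floor(C/8) (min 1) channels; attention is scaled dot-product
  with row-wise softmax; aggregation is multiplicative (sigmoid gate),
  concatenative, or additive.

Parameter counts: convolutions count weights + biases; a batch-renorm layer
counts 2 trainable parameters per channel (scale, shift) plus 3 tracked
statistics per channel (moving mean, variance and stddev), reported
separately as ``trainable_parameter_count`` and ``total_parameter_count``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import pandas as pd

__all__ = ["NetworkConfig", "AttentionSpec", "LayerSpec", "ModelGraph", "build_network"]

#: parameters per batch-renorm channel: (trainable, total incl. statistics)
BN_TRAINABLE_PER_CHANNEL = 2
BN_TOTAL_PER_CHANNEL = 5


@dataclass(frozen=True)
class NetworkConfig:
    """Configuration of a segmentation network backbone."""

    backbone: str = "denseunet"
    multiscale: str = "none"       # none | plus | plusplus
    attention: str = "none"        # none | fnla
    aggregation: str = "mul"       # mul | conc | add
    growth_rate: int | None = None  # default: 5 basic, 4 multiscale
    stages: int = 5
    blocks_per_stage: tuple = (4, 8, 12, 16, 20)
    dropout_rate: float = 0.20
    input_channels: int = 1
    output_maps: int = 2

    def __post_init__(self) -> None:
        if self.backbone not in ("denseunet",):
            raise ValueError(f"unsupported backbone: {self.backbone!r}")
        if self.multiscale not in ("none", "plus", "plusplus"):
            raise ValueError(f"unknown multiscale variant: {self.multiscale!r}")
        if self.attention not in ("none", "fnla"):
            raise ValueError(f"unknown attention: {self.attention!r}")
        if self.aggregation not in ("mul", "conc", "add"):
            raise ValueError(f"unknown aggregation: {self.aggregation!r}")
        if self.stages != 5:
            raise ValueError("the architecture is defined for 5 resolution stages")
        if len(self.blocks_per_stage) != self.stages:
            raise ValueError("blocks_per_stage must have one entry per stage")
        if any(b2 <= b1 for b1, b2 in zip(self.blocks_per_stage, self.blocks_per_stage[1:])):
            raise ValueError("blocks_per_stage must be strictly increasing")
        if self.growth_rate is None:
            object.__setattr__(self, "growth_rate", 5 if self.multiscale == "none" else 4)
        if self.growth_rate < 1:
            raise ValueError("growth rate must be >= 1")

    def to_json(self) -> str:
        d = dict(self.__dict__)
        d["blocks_per_stage"] = list(d["blocks_per_stage"])
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "NetworkConfig":
        d = json.loads(text)
        d["blocks_per_stage"] = tuple(d["blocks_per_stage"])
        return cls(**d)


@dataclass(frozen=True)
class AttentionSpec:
    """Resolved attention-block geometry at one network site."""

    mode: str            # fnla | snla
    aggregation: str     # mul | conc | add
    in_channels: int     # C of the transformed tensor X
    key_channels: int    # channels of the companion tensor Y (== C for sNLA)
    proj_channels: int   # floor(C/8), min 1

    def __post_init__(self) -> None:
        if self.mode not in ("fnla", "snla"):
            raise ValueError(f"unknown attention mode: {self.mode!r}")


@dataclass(frozen=True)
class LayerSpec:
    """One operation of the network DAG."""

    name: str
    op: str                       # input|conv|convT|bn|elu|relu|sigmoid|dropout|concat|add|mul|attend|softmax
    inputs: tuple = ()
    kernel: int = 0
    stride: int = 1
    in_channels: int = 0
    out_channels: int = 0
    rate: float = 0.0             # dropout rate
    scale_channels: int = 0       # attend: projection width for 1/sqrt scaling

    @property
    def trainable_params(self) -> int:
        if self.op == "conv" or self.op == "convT":
            return self.kernel * self.kernel * self.in_channels * self.out_channels + self.out_channels
        if self.op == "bn":
            return BN_TRAINABLE_PER_CHANNEL * self.out_channels
        return 0

    @property
    def total_params(self) -> int:
        if self.op == "bn":
            return BN_TOTAL_PER_CHANNEL * self.out_channels
        return self.trainable_params


class ModelGraph:
    """An ordered DAG of :class:`LayerSpec` with countable parameters."""

    def __init__(self, config: NetworkConfig, layers: list[LayerSpec]):
        self.config = config
        self.layers = list(layers)
        self._by_name = {l.name: l for l in self.layers}
        if len(self._by_name) != len(self.layers):
            raise ValueError("duplicate layer names in graph")
        seen = set()
        for l in self.layers:
            for inp in l.inputs:
                if inp not in seen:
                    raise ValueError(f"layer {l.name!r} consumes undefined input {inp!r}")
            seen.add(l.name)

    def __getitem__(self, name: str) -> LayerSpec:
        return self._by_name[name]

    def __len__(self) -> int:
        return len(self.layers)

    @property
    def trainable_parameter_count(self) -> int:
        return sum(l.trainable_params for l in self.layers)

    @property
    def total_parameter_count(self) -> int:
        """Parameter count including per-channel normalization statistics."""
        return sum(l.total_params for l in self.layers)

    def summary(self) -> pd.DataFrame:
        rows = [
            {
                "layer": l.name,
                "op": l.op,
                "kernel": l.kernel,
                "stride": l.stride,
                "in_channels": l.in_channels,
                "out_channels": l.out_channels,
                "inputs": ";".join(l.inputs),
                "trainable_params": l.trainable_params,
                "total_params": l.total_params,
            }
            for l in self.layers
        ]
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.summary().to_csv(path, index=False)


class _Builder:
    def __init__(self, cfg: NetworkConfig):
        self.cfg = cfg
        self.layers: list[LayerSpec] = []
        self.channels: dict[str, int] = {}

    def emit(self, spec: LayerSpec) -> str:
        self.layers.append(spec)
        self.channels[spec.name] = spec.out_channels
        return spec.name

    def input(self, name: str, channels: int) -> str:
        return self.emit(LayerSpec(name, "input", (), out_channels=channels))

    def conv(self, name: str, x: str, kernel: int, cout: int, stride: int = 1) -> str:
        return self.emit(
            LayerSpec(name, "conv", (x,), kernel=kernel, stride=stride,
                      in_channels=self.channels[x], out_channels=cout)
        )

    def convT(self, name: str, x: str, cout: int) -> str:
        return self.emit(
            LayerSpec(name, "convT", (x,), kernel=2, stride=2,
                      in_channels=self.channels[x], out_channels=cout)
        )

    def bn(self, name: str, x: str) -> str:
        c = self.channels[x]
        return self.emit(LayerSpec(name, "bn", (x,), in_channels=c, out_channels=c))

    def act(self, name: str, x: str, op: str) -> str:
        c = self.channels[x]
        return self.emit(LayerSpec(name, op, (x,), in_channels=c, out_channels=c))

    def dropout(self, name: str, x: str) -> str:
        c = self.channels[x]
        return self.emit(LayerSpec(name, "dropout", (x,), in_channels=c, out_channels=c,
                                   rate=self.cfg.dropout_rate))

    def concat(self, name: str, xs: list[str]) -> str:
        c = sum(self.channels[x] for x in xs)
        return self.emit(LayerSpec(name, "concat", tuple(xs), out_channels=c))

    def add(self, name: str, xs: list[str]) -> str:
        cs = {self.channels[x] for x in xs}
        if len(cs) != 1:
            raise ValueError(f"feature addition of unequal channel counts {cs} at {name}")
        return self.emit(LayerSpec(name, "add", tuple(xs), out_channels=cs.pop()))

    def mul(self, name: str, x: str, gate: str) -> str:
        return self.emit(LayerSpec(name, "mul", (x, gate), out_channels=self.channels[x]))

    def attend(self, name: str, q: str, k: str, v: str, c8: int) -> str:
        return self.emit(LayerSpec(name, "attend", (q, k, v), out_channels=c8, scale_channels=c8))

    # --- composite blocks -------------------------------------------------

    def conv_bn_elu(self, prefix: str, x: str, kernel: int, cout: int, stride: int = 1,
                    transposed: bool = False) -> str:
        if transposed:
            x = self.convT(f"{prefix}/convT", x, cout)
        else:
            x = self.conv(f"{prefix}/conv", x, kernel, cout, stride)
        x = self.bn(f"{prefix}/bn", x)
        return self.act(f"{prefix}/elu", x, "elu")

    def dense_node(self, prefix: str, x: str, n_blocks: int, stage: int,
                   first_of_network: bool) -> str:
        gr = self.cfg.growth_rate
        use_dropout = stage > 0
        for i in range(n_blocks):
            block_in = x
            h = x
            if not (first_of_network and i == 0):
                h = self.conv_bn_elu(f"{prefix}/b{i}/comp", h, 1, 4 * gr)
            h = self.conv_bn_elu(f"{prefix}/b{i}/growth", h, 3, gr)
            if use_dropout and not (first_of_network and i == 0):
                h = self.dropout(f"{prefix}/b{i}/drop", h)
            x = self.concat(f"{prefix}/b{i}/cat", [block_in, h])
        return x

    def attention_block(self, prefix: str, x: str, y: str | None) -> str:
        """Attach fNLA (y given, half resolution) or sNLA (y None) to x."""
        cfg = self.cfg
        cx = self.channels[x]
        c8 = max(cx // 8, 1)
        q = self.conv(f"{prefix}/theta", x, 1, c8)
        if y is not None:
            k = self.convT(f"{prefix}/phi", y, c8)
            v = self.convT(f"{prefix}/g", y, c8)
        else:
            k = self.conv(f"{prefix}/phi", x, 1, c8)
            v = self.conv(f"{prefix}/g", x, 1, c8)
        z = self.attend(f"{prefix}/attend", q, k, v, c8)
        if cfg.aggregation == "mul":
            gate = self.conv(f"{prefix}/omega", z, 1, 1)
            gate = self.act(f"{prefix}/sigmoid", gate, "sigmoid")
            return self.mul(f"{prefix}/out", x, gate)
        if cfg.aggregation == "conc":
            z = self.act(f"{prefix}/omega_elu", z, "elu")
            return self.concat(f"{prefix}/out", [x, z])
        z = self.conv(f"{prefix}/omega", z, 1, cx)
        z = self.act(f"{prefix}/relu", z, "relu")
        return self.add(f"{prefix}/out", [x, z])


def _alpha(cfg: NetworkConfig, stage: int) -> int:
    return cfg.blocks_per_stage[stage] * cfg.growth_rate // 2


def _build_basic(b: _Builder) -> None:
    cfg = b.cfg
    x = b.input("image", cfg.input_channels)
    raw = {}
    for a in range(cfg.stages):
        raw[a] = b.dense_node(f"enc{a}", x, cfg.blocks_per_stage[a], a, first_of_network=(a == 0))
        if a < cfg.stages - 1:
            x = b.conv_bn_elu(f"down{a}", raw[a], 2, _alpha(cfg, a), stride=2)
    out = dict(raw)
    if cfg.attention == "fnla":
        # feedback path: deepest first; each node keys on the attended node below
        out[4] = b.attention_block("att_enc4", raw[4], None)
        for a in (3, 2, 1, 0):
            out[a] = b.attention_block(f"att_enc{a}", raw[a], out[a + 1])
    x = out[cfg.stages - 1]
    for a in range(cfg.stages - 2, -1, -1):
        u = b.conv_bn_elu(f"up{a}", x, 2, _alpha(cfg, a + 1), transposed=True)
        s = b.conv_bn_elu(f"skip{a}", out[a], 1, _alpha(cfg, a))
        x = b.concat(f"dec{a}/in", [u, s])
        x = b.dense_node(f"dec{a}", x, cfg.blocks_per_stage[a], a, first_of_network=False)
        if cfg.attention == "fnla":
            x = b.attention_block(f"att_dec{a}", x, None)
    logits = b.conv(f"head/conv", x, 1, cfg.output_maps)
    logits = b.bn("logits", logits)
    b.emit(LayerSpec("output", "softmax", (logits,), out_channels=cfg.output_maps))


def _build_multiscale(b: _Builder) -> None:
    cfg = b.cfg
    top = cfg.stages - 1
    x = b.input("image", cfg.input_channels)
    raw, out, trans = {}, {}, {}
    for a in range(cfg.stages):
        raw[(a, 0)] = b.dense_node(f"x{a}0", x, cfg.blocks_per_stage[a], a, first_of_network=(a == 0))
        if a < top:
            x = b.conv_bn_elu(f"down{a}", raw[(a, 0)], 2, _alpha(cfg, a), stride=2)
    out.update(raw)
    if cfg.attention == "fnla":
        out[(top, 0)] = b.attention_block(f"att_x{top}0", raw[(top, 0)], None)
        for a in range(top - 1, -1, -1):
            out[(a, 0)] = b.attention_block(f"att_x{a}0", raw[(a, 0)], out[(a + 1, 0)])

    def transition_of(a: int, c: int) -> str:
        key = (a, c)
        if key not in trans:
            trans[key] = b.conv_bn_elu(f"trans_x{a}{c}", out[key], 1, _alpha(cfg, a))
        return trans[key]

    for col in range(1, cfg.stages):
        for a in range(top - col, -1, -1):
            u = b.conv_bn_elu(f"up_x{a}{col}", out[(a + 1, col - 1)], 2, _alpha(cfg, a + 1),
                              transposed=True)
            if cfg.multiscale == "plus":
                s = transition_of(a, col - 1)
            else:  # plusplus: feature addition of all previous transitions of the row
                skips = [transition_of(a, c) for c in range(col)]
                s = skips[0] if len(skips) == 1 else b.add(f"sum_x{a}{col}", skips)
            x = b.concat(f"x{a}{col}/in", [u, s])
            x = b.dense_node(f"x{a}{col}", x, cfg.blocks_per_stage[a], a, first_of_network=False)
            raw[(a, col)] = x
            if cfg.attention == "fnla":
                below = out.get((a + 1, col))
                x = b.attention_block(f"att_x{a}{col}", x, below)
            out[(a, col)] = x
    logits = b.conv("head/conv", out[(0, cfg.stages - 1)], 1, cfg.output_maps)
    logits = b.bn("logits", logits)
    b.emit(LayerSpec("output", "softmax", (logits,), out_channels=cfg.output_maps))


def build_network(config: NetworkConfig) -> ModelGraph:
    """Build the configured network as a deterministic :class:`ModelGraph`.

    The spatial size is not part of the graph; at execution time the input
    height and width must be divisible by ``2**(stages - 1)``.
    """
    b = _Builder(config)
    if config.multiscale == "none":
        _build_basic(b)
    else:
        _build_multiscale(b)
    return ModelGraph(config, b.layers)
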