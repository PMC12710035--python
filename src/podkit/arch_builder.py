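"""Symbolic architecture graphs for prototype-mask pod segmentation networks.

This module builds the single-class prototype segmentation baseline (a nano-
scale CSP backbone with a three-level feature pyramid, decoupled detection
heads, a mask-coefficient head and a prototype branch) and its variants:

* hierarchical prototype aggregation (HPA): the prototype branch is fed a
  channel-wise concatenation of c3/c4/c5 channels drawn from the P3/P4/P5
  pyramid taps, with c3 + c4 + c5 = k (the prototype count);
* the U-shaped prototype decoder with efficient multiscale attention (EMA)
  after each prototype-branch convolution, emitting prototypes at 1/4 of the
  input resolution.

Graphs are DAGs of :class:`LayerSpec` primitives with closed-form parameter
counts.  Counting conventions (pinned by tests against an instantiated-tensor
oracle):

* convolutions are counted *fused*: batch-norm is folded into the conv, so a
  normalised conv costs ``cin*cout*k²/groups + cout``;
* FLOPs are ``2 x`` multiply-accumulates of conv / transposed-conv / linear
  layers; a transposed conv is costed as its equivalent dense convolution
  over the zero-inserted input (``k²*cin/groups`` MACs per output element),
  which is what mainstream profilers report; nearest upsampling, pooling and
  concatenation cost nothing;
* parameter totals in millions are *floored* at three decimals by
  :func:`format_millions`, matching how such tables are conventionally
  printed from raw counts.
"""

from __future__ import annotations

from collections import OrderedDict
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "TensorShape",
    "LayerKind",
    "LayerSpec",
    "ModelGraph",
    "HPAVariant",
    "HPAConfig",
    "UpsampleMode",
    "ProtonetConfig",
    "PodkitError",
    "InvalidConfigError",
    "ConstraintViolationError",
    "MissingTapError",
    "ShapeMismatchError",
    "build_baseline",
    "apply_hpa",
    "apply_u_ema",
    "apply_ema",
    "build_podnet",
    "infer_shapes",
    "count_parameters",
    "count_flops",
    "format_millions",
    "instantiate_parameters",
    "parameter_shapes",
    "profile",
    "graph_from_config",
]

REG_MAX = 16  # distribution-focal bins per box side


# ---------------------------------------------------------------------------
# errors
# ---------------------------------------------------------------------------

class PodkitError(ValueError):
    """Base class for configuration and contract violations."""


class InvalidConfigError(PodkitError):
    pass


class ConstraintViolationError(PodkitError):
    pass


class MissingTapError(PodkitError):
    pass


class ShapeMismatchError(PodkitError):
    pass


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TensorShape:
    """Channels-first feature map shape."""

    channels: int
    height: int
    width: int

    def __post_init__(self) -> None:
        if min(self.channels, self.height, self.width) < 1:
            raise InvalidConfigError(f"all TensorShape fields must be >= 1, got {self}")

    @property
    def hw(self) -> tuple[int, int]:
        return (self.height, self.width)


class LayerKind(str, Enum):
    CONV = "conv"
    TRANSPOSED_CONV = "transposed_conv"
    NEAREST_UPSAMPLE = "nearest_upsample"
    CONCAT = "concat"
    ADD = "add"
    SPLIT_CSP_BLOCK = "split_csp_block"
    SPPF = "sppf"
    EMA = "ema"
    DETECT_HEAD = "detect_head"
    COEFF_HEAD = "coeff_head"
    PROTO_HEAD = "proto_head"
    MAXPOOL = "maxpool"
    ACTIVATION = "activation"
    BATCHNORM = "batchnorm"


@dataclass(frozen=True)
class LayerSpec:
    """One primitive node of the model DAG.

    ``param_count`` is the closed-form parameter cost of the node; it is
    recomputed (never stored free-form) so that the symbolic total always
    agrees with the instantiated-tensor oracle.
    """

    name: str
    kind: LayerKind
    inputs: tuple[str, ...]
    out_channels: int = 0
    kernel: int = 1
    stride: int = 1
    groups: int = 1
    bias: bool = True
    in_channels: int = 0
    tag: str = ""

    @property
    def param_count(self) -> int:
        if self.kind in (LayerKind.CONV, LayerKind.TRANSPOSED_CONV):
            p = self.in_channels * self.out_channels * self.kernel ** 2 // self.groups
            return p + (self.out_channels if self.bias else 0)
        if self.kind == LayerKind.EMA:
            cg = self.in_channels // self.groups
            # group-norm affine + 1x1 branch + 3x3 branch (per published EMA)
            return 2 * cg + (cg * cg + cg) + (9 * cg * cg + cg)
        if self.kind == LayerKind.BATCHNORM:
            return 2 * self.out_channels
        return 0


@dataclass
class ModelGraph:
    """Ordered, acyclic layer graph with named pyramid taps.

    ``meta`` stores the assembly recipe (nc, k, input size, variant configs),
    which lets :func:`apply_hpa` / :func:`apply_u_ema` rebuild the prototype
    branch instead of performing ad-hoc surgery, so composing operations is
    exactly equivalent to building the composite directly.
    """

    layers: "OrderedDict[str, LayerSpec]"
    taps: dict[str, object]
    meta: dict[str, object]

    def __iter__(self):
        return iter(self.layers.values())

    def tap(self, name: str) -> str:
        if name not in self.taps:
            raise MissingTapError(f"graph has no tap {name!r}")
        return self.taps[name]  # type: ignore[return-value]


class HPAVariant(str, Enum):
    CASCADED_CONVT = "cascaded_convT"
    PARALLEL_CONVT = "parallel_convT"
    PARALLEL_INTERP = "parallel_interp"


@dataclass(frozen=True)
class HPAConfig:
    """Channel allocation of the hierarchical prototype aggregation.

    ``c3 + c4 + c5 = k`` is enforced at construction: the three pyramid
    scales contribute exactly the k prototype-input channels.
    """

    variant: HPAVariant = HPAVariant.PARALLEL_CONVT
    c3: int = 24
    c4: int = 6
    c5: int = 2
    k: int = 32

    def __post_init__(self) -> None:
        if min(self.c3, self.c4, self.c5) < 0 or self.k < 1:
            raise InvalidConfigError(f"negative channel split in {self}")
        if self.c3 + self.c4 + self.c5 != self.k:
            raise ConstraintViolationError(
                f"channel split must satisfy c3+c4+c5=k: "
                f"{self.c3}+{self.c4}+{self.c5} != {self.k}"
            )


class UpsampleMode(str, Enum):
    TRANSPOSED_CONV = "transposed_conv"
    NEAREST = "nearest"


@dataclass(frozen=True)
class ProtonetConfig:
    """U-decoder prototype branch configuration."""

    upsample_mode: UpsampleMode = UpsampleMode.NEAREST
    use_ema: bool = True
    k: int = 32
    ema_groups: int = 32

    def __post_init__(self) -> None:
        if self.k < 1:
            raise InvalidConfigError("prototype count k must be >= 1")
        if self.ema_groups < 1:
            raise InvalidConfigError("ema_groups must be >= 1")


# ---------------------------------------------------------------------------
# graph assembly
# ---------------------------------------------------------------------------

class _Assembler:
    def __init__(self) -> None:
        self.layers: "OrderedDict[str, LayerSpec]" = OrderedDict()
        self.channels: dict[str, int] = {}

    def add(self, spec: LayerSpec) -> str:
        if spec.name in self.layers:
            raise InvalidConfigError(f"duplicate layer name {spec.name!r}")
        for src in spec.inputs:
            if src not in self.layers and src != "input":
                raise InvalidConfigError(f"layer {spec.name!r} references unknown input {src!r}")
        self.layers[spec.name] = spec
        self.channels[spec.name] = spec.out_channels
        return spec.name

    def cin(self, src: str) -> int:
        return 3 if src == "input" else self.channels[src]

    def conv(self, name: str, src: str, cout: int, k: int = 1, s: int = 1,
             bias: bool = True, tag: str = "") -> str:
        return self.add(LayerSpec(name, LayerKind.CONV, (src,), cout, k, s,
                                  bias=bias, in_channels=self.cin(src), tag=tag))

    def convt(self, name: str, src: str, cout: int, k: int = 2, s: int = 2,
              tag: str = "") -> str:
        return self.add(LayerSpec(name, LayerKind.TRANSPOSED_CONV, (src,), cout, k, s,
                                  in_channels=self.cin(src), tag=tag))

    def upsample(self, name: str, src: str, s: int = 2, tag: str = "") -> str:
        return self.add(LayerSpec(name, LayerKind.NEAREST_UPSAMPLE, (src,),
                                  self.cin(src), stride=s, in_channels=self.cin(src), tag=tag))

    def concat(self, name: str, srcs: Iterable[str], tag: str = "") -> str:
        srcs = tuple(srcs)
        cout = sum(self.cin(s) for s in srcs)
        return self.add(LayerSpec(name, LayerKind.CONCAT, srcs, cout, tag=tag))

    def addn(self, name: str, srcs: Iterable[str], tag: str = "") -> str:
        srcs = tuple(srcs)
        return self.add(LayerSpec(name, LayerKind.ADD, srcs, self.cin(srcs[0]), tag=tag))

    def maxpool(self, name: str, src: str, k: int, s: int, tag: str = "") -> str:
        return self.add(LayerSpec(name, LayerKind.MAXPOOL, (src,), self.cin(src),
                                  k, s, in_channels=self.cin(src), tag=tag))

    def ema(self, name: str, src: str, groups: int, tag: str = "") -> str:
        c = self.cin(src)
        if c % groups:
            raise InvalidConfigError(
                f"EMA at {name!r}: channel count {c} not divisible by groups {groups}")
        return self.add(LayerSpec(name, LayerKind.EMA, (src,), c, groups=groups,
                                  in_channels=c, tag=tag))

    # -- composite blocks ---------------------------------------------------

    def csp_block(self, prefix: str, src: str, cout: int, n: int) -> str:
        """Split-CSP block: 1x1 expand, channel split, n twin-3x3 bottlenecks
        chained on the second half, 1x1 fuse of all branches."""
        c = cout // 2
        cv1 = self.conv(f"{prefix}.cv1", src, 2 * c, 1)
        # zero-param slice: bottlenecks consume the second c-channel half
        prev = self.add(LayerSpec(f"{prefix}.split", LayerKind.SPLIT_CSP_BLOCK,
                                  (cv1,), c))
        parts = [cv1]
        for i in range(n):
            b1 = self.conv(f"{prefix}.m{i}.cv1", prev, c, 3)
            b2 = self.conv(f"{prefix}.m{i}.cv2", b1, c, 3)
            parts.append(b2)
            prev = b2
        cat = self.add(LayerSpec(f"{prefix}.cat", LayerKind.CONCAT, tuple(parts),
                                 (2 + n) * c))
        return self.conv(f"{prefix}.cv2", cat, cout, 1)

    def sppf(self, prefix: str, src: str, cout: int) -> str:
        cin = self.cin(src)
        c = cin // 2
        cv1 = self.conv(f"{prefix}.cv1", src, c, 1)
        p1 = self.maxpool(f"{prefix}.pool1", cv1, 5, 1)
        p2 = self.maxpool(f"{prefix}.pool2", p1, 5, 1)
        p3 = self.maxpool(f"{prefix}.pool3", p2, 5, 1)
        cat = self.concat(f"{prefix}.cat", [cv1, p1, p2, p3])
        return self.conv(f"{prefix}.cv2", cat, cout, 1)


def _proto_trunk_width(k: int) -> int:
    # prototype trunk width tracks twice the prototype count, capped at 64
    return min(64, 2 * k)


def _assemble(meta: dict) -> ModelGraph:
    """Build the full graph from an assembly recipe (see ``build_baseline``)."""
    nc = int(meta["nc"])
    k = int(meta["k"])
    include_p5 = bool(meta.get("include_p5", True))
    hpa: HPAConfig | None = meta.get("hpa")  # type: ignore[assignment]
    proto_cfg: ProtonetConfig | None = meta.get("protonet")  # type: ignore[assignment]
    ema_after_proto: int | None = meta.get("ema_after_proto")  # type: ignore[assignment]
    cw = int(meta.get("proto_width", _proto_trunk_width(k)))

    a = _Assembler()
    w = (16, 32, 64, 128, 256)

    # backbone -------------------------------------------------------------
    x = a.conv("stem.0", "input", w[0], 3, 2)
    x = a.conv("stem.1", x, w[1], 3, 2)
    x = a.csp_block("b2", x, w[1], 1)
    x = a.conv("down3", x, w[2], 3, 2)
    c4_tap = x = a.csp_block("b4", x, w[2], 2)
    x = a.conv("down5", x, w[3], 3, 2)
    c6_tap = x = a.csp_block("b6", x, w[3], 2)
    x = a.conv("down7", x, w[4], 3, 2)
    x = a.csp_block("b8", x, w[4], 1)
    sppf = a.sppf("sppf", x, w[4])

    # pyramid neck ---------------------------------------------------------
    u1 = a.upsample("neck.up1", sppf)
    cat1 = a.concat("neck.cat1", [u1, c6_tap])
    n12 = a.csp_block("neck.b12", cat1, w[3], 1)
    u2 = a.upsample("neck.up2", n12)
    cat2 = a.concat("neck.cat2", [u2, c4_tap])
    p3 = a.csp_block("neck.b15", cat2, w[2], 1)
    d1 = a.conv("neck.down16", p3, w[2], 3, 2)
    cat3 = a.concat("neck.cat3", [d1, n12])
    p4 = a.csp_block("neck.b18", cat3, w[3], 1)
    taps: dict[str, object] = {"P3": p3, "P4": p4}
    head_levels = [(p3, w[2]), (p4, w[3])]
    if include_p5:
        d2 = a.conv("neck.down19", p4, w[3], 3, 2)
        cat4 = a.concat("neck.cat4", [d2, sppf])
        p5 = a.csp_block("neck.b21", cat4, w[4], 1)
        taps["P5"] = p5
        head_levels.append((p5, w[4]))

    # decoupled detection + mask-coefficient heads --------------------------
    c2h = max(16, w[2] // 4, 4 * REG_MAX)
    c3h = max(w[2], min(nc, 100))
    c4h = max(w[2] // 4, k)
    head_outs = []
    for i, (src, _) in enumerate(head_levels):
        b = a.conv(f"head{i}.box.0", src, c2h, 3, tag="detect_head")
        b = a.conv(f"head{i}.box.1", b, c2h, 3, tag="detect_head")
        b = a.conv(f"head{i}.box.2", b, 4 * REG_MAX, 1, tag="detect_head")
        c = a.conv(f"head{i}.cls.0", src, c3h, 3, tag="detect_head")
        c = a.conv(f"head{i}.cls.1", c, c3h, 3, tag="detect_head")
        c = a.conv(f"head{i}.cls.2", c, nc, 1, tag="detect_head")
        m = a.conv(f"head{i}.coef.0", src, c4h, 3, tag="coeff_head")
        m = a.conv(f"head{i}.coef.1", m, c4h, 3, tag="coeff_head")
        m = a.conv(f"head{i}.coef.2", m, k, 1, tag="coeff_head")
        head_outs.append((b, c, m))
    a.conv("head.dfl", head_outs[0][0], 1, 1, bias=False, tag="detect_head")
    # distribution-focal projection reads 16 bins per side
    a.layers["head.dfl"] = replace(a.layers["head.dfl"], in_channels=REG_MAX)

    # prototype branch -----------------------------------------------------
    u_mode = proto_cfg.upsample_mode if proto_cfg is not None else None

    def up(name: str, src: str, mode: UpsampleMode | None, cout: int) -> str:
        if mode is UpsampleMode.TRANSPOSED_CONV or mode is None:
            return a.convt(name, src, cout, 2, 2, tag="proto_head")
        return a.upsample(name, src, 2, tag="proto_head")

    if hpa is not None and (hpa.c5 > 0 or hpa.variant is HPAVariant.CASCADED_CONVT) \
            and "P5" not in taps:
        raise MissingTapError("HPA path from P5 requires the P5 tap")
    if hpa is None:
        proto_in = p3
    else:
        paths = []
        if hpa.c3 > 0:
            paths.append(a.conv("hpa.p3.proj", p3, hpa.c3, 1, tag="proto_head"))
        if hpa.variant is HPAVariant.CASCADED_CONVT:
            if hpa.c4 > 0 or hpa.c5 > 0:
                t5 = a.convt("hpa.p5.up2", taps["P5"], 128, tag="proto_head")  # type: ignore[index]
                c45 = a.concat("hpa.cat45", [t5, p4], tag="proto_head")
                t45 = a.convt("hpa.p45.up2", c45, 64, tag="proto_head")
                paths.append(a.conv("hpa.p45.proj", t45, hpa.c4 + hpa.c5, 1, tag="proto_head"))
        else:
            interp = hpa.variant is HPAVariant.PARALLEL_INTERP
            if hpa.c4 > 0:
                if interp:
                    u4 = a.upsample("hpa.p4.up2", p4, tag="proto_head")
                    paths.append(a.conv("hpa.p4.proj", u4, hpa.c4, 1, tag="proto_head"))
                elif proto_cfg is not None:
                    # U-decoder composition: the P4 skip enters at native
                    # resolution and rises by interpolation (decoder-stage
                    # upsampling), so the standalone transposed conv is dropped.
                    q4 = a.conv("hpa.p4.proj", p4, hpa.c4, 1, tag="proto_head")
                    paths.append(a.upsample("hpa.p4.up2", q4, tag="proto_head"))
                else:
                    u4 = a.convt("hpa.p4.up2", p4, 64, tag="proto_head")
                    paths.append(a.conv("hpa.p4.proj", u4, hpa.c4, 1, tag="proto_head"))
            if hpa.c5 > 0:
                p5s = taps["P5"]  # raises via _require_tap before assembly
                if interp:
                    u5 = a.upsample("hpa.p5.up2", p5s, tag="proto_head")  # type: ignore[arg-type]
                    u5 = a.upsample("hpa.p5.up4", u5, tag="proto_head")
                    paths.append(a.conv("hpa.p5.proj", u5, hpa.c5, 1, tag="proto_head"))
                else:
                    u5 = a.convt("hpa.p5.up2", p5s, 256, tag="proto_head")  # type: ignore[arg-type]
                    u5 = a.convt("hpa.p5.up4", u5, 48, tag="proto_head")
                    paths.append(a.conv("hpa.p5.proj", u5, hpa.c5, 1, tag="proto_head"))
        proto_in = paths[0] if len(paths) == 1 else a.concat("hpa.cat", paths, tag="proto_head")

    trunk_convs = []
    if proto_cfg is None:
        x = a.conv("proto.cv1", proto_in, cw, 3, tag="proto_head")
        trunk_convs.append(x)
        x = a.convt("proto.up", x, cw, 2, 2, tag="proto_head")
        x = a.conv("proto.cv2", x, cw, 3, tag="proto_head")
        trunk_convs.append(x)
        proto_out = a.conv("proto.cv3", x, k, 1, tag="proto_head")
        trunk_convs.append(proto_out)
    else:
        # U-dip decoder: conv at 1/8, pool to 1/16, two x2 rises with an
        # additive skip, conv at 1/4, 1x1 prototype head.  Output = input/4.
        cv1 = a.conv("proto.cv1", proto_in, cw, 3, tag="proto_head")
        trunk_convs.append(cv1)
        x = a.maxpool("proto.pool", cv1, 2, 2, tag="proto_head")
        x = up("proto.up_a", x, u_mode, cw)
        x = a.addn("proto.skip", [x, cv1], tag="proto_head")
        x = up("proto.up_b", x, u_mode, cw)
        x = a.conv("proto.cv2", x, cw, 3, tag="proto_head")
        trunk_convs.append(x)
        proto_out = a.conv("proto.cv3", x, k, 1, tag="proto_head")
        trunk_convs.append(proto_out)

    ema_groups = None
    if proto_cfg is not None and proto_cfg.use_ema:
        ema_groups = proto_cfg.ema_groups
    elif ema_after_proto is not None:
        ema_groups = int(ema_after_proto)
    if ema_groups is not None:
        rewired: "OrderedDict[str, LayerSpec]" = OrderedDict()
        ema_of: dict[str, str] = {}
        for spec in a.layers.values():
            new_inputs = tuple(ema_of.get(s, s) for s in spec.inputs)
            spec = replace(spec, inputs=new_inputs)
            rewired[spec.name] = spec
            if spec.name in trunk_convs:
                ema_name = f"{spec.name}.ema"
                c = spec.out_channels
                if c % ema_groups:
                    raise InvalidConfigError(
                        f"EMA at {ema_name!r}: channel count {c} not divisible "
                        f"by groups {ema_groups}")
                rewired[ema_name] = LayerSpec(ema_name, LayerKind.EMA, (spec.name,),
                                              c, groups=ema_groups, in_channels=c,
                                              tag="proto_head")
                ema_of[spec.name] = ema_name
        a.layers = rewired
        if proto_out in ema_of:
            proto_out = ema_of[proto_out]

    taps["proto_out"] = proto_out
    taps["head_outs"] = tuple(head_outs)
    return ModelGraph(layers=a.layers, taps=taps, meta=dict(meta))


# ---------------------------------------------------------------------------
# public builders
# ---------------------------------------------------------------------------

def build_baseline(nc: int = 1, k: int = 32, input_size: int = 640, *,
                   include_p5: bool = True) -> ModelGraph:
    """Baseline single-class prototype segmentation network.

    The prototype branch consumes only the P3 pyramid tap.  ``include_p5``
    set to False removes the deepest pyramid level and its prediction heads
    (the P3/P4-only ablation).
    """
    if nc < 1 or k < 1:
        raise InvalidConfigError(f"nc and k must be >= 1, got nc={nc}, k={k}")
    if input_size % 32:
        raise InvalidConfigError(f"input_size must be divisible by 32, got {input_size}")
    meta = {"nc": nc, "k": k, "input_size": input_size, "include_p5": include_p5,
            "proto_width": _proto_trunk_width(k), "hpa": None, "protonet": None,
            "ema_after_proto": None}
    return _assemble(meta)


def apply_hpa(graph: ModelGraph, cfg: HPAConfig) -> ModelGraph:
    """Feed the prototype branch the c3/c4/c5 multiscale channel concatenation."""
    if cfg.k != graph.meta["k"]:
        raise ConstraintViolationError(
            f"HPA k={cfg.k} does not match graph prototype count {graph.meta['k']}")
    if cfg.c4 > 0 and "P4" not in graph.taps:
        raise MissingTapError("HPA requires a P4 tap for c4 > 0")
    if cfg.c5 > 0 and "P5" not in graph.taps:
        raise MissingTapError("HPA requires a P5 tap for c5 > 0")
    meta = dict(graph.meta)
    meta["hpa"] = cfg
    return _assemble(meta)


def apply_u_ema(graph: ModelGraph, cfg: ProtonetConfig) -> ModelGraph:
    """Rebuild the prototype branch as the U-shaped decoder (optionally with EMA)."""
    if "proto_out" not in graph.taps:
        raise MissingTapError("graph has no prototype branch to rebuild")
    if cfg.k != graph.meta["k"]:
        raise ConstraintViolationError(
            f"protonet k={cfg.k} does not match graph prototype count {graph.meta['k']}")
    meta = dict(graph.meta)
    meta["protonet"] = cfg
    return _assemble(meta)


def apply_ema(graph: ModelGraph, groups: int = 32) -> ModelGraph:
    """Insert EMA after each prototype-branch convolution without the U rebuild."""
    if "proto_out" not in graph.taps:
        raise MissingTapError("graph has no prototype branch")
    meta = dict(graph.meta)
    meta["ema_after_proto"] = groups
    return _assemble(meta)


def build_podnet(nc: int = 1, input_size: int = 640, *, k: int = 32,
                 hpa: HPAConfig | None = None,
                 protonet: ProtonetConfig | None = None) -> ModelGraph:
    """Full composed model: HPA (parallel transposed conv, 24/6/2) plus the
    U-decoder prototype branch with nearest upsampling and EMA."""
    hpa = hpa or HPAConfig(HPAVariant.PARALLEL_CONVT, 24, 6, 2, k)
    protonet = protonet or ProtonetConfig(UpsampleMode.NEAREST, True, k, 32)
    return apply_u_ema(apply_hpa(build_baseline(nc, k, input_size), hpa), protonet)


# ---------------------------------------------------------------------------
# shape inference and accounting
# ---------------------------------------------------------------------------

def infer_shapes(graph: ModelGraph, input_size: int | None = None
                 ) -> dict[str, TensorShape]:
    """Propagate shapes through the DAG; raises on inconsistent concat/add."""
    size = int(input_size or graph.meta["input_size"])
    shapes: dict[str, TensorShape] = {"input": TensorShape(3, size, size)}
    for spec in graph:
        ins = [shapes[s] for s in spec.inputs]
        if spec.kind == LayerKind.CONV:
            h = -(-ins[0].height // spec.stride)
            w = -(-ins[0].width // spec.stride)
            out = TensorShape(spec.out_channels, h, w)
        elif spec.kind == LayerKind.TRANSPOSED_CONV:
            out = TensorShape(spec.out_channels, ins[0].height * spec.stride,
                              ins[0].width * spec.stride)
        elif spec.kind == LayerKind.NEAREST_UPSAMPLE:
            out = TensorShape(ins[0].channels, ins[0].height * spec.stride,
                              ins[0].width * spec.stride)
        elif spec.kind == LayerKind.MAXPOOL:
            if spec.stride == 1:
                out = ins[0]
            else:
                out = TensorShape(ins[0].channels, ins[0].height // spec.stride,
                                  ins[0].width // spec.stride)
        elif spec.kind == LayerKind.CONCAT:
            hw = {i.hw for i in ins}
            if len(hw) > 1:
                detail = ", ".join(f"{n}={shapes[n].hw}" for n in spec.inputs)
                raise ShapeMismatchError(
                    f"concat {spec.name!r} has mismatched operand resolutions: {detail}")
            out = TensorShape(spec.out_channels, *ins[0].hw)
        elif spec.kind == LayerKind.SPLIT_CSP_BLOCK:
            out = TensorShape(spec.out_channels, *ins[0].hw)
        elif spec.kind == LayerKind.ADD:
            if len({(i.channels, *i.hw) for i in ins}) > 1:
                detail = ", ".join(f"{n}={shapes[n]}" for n in spec.inputs)
                raise ShapeMismatchError(
                    f"add {spec.name!r} has mismatched operands: {detail}")
            out = ins[0]
        else:  # ema, activation, batchnorm: shape preserving
            out = ins[0]
        shapes[spec.name] = out
    return shapes


def count_parameters(graph: ModelGraph) -> int:
    """Total learnable parameters of the symbolic graph (fused convention)."""
    infer_shapes(graph)  # validates the DAG end to end
    return sum(spec.param_count for spec in graph)


def format_millions(count: int) -> float:
    """Parameter count in millions, floored at three decimals (table style)."""
    return (count // 1000) / 1000.0


def count_flops(graph: ModelGraph, input_size: int | None = None) -> float:
    """GFLOPs at the given input size under the 2xMAC profiler convention."""
    shapes = infer_shapes(graph, input_size)
    macs = 0
    for spec in graph:
        if spec.kind in (LayerKind.CONV, LayerKind.TRANSPOSED_CONV):
            out = shapes[spec.name]
            per_px = spec.kernel ** 2 * spec.in_channels // spec.groups
            macs += per_px * spec.out_channels * out.height * out.width
    return 2.0 * macs / 1e9


def parameter_shapes(spec: LayerSpec) -> list[tuple[int, ...]]:
    """Tensor shapes a layer would allocate when instantiated."""
    if spec.kind == LayerKind.CONV:
        shp = [(spec.out_channels, spec.in_channels // spec.groups, spec.kernel, spec.kernel)]
        if spec.bias:
            shp.append((spec.out_channels,))
        return shp
    if spec.kind == LayerKind.TRANSPOSED_CONV:
        shp = [(spec.in_channels, spec.out_channels // spec.groups, spec.kernel, spec.kernel)]
        if spec.bias:
            shp.append((spec.out_channels,))
        return shp
    if spec.kind == LayerKind.EMA:
        cg = spec.in_channels // spec.groups
        return [(cg,), (cg,), (cg, cg, 1, 1), (cg,), (cg, cg, 3, 3), (cg,)]
    if spec.kind == LayerKind.BATCHNORM:
        return [(spec.out_channels,), (spec.out_channels,)]
    return []


def instantiate_parameters(graph: ModelGraph, seed: int = 0
                           ) -> dict[str, list[np.ndarray]]:
    """Materialise every layer's tensors (the independent counting oracle)."""
    rng = np.random.default_rng(seed)
    out: dict[str, list[np.ndarray]] = {}
    for spec in graph:
        shapes = parameter_shapes(spec)
        if shapes:
            out[spec.name] = [rng.standard_normal(s).astype(np.float32) * 0.05
                              for s in shapes]
    return out


def profile(graph: ModelGraph, input_size: int | None = None) -> dict[str, object]:
    """Layers / params / GFLOPs summary row for a model variant."""
    n_params = count_parameters(graph)
    return {
        "layers": len(graph.layers),
        "parameters": n_params,
        "parameters_millions": format_millions(n_params),
        "gflops": round(count_flops(graph, input_size), 1),
        "input_size": int(input_size or graph.meta["input_size"]),
        "nc": graph.meta["nc"],
        "k": graph.meta["k"],
    }


# ---------------------------------------------------------------------------
# YAML model configuration
# ---------------------------------------------------------------------------

def graph_from_config(cfg: Mapping[str, object]) -> ModelGraph:
    """Build a graph from a plain mapping (parsed model YAML).

    Schema::

        nc: 1
        input_size: 640
        k: 32
        include_p5: true           # optional
        hpa: {variant: parallel_convT, c3: 24, c4: 6, c5: 2}   # optional
        protonet: {upsample: nearest, ema: true, groups: 32}   # optional
    """
    nc = int(cfg.get("nc", 1))  # type: ignore[arg-type]
    k = int(cfg.get("k", 32))  # type: ignore[arg-type]
    size = int(cfg.get("input_size", 640))  # type: ignore[arg-type]
    g = build_baseline(nc, k, size, include_p5=bool(cfg.get("include_p5", True)))
    if cfg.get("hpa"):
        h = cfg["hpa"]  # type: ignore[index]
        g = apply_hpa(g, HPAConfig(HPAVariant(str(h.get("variant", "parallel_convT"))),
                                   int(h.get("c3", 24)), int(h.get("c4", 6)),
                                   int(h.get("c5", 2)), k))
    if cfg.get("protonet"):
        p = cfg["protonet"]  # type: ignore[index]
        g = apply_u_ema(g, ProtonetConfig(UpsampleMode(str(p.get("upsample", "nearest"))),
                                          bool(p.get("ema", True)), k,
                                          int(p.get("groups", 32))))
    return g
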