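"""WFCN architectures: a base fully-convolutional U-Net and its
wavelet-injected variants.

The base network is a standard two-class U-Net: an encoder that halves the
spatial side at each of ``encoder_levels`` levels while doubling channels, a
mirrored decoder with skip connections, and a 1x1 head producing per-pixel
softmax probabilities.  A *wavelet injection path* ``k`` concatenates, to the
input of encoder block ``k``, the level-``k`` wavelet subbands of every input
modality — these have exactly the spatial side of that block
(``input_side / 2**k``; 120/60/30/15 for a 240 input), so they enter the
graph without resampling.  Injection only widens the targeted block's input;
the rest of the network, in particular the whole decoder, is unchanged, so
base and injected variants are structurally comparable.

The named variants ``wfcn1`` … ``wfcn4`` each activate the single path of
the matching level; ``base`` activates none.  Arbitrary subsets are allowed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np

from . import _nn
from ._nn import (Conv2d, MaxPool2, Param, ReLU, UpsampleNearest2,
                  concat_channels, softmax)
from .phantom_gen import MultimodalSlice
from .wavelet_bank import get_kernel, wavedec2

__all__ = [
    "ConfigError",
    "WfcnConfig",
    "ModelSpec",
    "ARCHITECTURE_PRESETS",
    "preset_config",
    "model_spec",
    "forward_shapes",
    "build_model",
    "compute_injection",
    "WfcnNetwork",
]

#: Named architecture presets → set of active injection paths.
ARCHITECTURE_PRESETS: Mapping[str, frozenset[int]] = {
    "base": frozenset(),
    "wfcn1": frozenset({1}),
    "wfcn2": frozenset({2}),
    "wfcn3": frozenset({3}),
    "wfcn4": frozenset({4}),
}


class ConfigError(ValueError):
    """Raised for inconsistent architecture configurations."""


@dataclass(frozen=True)
class WfcnConfig:
    """Architecture description.

    ``injection_subbands`` selects what each path injects per modality:
    ``"all4"`` (approximation + horizontal/vertical/diagonal details, the
    default) or ``"approximation"`` only.
    """

    input_side: int = 240
    in_channels: int = 4
    encoder_levels: int = 4
    base_channels: int = 8
    injection_paths: frozenset[int] = frozenset()
    injection_subbands: str = "all4"
    kernel_name: str = "db1"
    num_classes: int = 2

    def __post_init__(self) -> None:
        object.__setattr__(self, "injection_paths",
                           frozenset(int(p) for p in self.injection_paths))
        if self.input_side % (1 << self.encoder_levels):
            raise ConfigError(
                f"input_side {self.input_side} is not divisible by "
                f"2^{self.encoder_levels}")
        bad = [p for p in self.injection_paths
               if not 1 <= p <= self.encoder_levels]
        if bad:
            raise ConfigError(
                f"injection paths {sorted(bad)} exceed encoder_levels="
                f"{self.encoder_levels}")
        if self.injection_subbands not in ("approximation", "all4"):
            raise ConfigError(
                f"injection_subbands must be 'approximation' or 'all4', "
                f"got {self.injection_subbands!r}")
        if self.num_classes != 2:
            raise ConfigError("the segmentation network is two-class")
        get_kernel(self.kernel_name)  # fail early on unknown kernels

    @property
    def subbands_per_modality(self) -> int:
        return 4 if self.injection_subbands == "all4" else 1

    @property
    def injection_channels(self) -> int:
        """Extra channels an active path contributes to its encoder block."""
        return self.in_channels * self.subbands_per_modality

    def channels_at(self, level: int) -> int:
        return self.base_channels * (1 << level)

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["injection_paths"] = sorted(self.injection_paths)
        return json.dumps(d)

    @classmethod
    def from_json(cls, document: str) -> "WfcnConfig":
        d = json.loads(document)
        d["injection_paths"] = frozenset(d.get("injection_paths", ()))
        return cls(**d)


def preset_config(name: str, **overrides) -> WfcnConfig:
    """Config for a named architecture (``base``, ``wfcn1`` … ``wfcn4``)."""
    try:
        paths = ARCHITECTURE_PRESETS[name.lower()]
    except KeyError:
        raise ConfigError(
            f"unknown architecture {name!r}; available: "
            f"{', '.join(ARCHITECTURE_PRESETS)}") from None
    return WfcnConfig(injection_paths=paths, **overrides)


@dataclass(frozen=True)
class ModelSpec:
    """The realized layer plan: ordered blocks with role, spatial side and
    input/output channel counts, plus injection widths and parameter count."""

    blocks: tuple[dict, ...]
    injection_points: Mapping[int, int]
    parameter_count: int

    def to_json(self) -> str:
        return json.dumps({
            "blocks": list(self.blocks),
            "injection_points": {str(k): v
                                 for k, v in sorted(self.injection_points.items())},
            "parameter_count": self.parameter_count,
        }, indent=1)


def _conv_params(cin: int, cout: int, k: int) -> int:
    return cout * (cin * k * k + 1)


def model_spec(config: WfcnConfig) -> ModelSpec:
    """Layer plan implied by ``config`` (what :func:`build_model` realizes)."""
    s, e = config.input_side, config.encoder_levels
    inj = {p: config.injection_channels for p in sorted(config.injection_paths)}
    blocks: list[dict] = []
    nparams = 0

    def add(name, role, side, cin, cout):
        blocks.append({"name": name, "role": role, "side": side,
                       "in_channels": cin, "out_channels": cout})

    add("stem", "encoder", s, config.in_channels, config.channels_at(0))
    nparams += (_conv_params(config.in_channels, config.channels_at(0), 3)
                + _conv_params(config.channels_at(0), config.channels_at(0), 3))
    for k in range(1, e + 1):
        cin = config.channels_at(k - 1) + inj.get(k, 0)
        cout = config.channels_at(k)
        role = "bottleneck" if k == e else "encoder"
        add(f"enc{k}", role, s >> k, cin, cout)
        nparams += _conv_params(cin, cout, 3) + _conv_params(cout, cout, 3)
    for k in range(e - 1, -1, -1):
        cin, cout = config.channels_at(k + 1), config.channels_at(k)
        add(f"dec{k}", "decoder", s >> k, cin, cout)
        nparams += (_conv_params(cin, cout, 3)          # up-convolution
                    + _conv_params(2 * cout, cout, 3)   # after skip concat
                    + _conv_params(cout, cout, 3))
    add("head", "decoder", s, config.channels_at(0), config.num_classes)
    nparams += _conv_params(config.channels_at(0), config.num_classes, 1)
    add("output", "output", s, config.num_classes, config.num_classes)
    return ModelSpec(blocks=tuple(blocks), injection_points=inj,
                     parameter_count=nparams)


def forward_shapes(config: WfcnConfig) -> list[tuple[str, int, tuple[int, int]]]:
    """``(block name, spatial side, (in_channels, out_channels))`` per block."""
    return [(b["name"], b["side"], (b["in_channels"], b["out_channels"]))
            for b in model_spec(config).blocks]


# --------------------------------------------------------------------------
# Wavelet injection
# --------------------------------------------------------------------------

def compute_injection(case: MultimodalSlice | np.ndarray, config: WfcnConfig,
                      ) -> dict[int, np.ndarray]:
    """Level-``k`` wavelet subbands of every modality for each active path.

    Returns ``{path: (channels, side/2**path, side/2**path) array}``, channels
    ordered modality-major then (approximation, horizontal, vertical,
    diagonal).  Each subband channel is min–max normalized to [0, 1]
    (zero-range channels map to 0).
    """
    if not config.injection_paths:
        return {}
    stack = case.stack() if isinstance(case, MultimodalSlice) else np.asarray(case)
    if stack.shape[0] != config.in_channels:
        raise ConfigError(
            f"expected {config.in_channels} modalities, got {stack.shape[0]}")
    if stack.shape[1] != config.input_side or stack.shape[2] != config.input_side:
        raise ConfigError(
            f"slice side {stack.shape[1:]} does not match config.input_side="
            f"{config.input_side}")
    kernel = get_kernel(config.kernel_name)
    max_level = max(config.injection_paths)
    decomps = [wavedec2(stack[m], kernel, max_level)
               for m in range(config.in_channels)]
    out: dict[int, np.ndarray] = {}
    for path in sorted(config.injection_paths):
        channels = []
        for dec in decomps:
            sb = dec.levels[path - 1]
            grids = (sb.grids() if config.injection_subbands == "all4"
                     else (sb.approximation,))
            for g in grids:
                lo, hi = g.min(), g.max()
                channels.append(np.zeros_like(g) if hi == lo
                                else (g - lo) / (hi - lo))
        out[path] = np.stack(channels).astype(np.float32)
    return out


# --------------------------------------------------------------------------
# Network
# --------------------------------------------------------------------------

class _DoubleConv:
    """conv3x3 → ReLU → conv3x3 → ReLU."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator,
                 name: str) -> None:
        self.conv1 = Conv2d(cin, cout, 3, rng, f"{name}.conv1")
        self.act1 = ReLU()
        self.conv2 = Conv2d(cout, cout, 3, rng, f"{name}.conv2")
        self.act2 = ReLU()

    def params(self) -> list[Param]:
        return self.conv1.params() + self.conv2.params()

    def forward(self, x: np.ndarray) -> np.ndarray:
        return self.act2.forward(self.conv2.forward(
            self.act1.forward(self.conv1.forward(x))))

    def backward(self, g: np.ndarray) -> np.ndarray:
        return self.conv1.backward(self.act1.backward(
            self.conv2.backward(self.act2.backward(g))))


class WfcnNetwork:
    """Instantiated trainable WFCN (see module docstring for the topology)."""

    def __init__(self, config: WfcnConfig, seed: int = 0) -> None:
        self.config = config
        self.spec = model_spec(config)
        rng = np.random.default_rng(seed)
        e = config.encoder_levels
        inj = dict(self.spec.injection_points)
        self.stem = _DoubleConv(config.in_channels, config.channels_at(0),
                                rng, "stem")
        self.pools = [MaxPool2() for _ in range(e)]
        self.enc = [
            _DoubleConv(config.channels_at(k - 1) + inj.get(k, 0),
                        config.channels_at(k), rng, f"enc{k}")
            for k in range(1, e + 1)
        ]
        self.ups = [UpsampleNearest2() for _ in range(e)]
        self.upconvs = []
        self.upacts = []
        self.dec = []
        for k in range(e - 1, -1, -1):
            self.upconvs.append(Conv2d(config.channels_at(k + 1),
                                       config.channels_at(k), 3, rng,
                                       f"dec{k}.upconv"))
            self.upacts.append(ReLU())
            self.dec.append(_DoubleConv(2 * config.channels_at(k),
                                        config.channels_at(k), rng,
                                        f"dec{k}.block"))
        self.head = Conv2d(config.channels_at(0), config.num_classes, 1,
                           rng, "head")
        assert sum(p.value.size for p in self.parameters()) \
            == self.spec.parameter_count

    def parameters(self) -> list[Param]:
        ps = self.stem.params()
        for b in self.enc:
            ps += b.params()
        for c, b in zip(self.upconvs, self.dec):
            ps += c.params() + b.params()
        return ps + self.head.params()

    # -- forward / backward ------------------------------------------------

    def forward_logits(self, x: np.ndarray,
                       injections: Mapping[int, np.ndarray] | None = None
                       ) -> np.ndarray:
        """x: (B, in_channels, side, side) float array → (B, 2, side, side)
        logits.  ``injections[k]`` must be ``(B, C_inj, side/2**k, ...)``
        when path ``k`` is active."""
        cfg = self.config
        x = np.ascontiguousarray(x, dtype=_nn.DTYPE)
        if cfg.injection_paths and injections is None:
            raise ConfigError("active injection paths need injection maps; "
                              "see compute_injection")
        skips = [self.stem.forward(x)]
        for k in range(1, cfg.encoder_levels + 1):
            h = self.pools[k - 1].forward(skips[-1])
            if k in cfg.injection_paths:
                extra = np.ascontiguousarray(injections[k], dtype=_nn.DTYPE)
                h = concat_channels([h, extra])
            skips.append(self.enc[k - 1].forward(h))
        y = skips[-1]
        for i, k in enumerate(range(cfg.encoder_levels - 1, -1, -1)):
            y = self.ups[i].forward(y)
            y = self.upacts[i].forward(self.upconvs[i].forward(y))
            y = concat_channels([y, skips[k]])
            y = self.dec[i].forward(y)
        return self.head.forward(y)

    def backward(self, grad_logits: np.ndarray) -> None:
        cfg = self.config
        g = self.head.backward(grad_logits)
        skip_grads: dict[int, np.ndarray] = {}
        for i in range(cfg.encoder_levels - 1, -1, -1):
            k = cfg.encoder_levels - 1 - i  # encoder level fed by dec step i
            gi = self.dec[i].backward(g)
            c = self.upconvs[i].out_channels
            g_up, g_skip = gi[:, :c], gi[:, c:]
            skip_grads[k] = g_skip
            g = self.ups[i].backward(self.upconvs[i].backward(
                self.upacts[i].backward(np.ascontiguousarray(g_up))))
        # g now flows into the bottleneck encoder block output
        for k in range(cfg.encoder_levels, 0, -1):
            if k in skip_grads:
                g = g + skip_grads[k]
            g = self.enc[k - 1].backward(g)
            if k in cfg.injection_paths:
                g = g[:, :-cfg.injection_channels]  # drop injected channels
            g = self.pools[k - 1].backward(np.ascontiguousarray(g))
        if 0 in skip_grads:
            g = g + skip_grads[0]
        self.stem.backward(g)

    def predict_proba(self, x: np.ndarray,
                      injections: Mapping[int, np.ndarray] | None = None
                      ) -> np.ndarray:
        """Per-pixel class probabilities (softmax over channel axis)."""
        return softmax(self.forward_logits(x, injections), axis=1)

    def predict_case(self, case: MultimodalSlice) -> np.ndarray:
        """Probabilities (2, side, side) for one slice, computing any
        injection maps from its modalities."""
        inj = compute_injection(case, self.config)
        inj_b = {k: v[None] for k, v in inj.items()}
        return self.predict_proba(case.stack()[None], inj_b)[0]

    # -- persistence -------------------------------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        return {p.name: p.value.copy() for p in self.parameters()}

    def load_state_dict(self, state: Mapping[str, np.ndarray]) -> None:
        for p in self.parameters():
            if p.name not in state:
                raise KeyError(f"missing parameter {p.name!r} in checkpoint")
            if state[p.name].shape != p.value.shape:
                raise ValueError(
                    f"shape mismatch for {p.name!r}: checkpoint "
                    f"{state[p.name].shape} vs model {p.value.shape}")
            p.value[...] = state[p.name]

    def save(self, path: str | Path) -> None:
        np.savez_compressed(path, __config__=np.asarray(self.config.to_json()),
                            **self.state_dict())

    @classmethod
    def load(cls, path: str | Path) -> "WfcnNetwork":
        with np.load(path, allow_pickle=False) as z:
            config = WfcnConfig.from_json(str(z["__config__"]))
            net = cls(config)
            net.load_state_dict({k: z[k] for k in z.files if k != "__config__"})
        return net


def build_model(config: WfcnConfig, seed: int = 0) -> WfcnNetwork:
    """Instantiate the trainable network for ``config`` (its realized layer
    plan is available as ``model.spec``)."""
    return WfcnNetwork(config, seed=seed)
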