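"""The coarse-output 7-class segmentation network.

The network maps an RGB patch to class probability maps 2^(n_blocks-1) times
smaller than the input: n_blocks residual squeeze-and-excitation conv blocks
with a learned 2x2 stride-2 downsampling convolution (followed by BN and
ReLU) between consecutive blocks, a final 1x1 projection to the class
channels and a softmax over channels.  With the default 6 blocks a 1024x1024
patch yields a 32x32x7 output.

Feature widths double per block from ``base_features``; widths, SE reduction
and the initialization scale are configuration, not architecture constants.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import ops
from .layers import BatchNorm, Conv1x1, Conv2x2Down, Layer, ReLU, ResidualSEBlock


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture hyperparameters of the segmentation CNN."""

    n_blocks: int = 6
    base_features: int = 32
    features: tuple[int, ...] | None = None   # explicit per-block widths
    se_reduction: int = 16
    input_size: int = 1024
    n_classes: int = 7

    def __post_init__(self) -> None:
        if self.n_blocks < 1:
            raise ValueError("need at least one block")
        widths = self.block_features
        if len(widths) != self.n_blocks or any(f < 1 for f in widths):
            raise ValueError("features must list one positive width per block")
        if self.input_size % self.downsample_factor:
            raise ValueError(
                f"input size {self.input_size} not divisible by the total "
                f"downsampling factor {self.downsample_factor}")

    @property
    def block_features(self) -> tuple[int, ...]:
        if self.features is not None:
            return tuple(self.features)
        return tuple(self.base_features * 2 ** i for i in range(self.n_blocks))

    @property
    def downsample_factor(self) -> int:
        """Total spatial reduction: one 2x downsampling between blocks."""
        return 2 ** (self.n_blocks - 1)

    @property
    def output_size(self) -> int:
        return self.input_size // self.downsample_factor


class SegmentationNetwork:
    """Stateful network handle: layers, forward/backward, weight dicts."""

    def __init__(self, config: NetworkConfig, rng: np.random.Generator | None = None,
                 dtype=np.float32) -> None:
        self.config = config
        self.dtype = dtype
        rng = rng or np.random.default_rng(0)
        widths = config.block_features
        self._named: list[tuple[str, Layer]] = []
        c_in = 3
        for b, f in enumerate(widths):
            self._named.append(
                (f"block{b}", ResidualSEBlock(rng, c_in, f, config.se_reduction, dtype)))
            if b < len(widths) - 1:
                self._named.append((f"down{b}", Conv2x2Down(rng, f, widths[b + 1], dtype)))
                self._named.append((f"down{b}_bn", BatchNorm(widths[b + 1], dtype=dtype)))
                self._named.append((f"down{b}_relu", ReLU()))
                c_in = widths[b + 1]
        self._named.append(("head", Conv1x1(rng, widths[-1], config.n_classes, dtype)))
        # the gradient w.r.t. the RGB input is never used
        first = self._named[0][1]
        first.conv1.skip_input_grad = True
        if first.proj is not None:
            first.proj.skip_input_grad = True
        self._probs = None

    # -- execution ---------------------------------------------------------
    def forward(self, batch: np.ndarray, train: bool = False) -> np.ndarray:
        """RGB batch (N, H, W, 3) in [0,1] -> probability maps (N, L, h, w)."""
        x = np.ascontiguousarray(batch.transpose(0, 3, 1, 2), dtype=self.dtype)
        if x.shape[1] != 3:
            raise ValueError("expected 3-channel RGB input")
        for _, layer in self._named:
            x = layer.forward(x, train)
        probs = ops.channel_softmax(x.astype(np.float64)).astype(self.dtype)
        self._probs = probs if train else None
        return probs

    def backward(self, dprobs: np.ndarray) -> None:
        """Backpropagate dL/dprobs through the softmax and all layers."""
        dx = ops.channel_softmax_backward(self._probs.astype(np.float64),
                                          dprobs.astype(np.float64))
        dx = dx.astype(self.dtype)
        for _, layer in reversed(self._named):
            dx = layer.backward(dx)

    # -- parameter access --------------------------------------------------
    def _walk(self):
        for name, layer in self._named:
            stack = [(name, layer)]
            while stack:
                prefix, lyr = stack.pop()
                for pname, arr in lyr.params.items():
                    yield f"{prefix}.{pname}", lyr, pname
                for i, child in enumerate(lyr.children()):
                    stack.append((f"{prefix}.{i}", child))

    def parameters(self) -> dict[str, np.ndarray]:
        return {key: lyr.params[p] for key, lyr, p in self._walk()}

    def gradients(self) -> dict[str, np.ndarray]:
        return {key: lyr.grads.get(p) for key, lyr, p in self._walk()}

    def batchnorm_layers(self) -> list[BatchNorm]:
        out = []
        for name, layer in self._named:
            stack = [layer]
            while stack:
                lyr = stack.pop()
                if isinstance(lyr, BatchNorm):
                    out.append(lyr)
                stack.extend(lyr.children())
        return out

    def get_weights(self) -> dict[str, np.ndarray]:
        """Copy of all parameters and BN running statistics."""
        state = {k: v.copy() for k, v in self.parameters().items()}
        for i, bn in enumerate(self.batchnorm_layers()):
            state[f"__bn{i}.mean"] = bn.running_mean.copy()
            state[f"__bn{i}.var"] = bn.running_var.copy()
        return state

    def set_weights(self, state: dict[str, np.ndarray]) -> None:
        params = {key: (lyr, p) for key, lyr, p in self._walk()}
        for key, (lyr, p) in params.items():
            lyr.params[p] = state[key].copy()
        for i, bn in enumerate(self.batchnorm_layers()):
            bn.running_mean = state[f"__bn{i}.mean"].copy()
            bn.running_var = state[f"__bn{i}.var"].copy()

    def count_parameters(self) -> int:
        return sum(int(np.prod(v.shape)) for v in self.parameters().values())


def build_network(config: NetworkConfig, seed: int | None = None,
                  dtype=np.float32) -> SegmentationNetwork:
    """Construct a randomly initialized network (fan-in-scaled uniform)."""
    return SegmentationNetwork(config, np.random.default_rng(seed), dtype=dtype)


def save_checkpoint(net: SegmentationNetwork, path: str | Path,
                    provenance: dict | None = None) -> None:
    """Write weights as NPZ with a JSON sidecar carrying the configuration."""
    path = Path(path)
    np.savez(path, **net.get_weights())
    sidecar = {"config": asdict(net.config), "provenance": provenance or {}}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))


def load_checkpoint(path: str | Path) -> SegmentationNetwork:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    cfg_kwargs = sidecar["config"]
    if cfg_kwargs.get("features") is not None:
        cfg_kwargs["features"] = tuple(cfg_kwargs["features"])
    net = SegmentationNetwork(NetworkConfig(**cfg_kwargs))
    with np.load(path if path.suffix == ".npz" else str(path) + ".npz") as data:
        net.set_weights({k: data[k] for k in data.files})
    return net
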