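"""The two Q-function approximators.

Agent 1 (spatial): a CNN feature extractor over the raw 64x64 patch (with
ImageNet channel normalization applied at model input), concatenated with
the positional embedding and mapped by a two-layer MLP (hidden 512, ReLU)
to action values over the K+4 joint actions.

Agent 2 (temporal/text): token embeddings of the lesion descriptor encoded
by a bidirectional GRU (default) or LSTM whose final hidden state is mapped
to K classification action values.

The default spatial backbone is a desk-scale 3-block CNN (channels
16/32/64, global average pooling, d_f = 64); a ResNet-50-style residual
backbone with d_f = 2048 is available behind the same interface.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .errors import ConfigurationError, ContractError, DomainError
from .nn import (
    GRU,
    LSTM,
    Adam,
    Bidirectional,
    Conv2d,
    Dense,
    Embedding,
    GlobalAvgPool,
    Module,
    ReLU,
    Sequential,
)

# standard published ImageNet channel statistics
IMAGENET_MEAN = np.array([0.485, 0.456, 0.406])
IMAGENET_STD = np.array([0.229, 0.224, 0.225])

N_NAV_ACTIONS = 4

SPATIAL_BACKBONES = ("small-cnn", "resnet50-style")
TEMPORAL_BACKBONES = ("gru", "lstm")


class _ResidualBlock(Module):
    def __init__(self, channels: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.conv1 = self.add_child("conv1", Conv2d(channels, channels, rng))
        self.relu1 = self.add_child("relu1", ReLU())
        self.conv2 = self.add_child("conv2", Conv2d(channels, channels, rng))
        self.relu2 = self.add_child("relu2", ReLU())

    def forward(self, x: np.ndarray) -> np.ndarray:
        y = self.conv2.forward(self.relu1.forward(self.conv1.forward(x)))
        return self.relu2.forward(x + y)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        d = self.relu2.backward(dout)
        dy = self.conv1.backward(self.relu1.backward(self.conv2.backward(d)))
        return d + dy


class _SmallCNN(Module):
    """3 stride-2 conv blocks (16/32/64) + global average pooling; d_f = 64."""

    out_dim = 64

    def __init__(self, rng: np.random.Generator) -> None:
        super().__init__()
        self.net = self.add_child(
            "net",
            Sequential(
                Conv2d(3, 16, rng, stride=2),
                ReLU(),
                Conv2d(16, 32, rng, stride=2),
                ReLU(),
                Conv2d(32, 64, rng, stride=2),
                ReLU(),
                GlobalAvgPool(),
            ),
        )

    def forward(self, x: np.ndarray) -> np.ndarray:
        return self.net.forward(x)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return self.net.backward(dout)


class _ResNet50Style(Module):
    """Residual CNN ending in a 2048-dim pooled feature, mirroring the
    heavyweight backbone's interface (d_f = 2048 after global average
    pooling). Randomly initialized; no pretrained weights."""

    out_dim = 2048

    def __init__(self, rng: np.random.Generator) -> None:
        super().__init__()
        self.net = self.add_child(
            "net",
            Sequential(
                Conv2d(3, 64, rng, stride=4),
                ReLU(),
                _ResidualBlock(64, rng),
                Conv2d(64, 256, rng, stride=2),
                ReLU(),
                _ResidualBlock(256, rng),
                Conv2d(256, 2048, rng, ksize=1, stride=1, pad=0),
                ReLU(),
                GlobalAvgPool(),
            ),
        )

    def forward(self, x: np.ndarray) -> np.ndarray:
        return self.net.forward(x)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return self.net.backward(dout)


def make_backbone(
    name: str,
    rng: np.random.Generator,
    *,
    d_in: int = 32,
    d_hidden: int = 32,
):
    """Build a spatial feature extractor or temporal sequence encoder by name.

    Spatial names: ``small-cnn`` (desk-scale default) and ``resnet50-style``.
    Temporal names: ``gru`` and ``lstm`` (both bidirectional).
    """
    if name == "small-cnn":
        return _SmallCNN(rng)
    if name == "resnet50-style":
        return _ResNet50Style(rng)
    if name == "gru":
        return Bidirectional(GRU(d_in, d_hidden, rng), GRU(d_in, d_hidden, rng))
    if name == "lstm":
        return Bidirectional(LSTM(d_in, d_hidden, rng), LSTM(d_in, d_hidden, rng))
    raise ConfigurationError(f"unknown backbone {name!r}")


class SpatialQNet(Module):
    """CNN Q-network over the K+4 joint actions (agent 1)."""

    def __init__(
        self,
        n_classes: int,
        pos_dim: int,
        rng: np.random.Generator,
        backbone: str = "small-cnn",
        patch_size: int = 64,
        head_hidden: int = 512,
    ) -> None:
        super().__init__()
        if backbone not in SPATIAL_BACKBONES:
            raise ConfigurationError(f"unknown spatial backbone {backbone!r}")
        self.n_classes = n_classes
        self.pos_dim = pos_dim
        self.patch_size = patch_size
        self.backbone_name = backbone
        self.backbone = self.add_child("backbone", make_backbone(backbone, rng))
        self.head = self.add_child(
            "head",
            Sequential(
                Dense(self.backbone.out_dim + pos_dim, head_hidden, rng),
                ReLU(),
                Dense(head_hidden, n_classes + N_NAV_ACTIONS, rng),
            ),
        )
        self._last_features: np.ndarray | None = None

    @property
    def n_actions(self) -> int:
        return self.n_classes + N_NAV_ACTIONS

    def q_values(self, patches: np.ndarray, pos_embeds: np.ndarray) -> np.ndarray:
        """(N, p, p, 3) raw patches + (N, d_pos) embeddings -> (N, K+4)."""
        patches = np.asarray(patches, dtype=np.float64)
        if patches.ndim == 3:
            patches = patches[None]
            pos_embeds = np.asarray(pos_embeds)[None]
        if patches.shape[1:] != (self.patch_size, self.patch_size, 3):
            raise ContractError(
                f"expected patches of shape (N, {self.patch_size}, {self.patch_size}, 3), "
                f"got {patches.shape}"
            )
        x = (patches - IMAGENET_MEAN) / IMAGENET_STD
        f = self.backbone.forward(x)
        self._last_features = f
        z = np.concatenate([f, np.asarray(pos_embeds, dtype=np.float64)], axis=1)
        return self.head.forward(z)

    def backward(self, dq: np.ndarray) -> None:
        dz = self.head.backward(dq)
        self.backbone.backward(dz[:, : self.backbone.out_dim])

    @property
    def last_features(self) -> np.ndarray:
        """Pooled backbone features of the last forward pass (fusion summary)."""
        return self._last_features


class TemporalQNet(Module):
    """Recurrent text Q-network over the K classification actions (agent 2)."""

    def __init__(
        self,
        vocab_size: int,
        n_classes: int,
        rng: np.random.Generator,
        backbone: str = "gru",
        d_emb: int = 32,
        d_hidden: int = 32,
        head_hidden: int = 64,
    ) -> None:
        super().__init__()
        if backbone not in TEMPORAL_BACKBONES:
            raise ConfigurationError(f"unknown temporal backbone {backbone!r}")
        self.vocab_size = vocab_size
        self.n_classes = n_classes
        self.backbone_name = backbone
        self.d_hidden = 2 * d_hidden  # bidirectional concatenation
        self.embedding = self.add_child("embedding", Embedding(vocab_size, d_emb, rng))
        self.encoder = self.add_child(
            "encoder", make_backbone(backbone, rng, d_in=d_emb, d_hidden=d_hidden)
        )
        self.head = self.add_child(
            "head",
            Sequential(
                Dense(self.d_hidden, head_hidden, rng),
                ReLU(),
                Dense(head_hidden, n_classes, rng),
            ),
        )

    def _pad(self, token_lists) -> tuple[np.ndarray, np.ndarray]:
        if isinstance(token_lists[0], (int, np.integer)):
            token_lists = [token_lists]
        lengths = [len(t) for t in token_lists]
        if min(lengths) == 0:
            raise DomainError("empty token sequence")
        arr = np.zeros((len(token_lists), max(lengths)), dtype=int)
        mask = np.zeros_like(arr, dtype=bool)
        for i, toks in enumerate(token_lists):
            toks = np.asarray(toks, dtype=int)
            if toks.min() < 0 or toks.max() >= self.vocab_size:
                raise DomainError("token index outside vocabulary")
            arr[i, : len(toks)] = toks
            mask[i, : len(toks)] = True
        return arr, mask

    def encode(self, token_lists) -> np.ndarray:
        """Token sequences -> bidirectional hidden state h (N, d_h)."""
        tokens, mask = self._pad(token_lists)
        emb = self.embedding.forward(tokens, mask)
        return self.encoder.forward(emb, mask)

    def head_values(self, hidden: np.ndarray) -> np.ndarray:
        """Q-values from a precomputed hidden state (no encoder pass)."""
        if hidden.ndim == 1:
            hidden = hidden[None]
        return self.head.forward(hidden)

    def q_values(self, token_lists) -> np.ndarray:
        return self.head_values(self.encode(token_lists))

    def backward(self, dq: np.ndarray) -> None:
        dh = self.head.backward(dq)
        demb = self.encoder.backward(dh)
        self.embedding.backward(demb)


# ---------------------------------------------------------------------------
# checkpoints: one .npz archive of weights + a JSON metadata sidecar
# ---------------------------------------------------------------------------

def save_checkpoint(path, modules: dict[str, Module], metadata: dict) -> None:
    path = Path(path)
    arrays: dict[str, np.ndarray] = {}
    for mod_name, module in modules.items():
        for pname, value in module.state_dict().items():
            arrays[f"{mod_name}/{pname}"] = value
    np.savez(path, **arrays)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps(metadata, indent=2, sort_keys=True))


def load_checkpoint(path) -> tuple[dict[str, dict[str, np.ndarray]], dict]:
    path = Path(path)
    with np.load(path) as data:
        states: dict[str, dict[str, np.ndarray]] = {}
        for key in data.files:
            mod_name, pname = key.split("/", 1)
            states.setdefault(mod_name, {})[pname] = data[key]
    sidecar = path.with_suffix(path.suffix + ".json")
    metadata = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return states, metadata


def make_optimizers(modules: list[Module], lr: float) -> list[Adam]:
    return [Adam(m, lr=lr) for m in modules]
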