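"""Model containers: sequential stacks and a two-branch fused network.

Models output *logits*; :func:`softmax` turns them into the probability
simplex, and the training loop pairs them with the softmax cross-entropy
gradient. Each model exposes a uniform surface: ``forward``, ``backward``,
``predict_proba``, ``param_items``, ``n_params``, and ``summary``.
"""

from __future__ import annotations

import json

import numpy as np

from .layers import Layer


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class Model:
    """Common surface for all network containers."""

    config: dict

    def forward(self, inputs, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> None:
        raise NotImplementedError

    def param_items(self):
        """Yield (unique key, layer, param name) for every trainable array."""
        raise NotImplementedError

    @property
    def n_params(self) -> int:
        return int(sum(layer.params[name].size for _, layer, name in self.param_items()))

    def predict_proba(self, inputs, batch_size: int = 32) -> np.ndarray:
        """Class probabilities (softmax of the logits), batched, inference mode."""
        n = _batch_len(inputs)
        chunks = []
        for s in range(0, n, batch_size):
            chunk = _batch_slice(inputs, s, min(s + batch_size, n))
            chunks.append(softmax(self.forward(chunk, training=False)))
        return np.concatenate(chunks, axis=0)

    def summary(self) -> str:
        raise NotImplementedError

    # -- weight (de)serialization ------------------------------------------
    def state_arrays(self) -> dict[str, np.ndarray]:
        out = {}
        for key, layer, name in self.param_items():
            out[f"{key}:{name}"] = layer.params[name]
            if hasattr(layer, "running_mean"):
                out[f"{key}:running_mean"] = layer.running_mean
                out[f"{key}:running_var"] = layer.running_var
        return out

    def load_state_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        for key, layer, name in self.param_items():
            layer.params[name] = np.asarray(arrays[f"{key}:{name}"])
            if hasattr(layer, "running_mean"):
                layer.running_mean = np.asarray(arrays[f"{key}:running_mean"])
                layer.running_var = np.asarray(arrays[f"{key}:running_var"])

    def weight_checksum(self) -> float:
        """A cheap fingerprint of all weights (for reproducibility checks)."""
        return float(
            sum(np.abs(a).sum() for a in self.state_arrays().values())
        )


def _batch_len(inputs) -> int:
    if isinstance(inputs, (tuple, list)):
        return inputs[0].shape[0]
    return inputs.shape[0]


def _batch_slice(inputs, a, b):
    if isinstance(inputs, (tuple, list)):
        return type(inputs)(x[a:b] for x in inputs)
    return inputs[a:b]


class Sequential(Model):
    def __init__(self, layers: list[Layer], config: dict | None = None):
        self.layers = layers
        self.config = config or {}

    def forward(self, x, training=False):
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def param_items(self):
        for li, layer in enumerate(self.layers):
            if layer.trainable:
                for name in layer.params:
                    yield f"seq{li}", layer, name
        # frozen layers still carry state (e.g. BatchNorm running stats)

    def summary(self) -> str:
        lines = [f"{type(self).__name__}:"]
        for li, layer in enumerate(self.layers):
            lines.append(f"  [{li:2d}] {layer.describe():45s} params={layer.n_params}")
        lines.append(f"  total params: {self.n_params}")
        return "\n".join(lines)


class FusedNetwork(Model):
    """Two branches (image, GLCM sequence) concatenated into one head.

    ``forward`` takes the pair ``(image_batch, sequence_batch)``; branch
    feature vectors are concatenated and passed through the head, which
    emits the class logits.
    """

    def __init__(self, image_branch: Sequential, seq_branch: Sequential,
                 head: Sequential, config: dict | None = None):
        self.image_branch = image_branch
        self.seq_branch = seq_branch
        self.head = head
        self.config = config or {}

    def forward(self, inputs, training=False):
        x_img, x_seq = inputs
        f_img = self.image_branch.forward(x_img, training=training)
        f_seq = self.seq_branch.forward(x_seq, training=training)
        self._split = f_img.shape[1]
        return self.head.forward(np.concatenate([f_img, f_seq], axis=1),
                                 training=training)

    def backward(self, grad):
        g = self.head.backward(grad)
        self.image_branch.backward(g[:, : self._split])
        self.seq_branch.backward(g[:, self._split :])

    def param_items(self):
        for prefix, branch in (
            ("img", self.image_branch),
            ("seq", self.seq_branch),
            ("head", self.head),
        ):
            for key, layer, name in branch.param_items():
                yield f"{prefix}.{key}", layer, name

    def summary(self) -> str:
        return "\n".join(
            [
                "FusedNetwork:",
                "-- image branch --",
                self.image_branch.summary(),
                "-- sequence branch --",
                self.seq_branch.summary(),
                "-- fusion head --",
                self.head.summary(),
                f"total params: {self.n_params}",
            ]
        )


def save_model(model: Model, path: str) -> None:
    """Save weights (+ running stats) and config as a .npz checkpoint.

    An architecture summary text dump is written beside the checkpoint for
    auditability.
    """
    arrays = {k: np.asarray(v) for k, v in model.state_arrays().items()}
    arrays["__config__"] = np.frombuffer(
        json.dumps(model.config).encode(), dtype=np.uint8
    )
    np.savez(path, **arrays)
    base = path[:-4] if path.endswith(".npz") else path
    with open(base + "_summary.txt", "w") as fh:
        fh.write(model.summary() + "\n")


def load_model(path: str) -> Model:
    """Rebuild a model from a checkpoint written by :func:`save_model`."""
    import dataclasses

    from ..networks import build_model, ArchitectureConfig
    from ..exceptions import CheckpointError

    try:
        data = np.load(path)
        config = json.loads(bytes(data["__config__"]).decode())
        arch_keys = {f.name for f in dataclasses.fields(ArchitectureConfig)}
        model = build_model(
            ArchitectureConfig(**{k: v for k, v in config.items() if k in arch_keys})
        )
        model.config = config  # keep extras (e.g. sequence-scaler state)
        model.load_state_arrays({k: data[k] for k in data.files if k != "__config__"})
    except CheckpointError:
        raise
    except Exception as exc:
        raise CheckpointError(f"cannot load checkpoint {path}: {exc}") from exc
    return model
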