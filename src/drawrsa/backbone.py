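"""Convolutional feature extractors exposing the seven analysis layers.

The analysis only ever sees seven named layers — the five pooling stages and
the two fully connected stages of a VGG-style hierarchy — so backbones are
adapters mapping those names onto a concrete network.  Two are provided:

* :func:`make_test_backbone` — a small numpy network with seed-deterministic
  random weights.  Random convolutional features are a standard device for
  architecture-driven image descriptors; they preserve enough image structure
  for the relative-dissimilarity analyses while keeping the whole pipeline
  runnable offline in seconds.
* :func:`load_pretrained_backbone` — the ImageNet-pretrained VGG19 route,
  available only when torch/torchvision (and the weights) are installed.

Features are taken after each layer's nonlinearity and flattened.
"""
from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np

from .imageops import BackboneInput

LAYER_NAMES = ("pool1", "pool2", "pool3", "pool4", "pool5", "fc6", "fc7")

#: classical mean-RGB constants used for VGG-style preprocessing
VGG_CHANNEL_MEANS = (123.68, 116.779, 103.939)

__all__ = [
    "LAYER_NAMES",
    "BackboneSpec",
    "FeatureVector",
    "TestBackbone",
    "make_test_backbone",
    "load_pretrained_backbone",
    "PretrainedBackboneUnavailableError",
    "UnknownLayerError",
    "FeatureExtractor",
    "conv2d_same",
    "max_pool2",
]


class UnknownLayerError(KeyError):
    pass


class PretrainedBackboneUnavailableError(RuntimeError):
    pass


@dataclass(frozen=True)
class BackboneSpec:
    backbone_id: str
    layer_names: tuple = LAYER_NAMES
    input_size: tuple = (224, 224, 3)
    channel_means: tuple = VGG_CHANNEL_MEANS
    channel_order: str = "rgb"

    def __post_init__(self) -> None:
        if tuple(self.layer_names) != LAYER_NAMES:
            raise ValueError(f"a backbone must expose exactly the layers {LAYER_NAMES}")


@dataclass(frozen=True)
class FeatureVector:
    layer: str
    values: np.ndarray
    drawing_id: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64).ravel()
        if v.size < 2:
            raise ValueError("feature vector needs length >= 2")
        if not np.all(np.isfinite(v)):
            raise ValueError("feature vector contains non-finite values")
        object.__setattr__(self, "values", v)


def conv2d_same(x: np.ndarray, weights: np.ndarray, bias: np.ndarray) -> np.ndarray:
    """3x3 'same' convolution (cross-correlation), zero padding.

    x: (H, W, Cin); weights: (3, 3, Cin, Cout); bias: (Cout,).
    """
    kh, kw, cin, cout = weights.shape
    if (kh, kw) != (3, 3) or x.shape[2] != cin:
        raise ValueError("conv2d_same expects 3x3 kernels matching the input channels")
    xp = np.pad(x, ((1, 1), (1, 1), (0, 0)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(0, 1))
    # win: (H, W, Cin, 3, 3) -> (H*W, Cin*9) matching weights (3,3,Cin,Cout)
    h, w = x.shape[:2]
    cols = win.transpose(0, 1, 3, 4, 2).reshape(h * w, 9 * cin)
    wmat = weights.transpose(0, 1, 2, 3).reshape(9 * cin, cout)
    out = cols @ wmat + bias
    return out.reshape(h, w, cout)


def max_pool2(x: np.ndarray) -> np.ndarray:
    """2x2 max pooling, stride 2 (even spatial dims required)."""
    h, w, c = x.shape
    if h % 2 or w % 2:
        raise ValueError("max_pool2 requires even spatial dimensions")
    return x.reshape(h // 2, 2, w // 2, 2, c).max(axis=(1, 3))


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


class TestBackbone:
    """Fixed-architecture random-weight network mirroring the VGG layer
    taxonomy: five conv+pool blocks and two fully connected layers, all narrow
    so a forward pass takes milliseconds."""

    def __init__(self, seed: int, channels=(8, 8, 16, 16, 16), fc_dim: int = 64):
        if len(channels) != 5:
            raise ValueError("need 5 conv blocks")
        self.spec = BackboneSpec(backbone_id=f"test-{seed}")
        self.channels = tuple(channels)
        self.fc_dim = int(fc_dim)
        rng = np.random.default_rng(seed)
        self._conv = []
        cin = 3
        for cout in channels:
            w = rng.standard_normal((3, 3, cin, cout)) * np.sqrt(2.0 / (9 * cin))
            b = rng.standard_normal(cout) * 0.1
            self._conv.append((w.astype(np.float32), b.astype(np.float32)))
            cin = cout
        flat = 7 * 7 * channels[-1]
        self._fc6 = (
            (rng.standard_normal((flat, fc_dim)) * np.sqrt(2.0 / flat)).astype(np.float32),
            (rng.standard_normal(fc_dim) * 0.1).astype(np.float32),
        )
        self._fc7 = (
            (rng.standard_normal((fc_dim, fc_dim)) * np.sqrt(2.0 / fc_dim)).astype(np.float32),
            (rng.standard_normal(fc_dim) * 0.1).astype(np.float32),
        )

    @property
    def layer_names(self) -> tuple:
        return self.spec.layer_names

    def forward_all(self, x: BackboneInput) -> dict:
        """One forward pass; returns {layer name: flattened post-ReLU activation}."""
        arr = np.asarray(x.array, dtype=np.float32)
        if arr.shape != tuple(self.spec.input_size):
            raise ValueError(
                f"input shape {arr.shape} does not match {self.spec.input_size}"
            )
        arr = arr / 255.0  # keep activations O(1)
        out: dict = {}
        for i, (w, b) in enumerate(self._conv, start=1):
            arr = _relu(conv2d_same(arr, w, b))
            arr = max_pool2(arr)
            out[f"pool{i}"] = arr.ravel().astype(np.float64)
        flat = arr.ravel().astype(np.float32)
        h6 = _relu(flat @ self._fc6[0] + self._fc6[1])
        out["fc6"] = h6.astype(np.float64)
        h7 = _relu(h6 @ self._fc7[0] + self._fc7[1])
        out["fc7"] = h7.astype(np.float64)
        return out

    def extract_features(self, x: BackboneInput, layer: str, drawing_id: str = "") -> FeatureVector:
        if layer not in self.layer_names:
            raise UnknownLayerError(f"unknown layer {layer!r}; valid: {self.layer_names}")
        return FeatureVector(layer, self.forward_all(x)[layer], drawing_id)


def make_test_backbone(seed: int = 0, **kwargs) -> TestBackbone:
    """Seed-deterministic offline backbone; same seed -> identical features."""
    return TestBackbone(seed, **kwargs)


class _TorchVGG19Adapter:
    """Maps the abstract layer names onto torchvision's VGG19 graph nodes.

    pool1..pool5 are features[4, 9, 18, 27, 36]; fc6/fc7 are the two
    4096-unit linear layers of the classifier, taken after ReLU.
    """

    _POOL_IDX = {"pool1": 4, "pool2": 9, "pool3": 18, "pool4": 27, "pool5": 36}

    def __init__(self, model, torch):
        self._torch = torch
        self._model = model.eval()
        self.spec = BackboneSpec(backbone_id="vgg19-imagenet")

    @property
    def layer_names(self) -> tuple:
        return self.spec.layer_names

    def forward_all(self, x: BackboneInput) -> dict:
        torch = self._torch
        with torch.no_grad():
            t = torch.from_numpy(np.ascontiguousarray(x.array)).permute(2, 0, 1)[None].float()
            out: dict = {}
            h = t
            for i, mod in enumerate(self._model.features):
                h = mod(h)
                for name, idx in self._POOL_IDX.items():
                    if i == idx:
                        out[name] = h.numpy().ravel().astype(np.float64)
            h = torch.flatten(self._model.avgpool(h), 1)
            cls = self._model.classifier
            h = cls[1](cls[0](h))          # fc6 + ReLU
            out["fc6"] = h.numpy().ravel().astype(np.float64)
            h = cls[4](cls[3](cls[2](h)))  # dropout (inert in eval) + fc7 + ReLU
            out["fc7"] = h.numpy().ravel().astype(np.float64)
        return out

    def extract_features(self, x: BackboneInput, layer: str, drawing_id: str = "") -> FeatureVector:
        if layer not in self.layer_names:
            raise UnknownLayerError(f"unknown layer {layer!r}; valid: {self.layer_names}")
        return FeatureVector(layer, self.forward_all(x)[layer], drawing_id)


def load_pretrained_backbone(name: str = "vgg19-imagenet", weights_path=None):
    """ImageNet-pretrained VGG19 exposing the same seven-layer interface.

    Requires torch + torchvision (and locally available weights).  When they
    are not installed, a named error points at the offline test backbone.
    """
    if name != "vgg19-imagenet":
        raise ValueError(f"unknown pretrained backbone {name!r}")
    try:
        import torch
        import torchvision
    except ImportError as exc:
        raise PretrainedBackboneUnavailableError(
            "torch/torchvision are not installed, so the pretrained VGG19 backbone "
            "is unavailable; use make_test_backbone(seed) for offline analysis"
        ) from exc
    model = torchvision.models.vgg19(weights=None)
    if weights_path is not None:
        model.load_state_dict(torch.load(weights_path, map_location="cpu"))
    else:
        try:
            model = torchvision.models.vgg19(
                weights=torchvision.models.VGG19_Weights.IMAGENET1K_V1
            )
        except Exception as exc:  # no network / no cached weights
            raise PretrainedBackboneUnavailableError(
                "pretrained VGG19 weights are unavailable offline; pass weights_path "
                "or use make_test_backbone(seed)"
            ) from exc
    return _TorchVGG19Adapter(model, torch)


class FeatureExtractor:
    """Caches feature vectors per (drawing, produced_only) image variant.

    One forward pass serves all layers, but only the requested layer and the
    small fully connected layers are retained (the early pooling layers are
    large, and holding all of them for a whole cohort would cost gigabytes).
    Requesting a further pooling layer for the same image triggers one more
    forward pass.
    """

    def __init__(self, backbone, canvas_size: int | None = None, stroke_width: int | None = None):
        from .imageops import DEFAULT_STROKE_WIDTH
        from .stimuli import CANVAS_SIZE

        self.backbone = backbone
        self.canvas_size = canvas_size or CANVAS_SIZE
        self.stroke_width = stroke_width or DEFAULT_STROKE_WIDTH
        self._cache: dict = {}

    @staticmethod
    def _drawing_key(drawing) -> str:
        """Content digest of the stroke geometry — drawing ids alone are not
        unique across independently simulated cohorts."""
        h = hashlib.sha1()
        for layer_set in (drawing.presented_strokes, drawing.produced_strokes):
            for s in layer_set:
                h.update(s.name.encode())
                h.update(np.ascontiguousarray(s.points).tobytes())
        return h.hexdigest()

    def _activation(self, drawing, produced_only: bool, layer: str) -> np.ndarray:
        key = (self._drawing_key(drawing), produced_only)
        stored = self._cache.setdefault(key, {})
        if layer not in stored:
            from .imageops import full_drawing_image, preprocess_for_backbone, produced_only_image

            img = (
                produced_only_image(drawing, self.canvas_size, self.stroke_width)
                if produced_only
                else full_drawing_image(drawing, self.canvas_size, self.stroke_width)
            )
            x = preprocess_for_backbone(img, self.backbone.spec)
            acts = self.backbone.forward_all(x)
            for keep in {layer, "fc6", "fc7"}:
                stored[keep] = np.asarray(acts[keep], dtype=np.float32)
        return stored[layer]

    def features(self, drawing, layer: str, produced_only: bool) -> FeatureVector:
        if layer not in self.backbone.layer_names:
            raise UnknownLayerError(f"unknown layer {layer!r}")
        return FeatureVector(layer, self._activation(drawing, produced_only, layer),
                             drawing.drawing_id)
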