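"""Channel-weighting operators for the TA12 and DM feature planes.

Two schemes, both emitting sigmoid-bounded scalar weights applied only to
the TA12 and DM channels (the RGB planes pass through bit-identical):

* **Fixed weighting** — two learnable scalars ``alpha``, ``beta``; the
  applied weights are ``sigmoid(alpha)`` and ``sigmoid(beta)``, independent
  of the input.
* **Modified Squeeze-and-Excitation** — input-aware.  A stem of two 3x3
  stride-1 same-padded convolutions with an intermediate ReLU maps the
  5-channel stack to a feature map X; global average pooling squeezes X to a
  per-channel vector z; the excitation ``sigmoid(W2 . relu(W1 . z))`` emits
  exactly two weights (unlike the classic block, which scales every channel).

Both are framework-free numeric forward passes with analytic gradients for a
scalar test loss (the sum of output entries), validated against central
finite differences, so a downstream training framework can adopt them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from sklearn.base import BaseEstimator, TransformerMixin

from traplapse.features import ChannelStack

N_CHANNELS = 5
_TA, _DM = 3, 4


def sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=np.float64)))


@dataclass
class FixedWeights:
    """Learnable logits for the fixed scheme; applied weights are sigmoid-bounded."""

    alpha: float = 0.0
    beta: float = 0.0

    @property
    def w_ta(self) -> float:
        return float(sigmoid(self.alpha))

    @property
    def w_dm(self) -> float:
        return float(sigmoid(self.beta))


@dataclass
class SEParams:
    """Parameters of the modified Squeeze-and-Excitation block.

    Kernels are (3, 3, C_in, C_out); both convolutions map C -> C with no
    bias.  ``w1`` is (C, C), ``w2`` is (2, C): the excitation emits exactly
    two weights, one for TA12 and one for DM.
    """

    conv1_kernel: np.ndarray
    conv2_kernel: np.ndarray
    w1: np.ndarray
    w2: np.ndarray
    C: int = N_CHANNELS

    def __post_init__(self):
        self.conv1_kernel = np.asarray(self.conv1_kernel, dtype=np.float64)
        self.conv2_kernel = np.asarray(self.conv2_kernel, dtype=np.float64)
        self.w1 = np.asarray(self.w1, dtype=np.float64)
        self.w2 = np.asarray(self.w2, dtype=np.float64)
        C = self.C
        for name, arr, shape in [
            ("conv1_kernel", self.conv1_kernel, (3, 3, C, C)),
            ("conv2_kernel", self.conv2_kernel, (3, 3, C, C)),
            ("w1", self.w1, (C, C)),
            ("w2", self.w2, (2, C)),
        ]:
            if arr.shape != shape:
                raise ValueError(f"{name}: expected shape {shape}, got {arr.shape}")

    @classmethod
    def random(cls, seed: int, scale: float = 0.05, C: int = N_CHANNELS) -> "SEParams":
        """Seeded standard-normal initialisation scaled by ``scale`` (demo/test default)."""
        rng = np.random.default_rng(seed)
        return cls(
            conv1_kernel=rng.standard_normal((3, 3, C, C)) * scale,
            conv2_kernel=rng.standard_normal((3, 3, C, C)) * scale,
            w1=rng.standard_normal((C, C)) * scale,
            w2=rng.standard_normal((2, C)) * scale,
            C=C,
        )

    @classmethod
    def zeros(cls, C: int = N_CHANNELS) -> "SEParams":
        return cls(
            conv1_kernel=np.zeros((3, 3, C, C)),
            conv2_kernel=np.zeros((3, 3, C, C)),
            w1=np.zeros((C, C)),
            w2=np.zeros((2, C)),
            C=C,
        )

    def to_json(self, path: Path | str) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "C": self.C,
                    "conv1_kernel": self.conv1_kernel.tolist(),
                    "conv2_kernel": self.conv2_kernel.tolist(),
                    "w1": self.w1.tolist(),
                    "w2": self.w2.tolist(),
                },
                fh,
            )

    @classmethod
    def from_json(cls, path: Path | str) -> "SEParams":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            conv1_kernel=np.array(d["conv1_kernel"]),
            conv2_kernel=np.array(d["conv2_kernel"]),
            w1=np.array(d["w1"]),
            w2=np.array(d["w2"]),
            C=int(d["C"]),
        )


# --------------------------------------------------------------------------
# Numeric primitives


def _conv2d_same(x: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """3x3 stride-1 same-padded cross-correlation: (H,W,Cin) x (3,3,Cin,Cout)."""
    xp = np.pad(x, ((1, 1), (1, 1), (0, 0)))
    win = sliding_window_view(xp, (3, 3), axis=(0, 1))  # (H, W, Cin, 3, 3)
    return np.einsum("hwcij,ijcd->hwd", win, kernel)


def _conv2d_kernel_grad(x: np.ndarray, d_out: np.ndarray) -> np.ndarray:
    """Gradient of a same-padded conv w.r.t. its kernel."""
    xp = np.pad(x, ((1, 1), (1, 1), (0, 0)))
    win = sliding_window_view(xp, (3, 3), axis=(0, 1))
    return np.einsum("hwcij,hwd->ijcd", win, d_out)


def _conv2d_input_grad(d_out: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Gradient of a same-padded conv w.r.t. its input (transposed convolution)."""
    flipped = kernel[::-1, ::-1].transpose(0, 1, 3, 2)  # swap Cin/Cout, flip taps
    return _conv2d_same(d_out, flipped)


# --------------------------------------------------------------------------
# Operators


def apply_fixed_weighting(stack: ChannelStack, weights: FixedWeights) -> ChannelStack:
    """Scale TA12 by sigmoid(alpha) and DM by sigmoid(beta); RGB untouched."""
    out = stack.channels.copy()
    out[..., _TA] *= weights.w_ta
    out[..., _DM] *= weights.w_dm
    return ChannelStack(channels=out, frame_id=stack.frame_id)


def se_forward(
    stack: ChannelStack, params: SEParams
) -> tuple[ChannelStack, tuple[float, float]]:
    """Forward pass of the modified SE block.

    Returns the weighted stack (TA12 scaled by w_ta, DM by w_dm, RGB
    bit-identical) together with the emitted weight pair for inspection.
    """
    _, cache = _se_forward_cached(stack, params)
    w_ta, w_dm = cache["w"]
    out = stack.channels.copy()
    out[..., _TA] *= w_ta
    out[..., _DM] *= w_dm
    return ChannelStack(channels=out, frame_id=stack.frame_id), (float(w_ta), float(w_dm))


def _se_forward_cached(stack: ChannelStack, params: SEParams):
    x = np.asarray(stack.channels, dtype=np.float64)
    if x.shape[2] != params.C:
        raise ValueError(f"stack has {x.shape[2]} channels, params expect {params.C}")
    a = _conv2d_same(x, params.conv1_kernel)  # pre-activation of conv1
    r = np.maximum(a, 0.0)
    X = _conv2d_same(r, params.conv2_kernel)
    z = X.mean(axis=(0, 1))  # squeeze: global average pool per channel
    pre = params.w1 @ z
    h = np.maximum(pre, 0.0)
    u = params.w2 @ h
    w = sigmoid(u)
    cache = dict(x=x, a=a, r=r, X=X, z=z, pre=pre, h=h, u=u, w=w)
    return w, cache


def se_gradients(stack: ChannelStack, params: SEParams) -> dict[str, np.ndarray]:
    """Analytic parameter gradients for the test loss L = sum of output entries.

    Because only TA12 and DM are rescaled, L = sum(RGB) + w_ta * sum(TA12_in)
    + w_dm * sum(DM_in); gradients flow to the parameters through the two
    emitted weights only.
    """
    _, c = _se_forward_cached(stack, params)
    H, W, _ = c["x"].shape
    d_w = np.array([c["x"][..., _TA].sum(), c["x"][..., _DM].sum()])
    d_u = d_w * c["w"] * (1.0 - c["w"])  # sigmoid'
    d_w2 = np.outer(d_u, c["h"])
    d_h = params.w2.T @ d_u
    d_pre = d_h * (c["pre"] > 0)
    d_w1 = np.outer(d_pre, c["z"])
    d_z = params.w1.T @ d_pre
    d_X = np.broadcast_to(d_z / (H * W), c["X"].shape)
    d_conv2 = _conv2d_kernel_grad(c["r"], d_X)
    d_r = _conv2d_input_grad(d_X, params.conv2_kernel)
    d_a = d_r * (c["a"] > 0)
    d_conv1 = _conv2d_kernel_grad(c["x"], d_a)
    return {"conv1_kernel": d_conv1, "conv2_kernel": d_conv2, "w1": d_w1, "w2": d_w2}


def fixed_weighting_gradients(stack: ChannelStack, weights: FixedWeights) -> dict[str, float]:
    """Analytic gradients of L = sum of output entries for the fixed scheme.

    Includes the constant unit gradient w.r.t. every RGB input entry (the RGB
    path is the identity).
    """
    w_ta, w_dm = weights.w_ta, weights.w_dm
    return {
        "alpha": float(stack.ta12.sum() * w_ta * (1.0 - w_ta)),
        "beta": float(stack.dm.sum() * w_dm * (1.0 - w_dm)),
        "rgb": 1.0,
    }


def finite_difference_check(
    params: SEParams, stack: ChannelStack, epsilon: float = 1e-5
) -> float:
    """Validate analytic SE gradients against central finite differences.

    Perturbs every parameter entry by +/- epsilon, differences the test loss
    L = sum of output entries, and returns the maximum relative error
    ``|analytic - numeric| / max(|analytic| + |numeric|, 1)`` over all
    entries.
    """

    def loss(p: SEParams) -> float:
        out, _ = se_forward(stack, p)
        return float(out.channels.sum())

    analytic = se_gradients(stack, params)
    arrays = {
        "conv1_kernel": params.conv1_kernel,
        "conv2_kernel": params.conv2_kernel,
        "w1": params.w1,
        "w2": params.w2,
    }
    max_err = 0.0
    for name, arr in arrays.items():
        ana = analytic[name]
        flat = arr.reshape(-1)
        for i in range(flat.size):
            orig = flat[i]
            flat[i] = orig + epsilon
            lp = loss(params)
            flat[i] = orig - epsilon
            lm = loss(params)
            flat[i] = orig
            num = (lp - lm) / (2.0 * epsilon)
            a = ana.reshape(-1)[i]
            err = abs(a - num) / max(abs(a) + abs(num), 1.0)
            max_err = max(max_err, err)
    return max_err


# --------------------------------------------------------------------------
# sklearn-style transformer facades


class FixedChannelWeighting(BaseEstimator, TransformerMixin):
    """Stateless transformer applying the fixed sigmoid channel weighting.

    Parameters are the logits; ``transform`` accepts a ChannelStack or an
    (H, W, 5) array and returns the same type.
    """

    def __init__(self, alpha: float = 0.0, beta: float = 0.0):
        self.alpha = alpha
        self.beta = beta

    def fit(self, X=None, y=None):
        self.weights_ = FixedWeights(self.alpha, self.beta)
        return self

    def transform(self, X):
        if not hasattr(self, "weights_"):
            self.fit()
        stack = X if isinstance(X, ChannelStack) else ChannelStack(np.asarray(X), frame_id="")
        out = apply_fixed_weighting(stack, self.weights_)
        return out if isinstance(X, ChannelStack) else out.channels


class SqueezeExcitationWeighting(BaseEstimator, TransformerMixin):
    """Transformer applying the modified SE weighting with fixed parameters.

    ``random_state`` seeds the default small-normal parameter initialisation
    when no explicit ``params`` are supplied.  After ``transform``, the last
    emitted weight pair is available as ``last_weights_``.
    """

    def __init__(self, params: SEParams | None = None, random_state: int = 0,
                 init_scale: float = 0.05):
        self.params = params
        self.random_state = random_state
        self.init_scale = init_scale

    def fit(self, X=None, y=None):
        self.params_ = (
            self.params
            if self.params is not None
            else SEParams.random(self.random_state, self.init_scale)
        )
        return self

    def transform(self, X):
        if not hasattr(self, "params_"):
            self.fit()
        stack = X if isinstance(X, ChannelStack) else ChannelStack(np.asarray(X), frame_id="")
        out, weights = se_forward(stack, self.params_)
        self.last_weights_ = weights
        return out if isinstance(X, ChannelStack) else out.channels
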