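"""Temporal-average background model, colour correction, difference mask, 5-channel stack.

All arithmetic is on unit-interval floats; 8-bit I/O is scaled by 255.  The
background model for a frame is the pixelwise mean of up to 12 prior
same-modality frames (``TA12``), flattened to greyscale with the standard
luminosity coefficients.  Before differencing, the RGB background is aligned
to the current frame's colour distribution with a least-squares 3x3 channel
mixing matrix, so the difference mask (``DM``) responds to motion rather than
global illumination change.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image
from skimage import color as skcolor
from sklearn.base import BaseEstimator, TransformerMixin

from traplapse.sequence import (
    FrameRecord,
    Modality,
    SequenceIndex,
    load_frame,
    select_background_frames,
)

logger = logging.getLogger(__name__)

#: Luminosity greyscale coefficients (ITU-R BT.601).
GREY_WEIGHTS = np.array([0.299, 0.587, 0.114])

#: Rank-deficiency threshold: smallest/largest singular value of the pixel matrix.
CONDITION_THRESHOLD = 1e-6


@dataclass
class BackgroundModel:
    """RGB temporal average with its greyscale flattening and provenance."""

    ta_rgb: np.ndarray
    ta_grey: np.ndarray
    source_frame_ids: list[str]
    modality: Modality
    n_sources: int

    def __post_init__(self):
        if self.n_sources != len(self.source_frame_ids):
            raise ValueError("n_sources must equal len(source_frame_ids)")


@dataclass
class ChannelStack:
    """The 5-channel detector input: (R, G, B, TA12, DM), unit-interval."""

    channels: np.ndarray
    frame_id: str

    def __post_init__(self):
        if self.channels.ndim != 3 or self.channels.shape[2] != 5:
            raise ValueError(f"expected H x W x 5 channels, got {self.channels.shape}")

    @property
    def rgb(self) -> np.ndarray:
        return self.channels[..., :3]

    @property
    def ta12(self) -> np.ndarray:
        return self.channels[..., 3]

    @property
    def dm(self) -> np.ndarray:
        return self.channels[..., 4]


def temporal_average(frames: Sequence[np.ndarray]) -> np.ndarray:
    """Pixelwise per-channel arithmetic mean of the background window.

    With the full 12-frame window this is the TA12 RGB model; near the start
    of a sequence the 1/12 generalises to 1/n over however many same-modality
    priors exist.
    """
    if len(frames) == 0:
        raise ValueError("temporal_average requires at least one frame")
    shapes = {f.shape for f in frames}
    if len(shapes) != 1:
        raise ValueError(f"frames have mismatched shapes: {sorted(shapes)}")
    return np.mean(np.stack([np.asarray(f, dtype=np.float64) for f in frames]), axis=0)


def to_greyscale(rgb: np.ndarray) -> np.ndarray:
    """Luminosity flattening: 0.299 R + 0.587 G + 0.114 B."""
    rgb = np.asarray(rgb, dtype=np.float64)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError(f"expected H x W x 3, got {rgb.shape}")
    return rgb @ GREY_WEIGHTS


class ColorCorrector(BaseEstimator, TransformerMixin):
    """Least-squares 3x3 channel-mixing correction of a background model.

    Fits ``M = argmin_M || I - B M ||^2`` with pixels as rows (no intercept):
    the matrix that best maps the background's colour distribution onto the
    current frame's.  Night IR imagery is rank-1 (R=G=B) and would produce
    wild matrices, so when the ratio of smallest to largest singular value of
    the background pixel matrix falls below ``condition_threshold`` the fit
    is declared degenerate and the identity is used.

    Attributes
    ----------
    matrix_ : (3, 3) ndarray
        Fitted mixing matrix (identity when degenerate).
    residual_rms_ : float
        Root-mean-square of ``I - B M`` over all pixel-channel entries.
    degenerate_ : bool
        True when the background pixel matrix was rank-deficient.
    """

    def __init__(self, condition_threshold: float = CONDITION_THRESHOLD,
                 subsample: int | None = None, random_state: int | None = None):
        self.condition_threshold = condition_threshold
        self.subsample = subsample
        self.random_state = random_state

    def fit(self, X: np.ndarray, y: np.ndarray) -> "ColorCorrector":
        """Fit the mixing matrix mapping background ``X`` onto frame ``y``.

        Parameters
        ----------
        X : (H, W, 3) or (N, 3) array
            Background model pixels (regressors).
        y : same shape as X
            Current frame pixels (targets).
        """
        B = np.asarray(X, dtype=np.float64).reshape(-1, 3)
        I = np.asarray(y, dtype=np.float64).reshape(-1, 3)
        if B.shape != I.shape:
            raise ValueError(f"shape mismatch: background {B.shape} vs frame {I.shape}")
        if B.shape[0] < 3:
            raise ValueError("need at least 3 pixels to fit a 3x3 matrix")
        Bf, If = B, I
        if self.subsample is not None and B.shape[0] > self.subsample:
            rng = np.random.default_rng(self.random_state)
            idx = rng.choice(B.shape[0], size=self.subsample, replace=False)
            Bf, If = B[idx], I[idx]
        sv = np.linalg.svd(Bf, compute_uv=False)
        if sv[0] <= 0 or sv[-1] / sv[0] < self.condition_threshold:
            self.degenerate_ = True
            self.matrix_ = np.eye(3)
            logger.warning("degenerate colour correction (rank-deficient background); using identity")
        else:
            self.degenerate_ = False
            self.matrix_, *_ = np.linalg.lstsq(Bf, If, rcond=None)
        self.residual_rms_ = float(np.sqrt(np.mean((I - B @ self.matrix_) ** 2)))
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Apply the fitted matrix per pixel (row vector x matrix), clipped to [0, 1]."""
        if not hasattr(self, "matrix_"):
            raise RuntimeError("ColorCorrector is not fitted")
        X = np.asarray(X, dtype=np.float64)
        out = X.reshape(-1, 3) @ self.matrix_
        return np.clip(out.reshape(X.shape), 0.0, 1.0)


def fit_colour_correction(I: np.ndarray, ta_rgb: np.ndarray, **kwargs) -> ColorCorrector:
    """Fit the 3x3 correction mapping ``ta_rgb`` onto the current frame ``I``."""
    return ColorCorrector(**kwargs).fit(ta_rgb, I)


def apply_colour_correction(ta_rgb: np.ndarray, cc: ColorCorrector) -> np.ndarray:
    return cc.transform(ta_rgb)


def difference_mask(I: np.ndarray, ta_corrected: np.ndarray) -> np.ndarray:
    """Per-pixel mean absolute channel difference between frame and background."""
    I = np.asarray(I, dtype=np.float64)
    T = np.asarray(ta_corrected, dtype=np.float64)
    if I.shape != T.shape:
        raise ValueError(f"shape mismatch: {I.shape} vs {T.shape}")
    return np.abs(I - T).mean(axis=2)


def build_channel_stack(
    I: np.ndarray, ta_grey: np.ndarray, dm: np.ndarray, frame_id: str
) -> ChannelStack:
    """Stack (R, G, B, TA12, DM); the RGB planes are the input, bit-identical."""
    I = np.asarray(I, dtype=np.float64)
    if I.shape[:2] != np.shape(ta_grey) or I.shape[:2] != np.shape(dm):
        raise ValueError(
            f"spatial dimension mismatch: rgb {I.shape[:2]}, ta {np.shape(ta_grey)}, dm {np.shape(dm)}"
        )
    channels = np.dstack([I, np.asarray(ta_grey, dtype=np.float64), np.asarray(dm, dtype=np.float64)])
    return ChannelStack(channels=channels, frame_id=frame_id)


def augment_hsv_stack(
    stack: ChannelStack,
    h_gain: float = 1.0,
    s_gain: float = 1.0,
    v_gain: float = 1.0,
    rng_seed: int | None = None,
) -> ChannelStack:
    """Channel-aware HSV jitter for a 5-channel stack.

    The RGB channels receive standard multiplicative HSV gain jitter (hue
    wraps modulo 1, saturation and value clip to [0, 1]).  The TA12 channel
    is greyscale, so only the value gain applies — the *same* value gain used
    for RGB.  The DM channel is returned bit-identical so the difference
    intensity is fully preserved.

    With ``rng_seed`` given, the supplied gains are half-ranges and the
    applied multipliers are drawn as ``1 + uniform(-1, 1) * gain`` (the usual
    detector-training convention); with ``rng_seed=None`` they are applied as
    direct multipliers.
    """
    if rng_seed is not None:
        rng = np.random.default_rng(rng_seed)
        h_gain, s_gain, v_gain = 1.0 + rng.uniform(-1, 1, size=3) * np.array(
            [h_gain, s_gain, v_gain]
        )
    hsv = skcolor.rgb2hsv(stack.rgb)
    hsv[..., 0] = (hsv[..., 0] * h_gain) % 1.0
    hsv[..., 1] = np.clip(hsv[..., 1] * s_gain, 0.0, 1.0)
    hsv[..., 2] = np.clip(hsv[..., 2] * v_gain, 0.0, 1.0)
    rgb = np.clip(skcolor.hsv2rgb(hsv), 0.0, 1.0)
    ta12 = np.clip(stack.ta12 * v_gain, 0.0, 1.0)
    channels = np.dstack([rgb, ta12, stack.dm.copy()])
    return ChannelStack(channels=channels, frame_id=stack.frame_id)


# --------------------------------------------------------------------------
# Pipeline orchestration


def compute_background_model(
    index: SequenceIndex,
    current: FrameRecord,
    window: int = 12,
    min_window: int = 1,
) -> BackgroundModel:
    """Select the background window for ``current`` and average it."""
    sources = select_background_frames(index, current, count=window, min_count=min_window)
    ta_rgb = temporal_average([load_frame(f) for f in sources])
    return BackgroundModel(
        ta_rgb=ta_rgb,
        ta_grey=to_greyscale(ta_rgb),
        source_frame_ids=[f.frame_id for f in sources],
        modality=current.modality,
        n_sources=len(sources),
    )


def compute_channel_stack(
    index: SequenceIndex,
    current: FrameRecord,
    window: int = 12,
    min_window: int = 1,
    colour_correction: bool = True,
) -> tuple[ChannelStack, BackgroundModel, ColorCorrector | None]:
    """Full per-frame feature pass: background model -> correction -> DM -> stack."""
    bg = compute_background_model(index, current, window, min_window)
    I = load_frame(current)
    cc = None
    ta = bg.ta_rgb
    if colour_correction:
        cc = fit_colour_correction(I, bg.ta_rgb)
        ta = cc.transform(bg.ta_rgb)
    dm = difference_mask(I, ta)
    stack = build_channel_stack(I, bg.ta_grey, dm, current.frame_id)
    return stack, bg, cc


@dataclass
class FeatureManifestEntry:
    frame_id: str
    source_frame_ids: list[str]
    n_sources: int
    matrix: list[list[float]] | None
    residual_rms: float | None
    degenerate: bool | None


def _write_grey_png(arr: np.ndarray, path: Path) -> None:
    Image.fromarray(np.round(np.clip(arr, 0, 1) * 255).astype(np.uint8)).save(path)


def extract_features(
    index: SequenceIndex,
    out_dir: Path | str | None = None,
    window: int = 12,
    min_window: int = 1,
    colour_correction: bool = True,
) -> list[FeatureManifestEntry]:
    """Run the feature pass over a whole sequence, writing TA12/DM PNGs.

    Frames without enough same-modality history are skipped with a warning.
    Feature planes are written as 8-bit PNGs next to each source image
    (suffixes ``.ta12.png`` / ``.dm.png``) unless ``out_dir`` overrides the
    location; a JSON manifest of provenance and fitted matrices is returned
    and written as ``features.json``.
    """
    from traplapse.sequence import BackgroundUnavailable

    entries: list[FeatureManifestEntry] = []
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
    for frame in index.frames:
        try:
            stack, bg, cc = compute_channel_stack(
                index, frame, window, min_window, colour_correction
            )
        except BackgroundUnavailable as exc:
            logger.warning("skipping frame %s: %s", frame.frame_id, exc)
            continue
        base = out_dir if out_dir is not None else frame.path.parent
        _write_grey_png(stack.ta12, base / f"{frame.path.stem}.ta12.png")
        _write_grey_png(stack.dm, base / f"{frame.path.stem}.dm.png")
        entries.append(
            FeatureManifestEntry(
                frame_id=frame.frame_id,
                source_frame_ids=bg.source_frame_ids,
                n_sources=bg.n_sources,
                matrix=None if cc is None else cc.matrix_.tolist(),
                residual_rms=None if cc is None else cc.residual_rms_,
                degenerate=None if cc is None else cc.degenerate_,
            )
        )
    if entries:
        base = out_dir if out_dir is not None else index.frames[0].path.parent
        with open(base / "features.json", "w") as fh:
            json.dump([e.__dict__ for e in entries], fh, indent=1)
    return entries
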