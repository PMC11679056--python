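import numpy as np
import pytest
from PIL import Image

from traplapse.features import ChannelStack
from traplapse.sequence import index_sequence
from traplapse.synth import ObjectSpec, SceneConfig, generate_scene_sequence

FILENAME_PATTERN = "CAM_%Y%m%d_%H%M%S"


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_stack(rng) -> ChannelStack:
    return ChannelStack(rng.uniform(0.05, 0.95, size=(6, 7, 5)), frame_id="fixture")


def write_exif_jpeg(path, dt, colour=(120, 80, 40), size=(8, 8)):
    """Tiny JPEG carrying an EXIF DateTime tag, generated at test time."""
    img = Image.new("RGB", size, colour)
    exif = Image.Exif()
    exif[306] = dt.strftime("%Y:%m:%d %H:%M:%S")  # DateTime
    img.save(path, format="JPEG", exif=exif)


def make_scene(tmp_path, name="scene", **overrides):
    """Render a synthetic sequence to disk and index it."""
    defaults = dict(n_frames=16, seed=7)
    defaults.update(overrides)
    cfg = SceneConfig(**defaults)
    out = tmp_path / name
    frames = generate_scene_sequence(cfg, out_dir=out)
    seq = index_sequence(
        sorted(out.glob("*.png")), cfg.camera_id, "filename_pattern",
        filename_pattern=f"{cfg.camera_id}_%Y%m%d_%H%M%S",
    )
    return cfg, frames, seq


@pytest.fixture
def moving_blob_scene(tmp_path):
    """Static background with one blob entering in the final frame."""
    obj = ObjectSpec(shape="ellipse", size=(14, 10), colour=(0.95, 0.85, 0.1),
                     schedule={15: (32, 24)})
    return make_scene(tmp_path, objects=[obj])
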