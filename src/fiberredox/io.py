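"""Reading/writing sections, ROIs and result tables (TIFF/CSV/JSON)."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from fiberredox.types import ChannelImage
from fiberredox.synthetic_section import SectionParams, SectionTruth

__all__ = [
    "write_channel_tiff",
    "read_channel_tiff",
    "save_section",
]


def write_channel_tiff(image: ChannelImage, path: str | Path) -> None:
    """Write one channel as a 16-bit single-channel TIFF with resolution and
    acquisition metadata embedded in the image description."""
    data = np.clip(np.round(image.pixels), 0, 65535).astype(np.uint16)
    meta = {
        "channel": image.channel,
        "pixel_size_um": image.pixel_size,
        "exposure_ms": image.exposure,
        "gain": image.gain,
    }
    tifffile.imwrite(str(path), data, description=json.dumps(meta))


def read_channel_tiff(
    path: str | Path,
    channel: str | None = None,
    pixel_size: float | None = None,
) -> ChannelImage:
    """Read a single-channel TIFF; metadata from the description JSON unless
    overridden by the arguments."""
    with tifffile.TiffFile(str(path)) as tf:
        data = tf.asarray().astype(float)
        desc = tf.pages[0].description
    meta = {}
    if desc:
        try:
            meta = json.loads(desc)
        except (json.JSONDecodeError, TypeError):
            meta = {}
    return ChannelImage(
        data,
        channel=channel or meta.get("channel", "NADH"),
        pixel_size=pixel_size or meta.get("pixel_size_um", 1.0),
        exposure=meta.get("exposure_ms", 1.0),
        gain=meta.get("gain", 1.0),
    )


def save_section(
    images: dict[str, ChannelImage],
    truth: SectionTruth,
    out_dir: str | Path,
) -> None:
    """Write a simulated section: one TIFF per channel, truth CSVs, params JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for ch, img in images.items():
        write_channel_tiff(img, out / f"{ch}.tif")
    truth.fibers.to_csv(out / "fibers.csv", index=False)
    pd.DataFrame(truth.capillaries, columns=["x", "y"]).to_csv(
        out / "capillaries.csv", index=False
    )
    params = dataclasses.asdict(truth.params)
    params["channel_means"] = {k: dict(v) for k, v in params["channel_means"].items()}
    (out / "params.json").write_text(json.dumps(params, indent=2, default=list))
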