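"""TIFF / CSV / YAML I/O for the bead-assay pipeline."""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import tifffile
import yaml

__all__ = [
    "ImageReadError",
    "read_multichannel_image",
    "write_multichannel_image",
    "write_labels_tiff",
    "write_scene",
    "load_yaml",
    "dump_yaml",
]


class ImageReadError(IOError):
    """Unreadable image file or channel-count/name mismatch."""


def read_multichannel_image(path: str | Path,
                            channel_names: Sequence[str],
                            ) -> dict[str, np.ndarray]:
    """Read a TIFF and split it into named single-channel 2D arrays.

    Axis order is normalized to (channel, row, col): a 2D file is one
    channel; for a 3D file the axis whose length equals the number of
    requested names is taken as the channel axis (leading axis
    preferred).  Bit depth is preserved.
    """
    path = Path(path)
    try:
        arr = tifffile.imread(path)
    except Exception as exc:  # noqa: BLE001 - rewrap with the file name
        raise ImageReadError(f"cannot read TIFF {path}: {exc}") from exc
    n = len(channel_names)
    if arr.ndim == 2:
        planes = arr[None]
    elif arr.ndim == 3:
        if arr.shape[0] == n:
            planes = arr
        elif arr.shape[-1] == n:
            planes = np.moveaxis(arr, -1, 0)
        else:
            raise ImageReadError(
                f"{path}: cannot match {n} channel name(s) "
                f"{list(channel_names)} to TIFF of shape {arr.shape}"
            )
    else:
        raise ImageReadError(f"{path}: unsupported TIFF dimensionality "
                             f"{arr.ndim}")
    if planes.shape[0] != n:
        raise ImageReadError(
            f"{path}: file has {planes.shape[0]} channel(s) but "
            f"{n} name(s) were requested: {list(channel_names)}"
        )
    return {name: planes[i] for i, name in enumerate(channel_names)}


def write_multichannel_image(path: str | Path,
                             channels: Mapping[str, np.ndarray] | Sequence[np.ndarray],
                             ) -> None:
    """Write channels stacked on the leading axis; single channel stays 2D."""
    if isinstance(channels, Mapping):
        arrays = list(channels.values())
    else:
        arrays = list(channels)
    stack = np.stack(arrays) if len(arrays) > 1 else np.asarray(arrays[0])
    kwargs = {}
    if stack.ndim == 3:
        kwargs = {"photometric": "minisblack", "planarconfig": "separate"}
    tifffile.imwrite(Path(path), stack, **kwargs)


def to_uint16(image: np.ndarray) -> np.ndarray:
    """Clip and round a float image into the 16-bit gray-value range."""
    return np.clip(np.rint(image), 0, 65535).astype(np.uint16)


def write_labels_tiff(path: str | Path, labels: np.ndarray) -> None:
    if labels.max() > 65535:
        raise ValueError("more than 65535 labels do not fit 16-bit TIFF")
    tifffile.imwrite(Path(path), labels.astype(np.uint16))


def write_scene(scene, directory: str | Path, stem: str,
                extra_channels: Mapping[str, np.ndarray] | None = None,
                ) -> dict[str, Path]:
    """Serialize a synthetic scene: 16-bit image TIFF (multichannel when
    ``extra_channels`` is given), 16-bit truth-label TIFF, ground-truth
    CSV and config YAML.  Returns the paths written."""
    from .synthetic import scene_config_to_dict

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "image": directory / f"{stem}.tif",
        "labels": directory / f"{stem}_truth_labels.tif",
        "truth": directory / f"{stem}_truth.csv",
        "config": directory / f"{stem}_config.yaml",
    }
    channels = {"ch0": scene.image}
    if extra_channels:
        channels = dict(extra_channels)
    write_multichannel_image(paths["image"],
                             {k: to_uint16(v) for k, v in channels.items()})
    write_labels_tiff(paths["labels"], scene.truth_labels)
    scene.truth_table().to_csv(paths["truth"], index=False)
    dump_yaml(paths["config"], scene_config_to_dict(scene.config))
    return paths


def load_yaml(path: str | Path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        return yaml.safe_load(fh)


def dump_yaml(path: str | Path, data: Mapping) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(dict(data), fh, sort_keys=False)
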