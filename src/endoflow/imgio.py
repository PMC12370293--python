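"""Reading and writing of image stacks, label maps and sidecar files."""

from __future__ import annotations

import hashlib
import json
import pathlib

import numpy as np
import tifffile
import yaml

from .segment import CHANNELS, ImageStack

__all__ = [
    "read_stack",
    "write_stack",
    "write_labels",
    "read_labels",
    "write_dataset",
    "sha256_of",
    "load_yaml_strict",
    "write_provenance",
]


def write_stack(path, stack: ImageStack) -> pathlib.Path:
    """Write a 3-page (nuclei, actin, VE-cadherin) 16-bit TIFF."""
    path = pathlib.Path(path)
    data = np.stack([np.asarray(stack.channel(c)) for c in CHANNELS])
    data = np.clip(np.rint(data), 0, 65535).astype(np.uint16)
    tifffile.imwrite(
        path,
        data,
        photometric="minisblack",
        metadata={"axes": "CYX", "channels": list(CHANNELS), "pixel_size_um": stack.pixel_size},
    )
    return path


def read_stack(path, pixel_size: float | None = None, channel_order=CHANNELS) -> ImageStack:
    """Read a multi-page TIFF into an ImageStack.

    ``channel_order`` maps TIFF pages onto (nuclei, actin, ve_cadherin)
    when the file was written in a different order.
    """
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
    if data.ndim != 3 or data.shape[0] != 3:
        raise ValueError(f"{path}: expected a 3-channel stack, got shape {data.shape}")
    if pixel_size is None:
        pixel_size = float(meta.get("pixel_size_um", 1.0))
    by_name = dict(zip(channel_order, data.astype(float)))
    return ImageStack(
        nuclei=by_name["nuclei"],
        actin=by_name["actin"],
        ve_cadherin=by_name["ve_cadherin"],
        pixel_size=pixel_size,
    )


def write_labels(path, labels: np.ndarray) -> pathlib.Path:
    path = pathlib.Path(path)
    if labels.max() > 65535:
        raise ValueError("label ids exceed 16-bit range")
    tifffile.imwrite(path, labels.astype(np.uint16))
    return path


def read_labels(path) -> np.ndarray:
    return tifffile.imread(path).astype(np.int32)


def write_dataset(stem, stack: ImageStack, truth) -> dict[str, pathlib.Path]:
    """Write one synthetic field: stack + truth label maps + truth tables."""
    stem = pathlib.Path(stem)
    paths = {
        "stack": write_stack(stem.with_suffix(".tif"), stack),
        "cell_labels": write_labels(stem.parent / f"{stem.name}_cells.tif", truth.cell_labels),
        "nuclei_labels": write_labels(stem.parent / f"{stem.name}_nuclei.tif", truth.nuclei_labels),
    }
    cells_csv = stem.parent / f"{stem.name}_truth_cells.csv"
    truth.cells.to_csv(cells_csv)
    paths["truth_cells"] = cells_csv
    fingers_csv = stem.parent / f"{stem.name}_truth_fingers.csv"
    truth.fingers.to_csv(fingers_csv, index=False)
    paths["truth_fingers"] = fingers_csv
    return paths


def sha256_of(path) -> str:
    hsh = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            hsh.update(chunk)
    return hsh.hexdigest()


def load_yaml_strict(path, allowed_keys: set[str]) -> dict:
    """Load a YAML mapping, rejecting unknown top-level keys."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a mapping at top level")
    unknown = set(data) - allowed_keys
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    return data


def write_provenance(path, config_dict: dict, seed: int, artifacts: list[str]) -> pathlib.Path:
    """Sidecar with everything needed to re-run an artifact."""
    from . import __version__

    payload = json.dumps(config_dict, sort_keys=True, default=str)
    sidecar = {
        "config_sha256": hashlib.sha256(payload.encode()).hexdigest(),
        "seed": seed,
        "package_version": __version__,
        "artifacts": artifacts,
    }
    path = pathlib.Path(path)
    path.write_text(json.dumps(sidecar, indent=2))
    return path
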