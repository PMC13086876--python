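"""Reading and writing pipeline artifacts.

Fields travel as multi-page grayscale TIFF (one page per channel, in
the declared channel order) with a JSON sidecar recording the channel
map, bit depth and generator config — the pipeline never relies on
embedded TIFF metadata.  Label maps are 16-bit TIFF; tables are UTF-8
CSV with a header row and '.' decimals.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import tifffile

from .segment import LabelMap
from .simgen import CHANNEL_ORDER, FieldImage, GroundTruth, SimulationConfig

__all__ = [
    "write_field",
    "read_field",
    "write_label_map",
    "read_label_map",
    "write_truth",
    "write_json",
]


def write_field(path, field: FieldImage, config: SimulationConfig | None = None) -> None:
    """Write a field as multi-page TIFF plus a JSON sidecar.

    Pages follow ``CHANNEL_ORDER`` restricted to the channels present;
    the sidecar (``<stem>.json``) records the channel map, bit depth,
    pixel size and, when given, the full simulation config.
    """
    path = Path(path)
    roles = [r for r in CHANNEL_ORDER if r in field.channels]
    extra = sorted(set(field.channels) - set(roles))
    roles += extra
    stack = np.stack([field.channels[r] for r in roles])
    tifffile.imwrite(path, stack, photometric="minisblack")
    sidecar = {
        "channels": roles,
        "bit_depth": field.bit_depth,
        "pixel_size": field.pixel_size,
    }
    if config is not None:
        sidecar["config"] = _config_dict(config)
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_field(path, channel_order: Sequence[str] | None = None) -> FieldImage:
    """Read a multi-page TIFF field.

    The channel order comes from the sidecar JSON when present, else
    from ``channel_order``; one of the two is required.
    """
    path = Path(path)
    stack = tifffile.imread(path)
    if stack.ndim == 2:
        stack = stack[None]
    sidecar = path.with_suffix(".json")
    meta: dict = {}
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    roles = list(channel_order or meta.get("channels") or [])
    if not roles:
        raise ValueError(
            f"no channel order: pass channel_order or provide {sidecar.name}"
        )
    if len(roles) != stack.shape[0]:
        raise ValueError(
            f"channel order names {len(roles)} channels but TIFF has {stack.shape[0]} pages"
        )
    bit_depth = int(meta.get("bit_depth") or (16 if stack.dtype.itemsize > 1 else 8))
    return FieldImage(
        channels={r: stack[i] for i, r in enumerate(roles)},
        pixel_size=meta.get("pixel_size"),
        bit_depth=bit_depth,
    )


def write_label_map(path, labels: LabelMap | np.ndarray) -> None:
    arr = labels.label_image if isinstance(labels, LabelMap) else np.asarray(labels)
    if arr.max() > np.iinfo(np.uint16).max:
        raise ValueError("too many labels for a 16-bit label TIFF")
    tifffile.imwrite(Path(path), arr.astype(np.uint16))


def read_label_map(path) -> LabelMap:
    return LabelMap(tifffile.imread(Path(path)).astype(np.int32))


def write_truth(directory, truth: GroundTruth, stem: str = "truth") -> None:
    """Write ground-truth label maps (16-bit TIFF) and parameters (JSON)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_label_map(directory / f"{stem}_nuclei.tif", truth.nucleus_labels)
    write_label_map(directory / f"{stem}_nucleoli.tif", truth.nucleolus_labels)
    meta = {
        "enrichment": {str(k): v for k, v in truth.enrichment.items()},
        "phase": {str(k): v for k, v in truth.phase.items()},
        "axes": {str(k): list(v) for k, v in truth.axes.items()},
        "config": _config_dict(truth.config),
    }
    write_json(directory / f"{stem}.json", meta)


def write_json(path, obj: Mapping) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonable))


def _config_dict(config: SimulationConfig) -> dict:
    return dataclasses.asdict(config)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
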