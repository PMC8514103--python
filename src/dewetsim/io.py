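"""File I/O: masks (TIFF/PNG), vector-field CSV grids, traces, and configs."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile
import yaml

from dewetsim.fem import ElasticMaterial, FoundationModel
from dewetsim.traction import BinaryMask, VectorField2D


def write_mask(mask: BinaryMask, path) -> None:
    """Write a binary mask as an 8-bit TIFF (255 = tissue)."""
    tifffile.imwrite(str(path), mask.data.astype(np.uint8) * 255)


def read_mask(path, pixel_size: float = 1.0) -> BinaryMask:
    data = tifffile.imread(str(path))
    return BinaryMask(data=data > 0, pixel_size=pixel_size)


def write_field(field: VectorField2D, tx_path, ty_path) -> None:
    """Write the two component grids as plain CSV matrices."""
    np.savetxt(tx_path, field.tx, delimiter=",")
    np.savetxt(ty_path, field.ty, delimiter=",")


def read_field(tx_path, ty_path) -> VectorField2D:
    return VectorField2D(
        tx=np.loadtxt(tx_path, delimiter=","), ty=np.loadtxt(ty_path, delimiter=",")
    )


def load_config(path) -> dict:
    """Load a model configuration from YAML or JSON."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".json",):
        return json.loads(text)
    return yaml.safe_load(text)


def material_from_config(cfg: dict) -> ElasticMaterial:
    return ElasticMaterial(
        E=float(cfg.get("E", 1.0)),
        nu=float(cfg.get("nu", 0.46)),
        constitutive_mode=cfg.get("constitutive_mode", "printed_lame"),
    )


def foundation_from_config(cfg: dict) -> FoundationModel:
    return FoundationModel(
        k=float(cfg.get("k", 5e-3)),
        alpha=float(cfg.get("alpha", 1.0)),
        c=float(cfg.get("c", 0.0)),
    )
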