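"""Readers and writers for every format the pipeline touches.

Multi-page 16-bit TIFF stacks with a JSON sidecar for stage metadata, SWC
neuron morphologies, CSV tables, and YAML/JSON configuration.  Round trips
are lossless for 16-bit voxels and SWC node tables, and every artifact
embeds the config hash and seed so reruns are bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .acquisition import TileStack
from .phantom import NeuronTreeSWC, SpikeTrackData

__all__ = [
    "write_tile_stack",
    "read_tile_stack",
    "write_swc",
    "read_swc",
    "write_spike_track_csv",
    "read_spike_track_csv",
    "load_config",
    "dump_config",
    "config_hash",
    "RunManifest",
]


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def write_tile_stack(path: str | Path, stack: TileStack) -> Path:
    """Write voxels as multi-page TIFF and metadata as a ``.json`` sidecar."""
    path = Path(path)
    tifffile.imwrite(path, stack.voxels, photometric="minisblack")
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps(_jsonable(stack.meta), indent=1, sort_keys=True))
    return path


def read_tile_stack(path: str | Path) -> TileStack:
    """Read a stack written by :func:`write_tile_stack` (lossless)."""
    path = Path(path)
    try:
        voxels = tifffile.imread(path)
    except Exception as exc:  # tifffile raises several types on corruption
        raise ValueError(f"cannot parse TIFF {path}: {exc}") from exc
    if voxels.ndim == 2:
        voxels = voxels[None]
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return TileStack(voxels=np.asarray(voxels, dtype=np.uint16), meta=meta)


def write_swc(path: str | Path, tree: NeuronTreeSWC, comment: str = "") -> Path:
    """Standard 7-column SWC with ``#`` comments."""
    path = Path(path)
    lines = []
    if comment:
        for ln in comment.splitlines():
            lines.append(f"# {ln}")
    lines.append("# id type x y z radius parent")
    for k in range(tree.n_nodes()):
        x, y, z = tree.xyz_um[k]
        # shortest exact repr keeps the round trip lossless
        lines.append(
            f"{int(tree.ids[k])} {int(tree.type_code[k])} "
            f"{float(x)!r} {float(y)!r} {float(z)!r} "
            f"{float(tree.radius_um[k])!r} {int(tree.parent[k])}"
        )
    path.write_text("\n".join(lines) + "\n")
    return path


def read_swc(path: str | Path) -> NeuronTreeSWC:
    path = Path(path)
    ids, types, xyz, radii, parents = [], [], [], [], []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 7:
            raise ValueError(f"{path}:{lineno}: expected 7 SWC columns, got {len(parts)}")
        try:
            ids.append(int(parts[0]))
            types.append(int(parts[1]))
            xyz.append([float(parts[2]), float(parts[3]), float(parts[4])])
            radii.append(float(parts[5]))
            parents.append(int(parts[6]))
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: malformed SWC line: {exc}") from exc
    tree = NeuronTreeSWC(
        ids=np.array(ids, int),
        type_code=np.array(types, int),
        xyz_um=np.array(xyz, float),
        radius_um=np.array(radii, float),
        parent=np.array(parents, int),
    )
    tree.validate()
    return tree


def write_spike_track_csv(path: str | Path, data: SpikeTrackData) -> Path:
    df = pd.DataFrame(
        {"distance_um": data.distance_um, "is_narrow": data.is_narrow.astype(int)}
    )
    if data.track_id is not None:
        df["track_id"] = data.track_id
    df.to_csv(path, index=False)
    return Path(path)


def read_spike_track_csv(path: str | Path) -> SpikeTrackData:
    df = pd.read_csv(path)
    for col in ("distance_um", "is_narrow"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    return SpikeTrackData(
        distance_um=df["distance_um"].to_numpy(float),
        is_narrow=df["is_narrow"].to_numpy() != 0,
        track_id=df["track_id"].to_numpy(int) if "track_id" in df.columns else None,
    )


def load_config(path: str | Path) -> dict:
    """YAML or JSON configuration (YAML is a superset; both parse here)."""
    text = Path(path).read_text()
    try:
        cfg = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ValueError(f"cannot parse config {path}: {exc}") from exc
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a mapping")
    return cfg


def dump_config(path: str | Path, config: dict) -> Path:
    Path(path).write_text(yaml.safe_dump(_jsonable(config), sort_keys=True))
    return Path(path)


def config_hash(config) -> str:
    """Stable short hash of a configuration (dataclass or mapping)."""
    canon = json.dumps(_jsonable(config), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


@dataclasses.dataclass
class RunManifest:
    """Record of one pipeline run: config identity, seed, per-tile records."""

    config_hash: str
    seed: int
    passes: list[dict]
    tiles: list[dict]
    metrics: dict

    def to_json(self) -> str:
        return json.dumps(_jsonable(dataclasses.asdict(self)), indent=1, sort_keys=True)

    def write(self, path: str | Path) -> Path:
        Path(path).write_text(self.to_json())
        return Path(path)

    @classmethod
    def read(cls, path: str | Path) -> "RunManifest":
        d = json.loads(Path(path).read_text())
        return cls(**d)
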