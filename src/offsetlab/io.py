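"""Plain-text output formats: TSV tables, JSON sidecars, run manifests."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .gf import GFModel
from .landscape import EnvField, MetapopulationMap, env_table
from .metrics import OffsetMatrix

__all__ = [
    "write_env_table",
    "read_env_table",
    "write_offset_matrix",
    "read_offset_matrix",
    "write_turnover_curves",
    "write_manifest",
]


def write_env_table(path: str | Path, grid: MetapopulationMap, fields: list[EnvField]) -> None:
    """Deme-by-environment TSV plus a sidecar JSON recording causal flags."""
    path = Path(path)
    env_table(grid, fields).to_csv(path, sep="\t", index=False)
    sidecar = {f.name: bool(f.causal) for f in fields}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps({"causal": sidecar}, indent=1))


def read_env_table(path: str | Path) -> tuple[pd.DataFrame, dict[str, bool]]:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    sidecar = path.with_suffix(path.suffix + ".json")
    causal = json.loads(sidecar.read_text())["causal"] if sidecar.exists() else {}
    return df, causal


def write_offset_matrix(path: str | Path, matrix: OffsetMatrix) -> None:
    path = Path(path)
    matrix.to_frame().to_csv(path, sep="\t", index_label="deme_id")
    meta = {"metric": matrix.metric, "subset": matrix.subset, **matrix.metadata}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))


def read_offset_matrix(path: str | Path) -> OffsetMatrix:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col="deme_id")
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    metric = meta.pop("metric")
    subset = meta.pop("subset")
    return OffsetMatrix(metric=metric, subset=subset, values=df.to_numpy(), metadata=meta)


def write_turnover_curves(path: str | Path, model: GFModel) -> None:
    """Long-format TSV of the aggregate turnover curves (predictor, knot, ci)."""
    rows = []
    for name, tf in model.aggregates.items():
        for knot, ci in zip(tf.knots, tf.ci):
            rows.append({"predictor": name, "knot": knot, "ci": ci})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_dir: str | Path, extra: dict | None = None) -> Path:
    """JSON manifest listing every artifact in ``out_dir`` with its checksum."""
    out_dir = Path(out_dir)
    files = sorted(
        p for p in out_dir.rglob("*") if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "artifacts": [
            {"path": str(p.relative_to(out_dir)), "sha256": _sha256(p), "bytes": p.stat().st_size}
            for p in files
        ],
    }
    if extra:
        manifest.update(extra)
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1, default=_json_default))
    return path


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
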