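"""Readers and writers for panels, schemes, coordinates, and reports.

Panel format: comma-delimited, header row of indicator codes, first
column the region label, missing cells empty. Scheme format: a table
with columns ``code, dimension, attribute`` (attribute ``P``/``N`` or
``positive``/``negative``) and optional ``description, units``.
Coordinates: a ``label, x, y`` table, or a GeoJSON file of point
features with a label property.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .core import IndicatorDefinition, IndicatorPanel

PathLike = Union[str, Path]

_ATTR_ALIASES = {
    "p": "positive",
    "positive": "positive",
    "n": "negative",
    "negative": "negative",
}


def read_scheme(path: PathLike) -> list[IndicatorDefinition]:
    """Read an indicator scheme table (code, dimension, attribute[, ...])."""
    df = pd.read_csv(path, dtype=str).fillna("")
    df.columns = [c.strip().lower() for c in df.columns]
    required = {"code", "dimension", "attribute"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"scheme file lacks column(s): {', '.join(sorted(missing))}")
    scheme = []
    for _, row in df.iterrows():
        attr = _ATTR_ALIASES.get(row["attribute"].strip().lower())
        if attr is None:
            raise ValueError(
                f"indicator {row['code']!r}: attribute must be P/N or "
                f"positive/negative, got {row['attribute']!r}"
            )
        scheme.append(
            IndicatorDefinition(
                code=row["code"].strip(),
                dimension=row["dimension"].strip().lower(),
                attribute=attr,
                description=row.get("description", ""),
                units=row.get("units", ""),
            )
        )
    return scheme


def write_scheme(scheme: list[IndicatorDefinition], path: PathLike) -> None:
    pd.DataFrame(
        [
            {
                "code": d.code,
                "dimension": d.dimension,
                "attribute": "P" if d.attribute == "positive" else "N",
                "description": d.description,
                "units": d.units,
            }
            for d in scheme
        ]
    ).to_csv(path, index=False)


def read_panel(path: PathLike, scheme_path: PathLike) -> IndicatorPanel:
    """Read a panel table against its scheme; empty cells become missing."""
    scheme = read_scheme(scheme_path)
    df = pd.read_csv(path)
    header = [str(c).strip() for c in df.columns[1:]]
    codes = [d.code for d in scheme]
    if header != codes:
        extra = [c for c in header if c not in codes]
        absent = [c for c in codes if c not in header]
        parts = []
        if extra:
            parts.append(f"unknown code(s) in panel header: {', '.join(extra)}")
        if absent:
            parts.append(f"scheme code(s) absent from panel: {', '.join(absent)}")
        if not parts:
            parts.append("panel header order differs from the scheme order")
        raise ValueError("; ".join(parts))
    labels = df.iloc[:, 0].astype(str).tolist()
    body = df.iloc[:, 1:].apply(pd.to_numeric, errors="raise")
    values = body.to_numpy(dtype=float)
    mask = np.isnan(values)
    return IndicatorPanel(labels, scheme, values, mask)


def write_panel(panel: IndicatorPanel, path: PathLike, *, float_format: str = "%.17g") -> None:
    """Write a panel; masked cells are written empty."""
    values = panel.values.astype(object)
    values[panel.missing_mask] = ""
    df = pd.DataFrame(values, columns=panel.codes)
    df.insert(0, "region", panel.region_labels)
    out = df.copy()
    for c in panel.codes:
        out[c] = [
            "" if v == "" else float_format % v for v in df[c]
        ]
    out.to_csv(path, index=False)


def read_coords(path: PathLike) -> tuple[list[str], np.ndarray]:
    """Read region coordinates from a delimited table or GeoJSON points."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".json", ".geojson") or text.lstrip().startswith("{"):
        data = json.loads(text)
        labels, pts = [], []
        for feat in data.get("features", []):
            geom = feat.get("geometry", {})
            if geom.get("type") != "Point":
                raise ValueError("coordinate GeoJSON must contain Point features")
            props = feat.get("properties", {})
            label = props.get("label") or props.get("name") or props.get("region")
            if label is None:
                raise ValueError("each GeoJSON feature needs a label/name property")
            labels.append(str(label))
            pts.append(geom["coordinates"][:2])
        return labels, np.asarray(pts, dtype=float)
    df = pd.read_csv(path)
    labels = df.iloc[:, 0].astype(str).tolist()
    coords = df.iloc[:, 1:3].to_numpy(dtype=float)
    return labels, coords


def write_coords(labels: list[str], coords: np.ndarray, path: PathLike) -> None:
    pd.DataFrame({"region": labels, "x": coords[:, 0], "y": coords[:, 1]}).to_csv(
        path, index=False
    )


def sha256_of(path: PathLike) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


@dataclasses.dataclass
class RunManifest:
    """Provenance record sufficient to reproduce a run bit-for-bit."""

    input_hashes: dict[str, str]
    config: dict
    seeds: dict[str, int]
    package_version: str
    timestamp: str = ""

    def __post_init__(self) -> None:
        if not self.timestamp:
            self.timestamp = datetime.now(timezone.utc).isoformat()

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def write(self, path: PathLike) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))
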