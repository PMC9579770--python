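"""Landmark file formats, specimen tables and dataset assembly.

Supported landmark dialects
---------------------------
* ``csv`` — header row then one ``label,x,y,z`` row per landmark.
* ``fcsv`` — 3D Slicer markups fiducial file: comment header lines
  starting with ``#`` (including a ``CoordinateSystem`` field), then rows
  ``id,x,y,z,ow,ox,oy,oz,vis,sel,lock,label,desc,assoc``. Coordinates
  declared LPS are converted to the package's single internal frame (RAS:
  x and y are negated).
* ``tps`` — ``LM3=<k>`` blocks of ``x y z`` lines, optional ``ID=`` line.

Landmark order is taken from file order; all indices are 0-based.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import LandmarkConfiguration, SchemeError, ShapeDataset

__all__ = [
    "ParseError",
    "read_landmarks",
    "write_landmarks",
    "read_specimen_table",
    "load_dataset",
]


class ParseError(ValueError):
    """Malformed landmark or table file (carries the offending line)."""

    def __init__(self, path, line_no, msg):
        super().__init__(f"{path}:{line_no}: {msg}")
        self.path = str(path)
        self.line_no = line_no


def _infer_dialect(path: Path) -> str:
    suffix = path.suffix.lower().lstrip(".")
    if suffix in ("fcsv", "tps", "csv"):
        return suffix
    raise ValueError(f"cannot infer landmark dialect from {path.name!r}")


def read_landmarks(path, dialect: str | None = None) -> LandmarkConfiguration:
    """Read one specimen's landmark configuration."""
    path = Path(path)
    dialect = dialect or _infer_dialect(path)
    if dialect == "csv":
        return _read_csv(path)
    if dialect == "fcsv":
        return _read_fcsv(path)
    if dialect == "tps":
        return _read_tps(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_csv(path: Path) -> LandmarkConfiguration:
    lines = path.read_text().splitlines()
    if not lines:
        raise ParseError(path, 1, "empty file")
    header = [h.strip().lower() for h in lines[0].split(",")]
    try:
        cols = [header.index(c) for c in ("label", "x", "y", "z")]
    except ValueError as exc:
        raise ParseError(path, 1, f"header must name label,x,y,z ({exc})") from None
    labels, coords = [], []
    for ln, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split(",")
        if len(parts) < 4:
            raise ParseError(path, ln, "expected label,x,y,z")
        try:
            coords.append([float(parts[c]) for c in cols[1:]])
        except ValueError:
            raise ParseError(path, ln, f"non-numeric coordinate in {line!r}") from None
        labels.append(parts[cols[0]].strip())
    return LandmarkConfiguration(np.array(coords), labels)


def _read_fcsv(path: Path) -> LandmarkConfiguration:
    lines = path.read_text().splitlines()
    system = "LPS"
    data_start = 0
    columns = None
    for ln, line in enumerate(lines, start=1):
        if line.startswith("#"):
            stripped = line.lstrip("#").strip()
            if stripped.lower().startswith("coordinatesystem"):
                value = stripped.split("=", 1)[1].strip()
                system = {"0": "LPS", "1": "RAS"}.get(value, value.upper())
            if stripped.lower().startswith("columns"):
                columns = [c.strip() for c in stripped.split("=", 1)[1].split(",")]
            data_start = ln
        else:
            break
    if columns is None:
        columns = ["id", "x", "y", "z", "ow", "ox", "oy", "oz", "vis", "sel", "lock", "label", "desc", "associatedNodeID"]
    try:
        ix, iy, iz = columns.index("x"), columns.index("y"), columns.index("z")
        ilabel = columns.index("label")
    except ValueError:
        raise ParseError(path, data_start, "columns header must name x,y,z,label") from None
    labels, coords = [], []
    for ln, line in enumerate(lines[data_start:], start=data_start + 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split(",")
        if len(parts) <= max(ix, iy, iz):
            raise ParseError(path, ln, "too few comma-separated fields")
        try:
            xyz = [float(parts[ix]), float(parts[iy]), float(parts[iz])]
        except ValueError:
            raise ParseError(path, ln, f"non-numeric coordinate in {line!r}") from None
        coords.append(xyz)
        labels.append(parts[ilabel].strip() if len(parts) > ilabel else f"F-{ln}")
    coords = np.array(coords)
    if system == "LPS":
        # internal frame is RAS
        coords[:, 0] *= -1
        coords[:, 1] *= -1
    elif system != "RAS":
        raise ParseError(path, 1, f"unknown coordinate system {system!r}")
    return LandmarkConfiguration(coords, labels)


def _read_tps(path: Path) -> LandmarkConfiguration:
    lines = path.read_text().splitlines()
    count = None
    coords = []
    header_line = 1
    for ln, line in enumerate(lines, start=1):
        s = line.strip()
        if not s:
            continue
        upper = s.upper()
        if upper.startswith("LM3=") or upper.startswith("LM="):
            if count is not None:
                break  # only the first block of a multi-specimen file
            count = int(s.split("=", 1)[1])
            header_line = ln
        elif upper.startswith(("ID=", "IMAGE=", "SCALE=")):
            continue
        elif count is not None:
            parts = s.split()
            if len(parts) != 3:
                raise ParseError(path, ln, f"expected 3 coordinates, got {len(parts)}")
            try:
                coords.append([float(v) for v in parts])
            except ValueError:
                raise ParseError(path, ln, f"non-numeric coordinate in {s!r}") from None
    if count is None:
        raise ParseError(path, 1, "no LM3= block found")
    if len(coords) != count:
        raise ParseError(
            path,
            header_line,
            f"LM3={count} but {len(coords)} coordinate rows found",
        )
    return LandmarkConfiguration(
        np.array(coords), [f"lm{i}" for i in range(count)]
    )


def write_landmarks(config: LandmarkConfiguration, path, dialect: str | None = None) -> None:
    """Write a configuration in the named dialect (round-trips with
    :func:`read_landmarks` to 1e-9 or better)."""
    path = Path(path)
    dialect = dialect or _infer_dialect(path)
    if dialect == "csv":
        lines = ["label,x,y,z"] + [
            f"{lab},{x:.12g},{y:.12g},{z:.12g}"
            for lab, (x, y, z) in zip(config.labels, config.coords)
        ]
        path.write_text("\n".join(lines) + "\n")
    elif dialect == "fcsv":
        lines = [
            "# Markups fiducial file version = 4.11",
            "# CoordinateSystem = RAS",
            "# columns = id,x,y,z,ow,ox,oy,oz,vis,sel,lock,label,desc,associatedNodeID",
        ]
        for i, (lab, (x, y, z)) in enumerate(zip(config.labels, config.coords)):
            lines.append(
                f"vtkMRMLMarkupsFiducialNode_{i},{x:.12g},{y:.12g},{z:.12g},"
                f"0,0,0,1,1,1,0,{lab},,"
            )
        path.write_text("\n".join(lines) + "\n")
    elif dialect == "tps":
        lines = [f"LM3={config.k}"]
        lines += [f"{x:.12g} {y:.12g} {z:.12g}" for x, y, z in config.coords]
        lines.append("ID=0")
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_specimen_table(path, check_files: bool = True) -> pd.DataFrame:
    """Read the specimen table (CSV): id, species, age, landmark_path,
    optional mesh_path and family. Validates unique ids, positive integer
    ages and (optionally) that the referenced files exist."""
    path = Path(path)
    table = pd.read_csv(path)
    required = {"id", "species", "age", "landmark_path"}
    missing = required - set(table.columns)
    if missing:
        raise SchemeError(f"specimen table misses columns: {sorted(missing)}")
    if table["id"].duplicated().any():
        dup = table.loc[table["id"].duplicated(), "id"].iloc[0]
        raise SchemeError(f"duplicate specimen id {dup!r}")
    ages = table["age"]
    if not np.issubdtype(ages.dtype, np.number) or (ages <= 0).any() or (ages != ages.astype(int)).any():
        raise SchemeError("ages must be positive integers (days)")
    table["age"] = ages.astype(int)
    if check_files:
        root = path.parent
        for p in table["landmark_path"]:
            f = Path(p)
            if not f.is_absolute():
                f = root / f
            if not f.exists():
                raise FileNotFoundError(f"landmark file not found: {f}")
    return table


def load_dataset(table, dialect: str | None = None, root=None) -> ShapeDataset:
    """Assemble a ShapeDataset from a specimen table.

    ``table`` may be a path to a specimen-table CSV or a DataFrame with
    the same columns; relative landmark paths resolve against ``root``
    (defaulting to the table's directory).
    """
    if not isinstance(table, pd.DataFrame):
        root = Path(root) if root is not None else Path(table).parent
        table = read_specimen_table(table)
    else:
        root = Path(root) if root is not None else Path(".")
    configs = []
    labels = None
    for _, row in table.iterrows():
        p = Path(row["landmark_path"])
        if not p.is_absolute():
            p = root / p
        cfg = read_landmarks(p, dialect)
        if labels is None:
            labels = cfg.labels
        elif cfg.k != len(labels):
            raise SchemeError(
                f"specimen {row['id']!r} has {cfg.k} landmarks; expected {len(labels)}"
            )
        configs.append(cfg.coords)
    meta = table[[c for c in ("id", "species", "age", "family") if c in table.columns]].copy()
    return ShapeDataset(np.array(configs), meta, labels or [])
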