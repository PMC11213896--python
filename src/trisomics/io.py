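"""File formats: TSV matrices, sample tables, GMT gene sets, YAML config.

Matrices are tab-delimited, features x samples, first column the feature id,
"NA" for missing entries.  Output tables carry a leading ``#`` comment line
recording the producing stage and seed.  TSV (not CSV) throughout: analyte
names may contain commas.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .matrix import OmicsMatrix
from .stats import GeneSet

__all__ = ["read_matrix", "write_matrix", "read_sample_table", "write_sample_table",
           "read_gmt", "load_config", "save_config"]

_FLOAT_FMT = "%.10g"


def write_matrix(m: OmicsMatrix, path, stage: str = "", seed=None) -> None:
    """Write a matrix as TSV with NA for missing and a provenance comment."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# layer={m.layer} stage={stage} seed={seed}\n")
        fh.write("feature_id\t" + "\t".join(map(str, m.sample_ids)) + "\n")
        arr = m.values.to_numpy(float)
        for fid, row in zip(m.feature_ids, arr):
            cells = ["NA" if np.isnan(v) else _FLOAT_FMT % v for v in row]
            fh.write(str(fid) + "\t" + "\t".join(cells) + "\n")


def read_matrix(path, layer: str = "", units: str = "") -> OmicsMatrix:
    """Read a TSV matrix; errors report the offending line number."""
    path = Path(path)
    header = None
    feature_ids: list[str] = []
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields[1:]
                if len(set(header)) != len(header):
                    raise ValueError(f"{path}:{lineno}: duplicate sample ids")
                continue
            if len(fields) != len(header) + 1:
                raise ValueError(
                    f"{path}:{lineno}: ragged row ({len(fields)} fields, expected "
                    f"{len(header) + 1})")
            feature_ids.append(fields[0])
            parsed = []
            for j, cell in enumerate(fields[1:], start=2):
                if cell == "NA" or cell == "":
                    parsed.append(np.nan)
                else:
                    try:
                        parsed.append(float(cell))
                    except ValueError as exc:
                        raise ValueError(
                            f"{path}:{lineno}: non-numeric cell in column {j}: {cell!r}"
                        ) from exc
            rows.append(parsed)
    if header is None:
        raise ValueError(f"{path}: empty matrix file")
    if len(set(feature_ids)) != len(feature_ids):
        raise ValueError(f"{path}: duplicate feature ids")
    values = pd.DataFrame(rows, index=pd.Index(feature_ids, name="feature_id"),
                          columns=header)
    return OmicsMatrix(values, layer or path.stem, units)


def write_sample_table(samples: pd.DataFrame, path, stage: str = "", seed=None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# stage={stage} seed={seed}\n")
        samples.to_csv(fh, sep="\t")


def read_sample_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0, comment="#")


def read_gmt(path, keep_description: bool = True) -> list[GeneSet]:
    """Read gene sets from a GMT file (name, description, members...)."""
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            name, desc = fields[0], fields[1]
            members = [m for m in fields[2:] if m]
            unique = list(dict.fromkeys(members))
            if len(unique) != len(members):
                import warnings
                warnings.warn(f"{path}:{lineno}: duplicate members in set {name!r} deduplicated")
            sets.append(GeneSet(name=name, members=frozenset(unique),
                                description=desc if keep_description else ""))
    return sets


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


def save_config(cfg: dict, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def write_json(obj, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not serialisable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=default)
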