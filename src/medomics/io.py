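"""Reading study tables and omics layers; writing result tables.

Study tables are delimited text with a header row; a YAML (or dict) column
mapping names the exposure, outcome, covariate, and cohort columns. Omics
layers are one delimited file per layer: first column sample ids, remaining
columns features. Gzipped files are read transparently.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .containers import MultiOmics, StudyFrame

log = logging.getLogger(__name__)


def _sep_for(path: Path) -> str:
    name = path.name.removesuffix(".gz")
    return "\t" if name.endswith((".tsv", ".txt")) else ","


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config must be a YAML mapping")
    return cfg


def read_study(path, mapping: Mapping) -> StudyFrame:
    """Read a study table given a column mapping.

    ``mapping`` needs keys ``exposure``, ``outcome``, ``cohort``, and
    optionally ``covariates`` (list) and ``sample_id`` (defaults to the
    first column). Rows with any missing mapped value are dropped
    (complete-case) with a logged count.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    id_col = mapping.get("sample_id", df.columns[0])
    covs = list(mapping.get("covariates", []))
    needed = [id_col, mapping["exposure"], mapping["outcome"],
              mapping["cohort"], *covs]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValueError(f"missing mapped columns: {missing}")
    if df[id_col].duplicated().any():
        dup = df.loc[df[id_col].duplicated(), id_col].tolist()
        raise ValueError(f"duplicate sample ids: {dup[:5]}")
    df = df.set_index(id_col)
    complete = df[needed[1:]].notna().all(axis=1)
    if (~complete).any():
        log.info("dropping %d incomplete rows", int((~complete).sum()))
        df = df[complete]
    return StudyFrame(
        exposure=df[mapping["exposure"]].astype(float),
        outcome=df[mapping["outcome"]].astype(float),
        covariates=df[covs],
        cohort=df[mapping["cohort"]].astype(str),
    )


def read_layer(path) -> pd.DataFrame:
    """Read one omics layer (samples × features, first column sample ids)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0,
                     float_precision="round_trip")
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError(f"{path}: empty matrix")
    try:
        mat = df.astype(float)
    except (TypeError, ValueError):
        for j, col in enumerate(df.columns):
            bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
            if bad.any():
                i = int(np.where(bad)[0][0])
                raise ValueError(
                    f"{path}: non-numeric cell at row {df.index[i]!r}, "
                    f"column {col!r}"
                ) from None
        raise
    return mat


def read_multiomics(paths: Mapping[str, str], sample_ids=None) -> MultiOmics:
    layers = {}
    for name, p in paths.items():
        mat = read_layer(p)
        if sample_ids is not None:
            absent = [s for s in sample_ids if s not in mat.index]
            if absent:
                raise ValueError(
                    f"layer {name!r}: samples missing: {absent[:5]}"
                )
            mat = mat.loc[sample_ids]
        layers[name] = mat
    return MultiOmics(layers)


def write_table(df: pd.DataFrame, path, precision: int | None = None,
                index: bool = False) -> None:
    """Write a result table as TSV.

    With ``precision`` set, floats are formatted to that many significant
    digits (diff-friendly result files); without it, full precision is kept
    so that read(write(x)) round-trips exactly.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fmt = f"%.{precision}g" if precision is not None else "%.17g"
    df.to_csv(path, sep="\t", float_format=fmt, index=index)


def write_layer(mat: pd.DataFrame, path) -> None:
    write_table(mat, path, precision=None, index=True)


def write_provenance(path, config: Mapping, seed: int | None) -> None:
    """Machine-readable run record: config hash, package version, seed."""
    from . import __version__

    blob = json.dumps(config, sort_keys=True, default=str).encode()
    rec = {
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "config": config,
        "seed": seed,
        "medomics_version": __version__,
    }
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(rec, indent=2, default=str) + "\n")
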