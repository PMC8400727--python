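"""Readers and writers: matrix TSV/CSV, block manifests, model directories.

On-disk conventions: TSV is canonical (CSV accepted on input); matrices
carry column ids in the first row and row ids in the first column.  A block
manifest (YAML or JSON) lists, per block, the file, a name, and which axis
carries the matched entities (``rows`` or ``columns``); blocks whose
matched axis is columns are transposed on load so the matched axis is
always the rows.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datatypes import DataBlock, FactorModel, ModelConfig
from .exceptions import AlignmentError, IntegrityError, ParseError
from .factorization import layer_latents, objective

__all__ = ["read_matrix", "write_matrix", "load_blocks", "save_model", "load_model"]


def read_matrix(path) -> pd.DataFrame:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    try:
        df = pd.read_csv(path, sep=sep, index_col=0)
    except Exception as exc:  # noqa: BLE001 - rewrap with file context
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    bad = df.isna()
    if bad.to_numpy().any():
        r = bad.any(axis=1).idxmax()
        c = bad.loc[r].idxmax()
        raise ParseError(f"{path}: missing or non-numeric value at row {r!r}, column {c!r}")
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        for c in df.columns:
            coerced = pd.to_numeric(df[c], errors="coerce")
            if coerced.isna().any():
                r = coerced.isna().idxmax()
                raise ParseError(f"{path}: non-numeric value at row {r!r}, column {c!r}") from exc
        raise ParseError(f"{path}: non-numeric content") from exc
    return df


def write_matrix(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t")


def load_blocks(manifest_path) -> list[DataBlock]:
    """Load and align the blocks listed in a YAML/JSON manifest.

    All blocks must share the matched-axis id set; when orders differ the
    later blocks are reordered to match the first.
    """
    manifest_path = Path(manifest_path)
    text = manifest_path.read_text()
    manifest = json.loads(text) if manifest_path.suffix == ".json" else yaml.safe_load(text)
    entries = manifest["blocks"] if isinstance(manifest, dict) else manifest
    if not entries:
        raise ParseError(f"{manifest_path}: manifest lists no blocks")
    blocks: list[DataBlock] = []
    for entry in entries:
        fpath = Path(entry["file"])
        if not fpath.is_absolute():
            fpath = manifest_path.parent / fpath
        df = read_matrix(fpath)
        axis = entry.get("matched_axis", "rows")
        orientation = "as_is"
        if axis == "columns":
            df = df.T
            orientation = "transposed"
        elif axis != "rows":
            raise ParseError(f"{manifest_path}: matched_axis must be 'rows' or 'columns'")
        blocks.append(
            DataBlock(
                name=str(entry.get("name", fpath.stem)),
                values=df.to_numpy(dtype=float),
                row_ids=[str(i) for i in df.index],
                col_ids=[str(c) for c in df.columns],
                orientation=orientation,
            )
        )
    ref = blocks[0]
    for b in blocks[1:]:
        if b.row_ids != ref.row_ids:
            if set(b.row_ids) != set(ref.row_ids):
                missing = sorted(set(ref.row_ids) ^ set(b.row_ids))[:5]
                raise AlignmentError(
                    f"blocks {ref.name!r} and {b.name!r} disagree on matched-axis ids "
                    f"(examples: {missing})"
                )
            order = [b.row_ids.index(r) for r in ref.row_ids]
            b.values = b.values[order]
            b.row_ids = [b.row_ids[i] for i in order]
    return blocks


def save_model(model: FactorModel, out_dir) -> None:
    """Write per-factor TSVs plus a JSON config/trace sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    row_ids = model.row_ids or [f"r{i}" for i in range(model.U.shape[0])]
    k0 = model.config.dims[0]
    write_matrix(
        pd.DataFrame(model.U, index=row_ids, columns=[f"k{j}" for j in range(k0)]),
        out / "U.tsv",
    )
    for i, name in enumerate(model.block_names):
        cols = (model.col_ids[i] if model.col_ids else
                [f"c{j}" for j in range(model.H_deep[i].shape[1])])
        for n, z in enumerate(model.Z[i], start=1):
            write_matrix(
                pd.DataFrame(z, index=[f"k{j}" for j in range(z.shape[0])],
                             columns=[f"k{j}" for j in range(z.shape[1])]),
                out / f"Z_{name}_{n}.tsv",
            )
        latents = layer_latents(model, i)
        for n, h in enumerate(latents):
            write_matrix(
                pd.DataFrame(h, index=[f"k{j}" for j in range(h.shape[0])], columns=cols),
                out / f"H_{name}_{n}.tsv",
            )
    sidecar = {
        "config": model.config.to_dict(),
        "block_names": model.block_names,
        "loss_trace": model.loss_trace,
    }
    (out / "model.json").write_text(json.dumps(sidecar, indent=1))


def load_model(model_dir) -> FactorModel:
    """Inverse of :func:`save_model`; validates shapes against the sidecar."""
    d = Path(model_dir)
    sidecar_path = d / "model.json"
    if not sidecar_path.exists():
        raise IntegrityError(f"{d}: missing model.json sidecar")
    sidecar = json.loads(sidecar_path.read_text())
    config = ModelConfig(**sidecar["config"])
    names = sidecar["block_names"]
    try:
        u_df = read_matrix(d / "U.tsv")
    except (ParseError, FileNotFoundError) as exc:
        raise IntegrityError(f"{d}: cannot read U.tsv: {exc}") from exc
    Z, H_deep, col_ids = [], [], []
    n_layers = config.n_layers
    for name in names:
        z_list = []
        for n in range(1, n_layers + 1):
            p = d / f"Z_{name}_{n}.tsv"
            if not p.exists():
                raise IntegrityError(f"{d}: missing factor file {p.name}")
            z_list.append(read_matrix(p).to_numpy(dtype=float))
        hp = d / f"H_{name}_{n_layers}.tsv"
        if not hp.exists():
            raise IntegrityError(f"{d}: missing factor file {hp.name}")
        h_df = read_matrix(hp)
        Z.append(z_list)
        H_deep.append(h_df.to_numpy(dtype=float))
        col_ids.append([str(c) for c in h_df.columns])
    model = FactorModel(
        U=u_df.to_numpy(dtype=float),
        Z=Z,
        H_deep=H_deep,
        config=config,
        block_names=list(names),
        row_ids=[str(i) for i in u_df.index],
        col_ids=col_ids,
        loss_trace=list(sidecar.get("loss_trace", [])),
    )
    try:
        model.check_shapes()
    except Exception as exc:
        raise IntegrityError(f"{d}: factor shapes inconsistent with sidecar dims: {exc}") from exc
    return model


def model_objective(model: FactorModel, blocks) -> float:
    total, _, _ = objective(model, blocks)
    return total
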