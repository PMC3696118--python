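"""Readers and writers for the pipeline's tabular and network artifacts.

Formats are deliberately plain: delimited tables (comma or tab, header row,
UTF-8) for morphometry and association matrices, two-column edge lists for
networks, long-format CSV for metric curves, and JSON for reports.  Every
stochastic artifact embeds the seed that produced it.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .netcon import AssociationMatrix, BinaryNetwork
from .preprocess import MorphometryDataset

__all__ = [
    "read_morphometry_table",
    "write_morphometry_table",
    "read_association_matrix",
    "write_association_matrix",
    "write_network",
    "read_network",
    "write_curves",
    "read_curves",
    "write_json_report",
    "read_config",
    "write_config",
]


class ParseError(ValueError):
    """A malformed input file, with row/column context in the message."""


def _read_table(path: Path | str, index_col: int = 0) -> pd.DataFrame:
    path = Path(path)
    # check the raw header before pandas de-duplicates repeated names
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().strip()
    for sep in ("\t", ";", ","):
        if sep in header:
            cols = header.split(sep)[1:]
            dupes = sorted({c for c in cols if cols.count(c) > 1})
            if dupes:
                raise ParseError(f"{path}: duplicate column names {dupes}")
            break
    try:
        df = pd.read_csv(path, sep=None, engine="python", index_col=index_col)
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: empty file") from exc
    for col in df.columns:
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(
                f"{path}: non-numeric cell at row {row} (subject "
                f"{df.index[row]!r}), column {col!r}: {df[col].iloc[row]!r}"
            )
        if df[col].isna().any():
            row = int(np.flatnonzero(df[col].isna().to_numpy())[0])
            raise ParseError(f"{path}: missing value at row {row}, column {col!r}")
    return df.astype(float)


def read_morphometry_table(
    values_path: Path | str, covariates_path: Path | str | None = None
) -> MorphometryDataset:
    """Read a subject x region table plus an optional sibling covariate table.

    Both tables are keyed by subject identifier (first column); the
    covariate table must cover every subject in the values table.
    """
    df = _read_table(values_path)
    if covariates_path is not None:
        cov = _read_table(covariates_path)
        missing = set(df.index) - set(cov.index)
        if missing:
            raise ParseError(
                f"{covariates_path}: missing covariates for subjects {sorted(missing)}"
            )
        cov = cov.loc[df.index]
    else:
        cov = pd.DataFrame(index=df.index)
    return MorphometryDataset(
        values=df.to_numpy(),
        region_names=[str(c) for c in df.columns],
        subject_ids=[str(i) for i in df.index],
        covariates=cov.reset_index(drop=True),
    )


def write_morphometry_table(
    data: MorphometryDataset, values_path: Path | str,
    covariates_path: Path | str | None = None,
) -> None:
    df = data.to_frame()
    df.index.name = "subject_id"
    df.to_csv(values_path)
    if covariates_path is not None:
        cov = data.covariates.copy()
        cov.index = pd.Index(data.subject_ids, name="subject_id")
        cov.to_csv(covariates_path)


def write_association_matrix(A: AssociationMatrix, path: Path | str) -> None:
    """Square labeled table of the correlation matrix (covariance alongside)."""
    path = Path(path)
    pd.DataFrame(A.r, index=A.region_names, columns=A.region_names).to_csv(path)
    cov_path = path.with_name(path.stem + ".cov" + path.suffix)
    pd.DataFrame(A.cov, index=A.region_names, columns=A.region_names).to_csv(cov_path)
    meta = {"n_subjects": A.n_subjects}
    path.with_suffix(".meta.json").write_text(json.dumps(meta))


def read_association_matrix(path: Path | str) -> AssociationMatrix:
    path = Path(path)
    r = _read_table(path)
    cov = _read_table(path.with_name(path.stem + ".cov" + path.suffix))
    meta = json.loads(path.with_suffix(".meta.json").read_text())
    return AssociationMatrix(
        r=r.to_numpy(), cov=cov.to_numpy(),
        n_subjects=int(meta["n_subjects"]),
        region_names=[str(c) for c in r.columns],
    )


def write_network(net: BinaryNetwork, path: Path | str) -> None:
    """Edge list (two name columns) with threshold provenance in the header."""
    path = Path(path)
    names = net.region_names or [f"N{i:03d}" for i in range(net.n_nodes)]
    lines = [
        f"# provenance={net.provenance} threshold_kind={net.threshold_kind} "
        f"threshold_value={net.threshold_value} density={net.density:.6f}",
        "source\ttarget",
    ]
    for i, j in net.edge_list():
        lines.append(f"{names[i]}\t{names[j]}")
    path.write_text("\n".join(lines) + "\n")


def read_network(path: Path | str, region_names: list[str]) -> BinaryNetwork:
    path = Path(path)
    index = {name: k for k, name in enumerate(region_names)}
    n = len(region_names)
    adj = np.zeros((n, n), dtype=np.uint8)
    meta: dict[str, str] = {}
    for ln, line in enumerate(path.read_text().splitlines()):
        if line.startswith("#"):
            meta = dict(tok.split("=", 1) for tok in line[1:].split())
            continue
        if line.strip() == "" or line.startswith("source"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ParseError(f"{path}: malformed edge at line {ln + 1}: {line!r}")
        a, b = parts[0], parts[1]
        if a not in index or b not in index:
            raise ParseError(f"{path}: unknown region name at line {ln + 1}")
        adj[index[a], index[b]] = 1
        adj[index[b], index[a]] = 1
    return BinaryNetwork(
        adjacency=adj,
        density=float(meta.get("density", adj.sum() / (n * (n - 1)))),
        threshold_kind=meta.get("threshold_kind", "density"),
        threshold_value=float(meta.get("threshold_value", np.nan)),
        provenance=meta.get("provenance", "empirical"),
        region_names=list(region_names),
    )


def write_adjacency_matrix(net: BinaryNetwork, path: Path | str) -> None:
    """Labeled 0/1 matrix form of a binary network."""
    names = net.region_names or [f"N{i:03d}" for i in range(net.n_nodes)]
    pd.DataFrame(net.adjacency, index=names, columns=names).to_csv(path)


def read_adjacency_matrix(path: Path | str, **net_kwargs) -> BinaryNetwork:
    df = _read_table(path)
    adj = df.to_numpy().astype(np.uint8)
    n = adj.shape[0]
    net_kwargs.setdefault("density", float(adj.sum() / (n * (n - 1))))
    net_kwargs.setdefault("threshold_kind", "density")
    net_kwargs.setdefault("threshold_value", float("nan"))
    return BinaryNetwork(adjacency=adj,
                         region_names=[str(c) for c in df.columns],
                         **net_kwargs)


def write_curves(curves: pd.DataFrame, path: Path | str) -> None:
    """Long-format curve table: grid_value, metric, model, group, value."""
    expected = {"grid_value", "metric", "model", "group", "value"}
    if not expected.issubset(curves.columns):
        raise ValueError(f"curve table needs columns {sorted(expected)}")
    curves.to_csv(path, index=False)


def read_curves(path: Path | str) -> pd.DataFrame:
    return pd.read_csv(path)


def write_json_report(report: dict, path: Path | str) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    Path(path).write_text(json.dumps(report, indent=2, default=_default) + "\n")


def read_config(path: Path | str) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ParseError(f"{path}: config must be a mapping")
    return cfg


def write_config(cfg: dict, path: Path | str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
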