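"""Dataset container and plain-text I/O (TSV / CSV / MatrixMarket MTX).

Orientation is fixed everywhere: cells (samples) are rows, features are
columns.  MTX files are accompanied by ``<stem>.rows.txt`` and
``<stem>.cols.txt`` id sidecars, one id per line; labels travel in a
two-column TSV (``sample_id<TAB>label``).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import mmread, mmwrite
from scipy.sparse import csr_matrix

from .ot_core import DimensionError, DomainError

__all__ = [
    "OmicsDataset",
    "RunConfig",
    "read_dataset",
    "write_dataset",
    "read_labels",
    "write_labels",
    "write_coupling",
    "read_coupling",
]

logger = logging.getLogger(__name__)


@dataclass
class OmicsDataset:
    """One modality's measurements: cells x features with ids and labels."""

    matrix: np.ndarray
    sample_ids: list[str]
    feature_ids: list[str]
    labels: np.ndarray | None = None

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise DimensionError("matrix must be 2-D (cells x features)")
        if not np.all(np.isfinite(self.matrix)):
            raise DomainError("matrix must be finite")
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.feature_ids = [str(s) for s in self.feature_ids]
        n, d = self.matrix.shape
        if len(self.sample_ids) != n:
            raise DimensionError(f"{len(self.sample_ids)} sample ids for {n} rows")
        if len(self.feature_ids) != d:
            raise DimensionError(f"{len(self.feature_ids)} feature ids for {d} columns")
        if len(set(self.sample_ids)) != n:
            raise DomainError("duplicate sample ids")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if len(self.labels) != n:
                raise DimensionError("labels length must equal number of cells")

    @property
    def n_cells(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]

    def subset(self, indices) -> "OmicsDataset":
        indices = np.asarray(indices)
        return OmicsDataset(
            matrix=self.matrix[indices],
            sample_ids=[self.sample_ids[i] for i in indices],
            feature_ids=list(self.feature_ids),
            labels=None if self.labels is None else self.labels[indices],
        )


def _sidecars(path: Path) -> tuple[Path, Path]:
    stem = path.with_suffix("")
    return Path(str(stem) + ".rows.txt"), Path(str(stem) + ".cols.txt")


def read_dataset(path, fmt: str | None = None, transpose: bool = False) -> OmicsDataset:
    """Read a dense TSV/CSV (ids in header row + first column) or an MTX file.

    ``fmt`` is inferred from the suffix when omitted.  ``transpose`` handles
    genes-as-rows files.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        fmt = {".tsv": "tsv", ".csv": "csv", ".mtx": "mtx", ".txt": "tsv"}.get(
            path.suffix.lower()
        )
        if fmt is None:
            raise ValueError(f"cannot infer format from suffix of {path.name}")

    if fmt in ("tsv", "csv"):
        sep = "\t" if fmt == "tsv" else ","
        try:
            df = pd.read_csv(path, sep=sep, index_col=0)
            matrix = df.to_numpy(dtype=float)
        except ValueError as exc:
            raise ValueError(f"non-numeric value in {path.name}: {exc}") from exc
        ds = OmicsDataset(
            matrix=matrix,
            sample_ids=[str(i) for i in df.index],
            feature_ids=[str(c) for c in df.columns],
        )
    elif fmt == "mtx":
        rows_f, cols_f = _sidecars(path)
        for f in (rows_f, cols_f):
            if not f.exists():
                raise FileNotFoundError(f"MTX sidecar missing: {f}")
        m = mmread(path)
        mat = np.asarray(m.toarray() if hasattr(m, "toarray") else m, dtype=float)
        sample_ids = rows_f.read_text().split()
        feature_ids = cols_f.read_text().split()
        if mat.shape != (len(sample_ids), len(feature_ids)):
            raise ValueError(
                f"{path.name}: declared shape {mat.shape} does not match sidecar "
                f"id counts ({len(sample_ids)}, {len(feature_ids)})"
            )
        ds = OmicsDataset(matrix=mat, sample_ids=sample_ids, feature_ids=feature_ids)
    else:
        raise ValueError(f"unknown format {fmt!r}")

    if transpose:
        ds = OmicsDataset(
            matrix=ds.matrix.T, sample_ids=ds.feature_ids, feature_ids=ds.sample_ids
        )
    return ds


def write_dataset(ds: OmicsDataset, path, fmt: str | None = None) -> None:
    """Write a dataset in TSV/CSV (dense, ids attached) or MTX + sidecars."""
    path = Path(path)
    if fmt is None:
        fmt = {".tsv": "tsv", ".csv": "csv", ".mtx": "mtx"}.get(path.suffix.lower())
        if fmt is None:
            raise ValueError(f"cannot infer format from suffix of {path.name}")
    if fmt in ("tsv", "csv"):
        sep = "\t" if fmt == "tsv" else ","
        pd.DataFrame(ds.matrix, index=ds.sample_ids, columns=ds.feature_ids).to_csv(
            path, sep=sep
        )
    elif fmt == "mtx":
        mmwrite(str(path), csr_matrix(ds.matrix))
        rows_f, cols_f = _sidecars(path)
        rows_f.write_text("\n".join(ds.sample_ids) + "\n")
        cols_f.write_text("\n".join(ds.feature_ids) + "\n")
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_labels(path) -> dict[str, str]:
    """Read a two-column (sample_id, label) TSV into a dict."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample_id", "label"], dtype=str)
    return dict(zip(df["sample_id"], df["label"]))


def write_labels(sample_ids, labels, path) -> None:
    pd.DataFrame({"sample_id": sample_ids, "label": labels}).to_csv(
        path, sep="\t", header=False, index=False
    )


def write_coupling(plan, row_ids, col_ids, path) -> None:
    """Write a coupling dense as TSV with sample/feature ids as headers."""
    pd.DataFrame(np.asarray(plan, dtype=float), index=row_ids, columns=col_ids).to_csv(
        path, sep="\t"
    )


def read_coupling(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


_INF_TOKEN = "inf"


def _encode(value):
    if isinstance(value, float) and math.isinf(value):
        return _INF_TOKEN
    if isinstance(value, np.ndarray):
        return {"__array__": value.tolist()}
    if isinstance(value, Path):
        return str(value)
    return value


def _decode(value):
    if value == _INF_TOKEN:
        return float("inf")
    if isinstance(value, dict) and "__array__" in value:
        return np.asarray(value["__array__"], dtype=float)
    return value


@dataclass
class RunConfig:
    """Everything one pipeline run needs; round-trips losslessly via JSON."""

    mode: str = "gw"
    x_path: str | None = None
    y_path: str | None = None
    x_labels_path: str | None = None
    y_labels_path: str | None = None
    out_dir: str = "otalign_out"
    # preprocessing
    normalize: str = "none"  # none | l2 | zscore
    pca_components: int | None = None
    k_neighbors: int = 30
    normalize_distances: bool = True
    transpose: bool = False
    # solver hyperparameters (mirrors formulations.SolverConfig)
    alpha: float = 0.5
    eps_gw: float = 1e-3
    eps_coot: float = 1e-3
    rho_gw1: float = float("inf")
    rho_gw2: float = float("inf")
    rho_coot1: float = float("inf")
    rho_coot2: float = float("inf")
    beta_sample: float = 0.0
    beta_feature: float = 0.0
    n_outer: int = 50
    inner_max_iter: int = 1000
    inner_tol: float = 1e-9
    seed: int = 0
    # metric toggles
    compute_foscttm: bool = True
    compute_lta: bool = True

    def to_json(self, path=None) -> str:
        payload = {k: _encode(v) for k, v in dataclasses.asdict(self).items()}
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "RunConfig":
        p = Path(str(source))
        text = p.read_text() if p.exists() else str(source)
        payload = json.loads(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**{k: _decode(v) for k, v in payload.items()})
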