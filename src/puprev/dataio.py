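"""File formats: MatrixMarket features, TSV metadata, JSON reports.

All outputs are plain text and deterministic (sorted keys, fixed float
formatting) so pipeline runs are byte-stable and auditable.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

from .synthetic import PUDataset

__all__ = [
    "write_pu_dataset",
    "read_pu_dataset",
    "write_json_report",
    "read_json_report",
    "write_probs_tsv",
    "read_probs_tsv",
    "read_ratings_tsv",
]

SCHEMA_VERSION = 1

PathLike = Union[str, Path]


def write_pu_dataset(dataset: PUDataset, path: PathLike) -> None:
    """Write features.mtx + records.tsv + covariates.tsv into a directory."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    mmwrite(path / "features.mtx", dataset.features.tocoo(), field="integer")
    records = pd.DataFrame({"record_id": dataset.record_ids, "label": dataset.labels})
    if dataset.latent_status is not None:
        records["latent_status"] = dataset.latent_status
    if dataset.latent_subtype is not None:
        records["latent_subtype"] = dataset.latent_subtype
    records.to_csv(path / "records.tsv", sep="\t", index=False)
    if dataset.covariate_meta is not None:
        cov = dataset.covariate_meta
    else:
        cov = pd.DataFrame({"covariate_id": dataset.covariate_ids})
    cov.to_csv(path / "covariates.tsv", sep="\t", index=False)


def read_pu_dataset(path: PathLike) -> PUDataset:
    """Read a dataset directory, validating shape and binary values."""
    path = Path(path)
    mat = mmread(path / "features.mtx")
    feats = sp.csr_matrix(mat)
    bad = np.flatnonzero(~np.isin(feats.data, (0, 1)))
    if bad.size:
        coo = feats.tocoo()
        i, j = int(coo.row[bad[0]]), int(coo.col[bad[0]])
        raise ValueError(
            f"non-binary feature value {feats.data[bad[0]]} at row {i}, col {j}"
        )
    records = pd.read_csv(path / "records.tsv", sep="\t")
    covariates = pd.read_csv(path / "covariates.tsv", sep="\t")
    if len(records) != feats.shape[0]:
        raise ValueError(
            f"dimension mismatch: matrix has {feats.shape[0]} rows but "
            f"records.tsv lists {len(records)}"
        )
    if len(covariates) != feats.shape[1]:
        raise ValueError(
            f"dimension mismatch: matrix has {feats.shape[1]} columns but "
            f"covariates.tsv lists {len(covariates)}"
        )
    if records["record_id"].duplicated().any():
        dupes = records.loc[records["record_id"].duplicated(), "record_id"].iloc[0]
        raise ValueError(f"duplicate record_id {dupes!r}")
    feats = sp.csr_matrix(feats, dtype=np.int8)
    return PUDataset(
        features=feats,
        labels=records["label"].to_numpy(dtype=np.int8),
        record_ids=records["record_id"].to_numpy(dtype=str),
        covariate_ids=covariates["covariate_id"].to_numpy(dtype=str),
        latent_status=(
            records["latent_status"].to_numpy(dtype=np.int8)
            if "latent_status" in records
            else None
        ),
        latent_subtype=(
            records["latent_subtype"].to_numpy(dtype=np.int32)
            if "latent_subtype" in records
            else None
        ),
        covariate_meta=covariates,
    )


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        return float(obj)
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return [_jsonify(v) for v in obj.tolist()]
    return obj


def write_json_report(report: dict, path: PathLike) -> None:
    payload = {"schema_version": SCHEMA_VERSION}
    payload.update(_jsonify(report))
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json_report(path: PathLike) -> dict:
    with open(path) as fh:
        return json.load(fh)


def write_probs_tsv(record_ids, probs, path: PathLike, column: str = "prob") -> None:
    df = pd.DataFrame({"record_id": record_ids, column: probs})
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_probs_tsv(path: PathLike, column: Optional[str] = None):
    df = pd.read_csv(path, sep="\t")
    if column is None:
        column = [c for c in df.columns if c != "record_id"][0]
    return df["record_id"].to_numpy(dtype=str), df[column].to_numpy(dtype=float)


def read_ratings_tsv(path: PathLike):
    """Ratings TSV: record_id, rater_* columns, optional consensus."""
    from .agreement import RatingsMatrix

    df = pd.read_csv(path, sep="\t")
    rater_cols = [c for c in df.columns if c.startswith("rater")]
    if not rater_cols:
        raise ValueError("ratings file has no rater_* columns")
    consensus = df["consensus"].to_numpy(dtype=int) if "consensus" in df else None
    return RatingsMatrix(
        cases=df["record_id"].to_numpy(dtype=str),
        raters=np.array(rater_cols),
        values=df[rater_cols].to_numpy(dtype=int),
        consensus=consensus,
    )
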