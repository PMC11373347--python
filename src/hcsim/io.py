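"""Model archive serialization and partition I/O.

A fitted :class:`~hcsim.hcd.HCDModel` is stored as a single zip archive
holding one JSON metadata document (``meta.json``) plus dense arrays as
``.npy`` entries — inspectable with any zip tool, language-portable, and
protected by a SHA-256 payload checksum recorded in the metadata.
"""

from __future__ import annotations

import hashlib
import io as _io
import json
import zipfile
from pathlib import Path

import numpy as np
import pandas as pd

from .clustering import Partition
from .hcd import SCHEMA_VERSION, ClusterPCA, HCDModel, Level

__all__ = [
    "serialize_model",
    "deserialize_model",
    "write_partition",
    "read_partition",
    "ModelFormatError",
    "ModelIntegrityError",
]


class ModelFormatError(ValueError):
    """Unreadable or version-incompatible model archive."""


class ModelIntegrityError(ValueError):
    """Archive payload does not match its recorded checksum."""


def _npy_bytes(arr: np.ndarray) -> bytes:
    buf = _io.BytesIO()
    np.save(buf, np.ascontiguousarray(arr))
    return buf.getvalue()


def serialize_model(model: HCDModel, path: str | Path) -> None:
    """Write the model as meta.json + .npy arrays in one zip archive."""
    arrays: dict[str, np.ndarray] = {
        "global_center": model.global_center,
        "original_variances": model.original_variances,
        "residual_variances": model.residual_variances,
        "noise_indices": model.noise_indices,
    }
    meta_levels = []
    for li, lv in enumerate(model.levels):
        arrays[f"level{li}/partition_labels"] = lv.partition.labels
        meta_clusters = []
        for ci, cp in enumerate(lv.clusters):
            pre = f"level{li}/cluster{ci}"
            arrays[f"{pre}/member_indices"] = cp.member_indices
            arrays[f"{pre}/scores"] = cp.scores
            arrays[f"{pre}/loadings"] = cp.loadings
            arrays[f"{pre}/center"] = cp.center
            arrays[f"{pre}/pc_variances"] = cp.pc_variances
            meta_clusters.append(
                {"cluster_id": cp.cluster_id, "level": cp.level,
                 "n_pcs_used": cp.n_pcs_used}
            )
        meta_levels.append(
            {"v_explained_after": lv.v_explained_after, "clusters": meta_clusters}
        )

    payload = {name: _npy_bytes(a) for name, a in arrays.items()}
    checksum = hashlib.sha256()
    for name in sorted(payload):
        checksum.update(name.encode())
        checksum.update(payload[name])
    meta = {
        "schema_version": model.schema_version,
        "variable_ids": model.variable_ids,
        "n_samples": model.n_samples,
        "k": model.k,
        "f_E": model.f_E,
        "levels": meta_levels,
        "payload_sha256": checksum.hexdigest(),
    }
    with zipfile.ZipFile(path, "w", compression=zipfile.ZIP_DEFLATED) as zf:
        zf.writestr("meta.json", json.dumps(meta, indent=1))
        for name, data in payload.items():
            zf.writestr(name + ".npy", data)


def deserialize_model(path: str | Path) -> HCDModel:
    """Read a model archive, verifying schema version and payload checksum."""
    try:
        with zipfile.ZipFile(path) as zf:
            meta = json.loads(zf.read("meta.json"))
            payload = {
                info.filename[:-4]: zf.read(info.filename)
                for info in zf.infolist()
                if info.filename.endswith(".npy")
            }
    except (zipfile.BadZipFile, KeyError) as exc:
        raise ModelFormatError(f"unreadable model archive {path}: {exc}") from exc

    version = meta.get("schema_version")
    if version != SCHEMA_VERSION:
        raise ModelFormatError(
            f"model archive schema version {version} is not supported by this "
            f"reader (expects {SCHEMA_VERSION})"
        )
    checksum = hashlib.sha256()
    for name in sorted(payload):
        checksum.update(name.encode())
        checksum.update(payload[name])
    if checksum.hexdigest() != meta.get("payload_sha256"):
        raise ModelIntegrityError(f"payload checksum mismatch in {path}")

    def arr(name: str) -> np.ndarray:
        return np.load(_io.BytesIO(payload[name]), allow_pickle=False)

    levels = []
    for li, lv_meta in enumerate(meta["levels"]):
        partition = Partition(labels=arr(f"level{li}/partition_labels"))
        clusters = []
        for ci, cmeta in enumerate(lv_meta["clusters"]):
            pre = f"level{li}/cluster{ci}"
            clusters.append(
                ClusterPCA(
                    cluster_id=int(cmeta["cluster_id"]),
                    level=int(cmeta["level"]),
                    member_indices=arr(f"{pre}/member_indices"),
                    n_pcs_used=int(cmeta["n_pcs_used"]),
                    scores=arr(f"{pre}/scores"),
                    loadings=arr(f"{pre}/loadings"),
                    center=arr(f"{pre}/center"),
                    pc_variances=arr(f"{pre}/pc_variances"),
                )
            )
        levels.append(
            Level(partition=partition, clusters=clusters,
                  v_explained_after=float(lv_meta["v_explained_after"]))
        )
    return HCDModel(
        variable_ids=list(meta["variable_ids"]),
        n_samples=int(meta["n_samples"]),
        k=int(meta["k"]),
        f_E=float(meta["f_E"]),
        levels=levels,
        global_center=arr("global_center"),
        original_variances=arr("original_variances"),
        residual_variances=arr("residual_variances"),
        noise_indices=arr("noise_indices"),
        schema_version=int(version),
    )


def write_partition(p: Partition, variable_ids: list[str], path: str | Path) -> None:
    """Two-column TSV: variable_id, cluster_label (0 = noise subset)."""
    pd.DataFrame({"variable_id": variable_ids, "cluster_label": p.labels}).to_csv(
        path, sep="\t", index=False
    )


def read_partition(path: str | Path, variable_ids: list[str] | None = None) -> Partition:
    df = pd.read_csv(path, sep="\t")
    if variable_ids is not None:
        df = df.set_index("variable_id").loc[list(variable_ids)].reset_index()
    return Partition(labels=df["cluster_label"].to_numpy(dtype=int))
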