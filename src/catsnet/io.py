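"""Readers and writers for every on-disk artifact.

Text formats are UTF-8 with '.' decimal separators and LF line endings:

* concept sets — CSV with header ``category_id,dim_0,...,dim_{d_c-1}``,
  values in scientific notation with >= 9 significant digits;
* RDMs — square CSV with item labels as header row and first column, or a
  long format ``item_a,item_b,d``;
* hyper-category maps — two-column CSV ``class_id,hyper_category``;
* feature tables — CSV with a ``class_id`` column plus ``f0..f{d-1}``;
* checkpoints — a numpy ``.npz`` container of named weight/normalization
  arrays plus layer-size metadata and a SHA-256 content checksum
  (round-trips bit-exactly);
* run manifests — JSON with the config hash, seeds and package version.
"""

from __future__ import annotations

import hashlib
import json

import numpy as np
import pandas as pd

from .concept_analysis import RDM
from .core_model import CatsNet, CatsNetError, ConceptSet

__all__ = [
    "ParseError",
    "CorruptionError",
    "write_conceptset",
    "read_conceptset",
    "write_rdm",
    "read_rdm",
    "write_rdm_long",
    "write_hyper_map",
    "read_hyper_map",
    "write_features",
    "read_features",
    "save_checkpoint",
    "load_checkpoint",
    "write_manifest",
]


class ParseError(CatsNetError, ValueError):
    """A text file did not conform to its documented format."""


class CorruptionError(CatsNetError):
    """Checkpoint content does not match its stored checksum."""


# ---------------------------------------------------------- concept sets

def write_conceptset(concepts: ConceptSet, path):
    cols = [f"dim_{i}" for i in range(concepts.d_c)]
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("category_id," + ",".join(cols) + "\n")
        for cid, row in zip(concepts.ids, concepts.matrix):
            fh.write(str(cid) + "," +
                     ",".join(f"{v:.12e}" for v in row) + "\n")


def read_conceptset(path) -> ConceptSet:
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - passthrough detail
        raise ParseError(f"cannot parse concept set {path}: {exc}") from exc
    if df.columns[0] != "category_id":
        raise ParseError(
            f"{path}: first column must be 'category_id', "
            f"got {df.columns[0]!r}")
    dims = [c for c in df.columns[1:]]
    expect = [f"dim_{i}" for i in range(len(dims))]
    if dims != expect:
        raise ParseError(f"{path}: dimension columns must be {expect}")
    return ConceptSet(df["category_id"].tolist(),
                      df[dims].to_numpy(dtype=float))


# ------------------------------------------------------------------ RDMs

def write_rdm(rdm: RDM, path):
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("item," + ",".join(str(i) for i in rdm.items) + "\n")
        for label, row in zip(rdm.items, rdm.d):
            fh.write(str(label) + "," +
                     ",".join(f"{v:.12e}" for v in row) + "\n")


def read_rdm(path, metric="euclidean") -> RDM:
    with open(path, encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise ParseError(f"{path}: empty RDM file")
    header = lines[0].split(",")
    items = header[1:]
    n = len(items)
    rows = []
    for lineno, ln in enumerate(lines[1:], start=2):
        parts = ln.split(",")
        if len(parts) != n + 1:
            raise ParseError(
                f"{path}:{lineno}: expected {n + 1} fields, "
                f"got {len(parts)}")
        try:
            rows.append([float(v) for v in parts[1:]])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
    if len(rows) != n:
        raise ParseError(
            f"{path}: {len(rows)} data rows for {n} items (truncated?)")
    return RDM(items=items, d=np.asarray(rows), metric=metric)


def write_rdm_long(rdm: RDM, path):
    """Long-format variant: one ``item_a,item_b,d`` row per upper pair."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("item_a,item_b,d\n")
        n = len(rdm.items)
        for i in range(n):
            for j in range(i + 1, n):
                fh.write(f"{rdm.items[i]},{rdm.items[j]},"
                         f"{rdm.d[i, j]:.12e}\n")


# -------------------------------------------------- mappings and features

def write_hyper_map(hyper_map: dict, path):
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("class_id,hyper_category\n")
        for cid in hyper_map:
            fh.write(f"{cid},{hyper_map[cid]}\n")


def read_hyper_map(path) -> dict:
    df = pd.read_csv(path)
    if list(df.columns) != ["class_id", "hyper_category"]:
        raise ParseError(
            f"{path}: columns must be class_id,hyper_category")
    return dict(zip(df["class_id"], df["hyper_category"]))


def write_features(features_by_class: dict, path):
    rows = []
    for cid, feats in features_by_class.items():
        for f in feats:
            rows.append([cid] + list(np.asarray(f, dtype=float)))
    d = len(rows[0]) - 1
    df = pd.DataFrame(rows, columns=["class_id"] +
                      [f"f{i}" for i in range(d)])
    df.to_csv(path, index=False, float_format="%.9e", lineterminator="\n")


def read_features(path) -> dict:
    df = pd.read_csv(path)
    if df.columns[0] != "class_id":
        raise ParseError(f"{path}: first column must be class_id")
    cols = df.columns[1:]
    out = {}
    for cid, grp in df.groupby("class_id", sort=False):
        out[cid] = grp[cols].to_numpy(dtype=float)
    return out


# ------------------------------------------------------------ checkpoints

def save_checkpoint(net: CatsNet, path, concepts: ConceptSet | None = None):
    """Binary container of all weight/normalization arrays + metadata."""
    arrays = {f"param::{k}": v for k, v in net.params.items()}
    arrays.update({f"buffer::{k}": v for k, v in net.buffers.items()})
    if concepts is not None:
        arrays["concepts::matrix"] = concepts.matrix
        arrays["concepts::ids"] = np.array([str(i) for i in concepts.ids])
    meta = {"ts_sizes": net.ts_sizes, "d_c": net.d_c,
            "checksum": net.checksum()}
    arrays["meta::json"] = np.array(json.dumps(meta))
    np.savez(path, **arrays)


def load_checkpoint(path):
    """Returns ``(net, concepts_or_None)``; verifies the content checksum."""
    with np.load(path) as data:
        meta = json.loads(str(data["meta::json"]))
        net = CatsNet(meta["ts_sizes"], d_c=meta["d_c"], seed=0)
        state = {}
        for key in data.files:
            if key.startswith("param::"):
                state[key[len("param::"):]] = data[key]
            elif key.startswith("buffer::"):
                state[key[len("buffer::"):]] = data[key]
        net.load_state_dict(state)
        if net.checksum() != meta["checksum"]:
            raise CorruptionError(f"{path}: checkpoint checksum mismatch")
        concepts = None
        if "concepts::matrix" in data.files:
            ids = [str(s) for s in data["concepts::ids"]]
            concepts = ConceptSet(ids, data["concepts::matrix"].astype(float))
    return net, concepts


# --------------------------------------------------------------- manifest

def write_manifest(path, subcommand, config: dict, seed):
    """Reproducibility manifest: config hash, seed and package version."""
    from . import __version__
    payload = json.dumps(config, sort_keys=True, default=str)
    manifest = {
        "subcommand": subcommand,
        "config": config,
        "config_sha256": hashlib.sha256(payload.encode()).hexdigest(),
        "seed": seed,
        "catsnet_version": __version__,
        "numpy_version": np.__version__,
    }
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return manifest
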