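"""Readers and writers shared across the pipeline.

FASTA in (via Biopython), TSV manifests and annotation tables, CSV
tabular outputs, Newick trees for the clustering results, and flat
key:value YAML parameter files.  All writes are atomic (temp file in the
target directory, then rename).
"""

from __future__ import annotations

import hashlib
import logging
import os
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from scipy.cluster.hierarchy import to_tree

from .dynamics import NormalizedParameters
from .genome_bias import AMINO_ACIDS, EnzymeAnnotation, Proteome

logger = logging.getLogger(__name__)

__all__ = [
    "read_fasta",
    "read_proteome",
    "read_manifest",
    "read_annotations",
    "write_fasta",
    "write_annotations_tsv",
    "write_csv_atomic",
    "write_tree_newick",
    "linkage_to_newick",
    "read_params_yaml",
    "write_params_yaml",
    "file_sha256",
]

_ANNOTATION_COLUMNS = ["organism_id", "protein_id", "amino_acid", "pathway_id"]


class FastaParseError(ValueError):
    pass


def _atomic_write_text(path, text: str) -> None:
    path = Path(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def read_fasta(path) -> list:
    """Parse a FASTA file into ``[(id, SEQUENCE), ...]``.

    The record id is the first whitespace-delimited token of the header;
    sequences are uppercased and may be line-wrapped arbitrarily.  An
    empty file or a header with no sequence raises, naming the record.
    """
    path = Path(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise FastaParseError(f"record {rec.id!r} in {path} has an empty sequence")
        records.append((rec.id, seq))
    if not records:
        raise FastaParseError(f"no FASTA records found in {path}")
    return records


def read_proteome(path, organism_id: str | None = None) -> Proteome:
    """Read one organism's FASTA as a :class:`Proteome`.

    ``organism_id`` defaults to the file stem (one organism = one file).
    """
    path = Path(path)
    return Proteome(organism_id=organism_id or path.stem, proteins=tuple(read_fasta(path)))


def read_manifest(path) -> pd.DataFrame:
    """TSV mapping ``organism_id`` to ``fasta_path`` (relative to the manifest)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"organism_id", "fasta_path"} - set(df.columns)
    if missing:
        raise ValueError(f"manifest {path} lacks columns {sorted(missing)}; "
                         "expected header: organism_id\tfasta_path")
    df["fasta_path"] = [str((path.parent / p).resolve()) for p in df["fasta_path"]]
    return df


def read_annotations(path) -> list:
    """Read the enzyme-annotation TSV into :class:`EnzymeAnnotation` rows.

    The header must contain ``organism_id, protein_id, amino_acid,
    pathway_id``.  Rows with an unknown amino-acid code are rejected with
    a logged warning, not an error.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(_ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"annotation table {path} lacks columns {sorted(missing)}; "
                         f"expected header: {chr(9).join(_ANNOTATION_COLUMNS)}")
    rows = []
    for _, r in df.iterrows():
        aa = str(r["amino_acid"]).upper()
        if aa not in AMINO_ACIDS:
            logger.warning("annotation row with unknown amino-acid code %r rejected "
                           "(organism %s, protein %s)", r["amino_acid"],
                           r["organism_id"], r["protein_id"])
            continue
        rows.append(EnzymeAnnotation(
            organism_id=str(r["organism_id"]), protein_id=str(r["protein_id"]),
            amino_acid=aa, pathway_id=str(r["pathway_id"])))
    return rows


def write_fasta(path, records, width: int = 60) -> None:
    """Write ``[(id, sequence), ...]`` as wrapped FASTA, atomically."""
    lines = []
    for pid, seq in records:
        lines.append(f">{pid}")
        for i in range(0, len(seq), width):
            lines.append(seq[i:i + width])
    _atomic_write_text(path, "\n".join(lines) + "\n")


def write_annotations_tsv(path, annotations) -> None:
    df = pd.DataFrame([{
        "organism_id": a.organism_id, "protein_id": a.protein_id,
        "amino_acid": a.amino_acid, "pathway_id": a.pathway_id,
    } for a in annotations], columns=_ANNOTATION_COLUMNS)
    _atomic_write_text(path, df.to_csv(sep="\t", index=False))


def write_csv_atomic(path, df: pd.DataFrame) -> None:
    """Write a DataFrame as CSV with a stable column order, atomically."""
    _atomic_write_text(path, df.to_csv(index=False))


def linkage_to_newick(Z: np.ndarray, labels) -> str:
    """Render a scipy linkage matrix as a Newick string.

    Branch lengths are the increments in merge height, so root-to-leaf
    path lengths reproduce the dendrogram heights; parseable by standard
    tree readers.
    """
    labels = list(labels)
    tree = to_tree(Z)

    # leaves hang at height 0; each branch spans the height difference
    def walk2(node, parent_height: float | None) -> str:
        if node.is_leaf():
            name = str(labels[node.id]).replace(" ", "_")
            bl = parent_height if parent_height is not None else 0.0
            return f"{name}:{bl:.10g}"
        left = walk2(node.left, node.dist)
        right = walk2(node.right, node.dist)
        if parent_height is None:
            return f"({left},{right});"
        return f"({left},{right}):{(parent_height - node.dist):.10g}"

    return walk2(tree, None)


def write_tree_newick(path, Z: np.ndarray, labels) -> None:
    _atomic_write_text(path, linkage_to_newick(Z, labels) + "\n")


_PARAM_FIELDS = ("A", "B", "C", "g13", "sigma", "k13", "k23", "m", "n")


def read_params_yaml(path) -> NormalizedParameters:
    """Flat key:value YAML of normalized parameters; unknown keys rejected."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"parameter file {path} must be a flat key:value mapping")
    unknown = set(data) - set(_PARAM_FIELDS)
    if unknown:
        raise ValueError(f"unknown parameter keys in {path}: {sorted(unknown)}; "
                         f"allowed: {', '.join(_PARAM_FIELDS)}")
    return NormalizedParameters(**{k: float(v) for k, v in data.items()})


def write_params_yaml(path, p: NormalizedParameters) -> None:
    data = {k: getattr(p, k) for k in _PARAM_FIELDS}
    _atomic_write_text(path, yaml.safe_dump(data, sort_keys=False))


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
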