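"""Reading and writing datasets in AIRR Rearrangement TSV form.

One TSV per repertoire with at minimum the ``junction_aa`` column, plus a
``metadata.tsv`` (``repertoire_id``, ``filename``, ``label``, ``seed``),
an ``implant_log.tsv`` with the ground-truth implantation records, and a
``config.yaml`` snapshot of the simulation parameters.  Plain one-sequence-
per-line text import is supported so externally generated sequences (e.g.
from a V(D)J recombination model) can be used as reference repertoires.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
import yaml

from .features import FeatureIndex, FeatureMatrix
from .repertoires import Repertoire
from .signals import ImplantRecord, LabeledRepertoireDataset, Motif, Signal

__all__ = [
    "write_repertoire",
    "read_repertoire",
    "read_sequence_lines",
    "write_dataset",
    "read_dataset",
    "export_matrix",
    "import_matrix",
]

_LOG_COLUMNS = [
    "repertoire_id",
    "sequence_index",
    "motif",
    "instantiated",
    "imgt_position",
    "start_index",
]


class FormatError(ValueError):
    """Raised when an on-disk dataset violates the expected layout."""


def write_repertoire(rep: Repertoire, path: str | os.PathLike) -> None:
    """Write one repertoire as an AIRR Rearrangement TSV."""
    df = pd.DataFrame(
        {
            "sequence_id": [
                f"{rep.repertoire_id}-{i}" for i in range(len(rep.sequences))
            ],
            "junction_aa": rep.sequences,
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_repertoire(
    path: str | os.PathLike, repertoire_id: str | None = None, seed: int = -1
) -> Repertoire:
    """Read an AIRR Rearrangement TSV; ``junction_aa`` is required."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "junction_aa" not in df.columns:
        raise FormatError(f"{path}: AIRR TSV lacks the junction_aa column")
    sequences = df["junction_aa"].dropna().tolist()
    return Repertoire(
        sequences=sequences,
        repertoire_id=repertoire_id or Path(path).stem,
        seed=seed,
        source_kind="imported",
    )


def read_sequence_lines(
    path: str | os.PathLike, repertoire_id: str | None = None
) -> Repertoire:
    """Import hook: one amino-acid sequence per line."""
    with open(path) as fh:
        sequences = [line.strip() for line in fh if line.strip()]
    return Repertoire(
        sequences=sequences,
        repertoire_id=repertoire_id or Path(path).stem,
        seed=-1,
        source_kind="imported",
    )


def write_dataset(dataset: LabeledRepertoireDataset, directory: str | os.PathLike) -> None:
    """Write a labeled dataset: per-repertoire AIRR TSVs + metadata + log."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for rep, label in zip(dataset.repertoires, dataset.labels):
        filename = f"{rep.repertoire_id}.tsv"
        write_repertoire(rep, directory / filename)
        rows.append(
            {
                "repertoire_id": rep.repertoire_id,
                "filename": filename,
                "label": int(label),
                "seed": rep.seed,
            }
        )
    pd.DataFrame(rows).to_csv(directory / "metadata.tsv", sep="\t", index=False)
    log_df = pd.DataFrame(
        [
            {col: getattr(record, col) for col in _LOG_COLUMNS}
            for record in dataset.implant_log
        ],
        columns=_LOG_COLUMNS,
    )
    log_df.to_csv(directory / "implant_log.tsv", sep="\t", index=False)
    with open(directory / "config.yaml", "w") as fh:
        yaml.safe_dump(dataset.config, fh, sort_keys=False)


def read_dataset(directory: str | os.PathLike) -> LabeledRepertoireDataset:
    """Read a dataset written by :func:`write_dataset`."""
    directory = Path(directory)
    metadata_path = directory / "metadata.tsv"
    if not metadata_path.exists():
        raise FormatError(f"{directory}: missing metadata.tsv")
    metadata = pd.read_csv(metadata_path, sep="\t")
    repertoires, labels = [], []
    for row in metadata.itertuples():
        rep_path = directory / row.filename
        if not rep_path.exists():
            raise FormatError(
                f"metadata references missing repertoire file {row.filename}"
            )
        repertoires.append(
            read_repertoire(rep_path, repertoire_id=row.repertoire_id, seed=row.seed)
        )
        labels.append(int(row.label))

    log_path = directory / "implant_log.tsv"
    implant_log: list[ImplantRecord] = []
    if log_path.exists():
        log_df = pd.read_csv(log_path, sep="\t")
        implant_log = [
            ImplantRecord(
                repertoire_id=str(row.repertoire_id),
                sequence_index=int(row.sequence_index),
                motif=str(row.motif),
                instantiated=str(row.instantiated),
                imgt_position=int(row.imgt_position),
                start_index=int(row.start_index),
            )
            for row in log_df.itertuples()
        ]

    config = {}
    config_path = directory / "config.yaml"
    if config_path.exists():
        with open(config_path) as fh:
            config = yaml.safe_load(fh) or {}
    signal = None
    if config.get("signal"):
        signal = Signal(tuple(Motif(p) for p in config["signal"]))
    return LabeledRepertoireDataset(
        repertoires=repertoires,
        labels=np.asarray(labels, dtype=int),
        implant_log=implant_log,
        signal=signal,
        config=config,
    )


def export_matrix(matrix: FeatureMatrix, directory: str | os.PathLike) -> None:
    """Cache an encoded matrix as MatrixMarket text + feature-index TSV."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    from scipy.io import mmwrite

    mmwrite(directory / "matrix.mtx", sp.coo_matrix(matrix.values))
    pd.DataFrame(
        {"column": range(len(matrix.feature_index)), "kmer": matrix.feature_index.kmers}
    ).to_csv(directory / "features.tsv", sep="\t", index=False)
    pd.DataFrame({"row": range(len(matrix.row_ids)), "repertoire_id": matrix.row_ids}).to_csv(
        directory / "rows.tsv", sep="\t", index=False
    )


def import_matrix(directory: str | os.PathLike) -> FeatureMatrix:
    from scipy.io import mmread

    directory = Path(directory)
    values = sp.csr_matrix(mmread(directory / "matrix.mtx"))
    features = pd.read_csv(directory / "features.tsv", sep="\t")
    rows = pd.read_csv(directory / "rows.tsv", sep="\t")
    index = FeatureIndex.from_kmers(features["kmer"].tolist())
    return FeatureMatrix(
        values=values,
        row_ids=rows["repertoire_id"].tolist(),
        feature_index=index,
        l2_normalized=True,
    )
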