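"""Readers and writers for the pipeline's plain-text formats.

* Expression: TSV (first column gene id, header row sample ids) with a
  sidecar YAML mapping sample id -> condition.
* UTRs: FASTA with headers ``>geneID|transcriptID``; a header without
  ``|`` uses its first token as both ids.  Sequences are uppercased and
  U is normalized to T on read; N is accepted (and never matches a site).
* Tabular outputs: TSV with a ``#`` comment header naming the tool
  version; hits, classes, edges and DE tables have fixed column orders.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from coexmir.expression import ExpressionMatrix
from coexmir.seeds import SeedHit

_VALID_BASES = re.compile(r"^[ACGTN]+$")


def _version_comment() -> str:
    from coexmir import __version__

    return f"# coexmir v{__version__}\n"


# ---------------------------------------------------------------------------
# expression matrix
# ---------------------------------------------------------------------------

def read_conditions_yaml(path: str | Path) -> dict[str, str]:
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict) or not all(
        isinstance(k, str) and isinstance(v, str) for k, v in data.items()
    ):
        raise ValueError(f"{path}: expected a flat sample -> condition mapping")
    return data


def write_conditions_yaml(conditions: dict[str, str], path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(dict(conditions), sort_keys=True))


def read_expression_tsv(path: str | Path, conditions_path: str | Path) -> ExpressionMatrix:
    """Read a genes x samples TSV plus its condition sidecar.

    Rejects duplicate gene ids (naming them), non-numeric or missing
    cells, and samples absent from the sidecar.
    """
    frame = pd.read_csv(path, sep="\t", index_col=0, comment="#",
                        float_precision="round_trip")
    if frame.index.has_duplicates:
        dupes = frame.index[frame.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate gene ids {dupes}")
    if frame.isna().any().any():
        rows = frame.index[frame.isna().any(axis=1)].tolist()
        raise ValueError(f"{path}: missing/non-numeric values in rows {rows}")
    try:
        frame = frame.astype(float)
    except (TypeError, ValueError) as err:
        raise ValueError(f"{path}: non-numeric cell: {err}") from err
    conditions = read_conditions_yaml(conditions_path)
    missing = [s for s in frame.columns if s not in conditions]
    if missing:
        raise ValueError(f"{conditions_path}: samples without condition: {missing}")
    frame.index = frame.index.astype(str)
    frame.index.name = "gene"
    return ExpressionMatrix(values=frame, conditions={str(k): v for k, v in conditions.items()})


def write_expression_tsv(
    matrix: ExpressionMatrix, path: str | Path, conditions_path: str | Path | None = None
) -> None:
    with open(path, "w") as fh:
        fh.write(_version_comment())
        matrix.values.to_csv(fh, sep="\t")
    if conditions_path is not None:
        write_conditions_yaml(matrix.conditions, conditions_path)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def parse_fasta_id(header_id: str) -> tuple[str, str]:
    """``geneID|transcriptID``; otherwise the first token doubles as both."""
    if "|" in header_id:
        gene, transcript = header_id.split("|", 1)
        return gene, transcript
    return header_id, header_id


def read_fasta(path: str | Path) -> list[tuple[str, str, str]]:
    """UTR records as ``(gene_id, transcript_id, sequence)`` tuples.

    Sequences are uppercased with U -> T; empty records or characters
    outside ACGTN(U) are rejected.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().replace("U", "T")
        if not seq:
            raise ValueError(f"{path}: empty sequence for record {rec.id!r}")
        if not _VALID_BASES.match(seq):
            bad = sorted(set(seq) - set("ACGTN"))
            raise ValueError(f"{path}: illegal characters {bad} in record {rec.id!r}")
        gene, transcript = parse_fasta_id(rec.id)
        records.append((gene, transcript, seq))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[tuple[str, str, str]], path: str | Path) -> None:
    seq_records = [
        SeqRecord(Seq(seq), id=f"{gene}|{transcript}", description="")
        for gene, transcript, seq in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


# ---------------------------------------------------------------------------
# tabular outputs
# ---------------------------------------------------------------------------

def _write_tsv(frame: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(_version_comment())
        frame.to_csv(fh, sep="\t", index=False)


def write_hits_tsv(hits: Sequence[SeedHit], path: str | Path) -> None:
    frame = pd.DataFrame(
        [(h.gene_id, h.transcript_id, h.arm, h.quality, h.position, h.site_sequence) for h in hits],
        columns=["gene", "transcript", "arm", "quality", "position", "site"],
    )
    _write_tsv(frame, path)


def write_classes_tsv(classes: dict[str, str], path: str | Path) -> None:
    frame = pd.DataFrame(sorted(classes.items()), columns=["gene", "seed_class"])
    _write_tsv(frame, path)


def write_edges_tsv(pairs: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in ["gene_a", "gene_b", "r", "p_raw", "p_adj"] if c in pairs.columns]
    _write_tsv(pairs[cols], path)


def write_de_tsv(table: pd.DataFrame, path: str | Path) -> None:
    cols = ["gene", "test", "statistic", "p_raw", "p_adj", "direction", "log2fc"]
    _write_tsv(table[cols], path)
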