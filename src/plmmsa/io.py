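"""Readers and writers for FASTA, A3M, taxonomy TSV and embedding stores."""

from __future__ import annotations

import math
from typing import Dict, Iterable, List, Tuple

import h5py
import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .encoder import ResidueEmbedding
from .errors import ParseError
from .msa_build import Msa, MsaRowMeta


def read_fasta(path: str) -> List[Tuple[str, str]]:
    """Read a multi-record FASTA into (id, sequence) tuples."""
    records = []
    for rec in SeqIO.parse(path, "fasta"):
        records.append((rec.id, str(rec.seq).upper()))
    if not records:
        raise ParseError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[Tuple[str, str]], path: str) -> None:
    SeqIO.write(
        [SeqRecord(Seq(seq), id=sid, description="") for sid, seq in records],
        path,
        "fasta-2line",
    )


def read_a3m(path: str) -> Msa:
    """Read an A3M alignment; validates the column-count invariant.

    Per-row metadata (score, taxid) is recovered from ``key=value`` tokens
    in the FASTA description when present.
    """
    rows: List[str] = []
    meta: List[MsaRowMeta] = []
    for n, rec in enumerate(SeqIO.parse(path, "fasta")):
        row = str(rec.seq)
        score = math.nan
        taxid = None
        for token in rec.description.split()[1:]:
            if token.startswith("score="):
                score = float(token[6:])
            elif token.startswith("taxid="):
                taxid = token[6:]
        if n == 0:
            if "-" in row:
                raise ParseError(f"{path}: record 1 (query) contains gaps")
            row = row.upper()
        else:
            cols = sum(1 for ch in row if ch == "-" or ch.isupper())
            if cols != len(rows[0]):
                raise ParseError(
                    f"{path}: record {n + 1} ({rec.id!r}) has {cols} match "
                    f"columns, expected {len(rows[0])}"
                )
        rows.append(row)
        meta.append(MsaRowMeta(sequence_id=rec.id, score=score, taxid=taxid))
    if not rows:
        raise ParseError(f"{path}: no A3M records found")
    return Msa(rows=rows, meta=meta)


def write_a3m(msa: Msa, path: str) -> None:
    """Write an Msa as A3M with score/taxid tokens in the headers."""
    with open(path, "w") as f:
        for row, m in zip(msa.rows, msa.meta):
            header = f">{m.sequence_id} score={m.score:.6g}"
            if m.taxid is not None:
                header += f" taxid={m.taxid}"
            f.write(header + "\n" + row + "\n")


def write_msa_metadata(msa: Msa, path: str) -> None:
    """Sidecar TSV: sequence_id, alignment score, taxid per row."""
    with open(path, "w") as f:
        f.write("sequence_id\tscore\ttaxid\n")
        for m in msa.meta:
            f.write(f"{m.sequence_id}\t{m.score:.6g}\t{m.taxid or ''}\n")


def read_taxonomy_tsv(path: str) -> Dict[str, str]:
    """Read a (sequence_id, taxid) tab-separated mapping.

    A header line ``sequence_id<TAB>taxid`` is accepted and skipped.
    """
    mapping: Dict[str, str] = {}
    with open(path) as f:
        for lineno, line in enumerate(f, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(f"{path}: line {lineno}: expected 2 tab-separated fields")
            if lineno == 1 and parts == ["sequence_id", "taxid"]:
                continue
            mapping[parts[0]] = parts[1]
    return mapping


def write_taxonomy_tsv(mapping: Dict[str, str], path: str) -> None:
    with open(path, "w") as f:
        f.write("sequence_id\ttaxid\n")
        for sid in sorted(mapping):
            f.write(f"{sid}\t{mapping[sid]}\n")


def save_embeddings(path: str, embeddings: Iterable[ResidueEmbedding]) -> None:
    """Persist per-sequence embedding matrices in one HDF5 container,
    one dataset per sequence id with the residue string as attribute."""
    with h5py.File(path, "w") as f:
        g = f.create_group("embeddings")
        for emb in embeddings:
            d = g.create_dataset(emb.sequence_id, data=emb.matrix)
            d.attrs["residues"] = emb.residues


def load_embeddings(path: str) -> Dict[str, ResidueEmbedding]:
    with h5py.File(path, "r") as f:
        g = f["embeddings"]
        return {
            sid: ResidueEmbedding(
                sequence_id=sid,
                residues=g[sid].attrs["residues"],
                matrix=g[sid][...],
            )
            for sid in g
        }


def read_coords_tsv(path: str) -> np.ndarray:
    """Read CA coordinates from a 3-column (x, y, z) TSV."""
    arr = np.loadtxt(path, delimiter="\t", ndmin=2)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise ParseError(f"{path}: expected 3 tab-separated columns of coordinates")
    return arr


def write_coords_tsv(coords: np.ndarray, path: str) -> None:
    np.savetxt(path, np.asarray(coords, dtype=float), delimiter="\t", fmt="%.6f")
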