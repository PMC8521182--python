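"""FASTA input and fingerprint TSV serialization.

Fingerprint files are TSV, one row per protein:
``protein_id<TAB>w1;w2;...;wn`` with weights in Da at fixed 4-decimal
formatting; an empty fingerprint is an empty second field. A JSON sidecar
(``<file>.params.json``) records the simulation parameters, seed and an
input checksum so runs are reproducible.
"""

from __future__ import annotations

import dataclasses
import gzip
import hashlib
import json
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

from .chemistry import CANONICAL_RESIDUES
from .digestion import Fingerprint, SimParams

__all__ = [
    "read_fasta",
    "screen_canonical",
    "write_fingerprints",
    "read_fingerprints",
    "write_params_sidecar",
]


def _parse_id(header_id: str) -> str:
    """UniProt accession when the header is ``db|ACC|NAME``, else the token."""
    parts = header_id.split("|")
    if len(parts) >= 3 and parts[1]:
        return parts[1]
    return header_id


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """(id, sequence) pairs from a plain or gzipped FASTA file."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        records = [(_parse_id(rec.id), str(rec.seq).upper()) for rec in SeqIO.parse(fh, "fasta")]
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def screen_canonical(
    records: Iterable[tuple[str, str]],
) -> tuple[list[tuple[str, str]], list[str]]:
    """Split records into canonical-only sequences and excluded ids.

    UniProt proteomes contain a handful of records with non-canonical
    characters (X, B, Z, U, O); those proteins are excluded from both the
    database and the query set, and their ids returned so the realized n
    is visible.
    """
    kept, excluded = [], []
    for pid, seq in records:
        if set(seq) <= CANONICAL_RESIDUES:
            kept.append((pid, seq))
        else:
            excluded.append(pid)
    return kept, excluded


def write_fingerprints(fingerprints: Iterable[Fingerprint], path: str | Path) -> None:
    with open(path, "w") as fh:
        for fp in fingerprints:
            weights = ";".join(f"{w:.4f}" for w in fp.weights)
            fh.write(f"{fp.protein_id}\t{weights}\n")


def read_fingerprints(path: str | Path) -> list[Fingerprint]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            pid, _, field = line.partition("\t")
            weights = tuple(float(w) for w in field.split(";")) if field else ()
            out.append(Fingerprint(protein_id=pid, weights=weights))
    return out


def file_checksum(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_params_sidecar(
    params: SimParams, out_path: str | Path, input_path: str | Path | None = None
) -> Path:
    sidecar = Path(str(out_path) + ".params.json")
    payload = dataclasses.asdict(params)
    payload["cleave_after"] = sorted(payload["cleave_after"])
    if input_path is not None:
        payload["input_checksum"] = file_checksum(input_path)
    sidecar.write_text(json.dumps(payload, indent=2) + "\n")
    return sidecar
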