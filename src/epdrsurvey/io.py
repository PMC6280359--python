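"""FASTA and table I/O helpers.

Proteome headers of the form ``id|taxon`` are sniffed automatically; a
user-supplied id -> taxon mapping (TSV) takes precedence, and sequences with
neither source of metadata fall back to the taxon ``unknown``.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO

__all__ = ["read_proteomes", "write_fasta", "read_taxon_map", "write_taxon_map"]


def _split_header(header: str) -> tuple[str, str | None]:
    if "|" in header:
        sid, taxon = header.split("|", 1)
        return sid, taxon or None
    return header, None


def read_proteomes(
    sources, taxa: Mapping[str, str] | None = None
) -> tuple[list[tuple[str, str]], dict[str, str]]:
    """Load protein sequences plus a per-sequence taxon map.

    ``sources`` may be FASTA paths or in-memory ``(id, sequence)`` pairs
    (ids may embed a taxon as ``id|taxon``).
    """
    pairs: list[tuple[str, str]] = []
    taxon_of: dict[str, str] = {}
    items: Iterable
    if isinstance(sources, (str, Path)):
        sources = [sources]
    for src in sources:
        if isinstance(src, (str, Path)):
            records = ((r.id, str(r.seq).upper())
                       for r in SeqIO.parse(str(src), "fasta"))
        else:
            records = [src]
        for header, seq in records:
            sid, taxon = _split_header(header)
            if sid in taxon_of:
                raise ValueError(f"duplicate sequence id {sid!r}")
            pairs.append((sid, seq))
            taxon_of[sid] = taxon or "unknown"
    if taxa:
        for sid, taxon in taxa.items():
            if sid in taxon_of:
                taxon_of[sid] = taxon
    return pairs, taxon_of


def write_fasta(pairs, path, taxa: Mapping[str, str] | None = None) -> None:
    """Write ``(id, sequence)`` pairs; taxa, when given, join headers as
    ``id|taxon``."""
    with open(path, "w") as fh:
        for sid, seq in pairs:
            header = f"{sid}|{taxa[sid]}" if taxa and sid in taxa else sid
            fh.write(f">{header}\n{seq}\n")


def read_taxon_map(path) -> dict[str, str]:
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            sid, taxon = line.split("\t")[:2]
            out[sid] = taxon
    return out


def write_taxon_map(taxa: Mapping[str, str], path) -> None:
    with open(path, "w") as fh:
        for sid, taxon in taxa.items():
            fh.write(f"{sid}\t{taxon}\n")
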