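"""Readers and writers for all on-disk artifacts.

Formats
-------
* FASTA / FASTQ (Phred+33) for reads and reference sequences. Reference
  FASTA headers may carry ``key=value`` attributes after the identifier
  (``gene=narG length_nt=1250``); lineages live in a companion table.
* Lineage tables: two tab-separated columns, ``ref_id`` and a
  semicolon-joined root-to-leaf lineage.
* Tabular hit files: the standard 12-column dialect (query, subject,
  percent identity, alignment length, mismatches, gap opens, qstart, qend,
  sstart, send, E-value, bit score), deterministically ordered by query id,
  then descending bit score, then subject id. Coordinates are 1-based
  inclusive; translated hits on the reverse strand have qstart > qend.
* Flat ``key=value`` run-configuration files (see :mod:`ncyc.config`).

Parsers raise :class:`ParseError` naming the offending line.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .config import RunConfig
from .records import AlignmentHit, ReferenceRecord, SequenceRead

__all__ = [
    "ParseError",
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "read_lineage_table",
    "write_lineage_table",
    "load_reference_db",
    "write_reference_db",
    "read_hits_table",
    "write_hits_table",
    "read_config",
    "write_config",
]


class ParseError(ValueError):
    """Malformed input file; the message names the file and line number."""


def _iter_fasta(path: str | Path):
    """Yield (line_number_of_header, id, description, sequence)."""
    header: str | None = None
    header_line = 0
    chunks: list[str] = []
    with open(path) as fh:
        lineno = 0
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(">"):
                if header is not None:
                    yield header_line, header, "".join(chunks)
                name = line[1:].strip()
                if not name:
                    raise ParseError(f"{path}:{lineno}: empty FASTA header")
                header = name
                header_line = lineno
                chunks = []
            else:
                if header is None:
                    raise ParseError(
                        f"{path}:{lineno}: sequence data before first header"
                    )
                chunks.append(line.strip())
        if header is not None:
            yield header_line, header, "".join(chunks)


def read_fasta(path: str | Path) -> list[SequenceRead]:
    """Read a FASTA file into :class:`SequenceRead` records.

    Sequences are uppercased and order is preserved. Duplicate identifiers,
    empty sequences and malformed headers are rejected with the line number.
    """
    records: list[SequenceRead] = []
    seen: set[str] = set()
    for lineno, header, seq in _iter_fasta(path):
        rid = header.split()[0]
        if rid in seen:
            raise ParseError(f"{path}:{lineno}: duplicate record id {rid!r}")
        if not seq:
            raise ParseError(f"{path}:{lineno}: record {rid!r} has no sequence")
        seen.add(rid)
        records.append(SequenceRead(rid, seq.upper()))
    return records


def write_fasta(records: Iterable[SequenceRead | ReferenceRecord],
                path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            if isinstance(rec, ReferenceRecord):
                fh.write(
                    f">{rec.ref_id} gene={rec.gene_family} "
                    f"length_nt={rec.length_nt}\n{rec.seq}\n"
                )
            else:
                fh.write(f">{rec.read_id}\n{rec.seq}\n")


def read_fastq(path: str | Path) -> list[SequenceRead]:
    """Read 4-line-record FASTQ with Phred+33 qualities."""
    records: list[SequenceRead] = []
    seen: set[str] = set()
    with open(path) as fh:
        lines = fh.read().splitlines()
    n = len(lines)
    # tolerate trailing blank lines only
    while n and not lines[n - 1].strip():
        n -= 1
    if n % 4 != 0:
        raise ParseError(f"{path}:{n}: truncated FASTQ record at end of file")
    for i in range(0, n, 4):
        head, seq, plus, qual = lines[i:i + 4]
        lineno = i + 1
        if not head.startswith("@"):
            raise ParseError(f"{path}:{lineno}: expected '@' header")
        rid = head[1:].split()[0] if head[1:].strip() else ""
        if not rid:
            raise ParseError(f"{path}:{lineno}: empty FASTQ header")
        if rid in seen:
            raise ParseError(f"{path}:{lineno}: duplicate record id {rid!r}")
        if not plus.startswith("+"):
            raise ParseError(f"{path}:{lineno + 2}: expected '+' separator")
        if len(seq) != len(qual):
            raise ParseError(
                f"{path}:{lineno + 3}: quality length {len(qual)} != "
                f"sequence length {len(seq)}"
            )
        if not seq:
            raise ParseError(f"{path}:{lineno + 1}: record {rid!r} has no sequence")
        seen.add(rid)
        records.append(
            SequenceRead(rid, seq.upper(), [ord(c) - 33 for c in qual])
        )
    return records


def write_fastq(records: Iterable[SequenceRead], path: str | Path,
                default_quality: int = 25) -> None:
    with open(path, "w") as fh:
        for rec in records:
            qual = rec.qual if rec.qual is not None \
                else [default_quality] * len(rec.seq)
            fh.write(
                f"@{rec.read_id}\n{rec.seq}\n+\n"
                + "".join(chr(q + 33) for q in qual) + "\n"
            )


def read_lineage_table(path: str | Path) -> dict[str, tuple[str, ...]]:
    """Read a two-column TSV mapping ref_id to a semicolon-joined lineage.

    Duplicate rows with identical lineages are deduplicated; conflicting
    duplicates are an error.
    """
    lineages: dict[str, tuple[str, ...]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2:
                raise ParseError(
                    f"{path}:{lineno}: expected 2 tab-separated columns, "
                    f"got {len(parts)}"
                )
            rid, path_str = parts
            lineage = tuple(t.strip() for t in path_str.split(";") if t.strip())
            if not lineage:
                raise ParseError(f"{path}:{lineno}: empty lineage for {rid!r}")
            if rid in lineages and lineages[rid] != lineage:
                raise ParseError(
                    f"{path}:{lineno}: conflicting lineages for {rid!r}"
                )
            lineages[rid] = lineage
    return lineages


def write_lineage_table(lineages: dict[str, Sequence[str]],
                        path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid in sorted(lineages):
            fh.write(f"{rid}\t{';'.join(lineages[rid])}\n")


def load_reference_db(fasta_path: str | Path,
                      lineage_path: str | Path) -> list[ReferenceRecord]:
    """Assemble :class:`ReferenceRecord` objects from FASTA + lineage TSV.

    The FASTA headers carry ``gene=`` and optionally ``length_nt=``
    attributes; every FASTA id must appear in the lineage table.
    """
    lineages = read_lineage_table(lineage_path)
    records: list[ReferenceRecord] = []
    missing: list[str] = []
    seen: set[str] = set()
    for lineno, header, seq in _iter_fasta(fasta_path):
        tokens = header.split()
        rid = tokens[0]
        if rid in seen:
            raise ParseError(
                f"{fasta_path}:{lineno}: duplicate record id {rid!r}"
            )
        seen.add(rid)
        if not seq:
            raise ParseError(
                f"{fasta_path}:{lineno}: record {rid!r} has no sequence"
            )
        attrs = dict(t.split("=", 1) for t in tokens[1:] if "=" in t)
        gene = attrs.get("gene", "background")
        length_nt = int(attrs.get("length_nt", 3 * len(seq)))
        if rid not in lineages:
            missing.append(rid)
            continue
        records.append(
            ReferenceRecord(rid, seq.upper(), gene, lineages[rid], length_nt)
        )
    if missing:
        raise ParseError(
            f"{fasta_path}: ids missing from lineage table "
            f"{Path(lineage_path).name}: {', '.join(sorted(missing))}"
        )
    return records


def write_reference_db(records: Sequence[ReferenceRecord],
                       fasta_path: str | Path,
                       lineage_path: str | Path) -> None:
    write_fasta(records, fasta_path)
    write_lineage_table({r.ref_id: r.lineage for r in records}, lineage_path)


_HIT_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def hit_sort_key(hit: AlignmentHit):
    return (hit.query_id, -hit.bit_score, hit.subject_id)


def write_hits_table(hits: Iterable[AlignmentHit], path: str | Path) -> None:
    """Write hits in the 12-column tabular dialect, deterministically ordered."""
    ordered = sorted(hits, key=hit_sort_key)
    with open(path, "w") as fh:
        for h in ordered:
            fh.write(
                "\t".join([
                    h.query_id,
                    h.subject_id,
                    f"{100.0 * h.identity_fraction:.2f}",
                    str(h.aligned_cols),
                    str(h.mismatches),
                    str(h.gap_opens),
                    str(h.q_start),
                    str(h.q_end),
                    str(h.s_start),
                    str(h.s_end),
                    f"{h.evalue:.3e}",
                    f"{h.bit_score:.6g}",
                ]) + "\n"
            )


def read_hits_table(path: str | Path) -> list[AlignmentHit]:
    """Read a 12-column hit table.

    The dialect does not carry the translation frame explicitly; hits with
    qstart > qend are restored with frame -1 and the rest with frame +1
    (strand only). Raw scores are not stored and come back as 0.
    """
    hits: list[AlignmentHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 12:
                raise ParseError(
                    f"{path}:{lineno}: expected 12 columns, got {len(parts)}"
                )
            qstart, qend = int(parts[6]), int(parts[7])
            hits.append(AlignmentHit(
                query_id=parts[0],
                subject_id=parts[1],
                frame=-1 if qstart > qend else 1,
                raw_score=0,
                bit_score=float(parts[11]),
                evalue=float(parts[10]),
                identity_fraction=float(parts[2]) / 100.0,
                aligned_cols=int(parts[3]),
                mismatches=int(parts[4]),
                gap_opens=int(parts[5]),
                q_start=qstart,
                q_end=qend,
                s_start=int(parts[8]),
                s_end=int(parts[9]),
            ))
    return hits


def write_config(config: RunConfig, path: str | Path) -> None:
    flat = config.to_flat()
    with open(path, "w") as fh:
        for key in sorted(flat):
            fh.write(f"{key}={flat[key]}\n")


def read_config(path: str | Path) -> RunConfig:
    flat: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ParseError(f"{path}:{lineno}: expected key=value")
            key, _, val = line.partition("=")
            flat[key.strip()] = val.strip()
    return RunConfig.from_flat(flat)


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a pandas table as TSV (stable column order, no index)."""
    df.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
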