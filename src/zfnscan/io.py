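"""Readers and writers for the plain-text formats used throughout the package.

FASTA/FASTQ parsing is delegated to Biopython; BED and the amplicon manifest
are simple tab-delimited formats validated here with line-number errors.
All writers go through :func:`atomic_write` so no output file is ever left
half-written on error.
"""

from __future__ import annotations

import contextlib
import gzip
import hashlib
import os
import tempfile
from typing import IO, Iterable, Iterator

from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator


def _open_text(path: str) -> IO[str]:
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fasta(path: str, uppercase: bool = True) -> list[tuple[str, str]]:
    """Read a (possibly multi-record, arbitrarily wrapped) FASTA file."""
    records = []
    with _open_text(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            seq = str(rec.seq)
            records.append((rec.id, seq.upper() if uppercase else seq))
    return records


def write_fasta(path: str, records: Iterable[tuple[str, str]], width: int = 70) -> None:
    with atomic_write(path) as out:
        for name, seq in records:
            out.write(f">{name}\n")
            for i in range(0, len(seq), width):
                out.write(seq[i : i + width] + "\n")


def read_fastq(path: str) -> Iterator[tuple[str, str, str]]:
    """Yield (id, sequence, quality); gzip transparent; truncation errors
    name the offending record index."""
    with _open_text(path) as handle:
        it = FastqGeneralIterator(handle)
        index = 0
        while True:
            try:
                title, seq, qual = next(it)
            except StopIteration:
                return
            except ValueError as exc:
                raise ValueError(f"truncated/malformed FASTQ record {index} in {path}: {exc}") from exc
            yield title.split()[0], seq.upper(), qual
            index += 1


def write_fastq(path: str, records: Iterable[tuple[str, str, str]]) -> None:
    opener = gzip.open if str(path).endswith(".gz") else open
    with atomic_write(path, opener=opener) as out:
        for name, seq, qual in records:
            out.write(f"@{name}\n{seq}\n+\n{qual}\n")


def read_seqs(path: str) -> list[str]:
    """Read sequences from FASTA or one-sequence-per-line text (auto-detected)."""
    with _open_text(path) as handle:
        first = handle.read(1)
    if first == ">":
        return [seq for _, seq in read_fasta(path)]
    with _open_text(path) as handle:
        return [line.strip().upper() for line in handle if line.strip()]


def read_bed(path: str) -> list[tuple]:
    """Read a BED file (0-based, half-open). Returns tuples of the first
    3+ columns; malformed lines raise with their line number."""
    intervals = []
    with _open_text(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\r\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: BED line has {len(fields)} fields, need >= 3")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer BED coordinates") from exc
            if end <= start:
                raise ValueError(f"{path}:{lineno}: BED interval end <= start ({start}, {end})")
            intervals.append((fields[0], start, end, *fields[3:]))
    return intervals


def write_bed(path: str, rows: Iterable[Iterable]) -> None:
    with atomic_write(path) as out:
        for row in rows:
            out.write("\t".join(str(x) for x in row) + "\n")


def write_tsv(path: str, frame) -> None:
    """Write a pandas DataFrame as TSV (deterministic, no index)."""
    with atomic_write(path) as out:
        frame.to_csv(out, sep="\t", index=False)


@contextlib.contextmanager
def atomic_write(path: str, opener=open):
    """Write to a temp file in the target directory, rename on success."""
    directory = os.path.dirname(os.path.abspath(path))
    fd, tmp = tempfile.mkstemp(dir=directory, prefix=".tmp-", suffix=os.path.basename(path))
    os.close(fd)
    try:
        with opener(tmp, "wt") as handle:
            yield handle
        os.replace(tmp, path)
    finally:
        with contextlib.suppress(FileNotFoundError):
            os.remove(tmp)


def sha256_of(path: str) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(1 << 20), b""):
            digest.update(chunk)
    return digest.hexdigest()
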