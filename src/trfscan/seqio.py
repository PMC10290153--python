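"""Sequence and interval file I/O.

FASTA goes through Bio.SeqIO.  FASTQ uses a strict four-line reader so that a
malformed record can be reported by its record index (plain or gzip input;
fixed 'I' qualities on output).  tRNA locus tables are 5-column TSV
(chrom, start, end, strand, gene_name) in 1-based fully-closed coordinates —
the dialect of published tRNA locus tables where length = end - start + 1 —
with an optional flag to ingest UCSC-style 0-based half-open BED intervals.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import IO, Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .annotation import TrnaLocus
from .errors import DataError, FastqParseError
from .sequtils import VALID_BASES, revcomp

__all__ = ["read_fasta", "write_fasta", "read_fastq_sequences", "write_fastq",
           "read_loci_tsv", "write_loci_tsv", "revcomp"]


def _open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)  # type: ignore[return-value]
    return open(path, mode)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered {name: sequence} mapping."""
    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="")
               for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fastq_sequences(path: str | Path) -> list[str]:
    """Read sequences from a FASTQ file (plain or gzip).

    Raises FastqParseError naming the 0-based index of the offending record
    when a record is truncated or its markers/lengths are inconsistent.
    """
    reads: list[str] = []
    with _open_text(path) as fh:
        idx = 0
        while True:
            header = fh.readline()
            if header == "":
                break
            header = header.rstrip("\n")
            seq = fh.readline().rstrip("\n")
            plus = fh.readline().rstrip("\n")
            qual = fh.readline().rstrip("\n")
            if not header.startswith("@"):
                raise FastqParseError("header does not start with '@'", idx)
            if seq == "" and plus == "" and qual == "":
                raise FastqParseError("truncated record", idx)
            if not plus.startswith("+"):
                raise FastqParseError("separator line does not start with '+'", idx)
            if len(qual) != len(seq):
                raise FastqParseError(
                    f"quality length {len(qual)} != sequence length {len(seq)}", idx
                )
            bad = set(seq.upper()) - VALID_BASES
            if bad:
                raise FastqParseError(f"invalid bases {sorted(bad)}", idx)
            reads.append(seq.upper())
            idx += 1
    return reads


def write_fastq(reads: Iterable[str], path: str | Path, prefix: str = "read") -> None:
    with _open_text(path, "wt") as fh:
        for i, seq in enumerate(reads):
            fh.write(f"@{prefix}_{i}\n{seq}\n+\n{'I' * len(seq)}\n")


def read_loci_tsv(path: str | Path, zero_based: bool = False) -> list[TrnaLocus]:
    """Read a 5-column locus TSV; header line optional.

    With ``zero_based=True`` intervals are interpreted as 0-based half-open
    (BED) and converted to the 1-based closed convention used internally.
    """
    loci: list[TrnaLocus] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if lineno == 1 and parts[0].lower() in {"chrom", "chr"}:
                continue
            if len(parts) < 5:
                raise DataError(f"{path}:{lineno}: expected 5 columns, got {len(parts)}")
            chrom, start_s, end_s, strand, name = parts[:5]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise DataError(f"{path}:{lineno}: non-integer coordinate") from exc
            if zero_based:
                start = start + 1  # half-open end equals closed end
            if strand not in {"+", "-"}:
                raise DataError(f"{path}:{lineno}: strand must be '+' or '-'")
            if end < start:
                raise DataError(f"{path}:{lineno}: end < start ({end} < {start})")
            loci.append(TrnaLocus(chrom, start, end, strand, name))
    return loci


def write_loci_tsv(loci: Iterable[TrnaLocus], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tstrand\tgene_name\n")
        for loc in loci:
            fh.write(f"{loc.chrom}\t{loc.start}\t{loc.end}\t{loc.strand}\t{loc.gene_name}\n")
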