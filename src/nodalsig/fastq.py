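"""Split overlap-merged single-end reads back into paired-end mates.

Adapter-removal tools that detect overlapping R1/R2 mates emit a merged
single-end read per fragment.  To keep such fragments usable by a
paired-end aligner, each merged read is split at its midpoint into
non-overlapping mates: R1 keeps the first ceil(L/2) bases in the original
orientation, R2 is the reverse complement of the remaining floor(L/2) bases
with reversed qualities, restoring standard forward/reverse pair
orientation.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass

_COMPLEMENT = str.maketrans("ACGTUNRYSWKMBDHVacgtunryswkmbdhv",
                            "TGCAANYRSWMKVHDBtgcaanyrswmkvhdb")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class FastqRecord:
    read_id: str
    sequence: str
    qualities: str

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError(
                f"sequence/quality length mismatch for {self.read_id!r}"
            )


def split_merged_read(
    record: FastqRecord, suffixes: tuple[str, str] = ("/1", "/2")
) -> tuple[FastqRecord, FastqRecord]:
    """Split a merged read at its midpoint into an (R1, R2) mate pair.

    R1 = first ceil(L/2) bases unchanged; R2 = reverse complement of the
    rest with reversed qualities.  The two mates partition the merged read:
    ``R1.sequence + reverse_complement(R2.sequence)`` reconstructs it.
    """
    length = len(record.sequence)
    if length < 2:
        raise ValueError("merged read must be at least 2 bases long")
    cut = (length + 1) // 2
    r1 = FastqRecord(record.read_id + suffixes[0],
                     record.sequence[:cut], record.qualities[:cut])
    r2 = FastqRecord(record.read_id + suffixes[1],
                     reverse_complement(record.sequence[cut:]),
                     record.qualities[cut:][::-1])
    return r1, r2


def _open(path, mode: str):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode + "t")
    return open(path, mode)


def read_fastq(path):
    """Yield FastqRecord from a (possibly gzipped) Phred+33 FASTQ file."""
    with _open(path, "r") as fh:
        index = 0
        while True:
            block = [fh.readline() for _ in range(4)]
            if block[0] == "":
                return
            if any(line == "" for line in block[1:]):
                raise ValueError(f"truncated FASTQ record at index {index}")
            header, seq, plus, qual = (line.rstrip("\n") for line in block)
            if not header.startswith("@") or not plus.startswith("+"):
                raise ValueError(f"malformed FASTQ record at index {index}")
            yield FastqRecord(header[1:], seq, qual)
            index += 1


def write_fastq(records, path) -> int:
    n = 0
    with _open(path, "w") as fh:
        for rec in records:
            fh.write(f"@{rec.read_id}\n{rec.sequence}\n+\n{rec.qualities}\n")
            n += 1
    return n


def split_merged_fastq(in_path, out_r1_path, out_r2_path,
                       suffixes: tuple[str, str] = ("/1", "/2")) -> int:
    """Split every record of a merged-read FASTQ into R1/R2 files.

    Order is preserved and both outputs contain one record per input
    record.  Returns the number of reads split.
    """
    n = 0
    with _open(out_r1_path, "w") as fh1, _open(out_r2_path, "w") as fh2:
        for rec in read_fastq(in_path):
            r1, r2 = split_merged_read(rec, suffixes)
            fh1.write(f"@{r1.read_id}\n{r1.sequence}\n+\n{r1.qualities}\n")
            fh2.write(f"@{r2.read_id}\n{r2.sequence}\n+\n{r2.qualities}\n")
            n += 1
    return n
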