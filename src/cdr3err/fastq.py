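"""FASTQ input/output and the basic read container.

Reads are single-end amplicon reads with Sanger-style encoded qualities
(Phred+33 by default; a ``phred_offset`` switch handles Phred+64 data from
older instruments). Lane and sample labels may travel in the FASTQ title
line as ``lane=<int>`` / ``sample=<label>`` tokens, which keeps simulated
data round-trippable through plain FASTQ without a side-car file.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field, replace
from typing import IO, Iterable, Iterator

import numpy as np
from Bio.SeqIO.QualityIO import FastqGeneralIterator


@dataclass
class SequencingRead:
    """One FASTQ record: id, nucleotide string, per-base integer qualities."""

    read_id: str
    seq: str
    quals: np.ndarray
    lane: int | None = None
    sample_path: str | None = None

    def __post_init__(self) -> None:
        self.quals = np.asarray(self.quals, dtype=np.int16)
        if len(self.quals) != len(self.seq):
            raise ValueError(
                f"read {self.read_id}: {len(self.quals)} qualities for "
                f"{len(self.seq)} bases"
            )

    def __len__(self) -> int:
        return len(self.seq)


class FastqFormatError(ValueError):
    """Raised for malformed FASTQ records, reporting the offending line."""


def _open_text(path, mode: str = "rt") -> IO[str]:
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def _parse_title(title: str) -> tuple[str, int | None, str | None]:
    tokens = title.split()
    read_id = tokens[0] if tokens else ""
    lane: int | None = None
    sample: str | None = None
    for tok in tokens[1:]:
        if tok.startswith("lane="):
            try:
                lane = int(tok[5:])
            except ValueError:
                pass
        elif tok.startswith("sample="):
            sample = tok[7:]
    return read_id, lane, sample


def read_fastq(
    path,
    phred_offset: int = 33,
    lane: int | None = None,
    sample_path: str | None = None,
) -> Iterator[SequencingRead]:
    """Stream ``SequencingRead`` objects from a (optionally gzipped) FASTQ file.

    Qualities are decoded as ``ord(char) - phred_offset``. ``lane`` /
    ``sample_path`` act as defaults for reads whose title line does not carry
    its own ``lane=`` / ``sample=`` tokens. Malformed records raise
    :class:`FastqFormatError` naming the approximate line number.
    """
    n_records = 0
    with _open_text(path) as handle:
        try:
            for title, seq, qual in FastqGeneralIterator(handle):
                read_id, rl, rs = _parse_title(title)
                quals = (
                    np.frombuffer(qual.encode("ascii"), dtype=np.uint8).astype(np.int16)
                    - phred_offset
                )
                if quals.size and quals.min() < 0:
                    raise FastqFormatError(
                        f"negative quality near line {4 * n_records + 4}: "
                        f"wrong phred offset ({phred_offset})?"
                    )
                yield SequencingRead(
                    read_id=read_id,
                    seq=seq.upper(),
                    quals=quals,
                    lane=rl if rl is not None else lane,
                    sample_path=rs if rs is not None else sample_path,
                )
                n_records += 1
        except ValueError as exc:
            if isinstance(exc, FastqFormatError):
                raise
            raise FastqFormatError(
                f"malformed FASTQ record near line {4 * n_records + 1}: {exc}"
            ) from exc


def write_fastq(reads: Iterable[SequencingRead], path_or_handle, phred_offset: int = 33) -> int:
    """Write 4-line FASTQ; returns the number of records written."""

    def _emit(handle) -> int:
        n = 0
        for read in reads:
            title = read.read_id
            if read.lane is not None:
                title += f" lane={read.lane}"
            if read.sample_path is not None:
                title += f" sample={read.sample_path}"
            qual = "".join(chr(int(q) + phred_offset) for q in read.quals)
            handle.write(f"@{title}\n{read.seq}\n+\n{qual}\n")
            n += 1
        return n

    if hasattr(path_or_handle, "write"):
        return _emit(path_or_handle)
    with _open_text(path_or_handle, "wt") as handle:
        return _emit(handle)
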