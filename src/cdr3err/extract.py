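"""Read validation and CDR3 extraction.

Implements the acceptance criteria for a CDR3 read:

(i)   exact (100%-identity) matches of the V- and J-side mapping segments,
      found in either read orientation;
(ii)  the spanned CDR3 is in frame, free of N, and translates without a stop;
(iii) the conserved C codon sits immediately V-proximal to the CDR3 and an
      FGXG/FAXG/HGXG motif immediately J-proximal (with flank segments that
      end in the C codon / start at the F codon this is enforced structurally
      by the exact flank match, but it is re-checked on the oriented read so
      that arbitrary flank choices still honour the criterion).

The returned CDR3 excludes the C and F codons. Rejections carry a single
reason, evaluated in a fixed order so counts are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .fastq import SequencingRead, read_fastq, write_fastq  # noqa: F401  (re-export)
from .sequtil import matches_cdr3_motif, revcomp, translate

REJECTION_REASONS = (
    "no_flank_match",
    "v_mismatch",
    "j_mismatch",
    "out_of_frame",
    "stop_codon",
    "contains_N",
    "motif_fail",
    "low_quality",
)


@dataclass(frozen=True)
class FlankSpec:
    """The V- and J-side mapping segments flanking the CDR3.

    ``v_segment`` must end with the conserved cysteine codon and ``j_segment``
    begin with the F/H codon of the J motif (the usual configuration; 27-nt J
    segments and 25-30-nt V segments are typical).
    """

    v_segment: str
    j_segment: str

    def __post_init__(self) -> None:
        if len(self.v_segment) < 3:
            raise ValueError("v_segment must be at least one codon long")
        if len(self.j_segment) < 12:
            raise ValueError("j_segment must cover the 4-codon J motif (>= 12 nt)")
        for label, s in (("v_segment", self.v_segment), ("j_segment", self.j_segment)):
            if set(s) - set("ACGT"):
                raise ValueError(f"{label} contains non-ACGT characters")

    @classmethod
    def from_template(cls, template, v_len: int = 27, j_len: int = 27) -> "FlankSpec":
        """Mapping segments taken from a simulation template (V suffix, J prefix)."""
        v_len = min(v_len, len(template.v_flank))
        j_len = min(j_len, len(template.j_flank))
        return cls(template.v_flank[-v_len:], template.j_flank[:j_len])


@dataclass
class CDR3Record:
    """A validated CDR3 extraction: sequence, window qualities, provenance."""

    read_id: str
    cdr3_nt: str
    cdr3_quals: np.ndarray
    orientation: str
    lane: int | None = None
    sample_path: str | None = None

    def __post_init__(self) -> None:
        self.cdr3_quals = np.asarray(self.cdr3_quals, dtype=np.int16)

    @property
    def min_q(self) -> int:
        return int(self.cdr3_quals.min()) if self.cdr3_quals.size else 0


@dataclass(frozen=True)
class RejectionRecord:
    read_id: str
    reason: str

    def __post_init__(self) -> None:
        if self.reason not in REJECTION_REASONS:
            raise ValueError(f"unknown rejection reason {self.reason!r}")


@dataclass(frozen=True)
class FlankMatch:
    orientation: str
    v_end: int
    j_start: int


def trim_adapters(read: SequencingRead, adapters: Sequence[str]) -> SequencingRead:
    """Remove exact adapter occurrences at the read ends (qualities in lockstep)."""
    seq, quals = read.seq, read.quals
    for adapter in adapters:
        if adapter and seq.startswith(adapter):
            seq = seq[len(adapter) :]
            quals = quals[len(adapter) :]
        if adapter and seq.endswith(adapter):
            seq = seq[: -len(adapter)]
            quals = quals[: -len(adapter)]
    if seq is read.seq:
        return read
    return SequencingRead(read.read_id, seq, quals, read.lane, read.sample_path)


def orient_and_match(read: SequencingRead, flanks: FlankSpec) -> FlankMatch | RejectionRecord:
    """Locate the flanks by exact substring search, trying both orientations.

    The V segment is searched first (leftmost match), then the J segment
    strictly 3' of it (leftmost). The forward strand is tried before the
    reverse complement. Any N inside a flank cannot exact-match, so the
    100%-identity criterion is enforced by construction.
    """
    v_found = False
    for orientation, s in ((("forward"), read.seq), (("reverse"), revcomp(read.seq))):
        vpos = s.find(flanks.v_segment)
        if vpos == -1:
            continue
        v_found = True
        v_end = vpos + len(flanks.v_segment)
        jpos = s.find(flanks.j_segment, v_end)
        if jpos == -1:
            continue
        return FlankMatch(orientation=orientation, v_end=v_end, j_start=jpos)
    return RejectionRecord(read.read_id, "j_mismatch" if v_found else "no_flank_match")


def validate_and_extract(read: SequencingRead, flanks: FlankSpec) -> CDR3Record | RejectionRecord:
    """Apply the full validity criteria to one read.

    Check order (short-circuit): flank match → frame → N content → stop
    codon → conserved-residue motif. The CDR3 returned excludes the C and F
    codons, which lie inside the matched flanks.
    """
    match = orient_and_match(read, flanks)
    if isinstance(match, RejectionRecord):
        return match
    if match.orientation == "forward":
        s, q = read.seq, read.quals
    else:
        s, q = revcomp(read.seq), read.quals[::-1]
    span = s[match.v_end : match.j_start]
    if len(span) % 3:
        return RejectionRecord(read.read_id, "out_of_frame")
    if "N" in span:
        return RejectionRecord(read.read_id, "contains_N")
    if "*" in translate(span):
        return RejectionRecord(read.read_id, "stop_codon")
    c_aa = translate(s[match.v_end - 3 : match.v_end])
    if match.j_start + 12 > len(s):
        return RejectionRecord(read.read_id, "motif_fail")
    motif_aa = translate(s[match.j_start : match.j_start + 12])
    if c_aa != "C" or not matches_cdr3_motif(motif_aa):
        return RejectionRecord(read.read_id, "motif_fail")
    return CDR3Record(
        read_id=read.read_id,
        cdr3_nt=span,
        cdr3_quals=q[match.v_end : match.j_start],
        orientation=match.orientation,
        lane=read.lane,
        sample_path=read.sample_path,
    )


def extract_all(
    reads: Iterable[SequencingRead],
    flanks: FlankSpec,
    adapters: Sequence[str] = (),
) -> tuple[list[CDR3Record], list[RejectionRecord]]:
    """Validate every read; each input lands in exactly one of the two outputs."""
    records: list[CDR3Record] = []
    rejections: list[RejectionRecord] = []
    for read in reads:
        if adapters:
            read = trim_adapters(read, adapters)
        result = validate_and_extract(read, flanks)
        if isinstance(result, CDR3Record):
            records.append(result)
        else:
            rejections.append(result)
    return records, rejections


def phred_filter(records: Iterable[CDR3Record], q_cutoff: int) -> tuple[list[CDR3Record], int]:
    """Keep records whose minimum CDR3 base quality is >= q_cutoff.

    A cutoff of 0 passes everything (qualities are non-negative). Pass sets
    are nested: the q=30 set is a subset of q=20, of q=10, of q=0.
    """
    if q_cutoff < 0:
        raise ValueError("q_cutoff must be non-negative")
    records = list(records)
    passing = [r for r in records if r.min_q >= q_cutoff]
    return passing, len(records) - len(passing)


def records_to_table(records: Sequence[CDR3Record]):
    """CDR3 records as a tidy DataFrame (read_id, cdr3_nt, orientation, lane, sample_path, min_q)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "read_id": [r.read_id for r in records],
            "cdr3_nt": [r.cdr3_nt for r in records],
            "orientation": [r.orientation for r in records],
            "lane": [r.lane for r in records],
            "sample_path": [r.sample_path for r in records],
            "min_q": [r.min_q for r in records],
        }
    )


def rejections_to_table(rejections: Sequence[RejectionRecord]):
    import pandas as pd

    return pd.DataFrame(
        {
            "read_id": [r.read_id for r in rejections],
            "reason": [r.reason for r in rejections],
        }
    )
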