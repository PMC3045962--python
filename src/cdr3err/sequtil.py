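"""Small nucleotide-sequence helpers shared across modules."""

from __future__ import annotations

from Bio.Data import CodonTable

NT_ORDER = "ACGT"
NT_INDEX = {nt: i for i, nt in enumerate(NT_ORDER)}
TRANSITION_PARTNER = {"A": "G", "G": "A", "C": "T", "T": "C"}

_STANDARD = CodonTable.unambiguous_dna_by_id[1]
CODON_TO_AA: dict[str, str] = dict(_STANDARD.forward_table)
for _stop in _STANDARD.stop_codons:
    CODON_TO_AA[_stop] = "*"
STOP_CODONS = frozenset(_STANDARD.stop_codons)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# Codons for which no single-nucleotide substitution yields a stop codon:
# all stops start with T, so it suffices that the codon does not start with
# T and that positions 2-3 are not one of AA/AG/GA (which a first-position
# change to T would turn into TAA/TAG/TGA).
SAFE_CODONS: tuple[str, ...] = tuple(
    a + b + c
    for a in "ACG"
    for b in "ACGT"
    for c in "ACGT"
    if (b + c) not in ("AA", "AG", "GA")
)


def revcomp(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


def translate(nt: str) -> str:
    """Translate an in-frame nucleotide string; stops are '*', unknown codons 'X'."""
    if len(nt) % 3:
        raise ValueError(f"length {len(nt)} is not divisible by 3")
    return "".join(CODON_TO_AA.get(nt[i : i + 3], "X") for i in range(0, len(nt), 3))


def matches_cdr3_motif(aa4: str) -> bool:
    """True if a 4-residue peptide matches the conserved J-side FGXG/FAXG/HGXG motif."""
    if len(aa4) != 4 or aa4[3] != "G":
        return False
    return (aa4[0], aa4[1]) in (("F", "G"), ("F", "A"), ("H", "G"))
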