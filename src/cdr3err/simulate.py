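"""Synthetic CDR3 amplicon reads with a controllable error process.

This module generates single-end FASTQ reads of a V-flank/CDR3/J-flank
amplicon together with a per-read ground-truth table, emulating the error
structure of Illumina-style amplicon sequencing of T-cell receptor CDR3β
regions:

* position- and substitution-specific error rates (up to several-hundred-fold
  differences between cells),
* a transition-enriched substitution spectrum (C→T, G→A, A→G, T→C),
* lane-specific multiplicative perturbations of cell rates,
* read-orientation-specific rates (templates cluster on the flow cell in
  either orientation; reverse reads are emitted reverse-complemented),
* quality scores correlated with error status (error bases draw from a
  low-Phred distribution), and
* rare in-frame single-codon deletions/insertions inside the CDR3, so the
  truncated/elongated length classes seen among frame-valid reads are
  exercisable.

All randomness flows from a single integer seed; identical seeds and
configurations give byte-identical FASTQ output and truth tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .fastq import SequencingRead
from .sequtil import (
    NT_INDEX,
    NT_ORDER,
    SAFE_CODONS,
    TRANSITION_PARTNER,
    matches_cdr3_motif,
    revcomp,
    translate,
)

FORWARD = "forward"
REVERSE = "reverse"

_NT_BYTES = np.frombuffer(NT_ORDER.encode("ascii"), dtype=np.uint8)


class InvalidTemplateError(ValueError):
    """Template violates a named construction criterion."""

    def __init__(self, criterion: str, message: str):
        self.criterion = criterion
        super().__init__(f"{criterion}: {message}")


@dataclass(frozen=True)
class TemplateSpec:
    """A monoclonal amplicon template.

    The amplicon is ``pad_5p + v_flank + cdr3 + j_flank + pad_3p``; the
    V flank ends with the codon of the conserved cysteine and the J flank
    begins with the codon of the conserved phenylalanine of an FGXG-type
    motif, so the CDR3 proper (between C and F, exclusive) is ``cdr3``.
    """

    name: str
    v_flank: str
    cdr3: str
    j_flank: str
    pad_5p: str = ""
    pad_3p: str = ""

    def __post_init__(self) -> None:
        for label, s in (
            ("pad_5p", self.pad_5p),
            ("v_flank", self.v_flank),
            ("cdr3", self.cdr3),
            ("j_flank", self.j_flank),
            ("pad_3p", self.pad_3p),
        ):
            if set(s) - set("ACGT"):
                raise InvalidTemplateError("alphabet", f"{label} contains non-ACGT characters")
        if len(self.v_flank) < 3:
            raise InvalidTemplateError("v_flank_c", "v_flank shorter than one codon")
        if translate(self.v_flank[-3:]) != "C":
            raise InvalidTemplateError(
                "v_flank_c", f"v_flank must end with a cysteine codon, got {self.v_flank[-3:]}"
            )
        if len(self.cdr3) % 3:
            raise InvalidTemplateError("cdr3_frame", f"CDR3 length {len(self.cdr3)} not in frame")
        if len(self.j_flank) < 12:
            raise InvalidTemplateError("j_motif", "j_flank shorter than the 4-codon motif")
        motif = translate(self.j_flank[:12])
        if not matches_cdr3_motif(motif):
            raise InvalidTemplateError(
                "j_motif", f"j_flank must start with FGXG/FAXG/HGXG, got {motif}"
            )
        context = translate(self.v_flank[-3:] + self.cdr3 + self.j_flank[:12])
        if "*" in context:
            raise InvalidTemplateError("stop_codon", f"stop codon in CDR3 context ({context})")

    @property
    def sequence(self) -> str:
        return self.pad_5p + self.v_flank + self.cdr3 + self.j_flank + self.pad_3p

    @property
    def cdr3_start(self) -> int:
        """0-based start of the CDR3 window in template coordinates (half-open)."""
        return len(self.pad_5p) + len(self.v_flank)

    @property
    def cdr3_end(self) -> int:
        return self.cdr3_start + len(self.cdr3)

    def __len__(self) -> int:
        return len(self.sequence)


# --- built-in synthetic templates ------------------------------------------
# Flanks are synthetic stand-ins with the conserved C / FGXG architecture of
# real Vβ/Jβ segments (V segment 30 nt, J segment 27 nt). The CDR3s are built
# from codons no single substitution of which creates a stop codon, so every
# injected substitution remains observable downstream.

DEFAULT_V_FLANK = "GCCTCAAGTCTCTCCTACGAGCAGTACTGT"  # 30 nt, ends ...TGT (C)
DEFAULT_J_FLANK = "TTTGGCGCAGGCACCACGCTGACTGTG"  # 27 nt, starts FGAG motif
DEFAULT_CDR3_36 = "GCCAGTGGCCTCCATATCGTCCCTGGGCGTACCGCG"
DEFAULT_CDR3_30 = DEFAULT_CDR3_36[:30]


def example_template(cdr3_length: int = 36, name: str | None = None, read_length: int = 125) -> TemplateSpec:
    """A built-in synthetic monoclonal template with a 30- or 36-nt CDR3."""
    if cdr3_length == 36:
        cdr3 = DEFAULT_CDR3_36
    elif cdr3_length == 30:
        cdr3 = DEFAULT_CDR3_30
    else:
        raise ValueError("built-in templates have CDR3 length 30 or 36")
    core = len(DEFAULT_V_FLANK) + cdr3_length + len(DEFAULT_J_FLANK)
    pad_total = read_length - core
    if pad_total < 0:
        raise ValueError(f"read_length {read_length} shorter than core amplicon ({core})")
    pad5 = ("ACGT" * read_length)[: pad_total // 2]
    pad3 = ("TGCA" * read_length)[: pad_total - pad_total // 2]
    return TemplateSpec(
        name=name or f"mono{cdr3_length}",
        v_flank=DEFAULT_V_FLANK,
        cdr3=cdr3,
        j_flank=DEFAULT_J_FLANK,
        pad_5p=pad5,
        pad_3p=pad3,
    )


def random_cdr3(n_codons: int, rng: np.random.Generator) -> str:
    """Random CDR3 from stop-robust codons (no single substitution creates a stop)."""
    idx = rng.integers(0, len(SAFE_CODONS), size=n_codons)
    return "".join(SAFE_CODONS[i] for i in idx)


def random_polyclonal_templates(
    n_clones: int,
    seed: int = 0,
    cdr3_length: int = 36,
    read_length: int = 125,
) -> list[TemplateSpec]:
    """Distinct random clonotypes sharing the built-in V/J flanks (one 'repertoire')."""
    rng = np.random.default_rng(seed)
    base = example_template(cdr3_length, read_length=read_length)
    seen: set[str] = set()
    out: list[TemplateSpec] = []
    while len(out) < n_clones:
        cdr3 = random_cdr3(cdr3_length // 3, rng)
        if cdr3 in seen:
            continue
        seen.add(cdr3)
        out.append(
            TemplateSpec(
                name=f"clone{len(out):04d}",
                v_flank=base.v_flank,
                cdr3=cdr3,
                j_flank=base.j_flank,
                pad_5p=base.pad_5p,
                pad_3p=base.pad_3p,
            )
        )
    return out


def zipf_abundances(n_clones: int, exponent: float = 1.0) -> np.ndarray:
    """Power-law clone frequencies p_i ∝ rank^-exponent (a skewed repertoire)."""
    w = np.arange(1, n_clones + 1, dtype=float) ** (-exponent)
    return w / w.sum()


# --- quality model -----------------------------------------------------------


@dataclass(frozen=True)
class QualityModel:
    """Discrete Phred distributions for correct vs erroneous base calls.

    Error bases draw mostly low scores, correct bases mostly high ones, giving
    the quality/error association that makes Phred-cutoff filtering selective.
    A fraction of error bases nevertheless receives high scores, so a q=30
    filter reduces but does not eliminate errors.
    """

    correct_values: np.ndarray
    correct_probs: np.ndarray
    error_values: np.ndarray
    error_probs: np.ndarray

    def __post_init__(self) -> None:
        for label, p in (("correct", self.correct_probs), ("error", self.error_probs)):
            if abs(float(np.sum(p)) - 1.0) > 1e-9:
                raise ValueError(f"{label} probabilities must sum to 1")

    @classmethod
    def default(
        cls, p_correct_high: float = 0.99, p_error_high: float = 0.10
    ) -> "QualityModel":
        high = np.arange(30, 41)
        low_correct = np.arange(20, 30)
        low_error = np.arange(2, 26)
        cv = np.concatenate([low_correct, high])
        cp = np.concatenate(
            [
                np.full(low_correct.size, (1 - p_correct_high) / low_correct.size),
                np.full(high.size, p_correct_high / high.size),
            ]
        )
        ev = np.concatenate([low_error, high])
        ep = np.concatenate(
            [
                np.full(low_error.size, (1 - p_error_high) / low_error.size),
                np.full(high.size, p_error_high / high.size),
            ]
        )
        return cls(cv, cp, ev, ep)

    @staticmethod
    def _draw(values, probs, rng: np.random.Generator, size) -> np.ndarray:
        cum = np.cumsum(probs)
        cum[-1] = 1.0
        idx = np.searchsorted(cum, rng.random(size), side="right")
        return np.asarray(values, dtype=np.int16)[idx]

    def sample_correct(self, rng: np.random.Generator, size) -> np.ndarray:
        return self._draw(self.correct_values, self.correct_probs, rng, size)

    def sample_error(self, rng: np.random.Generator, size) -> np.ndarray:
        return self._draw(self.error_values, self.error_probs, rng, size)


# --- error model -------------------------------------------------------------


@dataclass
class ErrorModel:
    """Parameterized per-read error process.

    ``sub_rate`` is either a scalar (per position per alternative nucleotide)
    or an (L, 4) matrix of per-read probabilities of substituting the template
    base at each position to A/C/G/T (self-cells are ignored).
    ``direction_bias`` multiplies rates on reverse-orientation reads;
    ``lane_multipliers`` maps lane → multiplier (scalar or (L, 4)).
    ``del_rate``/``ins_rate`` are per-read probabilities of one in-frame codon
    deletion/insertion inside the CDR3. ``burst_fraction`` of reads have all
    substitution rates multiplied by ``burst_boost``, correlating errors
    within a read (an error 'complementation' regime); the default process is
    position-independent.
    """

    sub_rate: float | np.ndarray = 0.0
    direction_bias: float | np.ndarray = 1.0
    lane_multipliers: Mapping[int, float | np.ndarray] = field(default_factory=dict)
    del_rate: float = 0.0
    ins_rate: float = 0.0
    burst_fraction: float = 0.0
    burst_boost: float = 1.0
    qual: QualityModel = field(default_factory=QualityModel.default)
    p_forward: float = 0.5

    def rate_matrix(self, template: TemplateSpec, lane: int, orientation: str) -> np.ndarray:
        """Effective (L, 4) substitution-probability matrix for one stratum."""
        seq = template.sequence
        L = len(seq)
        if np.isscalar(self.sub_rate):
            m = np.full((L, 4), float(self.sub_rate))
        else:
            m = np.array(self.sub_rate, dtype=float)
            if m.shape != (L, 4):
                raise ValueError(f"sub_rate shape {m.shape} != ({L}, 4)")
            m = m.copy()
        mult = self.lane_multipliers.get(lane, 1.0)
        m *= mult
        if orientation == REVERSE:
            m *= self.direction_bias
        self_idx = np.fromiter((NT_INDEX[c] for c in seq), dtype=np.int64, count=L)
        m[np.arange(L), self_idx] = 0.0
        if (m < 0).any():
            raise ValueError("negative substitution rates")
        if (m.sum(axis=1) * max(self.burst_boost, 1.0) >= 1.0).any():
            raise ValueError("per-position total substitution probability must stay < 1")
        return m


def heterogeneous_rate_matrix(
    length: int,
    seed: int = 0,
    low: float = 1e-5,
    high: float = 5e-3,
) -> np.ndarray:
    """Log-uniform per-(position, substitution) rates, emulating the large
    (tens- to hundreds-fold) spread between the least and most error-prone cells."""
    rng = np.random.default_rng(seed)
    return 10.0 ** rng.uniform(np.log10(low), np.log10(high), size=(length, 4))


def transition_enriched(matrix: np.ndarray, template_seq: str, boost: float = 8.0, cap: float = 5e-3) -> np.ndarray:
    """Boost the transition cell (ref→transition partner) at every position.

    Emulates the dominance of the four substitutions C→T, G→A, A→G, T→C.
    Boosted cells are capped so per-position totals stay well below 1.
    """
    out = np.array(matrix, dtype=float)
    for pos, ref in enumerate(template_seq):
        j = NT_INDEX[TRANSITION_PARTNER[ref]]
        out[pos, j] = min(out[pos, j] * boost, cap)
    return out


def default_error_model(
    template: TemplateSpec,
    seed: int = 0,
    n_lanes: int = 3,
    rate_range: tuple[float, float] = (1e-5, 1.2e-3),
    transition_boost: float = 8.0,
    transition_cap: float = 1.5e-3,
    lane_spread: tuple[float, float] = (0.5, 2.0),
    direction_spread: tuple[float, float] = (0.2, 5.0),
    del_rate: float = 2e-5,
    ins_rate: float = 5e-6,
    p_forward: float = 0.5,
) -> ErrorModel:
    """Study-condition default error process for a template.

    Heterogeneous log-uniform cell rates with transition enrichment, per-cell
    lane multipliers, and per-cell direction bias (so erroneous clonotypes
    acquire orientation skew). The default rate range yields a raw CDR3 error
    rate of a few percent over a 36-nt window with a ~200-fold spread between
    the least and most error-prone cells. Indels are rare enough that
    non-correct-length errors stay <1% of the error population.
    """
    rng = np.random.default_rng(seed)
    L = len(template)
    base = 10.0 ** rng.uniform(np.log10(rate_range[0]), np.log10(rate_range[1]), size=(L, 4))
    base = transition_enriched(base, template.sequence, boost=transition_boost, cap=transition_cap)
    lanes = {
        lane: 10.0 ** rng.uniform(np.log10(lane_spread[0]), np.log10(lane_spread[1]), size=(L, 4))
        for lane in range(1, n_lanes + 1)
    }
    direction = 10.0 ** rng.uniform(
        np.log10(direction_spread[0]), np.log10(direction_spread[1]), size=(L, 4)
    )
    return ErrorModel(
        sub_rate=base,
        direction_bias=direction,
        lane_multipliers=lanes,
        del_rate=del_rate,
        ins_rate=ins_rate,
        p_forward=p_forward,
    )


# --- study design ------------------------------------------------------------


@dataclass(frozen=True)
class StudyDesign:
    """Sample-path × lane structure of a sequencing experiment.

    The trifurcating preset splits material into 3 preparation paths × 3
    ligation paths × 3 flow-cell lanes = 27 independent sequencing reactions;
    lane effects apply per lane only, not per preparation path.
    """

    combos: tuple[tuple[str, int], ...]
    seed: int = 0

    @property
    def sample_paths(self) -> tuple[str, ...]:
        return tuple(sorted({s for s, _ in self.combos}))

    @property
    def lanes(self) -> tuple[int, ...]:
        return tuple(sorted({l for _, l in self.combos}))

    @property
    def n_lanes(self) -> int:
        return len(self.lanes)


def preset_study_design(seed: int = 0) -> StudyDesign:
    """The 3 × 3 × 3 trifurcating design: 27 (sample_path, lane) reactions."""
    sample_paths = [f"p{a}.l{b}" for a in (1, 2, 3) for b in (1, 2, 3)]
    combos = tuple((s, lane) for lane in (1, 2, 3) for s in sample_paths)
    return StudyDesign(combos=combos, seed=seed)


# --- the simulator -----------------------------------------------------------

TRUTH_COLUMNS = ["read_id", "template", "orientation", "lane", "sample_path", "errors", "indels"]


def simulate_reads(
    templates: TemplateSpec | Sequence[TemplateSpec],
    model: ErrorModel,
    n_reads: int,
    n_lanes: int = 1,
    seed: int = 0,
    abundances: Sequence[float] | None = None,
    design: StudyDesign | None = None,
    id_prefix: str = "sim",
) -> tuple[list[SequencingRead], pd.DataFrame]:
    """Simulate reads and their ground truth.

    Returns ``(reads, truth)`` where ``reads`` is a list of
    :class:`~cdr3err.fastq.SequencingRead` (reverse-orientation reads already
    reverse-complemented, with reversed qualities) and ``truth`` is a table
    with one row per read: template name, true orientation, lane, sample
    path, and the injected substitutions (``pos:from>to`` in 0-based template
    coordinates, semicolon-joined) and indels (``del:pos`` / ``ins:pos:SEQ``).

    With a ``design``, reads are split near-evenly over its (sample_path,
    lane) reactions; otherwise lanes 1..n_lanes are assigned uniformly at
    random and the sample path is ``"s1"``.
    """
    if isinstance(templates, TemplateSpec):
        templates = [templates]
    templates = list(templates)
    if not templates:
        raise ValueError("at least one template required")
    if n_reads <= 0:
        raise ValueError("n_reads must be positive")
    if abundances is None:
        abundances = np.full(len(templates), 1.0 / len(templates))
    else:
        abundances = np.asarray(abundances, dtype=float)
        if abundances.size != len(templates):
            raise ValueError("one abundance per template required")
        if abs(abundances.sum() - 1.0) > 1e-8:
            raise ValueError("abundances must sum to 1")

    rng = np.random.default_rng(seed)

    t_idx = (
        rng.choice(len(templates), size=n_reads, p=abundances)
        if len(templates) > 1
        else np.zeros(n_reads, dtype=np.int64)
    )
    if design is not None:
        combos = list(design.combos)
        combo_idx = rng.permutation(np.resize(np.arange(len(combos)), n_reads))
        lanes = np.array([combos[i][1] for i in combo_idx], dtype=np.int64)
        samples = np.array([combos[i][0] for i in combo_idx], dtype=object)
    else:
        lanes = rng.integers(1, n_lanes + 1, size=n_reads)
        samples = np.full(n_reads, "s1", dtype=object)
    is_fwd = rng.random(n_reads) < model.p_forward
    is_burst = (
        rng.random(n_reads) < model.burst_fraction
        if model.burst_fraction > 0
        else np.zeros(n_reads, dtype=bool)
    )

    reads: list[SequencingRead | None] = [None] * n_reads
    truth_rows: list[tuple | None] = [None] * n_reads

    # Group reads by stratum so error sampling is vectorized; iterate strata in
    # sorted order so output is a pure function of (config, seed).
    keys = sorted(
        set(zip(t_idx.tolist(), lanes.tolist(), is_fwd.tolist(), is_burst.tolist()))
    )
    for ti, lane, fwd, burst in keys:
        sel = (t_idx == ti) & (lanes == lane) & (is_fwd == fwd) & (is_burst == burst)
        idx = np.nonzero(sel)[0]
        tpl = templates[ti]
        seq = tpl.sequence
        L = len(seq)
        orientation = FORWARD if fwd else REVERSE
        R = model.rate_matrix(tpl, int(lane), orientation)
        if burst:
            R = R * model.burst_boost
        tot = R.sum(axis=1)
        cum = np.cumsum(R, axis=1)
        m = idx.size

        err_mask = rng.random((m, L)) < tot[None, :]
        rows, cols = np.nonzero(err_mask)
        if rows.size:
            targets = rng.random(rows.size) * tot[cols]
            to_idx = (cum[cols] <= targets[:, None]).sum(axis=1)
        else:
            to_idx = np.empty(0, dtype=np.int64)

        quals = model.qual.sample_correct(rng, (m, L))
        if rows.size:
            quals[rows, cols] = model.qual.sample_error(rng, rows.size)

        n_codons = len(tpl.cdr3) // 3
        has_del = rng.random(m) < model.del_rate if model.del_rate > 0 else np.zeros(m, bool)
        has_ins = rng.random(m) < model.ins_rate if model.ins_rate > 0 else np.zeros(m, bool)
        has_ins &= ~has_del  # at most one indel per read

        seq_bytes = seq.encode("ascii")
        # split error cells per read (rows are sorted: np.nonzero is row-major)
        split_at = np.searchsorted(rows, np.arange(1, m))
        per_read_cells = np.split(np.arange(rows.size), split_at)

        for local, i in enumerate(idx):
            cells = per_read_cells[local] if rows.size else ()
            q = quals[local]
            err_tokens: list[str] = []
            if len(cells):
                b = bytearray(seq_bytes)
                for k in cells:
                    pos = int(cols[k])
                    b[pos] = _NT_BYTES[to_idx[k]]
                    err_tokens.append(f"{pos}:{seq[pos]}>{NT_ORDER[to_idx[k]]}")
                read_seq = b.decode("ascii")
            else:
                read_seq = seq
            indel_tokens: list[str] = []
            if has_del[local] and n_codons:
                p = tpl.cdr3_start + 3 * int(rng.integers(0, n_codons))
                read_seq = read_seq[:p] + read_seq[p + 3 :]
                q = np.concatenate([q[:p], q[p + 3 :]])
                indel_tokens.append(f"del:{p}")
            elif has_ins[local]:
                p = tpl.cdr3_start + 3 * int(rng.integers(0, n_codons + 1))
                codon = SAFE_CODONS[int(rng.integers(0, len(SAFE_CODONS)))]
                read_seq = read_seq[:p] + codon + read_seq[p:]
                q = np.concatenate([q[:p], model.qual.sample_error(rng, 3), q[p:]])
                indel_tokens.append(f"ins:{p}:{codon}")
            if not fwd:
                read_seq = revcomp(read_seq)
                q = q[::-1]
            rid = f"{id_prefix}-{i:07d}"
            reads[i] = SequencingRead(
                read_id=rid, seq=read_seq, quals=q, lane=int(lane), sample_path=str(samples[i])
            )
            truth_rows[i] = (
                rid,
                tpl.name,
                orientation,
                int(lane),
                str(samples[i]),
                ";".join(err_tokens),
                ";".join(indel_tokens),
            )

    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    return [r for r in reads if r is not None], truth


def write_truth(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def read_truth(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", keep_default_na=False, dtype={"errors": str, "indels": str})
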