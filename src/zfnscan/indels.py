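"""Quantification of ZFN-induced NHEJ indels at candidate loci from treated
and untreated amplicon deep-sequencing reads.

Workflow per arm (treated / control):

1. reads are demultiplexed to amplicons by primer match (Hamming budget);
2. each unique read sequence is globally aligned to its amplicon reference
   with affine gap penalties;
3. alignments covering < 40 reference bases are dropped, and reads whose
   best-scoring reference is a *different* amplicon are excluded
   (cross-amplicon best-hit check);
4. a read is NHEJ-positive when it carries at least one indel of >= 2 nt
   whose left-normalized reference interval intersects the ZFN spacer;
5. per amplicon, treated vs control NHEJ read counts are compared with a
   one-sided Fisher's exact test; a site is significant at p < 0.05
   (strict), provided both arms retain >= 1500 usable reads.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import pandas as pd
from scipy.stats import fisher_exact

from . import _align
from ._dna import encode, revcomp


@dataclass(frozen=True)
class AlignScoring:
    match: float = 2.0
    mismatch: float = -2.0
    gap_open: float = -6.0
    gap_extend: float = -1.0


@dataclass(frozen=True)
class Amplicon:
    """One locus of the amplicon manifest.

    ``spacer_interval`` = [spacer_start, spacer_end) in 0-based half-open
    reference coordinates of the ZFN spacer.
    """

    name: str
    reference_seq: str
    fwd_primer: str
    rev_primer: str
    spacer_start: int
    spacer_end: int

    def __post_init__(self):
        object.__setattr__(self, "reference_seq", self.reference_seq.upper())
        object.__setattr__(self, "fwd_primer", self.fwd_primer.upper())
        object.__setattr__(self, "rev_primer", self.rev_primer.upper())
        ref = self.reference_seq
        if not ref.startswith(self.fwd_primer):
            raise ValueError(f"amplicon {self.name}: forward primer is not a reference prefix")
        if not ref.endswith(revcomp(self.rev_primer)):
            raise ValueError(f"amplicon {self.name}: reverse primer does not match the reference 3' end")
        if not 0 <= self.spacer_start < self.spacer_end <= len(ref):
            raise ValueError(f"amplicon {self.name}: invalid spacer interval")

    @property
    def spacer_interval(self) -> tuple[int, int]:
        return (self.spacer_start, self.spacer_end)


class AlnOp(NamedTuple):
    op: str  # "match" | "mismatch" | "ins" | "del"
    length: int
    ref_pos: int  # reference start of the op (insertion point for "ins")
    read_pos: int


@dataclass
class ReadAlignment:
    read_id: str
    amplicon: str
    score: float
    ops: tuple  # tuple[AlnOp, ...], indels left-normalized
    read: str

    @property
    def ref_bases_aligned(self) -> int:
        """Reference bases paired with read bases (match/mismatch columns).

        Deletion columns are excluded: a global alignment always consumes the
        full reference through deletions, so counting them would make the
        minimum-coverage filter vacuous — a 30-nt fragment must count as
        covering 30 reference bases, not the whole amplicon.
        """
        return sum(op.length for op in self.ops if op.op in ("match", "mismatch"))


@dataclass(frozen=True)
class IndelEvent:
    type: str  # "ins" | "del"
    length: int
    ref_start: int
    ref_end: int  # == ref_start for insertions (point interval)
    qualifies: bool


@dataclass
class SiteCallResult:
    amplicon: str
    treated_indel_reads: int
    treated_total_reads: int
    control_indel_reads: int
    control_total_reads: int
    p_value: float | None
    significant: bool
    status: str  # "called" | "excluded_low_depth" | "excluded_ambiguous"

    @property
    def indel_rate_treated(self) -> float:
        return self.treated_indel_reads / self.treated_total_reads if self.treated_total_reads else float("nan")

    @property
    def indel_rate_control(self) -> float:
        return self.control_indel_reads / self.control_total_reads if self.control_total_reads else float("nan")


# --- read -> amplicon assignment ----------------------------------------

def _hamming_prefix(read: str, primer: str) -> int | None:
    if len(read) < len(primer):
        return None
    return sum(a != b for a, b in zip(read, primer))


@dataclass
class AssignmentResult:
    assigned: dict  # amplicon name -> list[(read_id, oriented_seq)]
    n_total: int = 0
    n_unassigned_nomatch: int = 0
    n_unassigned_ambiguous: int = 0


def assign_reads(
    reads: Iterable[tuple],
    amplicons: Sequence[Amplicon],
    max_primer_mismatches: int = 2,
) -> AssignmentResult:
    """Map reads to amplicons by primer sequence.

    A read matches an amplicon when its prefix is within the mismatch budget
    of the forward primer (read in reference orientation) or of the reverse
    primer (read is the reverse-complement strand and gets re-oriented).
    Reads matching zero or >= 2 amplicons are counted as unassigned.
    """
    names = [a.name for a in amplicons]
    if len(set(names)) != len(names):
        raise ValueError("duplicate amplicon names in manifest")
    result = AssignmentResult(assigned={a.name: [] for a in amplicons})
    for rec in reads:
        read_id, seq = rec[0], rec[1].upper()
        result.n_total += 1
        hits = []
        for amp in amplicons:
            d_fwd = _hamming_prefix(seq, amp.fwd_primer)
            d_rev = _hamming_prefix(seq, amp.rev_primer)
            candidates = [(d, o) for d, o in ((d_fwd, "fwd"), (d_rev, "rev")) if d is not None and d <= max_primer_mismatches]
            if candidates:
                d, orient = min(candidates)  # tie -> fwd ("fwd" < "rev")
                hits.append((amp, orient))
        if not hits:
            result.n_unassigned_nomatch += 1
        elif len(hits) > 1:
            result.n_unassigned_ambiguous += 1
        else:
            amp, orient = hits[0]
            oriented = seq if orient == "fwd" else revcomp(seq)
            result.assigned[amp.name].append((read_id, oriented))
    return result


# --- alignment -----------------------------------------------------------

def _moves_to_ops(moves: list[str], read: str, ref: str) -> tuple[AlnOp, ...]:
    ops: list[AlnOp] = []
    i = j = 0
    for move in moves:
        if move == "M":
            kind = "match" if (read[i] == ref[j] and read[i] in "ACGT") else "mismatch"
            di, dj = 1, 1
        elif move == "D":
            kind, di, dj = "del", 0, 1
        else:
            kind, di, dj = "ins", 1, 0
        if ops and ops[-1].op == kind:
            prev = ops[-1]
            ops[-1] = AlnOp(kind, prev.length + 1, prev.ref_pos, prev.read_pos)
        else:
            ops.append(AlnOp(kind, 1, j, i))
        i += di
        j += dj
    return tuple(ops)


def align_affine(
    read: str,
    reference: str,
    match: float = 2.0,
    mismatch: float = -2.0,
    gap_open: float = -6.0,
    gap_extend: float = -1.0,
    read_id: str = "",
    amplicon: str = "",
) -> ReadAlignment:
    """Global affine-gap alignment of a read against an amplicon reference.

    Deterministic traceback (ties prefer diagonal > deletion > insertion);
    indels in the returned op-list are left-normalized.
    """
    read, reference = read.upper(), reference.upper()
    if not read or not reference:
        raise ValueError("empty sequence")
    score, moves = _align.align_moves(encode(read), encode(reference), match, mismatch, gap_open, gap_extend)
    moves = _align.left_normalize(moves, read, reference)
    return ReadAlignment(read_id=read_id, amplicon=amplicon, score=score, ops=_moves_to_ops(moves, read, reference), read=read)


def alignment_score(read: str, reference: str, scoring: AlignScoring) -> float:
    return _align.align_score(
        encode(read.upper()), encode(reference.upper()), scoring.match, scoring.mismatch, scoring.gap_open, scoring.gap_extend
    )


# --- filters -------------------------------------------------------------

def filter_alignments(
    alignments: Iterable[ReadAlignment], min_ref_bases: int = 40
) -> tuple[list[ReadAlignment], list[ReadAlignment]]:
    """Drop alignments covering fewer than ``min_ref_bases`` reference bases
    (the minimum combined primer length).  Returns (kept, dropped)."""
    kept, dropped = [], []
    for aln in alignments:
        (kept if aln.ref_bases_aligned >= min_ref_bases else dropped).append(aln)
    return kept, dropped


def depth_ok(n_treated: int, n_control: int, min_reads: int = 1500) -> bool:
    """Amplicon passes the depth gate only when both arms retain enough reads."""
    return n_treated >= min_reads and n_control >= min_reads


# --- collapsing & cross-amplicon exclusion -------------------------------

@dataclass
class CollapsedRecord:
    ops: tuple
    count: int
    representative: ReadAlignment


def collapse_alignments(
    alignments: Sequence[tuple[ReadAlignment, int]],
    amplicon: Amplicon,
    all_amplicons: Sequence[Amplicon],
    scoring: AlignScoring = AlignScoring(),
) -> tuple[list[CollapsedRecord], list[tuple[ReadAlignment, int]]]:
    """Condense identical alignments into counted records, excluding reads
    that align strictly better to a different amplicon's reference."""
    others = [a for a in all_amplicons if a.name != amplicon.name]
    collapsed: dict[tuple, CollapsedRecord] = {}
    excluded: list[tuple[ReadAlignment, int]] = []
    best_other_cache: dict[str, float] = {}
    for aln, count in alignments:
        if others:
            if aln.read not in best_other_cache:
                best_other_cache[aln.read] = max(
                    alignment_score(aln.read, other.reference_seq, scoring) for other in others
                )
            if best_other_cache[aln.read] > aln.score:
                excluded.append((aln, count))
                continue
        key = aln.ops
        if key in collapsed:
            collapsed[key].count += count
        else:
            collapsed[key] = CollapsedRecord(ops=key, count=count, representative=aln)
    return list(collapsed.values()), excluded


# --- indel calling -------------------------------------------------------

def call_indels(alignment: ReadAlignment, spacer_interval: tuple[int, int]) -> tuple[list[IndelEvent], bool]:
    """Emit every indel op as an event; an event *qualifies* as a putative
    mutagenic NHEJ scar when it is >= 2 nt and originates from the spacer:
    deletions must intersect [s_start, s_end); insertion points satisfy
    s_start <= point <= s_end (inclusive at both spacer ends)."""
    s_start, s_end = spacer_interval
    events: list[IndelEvent] = []
    for op in alignment.ops:
        if op.op == "del":
            a, b = op.ref_pos, op.ref_pos + op.length
            qualifies = op.length >= 2 and a < s_end and b > s_start
            events.append(IndelEvent("del", op.length, a, b, qualifies))
        elif op.op == "ins":
            a = op.ref_pos
            qualifies = op.length >= 2 and s_start <= a <= s_end
            events.append(IndelEvent("ins", op.length, a, a, qualifies))
    return events, any(e.qualifies for e in events)


# --- per-site significance test ------------------------------------------

def test_site(
    treated: tuple[int, int],
    control: tuple[int, int],
    alpha: float = 0.05,
    alternative: str = "greater",
    name: str = "",
) -> SiteCallResult:
    """One-sided Fisher's exact test for indel enrichment in the treated arm.

    The 2x2 table is [[k1, n1-k1], [k0, n0-k0]]; significance requires
    p < alpha strictly."""
    k1, n1 = treated
    k0, n0 = control
    if k1 > n1 or k0 > n0 or k1 < 0 or k0 < 0:
        raise ValueError("indel read counts must satisfy 0 <= k <= n")
    if n1 == 0 or n0 == 0:
        return SiteCallResult(name, k1, n1, k0, n0, None, False, "excluded_low_depth")
    _, p = fisher_exact([[k1, n1 - k1], [k0, n0 - k0]], alternative=alternative)
    p = float(p)
    return SiteCallResult(name, k1, n1, k0, n0, p, p < alpha, "called")


# --- orchestration -------------------------------------------------------

@dataclass
class ArmAccounting:
    reads_total: int = 0
    unassigned_nomatch: int = 0
    unassigned_ambiguous: int = 0
    assigned: Counter = field(default_factory=Counter)
    dropped_short: Counter = field(default_factory=Counter)
    cross_target: Counter = field(default_factory=Counter)
    retained: Counter = field(default_factory=Counter)
    nhej_reads: Counter = field(default_factory=Counter)


@dataclass
class PipelineReport:
    results: list  # SiteCallResult per amplicon (manifest order)
    treated: ArmAccounting
    control: ArmAccounting
    events: pd.DataFrame  # one row per (unique alignment, indel event)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "amplicon": r.amplicon,
                    "treated_indel_reads": r.treated_indel_reads,
                    "treated_total_reads": r.treated_total_reads,
                    "control_indel_reads": r.control_indel_reads,
                    "control_total_reads": r.control_total_reads,
                    "indel_rate_treated": r.indel_rate_treated,
                    "indel_rate_control": r.indel_rate_control,
                    "p_value": r.p_value if r.p_value is not None else float("nan"),
                    "significant": bool(r.significant),
                    "status": r.status,
                }
                for r in self.results
            ]
        )


def _process_arm(
    reads: Iterable[tuple],
    amplicons: Sequence[Amplicon],
    arm: str,
    scoring: AlignScoring,
    max_primer_mismatches: int,
    min_ref_bases: int,
    alignment_cache: dict,
    event_rows: list,
) -> ArmAccounting:
    acct = ArmAccounting()
    assignment = assign_reads(reads, amplicons, max_primer_mismatches)
    acct.reads_total = assignment.n_total
    acct.unassigned_nomatch = assignment.n_unassigned_nomatch
    acct.unassigned_ambiguous = assignment.n_unassigned_ambiguous
    for amp in amplicons:
        assigned = assignment.assigned[amp.name]
        acct.assigned[amp.name] = len(assigned)
        seq_counts = Counter(seq for _, seq in assigned)
        aligned: list[tuple[ReadAlignment, int]] = []
        for seq, count in seq_counts.items():
            cache_key = (amp.name, seq)
            if cache_key not in alignment_cache:
                alignment_cache[cache_key] = align_affine(
                    seq,
                    amp.reference_seq,
                    scoring.match,
                    scoring.mismatch,
                    scoring.gap_open,
                    scoring.gap_extend,
                    amplicon=amp.name,
                )
            aln = alignment_cache[cache_key]
            if aln.ref_bases_aligned < min_ref_bases:
                acct.dropped_short[amp.name] += count
            else:
                aligned.append((aln, count))
        collapsed, excluded = collapse_alignments(aligned, amp, amplicons, scoring)
        acct.cross_target[amp.name] += sum(count for _, count in excluded)
        for record in collapsed:
            acct.retained[amp.name] += record.count
            events, flag = call_indels(record.representative, amp.spacer_interval)
            if flag:
                acct.nhej_reads[amp.name] += record.count
            for ev in events:
                event_rows.append(
                    {
                        "arm": arm,
                        "amplicon": amp.name,
                        "type": ev.type,
                        "length": ev.length,
                        "ref_start": ev.ref_start,
                        "ref_end": ev.ref_end,
                        "qualifies": ev.qualifies,
                        "read_count": record.count,
                    }
                )
    return acct


def quantify_indels(
    amplicons: Sequence[Amplicon],
    treated_reads: Iterable[tuple],
    control_reads: Iterable[tuple],
    max_primer_mismatches: int = 2,
    min_ref_bases: int = 40,
    min_reads: int = 1500,
    alpha: float = 0.05,
    scoring: AlignScoring = AlignScoring(),
    alternative: str = "greater",
    multiple_testing: str = "none",
) -> PipelineReport:
    """Run the full treated-vs-control indel quantification pipeline."""
    if multiple_testing not in ("none", "bh"):
        raise ValueError("multiple_testing must be 'none' or 'bh'")
    cache: dict = {}
    event_rows: list[dict] = []
    treated = _process_arm(treated_reads, amplicons, "treated", scoring, max_primer_mismatches, min_ref_bases, cache, event_rows)
    control = _process_arm(control_reads, amplicons, "control", scoring, max_primer_mismatches, min_ref_bases, cache, event_rows)
    results = []
    for amp in amplicons:
        n1, n0 = treated.retained[amp.name], control.retained[amp.name]
        k1, k0 = treated.nhej_reads[amp.name], control.nhej_reads[amp.name]
        if not depth_ok(n1, n0, min_reads):
            results.append(SiteCallResult(amp.name, k1, n1, k0, n0, None, False, "excluded_low_depth"))
        else:
            results.append(test_site((k1, n1), (k0, n0), alpha=alpha, alternative=alternative, name=amp.name))
    if multiple_testing == "bh":
        from statsmodels.stats.multitest import multipletests

        called = [r for r in results if r.status == "called"]
        if called:
            reject, _, _, _ = multipletests([r.p_value for r in called], alpha=alpha, method="fdr_bh")
            for r, rej in zip(called, reject):
                r.significant = bool(rej)
    columns = ["arm", "amplicon", "type", "length", "ref_start", "ref_end", "qualifies", "read_count"]
    events = pd.DataFrame(event_rows, columns=columns)
    return PipelineReport(results=results, treated=treated, control=control, events=events)


def read_manifest(path: str) -> list[Amplicon]:
    """Read the amplicon manifest TSV: name, reference, fwd_primer,
    rev_primer, spacer_start, spacer_end (0-based half-open)."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    required = ["name", "reference", "fwd_primer", "rev_primer", "spacer_start", "spacer_end"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValueError(f"manifest {path} is missing column(s) {missing}")
    return [
        Amplicon(
            name=row["name"],
            reference_seq=row["reference"],
            fwd_primer=row["fwd_primer"],
            rev_primer=row["rev_primer"],
            spacer_start=int(row["spacer_start"]),
            spacer_end=int(row["spacer_end"]),
        )
        for _, row in frame.iterrows()
    ]
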