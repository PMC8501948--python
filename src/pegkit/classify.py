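"""Amplicon-read outcome classification.

Reads are assigned to the outcome taxonomy used for prime-editing amplicon
sequencing: unmodified (WT), correct prime edit, partial template duplication
(PTD: the intended edit plus extra RT-template-derived sequence inserted at
the break), or other indels. Summary percentages follow the field's
arithmetic: unintended = 100 - correct - WT, indels = unintended - PTDs, and
"any intended edit" counts every read carrying the PBS-adjacent edit
signature regardless of additional modifications.

Classification precedence per read (after orientation normalisation):

1. no indel in the quantification window against the reference and the
   reference allele intact at the edit site -> WT;
2. same against the correct allele, with the alt allele and the edit
   signature intact -> correct_PE;
3. edit signature present and a template-derived insertion at the junction
   (>= ``ptd_min_match`` nt matching RT-template-derived sequence) -> PTD;
4. otherwise -> indel_other.

Isolated substitutions in the window (up to ``max_window_mismatches``,
sequencing noise) are tolerated in branches 1-2 as long as they do not touch
the intended-edit bases; indels in the window are never tolerated there.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import edlib
from Bio import Align

from .core import (
    EditSpec,
    Locus,
    edit_in_pam_frame,
    nick_in_pam_frame,
    pam_frame_sequence,
    revcomp,
)
from .design import PegRNADesign

MIN_SIGNATURE_LEN = 6


class ReadTooShortError(ValueError):
    """Read below the minimum-length pre-filter."""


class EmptyReportError(ValueError):
    """summarize() called with no read calls."""


class AlignOp(NamedTuple):
    """One alignment operation against the target sequence.

    ``kind`` is match/mismatch/ins/del; ``target_pos`` the 0-based target
    coordinate (for insertions: the gap position); ``seq`` the query bases
    involved (empty for deletions).
    """

    kind: str
    target_pos: int
    query_pos: int
    length: int
    seq: str


@dataclass
class ClassifyParams:
    """Tunables for read classification; defaults suit short amplicons."""

    match_score: float = 2.0
    mismatch_score: float = -4.0
    open_gap_score: float = -10.0
    extend_gap_score: float = -1.0
    #: template-derived insertion length required to call a PTD
    ptd_min_match: int = 3
    #: substitutions tolerated inside the window away from the edit site
    max_window_mismatches: int = 3
    #: quantification window, target coords; None -> [nick-pbs, nick+rt+5]
    window: tuple[int, int] | None = None
    #: None -> min(50, 80% of amplicon length)
    min_read_len: int | None = None
    signature_flank: int | None = None
    signature_downstream: int | None = None
    #: half-width of the ops-free neighbourhood around the edit site that
    #: counts as alignment-verified signature evidence
    signature_guard: int = 3
    #: "alignment" (default) or "substring" PTD detection
    ptd_rule: str = "alignment"


def make_aligner(params: ClassifyParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = params.match_score
    aligner.mismatch_score = params.mismatch_score
    aligner.open_gap_score = params.open_gap_score
    aligner.extend_gap_score = params.extend_gap_score
    return aligner


def align_read(read: str, reference: str, params: ClassifyParams | None = None,
               aligner: Align.PairwiseAligner | None = None) -> list[AlignOp]:
    """Optimal global alignment of ``read`` to ``reference`` as an op list.

    Affine scoring per ``params``; the first optimal alignment reported by
    the dynamic program is used, giving deterministic tie-breaking.
    """
    if not read or not reference:
        raise ValueError("align_read requires two non-empty sequences")
    if aligner is None:
        aligner = make_aligner(params or ClassifyParams())
    aln = aligner.align(reference, read)[0]
    t_blocks, q_blocks = aln.aligned
    ops: list[AlignOp] = []
    pt = pq = 0
    for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
        if ts > pt:
            ops.append(AlignOp("del", pt, pq, ts - pt, ""))
        if qs > pq:
            ops.append(AlignOp("ins", ts, pq, qs - pq, read[pq:qs]))
        for k in range(te - ts):
            if reference[ts + k] != read[qs + k]:
                ops.append(AlignOp("mismatch", ts + k, qs + k, 1, read[qs + k]))
        pt, pq = te, qe
    if pt < len(reference):
        ops.append(AlignOp("del", pt, pq, len(reference) - pt, ""))
    if pq < len(read):
        ops.append(AlignOp("ins", len(reference), pq, len(read) - pq, read[pq:]))
    return ops


def edit_signature(pegrna: PegRNADesign, edit: EditSpec | None = None,
                   flank: int | None = None, downstream: int | None = None) -> str:
    """The PAM-strand string whose presence defines "any intended edit".

    The last ``flank`` nt of the genomic PBS (default: the whole PBS)
    followed by the edited segment through the alt allele plus ``downstream``
    nt of homology (default: min(3, homology length)). A read carrying this
    string — in either orientation — contains the full intended edit in its
    native context, whatever else happened to the allele.
    """
    if flank is None:
        flank = pegrna.pbs_len
    if downstream is None:
        downstream = min(3, pegrna.rt_homology_len)
    if flank < 0 or downstream < 0 or downstream > pegrna.rt_homology_len:
        raise ValueError("invalid signature flank/downstream lengths")
    edited_core = pegrna.rt_seq[: pegrna.rt_len - pegrna.rt_homology_len + downstream]
    sig = (pegrna.pbs_seq[-flank:] if flank else "") + edited_core
    if len(sig) < MIN_SIGNATURE_LEN:
        raise ValueError(
            f"edit signature of {len(sig)} nt is too short to be discriminating "
            f"(minimum {MIN_SIGNATURE_LEN}); increase flank or downstream"
        )
    return sig


@dataclass(frozen=True)
class ReadCall:
    """Per-read classification outcome."""

    read_id: str
    label: str  # WT | correct_PE | PTD | indel_other
    has_signature: bool
    extra_ins_len: int = 0
    notes: str = ""

    def __post_init__(self) -> None:
        if self.label not in ("WT", "correct_PE", "PTD", "indel_other"):
            raise ValueError(f"unknown call label {self.label!r}")
        if self.label in ("correct_PE", "PTD") and not self.has_signature:
            raise ValueError(f"{self.label} calls must carry the edit signature")


#: truth labels of the simulator vs the classifier's call labels
TRUTH_TO_CALL = {"WT": "WT", "correct": "correct_PE", "PTD": "PTD",
                 "indel": "indel_other"}


class ReadClassifier:
    """Precomputed classification context for one design.

    Builds the PAM-frame reference and correct-allele sequences, the
    quantification window and the edit signature once, then classifies reads
    with :meth:`call`.
    """

    def __init__(self, locus: Locus, edit: EditSpec, pegrna: PegRNADesign,
                 params: ClassifyParams | None = None):
        from .editsim import simulate_flap  # allele oracle; no cycle at import time

        self.params = params or ClassifyParams()
        self.pegrna = pegrna
        site = pegrna.site
        L = len(locus)
        self.ref = pam_frame_sequence(locus.sequence, site.strand)
        correct_top = simulate_flap(locus, pegrna)
        self.correct = pam_frame_sequence(correct_top, site.strand)
        self.nick = nick_in_pam_frame(site, L)
        self.e_pam = edit_in_pam_frame(edit, L, site.strand)
        self.sig = edit_signature(
            pegrna, edit,
            flank=self.params.signature_flank,
            downstream=self.params.signature_downstream,
        )
        if self.params.window is not None:
            self.window = self.params.window
        else:
            self.window = (max(0, self.nick - pegrna.pbs_len),
                           self.nick + pegrna.rt_len + 5)
        self.min_read_len = (
            self.params.min_read_len
            if self.params.min_read_len is not None
            else min(50, int(0.8 * len(self.ref)))
        )
        self.template_region = self.ref[self.nick : self.nick + pegrna.rt_len + 5]
        self.aligner = make_aligner(self.params)
        # edit span on the reference and on the correct allele
        self.edit_span_ref = (self.e_pam.start, self.e_pam.end)
        self.edit_span_corr = (self.e_pam.start,
                               self.e_pam.start + len(self.e_pam.alt_allele))
        # ops-free neighbourhood around the edit (correct-allele coords) that
        # counts as alignment-verified signature evidence
        g = self.params.signature_guard
        self.guard_span = (self.edit_span_corr[0] - g, self.edit_span_corr[1] + g)

    # -- helpers ----------------------------------------------------------

    def _orient(self, seq: str) -> str:
        rc = revcomp(seq)
        d_f = edlib.align(seq, self.ref, mode="NW", task="distance")["editDistance"]
        d_r = edlib.align(rc, self.ref, mode="NW", task="distance")["editDistance"]
        return rc if d_r < d_f else seq

    def _window_summary(self, ops: list[AlignOp], target_len: int,
                        edit_span: tuple[int, int]):
        w0, w1 = self.window
        w1 = min(w1, target_len)
        indels = []
        ins_total = 0
        edit_mm = 0
        other_mm = 0
        ins_ops = []
        for op in ops:
            if op.kind == "mismatch":
                if w0 <= op.target_pos < w1:
                    if edit_span[0] <= op.target_pos < edit_span[1]:
                        edit_mm += 1
                    else:
                        other_mm += 1
            elif op.kind == "del":
                if op.target_pos < w1 and op.target_pos + op.length > w0:
                    indels.append(op)
            elif op.kind == "ins":
                if w0 <= op.target_pos <= w1:
                    indels.append(op)
                    ins_ops.append(op)
                    ins_total += op.length
        return indels, ins_ops, ins_total, edit_mm, other_mm

    def _template_derived(self, ins_ops: list[AlignOp]) -> bool:
        m = self.params.ptd_min_match
        for op in ins_ops:
            if op.length < m:
                continue
            for i in range(op.length - m + 1):
                if op.seq[i : i + m] in self.template_region:
                    return True
        return False

    def _substring_ptd(self, read: str) -> tuple[bool, int]:
        """Exact-substring PTD rule: find the duplication junction directly."""
        m = self.params.ptd_min_match
        h = self.pegrna.rt_homology_len
        rt = self.pegrna.rt_seq
        restart = self.ref[self.nick : self.nick + m]
        for dup in range(1, h + 1):
            flap_prefix = rt[: self.pegrna.rt_len - h + dup]
            probe = flap_prefix[-min(m, len(flap_prefix)) :] + restart
            if probe in read:
                extra = (self.e_pam.end - self.nick) + dup
                return True, extra
        return False, 0

    def _edit_intact(self, ops_corr: list[AlignOp]) -> bool:
        """Alignment-verified signature: no op touches the edit neighbourhood.

        Against the correct allele, a read whose alignment has no mismatch,
        insertion or deletion inside the guard span carries the full intended
        edit in its native junction context, whatever else happened to the
        allele. This is the error-tolerant generalisation of the exact
        signature substring.
        """
        g0, g1 = self.guard_span
        for op in ops_corr:
            if op.kind == "mismatch":
                if g0 <= op.target_pos < g1:
                    return False
            elif op.kind == "del":
                if op.target_pos < g1 and op.target_pos + op.length > g0:
                    return False
            elif op.kind == "ins":
                if g0 < op.target_pos < g1:
                    return False
        return True

    # -- main entry -------------------------------------------------------

    def call(self, read_id: str, seq: str) -> ReadCall:
        seq = seq.upper()
        if len(seq) < self.min_read_len:
            raise ReadTooShortError(
                f"read {read_id} is {len(seq)} nt, below the minimum "
                f"{self.min_read_len}"
            )
        read = self._orient(seq)
        has_sig_exact = self.sig in read

        if read == self.ref:
            return ReadCall(read_id, "WT", has_sig_exact)
        if read == self.correct:
            return ReadCall(read_id, "correct_PE", True)

        tol = self.params.max_window_mismatches

        ops_ref = align_read(read, self.ref, aligner=self.aligner)
        indels_r, _, _, edit_mm_r, other_mm_r = self._window_summary(
            ops_ref, len(self.ref), self.edit_span_ref
        )
        if not indels_r and edit_mm_r == 0 and other_mm_r <= tol:
            return ReadCall(read_id, "WT", has_sig_exact)

        ops_corr = align_read(read, self.correct, aligner=self.aligner)
        indels_c, ins_ops, ins_total, edit_mm_c, other_mm_c = self._window_summary(
            ops_corr, len(self.correct), self.edit_span_corr
        )
        if not indels_c and edit_mm_c == 0 and other_mm_c <= tol:
            return ReadCall(read_id, "correct_PE", True)

        has_sig = has_sig_exact or self._edit_intact(ops_corr)
        if has_sig:
            if self.params.ptd_rule == "substring":
                is_ptd, extra = self._substring_ptd(read)
                if is_ptd:
                    return ReadCall(read_id, "PTD", True, extra_ins_len=extra)
            elif ins_ops and self._template_derived(ins_ops):
                return ReadCall(read_id, "PTD", True, extra_ins_len=ins_total)

        return ReadCall(read_id, "indel_other", has_sig, extra_ins_len=ins_total)


def classify_read(read: str, locus: Locus, edit: EditSpec, pegrna: PegRNADesign,
                  params: ClassifyParams | None = None,
                  read_id: str = "read") -> ReadCall:
    """Classify a single read (convenience wrapper over ReadClassifier)."""
    return ReadClassifier(locus, edit, pegrna, params).call(read_id, read)


def classify_reads(reads, locus: Locus, edit: EditSpec, pegrna: PegRNADesign,
                   params: ClassifyParams | None = None):
    """Classify an iterable of (read_id, sequence) pairs.

    Returns ``(calls, n_filtered)`` where ``n_filtered`` counts reads dropped
    by the minimum-length pre-filter.
    """
    clf = ReadClassifier(locus, edit, pegrna, params)
    calls: list[ReadCall] = []
    n_filtered = 0
    for read_id, seq in reads:
        try:
            calls.append(clf.call(read_id, seq))
        except ReadTooShortError:
            n_filtered += 1
    return calls, n_filtered


@dataclass(frozen=True)
class OutcomeReport:
    """Per-sample outcome percentages, on [0, 100].

    ``pct_unintended`` and ``pct_indel`` are computed by the standard
    identities (unintended = 100 - correct - WT; indel = unintended - PTD),
    not tallied independently. ``pct_any_intended`` is the fraction of reads
    carrying the edit signature.
    """

    n_reads: int
    pct_correct: float
    pct_wt: float
    pct_unintended: float
    pct_ptd: float
    pct_indel: float
    pct_any_intended: float
    n_filtered: int = 0

    def to_dict(self) -> dict:
        return {
            "n_reads": self.n_reads,
            "pct_correct": self.pct_correct,
            "pct_wt": self.pct_wt,
            "pct_unintended": self.pct_unintended,
            "pct_ptd": self.pct_ptd,
            "pct_indel": self.pct_indel,
            "pct_any_intended": self.pct_any_intended,
            "n_filtered": self.n_filtered,
        }


def summarize(calls: list[ReadCall], n_filtered: int = 0) -> OutcomeReport:
    """Aggregate per-read calls into the standard outcome percentages."""
    if not calls:
        raise EmptyReportError("cannot summarize an empty set of read calls")
    n = len(calls)
    n_correct = sum(c.label == "correct_PE" for c in calls)
    n_wt = sum(c.label == "WT" for c in calls)
    n_ptd = sum(c.label == "PTD" for c in calls)
    n_sig = sum(c.has_signature for c in calls)
    pct_correct = 100.0 * n_correct / n
    pct_wt = 100.0 * n_wt / n
    pct_ptd = 100.0 * n_ptd / n
    pct_unintended = 100.0 - pct_correct - pct_wt
    pct_indel = pct_unintended - pct_ptd
    return OutcomeReport(
        n_reads=n,
        pct_correct=pct_correct,
        pct_wt=pct_wt,
        pct_unintended=pct_unintended,
        pct_ptd=pct_ptd,
        pct_indel=pct_indel,
        pct_any_intended=100.0 * n_sig / n,
        n_filtered=n_filtered,
    )
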