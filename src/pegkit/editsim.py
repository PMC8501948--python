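"""Ground-truth allele construction and synthetic amplicon reads.

Encodes the flap model of prime editing: the reverse-transcribed 3' flap
carries the edit plus downstream homology. Correct resolution anneals the
flap's terminal homology to the genomic sequence downstream of the edit
(:func:`simulate_flap`, the design oracle). Imperfect resolution end-joins a
flap prefix directly to the unresected DNA at the break, duplicating template
sequence — a partial template duplication (:func:`make_ptd_allele`). Classic
end-joining errors at the cut produce plain indels
(:func:`make_indel_allele`).

:func:`generate_reads` draws amplicon reads from a configurable mixture of
these allele classes with a uniform per-base substitution error, emitting a
truth table for classifier validation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import (
    EditSpec,
    Locus,
    edit_in_pam_frame,
    nick_in_pam_frame,
    pam_frame_sequence,
    revcomp,
)
from .design import PegRNADesign, ProtospacerSite

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class FlapResolutionError(ValueError):
    """The pegRNA's PBS or RT homology cannot anneal to the locus."""


def simulate_flap(locus: Locus, pegrna: PegRNADesign) -> str:
    """Reconstruct the edited allele purely from the pegRNA's fields.

    Checks that the PBS matches the genomic bases 5' of the nick, synthesises
    the flap (the RT template read back into DNA), locates where the flap's
    terminal ``rt_homology_len`` bases re-anneal downstream of the nick, and
    returns nicked-strand-upstream + flap + genomic remainder, top-strand
    oriented. For a valid design this equals ``apply_edit(locus, edit)``,
    which is exactly what makes it the design oracle.

    When the terminal homology occurs at several downstream positions the one
    nearest the expected junction (``nick + rt_len - rt_homology_len``) is
    used; chance k-mer repeats elsewhere in the locus then cannot derail the
    reconstruction.
    """
    site = pegrna.site
    L = len(locus)
    P = pam_frame_sequence(locus.sequence, site.strand)
    nick = nick_in_pam_frame(site, L)
    if P[nick - pegrna.pbs_len : nick] != pegrna.pbs_seq:
        raise FlapResolutionError(
            "PBS does not match the genomic bases 5' of the nick; "
            "pegRNA and locus are inconsistent"
        )
    h = pegrna.rt_homology_len
    homology = pegrna.rt_seq[-h:]
    hits = []
    p = nick
    while True:
        p = P.find(homology, p)
        if p < 0:
            break
        hits.append(p)
        p += 1
    if not hits:
        raise FlapResolutionError(
            "RT-template terminal homology not found downstream of the nick; "
            "the flap cannot resolve on this locus"
        )
    expected = nick + pegrna.rt_len - h
    anneal = min(hits, key=lambda q: (abs(q - expected), q))
    edited_pam = P[:nick] + pegrna.rt_seq + P[anneal + h :]
    return edited_pam if site.strand == "+" else revcomp(edited_pam)


@dataclass(frozen=True)
class AlleleModel:
    """One ground-truth allele class with its generating parameters."""

    label: str  # WT | correct | PTD | indel
    sequence: str
    ptd_dup_len: int = 0
    junction_del: int = 0

    def __post_init__(self) -> None:
        if self.label not in ("WT", "correct", "PTD", "indel"):
            raise ValueError(f"unknown allele label {self.label!r}")


def make_ptd_allele(
    locus: Locus,
    edit: EditSpec,
    pegrna: PegRNADesign,
    dup_len: int,
    junction_del: int = 0,
) -> AlleleModel:
    """Build a partial-template-duplication allele.

    The synthesised flap prefix — the edited segment plus the first
    ``dup_len`` homology bases — end-joins to the unresected genomic DNA at
    the break, duplicating those homology bases (``junction_del`` bases are
    lost at the junction, if any). With ``junction_del == 0`` the allele is
    strictly longer than the correct one and always contains the full alt
    allele.
    """
    h = pegrna.rt_homology_len
    if not 1 <= dup_len <= h:
        raise ValueError(f"dup_len must be in [1, {h}] (rt homology length)")
    if junction_del < 0:
        raise ValueError("junction_del must be >= 0")
    site = pegrna.site
    L = len(locus)
    P = pam_frame_sequence(locus.sequence, site.strand)
    nick = nick_in_pam_frame(site, L)
    flap_prefix = pegrna.rt_seq[: pegrna.rt_len - h + dup_len]
    seq_pam = P[:nick] + flap_prefix + P[nick + junction_del :]
    seq = seq_pam if site.strand == "+" else revcomp(seq_pam)
    return AlleleModel(label="PTD", sequence=seq, ptd_dup_len=dup_len,
                       junction_del=junction_del)


def make_indel_allele(
    locus: Locus,
    site: ProtospacerSite,
    size: int,
    kind: str,
    rng: np.random.Generator,
    forbidden: tuple[str, ...] = (),
    validator=None,
) -> AlleleModel:
    """Build a plain indel allele at the cut site.

    Deletions remove ``size`` nt centred on the nick; insertions add ``size``
    random nt at the nick. Alleles that reproduce any ``forbidden`` string
    (e.g. the edit signature), coincide with the unedited locus, or fail the
    optional ``validator`` (a callable on the top-strand sequence) are
    resampled/jittered so that the truth label stays identifiable: a random
    indel that happens to reconstruct the intended edit junction is not a
    distinguishable "other indel" in any read.
    """
    if size < 1:
        raise ValueError("indel size must be >= 1")
    if size >= len(locus):
        raise ValueError("indel size must be smaller than the locus")
    if kind not in ("insertion", "deletion"):
        raise ValueError(f"unknown indel kind {kind!r}")
    L = len(locus)
    P = pam_frame_sequence(locus.sequence, site.strand)
    nick = nick_in_pam_frame(site, L)

    def bad(seq_pam: str, seq_top: str) -> bool:
        if seq_pam == P:
            return True
        if any(f in seq_pam or revcomp(f) in seq_pam for f in forbidden):
            return True
        return validator is not None and not validator(seq_top)

    for attempt in range(100):
        eff_size = size + attempt // 25  # escape pathological repeat contexts
        if kind == "deletion":
            jitter = int(rng.integers(-3, 4)) if attempt else 0
            start = min(max(0, nick - eff_size // 2 + jitter), len(P) - eff_size)
            seq_pam = P[:start] + P[start + eff_size :]
        else:
            ins = "".join(
                "ACGT"[i] for i in rng.integers(0, 4, size=eff_size)
            )
            seq_pam = P[:nick] + ins + P[nick:]
        seq = seq_pam if site.strand == "+" else revcomp(seq_pam)
        if not bad(seq_pam, seq):
            return AlleleModel(label="indel", sequence=seq,
                               junction_del=eff_size if kind == "deletion" else 0)
    raise RuntimeError(
        "could not draw an indel allele distinct from the forbidden sequences"
    )


@dataclass
class SimulationConfig:
    """Mixture and noise parameters for read generation.

    ``fractions`` maps the four allele classes to probabilities summing to 1.
    PTD duplication lengths are drawn uniformly from ``ptd_dup_range``
    (default: 1 to the pegRNA's RT homology length); junction deletions
    uniformly from ``junction_del_range`` (default none); indel sizes
    uniformly from ``indel_size_range``. ``per_base_error`` is the uniform
    substitution-error probability per base.
    """

    fractions: dict
    n_reads: int = 1000
    per_base_error: float = 0.0
    seed: int = 0
    ptd_dup_range: tuple[int, int] | None = None
    junction_del_range: tuple[int, int] = (0, 0)
    indel_size_range: tuple[int, int] = (1, 10)

    CLASSES = ("correct", "WT", "PTD", "indel")

    def __post_init__(self) -> None:
        unknown = set(self.fractions) - set(self.CLASSES)
        if unknown:
            raise ValueError(f"unknown mixture classes {sorted(unknown)}")
        vals = [float(self.fractions.get(c, 0.0)) for c in self.CLASSES]
        if any(v < 0 for v in vals):
            raise ValueError("mixture fractions must be non-negative")
        if abs(sum(vals) - 1.0) > 1e-9:
            raise ValueError(f"mixture fractions must sum to 1, got {sum(vals)}")
        self.fractions = dict(zip(self.CLASSES, vals))
        if self.n_reads < 1:
            raise ValueError("n_reads must be >= 1")
        if not 0.0 <= self.per_base_error < 1.0:
            raise ValueError("per_base_error must be in [0, 1)")
        for name in ("junction_del_range", "indel_size_range"):
            lo, hi = getattr(self, name)
            if lo < 0 or hi < lo:
                raise ValueError(f"{name} must be a non-negative (lo, hi) range")


def _add_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0.0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = np.nonzero(rng.random(arr.size) < rate)[0]
    for i in hit:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return arr.tobytes().decode()


def generate_reads(
    locus: Locus,
    edit: EditSpec,
    pegrna: PegRNADesign,
    config: SimulationConfig,
):
    """Draw amplicon reads from the allele mixture.

    Returns ``(records, truth)``: a list of FASTQ-ready ``SeqRecord`` objects
    (uniform quality 40) and a truth table (pandas DataFrame with columns
    read_id, label, ptd_dup_len, junction_del) mapping every read to its
    generating allele. Deterministic given ``config.seed``.
    """
    import pandas as pd

    from .classify import ReadClassifier, edit_signature

    rng = np.random.default_rng(config.seed)
    wt = AlleleModel(label="WT", sequence=locus.sequence)
    correct = AlleleModel(label="correct", sequence=simulate_flap(locus, pegrna))
    sig = edit_signature(pegrna, edit)
    # identifiability guard for indel alleles (default classifier params)
    from .classify import ReadTooShortError

    clf = ReadClassifier(locus, edit, pegrna)

    def validator(seq: str) -> bool:
        try:
            return clf.call("candidate", seq).label == "indel_other"
        except ReadTooShortError:
            return True  # dropped by the length pre-filter downstream
    h = pegrna.rt_homology_len
    dup_lo, dup_hi = config.ptd_dup_range if config.ptd_dup_range else (1, h)
    if not 1 <= dup_lo <= dup_hi <= h:
        raise ValueError(f"ptd_dup_range must lie within [1, {h}]")

    labels = rng.choice(
        len(SimulationConfig.CLASSES),
        size=config.n_reads,
        p=[config.fractions[c] for c in SimulationConfig.CLASSES],
    )
    records: list[SeqRecord] = []
    rows = []
    for i, li in enumerate(labels):
        cls = SimulationConfig.CLASSES[li]
        if cls == "correct":
            allele = correct
        elif cls == "WT":
            allele = wt
        elif cls == "PTD":
            dup = int(rng.integers(dup_lo, dup_hi + 1))
            jd_lo, jd_hi = config.junction_del_range
            jd = int(rng.integers(jd_lo, jd_hi + 1))
            allele = make_ptd_allele(locus, edit, pegrna, dup, jd)
        else:
            size_lo, size_hi = config.indel_size_range
            size = int(rng.integers(max(1, size_lo), size_hi + 1))
            kind = "deletion" if rng.random() < 0.5 else "insertion"
            allele = make_indel_allele(
                locus, pegrna.site, size, kind, rng,
                forbidden=(sig, correct.sequence),
                validator=validator,
            )
        seq = _add_errors(allele.sequence, config.per_base_error, rng)
        rid = f"read{i:06d}"
        rec = SeqRecord(Seq(seq), id=rid, description="")
        rec.letter_annotations["phred_quality"] = [40] * len(seq)
        records.append(rec)
        rows.append((rid, allele.label, allele.ptd_dup_len, allele.junction_del))
    truth = pd.DataFrame(rows, columns=["read_id", "label", "ptd_dup_len", "junction_del"])
    return records, truth


# ---------------------------------------------------------------------------
# Randomised design cases, shared by the property tests and the acceptance
# script: a locus with one embedded protospacer and a random reachable edit.


def random_design_case(rng: np.random.Generator):
    """Draw a random (locus, edit, site, pbs_len, rt_homology_len) tuple.

    The locus embeds one NGG protospacer on a random strand with enough
    flanking sequence for any PBS/RT window; the edit is a random
    substitution, insertion or deletion starting 1-6 nt 3' of the nick.
    """
    def rand_seq(n: int) -> str:
        return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))

    up = int(rng.integers(25, 41))
    down = int(rng.integers(35, 56))
    spacer = rand_seq(20)
    pam = rand_seq(1) + "GG"
    strand = "+" if rng.random() < 0.5 else "-"
    core = rand_seq(up) + spacer + pam + rand_seq(down)
    sequence = core if strand == "+" else revcomp(core)
    locus = Locus(name="synthetic", sequence=sequence)

    if strand == "+":
        spacer_start = up
    else:
        # revcomp maps the core's spacer [up, up+20) to [L-up-20, L-up)
        spacer_start = len(sequence) - up - 20
    site = ProtospacerSite.at(locus, strand, spacer_start)

    nick = nick_in_pam_frame(site, len(locus))
    P = pam_frame_sequence(locus.sequence, strand)
    offset = int(rng.integers(1, 7))
    kind = ("substitution", "insertion", "deletion")[int(rng.integers(0, 3))]
    span = int(rng.integers(1, 4))
    start_pam = nick + offset - 1
    if kind == "insertion":
        e_pam = EditSpec(kind="insertion", start=start_pam, alt_allele=rand_seq(span))
    elif kind == "deletion":
        e_pam = EditSpec(kind="deletion", start=start_pam,
                         ref_allele=P[start_pam : start_pam + span])
    else:
        ref = P[start_pam : start_pam + span]
        while True:
            alt = rand_seq(span)
            if alt != ref:
                break
        e_pam = EditSpec(kind="substitution", start=start_pam, ref_allele=ref,
                         alt_allele=alt)
    edit = edit_in_pam_frame(e_pam, len(locus), strand)  # involution: pam -> top
    pbs_len = int(rng.integers(8, 16))
    rt_homology_len = int(rng.integers(8, 14))
    return locus, edit, site, pbs_len, rt_homology_len
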