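"""Prime-editing design engine.

Enumerates SpCas9 NGG protospacers around a locus, builds pegRNAs (spacer,
primer binding site, reverse-transcriptase template, 3' extension), selects
opposite-strand second-nick guides for PE3, and emits the three golden-gate
oligo duplexes plus T7 in-vitro-transcription primers needed to build the
corresponding all-in-one constructs.

Geometry: SpCas9 nicks the PAM strand between protospacer positions 17 and 18
(3 nt 5' of the PAM). All design arithmetic is done in the PAM-strand frame of
the chosen site (see :mod:`pegkit.core`) and converted back for output.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

from .core import (
    EditSpec,
    Locus,
    UnreachableEditError,
    edit_in_pam_frame,
    nick_in_pam_frame,
    pam_frame_sequence,
    revcomp,
)

logger = logging.getLogger(__name__)

SPACER_LEN = 20
#: cut falls between protospacer positions 17 and 18 on the PAM strand
CUT_OFFSET = 17

#: canonical T7 promoter (transcription starts at the final G)
T7_PROMOTER = "TAATACGACTCACTATAG"

#: SpCas9 single-guide scaffold, 5'->3' DNA sense
SGRNA_SCAFFOLD = (
    "GTTTTAGAGCTAGAAATAGCAAGTTAAAATAAGGCTAGTCCGTTATCAACTTGAAAAAGTGGCACCGAGTCGGTGC"
)

#: default non-genome-targeting guide for the second-nick cassette of
#: nuclease (and PE2) kits; verification of non-targeting is out of scope.
DEFAULT_SHAM_GUIDE = "GTAGCGAACGTGTCCGGCGT"

DEFAULT_PBS_LEN = 13
DEFAULT_RT_HOMOLOGY_LEN = 13
DEFAULT_MAX_NICK_TO_EDIT = 30


class NoReachableProtospacerError(ValueError):
    """No protospacer places the edit 3' of its nick within range."""

    def __init__(self, message: str, rejected=()):
        super().__init__(message)
        self.rejected = list(rejected)


class DesignBoundsError(ValueError):
    """A PBS or RT window falls outside the locus."""


class AdapterConfigError(ValueError):
    """Adapter table is missing or structurally invalid for a dialect/slot."""


@dataclass(frozen=True)
class ProtospacerSite:
    """A 20-nt SpCas9 target adjacent to an NGG PAM.

    ``spacer_start`` is the 0-based top-strand index of the spacer's leftmost
    base regardless of strand; ``spacer_seq`` and ``pam_seq`` are given in
    PAM-strand orientation. ``nick_pos`` is the top-strand index such that the
    PAM-strand nick falls between top-strand indices ``nick_pos - 1`` and
    ``nick_pos``.
    """

    strand: str
    spacer_start: int
    spacer_seq: str
    pam_seq: str
    nick_pos: int

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        if len(self.spacer_seq) != SPACER_LEN:
            raise ValueError("spacer must be 20 nt")
        if not re.fullmatch(r"[ACGT]GG", self.pam_seq):
            raise ValueError(f"PAM {self.pam_seq!r} does not match NGG")
        expected = (
            self.spacer_start + CUT_OFFSET
            if self.strand == "+"
            else self.spacer_start + (SPACER_LEN - CUT_OFFSET)
        )
        if self.nick_pos != expected:
            raise ValueError(
                f"nick_pos {self.nick_pos} inconsistent with {self.strand} strand "
                f"spacer at {self.spacer_start} (expected {expected})"
            )

    @classmethod
    def at(cls, locus: Locus, strand: str, spacer_start: int) -> "ProtospacerSite":
        """Construct the site at a known position, reading spacer and PAM."""
        s = locus.sequence
        if strand == "+":
            spacer = s[spacer_start : spacer_start + SPACER_LEN]
            pam = s[spacer_start + SPACER_LEN : spacer_start + SPACER_LEN + 3]
            nick = spacer_start + CUT_OFFSET
        else:
            spacer = revcomp(s[spacer_start : spacer_start + SPACER_LEN])
            pam = revcomp(s[spacer_start - 3 : spacer_start])
            nick = spacer_start + (SPACER_LEN - CUT_OFFSET)
        return cls(strand=strand, spacer_start=spacer_start, spacer_seq=spacer,
                   pam_seq=pam, nick_pos=nick)


def scan_pam_sites(locus: Locus, window: tuple[int, int] | None = None) -> list[ProtospacerSite]:
    """Enumerate every 20-nt spacer + NGG PAM on both strands.

    ``window`` is a 0-based half-open top-strand interval; a site is kept when
    its PAM lies entirely inside it. Sites are returned in deterministic order:
    top strand 5'->3' first, then bottom strand by ascending top-strand
    coordinate. A window too small to hold any site yields an empty list.
    """
    s = locus.sequence
    L = len(s)
    lo, hi = window if window is not None else (0, L)
    if lo < 0 or hi > L:
        raise ValueError(f"window [{lo}, {hi}) outside locus bounds [0, {L})")
    sites: list[ProtospacerSite] = []
    for m in re.finditer(r"(?=[ACGT]{21}GG)", s):
        start = m.start()
        if lo <= start + SPACER_LEN and start + SPACER_LEN + 3 <= hi:
            sites.append(ProtospacerSite.at(locus, "+", start))
    for m in re.finditer(r"(?=CC[ACGT]{21})", s):
        start = m.start() + 3  # leftmost spacer base on the top strand
        if lo <= start - 3 and start <= hi and start + SPACER_LEN <= L:
            sites.append(ProtospacerSite.at(locus, "-", start))
    return sites


@dataclass(frozen=True)
class PegRNADesign:
    """A pegRNA: spacer plus 3' extension (RT template then PBS).

    ``pbs_seq`` are the genomic PAM-strand bases immediately 5' of the nick;
    ``rt_seq`` the edited PAM-strand bases running 3' from the nick through
    the whole alt allele plus ``rt_homology_len`` nt of downstream genomic
    homology. The extension as synthesised is
    ``revcomp(rt_seq) + revcomp(pbs_seq)``. The spacer oligo gets a G
    prepended when the genomic spacer does not start with one (U6/T7
    transcription initiation).
    """

    site: ProtospacerSite
    pbs_len: int
    pbs_seq: str
    rt_len: int
    rt_seq: str
    rt_homology_len: int
    extension_seq: str
    spacer_oligo_seq: str
    g_prepended: bool

    def __post_init__(self) -> None:
        if self.extension_seq != revcomp(self.rt_seq) + revcomp(self.pbs_seq):
            raise ValueError("extension must be revcomp(rt) + revcomp(pbs)")
        if not self.spacer_oligo_seq.startswith("G"):
            raise ValueError("spacer oligo must start with G")
        if self.rt_len != len(self.rt_seq) or self.pbs_len != len(self.pbs_seq):
            raise ValueError("stated lengths disagree with sequences")


def g_prepend(spacer: str) -> tuple[str, bool]:
    """Return the spacer oligo sequence and whether a G was prepended."""
    if spacer.startswith("G"):
        return spacer, False
    return "G" + spacer, True


def edit_offset_from_nick(edit: EditSpec, site: ProtospacerSite, locus_length: int) -> int:
    """Nick-relative offset (+1 = first base 3' of the nick) of the edit start."""
    e = edit_in_pam_frame(edit, locus_length, site.strand)
    nick = nick_in_pam_frame(site, locus_length)
    return e.start - nick + 1


def candidate_pegrna_sites(
    locus: Locus,
    edit: EditSpec,
    max_nick_to_edit: int = DEFAULT_MAX_NICK_TO_EDIT,
) -> list[ProtospacerSite]:
    """Rank protospacers that can write the edit.

    Keeps sites where the edit lies fully 3' of the nick on the PAM strand and
    starts within ``max_nick_to_edit`` nt of it; ranked by ascending
    nick-to-edit distance, ties broken + strand first, then lower coordinate.

    Raises :class:`NoReachableProtospacerError` when nothing qualifies; the
    exception carries the nearest rejected sites for diagnostics.
    """
    edit.validate_against(locus)
    kept: list[tuple[int, ProtospacerSite]] = []
    rejected: list[tuple[int, ProtospacerSite]] = []
    for site in scan_pam_sites(locus):
        off = edit_offset_from_nick(edit, site, len(locus))
        if 1 <= off <= max_nick_to_edit:
            kept.append((off, site))
        else:
            rejected.append((off, site))
    if not kept:
        rejected.sort(key=lambda t: abs(t[0]))
        nearest = ", ".join(
            f"{s.strand}@{s.spacer_start} (offset {o:+d})" for o, s in rejected[:5]
        )
        raise NoReachableProtospacerError(
            "no reachable protospacer: no NGG site places the edit 3' of its nick "
            f"within {max_nick_to_edit} nt"
            + (f"; nearest rejected: {nearest}" if nearest else ""),
            rejected=[s for _, s in rejected],
        )
    kept.sort(key=lambda t: (t[0], t[1].strand != "+", t[1].spacer_start))
    return [s for _, s in kept]


def build_pegrna(
    locus: Locus,
    edit: EditSpec,
    site: ProtospacerSite,
    pbs_len: int = DEFAULT_PBS_LEN,
    rt_homology_len: int = DEFAULT_RT_HOMOLOGY_LEN,
) -> PegRNADesign:
    """Build the pegRNA writing ``edit`` from ``site``.

    The PBS covers the ``pbs_len`` genomic PAM-strand bases 5' of the nick;
    the RT template covers the edited PAM-strand bases from the nick through
    the alt allele plus ``rt_homology_len`` nt of downstream homology.
    """
    if pbs_len < 1:
        raise ValueError("pbs_len must be >= 1")
    if pbs_len < 8:
        logger.warning(
            "pbs_len %d is below the practical range (8-17); annealing may fail",
            pbs_len,
        )
    if rt_homology_len < 1:
        raise ValueError("rt_homology_len must be >= 1")
    edit.validate_against(locus)
    L = len(locus)
    P = pam_frame_sequence(locus.sequence, site.strand)
    nick = nick_in_pam_frame(site, L)
    e = edit_in_pam_frame(edit, L, site.strand)
    if e.start - nick + 1 < 1:
        raise UnreachableEditError(
            f"edit starts {nick - e.start} nt 5' of the nick of site "
            f"{site.strand}@{site.spacer_start}; not writable by this pegRNA"
        )
    if nick - pbs_len < 0:
        raise DesignBoundsError(
            f"PBS window [{nick - pbs_len}, {nick}) extends past the locus start"
        )
    edited = P[: e.start] + e.alt_allele + P[e.end :]
    rt_end = e.start + len(e.alt_allele) + rt_homology_len
    if rt_end > len(edited):
        raise DesignBoundsError(
            f"RT template would need {rt_end - len(edited)} nt beyond the locus end; "
            "shorten rt_homology_len or extend the locus"
        )
    pbs_seq = P[nick - pbs_len : nick]
    rt_seq = edited[nick:rt_end]
    spacer_oligo, prepended = g_prepend(site.spacer_seq)
    return PegRNADesign(
        site=site,
        pbs_len=pbs_len,
        pbs_seq=pbs_seq,
        rt_len=len(rt_seq),
        rt_seq=rt_seq,
        rt_homology_len=rt_homology_len,
        extension_seq=revcomp(rt_seq) + revcomp(pbs_seq),
        spacer_oligo_seq=spacer_oligo,
        g_prepended=prepended,
    )


@dataclass(frozen=True)
class SecondNickGuide:
    """Opposite-strand guide creating the PE3 second nick.

    ``signed_offset`` is the nick-to-nick distance, positive when the second
    nick lies 3' of the pegRNA nick on the pegRNA's PAM strand (the "+48" /
    "-60" convention).
    """

    site: ProtospacerSite
    signed_offset: int


def choose_second_nick(
    locus: Locus,
    pegrna: PegRNADesign,
    offset_window: tuple[int, int] = (-120, 120),
    exclusion: tuple[int, int] = (-10, 10),
) -> list[SecondNickGuide]:
    """List opposite-strand second-nick guides, sorted by |offset|.

    Guides whose signed nick-to-nick offset falls inside ``exclusion`` are
    dropped (nicks too close behave like a double-strand break). An empty
    list is a valid outcome.
    """
    L = len(locus)
    peg_site = pegrna.site
    n1 = nick_in_pam_frame(peg_site, L)
    out: list[SecondNickGuide] = []
    for site in scan_pam_sites(locus):
        if site.strand == peg_site.strand:
            continue
        n2_top = site.nick_pos
        n2 = n2_top if peg_site.strand == "+" else L - n2_top
        off = n2 - n1
        if offset_window[0] <= off <= offset_window[1] and not (
            exclusion[0] <= off <= exclusion[1]
        ):
            out.append(SecondNickGuide(site=site, signed_offset=off))
    out.sort(key=lambda g: (abs(g.signed_offset), g.signed_offset < 0))
    return out


@dataclass(frozen=True)
class ConstructPlan:
    """What goes into one all-in-one construct."""

    mode: str  # pe2 | pe3 | nuclease
    pegrna: PegRNADesign
    second_nick: SecondNickGuide | None = None
    sham_guide_seq: str = DEFAULT_SHAM_GUIDE
    dialect: str = "pea1"

    def __post_init__(self) -> None:
        if self.mode not in ("pe2", "pe3", "nuclease"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "pe3" and self.second_nick is None:
            raise ValueError("pe3 plans require a second-nick guide")
        if self.mode != "pe3" and self.second_nick is not None:
            raise ValueError(
                f"{self.mode} constructs carry the sham guide, never a genomic second nick"
            )


@dataclass(frozen=True)
class OligoDuplex:
    """One annealed oligo pair with its golden-gate overhangs.

    Both oligos are written 5'->3'. Stripping the two declared 4-nt 5'
    overhangs leaves a core and its exact reverse complement.
    """

    slot: str  # spacer | extension | second_nick
    top_seq: str
    bottom_seq: str
    top_overhang: str
    bottom_overhang: str

    def __post_init__(self) -> None:
        if len(self.top_overhang) != 4 or len(self.bottom_overhang) != 4:
            raise ValueError("golden-gate overhangs must be exactly 4 nt")
        core_top = self.top_seq[len(self.top_overhang) :]
        core_bottom = self.bottom_seq[len(self.bottom_overhang) :]
        if core_top != revcomp(core_bottom):
            raise ValueError(
                f"{self.slot} duplex cores are not reverse complements after "
                "stripping the overhangs"
            )


SLOTS = ("spacer", "extension", "second_nick")


@dataclass(frozen=True)
class AdapterTable:
    """Per-dialect, per-slot 5' additions (first 4 nt = golden-gate overhang).

    ``table[dialect][slot] = (top_addition, bottom_addition)``. The three
    slots of one dialect must carry mutually distinct overhang pairs so the
    one-pot digestion-ligation assembles directionally.
    """

    table: dict

    def __post_init__(self) -> None:
        for dialect, slots in self.table.items():
            missing = set(SLOTS) - set(slots)
            if missing:
                raise AdapterConfigError(
                    f"dialect {dialect!r} missing adapter entry for slot(s) "
                    f"{sorted(missing)}"
                )
            pairs = []
            for slot in SLOTS:
                top, bottom = slots[slot]
                if len(top) < 4 or len(bottom) < 4:
                    raise AdapterConfigError(
                        f"dialect {dialect!r} slot {slot!r}: additions must carry "
                        "a 4-nt overhang"
                    )
                pairs.append((top[:4], bottom[:4]))
            if len(set(pairs)) != 3:
                raise AdapterConfigError(
                    f"dialect {dialect!r}: the three slots must have three distinct "
                    "overhang pairs for directional assembly"
                )

    def additions(self, dialect: str, slot: str) -> tuple[str, str]:
        try:
            return self.table[dialect][slot]
        except KeyError:
            raise AdapterConfigError(
                f"no adapter entry for dialect {dialect!r}, slot {slot!r}"
            ) from None


#: editable defaults; the 5' additions are exactly the 4-nt BbsI overhangs
#: (PX459-lineage conventions for the spacer slot).
DEFAULT_ADAPTERS = AdapterTable(
    table={
        "pea1": {
            "spacer": ("CACC", "AAAC"),
            "extension": ("GTGC", "AAAA"),
            "second_nick": ("ACCG", "CAAA"),
        },
        "pu6": {
            "spacer": ("ACCG", "AAAC"),
            "extension": ("TGCA", "CGTA"),
            "second_nick": ("CACC", "CAAA"),
        },
    }
)


def _duplex(slot: str, core: str, additions: tuple[str, str]) -> OligoDuplex:
    top_add, bottom_add = additions
    return OligoDuplex(
        slot=slot,
        top_seq=top_add + core,
        bottom_seq=bottom_add + revcomp(core),
        top_overhang=top_add[:4],
        bottom_overhang=bottom_add[:4],
    )


def emit_oligos(plan: ConstructPlan, adapters: AdapterTable = DEFAULT_ADAPTERS) -> list[OligoDuplex]:
    """Emit the three annealed oligo pairs for one construct.

    Slots: the pegRNA spacer, the 3' extension (RT template + PBS), and the
    second-nick spacer — which carries the sham guide for nuclease (and PE2)
    kits. Deterministic: identical inputs give byte-identical oligos.
    """
    peg = plan.pegrna
    if plan.mode == "pe3":
        second_core, _ = g_prepend(plan.second_nick.site.spacer_seq)
    else:
        second_core, _ = g_prepend(plan.sham_guide_seq)
    cores = {
        "spacer": peg.spacer_oligo_seq,
        "extension": peg.extension_seq,
        "second_nick": second_core,
    }
    return [
        _duplex(slot, cores[slot], adapters.additions(plan.dialect, slot))
        for slot in SLOTS
    ]


@dataclass(frozen=True)
class IVTPrimerPair:
    """PCR primers producing the T7 in-vitro-transcription template.

    The forward primer carries the T7 promoter plus the spacer and anneals to
    the scaffold; the reverse primer is the reverse complement of the 3' end
    of the template (scaffold + extension), so the run-off transcript ends at
    the pegRNA's 3' extension.
    """

    forward: str
    reverse: str
    t7_promoter: str = T7_PROMOTER


def emit_ivt_primers(
    pegrna: PegRNADesign,
    scaffold_seq: str = SGRNA_SCAFFOLD,
    anneal_len: int = 20,
    scaffold_head_len: int = 15,
) -> IVTPrimerPair:
    """Design the T7 IVT primer pair for a pegRNA.

    ``anneal_len`` (>= 15) is the length of the template suffix the reverse
    primer anneals to. When the extension is shorter than ``anneal_len`` the
    reverse primer reaches into the scaffold (logged as a warning, not an
    error).
    """
    if anneal_len < 15:
        raise ValueError("anneal_len must be >= 15")
    forward = T7_PROMOTER + pegrna.spacer_oligo_seq + scaffold_seq[:scaffold_head_len]
    template_tail = (scaffold_seq + pegrna.extension_seq)[-anneal_len:]
    if len(pegrna.extension_seq) < anneal_len:
        logger.warning(
            "pegRNA extension (%d nt) shorter than anneal_len (%d); reverse primer "
            "extends %d nt into the scaffold",
            len(pegrna.extension_seq), anneal_len, anneal_len - len(pegrna.extension_seq),
        )
    return IVTPrimerPair(forward=forward, reverse=revcomp(template_tail))
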