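"""Coordinate conventions, edit representation and nick-relative nomenclature.

All genomic coordinates in this package are 0-based, half-open, on the given
("top") strand of the locus. Human-facing output (labels, reports) uses the
field convention instead: positions counted from the pegRNA nick on the PAM
strand, with +1 being the first base 3' of the nick. Edits are stored in
top-strand orientation and converted to PAM-strand orientation only when a
label is rendered or parsed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_DNA_RE = re.compile(r"^[ACGT]+$")

#: en dash, as used in range labels such as "+1–3 CTT del"
EN_DASH = "–"


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGT string."""
    return seq.translate(_COMPLEMENT)[::-1]


def _check_dna(seq: str, what: str, allow_empty: bool = False) -> str:
    seq = seq.upper()
    if not seq:
        if allow_empty:
            return seq
        raise ValueError(f"{what} must be a non-empty DNA sequence")
    if not _DNA_RE.match(seq):
        raise ValueError(f"{what} contains characters outside ACGT: {seq!r}")
    return seq


class AlleleMismatchError(ValueError):
    """The stated reference allele does not match the locus sequence."""


class UnreachableEditError(ValueError):
    """The edit lies 5' of the nick on the PAM strand; PE cannot write there."""


class LabelParseError(ValueError):
    """A nick-relative label does not match any of the rendering grammars."""


@dataclass(frozen=True)
class Locus:
    """A named reference sequence, uppercase ACGT, top-strand oriented."""

    name: str
    sequence: str
    origin_note: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", _check_dna(self.sequence, "locus sequence"))

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class EditSpec:
    """An intended edit in top-strand coordinates.

    ``start`` is the 0-based top-strand position of the first affected base
    (for insertions: the position the new bases are inserted before).
    Substitutions are equal-length ref/alt replacements; an insertion has an
    empty ``ref_allele`` and a deletion an empty ``alt_allele``.
    """

    kind: str  # substitution | insertion | deletion
    start: int
    ref_allele: str = ""
    alt_allele: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("substitution", "insertion", "deletion"):
            raise ValueError(f"unknown edit kind {self.kind!r}")
        ref = _check_dna(self.ref_allele, "ref_allele", allow_empty=True)
        alt = _check_dna(self.alt_allele, "alt_allele", allow_empty=True)
        object.__setattr__(self, "ref_allele", ref)
        object.__setattr__(self, "alt_allele", alt)
        if self.start < 0:
            raise ValueError("edit start must be >= 0")
        if self.kind == "substitution":
            if not ref or not alt:
                raise ValueError("substitution needs non-empty ref and alt alleles")
            if len(ref) != len(alt):
                raise ValueError("substitutions are equal-length replacements")
        elif self.kind == "insertion":
            if ref or not alt:
                raise ValueError("insertion needs empty ref and non-empty alt")
        else:  # deletion
            if alt or not ref:
                raise ValueError("deletion needs non-empty ref and empty alt")

    @property
    def end(self) -> int:
        """0-based end (exclusive) of the replaced reference span."""
        return self.start + len(self.ref_allele)

    @property
    def net_length_change(self) -> int:
        return len(self.alt_allele) - len(self.ref_allele)

    def validate_against(self, locus: Locus) -> None:
        if self.end > len(locus):
            raise AlleleMismatchError(
                f"edit span [{self.start}, {self.end}) exceeds locus {locus.name} "
                f"of length {len(locus)}"
            )
        found = locus.sequence[self.start : self.end]
        if found != self.ref_allele:
            raise AlleleMismatchError(
                f"ref allele mismatch at position {self.start} of {locus.name}: "
                f"expected {self.ref_allele!r}, locus has {found!r}"
            )


def apply_edit(locus: Locus, edit: EditSpec) -> str:
    """Apply ``edit`` to the locus and return the edited top-strand sequence.

    Pure function; the result length differs from the locus by
    ``len(alt) - len(ref)``.
    """
    edit.validate_against(locus)
    s = locus.sequence
    return s[: edit.start] + edit.alt_allele + s[edit.end :]


# ---------------------------------------------------------------------------
# PAM-strand frame conversion
#
# A protospacer site (see pegkit.design) carries a strand and a nick position.
# For '+' sites the PAM strand is the top strand and coordinates carry over
# unchanged; for '-' sites the PAM-strand frame is the reverse complement of
# the locus, and a top-strand position i maps to L - i.


def pam_frame_sequence(sequence: str, strand: str) -> str:
    return sequence if strand == "+" else revcomp(sequence)


def nick_in_pam_frame(site, locus_length: int) -> int:
    """Nick position expressed as an index into the PAM-strand frame."""
    return site.nick_pos if site.strand == "+" else locus_length - site.nick_pos


def edit_in_pam_frame(edit: EditSpec, locus_length: int, strand: str) -> EditSpec:
    """Re-express a top-strand edit in the PAM-strand frame of a site."""
    if strand == "+":
        return edit
    start = locus_length - edit.end
    return EditSpec(
        kind=edit.kind,
        start=start,
        ref_allele=revcomp(edit.ref_allele),
        alt_allele=revcomp(edit.alt_allele),
    )


def edit_from_pam_frame(edit: EditSpec, locus_length: int, strand: str) -> EditSpec:
    """Inverse of :func:`edit_in_pam_frame` (the mapping is an involution)."""
    return edit_in_pam_frame(edit, locus_length, strand)


@dataclass(frozen=True)
class NickRelativeLabel:
    """An edit written in the field's nick-relative style.

    ``start_offset`` counts from the nick on the PAM strand; +1 is the first
    base 3' of the nick. ``from_seq``/``to_seq`` are written in PAM-strand
    orientation. Rendered forms: "+1 CTT ins", "+1{en dash}3 CTT del",
    "+5 G to C", "+1{en dash}3 CAA to ACC".
    """

    start_offset: int
    end_offset: int
    kind: str
    from_seq: str = ""
    to_seq: str = ""

    def __post_init__(self) -> None:
        if self.start_offset < 1 or self.end_offset < self.start_offset:
            raise ValueError("offsets must satisfy 1 <= start_offset <= end_offset")

    def render(self) -> str:
        if self.start_offset == self.end_offset:
            pos = f"+{self.start_offset}"
        else:
            pos = f"+{self.start_offset}{EN_DASH}{self.end_offset}"
        if self.kind == "insertion":
            return f"+{self.start_offset} {self.to_seq} ins"
        if self.kind == "deletion":
            return f"{pos} {self.from_seq} del"
        return f"{pos} {self.from_seq} to {self.to_seq}"

    def __str__(self) -> str:
        return self.render()


def label_edit(edit: EditSpec, site, locus: Locus) -> NickRelativeLabel:
    """Express ``edit`` relative to the nick of ``site``, PAM-strand oriented.

    Raises :class:`UnreachableEditError` when any affected base lies 5' of the
    nick on the PAM strand (prime editing can only write 3' of the nick).
    """
    edit.validate_against(locus)
    L = len(locus)
    e = edit_in_pam_frame(edit, L, site.strand)
    nick = nick_in_pam_frame(site, L)
    start_offset = e.start - nick + 1
    if start_offset < 1:
        raise UnreachableEditError(
            f"edit at PAM-strand offset {start_offset} lies 5' of the nick; "
            "prime editing cannot write upstream of the nick"
        )
    if e.kind == "insertion":
        end_offset = start_offset + len(e.alt_allele) - 1
    else:
        end_offset = start_offset + len(e.ref_allele) - 1
    return NickRelativeLabel(
        start_offset=start_offset,
        end_offset=end_offset,
        kind=e.kind,
        from_seq=e.ref_allele,
        to_seq=e.alt_allele,
    )


_LABEL_RE = re.compile(
    r"^\+(?P<a>\d+)(?:[–-](?P<b>\d+))?\s+"
    r"(?:(?P<sub_from>[ACGTacgt]+)\s+to\s+(?P<sub_to>[ACGTacgt]+)"
    r"|(?P<seq>[ACGTacgt]+)\s+(?P<indel>ins|del))$"
)

_GRAMMAR_HINT = (
    'expected one of: "+k SEQ ins", "+a–b SEQ del" / "+k X del", '
    '"+k X to Y" / "+a–b XYZ to ABC"'
)


def parse_label(text: str, site, locus: Locus) -> EditSpec:
    """Parse a nick-relative label back into a top-strand :class:`EditSpec`.

    Inverse of :func:`label_edit`: ``parse_label(str(label_edit(e)))`` equals
    ``e`` for any valid edit. The locus is needed to recover and validate the
    reference allele of deletions and substitutions.
    """
    m = _LABEL_RE.match(text.strip())
    if not m:
        raise LabelParseError(f"cannot parse edit label {text!r}; {_GRAMMAR_HINT}")
    a = int(m.group("a"))
    b = int(m.group("b")) if m.group("b") else None
    if a < 1 or (b is not None and b < a):
        raise LabelParseError(f"bad offset range in {text!r}; {_GRAMMAR_HINT}")

    L = len(locus)
    pam_seq = pam_frame_sequence(locus.sequence, site.strand)
    nick = nick_in_pam_frame(site, L)
    start_pam = nick + a - 1

    if m.group("indel") == "ins":
        alt = m.group("seq").upper()
        if b is not None and b - a + 1 != len(alt):
            raise LabelParseError(f"range in {text!r} disagrees with inserted length")
        e_pam = EditSpec(kind="insertion", start=start_pam, alt_allele=alt)
    elif m.group("indel") == "del":
        ref = m.group("seq").upper()
        span = (b - a + 1) if b is not None else len(ref)
        if span != len(ref):
            raise LabelParseError(f"range in {text!r} disagrees with deleted length")
        e_pam = EditSpec(kind="deletion", start=start_pam, ref_allele=ref)
    else:
        ref = m.group("sub_from").upper()
        alt = m.group("sub_to").upper()
        if len(ref) != len(alt):
            raise LabelParseError(f"substitution alleles differ in length in {text!r}")
        span = (b - a + 1) if b is not None else 1
        if span != len(ref):
            raise LabelParseError(f"range in {text!r} disagrees with allele length")
        e_pam = EditSpec(kind="substitution", start=start_pam, ref_allele=ref, alt_allele=alt)

    if e_pam.end > L:
        raise LabelParseError(f"label {text!r} extends past the end of locus {locus.name}")
    if e_pam.ref_allele and pam_seq[e_pam.start : e_pam.end] != e_pam.ref_allele:
        raise AlleleMismatchError(
            f"label {text!r}: PAM-strand bases at offset +{a} are "
            f"{pam_seq[e_pam.start:e_pam.end]!r}, not {e_pam.ref_allele!r}"
        )
    edit = edit_from_pam_frame(e_pam, L, site.strand)
    edit.validate_against(locus)
    return edit
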