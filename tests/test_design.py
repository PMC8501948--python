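"""Protospacer scanning, pegRNA construction, oligo and primer emission."""

import numpy as np
import pytest

from pegkit import (
    AdapterTable,
    ConstructPlan,
    EditSpec,
    Locus,
    build_pegrna,
    candidate_pegrna_sites,
    choose_second_nick,
    emit_ivt_primers,
    emit_oligos,
    revcomp,
    scan_pam_sites,
)
from pegkit.design import (
    DEFAULT_ADAPTERS,
    DEFAULT_SHAM_GUIDE,
    SGRNA_SCAFFOLD,
    T7_PROMOTER,
    AdapterConfigError,
    NoReachableProtospacerError,
    g_prepend,
)


def brute_force_sites(seq):
    """Independent oracle: check every 23-mer on both strands for NGG."""
    found = []
    for i in range(len(seq) - 22):
        w = seq[i : i + 23]
        if w[21:23] == "GG":
            found.append(("+", i))
        if w[0:2] == "CC":
            found.append(("-", i + 3))
    return found


def test_scan_single_site_minimal_locus():
    locus = Locus("one", "G" + "A" * 19 + "AGG")
    sites = scan_pam_sites(locus)
    assert len(sites) == 1
    s = sites[0]
    assert (s.strand, s.spacer_start, s.pam_seq) == ("+", 0, "AGG")
    assert s.nick_pos == 17


def test_scan_no_gg_or_cc_yields_nothing():
    locus = Locus("none", "GATATAGATATAGATATAGATATAGA")
    assert scan_pam_sites(locus) == []


def test_scan_agrees_with_brute_force(rng):
    for _ in range(25):
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=80))
        locus = Locus("r", seq)
        got = [(s.strand, s.spacer_start) for s in scan_pam_sites(locus)]
        assert sorted(got) == sorted(brute_force_sites(seq))


def test_scan_sites_relocate_by_substring_search(rng):
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=120))
    locus = Locus("r", seq)
    for s in scan_pam_sites(locus):
        if s.strand == "+":
            assert seq[s.spacer_start : s.spacer_start + 23] == s.spacer_seq + s.pam_seq
        else:
            # bottom strand reads spacer then PAM 5'->3'
            assert revcomp(s.spacer_seq + s.pam_seq) in seq


def test_scan_window_filters_on_pam_position():
    locus = Locus("one", "G" + "A" * 19 + "AGG" + "T" * 10)
    assert len(scan_pam_sites(locus, window=(0, 23))) == 1
    # PAM occupies [20, 23); a window ending before that excludes the site
    assert scan_pam_sites(locus, window=(0, 22)) == []


def test_candidate_ranking_by_nick_to_edit_distance():
    # two + strand sites whose nicks differ; edit 2 nt from one, 9 from other
    rng = np.random.default_rng(3)
    while True:
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=90))
        locus = Locus("r", seq)
        sites = [s for s in scan_pam_sites(locus) if s.strand == "+"]
        if len(sites) >= 2:
            break
    edit_pos = sites[0].nick_pos + 1
    edit = EditSpec("substitution", edit_pos, seq[edit_pos],
                    "A" if seq[edit_pos] != "A" else "C")
    ranked = candidate_pegrna_sites(locus, edit, max_nick_to_edit=60)
    offs = []
    from pegkit.design import edit_offset_from_nick
    for s in ranked:
        offs.append(edit_offset_from_nick(edit, s, len(locus)))
    assert offs == sorted(offs)
    assert all(o >= 1 for o in offs)


def test_candidate_unreachable_edit_raises_with_diagnostics():
    locus = Locus("one", "G" + "A" * 19 + "AGG" + "T" * 5)
    edit = EditSpec("substitution", 0, "G", "C")  # far 5' of the only nick
    with pytest.raises(NoReachableProtospacerError, match="no reachable protospacer"):
        candidate_pegrna_sites(locus, edit)


def test_build_pegrna_toy_values(toy_locus, toy_edit, toy_site, toy_pegrna):
    assert toy_pegrna.pbs_seq == "GCAA"
    assert toy_pegrna.rt_seq == "TGTCAG"
    assert toy_pegrna.extension_seq == "CTGACATTGC"
    assert toy_pegrna.extension_seq == revcomp(toy_pegrna.rt_seq) + revcomp(toy_pegrna.pbs_seq)


@pytest.mark.parametrize(
    "spacer,expected,flag",
    [("ATTTCCCGGGTTTCCCGGGT", "GATTTCCCGGGTTTCCCGGGT", True),
     ("GTTTCCCGGGTTTCCCGGGT", "GTTTCCCGGGTTTCCCGGGT", False)],
)
def test_g_prepend_rule(spacer, expected, flag):
    assert g_prepend(spacer) == (expected, flag)


def test_build_pegrna_g_prepend_flag(toy_pegrna):
    # toy spacer already starts with G: identity branch
    assert toy_pegrna.spacer_oligo_seq == toy_pegrna.site.spacer_seq
    assert toy_pegrna.g_prepended is False
    assert toy_pegrna.spacer_oligo_seq[0] == "G"


def test_build_pegrna_bounds_errors(toy_locus, toy_edit, toy_site):
    from pegkit.design import DesignBoundsError

    with pytest.raises(DesignBoundsError):
        build_pegrna(toy_locus, toy_edit, toy_site, pbs_len=18, rt_homology_len=2)
    with pytest.raises(DesignBoundsError):
        build_pegrna(toy_locus, toy_edit, toy_site, pbs_len=4, rt_homology_len=50)


def test_second_nick_sign_convention_and_opposite_strand(rng):
    # build a locus with a + strand pegRNA site and a - strand site downstream
    for _ in range(200):
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=200))
        locus = Locus("r", seq)
        plus = [s for s in scan_pam_sites(locus) if s.strand == "+"
                and 30 < s.nick_pos < 120]
        if not plus:
            continue
        site = plus[0]
        pos = site.nick_pos + 1
        edit = EditSpec("substitution", pos, seq[pos], "A" if seq[pos] != "A" else "C")
        try:
            peg = build_pegrna(locus, edit, site)
        except Exception:
            continue
        guides = choose_second_nick(locus, peg)
        if guides:
            break
    assert guides, "no second-nick guide found in 200 random loci"
    for g in guides:
        assert g.site.strand != site.strand
        off = g.site.nick_pos - site.nick_pos  # + strand pegRNA: PAM frame is top
        assert g.signed_offset == off
        assert 10 < abs(off) <= 120
    assert [abs(g.signed_offset) for g in guides] == sorted(
        abs(g.signed_offset) for g in guides
    )


def test_second_nick_excludes_same_strand_and_near_offsets(toy_locus, toy_pegrna):
    guides = choose_second_nick(toy_locus, toy_pegrna)
    for g in guides:
        assert g.site.strand == "-"
        assert not -10 <= g.signed_offset <= 10


def _pe3_plan(toy_locus, toy_pegrna):
    guides = choose_second_nick(toy_locus, toy_pegrna, exclusion=(-3, 3))
    return ConstructPlan(mode="pe3", pegrna=toy_pegrna, second_nick=guides[0])


def test_emit_oligos_three_slots_and_complementarity(toy_locus, toy_pegrna):
    plan = _pe3_plan(toy_locus, toy_pegrna)
    duplexes = emit_oligos(plan)
    assert [d.slot for d in duplexes] == ["spacer", "extension", "second_nick"]
    for d in duplexes:
        core_top = d.top_seq[len(d.top_overhang):]
        core_bottom = d.bottom_seq[len(d.bottom_overhang):]
        assert core_top == revcomp(core_bottom)
        assert len(d.top_overhang) == len(d.bottom_overhang) == 4


def test_emit_oligos_nuclease_uses_sham_guide(toy_pegrna):
    plan = ConstructPlan(mode="nuclease", pegrna=toy_pegrna)
    duplexes = emit_oligos(plan)
    second = duplexes[2]
    assert DEFAULT_SHAM_GUIDE in second.top_seq
    with pytest.raises(ValueError, match="sham"):
        ConstructPlan(mode="nuclease", pegrna=toy_pegrna,
                      second_nick=object.__new__(type("X", (), {})))


def test_emit_oligos_deterministic(toy_locus, toy_pegrna):
    plan = _pe3_plan(toy_locus, toy_pegrna)
    a = emit_oligos(plan)
    b = emit_oligos(plan)
    assert a == b


def test_adapter_table_validation():
    with pytest.raises(AdapterConfigError, match="missing"):
        AdapterTable(table={"d": {"spacer": ("CACC", "AAAC")}})
    with pytest.raises(AdapterConfigError, match="distinct"):
        AdapterTable(table={"d": {
            "spacer": ("CACC", "AAAC"),
            "extension": ("CACC", "AAAC"),
            "second_nick": ("ACCG", "CAAA"),
        }})
    # every shipped dialect/slot has 4-nt overhangs, three distinct pairs
    for dialect, slots in DEFAULT_ADAPTERS.table.items():
        pairs = {(t[:4], b[:4]) for t, b in slots.values()}
        assert len(pairs) == 3


def test_ivt_primer_structure(toy_pegrna):
    pair = emit_ivt_primers(toy_pegrna, anneal_len=20)
    assert pair.forward.startswith(T7_PROMOTER)
    assert toy_pegrna.spacer_oligo_seq in pair.forward
    # revcomp(reverse) is a suffix of scaffold + extension
    template = SGRNA_SCAFFOLD + toy_pegrna.extension_seq
    assert template.endswith(revcomp(pair.reverse))
    # extension is 10 nt here, so a 20-nt anneal reaches 10 nt into the scaffold
    assert revcomp(pair.reverse)[-len(toy_pegrna.extension_seq):] == toy_pegrna.extension_seq
    assert len(pair.reverse) == 20


def test_ivt_primer_rejects_short_anneal(toy_pegrna):
    with pytest.raises(ValueError):
        emit_ivt_primers(toy_pegrna, anneal_len=10)
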