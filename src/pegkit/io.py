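"""File I/O: FASTA loci, FASTQ reads, design JSON, TSV tables.

All formats go through Biopython/pandas; design descriptions round-trip
losslessly through JSON so the simulate and classify subcommands can consume
what design produced.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import EditSpec, Locus
from .design import (
    ConstructPlan,
    IVTPrimerPair,
    OligoDuplex,
    PegRNADesign,
    ProtospacerSite,
    SecondNickGuide,
)

logger = logging.getLogger(__name__)


def read_fasta(path) -> Locus:
    """Load a single-record FASTA as a :class:`Locus` (uppercased)."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    if len(records) > 1:
        raise ValueError(
            f"{path}: {len(records)} records found; a locus must be a single "
            "record — extract the one of interest first"
        )
    rec = records[0]
    seq = str(rec.seq)
    if seq != seq.upper():
        logger.info("%s: lowercase bases uppercased on load", path)
    return Locus(name=rec.id, sequence=seq.upper(), origin_note=rec.description)


def write_fasta(locus: Locus, path) -> None:
    rec = SeqRecord(Seq(locus.sequence), id=locus.name, description="")
    SeqIO.write([rec], str(path), "fasta")


def write_fastq(records, path) -> None:
    SeqIO.write(records, str(path), "fastq")


def read_fastq(path):
    """Yield (read_id, sequence) pairs from a FASTQ file."""
    for rec in SeqIO.parse(str(path), "fastq"):
        yield rec.id, str(rec.seq)


# -- design JSON ------------------------------------------------------------


def plan_to_dict(locus: Locus, edit: EditSpec, plan: ConstructPlan) -> dict:
    d = {
        "locus": {"name": locus.name, "sequence": locus.sequence,
                  "origin_note": locus.origin_note},
        "edit": asdict(edit),
        "mode": plan.mode,
        "dialect": plan.dialect,
        "sham_guide_seq": plan.sham_guide_seq,
        "pegrna": asdict(plan.pegrna),
        "second_nick": asdict(plan.second_nick) if plan.second_nick else None,
    }
    return d


def plan_from_dict(d: dict):
    """Inverse of :func:`plan_to_dict`: returns (locus, edit, plan)."""
    locus = Locus(**d["locus"])
    edit = EditSpec(**d["edit"])
    peg_d = dict(d["pegrna"])
    peg_d["site"] = ProtospacerSite(**peg_d["site"])
    pegrna = PegRNADesign(**peg_d)
    second = None
    if d.get("second_nick"):
        sn = dict(d["second_nick"])
        sn["site"] = ProtospacerSite(**sn["site"])
        second = SecondNickGuide(**sn)
    plan = ConstructPlan(
        mode=d["mode"],
        pegrna=pegrna,
        second_nick=second,
        sham_guide_seq=d.get("sham_guide_seq", ""),
        dialect=d.get("dialect", "pea1"),
    )
    return locus, edit, plan


def write_design_json(locus: Locus, edit: EditSpec, plan: ConstructPlan, path) -> None:
    Path(path).write_text(json.dumps(plan_to_dict(locus, edit, plan), indent=2) + "\n")


def read_design_json(path):
    return plan_from_dict(json.loads(Path(path).read_text()))


# -- tables ------------------------------------------------------------------

DESIGNS_COLUMNS = [
    "rank", "strand", "spacer_start", "spacer_seq", "pam_seq", "nick_pos",
    "pbs_seq", "rt_seq", "extension_seq", "second_nick_offset",
]


def designs_table(rows) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=DESIGNS_COLUMNS)


def oligos_table(duplexes: list[OligoDuplex]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "slot": d.slot,
                "top_seq": d.top_seq,
                "bottom_seq": d.bottom_seq,
                "top_overhang": d.top_overhang,
                "bottom_overhang": d.bottom_overhang,
            }
            for d in duplexes
        ],
        columns=["slot", "top_seq", "bottom_seq", "top_overhang", "bottom_overhang"],
    )


def ivt_table(primers: IVTPrimerPair) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"primer": "forward", "sequence": primers.forward},
            {"primer": "reverse", "sequence": primers.reverse},
        ],
        columns=["primer", "sequence"],
    )


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(str(path), sep="\t", index=False)


def write_truth_tsv(truth: pd.DataFrame, path) -> None:
    truth.to_csv(str(path), sep="\t", index=False)


def calls_table(calls) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "read_id": c.read_id,
                "label": c.label,
                "has_signature": c.has_signature,
                "extra_ins_len": c.extra_ins_len,
            }
            for c in calls
        ],
        columns=["read_id", "label", "has_signature", "extra_ins_len"],
    )


def write_report_json(report, path) -> None:
    Path(path).write_text(json.dumps(report.to_dict(), indent=2) + "\n")
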