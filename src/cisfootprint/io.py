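"""FASTA / BED-like TSV / report readers and writers."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .are import AREReport
from .pwm import MotifHit, ScanReport
from .synthetic import GroundTruth

BED_COLUMNS = ["seq_id", "start", "end", "label", "score", "strand"]


def write_fasta(records: Mapping[str, str] | Sequence[tuple[str, str]],
                path: str | Path) -> None:
    items = records.items() if isinstance(records, Mapping) else records
    seqs = [SeqRecord(Seq(s), id=name, description="") for name, s in items]
    SeqIO.write(seqs, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}


def write_hits_bed(hits: Iterable[MotifHit], path: str | Path) -> None:
    """Hits as BED6-like TSV; score column is 1000 * relative score."""
    rows = [
        {
            "seq_id": h.seq_id,
            "start": h.start,
            "end": h.end,
            "label": h.pwm_id,
            "score": int(round(1000 * h.rel_score)),
            "strand": h.strand,
        }
        for h in hits
    ]
    pd.DataFrame(rows, columns=BED_COLUMNS).to_csv(path, sep="\t", index=False,
                                                   header=False)


def read_hits_bed(path: str | Path) -> list[MotifHit]:
    df = pd.read_csv(path, sep="\t", names=BED_COLUMNS)
    return [
        MotifHit(seq_id=r.seq_id, start=int(r.start), end=int(r.end),
                 pwm_id=r.label, strand=r.strand,
                 rel_score=float(r.score) / 1000.0)
        for r in df.itertuples()
    ]


def write_ground_truth(truths: Mapping[str, GroundTruth], path: str | Path) -> None:
    """Planted elements as BED-like TSV (0-based, half-open)."""
    rows = []
    for seq_id, truth in truths.items():
        for pwm_id, start, end, strand in truth.planted_tfbs:
            rows.append({"seq_id": seq_id, "start": start, "end": end,
                         "label": pwm_id, "score": 0, "strand": strand})
        for label, start, end in truth.planted_ares:
            rows.append({"seq_id": seq_id, "start": start, "end": end,
                         "label": f"ARE_{label}", "score": 0, "strand": "."})
    pd.DataFrame(rows, columns=BED_COLUMNS).to_csv(path, sep="\t", index=False,
                                                   header=False)


def scan_reports_frame(reports: Sequence[ScanReport]) -> pd.DataFrame:
    rows = []
    for r in reports:
        row = {"seq_id": r.seq_id, "distinct_total": r.distinct_total,
               "all_total": r.all_total}
        for pid, c in r.per_pwm_distinct.items():
            row[f"distinct_{pid}"] = c
        rows.append(row)
    return pd.DataFrame(rows)


def are_reports_frame(reports: Sequence[AREReport],
                      groups: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Per-gene ARE counts, columns ordered class III / II / I / core."""
    rows = []
    for r in reports:
        rows.append({
            "seq_id": r.seq_id,
            "group": groups.get(r.seq_id, "") if groups else "",
            "ARE_III": r.count_class3,
            "ARE_II": r.count_class2,
            "ARE_I": r.count_class1,
            "core": r.count_core,
        })
    return pd.DataFrame(rows)
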