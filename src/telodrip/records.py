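"""Core domain containers: subtelomere records and interval utilities.

A :class:`SubtelomereRecord` holds the distal sequence of one chromosome
end, oriented 5'->3' on the TERRA-sense strand so that the telomeric
(TTAGGG)n tract, when present, is rightmost.  All coordinates are 0-based
half-open, FASTA headers carry the chromosome-arm label (e.g. ``10q``).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

Interval = tuple[int, int]

VALID_BASES = frozenset("ACGTN")


def _check_interval(iv: Interval, name: str, hi: int) -> None:
    s, e = iv
    if not (0 <= s <= e <= hi):
        raise ValueError(f"{name} interval {iv} outside [0, {hi}]")


@dataclass
class SubtelomereRecord:
    """One chromosome end's distal sequence with its annotations.

    Parameters
    ----------
    id:
        Chromosome-arm label, e.g. ``"10q"``.
    seq:
        DNA over {A,C,G,T,N}, TERRA-sense strand, telomere tract rightmost.
    tss_pos:
        0-based offset of the TERRA transcription start site, or None.
    promoter, amplicon:
        Half-open intervals within the subtelomeric portion, or None.
    telomere_span:
        Half-open interval of the telomeric repeat tract; when non-empty it
        must end at ``len(seq)``.  ``(L, L)`` denotes an absent tract.
    """

    id: str
    seq: str
    tss_pos: Optional[int] = None
    promoter: Optional[Interval] = None
    amplicon: Optional[Interval] = None
    telomere_span: Optional[Interval] = None

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()
        bad = set(self.seq) - VALID_BASES
        if bad:
            raise ValueError(f"record {self.id}: invalid bases {sorted(bad)}")
        n = len(self.seq)
        if self.telomere_span is None:
            self.telomere_span = (n, n)
        _check_interval(self.telomere_span, "telomere_span", n)
        if self.telomere_span[1] > self.telomere_span[0] and self.telomere_span[1] != n:
            raise ValueError(
                f"record {self.id}: non-empty telomere_span must end at len(seq)"
            )
        sub_end = self.telomere_span[0]
        for name, iv in (("promoter", self.promoter), ("amplicon", self.amplicon)):
            if iv is not None:
                _check_interval(iv, name, n)
                if iv[1] > sub_end:
                    raise ValueError(
                        f"record {self.id}: {name} {iv} overlaps telomere tract"
                    )
        if self.tss_pos is not None and not (0 <= self.tss_pos < sub_end):
            raise ValueError(
                f"record {self.id}: tss_pos {self.tss_pos} not in subtelomeric portion"
            )

    @property
    def subtelomere_end(self) -> int:
        """Start of the telomere tract (== len(seq) when tract absent)."""
        return self.telomere_span[0]

    @property
    def telomere_length(self) -> int:
        return self.telomere_span[1] - self.telomere_span[0]


# ---------------------------------------------------------------------------
# FASTA / BED round-trip
# ---------------------------------------------------------------------------

_BED_FEATURES = ("tss", "promoter", "amplicon", "telomere_tract")


def write_fasta(records: Iterable[SubtelomereRecord], path: str | Path) -> None:
    seq_records = [
        SeqRecord(Seq(r.seq), id=r.id, description="") for r in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def write_bed(records: Iterable[SubtelomereRecord], path: str | Path) -> None:
    """Write TSS/promoter/amplicon/telomere-tract annotations as BED6."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for r in records:
            if r.tss_pos is not None:
                w.writerow([r.id, r.tss_pos, r.tss_pos + 1, "tss", 0, "+"])
            if r.promoter is not None:
                w.writerow([r.id, *r.promoter, "promoter", 0, "+"])
            if r.amplicon is not None:
                w.writerow([r.id, *r.amplicon, "amplicon", 0, "+"])
            if r.telomere_length > 0:
                w.writerow([r.id, *r.telomere_span, "telomere_tract", 0, "+"])


def read_records(fasta_path: str | Path, bed_path: str | Path | None = None
                 ) -> list[SubtelomereRecord]:
    """Load records from FASTA plus an optional BED annotation file."""
    ann: dict[str, dict[str, Interval]] = {}
    if bed_path is not None:
        with open(bed_path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("#", "track")):
                    continue
                parts = line.rstrip("\n").split("\t")
                chrom, start, end, name = parts[0], int(parts[1]), int(parts[2]), parts[3]
                if name not in _BED_FEATURES:
                    raise ValueError(f"unknown BED feature {name!r}")
                ann.setdefault(chrom, {})[name] = (start, end)
        missing = []
    records = []
    for sr in SeqIO.parse(str(fasta_path), "fasta"):
        a = ann.get(sr.id, {})
        tss = a.get("tss")
        records.append(
            SubtelomereRecord(
                id=sr.id,
                seq=str(sr.seq),
                tss_pos=tss[0] if tss else None,
                promoter=a.get("promoter"),
                amplicon=a.get("amplicon"),
                telomere_span=a.get("telomere_tract"),
            )
        )
    return records
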