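"""DRIP-seq peak summarization over distal subtelomeric windows.

Peak calling itself (MACS2 on mapped reads) is upstream of this package; we
consume its narrowPeak/BED output and reproduce the subtelomeric summary:
fold enrichment aggregated over the most distal 2 kb of each chromosome end,
plus a replicate-consistency call (both replicates of a dataset must show at
least one peak in the window).

Aggregation is the overlap-length-weighted mean of fold enrichment over the
window bases covered by peaks; bases under k overlapping peaks contribute k
terms to both numerator and denominator, which makes the result invariant
under splitting a peak into abutting equal-enrichment pieces.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .records import Interval

#: Width of the distal window aggregated per subtelomere (bp).
DISTAL_WINDOW_BP = 2000


@dataclass(frozen=True)
class Peak:
    chrom: str
    start: int
    end: int
    fold_enrichment: float
    q_value: Optional[float] = None
    name: str = "."

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"peak {self.chrom}:{self.start}-{self.end}: start >= end")
        if self.fold_enrichment < 0:
            raise ValueError("fold_enrichment must be >= 0")


@dataclass
class PeakSet:
    """A collection of called peaks with fold-enrichment scores."""

    peaks: list[Peak] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.peaks)

    def for_chrom(self, chrom: str) -> list[Peak]:
        return [p for p in self.peaks if p.chrom == chrom]

    # -- narrowPeak IO (ENCODE 6+4; column 7 = signalValue = fold enrichment)
    def write_narrowpeak(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            for p in self.peaks:
                q = -1 if p.q_value is None else p.q_value
                w.writerow([p.chrom, p.start, p.end, p.name, 0, ".",
                            p.fold_enrichment, -1, q, -1])

    @classmethod
    def read_narrowpeak(cls, path: str | Path) -> "PeakSet":
        peaks = []
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("#", "track")):
                    continue
                f = line.rstrip("\n").split("\t")
                if len(f) < 7:
                    raise ValueError(
                        f"narrowPeak line has {len(f)} columns, need >= 7: {line!r}")
                q = float(f[8]) if len(f) > 8 else -1.0
                peaks.append(Peak(f[0], int(f[1]), int(f[2]),
                                  fold_enrichment=float(f[6]),
                                  q_value=None if q < 0 else q,
                                  name=f[3]))
        return cls(peaks)


def _check_window(window: Interval) -> None:
    if window[0] >= window[1]:
        raise ValueError(f"malformed window {window}")


def aggregate_enrichment(peaks: PeakSet, window: Interval,
                         chrom: Optional[str] = None,
                         agg: str = "weighted_mean") -> float:
    """Aggregate fold enrichment of *peaks* over *window*.

    ``weighted_mean`` (default): overlap-length-weighted mean over covered
    bases; ``sum``: sum of FE x overlap-length; ``max``: maximum FE of any
    overlapping peak.  Returns 0.0 when no peak overlaps the window.
    """
    _check_window(window)
    pool = peaks.peaks if chrom is None else peaks.for_chrom(chrom)
    overlaps = []
    for p in pool:
        ov = min(p.end, window[1]) - max(p.start, window[0])
        if ov > 0:
            overlaps.append((ov, p.fold_enrichment))
    if not overlaps:
        return 0.0
    if agg == "weighted_mean":
        num = sum(ov * fe for ov, fe in overlaps)
        den = sum(ov for ov, _ in overlaps)
        return num / den
    if agg == "sum":
        return float(sum(ov * fe for ov, fe in overlaps))
    if agg == "max":
        return float(max(fe for _, fe in overlaps))
    raise ValueError(f"unknown agg {agg!r}")


def replicate_consistency(peaks_rep1: PeakSet, peaks_rep2: PeakSet,
                          window: Interval,
                          chrom: Optional[str] = None) -> bool:
    """True iff each replicate has >= 1 peak overlapping *window*
    (half-open: a peak ending exactly at window start does not overlap)."""
    _check_window(window)

    def hits(ps: PeakSet) -> bool:
        pool = ps.peaks if chrom is None else ps.for_chrom(chrom)
        return any(min(p.end, window[1]) > max(p.start, window[0]) for p in pool)

    return hits(peaks_rep1) and hits(peaks_rep2)


def enrichment_matrix(peaksets: Mapping[str, Sequence[PeakSet]],
                      windows: Mapping[str, Interval],
                      order: Optional[Sequence[str]] = None,
                      agg: str = "weighted_mean"
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Heatmap-ready matrix of aggregated enrichment.

    *peaksets* maps dataset name -> replicate PeakSets (peak chrom ids must
    match the subtelomere ids keying *windows*).  Returns ``(matrix,
    consistent)``: rows are subtelomeres (in *order*, default the window
    order), columns datasets; cell value is the mean across replicates of
    the per-replicate aggregate, and the flag is True when every replicate
    shows >= 1 overlapping peak.
    """
    if not peaksets or not windows:
        raise ValueError("need >= 1 dataset and >= 1 window")
    rows = list(order) if order is not None else list(windows)
    unmatched = [r for r in rows if r not in windows]
    if unmatched:
        raise KeyError(f"no window for subtelomere(s): {unmatched}")
    known = set(windows)
    for name, reps in peaksets.items():
        bad = sorted({p.chrom for ps in reps for p in ps.peaks} - known)
        if bad:
            raise KeyError(
                f"dataset {name!r} has peaks on unmatched id(s): {bad}")
    mat = pd.DataFrame(index=rows, columns=list(peaksets), dtype=float)
    cons = pd.DataFrame(index=rows, columns=list(peaksets), dtype=bool)
    for ds, reps in peaksets.items():
        if not reps:
            raise ValueError(f"dataset {ds!r} has no replicates")
        for sub in rows:
            win = windows[sub]
            vals = [aggregate_enrichment(ps, win, chrom=sub, agg=agg)
                    for ps in reps]
            mat.loc[sub, ds] = float(np.mean(vals))
            cons.loc[sub, ds] = all(
                replicate_consistency(ps, ps, win, chrom=sub) for ps in reps)
    return mat, cons
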