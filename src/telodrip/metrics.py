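"""Windowed sequence metrics and GC-skew-based hybrid-propensity scoring.

GC skew on the TERRA-sense strand is (G - C)/(G + C): positive skew means a
G-rich transcript over a C-rich template, the configuration that favours
co-transcriptional DNA:RNA hybrid (R-loop) formation.  The distal 2 kb of
each subtelomere is profiled in tiled overlapping windows (default 200 bp,
step 100 bp) for GC skew, GC content and CpG density; the cumulative skew of
the region downstream of the TERRA TSS summarizes each chromosome end into a
single hybrid-propensity score.

Undefined skew (a window with zero G+C) is encoded as NaN and propagated,
never coerced to 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

from .records import Interval, SubtelomereRecord

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


def _encode(seq: str) -> np.ndarray:
    try:
        return np.array([_BASE_CODE[b] for b in seq.upper()], dtype=np.int8)
    except KeyError as exc:
        raise ValueError(f"invalid base {exc.args[0]!r}") from None


def window_metrics(seq: str, cpg_mode: Literal["per_bp", "obs_exp"] = "per_bp"
                   ) -> tuple[float, float, float]:
    """GC skew, GC content and CpG density of a single window.

    skew = (#G - #C)/(#G + #C), NaN when the window has no G or C;
    gc_content = (#G + #C) / (non-N length);
    cpg_density = #CG dinucleotides / window length (``per_bp``) or the
    observed/expected CpG ratio n_CG * len / (n_C * n_G) (``obs_exp``).
    N bases are excluded from all counts.
    """
    if not seq:
        raise ValueError("empty sequence")
    seq = seq.upper()
    n_g = seq.count("G")
    n_c = seq.count("C")
    n_cg = seq.count("CG")
    non_n = len(seq) - seq.count("N")
    gc = n_g + n_c
    skew = (n_g - n_c) / gc if gc else float("nan")
    gc_content = gc / non_n if non_n else float("nan")
    if cpg_mode == "per_bp":
        cpg = n_cg / len(seq)
    elif cpg_mode == "obs_exp":
        cpg = n_cg * len(seq) / (n_c * n_g) if n_c and n_g else float("nan")
    else:
        raise ValueError(f"unknown cpg_mode {cpg_mode!r}")
    return skew, gc_content, cpg


@dataclass
class WindowProfile:
    """Per-window metric vectors over a profiled region of one record."""

    record_id: str
    window_starts: np.ndarray  # 0-based offsets into the record sequence
    window_len: int
    step: int
    skew: np.ndarray        # in [-1, 1], NaN where window has zero G+C
    gc_content: np.ndarray  # in [0, 1]
    cpg_density: np.ndarray  # >= 0

    def __post_init__(self) -> None:
        n = len(self.window_starts)
        for name in ("skew", "gc_content", "cpg_density"):
            v = getattr(self, name)
            if len(v) != n:
                raise ValueError(f"{name} length {len(v)} != {n} windows")

    @property
    def n_windows(self) -> int:
        return len(self.window_starts)


def sliding_window_profile(record: SubtelomereRecord,
                           region: Optional[Interval] = None,
                           window_len: int = 200, step: int = 100,
                           cpg_mode: Literal["per_bp", "obs_exp"] = "per_bp"
                           ) -> WindowProfile:
    """Tile *region* (default: the whole subtelomeric portion) left-to-right
    with overlapping windows; a trailing partial window is dropped."""
    if region is None:
        region = (0, record.subtelomere_end)
    start, end = region
    if not (0 <= start < end <= len(record.seq)):
        raise ValueError(f"region {region} outside record {record.id}")
    if window_len < 1 or not (1 <= step <= window_len):
        raise ValueError("require window_len >= 1 and 1 <= step <= window_len")
    if end - start < window_len:
        raise ValueError(
            f"region of {end - start} bp shorter than window ({window_len} bp)")
    starts = np.arange(start, end - window_len + 1, step)
    skew = np.empty(len(starts))
    gc = np.empty(len(starts))
    cpg = np.empty(len(starts))
    for i, s in enumerate(starts):
        skew[i], gc[i], cpg[i] = window_metrics(
            record.seq[s:s + window_len], cpg_mode=cpg_mode)
    return WindowProfile(record.id, starts, window_len, step, skew, gc, cpg)


def cumulative_gc_skew(record: SubtelomereRecord,
                       anchor: Literal["tss", "promoter_start"] = "tss"
                       ) -> float:
    """Region-wide GC skew downstream of the TERRA TSS (or promoter start).

    Computed on raw base counts over [anchor, telomere tract start), so it is
    independent of any window/step choice.  Returns NaN when the region
    contains no G or C.
    """
    if anchor == "tss":
        if record.tss_pos is None:
            raise ValueError(f"record {record.id} has no TSS annotation")
        start = record.tss_pos
    elif anchor == "promoter_start":
        if record.promoter is None:
            raise ValueError(f"record {record.id} has no promoter annotation")
        start = record.promoter[0]
    else:
        raise ValueError(f"unknown anchor {anchor!r}")
    end = record.subtelomere_end
    if start >= end:
        raise ValueError(
            f"record {record.id}: empty region downstream of {anchor}")
    region = record.seq[start:end]
    skew, _, _ = window_metrics(region)
    return skew


# ---------------------------------------------------------------------------
# Clustering and classification
# ---------------------------------------------------------------------------

def downstream_skew_vector(profile: WindowProfile, boundary: int,
                           n_points: int) -> Optional[np.ndarray]:
    """Skew of the windows starting at/after *boundary*, linearly resampled
    to *n_points*; None when every downstream window has undefined skew."""
    mask = profile.window_starts >= boundary
    skew = profile.skew[mask]
    if skew.size == 0 or np.all(np.isnan(skew)):
        return None
    defined = ~np.isnan(skew)
    # interpolate over undefined windows so records stay comparable
    x = np.arange(skew.size)
    skew = np.interp(x, x[defined], skew[defined])
    return np.interp(np.linspace(0, skew.size - 1, n_points), x, skew)


def cluster_profiles(profiles: Sequence[WindowProfile],
                     boundaries: Sequence[int],
                     n_points: int = 20,
                     method: str = "average"):
    """Hierarchically cluster records by downstream-of-promoter GC skew.

    Feature vector per record: skew values of windows downstream of that
    record's promoter end (*boundaries*), resampled to a common length.
    Euclidean distance, average linkage by default; fully deterministic.

    Returns ``(leaf_ids, linkage_matrix, excluded_ids)``; records whose
    downstream skew is entirely undefined are excluded with a warning.
    """
    if len(profiles) != len(boundaries):
        raise ValueError("one boundary per profile required")
    feats, ids, excluded = [], [], []
    for p, b in zip(profiles, boundaries):
        v = downstream_skew_vector(p, b, n_points)
        if v is None:
            warnings.warn(
                f"record {p.record_id}: downstream skew entirely undefined; "
                "excluded from clustering", stacklevel=2)
            excluded.append(p.record_id)
        else:
            feats.append(v)
            ids.append(p.record_id)
    if len(feats) < 2:
        raise ValueError("need at least 2 scorable profiles to cluster")
    X = np.vstack(feats)
    Z = linkage(pdist(X, metric="euclidean"), method=method)
    order = leaves_list(Z)
    return [ids[i] for i in order], Z, excluded


def classify_hybrid_prone(records: Iterable[SubtelomereRecord],
                          threshold: float = 0.0,
                          anchor: Literal["tss", "promoter_start"] = "tss"
                          ) -> dict[str, Optional[bool]]:
    """Label each record hybrid-prone iff its cumulative downstream GC skew
    strictly exceeds *threshold*.

    Undefined skew maps to ``None`` ("unscorable"), never silently False.
    """
    labels: dict[str, Optional[bool]] = {}
    for r in records:
        skew = cumulative_gc_skew(r, anchor=anchor)
        labels[r.id] = None if np.isnan(skew) else bool(skew > threshold)
    return labels


def profile_table(profiles: Sequence[WindowProfile]):
    """Long-format table of window metrics (one row per record x window)."""
    import pandas as pd

    rows = []
    for p in profiles:
        for i in range(p.n_windows):
            rows.append({
                "record": p.record_id,
                "window_start": int(p.window_starts[i]),
                "window_end": int(p.window_starts[i]) + p.window_len,
                "skew": p.skew[i],
                "gc_content": p.gc_content[i],
                "cpg_density": p.cpg_density[i],
            })
    return pd.DataFrame(rows)
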