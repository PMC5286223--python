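"""Synthetic subtelomeres, qPCR cohorts and peak files with known truth.

Every downstream stage of the pipeline is testable without patient material:
this module emulates the study's inputs — skew-structured distal subtelomeric
sequence ending in a (TTAGGG)n tract, planted restriction sites, DRIP-qPCR
Ct cohorts for WT vs ICF groups with RNase H / HinfI / cell-cycle-phase
effects, and DRIP-seq-style peak files — and records the ground truth each
generator used.

Composition blocks are i.i.d. per-base multinomial draws, the simplest model
whose expected window GC skew is known analytically: a block with G and C
fractions (g, c) has expected skew (g - c)/(g + c).  Planted recognition
sites overwrite the sampled bases in place, keeping coordinates stable.
Ct values anchor at Ct(1% input) = 25.0 cycles for every locus; the anchor
is arbitrary and cancels in every ratio the pipeline reports.  One master
seed spawns a fixed child stream per sample, so sub-cohorts reproduce
independently of cohort size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .digestion import ENZYMES
from .peaks import DISTAL_WINDOW_BP, Peak, PeakSet
from .records import Interval, SubtelomereRecord

TELOMERE_HEXAMER = "TTAGGG"

#: Ct of the reserved 1% input aliquot (cycles); arbitrary anchor.
DEFAULT_INPUT_CT = 25.0

_BASES = np.array(list("GCAT"))


@dataclass
class CompositionBlock:
    """A stretch of sequence with fixed base composition (g, c, a, t)."""

    length: int
    g_frac: float
    c_frac: float
    a_frac: float
    t_frac: float

    def __post_init__(self) -> None:
        fr = (self.g_frac, self.c_frac, self.a_frac, self.t_frac)
        if self.length < 1:
            raise ValueError("block length must be >= 1")
        if any(f < 0 for f in fr):
            raise ValueError("base fractions must be >= 0")
        if not math.isclose(sum(fr), 1.0, abs_tol=1e-9):
            raise ValueError(f"base fractions sum to {sum(fr)}, not 1")

    @property
    def expected_skew(self) -> float:
        gc = self.g_frac + self.c_frac
        return (self.g_frac - self.c_frac) / gc if gc else float("nan")


@dataclass
class SyntheticSubteloConfig:
    """Blueprint for one synthetic chromosome end."""

    record_id: str
    blocks: Sequence[CompositionBlock]
    telomere_repeats: int = 0
    planted_sites: Sequence[tuple[str, int]] = ()  # (enzyme name, 0-based pos)
    tss_pos: Optional[int] = None
    promoter: Optional[Interval] = None
    amplicon: Optional[Interval] = None
    seed: int = 0

    @property
    def total_length(self) -> int:
        return sum(b.length for b in self.blocks)

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError("need at least one composition block")
        if self.telomere_repeats < 0:
            raise ValueError("telomere_repeats must be >= 0")
        L = self.total_length
        prev_end = -1
        last_pos = -1
        for name, pos in self.planted_sites:
            if name not in ENZYMES:
                raise ValueError(f"unknown enzyme {name!r}")
            if pos <= last_pos:
                raise ValueError("planted positions must be strictly increasing")
            if pos < prev_end:
                raise ValueError(
                    f"planted site {name} at {pos} overlaps previous site")
            end = pos + len(ENZYMES[name].recognition)
            if pos < 0 or end > L:
                raise ValueError(
                    f"planted site {name} at {pos} outside subtelomeric portion")
            prev_end, last_pos = end, pos
        if self.amplicon is not None and not (
                0 <= self.amplicon[0] < self.amplicon[1] <= L):
            raise ValueError("amplicon must lie within the subtelomeric portion")


@dataclass
class SubteloTruth:
    """Ground truth recorded alongside a generated subtelomere."""

    record_id: str
    planted_sites: list[tuple[str, int]]
    expected_block_skew: list[float]
    telomere_span: Interval
    expected_downstream_skew: Optional[float]  # None when no TSS
    prone: Optional[bool]                      # expected_downstream_skew > 0


def make_subtelomere(config: SyntheticSubteloConfig
                     ) -> tuple[SubtelomereRecord, SubteloTruth]:
    """Sample a subtelomere record per *config*; deterministic given seed."""
    rng = np.random.default_rng(config.seed)
    parts = []
    for b in config.blocks:
        probs = [b.g_frac, b.c_frac, b.a_frac, b.t_frac]
        parts.append("".join(rng.choice(_BASES, size=b.length, p=probs)))
    chars = list("".join(parts))
    for name, pos in config.planted_sites:
        site = ENZYMES[name].concrete_site()
        chars[pos:pos + len(site)] = site
    sub = "".join(chars)
    tract = TELOMERE_HEXAMER * config.telomere_repeats
    L = config.total_length
    record = SubtelomereRecord(
        id=config.record_id,
        seq=sub + tract,
        tss_pos=config.tss_pos,
        promoter=config.promoter,
        amplicon=config.amplicon,
        telomere_span=(L, L + len(tract)),
    )
    exp_down: Optional[float] = None
    prone: Optional[bool] = None
    if config.tss_pos is not None:
        # length-weighted expected (g - c)/(g + c) over blocks past the TSS
        g = c = n = 0.0
        off = 0
        for b in config.blocks:
            s, e = off, off + b.length
            ov = max(0, min(e, L) - max(s, config.tss_pos))
            g += ov * b.g_frac
            c += ov * b.c_frac
            n += ov
            off = e
        exp_down = (g - c) / (g + c) if (g + c) else float("nan")
        prone = exp_down > 0 if not math.isnan(exp_down) else None
    return record, SubteloTruth(
        record_id=config.record_id,
        planted_sites=list(config.planted_sites),
        expected_block_skew=[b.expected_skew for b in config.blocks],
        telomere_span=record.telomere_span,
        expected_downstream_skew=exp_down,
        prone=prone,
    )


# ---------------------------------------------------------------------------
# qPCR cohorts
# ---------------------------------------------------------------------------

@dataclass
class LocusSpec:
    """True DRIP enrichment of one subtelomeric locus, per group.

    Levels are on the percent-of-input scale (1.0 = recovery equal to the
    reserved 1% aliquot).  ``telomere_linked`` marks loci whose amplicon is
    severed from the telomere tract by the extra HinfI digestion, so the
    HinfI reduction factor applies there and nowhere else.
    """

    locus: str
    level_wt: float
    level_icf: float
    telomere_linked: bool = True

    def __post_init__(self) -> None:
        if self.level_wt <= 0 or self.level_icf <= 0:
            raise ValueError(f"locus {self.locus}: levels must be > 0")

    def level(self, group: str) -> float:
        return self.level_wt if group == "WT" else self.level_icf


@dataclass
class CohortDesign:
    """Design of a simulated WT vs ICF DRIP-qPCR cohort."""

    loci: Sequence[LocusSpec]
    n_wt: int = 4
    n_icf: int = 4
    rnaseh_ablation: float = 0.05      # residual signal fraction after RNase H
    hinfi_linked_reduction: float = 0.3  # applied at telomere-linked loci, +HinfI
    phase_effects: Optional[Mapping[str, Mapping[str, float]]] = None
    ct_noise_sd: float = 0.3           # Gaussian noise on IP Ct, cycles
    input_ct: float = DEFAULT_INPUT_CT
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.loci:
            raise ValueError("need at least one locus")
        if self.n_wt < 1 or self.n_icf < 1:
            raise ValueError("group sizes must be >= 1")
        if self.rnaseh_ablation <= 0 or self.hinfi_linked_reduction <= 0:
            raise ValueError("multipliers must be > 0")
        if self.ct_noise_sd < 0:
            raise ValueError("ct_noise_sd must be >= 0")
        if self.phase_effects is not None:
            for grp, mults in self.phase_effects.items():
                if grp not in ("WT", "ICF"):
                    raise ValueError(f"unknown group {grp!r} in phase_effects")
                if any(m <= 0 for m in mults.values()):
                    raise ValueError("phase multipliers must be > 0")

    @property
    def samples(self) -> list[tuple[str, str]]:
        return ([(f"WT{i + 1}", "WT") for i in range(self.n_wt)]
                + [(f"ICF{i + 1}", "ICF") for i in range(self.n_icf)])


CT_COLUMNS = ["sample", "group", "locus", "fraction", "treatment", "phase",
              "replicate", "ct"]


def _true_level(design: CohortDesign, spec: LocusSpec, group: str,
                treatment: str, phase: str) -> float:
    level = spec.level(group)
    if treatment == "rnaseh":
        level *= design.rnaseh_ablation
    elif treatment == "hinfi" and spec.telomere_linked:
        level *= design.hinfi_linked_reduction
    if phase != "NA" and design.phase_effects is not None:
        level *= design.phase_effects.get(group, {}).get(phase, 1.0)
    return level


def make_qpcr_cohort(design: CohortDesign
                     ) -> tuple[pd.DataFrame, dict[tuple, float]]:
    """Simulate a long-format DRIP-qPCR Ct table plus its truth record.

    For every sample x locus x condition an ``input_1pct`` row at the anchor
    Ct and an ``IP`` row at ``Ct_input - log2(true level) + N(0, sd)`` are
    emitted.  Conditions: treatments none / rnaseh / hinfi at phase NA, and
    (when ``phase_effects`` is set) untreated G1/S/G2 rows.  The truth dict
    maps ``(sample, locus, treatment, phase)`` to the noise-free true level.
    """
    conditions = [("none", "NA"), ("rnaseh", "NA"), ("hinfi", "NA")]
    if design.phase_effects is not None:
        conditions += [("none", ph) for ph in ("G1", "S", "G2")]
    rows, truth = [], {}
    for idx, (sample, group) in enumerate(design.samples):
        rng = np.random.default_rng([design.seed, idx])  # fixed child stream
        for spec in design.loci:
            for treatment, phase in conditions:
                level = _true_level(design, spec, group, treatment, phase)
                truth[(sample, spec.locus, treatment, phase)] = level
                noise = rng.normal(0.0, design.ct_noise_sd) \
                    if design.ct_noise_sd else 0.0
                base = [sample, group, spec.locus]
                tail = [treatment, phase, 1]
                rows.append(base + ["input_1pct"] + tail + [design.input_ct])
                rows.append(base + ["IP"] + tail
                            + [design.input_ct - math.log2(level) + noise])
    df = pd.DataFrame(rows, columns=CT_COLUMNS)
    return df, truth


#: Ct of the reference (beta-actin) amplicon in expression tables; arbitrary.
REFERENCE_CT = 20.0
REFERENCE_LOCUS = "ACTB"


def make_expression_table(design: CohortDesign) -> tuple[pd.DataFrame, dict]:
    """Simulate a TERRA qRT-PCR table for the ddCt workflow.

    Emits per sample x locus x phase a target Ct row plus a constant-level
    beta-actin reference row; target abundance is the locus level times the
    group's phase multiplier.  Requires ``phase_effects``.
    """
    if design.phase_effects is None:
        raise ValueError("expression table requires phase_effects")
    rows, truth = [], {}
    for idx, (sample, group) in enumerate(design.samples):
        rng = np.random.default_rng([design.seed, 10_000 + idx])
        for phase in ("G1", "S", "G2"):
            rows.append([sample, group, REFERENCE_LOCUS, phase, 1,
                         REFERENCE_CT])
            for spec in design.loci:
                level = spec.level(group) \
                    * design.phase_effects.get(group, {}).get(phase, 1.0)
                truth[(sample, spec.locus, phase)] = level
                noise = rng.normal(0.0, design.ct_noise_sd) \
                    if design.ct_noise_sd else 0.0
                rows.append([sample, group, spec.locus, phase, 1,
                             design.input_ct - math.log2(level) + noise])
    cols = ["sample", "group", "locus", "phase", "replicate", "ct"]
    return pd.DataFrame(rows, columns=cols), truth


# ---------------------------------------------------------------------------
# Peak files
# ---------------------------------------------------------------------------

def make_peakset(record: SubtelomereRecord, truth: SubteloTruth,
                 replicate_seed: int = 0, fold_enrichment: float = 5.0,
                 fe_noise_sd: float = 0.0) -> PeakSet:
    """Emit a DRIP-seq-style peak set for one synthetic subtelomere.

    Hybrid-prone truth records receive one peak spanning the
    downstream-of-TSS part of the distal window, at *fold_enrichment* plus
    optional Gaussian noise; non-prone records yield an empty set.  Distinct
    ``replicate_seed`` values emulate technical replicates of one dataset.
    """
    if not truth.prone:
        return PeakSet([])
    sub_end = record.subtelomere_end
    win_start = max(0, sub_end - DISTAL_WINDOW_BP)
    start = max(win_start, record.tss_pos if record.tss_pos is not None
                else win_start)
    rng = np.random.default_rng(replicate_seed)
    fe = fold_enrichment + (rng.normal(0.0, fe_noise_sd) if fe_noise_sd else 0.0)
    fe = max(fe, 0.0)
    return PeakSet([Peak(record.id, start, sub_end, fold_enrichment=fe,
                         name=f"{record.id}_peak1")])


def distal_window(record: SubtelomereRecord,
                  width: int = DISTAL_WINDOW_BP) -> Interval:
    """The most distal *width* bp of the subtelomeric portion."""
    sub_end = record.subtelomere_end
    return (max(0, sub_end - width), sub_end)
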