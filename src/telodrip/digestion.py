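"""In-silico restriction digestion and telomere-linkage logic.

Models the DRIP fragmentation step: genomic DNA is cut with a five-enzyme
cocktail (XhoI, SspI, HindIII, EcoRI, BsrGI), optionally followed by HinfI.
At subtelomeres where a HinfI site sits between the qPCR amplicon and the
telomeric repeat tract, the extra digestion physically severs the amplified
region from the telomere — the basis of the linkage assay that asks whether
DNA:RNA hybrids reside in the hexameric repeats themselves.

All six built-in sites are palindromic, so single-strand search is
sufficient; a both-strand option exists for user-supplied enzymes.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .records import SubtelomereRecord

# IUPAC nucleotide codes -> concrete base sets
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}


@dataclass(frozen=True)
class RestrictionEnzyme:
    """A restriction enzyme: recognition site (IUPAC) and cut offset.

    ``cut_offset`` is measured in bp from the 5' end of the site on the
    given strand; a cut at site position p produces fragments
    ``[..., p + cut_offset)`` and ``[p + cut_offset, ...)``.
    """

    name: str
    recognition: str
    cut_offset: int

    def __post_init__(self) -> None:
        site = self.recognition.upper()
        object.__setattr__(self, "recognition", site)
        if not site or any(b not in IUPAC for b in site):
            raise ValueError(f"{self.name}: invalid recognition site {site!r}")
        if not (0 <= self.cut_offset <= len(site)):
            raise ValueError(f"{self.name}: cut_offset outside recognition site")

    def regex(self) -> re.Pattern[str]:
        pat = "".join(b if len(IUPAC[b]) == 1 else f"[{IUPAC[b]}]"
                      for b in self.recognition)
        return re.compile(f"(?={pat})")  # lookahead: overlapping matches too

    def concrete_site(self) -> str:
        """A fixed concrete expansion (degenerate codes -> first base)."""
        return "".join(IUPAC[b][0] for b in self.recognition)


# Standard REBASE cut offsets; fixing them makes fragment lengths exact.
XHOI = RestrictionEnzyme("XhoI", "CTCGAG", 1)
SSPI = RestrictionEnzyme("SspI", "AATATT", 3)
HINDIII = RestrictionEnzyme("HindIII", "AAGCTT", 1)
ECORI = RestrictionEnzyme("EcoRI", "GAATTC", 1)
BSRGI = RestrictionEnzyme("BsrGI", "TGTACA", 1)
HINFI = RestrictionEnzyme("HinfI", "GANTC", 1)

#: The five-enzyme fragmentation cocktail used ahead of immunoprecipitation.
COCKTAIL: tuple[RestrictionEnzyme, ...] = (XHOI, SSPI, HINDIII, ECORI, BSRGI)

ENZYMES = {e.name: e for e in (*COCKTAIL, HINFI)}


def find_cut_sites(seq: str, enzyme: RestrictionEnzyme,
                   both_strands: bool = False) -> list[int]:
    """Ascending, de-duplicated cut positions of *enzyme* in *seq*.

    Overlapping recognition-site matches are all reported.  With
    ``both_strands`` the reverse-complement strand is searched as well
    (needed only for non-palindromic user enzymes).
    """
    seq = seq.upper()
    cuts = {m.start() + enzyme.cut_offset for m in enzyme.regex().finditer(seq)}
    if both_strands:
        # a site matching the minus strand at [s, s+k) cuts the plus strand
        # at s + (k - cut_offset)
        rc_enzyme = RestrictionEnzyme(
            enzyme.name, reverse_complement_iupac(enzyme.recognition),
            len(enzyme.recognition) - enzyme.cut_offset)
        cuts |= {m.start() + rc_enzyme.cut_offset
                 for m in rc_enzyme.regex().finditer(seq)}
    return sorted(c for c in cuts if 0 < c < len(seq))


_IUPAC_COMPLEMENT = {
    "A": "T", "T": "A", "G": "C", "C": "G", "N": "N",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D",
}


def reverse_complement_iupac(site: str) -> str:
    return "".join(_IUPAC_COMPLEMENT[b] for b in reversed(site.upper()))


@dataclass(frozen=True)
class Fragment:
    start: int
    end: int
    left_enzyme: str   # enzyme that produced the left boundary, or "5'-end"
    right_enzyme: str  # ditto, or "3'-end"

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, iv: tuple[int, int]) -> bool:
        return self.start <= iv[0] and iv[1] <= self.end

    def overlaps(self, iv: tuple[int, int]) -> bool:
        return max(self.start, iv[0]) < min(self.end, iv[1])


@dataclass
class DigestResult:
    """Ordered fragments partitioning [0, len(seq)) with cut provenance."""

    seq_length: int
    fragments: list[Fragment]
    cut_positions: dict[str, list[int]] = field(default_factory=dict)

    def fragment_containing(self, pos: int) -> Fragment:
        for f in self.fragments:
            if f.start <= pos < f.end:
                return f
        raise IndexError(f"position {pos} outside [0, {self.seq_length})")

    @property
    def lengths(self) -> list[int]:
        return [f.length for f in self.fragments]


def digest(seq: str, enzymes: Sequence[RestrictionEnzyme]) -> DigestResult:
    """Cut *seq* with every enzyme; fragments are the induced partition."""
    if not enzymes:
        raise ValueError("at least one enzyme required")
    per_enzyme = {e.name: find_cut_sites(seq, e) for e in enzymes}
    by_pos: dict[int, str] = {}
    for name, cuts in per_enzyme.items():
        for c in cuts:
            by_pos.setdefault(c, name)
    bounds = [0, *sorted(by_pos), len(seq)]
    frags = []
    for i in range(len(bounds) - 1):
        s, e = bounds[i], bounds[i + 1]
        frags.append(Fragment(
            start=s, end=e,
            left_enzyme=by_pos.get(s, "5'-end") if i else "5'-end",
            right_enzyme=by_pos.get(e, "3'-end"),
        ))
    return DigestResult(len(seq), frags, per_enzyme)


def terminal_fragment(record: SubtelomereRecord,
                      enzymes: Sequence[RestrictionEnzyme]) -> Fragment:
    """The rightmost fragment — the terminal restriction fragment (TRF),
    containing the telomere tract when one is present."""
    return digest(record.seq, enzymes).fragments[-1]


@dataclass
class LinkageReport:
    """Whether a record's qPCR amplicon stays linked to its telomere tract."""

    record_id: str
    fragment: Fragment
    telomere_linked: bool
    category: str            # "+HinfI" if a HinfI site lies strictly between
                             # amplicon end and telomere tract, else "-HinfI"
    amplicon_destroyed: bool  # amplicon spans a cut site -> qPCR would fail
    hinfi_included: bool


def amplicon_telomere_linkage(record: SubtelomereRecord,
                              enzymes: Sequence[RestrictionEnzyme] = COCKTAIL,
                              include_hinfi: bool = False) -> LinkageReport:
    """Classify a subtelomere for the HinfI linkage assay.

    ``telomere_linked`` is True iff the amplicon and the telomere tract fall
    in the same fragment of the (cocktail +/- HinfI) digest.  The category
    records the record's geometry — "+HinfI" when a HinfI site lies strictly
    between the amplicon and the tract — independent of whether HinfI was
    actually included in this digest.
    """
    if record.amplicon is None:
        raise ValueError(f"record {record.id} has no amplicon annotation")
    if record.telomere_length == 0:
        raise ValueError(f"record {record.id} has no telomere tract")
    used = list(enzymes)
    if include_hinfi and not any(e.name == "HinfI" for e in used):
        used.append(HINFI)
    result = digest(record.seq, used)

    amp = record.amplicon
    hinfi_cuts = find_cut_sites(record.seq, HINFI)
    has_distal_hinfi = any(amp[1] <= c <= record.telomere_span[0]
                           for c in hinfi_cuts)
    category = "+HinfI" if has_distal_hinfi else "-HinfI"

    frag = result.fragment_containing(amp[0])
    destroyed = not frag.contains(amp)
    linked = (not destroyed) and frag.overlaps(record.telomere_span)
    return LinkageReport(
        record_id=record.id,
        fragment=frag,
        telomere_linked=linked,
        category=category,
        amplicon_destroyed=destroyed,
        hinfi_included=include_hinfi,
    )
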