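"""Degenerate-pattern matching and bipartite -35/spacer/-10 promoter scanning.

The promoter model is the three-motif anatomy of sigma-I-dependent promoters:
a homopolymeric A-tract terminating the -35 element, a variable 12-15 nt
spacer, and a short -10 core (CGHH by default, i.e. CG followed by two
non-G bases).  The "region of specificity" immediately 5' of the A-tract and
a short context window 3' of the -10 core are carried along with every match
for downstream classification.

A-tracts are reported as *maximal* runs of A: one biological site yields one
match even when the run is longer than the -35 core, so hit counts are not
inflated on long A-runs.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Mapping

from .genome_io import Genome, revcomp

IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

#: minimal IUPAC code covering each nonempty base set
SET_TO_CODE: dict[frozenset[str], str] = {v: k for k, v in IUPAC_CODES.items()}


@dataclass(frozen=True)
class DegeneratePattern:
    """A fixed-length pattern over the full IUPAC nucleotide alphabet."""

    symbols: str

    def __post_init__(self) -> None:
        if not self.symbols:
            raise ValueError("empty pattern")
        bad = set(self.symbols.upper()) - set(IUPAC_CODES)
        if bad:
            raise ValueError(f"invalid IUPAC symbols: {sorted(bad)}")
        object.__setattr__(self, "symbols", self.symbols.upper())

    def __len__(self) -> int:
        return len(self.symbols)

    def __str__(self) -> str:
        return self.symbols

    @property
    def expansions(self) -> tuple[frozenset[str], ...]:
        return tuple(IUPAC_CODES[s] for s in self.symbols)


def as_pattern(p: "DegeneratePattern | str") -> DegeneratePattern:
    return p if isinstance(p, DegeneratePattern) else DegeneratePattern(p)


def iupac_match(pattern: "DegeneratePattern | str", seq: str) -> bool:
    """True iff ``seq`` (over A/C/G/T/N) is covered position-wise by ``pattern``.

    An N in the sequence matches nothing except the pattern symbol N: an
    assembly gap is never evidence for a concrete motif base.
    """
    pattern = as_pattern(pattern)
    if len(seq) != len(pattern):
        raise ValueError(f"length mismatch: pattern {len(pattern)}, seq {len(seq)}")
    for sym, base in zip(pattern.symbols, seq):
        if base == "N":
            if sym != "N":
                return False
        elif base not in IUPAC_CODES[sym]:
            return False
    return True


@dataclass(frozen=True)
class MotifSpec:
    """Definition of the bipartite promoter search.

    ``spacer_min``/``spacer_max`` bound the gap from the 3' end of the
    maximal A-tract to the 5' start of the -10 core.  ``specificity_window``
    nucleotides upstream of the A-tract and ``downstream_window`` nucleotides
    after the -10 core are retained on every match.
    """

    minus35_core: str = "AAA"
    minus10_core: str = "CGHH"
    spacer_min: int = 12
    spacer_max: int = 15
    specificity_window: int = 6
    downstream_window: int = 6

    def __post_init__(self) -> None:
        as_pattern(self.minus35_core)
        as_pattern(self.minus10_core)
        if not (0 < self.spacer_min <= self.spacer_max):
            raise ValueError("require 0 < spacer_min <= spacer_max")
        if self.specificity_window < 0 or self.downstream_window < 0:
            raise ValueError("windows must be >= 0")

    def to_dict(self) -> dict:
        return {
            "minus35_core": self.minus35_core,
            "minus10_core": self.minus10_core,
            "spacer_min": self.spacer_min,
            "spacer_max": self.spacer_max,
            "specificity_window": self.specificity_window,
            "downstream_window": self.downstream_window,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "MotifSpec":
        return cls(**{k: d[k] for k in cls().to_dict() if k in d})


@dataclass(frozen=True)
class ElementMatch:
    """One located bipartite promoter match.

    Coordinates refer to the scanned coordinate system: the local sequence
    for :func:`scan_bipartite`, forward-strand genomic coordinates for
    :func:`scan_genome` (minus-strand matches keep their genomic footprint;
    the sequence fields are always written 5'->3' on the match strand).
    """

    sequence_id: str
    strand: str
    atract_start: int
    atract_end: int
    spacer_len: int
    minus10_start: int
    minus10_end: int
    specificity_seq: str
    atract_seq: str
    minus10_seq: str
    downstream_seq: str

    @property
    def promoter_start(self) -> int:
        """Start of the core footprint (A-tract through -10 core), forward strand."""
        return min(self.atract_start, self.minus10_start)

    @property
    def promoter_end(self) -> int:
        return max(self.atract_end, self.minus10_end)


_A_RUN = re.compile(r"A+")


def _pattern_regex(pattern: DegeneratePattern) -> re.Pattern:
    parts = []
    for exp in pattern.expansions:
        bases = "".join(sorted(exp))
        parts.append(bases if len(bases) == 1 else f"[{bases}]")
    # lookahead capture so overlapping occurrences are all found
    return re.compile(r"(?=(" + "".join(parts) + r"))")


def _match_at(seq: str, pos: int, expansions: tuple[frozenset[str], ...]) -> bool:
    if pos < 0 or pos + len(expansions) > len(seq):
        return False
    for off, exp in enumerate(expansions):
        base = seq[pos + off]
        if base == "N" or base not in exp:
            return False
    return True


def scan_bipartite(seq: str, spec: MotifSpec | None = None, sequence_id: str = "seq",
                   strand: str = "+") -> list[ElementMatch]:
    """Find every bipartite promoter match in ``seq``, left to right.

    Each distinct (maximal A-tract, -10 start) pair is reported exactly once;
    overlapping but distinct matches are all reported.  Specificity and
    downstream context are truncated at the sequence edges.
    """
    if spec is None:
        spec = MotifSpec()
    core35 = as_pattern(spec.minus35_core)
    core10 = as_pattern(spec.minus10_core)
    exp10 = core10.expansions
    k35, k10 = len(core35), len(core10)

    # -35 anchors: maximal A-runs when the core is A-compatible (the normal
    # sigma-I case), otherwise plain pattern occurrences.
    anchors: list[tuple[int, int]] = []
    if iupac_match(core35, "A" * k35):
        for m in _A_RUN.finditer(seq):
            if m.end() - m.start() >= k35:
                anchors.append((m.start(), m.end()))
    else:
        rx = _pattern_regex(core35)
        for m in rx.finditer(seq):
            anchors.append((m.start(), m.start() + k35))

    out: list[ElementMatch] = []
    for a_start, a_end in anchors:
        for spacer in range(spec.spacer_min, spec.spacer_max + 1):
            m10s = a_end + spacer
            m10e = m10s + k10
            if m10e > len(seq):
                break
            if _match_at(seq, m10s, exp10):
                out.append(
                    ElementMatch(
                        sequence_id=sequence_id,
                        strand=strand,
                        atract_start=a_start,
                        atract_end=a_end,
                        spacer_len=spacer,
                        minus10_start=m10s,
                        minus10_end=m10e,
                        specificity_seq=seq[max(0, a_start - spec.specificity_window): a_start],
                        atract_seq=seq[a_start:a_end],
                        minus10_seq=seq[m10s:m10e],
                        downstream_seq=seq[m10e: m10e + spec.downstream_window],
                    )
                )
    out.sort(key=lambda m: (m.atract_start, m.minus10_start))
    return out


def _map_minus_strand(match: ElementMatch, contig_len: int) -> ElementMatch:
    """Re-express a match found on the reverse complement in forward coordinates."""
    L = contig_len

    def flip(s: int, e: int) -> tuple[int, int]:
        return L - e, L - s

    a_s, a_e = flip(match.atract_start, match.atract_end)
    m_s, m_e = flip(match.minus10_start, match.minus10_end)
    return ElementMatch(
        sequence_id=match.sequence_id,
        strand="-",
        atract_start=a_s,
        atract_end=a_e,
        spacer_len=match.spacer_len,
        minus10_start=m_s,
        minus10_end=m_e,
        specificity_seq=match.specificity_seq,
        atract_seq=match.atract_seq,
        minus10_seq=match.minus10_seq,
        downstream_seq=match.downstream_seq,
    )


def scan_genome(genome: Genome, spec: MotifSpec | None = None,
                strands: str = "both") -> list[ElementMatch]:
    """Scan every contig on the requested strand(s).

    Minus-strand matches are reported with their forward-strand genomic
    footprint and ``strand='-'``; output is sorted by (contig order in the
    genome, footprint start, strand).
    """
    if spec is None:
        spec = MotifSpec()
    if strands not in ("+", "-", "both"):
        raise ValueError(f"strands must be '+', '-' or 'both', got {strands!r}")
    order = {cid: i for i, cid in enumerate(genome.contig_ids)}
    out: list[ElementMatch] = []
    for cid, seq in genome.contigs.items():
        if strands in ("+", "both"):
            out.extend(scan_bipartite(seq, spec, sequence_id=cid, strand="+"))
        if strands in ("-", "both"):
            rc_matches = scan_bipartite(revcomp(seq), spec, sequence_id=cid, strand="-")
            out.extend(_map_minus_strand(m, len(seq)) for m in rc_matches)
    out.sort(key=lambda m: (order[m.sequence_id], m.promoter_start, m.strand))
    return out


def background_hit_rate(spec: MotifSpec, base_frequencies: Mapping[str, float]) -> float:
    """Expected bipartite hits per position per strand under an i.i.d. background.

    Sums, over the allowed spacer lengths, the product of per-position pattern
    probabilities of the two cores.  Because the scanner deduplicates matches
    onto maximal A-tracts, this closed form is an *upper bound* on realized
    counts (long A-runs contribute several core placements but one match).
    The bound is exact up to a factor ~(1 - p_A) for the default all-A core.
    """
    freqs = {b: float(base_frequencies[b]) for b in "ACGT"}
    if any(v < 0 for v in freqs.values()):
        raise ValueError("negative base frequency")
    total = sum(freqs.values())
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"base frequencies must sum to 1 (got {total})")

    def pattern_prob(pattern: str) -> float:
        p = 1.0
        for exp in as_pattern(pattern).expansions:
            p *= sum(freqs[b] for b in exp)
        return p

    n_spacers = spec.spacer_max - spec.spacer_min + 1
    return pattern_prob(spec.minus35_core) * n_spacers * pattern_prob(spec.minus10_core)
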