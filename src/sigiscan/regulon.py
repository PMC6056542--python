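"""End-to-end promoter prediction, region-of-specificity filtering, per-sigma
regulon assignment with cross-talk detection, and cross-species transfer.

Classification is deliberately rule-plus-score, not argmax: a candidate is
assigned to *every* sigma whose specificity rule it satisfies and whose
profile scores it above threshold.  Promoters recognized by several sigma
factors (the cipA/cel48S-style "universal" promoters) are reported as
cross-talk, which is data, not an error.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .genome_io import GeneAnnotation, Genome, extract_upstream
from .motif import ElementMatch, MotifSpec, as_pattern, iupac_match, scan_bipartite, scan_genome
from .profile import PositionProfile, score_window


@dataclass(frozen=True)
class SpecificityRule:
    """Declarative region-of-specificity constraints for one sigma factor.

    ``triad`` must match with its 3' end between ``offset_min`` and
    ``offset_max`` nucleotides upstream of the A-tract 5' start (offset 0 =
    immediately adjacent, the sigma-I1 CTC case; offset 2 covers the
    sigma-I3 CCC-two-nucleotides-upstream case).  ``minus10_tetrad``
    constrains the -10 core realization (CGAA vs CGTA), and the optional
    ``downstream_dyad`` is checked ``dyad_gap`` nucleotides after the tetrad
    (AT in nearly all promoters, GT for the sigI3 gene's own promoter).
    """

    sigma_label: str
    triad: str
    offset_min: int = 0
    offset_max: int = 0
    minus10_tetrad: str = "CGAA"
    downstream_dyad: Optional[str] = None
    dyad_gap: int = 3

    def __post_init__(self) -> None:
        if len(as_pattern(self.triad)) != 3:
            raise ValueError("triad must have length 3")
        if not (0 <= self.offset_min <= self.offset_max):
            raise ValueError("require 0 <= offset_min <= offset_max")
        as_pattern(self.minus10_tetrad)
        if self.downstream_dyad is not None:
            as_pattern(self.downstream_dyad)

    def matched_offset(self, match: ElementMatch) -> Optional[int]:
        """Smallest passing offset, or None if the rule fails."""
        spec_seq = match.specificity_seq
        m10 = match.minus10_seq + match.downstream_seq
        k = len(self.minus10_tetrad)
        if len(m10) < k or not iupac_match(self.minus10_tetrad, m10[:k]):
            return None
        if self.downstream_dyad is not None:
            d = len(self.downstream_dyad)
            lo = k + self.dyad_gap
            if len(m10) < lo + d or not iupac_match(self.downstream_dyad, m10[lo: lo + d]):
                return None
        for off in range(self.offset_min, self.offset_max + 1):
            hi = len(spec_seq) - off
            lo = hi - 3
            if lo < 0:
                break
            if iupac_match(self.triad, spec_seq[lo:hi]):
                return off
        return None

    def passes(self, match: ElementMatch) -> bool:
        return self.matched_offset(match) is not None


def cytosine_count_pass(match: ElementMatch, min_c: int = 3, window: int = 5) -> bool:
    """Alternative count-based cytosine-enrichment filter: at least ``min_c``
    C's in the ``window`` nt immediately upstream of the A-tract."""
    return match.specificity_seq[-window:].count("C") >= min_c


@dataclass(frozen=True)
class PromoterCandidate:
    """A located promoter match, optionally tied to its downstream gene.

    ``utr5`` is measured from the 3' end of the -10 core (in the promoter's
    reading orientation) to the first codon of the assigned gene.
    """

    match: ElementMatch
    assigned_gene: Optional[str] = None  # locus_tag
    utr5: Optional[int] = None

    def __post_init__(self) -> None:
        if self.utr5 is not None and self.utr5 < 0:
            raise ValueError("utr5 must be >= 0 when assigned")

    def key(self) -> tuple:
        m = self.match
        return (m.sequence_id, m.strand, m.atract_start, m.atract_end,
                m.minus10_start, m.minus10_end)


@dataclass
class RegulonAssignment:
    """Classification of one candidate against a panel of sigma factors."""

    candidate: PromoterCandidate
    scores: dict[str, float]
    passed_rules: set[str]
    assigned: set[str]

    @property
    def crosstalk(self) -> bool:
        return len(self.assigned) > 1


def predict_promoters(
    genome: Genome,
    annotations: Sequence[GeneAnnotation],
    spec: MotifSpec | None = None,
    window: int = 600,
    scope: str = "upstream_only",
) -> list[PromoterCandidate]:
    """Locate bipartite promoter candidates and tie them to genes.

    ``upstream_only`` scans each gene's upstream window on the gene's sense
    strand and assigns matches to that gene; matches shared by overlapping
    windows are collapsed by genomic coordinates, keeping the nearest gene.
    ``whole_genome`` scans both strands of every contig and assigns each
    match to the nearest downstream gene on the match strand within
    ``window`` (unassigned matches are kept with no gene).
    """
    if spec is None:
        spec = MotifSpec()
    if scope == "upstream_only":
        best: dict[tuple, PromoterCandidate] = {}
        for gene in annotations:
            region = extract_upstream(genome, gene, window)
            if not region.sequence:
                continue
            for m in scan_bipartite(region.sequence, spec, sequence_id=gene.contig_id,
                                    strand=gene.strand):
                a_s, a_e = region.to_genomic(m.atract_start, m.atract_end)
                m10_s, m10_e = region.to_genomic(m.minus10_start, m.minus10_end)
                utr5 = len(region.sequence) - m.minus10_end
                gm = ElementMatch(
                    sequence_id=gene.contig_id,
                    strand=gene.strand,
                    atract_start=a_s,
                    atract_end=a_e,
                    spacer_len=m.spacer_len,
                    minus10_start=m10_s,
                    minus10_end=m10_e,
                    specificity_seq=m.specificity_seq,
                    atract_seq=m.atract_seq,
                    minus10_seq=m.minus10_seq,
                    downstream_seq=m.downstream_seq,
                )
                cand = PromoterCandidate(match=gm, assigned_gene=gene.locus_tag, utr5=utr5)
                prev = best.get(cand.key())
                if prev is None or cand.utr5 < prev.utr5:
                    best[cand.key()] = cand
        out = list(best.values())
    elif scope == "whole_genome":
        by_contig_strand: dict[tuple[str, str], list[GeneAnnotation]] = {}
        for gene in annotations:
            by_contig_strand.setdefault((gene.contig_id, gene.strand), []).append(gene)
        out = []
        for m in scan_genome(genome, spec, strands="both"):
            genes = by_contig_strand.get((m.sequence_id, m.strand), [])
            best_gene, best_utr = None, None
            for gene in genes:
                if m.strand == "+":
                    utr = gene.start - m.minus10_end
                else:
                    utr = m.minus10_start - gene.end
                if 0 <= utr <= window and (best_utr is None or utr < best_utr):
                    best_gene, best_utr = gene.locus_tag, utr
            out.append(PromoterCandidate(match=m, assigned_gene=best_gene, utr5=best_utr))
    else:
        raise ValueError(f"unknown scope: {scope!r}")
    out.sort(key=lambda c: (c.match.sequence_id, c.match.promoter_start, c.match.strand))
    return out


def apply_specificity_rule(
    candidates: Iterable[PromoterCandidate],
    rule: SpecificityRule,
    use_c_count: bool = False,
) -> list[PromoterCandidate]:
    """Keep candidates satisfying the rule (monotone filter: output is a subset).

    With ``use_c_count`` the triad/offset test is replaced by the count-based
    cytosine-enrichment variant; the -10 tetrad and optional dyad are still
    enforced.
    """
    kept = []
    for cand in candidates:
        if use_c_count:
            m10 = cand.match.minus10_seq + cand.match.downstream_seq
            k = len(rule.minus10_tetrad)
            ok = (
                len(m10) >= k
                and iupac_match(rule.minus10_tetrad, m10[:k])
                and cytosine_count_pass(cand.match)
            )
            if ok and rule.downstream_dyad is not None:
                d = len(rule.downstream_dyad)
                lo = k + rule.dyad_gap
                ok = len(m10) >= lo + d and iupac_match(rule.downstream_dyad, m10[lo: lo + d])
        else:
            ok = rule.passes(cand.match)
        if ok:
            kept.append(cand)
    return kept


def _as_profile_map(profiles) -> dict[str, PositionProfile]:
    if isinstance(profiles, Mapping):
        return dict(profiles)
    return {p.sigma_label: p for p in profiles}


def classify_regulon(
    candidate: PromoterCandidate,
    profiles,
    rules: Mapping[str, SpecificityRule] | Sequence[SpecificityRule],
    min_score: float = 0.0,
) -> RegulonAssignment:
    """Assign a candidate to every sigma whose rule passes and whose profile
    scores it at or above ``min_score`` (bits).  Scores are reported for all
    profiles; a sigma without a rule is constrained by score alone.
    """
    pmap = _as_profile_map(profiles)
    if not pmap:
        raise ValueError("empty profile list")
    rmap = rules if isinstance(rules, Mapping) else {r.sigma_label: r for r in rules}
    scores = {label: score_window(prof, candidate.match) for label, prof in pmap.items()}
    passed = {
        label
        for label in pmap
        if label not in rmap or rmap[label].passes(candidate.match)
    }
    assigned = {label for label in passed if scores[label] >= min_score}
    return RegulonAssignment(candidate=candidate, scores=scores,
                             passed_rules=passed, assigned=assigned)


def classify_regulons(candidates, profiles, rules, min_score: float = 0.0) -> list[RegulonAssignment]:
    return [classify_regulon(c, profiles, rules, min_score) for c in candidates]


def transfer_regulon(
    source_profile: PositionProfile,
    source_rule: SpecificityRule,
    target_genome: Genome,
    target_annotations: Sequence[GeneAnnotation],
    spec: MotifSpec | None = None,
    window: int = 600,
    scope: str = "whole_genome",
    min_score: float = 0.0,
) -> list[RegulonAssignment]:
    """Project one sigma factor's promoter model onto another genome.

    Composition of :func:`predict_promoters`, :func:`apply_specificity_rule`
    and :func:`classify_regulon` against the single source profile; the
    report is sorted by descending score.
    """
    candidates = predict_promoters(target_genome, target_annotations, spec, window, scope)
    candidates = apply_specificity_rule(candidates, source_rule)
    label = source_profile.sigma_label
    assignments = classify_regulons(
        candidates, {label: source_profile}, {label: source_rule}, min_score
    )
    assignments.sort(key=lambda a: -a.scores[label])
    return assignments


def _candidate_id(cand: PromoterCandidate) -> str:
    m = cand.match
    base = f"{m.sequence_id}:{m.promoter_start}-{m.promoter_end}({m.strand})"
    return f"{cand.assigned_gene}|{base}" if cand.assigned_gene else base


def crosstalk_matrix(
    assignments: Sequence[RegulonAssignment], sigma_labels: Sequence[str]
) -> pd.DataFrame:
    """Candidate x sigma boolean assignment matrix plus a per-candidate
    cross-talk degree column (``n_assigned``); TSV-serializable via
    ``DataFrame.to_csv(sep='\\t')``."""
    rows = []
    index = []
    for a in assignments:
        row = {label: (label in a.assigned) for label in sigma_labels}
        row["n_assigned"] = len(a.assigned & set(sigma_labels))
        rows.append(row)
        index.append(_candidate_id(a.candidate))
    df = pd.DataFrame(rows, index=index, columns=[*sigma_labels, "n_assigned"])
    df.index.name = "candidate"
    return df
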