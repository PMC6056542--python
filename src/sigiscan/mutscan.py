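"""In-silico saturation transversion mutagenesis of a promoter window.

Reconstructs, computationally, the classic reporter-library experiment in
which every position of a sigma-I3-dependent promoter receives a single
transversion (A<->T, C<->G) and the mutant's activity is compared with the
wild type.  Two decoupled behaviours are modelled: a *hard ablation* when
the mutant no longer contains a valid bipartite core match (mirroring "not
detected" reporter activity), and a *graded* log-odds score difference
against a promoter profile (mirroring relative activity).

For a sigma-I3-style analysis the :class:`~sigiscan.motif.MotifSpec` should
carry the sigma-specific -10 core (``CGAA``) rather than the permissive
genome-search core ``CGHH``; with CGHH an A->T change at tetrad position 3
would still match and the mutant would not read as ablated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd

from .motif import ElementMatch, MotifSpec, scan_bipartite
from .profile import PositionProfile, score_window

#: purine<->pyrimidine exchange used for the mutant library
TRANSVERSION = {"A": "T", "T": "A", "C": "G", "G": "C"}

EFFECT_CLASSES = ("ablated", "reduced", "neutral", "increased")


@dataclass(frozen=True)
class MutationRecord:
    """Predicted effect of one single-base transversion.

    ``delta_score`` is score(mutant) - score(wild type) in bits and is NaN
    for ablated mutants (no score is defined without a core match);
    ``predicted_class`` is ``ablated`` iff ``core_intact`` is False.
    """

    position: int
    wt_base: str
    mut_base: str
    region: str
    core_intact: bool
    delta_score: float
    predicted_class: str


def enumerate_transversions(
    window: str, positions: Optional[Iterable[int]] = None
) -> list[tuple[int, str]]:
    """One mutant window per selected position, applying the fixed
    transversion map; ordered by position.  N at a selected position is an
    error (no transversion partner exists)."""
    if positions is None:
        positions = range(len(window))
    out = []
    for pos in sorted(positions):
        base = window[pos]
        if base not in TRANSVERSION:
            raise ValueError(f"position {pos}: cannot transvert {base!r}")
        out.append((pos, window[:pos] + TRANSVERSION[base] + window[pos + 1:]))
    return out


def _best_match(window: str, spec: MotifSpec,
                profile: PositionProfile) -> tuple[Optional[ElementMatch], float]:
    matches = scan_bipartite(window, spec)
    if not matches:
        return None, float("nan")
    scored = [(score_window(profile, m), m) for m in matches]
    score, match = max(scored, key=lambda t: t[0])
    return match, score


def _region_of(position: int, match: ElementMatch, spec: MotifSpec) -> str:
    if match.atract_start - spec.specificity_window <= position < match.atract_start:
        return "specificity"
    if match.atract_start <= position < match.atract_end:
        return "atract"
    if match.atract_end <= position < match.minus10_start:
        return "spacer"
    if match.minus10_start <= position < match.minus10_end:
        return "minus10"
    if match.minus10_end <= position < match.minus10_end + spec.downstream_window:
        return "downstream"
    return "flank"


def predict_effect(
    mutant_window: str,
    wt_window: str,
    profile: PositionProfile,
    spec: MotifSpec | None = None,
    neutral_band: float = 0.5,
) -> MutationRecord:
    """Classify one mutant window against its wild type.

    The mutant is re-scanned with ``spec``: if no bipartite core match
    survives the mutation the effect is ``ablated``.  Otherwise the change
    in best log-odds score decides: above +``neutral_band`` bits ->
    ``increased``, below -``neutral_band`` -> ``reduced``, else ``neutral``.
    """
    if spec is None:
        spec = MotifSpec()
    if len(mutant_window) != len(wt_window):
        raise ValueError("mutant and wild-type windows differ in length")
    diffs = [i for i, (a, b) in enumerate(zip(wt_window, mutant_window)) if a != b]
    if len(diffs) != 1:
        raise ValueError(f"expected exactly one substitution, found {len(diffs)}")
    pos = diffs[0]

    wt_match, wt_score = _best_match(wt_window, spec, profile)
    if wt_match is None:
        raise ValueError("wild-type window contains no bipartite promoter match")
    region = _region_of(pos, wt_match, spec)

    mut_match, mut_score = _best_match(mutant_window, spec, profile)
    core_intact = mut_match is not None
    if not core_intact:
        delta = float("nan")
        cls = "ablated"
    else:
        delta = mut_score - wt_score
        if delta > neutral_band:
            cls = "increased"
        elif delta < -neutral_band:
            cls = "reduced"
        else:
            cls = "neutral"
    return MutationRecord(
        position=pos,
        wt_base=wt_window[pos],
        mut_base=mutant_window[pos],
        region=region,
        core_intact=core_intact,
        delta_score=delta,
        predicted_class=cls,
    )


def mutagenesis_report(
    wt_window: str,
    profile: PositionProfile,
    spec: MotifSpec | None = None,
    neutral_band: float = 0.5,
) -> pd.DataFrame:
    """Saturation transversion table over every position of ``wt_window``.

    One row per position with the mutated base, the promoter region the
    position falls in (specificity / atract / spacer / minus10 / downstream
    / flank, relative to the wild-type match), the score change and the
    predicted effect class.
    """
    if spec is None:
        spec = MotifSpec()
    records = []
    for pos, mutant in enumerate_transversions(wt_window):
        rec = predict_effect(mutant, wt_window, profile, spec, neutral_band)
        records.append(rec)
    return pd.DataFrame(
        {
            "position": [r.position for r in records],
            "wt_base": [r.wt_base for r in records],
            "mut_base": [r.mut_base for r in records],
            "region": [r.region for r in records],
            "core_intact": [r.core_intact for r in records],
            "delta_score": [r.delta_score for r in records],
            "predicted_class": [r.predicted_class for r in records],
        }
    )
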