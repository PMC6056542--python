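"""Per-sigma promoter profiles: element-anchored stacking, base frequencies,
information content, consensus strings and log-odds scoring.

Curated sigma-I promoters are short and element-structured, so no gapped
alignment search is needed: records are stacked on two anchors, the 3' end
of the A-tract and the 5' start of the -10 core.  The variable spacer is
excluded from the columns; its length distribution is kept separately.
Columns a record does not reach (short specificity region, short A-tract)
hold a gap symbol that is ignored in the counts.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .motif import ElementMatch, MotifSpec, SET_TO_CODE, as_pattern

GAP = "-"
BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

UNIFORM = np.full(4, 0.25)


@dataclass(frozen=True)
class PromoterRecord:
    """One curated promoter, decomposed into its three motifs.

    ``minus10_seq`` holds the -10 core realization plus downstream context
    (including the AT-dyad position three nucleotides after the tetrad);
    ``utr5`` is the distance in nt from the promoter to the first codon.
    """

    label: str
    sigma_label: str
    specificity_seq: str
    atract_seq: str
    spacer_seq: str
    minus10_seq: str
    utr5: Optional[int] = None

    def __post_init__(self) -> None:
        if len(self.atract_seq) < 3 or set(self.atract_seq) != {"A"}:
            raise ValueError(f"{self.label}: A-tract must be all A, length >= 3")
        if len(self.minus10_seq) < 4:
            raise ValueError(f"{self.label}: minus10_seq shorter than the tetrad")


@dataclass
class PromoterSet:
    sigma_label: str
    records: list[PromoterRecord]

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("empty promoter set")
        for rec in self.records:
            if rec.sigma_label != self.sigma_label:
                raise ValueError(
                    f"record {rec.label} labelled {rec.sigma_label}, set is {self.sigma_label}"
                )

    def __len__(self) -> int:
        return len(self.records)


_FIXTURE_COLUMNS = [
    "sigma_label",
    "gene_label",
    "specificity_seq",
    "atract_seq",
    "spacer_seq",
    "minus10_seq",
    "utr5",
]


def read_promoter_table(path: str | os.PathLike) -> dict[str, PromoterSet]:
    """Read a promoter fixture TSV into per-sigma :class:`PromoterSet` objects."""
    df = pd.read_csv(path, sep="\t", comment="#", keep_default_na=False, dtype=str)
    missing = set(_FIXTURE_COLUMNS[:6]) - set(df.columns)
    if missing:
        raise ValueError(f"promoter table missing columns: {sorted(missing)}")
    sets: dict[str, list[PromoterRecord]] = {}
    for row in df.itertuples():
        rec = PromoterRecord(
            label=row.gene_label,
            sigma_label=row.sigma_label,
            specificity_seq=row.specificity_seq,
            atract_seq=row.atract_seq,
            spacer_seq=row.spacer_seq,
            minus10_seq=row.minus10_seq,
            utr5=int(row.utr5) if getattr(row, "utr5", "") != "" else None,
        )
        sets.setdefault(rec.sigma_label, []).append(rec)
    return {label: PromoterSet(label, recs) for label, recs in sets.items()}


def write_promoter_table(sets: Iterable[PromoterSet], path: str | os.PathLike,
                         header_comment: str = "") -> None:
    rows = []
    for pset in sets:
        for rec in pset.records:
            rows.append(
                {
                    "sigma_label": rec.sigma_label,
                    "gene_label": rec.label,
                    "specificity_seq": rec.specificity_seq,
                    "atract_seq": rec.atract_seq,
                    "spacer_seq": rec.spacer_seq,
                    "minus10_seq": rec.minus10_seq,
                    "utr5": "" if rec.utr5 is None else rec.utr5,
                }
            )
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        pd.DataFrame(rows, columns=_FIXTURE_COLUMNS).to_csv(fh, sep="\t", index=False)


@dataclass
class PromoterStack:
    """Fixed-width aligned rows over the three anchored blocks."""

    rows: list[str]
    anchor_map: tuple[str, ...]  # per-column region: specificity | atract | minus10
    sigma_label: str = ""
    spacer_lengths: list[int] = field(default_factory=list)

    @property
    def width(self) -> int:
        return len(self.anchor_map)


def _pad_left(s: str, width: int) -> str:
    return (GAP * (width - len(s)) + s)[-width:] if width else ""


def _pad_right(s: str, width: int) -> str:
    return (s + GAP * (width - len(s)))[:width] if width else ""


def stack_promoters(pset: PromoterSet, spec: MotifSpec | None = None) -> PromoterStack:
    """Dual-anchored stack of a promoter set.

    Specificity sequences are right-aligned (padded/truncated on the left) to
    ``spec.specificity_window`` columns; A-tracts are right-aligned so their
    3' ends coincide; -10 sequences are left-aligned on the core start into
    ``len(minus10_core) + downstream_window`` columns.
    """
    if spec is None:
        spec = MotifSpec()
    w_spec = spec.specificity_window
    w_atract = max(len(r.atract_seq) for r in pset.records)
    w_m10 = len(as_pattern(spec.minus10_core)) + spec.downstream_window
    rows = [
        _pad_left(r.specificity_seq, w_spec)
        + _pad_left(r.atract_seq, w_atract)
        + _pad_right(r.minus10_seq, w_m10)
        for r in pset.records
    ]
    anchor_map = ("specificity",) * w_spec + ("atract",) * w_atract + ("minus10",) * w_m10
    return PromoterStack(
        rows=rows,
        anchor_map=anchor_map,
        sigma_label=pset.sigma_label,
        spacer_lengths=[len(r.spacer_seq) for r in pset.records],
    )


@dataclass
class PositionProfile:
    """Per-column base frequencies with information content and log-odds scoring.

    ``matrix`` is (width, 4) over A,C,G,T; every row sums to 1.  ``support``
    counts the non-gap records behind each column; zero-support columns hold
    the background exactly (log-odds contribution 0).  The spacer length
    distribution is stored separately from the columns.
    """

    sigma_label: str
    matrix: np.ndarray
    anchor_map: tuple[str, ...]
    background: np.ndarray
    pseudocount: float
    support: np.ndarray
    n_records: int = 0
    spacer_dist: dict[int, float] = field(default_factory=dict)
    small_sample_correction: bool = False

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.shape != (len(self.anchor_map), 4):
            raise ValueError("matrix shape does not match anchor map")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("profile columns must sum to 1")

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    def block_widths(self) -> dict[str, int]:
        w: dict[str, int] = {}
        for region in self.anchor_map:
            w[region] = w.get(region, 0) + 1
        return w

    def information_content(self) -> np.ndarray:
        """Per-column relative entropy vs background, in bits.

        Under a uniform background this is 2 + sum_b f log2 f, bounded by
        [0, 2] bits.
        """
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = self.matrix * np.log2(self.matrix / self.background[None, :])
        terms = np.where(self.matrix > 0, terms, 0.0)
        ic = terms.sum(axis=1)
        if self.small_sample_correction:
            with np.errstate(divide="ignore"):
                e_n = np.where(self.support > 0, 3.0 / (2.0 * np.log(2) * np.maximum(self.support, 1)), 0.0)
            ic = ic - e_n
        return np.maximum(ic, 0.0)

    def to_text(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            fh.write(f"# sigma_label={self.sigma_label}\n")
            fh.write(f"# pseudocount={self.pseudocount}\n")
            fh.write(f"# n_records={self.n_records}\n")
            fh.write("# background=" + ",".join(f"{x:.6g}" for x in self.background) + "\n")
            if self.spacer_dist:
                fh.write(
                    "# spacer_dist="
                    + ",".join(f"{k}:{v:.6g}" for k, v in sorted(self.spacer_dist.items()))
                    + "\n"
                )
            fh.write("pos\tregion\tsupport\tA\tC\tG\tT\n")
            for j in range(self.width):
                fh.write(
                    f"{j}\t{self.anchor_map[j]}\t{int(self.support[j])}\t"
                    + "\t".join(f"{x:.10g}" for x in self.matrix[j])
                    + "\n"
                )

    @classmethod
    def from_text(cls, path: str | os.PathLike) -> "PositionProfile":
        meta: dict[str, str] = {}
        rows = []
        regions = []
        support = []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("#"):
                    key, _, val = line[1:].strip().partition("=")
                    meta[key.strip()] = val
                elif line and not line.startswith("pos\t"):
                    parts = line.split("\t")
                    regions.append(parts[1])
                    support.append(int(parts[2]))
                    rows.append([float(x) for x in parts[3:7]])
        spacer_dist = {}
        if meta.get("spacer_dist"):
            for item in meta["spacer_dist"].split(","):
                k, v = item.split(":")
                spacer_dist[int(k)] = float(v)
        return cls(
            sigma_label=meta.get("sigma_label", ""),
            matrix=np.array(rows),
            anchor_map=tuple(regions),
            background=np.array([float(x) for x in meta["background"].split(",")]),
            pseudocount=float(meta.get("pseudocount", 0)),
            support=np.array(support),
            n_records=int(meta.get("n_records", 0)),
            spacer_dist=spacer_dist,
        )


def build_profile(
    stack: PromoterStack,
    pseudocount: float = 0.5,
    background: Optional[Sequence[float]] = None,
    small_sample_correction: bool = False,
) -> PositionProfile:
    """Column frequencies f(b,j) = (count + pc) / (n_eff + 4 pc), gap-aware.

    ``n_eff`` is the number of non-gap characters in column j, so short
    records do not dilute columns they never reach.  With
    ``small_sample_correction`` the logo-style small-sample term
    e_n = 3/(2 ln2 n_eff) is subtracted from each column's information
    content (frequencies are untouched); it is off by default because the
    curated sets are tiny and the correction would hide real conservation.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    if not stack.rows:
        raise ValueError("empty stack")
    bg = UNIFORM.copy() if background is None else np.asarray(background, dtype=float)
    if bg.shape != (4,) or abs(bg.sum() - 1.0) > 1e-6 or (bg <= 0).any():
        raise ValueError("background must be 4 positive frequencies summing to 1")

    width = stack.width
    counts = np.zeros((width, 4))
    for row in stack.rows:
        for j, ch in enumerate(row):
            idx = _BASE_INDEX.get(ch)
            if idx is not None:
                counts[j, idx] += 1
    support = counts.sum(axis=1)
    matrix = np.empty_like(counts)
    for j in range(width):
        if support[j] == 0 and pseudocount == 0:
            matrix[j] = bg
        else:
            matrix[j] = (counts[j] + pseudocount) / (support[j] + 4 * pseudocount)

    n = len(stack.rows)
    spacer_dist: dict[int, float] = {}
    for L in stack.spacer_lengths:
        spacer_dist[L] = spacer_dist.get(L, 0.0) + 1.0 / len(stack.spacer_lengths)

    return PositionProfile(
        sigma_label=stack.sigma_label,
        matrix=matrix,
        anchor_map=stack.anchor_map,
        background=bg,
        pseudocount=pseudocount,
        support=support,
        n_records=n,
        spacer_dist=spacer_dist,
        small_sample_correction=small_sample_correction,
    )


def consensus_string(profile: PositionProfile, majority_threshold: float = 0.75) -> str:
    """Per-column consensus with IUPAC fallback.

    A column contributes its majority base when that base's frequency reaches
    the threshold; otherwise the minimal IUPAC code covering all bases with
    frequency above 1/4; otherwise N.
    """
    if not (0.25 < majority_threshold <= 1.0):
        raise ValueError("majority_threshold must be in (0.25, 1]")
    out = []
    for j in range(profile.width):
        col = profile.matrix[j]
        best = int(np.argmax(col))
        if col[best] >= majority_threshold:
            out.append(BASES[best])
            continue
        above = frozenset(BASES[i] for i in range(4) if col[i] > 0.25)
        out.append(SET_TO_CODE.get(above, "N") if above else "N")
    return "".join(out)


def assemble_window(profile: PositionProfile, specificity_seq: str, atract_seq: str,
                    minus10_context: str) -> str:
    """Lay candidate elements onto the profile's columns (same dual anchoring
    as :func:`stack_promoters`); positions the candidate does not cover are
    gaps and score 0."""
    w = profile.block_widths()
    return (
        _pad_left(specificity_seq, w.get("specificity", 0))
        + _pad_left(atract_seq, w.get("atract", 0))
        + _pad_right(minus10_context, w.get("minus10", 0))
    )


def score_window(profile: PositionProfile, candidate: ElementMatch) -> float:
    """Log-odds score (bits) of a scanned candidate against the profile.

    Sum over counted columns of log2(f(b_j, j) / background(b_j)); columns
    where the candidate has no base (edge truncation, N) contribute 0.  The
    score depends only on the element sequences, never on genomic
    coordinates or strand.
    """
    row = assemble_window(
        profile,
        candidate.specificity_seq,
        candidate.atract_seq,
        candidate.minus10_seq + candidate.downstream_seq,
    )
    score = 0.0
    for j, ch in enumerate(row):
        idx = _BASE_INDEX.get(ch)
        if idx is None:
            continue
        f = max(profile.matrix[j, idx], 1e-12)
        score += math.log2(f / profile.background[idx])
    return score
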