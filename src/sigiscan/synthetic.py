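"""Synthetic clostridial-like genomes with planted bipartite promoters.

The generator emulates the statistical structure the analysis assumes: an
i.i.d. background at configurable GC (default 0.38, clostridial-like),
planted promoters with the three-motif anatomy (region of specificity,
homopolymeric A-tract, 12-15 nt spacer, -10 core with downstream context),
and one downstream gene per plant at a sampled 5'-UTR distance.

Each sigma class is described by a small parametric generator: a concrete
specificity triad, an optional (possibly IUPAC-degenerate) gap between
triad and A-tract, a -10 tetrad and a downstream context carrying the
conserved dyad.  Core positions (triad, A-tract, tetrad, dyad) are fully
conserved — sigma-I promoters are highly stringent — while degenerate
positions are realized uniformly over their IUPAC expansion.  The truth
table records the realized elements exactly; spacers are rejection-sampled
so no accidental in-plant promoter arises, and truth-based tests therefore
match on coordinates, never on total counts (background hits elsewhere are
expected and untouched).

Every operation is seeded; an identical spec yields byte-identical genome,
annotation and truth outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .genome_io import GeneAnnotation, Genome, revcomp
from .motif import MotifSpec, scan_bipartite
from .profile import PositionProfile, PromoterRecord, PromoterSet, UNIFORM
from .regulon import SpecificityRule

BASES = "ACGT"


def _gc_frequencies(gc: float) -> np.ndarray:
    """Base frequencies (A,C,G,T order) for an i.i.d. background at given GC."""
    if not (0.0 < gc < 1.0):
        raise ValueError("gc_content must be in (0, 1)")
    at = (1.0 - gc) / 2.0
    return np.array([at, gc / 2.0, gc / 2.0, at])


def make_background(length: int, gc: float = 0.38, seed: int | np.random.Generator = 0,
                    contig_id: str = "synth1") -> Genome:
    """i.i.d. background contig with P(G)=P(C)=gc/2, P(A)=P(T)=(1-gc)/2."""
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    bases = rng.choice(list(BASES), size=length, p=_gc_frequencies(gc))
    return Genome({contig_id: "".join(bases)})


@dataclass(frozen=True)
class SigmaGenerator:
    """Parametric promoter model for one sigma class.

    ``triad`` and ``tetrad`` are concrete, fully conserved core sequences
    (sigma-I promoters are highly stringent).  ``gap`` sits between the
    triad's 3' end and the A-tract (its length is the triad offset of the
    matching specificity rule) and may use IUPAC symbols: each degenerate
    position is realized uniformly over its expansion, so the default
    sigma-I3 gap "YY" covers both pyrimidine gaps seen in real promoters
    (CT in rgl11A-style promoters, TC in the cipA/cel48S-style universal
    promoter).  ``downstream`` is the context after the -10 core, IUPAC
    likewise, with the conserved AT dyad three nucleotides after the tetrad
    written as concrete symbols.  ``atract_lengths`` maps A-tract length to
    probability.
    """

    sigma_label: str
    triad: str = "CCC"
    gap: str = ""
    tetrad: str = "CGAA"
    downstream: str = "TGTATT"
    atract_lengths: tuple[tuple[int, float], ...] = ((4, 0.5), (5, 0.3), (6, 0.2))

    def __post_init__(self) -> None:
        from .motif import IUPAC_CODES

        if len(self.triad) != 3 or set(self.triad) - set(BASES):
            raise ValueError("triad must be 3 concrete bases")
        if set(self.tetrad) - set(BASES):
            raise ValueError("tetrad must be concrete bases")
        for name, s in (("gap", self.gap), ("downstream", self.downstream)):
            bad = set(s) - set(IUPAC_CODES)
            if bad:
                raise ValueError(f"{name} has invalid symbols: {sorted(bad)}")
        if self.gap and "A" in IUPAC_CODES[self.gap[-1]]:
            raise ValueError("last gap symbol must exclude A (would merge with the A-tract)")
        if abs(sum(p for _, p in self.atract_lengths) - 1.0) > 1e-9:
            raise ValueError("atract_lengths probabilities must sum to 1")
        if min(L for L, _ in self.atract_lengths) < 3:
            raise ValueError("A-tract lengths must be >= 3")

    @property
    def offset(self) -> int:
        return len(self.gap)

    def rule(self) -> SpecificityRule:
        return SpecificityRule(
            sigma_label=self.sigma_label,
            triad=self.triad,
            offset_min=0,
            offset_max=self.offset,
            minus10_tetrad=self.tetrad,
        )

    # -- sampling -----------------------------------------------------------

    @staticmethod
    def _realize(iupac: str, rng: np.random.Generator) -> str:
        from .motif import IUPAC_CODES

        out = []
        for sym in iupac:
            exp = sorted(IUPAC_CODES[sym])
            out.append(exp[0] if len(exp) == 1 else str(rng.choice(exp)))
        return "".join(out)

    def sample_elements(self, rng: np.random.Generator) -> tuple[str, str, str]:
        """(specificity_seq, tetrad, downstream context) — degenerate
        positions realized uniformly over their IUPAC expansion."""
        return (
            self.triad + self._realize(self.gap, rng),
            self.tetrad,
            self._realize(self.downstream, rng),
        )

    def sample_atract_length(self, rng: np.random.Generator) -> int:
        lengths = [L for L, _ in self.atract_lengths]
        probs = [p for _, p in self.atract_lengths]
        return int(rng.choice(lengths, p=probs))

    def to_profile(self, spec: MotifSpec | None = None,
                   background: Optional[Sequence[float]] = None) -> PositionProfile:
        """The generating distribution laid out on the profile's dual-anchored
        columns: one-hot for concrete symbols, uniform over the expansion for
        degenerate ones.  Structural columns no record reaches hold the
        background."""
        from .motif import IUPAC_CODES

        if spec is None:
            spec = MotifSpec()
        bg = UNIFORM.copy() if background is None else np.asarray(background, dtype=float)
        cols: list[np.ndarray] = []
        regions: list[str] = []
        support: list[int] = []

        def symbol_col(sym: str) -> np.ndarray:
            exp = IUPAC_CODES[sym]
            v = np.zeros(4)
            for b in exp:
                v[BASES.index(b)] = 1.0 / len(exp)
            return v

        w_spec = spec.specificity_window
        spec_cons = self.triad + self.gap
        for _ in range(w_spec - len(spec_cons)):
            cols.append(bg.copy()); regions.append("specificity"); support.append(0)
        for sym in spec_cons[max(0, len(spec_cons) - w_spec):]:
            cols.append(symbol_col(sym)); regions.append("specificity"); support.append(1)

        w_atract = max(L for L, _ in self.atract_lengths)
        for _ in range(w_atract):
            cols.append(symbol_col("A")); regions.append("atract"); support.append(1)

        w_m10 = len(spec.minus10_core) + spec.downstream_window
        m10_cons = self.tetrad + self.downstream
        for i in range(w_m10):
            if i >= len(m10_cons):
                cols.append(bg.copy()); regions.append("minus10"); support.append(0)
            else:
                cols.append(symbol_col(m10_cons[i])); regions.append("minus10"); support.append(1)

        return PositionProfile(
            sigma_label=self.sigma_label,
            matrix=np.vstack(cols),
            anchor_map=tuple(regions),
            background=bg,
            pseudocount=0.0,
            support=np.array(support),
            n_records=0,
            spacer_dist={},
        )


#: Default five-sigma panel.  Triads for sigma-I1 (CTC, immediately upstream
#: of the A-tract) and sigma-I3 (CCC, two nucleotides upstream) follow the
#: characterized preferences; the remaining triads are plausible divergent
#: choices.  The sigma-I3 "YY" gap means sigma-I3-style promoters whose gap
#: realizes as TC also satisfy the sigma-I1 CTC rule — the universal-promoter
#: cross-talk — which default-panel analyses must expect.
DEFAULT_GENERATORS: dict[str, SigmaGenerator] = {
    "sigI1": SigmaGenerator("sigI1", triad="CTC", gap=""),
    "sigI2": SigmaGenerator("sigI2", triad="TGC", gap=""),
    "sigI3": SigmaGenerator("sigI3", triad="CCC", gap="YY"),
    "sigI4": SigmaGenerator("sigI4", triad="GGT", gap=""),
    "sigI6": SigmaGenerator("sigI6", triad="GTT", gap=""),
}


def _default_plants() -> dict[str, int]:
    return {label: 10 for label in DEFAULT_GENERATORS}


@dataclass
class SyntheticSpec:
    """Study conditions for one synthetic benchmark genome."""

    seed: int
    genome_length: int = 100_000
    gc_content: float = 0.38
    per_sigma_plants: dict[str, int] = field(default_factory=_default_plants)
    generators: dict[str, SigmaGenerator] = field(
        default_factory=lambda: dict(DEFAULT_GENERATORS)
    )
    motif: MotifSpec = field(default_factory=MotifSpec)
    utr5_range: tuple[int, int] = (30, 300)
    gene_length: int = 300
    n_decoy_genes: int = 10
    contig_id: str = "synth1"

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if any(n < 0 for n in self.per_sigma_plants.values()):
            raise ValueError("plant counts must be >= 0")
        missing = set(self.per_sigma_plants) - set(self.generators)
        if missing:
            raise ValueError(f"no generator for sigma labels: {sorted(missing)}")


TRUTH_COLUMNS = [
    "contig", "strand", "sigma_label", "locus_tag",
    "promoter_start", "promoter_end",
    "atract_start", "atract_end", "spacer_len",
    "minus10_start", "minus10_end",
    "specificity_seq", "utr5", "gene_start", "gene_end",
]


def _sample_spacer(rng: np.random.Generator, length: int, freqs: np.ndarray) -> str:
    return "".join(rng.choice(list(BASES), size=length, p=freqs))


def _build_plant(gen: SigmaGenerator, sspec: SyntheticSpec,
                 rng: np.random.Generator) -> dict:
    """Assemble one plant; rejection-sample the spacer until a self-scan of
    the plant yields exactly the intended match (this forbids accidental
    in-plant promoters and A-tract extension into spacer or gap)."""
    motif = sspec.motif
    freqs = _gc_frequencies(sspec.gc_content)
    spec_seq, tetrad, downstream = gen.sample_elements(rng)
    atract_len = gen.sample_atract_length(rng)
    for _ in range(200):
        spacer_len = int(rng.integers(motif.spacer_min, motif.spacer_max + 1))
        spacer = _sample_spacer(rng, spacer_len, freqs)
        plant = spec_seq + "A" * atract_len + spacer + tetrad + downstream
        matches = scan_bipartite(plant, motif)
        a_start = len(spec_seq)
        m10_start = a_start + atract_len + spacer_len
        if (
            len(matches) == 1
            and matches[0].atract_start == a_start
            and matches[0].atract_end == a_start + atract_len
            and matches[0].minus10_start == m10_start
        ):
            return {
                "seq": plant,
                "spec_seq": spec_seq,
                "atract_len": atract_len,
                "spacer_len": spacer_len,
                "tetrad": tetrad,
                "downstream": downstream,
            }
    raise RuntimeError(
        f"could not realize a clean plant for {gen.sigma_label}; check that the "
        "generator's elements are compatible with the motif spec"
    )


def plant_promoters(genome: Genome, sspec: SyntheticSpec,
                    rng: Optional[np.random.Generator] = None
                    ) -> tuple[Genome, pd.DataFrame]:
    """Insert the requested promoters (plus their gene layout) into the first
    contig of ``genome`` and return the modified genome with the truth table.

    Each plant reserves a non-overlapping zone covering promoter, sampled
    5'-UTR and gene footprint, so that in ``upstream_only`` prediction every
    promoter's nearest downstream same-strand gene is its own gene.
    """
    if rng is None:
        rng = np.random.default_rng(sspec.seed + 1)
    contig_id = genome.contig_ids[0]
    seq = list(genome[contig_id])
    L = len(seq)
    motif = sspec.motif

    plants = []
    for label in sorted(sspec.per_sigma_plants):
        gen = sspec.generators[label]
        for _ in range(sspec.per_sigma_plants[label]):
            built = _build_plant(gen, sspec, rng)
            utr5 = int(rng.integers(sspec.utr5_range[0], sspec.utr5_range[1] + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            zone_len = len(built["seq"]) + utr5 + sspec.gene_length
            plants.append(
                {"sigma_label": label, "strand": strand, "utr5": utr5,
                 "zone_len": zone_len, **built}
            )

    order = rng.permutation(len(plants))
    plants = [plants[i] for i in order]

    margin = 10
    total = sum(p["zone_len"] for p in plants)
    free = L - 2 * margin - total
    if free < 0:
        raise ValueError(
            f"genome too small for requested plants: need {total + 2 * margin}, have {L}"
        )
    gaps = rng.multinomial(free, np.full(len(plants) + 1, 1.0 / (len(plants) + 1)))

    rows = []
    pos = margin + int(gaps[0])
    for i, p in enumerate(plants):
        z_start, z_len = pos, p["zone_len"]
        plen = len(p["seq"])
        dw = len(p["downstream"])
        if p["strand"] == "+":
            p_start = z_start
            seq[p_start: p_start + plen] = list(p["seq"])

            def g(a: int, b: int) -> tuple[int, int]:
                return p_start + a, p_start + b
        else:
            p_start = z_start + z_len - plen
            seq[p_start: p_start + plen] = list(revcomp(p["seq"]))

            def g(a: int, b: int) -> tuple[int, int]:
                return p_start + plen - b, p_start + plen - a

        a_local = len(p["spec_seq"])
        a_s, a_e = g(a_local, a_local + p["atract_len"])
        m10_local = a_local + p["atract_len"] + p["spacer_len"]
        m10_s, m10_e = g(m10_local, m10_local + len(p["tetrad"]))
        if p["strand"] == "+":
            gene_start = m10_e + p["utr5"]
            gene_end = gene_start + sspec.gene_length
        else:
            gene_end = m10_s - p["utr5"]
            gene_start = gene_end - sspec.gene_length
        rows.append(
            {
                "contig": contig_id,
                "strand": p["strand"],
                "sigma_label": p["sigma_label"],
                "locus_tag": f"SYN{i:04d}",
                "promoter_start": min(a_s, m10_s),
                "promoter_end": max(a_e, m10_e),
                "atract_start": a_s,
                "atract_end": a_e,
                "spacer_len": p["spacer_len"],
                "minus10_start": m10_s,
                "minus10_end": m10_e,
                "specificity_seq": p["spec_seq"],
                "utr5": p["utr5"],
                "gene_start": gene_start,
                "gene_end": gene_end,
            }
        )
        pos += z_len + int(gaps[i + 1])

    truth = pd.DataFrame(rows, columns=TRUTH_COLUMNS)
    truth = truth.sort_values(["contig", "promoter_start"]).reset_index(drop=True)
    planted = Genome({**genome.contigs, contig_id: "".join(seq)})
    return planted, truth


def make_annotations(truth: pd.DataFrame, sspec: SyntheticSpec,
                     rng: Optional[np.random.Generator] = None
                     ) -> list[GeneAnnotation]:
    """One gene per truth row (at its recorded coordinates) plus optional
    decoy genes placed outside every planted zone."""
    if rng is None:
        rng = np.random.default_rng(sspec.seed + 2)
    anns = [
        GeneAnnotation(
            contig_id=row.contig,
            start=int(row.gene_start),
            end=int(row.gene_end),
            strand=row.strand,
            locus_tag=row.locus_tag,
            product=f"synthetic {row.sigma_label} target",
        )
        for row in truth.itertuples()
    ]
    if sspec.n_decoy_genes:
        zones = [
            (min(int(r.promoter_start), int(r.gene_start)),
             max(int(r.promoter_end), int(r.gene_end)))
            for r in truth.itertuples()
        ]
        L = sspec.genome_length
        placed = 0
        attempts = 0
        while placed < sspec.n_decoy_genes and attempts < 200 * sspec.n_decoy_genes:
            attempts += 1
            start = int(rng.integers(0, max(1, L - sspec.gene_length)))
            end = start + sspec.gene_length
            if any(start < ze and zs < end for zs, ze in zones):
                continue
            strand = "+" if rng.random() < 0.5 else "-"
            anns.append(
                GeneAnnotation(
                    contig_id=truth.contig.iloc[0] if len(truth) else sspec.contig_id,
                    start=start,
                    end=end,
                    strand=strand,
                    locus_tag=f"DEC{placed:04d}",
                    product="synthetic decoy",
                )
            )
            zones.append((start, end))
            placed += 1
    return anns


def sample_promoter_set(generator: SigmaGenerator, n: int,
                        seed: int | np.random.Generator,
                        spec: MotifSpec | None = None,
                        gc_content: float = 0.38,
                        utr5_range: tuple[int, int] = (30, 300)) -> PromoterSet:
    """Sample ``n`` promoter records column-independently from the generator
    (cores exact, variable positions at the generator's conservation)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if spec is None:
        spec = MotifSpec()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    freqs = _gc_frequencies(gc_content)
    records = []
    for i in range(n):
        spec_seq, tetrad, downstream = generator.sample_elements(rng)
        atract_len = generator.sample_atract_length(rng)
        spacer_len = int(rng.integers(spec.spacer_min, spec.spacer_max + 1))
        records.append(
            PromoterRecord(
                label=f"{generator.sigma_label}_s{i:03d}",
                sigma_label=generator.sigma_label,
                specificity_seq=spec_seq,
                atract_seq="A" * atract_len,
                spacer_seq=_sample_spacer(rng, spacer_len, freqs),
                minus10_seq=tetrad + downstream,
                utr5=int(rng.integers(utr5_range[0], utr5_range[1] + 1)),
            )
        )
    return PromoterSet(generator.sigma_label, records)


def simulate(sspec: SyntheticSpec) -> tuple[Genome, list[GeneAnnotation], pd.DataFrame]:
    """Background -> plant -> annotate, all derived from ``sspec.seed``."""
    background = make_background(
        sspec.genome_length, sspec.gc_content, sspec.seed, sspec.contig_id
    )
    genome, truth = plant_promoters(background, sspec)
    annotations = make_annotations(truth, sspec)
    return genome, annotations, truth
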