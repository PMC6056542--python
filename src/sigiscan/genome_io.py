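"""Genome, annotation and candidate I/O with strand-aware upstream extraction.

Coordinate conventions
----------------------
Internally every interval is 0-based, half-open ``[start, end)`` on the
forward strand of its contig.  GFF3 input/output uses the standard 1-based
inclusive convention and is converted at the boundary; BED output is 0-based
half-open.  Minus-strand sequences are always reported 5'->3' in the reading
orientation of the feature (i.e. reverse-complemented).
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

_VALID = set("ACGTN")
# IUPAC ambiguity codes other than N are degraded to N so that draft genomes
# with rare ambiguous calls remain scannable (N never matches a concrete
# pattern symbol, so this is conservative).
_AMBIGUOUS = set("RYSWKMBDHV")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an A/C/G/T/N string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class Genome:
    """Ordered collection of contig sequences (uppercase A/C/G/T/N)."""

    contigs: dict[str, str]

    def __post_init__(self) -> None:
        if not self.contigs:
            raise ValueError("genome has no contigs")
        for cid, seq in self.contigs.items():
            if not cid:
                raise ValueError("empty contig id")
            bad = set(seq) - _VALID
            if bad:
                raise ValueError(
                    f"contig {cid!r} contains non-nucleotide characters: {sorted(bad)}"
                )

    def __getitem__(self, contig_id: str) -> str:
        return self.contigs[contig_id]

    def __contains__(self, contig_id: str) -> bool:
        return contig_id in self.contigs

    @property
    def contig_ids(self) -> list[str]:
        return list(self.contigs)

    def reverse_complement(self) -> "Genome":
        return Genome({cid: revcomp(seq) for cid, seq in self.contigs.items()})


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene feature in internal 0-based half-open coordinates."""

    contig_id: str
    start: int
    end: int
    strand: str
    locus_tag: str
    product: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"{self.locus_tag}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.locus_tag}: strandless feature (strand={self.strand!r})")


@dataclass
class UpstreamRegion:
    """Sequence upstream of a gene, written 5'->3' in the gene's orientation.

    ``genomic_start``/``genomic_end`` delimit the forward-strand slice the
    region was taken from; :meth:`to_genomic` back-maps a local half-open
    interval to forward-strand genomic coordinates.
    """

    gene: GeneAnnotation
    sequence: str
    genomic_start: int
    genomic_end: int
    window_requested: int

    def __len__(self) -> int:
        return len(self.sequence)

    def to_genomic(self, start: int, end: int) -> tuple[int, int]:
        """Map local [start, end) to a forward-strand genomic interval."""
        if not (0 <= start <= end <= len(self.sequence)):
            raise ValueError(f"local interval [{start}, {end}) outside region")
        if self.gene.strand == "+":
            return self.genomic_start + start, self.genomic_start + end
        return self.genomic_end - end, self.genomic_end - start


def _clean_sequence(raw: str, record_id: str) -> str:
    seq = raw.upper()
    chars = set(seq)
    ambiguous = chars & _AMBIGUOUS
    if ambiguous:
        log.warning(
            "record %s: converting ambiguity codes %s to N",
            record_id,
            "".join(sorted(ambiguous)),
        )
        seq = seq.translate(str.maketrans({c: "N" for c in ambiguous}))
    bad = set(seq) - _VALID
    if bad:
        raise ValueError(
            f"record {record_id!r} contains non-nucleotide characters: {sorted(bad)}"
        )
    return seq


def read_fasta(path: str | os.PathLike) -> Genome:
    """Read a (multi-)FASTA file into a :class:`Genome`.

    Lowercase input is uppercased; IUPAC ambiguity codes other than N are
    degraded to N with a logged warning.  Duplicate headers, empty files and
    non-nucleotide characters raise ``ValueError``.
    """
    contigs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in contigs:
            raise ValueError(f"duplicate FASTA header: {rec.id!r}")
        contigs[rec.id] = _clean_sequence(str(rec.seq), rec.id)
    if not contigs:
        raise ValueError(f"no FASTA records found in {path}")
    return Genome(contigs)


def write_fasta(genome: Genome, path: str | os.PathLike, width: int = 70) -> None:
    """Write contigs in input order, wrapped at ``width`` columns."""
    records = [
        SeqRecord(Seq(seq), id=cid, description="") for cid, seq in genome.contigs.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


_TSV_ANNOTATION_COLUMNS = ["contig", "start", "end", "strand", "locus_tag", "product"]


def read_annotations(
    path: str | os.PathLike,
    dialect: str = "gff3",
    genome: Optional[Genome] = None,
) -> list[GeneAnnotation]:
    """Read gene annotations from GFF3 or a minimal TSV.

    GFF3 coordinates (1-based inclusive) are converted to the internal
    0-based half-open convention; ``gene`` features are used when present,
    otherwise ``CDS``.  The TSV dialect carries internal coordinates directly
    (columns contig, start, end, strand, locus_tag[, product]).  When a
    ``genome`` is supplied, features on unknown contigs are rejected.
    """
    if dialect == "gff3":
        anns = _read_gff3(path)
    elif dialect == "tsv":
        anns = _read_annotation_tsv(path)
    else:
        raise ValueError(f"unknown annotation dialect: {dialect!r}")

    seen: set[str] = set()
    for ann in anns:
        if ann.locus_tag in seen:
            raise ValueError(f"duplicate locus_tag: {ann.locus_tag!r}")
        seen.add(ann.locus_tag)
        if genome is not None:
            if ann.contig_id not in genome:
                raise ValueError(
                    f"{ann.locus_tag}: contig {ann.contig_id!r} absent from genome"
                )
            if ann.end > len(genome[ann.contig_id]):
                raise ValueError(f"{ann.locus_tag}: feature extends past contig end")
    return anns


def _read_gff3(path: str | os.PathLike) -> list[GeneAnnotation]:
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    featuretypes = set(db.featuretypes())
    ftype = "gene" if "gene" in featuretypes else "CDS"
    anns = []
    for feat in db.features_of_type(ftype, order_by=("seqid", "start")):
        tags = feat.attributes.get("locus_tag") or feat.attributes.get("ID")
        if not tags:
            raise ValueError(f"feature at {feat.seqid}:{feat.start} lacks locus_tag/ID")
        product = (feat.attributes.get("product") or [""])[0]
        if feat.strand not in ("+", "-"):
            raise ValueError(f"{tags[0]}: strandless feature (strand={feat.strand!r})")
        anns.append(
            GeneAnnotation(
                contig_id=feat.seqid,
                start=feat.start - 1,  # GFF3 1-based inclusive -> 0-based half-open
                end=feat.end,
                strand=feat.strand,
                locus_tag=tags[0],
                product=product,
            )
        )
    return anns


def _read_annotation_tsv(path: str | os.PathLike) -> list[GeneAnnotation]:
    df = pd.read_csv(path, sep="\t", dtype={"contig": str, "locus_tag": str})
    missing = set(_TSV_ANNOTATION_COLUMNS[:5]) - set(df.columns)
    if missing:
        raise ValueError(f"annotation TSV missing columns: {sorted(missing)}")
    if "product" not in df.columns:
        df["product"] = ""
    return [
        GeneAnnotation(
            contig_id=row.contig,
            start=int(row.start),
            end=int(row.end),
            strand=str(row.strand),
            locus_tag=row.locus_tag,
            product="" if pd.isna(row.product) else str(row.product),
        )
        for row in df.itertuples()
    ]


def write_annotations_gff3(
    annotations: Sequence[GeneAnnotation], path: str | os.PathLike
) -> None:
    """Write gene features as GFF3 (1-based inclusive), in input order."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for ann in annotations:
            attrs = f"ID={ann.locus_tag};locus_tag={ann.locus_tag}"
            if ann.product:
                attrs += f";product={ann.product}"
            fh.write(
                "\t".join(
                    [
                        ann.contig_id,
                        "sigiscan",
                        "gene",
                        str(ann.start + 1),
                        str(ann.end),
                        ".",
                        ann.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )


def extract_upstream(genome: Genome, gene: GeneAnnotation, window: int = 600) -> UpstreamRegion:
    """Extract up to ``window`` nt immediately upstream of a gene.

    For a plus-strand gene the region covers genomic ``[start-window, start)``
    read forward; for a minus-strand gene ``[end, end+window)``
    reverse-complemented.  The region is silently truncated at contig edges.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if gene.contig_id not in genome:
        raise ValueError(f"contig {gene.contig_id!r} absent from genome")
    contig = genome[gene.contig_id]
    if gene.end > len(contig):
        raise ValueError(f"{gene.locus_tag}: gene lies outside its contig")
    if gene.strand == "+":
        gstart = max(0, gene.start - window)
        gend = gene.start
        seq = contig[gstart:gend]
    else:
        gstart = gene.end
        gend = min(len(contig), gene.end + window)
        seq = revcomp(contig[gstart:gend])
    return UpstreamRegion(
        gene=gene,
        sequence=seq,
        genomic_start=gstart,
        genomic_end=gend,
        window_requested=window,
    )


# ---------------------------------------------------------------------------
# Candidate tables

_CANDIDATE_COLUMNS = [
    "contig",
    "strand",
    "promoter_start",
    "promoter_end",
    "atract_start",
    "atract_end",
    "spacer_len",
    "minus10_start",
    "minus10_end",
    "specificity_seq",
    "atract_seq",
    "minus10_seq",
    "downstream_seq",
    "assigned_gene",
    "utr5",
]


def write_candidates(candidates: Sequence, path: str | os.PathLike, fmt: str = "tsv") -> None:
    """Write promoter candidates as TSV (full fields) or BED6 (core footprint).

    The BED name column encodes the assigned gene (or a running index) and,
    when present on the candidate, the assigned sigma labels.
    """
    if fmt == "tsv":
        rows = []
        for cand in candidates:
            m = cand.match
            rows.append(
                {
                    "contig": m.sequence_id,
                    "strand": m.strand,
                    "promoter_start": m.promoter_start,
                    "promoter_end": m.promoter_end,
                    "atract_start": m.atract_start,
                    "atract_end": m.atract_end,
                    "spacer_len": m.spacer_len,
                    "minus10_start": m.minus10_start,
                    "minus10_end": m.minus10_end,
                    "specificity_seq": m.specificity_seq,
                    "atract_seq": m.atract_seq,
                    "minus10_seq": m.minus10_seq,
                    "downstream_seq": m.downstream_seq,
                    "assigned_gene": cand.assigned_gene if cand.assigned_gene else "",
                    "utr5": "" if cand.utr5 is None else cand.utr5,
                }
            )
        df = pd.DataFrame(rows, columns=_CANDIDATE_COLUMNS)
        df.to_csv(path, sep="\t", index=False)
    elif fmt == "bed":
        with open(path, "w") as fh:
            for i, cand in enumerate(candidates):
                m = cand.match
                name = cand.assigned_gene or f"cand{i}"
                sigmas = getattr(cand, "sigma_labels", None)
                if sigmas:
                    name += "|" + ",".join(sorted(sigmas))
                fh.write(
                    "\t".join(
                        [
                            m.sequence_id,
                            str(m.promoter_start),
                            str(m.promoter_end),
                            name,
                            "0",
                            m.strand,
                        ]
                    )
                    + "\n"
                )
    else:
        raise ValueError(f"unknown candidate format: {fmt!r}")


def read_candidates(path: str | os.PathLike) -> list:
    """Read a candidate TSV written by :func:`write_candidates` (exact round-trip)."""
    from .motif import ElementMatch
    from .regulon import PromoterCandidate

    df = pd.read_csv(path, sep="\t", keep_default_na=False, dtype=str)
    out = []
    for row in df.itertuples():
        match = ElementMatch(
            sequence_id=row.contig,
            strand=row.strand,
            atract_start=int(row.atract_start),
            atract_end=int(row.atract_end),
            spacer_len=int(row.spacer_len),
            minus10_start=int(row.minus10_start),
            minus10_end=int(row.minus10_end),
            specificity_seq=row.specificity_seq,
            atract_seq=row.atract_seq,
            minus10_seq=row.minus10_seq,
            downstream_seq=row.downstream_seq,
        )
        out.append(
            PromoterCandidate(
                match=match,
                assigned_gene=row.assigned_gene or None,
                utr5=int(row.utr5) if row.utr5 != "" else None,
            )
        )
    return out
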