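"""Gene annotation parsing, region classification and tract localization.

One splice variant is kept per gene (longest CDS by default).  Genomic
positions are classified into mutually exclusive region classes with the
precedence exonic > utr5 > utr3 > intron > upstream > intergenic, and repeat
tracts are assigned the class with the largest nucleotide overlap (ties go
to the higher-precedence class).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import gffutils
from intervaltree import IntervalTree

from .scanner import RepeatTract

log = logging.getLogger(__name__)

EXONIC = "exonic"
UTR5 = "utr5"
UTR3 = "utr3"
INTRON = "intron"
UPSTREAM = "upstream"
INTERGENIC = "intergenic"

#: genic classes first, in tie-breaking precedence order
PRECEDENCE = (EXONIC, UTR5, UTR3, INTRON, UPSTREAM, INTERGENIC)
_GENIC = {EXONIC, UTR5, UTR3, INTRON}


class AnnotationError(ValueError):
    """Malformed annotation input."""


@dataclass
class GeneModel:
    """One splice variant of a gene.

    Interval lists are 0-based half-open genomic coordinates.  ``exons`` are
    sorted in ascending genomic order; ``cds_segments``, ``utr5`` and
    ``utr3`` are kept in transcription (5'->3') order, so for minus-strand
    genes they run from high to low coordinates.
    """

    gene_id: str
    sequence_id: str
    strand: str
    exons: list[tuple[int, int]]
    cds_segments: list[tuple[int, int]]
    utr5: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)
    protein_id: str | None = None
    transcript_id: str | None = None

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds_segments)

    @property
    def start(self) -> int:
        return min(s for s, _ in self.exons)

    @property
    def end(self) -> int:
        return max(e for _, e in self.exons)

    def upstream_window(self, length: int) -> tuple[int, int]:
        """Window abutting the transcription start on the strand-correct side."""
        if self.strand == "+":
            return (max(0, self.start - length), self.start)
        return (self.end, self.end + length)

    def introns(self) -> list[tuple[int, int]]:
        ex = sorted(self.exons)
        return [(ex[i][1], ex[i + 1][0]) for i in range(len(ex) - 1)]


def load_annotation(
    gff3_path,
    variant_rule: str = "longest_cds",
    sequence_blacklist: Iterable[str] | None = None,
) -> list[GeneModel]:
    """Load gene models from GFF3, one splice variant per gene.

    ``variant_rule`` is "longest_cds" (default) or "first_listed".  Genes
    without CDS, or whose CDS length is not divisible by 3, are dropped with
    a warning.  Genes on blacklisted sequences (e.g. organellar or unplaced
    contigs) are excluded.
    """
    if variant_rule not in ("longest_cds", "first_listed"):
        raise AnnotationError(f"unknown variant_rule: {variant_rule!r}")
    blacklist = set(sequence_blacklist or ())
    db = gffutils.create_db(
        str(gff3_path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    models: list[GeneModel] = []
    for gene in db.features_of_type("gene", order_by=("seqid", "start")):
        if gene.seqid in blacklist:
            continue
        variants = []
        for mrna in db.children(gene, featuretype="mRNA", order_by="start"):
            cds = [(f.start - 1, f.end) for f in db.children(mrna, featuretype="CDS")]
            if not cds:
                continue
            exons = [(f.start - 1, f.end) for f in db.children(mrna, featuretype="exon")]
            u5 = [(f.start - 1, f.end) for f in db.children(mrna, featuretype="five_prime_UTR")]
            u3 = [(f.start - 1, f.end) for f in db.children(mrna, featuretype="three_prime_UTR")]
            variants.append((mrna, exons or cds, cds, u5, u3))
        if not variants:
            log.warning("gene %s has no CDS-bearing transcript; dropped", gene.id)
            continue
        if variant_rule == "longest_cds":
            chosen = max(variants, key=lambda v: sum(e - s for s, e in v[2]))
        else:
            chosen = variants[0]
        mrna, exons, cds, u5, u3 = chosen
        if sum(e - s for s, e in cds) % 3 != 0:
            log.warning("gene %s: CDS length not divisible by 3; dropped", gene.id)
            continue
        strand = gene.strand if gene.strand in "+-" else "+"
        rev = strand == "-"
        models.append(
            GeneModel(
                gene_id=gene.id,
                sequence_id=gene.seqid,
                strand=strand,
                exons=sorted(exons),
                cds_segments=sorted(cds, reverse=rev),
                utr5=sorted(u5, reverse=rev),
                utr3=sorted(u3, reverse=rev),
                protein_id=(mrna.attributes.get("protein_id") or [None])[0],
                transcript_id=mrna.id,
            )
        )
    return models


class RegionIndex:
    """Interval index over gene models for position/tract classification."""

    def __init__(self, models: Sequence[GeneModel], upstream: int = 1000,
                 known_sequences: Iterable[str] | None = None):
        self.upstream = upstream
        self.models = list(models)
        self.known = set(known_sequences) if known_sequences is not None else {
            m.sequence_id for m in models
        }
        self._trees: dict[tuple[str, str], IntervalTree] = {}
        for m in models:
            self._add(m.sequence_id, EXONIC, m.cds_segments, m)
            self._add(m.sequence_id, UTR5, m.utr5, m)
            self._add(m.sequence_id, UTR3, m.utr3, m)
            self._add(m.sequence_id, INTRON, m.introns(), m)
            self._add(m.sequence_id, UPSTREAM, [m.upstream_window(upstream)], m)

    def _add(self, seq_id: str, cls: str, intervals, model: GeneModel) -> None:
        tree = self._trees.setdefault((seq_id, cls), IntervalTree())
        for s, e in intervals:
            if e > s:
                tree[s:e] = model

    def classify(self, sequence_id: str, position: int) -> tuple[str, GeneModel | None]:
        """(region class, owning gene model) for one position."""
        if sequence_id not in self.known:
            raise AnnotationError(f"unknown sequence_id: {sequence_id!r}")
        for cls in PRECEDENCE[:-1]:
            tree = self._trees.get((sequence_id, cls))
            if tree:
                hits = tree[position]
                if hits:
                    model = min(hits, key=lambda iv: iv.data.gene_id).data
                    return cls, model
        return INTERGENIC, None


def classify_position(
    models: Sequence[GeneModel] | RegionIndex, sequence_id: str, position: int,
    upstream: int = 1000,
) -> str:
    """Mutually exclusive region class of a genomic position.

    Overlapping features resolve by precedence: exonic > utr5 > utr3 >
    intron > upstream > intergenic.
    """
    index = models if isinstance(models, RegionIndex) else RegionIndex(models, upstream)
    return index.classify(sequence_id, position)[0]


def localize_tracts(
    tracts: Iterable[RepeatTract],
    models: Sequence[GeneModel] | RegionIndex,
    upstream: int = 1000,
    known_sequences: Iterable[str] | None = None,
) -> list[RepeatTract]:
    """Assign each tract the region class with maximal nucleotide overlap.

    Positions are classified individually (so classes stay mutually
    exclusive), the majority class wins, and ties break by precedence.
    Tracts in genic classes are linked to the owning gene/protein.
    """
    index = (
        models
        if isinstance(models, RegionIndex)
        else RegionIndex(models, upstream, known_sequences)
    )
    out: list[RepeatTract] = []
    for t in tracts:
        votes: Counter[str] = Counter()
        genes: Counter[tuple[str, str]] = Counter()
        for pos in range(t.start, t.end):
            cls, model = index.classify(t.sequence_id, pos)
            votes[cls] += 1
            if model is not None and cls in _GENIC:
                genes[(cls, model.gene_id)] += 1
        best = max(votes, key=lambda c: (votes[c], -PRECEDENCE.index(c)))
        t.region_class = best
        if best in _GENIC:
            gene_id = max(
                (g for g in genes if g[0] == best), key=lambda g: genes[g]
            )[1]
            t.gene_id = gene_id
            model = next(m for m in index.models if m.gene_id == gene_id)
            t.protein_id = model.protein_id
        else:
            t.gene_id = None
            t.protein_id = None
        out.append(t)
    return out
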