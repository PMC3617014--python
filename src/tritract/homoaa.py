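"""Homo-amino-acid tract detection, encoding classification and reverse mapping.

A homo-AA tract is a maximal run of a single residue of at least
``min_run_length`` residues (default 7).  Each tract is classified from the
codons of its coding sequence: it is repeat-encoded ("tnr") when at least
``min_same_codon_run`` consecutive residues of the tract are encoded by one
identical codon, and variant-encoded otherwise.  Tract residue spans are
reverse-mapped through the spliced CDS onto genomic intervals, strand-aware.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import groupby
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio.Seq import Seq

from .annotation import GeneModel

log = logging.getLogger(__name__)

#: residues that never form runs (ambiguity codes, rare residues, stops)
_RUN_BREAKERS = set("XBZJUO*")

TNR = "tnr"
VARIANT = "variant"


class HomoAAError(ValueError):
    """Invalid input to the homo-AA mapper."""


@dataclass(frozen=True)
class HomoAAParams:
    min_run_length: int = 7
    min_same_codon_run: int = 7

    def __post_init__(self) -> None:
        if self.min_run_length < 2 or self.min_same_codon_run < 2:
            raise HomoAAError("run thresholds must be >= 2")
        if self.min_same_codon_run > self.min_run_length:
            raise HomoAAError("min_same_codon_run cannot exceed min_run_length")


@dataclass
class HomoAATract:
    """One homo-AA run (0-based half-open residue coordinates)."""

    protein_id: str
    residue: str
    start: int
    end: int
    encoding_class: str | None = None
    max_same_codon_run: int | None = None
    genomic_loci: list[tuple[int, int]] = field(default_factory=list)
    sequence_id: str | None = None
    strand: str | None = None
    gene_id: str | None = None

    @property
    def length(self) -> int:
        return self.end - self.start


def find_homoaa_runs(
    protein_seq: str, params: HomoAAParams | None = None
) -> list[tuple[str, int, int]]:
    """All maximal single-residue runs of length >= min_run_length.

    Returns (residue, start, end) triples; ambiguity codes break runs and
    never form runs themselves.
    """
    params = params or HomoAAParams()
    runs: list[tuple[str, int, int]] = []
    pos = 0
    for res, grp in groupby(protein_seq):
        n = sum(1 for _ in grp)
        if n >= params.min_run_length and res not in _RUN_BREAKERS:
            runs.append((res, pos, pos + n))
        pos += n
    return runs


def classify_encoding(
    tract: HomoAATract | tuple[str, int, int],
    cds_codons: Sequence[str],
    params: HomoAAParams | None = None,
) -> tuple[str, int]:
    """(encoding class, longest identical-codon run) for one tract.

    ``cds_codons`` is the full codon list aligned 1:1 with the protein.
    Codons inside the tract must translate to the tract residue; the
    identical-codon run is counted strictly within the tract span.
    """
    params = params or HomoAAParams()
    if isinstance(tract, HomoAATract):
        res, start, end = tract.residue, tract.start, tract.end
    else:
        res, start, end = tract
    if end > len(cds_codons):
        raise HomoAAError("tract extends past the coding sequence")
    codons = [c.upper() for c in cds_codons[start:end]]
    for c in codons:
        if str(Seq(c).translate()) != res:
            raise HomoAAError(f"codon {c} does not encode tract residue {res}")
    max_run = max(sum(1 for _ in grp) for _, grp in groupby(codons))
    cls = TNR if max_run >= params.min_same_codon_run else VARIANT
    return cls, max_run


def map_tract_to_genome(
    tract: HomoAATract | tuple[str, int, int], gene_model: GeneModel
) -> list[tuple[int, int]]:
    """Genomic intervals (forward-strand, ascending) covering a tract's codons.

    The residue span maps to a CDS nucleotide span (x3), which is walked
    through the spliced CDS segments; intervals split at intron boundaries
    and their lengths always sum to 3x the tract length.
    """
    if isinstance(tract, HomoAATract):
        start, end = tract.start, tract.end
    else:
        _, start, end = tract
    nt_start, nt_end = 3 * start, 3 * end
    if nt_end > gene_model.cds_length:
        raise HomoAAError("tract extends past the CDS length")
    loci: list[tuple[int, int]] = []
    offset = 0
    for s, e in gene_model.cds_segments:  # transcription order
        seg_len = e - s
        lo = max(nt_start, offset)
        hi = min(nt_end, offset + seg_len)
        if hi > lo:
            if gene_model.strand == "+":
                loci.append((s + (lo - offset), s + (hi - offset)))
            else:
                loci.append((e - (hi - offset), e - (lo - offset)))
        offset += seg_len
    return sorted(loci)


def extract_tract_dna(
    genome_seq: str, loci: Sequence[tuple[int, int]], strand: str
) -> str:
    """Strand-corrected concatenated DNA of a tract's genomic intervals."""
    forward = "".join(genome_seq[s:e] for s, e in sorted(loci))
    if strand == "-":
        return str(Seq(forward).reverse_complement())
    return forward


def split_codons(cds: str) -> list[str]:
    if len(cds) % 3 != 0:
        raise HomoAAError("CDS length not divisible by 3")
    return [cds[i : i + 3] for i in range(0, len(cds), 3)]


def scan_proteins(
    proteins: Mapping[str, str],
    cds_by_protein: Mapping[str, str],
    params: HomoAAParams | None = None,
    gene_models: Mapping[str, GeneModel] | None = None,
) -> list[HomoAATract]:
    """Find and classify homo-AA tracts across a proteome.

    ``cds_by_protein`` maps protein id -> coding DNA (with or without the
    stop codon).  Proteins whose CDS does not translate to the recorded
    protein sequence are dropped with a warning.  When ``gene_models`` maps
    protein ids to gene models, tracts are also reverse-mapped to genomic
    loci.
    """
    params = params or HomoAAParams()
    tracts: list[HomoAATract] = []
    for pid in sorted(proteins):
        pseq = proteins[pid].upper().rstrip("*")
        cds = cds_by_protein.get(pid)
        if cds is None:
            log.warning("protein %s has no coding sequence; dropped", pid)
            continue
        cds = cds.upper()
        codons = split_codons(cds)
        # strip a trailing stop codon if present
        if codons and str(Seq(codons[-1]).translate()) == "*":
            codons = codons[:-1]
        translated = str(Seq("".join(codons)).translate())
        if translated != pseq:
            log.warning("protein %s: CDS does not translate to protein; dropped", pid)
            continue
        model = gene_models.get(pid) if gene_models else None
        for res, s, e in find_homoaa_runs(pseq, params):
            t = HomoAATract(protein_id=pid, residue=res, start=s, end=e)
            t.encoding_class, t.max_same_codon_run = classify_encoding(
                (res, s, e), codons, params
            )
            if model is not None:
                t.genomic_loci = map_tract_to_genome((res, s, e), model)
                t.sequence_id = model.sequence_id
                t.strand = model.strand
                t.gene_id = model.gene_id
            tracts.append(t)
    return tracts


def build_protein_sets(
    tracts: Iterable[HomoAATract],
) -> tuple[set[str], set[str], set[str]]:
    """(repeat-encoded set, variant-encoded set, all homo-AA proteins).

    A protein joins a per-class set when at least one of its tracts is of
    that class, so the two sets may overlap; their union is the full set of
    homo-AA tract-containing proteins.
    """
    tnr_set: set[str] = set()
    var_set: set[str] = set()
    for t in tracts:
        if t.encoding_class == TNR:
            tnr_set.add(t.protein_id)
        elif t.encoding_class == VARIANT:
            var_set.add(t.protein_id)
    return tnr_set, var_set, tnr_set | var_set


def _format_loci(t: HomoAATract) -> str:
    if not t.genomic_loci:
        return ""
    chrom = t.sequence_id or "?"
    strand = t.strand or "+"
    return ";".join(f"{chrom}:{s}-{e}:{strand}" for s, e in t.genomic_loci)


def tracts_to_frame(tracts: Iterable[HomoAATract]) -> pd.DataFrame:
    rows = [
        (
            t.protein_id, t.residue, t.start, t.end, t.length,
            t.encoding_class, t.max_same_codon_run, _format_loci(t), t.gene_id,
        )
        for t in tracts
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "protein_id", "residue", "start", "end", "length",
            "encoding_class", "max_same_codon_run", "genomic_loci", "gene_id",
        ],
    )


def write_tracts_tsv(tracts: Iterable[HomoAATract], path) -> None:
    tracts_to_frame(tracts).to_csv(path, sep="\t", index=False)


def read_tracts_tsv(path) -> list[HomoAATract]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    out: list[HomoAATract] = []
    for row in df.itertuples(index=False):
        loci = []
        seq_id = strand = None
        if row.genomic_loci:
            for piece in str(row.genomic_loci).split(";"):
                chrom, span, strand = piece.rsplit(":", 2)
                s, e = span.split("-")
                seq_id = chrom
                loci.append((int(s), int(e)))
        out.append(
            HomoAATract(
                protein_id=str(row.protein_id),
                residue=row.residue,
                start=int(row.start),
                end=int(row.end),
                encoding_class=row.encoding_class or None,
                max_same_codon_run=int(row.max_same_codon_run),
                genomic_loci=loci,
                sequence_id=seq_id,
                strand=strand,
                gene_id=str(row.gene_id) if row.gene_id else None,
            )
        )
    return out
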