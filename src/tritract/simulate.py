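"""Synthetic genomes, proteomes and annotation with planted ground truth.

Everything the pipeline consumes can be generated here with known truth:
an order-2 Markov genomic background with planted tandem repeat tracts of
chosen unit, copy number and mismatch count; spliced, stranded gene models
whose proteins carry planted homo-AA runs with controlled repeat-codon vs
variant-codon encoding and class-specific length distributions; an ontology
DAG with one term planted at a chosen enrichment odds in repeat-carrying
genes; a protein-interaction pair list; and a per-base conservation track
over coding sequence.

Planted features never overlap and planted DNA tracts keep >= 50 nt of
clearance plus phase-breaking 1-nt flanks, so a scan of the emitted genome
recovers each planted tract at its exact boundaries.  The seed fully
determines every emitted byte.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml
from Bio import SeqIO
from Bio.Data.CodonTable import unambiguous_dna_by_id
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}
_TABLE = unambiguous_dna_by_id[1]
CODONS_FOR: dict[str, list[str]] = {}
for codon, aa in sorted(_TABLE.forward_table.items()):
    CODONS_FOR.setdefault(aa, []).append(codon)
STOP_CODONS = sorted(_TABLE.stop_codons)
_AMINO_ACIDS = sorted(CODONS_FOR)
_SINGLE_CODON = {aa for aa, cs in CODONS_FOR.items() if len(cs) == 1}

REGION_CLASSES = ("intergenic", "intron", "upstream", "utr5", "utr3", "exonic")


class ConfigError(ValueError):
    """Invalid simulation configuration."""


class SizingError(ConfigError):
    """Planted footprint does not fit in the requested genome length."""


@dataclass(frozen=True)
class PlantedTNR:
    unit: str
    copies: int
    mismatches: int = 0
    region_class: str = "intergenic"

    def __post_init__(self) -> None:
        if len(self.unit) != 3 or any(b not in _BASES for b in self.unit):
            raise ConfigError(f"planted unit must be a 3-mer over ACGT: {self.unit!r}")
        if self.copies < 2:
            raise ConfigError("planted tracts need at least 2 copies")
        if self.region_class not in REGION_CLASSES:
            raise ConfigError(f"unknown region class: {self.region_class!r}")
        if self.mismatches < 0 or self.mismatches > max(0, (self.length - 8) // 8):
            raise ConfigError("too many mismatches for tract length")
        if self.region_class == "exonic" and self.mismatches:
            raise ConfigError("exonic planted tracts must be mismatch-free")

    @property
    def length(self) -> int:
        return 3 * self.copies


@dataclass(frozen=True)
class ResidueRunSpec:
    """Planted homo-AA runs for one residue.

    ``theta`` is the probability a planted run is repeat-encoded; run
    lengths are 7-shifted geometric with the class-specific mean (>= 7).
    """

    theta: float
    mean_tnr_length: float = 12.0
    mean_variant_length: float = 10.0
    n_runs: int = 8

    def __post_init__(self) -> None:
        if not 0.0 <= self.theta <= 1.0:
            raise ConfigError("theta must be in [0, 1]")
        if self.mean_tnr_length < 7 or self.mean_variant_length < 7:
            raise ConfigError("mean run lengths must be >= 7 residues")
        if self.n_runs < 0:
            raise ConfigError("n_runs must be >= 0")


@dataclass(frozen=True)
class OntologySpec:
    n_terms: int = 60
    dag_depth: int = 4
    enrichment_odds: float = 5.0
    base_prob: float = 0.15
    annotation_prob: float = 0.12
    planted_term: str | None = None

    def __post_init__(self) -> None:
        if self.dag_depth < 1:
            raise ConfigError("dag_depth must be >= 1")
        if self.n_terms < self.dag_depth + 1:
            raise ConfigError("need at least one term per depth plus the root")
        if not 0 < self.base_prob < 1:
            raise ConfigError("base_prob must be in (0, 1)")
        if self.enrichment_odds <= 0:
            raise ConfigError("enrichment_odds must be positive")


@dataclass(frozen=True)
class PPISpec:
    mean_degree: float = 3.0

    def __post_init__(self) -> None:
        if self.mean_degree < 0:
            raise ConfigError("mean_degree must be >= 0")


@dataclass(frozen=True)
class ConservationSpec:
    baseline: float = 0.6
    sd: float = 0.15

    def __post_init__(self) -> None:
        if not 0 <= self.baseline <= 1 or self.sd < 0:
            raise ConfigError("baseline in [0,1] and sd >= 0 required")


def _default_planted_tnrs() -> list[PlantedTNR]:
    return [
        PlantedTNR("CAG", 20, 0, "intergenic"),
        PlantedTNR("CTG", 15, 0, "intergenic"),
        PlantedTNR("AAG", 12, 0, "intergenic"),
        PlantedTNR("CCG", 10, 0, "intergenic"),
        PlantedTNR("CAG", 30, 2, "intergenic"),
        PlantedTNR("ATC", 9, 0, "intergenic"),
        PlantedTNR("CAG", 25, 0, "intron"),
        PlantedTNR("CAA", 12, 1, "intron"),
        PlantedTNR("CTG", 13, 0, "upstream"),
        PlantedTNR("AAT", 11, 0, "utr3"),
    ]


def _default_homoaa_spec() -> dict[str, ResidueRunSpec]:
    # Mirrors the qualitative cross-species picture: glutamine runs are
    # disproportionately repeat-encoded and longer when repeat-encoded;
    # proline runs lean towards variant encoding.
    return {
        "Q": ResidueRunSpec(theta=0.55, mean_tnr_length=13.0, mean_variant_length=9.5, n_runs=12),
        "N": ResidueRunSpec(theta=0.30, mean_tnr_length=10.0, mean_variant_length=9.5, n_runs=6),
        "E": ResidueRunSpec(theta=0.30, mean_tnr_length=10.0, mean_variant_length=9.5, n_runs=6),
        "A": ResidueRunSpec(theta=0.20, mean_tnr_length=9.5, mean_variant_length=9.5, n_runs=6),
        "S": ResidueRunSpec(theta=0.15, mean_tnr_length=9.5, mean_variant_length=9.5, n_runs=6),
        "P": ResidueRunSpec(theta=0.10, mean_tnr_length=9.5, mean_variant_length=10.5, n_runs=6),
    }


@dataclass
class SimulationConfig:
    seed: int = 0
    genome_length: int | None = None  # None: auto-size to the layout
    markov_spec: object = "uniform"  # "uniform" | (4,4,4) ndarray | {dinuc: probs}
    planted_tnrs: list[PlantedTNR] = field(default_factory=_default_planted_tnrs)
    n_genes: int = 40
    homoaa_spec: dict[str, ResidueRunSpec] = field(default_factory=_default_homoaa_spec)
    ontology_spec: OntologySpec = field(default_factory=OntologySpec)
    ppi_spec: PPISpec = field(default_factory=PPISpec)
    conservation_spec: ConservationSpec = field(default_factory=ConservationSpec)
    upstream_window: int = 1000
    chrom_name: str = "chrS1"

    def __post_init__(self) -> None:
        for res, spec in self.homoaa_spec.items():
            if res not in CODONS_FOR:
                raise ConfigError(f"unknown residue: {res!r}")
            if res in _SINGLE_CODON and spec.theta < 1.0 and spec.n_runs > 0:
                raise ConfigError(
                    f"residue {res} has a single codon; variant encoding is impossible"
                )
        total_runs = sum(s.n_runs for s in self.homoaa_spec.values())
        n_exonic = sum(1 for t in self.planted_tnrs if t.region_class == "exonic")
        if total_runs + n_exonic > 2 * self.n_genes:
            raise ConfigError("too many planted runs for n_genes (max two per gene)")

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs: dict = {}
        for key in ("seed", "genome_length", "markov_spec", "n_genes",
                    "upstream_window", "chrom_name"):
            if key in raw:
                kwargs[key] = raw[key]
        if "planted_tnrs" in raw:
            kwargs["planted_tnrs"] = [PlantedTNR(**d) for d in raw["planted_tnrs"]]
        if "homoaa_spec" in raw:
            kwargs["homoaa_spec"] = {
                res: ResidueRunSpec(**d) for res, d in raw["homoaa_spec"].items()
            }
        for key, klass in (("ontology_spec", OntologySpec), ("ppi_spec", PPISpec),
                           ("conservation_spec", ConservationSpec)):
            if key in raw:
                kwargs[key] = klass(**raw[key])
        return cls(**kwargs)


@dataclass
class PlantedTNRRecord:
    tract_id: str
    sequence_id: str
    start: int
    end: int
    unit: str
    copies: int
    mismatches: int
    region_class: str
    gene_id: str | None = None


@dataclass
class PlantedRunRecord:
    protein_id: str
    gene_id: str
    residue: str
    start: int
    end: int
    length: int
    encoding_class: str


@dataclass
class TruthTable:
    tnr_records: list[PlantedTNRRecord]
    homoaa_records: list[PlantedRunRecord]
    planted_term: str
    enrichment_odds: float
    repeat_gene_ids: set[str]


@dataclass
class SimGene:
    index: int
    gene_id: str
    transcript_id: str
    protein_id: str
    sequence_id: str
    strand: str
    start: int  # genomic span of the transcript
    end: int
    exons: list[tuple[int, int]]  # ascending genomic
    cds_segments: list[tuple[int, int]]  # transcription order
    utr5: list[tuple[int, int]]
    utr3: list[tuple[int, int]]
    introns_genomic: list[tuple[int, int]]
    protein_seq: str
    cds_seq: str  # includes the stop codon
    codons: list[str]  # protein codons, stop excluded


@dataclass
class OntologyBundle:
    term_ids: list[str]
    names: dict[str, str]
    edges: list[tuple[str, str, str]]  # (child, parent, relation)
    root: str
    planted_term: str
    associations: list[tuple[str, str]]


@dataclass
class Simulation:
    config: SimulationConfig
    genome: str
    genes: list[SimGene]
    truth: TruthTable
    ontology: OntologyBundle
    ppi_pairs: list[tuple[str, str]]
    conservation: list[tuple[str, int, int, np.ndarray]]

    # -- emission ---------------------------------------------------------

    def write_genome(self, path) -> None:
        rec = SeqRecord(Seq(self.genome), id=self.config.chrom_name, description="")
        with open(path, "w") as fh:
            SeqIO.write([rec], fh, "fasta")

    def write_annotation(self, path) -> None:
        lines = ["##gff-version 3"]
        for g in self.genes:
            attrs = f"ID={g.gene_id}"
            lines.append(_gff_line(g.sequence_id, "gene", g.start, g.end, g.strand, ".", attrs))
            lines.append(
                _gff_line(g.sequence_id, "mRNA", g.start, g.end, g.strand, ".",
                          f"ID={g.transcript_id};Parent={g.gene_id};protein_id={g.protein_id}")
            )
            for i, (s, e) in enumerate(sorted(g.exons), 1):
                lines.append(
                    _gff_line(g.sequence_id, "exon", s, e, g.strand, ".",
                              f"ID={g.transcript_id}.exon{i};Parent={g.transcript_id}")
                )
            cum = 0
            for i, (s, e) in enumerate(g.cds_segments, 1):
                phase = (3 - cum % 3) % 3
                lines.append(
                    _gff_line(g.sequence_id, "CDS", s, e, g.strand, str(phase),
                              f"ID={g.transcript_id}.cds{i};Parent={g.transcript_id}")
                )
                cum += e - s
            for i, (s, e) in enumerate(g.utr5, 1):
                lines.append(
                    _gff_line(g.sequence_id, "five_prime_UTR", s, e, g.strand, ".",
                              f"ID={g.transcript_id}.utr5.{i};Parent={g.transcript_id}")
                )
            for i, (s, e) in enumerate(g.utr3, 1):
                lines.append(
                    _gff_line(g.sequence_id, "three_prime_UTR", s, e, g.strand, ".",
                              f"ID={g.transcript_id}.utr3.{i};Parent={g.transcript_id}")
                )
        Path(path).write_text("\n".join(lines) + "\n")

    def write_cds(self, path) -> None:
        recs = [
            SeqRecord(Seq(g.cds_seq), id=g.protein_id, description="")
            for g in self.genes
        ]
        with open(path, "w") as fh:
            SeqIO.write(recs, fh, "fasta")

    def write_proteins(self, path) -> None:
        recs = [
            SeqRecord(Seq(g.protein_seq), id=g.protein_id, description="")
            for g in self.genes
        ]
        with open(path, "w") as fh:
            SeqIO.write(recs, fh, "fasta")

    def write_protein_map(self, path) -> None:
        lines = ["protein_id\tgene_id\ttranscript_id"]
        for g in self.genes:
            lines.append(f"{g.protein_id}\t{g.gene_id}\t{g.transcript_id}")
        Path(path).write_text("\n".join(lines) + "\n")

    def write_truth(self, tnr_path, homoaa_path, meta_path=None) -> None:
        lines = ["tract_id\tsequence_id\tstart\tend\tunit\tcopies\tmismatches\tregion_class\tgene_id"]
        for r in self.truth.tnr_records:
            lines.append(
                f"{r.tract_id}\t{r.sequence_id}\t{r.start}\t{r.end}\t{r.unit}\t"
                f"{r.copies}\t{r.mismatches}\t{r.region_class}\t{r.gene_id or ''}"
            )
        Path(tnr_path).write_text("\n".join(lines) + "\n")
        lines = ["protein_id\tgene_id\tresidue\tstart\tend\tlength\tencoding_class"]
        for h in self.truth.homoaa_records:
            lines.append(
                f"{h.protein_id}\t{h.gene_id}\t{h.residue}\t{h.start}\t{h.end}\t"
                f"{h.length}\t{h.encoding_class}"
            )
        Path(homoaa_path).write_text("\n".join(lines) + "\n")
        if meta_path is not None:
            meta = {
                "planted_term": self.truth.planted_term,
                "enrichment_odds": self.truth.enrichment_odds,
                "repeat_gene_ids": sorted(self.truth.repeat_gene_ids),
            }
            Path(meta_path).write_text(yaml.safe_dump(meta, sort_keys=True))

    def write_obo(self, path) -> None:
        write_obo(self.ontology, path)

    def write_associations(self, path) -> None:
        write_associations(self.ontology, path)

    def write_ppi(self, path) -> None:
        lines = ["protein_a\tprotein_b"]
        for a, b in self.ppi_pairs:
            lines.append(f"{a}\t{b}")
        Path(path).write_text("\n".join(lines) + "\n")

    def write_conservation(self, path) -> None:
        with open(path, "w") as fh:
            for chrom, s, e, scores in self.conservation:
                for i, sc in enumerate(scores):
                    fh.write(f"{chrom}\t{s + i}\t{s + i + 1}\t{sc:.4f}\n")

    def write_all(self, outdir) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": outdir / "genome.fa",
            "annotation": outdir / "annotation.gff3",
            "cds": outdir / "cds.fa",
            "proteins": outdir / "proteins.fa",
            "protein_map": outdir / "protein_map.tsv",
            "truth_tnr": outdir / "truth_tnr.tsv",
            "truth_homoaa": outdir / "truth_homoaa.tsv",
            "truth_meta": outdir / "truth_meta.yaml",
            "obo": outdir / "ontology.obo",
            "associations": outdir / "associations.tsv",
            "ppi": outdir / "ppi.tsv",
            "conservation": outdir / "conservation.bedgraph",
        }
        self.write_genome(paths["genome"])
        self.write_annotation(paths["annotation"])
        self.write_cds(paths["cds"])
        self.write_proteins(paths["proteins"])
        self.write_protein_map(paths["protein_map"])
        self.write_truth(paths["truth_tnr"], paths["truth_homoaa"], paths["truth_meta"])
        self.write_obo(paths["obo"])
        self.write_associations(paths["associations"])
        self.write_ppi(paths["ppi"])
        self.write_conservation(paths["conservation"])
        return paths

    # -- convenience ------------------------------------------------------

    def proteins_by_id(self) -> dict[str, str]:
        return {g.protein_id: g.protein_seq for g in self.genes}

    def cds_by_protein(self) -> dict[str, str]:
        return {g.protein_id: g.cds_seq for g in self.genes}

    def planted_intervals(self) -> list[tuple[int, int]]:
        """Genomic intervals written over the background (genes + tracts)."""
        out = [(g.start, g.end) for g in self.genes]
        out += [(r.start - 3, r.end + 3) for r in self.truth.tnr_records]
        return sorted(out)


def _gff_line(seqid: str, ftype: str, s: int, e: int, strand: str, phase: str, attrs: str) -> str:
    return f"{seqid}\ttritract_sim\t{ftype}\t{s + 1}\t{e}\t.\t{strand}\t{phase}\t{attrs}"


# -- internal planning types ----------------------------------------------


@dataclass
class _PlannedRun:
    residue: str
    encoding_class: str  # "tnr" | "variant"
    length: int


@dataclass
class _GenePlan:
    index: int
    runs: list[_PlannedRun] = field(default_factory=list)
    exonic_tracts: list[PlantedTNR] = field(default_factory=list)
    intron_tracts: list[PlantedTNR] = field(default_factory=list)
    utr5_tracts: list[PlantedTNR] = field(default_factory=list)
    utr3_tracts: list[PlantedTNR] = field(default_factory=list)
    upstream_tracts: list[PlantedTNR] = field(default_factory=list)


def _shifted_geometric(rng: np.random.Generator, mean: float) -> int:
    """7-shifted geometric run length with the given mean (>= 7)."""
    if mean <= 7.0:
        return 7
    p = 1.0 / (mean - 6.0)
    return 6 + int(rng.geometric(p))


def _pick(rng: np.random.Generator, options: Sequence[str]) -> str:
    return options[int(rng.integers(len(options)))]


def simulate(config: SimulationConfig) -> Simulation:
    """Deterministically build a full synthetic dataset from a config."""
    ss = np.random.SeedSequence(config.seed)
    (layout_ss, background_ss, gene_ss, tnr_ss, onto_ss, ppi_ss, cons_ss) = ss.spawn(7)
    rng_layout = np.random.default_rng(layout_ss)
    rng_gene = np.random.default_rng(gene_ss)
    rng_tnr = np.random.default_rng(tnr_ss)

    plans = _assign_features(config, rng_layout)
    genes_data = [_build_gene_content(config, plan, rng_gene) for plan in plans]
    layout = _layout_genes(config, plans, genes_data, rng_layout)
    genome, tnr_records, genes = _assemble_genome(
        config, plans, genes_data, layout, background_ss, rng_tnr
    )

    homoaa_records = []
    for g, (plan, data) in zip(genes, zip(plans, genes_data)):
        for res, s, e, cls in data["runs"]:
            homoaa_records.append(
                PlantedRunRecord(g.protein_id, g.gene_id, res, s, e, e - s, cls)
            )
    repeat_genes = {
        h.gene_id for h in homoaa_records if h.encoding_class == "tnr"
    }
    gene_ids = [g.gene_id for g in genes]
    ontology = build_ontology_and_associations(
        config.ontology_spec, gene_ids, repeat_genes, np.random.default_rng(onto_ss)
    )
    truth = TruthTable(
        tnr_records=tnr_records,
        homoaa_records=homoaa_records,
        planted_term=ontology.planted_term,
        enrichment_odds=config.ontology_spec.enrichment_odds,
        repeat_gene_ids=repeat_genes,
    )
    ppi_pairs = build_ppi_pairs(
        config.ppi_spec, [g.protein_id for g in genes], np.random.default_rng(ppi_ss)
    )
    conservation = _build_conservation(
        config.conservation_spec, config.chrom_name, genes,
        np.random.default_rng(cons_ss),
    )
    return Simulation(
        config=config,
        genome=genome,
        genes=genes,
        truth=truth,
        ontology=ontology,
        ppi_pairs=ppi_pairs,
        conservation=conservation,
    )


def _assign_features(config: SimulationConfig, rng: np.random.Generator) -> list[_GenePlan]:
    plans = [_GenePlan(i) for i in range(config.n_genes)]
    runs: list[_PlannedRun] = []
    for res in sorted(config.homoaa_spec):
        spec = config.homoaa_spec[res]
        for _ in range(spec.n_runs):
            is_tnr = rng.random() < spec.theta
            mean = spec.mean_tnr_length if is_tnr else spec.mean_variant_length
            runs.append(
                _PlannedRun(res, "tnr" if is_tnr else "variant", _shifted_geometric(rng, mean))
            )
    order = rng.permutation(len(runs))
    slots = [(i, j) for j in range(2) for i in range(config.n_genes)]
    for k, run_idx in enumerate(order):
        gene_idx, _ = slots[k]
        plans[gene_idx].runs.append(runs[int(run_idx)])
    genic = {
        "exonic": "exonic_tracts", "intron": "intron_tracts",
        "utr5": "utr5_tracts", "utr3": "utr3_tracts", "upstream": "upstream_tracts",
    }
    counters = {cls: 0 for cls in genic}
    for t in config.planted_tnrs:
        if t.region_class == "intergenic":
            continue
        if config.n_genes == 0:
            raise ConfigError("genic planted tracts require n_genes > 0")
        idx = counters[t.region_class] % config.n_genes
        counters[t.region_class] += 1
        getattr(plans[idx], genic[t.region_class]).append(t)
    return plans


def _build_gene_content(
    config: SimulationConfig, plan: _GenePlan, rng: np.random.Generator
) -> dict:
    """Protein and codon sequence for one gene, with planted run coordinates."""
    codons: list[str] = ["ATG"]
    protein: list[str] = ["M"]
    runs: list[tuple[str, int, int, str]] = []  # residue, start, end, class
    exonic_spans: list[tuple[PlantedTNR, int]] = []  # (tract, aa start)

    def add_filler(n: int, forbid: set[str]) -> None:
        for _ in range(n):
            avoid = forbid | {protein[-1]}
            choices = [a for a in _AMINO_ACIDS if a not in avoid]
            aa = _pick(rng, choices)
            protein.append(aa)
            codons.append(_pick(rng, CODONS_FOR[aa]))

    blocks: list[object] = list(plan.runs) + list(plan.exonic_tracts)
    add_filler(int(rng.integers(5, 11)), {b.residue for b in plan.runs})
    for block in blocks:
        if isinstance(block, _PlannedRun):
            res, length = block.residue, block.length
            if protein[-1] == res:  # keep planted runs exactly maximal
                add_filler(1, {res})
            start = len(protein)
            if block.encoding_class == "tnr":
                codon = _pick(rng, CODONS_FOR[res])
                codons.extend([codon] * length)
            else:
                opts = CODONS_FOR[res]
                for _ in range(length):
                    cand = _pick(rng, opts)
                    if len(codons) >= 6 and all(c == cand for c in codons[-6:]):
                        cand = _pick(rng, [c for c in opts if c != cand])
                    codons.append(cand)
            protein.extend([res] * length)
            runs.append((res, start, start + length, block.encoding_class))
            add_filler(int(rng.integers(5, 11)), {res})
        else:  # exonic planted DNA tract, codon-aligned
            aa = str(Seq(block.unit).translate())
            if aa == "*":
                raise ConfigError(f"exonic unit {block.unit} encodes a stop codon")
            if protein[-1] == aa:
                add_filler(1, {aa})
            start = len(protein)
            codons.extend([block.unit] * block.copies)
            protein.extend([aa] * block.copies)
            exonic_spans.append((block, start))
            if block.copies >= 7:
                runs.append((aa, start, start + block.copies, "tnr"))
            add_filler(int(rng.integers(5, 11)), {aa})
    add_filler(int(rng.integers(8, 20)), set())
    stop = _pick(rng, STOP_CODONS)
    return {
        "protein": "".join(protein),
        "codons": codons,
        "cds": "".join(codons) + stop,
        "runs": runs,
        "exonic_spans": exonic_spans,
    }


@dataclass
class _GeneLayout:
    gene_start: int
    strand: str
    utr5_len: int
    utr3_len: int
    intron_offsets: list[int]  # nt offsets into the CDS (tx order)
    intron_lengths: list[int]


def _layout_genes(
    config: SimulationConfig,
    plans: list[_GenePlan],
    genes_data: list[dict],
    rng: np.random.Generator,
) -> list[_GeneLayout]:
    layouts: list[_GeneLayout] = []
    cursor = 300
    u = config.upstream_window
    for plan, data in zip(plans, genes_data):
        cds_len = len(data["cds"])
        strand = "+" if rng.random() < 0.5 else "-"
        utr5_len = int(rng.integers(60, 140))
        utr3_len = int(rng.integers(60, 160))
        for t in plan.utr5_tracts:
            utr5_len = max(utr5_len, t.length + 56)
        for t in plan.utr3_tracts:
            utr3_len = max(utr3_len, t.length + 56)
        n_introns = max(1, len(plan.intron_tracts))
        if len(plan.intron_tracts) == 0 and rng.random() < 0.5:
            n_introns = 2
        intron_lengths = []
        for i in range(n_introns):
            base = int(rng.integers(80, 180))
            if i < len(plan.intron_tracts):
                base = plan.intron_tracts[i].length + 56 + int(rng.integers(0, 40))
            intron_lengths.append(base)
        forbidden: list[tuple[int, int]] = [
            (3 * s0, 3 * s0 + 3 * t.copies) for t, s0 in data["exonic_spans"]
        ]
        offsets = _choose_intron_offsets(rng, cds_len, n_introns, forbidden, data["runs"])
        gene_start = cursor + u + 100
        layouts.append(_GeneLayout(gene_start, strand, utr5_len, utr3_len, offsets, intron_lengths))
        total = utr5_len + cds_len + utr3_len + sum(intron_lengths)
        cursor = gene_start + total + u + 100
    return layouts


def _choose_intron_offsets(
    rng: np.random.Generator,
    cds_len: int,
    n_introns: int,
    forbidden: list[tuple[int, int]],
    runs: list[tuple[str, int, int, str]],
) -> list[int]:
    """Intron insertion offsets inside the CDS.

    Offsets avoid planted exonic DNA tracts (which must stay contiguous);
    when the gene carries planted homo-AA runs, the first intron is biased
    into a run so that some runs split across exons.
    """

    def ok(o: int, chosen: list[int]) -> bool:
        if not 6 <= o <= cds_len - 6:
            return False
        if any(fs - 3 <= o <= fe + 3 for fs, fe in forbidden):
            return False
        return all(abs(o - c) >= 12 for c in chosen)

    chosen: list[int] = []
    if runs and rng.random() < 0.6:
        res, s, e, _cls = runs[int(rng.integers(len(runs)))]
        lo, hi = 3 * s + 2, 3 * e - 2
        if hi > lo:
            for _ in range(20):
                o = int(rng.integers(lo, hi))
                if ok(o, chosen):
                    chosen.append(o)
                    break
    while len(chosen) < n_introns:
        for _ in range(200):
            o = int(rng.integers(6, max(7, cds_len - 5)))
            if ok(o, chosen):
                chosen.append(o)
                break
        else:
            raise ConfigError("could not place introns inside the CDS")
    return sorted(chosen[:n_introns])


def _sample_background(
    config: SimulationConfig, length: int, seed_seq: np.random.SeedSequence
) -> np.ndarray:
    rng = np.random.default_rng(seed_seq)
    spec = config.markov_spec
    if isinstance(spec, str) and spec == "uniform":
        return rng.integers(0, 4, size=length, dtype=np.int64)
    if isinstance(spec, Mapping):
        table = np.zeros((4, 4, 4))
        for dinuc, probs in spec.items():
            table[_BASE_INDEX[dinuc[0]], _BASE_INDEX[dinuc[1]], :] = probs
    else:
        table = np.asarray(spec, dtype=float)
    if table.shape != (4, 4, 4):
        raise ConfigError("markov_spec must be 'uniform', a 4x4x4 table, or a dinuc->probs map")
    sums = table.sum(axis=2)
    if np.any(sums <= 0):
        raise ConfigError("every dinucleotide context needs positive probability mass")
    cum = np.cumsum(table / sums[:, :, None], axis=2)
    out = np.empty(length, dtype=np.int64)
    out[0] = rng.integers(0, 4)
    if length > 1:
        out[1] = rng.integers(0, 4)
    us = rng.random(length)
    for i in range(2, length):
        out[i] = np.searchsorted(cum[out[i - 2], out[i - 1]], us[i], side="right")
    return np.minimum(out, 3)


def _assemble_genome(
    config: SimulationConfig,
    plans: list[_GenePlan],
    genes_data: list[dict],
    layouts: list[_GeneLayout],
    background_ss: np.random.SeedSequence,
    rng: np.random.Generator,
) -> tuple[str, list[PlantedTNRRecord], list[SimGene]]:
    chrom = config.chrom_name
    u = config.upstream_window

    # genomic structures per gene
    genes: list[SimGene] = []
    for plan, data, lay in zip(plans, genes_data, layouts):
        cds_len = len(data["cds"])
        tx_len = lay.utr5_len + cds_len + lay.utr3_len
        # pieces in transcription order: (kind, length)
        pieces: list[tuple[str, int]] = []
        prev = 0
        for off, ilen in zip(lay.intron_offsets, lay.intron_lengths):
            split = lay.utr5_len + off
            pieces.append(("exon", split - prev))
            pieces.append(("intron", ilen))
            prev = split
        pieces.append(("exon", tx_len - prev))
        total = sum(n for _, n in pieces)
        gs, ge = lay.gene_start, lay.gene_start + total

        # genomic intervals of pieces, in transcription order
        piece_iv: list[tuple[str, int, int]] = []
        if lay.strand == "+":
            pos = gs
            for kind, n in pieces:
                piece_iv.append((kind, pos, pos + n))
                pos += n
        else:
            pos = ge
            for kind, n in pieces:
                piece_iv.append((kind, pos - n, pos))
                pos -= n

        def tx_span_to_genomic(a: int, b: int) -> list[tuple[int, int]]:
            """Map a transcript-coordinate span to genomic intervals (tx order)."""
            out = []
            off = 0
            for kind, s, e in piece_iv:
                if kind == "intron":
                    continue
                n = e - s
                lo, hi = max(a, off), min(b, off + n)
                if hi > lo:
                    if lay.strand == "+":
                        out.append((s + lo - off, s + hi - off))
                    else:
                        out.append((e - (hi - off), e - (lo - off)))
                off += n
            return out

        cds_a = lay.utr5_len
        cds_b = lay.utr5_len + cds_len
        gene = SimGene(
            index=plan.index,
            gene_id=f"g{plan.index:04d}",
            transcript_id=f"t{plan.index:04d}",
            protein_id=f"p{plan.index:04d}",
            sequence_id=chrom,
            strand=lay.strand,
            start=gs,
            end=ge,
            exons=sorted((s, e) for k, s, e in piece_iv if k == "exon"),
            cds_segments=tx_span_to_genomic(cds_a, cds_b),
            utr5=tx_span_to_genomic(0, cds_a),
            utr3=tx_span_to_genomic(cds_b, tx_len),
            introns_genomic=sorted((s, e) for k, s, e in piece_iv if k == "intron"),
            protein_seq=data["protein"],
            cds_seq=data["cds"],
            codons=data["codons"],
        )
        genes.append(gene)

    # genome sizing
    last_end = max((g.end for g in genes), default=300) + u + 100
    intergenic = [t for t in config.planted_tnrs if t.region_class == "intergenic"]
    tail_needed = sum(t.length + 60 for t in intergenic) + 100
    required = last_end + tail_needed + 200
    if config.genome_length is None:
        glen = required
    else:
        if config.genome_length < required:
            raise SizingError(
                f"genome_length={config.genome_length} cannot hold the planted "
                f"footprint (need >= {required})"
            )
        glen = config.genome_length

    codes = _sample_background(config, glen, background_ss)
    arr = np.frombuffer(bytes(_BASES, "ascii"), dtype=np.uint8)[codes].copy()

    # write CDS bases over the background
    for g in genes:
        cds = g.cds_seq
        off = 0
        for s, e in g.cds_segments:
            n = e - s
            piece = cds[off : off + n]
            if g.strand == "-":
                piece = str(Seq(piece).reverse_complement())
            arr[s:e] = np.frombuffer(piece.encode(), dtype=np.uint8)
            off += n

    # plant DNA tracts
    records: list[PlantedTNRRecord] = []
    tid = 0

    def plant(t: PlantedTNR, pos: int, gene: SimGene | None) -> None:
        nonlocal tid
        seq = (t.unit * t.copies)
        seq_arr = bytearray(seq.encode())
        if t.mismatches:
            positions = _mismatch_positions(rng, t.length, t.mismatches)
            for mp in positions:
                orig = chr(seq_arr[mp])
                seq_arr[mp] = ord(_pick(rng, [b for b in _BASES if b != orig]))
        arr[pos : pos + t.length] = np.frombuffer(bytes(seq_arr), dtype=np.uint8)
        # repeat-breaking flanks: three bases absent from the unit on each
        # side, so no re-phased or indel-bridged extension can gain score
        absent = [b for b in _BASES if b not in t.unit] or ["A"]
        for k in range(1, 4):
            if pos - k >= 0:
                arr[pos - k] = ord(_pick(rng, absent))
            if pos + t.length + k - 1 < glen:
                arr[pos + t.length + k - 1] = ord(_pick(rng, absent))
        records.append(
            PlantedTNRRecord(
                tract_id=f"tnr{tid:04d}",
                sequence_id=chrom,
                start=pos,
                end=pos + t.length,
                unit=t.unit,
                copies=t.copies,
                mismatches=t.mismatches,
                region_class=t.region_class,
                gene_id=gene.gene_id if gene else None,
            )
        )
        tid += 1

    for g, plan in zip(genes, plans):
        for i, t in enumerate(plan.intron_tracts):
            # intron i in transcription order: genomically last-first on minus strand
            s, e = g.introns_genomic[i if g.strand == "+" else len(g.introns_genomic) - 1 - i]
            space = (e - s) - t.length
            pos = s + 25 + int(rng.integers(0, max(1, space - 50)))
            plant(t, pos, g)
        for t in plan.upstream_tracts:
            ws, we = (g.start - u, g.start) if g.strand == "+" else (g.end, g.end + u)
            pos = ws + 25 + int(rng.integers(0, max(1, (we - ws) - t.length - 50)))
            plant(t, pos, g)
        for t in plan.utr5_tracts:
            ivs = sorted(g.utr5)
            s, e = max(ivs, key=lambda iv: iv[1] - iv[0])
            pos = s + 25 + int(rng.integers(0, max(1, (e - s) - t.length - 50)))
            plant(t, pos, g)
        for t in plan.utr3_tracts:
            ivs = sorted(g.utr3)
            s, e = max(ivs, key=lambda iv: iv[1] - iv[0])
            pos = s + 25 + int(rng.integers(0, max(1, (e - s) - t.length - 50)))
            plant(t, pos, g)

    # exonic tracts are already embedded in the CDS; record their coordinates
    for g, plan, data in zip(genes, plans, genes_data):
        for t, aa_start in data["exonic_spans"]:
            nonl = _map_cds_span(g, 3 * aa_start, 3 * aa_start + t.length)
            assert len(nonl) == 1, "exonic planted tracts must stay contiguous"
            s, e = nonl[0]
            unit = t.unit if g.strand == "+" else str(Seq(t.unit).reverse_complement())
            records.append(
                PlantedTNRRecord(
                    tract_id=f"tnr{tid:04d}",
                    sequence_id=chrom,
                    start=s,
                    end=e,
                    unit=unit,
                    copies=t.copies,
                    mismatches=0,
                    region_class="exonic",
                    gene_id=g.gene_id,
                )
            )
            tid += 1

    tail = last_end + 50
    for t in intergenic:
        pos = tail + 30
        plant(t, pos, None)
        tail = pos + t.length + 30

    records.sort(key=lambda r: r.start)
    genome = arr.tobytes().decode("ascii")
    return genome, records, genes


def _map_cds_span(gene: SimGene, a: int, b: int) -> list[tuple[int, int]]:
    """CDS nt span (tx order) -> ascending genomic intervals."""
    out = []
    off = 0
    for s, e in gene.cds_segments:
        n = e - s
        lo, hi = max(a, off), min(b, off + n)
        if hi > lo:
            if gene.strand == "+":
                out.append((s + lo - off, s + hi - off))
            else:
                out.append((e - (hi - off), e - (lo - off)))
        off += n
    return sorted(out)


def _mismatch_positions(rng: np.random.Generator, length: int, k: int) -> list[int]:
    """Interior mismatch positions, >= 4 nt from the ends, >= 8 nt apart.

    Spacing keeps every pure sub-segment score-positive so planted tract
    boundaries remain exactly maximal.
    """
    for _ in range(500):
        pos = sorted(int(rng.integers(4, length - 4)) for _ in range(k))
        if all(pos[i + 1] - pos[i] >= 8 for i in range(len(pos) - 1)):
            return pos
    raise ConfigError("cannot place mismatches with the required spacing")


# -- ontology / PPI / conservation ----------------------------------------


def build_ontology_and_associations(
    spec: OntologySpec,
    gene_ids: Sequence[str],
    repeat_gene_ids: Iterable[str],
    rng: np.random.Generator,
) -> OntologyBundle:
    """Random is_a/part_of DAG with one term planted at the requested odds.

    The planted term is assigned to repeat-carrying genes with probability
    p1 and to other genes with probability p0 = base_prob, where
    p1/(1-p1) = enrichment_odds * p0/(1-p0).  All other terms are assigned
    independently of repeat status.
    """
    repeat = set(repeat_gene_ids)
    root = "T:0000001"
    term_ids = [root] + [f"T:{i + 2:07d}" for i in range(spec.n_terms - 1)]
    depths = {root: 0}
    by_depth: dict[int, list[str]] = {0: [root]}
    for i, term in enumerate(term_ids[1:]):
        d = 1 + i % spec.dag_depth
        depths[term] = d
        by_depth.setdefault(d, []).append(term)
    edges: list[tuple[str, str, str]] = []
    for term in term_ids[1:]:
        d = depths[term]
        parent = _pick(rng, by_depth[d - 1])
        edges.append((term, parent, "is_a"))
        if d > 1 and rng.random() < 0.3:
            shallower = [t for dd in range(d) for t in by_depth[dd] if t != parent]
            edges.append((term, _pick(rng, shallower), "part_of"))
    max_depth = max(by_depth)
    planted = spec.planted_term or by_depth[max_depth][-1]
    if planted not in depths:
        raise ConfigError(f"planted_term {planted!r} not among generated terms")
    names = {t: f"synthetic term {t[2:].lstrip('0') or '1'}" for t in term_ids}
    names[root] = "synthetic root"
    names[planted] = "planted signal term"

    p0 = spec.base_prob
    odds1 = spec.enrichment_odds * p0 / (1 - p0)
    p1 = odds1 / (1 + odds1)
    associations: list[tuple[str, str]] = []
    for gene in gene_ids:
        p_term = p1 if gene in repeat else p0
        if rng.random() < p_term:
            associations.append((gene, planted))
        for term in term_ids[1:]:
            if term == planted:
                continue
            if rng.random() < spec.annotation_prob:
                associations.append((gene, term))
    return OntologyBundle(
        term_ids=term_ids,
        names=names,
        edges=edges,
        root=root,
        planted_term=planted,
        associations=associations,
    )


def write_obo(bundle: OntologyBundle, path) -> None:
    buf = io.StringIO()
    buf.write("format-version: 1.2\nontology: tritract-synthetic\n")
    parents: dict[str, list[tuple[str, str]]] = {}
    for child, parent, rel in bundle.edges:
        parents.setdefault(child, []).append((rel, parent))
    for term in bundle.term_ids:
        buf.write(f"\n[Term]\nid: {term}\nname: {bundle.names[term]}\n")
        for rel, parent in sorted(parents.get(term, [])):
            if rel == "is_a":
                buf.write(f"is_a: {parent} ! {bundle.names[parent]}\n")
            else:
                buf.write(f"relationship: part_of {parent} ! {bundle.names[parent]}\n")
    Path(path).write_text(buf.getvalue())


def write_associations(bundle: OntologyBundle, path) -> None:
    lines = [f"{g}\t{t}" for g, t in sorted(bundle.associations)]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def build_ppi_pairs(
    spec: PPISpec, protein_ids: Sequence[str], rng: np.random.Generator
) -> list[tuple[str, str]]:
    """Undirected unique pairs from an Erdos-Renyi draw with the given mean degree."""
    n = len(protein_ids)
    if n < 2 or spec.mean_degree == 0:
        return []
    p = min(1.0, spec.mean_degree / (n - 1))
    pairs: list[tuple[str, str]] = []
    for i in range(n):
        draws = rng.random(n - i - 1)
        for j_off in np.nonzero(draws < p)[0]:
            pairs.append((protein_ids[i], protein_ids[i + 1 + int(j_off)]))
    return pairs


def _build_conservation(
    spec: ConservationSpec,
    chrom: str,
    genes: Sequence[SimGene],
    rng: np.random.Generator,
) -> list[tuple[str, int, int, np.ndarray]]:
    out: list[tuple[str, int, int, np.ndarray]] = []
    segments = sorted(
        (s, e) for g in genes for s, e in g.cds_segments
    )
    for s, e in segments:
        scores = np.clip(rng.normal(spec.baseline, spec.sd, e - s), 0.0, 1.0)
        out.append((chrom, s, e, scores))
    return out


# -- spec-level operation wrappers ----------------------------------------


def generate_genome(config: SimulationConfig, fasta_path, truth_tnr_path=None) -> Simulation:
    """Emit the genome FASTA (and optionally the DNA-tract truth table)."""
    sim = simulate(config)
    sim.write_genome(fasta_path)
    if truth_tnr_path is not None:
        sim.write_truth(truth_tnr_path, Path(str(truth_tnr_path)) .with_suffix(".homoaa.tsv"))
    return sim


def generate_gene_models(
    config: SimulationConfig, gff3_path, cds_path, protein_path, map_path
) -> Simulation:
    sim = simulate(config)
    sim.write_annotation(gff3_path)
    sim.write_cds(cds_path)
    sim.write_proteins(protein_path)
    sim.write_protein_map(map_path)
    return sim


def generate_ontology_and_associations(
    config: SimulationConfig,
    gene_ids: Sequence[str],
    repeat_gene_ids: Iterable[str],
    obo_path,
    assoc_path,
) -> OntologyBundle:
    """Standalone ontology + association emission for arbitrary gene ids."""
    ss = np.random.SeedSequence(config.seed).spawn(7)[4]
    bundle = build_ontology_and_associations(
        config.ontology_spec, gene_ids, repeat_gene_ids, np.random.default_rng(ss)
    )
    write_obo(bundle, obo_path)
    write_associations(bundle, assoc_path)
    return bundle


def generate_ppi_and_conservation(
    config: SimulationConfig, ppi_path, bedgraph_path
) -> Simulation:
    sim = simulate(config)
    sim.write_ppi(ppi_path)
    sim.write_conservation(bedgraph_path)
    return sim
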