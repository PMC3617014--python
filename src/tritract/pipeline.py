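"""End-to-end orchestration: simulate, scan, localize, classify, test, enrich.

Stages run in dependency order, every intermediate table is written as TSV,
and a JSON report collects the headline numbers: tract counts by region
class, the unit-frequency profile test, the repeat/variant protein set
split, the per-residue composition and length comparisons, the interaction
and conservation comparisons, and the top enriched terms.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO

from . import annotation, background, enrichment, homoaa, scanner, stats
from .simulate import SimulationConfig, simulate

log = logging.getLogger(__name__)

BACKGROUND_CHOICES = ("whole_set", "variant_encoded", "all_homoaa")


@dataclass
class PipelineConfig:
    outdir: str | Path = "tritract_run"
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    scan_params: scanner.ScanParams = field(default_factory=scanner.ScanParams)
    homoaa_params: homoaa.HomoAAParams = field(default_factory=homoaa.HomoAAParams)
    upstream: int = 1000
    alpha: float = 0.05
    enrichment_background: str = "all_homoaa"
    merge_revcomp_units: bool = False
    top_k: int = 5

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.enrichment_background not in BACKGROUND_CHOICES:
            raise ValueError(f"enrichment_background must be one of {BACKGROUND_CHOICES}")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage on a synthetic dataset and return the report dict."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def stage(msg: str) -> None:
        log_lines.append(f"{time.strftime('%Y-%m-%dT%H:%M:%S')} {msg}")
        log.info(msg)

    stage(f"parameters: seed={config.sim.seed} scan={dataclasses.asdict(config.scan_params)} "
          f"homoaa={dataclasses.asdict(config.homoaa_params)} upstream={config.upstream} "
          f"alpha={config.alpha} background={config.enrichment_background}")

    stage("simulate: generating synthetic inputs")
    sim = simulate(config.sim)
    inputs = sim.write_all(outdir / "inputs")

    stage("scan-dna: scanning the genome for repeat tracts")
    records = [(r.id, str(r.seq)) for r in SeqIO.parse(str(inputs["genome"]), "fasta")]
    tracts = scanner.scan_fasta(records, config.scan_params)
    scanner.write_tracts_tsv(tracts, outdir / "tracts.tsv")
    tri = scanner.filter_period3(tracts, config.scan_params)
    scanner.write_tracts_tsv(tri, outdir / "tracts_period3.tsv")

    stage("background: fitting the order-2 Markov model and unit profile")
    model = background.fit_markov2([s for _, s in records])
    model.write_tsv(outdir / "background_model.tsv")
    counts = background.tract_unit_counts(tri, merge_revcomp=config.merge_revcomp_units)
    profile = background.unit_frequency_profile(counts, model)
    profile.write_tsv(outdir / "unit_profile.tsv")

    stage("localize: classifying tracts by gene region")
    models = annotation.load_annotation(inputs["annotation"])
    index = annotation.RegionIndex(
        models, upstream=config.upstream, known_sequences=[r[0] for r in records]
    )
    tri = annotation.localize_tracts(tri, index)
    scanner.write_tracts_tsv(tri, outdir / "tracts_localized.tsv")
    region_counts: dict[str, int] = {c: 0 for c in annotation.PRECEDENCE}
    for t in tri:
        region_counts[t.region_class] += 1

    stage("scan-protein: homo-AA runs and codon-level encoding classes")
    gene_models = {m.protein_id: m for m in models if m.protein_id}
    aa_tracts = homoaa.scan_proteins(
        sim.proteins_by_id(), sim.cds_by_protein(), config.homoaa_params, gene_models
    )
    homoaa.write_tracts_tsv(aa_tracts, outdir / "homoaa_tracts.tsv")
    protein_sets = homoaa.build_protein_sets(aa_tracts)
    tnr_set, var_set, all_set = protein_sets

    stage("stats: composition, length, interaction and conservation comparisons")
    comp = stats.composition_analysis(aa_tracts, protein_sets, config.alpha)
    stats.composition_to_frame(comp).to_csv(outdir / "composition.tsv", sep="\t", index=False)
    lens = stats.length_analysis(aa_tracts, config.alpha)
    stats.lengths_to_frame(lens).to_csv(outdir / "lengths.tsv", sep="\t", index=False)
    ppi_pairs = sim.ppi_pairs
    _deg_table, ppi_u, ppi_p = stats.ppi_degree_comparison(ppi_pairs, protein_sets)
    track = stats.ConservationTrack.read_bedgraph(inputs["conservation"])
    _cons_table, cons_u, cons_p = stats.tract_conservation_comparison(aa_tracts, track)

    stage("enrich: term over-representation of repeat-encoded proteins")
    dag = enrichment.parse_obo(str(inputs["obo"]))
    pairs = enrichment.read_associations(inputs["associations"])
    pid_to_gene = {g.protein_id: g.gene_id for g in sim.genes}
    gene_pairs = pairs  # associations are keyed by gene id
    study = {pid_to_gene[p] for p in tnr_set}
    if config.enrichment_background == "whole_set":
        bg = {g.gene_id for g in sim.genes}
    elif config.enrichment_background == "variant_encoded":
        bg = study | {pid_to_gene[p] for p in var_set}
    else:
        bg = {pid_to_gene[p] for p in all_set}
    enrich_results = enrichment.fisher_overrepresentation(
        study, bg, gene_pairs, dag=dag
    ) if study and bg else []
    enrichment.write_results_tsv(enrich_results, outdir / "enrichment.tsv")

    report = {
        "seed": config.sim.seed,
        "n_tracts_all_periods": len(tracts),
        "n_trinucleotide_tracts": len(tri),
        "tract_region_counts": region_counts,
        "unit_profile": {
            "chisq_stat": profile.chisq_stat,
            "df": profile.df,
            "p_value": profile.p_value,
            "log2_ratios": dict(sorted(profile.log_ratios.items())),
        },
        "protein_sets": {
            "tnr_encoded": len(tnr_set),
            "variant_encoded": len(var_set),
            "all_homoaa": len(all_set),
        },
        "composition": [dataclasses.asdict(c) for c in comp],
        "length": [dataclasses.asdict(l) for l in lens],
        "ppi": {"u_statistic": ppi_u, "p_value": ppi_p},
        "conservation": {"u_statistic": cons_u, "p_value": cons_p},
        "top_enriched_terms": [
            dataclasses.asdict(r) for r in enrich_results[: config.top_k]
        ],
    }
    (outdir / "report.json").write_text(json.dumps(report, indent=2, default=float))
    (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
    stage("done")
    return report
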