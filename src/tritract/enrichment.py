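"""GO-style term over-representation with transitive-closure propagation.

The ontology is restricted to ``is_a`` and ``part_of`` edges (other
relationship types such as ``has_part`` or ``regulates`` are dropped to
avoid false positives from non-subsumption relations).  Gene annotations
are propagated to the reflexive transitive closure of their terms.
Over-representation of terms in a study set against a background set is
assessed by the one-sided Fisher exact test; the reported E-value is the
Bonferroni-scaled p-value (p times the number of terms tested), not capped
at 1 by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx
import obonet
import pandas as pd
from scipy import stats as sps

log = logging.getLogger(__name__)

KEPT_RELATIONS = ("is_a", "part_of")


class OntologyError(ValueError):
    """Malformed ontology or enrichment input."""


@dataclass
class OntologyDAG:
    """Terms plus typed is_a/part_of edges (child -> parent)."""

    graph: nx.MultiDiGraph
    names: dict[str, str]

    @property
    def terms(self) -> set[str]:
        return set(self.graph.nodes)

    def roots(self) -> set[str]:
        return {t for t in self.graph.nodes if self.graph.out_degree(t) == 0}


def parse_obo(path) -> OntologyDAG:
    """Parse an OBO 1.2 subset, keeping only is_a and part_of edges.

    Obsolete terms are excluded; a cycle over the retained edges is a parse
    error.
    """
    raw = obonet.read_obo(path, ignore_obsolete=True)
    g = nx.MultiDiGraph()
    names: dict[str, str] = {}
    for node, data in raw.nodes(data=True):
        g.add_node(node)
        names[node] = data.get("name", node)
    for child, parent, key in raw.edges(keys=True):
        if key in KEPT_RELATIONS:
            g.add_edge(child, parent, key=key)
    if not nx.is_directed_acyclic_graph(g):
        raise OntologyError("cycle detected over is_a/part_of edges")
    return OntologyDAG(graph=g, names=names)


def ancestors(dag: OntologyDAG, term: str) -> set[str]:
    """Reflexive transitive closure of a term over is_a/part_of edges."""
    if term not in dag.graph:
        raise OntologyError(f"unknown term: {term!r}")
    return {term} | nx.descendants(dag.graph, term)


def propagate_annotations(
    dag: OntologyDAG, gene_term_pairs: Iterable[tuple[str, str]]
) -> dict[str, set[str]]:
    """Annotate each gene with the closure of its directly associated terms.

    Unknown terms are logged and skipped.
    """
    cache: dict[str, set[str]] = {}
    out: dict[str, set[str]] = {}
    for gene, term in gene_term_pairs:
        if term not in dag.graph:
            log.warning("unknown term %s for gene %s; skipped", term, gene)
            continue
        if term not in cache:
            cache[term] = ancestors(dag, term)
        out.setdefault(gene, set()).update(cache[term])
    return out


@dataclass
class EnrichmentResult:
    term_id: str
    term_name: str
    study_with: int
    study_without: int
    bg_with: int
    bg_without: int
    fisher_p: float
    e_value: float


def fisher_overrepresentation(
    study: set[str],
    background: set[str],
    annotations: Mapping[str, set[str]] | Iterable[tuple[str, str]],
    dag: OntologyDAG | None = None,
    alternative: str = "greater",
    cap_e_value: bool = False,
) -> list[EnrichmentResult]:
    """Per-term over-representation of ``study`` within ``background``.

    ``annotations`` is either a gene -> term-set mapping (already
    propagated) or raw (gene, term) pairs to propagate through ``dag``.
    Genes with no annotation stay in the margins as "without term".  One
    result per term with at least one annotated background gene; E-value =
    p times the number of terms tested, sorted ascending.
    """
    if not study or not background:
        raise OntologyError("study and background must be non-empty")
    if not study <= background:
        raise OntologyError("study set must be a subset of the background")
    if isinstance(annotations, Mapping):
        gene_terms = {g: set(ts) for g, ts in annotations.items()}
    else:
        if dag is None:
            raise OntologyError("raw gene-term pairs require an ontology DAG")
        gene_terms = propagate_annotations(dag, annotations)
    term_genes: dict[str, set[str]] = {}
    for g in background:
        for t in gene_terms.get(g, ()):
            term_genes.setdefault(t, set()).add(g)
    m = len(term_genes)
    n_study = len(study)
    n_bg = len(background)
    names = dag.names if dag is not None else {}
    results: list[EnrichmentResult] = []
    for term in sorted(term_genes):
        with_term = term_genes[term]
        a = len(with_term & study)
        b = n_study - a
        bg_with = len(with_term)
        c = bg_with - a
        d = (n_bg - n_study) - c
        p = float(sps.fisher_exact([[a, b], [c, d]], alternative=alternative)[1])
        e = p * m
        if cap_e_value:
            e = min(e, 1.0)
        results.append(
            EnrichmentResult(
                term_id=term,
                term_name=names.get(term, term),
                study_with=a,
                study_without=b,
                bg_with=bg_with,
                bg_without=n_bg - bg_with,
                fisher_p=p,
                e_value=e,
            )
        )
    results.sort(key=lambda r: (r.e_value, r.term_id))
    return results


def read_associations(path) -> list[tuple[str, str]]:
    """Read a (gene_id, term_id) TSV, ignoring comment lines."""
    pairs: list[tuple[str, str]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "!")):
                continue
            gene, term = line.split("\t")[:2]
            pairs.append((gene, term))
    return pairs


def results_to_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in results])


def write_results_tsv(results: list[EnrichmentResult], path) -> None:
    results_to_frame(results).to_csv(path, sep="\t", index=False)
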