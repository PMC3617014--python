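"""Generator contracts: determinism, construction fidelity, planted truth."""

import numpy as np
import pytest
from Bio.Seq import Seq

from tritract.simulate import (
    ConfigError,
    OntologySpec,
    PlantedTNR,
    PPISpec,
    ResidueRunSpec,
    SimulationConfig,
    SizingError,
    build_ontology_and_associations,
    build_ppi_pairs,
    simulate,
)


class TestDeterminism:
    def test_identical_config_gives_byte_identical_outputs(self, tmp_path):
        cfg = SimulationConfig(seed=7)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        p1 = simulate(cfg).write_all(d1)
        p2 = simulate(cfg).write_all(d2)
        for key in p1:
            assert p1[key].read_bytes() == p2[key].read_bytes(), key

    def test_different_seed_changes_genome(self):
        assert simulate(SimulationConfig(seed=1)).genome != simulate(
            SimulationConfig(seed=2)
        ).genome


class TestGenomeGeneration:
    def test_planted_tract_written_verbatim(self):
        cfg = SimulationConfig(
            seed=3, planted_tnrs=[PlantedTNR("CAG", 20, 0, "intergenic")]
        )
        sim = simulate(cfg)
        recs = [r for r in sim.truth.tnr_records if r.region_class == "intergenic"]
        assert len(recs) == 1
        r = recs[0]
        assert r.end - r.start == 60
        assert sim.genome[r.start : r.end] == "CAG" * 20

    def test_mismatch_count_matches_truth(self):
        cfg = SimulationConfig(
            seed=4, planted_tnrs=[PlantedTNR("CAG", 30, 2, "intergenic")]
        )
        sim = simulate(cfg)
        r = sim.truth.tnr_records[-1]
        diff = sum(
            a != b for a, b in zip(sim.genome[r.start : r.end], "CAG" * 30)
        )
        assert diff == 2

    def test_markov_background_conditioning_outside_planted_features(self):
        table = np.full((4, 4, 4), 0.25)
        table[1, 1] = [0.0, 0.0, 1.0, 0.0]  # P(G | CC) = 1
        cfg = SimulationConfig(seed=5, markov_spec=table, n_genes=4,
                               homoaa_spec={"Q": ResidueRunSpec(1.0, n_runs=4)})
        sim = simulate(cfg)
        planted = sim.planted_intervals()

        def in_planted(i):
            return any(s <= i < e for s, e in planted)

        genome = sim.genome
        checked = 0
        for i in range(len(genome) - 2):
            if genome[i : i + 2] == "CC" and not (
                in_planted(i) or in_planted(i + 1) or in_planted(i + 2)
            ):
                assert genome[i + 2] == "G", i
                checked += 1
        assert checked > 50

    def test_explicit_genome_length_too_small_raises(self):
        with pytest.raises(SizingError):
            simulate(SimulationConfig(seed=1, genome_length=5000))

    def test_planted_tracts_respect_spacing(self, default_sim):
        recs = sorted(default_sim.truth.tnr_records, key=lambda r: r.start)
        for a, b in zip(recs, recs[1:]):
            assert b.start - a.end >= 50


class TestGeneModels:
    def test_cds_structure(self, default_sim):
        for g in default_sim.genes:
            assert len(g.cds_seq) % 3 == 0
            assert g.cds_seq.startswith("ATG")
            assert g.cds_seq[-3:] in ("TAA", "TAG", "TGA")
            assert str(Seq(g.cds_seq).translate()).rstrip("*") == g.protein_seq
            assert "*" not in str(Seq(g.cds_seq).translate())[:-1]
            assert len(g.introns_genomic) >= 1

    def test_theta_one_gives_single_repeated_codon(self):
        cfg = SimulationConfig(
            seed=6, n_genes=6, planted_tnrs=[],
            homoaa_spec={"Q": ResidueRunSpec(theta=1.0, n_runs=6)},
        )
        sim = simulate(cfg)
        for h in sim.truth.homoaa_records:
            assert h.encoding_class == "tnr"
            g = next(g for g in sim.genes if g.gene_id == h.gene_id)
            codons = g.codons[h.start : h.end]
            assert len(set(codons)) == 1 and len(codons) == h.length

    def test_theta_zero_caps_same_codon_run_below_seven(self):
        cfg = SimulationConfig(
            seed=7, n_genes=6, planted_tnrs=[],
            homoaa_spec={"Q": ResidueRunSpec(theta=0.0, n_runs=6)},
        )
        sim = simulate(cfg)
        for h in sim.truth.homoaa_records:
            assert h.encoding_class == "variant"
            g = next(g for g in sim.genes if g.gene_id == h.gene_id)
            codons = g.codons[h.start : h.end]
            assert set(codons) <= {"CAA", "CAG"}
            longest = max(
                len(list(grp)) for _, grp in __import__("itertools").groupby(codons)
            )
            assert longest <= 6

    def test_minus_strand_gene_translates_from_genome(self, default_sim):
        sim = default_sim
        minus = [g for g in sim.genes if g.strand == "-"]
        assert minus
        for g in minus:
            cds = "".join(
                str(Seq(sim.genome[s:e]).reverse_complement())
                for s, e in g.cds_segments
            )
            assert str(Seq(cds).translate()).rstrip("*") == g.protein_seq

    def test_single_codon_residue_with_variant_request_rejected(self):
        with pytest.raises(ConfigError):
            SimulationConfig(homoaa_spec={"W": ResidueRunSpec(theta=0.5, n_runs=2)})

    def test_run_lengths_at_least_seven(self, default_sim):
        assert all(h.length >= 7 for h in default_sim.truth.homoaa_records)


class TestScannerClosure:
    def test_fifty_planted_tracts_recovered_with_exact_loci(self):
        rng = np.random.default_rng(99)
        units = [u for u in
                 ("CAG", "CTG", "CAA", "AAT", "GCC", "ATC", "AGG", "CCT", "ACT", "GTC")]
        tnrs = [
            PlantedTNR(units[i % len(units)], int(rng.integers(7, 30)), 0, "intergenic")
            for i in range(50)
        ]
        cfg = SimulationConfig(seed=11, n_genes=0, planted_tnrs=tnrs, homoaa_spec={})
        sim = simulate(cfg)
        from tritract.scanner import scan

        found = {(t.start, t.end) for t in scan(sim.genome)}
        for r in sim.truth.tnr_records:
            assert (r.start, r.end) in found, r


class TestOntology:
    def test_all_terms_reachable_from_root(self):
        rng = np.random.default_rng(0)
        b = build_ontology_and_associations(
            OntologySpec(n_terms=40, dag_depth=5), [f"g{i}" for i in range(10)],
            set(), rng,
        )
        children = {}
        for c, p, _rel in b.edges:
            children.setdefault(c, set()).add(p)
        for t in b.term_ids:
            seen = {t}
            frontier = {t}
            while frontier:
                frontier = set().union(*(children.get(x, set()) for x in frontier)) - seen
                seen |= frontier
            assert b.root in seen

    def test_odds_one_means_independence(self):
        rng = np.random.default_rng(1)
        genes = [f"g{i}" for i in range(4000)]
        repeat = set(genes[:1000])
        b = build_ontology_and_associations(
            OntologySpec(n_terms=20, dag_depth=2, enrichment_odds=1.0),
            genes, repeat, rng,
        )
        with_term = {g for g, t in b.associations if t == b.planted_term}
        p_rep = len(with_term & repeat) / len(repeat)
        p_other = len(with_term - repeat) / (len(genes) - len(repeat))
        assert p_rep == pytest.approx(p_other, abs=0.04)

    def test_emitted_odds_ratio_near_planted_odds(self):
        rng = np.random.default_rng(2)
        genes = [f"g{i}" for i in range(1000)]
        repeat = set(genes[:300])
        b = build_ontology_and_associations(
            OntologySpec(n_terms=20, dag_depth=2, enrichment_odds=5.0),
            genes, repeat, rng,
        )
        with_term = {g for g, t in b.associations if t == b.planted_term}
        a = len(with_term & repeat)
        bb = len(repeat) - a
        c = len(with_term - repeat)
        d = len(genes) - len(repeat) - c
        odds = (a / bb) / (c / d)
        assert 3.0 < odds < 8.0


class TestPPIAndConservation:
    def test_zero_degree_parameter_gives_empty_list(self):
        rng = np.random.default_rng(0)
        assert build_ppi_pairs(PPISpec(0.0), [f"p{i}" for i in range(10)], rng) == []

    def test_no_self_pairs_or_duplicates(self, default_sim):
        pairs = default_sim.ppi_pairs
        assert all(a != b for a, b in pairs)
        norm = {tuple(sorted(p)) for p in pairs}
        assert len(norm) == len(pairs)

    def test_zero_sd_gives_constant_scores(self, tmp_path):
        from tritract.simulate import ConservationSpec

        cfg = SimulationConfig(
            seed=8, n_genes=3, planted_tnrs=[],
            homoaa_spec={"Q": ResidueRunSpec(1.0, n_runs=2)},
            conservation_spec=ConservationSpec(baseline=0.8, sd=0.0),
        )
        sim = simulate(cfg)
        path = tmp_path / "c.bedgraph"
        sim.write_conservation(path)
        scores = {float(l.split("\t")[3]) for l in path.read_text().splitlines()}
        assert scores == {0.8}

    def test_scores_clipped_to_unit_interval(self, default_sim):
        for _, _, _, scores in default_sim.conservation:
            assert scores.min() >= 0.0 and scores.max() <= 1.0
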