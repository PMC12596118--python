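"""Synthetic-data generator: determinism, truth closure, planted features."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lysismine.lysclass import detect_lipobox, predict_tmrs
from lysismine.records import fasta_bytes
from lysismine.synth import (
    GenomePlan,
    PlantSpec,
    PlantedGene,
    default_plant_spec,
    default_vocabulary,
    generate_dataset,
    generate_tree_pair,
    mutate_sequence,
)


class TestMutate:
    def test_zero_divergence_identity(self):
        assert mutate_sequence("ACDEFGHIKL", 0.0, seed=1) == "ACDEFGHIKL"

    @given(st.integers(0, 2**31 - 1), st.floats(0.0, 1.0))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_exact_substitution_count(self, seed, divergence):
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=100))
        mutant = mutate_sequence(seq, divergence, seed)
        diffs = sum(1 for a, b in zip(seq, mutant) if a != b)
        assert diffs == round(divergence * 100)
        assert len(mutant) == len(seq)

    def test_out_of_range_divergence(self):
        with pytest.raises(ValueError):
            mutate_sequence("ACDE", 1.5, seed=0)


class TestGenerate:
    def test_byte_identical_under_fixed_seed(self):
        spec = default_plant_spec(n_genomes=4, seed=7)
        a = generate_dataset(spec)
        b = generate_dataset(default_plant_spec(n_genomes=4, seed=7))
        assert fasta_bytes(a.genomes) == fasta_bytes(b.genomes)
        assert a.proteins == b.proteins

    def test_single_endolysin_plant(self):
        spec = PlantSpec(
            plans=[GenomePlan(genes=[PlantedGene("endolysin", families=("Ami2_like",))])],
            seed=1,
        )
        ds = generate_dataset(spec)
        rows = ds.truth_lytic()
        assert len(rows) == 1
        assert rows[0].subclass == "amidase" and rows[0].verdict == "pass"
        # the planted protein carries the family motif verbatim
        vocab = ds.vocabulary
        assert vocab.families["Ami2_like"].motif in ds.proteins[rows[0].gene_id]

    def test_no_system_means_no_lytic_rows(self):
        ds = generate_dataset(PlantSpec(plans=[GenomePlan(genes=[])], seed=2))
        assert ds.truth_lytic() == []

    def test_sizing_error_names_genome(self):
        spec = PlantSpec(
            plans=[GenomePlan(genes=[PlantedGene("holin", tmr_count=4)] * 10)],
            genome_length=(2_000, 2_100),
            seed=3,
        )
        with pytest.raises(ValueError, match="vg000"):
            generate_dataset(spec)

    def test_truth_closure_and_coordinates(self):
        ds = generate_dataset(default_plant_spec(n_genomes=6, seed=4))
        genomes = {g.id: g for g in ds.genomes}
        calls = {c.gene_id: c for c in ds.gene_calls}
        for row in ds.truth:
            assert row.gene_id in calls
            g = genomes[row.genome_id]
            assert 0 <= row.start < row.end <= len(g)

    def test_spanin_rows_reference_partner(self):
        ds = generate_dataset(default_plant_spec(n_genomes=8, seed=5))
        ids = {r.gene_id for r in ds.truth}
        for row in ds.truth_lytic():
            if row.lytic_type == "spanin" and row.subclass != "USP" and row.partner_id:
                assert row.partner_id in ids

    def test_planted_features_present(self):
        """Holin TMR counts and spanin features match the plan."""
        ds = generate_dataset(default_plant_spec(n_genomes=12, seed=6))
        for row in ds.truth_lytic():
            protein = ds.proteins[row.gene_id]
            if row.lytic_type == "holin" and row.verdict == "pass":
                k = len(predict_tmrs(protein))
                expected = row.subclass
                assert (f"TMRs-{k}" if k <= 4 else "TMRs-4+") == expected
            if row.subclass in ("SOS", "EOS", "OOS"):
                assert detect_lipobox(protein) is not None
            if row.subclass in ("SIS", "EIS", "OIS"):
                assert len(predict_tmrs(protein)) >= 1

    def test_background_proteins_lack_motifs(self):
        ds = generate_dataset(default_plant_spec(n_genomes=6, seed=8))
        motifs = [f.motif for f in ds.vocabulary.families.values()]
        lytic = {r.gene_id for r in ds.truth_lytic()}
        for gene_id, protein in ds.proteins.items():
            if gene_id not in lytic:
                assert not any(m in protein for m in motifs)


class TestTreePair:
    def test_zero_incongruence_identical_topology(self):
        ta, tb, assoc = generate_tree_pair(12, incongruence=0.0, seed=1)
        assert ta.compare_rfd(tb) == 0.0
        assert assoc == {f"T{i:03d}": f"T{i:03d}" for i in range(12)}

    def test_full_incongruence_perturbs_topology(self):
        ta, tb, _ = generate_tree_pair(16, incongruence=1.0, seed=2)
        assert ta.compare_rfd(tb) > 0.0

    def test_minimum_leaves_enforced(self):
        with pytest.raises(ValueError):
            generate_tree_pair(3, incongruence=0.0, seed=0)

    def test_branch_lengths_positive(self):
        ta, _, _ = generate_tree_pair(8, incongruence=0.5, seed=3)
        assert all((n.length or 0) > 0 for n in ta.traverse() if not n.is_root())
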