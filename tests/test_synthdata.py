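import dendropy
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cesakit import genestruct, motifscan, synthdata, wallclass
from cesakit.errors import GeneratorError
from cesakit.synthdata import (
    ProteinSpecTemplate,
    evolve_family,
    make_cesa_protein,
    make_counts,
    make_gene_model,
    mutate_sequence,
)


class TestTemplateInvariants:
    def test_pcw_requires_pcw_type(self):
        with pytest.raises(GeneratorError):
            ProteinSpecTemplate(wall_class="PCW", ortholog_type="CesA4-like", seed=0)

    def test_scw_requires_scw_type(self):
        with pytest.raises(GeneratorError):
            ProteinSpecTemplate(wall_class="SCW", ortholog_type="PCW-type", seed=0)

    def test_cesa7_forces_deleted_znf(self):
        template = ProteinSpecTemplate(
            wall_class="SCW", ortholog_type="CesA7-like", seed=0
        )
        assert template.znf_variant == "deleted_38"
        with pytest.raises(GeneratorError):
            ProteinSpecTemplate(
                wall_class="SCW",
                ortholog_type="CesA7-like",
                seed=0,
                znf_variant="full_46",
            )


class TestMakeCesaProtein:
    def test_length_within_published_range(self):
        for seed in range(5):
            template = ProteinSpecTemplate(
                wall_class="PCW", ortholog_type="PCW-type", seed=seed
            )
            record, _ = make_cesa_protein(template)
            assert 991 <= len(record) <= 1091

    def test_ground_truth_round_trips_through_detectors(self, pcw_protein):
        record, truth = pcw_protein
        znf = motifscan.detect_znf(record)
        assert znf.variant == "full_46"
        assert (znf.hit.start, znf.hit.end) == truth.znf_interval
        core = motifscan.detect_catalytic(record)
        d1, d2, d3, q = truth.catalytic
        assert (core.d1, core.d2, core.d3, core.qxxrw_start) == (d1, d2, d3, q)
        call = wallclass.classify(record)
        assert (call.call, call.confidence) == ("PCW", "high")

    def test_eight_tmds_two_before_catalytic(self, pcw_protein):
        record, truth = pcw_protein
        tmds = motifscan.tmd_scan(record)
        assert len(tmds) == 8
        q_start = truth.catalytic[3]
        before = [t for t in tmds if t[1] <= truth.catalytic[0]]
        after = [t for t in tmds if t[0] >= q_start]
        assert len(before) == 2
        assert len(after) == 6

    def test_deleted_variant_has_eight_residue_deletion(self):
        template = ProteinSpecTemplate(
            wall_class="SCW", ortholog_type="CesA7-like", seed=2
        )
        record, _ = make_cesa_protein(template)
        znf = motifscan.detect_znf(record)
        assert znf.variant == "deleted_38"
        assert znf.deletion_size == 8

    def test_too_small_target_rejected(self):
        template = ProteinSpecTemplate(
            wall_class="PCW", ortholog_type="PCW-type", seed=0, target_length=500
        )
        with pytest.raises(GeneratorError, match="too small"):
            make_cesa_protein(template)

    def test_same_seed_same_protein(self):
        template = ProteinSpecTemplate(
            wall_class="SCW", ortholog_type="CesA8-like", seed=99
        )
        assert make_cesa_protein(template)[0] == make_cesa_protein(template)[0]


class TestEvolution:
    @staticmethod
    def two_leaf_tree(t_half):
        tns = dendropy.TaxonNamespace(["x", "y"])
        root = dendropy.Node()
        for label in ("x", "y"):
            leaf = dendropy.Node()
            leaf.taxon = tns.get_taxon(label)
            root.add_child(leaf)
            leaf.edge.length = t_half
        tree = dendropy.Tree(taxon_namespace=tns)
        tree.seed_node = root
        return tree

    def test_zero_branch_length_is_identity(self):
        rng = np.random.default_rng(0)
        seq = "ACDEFGHIKLMNPQRSTVWY" * 10
        assert mutate_sequence(seq, 0.0, rng) == seq

    def test_p_distance_matches_closed_form(self):
        # observed divergence at separation t tracks 1 - exp(-19t/20)
        rng = np.random.default_rng(123)
        length = 1000
        seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), length))
        for t in (0.2, 0.5, 1.0):
            a = mutate_sequence(seq, t / 2, rng)
            b = mutate_sequence(seq, t / 2, rng)
            p_obs = np.mean([x != y for x, y in zip(a, b)])
            p_exp = 1.0 - np.exp(-t * 19.0 / 20.0)
            sd = np.sqrt(p_exp * (1 - p_exp) / length)
            assert abs(p_obs - p_exp) < 3 * sd

    def test_protected_positions_never_change(self, pcw_protein):
        record, truth = pcw_protein
        rng = np.random.default_rng(7)
        mutated = mutate_sequence(record.sequence, 1.5, rng, truth.protected_positions)
        for pos in truth.protected_positions:
            assert mutated[pos] == record.sequence[pos]

    def test_family_leaves_keep_classification_when_protected(self, pcw_protein):
        record, truth = pcw_protein
        leaves = evolve_family(
            record,
            self.two_leaf_tree(0.2),
            protect_motifs=True,
            ground_truth=truth,
            seed=5,
        )
        assert len(leaves) == 2
        for leaf in leaves:
            assert len(leaf) == len(record)  # substitution-only: self-aligned
            call = wallclass.classify(leaf)
            assert (call.call, call.ortholog_hint) == ("PCW", "PCW-type")


class TestMakeGeneModel:
    def test_requested_canonical_vector_realized(self):
        vector = genestruct.CANONICAL_PHASE_VECTORS["TaCesA4"]
        model = make_gene_model(vector, seed=0)
        assert genestruct.intron_phases(model).phases == vector

    def test_empty_request_gives_single_exon(self):
        model = make_gene_model([], seed=0)
        assert len(model.coding_exons) == 1
        assert genestruct.intron_phases(model).phases == ()

    @given(
        phases=st.lists(st.integers(min_value=0, max_value=2), max_size=14),
        seed=st.integers(min_value=0, max_value=10_000),
    )
    def test_round_trip_exact_for_random_requests(self, phases, seed):
        model = make_gene_model(phases, seed=seed)
        assert list(genestruct.intron_phases(model).phases) == phases

    def test_minus_strand_round_trips_too(self):
        model = make_gene_model([1, 2, 0], seed=4, strand="-")
        assert genestruct.intron_phases(model).phases == (1, 2, 0)

    def test_explicit_intron_lengths_respected(self):
        model = make_gene_model([0, 0], intron_lengths=[100, 200], seed=1)
        exons = sorted(model.coding_exons)
        gaps = [s2 - e1 for (_, e1), (s2, _) in zip(exons, exons[1:])]
        assert gaps == [100, 200]


class TestMakeCounts:
    def test_counts_are_finite_non_negative_integers(self):
        counts, labels = make_counts(seed=7)
        assert counts.counts.dtype.kind == "i"
        assert (counts.counts >= 0).all()
        assert set(labels.values()) == {"SCW", "PCW"}

    def test_same_seed_byte_identical(self, tmp_path):
        from cesakit import seqio

        for run in ("a", "b"):
            matrix, _ = make_counts(seed=11)
            seqio.write_counts(matrix, tmp_path / f"{run}.tsv")
        assert (tmp_path / "a.tsv").read_bytes() == (tmp_path / "b.tsv").read_bytes()

    def test_design_needs_mature_stem_sample(self):
        with pytest.raises(GeneratorError, match="mature-stem"):
            make_counts(samples=[("root", "seedling")], seed=0)

    def test_scw_elevated_in_mature_stem(self):
        counts, labels = make_counts(seed=3)
        frame = counts.to_frame()
        stem = [c for c in frame.columns if c.startswith("stem_anthesis")]
        other = [c for c in frame.columns if not c.startswith("stem_anthesis")]
        scw = [g for g, l in labels.items() if l == "SCW"]
        pcw = [g for g, l in labels.items() if l == "PCW"]
        assert frame.loc[scw, stem].mean().mean() > 3 * frame.loc[scw, other].mean().mean()
        assert frame.loc[pcw, other].mean().mean() > 2 * frame.loc[pcw, stem].mean().mean()
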