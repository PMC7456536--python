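"""The generator: planted truth must be recountable from emitted files."""

import json
import os

import numpy as np
import pytest

from zpevol.alignment import gap_proportion, locate_domain_map, read_alignment
from zpevol.connectivity import DEFAULT_REGISTRY, presence_vector
from zpevol.support import bipartitions
from zpevol.synthetic import (
    GenerationError,
    ParameterError,
    SyntheticSpec,
    build_truth,
    emit_replicate_alignments,
    evolve_sequences,
    make_fixture_bundle,
    plant_background_gaps,
    plant_domain_loss,
    simulate_family_tree,
    synthesize_coordinates,
)
from zpevol.trees import Tree, parse_newick, read_newick
from zpevol.connectivity import pair_distance, read_structure


class TestFamilyTree:
    def test_minimal_tree_has_no_nontrivial_bipartitions(self):
        spec = SyntheticSpec(n_subfamilies=1, n_species=3, seed=3,
                             loss_subfamilies=())
        t = simulate_family_tree(spec)
        assert t.n_tips == 3
        assert len(bipartitions(t)) == 0

    def test_tip_count_and_branch_count(self):
        spec = SyntheticSpec(n_subfamilies=4, n_species=5, seed=5,
                             loss_subfamilies=((1, "ZP-N"),))
        t = simulate_family_tree(spec)
        assert t.n_tips == 20
        assert len(bipartitions(t)) == 17  # n - 3 for a resolved unrooted tree

    def test_deterministic_newick(self):
        spec = SyntheticSpec(seed=42)
        assert simulate_family_tree(spec).to_newick() == simulate_family_tree(spec).to_newick()

    def test_subfamilies_are_clades(self):
        spec = SyntheticSpec(seed=7)
        t = simulate_family_tree(spec)
        sides = {frozenset(bp.smaller_side()) for bp in bipartitions(t)}
        for i in range(spec.n_subfamilies):
            clade = frozenset(
                nm for nm in t.tip_names() if nm.startswith(f"SF{i}_")
            )
            assert clade in sides

    def test_deep_branches_longer_on_average(self):
        spec = SyntheticSpec(n_subfamilies=8, n_species=6, seed=9,
                             loss_subfamilies=())
        t = simulate_family_tree(spec)
        deep, shallow = [], []
        for nd in t.preorder():
            if nd is t.root:
                continue
            tips = [x.name for x in Tree(nd).tips()]
            sfs = {nm.split("_")[0] for nm in tips}
            (deep if len(sfs) > 1 or (len(tips) == spec.n_species) else shallow).append(
                nd.length
            )
        assert np.mean(deep) > 2.5 * np.mean(shallow)

    def test_bad_counts_rejected(self):
        with pytest.raises(ParameterError):
            SyntheticSpec(n_subfamilies=0).validate()
        with pytest.raises(ParameterError):
            SyntheticSpec(n_species=2).validate()


class TestEvolveSequences:
    def test_zero_rate_gives_type_invariant_clones(self):
        spec = SyntheticSpec(subs_rate=0.0, seed=4)
        t = simulate_family_tree(spec)
        seqs = evolve_sequences(t, spec)
        # within one subfamily, zero substitutions means identical rows
        by_sf = {}
        for nm, s in seqs.items():
            by_sf.setdefault(nm.split("_")[0], set()).add(s)
        assert all(len(v) == 1 for v in by_sf.values())

    def test_type3_layout_columns(self):
        spec = SyntheticSpec(seed=4)
        types = spec.resolved_types()
        t = simulate_family_tree(spec)
        seqs = evolve_sequences(t, spec)
        t3 = [nm for nm in seqs if types[int(nm.split("_")[0][2:])] == "Type3"]
        assert t3
        for nm in t3:
            s = seqs[nm]
            assert s[104] == "C" and s[133] == "C" and s[139] == "C"
            assert s[205] != "C"

    def test_variable_fraction_matches_poisson_expectation(self):
        """Fraction of variable free columns vs an event-level Monte Carlo
        of the same substitution process (independent of the sequence
        machinery)."""
        realized, expected = [], []
        for seed in range(10):
            spec = SyntheticSpec(seed=seed, subs_rate=1.0)
            t = simulate_family_tree(spec)
            seqs = evolve_sequences(t, spec)
            reg = set()
            for name in DEFAULT_REGISTRY.columns:
                reg.update(DEFAULT_REGISTRY.site_columns(name))
            guard = DEFAULT_REGISTRY.tolerance + 3 + 5
            free = [
                c
                for c in range(1, spec.seq_length + 1)
                if all(abs(c - r) > guard for r in reg)
            ]
            rows = [seqs[nm] for nm in sorted(seqs)]
            var = sum(
                1 for c in free if len({r[c - 1] for r in rows}) > 1
            )
            realized.append(var / len(free))

            # oracle: per column, tips differ unless they share the same
            # residue; simulate only branch-level event indicators
            rng = np.random.default_rng(1000 + seed)
            n_cols = 4000
            branches = [
                (nd, nd.length or 0.0) for nd in t.preorder() if nd is not t.root
            ]
            var_count = 0
            for _ in range(n_cols):
                values = {}

                def walk(node, val):
                    for c in node.children:
                        v = val
                        if rng.poisson(c.length or 0.0) > 0:
                            v = rng.integers(20)
                        if c.is_tip:
                            values[c.name] = v
                        else:
                            walk(c, v)

                walk(t.root, 0)
                if len(set(values.values())) > 1:
                    var_count += 1
            expected.append(var_count / n_cols)
        assert abs(np.mean(realized) - np.mean(expected)) < 0.05


class TestDomainLoss:
    def test_noise_off_gaps_entire_interval(self):
        seqs = {"a": "A" * 100, "b": "A" * 100}
        out = plant_domain_loss(seqs, {"a"}, (1, 80), seed=0, noise=False)
        assert out["a"][:80] == "-" * 80
        assert out["b"] == "A" * 100

    def test_realized_gap_proportions_in_band(self):
        seqs = {f"s{i}": "A" * 200 for i in range(100)}
        out = plant_domain_loss(seqs, set(seqs), (1, 80), seed=1)
        for s in out.values():
            frac = s[:80].count("-") / 80
            assert 0.80 <= frac <= 0.99

    def test_empty_interval_rejected(self):
        with pytest.raises(ParameterError):
            plant_domain_loss({"a": "AAAA"}, {"a"}, (3, 2), seed=0)


class TestReplicates:
    def test_zero_jitter_gives_identical_replicates(self):
        spec = SyntheticSpec(gap_jitter_sd=0.0, seed=2)
        seqs = {"a": "AA--AA", "b": "AAAAAA", "c": "A--AAA"}
        reps = emit_replicate_alignments(seqs, spec)
        assert len(reps) == spec.n_replicates
        assert all(r.rows == reps[0].rows for r in reps)

    def test_same_names_every_replicate(self, default_bundle):
        names0 = default_bundle.replicates[0].names()
        for r in default_bundle.replicates:
            assert r.names() == names0

    def test_jitter_moves_gap_fractions_less_than_015(self):
        for seed in range(10):
            spec = SyntheticSpec(seed=seed, n_replicates=4)
            bundle_seqs = evolve_sequences(simulate_family_tree(spec), spec)
            seqs = plant_background_gaps(bundle_seqs, spec)
            reps = emit_replicate_alignments(seqs, spec)
            dms = [locate_domain_map(a) for a in reps]
            for nm in list(reps[0].names())[:5]:
                for dom in ("ZP-N", "ZP-C"):
                    base = gap_proportion(reps[0], nm, dms[0].interval(dom))
                    for a, dm in zip(reps[1:], dms[1:]):
                        v = gap_proportion(a, nm, dm.interval(dom))
                        assert abs(v - base) < 0.15


class TestCoordinates:
    def test_planted_pair_distance_remeasured_from_file(self, tmp_path):
        seq = list("A" * 240)
        for c in (105, 134, 146, 201):
            seq[c - 1] = "C"
        model, pdb_text, map_text = synthesize_coordinates(
            "".join(seq), [(105, 134)], seed=5
        )
        (tmp_path / "m.pdb").write_text(pdb_text)
        (tmp_path / "m.map.tsv").write_text(map_text)
        back = read_structure(tmp_path / "m.pdb", tmp_path / "m.map.tsv")
        d = pair_distance(back, 105, 134)
        assert 2.0 <= d <= 6.0

    def test_decoy_pairs_far_apart(self):
        seq = list("A" * 240)
        cys = (105, 134, 146, 201)
        for c in cys:
            seq[c - 1] = "C"
        model, _, _ = synthesize_coordinates("".join(seq), [], seed=6)
        for i, a in enumerate(cys):
            for b in cys[i + 1:]:
                assert pair_distance(model, a, b) >= 10.0

    def test_empty_sequence_rejected(self):
        with pytest.raises(GenerationError):
            synthesize_coordinates("----", [], seed=0)


class TestBundle:
    def test_files_written(self, default_bundle):
        d = default_bundle.path
        fastas = [f for f in os.listdir(d) if f.endswith(".fasta")]
        assert len(fastas) == default_bundle.spec.n_replicates
        assert os.path.exists(os.path.join(d, "truth.json"))
        assert os.path.exists(os.path.join(d, "true_tree.nwk"))

    def test_byte_identical_given_same_seed(self, tmp_path):
        spec = SyntheticSpec(seed=77, n_subfamilies=3, n_species=4,
                             n_replicates=3, loss_subfamilies=((0, "ZP-N"),),
                             type_assignments=((0, "Type2"), (1, "Type1"), (2, "Type3")))
        d1, d2 = tmp_path / "b1", tmp_path / "b2"
        make_fixture_bundle(spec, str(d1))
        make_fixture_bundle(spec, str(d2))
        for name in ("truth.json", "alignment_rep1.fasta", "true_tree.nwk",
                     "features.tsv"):
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes()

    def test_truth_loss_tips_match_tree_clades(self, default_bundle):
        d = default_bundle.path
        truth = json.load(open(os.path.join(d, "truth.json")))
        tree = read_newick(os.path.join(d, "true_tree.nwk"))
        loss_sfs = {sf for sf, _ in default_bundle.spec.loss_subfamilies}
        expected = {
            nm for nm in tree.tip_names() if int(nm.split("_")[0][2:]) in loss_sfs
        }
        assert set(truth["loss_tips"]) == expected

    def test_scale_regime_on_large_bundle(self, tmp_path):
        """Desk-scale rendition of the real regime: ~6-8% background
        missing data, >=0.80 gap fraction inside loss clades."""
        spec = SyntheticSpec(n_subfamilies=3, n_species=20, seed=13,
                             loss_subfamilies=((1, "ZP-N"),), n_replicates=2)
        b = make_fixture_bundle(spec, str(tmp_path / "big"), write_structures=False)
        a0 = b.replicates[0]
        bg = [
            a0.sequence(nm).count("-") / a0.n_cols
            for nm in a0.names()
            if nm not in b.truth.loss_tips
        ]
        assert abs(np.mean(bg) - 0.07) < 0.02
        for nm in b.truth.loss_tips:
            frac = a0.sequence(nm)[:80].count("-") / 80
            assert frac >= 0.78


class TestTruthConsistency:
    def test_consensus_has_c_at_invariant_registry_columns(self, default_bundle):
        from zpevol.alignment import consensus_sequence

        cons, _ = consensus_sequence(default_bundle.replicates[0])
        # Cys5/Cys6/Cys7 are invariant across every type layout
        for col in (146, 164, 201):
            assert cons[col - 1] == "C"

    def test_planted_types_recovered_from_alignment(self, default_bundle):
        from zpevol.connectivity import classify_type

        a0 = default_bundle.replicates[0]
        for nm in a0.names():
            call = classify_type(presence_vector(a0.sequence(nm)))
            assert call.type_ == default_bundle.truth.tip_types[nm]
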