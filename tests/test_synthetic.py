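"""Generators: ideal peptides, toy folds, simulated alignments, benchmark."""

import numpy as np
import pytest
from scipy.stats import chisquare

from surfcons.errors import ParameterError
from surfcons.sasa import residue_sasa, sasa_profile
from surfcons.structure_io import read_structure_text, write_pdb
from surfcons.synthetic import (
    SimAlignmentSpec,
    ToyFoldSpec,
    _min_interresidue_distance,
    balanced_tree,
    make_peptide,
    make_toy_fold,
    make_tripeptide,
    make_variant_benchmark,
    simulate_alignment,
)


class TestTripeptide:
    def test_alanine_central_residue_has_five_heavy_atoms(self):
        tri = make_tripeptide("ALA")
        central = [a for a in tri.atoms if a.residue.number == 2]
        assert len(central) == 5  # N CA C O CB

    def test_deterministic_coordinates(self):
        a = make_tripeptide("GLY", -120, 120)
        b = make_tripeptide("GLY", -120, 120)
        assert np.array_equal(a.coords, b.coords)

    def test_peptide_bond_lengths_ideal(self):
        pep = make_peptide(["ALA"] * 4)
        by_res = {}
        for a in pep.atoms:
            by_res.setdefault(a.residue.number, {})[a.name] = np.array(a.coords)
        for i in range(1, 4):
            d = np.linalg.norm(by_res[i]["C"] - by_res[i + 1]["N"])
            assert d == pytest.approx(1.329, abs=0.01)

    def test_exposed_in_tripeptide_vs_buried_in_fold(self):
        tri_sasa = residue_sasa(make_tripeptide("ALA"))
        central = next(v for rid, v in tri_sasa.items() if rid.number == 2)
        fold, labels = make_toy_fold(ToyFoldSpec(n_residues=20, seed=7))
        fold_sasa = residue_sasa(fold)
        buried_rid = next(rid for rid, lab in labels.items() if lab == "buried")
        assert central > fold_sasa[buried_rid]

    def test_nonstandard_residue_rejected(self):
        with pytest.raises(Exception):
            make_tripeptide("XXX")


class TestToyFold:
    def test_compact_shell_center_buried_engine_agrees(self):
        st, labels = make_toy_fold(ToyFoldSpec(n_residues=20, seed=7))
        prof = sasa_profile(st).set_index("residue_seq")
        rels = {rid: prof.loc[rid.number, "rel_sasa_pct"] for rid in labels}
        buried = [rid for rid, lab in labels.items() if lab == "buried"]
        exposed = [rid for rid, lab in labels.items() if lab == "exposed"]
        assert len(buried) == 1
        assert rels[buried[0]] < 5.0
        assert max(rels[r] for r in exposed) > 50.0
        assert all(rels[r] >= 5.0 for r in exposed)

    def test_extended_mode_all_exposed(self):
        st, labels = make_toy_fold(
            ToyFoldSpec(n_residues=10, packing="extended", seed=0)
        )
        prof = sasa_profile(st)
        assert (prof.rel_sasa_pct > 20.0).all()
        assert set(labels.values()) == {"exposed"}

    def test_clash_light(self):
        st, _ = make_toy_fold(ToyFoldSpec(n_residues=20, seed=3))
        assert _min_interresidue_distance(st.atoms) >= 2.0

    def test_seeded_determinism(self):
        a, _ = make_toy_fold(ToyFoldSpec(n_residues=16, seed=5))
        b, _ = make_toy_fold(ToyFoldSpec(n_residues=16, seed=5))
        assert np.array_equal(a.coords, b.coords)

    def test_too_small_shell_rejected(self):
        with pytest.raises(ParameterError):
            make_toy_fold(ToyFoldSpec(n_residues=4))

    def test_generated_pdb_rereads_losslessly(self):
        st, _ = make_toy_fold(ToyFoldSpec(n_residues=12, seed=1))
        again = read_structure_text(write_pdb(st), st.id)
        assert len(again) == len(st)
        assert np.allclose(again.coords, st.coords, atol=1.5e-3)


class TestAlignmentSimulation:
    def test_zero_rate_gives_invariant_columns(self):
        tree = balanced_tree(8, 0.5)
        msa, _ = simulate_alignment(
            SimAlignmentSpec(tree=tree, n_sites=10,
                             site_rates=np.zeros(10), seed=4)
        )
        for j in range(10):
            assert len(set(msa.column(j))) == 1

    def test_seeded_determinism(self):
        tree = balanced_tree(8)
        spec = SimAlignmentSpec(tree=tree, n_sites=50, site_rates=("gamma", 1.0),
                                seed=9)
        a, ra = simulate_alignment(spec)
        b, rb = simulate_alignment(spec)
        assert a.codes.tolist() == b.codes.tolist()
        assert np.array_equal(ra, rb)

    def test_shape_matches_spec(self):
        tree = balanced_tree(16)
        msa, rates = simulate_alignment(SimAlignmentSpec(tree=tree, n_sites=33,
                                                         seed=0))
        assert msa.n_sequences == 16 and msa.length == 33
        assert rates.shape == (33,)

    def test_saturating_rate_approaches_stationary_frequencies(self):
        # very fast sites on a deep tree: residue usage ~ uniform
        tree = balanced_tree(8, 0.5)
        msa, _ = simulate_alignment(
            SimAlignmentSpec(tree=tree, n_sites=500,
                             site_rates=np.full(500, 100.0), seed=6)
        )
        counts = np.bincount(msa.codes.ravel(), minlength=20)
        stat = chisquare(counts)
        assert stat.pvalue > 0.01

    def test_flux_symmetry_on_long_branches(self):
        # reversibility diagnostic: parent->child substitution flux between
        # any residue pair is symmetric within Monte-Carlo error
        tree = balanced_tree(4, 1.0)
        msa, _ = simulate_alignment(
            SimAlignmentSpec(tree=tree, n_sites=4000, seed=8)
        )
        a = msa.row(msa.ids[0])
        b = msa.row(msa.ids[1])
        flux = np.zeros((20, 20))
        for x, y in zip(a, b):
            flux[x, y] += 1
        asym = np.abs(flux - flux.T).sum() / flux.sum()
        assert asym < 0.35  # MC-level asymmetry only


class TestBenchmark:
    def test_group_sizes_default_to_published_design(self, benchmark):
        counts = benchmark.variants.group.value_counts()
        assert counts["hpa"] == 17
        assert counts["disease"] == 13
        assert counts["neutral"] == 8

    def test_truth_table_consistent_with_burial_design(self, benchmark):
        truth = benchmark.truth.set_index("id")
        variants = benchmark.variants.set_index("id")
        assert set(truth.index) == set(variants.index)
        disease = truth[variants.group == "disease"]
        assert (disease.true_exposure == "buried").all()
        assert (disease.true_rate == 0.1).all()
        hpa = truth[variants.group == "hpa"]
        assert (hpa.true_exposure == "exposed").all()
        assert (hpa.true_rate == 3.0).all()
        neutral = truth[variants.group == "neutral"]
        assert set(neutral.true_exposure) == {"buried", "exposed"}
        assert set(neutral.true_rate) == {0.1, 3.0}

    def test_seeded_determinism(self):
        a = make_variant_benchmark(seed=2)
        b = make_variant_benchmark(seed=2)
        assert a.variants.equals(b.variants)
        assert a.msa.codes.tolist() == b.msa.codes.tolist()
        sid = sorted(a.structures)[0]
        assert np.array_equal(a.structures[sid].coords, b.structures[sid].coords)
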