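"""Decoy generation: enumeration vs brute force, filters, builds, extraction."""

import itertools

import numpy as np
import pytest

import foldbench as fb
from foldbench.decoygen import (
    BuildError,
    CaModel,
    assign_sse_from_ca,
    has_loop_crossing,
    is_right_handed,
        read_ca_pdb,
    write_ca_pdb,
)
from foldbench.topology import TopologyError, _canonical_tuples

from conftest import build_fold_model, random_rotation


# ---------------------------------------------------------------------------
# independent enumeration oracle: raw product over every assignment, no
# gauge pruning, sharing only the filter predicates and canonical form

def oracle_enumerate(form, n_helices, n_strands):
    from foldbench.decoygen import _passes_filters

    m = n_helices + n_strands
    helix_slots = [("A", i) for i in range(form.n_a)] + [
        ("C", i) for i in range(form.n_c)
    ]
    found = set()
    for w0 in range(form.n_b - n_strands + 1):  # contiguous sheet window
        for helix_at in itertools.combinations(range(m), n_helices):
            for sperm in itertools.permutations(range(n_strands)):
                for sdirs in itertools.product((1, -1), repeat=n_strands):
                    for hslots in itertools.permutations(helix_slots, n_helices):
                        for hdirs in itertools.product((1, -1), repeat=n_helices):
                            elems = []
                            si = hi = 0
                            for k in range(m):
                                if k in helix_at:
                                    layer, slot = hslots[hi]
                                    elems.append((layer, slot, hdirs[hi]))
                                    hi += 1
                                else:
                                    elems.append(("B", w0 + sperm[si], sdirs[si]))
                                    si += 1
                            t = tuple(elems)
                            if _passes_filters(t, form):
                                found.add(_canonical_tuples(t))
    return found


class TestEnumeration:
    def test_single_strand_single_fold(self, form131):
        folds = fb.enumerate_folds(form131, 0, 1)
        assert [str(t) for t in folds] == ["+B+0"]

    def test_capacity_errors(self, form131):
        with pytest.raises(ValueError, match="capacity"):
            fb.enumerate_folds(form131, 0, 4)
        with pytest.raises(ValueError, match="capacity"):
            fb.enumerate_folds(form131, 3, 2)

    @pytest.mark.parametrize(
        "form_sizes,h,s",
        [((1, 3, 1), 2, 3), ((1, 3, 1), 1, 3), ((1, 2, 1), 2, 2), ((2, 3, 0), 1, 3)],
    )
    def test_matches_brute_force_oracle(self, form_sizes, h, s):
        form = fb.Form(*form_sizes)
        folds = {ts._tuples() for ts in fb.enumerate_folds(form, h, s)}
        assert folds == oracle_enumerate(form, h, s)

    def test_deterministic_lexicographic_order(self, form131):
        a = fb.enumerate_folds(form131, 1, 3)
        b = fb.enumerate_folds(form131, 1, 3)
        assert [str(t) for t in a] == [str(t) for t in b]
        assert [str(t) for t in a] == sorted(str(t) for t in a)

    def test_enumerated_folds_pass_filters(self, folds131, form131):
        for ts in folds131[:100]:
            n_pairs = ts.n_strands - 1
            assert all(is_right_handed(ts, i) for i in range(n_pairs))
            assert not has_loop_crossing(ts, form131)


class TestFilters:
    def test_right_handed_beta_alpha_beta(self):
        # classic unit: parallel strands with the crossover helix above
        ts = fb.parse_topology("+B+0 +A+0 +B+1")
        assert is_right_handed(ts, 0)

    def test_mirror_image_left_handed(self):
        ts = fb.parse_topology("+B+0 +C+0 +B+1")  # helix below: mirror image
        assert not is_right_handed(ts, 0)

    def test_hairpin_unconstrained(self):
        ts = fb.parse_topology("+B+0 -B+1")
        assert is_right_handed(ts, 0)

    def test_crossover_direction_symmetry(self):
        # rotating the whole frame preserves chirality
        assert not is_right_handed(fb.parse_topology("+B+1 +A+0 +B+0"), 0)
        assert is_right_handed(fb.parse_topology("-B+1 +A+0 -B+0"), 0)

    def test_nested_loops_do_not_cross(self):
        # two hairpins at the same sheet end, one inside the other's span
        ts = fb.parse_topology("+B+0 -B+3 +B+1 -B+2")
        assert not has_loop_crossing(ts)

    def test_interleaved_crossovers_cross(self):
        # two parallel crossovers over the top face with strictly
        # interleaved spans [0,10] and [5,15]
        ts = fb.parse_topology("+B+0 +B+2 +B+1 +B+3")
        assert has_loop_crossing(ts)

    def test_interleaved_hairpins_cross(self):
        # two hairpin connections at the same sheet end, spans [0,10], [5,15]
        ts = fb.parse_topology("+B+0 -B+2 +B+1 -B+3")
        assert has_loop_crossing(ts)

    def test_sequential_meander_does_not_cross(self):
        ts = fb.parse_topology("+B+0 -B+1 +B+2 -B+3")
        assert not has_loop_crossing(ts)

    def test_opposite_faces_never_cross(self):
        # bottom-face spans [10,15] and [5,10] touch, top spans are nested:
        # nothing on a shared face strictly interleaves
        ts = fb.parse_topology("+B+0 +A+0 +B+2 -B+3 +C+1 -B+1")
        assert not has_loop_crossing(ts)


class TestBuild:
    def test_determinism(self, rossmann_like, form252):
        ts, model = rossmann_like
        again = build_fold_model(ts, form252, seed=3)
        assert np.array_equal(model.coords, again.coords)

    def test_different_seed_differs(self, rossmann_like, form252):
        ts, model = rossmann_like
        other = build_fold_model(ts, form252, seed=4)
        assert not np.array_equal(model.coords, other.coords)

    def test_bond_lengths_within_limits(self, rossmann_like):
        _, model = rossmann_like
        bl = model.bond_lengths()
        assert bl.min() >= 3.6 and bl.max() <= 4.0

    def test_annotation_chain_order(self, rossmann_like):
        _, model = rossmann_like
        idx = model.element_index[model.element_index >= 0]
        assert np.array_equal(np.unique(idx), np.arange(model.n_elements))
        # element order equals chain order
        first_res = [model.element_residues(k)[0] for k in range(model.n_elements)]
        assert first_res == sorted(first_res)

    def test_loop_infeasible_error(self, form252):
        ts = fb.parse_topology("+B+0 +A+0 -B+1").canonical()
        lengths = [5, 8, 5]
        with pytest.raises(BuildError, match="infeasible"):
            fb.build_ca_model(ts, lengths, [1, 1], seed=0, form=form252)

    def test_length_validation(self, form131):
        ts = fb.parse_topology("+B+0 -B+1")
        with pytest.raises(ValueError):
            fb.build_ca_model(ts, [2, 5], [4], seed=0, form=form131)
        with pytest.raises(ValueError):
            fb.build_ca_model(ts, [5, 5], [20], seed=0, form=form131)
        with pytest.raises(ValueError):
            fb.build_ca_model(ts, [5], [4], seed=0, form=form131)


class TestExtraction:
    def test_round_trip_sample(self, folds131, form131):
        for i, ts in enumerate(folds131[::37]):
            model = build_fold_model(ts, form131, seed=10 + i)
            assert fb.same_fold(fb.extract_topology(model), ts)

    def test_rigid_motion_invariance(self, rossmann_like):
        ts, model = rossmann_like
        rng = np.random.default_rng(5)
        for _ in range(20):
            R = random_rotation(rng)
            shift = rng.normal(scale=30.0, size=3)
            moved = CaModel(
                coords=model.coords @ R.T + shift,
                element_index=model.element_index,
                element_kind=model.element_kind,
            )
            assert fb.same_fold(fb.extract_topology(moved), ts)

    def test_mirror_changes_chiral_fold(self, rossmann_like):
        ts, model = rossmann_like
        mirrored = CaModel(
            coords=model.coords * np.array([1.0, 1.0, -1.0]),
            element_index=model.element_index,
            element_kind=model.element_kind,
        )
        assert not fb.same_fold(fb.extract_topology(mirrored), ts)

    def test_no_strands_error(self):
        rng = np.random.default_rng(0)
        n = 10
        model = CaModel(
            coords=np.cumsum(rng.normal(size=(n, 3)), axis=0) * 2,
            element_index=np.zeros(n, int),
            element_kind=np.full(n, "H"),
        )
        with pytest.raises(TopologyError, match="no sheet layer"):
            fb.extract_topology(model)

    def test_helix_slot_gap_preserved(self, form252):
        # two helices separated by an empty slot on the same layer
        ts = fb.parse_topology("+B+0 +A+0 -B+1 +A+2 +B+2").canonical()
        model = build_fold_model(ts, fb.Form(3, 5, 3), seed=7)
        assert fb.same_fold(fb.extract_topology(model), ts)


class TestPdbIO:
    def test_write_read_round_trip(self, rossmann_like, tmp_path):
        ts, model = rossmann_like
        path = tmp_path / "decoy.pdb"
        write_ca_pdb(model, path)
        back = read_ca_pdb(path)
        assert len(back) == len(model)
        assert np.allclose(back.coords, model.coords, atol=1e-3)
        side = path.with_name(path.name + ".topology.txt")
        assert side.exists()
        assert fb.parse_topology(side.read_text().splitlines()[0]) == ts

    def test_heuristic_sse_assignment(self, rossmann_like):
        ts, model = rossmann_like
        stripped = CaModel(
            coords=model.coords,
            element_index=np.full(len(model), -1),
            element_kind=np.full(len(model), "-"),
        )
        ann = assign_sse_from_ca(stripped)
        # the heuristic recovers most element residues with the right kind
        true_sse = model.element_kind != "-"
        agree = (ann.element_kind == model.element_kind)[true_sse].mean()
        assert agree > 0.7
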