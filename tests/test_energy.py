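"""SASA engine and atomic-solvation-parameter stabilization energies."""

import numpy as np
import pytest

from fibrilkit.energy import (
    DEFAULT_ASP,
    SolvationParameterSet,
    build_extended_chain,
    calibration_scale,
    chain_sasa,
    compute_sasa,
    energy_map_values,
    reference_sasa,
    stabilization_energy,
    subunit_decomposition,
)
from fibrilkit.structure_io import AtomRecord, FibrilModel, ResidueSpan
from fibrilkit.synthetic import IdealFibrilSpec, make_ideal_fibril


def _atom(x, y, z, element="C", name="CA", res=1, chain="A", radius=1.7):
    return AtomRecord(element, name, res, "ALA", chain, np.array([x, y, z]), radius)


def _two_sphere_areas(r1, r2, d, probe):
    """Exact accessible areas of two overlapping probe-expanded spheres."""
    R1, R2 = r1 + probe, r2 + probe
    if d >= R1 + R2:
        return 4 * np.pi * R1**2, 4 * np.pi * R2**2
    # spherical cap heights from the intersection plane
    x = (d**2 - R2**2 + R1**2) / (2 * d)
    h1 = R1 - x
    h2 = R2 - (d - x)
    return (
        4 * np.pi * R1**2 - 2 * np.pi * R1 * h1,
        4 * np.pi * R2**2 - 2 * np.pi * R2 * h2,
    )


class TestSasa:
    def test_single_atom_closed_form(self):
        model = FibrilModel(atoms=[_atom(0, 0, 0)])
        res = compute_sasa(model, probe=1.4, n_points=960)
        assert res.total == pytest.approx(4 * np.pi * 3.1**2, rel=0.005)

    @pytest.mark.parametrize("d", [1.0, 2.5, 4.0, 5.5])
    def test_two_spheres_match_cap_formula(self, d):
        model = FibrilModel(atoms=[_atom(0, 0, 0), _atom(d, 0, 0, radius=1.5)])
        res = compute_sasa(model, probe=1.4, n_points=4000)
        exact = _two_sphere_areas(1.7, 1.5, d, 1.4)
        full = [4 * np.pi * 3.1**2, 4 * np.pi * 2.9**2]
        for got, want, scale in zip(res.areas, exact, full):
            assert abs(got - want) < 0.01 * scale

    def test_enclosed_atom_zero_area(self):
        # cage of atoms on a small sphere around the center
        from fibrilkit.energy import _golden_spiral

        cage = [_atom(*(2.0 * p), res=i + 2) for i, p in enumerate(_golden_spiral(60))]
        model = FibrilModel(atoms=[_atom(0, 0, 0)] + cage)
        res = compute_sasa(model)
        assert res.areas[0] == 0.0

    def test_duplicate_atoms_rejected(self):
        model = FibrilModel(atoms=[_atom(0, 0, 0), _atom(0, 0, 0, res=2)])
        with pytest.raises(ValueError, match="duplicate"):
            compute_sasa(model)

    def test_rigid_motion_invariance(self, ubend_stack):
        from scipy.spatial.transform import Rotation

        model, _ = ubend_stack
        res0 = compute_sasa(model)
        R = Rotation.from_euler("xyz", [15, 30, 45], degrees=True).as_matrix()
        res1 = compute_sasa(model.transformed(R, np.array([2.0, 2.0, 2.0])))
        # deterministic point set rotates with nothing: areas shift only by
        # quadrature sensitivity to orientation, bounded well below 1%
        assert res1.total == pytest.approx(res0.total, rel=0.01)

    def test_total_decreases_as_layers_added(self):
        totals = []
        for n_layers in (1, 3, 5):
            spec = IdealFibrilSpec(
                sequence="A" * 16, n_layers=n_layers, template="U_bend"
            )
            model, _ = make_ideal_fibril(spec)
            central = model.central_chain()
            res = compute_sasa(model)
            areas, _ = chain_sasa(res, central)
            totals.append(areas.sum())
        # adding the first neighbours buries >50% of the chain surface;
        # further layers cannot increase it beyond quadrature error (0.5%)
        assert totals[1] < 0.5 * totals[0]
        assert totals[2] <= totals[1] * 1.005

    def test_cross_check_against_biotite(self, mixed_sequence_stack, tmp_path):
        """Independent SASA oracle with identical radii and probe."""
        biotite_sasa = pytest.importorskip("biotite.structure").sasa
        import biotite.structure.io.pdbx as pdbx
        from fibrilkit.structure_io import write_structure

        model, _ = mixed_sequence_stack
        path = tmp_path / "stack.cif"
        write_structure(model, path)
        cif = pdbx.CIFFile.read(str(path))
        arr = pdbx.get_structure(cif, model=1)
        radii = np.array([{"C": 1.87, "N": 1.50, "O": 1.40, "S": 1.85}[e] for e in arr.element])
        ref = biotite_sasa(arr, probe_radius=1.4, vdw_radii=radii, point_number=960)
        ours = compute_sasa(model, probe=1.4, n_points=960)
        assert ours.total == pytest.approx(float(np.nansum(ref)), rel=0.01)


class TestReferenceStates:
    def test_isolated_reference_is_identity_for_single_chain(self):
        spec = IdealFibrilSpec(sequence="AQNYV" * 3, n_layers=1, template="U_bend")
        model, _ = make_ideal_fibril(spec)
        iso = reference_sasa(model, "A", "isolated_chain")
        direct = compute_sasa(model)
        assert np.allclose(iso.areas, direct.areas)

    def test_extended_polyala_interior_residues_uniform(self):
        spec = IdealFibrilSpec(sequence="A" * 10, n_layers=1, template="linear")
        model, _ = make_ideal_fibril(spec)
        ext = build_extended_chain(model, "A")
        res = compute_sasa(ext)
        per_res = {}
        for a, area in zip(res.atoms, res.areas):
            per_res[a.residue_index] = per_res.get(a.residue_index, 0.0) + area
        interior = [per_res[i] for i in range(3, 9)]
        assert (max(interior) - min(interior)) / np.mean(interior) < 0.02

    def test_extended_chain_has_ideal_bonds(self, mixed_sequence_stack):
        model, _ = mixed_sequence_stack
        ext = build_extended_chain(model, "A")
        co = {(a.residue_index, a.atom_name): a.coords for a in ext.atoms}
        for i in range(1, 40):
            assert np.linalg.norm(co[(i, "CA")] - co[(i, "N")]) == pytest.approx(1.458, abs=1e-6)
            assert np.linalg.norm(co[(i, "C")] - co[(i, "CA")]) == pytest.approx(1.525, abs=1e-6)
            if (i + 1, "N") in co:
                assert np.linalg.norm(co[(i + 1, "N")] - co[(i, "C")]) == pytest.approx(1.329, abs=1e-6)

    def test_reference_dominates_fibril_context(self, ubend_stack):
        """Burial monotonicity: isolation never decreases any atom's area."""
        model, _ = ubend_stack
        central = model.central_chain()
        fib = compute_sasa(model)
        a_fib, _ = chain_sasa(fib, central)
        a_iso = reference_sasa(model, central, "isolated_chain").areas
        assert np.all(a_iso - a_fib > -1e-9)


class TestStabilizationEnergy:
    def test_packed_stack_is_stabilizing(self, mixed_sequence_stack):
        model, _ = mixed_sequence_stack
        profile = stabilization_energy(model)
        assert profile.dg_per_chain < 0
        assert profile.context_layers == 7

    def test_per_residue_sums_to_chain_total(self, mixed_sequence_stack):
        model, _ = mixed_sequence_stack
        profile = stabilization_energy(model)
        assert sum(profile.per_residue.values()) == pytest.approx(
            profile.dg_per_chain, abs=1e-6
        )
        n = len(profile.per_residue)
        assert profile.dg_per_residue_mean * n == pytest.approx(
            profile.dg_per_chain, abs=0.05
        )

    def test_no_contact_stack_gives_zero_vs_isolated_reference(self):
        """Layers too far apart to touch: fibril SASA equals the isolated
        reference atom-by-atom, so the stabilization energy is exactly 0."""
        spec = IdealFibrilSpec(
            sequence="A" * 12, rise=100.0, twist=0.0, n_layers=5, template="U_bend"
        )
        model, _ = make_ideal_fibril(spec)
        params = SolvationParameterSet(reference_state="isolated_chain")
        profile = stabilization_energy(model, None, params)
        assert profile.dg_per_chain == pytest.approx(0.0, abs=1e-9)

    def test_polyala_contact_matches_hand_computed_burial(self):
        """Two flat poly-Ala layers: dG = ASP_C x (-buried carbon area)."""
        spec = IdealFibrilSpec(sequence="A" * 12, n_layers=5, template="U_bend")
        model, _ = make_ideal_fibril(spec)
        central = model.central_chain()
        params = SolvationParameterSet(reference_state="isolated_chain")
        profile = stabilization_energy(model, central, params)
        fib = compute_sasa(model)
        a_fib, atoms = chain_sasa(fib, central)
        a_iso = reference_sasa(model, central, "isolated_chain").areas
        by_class = {}
        for a, d in zip(atoms, a_fib - a_iso):
            by_class.setdefault(params.asp_for(a), 0.0)
            by_class[params.asp_for(a)] += d
        expected = sum(asp * total for asp, total in by_class.items())
        assert profile.dg_per_chain == pytest.approx(expected, abs=1e-9)
        # all-ala layers bury mostly carbon: stabilization must be negative
        assert profile.dg_per_chain < 0

    def test_edge_chain_without_symmetry_rejected(self, ubend_stack):
        model, _ = ubend_stack
        bare = FibrilModel(atoms=list(model.atoms), layers=list(model.layers))
        with pytest.raises(ValueError, match="edge"):
            stabilization_energy(bare, bare.layers[0])

    def test_short_stack_extended_by_helical_symmetry(self, ubend_stack):
        model, _ = ubend_stack
        two = FibrilModel(
            atoms=[a for a in model.atoms if a.chain_id in model.layers[:2]],
            layers=model.layers[:2],
            helical=model.helical,
        )
        profile = stabilization_energy(two, two.layers[0])
        assert profile.context_layers == 5
        full = stabilization_energy(model)
        assert profile.dg_per_chain == pytest.approx(full.dg_per_chain, rel=0.05)


class TestSubunits:
    def test_in_context_decomposition_is_additive(self, mixed_sequence_stack):
        model, _ = mixed_sequence_stack
        spans = [ResidueSpan(1, 20, "subunit 1"), ResidueSpan(21, 40, "subunit 2")]
        dec = subunit_decomposition(model, None, spans)
        total = stabilization_energy(model).dg_per_chain
        assert sum(dec.values()) == pytest.approx(total, abs=1e-6)

    def test_whole_chain_span_equals_total(self, mixed_sequence_stack):
        model, _ = mixed_sequence_stack
        dec = subunit_decomposition(model, None, [ResidueSpan(1, 40, "all")])
        assert dec["all"] == pytest.approx(
            stabilization_energy(model).dg_per_chain, abs=1e-6
        )

    def test_alone_not_more_stabilizing_than_in_context(self, mixed_sequence_stack):
        model, _ = mixed_sequence_stack
        spans = [ResidueSpan(1, 20, "s1"), ResidueSpan(21, 40, "s2")]
        ctx = subunit_decomposition(model, None, spans, mode="in_context")
        alone = subunit_decomposition(model, None, spans, mode="alone")
        # removing the partner subunit removes stabilizing contacts
        assert alone["s1"] >= ctx["s1"] - 0.5

    def test_non_partition_rejected(self, mixed_sequence_stack):
        model, _ = mixed_sequence_stack
        with pytest.raises(ValueError, match="partition"):
            subunit_decomposition(model, None, [ResidueSpan(1, 10)])


class TestDisplayAndCalibration:
    def test_energy_map_clipping_and_monotonicity(self, mixed_sequence_stack):
        model, _ = mixed_sequence_stack
        profile = stabilization_energy(model)
        vals = energy_map_values(profile)
        assert all(-2.5 <= v <= 2.5 for v in vals.values())
        raw = [profile.per_residue[r] for r in sorted(profile.per_residue)]
        clipped = [vals[r] for r in sorted(vals)]
        order = np.argsort(raw)
        assert np.all(np.diff(np.array(clipped)[order]) >= -1e-12)

    def test_clipping_endpoints(self):
        from fibrilkit.energy import StabilityProfile

        prof = StabilityProfile(
            dg_per_chain=-4.0,
            dg_per_residue_mean=-4.0,
            per_residue={1: -4.0, 2: 0.0, 3: 3.0},
            buried_area_per_atom=np.zeros(1),
            atoms=(),
            context_layers=5,
            chain="A",
            params=DEFAULT_ASP,
        )
        vals = energy_map_values(prof)
        assert vals == {1: -2.5, 2: 0.0, 3: 2.5}

    def test_calibration_scale_recovers_known_factor(self):
        computed = {"a": -10.0, "b": -20.0, "c": 3.0}
        reference = {k: 1.7 * v for k, v in computed.items()}
        assert calibration_scale(computed, reference) == pytest.approx(1.7)
        scaled = DEFAULT_ASP.scaled(1.7)
        assert scaled.apolar_carbon == pytest.approx(0.016 * 1.7)

    def test_parameter_sign_invariants_enforced(self):
        with pytest.raises(ValueError):
            SolvationParameterSet(apolar_carbon=-0.01)
        with pytest.raises(ValueError):
            SolvationParameterSet(charged_n=0.05)
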