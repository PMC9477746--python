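"""Conformational metrics: oracles from constructed geometry and generator ground truth."""

import numpy as np
import pytest

import ruvmotor as rm
from conftest import DNA_CHAINS, RUVA_CHAINS, make_decomps, random_rigid_transform
from ruvmotor.decomposition import MotorDecomposition
from ruvmotor.errors import MetricError
from ruvmotor.metrics import (
    angle_triplet,
    displacement_field,
    dna_contact_spacing,
    domain_rmsd_stats,
    gate_distance,
    lever_lift,
    motor_rotation,
    trajectory_length,
    variability_map,
)
from ruvmotor.structure_io import Atom, StructureModel
from ruvmotor.synthetic import hinge_axis, rotation_about_axis


def _shift_chain(model, chain, delta, new_id=None):
    atoms = [Atom(a.chain_id, a.res_num, a.res_name, a.atom_name, a.element,
                  a.pos + delta if a.chain_id == chain else a.pos,
                  a.hetero, a.occupancy)
             for a in model.atoms]
    return StructureModel(new_id or model.model_id, atoms)


# ---------------------------------------------------------------------------
# angle triplets


def test_collinear_domain_centroids_give_triangle_180():
    """Constructed subunit whose three triangle-range centroids are collinear."""
    centers = {"L": np.array([0.0, 0, 0]), "S": np.array([0.0, 0, 10]),
               "H": np.array([0.0, 0, 20])}
    spread = {"L": np.array([0.1, 0, 0]), "S": np.array([0, 0.1, 0]),
              "H": np.array([0.1, 0.1, 0])}
    ranges = {"L": (20, 180), "S": (181, 256), "H": (257, 325)}
    atoms = []
    for res in range(1, 331):
        dom = next((d for d, (lo, hi) in ranges.items() if lo <= res <= hi), None)
        if dom is None:
            atoms.append(Atom("A", res, "ALA", "CA", "C", centers["L"].copy()))
            continue
        lo, hi = ranges[dom]
        i, n = res - lo, hi - lo + 1
        # arithmetic offsets sum to zero: range centroid is exactly the centre
        atoms.append(Atom("A", res, "ALA", "CA", "C",
                          centers[dom] + spread[dom] * (i - (n - 1) / 2)))
    t = angle_triplet(StructureModel("collinear", atoms), "A")
    assert np.isclose(t.triangle, 180.0, atol=1e-9)


def test_head_rotation_about_d2_hinge_changes_d2_only(canonical_series):
    """Generator ground truth: +5 deg about the d2 torsion axis moves d2 by 5."""
    point, direction = hinge_axis("d2")
    pose = rotation_about_axis(point, direction, 5.0)
    spec = rm.SyntheticAssemblySpec(domain_poses={(1, "E", "H"): pose})
    models, _ = rm.build_motor_series(spec, 2)
    t0 = angle_triplet(models[0], "E")
    t1 = angle_triplet(models[1], "E")
    assert abs(abs(t1.d2 - t0.d2) - 5.0) < 0.1
    assert abs(t1.d1 - t0.d1) < 0.1


def test_angle_triplet_reports_missing_anchors(canonical_series):
    models, _, _ = canonical_series
    pruned = StructureModel("pruned", [a for a in models[0].atoms
                                       if not (a.chain_id == "A" and a.res_num == 36)])
    with pytest.raises((MetricError, Exception), match="36"):
        angle_triplet(pruned, "A")


def test_angle_triplet_invariant_under_rigid_transform(canonical_series):
    models, _, _ = canonical_series
    rng = np.random.default_rng(3)
    t0 = angle_triplet(models[0], "B")
    moved = models[0].transformed(random_rigid_transform(rng))
    t1 = angle_triplet(moved, "B")
    assert np.allclose([t0.d1, t0.d2, t0.triangle],
                       [t1.d1, t1.d2, t1.triangle], atol=1e-6)


# ---------------------------------------------------------------------------
# variability map


def test_variability_zero_for_identical_models(canonical_series):
    models, decomps, _ = canonical_series
    vm = variability_map([models[0]] * 3, [decomps[0]] * 3)
    assert vm.table["stddev"].max() < 1e-9


def test_variability_two_state_translation_closed_form(canonical_series):
    """One subunit translated 2 A: affected residues sit 1 A from their centroid."""
    models, decomps, _ = canonical_series
    moved = _shift_chain(models[0], "F", np.array([2.0, 0, 0]), "moved")
    vm = variability_map([models[0], moved], [decomps[0], decomps[0]])
    t = vm.table
    f_rows = t[t.subunit == "F"]
    other = t[t.subunit != "F"]
    assert np.allclose(f_rows["stddev"], 1.0, atol=1e-9)
    assert other["stddev"].max() < 1e-9


def test_variability_under_isotropic_noise_matches_chi_expectation(canonical_series):
    """Mean map value matches sigma/sqrt(n) * E[chi_{3(n-1)}] within MC error.

    The alignment-reference subunit C is left noise-free so the superposition
    is exactly the identity and the distances-to-centroid follow the chi
    distribution with 3(n-1) degrees of freedom without alignment leakage.
    """
    from scipy.special import gammaln

    models, decomps, _ = canonical_series
    sigma, n = 0.3, 4
    rng = np.random.default_rng(123)
    noisy, decs = [], []
    for k in range(n):
        atoms = [Atom(a.chain_id, a.res_num, a.res_name, a.atom_name, a.element,
                      a.pos if a.chain_id == "C" else a.pos + rng.normal(0, sigma, 3),
                      a.hetero, a.occupancy)
                 for a in models[0].atoms]
        noisy.append(StructureModel(f"n{k}", atoms))
        decs.append(decomps[0])
    vm = variability_map(noisy, decs, reference_subunit="C")
    dof = 3 * (n - 1)
    e_chi = np.sqrt(2) * np.exp(gammaln((dof + 1) / 2) - gammaln(dof / 2))
    expected = sigma / np.sqrt(n) * e_chi
    scored = vm.table[vm.table.subunit != "C"]
    observed = scored["stddev"].mean()
    # MC standard error of the mean over ~1550 residues is ~0.003
    assert abs(observed - expected) < 0.01
    assert vm.table[vm.table.subunit == "C"]["stddev"].max() < 1e-9


def test_variability_needs_two_states(canonical_series):
    models, decomps, _ = canonical_series
    with pytest.raises(MetricError):
        variability_map(models[:1], decomps[:1])


# ---------------------------------------------------------------------------
# domain RMSD statistics


def test_domain_rmsd_zero_for_congruent_instances(canonical_series):
    models, decomps, _ = canonical_series
    mean, mat = domain_rmsd_stats(models[:2], decomps[:2], "L")
    assert mean < 1e-9
    assert np.all(mat.to_numpy() < 1e-9)


def test_domain_rmsd_radial_scaling_closed_form(canonical_series):
    """Scaling a domain about its centroid by (1+e) gives RMSD e * rms_radius.

    The cross-covariance of the pair is symmetric positive definite, so the
    optimal rotation is the identity and the residual has a closed form.
    """
    models, decomps, _ = canonical_series
    m0 = models[0]
    ca = m0.ca_map("A", (21, 181))
    pts = np.array(list(ca.values()))
    c = pts.mean(axis=0)
    rms_radius = np.sqrt(((pts - c) ** 2).sum(axis=1).mean())
    eps = 1.5 / rms_radius
    atoms = [Atom(a.chain_id, a.res_num, a.res_name, a.atom_name, a.element,
                  c + (1 + eps) * (a.pos - c)
                  if (a.chain_id == "A" and a.atom_name == "CA"
                      and 21 <= a.res_num <= 181) else a.pos,
                  a.hetero, a.occupancy)
             for a in m0.atoms]
    scaled = StructureModel("scaled", atoms)
    from conftest import make_decomps

    decs = make_decomps([m0, scaled])
    _, mat = domain_rmsd_stats([m0, scaled], decs, "L")
    assert np.isclose(mat.loc["s1:A", "scaled:A"], 1.5, atol=1e-6)
    assert mat.loc["s1:B", "scaled:B"] < 1e-9


# ---------------------------------------------------------------------------
# displacement fields


def test_displacement_state_vs_itself_is_empty(canonical_series):
    models, decomps, _ = canonical_series
    f = displacement_field(models[0], models[0], decomps[0], decomps[0])
    assert len(f.vectors) == 0


def test_displacement_filter_threshold(canonical_series):
    models, decomps, _ = canonical_series
    moved = _shift_chain(models[0], "F", np.array([0.5, 0, 0]))
    f = displacement_field(models[0], moved, decomps[0], decomps[0],
                           filter_threshold=1.0)
    assert len(f.vectors) == 0  # 0.5 A vectors are below the 1 A filter
    f2 = displacement_field(models[0], moved, decomps[0], decomps[0],
                            filter_threshold=0.3)
    assert set(f2.vectors.subunit) == {"F"}
    assert np.allclose(f2.vectors.magnitude, 0.5, atol=1e-9)


def test_displacement_recovers_programmed_motion_and_ignores_render_scale():
    spec = rm.SyntheticAssemblySpec(trajectory_step_E=3.0,
                                    trajectory_direction=(1.0, 0.0, 0.0))
    models, _ = rm.build_motor_series(spec, 2)
    decs = make_decomps(models)
    f1 = displacement_field(models[0], models[1], decs[0], decs[1], "C",
                            render_scale=2.5)
    f2 = displacement_field(models[0], models[1], decs[0], decs[1], "C",
                            render_scale=10.0)
    assert set(f1.vectors.subunit) == {"E"}
    assert np.allclose(f1.vectors[["dx", "dy", "dz"]], [3.0, 0.0, 0.0], atol=1e-9)
    assert np.allclose(f1.vectors.magnitude, f2.vectors.magnitude)


def test_displacement_invariants_on_stored_magnitudes(canonical_series):
    models, decomps, _ = canonical_series
    moved = _shift_chain(models[0], "E", np.array([0, 2.5, 0]))
    f = displacement_field(models[0], moved, decomps[0], decomps[0],
                           filter_threshold=1.0)
    assert (f.magnitudes > f.filter_threshold).all()


# ---------------------------------------------------------------------------
# trajectory / lever / rotation


def test_trajectory_zero_for_stationary_cluster(canonical_series):
    models, decomps, _ = canonical_series
    path, net, direction = trajectory_length(models, decomps)
    assert path < 1e-9 and net < 1e-9 and direction is None


def test_trajectory_recovers_programmed_step(trajectory_series):
    models, decomps, gt = trajectory_series
    path, net, direction = trajectory_length(models, decomps, "[E]", "C")
    assert np.isclose(path, 7.0, atol=1e-6)
    assert np.isclose(net, 7.0, atol=1e-6)
    # programmed direction points toward the junction core (negative height)
    assert direction @ np.array(gt.trajectory_direction) > 0.999


def test_lever_zero_for_identical_states(canonical_series):
    models, decomps, _ = canonical_series
    rep = lever_lift(models, decomps)
    assert abs(rep.dna_lift) < 1e-6
    assert max(abs(v) for v in rep.per_subunit.values()) < 1e-6


def test_lever_recovers_programmed_lift(lever_series):
    models, decomps, gt = lever_series
    rep = lever_lift(models, decomps, reference_subunit="E", probe="dna")
    assert np.isclose(rep.dna_lift, gt.total_lift, atol=1e-4)
    for s in "ABCD":
        assert np.isclose(rep.per_subunit[s], gt.total_lift, atol=1e-4)
    for s in "EF":
        assert abs(rep.per_subunit[s]) < 1e-4
    # head-interface probe rides with the DNA
    rep2 = lever_lift(models, decomps, probe="head-interface")
    assert np.isclose(rep2.dna_lift, gt.total_lift, atol=1e-4)


def test_motor_rotation_zero_and_programmed_sixty():
    spec = rm.SyntheticAssemblySpec()
    m0, m1, gt = rm.build_rotation_pair(spec, 60.0)
    d0, d1 = make_decomps([m0, m1])
    same = motor_rotation(m0, m0, d0, d0, ("R",))
    assert abs(same.degrees) < 1e-9 and not same.warning
    res = motor_rotation(m0, m1, d0, d1, ("R",))
    assert abs(abs(res.degrees) - 60.0) < 0.5
    assert res.core_rmsd < 1e-9


def test_ideal_hexamer_consecutive_spacing_is_sixty(canonical_series):
    from ruvmotor.decomposition import DEFAULT_DOMAINS, _large_centroids, hexamer_axis
    from ruvmotor.geometry import angular_positions

    models, _, _ = canonical_series
    chains = list("ABCDEF")
    center, axis = hexamer_axis(models[0], chains, DNA_CHAINS)
    cents = _large_centroids(models[0], chains, DEFAULT_DOMAINS)
    az = np.sort(angular_positions(np.array([cents[c] for c in chains]), center, axis))
    spacings = np.diff(np.concatenate([az, [az[0] + 360]]))
    assert np.isclose(spacings.mean(), 60.0, atol=1e-9)


# ---------------------------------------------------------------------------
# gate distance


def _dummy_decomp(chain_map):
    return MotorDecomposition(
        state_label="t", subunits=chain_map,
        clusters={s: f"[{s}]" for s in "ABCDEF"},
        occupancy={s: "apo" for s in "ABCDEF"},
        dna_engaged={s: False for s in "ABCDEF"},
    )


def test_gate_distance_constructed_pocket():
    atoms = [
        Atom("a", 21, "ARG", "CZ", "C", np.zeros(3)),
        Atom("f", 128, "GLU", "CD", "C", np.array([9.0, 0, 0])),
    ]
    m = StructureModel("gate", atoms)
    dec = _dummy_decomp({"A": "a", "B": "b", "C": "c", "D": "d", "E": "e", "F": "f"})
    g = gate_distance(m, dec, "A")
    assert np.isclose(g.distance, 9.0)
    assert g.trans_subunit == "F" and not g.fallback_used


def test_gate_distance_ca_fallback_is_flagged():
    atoms = [
        Atom("a", 21, "ARG", "CA", "C", np.zeros(3)),
        Atom("f", 128, "GLU", "CA", "C", np.array([4.0, 3.0, 0])),
    ]
    m = StructureModel("gate", atoms)
    dec = _dummy_decomp({"A": "a", "B": "b", "C": "c", "D": "d", "E": "e", "F": "f"})
    g = gate_distance(m, dec, "A")
    assert np.isclose(g.distance, 5.0) and g.fallback_used


def test_gate_distance_rigid_invariance(canonical_series):
    models, decomps, _ = canonical_series
    rng = np.random.default_rng(9)
    g0 = gate_distance(models[0], decomps[0], "A")
    moved = models[0].transformed(random_rigid_transform(rng))
    g1 = gate_distance(moved, decomps[0], "A")
    assert np.isclose(g0.distance, g1.distance, atol=1e-6)


# ---------------------------------------------------------------------------
# DNA contacts


def test_contact_spacing_matches_programmed_staircase():
    """7 A staircase at 3.5 A/nt: contacts every 2 nt, one strand only."""
    spec = rm.SyntheticAssemblySpec(helical_rise=3.5)
    models, gt = rm.build_motor_series(spec, 1)
    dec = make_decomps(models)[0]
    rep = dna_contact_spacing(models[0], dec)
    assert np.isclose(rep.mean_axial_spacing, 7.0, atol=0.05)
    assert set(rep.contacts.strand) == {"X"}
    per_sub = rep.contacts.groupby("subunit")["nucleotide"].agg(
        lambda s: sorted(set(s))[0])
    assert per_sub["A"] - per_sub["B"] == 2
    assert per_sub["B"] - per_sub["C"] == 2
    assert per_sub["C"] - per_sub["D"] == 2
    assert {s: (gt.contacts[s][1] if s in gt.contacts else None)
            for s in "ABCD"} == per_sub.to_dict()
    # disengaged subunits have no contacts
    assert not set(rep.contacts.subunit) & {"E", "F"}


def test_contact_spacing_errors_without_contacts(canonical_series):
    models, decomps, _ = canonical_series
    with pytest.raises(MetricError, match="cutoff"):
        dna_contact_spacing(models[0], decomps[0], cutoff=0.5)


# ---------------------------------------------------------------------------
# joint rigid-transform invariance


def test_metrics_invariant_under_common_rigid_transform(lever_series):
    models, decomps, _ = lever_series
    rng = np.random.default_rng(77)
    tr = random_rigid_transform(rng)
    moved = [m.transformed(tr) for m in models]
    rep0 = lever_lift(models, decomps)
    rep1 = lever_lift(moved, decomps)
    assert np.isclose(rep0.dna_lift, rep1.dna_lift, atol=1e-6)
    p0, n0, _ = trajectory_length(models, decomps)
    p1, n1, _ = trajectory_length(moved, decomps)
    assert np.isclose(p0, p1, atol=1e-6) and np.isclose(n0, n1, atol=1e-6)
    c0 = dna_contact_spacing(models[0], decomps[0]).mean_axial_spacing
    c1 = dna_contact_spacing(moved[0], decomps[0]).mean_axial_spacing
    assert np.isclose(c0, c1, atol=1e-6)
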