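"""Coarse-grained synthetic motor/DNA assembly generator with ground truth.

The generator emulates the geometry that the analysis modules consume: an
ideal B-form DNA duplex represented by backbone-phosphorus and base-centroid
pseudo-atoms, and a hexamer of six rigid three-domain subunits (large/small/
head, one pseudo-C-alpha per residue) arranged as a four-subunit spiral
staircase (A-D, engaging one DNA strand every two nucleotides) closed by two
substrate-disengaged subunits (E, F).  Multi-state series carry programmable
whole-interface lifts, a programmable trajectory of subunit E, per-domain
rigid poses and seeded isotropic Gaussian coordinate noise — each recorded in
a :class:`GroundTruth` object before noise is applied, so every downstream
metric can be checked against what was injected.

The representation is deliberately coarse: the metrics only consume
C-alpha/phosphorus-level geometry, so side chains are reduced to a handful of
named pseudo-atoms (arginine NH1 contact atoms, the Arg21/Glu128 gate pair)
and nucleotide ligands to single pseudo-atoms with authentic chemical
component codes (AGS/ADP/MG).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import yaml

from .errors import RuvmotorError
from .geometry import RigidTransform, centroid
from .metrics import D1_POINT_GROUPS, D2_POINT_GROUPS
from .structure_io import Atom, StructureModel, write_pdb

__all__ = [
    "SyntheticAssemblySpec",
    "GroundTruth",
    "build_ideal_bdna",
    "build_motor_series",
    "build_rotation_pair",
    "write_fixture_set",
    "subunit_template",
    "hinge_axis",
    "rotation_about_axis",
    "CYCLE_OCCUPANCY_PATTERNS",
]

SUBUNITS = ("A", "B", "C", "D", "E", "F")
ENGAGED = ("A", "B", "C", "D")
DNA_ARGININES = (291, 310, 312, 315)

#: Nucleotide occupancy of subunits A-F through the five processive states,
#: as resolved in the deposited motor series (s1..s5).
CYCLE_OCCUPANCY_PATTERNS = (
    {"A": "ATP", "B": "ATP", "C": "ATP", "D": "ADP", "E": "ADP", "F": "ADP"},  # s1
    {"A": "ATP", "B": "ATP", "C": "ATP", "D": "apo", "E": "ADP", "F": "ADP"},  # s2
    {"A": "ADP_Mg", "B": "ATP", "C": "ATP", "D": "apo", "E": "ADP", "F": "ADP"},  # s3
    {"A": "ADP", "B": "ATP", "C": "ATP", "D": "apo", "E": "ADP", "F": "ADP"},  # s4
    {"A": "ADP", "B": "ATP", "C": "ATP", "D": "ATP", "E": "ADP", "F": "ADP"},  # s5
)


# ---------------------------------------------------------------------------
# subunit template (shared by every subunit, state and spec: domains are rigid)

_DOMAIN_CENTERS = {"L": np.array([0.0, 0.0, 10.0]),
                   "S": np.array([0.0, 0.0, -2.0]),
                   "H": np.array([10.0, 0.0, -10.0])}  # +x points into the pore

_D1_ANCHORS = D1_POINT_GROUPS
_D2_ANCHORS = D2_POINT_GROUPS


def _domain_of(res_num: int) -> str:
    if res_num <= 181:
        return "L"  # residues 1-20 (N terminus, gate region) ride with the large domain
    if res_num <= 254:
        return "S"
    return "H"


def _build_template() -> dict[int, np.ndarray]:
    """One pseudo-C-alpha per residue 1..330, fixed for the whole package."""
    rng = np.random.default_rng(20220824)
    template: dict[int, np.ndarray] = {}
    for res in range(1, 331):
        c = _DOMAIN_CENTERS[_domain_of(res)]
        template[res] = c + rng.uniform(-4.5, 4.5, size=3)
    return template


_TEMPLATE = _build_template()

_SPECIAL_RESNAMES = {21: "ARG", 65: "LYS", 128: "GLU",
                     291: "ARG", 310: "ARG", 312: "ARG", 315: "ARG"}

# side-chain pseudo-atoms for the nucleotide gate (fixed local offsets)
_GATE_ATOMS = {(21, "CZ"): np.array([1.2, 0.8, 0.5]),
               (128, "CD"): np.array([1.0, -0.6, 0.4])}

# nucleotide ligand pseudo-atom site, relative to the Walker-A Lys65 C-alpha
_LIGAND_OFFSET = np.array([3.0, 2.0, 0.0])
_MG_OFFSET = np.array([0.0, 0.0, 2.5])


def subunit_template() -> dict[int, np.ndarray]:
    """Local-frame pseudo-C-alpha coordinates of the subunit template (copy)."""
    return {r: p.copy() for r, p in _TEMPLATE.items()}


def _anchor_centroid(resnums: Sequence[int]) -> np.ndarray:
    return centroid([_TEMPLATE[r] for r in resnums])


def hinge_axis(which: str) -> tuple[np.ndarray, np.ndarray]:
    """Axis (point, unit direction) of the d1 or d2 torsion in the template frame.

    Rotating a domain about the returned axis changes the corresponding
    dihedral by exactly the rotation angle, which is what the ground-truth
    angle tests exploit.
    """
    if which == "d1":
        p2, p3 = _anchor_centroid(_D1_ANCHORS[1]), _anchor_centroid(_D1_ANCHORS[2])
    elif which == "d2":
        p2, p3 = _anchor_centroid(_D2_ANCHORS[1]), _anchor_centroid(_D2_ANCHORS[2])
    else:
        raise RuvmotorError(f"unknown hinge {which!r}; expected 'd1' or 'd2'")
    d = p3 - p2
    return p2, d / np.linalg.norm(d)


def rotation_about_axis(point, direction, angle_deg: float) -> RigidTransform:
    """Rigid rotation by ``angle_deg`` about the axis through ``point`` along ``direction``."""
    from scipy.spatial.transform import Rotation

    u = np.asarray(direction, dtype=float)
    u = u / np.linalg.norm(u)
    R = Rotation.from_rotvec(np.radians(angle_deg) * u).as_matrix()
    p = np.asarray(point, dtype=float)
    return RigidTransform(R, p - R @ p)


def _rz(angle_deg: float) -> np.ndarray:
    a = np.radians(angle_deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


# ---------------------------------------------------------------------------
# specs & ground truth


@dataclass
class SyntheticAssemblySpec:
    """Parameters of a synthetic assembly series.

    Defaults are the study conditions: canonical B-DNA fibre helix (3.4 A
    rise, 36 deg twist), a 7 A staircase rise (two-nucleotide spacing), 60 deg
    subunit spacing, contacts every second nucleotide on one strand.
    """

    n_bp: int = 40
    helical_rise: float = 3.4       # A per bp
    helical_twist: float = 36.0     # deg per bp
    backbone_radius: float = 1.0    # A; thin-helix coarse backbone (see docs)
    base_radius: float = 0.5
    ring_radius: float = 32.0       # A, subunit placement radius
    staircase_rise: float = 7.0     # A per engaged subunit
    subunit_angular_spacing: float = 60.0  # deg
    contact_period_nt: int = 2
    first_contact_nt: int = 5       # strand-X nucleotide contacted by subunit D
    lift_per_transition: float = 0.0        # A, DNA + staircase, along +axis
    trajectory_step_E: float = 0.0          # A per transition, subunit E
    trajectory_direction: tuple[float, float, float] = (0.0, 0.0, -1.0)
    domain_poses: dict = field(default_factory=dict)
    # {(state_index, subunit, domain): RigidTransform in the template frame}
    occupancy_patterns: Optional[Sequence[Mapping[str, str]]] = None
    ruva_d3_counts: Optional[Sequence[int]] = None  # per state, 0..2
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_bp < 4:
            raise RuvmotorError("n_bp must be >= 4")
        if self.noise_sigma < 0:
            raise RuvmotorError("noise_sigma must be >= 0")
        if not (2.0 <= self.helical_rise <= 4.0):
            raise RuvmotorError(f"helical rise {self.helical_rise} out of sane bounds 2-4 A")
        if not (20.0 <= self.helical_twist <= 45.0):
            raise RuvmotorError(f"helical twist {self.helical_twist} out of bounds 20-45 deg")
        if self.contact_period_nt < 1:
            raise RuvmotorError("contact_period_nt must be >= 1")


@dataclass
class GroundTruth:
    """Everything programmed into a synthetic series, recorded before noise."""

    subunit_chains: dict[str, str]
    clusters: dict[str, str]
    engaged: tuple[str, ...]
    contacts: dict[str, tuple[str, int]]  # subunit -> (dna chain, nucleotide index)
    occupancy_patterns: tuple[dict[str, str], ...]
    ruva_d3_counts: tuple[int, ...]
    lift_per_transition: float = 0.0
    total_lift: float = 0.0
    trajectory_step: float = 0.0
    trajectory_total: float = 0.0
    trajectory_direction: tuple[float, float, float] = (0.0, 0.0, -1.0)
    rotation_deg: float = 0.0
    domain_poses: dict = field(default_factory=dict)
    placements: dict = field(default_factory=dict)  # (state, subunit) -> RigidTransform
    helix: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# ideal B-DNA


def build_ideal_bdna(
    n_bp: int = 40,
    rise: float = 3.4,
    twist: float = 36.0,
    seed: int = 0,
    backbone_radius: float = 1.0,
    base_radius: float = 0.5,
    chain_ids: tuple[str, str] = ("X", "Y"),
) -> tuple[StructureModel, GroundTruth]:
    """Ideal duplex: P + base-centroid pseudo-atoms on two antiparallel strands.

    Strand ``X`` ascends the helix axis (+z) with nucleotide i at azimuth
    ``i * twist`` and height ``i * rise``; strand ``Y`` is its antiparallel
    complement at a fixed 140 deg azimuthal offset.  The builder is fully
    deterministic; ``seed`` is accepted for interface uniformity.
    """
    spec = SyntheticAssemblySpec(n_bp=n_bp, helical_rise=rise, helical_twist=twist,
                                 backbone_radius=backbone_radius, base_radius=base_radius,
                                 seed=seed)
    atoms = _dna_atoms(spec, chain_ids)
    model = StructureModel("ideal_bdna", atoms)
    gt = GroundTruth(
        subunit_chains={}, clusters={}, engaged=(), contacts={},
        occupancy_patterns=(), ruva_d3_counts=(),
        helix={"rise": rise, "twist": twist, "radius": backbone_radius, "n_bp": n_bp},
    )
    return model, gt


def _dna_atoms(spec: SyntheticAssemblySpec, chain_ids=("X", "Y")) -> list[Atom]:
    cx, cy = chain_ids
    atoms: list[Atom] = []

    def helix_pos(i: int, radius: float, azimuth_offset: float) -> np.ndarray:
        phi = np.radians(i * spec.helical_twist + azimuth_offset)
        return np.array([radius * np.cos(phi), radius * np.sin(phi), i * spec.helical_rise])

    for i in range(spec.n_bp):  # strand X: residues 1..n ascending z
        res = i + 1
        atoms.append(Atom(cx, res, "DA", "P", "P", helix_pos(i, spec.backbone_radius, 0.0)))
        atoms.append(Atom(cx, res, "DA", "C1'", "C", helix_pos(i, spec.base_radius, 60.0)))
    for j in range(spec.n_bp):  # strand Y: residue j pairs with X residue n-j
        res = j + 1
        i = spec.n_bp - 1 - j
        atoms.append(Atom(cy, res, "DT", "P", "P", helix_pos(i, spec.backbone_radius, 140.0)))
        atoms.append(Atom(cy, res, "DT", "C1'", "C", helix_pos(i, spec.base_radius, 200.0)))
    return atoms


# ---------------------------------------------------------------------------
# motor series


def _contact_nt(spec: SyntheticAssemblySpec) -> dict[str, int]:
    """Strand-X nucleotide index contacted by each engaged subunit (A at the top)."""
    p = spec.contact_period_nt
    i0 = spec.first_contact_nt
    return {"D": i0, "C": i0 + p, "B": i0 + 2 * p, "A": i0 + 3 * p}


def _strand_x_phosphate(spec: SyntheticAssemblySpec, nt: int) -> np.ndarray:
    phi = np.radians((nt - 1) * spec.helical_twist)
    return np.array([spec.backbone_radius * np.cos(phi),
                     spec.backbone_radius * np.sin(phi),
                     (nt - 1) * spec.helical_rise])


def _subunit_heights(spec: SyntheticAssemblySpec) -> dict[str, float]:
    contacts = _contact_nt(spec)
    z = {s: (contacts[s] - 1) * spec.helical_rise for s in ENGAGED}
    # staircase_rise sets the protein-frame spacing; contacts follow the DNA
    h = {s: z["D"] + i * spec.staircase_rise
         for i, s in zip((3, 2, 1, 0), ("A", "B", "C", "D"))}
    h["E"] = h["D"] - spec.staircase_rise / 2.0
    h["F"] = h["A"] + spec.staircase_rise / 2.0
    return h


def _placement(spec: SyntheticAssemblySpec, subunit: str) -> RigidTransform:
    k = SUBUNITS.index(subunit)
    theta = k * spec.subunit_angular_spacing
    h = _subunit_heights(spec)[subunit]
    R = _rz(theta + 180.0)  # template +x then points inward, toward the pore
    p = np.array([spec.ring_radius * np.cos(np.radians(theta)),
                  spec.ring_radius * np.sin(np.radians(theta)), h])
    return RigidTransform(R, p)


def _state_shift(spec: SyntheticAssemblySpec, state_idx: int, subunit: str) -> np.ndarray:
    """Programmed whole-body translation of a subunit in a given state."""
    if subunit == "E":
        d = np.asarray(spec.trajectory_direction, dtype=float)
        n = np.linalg.norm(d)
        if n < 1e-12:
            raise RuvmotorError("trajectory_direction must be nonzero")
        return state_idx * spec.trajectory_step_E * (d / n)
    if subunit in ENGAGED:
        return np.array([0.0, 0.0, state_idx * spec.lift_per_transition])
    return np.zeros(3)


def _assemble_state(
    spec: SyntheticAssemblySpec,
    state_idx: int,
    occupancy: Mapping[str, str],
    n_d3: int,
    placements_out: Optional[dict] = None,
    motor_rotation_deg: float = 0.0,
) -> list[Atom]:
    atoms: list[Atom] = []
    dna_shift = np.array([0.0, 0.0, state_idx * spec.lift_per_transition])
    for a in _dna_atoms(spec):
        atoms.append(Atom(a.chain_id, a.res_num, a.res_name, a.atom_name,
                          a.element, a.pos + dna_shift))

    contacts = _contact_nt(spec)
    rot = _rz(motor_rotation_deg)  # optional whole-motor rotation about the pore axis
    for subunit in SUBUNITS:
        base = _placement(spec, subunit)
        shift = _state_shift(spec, state_idx, subunit)
        place = RigidTransform(rot @ base.rotation, rot @ (base.translation) + shift)
        if placements_out is not None:
            placements_out[(state_idx, subunit)] = place

        def local_to_global(x_local: np.ndarray, domain: str) -> np.ndarray:
            pose = spec.domain_poses.get((state_idx, subunit, domain))
            if pose is not None:
                x_local = pose.apply(x_local[None, :])[0]
            return place.apply(x_local[None, :])[0]

        for res, p_local in _TEMPLATE.items():
            dom = _domain_of(res)
            name = _SPECIAL_RESNAMES.get(res, "ALA")
            atoms.append(Atom(subunit, res, name, "CA", "C", local_to_global(p_local, dom)))
        for (res, aname), off in _GATE_ATOMS.items():
            atoms.append(Atom(subunit, res, _SPECIAL_RESNAMES[res], aname, "C",
                              local_to_global(_TEMPLATE[res] + off, _domain_of(res))))
        # DNA-contact pseudo-atoms (engaged subunits): arginine NH1 placed
        # 3 A radially outward of the contacted strand-X phosphate
        if subunit in ENGAGED:
            nt = contacts[subunit]
            ppos = _strand_x_phosphate(spec, nt) + dna_shift
            radial = np.array([ppos[0], ppos[1], 0.0])
            nr = np.linalg.norm(radial)
            radial = radial / nr if nr > 1e-9 else np.array([1.0, 0.0, 0.0])
            for j, arg in enumerate(DNA_ARGININES):
                off = np.array([0.0, 0.0, 0.25 * (j - 1.5)])
                atoms.append(Atom(subunit, arg, "ARG", "NH1", "N", ppos + 3.0 * radial + off))
        # nucleotide ligand pseudo-atoms in the pocket next to Walker-A Lys65
        occ = occupancy.get(subunit, "apo")
        if occ not in ("ATP", "ADP", "ADP_Mg", "apo"):
            raise RuvmotorError(f"unknown occupancy {occ!r} for subunit {subunit}")
        if occ != "apo":
            site = local_to_global(_TEMPLATE[65] + _LIGAND_OFFSET, "L")
            code = "AGS" if occ == "ATP" else "ADP"
            atoms.append(Atom(subunit, 401, code, "PA", "P", site, hetero=True))
            if occ in ("ATP", "ADP_Mg"):
                atoms.append(Atom(subunit, 402, "MG", "MG", "MG", site + _MG_OFFSET,
                                  hetero=True))

    # RuvA domain-III pseudo-domains docked on subunits D (first) and E (second)
    for chain, host in (("U", "D"), ("V", "E"))[:n_d3]:
        place = _placement(spec, host)
        shift = _state_shift(spec, state_idx, host)
        anchor = rot @ (place.apply(_TEMPLATE[100][None, :])[0]) + shift
        outward = rot @ np.array([np.cos(np.radians(SUBUNITS.index(host) * spec.subunit_angular_spacing)),
                                  np.sin(np.radians(SUBUNITS.index(host) * spec.subunit_angular_spacing)), 0.0])
        center = anchor + 4.0 * outward
        for r in range(1, 6):
            off = np.array([0.6 * (r - 3), 0.4 * ((r % 2) - 0.5), 0.5 * (r - 3)])
            atoms.append(Atom(chain, r, "ALA", "CA", "C", center + off))
    return atoms


def _apply_noise(models: list[StructureModel], sigma: float, seed: int) -> list[StructureModel]:
    if sigma == 0:
        return models
    rng = np.random.default_rng(seed)
    noisy = []
    for m in models:
        noise = rng.normal(0.0, sigma, size=(len(m.atoms), 3))
        atoms = [Atom(a.chain_id, a.res_num, a.res_name, a.atom_name, a.element,
                      a.pos + noise[i], a.hetero, a.occupancy)
                 for i, a in enumerate(m.atoms)]
        noisy.append(StructureModel(m.model_id, atoms))
    return noisy


def build_motor_series(
    spec: SyntheticAssemblySpec, n_states: int = 5
) -> tuple[list[StructureModel], GroundTruth]:
    """Generate ``n_states`` assemblies with cumulative programmed motions."""
    if n_states < 1:
        raise RuvmotorError("n_states must be >= 1")
    if spec.occupancy_patterns is not None:
        if len(spec.occupancy_patterns) != n_states:
            raise RuvmotorError(
                f"occupancy_patterns has {len(spec.occupancy_patterns)} entries "
                f"for {n_states} states"
            )
        patterns = [dict(p) for p in spec.occupancy_patterns]
    else:
        patterns = [dict(CYCLE_OCCUPANCY_PATTERNS[min(t, 4)]) for t in range(n_states)]
    if spec.ruva_d3_counts is not None:
        if len(spec.ruva_d3_counts) != n_states:
            raise RuvmotorError("ruva_d3_counts length must equal n_states")
        d3 = list(spec.ruva_d3_counts)
    else:
        d3 = [1] + [2] * (n_states - 1)  # one tether in s1, two from s2 on
    for (t, s, dom) in spec.domain_poses:
        if not (0 <= t < n_states) or s not in SUBUNITS or dom not in ("L", "S", "H"):
            raise RuvmotorError(f"inconsistent domain pose key {(t, s, dom)!r}")

    placements: dict = {}
    models = [
        StructureModel(f"s{t + 1}", _assemble_state(spec, t, patterns[t], d3[t], placements))
        for t in range(n_states)
    ]
    models = _apply_noise(models, spec.noise_sigma, spec.seed)
    contacts = _contact_nt(spec)
    gt = GroundTruth(
        subunit_chains={s: s for s in SUBUNITS},
        clusters={s: f"[{s}]" for s in SUBUNITS},
        engaged=ENGAGED,
        contacts={s: ("X", contacts[s]) for s in ENGAGED},
        occupancy_patterns=tuple(patterns),
        ruva_d3_counts=tuple(d3),
        lift_per_transition=spec.lift_per_transition,
        total_lift=(n_states - 1) * spec.lift_per_transition,
        trajectory_step=spec.trajectory_step_E,
        trajectory_total=(n_states - 1) * spec.trajectory_step_E,
        trajectory_direction=spec.trajectory_direction,
        domain_poses=dict(spec.domain_poses),
        placements=placements,
        helix={"rise": spec.helical_rise, "twist": spec.helical_twist,
               "radius": spec.backbone_radius, "n_bp": spec.n_bp},
    )
    return models, gt


def _core_reference_atoms(spec: SyntheticAssemblySpec, chain: str = "R") -> list:
    """A wide pseudo-domain standing in for the RuvA-junction core.

    The core sits below the motor on the junction side and is azimuthally
    extended, so superposing on it constrains rotation about the pore axis
    well (a thin DNA helix alone does not).
    """
    z0 = _subunit_heights(spec)["E"] - 2.0 * spec.staircase_rise
    atoms = []
    res = 1
    for level in (0.0, -4.0):
        for k in range(18):
            phi = np.radians(20.0 * k + 5.0 * (level != 0.0))
            pos = np.array([24.0 * np.cos(phi), 24.0 * np.sin(phi), z0 + level])
            atoms.append(Atom(chain, res, "ALA", "CA", "C", pos))
            res += 1
    return atoms


def build_rotation_pair(
    spec: SyntheticAssemblySpec, angle_deg: float = 60.0
) -> tuple[StructureModel, StructureModel, GroundTruth]:
    """A canonical state and a copy whose motor is rotated about the pore axis.

    Both states share a fixed core-reference pseudo-domain (chain ``R``,
    emulating the junction core) and the DNA; only the motor chains rotate.
    """
    pattern = dict(CYCLE_OCCUPANCY_PATTERNS[0])
    placements: dict = {}
    core = _core_reference_atoms(spec)
    m0 = StructureModel("unrotated",
                        _assemble_state(spec, 0, pattern, 2, placements) + core)
    m1 = StructureModel("rotated",
                        _assemble_state(spec, 0, pattern, 2, None,
                                        motor_rotation_deg=angle_deg) + core)
    m0, m1 = _apply_noise([m0, m1], spec.noise_sigma, spec.seed)
    contacts = _contact_nt(spec)
    gt = GroundTruth(
        subunit_chains={s: s for s in SUBUNITS},
        clusters={s: f"[{s}]" for s in SUBUNITS},
        engaged=ENGAGED,
        contacts={s: ("X", contacts[s]) for s in ENGAGED},
        occupancy_patterns=(pattern,),
        ruva_d3_counts=(2,),
        rotation_deg=angle_deg,
        placements=placements,
    )
    return m0, m1, gt


# ---------------------------------------------------------------------------
# fixture sets on disk


def write_fixture_set(
    spec: SyntheticAssemblySpec | Sequence[SyntheticAssemblySpec],
    out_dir: str | Path,
    n_states: int = 5,
):
    """Write a state series as PDB files plus a manifest and ground-truth table.

    Returns the manifest path (or a list of paths when given several specs,
    each written into its own subdirectory).
    """
    if isinstance(spec, (list, tuple)):
        return [write_fixture_set(s, Path(out_dir) / f"set{i}", n_states)
                for i, s in enumerate(spec)]
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise RuvmotorError(f"fixture directory not writable: {out_dir}: {exc}") from exc

    models, gt = build_motor_series(spec, n_states)
    entries = []
    for m in models:
        pdb_path = out_dir / f"{m.model_id}.pdb"
        write_pdb(m, pdb_path)
        entries.append({
            "state": m.model_id,
            "file": pdb_path.name,
            "subunits": {s: s for s in SUBUNITS},
            "dna_chains": ["X", "Y"],
            "ruva_d3_chains": ["U", "V"],
        })
    manifest_path = out_dir / "manifest.yaml"
    manifest_path.write_text(yaml.safe_dump({"states": entries}, sort_keys=False))

    lines = ["# synthetic ground truth (programmed values, before noise)",
             f"# lift_per_transition_A\t{gt.lift_per_transition}",
             f"# total_lift_A\t{gt.total_lift}",
             f"# trajectory_step_A\t{gt.trajectory_step}",
             f"# trajectory_total_A\t{gt.trajectory_total}",
             f"# noise_sigma_A\t{spec.noise_sigma}",
             f"# seed\t{spec.seed}",
             "state\tsubunit\tchain\tcluster\toccupancy\truva_d3_count\tcontact_strand\tcontact_nt"]
    for t, m in enumerate(models):
        for s in SUBUNITS:
            strand, nt = gt.contacts.get(s, ("-", -1))
            lines.append("\t".join([
                m.model_id, s, s, gt.clusters[s], gt.occupancy_patterns[t][s],
                str(gt.ruva_d3_counts[t]), strand, str(nt),
            ]))
    (out_dir / "ground_truth.tsv").write_text("\n".join(lines) + "\n")
    return manifest_path
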