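"""Quantitative conformational metrics across motor states.

Implements the state-to-state analyses of the hexameric branch-migration
motor: per-subunit angle triplets (two inter-domain dihedrals d1/d2 plus a
domain-centroid triangle angle), per-residue variability maps, all-pairs
domain RMSD statistics, displacement fields between aligned states, the
trajectory of the flexible cluster-[E] subunit, the Arg21-Glu128 nucleotide
gate distance, the lever lift of the DNA-binding interface, whole-motor
rotation about the pore axis, and the arginine-phosphate DNA contact
spacing.

Every metric is built from relative geometry only and is therefore invariant
under a common rigid transform of its inputs.  All angles are in degrees,
all distances in Angstrom.

Angle constructions
-------------------
The inter-domain dihedrals are computed over four sub-centroids obtained by
a fixed split of each domain's anchor-residue list:

* d1 (large vs small): (c{36,73,80,174}, c{55,155,170,94,121}) in the large
  domain against (c{249,227}, c{209,196}) in the small domain;
* d2 (small vs head): (c{249,227}, c{209,196}) against (c{282,284,265},
  c{306,263}) in the head.

The triangle angle is measured at the small-domain centroid — the middle
domain connecting large and head — between the directions to the large- and
head-domain centroids, so it captures large/head scissoring about the hinge.
Absolute angle values depend on these documented constructions; analyses of
angle differences (dynamic ranges) are robust to any consistent choice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .decomposition import (
    DEFAULT_DOMAINS,
    DomainDefinition,
    MotorDecomposition,
    head_dna_contacts,
    hexamer_axis,
    _large_centroids,
)
from .errors import MetricError
from .geometry import (
    RigidTransform,
    angular_positions,
    centroid,
    dihedral,
    kabsch_superpose,
    vertex_angle,
)
from .structure_io import StructureModel

__all__ = [
    "AngleTriplet",
    "VariabilityMap",
    "DisplacementField",
    "LeverReport",
    "GateDistance",
    "RotationResult",
    "ContactReport",
    "D1_POINT_GROUPS",
    "D2_POINT_GROUPS",
    "angle_triplet",
    "angle_triplet_table",
    "variability_map",
    "domain_rmsd_stats",
    "displacement_field",
    "write_bild",
    "trajectory_length",
    "gate_distance",
    "lever_lift",
    "motor_rotation",
    "dna_contact_spacing",
]

#: Fixed split of the printed anchor-residue lists into dihedral sub-centroids.
D1_POINT_GROUPS = ((36, 73, 80, 174), (55, 155, 170, 94, 121), (249, 227), (209, 196))
D2_POINT_GROUPS = ((249, 227), (209, 196), (282, 284, 265), (306, 263))

#: cis subunit -> trans neighbour forming its nucleotide pocket
#: (the pocket of subunit A interfaces in trans with subunit F).
TRANS_NEIGHBOUR = {"A": "F", "B": "A", "C": "B", "D": "C", "E": "D", "F": "E"}


# ---------------------------------------------------------------------------
# result containers


@dataclass(frozen=True)
class AngleTriplet:
    d1: float          # degrees, large vs small domain torsion
    d2: float          # degrees, small vs head domain torsion
    triangle: float    # degrees, at the small-domain centroid
    subunit: str = ""
    state: str = ""


@dataclass
class VariabilityMap:
    """Per-residue positional spread across aligned states.

    ``stddev`` is the root-mean-square distance of each C-alpha from its
    per-residue centroid over all models (the standard deviation of the
    atom's position about its mean), after superposing every model on the
    alignment-reference subunit.
    """

    table: pd.DataFrame  # columns: subunit, residue, stddev
    alignment_reference: str

    def mean(self) -> float:
        return float(self.table["stddev"].mean())

    def per_subunit_mean(self) -> pd.Series:
        return self.table.groupby("subunit")["stddev"].mean()


@dataclass
class DisplacementField:
    vectors: pd.DataFrame  # subunit, residue, sx..sz (start), dx..dz, magnitude
    transition: str
    filter_threshold: Optional[float]
    render_scale: float = 2.5
    subsample: int = 2

    @property
    def magnitudes(self) -> np.ndarray:
        return self.vectors["magnitude"].to_numpy()


@dataclass
class GateDistance:
    distance: float
    cis_subunit: str
    trans_subunit: str
    fallback_used: bool = False  # True when side chains were unmodelled (CA-CA)


@dataclass
class LeverReport:
    per_subunit: dict[str, float]  # signed lift along the motor axis, Angstrom
    dna_lift: float
    alignment_reference: str
    axis: np.ndarray


@dataclass
class RotationResult:
    degrees: float
    core_rmsd: float
    warning: bool = False  # core superposition RMSD above the sanity bound


@dataclass
class ContactReport:
    contacts: pd.DataFrame  # subunit, arginine, strand, nucleotide
    mean_axial_spacing: float


# ---------------------------------------------------------------------------
# helpers


def _ca_positions(model: StructureModel, chain: str, resnums: Sequence[int],
                  context: str) -> dict[int, np.ndarray]:
    ca = model.ca_map(chain)
    missing = [r for r in resnums if r not in ca]
    if missing:
        raise MetricError(f"{context}: chain {chain} is missing CA atoms for "
                          f"residues {missing}")
    return {r: ca[r] for r in resnums}


def _group_centroid(ca: dict[int, np.ndarray], group: Sequence[int]) -> np.ndarray:
    return centroid([ca[r] for r in group])


def _superpose_on_subunit(
    model: StructureModel, reference_model: StructureModel,
    chain: str, ref_chain: str,
) -> tuple[StructureModel, RigidTransform]:
    """Superpose ``model`` onto ``reference_model`` using one subunit's CA set."""
    ca_m = model.ca_map(chain)
    ca_r = reference_model.ca_map(ref_chain)
    common = sorted(set(ca_m) & set(ca_r))
    if len(common) < 3:
        raise MetricError(
            f"alignment subunit shares only {len(common)} CA residues between states"
        )
    transform, _ = kabsch_superpose(
        np.array([ca_m[r] for r in common]),
        np.array([ca_r[r] for r in common]),
    )
    return model.transformed(transform), transform


def _subunit_ca_centroid(model: StructureModel, chain: str) -> np.ndarray:
    ca = model.ca_map(chain)
    if not ca:
        raise MetricError(f"chain {chain} has no CA atoms")
    return centroid(list(ca.values()))


def _check_series(models, decomps):
    if len(models) != len(decomps):
        raise MetricError("models and decompositions differ in length")
    if len(models) < 2:
        raise MetricError("at least two states are required")


# ---------------------------------------------------------------------------
# metrics


def angle_triplet(
    model: StructureModel,
    chain: str,
    domains: DomainDefinition = DEFAULT_DOMAINS,
    subunit: str = "",
    state: str = "",
) -> AngleTriplet:
    """The (d1, d2, triangle) conformational fingerprint of one subunit."""
    anchors = sorted({r for g in D1_POINT_GROUPS + D2_POINT_GROUPS for r in g})
    ca = _ca_positions(model, chain, anchors, "angle_triplet anchors")
    d1 = dihedral(*(_group_centroid(ca, g) for g in D1_POINT_GROUPS))
    d2 = dihedral(*(_group_centroid(ca, g) for g in D2_POINT_GROUPS))
    cents = {}
    for name, rng in (("L", domains.triangle_large), ("S", domains.triangle_small),
                      ("H", domains.triangle_head)):
        dom_ca = model.ca_map(chain, rng, required=True)
        cents[name] = centroid(list(dom_ca.values()))
    tri = vertex_angle(cents["L"], cents["S"], cents["H"])
    return AngleTriplet(d1=d1, d2=d2, triangle=tri, subunit=subunit, state=state)


def angle_triplet_table(
    models: Sequence[StructureModel],
    decomps: Sequence[MotorDecomposition],
    domains: DomainDefinition = DEFAULT_DOMAINS,
) -> pd.DataFrame:
    """One row per (state, subunit) with d1/d2/triangle and the cluster label."""
    rows = []
    for m, d in zip(models, decomps):
        for s, chain in d.subunits.items():
            t = angle_triplet(m, chain, domains, subunit=s, state=d.state_label)
            rows.append({"state": d.state_label, "subunit": s,
                         "cluster": d.clusters[s], "d1_deg": t.d1,
                         "d2_deg": t.d2, "triangle_deg": t.triangle})
    return pd.DataFrame(rows)


def variability_map(
    models: Sequence[StructureModel],
    decomps: Sequence[MotorDecomposition],
    reference_subunit: str = "C",
    domains: DomainDefinition = DEFAULT_DOMAINS,
) -> VariabilityMap:
    """Per-C-alpha positional spread after aligning all states on one subunit."""
    _check_series(models, decomps)
    ref_model, ref_dec = models[0], decomps[0]
    aligned = [ref_model]
    for m, d in zip(models[1:], decomps[1:]):
        sup, _ = _superpose_on_subunit(
            m, ref_model, d.chain(reference_subunit), ref_dec.chain(reference_subunit))
        aligned.append(sup)

    rows = []
    for s in ref_dec.subunits:
        maps = [m.ca_map(d.chain(s)) for m, d in zip(aligned, decomps)]
        common = sorted(set.intersection(*(set(mp) for mp in maps)))
        if not common:
            raise MetricError(f"subunit {s}: no common residues across states")
        for r in common:
            pts = np.array([mp[r] for mp in maps])
            c = pts.mean(axis=0)
            stddev = float(np.sqrt(((pts - c) ** 2).sum(axis=1).mean()))
            rows.append({"subunit": s, "residue": r, "stddev": stddev})
    return VariabilityMap(table=pd.DataFrame(rows),
                          alignment_reference=reference_subunit)


def domain_rmsd_stats(
    models: Sequence[StructureModel],
    decomps: Sequence[MotorDecomposition],
    domain: str = "L",
    domains: DomainDefinition = DEFAULT_DOMAINS,
) -> tuple[float, pd.DataFrame]:
    """All-pairs superposed C-alpha RMSD of one domain over all subunit instances.

    Returns the mean over distinct pairs and the full symmetric matrix,
    indexed by ``state:subunit``.
    """
    if domain not in ("L", "S", "H"):
        raise MetricError(f"unknown domain {domain!r}; expected L, S or H")
    rng = domains.range_of(domain)
    instances: dict[str, np.ndarray] = {}
    for m, d in zip(models, decomps):
        for s, chain in d.subunits.items():
            ca = m.ca_map(chain, rng, required=True)
            instances[f"{d.state_label}:{s}"] = np.array(
                [ca[r] for r in range(rng[0], rng[1] + 1)])
    keys = list(instances)
    if len(keys) < 2:
        raise MetricError("domain RMSD statistics need at least two subunit instances")
    mat = np.zeros((len(keys), len(keys)))
    vals = []
    for i in range(len(keys)):
        for j in range(i + 1, len(keys)):
            _, r = kabsch_superpose(instances[keys[i]], instances[keys[j]])
            mat[i, j] = mat[j, i] = r
            vals.append(r)
    return float(np.mean(vals)), pd.DataFrame(mat, index=keys, columns=keys)


def displacement_field(
    model_i: StructureModel,
    model_j: StructureModel,
    decomp_i: MotorDecomposition,
    decomp_j: MotorDecomposition,
    alignment_subunit: str = "C",
    filter_threshold: Optional[float] = 1.0,
    render_scale: float = 2.5,
    subsample: int = 2,
) -> DisplacementField:
    """Per-C-alpha displacement vectors between two states aligned on one subunit.

    ``render_scale`` and ``subsample`` are presentation conventions consumed
    by :func:`write_bild` only; stored magnitudes are never scaled.
    """
    if alignment_subunit not in decomp_i.subunits:
        raise MetricError(f"alignment selection {alignment_subunit!r} is not a subunit label")
    aligned_j, _ = _superpose_on_subunit(
        model_j, model_i, decomp_j.chain(alignment_subunit),
        decomp_i.chain(alignment_subunit))
    rows = []
    for s in decomp_i.subunits:
        ca_i = model_i.ca_map(decomp_i.chain(s))
        ca_j = aligned_j.ca_map(decomp_j.chain(s))
        for r in sorted(set(ca_i) & set(ca_j)):
            v = ca_j[r] - ca_i[r]
            mag = float(np.linalg.norm(v))
            if filter_threshold is not None and mag <= filter_threshold:
                continue
            rows.append({"subunit": s, "residue": r,
                         "sx": ca_i[r][0], "sy": ca_i[r][1], "sz": ca_i[r][2],
                         "dx": v[0], "dy": v[1], "dz": v[2], "magnitude": mag})
    cols = ["subunit", "residue", "sx", "sy", "sz", "dx", "dy", "dz", "magnitude"]
    return DisplacementField(
        vectors=pd.DataFrame(rows, columns=cols),
        transition=f"{decomp_i.state_label}->{decomp_j.state_label}",
        filter_threshold=filter_threshold,
        render_scale=render_scale,
        subsample=subsample,
    )


def write_bild(field: DisplacementField, path) -> None:
    """Export a displacement field as a BILD-style arrow file.

    Applies the field's rendering conventions: every ``subsample``-th vector
    is drawn and arrow lengths are multiplied by ``render_scale``.
    """
    lines = [f".comment displacement field {field.transition} "
             f"(scale x{field.render_scale}, every {field.subsample})"]
    for k, row in enumerate(field.vectors.itertuples(index=False)):
        if k % field.subsample:
            continue
        tip = (row.sx + field.render_scale * row.dx,
               row.sy + field.render_scale * row.dy,
               row.sz + field.render_scale * row.dz)
        lines.append(f".arrow {row.sx:.3f} {row.sy:.3f} {row.sz:.3f} "
                     f"{tip[0]:.3f} {tip[1]:.3f} {tip[2]:.3f}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def trajectory_length(
    models: Sequence[StructureModel],
    decomps: Sequence[MotorDecomposition],
    cluster: str = "[E]",
    reference_subunit: str = "C",
) -> tuple[float, float, Optional[np.ndarray]]:
    """Path length, net displacement and direction of a cluster's subunit centroid.

    All states are superposed on the reference subunit of the first state;
    the tracked point is the full-subunit C-alpha centroid of whichever
    subunit occupies ``cluster`` in each state.  State order is taken from
    the input sequence (the manifest order), never inferred.
    """
    _check_series(models, decomps)
    ref_model, ref_dec = models[0], decomps[0]
    points = []
    for m, d in zip(models, decomps):
        if m is ref_model:
            aligned = m
        else:
            aligned, _ = _superpose_on_subunit(
                m, ref_model, d.chain(reference_subunit),
                ref_dec.chain(reference_subunit))
        subunit = d.subunit_of_cluster(cluster)
        points.append(_subunit_ca_centroid(aligned, d.chain(subunit)))
    pts = np.array(points)
    segs = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    path = float(segs.sum())
    net_vec = pts[-1] - pts[0]
    net = float(np.linalg.norm(net_vec))
    direction = net_vec / net if net > 1e-9 else None
    return path, net, direction


def gate_distance(
    model: StructureModel,
    decomp: MotorDecomposition,
    subunit: str,
    domains: DomainDefinition = DEFAULT_DOMAINS,
) -> GateDistance:
    """Distance between cis-Arg21 and trans-Glu128 of a nucleotide pocket.

    Measures gate opening/closing of the N-terminal gate: Arg21 CZ of the
    cis subunit against Glu128 CD of its trans neighbour, falling back to
    the CA pair (flagged) when side chains are unmodelled.
    """
    trans = TRANS_NEIGHBOUR[subunit]
    cis_chain = decomp.chain(subunit)
    trans_chain = decomp.chain(trans)

    def pick(chain: str, resnum: int, preferred: str):
        atoms = {a.atom_name: a for a in model.atoms
                 if a.chain_id == chain and a.res_num == resnum}
        if not atoms:
            raise MetricError(f"gate residue {resnum} absent in chain {chain}")
        if preferred in atoms:
            return atoms[preferred].pos, False
        if "CA" in atoms:
            return atoms["CA"].pos, True
        raise MetricError(f"gate residue {resnum} in chain {chain} has neither "
                          f"{preferred} nor CA")

    p_cis, fb1 = pick(cis_chain, domains.gate_arg, "CZ")
    p_trans, fb2 = pick(trans_chain, domains.gate_glu, "CD")
    return GateDistance(
        distance=float(np.linalg.norm(p_cis - p_trans)),
        cis_subunit=subunit, trans_subunit=trans,
        fallback_used=fb1 or fb2,
    )


def lever_lift(
    models: Sequence[StructureModel],
    decomps: Sequence[MotorDecomposition],
    reference_subunit: str = "E",
    probe: str = "dna",
    domains: DomainDefinition = DEFAULT_DOMAINS,
) -> LeverReport:
    """Signed axial lift of the DNA (or head interface) with states aligned on E.

    The converter subunit E is the fulcrum: with every state superposed on
    it, the lift is the displacement of the probe centroid along the motor
    axis between the first and last state.  Positive values point toward the
    DNA exit side (away from the junction core).
    """
    _check_series(models, decomps)
    if probe not in ("dna", "head-interface"):
        raise MetricError(f"unknown probe {probe!r}; expected 'dna' or 'head-interface'")
    ref_model, ref_dec = models[0], decomps[0]
    if probe == "dna" and not ref_dec.dna_chains:
        raise MetricError("probe 'dna' requires DNA chains in the decomposition")
    chains = list(ref_dec.subunits.values())
    center, axis = hexamer_axis(ref_model, chains, ref_dec.dna_chains, domains)

    def probe_centroid(m: StructureModel, d: MotorDecomposition) -> np.ndarray:
        if probe == "dna":
            pts = [a.pos for a in m.atoms
                   if a.chain_id in d.dna_chains and a.atom_name == "P"]
            if not pts:
                raise MetricError("no DNA phosphorus atoms found for the probe")
            return centroid(pts)
        pts = []
        for s, engaged in d.dna_engaged.items():
            if engaged:
                ca = m.ca_map(d.chain(s), domains.head, required=True)
                pts.extend(ca.values())
        if not pts:
            raise MetricError("no engaged head domains found for the probe")
        return centroid(pts)

    aligned = [ref_model]
    for m, d in zip(models[1:], decomps[1:]):
        sup, _ = _superpose_on_subunit(
            m, ref_model, d.chain(reference_subunit), ref_dec.chain(reference_subunit))
        aligned.append(sup)

    p_first = probe_centroid(aligned[0], decomps[0])
    p_last = probe_centroid(aligned[-1], decomps[-1])
    dna_lift = float((p_last - p_first) @ axis)
    per_subunit = {}
    for s in ref_dec.subunits:
        c_first = _subunit_ca_centroid(aligned[0], decomps[0].chain(s))
        c_last = _subunit_ca_centroid(aligned[-1], decomps[-1].chain(s))
        per_subunit[s] = float((c_last - c_first) @ axis)
    return LeverReport(per_subunit=per_subunit, dna_lift=dna_lift,
                       alignment_reference=reference_subunit, axis=axis)


def motor_rotation(
    model_i: StructureModel,
    model_j: StructureModel,
    decomp_i: MotorDecomposition,
    decomp_j: MotorDecomposition,
    core_chains: Sequence[str],
    domains: DomainDefinition = DEFAULT_DOMAINS,
    core_rmsd_bound: float = 2.0,
) -> RotationResult:
    """Rotation of the hexamer about the pore axis between two core-aligned states.

    Both states are superposed on the shared core reference (e.g. the DNA of
    the junction core); the result is the circular mean of the azimuthal
    shifts of the six large-domain centroids.  A core superposition RMSD
    above ``core_rmsd_bound`` attaches a warning to the result.
    """
    pairs_i = {(a.chain_id, a.res_num, a.atom_name): a.pos
               for a in model_i.atoms if a.chain_id in core_chains}
    pairs_j = {(a.chain_id, a.res_num, a.atom_name): a.pos
               for a in model_j.atoms if a.chain_id in core_chains}
    common = sorted(set(pairs_i) & set(pairs_j))
    if len(common) < 3:
        raise MetricError("core reference shares fewer than 3 atoms between states")
    transform, core_rmsd = kabsch_superpose(
        np.array([pairs_j[k] for k in common]),
        np.array([pairs_i[k] for k in common]))
    aligned_j = model_j.transformed(transform)

    chains_i = list(decomp_i.subunits.values())
    center, axis = hexamer_axis(model_i, chains_i, decomp_i.dna_chains, domains)
    cents_i = _large_centroids(model_i, chains_i, domains)
    cents_j = _large_centroids(aligned_j, list(decomp_j.subunits.values()), domains)
    deltas = []
    for s in decomp_i.subunits:
        pi = cents_i[decomp_i.chain(s)]
        pj = cents_j[decomp_j.chain(s)]
        ai, aj = angular_positions(np.array([pi, pj]), center, axis)
        d = aj - ai
        if d <= -180.0:
            d += 360.0
        elif d > 180.0:
            d -= 360.0
        deltas.append(np.radians(d))
    mean_vec = np.mean(np.exp(1j * np.array(deltas)))
    degrees = float(np.degrees(np.angle(mean_vec)))
    return RotationResult(degrees=degrees, core_rmsd=float(core_rmsd),
                          warning=core_rmsd > core_rmsd_bound)


def dna_contact_spacing(
    model: StructureModel,
    decomp: MotorDecomposition,
    domains: DomainDefinition = DEFAULT_DOMAINS,
    cutoff: float = 4.0,
) -> ContactReport:
    """Arginine-phosphate contacts of the staircase and their axial spacing.

    The spacing is the mean axial distance between the contacted-phosphate
    centroids of consecutive staircase subunits ([A] through [D]).
    """
    rows = []
    per_subunit_phos: dict[str, list[np.ndarray]] = {}
    for s, engaged in decomp.dna_engaged.items():
        contacts = head_dna_contacts(model, decomp.chain(s), decomp.dna_chains,
                                     domains, cutoff)
        for arg, strand, nt, ppos in contacts:
            rows.append({"subunit": s, "arginine": arg, "strand": strand,
                         "nucleotide": nt})
            per_subunit_phos.setdefault(s, []).append(ppos)
    if not rows:
        raise MetricError(
            f"no arginine-phosphate contacts found at cutoff {cutoff} A; "
            "review the contact cutoff or the DNA chain declaration"
        )
    chains = list(decomp.subunits.values())
    center, axis = hexamer_axis(model, chains, decomp.dna_chains, domains)
    staircase = []
    for c in ("[A]", "[B]", "[C]", "[D]"):
        try:
            s = decomp.subunit_of_cluster(c)
        except Exception:
            continue
        if s in per_subunit_phos:
            staircase.append(centroid(per_subunit_phos[s]))
    spacings = [abs(float((staircase[k] - staircase[k + 1]) @ axis))
                for k in range(len(staircase) - 1)]
    mean_spacing = float(np.mean(spacings)) if spacings else float("nan")
    return ContactReport(
        contacts=pd.DataFrame(rows, columns=["subunit", "arginine", "strand",
                                             "nucleotide"]),
        mean_axial_spacing=mean_spacing,
    )
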