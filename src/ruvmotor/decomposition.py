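"""Decompose a motor state into subunits, domains, clusters and occupancy.

A hexameric motor state is resolved into six subunits labelled A-F: the four
subunits whose head-domain arginines contact one DNA strand form the spiral
staircase (A at the top, D at the bottom, ordered by descending height along
the motor axis); the two contact-free subunits close the ring (E adjacent to
D, F adjacent to A).  Positional conformational clusters [A]..[F] follow the
same geometric rule, so on canonical states the cluster of subunit X is [X].
Nucleotide occupancy is read from modelled ligands near the Walker-A lysine
of the clamping (cis) subunit; the count of docked RuvA domain-III tethers
comes from declared chains within contact distance of the motor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .errors import AmbiguousPocketError, DecompositionError
from .geometry import angular_positions, axis_from_points, centroid, ring_axis
from .structure_io import ManifestEntry, StructureModel

__all__ = [
    "DomainDefinition",
    "MotorDecomposition",
    "DEFAULT_DOMAINS",
    "hexamer_axis",
    "head_dna_contacts",
    "assign_subunit_labels",
    "assign_occupancy",
    "count_ruvA_d3",
    "decompose_state",
    "decomposition_table",
]

SUBUNIT_LABELS = ("A", "B", "C", "D", "E", "F")

_PHOSPHATE_ATOMS = {"P", "OP1", "OP2", "O1P", "O2P"}
_ARG_CONTACT_ATOMS = ("NH1", "NH2", "NE", "CZ", "CA")


@dataclass(frozen=True)
class DomainDefinition:
    """Residue-level anatomy of one subunit (1-based, inclusive ranges).

    The three rigid bodies are the large ATPase domain (L), the small ATPase
    domain (S) and the C-terminal head (H).  Separate, slightly wider ranges
    define the domain centroids of the triangle angle, and fixed anchor
    residues define the two inter-domain dihedrals.
    """

    large: tuple[int, int] = (21, 181)
    small: tuple[int, int] = (182, 254)
    head: tuple[int, int] = (255, 330)
    triangle_large: tuple[int, int] = (20, 180)
    triangle_small: tuple[int, int] = (181, 256)
    triangle_head: tuple[int, int] = (257, 325)
    dihedral_anchors_large: tuple[int, ...] = (36, 73, 80, 174, 55, 155, 170, 94, 121)
    dihedral_anchors_small: tuple[int, ...] = (249, 227, 209, 196)
    dihedral_anchors_head: tuple[int, ...] = (282, 284, 265, 306, 263)
    walker_a_lys: int = 65
    gate_arg: int = 21        # cis gate residue (N terminus)
    gate_glu: int = 128       # trans gate residue (signature motif)
    dna_arginines: tuple[int, ...] = (291, 310, 312, 315)

    def __post_init__(self):
        for name in ("large", "small", "head", "triangle_large", "triangle_small",
                     "triangle_head"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise DecompositionError(f"domain range {name} has low > high")
        for anchors, rng in ((self.dihedral_anchors_large, self.triangle_large),
                             (self.dihedral_anchors_small, self.triangle_small),
                             (self.dihedral_anchors_head, self.triangle_head)):
            bad = [a for a in anchors if not (rng[0] <= a <= rng[1])]
            if bad:
                raise DecompositionError(f"anchor residues {bad} outside their domain range {rng}")

    def range_of(self, domain: str) -> tuple[int, int]:
        return {"L": self.large, "S": self.small, "H": self.head}[domain]


DEFAULT_DOMAINS = DomainDefinition()


@dataclass
class MotorDecomposition:
    """Per-state assignment of chains to subunits and derived annotations."""

    state_label: str
    subunits: dict[str, str]                 # subunit label -> chain id
    clusters: dict[str, str]                 # subunit label -> positional cluster "[X]"
    occupancy: dict[str, str]                # subunit label -> ATP/ADP/ADP_Mg/apo/other
    dna_engaged: dict[str, bool]
    ruvA_d3_count: int = 0
    dna_chains: tuple[str, ...] = ()
    ruva_chains: tuple[str, ...] = ()

    def __post_init__(self):
        if sorted(self.subunits) != list(SUBUNIT_LABELS):
            raise DecompositionError(
                f"decomposition must cover subunits A-F, got {sorted(self.subunits)}"
            )
        if self.ruvA_d3_count not in (0, 1, 2):
            raise DecompositionError("ruvA_d3_count must be 0, 1 or 2")

    def chain(self, subunit: str) -> str:
        return self.subunits[subunit]

    def subunit_of_cluster(self, cluster: str) -> str:
        for s, c in self.clusters.items():
            if c == cluster:
                return s
        raise DecompositionError(f"no subunit in cluster {cluster!r}")


# ---------------------------------------------------------------------------
# geometry helpers


def _protein_chains(model: StructureModel, dna_chains: Sequence[str],
                    exclude: Sequence[str] = ()) -> list[str]:
    """Chains that look like full motor subunits (>=100 CA in residues 21-330)."""
    counts: dict[str, int] = {}
    for a in model.atoms:
        if a.atom_name == "CA" and 21 <= a.res_num <= 330:
            counts[a.chain_id] = counts.get(a.chain_id, 0) + 1
    return [c for c, n in counts.items()
            if n >= 100 and c not in dna_chains and c not in exclude]


def _large_centroids(model: StructureModel, chains: Sequence[str],
                     domains: DomainDefinition) -> dict[str, np.ndarray]:
    out = {}
    for c in chains:
        ca = model.ca_map(c, domains.large)
        if not ca:
            raise DecompositionError(f"chain {c}: no large-domain CA atoms")
        out[c] = centroid(list(ca.values()))
    return out


def hexamer_axis(
    model: StructureModel,
    chains: Sequence[str],
    dna_chains: Sequence[str],
    domains: DomainDefinition = DEFAULT_DOMAINS,
) -> tuple[np.ndarray, np.ndarray]:
    """Motor (pore) axis as ``(axis_point, unit_direction)``.

    With DNA present the axis is the principal (long) axis of the DNA
    phosphate trace, oriented so the DNA exit side (the phosphate centroid
    relative to the hexamer centre) is at positive height; the translocating
    strand runs straight through the pore, so this is the motor frame.
    Without DNA the minimum-variance axis of the six large-domain centroids
    is used with a deterministic (but physically arbitrary) sign.
    """
    cents = _large_centroids(model, chains, domains)
    ring_center = centroid(list(cents.values()))
    dna_p = [a.pos for a in model.atoms
             if a.chain_id in dna_chains and a.atom_name == "P"]
    if dna_p:
        dna_p = np.array(dna_p)
        axis = axis_from_points(dna_p)
        if (centroid(dna_p) - ring_center) @ axis < 0:
            axis = -axis
        return ring_center, axis
    axis = ring_axis(np.array(list(cents.values())))
    if axis[2] < 0:
        axis = -axis
    return ring_center, axis


def head_dna_contacts(
    model: StructureModel,
    chain: str,
    dna_chains: Sequence[str],
    domains: DomainDefinition = DEFAULT_DOMAINS,
    cutoff: float = 4.0,
):
    """Arginine-to-phosphate contacts of one subunit's head domain.

    Returns a list of ``(arg_resnum, dna_chain, nucleotide, phosphate_pos)``
    using the guanidinium nitrogens when modelled (CZ, then CA as fallbacks)
    against backbone phosphate/phosphate-oxygen atoms, at a standard
    salt-bridge heavy-atom cutoff.
    """
    dna_atoms = [a for a in model.atoms
                 if a.chain_id in dna_chains and a.atom_name in _PHOSPHATE_ATOMS]
    if not dna_atoms:
        return []
    tree = cKDTree(np.array([a.pos for a in dna_atoms]))
    contacts = []
    for arg in domains.dna_arginines:
        res_atoms = {a.atom_name: a for a in model.atoms
                     if a.chain_id == chain and a.res_num == arg}
        probe = next((res_atoms[n] for n in _ARG_CONTACT_ATOMS if n in res_atoms), None)
        if probe is None:
            continue
        for idx in tree.query_ball_point(probe.pos, cutoff):
            d = dna_atoms[idx]
            contacts.append((arg, d.chain_id, d.res_num, d.pos))
    return contacts


# ---------------------------------------------------------------------------
# operations


def assign_subunit_labels(
    model: StructureModel,
    dna_chains: Sequence[str],
    domains: DomainDefinition = DEFAULT_DOMAINS,
    protein_chains: Optional[Sequence[str]] = None,
    ruva_chains: Sequence[str] = (),
    contact_cutoff: float = 4.0,
) -> dict[str, str]:
    """Infer the chain -> subunit-label mapping from staircase geometry.

    The four DNA-contacting subunits become A-D by descending height along
    the motor axis; the two contact-free subunits become E (adjacent to D)
    and F (adjacent to A).  A manifest-supplied mapping always takes
    precedence over this inference (see :func:`decompose_state`).
    """
    if not dna_chains:
        raise DecompositionError("subunit labelling requires DNA chains")
    chains = list(protein_chains) if protein_chains else _protein_chains(
        model, dna_chains, exclude=ruva_chains)
    if len(chains) != 6:
        raise DecompositionError(
            f"expected six motor chains, found {len(chains)}: {sorted(chains)}"
        )
    engaged = [c for c in chains
               if head_dna_contacts(model, c, dna_chains, domains, contact_cutoff)]
    if len(engaged) != 4:
        raise DecompositionError(
            f"expected 4 DNA-contacting subunits, found {len(engaged)} "
            f"({sorted(engaged)}); supply an explicit manifest mapping instead"
        )
    center, axis = hexamer_axis(model, chains, dna_chains, domains)
    cents = _large_centroids(model, chains, domains)
    heights = {c: float((cents[c] - center) @ axis) for c in chains}
    order = sorted(engaged, key=lambda c: -heights[c])  # A at the top
    labels = dict(zip(("A", "B", "C", "D"), order))
    # ring adjacency from azimuths about the axis
    az = dict(zip(chains, angular_positions(
        np.array([cents[c] for c in chains]), center, axis)))
    ring = sorted(chains, key=lambda c: az[c])
    pos = {c: i for i, c in enumerate(ring)}
    free = [c for c in chains if c not in engaged]

    def adjacent(c1: str, c2: str) -> bool:
        return (pos[c1] - pos[c2]) % 6 in (1, 5)

    chain_d, chain_a = labels["D"], labels["A"]
    e = [c for c in free if adjacent(c, chain_d)]
    f = [c for c in free if adjacent(c, chain_a)]
    if len(e) != 1 or len(f) != 1 or e[0] == f[0]:
        raise DecompositionError(
            "disengaged subunits are not adjacent to the staircase ends D and A; "
            "cannot assign labels E/F"
        )
    labels["E"], labels["F"] = e[0], f[0]
    return labels


def assign_occupancy(
    model: StructureModel,
    subunit_chains: Mapping[str, str],
    domains: DomainDefinition = DEFAULT_DOMAINS,
    pocket_cutoff: float = 12.0,
    mg_cutoff: float = 3.5,
) -> dict[str, str]:
    """Nucleotide occupancy per subunit from modelled ligands.

    A nucleotide whose centroid lies within ``pocket_cutoff`` of the cis
    subunit's Walker-A lysine C-alpha fills that pocket (nucleotides bind at
    subunit interfaces with the nucleoside clamped by the cis subunit, so a
    cis-anchored cutoff disambiguates interfaces).  A magnesium ion within
    ``mg_cutoff`` of the nucleotide phosphates upgrades ADP to ADP_Mg.  No
    nucleotide within the cutoff means apo; two mean an ambiguity error.
    """
    ligands = model.ligands
    nucleotides = [l for l in ligands if l.kind in ("ATP", "ADP")]
    others = [l for l in ligands if l.kind == "other"]
    mgs = [l for l in ligands if l.kind == "MG"]
    occupancy: dict[str, str] = {}
    for label, chain in subunit_chains.items():
        lys = model.ca_map(chain).get(domains.walker_a_lys)
        if lys is None:
            raise DecompositionError(
                f"subunit {label} (chain {chain}): Walker-A Lys{domains.walker_a_lys} "
                "CA not present"
            )
        near = [l for l in nucleotides if np.linalg.norm(l.centroid - lys) <= pocket_cutoff]
        if len(near) > 1:
            listing = ", ".join(f"{l.code} {l.chain_id}/{l.res_num}" for l in near)
            raise AmbiguousPocketError(
                f"subunit {label}: {len(near)} nucleotides within {pocket_cutoff} A "
                f"of Walker-A Lys CA: {listing}"
            )
        if not near:
            near_other = [l for l in others
                          if np.linalg.norm(l.centroid - lys) <= pocket_cutoff]
            occupancy[label] = "other" if near_other else "apo"
            continue
        lig = near[0]
        kind = lig.kind
        if kind == "ADP":
            # beta-phosphate proximity when atoms are resolved, centroid otherwise
            ppos = [p for p, a in zip(lig.positions,
                                      _ligand_atom_names(model, lig))
                    if a in ("PB", "PG", "O1B", "O2B", "O3B")]
            ref = np.array(ppos) if ppos else lig.positions
            if any(np.min(np.linalg.norm(ref - m.centroid, axis=1)) <= mg_cutoff
                   for m in mgs):
                kind = "ADP_Mg"
        occupancy[label] = kind
    return occupancy


def _ligand_atom_names(model: StructureModel, lig) -> list[str]:
    return [a.atom_name for a in model.atoms
            if a.hetero and a.chain_id == lig.chain_id and a.res_num == lig.res_num]


def count_ruvA_d3(
    model: StructureModel,
    ruva_chains: Sequence[str],
    subunit_chains: Mapping[str, str],
    cutoff: float = 5.0,
) -> int:
    """Number of declared RuvA domain-III chains docked onto the motor.

    A chain counts as docked when at least one of its atoms lies within
    ``cutoff`` of any motor-subunit atom.
    """
    if not ruva_chains:
        return 0
    motor = np.array([a.pos for a in model.atoms
                      if a.chain_id in set(subunit_chains.values())])
    if motor.size == 0:
        return 0
    tree = cKDTree(motor)
    n = 0
    for c in ruva_chains:
        pts = np.array([a.pos for a in model.atoms if a.chain_id == c])
        if pts.size and np.any(tree.query(pts, k=1)[0] <= cutoff):
            n += 1
    return n


def decompose_state(
    model: StructureModel,
    entry: Optional[ManifestEntry] = None,
    dna_chains: Sequence[str] = (),
    ruva_chains: Sequence[str] = (),
    domains: DomainDefinition = DEFAULT_DOMAINS,
    pocket_cutoff: float = 12.0,
    contact_cutoff: float = 4.0,
) -> MotorDecomposition:
    """Full decomposition of one state.

    A manifest entry supplies the authoritative chain mapping and chain
    roles; without one, labels are inferred from the staircase geometry.
    Positional clusters are always recomputed from geometry (engagement +
    height order), so they remain meaningful when a manifest deliberately
    maps rotated states.
    """
    if entry is not None:
        subunits = dict(entry.subunit_map)
        dna_chains = tuple(entry.dna_chain_ids)
        ruva_chains = tuple(entry.ruvA_d3_chain_ids)
        state_label = entry.state_label
    else:
        subunits = assign_subunit_labels(
            model, dna_chains, domains, ruva_chains=ruva_chains,
            contact_cutoff=contact_cutoff)
        state_label = model.model_id

    engaged = {
        s: bool(head_dna_contacts(model, c, dna_chains, domains, contact_cutoff))
        for s, c in subunits.items()
    }
    clusters = _positional_clusters(model, subunits, engaged, dna_chains, domains)
    occupancy = assign_occupancy(model, subunits, domains, pocket_cutoff)
    d3 = count_ruvA_d3(model, ruva_chains, subunits)
    return MotorDecomposition(
        state_label=state_label,
        subunits=subunits,
        clusters=clusters,
        occupancy=occupancy,
        dna_engaged=engaged,
        ruvA_d3_count=d3,
        dna_chains=tuple(dna_chains),
        ruva_chains=tuple(ruva_chains),
    )


def _positional_clusters(model, subunits, engaged, dna_chains, domains):
    """Clusters [A]..[F] from DNA engagement + height order (position defines
    conformation class within the hexamer)."""
    chains = list(subunits.values())
    eng_labels = [s for s, e in engaged.items() if e]
    if len(eng_labels) != 4:
        # non-canonical state: fall back to label-identical clusters
        return {s: f"[{s}]" for s in subunits}
    center, axis = hexamer_axis(model, chains, dna_chains, domains)
    cents = _large_centroids(model, chains, domains)
    heights = {s: float((cents[c] - center) @ axis) for s, c in subunits.items()}
    order = sorted(eng_labels, key=lambda s: -heights[s])
    clusters = {s: f"[{c}]" for c, s in zip(("A", "B", "C", "D"), order)}
    az = dict(zip(chains, angular_positions(
        np.array([cents[c] for c in chains]), center, axis)))
    ring = sorted(subunits, key=lambda s: az[subunits[s]])
    pos = {s: i for i, s in enumerate(ring)}
    free = [s for s in subunits if s not in eng_labels]
    top = order[0]     # positional [A]
    bottom = order[-1]  # positional [D]
    for s in free:
        if (pos[s] - pos[bottom]) % 6 in (1, 5):
            clusters[s] = "[E]"
        elif (pos[s] - pos[top]) % 6 in (1, 5):
            clusters[s] = "[F]"
        else:
            clusters[s] = "[E]" if "[E]" not in clusters.values() else "[F]"
    return clusters


def decomposition_table(decompositions: Sequence[MotorDecomposition]):
    """Tab-separable report: one row per (state, subunit)."""
    import pandas as pd

    rows = []
    for d in decompositions:
        for s in SUBUNIT_LABELS:
            rows.append({
                "state": d.state_label,
                "subunit": s,
                "chain": d.subunits[s],
                "cluster": d.clusters[s],
                "occupancy": d.occupancy[s],
                "dna_engaged": d.dna_engaged[s],
                "ruva_d3_count": d.ruvA_d3_count,
            })
    return pd.DataFrame(rows)
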