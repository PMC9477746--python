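"""Coordinate-file input/output and the state manifest.

This module provides the universal in-memory coordinate container
(:class:`StructureModel`), readers for mmCIF/PDB built on gemmi, a minimal
PDB writer for synthetic fixtures, and the YAML state manifest that names
conformational states (s0^-A, s0, s0_t1, s1_t1, s1..s5) and maps chains to
motor subunits A-F.

Conventions
-----------
* Residue numbering is 1-based and taken verbatim from the source file;
  ranges are inclusive and never re-indexed.
* Alternate conformers are collapsed on read to the highest-occupancy
  conformer (ties broken by altloc identifier order).
* Ligand chemical-component codes are preserved verbatim ("AGS", "ADP",
  "MG", "ATP"); unknown codes are classified as "other".
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import gemmi
import numpy as np
import yaml

from .errors import ManifestError, ParseError, FormatError

__all__ = [
    "Atom",
    "Ligand",
    "StructureModel",
    "ManifestEntry",
    "StateManifest",
    "read_structure",
    "write_pdb",
    "select",
    "load_manifest",
    "STATE_LABELS",
    "LIGAND_KIND",
    "ligand_kind",
]

#: Recognised conformational-state labels, in canonical order.
STATE_LABELS = (
    "s0_minus_A",
    "s0",
    "s0_t1",
    "s1_t1",
    "s1",
    "s2",
    "s3",
    "s4",
    "s5",
)

SUBUNIT_LABELS = ("A", "B", "C", "D", "E", "F")

#: Chemical-component code -> chemical kind used by pocket assignment.
LIGAND_KIND = {
    "AGS": "ATP",  # ATP-gamma-S, slowly hydrolysable ATP analogue
    "ATP": "ATP",
    "ADP": "ADP",
    "MG": "MG",
}

_WATER_CODES = {"HOH", "WAT", "DOD", "H2O"}


def ligand_kind(code: str) -> str:
    """Map a chemical-component code to {ATP, ADP, MG, other}."""
    return LIGAND_KIND.get(code.strip().upper(), "other")


@dataclass(frozen=True)
class Atom:
    chain_id: str
    res_num: int
    res_name: str
    atom_name: str
    element: str
    pos: np.ndarray  # shape (3,), Angstrom
    hetero: bool = False
    occupancy: float = 1.0


@dataclass(frozen=True)
class Ligand:
    """A heteroatom group (one residue) that is not water."""

    chain_id: str
    res_num: int
    code: str
    positions: np.ndarray  # (n, 3)

    @property
    def kind(self) -> str:
        return ligand_kind(self.code)

    @property
    def centroid(self) -> np.ndarray:
        return self.positions.mean(axis=0)


class StructureModel:
    """Atoms with chain/residue/atom identity and 3-D coordinates in Angstrom.

    Invariants enforced at construction:

    * every atom position is a finite 3-vector;
    * ``(chain_id, res_num, atom_name)`` is unique within the model.
    """

    def __init__(self, model_id: str, atoms: Sequence[Atom]):
        self.model_id = model_id
        self.atoms = list(atoms)
        seen = set()
        for a in self.atoms:
            p = np.asarray(a.pos, dtype=float)
            if p.shape != (3,) or not np.all(np.isfinite(p)):
                raise ParseError(
                    f"{model_id}: non-finite or malformed position for atom "
                    f"{a.chain_id}/{a.res_num}/{a.atom_name}"
                )
            key = (a.chain_id, a.res_num, a.atom_name)
            if key in seen:
                raise ParseError(
                    f"{model_id}: duplicate atom record (chain {a.chain_id}, "
                    f"residue {a.res_num}, atom {a.atom_name})"
                )
            seen.add(key)

    def __len__(self) -> int:
        return len(self.atoms)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"StructureModel({self.model_id!r}, {len(self.atoms)} atoms)"

    @property
    def coords(self) -> np.ndarray:
        """All coordinates as an ``(n, 3)`` array (copy)."""
        if not self.atoms:
            return np.zeros((0, 3))
        return np.array([a.pos for a in self.atoms], dtype=float)

    @property
    def chains(self) -> list[str]:
        out: list[str] = []
        for a in self.atoms:
            if a.chain_id not in out:
                out.append(a.chain_id)
        return out

    @property
    def ligands(self) -> list[Ligand]:
        """Non-water heteroatom groups, one entry per (chain, residue)."""
        groups: dict[tuple[str, int, str], list[np.ndarray]] = {}
        for a in self.atoms:
            if a.hetero and a.res_name not in _WATER_CODES:
                groups.setdefault((a.chain_id, a.res_num, a.res_name), []).append(a.pos)
        return [
            Ligand(chain_id=c, res_num=r, code=name, positions=np.array(pos))
            for (c, r, name), pos in groups.items()
        ]

    def select(
        self,
        chain: Optional[str] = None,
        residue_range: Optional[tuple[int, int]] = None,
        atom_names: Optional[Iterable[str]] = None,
    ) -> "StructureModel":
        """Return the sub-model matching the query; empty selections are legal."""
        if residue_range is not None:
            lo, hi = residue_range
            if lo > hi:
                raise ValueError(f"residue range low > high: {residue_range}")
        names = set(atom_names) if atom_names is not None else None
        kept = []
        for a in self.atoms:
            if chain is not None and a.chain_id != chain:
                continue
            if residue_range is not None and not (lo <= a.res_num <= hi):
                continue
            if names is not None and a.atom_name not in names:
                continue
            kept.append(a)
        return StructureModel(self.model_id, kept)

    def ca_map(
        self,
        chain: str,
        residue_range: Optional[tuple[int, int]] = None,
        required: bool = False,
    ) -> dict[int, np.ndarray]:
        """C-alpha positions keyed by residue number for one chain.

        With ``required=True`` and an explicit range, missing residues raise
        a :class:`~ruvmotor.errors.ParseError` listing the gaps (no silent
        imputation).
        """
        sub = self.select(chain=chain, residue_range=residue_range, atom_names={"CA"})
        out = {a.res_num: np.asarray(a.pos, dtype=float) for a in sub.atoms}
        if required and residue_range is not None:
            lo, hi = residue_range
            gaps = [r for r in range(lo, hi + 1) if r not in out]
            if gaps:
                raise ParseError(
                    f"{self.model_id}: chain {chain} is missing CA atoms for "
                    f"residues {gaps} within declared range {lo}-{hi}"
                )
        return out

    def transformed(self, transform) -> "StructureModel":
        """Return a copy with ``transform`` (a RigidTransform) applied to all atoms."""
        atoms = [
            Atom(
                chain_id=a.chain_id,
                res_num=a.res_num,
                res_name=a.res_name,
                atom_name=a.atom_name,
                element=a.element,
                pos=transform.apply(a.pos[None, :])[0],
                hetero=a.hetero,
                occupancy=a.occupancy,
            )
            for a in self.atoms
        ]
        return StructureModel(self.model_id, atoms)


# ---------------------------------------------------------------------------
# readers / writers


_FORMATS = {
    "mmcif": gemmi.CoorFormat.Mmcif,
    "pdb": gemmi.CoorFormat.Pdb,
    "auto": gemmi.CoorFormat.Detect,
}


def _collapse_altlocs(residue: gemmi.Residue) -> list[gemmi.Atom]:
    """Keep the highest-occupancy conformer per atom name (ties: altloc order).

    Repeated atom names *without* altloc identifiers are genuine duplicate
    records and raise a parse error rather than being silently merged.
    """
    by_name: dict[str, list[gemmi.Atom]] = {}
    for at in residue:
        by_name.setdefault(at.name, []).append(at)
    kept = []
    for name, group in by_name.items():
        if len(group) == 1:
            kept.append(group[0])
        elif all(a.altloc in ("", " ", "\x00") for a in group):
            raise ParseError(
                f"duplicate atom record for residue {residue.seqid.num} "
                f"atom {name} (no altloc identifiers)"
            )
        else:
            group.sort(key=lambda a: (-a.occ, a.altloc or "~"))
            kept.append(group[0])
    return kept


def read_structure(path: str | Path, format: str = "auto") -> StructureModel:
    """Read a coordinate file (mmCIF or PDB) into a :class:`StructureModel`.

    All ATOM and HETATM records of the first model are represented; ligand
    codes are preserved verbatim.
    """
    path = Path(path)
    if format not in _FORMATS:
        raise FormatError(f"unknown coordinate format {format!r}; expected mmcif/pdb/auto")
    if not path.exists():
        raise ParseError(f"coordinate file not found: {path}")
    try:
        st = gemmi.read_structure(str(path), format=_FORMATS[format])
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"failed to parse {path}: {exc}") from exc
    if len(st) == 0:
        raise ParseError(f"{path}: file contains no coordinate model")
    atoms: list[Atom] = []
    model = st[0]
    for chain in model:
        for residue in chain:
            het = residue.het_flag == "H"
            for at in _collapse_altlocs(residue):
                atoms.append(
                    Atom(
                        chain_id=chain.name,
                        res_num=residue.seqid.num,
                        res_name=residue.name,
                        atom_name=at.name,
                        element=at.element.name,
                        pos=np.array([at.pos.x, at.pos.y, at.pos.z], dtype=float),
                        hetero=het,
                        occupancy=at.occ,
                    )
                )
    try:
        return StructureModel(path.stem, atoms)
    except ParseError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_pdb(model: StructureModel, path: str | Path) -> Path:
    """Write a model as a standard PDB file (used for synthetic fixtures)."""
    path = Path(path)
    # group atoms by chain, then residue, preserving first-seen order
    # (gemmi add_* methods copy their argument, so containers are built
    # bottom-up: atoms into residues, residues into chains, chains into model)
    by_chain: dict[str, dict[tuple[int, str, bool], list[Atom]]] = {}
    for a in model.atoms:
        by_chain.setdefault(a.chain_id, {}).setdefault(
            (a.res_num, a.res_name, a.hetero), []).append(a)
    st = gemmi.Structure()
    st.name = model.model_id
    gm = gemmi.Model("1")
    for chain_id, residues in by_chain.items():
        ch = gemmi.Chain(chain_id)
        for (res_num, res_name, hetero), atoms in residues.items():
            res = gemmi.Residue()
            res.name = res_name
            res.seqid = gemmi.SeqId(res_num, " ")
            res.het_flag = "H" if hetero else "A"
            for a in atoms:
                at = gemmi.Atom()
                at.name = a.atom_name
                at.element = gemmi.Element(a.element)
                at.occ = a.occupancy
                x, y, z = np.asarray(a.pos, dtype=float)
                at.pos = gemmi.Position(x, y, z)
                res.add_atom(at)
            ch.add_residue(res)
        gm.add_chain(ch)
    st.add_model(gm)
    st.setup_entities()
    st.write_pdb(str(path))
    return path


def select(
    model: StructureModel,
    chain: Optional[str] = None,
    residue_range: Optional[tuple[int, int]] = None,
    atom_names: Optional[Iterable[str]] = None,
) -> StructureModel:
    """Functional form of :meth:`StructureModel.select`."""
    return model.select(chain=chain, residue_range=residue_range, atom_names=atom_names)


# ---------------------------------------------------------------------------
# state manifest


@dataclass(frozen=True)
class ManifestEntry:
    state_label: str
    file_path: Path
    subunit_map: Mapping[str, str]  # subunit label A..F -> chain id
    dna_chain_ids: tuple[str, ...] = ()
    ruvA_d3_chain_ids: tuple[str, ...] = ()

    @property
    def protein_chains(self) -> tuple[str, ...]:
        return tuple(self.subunit_map[s] for s in SUBUNIT_LABELS)


@dataclass(frozen=True)
class StateManifest:
    entries: tuple[ManifestEntry, ...]

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def entry(self, state_label: str) -> ManifestEntry:
        for e in self.entries:
            if e.state_label == state_label:
                return e
        raise ManifestError(f"state {state_label!r} not present in manifest")

    @property
    def state_labels(self) -> tuple[str, ...]:
        return tuple(e.state_label for e in self.entries)


def load_manifest(path: str | Path) -> StateManifest:
    """Load and validate a YAML state manifest.

    Expected layout::

        states:
          - state: s1
            file: s1.pdb                 # relative to the manifest file
            subunits: {A: A, B: B, C: C, D: D, E: E, F: F}
            dna_chains: [X, Y]
            ruva_d3_chains: [U, V]

    Entry order defines state ordering for trajectory/lever analyses.
    """
    path = Path(path)
    if not path.exists():
        raise ManifestError(f"manifest file not found: {path}")
    try:
        doc = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ManifestError(f"malformed manifest {path}: {exc}") from exc
    if not isinstance(doc, dict) or "states" not in doc:
        raise ManifestError(f"{path}: manifest must be a mapping with a 'states' list")
    entries: list[ManifestEntry] = []
    seen_labels: set[str] = set()
    for i, raw in enumerate(doc["states"]):
        if not isinstance(raw, dict):
            raise ManifestError(f"{path}: states[{i}] is not a mapping")
        label = raw.get("state")
        if label not in STATE_LABELS:
            raise ManifestError(
                f"{path}: states[{i}] has unknown state label {label!r}; "
                f"expected one of {STATE_LABELS}"
            )
        if label in seen_labels:
            raise ManifestError(f"{path}: duplicate state label {label!r}")
        seen_labels.add(label)
        file_rel = raw.get("file")
        if not file_rel:
            raise ManifestError(f"{path}: state {label} has no 'file' entry")
        file_path = (path.parent / file_rel).resolve()
        if not file_path.exists():
            raise ManifestError(f"{path}: state {label}: file does not exist: {file_path}")
        sub = raw.get("subunits") or {}
        missing = [s for s in SUBUNIT_LABELS if s not in sub]
        if missing:
            raise ManifestError(
                f"{path}: state {label}: subunit map is missing labels {missing}"
            )
        extra = [s for s in sub if s not in SUBUNIT_LABELS]
        if extra:
            raise ManifestError(
                f"{path}: state {label}: unknown subunit labels {extra}"
            )
        chain_ids = [str(sub[s]) for s in SUBUNIT_LABELS]
        if len(set(chain_ids)) != 6:
            raise ManifestError(
                f"{path}: state {label}: subunit map must assign six distinct chains, "
                f"got {chain_ids}"
            )
        entries.append(
            ManifestEntry(
                state_label=label,
                file_path=file_path,
                subunit_map={s: str(sub[s]) for s in SUBUNIT_LABELS},
                dna_chain_ids=tuple(str(c) for c in raw.get("dna_chains", []) or []),
                ruvA_d3_chain_ids=tuple(str(c) for c in raw.get("ruva_d3_chains", []) or []),
            )
        )
    return StateManifest(entries=tuple(entries))
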