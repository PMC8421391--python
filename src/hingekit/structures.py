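"""Atomic structures, domain partitions, and rigid-body geometry.

This module is the geometric foundation of the package: it parses PDB and
mmCIF coordinate files into a lightweight array-backed :class:`Structure`,
labels domains through a :class:`DomainPartition`, and computes the scalar
descriptors used by the downstream scattering, surface, and electrostatics
stages -- radius of gyration, the hinge opening angle *theta*, minimal
interresidue distances, and rotamer-swap point mutants.

Conventions
-----------
* Residues are addressed 1-based as in PDB records, by ``(chain, resseq,
  insertion-code)``.
* Alternate locations: the first conformer encountered (normally altloc
  'A') is kept; occupancies are ignored for geometry, which keeps every
  computation deterministic.
* Waters are always dropped on input; hetero atoms (Zn, ligands) are kept
  only when ``include_hetero=True``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import gemmi
from scipy.spatial.transform import Rotation

__all__ = [
    "Structure",
    "ResidueKey",
    "Selection",
    "DomainPartition",
    "GeometryReport",
    "StructureError",
    "FormatError",
    "EmptyStructureError",
    "SelectionError",
    "read_structure",
    "radius_of_gyration",
    "opening_angle_theta",
    "min_interresidue_distance",
    "swap_residue_rotamer",
    "load_domain_partition",
    "default_erap1_partition",
]

BACKBONE_ATOMS = ("N", "CA", "C")


class StructureError(ValueError):
    """Base class for structure-layer errors."""


class FormatError(StructureError):
    """Coordinate text could not be parsed under the requested dialect."""


class EmptyStructureError(StructureError):
    """Parsing or filtering produced zero atoms."""


class SelectionError(StructureError):
    """A residue/atom selector resolved to nothing."""


ResidueKey = tuple  # (chain: str, resseq: int, icode: str)


@dataclass(frozen=True)
class Selection:
    """Residue selector: a chain with an optional residue range.

    ``resseq_end`` defaults to ``resseq_start`` (single residue). ``icode``
    restricts to one insertion code when given.
    """

    chain: str
    resseq_start: int | None = None
    resseq_end: int | None = None
    icode: str | None = None
    resname: str | None = None

    def mask(self, structure: "Structure") -> np.ndarray:
        m = structure.chain == self.chain
        if self.resseq_start is not None:
            end = self.resseq_end if self.resseq_end is not None else self.resseq_start
            m &= (structure.resseq >= self.resseq_start) & (structure.resseq <= end)
        if self.icode is not None:
            m &= structure.icode == self.icode
        if self.resname is not None:
            m &= structure.resname == self.resname
        return m


@dataclass
class Structure:
    """A set of atoms with chain/residue identity, backed by numpy arrays.

    All arrays share the first dimension (one entry per atom). ``record``
    is one of ``protein``, ``hetero``, ``water``.
    """

    element: np.ndarray          # str, element symbol e.g. 'C', 'Zn'
    coords: np.ndarray           # (N, 3) float, Angstrom
    chain: np.ndarray            # str
    resseq: np.ndarray           # int
    icode: np.ndarray            # str ('' when absent)
    resname: np.ndarray          # str
    atom_name: np.ndarray        # str
    altloc: np.ndarray           # str
    record: np.ndarray           # 'protein' | 'hetero' | 'water'
    atomic_number: np.ndarray    # int
    provenance: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if len(self) and not np.all(np.isfinite(self.coords)):
            raise StructureError("non-finite coordinates")

    def __len__(self) -> int:
        return len(self.element)

    def subset(self, mask: np.ndarray, provenance: str | None = None) -> "Structure":
        mask = np.asarray(mask)
        return Structure(
            element=self.element[mask],
            coords=self.coords[mask],
            chain=self.chain[mask],
            resseq=self.resseq[mask],
            icode=self.icode[mask],
            resname=self.resname[mask],
            atom_name=self.atom_name[mask],
            altloc=self.altloc[mask],
            record=self.record[mask],
            atomic_number=self.atomic_number[mask],
            provenance=self.provenance if provenance is None else provenance,
        )

    def select(self, *selections: Selection) -> "Structure":
        if not selections:
            return self
        m = np.zeros(len(self), dtype=bool)
        for sel in selections:
            m |= sel.mask(self)
        return self.subset(m)

    def residue_keys(self) -> list[ResidueKey]:
        """Unique (chain, resseq, icode) keys in order of first appearance."""
        seen: dict[ResidueKey, None] = {}
        for c, r, i in zip(self.chain, self.resseq, self.icode):
            seen.setdefault((str(c), int(r), str(i)), None)
        return list(seen)

    def residue_mask(self, key: ResidueKey) -> np.ndarray:
        c, r, i = key
        return (self.chain == c) & (self.resseq == r) & (self.icode == i)

    def centroid(self, weights: np.ndarray | None = None) -> np.ndarray:
        if weights is None:
            return self.coords.mean(axis=0)
        w = np.asarray(weights, dtype=float)
        return (self.coords * w[:, None]).sum(axis=0) / w.sum()

    def concat(self, other: "Structure") -> "Structure":
        return Structure(
            element=np.concatenate([self.element, other.element]),
            coords=np.vstack([self.coords, other.coords]),
            chain=np.concatenate([self.chain, other.chain]),
            resseq=np.concatenate([self.resseq, other.resseq]),
            icode=np.concatenate([self.icode, other.icode]),
            resname=np.concatenate([self.resname, other.resname]),
            atom_name=np.concatenate([self.atom_name, other.atom_name]),
            altloc=np.concatenate([self.altloc, other.altloc]),
            record=np.concatenate([self.record, other.record]),
            atomic_number=np.concatenate([self.atomic_number, other.atomic_number]),
            provenance=self.provenance,
        )

    def transformed(self, rotation: np.ndarray | None = None,
                    translation: np.ndarray | None = None) -> "Structure":
        """Return a copy under the rigid motion x -> R x + t."""
        xyz = self.coords
        if rotation is not None:
            xyz = xyz @ np.asarray(rotation).T
        if translation is not None:
            xyz = xyz + np.asarray(translation)
        out = replace(self)
        out.coords = xyz
        return out

    # -- output ----------------------------------------------------------

    def to_pdb(self) -> str:
        """Serialize as minimal PDB-format text (ATOM/HETATM records)."""
        lines = []
        for i in range(len(self)):
            rec = "HETATM" if self.record[i] != "protein" else "ATOM  "
            name = self.atom_name[i]
            # PDB atom-name column convention: element-aligned for short names
            name_f = f" {name:<3s}" if len(name) < 4 and len(self.element[i]) == 1 else f"{name:<4s}"
            x, y, z = self.coords[i]
            lines.append(
                f"{rec}{i + 1 % 100000:5d} {name_f}{self.altloc[i] or ' '}"
                f"{self.resname[i]:<3s} {self.chain[i][:1]}{self.resseq[i]:4d}"
                f"{self.icode[i] or ' '}   {x:8.3f}{y:8.3f}{z:8.3f}"
                f"{1.00:6.2f}{0.00:6.2f}          {self.element[i]:>2s}"
            )
        lines.append("END")
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Parsing


def _classify(res: gemmi.Residue) -> str:
    if res.is_water():
        return "water"
    if res.het_flag == "H":
        return "hetero"
    return "protein"


def read_structure(source: str, *, dialect: str | None = None,
                   include_hetero: bool = False, provenance: str = "") -> Structure:
    """Parse coordinate text (or a file path) into a :class:`Structure`.

    Parameters
    ----------
    source:
        PDB or mmCIF text, or a path to such a file.
    dialect:
        'pdb' or 'mmcif'; autodetected when omitted.
    include_hetero:
        Keep HETATM groups other than water (e.g. the catalytic Zn,
        ligands). Waters are always excluded.
    """
    text = source
    if "\n" not in source:
        with open(source) as fh:
            text = fh.read()
        if provenance == "":
            provenance = str(source)
    if dialect is None:
        stripped = text.lstrip()
        dialect = "mmcif" if (stripped.startswith("data_") or "_atom_site." in text) else "pdb"
    try:
        if dialect == "pdb":
            st = gemmi.read_pdb_string(text)
        elif dialect == "mmcif":
            doc = gemmi.cif.read_string(text)
            st = gemmi.make_structure_from_block(doc.sole_block())
        else:
            raise FormatError(f"unknown dialect {dialect!r}")
    except (RuntimeError, ValueError) as exc:  # gemmi reports the offending line
        raise FormatError(f"could not parse {dialect} input: {exc}") from exc

    cols: dict[str, list] = {k: [] for k in
                             ("element", "chain", "resseq", "icode", "resname",
                              "atom_name", "altloc", "record", "atomic_number")}
    xyz: list[tuple[float, float, float]] = []
    if len(st) == 0:
        raise EmptyStructureError("no models in input")
    model = st[0]
    for chain in model:
        for res in chain:
            kind = _classify(res)
            if kind == "water":
                continue
            if kind == "hetero" and not include_hetero:
                continue
            seen_names: set[str] = set()
            for atom in res:
                # keep the first conformer of each altloc group
                if atom.name in seen_names:
                    continue
                seen_names.add(atom.name)
                cols["element"].append(atom.element.name)
                cols["chain"].append(chain.name)
                cols["resseq"].append(res.seqid.num)
                cols["icode"].append(res.seqid.icode.strip())
                cols["resname"].append(res.name)
                cols["atom_name"].append(atom.name)
                cols["altloc"].append(atom.altloc.strip() if atom.altloc else "")
                cols["record"].append(kind)
                cols["atomic_number"].append(atom.element.atomic_number)
                xyz.append((atom.pos.x, atom.pos.y, atom.pos.z))
    if not xyz:
        raise EmptyStructureError("input contains no atoms after filtering")
    return Structure(
        element=np.array(cols["element"], dtype=object),
        coords=np.array(xyz, dtype=float),
        chain=np.array(cols["chain"], dtype=object),
        resseq=np.array(cols["resseq"], dtype=int),
        icode=np.array(cols["icode"], dtype=object),
        resname=np.array(cols["resname"], dtype=object),
        atom_name=np.array(cols["atom_name"], dtype=object),
        altloc=np.array(cols["altloc"], dtype=object),
        record=np.array(cols["record"], dtype=object),
        atomic_number=np.array(cols["atomic_number"], dtype=int),
        provenance=provenance,
    )


# ---------------------------------------------------------------------------
# Domain partitions


@dataclass
class DomainPartition:
    """Named, disjoint groups of residues plus the three hinge-geometry roles.

    ``groups`` maps a group name to a list of selectors. ``hinge``,
    ``proximal`` and ``distal`` name the groups used by
    :func:`opening_angle_theta`; for a domain IV lid closing over a
    domain II body about domain III, the natural assignment is hinge =
    domain III, proximal = domain II, distal = domain IV.
    """

    groups: Mapping[str, Sequence[Selection]]
    hinge: str
    proximal: str
    distal: str

    def group_mask(self, structure: Structure, name: str) -> np.ndarray:
        try:
            sels = self.groups[name]
        except KeyError:
            raise SelectionError(f"partition has no group {name!r}") from None
        m = np.zeros(len(structure), dtype=bool)
        for sel in sels:
            m |= sel.mask(structure)
        if not m.any():
            raise SelectionError(f"group {name!r} matches no atoms")
        return m

    def validate(self, structure: Structure) -> None:
        masks = {name: self.group_mask(structure, name) for name in self.groups}
        total = np.zeros(len(structure), dtype=int)
        for m in masks.values():
            total += m
        if (total > 1).any():
            raise SelectionError("partition groups overlap")


def load_domain_partition(path_or_mapping, chain: str = "A") -> DomainPartition:
    """Build a partition from a JSON config (path, text, or mapping).

    Expected form::

        {"groups": {"I": [[46, 254]], ...},
         "hinge": "III", "proximal": "II", "distal": "IV"}

    Ranges are inclusive residue-number pairs applied to ``chain``.
    """
    if isinstance(path_or_mapping, Mapping):
        cfg = path_or_mapping
    else:
        text = path_or_mapping
        if "\n" not in text and not text.lstrip().startswith("{"):
            with open(text) as fh:
                text = fh.read()
        cfg = json.loads(text)
    groups = {
        name: [Selection(chain, int(a), int(b)) for a, b in ranges]
        for name, ranges in cfg["groups"].items()
    }
    return DomainPartition(groups=groups, hinge=cfg["hinge"],
                           proximal=cfg["proximal"], distal=cfg["distal"])


def default_erap1_partition(chain: str = "A") -> DomainPartition:
    """ERAP1 domain I-IV boundaries from the shipped config.

    The ranges are literature-derived (see the packaged
    ``data/domains_erap1.json`` for the residue numbers and their source);
    override with :func:`load_domain_partition` for other numbering schemes
    or other enzymes.
    """
    text = resources.files("hingekit.data").joinpath("domains_erap1.json").read_text()
    return load_domain_partition(json.loads(text), chain=chain)


# ---------------------------------------------------------------------------
# Geometry


@dataclass
class GeometryReport:
    rg: float                       # Angstrom
    theta: float | None             # degrees, None when no partition given
    centroids: dict[str, np.ndarray] = field(default_factory=dict)


def _weights(structure: Structure, weighting: str) -> np.ndarray:
    if weighting == "uniform":
        return np.ones(len(structure))
    if weighting in ("electron-count", "electron_count"):
        return structure.atomic_number.astype(float)
    if weighting == "mass":
        # average atomic masses for the elements that occur in practice
        table = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "P": 30.974,
                 "S": 32.06, "Se": 78.971, "Zn": 65.38, "Fe": 55.845}
        return np.array([table.get(e, 2.0 * z) for e, z in
                         zip(structure.element, structure.atomic_number)])
    raise ValueError(f"unknown weighting {weighting!r}")


def radius_of_gyration(structure: Structure, weighting: str = "electron-count") -> float:
    """Weighted radius of gyration in Angstrom.

    Rg^2 = sum_i w_i |r_i - rbar|^2 / sum_i w_i with rbar the w-weighted
    centroid. The default electron-count weighting matches the scattering
    observable estimated by Guinier analysis.
    """
    if len(structure) == 0:
        raise EmptyStructureError("Rg of empty structure")
    w = _weights(structure, weighting)
    total = w.sum()
    if total <= 0:
        raise StructureError("zero total weight")
    center = structure.centroid(w)
    d2 = ((structure.coords - center) ** 2).sum(axis=1)
    return float(np.sqrt((w * d2).sum() / total))


def _ca_centroid(structure: Structure, mask: np.ndarray) -> np.ndarray:
    sub = mask & (structure.atom_name == "CA")
    if not sub.any():
        sub = mask  # fall back to all atoms (e.g. pseudo-atom fixtures)
    return structure.coords[sub].mean(axis=0)


def opening_angle_theta(structure: Structure, partition: DomainPartition) -> float:
    """Hinge opening angle in degrees.

    The angle at the hinge-group C-alpha centroid between the rays to the
    proximal-group and distal-group C-alpha centroids. Closed conformers of
    a hinged molecule give smaller theta than open conformers. The exact
    construction behind published per-model order parameters varies between
    studies; this centroid definition is a declared, configurable stand-in
    (the three group roles are set on the partition).
    """
    cen = {role: _ca_centroid(structure, partition.group_mask(structure, getattr(partition, role)))
           for role in ("hinge", "proximal", "distal")}
    v1 = cen["proximal"] - cen["hinge"]
    v2 = cen["distal"] - cen["hinge"]
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 < 1e-9 or n2 < 1e-9:
        raise StructureError("coincident centroids: opening angle undefined")
    cosang = np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


_SIDECHAIN_EXCLUDE = {"N", "CA", "C", "O", "OXT", "H", "HA"}


def _scope_mask(structure: Structure, base: np.ndarray, atom_scope: str) -> np.ndarray:
    if atom_scope == "all":
        return base
    if atom_scope in ("side-chain", "sidechain"):
        keep = ~np.isin(structure.atom_name.astype(str), sorted(_SIDECHAIN_EXCLUDE))
        return base & keep
    # a single named atom, e.g. 'CA' or 'ZN'
    return base & (structure.atom_name == atom_scope)


def min_interresidue_distance(structure: Structure, sel_a: Selection, sel_b: Selection,
                              atom_scope: str = "all") -> float:
    """Minimum interatomic distance (Angstrom) between two selections."""
    ma = _scope_mask(structure, sel_a.mask(structure), atom_scope)
    mb = _scope_mask(structure, sel_b.mask(structure), atom_scope)
    if not ma.any():
        raise SelectionError(f"selector {sel_a} resolves to no atoms under scope {atom_scope!r}")
    if not mb.any():
        raise SelectionError(f"selector {sel_b} resolves to no atoms under scope {atom_scope!r}")
    a, b = structure.coords[ma], structure.coords[mb]
    d = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=-1)
    return float(d.min())


def geometry_report(structure: Structure, partition: DomainPartition | None = None,
                    weighting: str = "electron-count") -> GeometryReport:
    rg = radius_of_gyration(structure, weighting)
    theta = None
    centroids: dict[str, np.ndarray] = {}
    if partition is not None:
        theta = opening_angle_theta(structure, partition)
        for name in partition.groups:
            centroids[name] = _ca_centroid(structure, partition.group_mask(structure, name))
    return GeometryReport(rg=rg, theta=theta, centroids=centroids)


# ---------------------------------------------------------------------------
# Rotamer swapping (computational mutagenesis on fixed backbones)


def _backbone_coords(structure: Structure, mask: np.ndarray) -> np.ndarray:
    out = []
    names = structure.atom_name
    for name in BACKBONE_ATOMS:
        sub = mask & (names == name)
        if not sub.any():
            raise StructureError(f"residue lacks backbone atom {name}")
        out.append(structure.coords[sub][0])
    return np.array(out)


def swap_residue_rotamer(target: Structure, position: Selection,
                         donor: Structure, donor_position: Selection) -> Structure:
    """Replace the side chain at ``position`` with the donor residue's rotamer.

    The donor residue's backbone (N, CA, C) is rigidly superposed onto the
    target's backbone; the transformed donor side-chain atoms then replace
    the target's side chain. The target backbone (including O) is untouched
    and the residue name is updated -- i.e. point mutagenesis using a
    rotamer observed in another structure.
    """
    tmask = position.mask(target)
    dmask = donor_position.mask(donor)
    if not tmask.any():
        raise SelectionError("target position resolves to no atoms")
    if not dmask.any():
        raise SelectionError("donor position resolves to no atoms")
    bb_t = _backbone_coords(target, tmask)
    bb_d = _backbone_coords(donor, dmask)
    ct, cd = bb_t.mean(axis=0), bb_d.mean(axis=0)
    rot, _ = Rotation.align_vectors(bb_t - ct, bb_d - cd)

    is_sidechain_d = dmask & ~np.isin(donor.atom_name.astype(str), list(_SIDECHAIN_EXCLUDE))
    side = donor.subset(is_sidechain_d)
    side.coords = rot.apply(side.coords - cd) + ct

    keep_backbone = tmask & np.isin(target.atom_name.astype(str), list(_SIDECHAIN_EXCLUDE))
    keep = ~tmask | keep_backbone
    out = target.subset(keep)

    # relabel the grafted side chain with the target's residue identity slot
    first = np.flatnonzero(tmask)[0]
    newname = donor.resname[np.flatnonzero(dmask)[0]]
    side.chain = np.full(len(side), target.chain[first], dtype=object)
    side.resseq = np.full(len(side), target.resseq[first], dtype=int)
    side.icode = np.full(len(side), target.icode[first], dtype=object)
    side.resname = np.full(len(side), newname, dtype=object)
    out.resname = out.resname.copy()
    out.resname[out.residue_mask((str(target.chain[first]), int(target.resseq[first]),
                                  str(target.icode[first])))] = newname
    return out.concat(side)
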