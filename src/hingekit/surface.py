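"""Solvent-accessible surface area, interdomain burial, and solvation energy.

Domain closure of a hinged enzyme buries surface at the lid/body interface;
long substrates that bridge the two sides add further buried area and so
bias the open/closed equilibrium. This module quantifies that picture:

* :func:`sasa` -- Shrake-Rupley accessible surface area (uniform sphere
  sampling, probe 1.4 A by default, Bondi-class radii).
* :func:`interdomain_bsa` -- buried surface area between two domain groups,
  BSA = SASA(A) + SASA(B) - SASA(A+B), total and per residue. The receptor
  is split lid-vs-body (for the shipped four-domain config: domains
  I+II+III on one side, domain IV on the other); bound peptides and the
  catalytic Zn ride with the body side, mirroring the convention of
  treating them as part of domains I-III.
* :func:`peptide_bsa_profile` / :func:`cumulative_bsa_difference` -- per
  peptide residue burial against each receptor group (N- to C-terminal),
  and the running closed-minus-open difference along the peptide.
* :func:`solvation_energy` -- atomic-solvation-parameter estimate
  G = sum sigma_class * ASA; only signs and orderings are meaningful at
  this level of theory, not absolute magnitudes.
* :func:`interdomain_contacts` -- residues of each group within a distance
  cutoff of the other group.

BSA is reported as the TOTAL occluded area (both surfaces); pass
``one_sided=True`` to halve it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy.spatial import cKDTree

from .structures import (DomainPartition, ResidueKey, Selection, Structure,
                         SelectionError, StructureError)

__all__ = [
    "SASAResult",
    "BSAResult",
    "BSAProfile",
    "ClosureEnergetics",
    "sasa",
    "interdomain_bsa",
    "peptide_bsa_profile",
    "cumulative_bsa_difference",
    "solvation_energy",
    "interdomain_contacts",
    "load_radii",
    "split_masks",
]


def load_radii(overrides: dict | None = None) -> dict:
    text = resources.files("hingekit.data").joinpath("vdw_radii.json").read_text()
    table = {k: v for k, v in json.loads(text).items() if not k.startswith("_")}
    if overrides:
        table.update(overrides)
    return table


def _atom_radii(structure: Structure, table: dict, allow_default: bool = False) -> np.ndarray:
    out = np.empty(len(structure))
    for i, el in enumerate(structure.element):
        if el in table:
            out[i] = table[el]
        elif allow_default:
            out[i] = table.get("default", 1.8)
        else:
            raise StructureError(f"no van der Waals radius for element {el!r}; "
                                 "pass an override or allow_default=True")
    return out


def _fibonacci_sphere(n: int) -> np.ndarray:
    """n near-uniform points on the unit sphere (golden-spiral lattice)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    golden = np.pi * (1.0 + np.sqrt(5.0))
    theta = golden * i
    return np.column_stack([np.cos(theta) * np.sin(phi),
                            np.sin(theta) * np.sin(phi),
                            np.cos(phi)])


@dataclass
class SASAResult:
    per_atom: np.ndarray            # A^2, aligned with the structure's atoms
    per_residue: dict               # ResidueKey -> A^2
    total: float
    probe: float
    n_points: int


def sasa(structure: Structure, probe: float = 1.4, points_per_atom: int = 960,
         radii: dict | None = None, allow_default_radius: bool = False) -> SASAResult:
    """Shrake-Rupley solvent-accessible surface area.

    Each atom's solvent-center sphere (radius r_i + probe) is sampled with
    a deterministic golden-spiral point set; points falling inside any
    neighbor's solvent sphere are occluded. Accessible area is the
    unoccluded fraction times 4*pi*(r_i+probe)^2.
    """
    if len(structure) == 0:
        raise StructureError("SASA of empty structure")
    table = load_radii() if radii is None else radii
    r = _atom_radii(structure, table, allow_default_radius)
    rs = r + probe
    pts = _fibonacci_sphere(points_per_atom)
    tree = cKDTree(structure.coords)
    # any neighbor whose solvent sphere can intersect ours lies within
    # r_i + r_j + 2*probe <= r_i + probe + max(r_j) + probe
    reach = rs + rs.max()
    per_atom = np.empty(len(structure))
    for i in range(len(structure)):
        nbrs = [j for j in tree.query_ball_point(structure.coords[i], reach[i]) if j != i]
        surf = structure.coords[i] + rs[i] * pts
        if nbrs:
            nbrs = np.array(nbrs)
            d2 = ((surf[:, None, :] - structure.coords[nbrs][None, :, :]) ** 2).sum(-1)
            buried = (d2 < (rs[nbrs] ** 2)[None, :]).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        per_atom[i] = frac * 4.0 * np.pi * rs[i] ** 2
    per_res: dict[ResidueKey, float] = {}
    for key in structure.residue_keys():
        per_res[key] = float(per_atom[structure.residue_mask(key)].sum())
    return SASAResult(per_atom=per_atom, per_residue=per_res,
                      total=float(per_atom.sum()), probe=probe,
                      n_points=points_per_atom)


# ---------------------------------------------------------------------------
# Interdomain burial


def split_masks(structure: Structure, partition: DomainPartition,
                split: tuple = (("I", "II", "III"), ("IV",)),
                hetero_with: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Two-group atom masks for a lid/body chain split.

    ``split`` names the partition groups on each side. Atoms not matched by
    any partition group (bound peptides, Zn and other hetero atoms) are
    routed to side ``hetero_with`` (0 = first/body side by convention).
    Every atom ends up on exactly one side.
    """
    side_masks = []
    for names in split:
        m = np.zeros(len(structure), dtype=bool)
        for name in names:
            m |= partition.group_mask(structure, name)
        side_masks.append(m)
    a, b = side_masks
    if (a & b).any():
        raise SelectionError("split sides overlap")
    rest = ~(a | b)
    if hetero_with == 0:
        a = a | rest
    else:
        b = b | rest
    if not a.any() or not b.any():
        raise SelectionError("empty split side")
    return a, b


@dataclass
class BSAResult:
    total: float                     # A^2, both surfaces
    per_residue: dict                # ResidueKey -> A^2 buried
    sasa_a: float
    sasa_b: float
    sasa_complex: float
    one_sided: bool = False


def interdomain_bsa(structure: Structure, partition: DomainPartition,
                    split: tuple = (("I", "II", "III"), ("IV",)),
                    hetero_with: int = 0, one_sided: bool = False,
                    **sasa_kw) -> BSAResult:
    """Buried surface area between the two sides of a domain split.

    BSA_total = SASA(A alone) + SASA(B alone) - SASA(complex); per-residue
    values use the same difference restricted to each residue's atoms.
    """
    ma, mb = split_masks(structure, partition, split, hetero_with)
    return _bsa_between(structure, ma, mb, one_sided=one_sided, **sasa_kw)


def _bsa_between(structure: Structure, ma: np.ndarray, mb: np.ndarray,
                 one_sided: bool = False, **sasa_kw) -> BSAResult:
    sub_a, sub_b = structure.subset(ma), structure.subset(mb)
    res_a = sasa(sub_a, **sasa_kw)
    res_b = sasa(sub_b, **sasa_kw)
    res_ab = sasa(structure.subset(ma | mb), **sasa_kw)
    factor = 0.5 if one_sided else 1.0
    per_res: dict[ResidueKey, float] = {}
    iso = {}
    for res, sub in ((res_a, sub_a), (res_b, sub_b)):
        for key, area in res.per_residue.items():
            iso[key] = iso.get(key, 0.0) + area
    for key, area in res_ab.per_residue.items():
        buried = iso.get(key, 0.0) - area
        per_res[key] = factor * buried
    total = factor * (res_a.total + res_b.total - res_ab.total)
    return BSAResult(total=float(total), per_residue=per_res,
                     sasa_a=res_a.total, sasa_b=res_b.total,
                     sasa_complex=res_ab.total, one_sided=one_sided)


# ---------------------------------------------------------------------------
# Peptide burial profiles


@dataclass
class BSAProfile:
    """Per-peptide-residue buried area against each receptor domain group.

    Arrays run N- to C-terminal along the peptide. ``group_a`` is burial
    against the body side (domains I-III analog), ``group_b`` against the
    lid side (domain IV analog).
    """

    residues: list                 # ResidueKey, N->C
    group_a: np.ndarray            # A^2
    group_b: np.ndarray            # A^2
    conformer: str = ""            # 'open' | 'closed' | free text

    @property
    def total(self) -> np.ndarray:
        return self.group_a + self.group_b

    def __len__(self) -> int:
        return len(self.residues)


def peptide_bsa_profile(complex_structure: Structure, peptide: Selection,
                        partition: DomainPartition,
                        split: tuple = (("I", "II", "III"), ("IV",)),
                        conformer: str = "", **sasa_kw) -> BSAProfile:
    """Burial of each peptide residue against each receptor domain group.

    For each receptor group G and peptide residue r, the buried area is
    SASA(r) + SASA(G) - SASA(r+G), i.e. the pairwise interface area with
    the residue as one side. Peptide residues are ordered N->C by residue
    number.
    """
    pep_mask = peptide.mask(complex_structure)
    if not pep_mask.any():
        raise SelectionError("peptide selector resolves to no atoms")
    receptor = complex_structure.subset(~pep_mask)
    pep = complex_structure.subset(pep_mask)
    keys = sorted(pep.residue_keys(), key=lambda k: (k[1], k[2]))
    group_masks = []
    for names in split:
        m = np.zeros(len(receptor), dtype=bool)
        for name in names:
            m |= partition.group_mask(receptor, name)
        group_masks.append(m)

    cols = []
    for gmask in group_masks:
        g = receptor.subset(gmask)
        sasa_g = sasa(g, **sasa_kw).total
        burial = np.empty(len(keys))
        for k, key in enumerate(keys):
            r = pep.subset(pep.residue_mask(key))
            sasa_r = sasa(r, **sasa_kw).total
            sasa_rg = sasa(r.concat(g), **sasa_kw).total
            burial[k] = sasa_r + sasa_g - sasa_rg
        cols.append(burial)
    return BSAProfile(residues=keys, group_a=cols[0], group_b=cols[1],
                      conformer=conformer)


def cumulative_bsa_difference(closed: BSAProfile, open_: BSAProfile) -> np.ndarray:
    """Running sum over residues 1..k of (closed - open) total burial.

    The final value telescopes to the total peptide Delta-BSA. The curve is
    monotone non-decreasing wherever closed >= open per residue; for
    substrates whose C-terminus only contacts the lid after closure it
    stays flat over the N-terminal residues and then rises.
    """
    if len(closed) != len(open_):
        raise ValueError("profiles have different peptide lengths")
    return np.cumsum(closed.total - open_.total)


# ---------------------------------------------------------------------------
# Solvation energy and contacts


def _load_asp() -> dict:
    text = resources.files("hingekit.data").joinpath("asp_params.json").read_text()
    return json.loads(text)


def _asp_sigma(structure: Structure, table: dict | None = None) -> np.ndarray:
    table = table if table is not None else _load_asp()
    by_el = table["by_element"]
    overrides = table.get("overrides", {})
    out = np.empty(len(structure))
    for i in range(len(structure)):
        res_over = overrides.get(str(structure.resname[i]), {})
        name = str(structure.atom_name[i])
        if name in res_over:
            out[i] = res_over[name]
            continue
        el = str(structure.element[i])
        if el not in by_el:
            raise StructureError(f"no atomic solvation parameter for element {el!r}")
        out[i] = by_el[el]
    return out


@dataclass
class ClosureEnergetics:
    g_a: float                      # kcal/mol, side A alone
    g_b: float                      # kcal/mol, side B alone
    g_complex: float                # kcal/mol
    delta: float                    # kcal/mol on association (negative = stabilizing)


def solvation_energy(structure: Structure, partition: DomainPartition,
                     split: tuple = (("I", "II", "III"), ("IV",)),
                     hetero_with: int = 0, asp_table: dict | None = None,
                     **sasa_kw) -> ClosureEnergetics:
    """ASP-model solvation energies (kcal/mol) for a domain split.

    G = sum sigma_class * ASA per body; ``delta`` = G(complex) - G(A) -
    G(B) is the association term -- negative when burying predominantly
    apolar surface, i.e. hydrophobic stabilization of the closed state.
    Magnitudes from this class of model are rough; use them for signs and
    orderings between conformers.
    """
    ma, mb = split_masks(structure, partition, split, hetero_with)
    parts = {}
    for label, mask in (("a", ma), ("b", mb), ("ab", ma | mb)):
        sub = structure.subset(mask)
        sig = _asp_sigma(sub, asp_table)
        areas = sasa(sub, **sasa_kw).per_atom
        parts[label] = float((sig * areas).sum())
    return ClosureEnergetics(g_a=parts["a"], g_b=parts["b"], g_complex=parts["ab"],
                             delta=parts["ab"] - parts["a"] - parts["b"])


def interdomain_contacts(structure: Structure, partition: DomainPartition,
                         split: tuple = (("I", "II", "III"), ("IV",)),
                         hetero_with: int = 0,
                         cutoff: float = 4.0) -> tuple[list, list]:
    """Residues of each split side with any atom within ``cutoff`` of the other.

    Returns ``(contacts_a, contacts_b)`` as sorted residue-key lists. By
    construction every contact residue on one side has a partner atom
    within the cutoff on the other side.
    """
    ma, mb = split_masks(structure, partition, split, hetero_with)
    a, b = structure.subset(ma), structure.subset(mb)
    tree_b = cKDTree(b.coords)
    d_a, _ = tree_b.query(a.coords)
    tree_a = cKDTree(a.coords)
    d_b, _ = tree_a.query(b.coords)

    def collect(sub: Structure, dist: np.ndarray) -> list:
        hits = set()
        close = dist <= cutoff
        for i in np.flatnonzero(close):
            hits.add((str(sub.chain[i]), int(sub.resseq[i]), str(sub.icode[i])))
        return sorted(hits, key=lambda k: (k[0], k[1], k[2]))

    return collect(a, d_a), collect(b, d_b)


def contact_difference(closed: tuple[list, list], open_: tuple[list, list]) -> tuple[list, list]:
    """Contacts present in the closed conformer but not the open one, per side."""
    return ([k for k in closed[0] if k not in set(open_[0])],
            [k for k in closed[1] if k not in set(open_[1])])
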