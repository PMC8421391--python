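"""Synthetic fixtures with known ground truth for every pipeline stage.

Real inputs to this kind of analysis -- experimental scattering curves,
molecular-dynamics conformer families, crystallographic complexes -- are
large and often not redistributable, so each generator here builds a
minimal object that exercises one analysis stage and records the truth it
was built from:

* :func:`make_hinge_structure` -- three random-packed pseudo-domain
  globules (proximal body, hinge, distal lid) whose centroid geometry
  realizes a requested opening angle exactly, emulating a hinge-motion
  conformer family.
* :func:`simulate_saxs` -- Debye curve plus seeded Gaussian noise with a
  populated uncertainty column.
* :func:`make_peptide_complex` -- a two-globule receptor with a pseudo-
  peptide threaded through the cleft so that planned residues touch the
  planned globule, in matched closed and open (lid translated away)
  variants.
* :func:`make_kinetics_dataset` -- saturation or dose-response data from a
  named rate law with known parameters.
* :func:`make_crosslink_dataset` -- observed-mass lists with a fixed-mass
  adduct planted at a known residue.

Pseudo-atoms are carbon-like (vdW radius 1.7 A, 6 electrons) packed by
rejection sampling at >= 3 A separation; every generator is deterministic
under its seed and returns its ground-truth record alongside the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .structures import DomainPartition, Selection, Structure
from .saxs import ScatteringProfile, debye_profile
from .kinetics import AllostericSigmoidal, DoseResponse, MichaelisMenten
from .xlink import adduct_mass, tryptic_digest, ALLOWED_CROSSLINK_RESIDUES

__all__ = [
    "HingeSpec",
    "FixtureBundle",
    "make_hinge_structure",
    "simulate_saxs",
    "make_peptide_complex",
    "make_kinetics_dataset",
    "make_crosslink_dataset",
    "CONTACT_THRESHOLD",
]

#: interatomic distance below which a planned contact counts as touching
CONTACT_THRESHOLD = 4.5


class FixtureError(ValueError):
    pass


@dataclass
class HingeSpec:
    """Recipe for a hinged three-globule pseudo-structure."""

    theta: float = 60.0             # requested opening angle, degrees
    globule_radius: float = 8.0     # A, each pseudo-domain
    atoms_per_globule: int = 60
    arm_length: float = 25.0        # A, hinge centroid to outer centroids
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.theta < 180:
            raise FixtureError("theta must lie in (0, 180)")
        if self.atoms_per_globule < 10:
            raise FixtureError("need >= 10 atoms per globule")
        if self.arm_length <= self.globule_radius:
            raise FixtureError("arm too short: globules would overlap the hinge")


@dataclass
class FixtureBundle:
    """Generated object(s) plus the machine-readable ground truth."""

    structure: Structure | None
    truth: dict
    seed: int
    extras: dict = field(default_factory=dict)


def _pack_globule(rng: np.random.Generator, n: int, radius: float,
                  min_sep: float = 3.0, max_tries: int = 200000) -> np.ndarray:
    """Rejection-sample n points in a sphere with pairwise separation >= min_sep."""
    pts: list[np.ndarray] = []
    tries = 0
    while len(pts) < n:
        tries += 1
        if tries > max_tries:
            raise FixtureError(f"cannot pack {n} atoms at >= {min_sep} A "
                               f"into radius {radius} A")
        p = rng.uniform(-radius, radius, size=3)
        if p @ p > radius ** 2:
            continue
        if pts and np.min(np.linalg.norm(np.array(pts) - p, axis=1)) < min_sep:
            continue
        pts.append(p)
    arr = np.array(pts)
    return arr - arr.mean(axis=0)   # exact zero centroid


def _pseudo_chain(coords: np.ndarray, chain: str, start_resseq: int = 1) -> Structure:
    """Carbon-like pseudo-atoms, one CA per single-residue 'GLY'."""
    n = len(coords)
    return Structure(
        element=np.array(["C"] * n, dtype=object),
        coords=np.asarray(coords, dtype=float),
        chain=np.array([chain] * n, dtype=object),
        resseq=np.arange(start_resseq, start_resseq + n, dtype=int),
        icode=np.array([""] * n, dtype=object),
        resname=np.array(["GLY"] * n, dtype=object),
        atom_name=np.array(["CA"] * n, dtype=object),
        altloc=np.array([""] * n, dtype=object),
        record=np.array(["protein"] * n, dtype=object),
        atomic_number=np.array([6] * n, dtype=int),
        provenance=f"synthetic:{chain}",
    )


def hinge_partition() -> DomainPartition:
    """Partition matching the chains emitted by :func:`make_hinge_structure`."""
    return DomainPartition(
        groups={"proximal": [Selection("P")], "hinge": [Selection("H")],
                "distal": [Selection("D")]},
        hinge="hinge", proximal="proximal", distal="distal")


def make_hinge_structure(spec: HingeSpec | None = None, **kwargs) -> FixtureBundle:
    """Three labeled pseudo-domains realizing the requested opening angle.

    Chains: 'H' (hinge, centered at the origin), 'P' (proximal, at
    ``arm_length`` along +x) and 'D' (distal, at ``arm_length`` in the xy
    plane at the requested angle from +x). Each globule is re-centered
    after packing, so the centroid construction reproduces theta exactly;
    the generator still verifies separation to catch infeasible specs.
    """
    spec = spec or HingeSpec(**kwargs)
    rng = np.random.default_rng(spec.seed)
    th = np.radians(spec.theta)
    centers = {
        "H": np.zeros(3),
        "P": np.array([spec.arm_length, 0.0, 0.0]),
        "D": spec.arm_length * np.array([np.cos(th), np.sin(th), 0.0]),
    }
    for a, b in (("H", "P"), ("H", "D"), ("P", "D")):
        if np.linalg.norm(centers[a] - centers[b]) < 2 * spec.globule_radius:
            raise FixtureError(
                f"globules {a}/{b} overlap at theta = {spec.theta} deg; "
                "increase arm_length or decrease globule_radius")
    chains = []
    start = 1
    for name in ("P", "H", "D"):
        pts = _pack_globule(rng, spec.atoms_per_globule, spec.globule_radius)
        chains.append(_pseudo_chain(pts + centers[name], name, start))
        start += spec.atoms_per_globule
    st = chains[0].concat(chains[1]).concat(chains[2])
    st.provenance = f"synthetic-hinge:theta={spec.theta}"
    from .structures import radius_of_gyration
    truth = {"theta": spec.theta, "rg": radius_of_gyration(st, "uniform"),
             "centers": {k: v.tolist() for k, v in centers.items()},
             "spec": spec}
    return FixtureBundle(structure=st, truth=truth, seed=spec.seed)


def simulate_saxs(structure: Structure, q_grid: Sequence[float] | None = None,
                  noise_fraction: float = 0.02, seed: int = 0,
                  form_factor_model: str = "electron-count") -> ScatteringProfile:
    """Debye curve with seeded Gaussian noise; sigma = noise_fraction * I.

    ``noise_fraction = 0`` returns the exact model curve with a tiny
    nominal sigma column so chi-square fitting stays defined.
    """
    if noise_fraction < 0:
        raise FixtureError("noise_fraction must be non-negative")
    if q_grid is None:
        q_grid = np.linspace(0.01, 0.5, 100)
    clean = debye_profile(structure, q_grid, form_factor_model)
    rng = np.random.default_rng(seed)
    if noise_fraction == 0:
        sigma = np.full_like(clean.I, max(clean.I.max() * 1e-9, 1e-12))
        return ScatteringProfile(clean.q, clean.I, sigma,
                                 label=clean.label + "+noiseless")
    sigma = noise_fraction * clean.I
    noisy = clean.I + rng.normal(0.0, sigma)
    return ScatteringProfile(clean.q, noisy, sigma, label=clean.label + "+noise")


# ---------------------------------------------------------------------------
# Peptide-in-cleft complexes


def receptor_partition() -> DomainPartition:
    """Partition for :func:`make_peptide_complex` receptors (body 'B', lid 'L')."""
    return DomainPartition(
        groups={"body": [Selection("B")], "lid": [Selection("L")]},
        hinge="body", proximal="body", distal="lid")


def make_peptide_complex(peptide_length: int = 10,
                         contact_plan: Mapping[int, str] | None = None,
                         globule_radius: float = 8.0,
                         atoms_per_globule: int = 60,
                         gap: float = 22.0,
                         open_shift: float = 100.0,
                         seed: int = 0) -> FixtureBundle:
    """Two-globule receptor plus a pseudo-peptide with planned contacts.

    The receptor has a body globule 'B' (centered at -gap/2 on x) and a lid
    globule 'L' (+gap/2); the peptide chain 'Q' runs along y between them,
    far from both except where the ``contact_plan`` (1-based residue index
    -> 'body' | 'lid') pulls a residue to within touching distance
    (< 4.5 A) of the planned globule's nearest atom. The bundle's extras
    hold the matched 'closed' complex and an 'open' variant with the lid
    translated ``open_shift`` A away (guaranteeing zero lid burial).
    """
    contact_plan = dict(contact_plan or {})
    for idx, grp in contact_plan.items():
        if not 1 <= idx <= peptide_length:
            raise FixtureError(f"contact plan index {idx} outside peptide")
        if grp not in ("body", "lid"):
            raise FixtureError(f"unknown group {grp!r} in contact plan")
    rng = np.random.default_rng(seed)
    half = gap / 2.0
    centers = {"B": np.array([-half, 0.0, 0.0]), "L": np.array([half, 0.0, 0.0])}
    if gap < 2 * globule_radius:
        raise FixtureError("gap smaller than globule diameter")
    body = _pseudo_chain(_pack_globule(rng, atoms_per_globule, globule_radius)
                         + centers["B"], "B", 1)
    lid = _pseudo_chain(_pack_globule(rng, atoms_per_globule, globule_radius)
                        + centers["L"], "L", 1001)

    # peptide backbone: straight line along y at standoff z, spaced 6 A so
    # neighbouring pseudo-residues never co-occlude a planned contact
    spacing = 6.0
    standoff = globule_radius + 12.0
    ys = (np.arange(peptide_length) - (peptide_length - 1) / 2.0) * spacing
    pep_coords = np.column_stack([np.zeros_like(ys), ys,
                                  np.full_like(ys, standoff)])
    planned_contacts = {}
    for idx, grp in contact_plan.items():
        target = body if grp == "body" else lid
        # nearest target atom to this residue's y station, then place the
        # residue 3.8 A outside it along the outward normal
        station = np.array([centers["B" if grp == "body" else "L"][0], ys[idx - 1], 0.0])
        j = int(np.argmin(np.linalg.norm(target.coords - station, axis=1)))
        anchor = target.coords[j]
        normal = anchor - centers["B" if grp == "body" else "L"]
        normal = normal / np.linalg.norm(normal)
        pep_coords[idx - 1] = anchor + 3.8 * normal
        planned_contacts[idx] = grp
    pep = _pseudo_chain(pep_coords, "Q", 1)
    closed = body.concat(lid).concat(pep)
    closed.provenance = "synthetic-peptide-complex:closed"
    lid_open = lid.transformed(translation=np.array([open_shift, 0.0, 0.0]))
    open_ = body.concat(lid_open).concat(pep)
    open_.provenance = "synthetic-peptide-complex:open"
    truth = {"contact_plan": planned_contacts, "peptide_length": peptide_length,
             "peptide_chain": "Q", "open_shift": open_shift}
    # verify the construction honors the plan
    for idx, grp in planned_contacts.items():
        target = body if grp == "body" else lid
        d = np.linalg.norm(target.coords - pep_coords[idx - 1], axis=1).min()
        if d >= CONTACT_THRESHOLD:
            raise FixtureError(f"unsatisfiable contact plan at residue {idx}")
    return FixtureBundle(structure=closed, truth=truth, seed=seed,
                         extras={"open": open_, "closed": closed,
                                 "partition": receptor_partition()})


# ---------------------------------------------------------------------------
# Kinetics and crosslink datasets


_KINETICS_MODELS = {"mm": MichaelisMenten, "hill": AllostericSigmoidal,
                    "dose": DoseResponse}


def make_kinetics_dataset(model: str, params: Mapping[str, float],
                          x_grid: Sequence[float], noise_fraction: float = 0.02,
                          seed: int = 0, direction: str = "inhibition"):
    """Rate-law data with known parameters plus seeded Gaussian noise.

    ``model`` is 'mm' (Vmax, Km), 'hill' (Vmax, Khalf, h) or 'dose' (XC50,
    h, top, bottom). Noise is Gaussian with sigma = noise_fraction * max
    response amplitude (constant across the grid, so low-signal points are
    not overweighted). Returns ``(x, y, truth)``.
    """
    if model not in _KINETICS_MODELS:
        raise FixtureError(f"unknown kinetics model {model!r}")
    if noise_fraction < 0:
        raise FixtureError("noise_fraction must be non-negative")
    x = np.asarray(x_grid, dtype=float)
    rng = np.random.default_rng(seed)
    # evaluate through a throwaway model object (the evaluate methods are
    # static in behaviour but live on instances)
    kwargs = {"direction": direction} if model == "dose" else {}
    dummy = _KINETICS_MODELS[model](x, np.zeros_like(x), **kwargs)
    y_true = dummy.evaluate(x, dict(params))
    scale = float(np.max(np.abs(y_true)))
    y = y_true + rng.normal(0.0, noise_fraction * scale if noise_fraction else 0.0,
                            size=x.shape) if noise_fraction else y_true.copy()
    truth = {"model": model, "params": dict(params),
             "noise_fraction": noise_fraction, "seed": seed}
    return x, y, truth


def make_crosslink_dataset(parent_sequence: str, planted_site: int,
                           adduct: float | None = None, seed: int = 0,
                           jitter_ppm: float = 2.0, mode: str = "monoisotopic",
                           missed_cleavages: int = 0):
    """Observed-mass list with an adduct planted at a known parent position.

    The peptide covering ``planted_site`` (1-based) gets the adduct mass
    added; every digest peptide's mass is reported, with seeded ppm jitter
    below the matching tolerance. Returns ``(observed_masses, truth)``.
    """
    peptides = tryptic_digest(parent_sequence, missed_cleavages=missed_cleavages)
    host = next((p for p in peptides if p.start <= planted_site <= p.end), None)
    if host is None:
        raise FixtureError(f"site {planted_site} outside parent")
    residue = host.tokens[planted_site - host.start]
    if residue not in ALLOWED_CROSSLINK_RESIDUES:
        raise FixtureError(f"planted residue {residue!r} at {planted_site} is not "
                           f"in the allowed set {sorted(ALLOWED_CROSSLINK_RESIDUES)}")
    add = adduct_mass(mode) if adduct is None else float(adduct)
    rng = np.random.default_rng(seed)
    observed = []
    for pep in peptides:
        m = pep.mass(mode)
        if pep is host:
            m += add
        observed.append(m * (1.0 + rng.normal(0.0, jitter_ppm * 1e-6)))
    truth = {"planted_site": planted_site, "residue": residue,
             "host_peptide": host.sequence, "adduct": add, "seed": seed}
    return observed, truth
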