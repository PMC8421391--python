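"""Photo-crosslink probe mass arithmetic and adduct-site mapping.

A benzophenone-bearing probe peptide (C-terminal p-benzoyl-L-phenylalanine
amide, "BPA") inserts into a nearby C-H bond on UV irradiation. Tryptic
digestion of the crosslinked conjugate cleaves the probe itself, leaving
the BPA-amide moiety -- C16H16N2O2, nominal 268 Da / average 268.31 Da /
monoisotopic 268.121 Da -- as a fixed-mass adduct on the receptor peptide
that carried the insertion site. Candidate sites are localized by adding
the adduct mass to each tryptic peptide of the receptor sequence and
matching observed parent masses within a ppm tolerance, restricted to the
residue types benzophenone prefers (Leu, Ser, Trp, Met by default).

Element masses and standard residue compositions come from pyteomics;
nonstandard residues (the BPA token) are declared by elemental composition
in :data:`EXTRA_RESIDUES`. Benzophenone insertion into a C-H bond adds the
whole probe moiety with no leaving group, hence the adduct mass equals the
BPA-amide fragment mass.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from pyteomics import mass as pmass

__all__ = [
    "Composition",
    "DigestPeptide",
    "CrosslinkHit",
    "XlinkError",
    "mass_from_composition",
    "parse_sequence",
    "peptide_mass",
    "tryptic_digest",
    "match_adduct_sites",
    "BPA_AMIDE_COMPOSITION",
    "adduct_mass",
    "ALLOWED_CROSSLINK_RESIDUES",
]


class XlinkError(ValueError):
    pass


Composition = pmass.Composition

#: BPA-amide: p-benzoyl-L-phenylalanine with an amidated carboxyl, the
#: fragment trypsin leaves behind at the insertion site.
BPA_AMIDE_COMPOSITION = Composition(formula="C16H16N2O2")

#: in-chain residue compositions beyond the 20 standard amino acids
EXTRA_RESIDUES = {
    # Bpa residue (amino acid C16H15NO3 minus water)
    "Bpa": Composition(formula="C16H13NO2"),
}

ALLOWED_CROSSLINK_RESIDUES = frozenset("LSWM")

_H2O = Composition(formula="H2O")
_NH3 = Composition(formula="NH3")


def _element_mass(element: str, mode: str) -> float:
    if element not in pmass.nist_mass:
        raise XlinkError(f"unknown element {element!r}")
    if mode == "monoisotopic":
        return pmass.nist_mass[element][0][0]
    if mode == "nominal":
        return float(round(pmass.nist_mass[element][0][0]))
    if mode == "average":
        iso = pmass.nist_mass[element]
        avg = sum(m * ab for k, (m, ab) in iso.items() if k != 0)
        return avg if avg > 0 else iso[0][0]
    raise XlinkError(f"unknown mass mode {mode!r}")


def mass_from_composition(comp: Composition | dict | str, mode: str = "average",
                          protonated: bool = False) -> float:
    """Mass in Da of an elemental composition.

    ``mode`` selects average, monoisotopic, or nominal (integer) element
    masses. ``protonated`` adds one proton, for comparison with singly
    protonated ESMS ions.
    """
    if isinstance(comp, str):
        comp = Composition(formula=comp)
    total = sum(count * _element_mass(el, mode) for el, count in comp.items())
    if protonated:
        proton = {"average": 1.00739, "monoisotopic": 1.00728, "nominal": 1.0}[mode]
        total += proton
    return float(total)


# ---------------------------------------------------------------------------
# Sequences and digestion

_TOKEN_RE = re.compile(r"[A-Z](?:[a-z]+)?")


def parse_sequence(sequence: str) -> tuple[list, str]:
    """Tokenize a residue string into residue tokens and a C-terminal group.

    Accepts plain one-letter strings ("LLKHHAFSFK"), multi-letter residue
    tokens joined by dashes ("LLKHHAFSFK-BPA"), and an optional trailing
    "-NH2" marking an amidated C-terminus. A trailing BPA token implies the
    amide terminus (the probe chemistry couples BPA as its amide).
    Returns ``(tokens, cterm)`` with cterm 'OH' or 'NH2'.
    """
    cterm = "OH"
    parts = sequence.strip().split("-")
    if parts and parts[-1].upper() == "NH2":
        cterm = "NH2"
        parts = parts[:-1]
    tokens: list[str] = []
    for part in parts:
        if not part:
            raise XlinkError(f"empty token in sequence {sequence!r}")
        if part.upper() == "BPA":
            tokens.append("Bpa")
            continue
        if len(part) > 1 and part in EXTRA_RESIDUES:
            tokens.append(part)
            continue
        for ch in part:
            if ch not in pmass.std_aa_comp and ch not in EXTRA_RESIDUES:
                raise XlinkError(f"unknown residue token {ch!r} in {sequence!r}")
            tokens.append(ch)
    if not tokens:
        raise XlinkError("empty sequence")
    if tokens[-1] == "Bpa":
        cterm = "NH2"
    return tokens, cterm


def _residue_comp(token: str) -> Composition:
    if token in EXTRA_RESIDUES:
        return EXTRA_RESIDUES[token]
    try:
        return pmass.std_aa_comp[token]
    except KeyError:
        raise XlinkError(f"unknown residue token {token!r}") from None


def peptide_mass(tokens, mode: str = "average", cterm: str = "OH") -> float:
    """Mass of a peptide given residue tokens; water or amide terminus."""
    if isinstance(tokens, str):
        tokens, cterm = parse_sequence(tokens)
    comp = Composition()
    for t in tokens:
        comp += _residue_comp(t)
    comp += _H2O if cterm == "OH" else _NH3
    return mass_from_composition(comp, mode)


@dataclass
class DigestPeptide:
    tokens: list                    # residue tokens, N->C
    start: int                      # 1-based inclusive position in parent
    end: int
    missed_cleavages: int
    cterm: str                      # 'OH' or 'NH2'

    @property
    def sequence(self) -> str:
        return "".join(t if len(t) == 1 else t.upper() for t in self.tokens)

    def mass(self, mode: str = "average") -> float:
        return peptide_mass(self.tokens, mode=mode, cterm=self.cterm)

    def __len__(self) -> int:
        return len(self.tokens)


def tryptic_digest(sequence: str, missed_cleavages: int = 0) -> list[DigestPeptide]:
    """Tryptic fragments of a residue string.

    Cleaves C-terminal to K or R except when the next residue is P.
    Fragments tile the parent without gaps; the parent's own C-terminal
    group (acid or amide) is inherited by the last fragment only.
    """
    tokens, cterm = parse_sequence(sequence)
    cut_after = [i for i in range(len(tokens) - 1)
                 if tokens[i] in ("K", "R") and tokens[i + 1] != "P"]
    bounds = [0] + [i + 1 for i in cut_after] + [len(tokens)]
    peptides = []
    n_frag = len(bounds) - 1
    for i in range(n_frag):
        for j in range(i + 1, min(i + 2 + missed_cleavages, n_frag + 1)):
            start, end = bounds[i], bounds[j]
            peptides.append(DigestPeptide(
                tokens=tokens[start:end], start=start + 1, end=end,
                missed_cleavages=j - i - 1,
                cterm=cterm if end == len(tokens) else "OH"))
    return peptides


# ---------------------------------------------------------------------------
# Adduct matching


def adduct_mass(mode: str = "average") -> float:
    """Mass of the BPA-amide adduct in the requested mode (268 Da nominal)."""
    return mass_from_composition(BPA_AMIDE_COMPOSITION, mode)


@dataclass
class CrosslinkHit:
    position: int                   # 1-based residue position in the parent
    residue: str
    peptide: DigestPeptide
    observed_mass: float
    candidate_mass: float
    delta_ppm: float
    tolerance_ppm: float


def match_adduct_sites(parent_sequence: str, observed_masses,
                       adduct: float | None = None,
                       allowed_residues=ALLOWED_CROSSLINK_RESIDUES,
                       tolerance_ppm: float = 10.0,
                       missed_cleavages: int = 0,
                       mode: str = "monoisotopic") -> list[CrosslinkHit]:
    """Candidate adduct sites explaining the observed parent masses.

    For every tryptic peptide of the parent and every allowed residue in
    it, the candidate mass is peptide mass + adduct mass; an observed mass
    within the ppm tolerance of a candidate yields one hit per compatible
    site (site-level ambiguity within a peptide is reported, not resolved
    -- fragment-level evidence is out of scope here).
    """
    if any(m <= 0 for m in observed_masses):
        raise XlinkError("observed masses must be positive")
    add = adduct_mass(mode) if adduct is None else float(adduct)
    allowed = frozenset(allowed_residues)
    hits: list[CrosslinkHit] = []
    for pep in tryptic_digest(parent_sequence, missed_cleavages=missed_cleavages):
        candidate = pep.mass(mode) + add
        for obs in observed_masses:
            ppm = (obs - candidate) / candidate * 1e6
            if abs(ppm) > tolerance_ppm:
                continue
            for offset, token in enumerate(pep.tokens):
                if token in allowed:
                    hits.append(CrosslinkHit(
                        position=pep.start + offset, residue=token,
                        peptide=pep, observed_mass=float(obs),
                        candidate_mass=float(candidate), delta_ppm=float(ppm),
                        tolerance_ppm=tolerance_ppm))
    hits.sort(key=lambda h: (h.position, abs(h.delta_ppm)))
    return hits
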