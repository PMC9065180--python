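"""In-silico chymotryptic digestion and glycopeptide candidate expansion.

Peptides are cut from isoforms with configurable chymotrypsin specificity
(C-terminal to F/Y/W/L, never before proline) and then expanded into
glycopeptide candidates by assigning O-glycan compositions from the observed
glycome to subsets of their Ser/Thr sites.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from pyteomics import mass as _pmass

from .chem import PROTON, WATER, GlycanComposition, modification_delta
from .isoforms import ProteinIsoform

__all__ = [
    "Peptide",
    "GlycopeptideCandidate",
    "CHYMOTRYPSIN_RESIDUES",
    "residue_mass",
    "peptide_backbone_mass",
    "cleavage_sites",
    "digest",
    "expand_glycoforms",
    "precursor_mz",
]

#: Chymotrypsin high-specificity cleavage residues (C-terminal side).
CHYMOTRYPSIN_RESIDUES = "FYWL"

#: Monoisotopic amino-acid residue masses (pyteomics CODATA/IUPAC values).
_AA_MASS: Dict[str, float] = dict(_pmass.std_aa_mass)


def residue_mass(aa: str) -> float:
    try:
        return _AA_MASS[aa]
    except KeyError:
        raise ValueError(f"unknown amino-acid residue {aa!r}") from None


@lru_cache(maxsize=262_144)
def peptide_backbone_mass(sequence: str) -> float:
    """Neutral monoisotopic mass of an unmodified peptide (residues + H2O)."""
    if not sequence:
        raise ValueError("empty peptide sequence")
    return sum(residue_mass(a) for a in sequence) + WATER


@dataclass(frozen=True)
class Peptide:
    """A proteolytic peptide located on its source isoform.

    ``start``/``end`` are 0-based half-open coordinates on the isoform;
    ``junction_tags`` lists the exon-exon junctions the peptide spans with at
    least one residue on each side.
    """

    isoform_id: str
    start: int
    end: int
    sequence: str
    missed_cleavages: int
    junction_tags: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.end - self.start != len(self.sequence):
            raise ValueError("peptide coordinates inconsistent with sequence length")

    @property
    def st_sites(self) -> Tuple[int, ...]:
        """Peptide-local indices of Ser/Thr residues (candidate glycosites)."""
        return tuple(i for i, a in enumerate(self.sequence) if a in "ST")


@dataclass(frozen=True)
class GlycopeptideCandidate:
    """A peptide plus a concrete modification state.

    ``glyco_sites`` maps peptide-local S/T indices to glycan compositions;
    ``fixed_mods`` and ``variable_mods`` carry (site, delta) pairs. The
    neutral mass is strictly additive: backbone + all deltas.
    """

    peptide: Peptide
    glyco_sites: Tuple[Tuple[int, GlycanComposition], ...] = ()
    fixed_mods: Tuple[Tuple[int, float], ...] = ()
    variable_mods: Tuple[Tuple[int, float], ...] = ()
    is_decoy: bool = False
    #: strictly additive, fixed at construction: backbone + all deltas
    neutral_mass: float = field(init=False, compare=False, default=0.0)

    def __post_init__(self) -> None:
        for site, _ in self.glyco_sites:
            if self.peptide.sequence[site] not in "ST":
                raise ValueError(
                    f"glyco site {site} is {self.peptide.sequence[site]!r}, not S/T"
                )
        m = peptide_backbone_mass(self.peptide.sequence)
        m += sum(d for _, d in self.fixed_mods)
        m += sum(d for _, d in self.variable_mods)
        for _, comp in self.glyco_sites:
            m += modification_delta(comp)
        object.__setattr__(self, "neutral_mass", m)

    @property
    def total_glycan(self) -> GlycanComposition:
        total = GlycanComposition()
        for _, comp in self.glyco_sites:
            total = total + comp
        return total

    @property
    def n_glyco_sites(self) -> int:
        return len(self.glyco_sites)

    @property
    def glycan_string(self) -> str:
        return str(self.total_glycan) if self.glyco_sites else "unmodified"


def cleavage_sites(sequence: str, residues: str = CHYMOTRYPSIN_RESIDUES) -> List[int]:
    """Cut positions (0-based, between ``i`` and ``i+1``) for the rule
    'after residues, never before P'. The C-terminus is not a cut site."""
    return [
        i + 1
        for i in range(len(sequence) - 1)
        if sequence[i] in residues and sequence[i + 1] != "P"
    ]


def digest(
    iso: ProteinIsoform,
    max_missed: int = 2,
    min_length: int = 5,
    max_length: int = 45,
    residues: str = CHYMOTRYPSIN_RESIDUES,
) -> List[Peptide]:
    """Chymotryptic digest of an isoform with 0..max_missed missed cleavages.

    Length bounds apply after product enumeration; set ``min_length=1`` and
    ``max_length`` large to obtain the full tiling. Junction tags are
    populated for products spanning a junction boundary with >= 1 residue on
    each side.
    """
    if max_missed < 0:
        raise ValueError("max_missed must be >= 0")
    seq = iso.aa_sequence
    if not seq:
        raise ValueError("empty isoform sequence")
    cuts = [0] + cleavage_sites(seq, residues) + [len(seq)]
    out: List[Peptide] = []
    for i in range(len(cuts) - 1):
        for j in range(i + 1, min(i + 2 + max_missed, len(cuts))):
            start, end = cuts[i], cuts[j]
            if not (min_length <= end - start <= max_length):
                continue
            tags = tuple(
                tag for tag, pos in iso.junctions if start < pos < end
            )
            out.append(
                Peptide(
                    isoform_id=iso.isoform_id,
                    start=start,
                    end=end,
                    sequence=seq[start:end],
                    missed_cleavages=j - i - 1,
                    junction_tags=tags,
                )
            )
    return out


def _fixed_modifications(sequence: str, carbamidomethyl_delta: Optional[float]) -> Tuple[Tuple[int, float], ...]:
    if carbamidomethyl_delta is None:
        return ()
    return tuple(
        (i, carbamidomethyl_delta) for i, a in enumerate(sequence) if a == "C"
    )


def expand_glycoforms(
    peptide: Peptide,
    space: Sequence[GlycanComposition],
    max_occupied_sites: int = 3,
    max_candidates: int = 10_000,
    carbamidomethyl_delta: Optional[float] = None,
) -> Tuple[List[GlycopeptideCandidate], bool]:
    """All glycoform candidates of a peptide over a composition space.

    Assigns 0..max_occupied_sites distinct S/T sites, each carrying any
    composition from ``space`` (with repetition across sites), in
    deterministic lexicographic order (site combinations ascending, then
    composition tuples in ``space`` order). Returns ``(candidates,
    truncated)``: when the combinatorial count exceeds ``max_candidates``
    enumeration stops there and ``truncated`` is True — never silent.
    """
    if not space:
        raise ValueError("empty glycan composition space")
    fixed = _fixed_modifications(peptide.sequence, carbamidomethyl_delta)
    sites = peptide.st_sites
    out: List[GlycopeptideCandidate] = []
    truncated = False
    max_k = min(max_occupied_sites, len(sites))
    for k in range(0, max_k + 1):
        for chosen in itertools.combinations(sites, k):
            for comps in itertools.product(space, repeat=k):
                if len(out) >= max_candidates:
                    truncated = True
                    return out, truncated
                out.append(
                    GlycopeptideCandidate(
                        peptide=peptide,
                        glyco_sites=tuple(zip(chosen, comps)),
                        fixed_mods=fixed,
                    )
                )
    return out, truncated


def precursor_mz(candidate: GlycopeptideCandidate, z: int) -> float:
    """(neutral mass + z protons) / z."""
    if z < 1:
        raise ValueError("charge must be >= 1")
    return (candidate.neutral_mass + z * PROTON) / z
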