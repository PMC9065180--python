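"""Monoisotopic mass calculus for mucin-type O-glycans and peptide modifications.

Two derivatization chemistries are covered:

* native Ser/Thr glyco-modification deltas (the glycosyl residue masses that a
  search engine adds to a peptide backbone), and
* permethylated benzyl glycosides measured by MALDI as [M+Na]+ — the readout
  of the benzyl-GalNAc O-glycome reporter assay.

All masses derive from elemental compositions via :mod:`pyteomics.mass`;
no literature mass is hardcoded anywhere in this module.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from typing import Dict, Iterable, List, Mapping, Tuple

from pyteomics import mass as _pmass

__all__ = [
    "GlycanComposition",
    "IonSpecies",
    "MONOSACCHARIDES",
    "RESIDUE_MASS",
    "PROTON",
    "WATER",
    "SODIUM_CATION",
    "modification_delta",
    "permethylated_bn_mz",
    "oxonium_series",
    "oxonium_trigger_mz",
    "sequence_modification_delta",
    "modification_catalogue",
]

# ---------------------------------------------------------------------------
# elemental building blocks

#: Glycosyl *residue* formulas (monosaccharide minus water), i.e. the mass a
#: glycan residue adds when condensed onto a peptide hydroxyl or another sugar.
MONOSACCHARIDES: Dict[str, str] = {
    "HexNAc": "C8H13NO5",
    "Hex": "C6H10O5",
    "dHex": "C6H10O4",
    "NeuAc": "C11H17NO8",
}

#: Canonical ordering used in composition strings ("HexNAc1Hex1NeuAc2").
MONOSACCHARIDE_ORDER: Tuple[str, ...] = ("HexNAc", "Hex", "dHex", "NeuAc")

RESIDUE_MASS: Dict[str, float] = {
    name: _pmass.calculate_mass(formula=f) for name, f in MONOSACCHARIDES.items()
}

_ELECTRON = _pmass.nist_mass["e*"][0][0]
PROTON = _pmass.calculate_mass(formula="H") - _ELECTRON
WATER = _pmass.calculate_mass(formula="H2O")
CH2 = _pmass.calculate_mass(formula="CH2")
#: Na+ adduct mass: atomic sodium minus one electron.
SODIUM_CATION = _pmass.calculate_mass(formula="Na") - _ELECTRON
_BENZYL_AGLYCONE = _pmass.calculate_mass(formula="C7H8O")  # benzyl alcohol

#: Methylation sites on each *free* monosaccharide (all hydroxyls including
#: the anomeric one; the acetamido NH; NeuAc additionally methyl-esterifies
#: its carboxyl). Each glycosidic linkage consumes two sites (donor anomeric
#: OH + acceptor OH) and the benzyl aglycone consumes the reducing-end
#: anomeric OH, so the total count depends only on composition, not linkage.
_METHYL_SITES: Dict[str, int] = {"Hex": 5, "HexNAc": 5, "dHex": 4, "NeuAc": 7}


# ---------------------------------------------------------------------------
# glycan compositions


@dataclass(frozen=True, order=True)
class GlycanComposition:
    """Monosaccharide count vector {HexNAc, Hex, dHex, NeuAc}.

    Immutable and hashable so compositions can key search-space sets.
    """

    hexnac: int = 0
    hex: int = 0
    dhex: int = 0
    neuac: int = 0

    def __post_init__(self) -> None:
        for field in ("hexnac", "hex", "dhex", "neuac"):
            v = getattr(self, field)
            if not isinstance(v, int) or v < 0:
                raise ValueError(f"{field} count must be a non-negative integer, got {v!r}")

    @property
    def counts(self) -> Dict[str, int]:
        return {"HexNAc": self.hexnac, "Hex": self.hex, "dHex": self.dhex, "NeuAc": self.neuac}

    @property
    def total(self) -> int:
        return self.hexnac + self.hex + self.dhex + self.neuac

    def __add__(self, other: "GlycanComposition") -> "GlycanComposition":
        return GlycanComposition(
            self.hexnac + other.hexnac,
            self.hex + other.hex,
            self.dhex + other.dhex,
            self.neuac + other.neuac,
        )

    def __str__(self) -> str:
        parts = [f"{name}{n}" for name, n in self.counts.items() if n]
        return "".join(parts) if parts else "unmodified"

    @classmethod
    def from_counts(cls, counts: Mapping[str, int]) -> "GlycanComposition":
        unknown = set(counts) - set(MONOSACCHARIDES)
        if unknown:
            raise ValueError(f"unknown monosaccharides: {sorted(unknown)}")
        return cls(
            counts.get("HexNAc", 0), counts.get("Hex", 0),
            counts.get("dHex", 0), counts.get("NeuAc", 0),
        )

    @classmethod
    def from_string(cls, s: str) -> "GlycanComposition":
        """Parse a composition string like ``"HexNAc1Hex1NeuAc2"``.

        Count 1 may be omitted (``"HexNAcHex"``); dHex must precede NeuAc in
        no particular order — tokens are matched greedily longest-first.
        """
        counts: Dict[str, int] = {}
        pos = 0
        token = re.compile(r"(HexNAc|NeuAc|dHex|Hex)(\d*)")
        while pos < len(s):
            m = token.match(s, pos)
            if not m:
                raise ValueError(f"cannot parse glycan composition {s!r} at offset {pos}")
            name, num = m.group(1), m.group(2)
            counts[name] = counts.get(name, 0) + (int(num) if num else 1)
            pos = m.end()
        return cls.from_counts(counts)


@lru_cache(maxsize=None)
def modification_delta(composition: GlycanComposition) -> float:
    """Ser/Thr glyco-modification mass delta in Da.

    The delta is the sum of glycosyl residue masses — additive and linear in
    the counts; e.g. a single HexNAc adds m(C8H13NO5). Cached: compositions
    are immutable and the search space is small.
    """
    if composition.total == 0:
        raise ValueError("all-zero glycan composition has no mass delta")
    return sum(RESIDUE_MASS[name] * n for name, n in composition.counts.items())


def permethylated_bn_mz(composition: GlycanComposition) -> float:
    """[M+Na]+ m/z of the permethylated benzyl glycoside of ``composition``.

    The molecule is the glycan condensed onto benzyl alcohol at the reducing
    end, with every free hydroxyl O-methylated, every acetamido nitrogen
    N-methylated, and NeuAc carboxyls methyl-esterified. For ``n`` residues
    the methyl-site count is ``Σ sites(residue) − 2(n−1) − 1`` (each of the
    n−1 glycosidic bonds removes a donor anomeric OH and an acceptor OH; the
    benzyl removes the reducing-end anomeric OH) and is therefore independent
    of linkage or branching.
    """
    if composition.hexnac < 1:
        raise ValueError(
            "permethylated benzyl glycosides require HexNAc >= 1 "
            "(reducing-end GalNAc on the benzyl aglycone)"
        )
    n = composition.total
    residue_sum = sum(RESIDUE_MASS[name] * c for name, c in composition.counts.items())
    n_sites = sum(_METHYL_SITES[name] * c for name, c in composition.counts.items()) - 2 * (n - 1) - 1
    neutral = residue_sum + _BENZYL_AGLYCONE + n_sites * CH2
    return neutral + SODIUM_CATION


# ---------------------------------------------------------------------------
# oxonium / diagnostic ions


@dataclass(frozen=True)
class IonSpecies:
    label: str
    mz: float
    charge: int = 1
    formula: str = ""


#: Fragment cation formulas for the HexNAc oxonium ion and its water /
#: cross-ring losses. The 144/138 pair discriminates GalNAc from GlcNAc.
_HEXNAC_OXONIUM_FORMULAS: Tuple[Tuple[str, str], ...] = (
    ("HexNAc-oxonium", "C8H14NO5"),
    ("HexNAc-H2O", "C8H12NO4"),
    ("HexNAc-2H2O", "C8H10NO3"),
    ("HexNAc-C2H4O2", "C6H10NO3"),
    ("HexNAc-CH6O3", "C7H8NO2"),
    ("HexNAc-C2H6O3", "C6H8NO2"),
)


def oxonium_series(kind: str = "HexNAc") -> List[IonSpecies]:
    """Diagnostic oxonium ion set for a monosaccharide kind (only HexNAc).

    Returns the parent oxonium cation (C8H14NO5+, m/z 204.087) and its
    neutral-loss / cross-ring fragments at 186.076, 168.066, 144.066,
    138.055 and 126.055, each computed from the fragment cation formula.
    """
    if kind != "HexNAc":
        raise ValueError(f"unknown oxonium kind {kind!r}; supported: 'HexNAc'")
    out = []
    for label, formula in _HEXNAC_OXONIUM_FORMULAS:
        mz = _pmass.calculate_mass(formula=formula) - _ELECTRON
        out.append(IonSpecies(label=label, mz=mz, charge=1, formula=formula + "+"))
    return out


def oxonium_trigger_mz() -> float:
    """m/z of the HexNAc oxonium cation used as the HCD→CID trigger."""
    return oxonium_series("HexNAc")[0].mz


# ---------------------------------------------------------------------------
# sequence (non-glyco) modification catalogue


@dataclass(frozen=True)
class SequenceModification:
    name: str
    targets: Tuple[str, ...]
    delta: float
    formula_gain: str
    formula_loss: str
    printed_delta: float
    printed_decimals: int = 4


def _parse_printed(s: str) -> float:
    # the catalogue (like some printed tables) may use a decimal comma
    return float(s.replace(",", "."))


def _load_catalogue() -> Dict[str, SequenceModification]:
    cat: Dict[str, SequenceModification] = {}
    text = resources.files("glycopg").joinpath("data/modifications.tsv").read_text()
    header = None
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        if header is None:
            header = line.split("\t")
            continue
        name, targets, gain, loss, printed = line.split("\t")
        delta = 0.0
        if gain != "-":
            delta += _pmass.calculate_mass(formula=gain)
        if loss != "-":
            delta -= _pmass.calculate_mass(formula=loss)
        cat[name] = SequenceModification(
            name=name,
            targets=tuple(t.strip() for t in targets.split(",")),
            delta=delta,
            formula_gain=gain,
            formula_loss=loss,
            printed_delta=_parse_printed(printed),
            printed_decimals=len(printed.replace(",", ".").split(".")[-1]),
        )
    return cat


_CATALOGUE: Dict[str, SequenceModification] = _load_catalogue()


def modification_catalogue() -> Dict[str, SequenceModification]:
    """The full registered sequence-modification catalogue (name -> entry)."""
    return dict(_CATALOGUE)


def _normalize_name(name: str) -> str:
    return name.replace("→", "->").strip()


def sequence_modification_delta(name: str) -> float:
    """Monoisotopic delta (Da) of a catalogued sequence modification.

    The value is computed from the elemental gain/loss formulas, not read from
    a printed table. Unknown names raise with the list of valid entries.
    """
    key = _normalize_name(name)
    if key not in _CATALOGUE:
        raise KeyError(
            f"unknown modification {name!r}; catalogue: {sorted(_CATALOGUE)}"
        )
    return _CATALOGUE[key].delta
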