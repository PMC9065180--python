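"""MALDI glycome annotation and search-space derivation.

Peak lists of permethylated benzyl O-glycosides ([M+Na]+, positive reflector
mode) are annotated against an enumerated composition library; the annotated
glycome is then converted into the Ser/Thr variable-modification search space
used for glycopeptide matching — optionally augmented with progressively
de-sialylated forms to cover incomplete sialidase digestion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .chem import GlycanComposition, permethylated_bn_mz

__all__ = [
    "PeakList",
    "Assignment",
    "GlycomeAnnotation",
    "COMPOSITION_NAMES",
    "composition_label",
    "enumerate_composition_library",
    "annotate_peaks",
    "glycome_to_search_space",
    "read_peaklist_csv",
]

#: Short names for mono-structure compositions of the mucin-type O-glycome.
COMPOSITION_NAMES: Dict[GlycanComposition, str] = {
    GlycanComposition(hexnac=1): "Tn",
    GlycanComposition(hexnac=1, neuac=1): "STn",
    GlycanComposition(hexnac=1, hex=1): "T",
    GlycanComposition(hexnac=2): "core 3",
    GlycanComposition(hexnac=1, hex=1, dhex=1): "fucosyl-T",
    GlycanComposition(hexnac=1, hex=1, neuac=1): "sialyl-T",
    GlycanComposition(hexnac=1, hex=1, neuac=2): "disialyl-T",
    GlycanComposition(hexnac=2, hex=1): "core 2",
}


def composition_label(comp: GlycanComposition) -> str:
    """Trivial name when the composition maps to a single known structure,
    otherwise the composition string itself."""
    return COMPOSITION_NAMES.get(comp, str(comp))


@dataclass
class PeakList:
    """A centroided MALDI peak list (m/z ascending, intensities >= 0)."""

    mz: np.ndarray
    intensity: np.ndarray
    polarity: str = "positive"
    adduct: str = "[M+Na]+"

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity must have the same shape")
        if self.mz.size:
            if np.any(self.mz <= 0):
                raise ValueError("m/z values must be strictly positive")
            if np.any(self.intensity < 0):
                raise ValueError("intensities must be non-negative")
            order = np.argsort(self.mz, kind="stable")
            self.mz = self.mz[order]
            self.intensity = self.intensity[order]

    def __len__(self) -> int:
        return int(self.mz.size)


@dataclass(frozen=True)
class Assignment:
    mz_observed: float
    composition: GlycanComposition
    mz_theoretical: float
    ppm_error: float
    label: str


@dataclass
class GlycomeAnnotation:
    assignments: List[Assignment]
    unassigned: List[float]
    tol_ppm: float

    @property
    def compositions(self) -> List[GlycanComposition]:
        return [a.composition for a in self.assignments]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "mz_observed": a.mz_observed,
                "composition": str(a.composition),
                "label": a.label,
                "mz_theoretical": a.mz_theoretical,
                "ppm_error": a.ppm_error,
            }
            for a in self.assignments
        ]
        return pd.DataFrame(
            rows,
            columns=["mz_observed", "composition", "label", "mz_theoretical", "ppm_error"],
        )


def enumerate_composition_library(
    max_counts: Dict[str, int],
    mz_range: Tuple[float, float] = (540.0, 2000.0),
) -> List[Tuple[GlycanComposition, float]]:
    """All compositions with HexNAc >= 1 whose permethylated benzyl-glycoside
    [M+Na]+ m/z falls inside ``mz_range``; deduplicated and sorted by m/z."""
    lo, hi = mz_range
    if lo >= hi:
        raise ValueError(f"invalid m/z range ({lo}, {hi})")
    out: List[Tuple[GlycanComposition, float]] = []
    for hexnac in range(1, max_counts.get("HexNAc", 0) + 1):
        for hx in range(0, max_counts.get("Hex", 0) + 1):
            for dh in range(0, max_counts.get("dHex", 0) + 1):
                for na in range(0, max_counts.get("NeuAc", 0) + 1):
                    comp = GlycanComposition(hexnac, hx, dh, na)
                    mz = permethylated_bn_mz(comp)
                    if lo <= mz <= hi:
                        out.append((comp, mz))
    out.sort(key=lambda cm: (cm[1], cm[0]))
    return out


def annotate_peaks(
    peaks: PeakList,
    library: Sequence[Tuple[GlycanComposition, float]],
    tol_ppm: float = 10.0,
) -> GlycomeAnnotation:
    """Nearest-mass composition assignment within a ppm tolerance.

    Ties are broken by smaller |ppm error|, then by fewer total
    monosaccharides. Peaks with no library entry in tolerance are reported
    as unassigned. Annotation depends only on m/z values, so it is invariant
    to peak order and intensity rescaling.
    """
    if not library:
        raise ValueError("empty composition library")
    assignments: List[Assignment] = []
    unassigned: List[float] = []
    for mz in peaks.mz:
        best: Optional[Tuple[float, int, GlycanComposition, float]] = None
        for comp, mz_theo in library:
            ppm = (mz - mz_theo) / mz_theo * 1e6
            if abs(ppm) > tol_ppm:
                continue
            key = (abs(ppm), comp.total)
            if best is None or key < (best[0], best[1]):
                best = (abs(ppm), comp.total, comp, mz_theo)
        if best is None:
            unassigned.append(float(mz))
        else:
            _, _, comp, mz_theo = best
            assignments.append(
                Assignment(
                    mz_observed=float(mz),
                    composition=comp,
                    mz_theoretical=mz_theo,
                    ppm_error=(mz - mz_theo) / mz_theo * 1e6,
                    label=composition_label(comp),
                )
            )
    return GlycomeAnnotation(assignments, unassigned, tol_ppm)


def glycome_to_search_space(
    annotation: GlycomeAnnotation,
    include_desialylated_partials: bool = True,
) -> List[GlycanComposition]:
    """Ser/Thr variable-modification list derived from an annotated glycome.

    The observed compositions are kept as-is; when
    ``include_desialylated_partials`` is set, every progressively
    NeuAc-stripped form of each observed composition is added as well (the
    samples are sialidase-treated before digestion, but de-sialylation can be
    incomplete). The single-HexNAc (Tn) composition is always present. The
    result is deduplicated and deterministically ordered.
    """
    space = {GlycanComposition(hexnac=1)}
    for comp in annotation.compositions:
        space.add(comp)
        if include_desialylated_partials:
            stripped = comp
            while stripped.neuac > 0:
                stripped = GlycanComposition(
                    stripped.hexnac, stripped.hex, stripped.dhex, stripped.neuac - 1
                )
                space.add(stripped)
    return sorted(space)


def read_peaklist_csv(path, **kwargs) -> PeakList:
    """Read a 2-column (m/z, intensity) CSV/TSV peak list."""
    df = pd.read_csv(path, sep=None, engine="python", comment="#", **kwargs)
    if df.shape[1] < 2:
        raise ValueError("peak list needs two columns: m/z, intensity")
    return PeakList(df.iloc[:, 0].to_numpy(float), df.iloc[:, 1].to_numpy(float))
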