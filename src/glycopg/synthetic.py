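"""Ground-truthed synthetic fixtures: exon grammars, glycome peaks, spectra.

Every stage of the toolkit can be exercised without external downloads: a
19-exon toy grammar shaped like the CD44 locus (5 constitutive N-terminal
exons, 9 variable exons, 5 constitutive C-terminal exons), MALDI peak lists
for a chosen glycome, and HCD/CID spectra for known glycopeptide candidates
with a configurable noise model. All outputs are bit-reproducible under a
fixed seed (single-threaded numpy Generator; peaks are sorted by m/z with a
stable sort before emission).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .chem import GlycanComposition, oxonium_series, permethylated_bn_mz
from .digest import GlycopeptideCandidate, precursor_mz
from .glycome import PeakList
from .isoforms import Exon, ExonModel, TranscriptModel
from .scoring import theoretical_fragments
from .spectra import Spectrum

__all__ = [
    "GeneratorConfig",
    "SpectrumTruth",
    "generate_toy_cd44_grammar",
    "generate_spectra",
    "generate_null_spectra",
    "generate_glycome_peaks",
]


@dataclass
class GeneratorConfig:
    """Knobs of the spectrum generator.

    * ``efficiency`` — probability that a theoretical fragment is observed.
    * ``noise_lambda`` — Poisson mean of the noise-peak count per spectrum;
      noise m/z is uniform over ``scan_range`` and noise intensity log-normal.
    * ``jitter_ppm`` — mass accuracy: every emitted m/z (precursor and
      fragments) is shifted by a uniform draw in ±jitter_ppm.
    * ``oxonium_ratio_144_138`` — the generated GalNAc-type intensity ratio
      between the 144.066 and 138.055 cross-ring fragments.
    """

    seed: int = 0
    efficiency: float = 0.7
    noise_lambda: float = 20.0
    jitter_ppm: float = 5.0
    scan_range: Tuple[float, float] = (110.0, 2000.0)
    intensity_mu: float = 10.0       # log-normal location of fragment intensities
    intensity_sigma: float = 0.5
    oxonium_ratio_144_138: float = 2.5
    oxonium_intensity_sigma: float = 0.1
    charge: int = 2

    def __post_init__(self) -> None:
        if not (0.0 < self.efficiency <= 1.0):
            raise ValueError("efficiency must be in (0, 1]")
        if self.noise_lambda < 0:
            raise ValueError("noise_lambda must be >= 0")


@dataclass
class SpectrumTruth:
    """Generator-side ground truth for one spectrum."""

    spectrum_id: str
    candidate: Optional[GlycopeptideCandidate]  # None for pure-noise spectra
    fragmentation: str
    glycosylated: bool


# ---------------------------------------------------------------------------
# toy exon grammar

_CODONS_BY_AA = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGA",
    "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG", "N": "AAT", "P": "CCT",
    "Q": "CAA", "R": "AGA", "S": "TCT", "T": "ACT", "V": "GTT", "W": "TGG",
    "Y": "TAT",
}
# Sampled residue pool: no Met (keeps the first AUG at the transcript start),
# cleavage residues present so chymotryptic products stay within length bounds.
_BASE_POOL = "ADEGKNQRVHIP"
_CLEAVE_POOL = "FYWL"


def _sample_exon_nt(
    rng: np.random.Generator,
    n_codons: int,
    st_density: float,
) -> str:
    """Seeded codon sampler with controlled Ser/Thr density.

    Every 6th codon is a cleavage residue (F/Y/W/L) so digests of any exon
    combination produce search-scale peptides; no ATG or stop codons are
    emitted inside an exon.
    """
    codons = []
    for i in range(n_codons):
        if i % 6 == 5:
            aa = _CLEAVE_POOL[rng.integers(len(_CLEAVE_POOL))]
        elif rng.random() < st_density:
            aa = "ST"[rng.integers(2)]
        else:
            aa = _BASE_POOL[rng.integers(len(_BASE_POOL))]
        codons.append(_CODONS_BY_AA[aa])
    return "".join(codons)


def generate_toy_cd44_grammar(
    seed: int = 44,
    variable_st_density: float = 0.35,
    constitutive_st_density: float = 0.10,
) -> Tuple[ExonModel, List[TranscriptModel]]:
    """A 19-exon synthetic grammar shaped like the CD44 splicing locus.

    Exons e1–e5 are constitutive and N-terminal (e1 opens with ATG), v2–v10
    are the nine variable exons (Ser/Thr-dense, as in the mucin-like variable
    region), and e15–e19 are the constitutive C-terminal exons (e19 ends with
    a stop codon). All exon lengths are codon multiples so any variable-exon
    subset preserves the reading frame. Returned transcripts emulate the
    standard-isoform (all variable exons skipped, producing the e5-e15
    junction), v2-10, v3-10 and v8-10 structures.
    """
    rng = np.random.default_rng(seed)
    exons: List[Exon] = []
    for i in range(1, 6):
        seq = _sample_exon_nt(rng, 18, constitutive_st_density)
        if i == 1:
            seq = "ATG" + seq[3:]
        exons.append(Exon(f"e{i}", "constitutive", seq))
    for i in range(2, 11):
        exons.append(
            Exon(f"v{i}", "variable", _sample_exon_nt(rng, 15, variable_st_density))
        )
    for i in range(15, 20):
        seq = _sample_exon_nt(rng, 15, constitutive_st_density)
        if i == 19:
            seq = seq + "TAA"
        exons.append(Exon(f"e{i}", "constitutive", seq))
    model = ExonModel.from_exons(exons, mode="nt")

    head = [f"e{i}" for i in range(1, 6)]
    tail = [f"e{i}" for i in range(15, 20)]

    def t(tid: str, variable: Sequence[str]) -> TranscriptModel:
        refs = [(e, None, None) for e in head + list(variable) + tail]
        return TranscriptModel(tid, refs)

    transcripts = [
        t("CD44s_like", []),
        t("CD44v2-10_like", [f"v{i}" for i in range(2, 11)]),
        t("CD44v3-10_like", [f"v{i}" for i in range(3, 11)]),
        t("CD44v8-10_like", [f"v{i}" for i in range(8, 11)]),
    ]
    return model, transcripts


# ---------------------------------------------------------------------------
# spectra


def _jitter(rng: np.random.Generator, mz: np.ndarray, ppm: float) -> np.ndarray:
    if ppm <= 0:
        return mz
    return mz * (1.0 + rng.uniform(-ppm, ppm, size=mz.shape) * 1e-6)


def _noise_peaks(
    rng: np.random.Generator, cfg: GeneratorConfig
) -> Tuple[np.ndarray, np.ndarray]:
    n = int(rng.poisson(cfg.noise_lambda))
    mz = rng.uniform(cfg.scan_range[0], cfg.scan_range[1], size=n)
    inten = rng.lognormal(cfg.intensity_mu - 2.0, 1.0, size=n)
    return mz, inten


_OXONIUM_BASE_INTENSITY = {
    # relative pattern of the HexNAc oxonium series in a GalNAc-type spectrum;
    # the 144/138 pair is overwritten from cfg.oxonium_ratio_144_138
    "HexNAc-oxonium": 1.0,
    "HexNAc-H2O": 0.6,
    "HexNAc-2H2O": 0.5,
    "HexNAc-C2H4O2": 0.5,
    "HexNAc-CH6O3": 0.2,
    "HexNAc-C2H6O3": 0.7,
}


def _generate_one(
    rng: np.random.Generator,
    candidate: GlycopeptideCandidate,
    cfg: GeneratorConfig,
    mode: str,
    scan_id: str,
) -> Spectrum:
    frags = theoretical_fragments(candidate, mode=mode)
    glycosylated = bool(candidate.glyco_sites)
    mzs: List[float] = []
    intens: List[float] = []
    base = float(np.exp(cfg.intensity_mu))
    for f in frags:
        if f.label.startswith("HexNAc-"):
            continue  # oxonium handled below with controlled intensities
        if rng.random() > cfg.efficiency:
            continue
        mzs.append(f.mz)
        intens.append(rng.lognormal(cfg.intensity_mu, cfg.intensity_sigma))
    if glycosylated and mode == "HCD":
        # diagnostic series always present (the trigger peak in particular),
        # with the configured 144/138 ratio under mild multiplicative noise
        for ion in oxonium_series("HexNAc"):
            rel = _OXONIUM_BASE_INTENSITY[ion.label]
            if ion.label == "HexNAc-CH6O3":  # 138.055
                rel = 0.2
            elif ion.label == "HexNAc-C2H4O2":  # 144.066
                rel = 0.2 * cfg.oxonium_ratio_144_138
            noise = rng.lognormal(0.0, cfg.oxonium_intensity_sigma)
            mzs.append(ion.mz)
            intens.append(2.0 * base * rel * noise)
    noise_mz, noise_int = _noise_peaks(rng, cfg)
    all_mz = np.concatenate([_jitter(rng, np.asarray(mzs), cfg.jitter_ppm), noise_mz])
    all_int = np.concatenate([np.asarray(intens), noise_int])
    z = cfg.charge
    pre = precursor_mz(candidate, z)
    pre = float(_jitter(rng, np.asarray([pre]), cfg.jitter_ppm)[0])
    return Spectrum(
        scan_id=scan_id,
        precursor_mz=pre,
        precursor_charge=z,
        fragmentation=mode,
        mz=all_mz,
        intensity=all_int,
        retention_time=float(rng.uniform(60, 3600)),
    )


def generate_spectra(
    candidates: Sequence[GlycopeptideCandidate],
    cfg: GeneratorConfig,
    modes: Sequence[str] = ("HCD",),
) -> Tuple[List[Spectrum], List[SpectrumTruth]]:
    """Generate one spectrum per (candidate, mode) with ground truth.

    Fragments of the candidate are observed with probability ``efficiency``
    at log-normal intensities; glycosylated HCD spectra always carry the
    HexNAc oxonium series; Poisson noise peaks and ppm mass jitter are added
    per the config. Deterministic for a fixed config.
    """
    rng = np.random.default_rng(cfg.seed)
    spectra: List[Spectrum] = []
    truths: List[SpectrumTruth] = []
    for i, cand in enumerate(candidates):
        for mode in modes:
            sid = f"T{i}_{mode}"
            spectra.append(_generate_one(rng, cand, cfg, mode, sid))
            truths.append(
                SpectrumTruth(sid, cand, mode, bool(cand.glyco_sites))
            )
    return spectra, truths


def generate_null_spectra(
    precursor_mzs: Sequence[float],
    cfg: GeneratorConfig,
    charge: Optional[int] = None,
) -> Tuple[List[Spectrum], List[SpectrumTruth]]:
    """Pure-noise HCD spectra parked at given precursor m/z values.

    These emulate co-isolated junk triggered on precursors that match a
    candidate by mass: all peaks are noise, so any confident GPSM on them is
    a false discovery by construction.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    z = charge if charge is not None else cfg.charge
    spectra, truths = [], []
    for i, pre in enumerate(precursor_mzs):
        noise_mz, noise_int = _noise_peaks(rng, cfg)
        sid = f"N{i}"
        spectra.append(
            Spectrum(
                scan_id=sid,
                precursor_mz=float(pre),
                precursor_charge=z,
                fragmentation="HCD",
                mz=noise_mz,
                intensity=noise_int,
                retention_time=float(rng.uniform(60, 3600)),
            )
        )
        truths.append(SpectrumTruth(sid, None, "HCD", False))
    return spectra, truths


# ---------------------------------------------------------------------------
# glycome peaks


def generate_glycome_peaks(
    compositions: Sequence[GlycanComposition],
    jitter_ppm: float = 0.0,
    seed: int = 0,
    intensities: Optional[Sequence[float]] = None,
) -> PeakList:
    """MALDI [M+Na]+ peak list for permethylated benzyl glycosides.

    Intensity ranks are configurable to emulate sample-specific abundance
    patterns; defaults to equal intensities.
    """
    rng = np.random.default_rng(seed)
    if not compositions:
        return PeakList(np.array([]), np.array([]))
    mz = np.array([permethylated_bn_mz(c) for c in compositions])
    mz = _jitter(rng, mz, jitter_ppm)
    if intensities is None:
        inten = np.full(len(compositions), 1000.0)
    else:
        inten = np.asarray(intensities, dtype=float)
        if inten.shape != mz.shape:
            raise ValueError("intensities length must match compositions")
    return PeakList(mz, inten)
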