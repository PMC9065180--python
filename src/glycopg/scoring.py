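"""Glycopeptide-spectrum matching, binomial scoring and target-decoy FDR.

The matcher is an open, documented surrogate for commercial search engines:
fragments are matched by presence/absence within a Da tolerance and a
candidate is scored by the binomial tail probability of matching at least as
many of its theoretical fragments by chance, given the spectrum's peak
density. Confidence is controlled with reversed-peptide decoys and q-values.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .chem import (
    PROTON,
    WATER,
    GlycanComposition,
    modification_delta,
    oxonium_series,
)
from .digest import GlycopeptideCandidate, Peptide, precursor_mz, residue_mass
from .spectra import Spectrum, diagnostic_ratio

__all__ = [
    "TheoreticalFragment",
    "FragmentMatch",
    "GPSM",
    "theoretical_fragments",
    "match_fragments",
    "score_spectrum",
    "make_decoy",
    "generate_decoys",
    "target_decoy_fdr",
    "localize_sites",
    "search_spectra",
    "gpsm_table",
    "DEFAULT_FRAGMENT_TOL",
]

#: Fragment-matching tolerances (Da) per fragmentation type: Orbitrap HCD
#: read-out vs linear-ion-trap CID read-out.
DEFAULT_FRAGMENT_TOL: Dict[str, float] = {"HCD": 0.02, "CID": 0.6}


@dataclass(frozen=True)
class TheoreticalFragment:
    label: str
    mz: float
    charge: int
    site_dependent: bool = False  # glycan-retained backbone ion (site-determining)


@dataclass(frozen=True)
class FragmentMatch:
    fragment: TheoreticalFragment
    observed_mz: float
    intensity: float

    @property
    def error_da(self) -> float:
        return self.observed_mz - self.fragment.mz


@dataclass
class GPSM:
    """A scored glycopeptide-spectrum match."""

    spectrum_id: str
    candidate: GlycopeptideCandidate
    matches: List[FragmentMatch]
    n_theoretical: int
    score: float
    is_decoy: bool = False
    q_value: Optional[float] = None
    site_localized: Optional[bool] = None
    oxonium_ratio: Optional[float] = None

    @property
    def n_matched(self) -> int:
        return len({m.fragment.mz for m in self.matches})


# ---------------------------------------------------------------------------
# theoretical fragment generation


def _site_deltas(candidate: GlycopeptideCandidate) -> Dict[int, float]:
    deltas: Dict[int, float] = {}
    for site, d in candidate.fixed_mods:
        deltas[site] = deltas.get(site, 0.0) + d
    for site, d in candidate.variable_mods:
        deltas[site] = deltas.get(site, 0.0) + d
    return deltas


def _glyco_deltas(candidate: GlycopeptideCandidate) -> Dict[int, float]:
    return {site: modification_delta(c) for site, c in candidate.glyco_sites}


def _sub_compositions(total: GlycanComposition) -> List[GlycanComposition]:
    """All compositions obtainable from ``total`` by removing monosaccharides
    (the composition-level Y-ion ladder), excluding ``total`` itself."""
    out = []
    for hexnac in range(total.hexnac + 1):
        for hx in range(total.hex + 1):
            for dh in range(total.dhex + 1):
                for na in range(total.neuac + 1):
                    c = GlycanComposition(hexnac, hx, dh, na)
                    if c != total:
                        out.append(c)
    return out


def theoretical_fragments(
    candidate: GlycopeptideCandidate,
    mode: str = "HCD",
    charges: Tuple[int, ...] = (1, 2),
) -> List[TheoreticalFragment]:
    """Theoretical fragment ions of a glycopeptide candidate.

    HCD: O-glycans are labile, so the b/y series is generated both naked
    (glycans stripped) and glycan-retained (each fragment keeps the glycans of
    the sites it contains); the HexNAc oxonium series is added when the
    candidate is glycosylated. CID: Y-ion ladder of the intact peptide with
    progressive glycan losses down to Y0, plus the naked b/y series.
    Singly and doubly charged fragments by default.
    """
    if mode not in ("HCD", "CID"):
        raise ValueError(f"bad fragmentation mode {mode!r}")
    seq = candidate.peptide.sequence
    n = len(seq)
    seq_deltas = _site_deltas(candidate)
    gly_deltas = _glyco_deltas(candidate)
    prefix = np.zeros(n + 1)
    prefix_gly = np.zeros(n + 1)
    for i, aa in enumerate(seq):
        prefix[i + 1] = prefix[i] + residue_mass(aa) + seq_deltas.get(i, 0.0)
        prefix_gly[i + 1] = prefix_gly[i] + gly_deltas.get(i, 0.0)
    backbone = prefix[n] + WATER  # peptide + sequence mods, no glycans
    total_glycan_mass = prefix_gly[n]
    glycosylated = bool(candidate.glyco_sites)

    frags: List[TheoreticalFragment] = []

    def add(label: str, neutral: float, site_dependent: bool = False) -> None:
        for z in charges:
            frags.append(
                TheoreticalFragment(
                    label=f"{label}^{z}",
                    mz=(neutral + z * PROTON) / z,
                    charge=z,
                    site_dependent=site_dependent,
                )
            )

    # naked b/y series (glycans stripped; HCD labile behaviour / CID backbone);
    # b-ion neutral = prefix residue sum, y-ion neutral = suffix residues + H2O
    for i in range(1, n):
        add(f"b{i}", prefix[i])
        add(f"y{n - i}", backbone - prefix[i])

    if mode == "HCD" and glycosylated:
        # glycan-retained b/y variants: fragments keep the glycans of their sites
        for i in range(1, n):
            if prefix_gly[i] > 0:
                add(f"b{i}+glyc", prefix[i] + prefix_gly[i], site_dependent=True)
            suffix_gly = total_glycan_mass - prefix_gly[i]
            if suffix_gly > 0:
                add(f"y{n - i}+glyc", backbone - prefix[i] + suffix_gly,
                    site_dependent=True)

    if mode == "CID" and glycosylated:
        # Y ladder: intact peptide retaining every sub-composition of the glycan
        add("Y0", backbone)
        for sub in _sub_compositions(candidate.total_glycan):
            if sub.total == 0:
                continue
            add(f"Y[{sub}]", backbone + modification_delta(sub))
        add(f"Y[{candidate.total_glycan}]", backbone + total_glycan_mass)
        # site-determining glycan-retained b/y ions are also observed in CID
        for i in range(1, n):
            if prefix_gly[i] > 0:
                add(f"b{i}+glyc", prefix[i] + prefix_gly[i], site_dependent=True)
            suffix_gly = total_glycan_mass - prefix_gly[i]
            if suffix_gly > 0:
                add(f"y{n - i}+glyc", backbone - prefix[i] + suffix_gly,
                    site_dependent=True)

    if glycosylated:
        for ion in oxonium_series("HexNAc"):
            frags.append(TheoreticalFragment(ion.label, ion.mz, 1))

    # deduplicate identical (label) entries, keep deterministic order
    seen = set()
    unique = []
    for f in sorted(frags, key=lambda f: (f.mz, f.label)):
        if f.label in seen:
            continue
        seen.add(f.label)
        unique.append(f)
    return unique


# ---------------------------------------------------------------------------
# matching + scoring


def match_fragments(
    spectrum: Spectrum,
    fragments: Sequence[TheoreticalFragment],
    tol: float,
) -> List[FragmentMatch]:
    """Presence/absence matching of theoretical fragments within ±tol Da.

    Each theoretical fragment matches at most one (the nearest) peak; the
    result depends only on peak positions, not intensity scale or order.
    """
    out = []
    for frag in fragments:
        lo = np.searchsorted(spectrum.mz, frag.mz - tol, side="left")
        hi = np.searchsorted(spectrum.mz, frag.mz + tol, side="right")
        if hi > lo:
            k = lo + int(np.argmin(np.abs(spectrum.mz[lo:hi] - frag.mz)))
            out.append(
                FragmentMatch(frag, float(spectrum.mz[k]), float(spectrum.intensity[k]))
            )
    return out


_SCORE_CAP = 350.0  # beyond double underflow of the binomial tail


def _binomial_score(n: int, k: int, p: float) -> float:
    """−log10 P[Binomial(n, p) ≥ k]; 0 when nothing matched.

    Evaluated in log space so scores keep resolving below the double
    underflow of the plain tail probability.
    """
    if k <= 0 or n <= 0:
        return 0.0
    logp = float(stats.binom.logsf(k - 1, n, p))
    if not math.isfinite(logp):
        return _SCORE_CAP
    return min(-logp / math.log(10.0), _SCORE_CAP)


def _random_match_probability(spectrum: Spectrum, tol: float) -> float:
    span = float(spectrum.mz[-1] - spectrum.mz[0]) if len(spectrum) > 1 else 0.0
    if span <= 0:
        return 0.5
    p = 2.0 * tol * len(spectrum) / span
    return min(max(p, 1e-9), 0.99)


def score_spectrum(
    spectrum: Spectrum,
    candidates: Sequence[GlycopeptideCandidate],
    tol: Optional[float] = None,
    compute_ratio: bool = True,
) -> List[GPSM]:
    """Score candidates against one spectrum; return GPSMs ranked best-first.

    score = −log10 P[Binomial(n_theoretical, p_random) ≥ n_matched] with
    p_random = 2·tol·n_peaks / m/z span. Ties are broken by fewer occupied
    glycosites, then lexicographic peptide sequence (deterministic output).
    """
    if not candidates:
        return []
    if tol is None:
        tol = DEFAULT_FRAGMENT_TOL[spectrum.fragmentation]
    p_rand = _random_match_probability(spectrum, tol)
    ratio = None
    if compute_ratio and spectrum.fragmentation == "HCD":
        ratio = diagnostic_ratio(spectrum)
    gpsms = []
    for cand in candidates:
        frags = theoretical_fragments(cand, mode=spectrum.fragmentation)
        matches = match_fragments(spectrum, frags, tol)
        k = len({m.fragment.mz for m in matches})
        score = _binomial_score(len(frags), k, p_rand)
        gpsms.append(
            GPSM(
                spectrum_id=spectrum.scan_id,
                candidate=cand,
                matches=matches,
                n_theoretical=len(frags),
                score=score,
                is_decoy=cand.is_decoy,
                oxonium_ratio=ratio,
            )
        )
    gpsms.sort(
        key=lambda g: (
            -g.score,
            g.candidate.n_glyco_sites,
            g.candidate.peptide.sequence,
            str(g.candidate.total_glycan),
        )
    )
    return gpsms


# ---------------------------------------------------------------------------
# decoys + FDR


def make_decoy(candidate: GlycopeptideCandidate) -> GlycopeptideCandidate:
    """Reversed-sequence decoy preserving the C-terminal residue and the
    glyco-site count (sites and mods move with their residues)."""
    pep = candidate.peptide
    n = len(pep.sequence)
    seq = pep.sequence[: n - 1][::-1] + pep.sequence[n - 1]

    def map_site(i: int) -> int:
        return i if i == n - 1 else n - 2 - i

    decoy_pep = Peptide(
        isoform_id=f"decoy_{pep.isoform_id}",
        start=pep.start,
        end=pep.end,
        sequence=seq,
        missed_cleavages=pep.missed_cleavages,
        junction_tags=pep.junction_tags,
    )
    return GlycopeptideCandidate(
        peptide=decoy_pep,
        glyco_sites=tuple(
            sorted((map_site(s), c) for s, c in candidate.glyco_sites)
        ),
        fixed_mods=tuple(sorted((map_site(s), d) for s, d in candidate.fixed_mods)),
        variable_mods=tuple(
            sorted((map_site(s), d) for s, d in candidate.variable_mods)
        ),
        is_decoy=True,
    )


def generate_decoys(
    candidates: Sequence[GlycopeptideCandidate],
) -> List[GlycopeptideCandidate]:
    """One reversed decoy per target, skipping palindromic sequences that
    would collide with their own target."""
    out = []
    for c in candidates:
        d = make_decoy(c)
        if d.peptide.sequence != c.peptide.sequence:
            out.append(d)
    return out


def target_decoy_fdr(gpsms: Sequence[GPSM]) -> List[GPSM]:
    """Assign q-values by the target-decoy method.

    GPSMs are sorted by decreasing score; at each threshold FDR is estimated
    as #decoys/#targets above it, and q is the running minimum from the tail
    (so q-values are monotone non-decreasing down the ranked list). Input
    order is not modified; the returned list is sorted best-first.
    """
    # conservative tie handling: at equal scores decoys rank above targets
    ranked = sorted(gpsms, key=lambda g: (-g.score, not g.is_decoy, g.spectrum_id))
    n_decoy = 0
    n_target = 0
    fdrs = []
    for g in ranked:
        if g.is_decoy:
            n_decoy += 1
        else:
            n_target += 1
        fdrs.append(n_decoy / max(n_target, 1))
    q = fdrs[:]
    for i in range(len(q) - 2, -1, -1):
        q[i] = min(q[i], q[i + 1])
    for g, qv in zip(ranked, q):
        g.q_value = qv
    return ranked


# ---------------------------------------------------------------------------
# site localization


def _alternative_assignments(
    candidate: GlycopeptideCandidate, cap: int = 200
) -> List[GlycopeptideCandidate]:
    """Isomeric site assignments: the same composition multiset placed on any
    other subset of the peptide's S/T sites."""
    sites = candidate.peptide.st_sites
    comps = tuple(c for _, c in candidate.glyco_sites)
    k = len(comps)
    if k == 0:
        return []
    current = tuple(sorted(candidate.glyco_sites))
    alts: List[GlycopeptideCandidate] = []
    seen = {current}
    for chosen in itertools.combinations(sites, k):
        for perm in set(itertools.permutations(comps)):
            assign = tuple(sorted(zip(chosen, perm)))
            if assign in seen:
                continue
            seen.add(assign)
            alts.append(replace(candidate, glyco_sites=assign))
            if len(alts) >= cap:
                return alts
    return alts


def localize_sites(
    gpsm: GPSM,
    spectrum: Spectrum,
    tol: Optional[float] = None,
) -> bool:
    """Decide whether the glycosite assignment is unambiguous.

    The assignment is localized iff, for every alternative isomeric placement
    of the same glycans, at least one *matched* site-determining ion
    (glycan-retained backbone fragment) is incompatible with the alternative
    (no theoretical m/z of the alternative within tolerance). Peptides with a
    single occupied-site choice (e.g. one S/T) are trivially localized.
    The decision is stored on ``gpsm.site_localized`` and returned.
    """
    if tol is None:
        tol = DEFAULT_FRAGMENT_TOL[spectrum.fragmentation]
    alternatives = _alternative_assignments(gpsm.candidate)
    if not alternatives:
        gpsm.site_localized = True
        return True
    matched_site_mz = [
        m.fragment.mz for m in gpsm.matches if m.fragment.site_dependent
    ]
    if not matched_site_mz:
        gpsm.site_localized = False
        return False
    mode = spectrum.fragmentation
    for alt in alternatives:
        alt_mz = np.array([f.mz for f in theoretical_fragments(alt, mode=mode)])
        distinguishing = any(
            np.min(np.abs(alt_mz - mz)) > tol for mz in matched_site_mz
        )
        if not distinguishing:
            gpsm.site_localized = False
            return False
    gpsm.site_localized = True
    return True


# ---------------------------------------------------------------------------
# pipeline + export

#: per (candidate, mode): (n_theoretical, unique fragment m/z values)
_FRAGMENT_MZ_CACHE: Dict[Tuple[GlycopeptideCandidate, str], Tuple[int, np.ndarray]] = {}
_FRAGMENT_MZ_CACHE_LIMIT = 400_000


_OXONIUM_MZ = np.array([ion.mz for ion in oxonium_series("HexNAc")])


def _fast_fragment_mz(
    candidate: GlycopeptideCandidate, mode: str, charges: Tuple[int, ...] = (1, 2)
) -> Tuple[int, np.ndarray]:
    """(n_theoretical, unique fragment m/z) for a candidate, computed as flat
    arrays. Mirrors :func:`theoretical_fragments` exactly (asserted by a
    parity test) but skips building per-ion objects."""
    seq = candidate.peptide.sequence
    n = len(seq)
    seq_deltas = _site_deltas(candidate)
    gly_deltas = _glyco_deltas(candidate)
    residues = np.array(
        [residue_mass(a) + seq_deltas.get(i, 0.0) for i, a in enumerate(seq)]
    )
    prefix = np.concatenate([[0.0], np.cumsum(residues)])
    gly = np.zeros(n)
    for site, d in gly_deltas.items():
        gly[site] = d
    prefix_gly = np.concatenate([[0.0], np.cumsum(gly)])
    backbone = prefix[n] + WATER
    total_gly = prefix_gly[n]
    glycosylated = bool(candidate.glyco_sites)

    neutrals = [prefix[1:n], backbone - prefix[1:n]]
    if glycosylated:
        b_mask = prefix_gly[1:n] > 0
        y_mask = (total_gly - prefix_gly[1:n]) > 0
        retained = [
            (prefix[1:n] + prefix_gly[1:n])[b_mask],
            (backbone - prefix[1:n] + total_gly - prefix_gly[1:n])[y_mask],
        ]
        if mode == "HCD":
            neutrals += retained
        else:  # CID: Y ladder of every sub-composition, plus retained b/y
            total = candidate.total_glycan
            ladder = [
                backbone + modification_delta(GlycanComposition(hx, h, d, na))
                if (hx, h, d, na) != (0, 0, 0, 0)
                else backbone
                for hx in range(total.hexnac + 1)
                for h in range(total.hex + 1)
                for d in range(total.dhex + 1)
                for na in range(total.neuac + 1)
            ]
            neutrals += [np.array(ladder)] + retained
    neutral = np.concatenate(neutrals)
    mz = np.concatenate([(neutral + z * PROTON) / z for z in charges])
    count = len(mz)
    if glycosylated:
        mz = np.concatenate([mz, _OXONIUM_MZ])
        count += len(_OXONIUM_MZ)
    return count, np.unique(mz)


def _fragment_mz_arrays(
    candidate: GlycopeptideCandidate, mode: str
) -> Tuple[int, np.ndarray]:
    key = (candidate, mode)
    hit = _FRAGMENT_MZ_CACHE.get(key)
    if hit is None:
        hit = _fast_fragment_mz(candidate, mode)
        if len(_FRAGMENT_MZ_CACHE) < _FRAGMENT_MZ_CACHE_LIMIT:
            _FRAGMENT_MZ_CACHE[key] = hit
    return hit


def _best_candidate_fast(
    spectrum: Spectrum,
    pool: Sequence[GlycopeptideCandidate],
    tol: float,
) -> Optional[GlycopeptideCandidate]:
    """Rank a candidate pool by the binomial score without materialising
    fragment objects; returns the winner under the same score and tie-break
    rules as :func:`score_spectrum` (n and k are computed identically)."""
    if not pool:
        return None
    p_rand = _random_match_probability(spectrum, tol)
    per_cand = [_fragment_mz_arrays(c, spectrum.fragmentation) for c in pool]
    n_arr = np.array([n for n, _ in per_cand])
    concat = np.concatenate([u for _, u in per_cand])
    lengths = np.array([len(u) for _, u in per_cand])
    matched = (
        np.searchsorted(spectrum.mz, concat + tol, side="right")
        > np.searchsorted(spectrum.mz, concat - tol, side="left")
    )
    bounds = np.concatenate([[0], np.cumsum(lengths)[:-1]])
    k_arr = np.add.reduceat(matched.astype(int), bounds)
    with np.errstate(divide="ignore"):
        logs = stats.binom.logsf(np.maximum(k_arr, 1) - 1, n_arr, p_rand)
    scores = np.where(
        k_arr <= 0, 0.0, np.minimum(-logs / math.log(10.0), _SCORE_CAP)
    )
    order = sorted(
        range(len(pool)),
        key=lambda i: (
            -scores[i],
            pool[i].n_glyco_sites,
            pool[i].peptide.sequence,
            str(pool[i].total_glycan),
        ),
    )
    return pool[order[0]]


def search_spectra(
    spectra: Iterable[Spectrum],
    candidates: Sequence[GlycopeptideCandidate],
    precursor_ppm: float = 5.0,
    tol: Optional[float] = None,
    with_decoys: bool = True,
    charges: Tuple[int, ...] = (2, 3, 4),
    localize: bool = True,
) -> List[GPSM]:
    """Search a spectrum stream against a candidate database.

    Candidates (plus reversed decoys when ``with_decoys``) are indexed by
    precursor m/z per charge state; each spectrum is scored against the
    candidates within ``precursor_ppm`` of its precursor at its charge
    (or at all ``charges`` when the charge is unassigned). The best GPSM per
    spectrum is kept and the full set is q-valued by target-decoy.
    """
    db = list(candidates)
    if with_decoys:
        db += generate_decoys(candidates)
    neutral = np.array([c.neutral_mass for c in db])
    index_mz = np.concatenate([(neutral + z * PROTON) / z for z in charges])
    index_cand = np.tile(np.arange(len(db)), len(charges))
    order = np.argsort(index_mz, kind="stable")
    index_mz = index_mz[order]
    index_cand = index_cand[order]

    results: List[GPSM] = []
    for s in spectra:
        window = s.precursor_mz * precursor_ppm * 1e-6
        lo = np.searchsorted(index_mz, s.precursor_mz - window, side="left")
        hi = np.searchsorted(index_mz, s.precursor_mz + window, side="right")
        pool = []
        for k in index_cand[lo:hi]:
            cand = db[k]
            if s.precursor_charge and abs(
                precursor_mz(cand, s.precursor_charge) - s.precursor_mz
            ) > window:
                continue
            pool.append(cand)
        # dedupe candidate objects that appear at several charges
        pool = list(dict.fromkeys(pool))
        tol_s = tol if tol is not None else DEFAULT_FRAGMENT_TOL[s.fragmentation]
        winner = _best_candidate_fast(s, pool, tol_s)
        if winner is None:
            continue
        best = score_spectrum(s, [winner], tol=tol_s)[0]
        if localize and best.candidate.glyco_sites:
            localize_sites(best, s, tol=tol_s)
        results.append(best)
    return target_decoy_fdr(results)


def gpsm_table(gpsms: Sequence[GPSM]) -> pd.DataFrame:
    """Flat GPSM table: scan, peptide, isoform, junctions, glycans, score, q."""
    rows = []
    for g in gpsms:
        pep = g.candidate.peptide
        rows.append(
            {
                "scan": g.spectrum_id,
                "peptide": pep.sequence,
                "isoform": pep.isoform_id,
                "junctions": ";".join(pep.junction_tags),
                "glycan": g.candidate.glycan_string,
                "sites": ";".join(str(s) for s, _ in g.candidate.glyco_sites),
                "n_matched": g.n_matched,
                "n_theoretical": g.n_theoretical,
                "score": g.score,
                "q_value": g.q_value,
                "is_decoy": g.is_decoy,
                "site_localized": g.site_localized,
                "oxonium_144_138_ratio": g.oxonium_ratio,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "scan", "peptide", "isoform", "junctions", "glycan", "sites",
            "n_matched", "n_theoretical", "score", "q_value", "is_decoy",
            "site_localized", "oxonium_144_138_ratio",
        ],
    )
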