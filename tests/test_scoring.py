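"""Fragment generation, binomial GPSM scoring, target-decoy FDR, localization."""

import numpy as np
import pytest
from pyteomics import mass as pmass

from glycopg.chem import PROTON, WATER, GlycanComposition
from glycopg.digest import GlycopeptideCandidate, Peptide
from glycopg.scoring import (
    GPSM,
    generate_decoys,
    localize_sites,
    make_decoy,
    match_fragments,
    score_spectrum,
    search_spectra,
    target_decoy_fdr,
    theoretical_fragments,
)
from glycopg.spectra import Spectrum

GC = GlycanComposition


def pep(seq):
    return Peptide("iso", 0, len(seq), seq, 0)


def cand(seq, *sites):
    return GlycopeptideCandidate(pep(seq), glyco_sites=tuple(sites))


def spectrum(mz, intensity=None, scan="s", pre=500.0, z=2, frag="HCD"):
    mz = np.asarray(mz, float)
    if intensity is None:
        intensity = np.ones_like(mz)
    return Spectrum(scan, pre, z, frag, mz, np.asarray(intensity, float))


def frag_mz(frags, label):
    return next(f.mz for f in frags if f.label == label)


# --- theoretical fragments


def test_dipeptide_by_ions_match_elemental_oracle():
    frags = theoretical_fragments(cand("GA"), mode="HCD", charges=(1,))
    # b1 = glycyl acylium C2H4NO+; y1 = protonated alanine C3H8NO2+
    b1 = pmass.calculate_mass(formula="C2H3NO") + PROTON
    y1 = pmass.calculate_mass(formula="C3H7NO2") + PROTON
    assert frag_mz(frags, "b1^1") == pytest.approx(b1, abs=1e-5)
    assert frag_mz(frags, "y1^1") == pytest.approx(y1, abs=1e-5)


def test_cid_y1_minus_y0_is_hexnac_residue():
    c = cand("SAGF", (0, GC(hexnac=1)))
    frags = theoretical_fragments(c, mode="CID", charges=(1,))
    y0 = frag_mz(frags, "Y0^1")
    y1 = frag_mz(frags, "Y[HexNAc1]^1")
    assert y1 - y0 == pytest.approx(203.0794, abs=1e-4)


def test_fragment_count_closed_form_six_mer_one_glycan():
    """For an n-mer with one glycan at site s (HCD, charges {1,2}):
    2(n-1) naked b + 2(n-1) naked y, plus glycan-retained variants for the
    b_i with i > s (n-1-s of them) and the y_(n-i) with i <= s (s of them),
    each at 2 charges, plus the 6 oxonium ions."""
    n, s = 6, 2
    c = cand("GASAGF", (s, GC(hexnac=1)))
    frags = theoretical_fragments(c, mode="HCD", charges=(1, 2))
    expected = 2 * (n - 1) + 2 * (n - 1) + 2 * (n - 1 - s) + 2 * s + 6
    assert len(frags) == expected


@pytest.mark.parametrize("mode", ["HCD", "CID"])
def test_fast_fragment_arrays_match_full_enumeration(mode):
    """The array fast path reproduces the object enumeration exactly:
    same theoretical-ion count, same unique m/z set."""
    from glycopg.scoring import _fast_fragment_mz

    cases = [
        cand("GASAGF"),
        cand("SAGKAF", (0, GC(hexnac=1))),
        cand("SATKASF", (0, GC(hexnac=1)), (2, GC(hexnac=1, hex=1, neuac=1))),
        GlycopeptideCandidate(
            pep("CSATKF"),
            glyco_sites=((1, GC(hexnac=1, hex=1)),),
            fixed_mods=((0, 57.02146),),
        ),
    ]
    for c in cases:
        frags = theoretical_fragments(c, mode=mode)
        n, uniq = _fast_fragment_mz(c, mode)
        assert n == len(frags)
        np.testing.assert_allclose(uniq, np.unique([f.mz for f in frags]), atol=1e-12)


def test_unmodified_candidate_has_no_oxonium_ions():
    frags = theoretical_fragments(cand("GASAGF"), mode="HCD")
    assert not any(f.label.startswith("HexNAc-") for f in frags)


# --- matching and scoring


def test_perfect_match_dominates():
    """A spectrum that is exactly one candidate's fragment set ranks that
    candidate first against competitors sharing the precursor window."""
    truth = cand("SAGKAF", (0, GC(hexnac=1, hex=1)))
    competitors = [
        cand("SAGKAF", (0, GC(hexnac=1))),
        cand("SAGKAF"),
        cand("TAGKAF", (0, GC(hexnac=1, hex=1))),
    ]
    mz = np.array(sorted({f.mz for f in theoretical_fragments(truth, "HCD")}))
    s = spectrum(mz)
    ranked = score_spectrum(s, [truth] + competitors)
    assert ranked[0].candidate == truth
    assert ranked[0].score > ranked[1].score


def test_score_invariant_to_intensity_scaling_and_order():
    c = cand("SAGKAF", (0, GC(hexnac=1)))
    mz = np.array([f.mz for f in theoretical_fragments(c, "HCD")])[:10]
    s1 = spectrum(mz, np.linspace(1, 10, 10))
    s2 = spectrum(mz[::-1], np.linspace(1000, 1, 10))
    g1 = score_spectrum(s1, [c])[0]
    g2 = score_spectrum(s2, [c])[0]
    assert g1.score == pytest.approx(g2.score, abs=1e-12)
    assert g1.n_matched == g2.n_matched


def test_noise_peak_never_increases_matched_count():
    c = cand("SAGKAF")
    mz = np.array([f.mz for f in theoretical_fragments(c, "HCD")])[:6]
    base = score_spectrum(spectrum(mz), [c])[0]
    with_noise = score_spectrum(spectrum(np.append(mz, 1234.567)), [c])[0]
    assert with_noise.n_matched == base.n_matched


def test_noise_spectra_score_below_half_matched_candidate():
    """Median best score on pure-noise spectra stays below the score of a
    candidate with half its fragments present."""
    rng = np.random.default_rng(17)
    c = cand("SAGKAFTHW", (0, GC(hexnac=1)))
    frags = sorted({f.mz for f in theoretical_fragments(c, "HCD")})
    half = spectrum(np.array(frags[:: 2]))
    half_score = score_spectrum(half, [c])[0].score
    noise_scores = []
    for _ in range(50):
        s = spectrum(rng.uniform(110, 2000, 40))
        noise_scores.append(score_spectrum(s, [c])[0].score)
    assert np.median(noise_scores) < half_score


def test_empty_candidate_set_empty_result():
    assert score_spectrum(spectrum([200.0]), []) == []


# --- decoys and FDR


def test_decoy_reversal_preserves_cterm_and_site_count():
    c = cand("SAGTKAF", (0, GC(hexnac=1)), (3, GC(hexnac=1, hex=1)))
    d = make_decoy(c)
    assert d.is_decoy
    assert d.peptide.sequence == "AKTGAS" + "F"
    assert d.peptide.sequence[-1] == c.peptide.sequence[-1]
    assert d.n_glyco_sites == c.n_glyco_sites
    assert d.total_glycan == c.total_glycan
    assert d.neutral_mass == pytest.approx(c.neutral_mass, abs=1e-9)


def test_self_reversing_sequences_skipped_in_decoy_db():
    # "AGAF": the N-terminal part "AGA" is a palindrome, so reversal with a
    # kept C-terminus reproduces the target — it must not enter the decoy db
    cands = [cand("AGAF"), cand("SAGF")]
    decoys = generate_decoys(cands)
    assert [d.peptide.sequence for d in decoys] == ["GASF"]


def mock_gpsm(score, is_decoy, sid="x"):
    return GPSM(sid, cand("SAGF"), [], 10, score, is_decoy=is_decoy)


def test_all_targets_q_zero():
    out = target_decoy_fdr([mock_gpsm(s, False, str(s)) for s in (5.0, 3.0, 1.0)])
    assert all(g.q_value == 0.0 for g in out)


def test_interleaved_equal_evidence_tail_q_near_one():
    gpsms = [mock_gpsm(10.0 - i, i % 2 == 1, str(i)) for i in range(20)]
    out = target_decoy_fdr(gpsms)
    assert out[-1].q_value == pytest.approx(1.0, abs=0.12)


def test_q_values_monotone_in_ranked_order():
    rng = np.random.default_rng(2)
    gpsms = [mock_gpsm(float(rng.normal()), bool(rng.random() < 0.5), str(i))
             for i in range(200)]
    out = target_decoy_fdr(gpsms)
    qs = [g.q_value for g in out]
    assert qs == sorted(qs)


def test_null_simulation_accepts_about_one_percent():
    """When targets and decoys are score-exchangeable (a pure null), the
    fraction of targets accepted at q <= 0.01 stays near 1%."""
    rates = []
    for seed in range(10):
        rng = np.random.default_rng(100 + seed)
        gpsms = [mock_gpsm(float(rng.normal()), bool(i % 2), str(i))
                 for i in range(1000)]
        out = target_decoy_fdr(gpsms)
        accepted = [g for g in out if not g.is_decoy and g.q_value <= 0.01]
        rates.append(len(accepted) / 500)
    assert np.mean(rates) <= 0.03


# --- localization


def run_localization(c, present_fraction=1.0):
    mz = np.array(sorted({f.mz for f in theoretical_fragments(c, "HCD")}))
    keep = mz[: max(1, int(len(mz) * present_fraction))]
    s = spectrum(keep)
    g = score_spectrum(s, [c])[0]
    return localize_sites(g, s)


def test_single_site_trivially_localized():
    assert run_localization(cand("SAGKAF", (0, GC(hexnac=1)))) is True


def test_two_sites_without_site_ions_ambiguous():
    c = cand("SATKAF", (0, GC(hexnac=1)))
    frags = theoretical_fragments(c, "HCD")
    naked = np.array(sorted({f.mz for f in frags if not f.site_dependent}))
    s = spectrum(naked)
    g = score_spectrum(s, [c])[0]
    assert localize_sites(g, s) is False


def test_site_determining_ions_recover_true_site():
    """Across generated spectra with full fragment evidence, the correct site
    is called localized in >= 95% of cases."""
    rng = np.random.default_rng(33)
    aas = "GAKVF"
    n_ok = 0
    n = 200
    for i in range(n):
        seq = list("SAT" + "".join(aas[j] for j in rng.integers(0, 5, 4)) + "F")
        rng.shuffle(seq)
        seq = "".join(seq)
        sites = [k for k, a in enumerate(seq) if a in "ST"]
        if not sites:
            n_ok += 1
            continue
        site = int(rng.choice(sites))
        c = cand(seq, (site, GC(hexnac=1)))
        if run_localization(c):
            n_ok += 1
    assert n_ok / n >= 0.95


# --- end-to-end search


def test_search_assigns_best_per_spectrum_and_qvalues(glycan_space, toy_isoforms):
    from glycopg.digest import digest, expand_glycoforms
    from glycopg.synthetic import GeneratorConfig, generate_spectra

    candidates = []
    for p in digest(toy_isoforms[0], max_missed=1)[:10]:
        cs, _ = expand_glycoforms(p, glycan_space, max_occupied_sites=1)
        candidates.extend(cs)
    truth = [c for c in candidates if c.glyco_sites][:8]
    cfg = GeneratorConfig(seed=4, efficiency=1.0, noise_lambda=0.0, jitter_ppm=0.0)
    spectra, truths = generate_spectra(truth, cfg)
    results = search_spectra(spectra, candidates)
    assert len(results) == len(truth)
    by_scan = {g.spectrum_id: g for g in results}
    for t in truths:
        g = by_scan[t.spectrum_id]
        assert g.candidate.peptide.sequence == t.candidate.peptide.sequence
        assert sorted(g.candidate.glyco_sites) == sorted(t.candidate.glyco_sites)
        assert g.q_value == 0.0
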