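"""Spectrum I/O, oxonium trigger logic, diagnostic ratios, inclusion lists."""

import numpy as np
import pytest

from glycopg.chem import oxonium_trigger_mz
from glycopg.spectra import (
    Spectrum,
    build_inclusion_list,
    detect_oxonium,
    diagnostic_ratio,
    inclusion_list_to_csv,
    oxonium_trigger,
    read_spectra,
    write_mgf,
    write_mzml,
)


def hcd(mz, intensity, scan="s1", pre=500.0, z=2, rt=100.0):
    return Spectrum(scan, pre, z, "HCD", np.asarray(mz, float),
                    np.asarray(intensity, float), rt)


@pytest.fixture
def three_scans():
    return [
        hcd([204.0870, 300.0, 450.5], [50.0, 10.0, 5.0], scan="1", pre=612.3, z=2, rt=60.0),
        hcd([150.0, 800.0], [1.0, 2.0], scan="2", pre=900.1, z=3, rt=120.0),
        Spectrum("3", 740.2, None, "CID", np.array([320.0, 540.0]),
                 np.array([7.0, 8.0]), 180.0),
    ]


def assert_streams_equal(a, b):
    assert len(a) == len(b)
    for x, y in zip(a, b):
        assert x.scan_id == y.scan_id
        assert x.fragmentation == y.fragmentation
        assert x.precursor_charge == y.precursor_charge
        assert x.precursor_mz == pytest.approx(y.precursor_mz, abs=1e-9)
        assert x.retention_time == pytest.approx(y.retention_time, abs=1e-6)
        np.testing.assert_allclose(x.mz, y.mz, atol=1e-9)
        np.testing.assert_allclose(x.intensity, y.intensity, atol=1e-9)


def test_mgf_round_trip(tmp_path, three_scans):
    path = tmp_path / "run.mgf"
    write_mgf(three_scans, path)
    assert_streams_equal(list(read_spectra(path)), three_scans)


def test_mzml_and_mgf_renderings_are_equivalent(tmp_path, three_scans):
    """The same synthetic run written as MGF and as mzML yields identical
    spectrum streams, unknown charges preserved."""
    write_mgf(three_scans, tmp_path / "run.mgf")
    write_mzml(three_scans, tmp_path / "run.mzml")
    assert_streams_equal(
        list(read_spectra(tmp_path / "run.mgf")),
        list(read_spectra(tmp_path / "run.mzml")),
    )


def test_peaks_sorted_and_validated():
    s = hcd([500.0, 100.0, 300.0], [1.0, 2.0, 3.0])
    assert list(s.mz) == [100.0, 300.0, 500.0]
    assert list(s.intensity) == [2.0, 3.0, 1.0]
    with pytest.raises(ValueError):
        hcd([100.0], [1.0], z=9)
    with pytest.raises(ValueError):
        Spectrum("x", 500.0, 2, "ETD", np.array([1.0]), np.array([1.0]))


# --- trigger logic


def test_trigger_true_at_exact_oxonium():
    assert oxonium_trigger(hcd([204.0870], [10.0]), window=0.01)


def test_trigger_false_outside_window():
    assert not oxonium_trigger(hcd([204.105], [10.0]), window=0.01)


def test_detect_oxonium_requires_hcd(three_scans):
    with pytest.raises(ValueError):
        detect_oxonium(three_scans[2])


def test_detection_equals_linear_scan_oracle():
    """Trigger decisions over random spiked spectra match a brute-force scan."""
    rng = np.random.default_rng(21)
    target = oxonium_trigger_mz()
    for _ in range(300):
        n = int(rng.integers(1, 30))
        mz = rng.uniform(110.0, 2000.0, n)
        if rng.random() < 0.5:
            mz[0] = target + rng.uniform(-0.02, 0.02)
        s = hcd(mz, np.ones(n))
        oracle = bool(np.any(np.abs(mz - target) <= 0.01))
        assert oxonium_trigger(s, 0.01) == oracle


def test_widening_window_is_monotone():
    rng = np.random.default_rng(5)
    for _ in range(50):
        mz = rng.uniform(110.0, 400.0, 20)
        s = hcd(mz, np.ones(20))
        triggered = [oxonium_trigger(s, w) for w in (0.005, 0.01, 0.05, 0.5)]
        # once triggered at some window, all wider windows trigger too
        assert triggered == sorted(triggered)


# --- diagnostic ratio


def test_ratio_equal_intensities_is_one():
    s = hcd([138.0550, 144.0656], [40.0, 40.0])
    assert diagnostic_ratio(s) == pytest.approx(1.0)


def test_ratio_undefined_without_denominator():
    s = hcd([144.0656], [40.0])
    assert diagnostic_ratio(s) is None


def test_generated_ratio_recovered():
    """Spectra generated with a GalNAc-like 144/138 ratio of 2.5 recover it
    within the generator's intensity-noise tolerance."""
    from glycopg.chem import GlycanComposition
    from glycopg.digest import GlycopeptideCandidate, Peptide
    from glycopg.synthetic import GeneratorConfig, generate_spectra

    pep = Peptide("iso", 0, 6, "SAGKAF", 0)
    cand = GlycopeptideCandidate(pep, glyco_sites=((0, GlycanComposition(hexnac=1)),))
    cfg = GeneratorConfig(seed=13, noise_lambda=0.0, jitter_ppm=0.0,
                          oxonium_ratio_144_138=2.5, oxonium_intensity_sigma=0.1)
    spectra, _ = generate_spectra([cand] * 40, cfg)
    ratios = [diagnostic_ratio(s) for s in spectra]
    assert all(r is not None for r in ratios)
    assert np.mean(ratios) == pytest.approx(2.5, rel=0.15)


# --- inclusion lists


def test_no_triggers_empty_list():
    spectra = [hcd([300.0], [1.0], scan=str(i)) for i in range(5)]
    assert build_inclusion_list(spectra) == []


def test_duplicate_precursors_merge():
    a = hcd([204.0870], [10.0], scan="a", pre=600.0, z=2, rt=100.0)
    b = hcd([204.0868], [20.0], scan="b", pre=600.0 * (1 + 3e-6), z=2, rt=200.0)
    entries = build_inclusion_list([a, b])
    assert len(entries) == 1
    e = entries[0]
    assert set(e.scan_ids) == {"a", "b"}
    assert (e.rt_start, e.rt_end) == (100.0, 200.0)


def test_same_mz_different_charge_not_merged():
    a = hcd([204.0870], [10.0], scan="a", pre=600.0, z=2)
    b = hcd([204.0870], [10.0], scan="b", pre=600.0, z=3)
    assert len(build_inclusion_list([a, b])) == 2


def test_entries_sorted_by_evidence_and_csv_written(tmp_path):
    spectra = [
        hcd([204.0870], [5.0], scan="lo", pre=500.0),
        hcd([204.0870], [50.0], scan="hi", pre=700.0),
        hcd([400.0], [99.0], scan="none", pre=900.0),
    ]
    entries = build_inclusion_list(spectra)
    assert [e.scan_ids[0] for e in entries] == ["hi", "lo"]
    out = tmp_path / "incl.csv"
    inclusion_list_to_csv(entries, out)
    lines = out.read_text().strip().splitlines()
    assert lines[0] == "mz,z,rt_start,rt_end,evidence_intensity"
    assert len(lines) == 3
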