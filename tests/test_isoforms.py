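"""Exon grammars: splicing, translation, ORF screening, junction catalogues."""

import itertools

import numpy as np
import pytest
from Bio.Seq import Seq

from glycopg.isoforms import (
    Exon,
    ExonModel,
    ProteinIsoform,
    TranscriptModel,
    enumerate_junction_windows,
    read_isoform_fasta,
    screen_transcript,
    splice,
    translate_transcript,
    write_isoform_fasta,
)


def nt_model(**exons):
    return ExonModel.from_exons(
        [Exon(k, "constitutive", v) for k, v in exons.items()], mode="nt"
    )


def transcript(tid, *exon_ids):
    return TranscriptModel(tid, [(e, None, None) for e in exon_ids])


# --- independent oracle: concatenate, scan every ATG, translate, keep longest


def oracle_translate(nt: str):
    best = None
    for start in (i for i in range(len(nt) - 2) if nt[i : i + 3] == "ATG"):
        aa = str(Seq(nt[start : start + (len(nt) - start) // 3 * 3]).translate(to_stop=True))
        if aa and (best is None or len(aa) > len(best[1])):
            best = (start, aa)
    return best


def test_two_exon_toy_translation():
    model = nt_model(e1="ATGGCT", e2="GGTTAA")
    iso = translate_transcript(model, transcript("t", "e1", "e2"), min_orf_aa=1)
    assert iso.aa_sequence == "MAG"
    assert iso.junctions == [("e1-e2", 2)]


def test_stop_codon_not_emitted():
    model = nt_model(e1="ATGTAA")
    iso = translate_transcript(model, transcript("t", "e1"), min_orf_aa=1)
    assert iso.aa_sequence == "M"


def test_partial_exon_tagging():
    model = nt_model(e1="ATGGCTAAAGCT", e2="GGTTAA")
    t = TranscriptModel("t", [("e1", 0, 6), ("e2", None, None)])
    iso = translate_transcript(model, t, min_orf_aa=1)
    assert iso.aa_sequence == "MAG"
    assert iso.junctions == [("e1(partial)-e2", 2)]


def test_splice_then_translate_equals_concatenate_oracle():
    """All 2^3 variable-exon subsets of a 9-exon grammar agree with the
    brute-force concatenate-then-translate oracle, junctions included."""
    rng = np.random.default_rng(7)
    codons = ["GCT", "GGA", "TCT", "ACT", "AAA", "CAT", "TTT", "CTG"]

    def seq(n):
        return "".join(codons[i] for i in rng.integers(0, len(codons), n))

    exons = {f"c{i}": ("ATG" if i == 1 else "") + seq(6) for i in range(1, 4)}
    exons.update({f"v{i}": seq(5) for i in range(1, 4)})
    exons.update({f"d{i}": seq(6) + ("TAA" if i == 3 else "") for i in range(1, 4)})
    model = nt_model(**exons)
    head = ["c1", "c2", "c3"]
    tail = ["d1", "d2", "d3"]
    for included in itertools.product([False, True], repeat=3):
        used = head + [f"v{i+1}" for i, inc in enumerate(included) if inc] + tail
        t = transcript("t", *used)
        nt, _ = splice(model, t)
        start, expected_aa = oracle_translate(nt)
        iso = translate_transcript(model, t, min_orf_aa=1)
        assert iso.aa_sequence == expected_aa
        # oracle junction tags: adjacency scan with cumulative lengths
        offsets = np.cumsum([len(model.exons[e].sequence) for e in used])[:-1]
        expected = [
            (f"{used[i]}-{used[i+1]}", (off - start) // 3)
            for i, off in enumerate(offsets)
            if off - start > 0 and 1 <= (off - start) // 3 <= len(expected_aa) - 1
        ]
        assert iso.junctions == expected


def test_junction_positions_strictly_increasing(toy_isoforms):
    for iso in toy_isoforms:
        positions = [pos for _, pos in iso.junctions]
        assert positions == sorted(positions)
        assert len(set(positions)) == len(positions)


# --- screening


def test_screen_no_orf():
    model = nt_model(e1="CCCCCC")
    v = screen_transcript(model, transcript("t", "e1"))
    assert v.status == "no_orf"


def test_screen_premature_stop():
    model = nt_model(e1="ATGTAA" + "GGG" * 5)
    v = screen_transcript(model, transcript("t", "e1"), min_orf_aa=10)
    assert v.status == "premature_stop"


def test_screen_fragment():
    model = nt_model(e1="AT")
    assert screen_transcript(model, transcript("t", "e1")).status == "fragment_noncoding"


def test_screen_requires_nt_mode():
    model = ExonModel.from_exons([Exon("e1", "constitutive", "MAW")], mode="aa")
    with pytest.raises(ValueError):
        screen_transcript(model, transcript("t", "e1"))


def test_screen_matches_bruteforce_on_random_set():
    """Verdicts on 100 random transcripts match a brute-force ORF scanner."""
    rng = np.random.default_rng(11)
    min_aa = 8
    statuses = []
    expected = []
    for i in range(100):
        nt = "".join("ACGT"[b] for b in rng.integers(0, 4, int(rng.integers(20, 200))))
        model = nt_model(e1=nt)
        statuses.append(screen_transcript(model, transcript("t", "e1"), min_aa).status)
        best = oracle_translate(nt)
        if len(nt) < 3:
            expected.append("fragment_noncoding")
        elif best is None:
            expected.append("no_orf")
        elif len(best[1]) < min_aa:
            expected.append("premature_stop")
        else:
            expected.append("coding")
    assert statuses == expected


def test_screen_idempotent_and_order_independent(toy_grammar):
    model, transcripts = toy_grammar
    first = [screen_transcript(model, t) for t in transcripts]
    again = [screen_transcript(model, t) for t in reversed(transcripts)][::-1]
    assert first == again
    assert all(v.status == "coding" for v in first)


# --- junction windows


def test_window_clipping():
    iso = ProteinIsoform("i", "MAG", [("e1-e2", 2)])
    assert enumerate_junction_windows(iso, flank=2) == [("e1-e2", "MAG")]


def test_cd44s_has_e5_e15_and_no_variable_window(cd44s_isoform):
    tags = [tag for tag, _ in enumerate_junction_windows(cd44s_isoform, flank=5)]
    assert "e5-e15" in tags
    assert not any("v" in tag for tag in tags)


def test_windows_substring_match_at_recorded_offsets(toy_isoforms):
    flank = 6
    for iso in toy_isoforms:
        for (tag, window), (tag2, pos) in zip(
            enumerate_junction_windows(iso, flank), iso.junctions
        ):
            assert tag == tag2
            lo = max(0, pos - flank)
            assert iso.aa_sequence[lo : lo + len(window)] == window


def test_flank_validation(cd44s_isoform):
    with pytest.raises(ValueError):
        enumerate_junction_windows(cd44s_isoform, flank=0)


# --- FASTA I/O


def test_fasta_round_trip(tmp_path, toy_isoforms):
    path = tmp_path / "iso.fasta"
    write_isoform_fasta(toy_isoforms, path)
    back = read_isoform_fasta(path)
    assert len(back) == len(toy_isoforms)
    for a, b in zip(toy_isoforms, back):
        assert (a.isoform_id, a.aa_sequence, a.junctions, a.source_transcript) == (
            b.isoform_id, b.aa_sequence, b.junctions, b.source_transcript
        )
    # 60-column wrapping
    body = [l for l in path.read_text().splitlines() if not l.startswith(">")]
    assert max(len(l) for l in body) <= 60


def test_fasta_duplicate_ids_rejected(tmp_path, cd44s_isoform):
    with pytest.raises(ValueError):
        write_isoform_fasta([cd44s_isoform, cd44s_isoform], tmp_path / "x.fasta")
    with pytest.raises(ValueError):
        write_isoform_fasta([], tmp_path / "y.fasta")
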