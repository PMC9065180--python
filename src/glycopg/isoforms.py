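"""Exon grammars, transcript translation and exon-junction catalogues.

A gene like CD44 is modelled as a small grammar: a set of exons (constitutive
or variable) plus transcripts given as ordered exon lists, possibly using
truncated ("partial") exons. Translating a transcript yields a protein
isoform annotated with exon-exon junction positions — the positions whose
spanning peptides are diagnostic of a splice event (e.g. the e5-e15 junction
diagnostic of the CD44s standard isoform).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Exon",
    "ExonModel",
    "TranscriptModel",
    "ProteinIsoform",
    "TranscriptVerdict",
    "translate_transcript",
    "screen_transcript",
    "enumerate_junction_windows",
    "write_isoform_fasta",
    "read_isoform_fasta",
    "read_exon_model_tsv",
    "read_transcripts_json",
]

_NT_ALPHABET = set("ACGT")


@dataclass(frozen=True)
class Exon:
    """A single exon: short id, constitutive/variable category, sequence."""

    exon_id: str
    category: str  # "constitutive" | "variable"
    sequence: str
    partial_allowed: bool = True

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"exon {self.exon_id!r} has an empty sequence")
        if self.category not in ("constitutive", "variable"):
            raise ValueError(f"exon {self.exon_id!r}: bad category {self.category!r}")


@dataclass
class ExonModel:
    """An exon grammar in nucleotide ('nt') or amino-acid ('aa') mode."""

    exons: Dict[str, Exon]
    mode: str = "nt"  # "nt" | "aa"

    def __post_init__(self) -> None:
        if self.mode not in ("nt", "aa"):
            raise ValueError(f"mode must be 'nt' or 'aa', got {self.mode!r}")
        for eid, exon in self.exons.items():
            if eid != exon.exon_id:
                raise ValueError(f"exon key {eid!r} != exon_id {exon.exon_id!r}")
            if self.mode == "nt" and not set(exon.sequence) <= _NT_ALPHABET:
                raise ValueError(f"exon {eid!r}: non-ACGT characters in nt mode")

    @classmethod
    def from_exons(cls, exons: Iterable[Exon], mode: str = "nt") -> "ExonModel":
        d: Dict[str, Exon] = {}
        for e in exons:
            if e.exon_id in d:
                raise ValueError(f"duplicate exon_id {e.exon_id!r}")
            d[e.exon_id] = e
        return cls(exons=d, mode=mode)


#: Exon reference within a transcript: (exon_id, start, end) with 0-based
#: half-open exon-local offsets; None offsets mean the full exon.
ExonRef = Tuple[str, Optional[int], Optional[int]]


@dataclass
class TranscriptModel:
    transcript_id: str
    exon_refs: List[ExonRef]
    declared_coding: bool = True

    def resolve(self, model: ExonModel) -> List[Tuple[str, str, bool]]:
        """Return [(ref_label, subsequence, is_partial)] in transcript order."""
        out = []
        for exon_id, start, end in self.exon_refs:
            if exon_id not in model.exons:
                raise KeyError(
                    f"transcript {self.transcript_id!r}: unknown exon {exon_id!r}"
                )
            exon = model.exons[exon_id]
            s = 0 if start is None else start
            e = len(exon.sequence) if end is None else end
            if not (0 <= s < e <= len(exon.sequence)):
                raise ValueError(
                    f"transcript {self.transcript_id!r}: offsets [{s},{e}) out of "
                    f"bounds for exon {exon_id!r} (len {len(exon.sequence)})"
                )
            partial = (s, e) != (0, len(exon.sequence))
            if partial and not exon.partial_allowed:
                raise ValueError(
                    f"exon {exon_id!r} does not allow partial usage"
                )
            label = f"{exon_id}(partial)" if partial else exon_id
            out.append((label, exon.sequence[s:e], partial))
        return out


@dataclass
class ProteinIsoform:
    """A translated isoform with its exon-junction annotation.

    ``junctions`` holds ``(junction_tag, aa_position)`` pairs where
    ``aa_position`` is the 0-based index of the first residue encoded (even
    partially) by the downstream exon; a peptide covering residues
    ``aa_position - 1`` and ``aa_position`` is junction-diagnostic.
    """

    isoform_id: str
    aa_sequence: str
    junctions: List[Tuple[str, int]] = field(default_factory=list)
    source_transcript: str = ""

    def __post_init__(self) -> None:
        n = len(self.aa_sequence)
        for tag, pos in self.junctions:
            if not (1 <= pos <= n - 1):
                raise ValueError(
                    f"isoform {self.isoform_id!r}: junction {tag!r} position {pos} "
                    f"outside interior [1, {n - 1}]"
                )

    @property
    def junction_tags(self) -> List[str]:
        return [tag for tag, _ in self.junctions]


@dataclass(frozen=True)
class TranscriptVerdict:
    transcript_id: str
    status: str  # coding | no_orf | premature_stop | fragment_noncoding
    reason: str = ""


# ---------------------------------------------------------------------------
# splicing + ORF machinery


def splice(model: ExonModel, t: TranscriptModel) -> Tuple[str, List[Tuple[str, int]]]:
    """Concatenate exon subsequences; return (sequence, junction boundaries).

    Boundaries are (junction_tag, offset) with offset = index of the first
    character contributed by the downstream exon.
    """
    parts = t.resolve(model)
    seq_parts: List[str] = []
    boundaries: List[Tuple[str, int]] = []
    offset = 0
    for i, (label, sub, _) in enumerate(parts):
        if i > 0:
            upstream = parts[i - 1][0]
            boundaries.append((f"{upstream}-{label}", offset))
        seq_parts.append(sub)
        offset += len(sub)
    return "".join(seq_parts), boundaries


def _orf_candidates(seq: str) -> List[Tuple[int, str]]:
    """All (start, peptide) ORFs beginning at each ATG, forward strand only.

    Translation runs codon by codon from the ATG until the first in-frame
    stop (not emitted) or the end of the sequence (trailing partial codon
    dropped).
    """
    out = []
    start = seq.find("ATG")
    while start != -1:
        coding_len = (len(seq) - start) // 3 * 3
        codons = Seq(seq[start : start + coding_len])
        aa = str(codons.translate(to_stop=True))
        if aa:
            out.append((start, aa))
        start = seq.find("ATG", start + 1)
    return out


def _best_orf(seq: str) -> Optional[Tuple[int, str]]:
    """Longest ORF over all ATG starts; earliest start breaks ties."""
    cands = _orf_candidates(seq)
    if not cands:
        return None
    return max(cands, key=lambda c: (len(c[1]), -c[0]))


def screen_transcript(
    model: ExonModel, t: TranscriptModel, min_orf_aa: int = 30
) -> TranscriptVerdict:
    """Classify a transcript's protein-coding plausibility.

    ``coding`` iff some AUG opens an ORF of at least ``min_orf_aa`` residues;
    ``no_orf`` when the spliced sequence has no AUG at all; ``premature_stop``
    when every ORF terminates before the minimum length;
    ``fragment_noncoding`` for sequences too short to hold a codon.
    """
    if model.mode != "nt":
        raise ValueError("transcript screening requires a nucleotide-mode model")
    seq, _ = splice(model, t)
    if len(seq) < 3:
        return TranscriptVerdict(t.transcript_id, "fragment_noncoding",
                                 f"spliced length {len(seq)} < 3 nt")
    best = _best_orf(seq)
    if best is None:
        return TranscriptVerdict(t.transcript_id, "no_orf", "no AUG in spliced sequence")
    start, aa = best
    if len(aa) < min_orf_aa:
        return TranscriptVerdict(
            t.transcript_id, "premature_stop",
            f"longest ORF {len(aa)} aa < {min_orf_aa} aa (start nt {start})",
        )
    return TranscriptVerdict(t.transcript_id, "coding", f"ORF {len(aa)} aa at nt {start}")


def translate_transcript(
    model: ExonModel,
    t: TranscriptModel,
    min_orf_aa: int = 30,
    isoform_id: Optional[str] = None,
) -> ProteinIsoform:
    """Translate a spliced transcript into a junction-annotated isoform.

    Raises ``ValueError`` carrying the screening verdict when the transcript
    is not plausibly coding (no AUG, or ORF below ``min_orf_aa``).

    In amino-acid mode the spliced sequence *is* the isoform and junction
    positions fall directly out of cumulative exon lengths.
    """
    seq, boundaries = splice(model, t)
    iso_id = isoform_id or f"{t.transcript_id}_iso"

    if model.mode == "aa":
        junctions = [(tag, off) for tag, off in boundaries if 1 <= off <= len(seq) - 1]
        return ProteinIsoform(iso_id, seq, junctions, t.transcript_id)

    verdict = screen_transcript(model, t, min_orf_aa=min_orf_aa)
    if verdict.status != "coding":
        raise ValueError(f"transcript {t.transcript_id!r} not coding: "
                         f"{verdict.status} ({verdict.reason})")
    start, aa = _best_orf(seq)  # type: ignore[misc]
    junctions: List[Tuple[str, int]] = []
    for tag, nt_off in boundaries:
        rel = nt_off - start
        if rel <= 0:
            continue  # junction upstream of the ORF start: not peptide-observable
        aa_pos = rel // 3  # first residue containing a downstream-exon nucleotide
        if 1 <= aa_pos <= len(aa) - 1:
            junctions.append((tag, aa_pos))
    return ProteinIsoform(iso_id, aa, junctions, t.transcript_id)


def enumerate_junction_windows(
    iso: ProteinIsoform, flank: int = 7
) -> List[Tuple[str, str]]:
    """Sequence windows of ``flank`` residues on each side of every junction.

    Windows are clipped at the sequence ends; a peptide is junction-diagnostic
    iff it spans the boundary with at least one residue on each side.
    """
    if flank < 1:
        raise ValueError("flank must be >= 1")
    out = []
    for tag, pos in iso.junctions:
        lo = max(0, pos - flank)
        hi = min(len(iso.aa_sequence), pos + flank)
        out.append((tag, iso.aa_sequence[lo:hi]))
    return out


# ---------------------------------------------------------------------------
# I/O


def write_isoform_fasta(isoforms: Sequence[ProteinIsoform], path) -> None:
    """Write isoforms as FASTA with a parseable junction-annotated header."""
    if not isoforms:
        raise ValueError("empty isoform set")
    ids = [iso.isoform_id for iso in isoforms]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate isoform_id in FASTA export")
    records = []
    for iso in isoforms:
        junc = ",".join(f"{tag}@{pos}" for tag, pos in iso.junctions)
        desc = f"transcript={iso.source_transcript} junctions={junc}"
        records.append(SeqRecord(Seq(iso.aa_sequence), id=iso.isoform_id, description=desc))
    SeqIO.write(records, str(path), "fasta")


def read_isoform_fasta(path) -> List[ProteinIsoform]:
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        fields = dict(
            kv.split("=", 1) for kv in rec.description.split()[1:] if "=" in kv
        )
        junctions: List[Tuple[str, int]] = []
        for item in filter(None, fields.get("junctions", "").split(",")):
            tag, pos = item.rsplit("@", 1)
            junctions.append((tag, int(pos)))
        out.append(
            ProteinIsoform(rec.id, str(rec.seq), junctions, fields.get("transcript", ""))
        )
    return out


def read_exon_model_tsv(path) -> ExonModel:
    """Read an exon table (exon_id, category, mode, sequence; tab-separated)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = {"exon_id", "category", "mode", "sequence"}
    if not required <= set(df.columns):
        raise ValueError(f"exon table must have columns {sorted(required)}")
    modes = set(df["mode"])
    if len(modes) != 1:
        raise ValueError(f"exon table mixes modes {sorted(modes)}")
    exons = [
        Exon(r.exon_id, r.category, r.sequence) for r in df.itertuples(index=False)
    ]
    return ExonModel.from_exons(exons, mode=modes.pop())


def read_transcripts_json(path) -> List[TranscriptModel]:
    """Read transcript definitions from JSON.

    Schema: ``[{"transcript_id": ..., "exons": ["e1", ["e2", 0, 30], ...]}]``;
    a bare string means the full exon, a 3-list gives partial offsets.
    """
    with open(path) as fh:
        data = json.load(fh)
    out = []
    for entry in data:
        refs: List[ExonRef] = []
        for ref in entry["exons"]:
            if isinstance(ref, str):
                refs.append((ref, None, None))
            else:
                eid, s, e = ref
                refs.append((eid, s, e))
        out.append(
            TranscriptModel(
                entry["transcript_id"], refs, entry.get("declared_coding", True)
            )
        )
    return out
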