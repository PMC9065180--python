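"""Aggregation of accepted GPSMs into junction, isoform and glycosite reports.

A "band" is a group of spectra sharing free-text metadata (in the source
study, a gel band at a molecular-weight window). Isoform assignment is
conservative: an isoform is called only on junction-diagnostic or
isoform-unique peptide evidence; peptides shared between isoforms contribute
to the coverage of every compatible isoform but never to an assignment.
"""

from __future__ import annotations

import json
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd

from .isoforms import ProteinIsoform
from .scoring import GPSM

__all__ = [
    "BandReport",
    "GlycositeSummary",
    "assign_isoforms",
    "summarize_glycosites",
    "write_reports",
]


@dataclass
class BandReport:
    band: str
    junction_counts: Dict[str, int] = field(default_factory=dict)
    assigned_isoforms: List[str] = field(default_factory=list)
    coverage: Dict[str, float] = field(default_factory=dict)
    n_accepted: int = 0

    @property
    def no_id(self) -> bool:
        return self.n_accepted == 0

    def to_dict(self) -> dict:
        return {
            "band": self.band,
            "status": "No ID" if self.no_id else "ID",
            "n_accepted_gpsms": self.n_accepted,
            "junction_counts": dict(sorted(self.junction_counts.items())),
            "assigned_isoforms": sorted(self.assigned_isoforms),
            "coverage": {k: round(v, 4) for k, v in sorted(self.coverage.items())},
        }


@dataclass
class GlycositeSummary:
    """Per-site composition spectrum, split into localized and ambiguous strata.

    Keys are (isoform_id, site_position_on_isoform, composition_string).
    """

    localized: Dict[Tuple[str, int, str], int] = field(default_factory=dict)
    ambiguous: Dict[Tuple[str, int, str], int] = field(default_factory=dict)

    @property
    def n_sites(self) -> int:
        return len({(iso, pos) for iso, pos, _ in self.localized})

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for stratum, table in (("localized", self.localized), ("ambiguous", self.ambiguous)):
            for (iso, pos, comp), count in sorted(table.items()):
                rows.append(
                    {"isoform": iso, "site": pos, "composition": comp,
                     "stratum": stratum, "n_gpsms": count}
                )
        return pd.DataFrame(
            rows, columns=["isoform", "site", "composition", "stratum", "n_gpsms"]
        )


def _accepted(gpsms: Iterable[GPSM], q_threshold: float) -> List[GPSM]:
    return [
        g for g in gpsms
        if not g.is_decoy and g.q_value is not None and g.q_value <= q_threshold
    ]


def _peptide_occurrences(sequence: str, isoform: ProteinIsoform) -> List[int]:
    """Start offsets of every occurrence of a peptide in an isoform."""
    out, start = [], isoform.aa_sequence.find(sequence)
    while start != -1:
        out.append(start)
        start = isoform.aa_sequence.find(sequence, start + 1)
    return out


def assign_isoforms(
    gpsms: Sequence[GPSM],
    isoforms: Sequence[ProteinIsoform],
    band: str = "",
    q_threshold: float = 0.01,
    min_junction_gpsms: int = 1,
) -> BandReport:
    """Aggregate accepted GPSMs into a per-band isoform report.

    An isoform is assigned when a junction diagnostic of it is supported by at
    least ``min_junction_gpsms`` accepted GPSMs, or an isoform-unique peptide
    is observed. Coverage is the fraction of distinct isoform residues covered
    by accepted peptides mapped onto the complete isoform sequence (shared
    peptides count toward every compatible isoform's coverage).
    """
    accepted = _accepted(gpsms, q_threshold)
    report = BandReport(band=band, n_accepted=len(accepted))
    if not accepted:
        return report

    junction_counts: Dict[str, int] = defaultdict(int)
    for g in accepted:
        for tag in g.candidate.peptide.junction_tags:
            junction_counts[tag] += 1
    report.junction_counts = dict(junction_counts)

    # coverage: union of residue positions per isoform
    covered: Dict[str, set] = {iso.isoform_id: set() for iso in isoforms}
    peptide_homes: Dict[str, set] = defaultdict(set)  # peptide seq -> isoform ids
    for g in accepted:
        seq = g.candidate.peptide.sequence
        for iso in isoforms:
            for start in _peptide_occurrences(seq, iso):
                covered[iso.isoform_id].update(range(start, start + len(seq)))
                peptide_homes[seq].add(iso.isoform_id)
    report.coverage = {
        iso.isoform_id: len(covered[iso.isoform_id]) / len(iso.aa_sequence)
        for iso in isoforms
        if covered[iso.isoform_id]
    }

    # assignment: junction evidence or isoform-unique peptides only
    assigned = set()
    for iso in isoforms:
        tags = set(iso.junction_tags)
        junction_support = sum(
            count for tag, count in junction_counts.items() if tag in tags
        )
        if junction_support >= min_junction_gpsms:
            assigned.add(iso.isoform_id)
            continue
        unique_support = sum(
            1
            for g in accepted
            if peptide_homes.get(g.candidate.peptide.sequence) == {iso.isoform_id}
        )
        if unique_support >= min_junction_gpsms:
            assigned.add(iso.isoform_id)
    report.assigned_isoforms = sorted(assigned)
    return report


def summarize_glycosites(
    gpsms: Sequence[GPSM],
    q_threshold: float = 0.01,
) -> GlycositeSummary:
    """Count accepted GPSMs per glycosite per composition.

    Site positions are reported on the isoform (peptide start + local index).
    GPSMs whose site assignment is not localized are counted in the ambiguous
    stratum (every candidate site of the reported assignment is credited
    there, flagged as such, never mixed with the localized counts).
    """
    summary = GlycositeSummary()
    for g in _accepted(gpsms, q_threshold):
        pep = g.candidate.peptide
        stratum = summary.localized if g.site_localized else summary.ambiguous
        for site, comp in g.candidate.glyco_sites:
            key = (pep.isoform_id, pep.start + site, str(comp))
            stratum[key] = stratum.get(key, 0) + 1
    return summary


def write_reports(
    band_reports: Sequence[BandReport],
    glycosites: Optional[GlycositeSummary],
    out_dir,
) -> Dict[str, Path]:
    """Write TSV + JSON reports with deterministic ordering.

    Output is byte-identical across runs given identical inputs: columns and
    rows are fully ordered and JSON keys sorted.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: Dict[str, Path] = {}

    rows = []
    for r in sorted(band_reports, key=lambda r: r.band):
        d = r.to_dict()
        rows.append(
            {
                "band": d["band"],
                "status": d["status"],
                "n_accepted_gpsms": d["n_accepted_gpsms"],
                "junctions": ";".join(
                    f"{t}:{c}" for t, c in d["junction_counts"].items()
                ),
                "assigned_isoforms": ";".join(d["assigned_isoforms"]),
                "coverage": ";".join(
                    f"{k}:{v:.4f}" for k, v in d["coverage"].items()
                ),
            }
        )
    bands_tsv = out_dir / "band_reports.tsv"
    pd.DataFrame(
        rows,
        columns=["band", "status", "n_accepted_gpsms", "junctions",
                 "assigned_isoforms", "coverage"],
    ).to_csv(bands_tsv, sep="\t", index=False)
    paths["band_reports_tsv"] = bands_tsv

    bands_json = out_dir / "band_reports.json"
    with open(bands_json, "w") as fh:
        json.dump(
            [r.to_dict() for r in sorted(band_reports, key=lambda r: r.band)],
            fh, indent=2, sort_keys=True,
        )
        fh.write("\n")
    paths["band_reports_json"] = bands_json

    if glycosites is not None:
        sites_tsv = out_dir / "glycosites.tsv"
        glycosites.to_frame().to_csv(sites_tsv, sep="\t", index=False)
        paths["glycosites_tsv"] = sites_tsv
    return paths
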