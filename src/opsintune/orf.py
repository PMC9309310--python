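"""ORF integrity evaluation: intact gene, pseudogene, or suspect copy.

Whole-genome duplication leaves salmonid genomes littered with opsin gene
copies in various states of decay. A candidate coding sequence is compared
against an intact paralogue/orthologue reference by codon-aware alignment
and classified:

* ``pseudogene`` — at least one frameshifting indel or premature stop
  codon (the copy cannot encode a full-length opsin);
* ``nonfunctional_suspect`` — reading frame and length preserved, but a
  large in-frame deletion (>= 30 nt by default) removes part of the
  protein, flagged specially when it hits an annotated transmembrane
  helix (a TM3 deletion guts the retinal binding pocket);
* ``intact`` — no frameshifts, no premature stops, no large deletions.

Coordinates in reports are 1-based reference codon positions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from Bio.Seq import Seq

from .sequences import (OpsinSequence, _nucleotide_aligner,
                        map_to_bovine_numbering)

__all__ = [
    "Indel",
    "OrfReport",
    "evaluate_orf",
    "default_tm_regions",
    "write_orf_report_json",
    "write_verdict_tsv",
]

#: In-frame deletions at least this long (nt) mark a copy as suspect.
LARGE_DELETION_NT = 30

#: Queries shorter than this fraction of the reference are truncated
#: beyond rescue and forced to pseudogene.
MIN_LENGTH_FRACTION = 0.5

#: Bovine rod opsin transmembrane helix boundaries (residue ranges).
_BOVINE_TM = {
    "TM1": (34, 64), "TM2": (71, 100), "TM3": (106, 140), "TM4": (150, 172),
    "TM5": (200, 229), "TM6": (241, 276), "TM7": (285, 309),
}


@dataclass(frozen=True)
class Indel:
    reference_codon_position: int
    length_nt: int
    kind: str  # "deletion" | "insertion"

    @property
    def frame_effect(self) -> str:
        return "in-frame" if self.length_nt % 3 == 0 else "frameshift"


@dataclass
class OrfReport:
    query_id: str
    reference_id: str
    indels: list[Indel] = field(default_factory=list)
    premature_stops: list[int] = field(default_factory=list)
    truncation: str = "none"  # none | 5prime | 3prime
    tm3_disruption: bool = False
    verdict: str = "intact"

    def to_dict(self) -> dict:
        return {
            "query_id": self.query_id,
            "reference_id": self.reference_id,
            "indels": [
                {"reference_codon_position": i.reference_codon_position,
                 "length_nt": i.length_nt, "kind": i.kind,
                 "frame_effect": i.frame_effect}
                for i in self.indels],
            "premature_stops": self.premature_stops,
            "truncation": self.truncation,
            "tm3_disruption": self.tm3_disruption,
            "verdict": self.verdict,
        }


def default_tm_regions(reference: OpsinSequence) -> list[tuple[int, int]]:
    """Transmembrane codon ranges of a reference, mapped from the bovine
    rod opsin helix annotation through the numbering alignment."""
    numbering = map_to_bovine_numbering(reference)
    b2q = numbering.bovine_to_query()
    regions = []
    for start, end in _BOVINE_TM.values():
        mapped = [b2q[b] for b in range(start, end + 1) if b in b2q]
        if mapped:
            regions.append((min(mapped), max(mapped)))
    return regions


def left_align_deletion(ref: str, start_nt: int, length: int) -> int:
    """Canonical (leftmost) placement of a deletion on the reference.

    Deleting ref[s..e] and ref[s-1..e-1] yield the same sequence whenever
    ref[s-1] == ref[e]; indel positions are therefore normalized to the
    leftmost equivalent placement (as VCF normalization does), so that
    independently produced coordinates are comparable. 1-based nt in/out.
    """
    s, e = start_nt, start_nt + length - 1
    while s > 1 and ref[s - 2] == ref[e - 1]:
        s -= 1
        e -= 1
    return s


def left_align_insertion(ref: str, after_nt: int, inserted: str) -> int:
    """Leftmost equivalent placement of an insertion after ``after_nt``
    (0 = before the first base). Returns the canonical after-position."""
    p, ins = after_nt, inserted
    while p >= 1 and ins[-1] == ref[p - 1]:
        ins = ins[-1] + ins[:-1]
        p -= 1
    return p


def _gap_runs(row: str) -> list[tuple[int, int]]:
    """(start_column, length) of each gap run in an alignment row."""
    runs = []
    start = None
    for i, ch in enumerate(row):
        if ch == "-" and start is None:
            start = i
        elif ch != "-" and start is not None:
            runs.append((start, i - start))
            start = None
    if start is not None:
        runs.append((start, len(row) - start))
    return runs


def _overlaps(a_start: int, a_end: int, regions: list[tuple[int, int]]) -> bool:
    return any(a_start <= r_end and a_end >= r_start
               for r_start, r_end in regions)


def evaluate_orf(query: OpsinSequence, reference: OpsinSequence,
                 tm_regions: list[tuple[int, int]] | None = None,
                 large_deletion_nt: int = LARGE_DELETION_NT) -> OrfReport:
    """Align a candidate CDS to an intact reference and call its status.

    ``tm_regions`` are reference codon ranges (1-based inclusive); when
    omitted they are derived from the bovine rod opsin helix annotation
    via the numbering alignment of the reference protein.
    """
    if query.cds is None or reference.cds is None:
        raise ValueError("both query and reference need coding sequences")
    ref_cds = reference.cds
    n_ref_codons = len(ref_cds) // 3
    ref_aa = str(Seq(ref_cds[:n_ref_codons * 3]).translate())
    if "*" in ref_aa[:-1]:
        raise ValueError(
            f"reference {reference.id} contains an internal stop codon")
    if tm_regions is None:
        tm_regions = default_tm_regions(reference)

    report = OrfReport(query_id=query.id, reference_id=reference.id)

    alignment = _nucleotide_aligner().align(query.cds, reference.cds)[0]
    q_row, r_row = str(alignment[0]), str(alignment[1])

    # column -> 1-based reference nt position (position of last ref nt seen)
    ref_pos_at = []
    pos = 0
    for ch in r_row:
        if ch != "-":
            pos += 1
        ref_pos_at.append(pos)

    n_cols = len(q_row)
    for start, length in _gap_runs(q_row):  # deletions relative to reference
        terminal = start == 0 or start + length == n_cols
        if terminal:
            if length >= 30:
                report.truncation = "5prime" if start == 0 else "3prime"
            continue
        ref_nt = ref_pos_at[start - 1] + 1  # first deleted ref nt
        ref_nt = left_align_deletion(ref_cds, ref_nt, length)
        codon = (ref_nt - 1) // 3 + 1
        report.indels.append(Indel(codon, length, "deletion"))
    for start, length in _gap_runs(r_row):  # insertions in the query
        if start == 0 or start + length == n_cols:
            continue
        after_nt = ref_pos_at[start - 1]
        inserted = q_row[start:start + length]
        after_nt = left_align_insertion(ref_cds, after_nt, inserted)
        codon = max(after_nt // 3 + 1, 1)
        report.indels.append(Indel(codon, length, "insertion"))
    report.indels.sort(key=lambda i: i.reference_codon_position)

    # premature stops: translate the query in the shared reading frame and
    # map each stop through the alignment into reference codon coordinates
    q_pos_at = []
    pos = 0
    for ch in q_row:
        if ch != "-":
            pos += 1
        q_pos_at.append(pos)
    q_nt_to_ref = {}
    for col in range(n_cols):
        if q_row[col] != "-":
            q_nt_to_ref[q_pos_at[col]] = ref_pos_at[col]
    n_q_codons = len(query.cds) // 3
    q_aa = str(Seq(query.cds[:n_q_codons * 3]).translate())
    for i, aa in enumerate(q_aa[:-1]):
        if aa == "*":
            ref_nt = q_nt_to_ref.get(3 * i + 1, 0)
            report.premature_stops.append(max((ref_nt - 1) // 3 + 1, 1))

    frameshifts = [i for i in report.indels if i.frame_effect == "frameshift"]
    large_dels = [i for i in report.indels
                  if i.kind == "deletion" and i.frame_effect == "in-frame"
                  and i.length_nt >= large_deletion_nt]
    report.tm3_disruption = any(
        _overlaps(i.reference_codon_position,
                  i.reference_codon_position + i.length_nt // 3 - 1,
                  tm_regions)
        for i in large_dels)

    if len(query.cds) < MIN_LENGTH_FRACTION * len(reference.cds):
        if report.truncation == "none":
            report.truncation = "3prime"
        report.verdict = "pseudogene"
    elif frameshifts or report.premature_stops:
        report.verdict = "pseudogene"
    elif report.tm3_disruption or large_dels:
        report.verdict = "nonfunctional_suspect"
    else:
        report.verdict = "intact"
    return report


def write_orf_report_json(report: OrfReport, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(report.to_dict(), fh, indent=2)
        fh.write("\n")


def write_verdict_tsv(reports: list[OrfReport], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("query_id\treference_id\tn_indels\tn_frameshifts\t"
                 "n_premature_stops\ttruncation\ttm3_disruption\tverdict\n")
        for r in reports:
            n_fs = sum(1 for i in r.indels if i.frame_effect == "frameshift")
            fh.write(f"{r.query_id}\t{r.reference_id}\t{len(r.indels)}\t"
                     f"{n_fs}\t{len(r.premature_stops)}\t{r.truncation}\t"
                     f"{str(r.tm3_disruption).lower()}\t{r.verdict}\n")
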