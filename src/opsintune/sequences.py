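"""Opsin sequence handling: FASTA ingestion, bovine-numbering maps,
tuning-site extraction, and pairwise identity screening.

All site arithmetic in this package uses the conventional bovine rod opsin
numbering (reference NP_001014890, 348 residues), so that e.g. the
Schiff-base lysine is K296 regardless of the query species. Mapping a query
opsin onto that frame is a global protein alignment; opsins are full-length
GPCRs and align end to end.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq

__all__ = [
    "OpsinSequence",
    "NumberingMap",
    "TuningSiteProfile",
    "OPSIN_CLASSES",
    "TUNING_SITE_REGISTRY",
    "GAP",
    "bovine_reference",
    "read_fasta",
    "write_fasta",
    "map_to_bovine_numbering",
    "extract_tuning_sites",
    "percent_identity",
    "cross_hybridization_flag",
    "write_profiles_tsv",
]

GAP = "-"

OPSIN_CLASSES = ("lws", "sws1", "sws2", "rh2", "rh1", "unknown")

#: Spectral-tuning sites interrogated per opsin class (bovine numbering).
#: RH1 carries the long list of rod-opsin sites reported as spectrally
#: important; LWS uses the five-sites rule positions; SWS1 hinges on site 86
#: (UV vs violet); RH2 on the E122Q switch. SWS2 tuning is not site-ruled
#: here (its lambda-max comes from the dynamics-descriptor regression), so
#: its registered list is empty.
TUNING_SITE_REGISTRY: dict[str, tuple[int, ...]] = {
    "rh1": (83, 90, 96, 102, 113, 118, 122, 124, 132, 164, 183, 194, 195,
            207, 208, 211, 214, 253, 261, 265, 269, 289, 292, 295, 299,
            300, 317),
    "lws": (164, 181, 261, 269, 292),
    "sws1": (86,),
    "rh2": (122,),
    "sws2": (),
}

_PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYBZXJUO*-")
_NUC_ALPHABET = set("ACGTUNRYSWKMBDHV-")
_STRICT_NUC = set("ACGTN")

_CLASS_TAG = re.compile(r"(sws1|sws2|rh2|rh1|lws)", re.IGNORECASE)


@dataclass
class OpsinSequence:
    """A visual opsin, optionally with its coding sequence.

    When ``cds`` is supplied, ``protein`` is its first-frame translation up
    to (not including) the first stop codon.
    """

    id: str
    species: str = ""
    opsin_class: str = "unknown"
    cds: str | None = None
    protein: str = ""

    def __post_init__(self) -> None:
        if self.opsin_class not in OPSIN_CLASSES:
            raise ValueError(
                f"unknown opsin class {self.opsin_class!r}; "
                f"valid classes: {', '.join(OPSIN_CLASSES)}"
            )
        if self.cds is not None:
            self.cds = self.cds.upper().replace("U", "T")
            if len(self.cds) < 3:
                raise ValueError(f"{self.id}: cds shorter than one codon")
            if not self.protein:
                self.protein = translate_to_first_stop(self.cds)
        self.protein = self.protein.upper()
        if not self.protein:
            raise ValueError(f"{self.id}: empty protein sequence")

    def __len__(self) -> int:
        return len(self.protein)


def translate_to_first_stop(cds: str) -> str:
    """First reading frame translation, truncated at the first stop."""
    n = len(cds) - len(cds) % 3
    aa = str(Seq(cds[:n]).translate())
    stop = aa.find("*")
    return aa if stop < 0 else aa[:stop]


@dataclass
class NumberingMap:
    """Query-position to bovine-position correspondence from a global
    alignment. Positions are 1-based; unaligned residues pair with None."""

    pairs: list[tuple[int | None, int | None]]
    reliable: bool = True

    def query_to_bovine(self) -> dict[int, int]:
        return {q: b for q, b in self.pairs if q is not None and b is not None}

    def bovine_to_query(self) -> dict[int, int]:
        return {b: q for q, b in self.pairs if q is not None and b is not None}


@dataclass
class TuningSiteProfile:
    """Residues observed at the registered tuning sites of one pigment."""

    pigment_id: str
    opsin_class: str
    residues: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        allowed = TUNING_SITE_REGISTRY.get(self.opsin_class)
        if allowed is None:
            raise ValueError(
                f"unknown opsin class {self.opsin_class!r}; valid classes "
                f"with registered sites: {', '.join(TUNING_SITE_REGISTRY)}"
            )
        bad = set(self.residues) - set(allowed)
        if bad:
            raise ValueError(
                f"{self.pigment_id}: sites {sorted(bad)} are not registered "
                f"for class {self.opsin_class}"
            )
        for site, res in self.residues.items():
            if res != GAP and (len(res) != 1 or res not in _PROTEIN_ALPHABET):
                raise ValueError(
                    f"{self.pigment_id}: invalid residue {res!r} at site {site}"
                )


def bovine_reference() -> OpsinSequence:
    """The packaged 348-residue bovine rod opsin numbering reference."""
    ref = resources.files("opsintune.data") / "bovine_rh1.fasta"
    with resources.as_file(ref) as path:
        record = next(SeqIO.parse(str(path), "fasta"))
    return OpsinSequence(
        id=record.id, species="Bos taurus", opsin_class="rh1",
        protein=str(record.seq),
    )


def _infer_class(header: str) -> str:
    m = _CLASS_TAG.search(header)
    return m.group(1).lower() if m else "unknown"


def read_fasta(path: str | Path) -> list[OpsinSequence]:
    """Read opsin records from FASTA.

    Sequences composed solely of unambiguous nucleotide letters are treated
    as coding sequences and translated; anything else is taken as protein.
    The opsin class is inferred from class tags (lws/sws1/sws2/rh2/rh1) in
    the header when present.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    out = []
    for rec in records:
        seq = str(rec.seq).upper()
        letters = set(seq)
        is_nuc = letters <= _STRICT_NUC
        if not is_nuc and not letters <= _PROTEIN_ALPHABET:
            bad = sorted(letters - _PROTEIN_ALPHABET)
            raise ValueError(
                f"record {rec.id!r}: non-IUPAC characters {bad}"
            )
        header = f"{rec.id} {rec.description}"
        if is_nuc:
            out.append(OpsinSequence(id=rec.id, opsin_class=_infer_class(header),
                                     cds=seq))
        else:
            out.append(OpsinSequence(id=rec.id, opsin_class=_infer_class(header),
                                     protein=seq))
    return out


def write_fasta(seqs: list[OpsinSequence], path: str | Path,
                what: str = "protein") -> None:
    with open(path, "w") as fh:
        for s in seqs:
            body = s.cds if what == "cds" else s.protein
            if body is None:
                raise ValueError(f"{s.id}: no {what} sequence to write")
            fh.write(f">{s.id} class={s.opsin_class}\n")
            for i in range(0, len(body), 60):
                fh.write(body[i:i + 60] + "\n")


def _protein_aligner(open_gap: float = -10.0, extend_gap: float = -0.5
                     ) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.mode = "global"
    aligner.open_gap_score = open_gap
    aligner.extend_gap_score = extend_gap
    return aligner


def _nucleotide_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 5.0
    aligner.mismatch_score = -4.0
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    return aligner


def _alignment_pairs(alignment) -> list[tuple[int | None, int | None]]:
    """Expand a Biopython alignment into per-column 1-based index pairs."""
    pairs: list[tuple[int | None, int | None]] = []
    a_idx = b_idx = 0
    col_a, col_b = alignment[0], alignment[1]
    for ca, cb in zip(col_a, col_b):
        qa = qb = None
        if ca != "-":
            a_idx += 1
            qa = a_idx
        if cb != "-":
            b_idx += 1
            qb = b_idx
        pairs.append((qa, qb))
    return pairs


def map_to_bovine_numbering(query: OpsinSequence,
                            reference_protein: str | None = None
                            ) -> NumberingMap:
    """Globally align a query opsin to the bovine rod opsin reference and
    return the residue-numbering correspondence.

    Queries shorter than 100 residues are mapped but flagged unreliable.
    """
    if reference_protein is None:
        reference_protein = bovine_reference().protein
    if len(reference_protein) != 348:
        raise ValueError(
            f"bovine reference must be 348 residues, got {len(reference_protein)}"
        )
    if not query.protein:
        raise ValueError("query protein is empty")
    alignment = _protein_aligner().align(query.protein, reference_protein)[0]
    return NumberingMap(pairs=_alignment_pairs(alignment),
                        reliable=len(query.protein) >= 100)


def extract_tuning_sites(query: OpsinSequence, numbering: NumberingMap,
                         opsin_class: str | None = None) -> TuningSiteProfile:
    """Read out the residues at the registered tuning sites of a class.

    Sites that fall in alignment gaps (deleted in the query) are recorded
    with the gap marker so downstream rules can flag them explicitly.
    """
    cls = opsin_class or query.opsin_class
    if cls not in TUNING_SITE_REGISTRY:
        raise ValueError(
            f"unknown opsin class {cls!r}; valid classes: "
            f"{', '.join(TUNING_SITE_REGISTRY)}"
        )
    b2q = numbering.bovine_to_query()
    residues = {}
    for site in TUNING_SITE_REGISTRY[cls]:
        q = b2q.get(site)
        residues[site] = query.protein[q - 1] if q is not None else GAP
    return TuningSiteProfile(pigment_id=query.id, opsin_class=cls,
                             residues=residues)


def percent_identity(a: str, b: str, codon_aware: bool = False) -> float:
    """Global-alignment identity of two nucleotide sequences, in percent.

    Identity = matches / aligned columns x 100, counting internal gap
    columns as mismatches. With ``codon_aware=True`` both inputs must be
    coding sequences; they are aligned via their protein translations and
    the alignment is threaded back onto codons, which keeps indels in frame.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    a = a.upper().replace("U", "T")
    b = b.upper().replace("U", "T")
    if codon_aware:
        pa = translate_to_first_stop(a)
        pb = translate_to_first_stop(b)
        alignment = _protein_aligner().align(pa, pb)[0]
        cols_a, cols_b = [], []
        ia = ib = 0
        for ca, cb in zip(alignment[0], alignment[1]):
            cols_a.append(a[3 * ia:3 * ia + 3] if ca != "-" else "---")
            cols_b.append(b[3 * ib:3 * ib + 3] if cb != "-" else "---")
            if ca != "-":
                ia += 1
            if cb != "-":
                ib += 1
        sa, sb = "".join(cols_a), "".join(cols_b)
    else:
        alignment = _nucleotide_aligner().align(a, b)[0]
        sa, sb = str(alignment[0]), str(alignment[1])
    matches = sum(1 for x, y in zip(sa, sb) if x == y and x != "-")
    columns = len(sa)
    return 100.0 * matches / columns


def cross_hybridization_flag(identity: float) -> str:
    """Classify probe cross-hybridization risk from pairwise identity.

    >=90% identity is high enough that a riboprobe binds paralogues;
    <=65% is safely class-specific; the band in between (which in practice
    contains e.g. ~87% within-class paralogue identity) is uncertain.
    """
    if not 0.0 <= identity <= 100.0:
        raise ValueError(f"identity must be in [0, 100], got {identity}")
    if identity >= 90.0:
        return "hybridizes"
    if identity <= 65.0:
        return "no_cross"
    return "uncertain"


def write_profiles_tsv(profiles: list[TuningSiteProfile],
                       path: str | Path) -> None:
    """Long-format TSV: pigment_id, class, site, residue."""
    with open(path, "w") as fh:
        fh.write("pigment_id\tclass\tsite\tresidue\n")
        for p in profiles:
            for site in sorted(p.residues):
                fh.write(f"{p.pigment_id}\t{p.opsin_class}\t{site}\t"
                         f"{p.residues[site]}\n")
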