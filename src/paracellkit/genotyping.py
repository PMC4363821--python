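"""Knockout-allele classification against a reference open reading frame.

Nuclease-mediated knockouts (TALEN/CRISPR) are repaired by error-prone end
joining, producing indels around the cut site near the start codon.  An
allele disrupts the gene when it either loses the initiating ATG
(``START_LOST``) or carries a net coding indel whose length is not a
multiple of 3 (``FRAMESHIFT``).  In-frame indels and pure substitutions
that spare the ATG leave the reading frame intact (``IN_FRAME``).

For disrupted alleles, translation can re-initiate at the next in-frame
downstream ATG of the transcript, producing an N-terminally truncated
product; the classifier predicts that alternative start codon and the
average molecular mass of the truncated peptide.

Alignment of allele to reference uses a global pairwise alignment with
affine gaps (match +1, mismatch -2, gap open -5, gap extend -1); gap
placement ties are resolved deterministically (leftmost equivalent
placement as produced by Biopython's alignment enumeration order).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

from Bio.Align import PairwiseAligner
from Bio.Seq import Seq

from .constants import WATER_MASS_DA
from .errors import OutOfRangeError, ParacellError, UnrelatedSequenceError

__all__ = [
    "ReferenceORF",
    "AlleleAlignment",
    "AlleleCall",
    "AVERAGE_RESIDUE_MASS_DA",
    "align_allele",
    "classify_allele",
    "call_allele",
    "call_alleles",
    "find_next_inframe_start",
    "predict_peptide_mass",
]

#: Average (not monoisotopic) residue masses, Da.
AVERAGE_RESIDUE_MASS_DA: dict[str, float] = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167, "V": 99.1326,
    "T": 101.1051, "C": 103.1388, "L": 113.1594, "I": 113.1594, "N": 114.1038,
    "D": 115.0886, "Q": 128.1307, "K": 128.1741, "E": 129.1155, "M": 131.1926,
    "H": 137.1411, "F": 147.1766, "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}

_STOPS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class ReferenceORF:
    """A reference coding sequence: starts with ATG, length divisible by 3,
    no internal stop codon before the terminal codon."""

    nucleotide_sequence: str
    id: str = "ref"

    def __post_init__(self) -> None:
        seq = self.nucleotide_sequence.upper()
        object.__setattr__(self, "nucleotide_sequence", seq)
        if set(seq) - set("ACGT"):
            raise OutOfRangeError(f"ORF {self.id!r} contains non-ACGT characters")
        if len(seq) % 3 != 0 or len(seq) < 6:
            raise OutOfRangeError(f"ORF {self.id!r} length {len(seq)} not a multiple of 3 (>= 6)")
        if not seq.startswith("ATG"):
            raise OutOfRangeError(f"ORF {self.id!r} does not begin with ATG")
        internal = [seq[i : i + 3] for i in range(0, len(seq) - 3, 3)]
        if any(c in _STOPS for c in internal):
            raise OutOfRangeError(f"ORF {self.id!r} has an internal stop codon")

    @property
    def n_codons(self) -> int:
        return len(self.nucleotide_sequence) // 3

    def codon(self, index_1based: int) -> str:
        i = 3 * (index_1based - 1)
        return self.nucleotide_sequence[i : i + 3]

    def translate(self) -> str:
        return str(Seq(self.nucleotide_sequence).translate(to_stop=True))


@dataclass(frozen=True)
class AlleleAlignment:
    """Indel/substitution calls of one allele in reference coordinates.

    Positions are 0-based nucleotide offsets into the reference ORF
    (negative / beyond-ORF positions refer to flanking sequence, which does
    not count toward the coding indel balance).
    """

    allele_id: str
    score: float
    identity: float
    deletions: tuple[tuple[int, int], ...]  # (ref_start, length)
    insertions: tuple[tuple[int, int, str], ...]  # (ref_pos, length, inserted_seq)
    substitutions: tuple[tuple[int, str, str], ...]  # (ref_pos, ref_base, alt_base)
    orf_length: int
    #: allele index aligned to the reference ORF start (None if unalignable)
    query_orf_start: Optional[int] = None
    #: the three allele bases at that position (the allele's effective start codon)
    query_start_codon: str = ""

    def _in_coding(self, pos: int) -> bool:
        return 0 <= pos < self.orf_length

    @property
    def net_indel_nt(self) -> int:
        """Net coding-region indel length (insertions positive)."""
        net = sum(n for p, n, _ in self.insertions if self._in_coding(min(p, self.orf_length - 1)))
        for start, length in self.deletions:
            lo = max(start, 0)
            hi = min(start + length, self.orf_length)
            if hi > lo:
                net -= hi - lo
        return net


@dataclass(frozen=True)
class AlleleCall:
    allele_id: str
    category: str  # START_LOST | FRAMESHIFT | IN_FRAME | WILD_TYPE
    net_indel_nt: int
    start_lost: bool
    frameshift: bool
    predicted_alt_start_codon_index: Optional[int] = None
    predicted_peptide: Optional[str] = None
    predicted_mass_kda: Optional[float] = None


def predict_peptide_mass(amino_acid_sequence: str) -> float:
    """Average molecular mass of a peptide in kDa (residue masses + one water)."""
    total = WATER_MASS_DA
    for i, aa in enumerate(amino_acid_sequence.upper()):
        try:
            total += AVERAGE_RESIDUE_MASS_DA[aa]
        except KeyError:
            raise OutOfRangeError(f"unknown residue {aa!r} at position {i + 1}") from None
    return total / 1000.0


def find_next_inframe_start(reference: ReferenceORF) -> Optional[int]:
    """Smallest 1-based codon index > 1 whose frame-0 codon is ATG, else None."""
    for k in range(2, reference.n_codons + 1):
        if reference.codon(k) == "ATG":
            return k
    return None


def _make_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -2.0
    aligner.open_gap_score = -5.0
    aligner.extend_gap_score = -1.0
    return aligner


def align_allele(
    reference: ReferenceORF,
    allele_sequence: str,
    allele_id: str = "",
    flank5: str = "",
    flank3: str = "",
) -> AlleleAlignment:
    """Globally align an allele to the (optionally flanked) reference.

    Event positions are reported relative to the ORF start so that flanking
    sequence never enters the coding indel balance.  Alignments with
    identity below 60% over aligned columns raise
    :class:`UnrelatedSequenceError`.
    """
    allele = allele_sequence.upper().replace("\n", "")
    if set(allele) - set("ACGT"):
        raise OutOfRangeError(f"allele {allele_id!r} contains non-ACGT characters")
    ref_full = (flank5 + reference.nucleotide_sequence + flank3).upper()
    offset = len(flank5)

    aligner = _make_aligner()
    aln = aligner.align(ref_full, allele)[0]
    ref_blocks, qry_blocks = aln.aligned

    deletions: list[tuple[int, int]] = []
    insertions: list[tuple[int, int, str]] = []
    substitutions: list[tuple[int, str, str]] = []
    matches = columns = 0

    prev_r = prev_q = 0
    blocks = list(zip(ref_blocks, qry_blocks)) + [
        (((len(ref_full), len(ref_full))), ((len(allele), len(allele))))
    ]
    for (r0, r1), (q0, q1) in blocks:
        if r0 > prev_r:  # reference bases skipped: deletion in allele
            deletions.append((prev_r - offset, r0 - prev_r))
            columns += r0 - prev_r
        if q0 > prev_q:  # allele bases not in reference: insertion
            insertions.append((prev_r - offset, q0 - prev_q, allele[prev_q:q0]))
            columns += q0 - prev_q
        for i in range(r1 - r0):
            rb, qb = ref_full[r0 + i], allele[q0 + i]
            columns += 1
            if rb == qb:
                matches += 1
            else:
                substitutions.append((r0 + i - offset, rb, qb))
        prev_r, prev_q = r1, q1

    identity = matches / columns if columns else 0.0
    if identity < 0.6:
        raise UnrelatedSequenceError(
            f"allele {allele_id!r} aligns at {identity:.1%} identity (< 60%): unrelated sequence"
        )

    # allele position aligned to the ORF start: inside a block it is the
    # direct mapping; if the start falls in a deletion, the next aligned
    # allele base takes its place (gap placement in repeat runs is
    # ambiguous, so start-codon integrity is judged on the allele side)
    q_start: Optional[int] = None
    for (r0, r1), (q0, q1) in zip(ref_blocks, qry_blocks):
        if r0 <= offset < r1:
            q_start = q0 + (offset - r0)
            break
        if r0 > offset:
            q_start = q0
            break
    start_codon = allele[q_start : q_start + 3] if q_start is not None else ""

    return AlleleAlignment(
        allele_id=allele_id,
        score=float(aln.score),
        identity=identity,
        deletions=tuple(deletions),
        insertions=tuple(insertions),
        substitutions=tuple(substitutions),
        orf_length=len(reference.nucleotide_sequence),
        query_orf_start=q_start,
        query_start_codon=start_codon,
    )


def _start_codon_lost(alignment: AlleleAlignment) -> bool:
    """The allele no longer carries ATG at the position of the reference start.

    Judged on the allele side rather than on reference gap positions: when a
    deletion sits in a repeat run adjacent to the start codon, leftmost gap
    placement may formally overlap ATG even though the allele still begins
    with an intact ATG.
    """
    return alignment.query_start_codon != "ATG"


def classify_allele(
    alignment: AlleleAlignment,
    reference: ReferenceORF,
    allele_sequence: str | None = None,
) -> AlleleCall:
    """Categorise one aligned allele and predict its translation product.

    * ``START_LOST`` when the allele no longer has an ATG aligned at the
      reference start (the initiating codon was deleted or substituted).
    * ``FRAMESHIFT`` when the start is intact but the net coding indel is
      not a multiple of 3.
    * ``IN_FRAME`` for net-multiple-of-3 indels or ATG-sparing
      substitutions; ``WILD_TYPE`` when there is no change at all.

    For disrupted alleles the predicted product is translation from the
    next in-frame ATG of the reference (truncation product); for intact
    alleles it is the full-length product.
    """
    start_lost = _start_codon_lost(alignment)
    net = alignment.net_indel_nt
    has_change = bool(alignment.deletions or alignment.insertions or alignment.substitutions)
    frameshift = (not start_lost) and net % 3 != 0

    if start_lost:
        category = "START_LOST"
    elif frameshift:
        category = "FRAMESHIFT"
    elif has_change:
        category = "IN_FRAME"
    else:
        category = "WILD_TYPE"

    alt_start: Optional[int] = None
    peptide: Optional[str] = None
    if category in ("START_LOST", "FRAMESHIFT"):
        alt_start = find_next_inframe_start(reference)
        if alt_start is not None:
            peptide = str(
                Seq(reference.nucleotide_sequence[3 * (alt_start - 1):]).translate(to_stop=True)
            )
    elif category == "WILD_TYPE":
        peptide = reference.translate()
    elif allele_sequence is not None:
        # in-frame variant: translate the allele from its (intact) start codon
        qpos = alignment.query_orf_start
        if qpos is not None:
            tail = allele_sequence.upper()[qpos:]
            tail = tail[: 3 * (len(tail) // 3)]
            if tail.startswith("ATG"):
                peptide = str(Seq(tail).translate(to_stop=True))

    mass = predict_peptide_mass(peptide) if peptide else None
    return AlleleCall(
        allele_id=alignment.allele_id,
        category=category,
        net_indel_nt=net,
        start_lost=start_lost,
        frameshift=frameshift,
        predicted_alt_start_codon_index=alt_start,
        predicted_peptide=peptide,
        predicted_mass_kda=round(mass, 4) if mass is not None else None,
    )


def call_allele(reference: ReferenceORF, allele_sequence: str, allele_id: str = "") -> AlleleCall:
    aln = align_allele(reference, allele_sequence, allele_id)
    return classify_allele(aln, reference, allele_sequence)


def call_alleles(reference: ReferenceORF, alleles: Mapping[str, str]) -> list[AlleleCall]:
    return [call_allele(reference, seq, allele_id) for allele_id, seq in alleles.items()]
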