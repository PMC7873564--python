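"""Sequence handling for the FcµR Ig-like domains.

Parsing, full-length numbering, global alignment, percent identity, mutant
construction and cysteine (disulfide) classification.  The printed human and
mouse domain fragments live in :mod:`fcmurkit.data`; everything here works on
any pair of protein sequences.

Numbering convention: residue numbers are full-length, 1-based from the
initiator Met of the receptor.  A :class:`ProteinSequence` stores the housed
fragment plus ``numbering_offset``, the full-length number of its first
residue, so the residue at local index ``i`` (1-based) has full-length number
``i + numbering_offset - 1``.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from Bio import Align, SeqIO
from Bio.Align import substitution_matrices
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")

#: sentinel for a deletion edit
DELETION = None


class SequenceParseError(ValueError):
    """Raised when a raw sequence contains a non-amino-acid character."""


class AnchorError(ValueError):
    """Raised when a numbering anchor motif is absent or ambiguous."""


class MutationError(ValueError):
    """Raised when a mutation edit does not match the housed sequence."""


class ClassificationError(ValueError):
    """Raised when a cysteine cannot be resolved through the alignment."""


# ---------------------------------------------------------------------------
# core types


@dataclass(frozen=True)
class ProteinSequence:
    """A protein fragment with a full-length numbering offset."""

    id: str
    residues: str
    numbering_offset: int = 1

    def __post_init__(self) -> None:
        bad = set(self.residues) - AMINO_ACIDS
        if bad:
            raise SequenceParseError(
                f"{self.id}: non-amino-acid characters {sorted(bad)}"
            )
        if self.numbering_offset < 1:
            raise ValueError("numbering_offset must be >= 1")

    def __len__(self) -> int:
        return len(self.residues)

    def full_position(self, local_index: int) -> int:
        """Full-length residue number for a 1-based local index."""
        if not 1 <= local_index <= len(self):
            raise IndexError(f"local index {local_index} out of range")
        return local_index + self.numbering_offset - 1

    def local_index(self, full_position: int) -> int:
        """1-based local index for a full-length residue number."""
        i = full_position - self.numbering_offset + 1
        if not 1 <= i <= len(self):
            raise IndexError(
                f"{self.id}: full-length position {full_position} outside "
                f"housed range {self.numbering_offset}-{self.full_position(len(self))}"
            )
        return i

    def residue_at(self, full_position: int) -> str:
        return self.residues[self.local_index(full_position) - 1]

    @property
    def full_range(self) -> tuple[int, int]:
        return self.numbering_offset, self.full_position(len(self))


def parse_domain_sequence(raw_text: str, id: str = "seq") -> ProteinSequence:
    """Parse a printed sequence, stripping hyphens, whitespace and digits.

    Hyphens inside the printed domain sequences are typesetting artifacts,
    not alignment gaps, and are removed.  Any remaining character outside the
    20-letter alphabet is an error reported with its position in the cleaned
    string.
    """
    cleaned = re.sub(r"[-\s\d]", "", raw_text).upper()
    if not cleaned:
        raise SequenceParseError(f"{id}: empty sequence after stripping")
    for i, ch in enumerate(cleaned, start=1):
        if ch not in AMINO_ACIDS:
            raise SequenceParseError(
                f"{id}: invalid character {ch!r} at position {i}"
            )
    return ProteinSequence(id=id, residues=cleaned)


def anchor_numbering(
    seq: ProteinSequence, motif: str, motif_full_position: int
) -> ProteinSequence:
    """Set the numbering offset so that ``motif`` starts at the given number.

    The motif must occur exactly once in the housed residues.
    """
    # overlapping occurrences count as distinct anchor candidates
    n = len(re.findall(f"(?={re.escape(motif)})", seq.residues))
    if n != 1:
        raise AnchorError(
            f"{seq.id}: motif {motif!r} occurs {n} times (need exactly 1)"
        )
    local0 = seq.residues.find(motif)  # 0-based
    offset = motif_full_position - local0
    if offset < 1:
        raise AnchorError(
            f"{seq.id}: anchoring {motif!r} at {motif_full_position} would give "
            f"offset {offset} < 1"
        )
    return replace(seq, numbering_offset=offset)


# ---------------------------------------------------------------------------
# alignment


@dataclass(frozen=True)
class PairwiseAlignment:
    """A global pairwise alignment with gap character ``-``."""

    aligned_a: str
    aligned_b: str
    score: float

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned rows must have equal length")
        if any(x == "-" and y == "-" for x, y in zip(self.aligned_a, self.aligned_b)):
            raise ValueError("gap-gap column in alignment")

    @property
    def n_columns(self) -> int:
        return len(self.aligned_a)

    @property
    def n_identical(self) -> int:
        return sum(
            x == y and x != "-" for x, y in zip(self.aligned_a, self.aligned_b)
        )

    @property
    def n_gaps_a(self) -> int:
        return self.aligned_a.count("-")

    @property
    def n_gaps_b(self) -> int:
        return self.aligned_b.count("-")

    def degapped(self) -> tuple[str, str]:
        return self.aligned_a.replace("-", ""), self.aligned_b.replace("-", "")

    def columns(self) -> Iterable[tuple[int, int | None, int | None, str, str]]:
        """Yield (column, local_a, local_b, res_a, res_b); locals are 1-based
        indices into the ungapped sequences, None at a gap."""
        ia = ib = 0
        for k, (x, y) in enumerate(zip(self.aligned_a, self.aligned_b)):
            la = lb = None
            if x != "-":
                ia += 1
                la = ia
            if y != "-":
                ib += 1
                lb = ib
            yield k, la, lb, x, y


def default_aligner(
    matrix: str = "BLOSUM62", gap_open: float = 10.0, gap_extend: float = 0.5
) -> Align.PairwiseAligner:
    """Global aligner with BLOSUM62 and affine gaps (open 10, extend 0.5).

    Gap run of length L costs ``gap_open + (L - 1) * gap_extend``.
    """
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    aligner.mode = "global"
    return aligner


def align_global(
    a: ProteinSequence,
    b: ProteinSequence,
    matrix: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> PairwiseAlignment:
    """Optimal global alignment of two sequences.

    Ties are broken deterministically (first alignment in the aligner's
    enumeration order), so repeated calls return the same alignment.
    """
    if not a.residues or not b.residues:
        raise ValueError("cannot align empty sequences")
    aligner = default_aligner(matrix, gap_open, gap_extend)
    result = aligner.align(a.residues, b.residues)
    best = result[0]
    return PairwiseAlignment(
        aligned_a=str(best[0]), aligned_b=str(best[1]), score=float(result.score)
    )


def percent_identity(
    aln: PairwiseAlignment, convention: str = "columns"
) -> float:
    """Unrounded percent identity under the chosen denominator convention.

    ``columns`` divides by alignment columns (gap columns count against
    identity); ``shorter``/``longer`` divide by the shorter/longer ungapped
    sequence length.
    """
    a, b = aln.degapped()
    denom = {
        "columns": aln.n_columns,
        "shorter": min(len(a), len(b)),
        "longer": max(len(a), len(b)),
    }[convention]
    return 100.0 * aln.n_identical / denom


def identity_report(aln: PairwiseAlignment, convention: str = "columns") -> dict:
    """Percent identity plus both integer renderings (the rounding convention
    used for published percentages is frequently unstated)."""
    value = percent_identity(aln, convention)
    return {
        "percent_identity": value,
        "round_half_up": int(math.floor(value + 0.5)),
        "truncated": int(value),
        "n_identical": aln.n_identical,
        "n_columns": aln.n_columns,
        "convention": convention,
    }


# ---------------------------------------------------------------------------
# mutations


@dataclass(frozen=True)
class Edit:
    """One residue edit in full-length numbering; ``to=None`` is a deletion."""

    position: int
    expected_from: str
    to: str | None


@dataclass(frozen=True)
class MutationSpec:
    label: str
    edits: tuple[Edit, ...]

    def __post_init__(self) -> None:
        positions = [e.position for e in self.edits]
        if positions != sorted(set(positions)):
            raise ValueError(f"{self.label}: edit positions must be strictly increasing")

    def inverse(self) -> "MutationSpec":
        """Reverse spec for substitution-only mutations (restores wild type)."""
        if any(e.to is None for e in self.edits):
            raise MutationError(f"{self.label}: deletions are not invertible")
        return MutationSpec(
            label=f"rev({self.label})",
            edits=tuple(Edit(e.position, e.to, e.expected_from) for e in self.edits),
        )


_LABEL_RE = re.compile(r"^([A-Z]+)(\d+)(?:-(\d+))?([A-Z]+|-)$")


def parse_mutation_label(label: str) -> MutationSpec:
    """Parse compact mutant notation: ``E41Q``, ``N66-``, ``EM41-42QL``,
    ``KQYPR79-83TPCLD``, ``KVEG24-27QLNV``."""
    m = _LABEL_RE.match(label)
    if not m:
        raise MutationError(f"cannot parse mutation label {label!r}")
    from_res, start_s, end_s, to_res = m.groups()
    start = int(start_s)
    end = int(end_s) if end_s else start + len(from_res) - 1
    if end - start + 1 != len(from_res):
        raise MutationError(f"{label}: range {start}-{end} does not span {from_res!r}")
    if to_res == "-":
        edits = tuple(
            Edit(start + i, aa, DELETION) for i, aa in enumerate(from_res)
        )
    else:
        if len(to_res) != len(from_res):
            raise MutationError(
                f"{label}: replacement {to_res!r} length differs from {from_res!r}"
            )
        edits = tuple(
            Edit(start + i, fr, to)
            for i, (fr, to) in enumerate(zip(from_res, to_res))
            if fr != to
        )
    return MutationSpec(label=label, edits=edits)


def apply_mutation(seq: ProteinSequence, spec: MutationSpec) -> ProteinSequence:
    """Apply a mutation spec; the original full-length offset is retained so
    substituted residues keep their wild-type numbering (deletions shift the
    internal indices of downstream residues only)."""
    residues = list(seq.residues)
    for e in spec.edits:
        found = seq.residue_at(e.position)
        if found != e.expected_from:
            raise MutationError(
                f"{spec.label}: position {e.position} expected "
                f"{e.expected_from}, found {found}"
            )
    delete = set()
    for e in spec.edits:
        i = seq.local_index(e.position) - 1
        if e.to is DELETION:
            delete.add(i)
        else:
            residues[i] = e.to
    mutated = "".join(r for i, r in enumerate(residues) if i not in delete)
    return ProteinSequence(
        id=f"{seq.id}|{spec.label}",
        residues=mutated,
        numbering_offset=seq.numbering_offset,
    )


# ---------------------------------------------------------------------------
# regions and cysteines


@dataclass(frozen=True)
class RegionMap:
    """Named full-length residue ranges plus disulfide/salt-bridge annotations.

    CDR boundaries are configurable: the structure-based limits are not
    published, so the defaults bracket the residues known to lie in each
    region (A strand 24-27, CDR1 containing 41-42, the two-residue CDR2
    containing 66, DE loop 79-83, CDR3 containing 109).
    """

    regions: dict[str, tuple[int, int]] = field(
        default_factory=lambda: {
            "A_strand": (24, 27),
            "CDR1": (38, 42),
            "CDR2": (65, 66),
            "DE_loop": (79, 83),
            "CDR3": (105, 111),
        }
    )
    disulfides: tuple[tuple[int, int], ...] = ((37, 104), (49, 58))
    salt_bridge: tuple[int, int] = (75, 98)

    def __post_init__(self) -> None:
        spans = sorted(self.regions.values())
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 <= e1:
                raise ValueError("region ranges overlap")

    def bridge_positions(self) -> set[int]:
        return {p for pair in self.disulfides for p in pair}

    def validate_against(self, seq: ProteinSequence) -> None:
        """Every annotated position must resolve to a residue of ``seq``."""
        for start, end in self.regions.values():
            for p in (start, end):
                seq.residue_at(p)
        for p in sorted(self.bridge_positions() | set(self.salt_bridge)):
            seq.residue_at(p)


@dataclass(frozen=True)
class CysteineCall:
    """Classification of one cysteine of the query sequence."""

    local_position: int          # 1-based index in the query
    reference_position: int      # full-length number of the aligned reference column
    bridged: bool


def cysteine_topology(
    seq: ProteinSequence,
    reference: ProteinSequence,
    aln: PairwiseAlignment | None = None,
    bridges: Sequence[tuple[int, int]] = ((37, 104), (49, 58)),
) -> list[CysteineCall]:
    """Classify each cysteine of ``seq`` as disulfide-bridged or free.

    A cysteine is bridged when its alignment column carries a
    bridge-annotated cysteine of the reference; any other cysteine is free
    and reported at the reference (human-aligned) column number.  ``aln``
    must align reference (row a) against ``seq`` (row b); it is computed
    under default scoring when omitted.
    """
    if aln is None:
        aln = align_global(reference, seq)
    ref_deg, seq_deg = aln.degapped()
    if ref_deg != reference.residues or seq_deg != seq.residues:
        raise ClassificationError("alignment rows do not match the given sequences")
    bridge_set = {p for pair in bridges for p in pair}
    calls: list[CysteineCall] = []
    for _, la, lb, res_ref, res_seq in aln.columns():
        if res_seq != "C" or lb is None:
            continue
        if la is None:
            raise ClassificationError(
                f"cysteine at local position {lb} of {seq.id} aligns to a gap "
                "in the reference; column not resolvable"
            )
        ref_full = reference.full_position(la)
        bridged = res_ref == "C" and ref_full in bridge_set
        calls.append(
            CysteineCall(local_position=lb, reference_position=ref_full, bridged=bridged)
        )
    return calls


def region_identity(
    aln: PairwiseAlignment,
    a_seq: ProteinSequence,
    regions: dict[str, tuple[int, int]],
) -> dict[str, dict]:
    """Per-region identity over alignment columns, with region membership
    decided by the full-length number of row a (the reference row)."""
    out: dict[str, dict] = {}
    cols: dict[str, list[tuple[str, str]]] = {name: [] for name in regions}
    for _, la, _lb, x, y in aln.columns():
        if la is None:
            continue
        full = a_seq.full_position(la)
        for name, (start, end) in regions.items():
            if start <= full <= end:
                cols[name].append((x, y))
    for name, pairs in cols.items():
        n = len(pairs)
        nid = sum(x == y and x != "-" for x, y in pairs)
        out[name] = {
            "n_columns": n,
            "n_identical": nid,
            "percent_identity": (100.0 * nid / n) if n else float("nan"),
        }
    return out


# ---------------------------------------------------------------------------
# FASTA IO


def read_fasta(path: str | Path) -> list[ProteinSequence]:
    return [
        parse_domain_sequence(str(rec.seq), id=rec.id)
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(path: str | Path, seqs: Iterable[ProteinSequence]) -> None:
    records = [
        SeqRecord(Seq(s.residues), id=s.id, description=f"offset={s.numbering_offset}")
        for s in seqs
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# convenience constructors for the housed domain pair


def human_domain() -> ProteinSequence:
    """The printed human Ig-like domain, anchored so KVEG sits at 24-27."""
    from . import data

    seq = parse_domain_sequence(data.HUMAN_DOMAIN_RAW, id=data.HUMAN_DOMAIN_ID)
    return anchor_numbering(seq, data.ANCHOR_MOTIF, data.ANCHOR_POSITION)


def mouse_domain() -> ProteinSequence:
    """The printed mouse Ig-like domain (offset 1; mouse numbering differs
    from human and reports default to human-aligned columns)."""
    from . import data

    return parse_domain_sequence(data.MOUSE_DOMAIN_RAW, id=data.MOUSE_DOMAIN_ID)
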