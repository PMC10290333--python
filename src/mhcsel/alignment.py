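"""In-frame codon alignments, translation, site masks, and reference numbering.

All downstream statistics operate on :class:`CodonAlignment` objects: aligned
nucleotide sequences (A/C/G/T plus ``-``) restricted to whole codon columns
after applying a reading-frame offset.  Amino-acid positions quoted in a
reference numbering (e.g. HLA-A2 residues 92-179) are related to alignment
columns through a :class:`SiteMap` built by globally aligning the ungapped
reference fragment against the alignment consensus.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Align import PairwiseAligner
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

GAP = "-"
NUCLEOTIDES = "ACGT"
_VALID_CHARS = frozenset(NUCLEOTIDES + GAP)

_standard = CodonTable.unambiguous_dna_by_id[1]
#: codon -> one-letter amino acid, with '*' for the three stop codons
GENETIC_CODE: Mapping[str, str] = {
    **_standard.forward_table,
    **{c: "*" for c in _standard.stop_codons},
}
STOP_CODONS = frozenset(_standard.stop_codons)
SENSE_CODONS = tuple(sorted(c for c, aa in GENETIC_CODE.items() if aa != "*"))


class DuplicateIdError(ValueError):
    pass


class AlignmentError(ValueError):
    pass


def read_fasta(path: str | Path) -> tuple[list[str], list[str]]:
    """Read a multi-record FASTA file into parallel (ids, seqs) lists.

    Ids are the header up to the first whitespace; record order is preserved.
    Raises on an empty file or a duplicated id.
    """
    ids: list[str] = []
    seqs: list[str] = []
    seen: set[str] = set()
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in seen:
            raise DuplicateIdError(f"duplicate sequence id {record.id!r} in {path}")
        seen.add(record.id)
        ids.append(record.id)
        seqs.append(str(record.seq).upper())
    if not ids:
        raise ValueError(f"no FASTA records found in {path}")
    return ids, seqs


def write_fasta(path: str | Path, ids: Sequence[str], seqs: Sequence[str]) -> None:
    records = [SeqRecord(Seq(s), id=i, description="") for i, s in zip(ids, seqs)]
    SeqIO.write(records, str(path), "fasta-2line")


@dataclass(frozen=True)
class CodonAlignment:
    """An in-frame codon alignment: equal-length sequences of whole codons.

    ``frame`` records the 1-based reading frame of the source alignment
    (frame f means f-1 leading columns were discarded); the stored sequences
    are already trimmed so their length is a multiple of three.
    """

    ids: tuple[str, ...]
    seqs: tuple[str, ...]
    frame: int = 1
    name: str = ""

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.seqs):
            raise AlignmentError("ids and seqs differ in length")
        if len(set(self.ids)) != len(self.ids):
            raise DuplicateIdError("sequence ids are not unique")
        lengths = {len(s) for s in self.seqs}
        if len(lengths) > 1:
            raise AlignmentError(f"sequences have unequal lengths: {sorted(lengths)}")
        if self.seqs and len(self.seqs[0]) % 3 != 0:
            raise AlignmentError("codon alignment length is not a multiple of 3")
        bad = {ch for s in self.seqs for ch in s} - _VALID_CHARS
        if bad:
            raise AlignmentError(
                f"invalid characters (only A/C/G/T/- allowed): {sorted(bad)}"
            )
        if self.frame not in (1, 2, 3):
            raise AlignmentError(f"frame must be 1, 2 or 3, got {self.frame}")

    @property
    def n_seqs(self) -> int:
        return len(self.seqs)

    @property
    def n_codons(self) -> int:
        return len(self.seqs[0]) // 3 if self.seqs else 0

    def codon(self, seq_index: int, column: int) -> str:
        return self.seqs[seq_index][3 * column : 3 * column + 3]

    def codon_rows(self) -> list[list[str]]:
        """Sequences split into codon columns: rows[i][c] is codon c of seq i."""
        return [
            [s[3 * c : 3 * c + 3] for c in range(self.n_codons)] for s in self.seqs
        ]


@dataclass(frozen=True)
class ProteinAlignment:
    """Translated codon alignment: '-' for gap-containing codons, '*' for stops."""

    ids: tuple[str, ...]
    aa_seqs: tuple[str, ...]
    frame: int = 1

    @property
    def n_seqs(self) -> int:
        return len(self.aa_seqs)

    @property
    def n_columns(self) -> int:
        return len(self.aa_seqs[0]) if self.aa_seqs else 0


def to_codon_alignment(
    ids: Sequence[str],
    seqs: Sequence[str],
    frame: int,
    name: str = "",
) -> CodonAlignment:
    """Frame-shift a nucleotide alignment into whole codon columns.

    Frame f drops the f-1 leading columns; a trailing remainder of fewer than
    three columns is trimmed (and logged).  For example a 258-column alignment
    at frame 3 yields 85 codon columns (258-2=256, trim 1, 255/3).
    """
    if frame not in (1, 2, 3):
        raise AlignmentError(f"frame must be 1, 2 or 3, got {frame}")
    lengths = {len(s) for s in seqs}
    if len(lengths) > 1:
        raise AlignmentError(f"sequences have unequal lengths: {sorted(lengths)}")
    bad = {ch for s in seqs for ch in s.upper()} - _VALID_CHARS
    if bad:
        raise AlignmentError(
            f"invalid characters (only A/C/G/T/- allowed): {sorted(bad)}"
        )
    lead = frame - 1
    length = lengths.pop() if lengths else 0
    tail = (length - lead) % 3
    if lead or tail:
        logger.info(
            "framing alignment %s: dropping %d leading and %d trailing column(s)",
            name or "<unnamed>",
            lead,
            tail,
        )
    end = length - tail
    trimmed = [s.upper()[lead:end] for s in seqs]
    return CodonAlignment(tuple(ids), tuple(trimmed), frame=frame, name=name)


def translate_codon(codon: str) -> str:
    """Translate one codon column: any gap base -> '-', stops -> '*'."""
    if GAP in codon:
        return GAP
    return GENETIC_CODE[codon]


def translate_seq(nt: str, frame: int = 1) -> str:
    """Translate a single (possibly gapped) nucleotide sequence in frame."""
    lead = frame - 1
    trimmed = nt.upper()[lead : lead + 3 * ((len(nt) - lead) // 3)]
    return "".join(
        translate_codon(trimmed[i : i + 3]) for i in range(0, len(trimmed), 3)
    )


def translate(alignment: CodonAlignment) -> ProteinAlignment:
    aa = tuple(
        "".join(translate_codon(s[i : i + 3]) for i in range(0, len(s), 3))
        for s in alignment.seqs
    )
    return ProteinAlignment(alignment.ids, aa, frame=alignment.frame)


@lru_cache(maxsize=None)
def classify_degeneracy(codon: str) -> tuple[int, int, int]:
    """Degeneracy class (0, 2 or 4) of each position of a sense codon.

    A position is fourfold degenerate if all three alternative bases are
    synonymous, nondegenerate (0) if none is, and twofold otherwise.  Changes
    to stop codons count as nonsynonymous alternatives.
    """
    codon = codon.upper()
    if GAP in codon or codon not in GENETIC_CODE:
        raise ValueError(f"not a valid codon: {codon!r}")
    aa = GENETIC_CODE[codon]
    if aa == "*":
        raise ValueError(f"stop codon {codon} has no degeneracy classes")
    classes = []
    for pos in range(3):
        syn = 0
        for base in NUCLEOTIDES:
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1 :]
            if GENETIC_CODE[alt] == aa:  # stop translates to '*', never equal
                syn += 1
        classes.append(4 if syn == 3 else (0 if syn == 0 else 2))
    return tuple(classes)


@dataclass(frozen=True)
class SiteMask:
    """A named set of amino-acid positions in a declared reference numbering."""

    name: str
    numbering_id: str
    positions: frozenset[int]

    def __post_init__(self) -> None:
        object.__setattr__(self, "positions", frozenset(self.positions))

    def __len__(self) -> int:
        return len(self.positions)


def read_site_mask(path: str | Path, name: str | None = None) -> SiteMask:
    """Read a mask file: two-column TSV (numbering_id, position) or a
    one-position-per-line list whose first line (``# <numbering_id>``) names
    the numbering."""
    path = Path(path)
    lines = [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise ValueError(f"empty site-mask file {path}")
    numbering: str | None = None
    positions: set[int] = set()
    if lines[0].startswith("#"):
        numbering = lines[0].lstrip("#").strip()
        body = lines[1:]
        for ln in body:
            positions.add(int(ln))
    else:
        for ln in lines:
            parts = ln.split("\t")
            if len(parts) != 2:
                raise ValueError(
                    f"mask line {ln!r} is neither '# numbering' header style "
                    "nor two-column TSV"
                )
            nid, pos = parts
            if numbering is None:
                numbering = nid
            elif nid != numbering:
                raise ValueError(
                    f"mixed numbering ids in {path}: {numbering!r} vs {nid!r}"
                )
            positions.add(int(pos))
    return SiteMask(name or path.stem, numbering or "", frozenset(positions))


def write_site_mask(path: str | Path, mask: SiteMask) -> None:
    with open(path, "w") as fh:
        for pos in sorted(mask.positions):
            fh.write(f"{mask.numbering_id}\t{pos}\n")


@dataclass(frozen=True)
class SiteMap:
    """Injective, monotone map from alignment codon columns (0-based) to
    positions in a reference numbering; columns absent from the mapping are
    unmapped (aligned to a reference gap)."""

    column_to_ref: Mapping[int, int]
    n_columns: int
    numbering_id: str = ""

    def __post_init__(self) -> None:
        items = sorted(self.column_to_ref.items())
        refs = [r for _, r in items]
        if len(set(refs)) != len(refs):
            raise ValueError("site map is not injective")
        if any(b <= a for a, b in zip(refs, refs[1:])):
            raise ValueError("site map is not monotone increasing")
        object.__setattr__(self, "column_to_ref", dict(items))

    @property
    def ref_to_column(self) -> dict[int, int]:
        return {r: c for c, r in self.column_to_ref.items()}

    def unmapped_columns(self) -> list[int]:
        return [c for c in range(self.n_columns) if c not in self.column_to_ref]

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("column_index_0based\treference_position\n")
            for c, r in self.column_to_ref.items():
                fh.write(f"{c}\t{r}\n")


def _consensus(protein: ProteinAlignment) -> str:
    cols = []
    for i in range(protein.n_columns):
        counts: dict[str, int] = {}
        for s in protein.aa_seqs:
            ch = s[i]
            if ch in (GAP, "*"):
                continue
            counts[ch] = counts.get(ch, 0) + 1
        if not counts:
            cols.append(GAP)
        else:
            # deterministic tie-break: highest count, then alphabetical
            cols.append(min(counts, key=lambda ch: (-counts[ch], ch)))
    return "".join(cols)


def build_site_map(
    protein: ProteinAlignment,
    reference_aa_seq: str,
    reference_start: int,
    numbering_id: str = "",
    min_identity: float = 0.5,
) -> SiteMap:
    """Map alignment codon columns to a reference residue numbering.

    The ungapped reference fragment is globally aligned to the alignment
    consensus (match=1, mismatch=0, gap=-1); each column aligned to a
    reference residue receives ``reference_start`` plus the number of
    reference residues preceding it.  The mapping is rejected if fewer than
    ``min_identity`` of the reference residues land on an identical consensus
    residue, which signals an unrelated reference.
    """
    reference_aa_seq = reference_aa_seq.upper().replace(GAP, "")
    if not reference_aa_seq:
        raise ValueError("empty reference sequence")
    consensus = _consensus(protein)
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = 0
    aligner.open_gap_score = -1
    aligner.extend_gap_score = -1
    aln = aligner.align(consensus, reference_aa_seq)[0]
    target_blocks, query_blocks = aln.aligned
    mapping: dict[int, int] = {}
    identical = 0
    for (t0, t1), (q0, q1) in zip(target_blocks, query_blocks):
        for offset in range(t1 - t0):
            t, q = t0 + offset, q0 + offset
            mapping[t] = reference_start + q
            if consensus[t] == reference_aa_seq[q]:
                identical += 1
    if identical / len(reference_aa_seq) < min_identity:
        raise ValueError(
            "unreliable site map: only "
            f"{identical}/{len(reference_aa_seq)} reference residues matched "
            "the alignment consensus"
        )
    return SiteMap(mapping, protein.n_columns, numbering_id=numbering_id)


def mask_to_columns(mask: SiteMask, site_map: SiteMap) -> tuple[int, ...]:
    """Resolve a reference-numbered mask to 0-based alignment codon columns."""
    if (
        mask.numbering_id
        and site_map.numbering_id
        and mask.numbering_id != site_map.numbering_id
    ):
        raise ValueError(
            f"mask numbering {mask.numbering_id!r} does not match site map "
            f"numbering {site_map.numbering_id!r}"
        )
    inverse = site_map.ref_to_column
    return tuple(sorted(inverse[p] for p in mask.positions if p in inverse))


def concat_alignments(
    a: CodonAlignment,
    b: CodonAlignment,
    pairing: Sequence[tuple[str, str]],
    name: str = "",
) -> CodonAlignment:
    """Column-wise concatenation of two codon alignments.

    ``pairing`` lists (id_in_a, id_in_b) tuples saying which sequence of ``b``
    is appended to which sequence of ``a`` (e.g. class II alpha/beta alleles
    paired by genotype).  The concatenated record is named ``id_a+id_b``.
    """
    index_a = {i: s for i, s in zip(a.ids, a.seqs)}
    index_b = {i: s for i, s in zip(b.ids, b.seqs)}
    ids, seqs = [], []
    for id_a, id_b in pairing:
        if id_a not in index_a:
            raise KeyError(f"id {id_a!r} not in first alignment")
        if id_b not in index_b:
            raise KeyError(f"id {id_b!r} not in second alignment")
        ids.append(f"{id_a}+{id_b}")
        seqs.append(index_a[id_a] + index_b[id_b])
    return CodonAlignment(tuple(ids), tuple(seqs), frame=1, name=name)
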