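"""Alignment polymorphism statistics: segregating sites, nucleotide diversity,
amino-acid p-distance and mean pairwise identity.

Gap handling follows the conventions of the classical tools: pairwise deletion
for k/Pi/p-distance, while pairwise identity scores every column in which at
least one sequence has a base (a gap aligned to a base is a mismatch; gap-gap
columns are excluded).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np

from .alignment import GAP, CodonAlignment, ProteinAlignment, translate


def _seq_list(alignment) -> list[str]:
    if isinstance(alignment, CodonAlignment):
        return list(alignment.seqs)
    if isinstance(alignment, ProteinAlignment):
        return list(alignment.aa_seqs)
    return list(alignment)


def _matrix(seqs: Sequence[str]) -> np.ndarray:
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences")
    if len({len(s) for s in seqs}) != 1:
        raise ValueError("sequences have unequal lengths")
    return np.array([list(s) for s in seqs], dtype="<U1")


def segregating_sites(alignment) -> tuple[int, int]:
    """Return (S, Eta): polymorphic site count and total mutation count.

    A site is segregating when >=2 distinct non-gap bases occur among the
    sequences covering it; Eta adds (number of distinct bases - 1) per site,
    so a triallelic column contributes 1 to S and 2 to Eta.  Sites covered by
    fewer than two sequences are skipped.
    """
    mat = _matrix(_seq_list(alignment))
    s = eta = 0
    for col in mat.T:
        bases = col[col != GAP]
        if bases.size < 2:
            continue
        distinct = np.unique(bases).size
        if distinct >= 2:
            s += 1
            eta += distinct - 1
    return s, eta


def nucleotide_diversity(alignment) -> tuple[float, float]:
    """Return (k, Pi): mean pairwise difference count and per-site diversity.

    Both use pairwise deletion: a column enters a pair's comparison only when
    both sequences carry a base there.  k averages raw difference counts; Pi
    averages per-pair (differences / compared sites).
    """
    mat = _matrix(_seq_list(alignment))
    nongap = mat != GAP
    ks, pis = [], []
    for i, j in combinations(range(mat.shape[0]), 2):
        comp = nongap[i] & nongap[j]
        n_comp = int(comp.sum())
        if n_comp == 0:
            warnings.warn(f"sequence pair ({i},{j}) shares no compared sites; skipped")
            continue
        diffs = int(((mat[i] != mat[j]) & comp).sum())
        ks.append(diffs)
        pis.append(diffs / n_comp)
    if not ks:
        raise ValueError("no comparable sequence pairs")
    return float(np.mean(ks)), float(np.mean(pis))


def aa_p_distance(protein) -> float:
    """Mean amino-acid p-distance over pairs, with pairwise deletion of
    columns containing a gap or stop in either sequence."""
    mat = _matrix(_seq_list(protein))
    ok = (mat != GAP) & (mat != "*")
    dists = []
    for i, j in combinations(range(mat.shape[0]), 2):
        comp = ok[i] & ok[j]
        n_comp = int(comp.sum())
        if n_comp == 0:
            warnings.warn(f"protein pair ({i},{j}) shares no compared residues; skipped")
            continue
        dists.append(int(((mat[i] != mat[j]) & comp).sum()) / n_comp)
    if not dists:
        raise ValueError("no comparable protein pairs")
    return float(np.mean(dists))


def pairwise_identity(alignment) -> float:
    """Mean percent identity over all unordered pairs.

    Scored columns are those where at least one sequence has a base; a gap
    aligned to a base counts as a mismatch and gap-gap columns are excluded.
    """
    mat = _matrix(_seq_list(alignment))
    nongap = mat != GAP
    pcts = []
    for i, j in combinations(range(mat.shape[0]), 2):
        scored = nongap[i] | nongap[j]
        n_scored = int(scored.sum())
        if n_scored == 0:
            warnings.warn(f"pair ({i},{j}) has no scored columns; skipped")
            continue
        same = int(((mat[i] == mat[j]) & scored).sum())
        pcts.append(100.0 * same / n_scored)
    if not pcts:
        raise ValueError("no scorable sequence pairs")
    return float(np.mean(pcts))


@dataclass(frozen=True)
class DiversityResult:
    """One row of polymorphism statistics for an alignment."""

    name: str
    n_seqs: int
    n_nucleotides: int
    n_effective_sites: int
    S: int
    Eta: int
    k: float
    Pi: float
    aa_p_distance: float
    pairwise_identity_pct: float


def summarize_alignment(
    ids: Sequence[str],
    seqs: Sequence[str],
    frame: int,
    name: str = "",
) -> DiversityResult:
    """Compute the full polymorphism row for a nucleotide alignment.

    Nucleotide statistics (S, Eta, k, Pi, identity) are computed on the raw
    alignment; the amino-acid p-distance is computed on the frame-shifted
    translation.  ``n_effective_sites`` counts columns with at least two
    non-gap observations (the columns that can contribute to S).
    """
    from .alignment import to_codon_alignment

    mat = _matrix(list(seqs))
    effective = int(((mat != GAP).sum(axis=0) >= 2).sum())
    s, eta = segregating_sites(seqs)
    k, pi = nucleotide_diversity(seqs)
    codon_aln = to_codon_alignment(ids, seqs, frame, name=name)
    return DiversityResult(
        name=name,
        n_seqs=len(seqs),
        n_nucleotides=len(seqs[0]),
        n_effective_sites=effective,
        S=s,
        Eta=eta,
        k=k,
        Pi=pi,
        aa_p_distance=aa_p_distance(translate(codon_aln)),
        pairwise_identity_pct=pairwise_identity(seqs),
    )
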