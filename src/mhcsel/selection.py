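"""Pairwise dN/dS estimation and the codon-based Z-test of positive selection.

Two distance methods are implemented:

* ``NG86-JC`` — Nei-Gojobori pathway counting of synonymous/nonsynonymous
  sites and differences, with the Jukes-Cantor correction
  d = -(3/4) ln(1 - (4/3) p) applied separately to the synonymous and
  nonsynonymous proportions.
* ``PBL-K2P`` — Pamilo-Bianchi-Li: codon positions are partitioned into
  nondegenerate (L0), twofold (L2) and fourfold (L4) classes, Kimura
  two-parameter transitional (A_i) and transversional (B_i) distances are
  estimated per class, and
  dS = (L2 A2 + L4 A4)/(L2 + L4) + B4,
  dN = A0 + (L0 B0 + L2 B2)/(L0 + L2).

Both methods use pairwise deletion: a codon column enters a pair's comparison
only when both codons are sense codons (no gap, no stop).  Variance of
(dN - dS) comes from a codon bootstrap: each replicate resamples codon
columns with replacement, the same resampling applied to every sequence, and
the Z statistic (dN - dS)/SE is referred to a one-sided standard normal test
of dN > dS.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations, permutations
from typing import Sequence

import numpy as np
from scipy.stats import norm

from .alignment import (
    GAP,
    GENETIC_CODE,
    NUCLEOTIDES,
    CodonAlignment,
    classify_degeneracy,
)

_TRANSITIONS = ({"A", "G"}, {"C", "T"})


def _is_sense(codon: str) -> bool:
    return GAP not in codon and GENETIC_CODE.get(codon, "*") != "*"


def _is_transition(a: str, b: str) -> bool:
    return {a, b} in _TRANSITIONS


@lru_cache(maxsize=None)
def ng86_sites(codon: str) -> tuple[float, float]:
    """Nei-Gojobori synonymous/nonsynonymous site counts (s, n) of a codon.

    Each position contributes (synonymous alternatives / valid alternatives),
    where alternatives creating stop codons are excluded from the
    denominator; n = 3 - s.
    """
    codon = codon.upper()
    if not _is_sense(codon):
        raise ValueError(f"not a sense codon: {codon!r}")
    aa = GENETIC_CODE[codon]
    s = 0.0
    for pos in range(3):
        syn = valid = 0
        for base in NUCLEOTIDES:
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1 :]
            alt_aa = GENETIC_CODE[alt]
            if alt_aa == "*":
                continue
            valid += 1
            if alt_aa == aa:
                syn += 1
        if valid:
            s += syn / valid
    return s, 3.0 - s


def _step_counts(src: str, dst: str) -> tuple[float, float]:
    """Classify a single-base step src->dst as (synonymous, nonsynonymous).

    Steps into or out of a stop codon count as nonsynonymous (used only by
    the all-pathways fallback).
    """
    aa_src, aa_dst = GENETIC_CODE[src], GENETIC_CODE[dst]
    if aa_src == aa_dst and aa_src != "*":
        return 1.0, 0.0
    return 0.0, 1.0


@lru_cache(maxsize=None)
def ng86_pair_diffs(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Pathway-averaged (synonymous, nonsynonymous) difference counts.

    Differences at one position are classified directly; at two (three)
    positions the counts are averaged over the 2 (6) orderings of
    intermediate codons.  Orderings passing through a stop codon are excluded
    from the average; should every ordering hit a stop, all orderings are
    used with stop steps counted as nonsynonymous.
    """
    codon_a, codon_b = codon_a.upper(), codon_b.upper()
    if codon_a > codon_b:  # symmetric; canonicalise for the cache
        codon_a, codon_b = codon_b, codon_a
    if not (_is_sense(codon_a) and _is_sense(codon_b)):
        raise ValueError(f"both codons must be sense codons: {codon_a}, {codon_b}")
    diff_pos = [p for p in range(3) if codon_a[p] != codon_b[p]]
    if not diff_pos:
        return 0.0, 0.0

    def walk(order: tuple[int, ...]) -> tuple[float, float, bool]:
        sd = nd = 0.0
        current = codon_a
        through_stop = False
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            s, n = _step_counts(current, nxt)
            sd += s
            nd += n
            if GENETIC_CODE[nxt] == "*":
                through_stop = True
            current = nxt
        return sd, nd, through_stop

    results = [walk(order) for order in permutations(diff_pos)]
    clean = [(s, n) for s, n, stop in results if not stop]
    if not clean:
        clean = [(s, n) for s, n, _ in results]
    sd = sum(s for s, _ in clean) / len(clean)
    nd = sum(n for _, n in clean) / len(clean)
    return sd, nd


_CLASS_INDEX = {0: 0, 2: 1, 4: 2}


@lru_cache(maxsize=None)
def pbl_pair_stats(
    codon_a: str, codon_b: str
) -> tuple[tuple[float, ...], tuple[float, ...], tuple[float, ...]]:
    """Per-pair degeneracy bookkeeping for one codon column.

    Returns (L, ts, tv): site counts, transition counts and transversion
    counts per degeneracy class (0-fold, 2-fold, 4-fold).  A position whose
    class differs between the two codons contributes half a site to each
    class; a substitution there is likewise split half/half.
    """
    codon_a, codon_b = codon_a.upper(), codon_b.upper()
    if codon_a > codon_b:
        codon_a, codon_b = codon_b, codon_a
    deg_a = classify_degeneracy(codon_a)
    deg_b = classify_degeneracy(codon_b)
    L = [0.0, 0.0, 0.0]
    ts = [0.0, 0.0, 0.0]
    tv = [0.0, 0.0, 0.0]
    for pos in range(3):
        ia, ib = _CLASS_INDEX[deg_a[pos]], _CLASS_INDEX[deg_b[pos]]
        memberships = [(ia, 1.0)] if ia == ib else [(ia, 0.5), (ib, 0.5)]
        for cls, w in memberships:
            L[cls] += w
        if codon_a[pos] != codon_b[pos]:
            target = ts if _is_transition(codon_a[pos], codon_b[pos]) else tv
            for cls, w in memberships:
                target[cls] += w
    return tuple(L), tuple(ts), tuple(tv)


# ---------------------------------------------------------------------------
# alignment-level machinery
# ---------------------------------------------------------------------------

METHODS = ("NG86-JC", "PBL-K2P")


def _resolve_columns(alignment: CodonAlignment, columns) -> np.ndarray:
    if columns is None:
        return np.arange(alignment.n_codons)
    cols = np.asarray(sorted(set(int(c) for c in columns)), dtype=int)
    if cols.size == 0:
        raise ValueError("empty column selection")
    if cols.min() < 0 or cols.max() >= alignment.n_codons:
        raise ValueError("mask columns outside the alignment")
    return cols


class _PairColumnStats:
    """Per-(pair, column) statistic arrays so the codon bootstrap reduces to
    reweighting columns; built once per alignment/mask/method."""

    def __init__(self, alignment: CodonAlignment, columns, method: str):
        if method not in METHODS:
            raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
        if alignment.n_seqs < 2:
            raise ValueError("need at least 2 sequences")
        self.method = method
        cols = _resolve_columns(alignment, columns)
        self.columns = cols
        rows = alignment.codon_rows()
        codons = [[rows[i][c] for c in cols] for i in range(alignment.n_seqs)]
        sense = [[_is_sense(c) for c in row] for row in codons]
        self.pairs = list(combinations(range(alignment.n_seqs), 2))
        P, C = len(self.pairs), len(cols)
        if method == "NG86-JC":
            self.sd = np.zeros((P, C))
            self.nd = np.zeros((P, C))
            self.s_sites = np.zeros((P, C))
            self.n_sites = np.zeros((P, C))
            for p, (i, j) in enumerate(self.pairs):
                for c in range(C):
                    if not (sense[i][c] and sense[j][c]):
                        continue
                    a, b = codons[i][c], codons[j][c]
                    sd, nd = ng86_pair_diffs(a, b)
                    sa, na = ng86_sites(a)
                    sb, nb = ng86_sites(b)
                    self.sd[p, c] = sd
                    self.nd[p, c] = nd
                    self.s_sites[p, c] = (sa + sb) / 2.0
                    self.n_sites[p, c] = (na + nb) / 2.0
        else:
            self.L = np.zeros((P, C, 3))
            self.ts = np.zeros((P, C, 3))
            self.tv = np.zeros((P, C, 3))
            for p, (i, j) in enumerate(self.pairs):
                for c in range(C):
                    if not (sense[i][c] and sense[j][c]):
                        continue
                    L, ts, tv = pbl_pair_stats(codons[i][c], codons[j][c])
                    self.L[p, c] = L
                    self.ts[p, c] = ts
                    self.tv[p, c] = tv

    # -- weighted column sums -> per-pair distances ------------------------
    def distances(self, weights: np.ndarray | None = None):
        """Per-pair (dN, dS, valid) under column weights (bootstrap counts).

        ``weights`` has shape (n_reps, n_columns); None means a single
        replicate with unit weights (the point estimate).
        """
        C = len(self.columns)
        if weights is None:
            weights = np.ones((1, C))
        if self.method == "NG86-JC":
            Sd = weights @ self.sd.T  # (reps, pairs)
            Nd = weights @ self.nd.T
            Ss = weights @ self.s_sites.T
            Ns = weights @ self.n_sites.T
            with np.errstate(divide="ignore", invalid="ignore"):
                pS = np.where(Ss > 0, Sd / np.maximum(Ss, 1e-300), np.nan)
                pN = np.where(Ns > 0, Nd / np.maximum(Ns, 1e-300), np.nan)
                dS = _jukes_cantor(pS)
                dN = _jukes_cantor(pN)
            valid = np.isfinite(dS) & np.isfinite(dN)
            return dN, dS, valid
        L = np.einsum("rc,pck->rpk", weights, self.L)
        TS = np.einsum("rc,pck->rpk", weights, self.ts)
        TV = np.einsum("rc,pck->rpk", weights, self.tv)
        with np.errstate(divide="ignore", invalid="ignore"):
            Pp = np.where(L > 0, TS / np.maximum(L, 1e-300), 0.0)
            Qq = np.where(L > 0, TV / np.maximum(L, 1e-300), 0.0)
            w1 = 1.0 - 2.0 * Pp - Qq
            w2 = 1.0 - 2.0 * Qq
            A = 0.5 * np.log(1.0 / w1) - 0.25 * np.log(1.0 / w2)
            B = 0.5 * np.log(1.0 / w2)
            L0, L2, L4 = L[..., 0], L[..., 1], L[..., 2]
            dS = (L2 * A[..., 1] + L4 * A[..., 2]) / np.maximum(L2 + L4, 1e-300) + B[
                ..., 2
            ]
            dN = A[..., 0] + (L0 * B[..., 0] + L2 * B[..., 1]) / np.maximum(
                L0 + L2, 1e-300
            )
        valid = (
            np.isfinite(dS)
            & np.isfinite(dN)
            & (L4 > 0)
            & (L0 > 0)
            & (L2 + L4 > 0)
            & (L0 + L2 > 0)
        )
        return dN, dS, valid


def _jukes_cantor(p: np.ndarray) -> np.ndarray:
    arg = 1.0 - 4.0 * p / 3.0
    out = np.full_like(p, np.nan, dtype=float)
    ok = np.isfinite(p) & (arg > 0)
    out[ok] = -0.75 * np.log(arg[ok])
    return out


@dataclass(frozen=True)
class DnDsEstimate:
    method: str
    dn: float
    ds: float
    n_pairs: int
    n_pairs_dropped: int

    @property
    def dnds(self) -> float:
        return self.dn / self.ds if self.ds > 0 else math.nan


def _mean_over_pairs(stats: _PairColumnStats) -> DnDsEstimate:
    dN, dS, valid = stats.distances()
    n_valid = int(valid.sum())
    n_dropped = valid.size - n_valid
    if n_valid == 0:
        raise ValueError("all sequence pairs have undefined distances")
    if n_dropped:
        warnings.warn(f"{n_dropped} sequence pair(s) dropped (undefined distance)")
    return DnDsEstimate(
        method=stats.method,
        dn=float(dN[valid].mean()),
        ds=float(dS[valid].mean()),
        n_pairs=n_valid,
        n_pairs_dropped=n_dropped,
    )


def dnds_ng86(alignment: CodonAlignment, columns=None) -> DnDsEstimate:
    """Mean Nei-Gojobori (Jukes-Cantor corrected) dN and dS over all pairs,
    optionally restricted to the given codon columns."""
    return _mean_over_pairs(_PairColumnStats(alignment, columns, "NG86-JC"))


def dnds_pbl(alignment: CodonAlignment, columns=None) -> DnDsEstimate:
    """Mean Pamilo-Bianchi-Li (Kimura 2-parameter) dN and dS over all pairs."""
    return _mean_over_pairs(_PairColumnStats(alignment, columns, "PBL-K2P"))


def dnds(alignment: CodonAlignment, method: str = "NG86-JC", columns=None) -> DnDsEstimate:
    return _mean_over_pairs(_PairColumnStats(alignment, columns, method))


def _bootstrap_diffs(
    stats: _PairColumnStats, reps: int, rng: np.random.Generator
) -> np.ndarray:
    """(dN - dS) across bootstrap replicates that produced a defined mean.

    Each replicate draws codon columns with replacement (implemented as
    multinomial column weights, one draw shared by all sequences).
    Replicates in which every pair is undefined are dropped; more than 50%
    dropped is an error.
    """
    if reps < 2:
        raise ValueError("need at least 2 bootstrap replicates")
    C = len(stats.columns)
    weights = rng.multinomial(C, np.full(C, 1.0 / C), size=reps).astype(float)
    dN, dS, valid = stats.distances(weights)
    diffs = []
    for r in range(reps):
        v = valid[r]
        if not v.any():
            continue
        diffs.append(dN[r, v].mean() - dS[r, v].mean())
    if len(diffs) < reps / 2:
        raise ValueError(
            f"more than half of the bootstrap replicates were undefined "
            f"({reps - len(diffs)}/{reps} dropped)"
        )
    return np.asarray(diffs)


def bootstrap_se(
    alignment: CodonAlignment,
    method: str = "NG86-JC",
    columns=None,
    reps: int = 1000,
    seed: int | None = None,
) -> float:
    """Bootstrap standard error of (dN - dS) from codon-column resampling."""
    stats = _PairColumnStats(alignment, columns, method)
    rng = np.random.default_rng(seed)
    diffs = _bootstrap_diffs(stats, reps, rng)
    return float(np.std(diffs, ddof=1))


@dataclass(frozen=True)
class SelectionResult:
    """Output of the codon-based Z-test of positive selection (dN > dS)."""

    mask_tag: str
    method: str
    dn: float
    ds: float
    diff: float
    se: float
    z: float
    p: float
    n_bootstrap: int
    seed: int | None
    n_pairs: int
    n_pairs_dropped: int

    @property
    def dnds(self) -> float:
        return self.dn / self.ds if self.ds > 0 else math.nan


def z_test_positive_selection(
    alignment: CodonAlignment,
    method: str = "NG86-JC",
    columns=None,
    reps: int = 1000,
    seed: int | None = 0,
    mask_tag: str = "All sites",
) -> SelectionResult:
    """One-tailed codon-based Z-test of positive selection (dN > dS).

    Z = (dN - dS)/SE with SE from the codon bootstrap; p = 1 - Phi(Z).
    When SE = 0 (e.g. a monomorphic alignment) Z is 0 with p = 0.5 if
    dN = dS, otherwise p collapses to 0 or 1 with a warning.
    """
    stats = _PairColumnStats(alignment, columns, method)
    est = _mean_over_pairs(stats)
    rng = np.random.default_rng(seed)
    diffs = _bootstrap_diffs(stats, reps, rng)
    se = float(np.std(diffs, ddof=1))
    diff = est.dn - est.ds
    if se == 0.0:
        if math.isclose(diff, 0.0, abs_tol=1e-12):
            z, p = 0.0, 0.5
        else:
            warnings.warn("zero bootstrap SE with dN != dS; p degenerate")
            z = math.inf if diff > 0 else -math.inf
            p = 0.0 if diff > 0 else 1.0
    else:
        z = diff / se
        p = float(norm.sf(z))
    return SelectionResult(
        mask_tag=mask_tag,
        method=method,
        dn=est.dn,
        ds=est.ds,
        diff=diff,
        se=se,
        z=float(z),
        p=p,
        n_bootstrap=reps,
        seed=seed,
        n_pairs=est.n_pairs,
        n_pairs_dropped=est.n_pairs_dropped,
    )
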