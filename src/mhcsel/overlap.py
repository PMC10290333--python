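"""Association between two site sets on a common numbering: Pearson
chi-square on the 2x2 classification of sites, with a permutation null.

The typical use is testing whether positively selected codon sites (PSS)
coincide with peptide-binding residues (PBR): every amino-acid site is
classified by membership in each set and the resulting 2x2 table
[[overlap, a-only], [b-only, neither]] is scored by the Pearson chi-square
statistic without continuity correction.  Significance comes from redrawing
one mask as a uniform random subset of the same size; when the subset space
is small the tail is computed by full enumeration instead of sampling.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb
from typing import Collection

import numpy as np
from scipy.stats import hypergeom

from .alignment import SiteMask

ENUMERATION_LIMIT = 100_000


def chi_square_2x2(n_sites: int, n_a: int, n_b: int, n_overlap: int) -> float:
    """Pearson chi-square (no Yates correction) of the 2x2 site table.

    The table is [[overlap, a-overlap], [b-overlap, neither]] with expected
    cells from the margins.  Raises on inconsistent counts or a zero margin
    (degenerate table).
    """
    a = n_overlap
    b = n_a - n_overlap
    c = n_b - n_overlap
    d = n_sites - n_a - n_b + n_overlap
    if min(a, b, c, d) < 0:
        raise ValueError(
            f"inconsistent counts: n_sites={n_sites} n_a={n_a} n_b={n_b} "
            f"overlap={n_overlap}"
        )
    margins = (n_a, n_sites - n_a, n_b, n_sites - n_b)
    if 0 in margins:
        raise ValueError(f"degenerate 2x2 table (zero margin): margins={margins}")
    num = n_sites * (a * d - b * c) ** 2
    den = margins[0] * margins[1] * margins[2] * margins[3]
    return num / den


@dataclass(frozen=True)
class OverlapResult:
    n_sites: int
    n_a: int
    n_b: int
    n_overlap: int
    chi2: float
    p_value: float
    n_replicates: int
    seed: int | None
    exact: bool


def _as_position_set(mask) -> frozenset[int]:
    if isinstance(mask, SiteMask):
        return frozenset(mask.positions)
    return frozenset(int(x) for x in mask)


def permutation_independence(
    sites: int | Collection[int],
    mask_a,
    mask_b,
    reps: int = 10_000,
    seed: int | None = None,
    exact: bool | None = None,
) -> OverlapResult:
    """Permutation test of independence between two site sets.

    ``sites`` is the universe of amino-acid positions: either an explicit
    collection or an integer n meaning positions 0..n-1.  ``mask_a`` is held
    fixed while ``mask_b`` is redrawn as a uniform random subset of the same
    size; the Pearson chi-square of each redrawn table is compared with the
    observed one and p = (#{chi2* >= chi2_obs} + 1)/(R + 1).

    Because the statistic depends on the redrawn mask only through its
    overlap with ``mask_a``, the null is the hypergeometric overlap
    distribution; the sampling path draws overlaps from it directly, and
    when C(n_sites, |mask_b|) <= 1e5 the tail probability is computed by
    full enumeration (``exact=True`` in the result, no +1 smoothing).
    """
    if isinstance(mask_a, SiteMask) and isinstance(mask_b, SiteMask):
        if mask_a.numbering_id != mask_b.numbering_id:
            raise ValueError(
                f"masks use different numberings: {mask_a.numbering_id!r} vs "
                f"{mask_b.numbering_id!r}"
            )
    set_a = _as_position_set(mask_a)
    set_b = _as_position_set(mask_b)
    universe = (
        frozenset(range(sites)) if isinstance(sites, int) else frozenset(int(x) for x in sites)
    )
    if not set_a <= universe or not set_b <= universe:
        raise ValueError("mask positions fall outside the site universe")
    n = len(universe)
    na, nb = len(set_a), len(set_b)
    observed_overlap = len(set_a & set_b)
    chi2_obs = chi_square_2x2(n, na, nb, observed_overlap)
    if reps < 1:
        raise ValueError("reps must be >= 1")

    k_min = max(0, na + nb - n)
    k_max = min(na, nb)
    ks = np.arange(k_min, k_max + 1)
    chi2_by_k = np.array([chi_square_2x2(n, na, nb, int(k)) for k in ks])
    in_tail = chi2_by_k >= chi2_obs - 1e-12

    use_exact = exact if exact is not None else comb(n, nb) <= ENUMERATION_LIMIT
    if use_exact:
        pmf = hypergeom.pmf(ks, n, na, nb)
        p = float(pmf[in_tail].sum())
        return OverlapResult(
            n, na, nb, observed_overlap, chi2_obs, p, comb(n, nb), seed, True
        )
    rng = np.random.default_rng(seed)
    draws = rng.hypergeometric(na, n - na, nb, size=reps)
    tail_lookup = dict(zip(ks.tolist(), in_tail.tolist()))
    hits = sum(tail_lookup[int(k)] for k in draws)
    p = (hits + 1) / (reps + 1)
    return OverlapResult(n, na, nb, observed_overlap, chi2_obs, p, reps, seed, False)
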