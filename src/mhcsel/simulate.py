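"""Synthetic data generators for the analysis pipeline.

Two generators cover the two kinds of input the statistics consume:

* :func:`simulate_codon_alignment` evolves allele sequences from a common
  root under site-specific selection (a designated codon subset with its own
  dN/dS acceptance ratio omega), transition/transversion bias kappa, and a
  target expected synonymous divergence per sequence pair.  A star genealogy
  (independent evolution from the root) is used so the planted truth is
  exact per branch.
* :func:`simulate_genotype_dataset` draws multi-locus diploid genotypes from
  per-locus allele pools with configurable frequency skew, copy-number
  variation, negative-binomial read counts, technical replicates with
  per-allele dropout, and a planted expressed subset embedded in transcript
  sequences with random flanks.

Both are deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .alignment import GENETIC_CODE, NUCLEOTIDES, SENSE_CODONS, CodonAlignment
from .selection import ng86_sites

_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}


@dataclass(frozen=True)
class CodonSimConfig:
    """Codon-alignment simulation parameters.

    ``pairwise_ds`` is the expected synonymous divergence between two
    alleles (twice the per-branch divergence from the root); 0.10 sits in
    the range typical of intra-population MHC allele panels.  ``omega_mask``
    applies to codons in ``mask`` and ``omega_background`` elsewhere;
    proposals are single-base changes with transitions weighted ``kappa``,
    nonsynonymous proposals accepted with probability min(1, omega) and
    synonymous proposals with min(1, 1/omega), so the realised
    nonsynonymous:synonymous rate ratio at a site equals its omega on both
    sides of 1.  Proposals creating stop codons are rejected.
    """

    n_alleles: int = 30
    n_codons: int = 90
    mask: tuple[int, ...] = ()
    omega_mask: float = 6.0
    omega_background: float = 1.0
    kappa: float = 2.0
    pairwise_ds: float = 0.10
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.omega_mask <= 0 or self.omega_background <= 0:
            raise ValueError("omega values must be positive")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if self.pairwise_ds < 0:
            raise ValueError("pairwise_ds must be non-negative")
        if self.pairwise_ds > 1.5:
            raise ValueError(
                f"pairwise_ds={self.pairwise_ds} would saturate synonymous sites"
            )
        if any(m < 0 or m >= self.n_codons for m in self.mask):
            raise ValueError("mask indices outside codon range")
        object.__setattr__(self, "mask", tuple(sorted(set(self.mask))))


def _propose_base(base: str, kappa: float, rng: np.random.Generator) -> str:
    """Draw a replacement base: the transition with weight kappa, each
    transversion with weight 1."""
    others = [b for b in NUCLEOTIDES if b != base]
    weights = np.array([kappa if _TRANSITION[base] == b else 1.0 for b in others])
    return others[rng.choice(3, p=weights / weights.sum())]


def simulate_codon_alignment(
    config: CodonSimConfig, seed: int | None = None
) -> tuple[CodonAlignment, dict]:
    """Evolve a star-genealogy codon alignment under site-specific selection.

    Each allele accumulates substitutions from the root until its Poisson
    branch target of accepted synonymous substitutions is met; targets are
    calibrated so the expected synonymous divergence between two alleles is
    ``config.pairwise_ds``.  Returns the alignment and a truth record
    (root sequence, mask, per-allele accepted substitution counts).
    """
    rng = np.random.default_rng(seed if seed is not None else config.seed)
    mask = set(config.mask)
    root_codons = [SENSE_CODONS[i] for i in rng.integers(0, len(SENSE_CODONS), config.n_codons)]
    s_root = sum(ng86_sites(c)[0] for c in root_codons)
    branch_mean = config.pairwise_ds / 2.0 * s_root
    max_proposals = max(10_000, int(branch_mean * 1_000))

    ids, seqs = [], []
    truth_counts = []
    for a in range(config.n_alleles):
        codons = list(root_codons)
        target = int(rng.poisson(branch_mean))
        syn = nonsyn = 0
        mask_nonsyn = 0
        proposals = 0
        while syn < target:
            proposals += 1
            if proposals > max_proposals:
                raise RuntimeError(
                    "divergence target unattainable (saturation): "
                    f"{syn}/{target} synonymous substitutions after "
                    f"{proposals} proposals"
                )
            site = int(rng.integers(0, 3 * config.n_codons))
            codon_idx, pos = divmod(site, 3)
            codon = codons[codon_idx]
            new_base = _propose_base(codon[pos], config.kappa, rng)
            candidate = codon[:pos] + new_base + codon[pos + 1 :]
            if GENETIC_CODE[candidate] == "*":
                continue
            omega = config.omega_mask if codon_idx in mask else config.omega_background
            if GENETIC_CODE[candidate] == GENETIC_CODE[codon]:
                if rng.random() < min(1.0, 1.0 / omega):
                    codons[codon_idx] = candidate
                    syn += 1
            else:
                if rng.random() < min(1.0, omega):
                    codons[codon_idx] = candidate
                    nonsyn += 1
                    if codon_idx in mask:
                        mask_nonsyn += 1
        ids.append(f"allele_{a + 1:03d}")
        seqs.append("".join(codons))
        truth_counts.append(
            {"synonymous": syn, "nonsynonymous": nonsyn, "nonsynonymous_on_mask": mask_nonsyn}
        )
    alignment = CodonAlignment(tuple(ids), tuple(seqs), frame=1, name="simulated")
    truth = {
        "root": "".join(root_codons),
        "mask": sorted(mask),
        "omega_mask": config.omega_mask,
        "omega_background": config.omega_background,
        "kappa": config.kappa,
        "pairwise_ds": config.pairwise_ds,
        "branch_mean_syn_substitutions": branch_mean,
        "per_allele_substitutions": truth_counts,
    }
    return alignment, truth


@dataclass(frozen=True)
class GenotypeSimConfig:
    """Multi-locus amplicon genotype simulation parameters.

    Defaults mirror a realistic raptor MHC genotyping campaign: 130
    individuals at 3 loci with ~30 alleles per locus pool, a skewed
    frequency spectrum with one near-fixed allele at the first locus, 57.5%
    of individuals with a technical replicate, 2% per-allele dropout per
    replicate, negative-binomial per-sample read totals with mean ~1900,
    and 35% of the allele pool expressed.  ``n_low_read`` plants that many
    individuals with a sub-threshold total read count (below 100) to
    exercise the depth filter.
    """

    n_individuals: int = 130
    n_loci: int = 3
    pool_sizes: tuple[int, ...] = (30, 30, 31)
    frequency_skew: str = "skewed"  # "skewed" | "uniform"
    near_fixed_freq: float = 0.95
    cnv_probability: float = 0.03
    replicate_fraction: float = 0.575
    dropout: float = 0.02
    read_mean: float = 1900.0
    read_dispersion: float = 1.0
    expressed_fraction: float = 0.35
    allele_length: int = 258
    flank_length: int = 100
    amplicon: str = "MHC"
    n_low_read: int = 0
    low_read_threshold: int = 100
    seed: int | None = None

    def __post_init__(self) -> None:
        if len(self.pool_sizes) != self.n_loci:
            raise ValueError("pool_sizes must have one entry per locus")
        if any(p < 1 for p in self.pool_sizes):
            raise ValueError("pool sizes must be >= 1")
        for name in ("cnv_probability", "replicate_fraction", "dropout", "expressed_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.frequency_skew not in ("skewed", "uniform"):
            raise ValueError("frequency_skew must be 'skewed' or 'uniform'")
        if self.n_low_read > self.n_individuals:
            raise ValueError("n_low_read exceeds n_individuals")


def _random_sequences(
    n: int, length: int, rng: np.random.Generator
) -> list[str]:
    seqs: set[str] = set()
    out = []
    while len(out) < n:
        s = "".join(np.array(list(NUCLEOTIDES))[rng.integers(0, 4, length)])
        if s not in seqs:
            seqs.add(s)
            out.append(s)
    return out


def simulate_genotype_dataset(
    config: GenotypeSimConfig, seed: int | None = None
) -> tuple[pd.DataFrame, dict[str, str], dict[str, str], dict]:
    """Simulate a genotype table with allele and transcript sequences.

    Returns (genotype table, allele id -> sequence, transcript id ->
    sequence, truth record).  The truth record carries the diploid genotype
    per individual, copy-number-variation events, planted allele
    frequencies, the expressed allele set, and which individuals were
    planted below the read threshold.
    """
    rng = np.random.default_rng(seed if seed is not None else config.seed)

    pools: list[list[str]] = []
    freqs: list[np.ndarray] = []
    for locus, size in enumerate(config.pool_sizes):
        pools.append([f"L{locus + 1}_A{a + 1:02d}" for a in range(size)])
        if config.frequency_skew == "uniform":
            f = np.full(size, 1.0 / size)
        else:
            f = rng.dirichlet(np.full(size, 0.5))
            if locus == 0 and size > 1:
                f = f / f.sum() * (1.0 - config.near_fixed_freq)
                f[0] = config.near_fixed_freq
                f = f / f.sum()
        freqs.append(f)

    all_alleles = [a for pool in pools for a in pool]
    allele_seqs = dict(zip(all_alleles, _random_sequences(len(all_alleles), config.allele_length, rng)))

    genotypes: dict[str, list[str]] = {}
    cnv_events: list[str] = []
    rows = []
    low_read_individuals = [
        f"ind_{i + 1:03d}" for i in rng.choice(config.n_individuals, config.n_low_read, replace=False)
    ]
    for i in range(config.n_individuals):
        ind = f"ind_{i + 1:03d}"
        drawn: list[str] = []
        for locus in range(config.n_loci):
            drawn.extend(rng.choice(pools[locus], size=2, p=freqs[locus]))
        if config.n_loci and rng.random() < config.cnv_probability:
            cnv_events.append(ind)
            locus = int(rng.integers(0, config.n_loci))
            drawn.extend(rng.choice(pools[locus], size=2, p=freqs[locus]))
        genotype = sorted(set(drawn))
        genotypes[ind] = genotype

        replicates = ["1"]
        if rng.random() < config.replicate_fraction:
            replicates.append("2")
        planted_low = ind in low_read_individuals
        for rep in replicates:
            kept = [a for a in genotype if rng.random() >= config.dropout]
            if not kept:  # a replicate always reports at least one allele
                kept = [genotype[int(rng.integers(0, len(genotype)))]]
            if planted_low:
                total = int(rng.integers(10, config.low_read_threshold))
                counts = rng.multinomial(total, np.full(len(kept), 1.0 / len(kept)))
            else:
                mean_per_allele = config.read_mean / len(kept)
                r = config.read_dispersion
                p = r / (r + mean_per_allele)
                counts = rng.negative_binomial(r, p, size=len(kept)) + 1
                # guard against an unlucky total below the depth threshold
                if counts.sum() < config.low_read_threshold:
                    counts[0] += config.low_read_threshold - counts.sum()
            for allele, reads in zip(kept, counts):
                rows.append(
                    {
                        "individual": ind,
                        "replicate": rep,
                        "amplicon": config.amplicon,
                        "allele": allele,
                        "reads": int(reads),
                    }
                )

    table = pd.DataFrame(rows, columns=["individual", "replicate", "amplicon", "allele", "reads"])

    n_expressed = int(round(config.expressed_fraction * len(all_alleles)))
    expressed = sorted(rng.choice(all_alleles, size=n_expressed, replace=False))
    transcripts: dict[str, str] = {}
    for t, allele in enumerate(expressed):
        flank5, flank3 = _random_sequences(2, config.flank_length, rng)
        body = flank5 + allele_seqs[allele] + flank3
        if rng.random() < 0.5:  # emit half the transcripts on the minus strand
            from .qc import reverse_complement

            body = reverse_complement(body)
        transcripts[f"transcript_{t + 1:03d}"] = body

    truth = {
        "genotypes": genotypes,
        "cnv_individuals": cnv_events,
        "allele_frequencies": {
            a: float(f) for pool, fs in zip(pools, freqs) for a, f in zip(pool, fs)
        },
        "expressed": list(expressed),
        "low_read_individuals": sorted(low_read_individuals),
    }
    return table, allele_seqs, transcripts, truth
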