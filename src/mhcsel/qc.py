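"""Amplicon-genotype quality control and allele validation.

Genotype tables hold one row per (individual, replicate, amplicon, allele)
with a read count, the shape produced by amplicon-genotyping pipelines.  The
QC steps implemented here are the standard post-clustering checks for
multigene-family genotyping: a minimum read-depth filter per sample, a cap on
plausible allele numbers given the known locus count (flagged, not removed),
percent reproducibility between technical replicates, translation-based
allele validation against conserved peptide-anchor residues, and an
expression cross-check against assembled transcripts at 100% identity.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .alignment import SiteMap, translate_seq

GENOTYPE_COLUMNS = ["individual", "replicate", "amplicon", "allele", "reads"]
_SAMPLE_KEY = ["individual", "replicate", "amplicon"]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def load_genotype_table(path: str | Path) -> pd.DataFrame:
    """Read a genotype TSV with columns individual, replicate, amplicon,
    allele, reads; validates uniqueness and non-negative read counts."""
    df = pd.read_csv(path, sep="\t", dtype={"reads": "int64"})
    return validate_genotype_table(df)


def validate_genotype_table(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in GENOTYPE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"genotype table missing columns: {missing}")
    if (df["reads"] < 0).any():
        raise ValueError("negative read counts in genotype table")
    key = df[GENOTYPE_COLUMNS[:4]]
    if key.duplicated().any():
        dupes = key[key.duplicated()].head(3).to_dict("records")
        raise ValueError(f"duplicated (individual, replicate, amplicon, allele) rows: {dupes}")
    return df


def filter_genotypes(
    table: pd.DataFrame,
    min_reads: int = 100,
    max_alleles: int = 6,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Depth-filter samples and flag implausibly allele-rich genotypes.

    A sample is one (individual, replicate, amplicon) amplicon; samples whose
    total read count is below ``min_reads`` are removed.  Samples carrying
    more than ``max_alleles`` alleles are *flagged* in the log but retained
    -- genotypes exceeding the expected locus count deserve scrutiny, not
    automatic deletion.  Returns (kept table, removal/flag log).
    """
    if table.empty:
        raise ValueError("empty genotype table")
    validate_genotype_table(table)
    grouped = table.groupby(_SAMPLE_KEY, sort=False)
    totals = grouped["reads"].sum()
    allele_counts = grouped["allele"].nunique()
    log_rows = []
    removed_keys = set()
    for key, total in totals.items():
        if total < min_reads:
            removed_keys.add(key)
            log_rows.append(
                {
                    **dict(zip(_SAMPLE_KEY, key)),
                    "total_reads": int(total),
                    "n_alleles": int(allele_counts[key]),
                    "action": "removed",
                    "reason": f"total reads {total} < {min_reads}",
                }
            )
        elif allele_counts[key] > max_alleles:
            log_rows.append(
                {
                    **dict(zip(_SAMPLE_KEY, key)),
                    "total_reads": int(total),
                    "n_alleles": int(allele_counts[key]),
                    "action": "flagged",
                    "reason": f"{allele_counts[key]} alleles > cap of {max_alleles}",
                }
            )
    keep = ~table.set_index(_SAMPLE_KEY).index.isin(removed_keys)
    kept = table.loc[keep].reset_index(drop=True)
    log = pd.DataFrame(
        log_rows,
        columns=_SAMPLE_KEY + ["total_reads", "n_alleles", "action", "reason"],
    )
    return kept, log


def replicate_reproducibility(alleles_rep1: Iterable, alleles_rep2: Iterable) -> float:
    """Percent reproducibility between two replicate genotypes:
    100 * 2|A intersect B| / (|A| + |B|)."""
    a, b = set(alleles_rep1), set(alleles_rep2)
    if not a or not b:
        raise ValueError("replicate allele sets must be non-empty")
    return 100.0 * 2 * len(a & b) / (len(a) + len(b))


def mean_reproducibility(table: pd.DataFrame) -> tuple[float, pd.DataFrame]:
    """Dataset-level mean percent reproducibility over all replicate pairs.

    For every (individual, amplicon) with two or more replicates, all
    unordered replicate pairs contribute one reproducibility value; returns
    the mean and a per-pair breakdown.
    """
    validate_genotype_table(table)
    rows = []
    for (ind, amp), group in table.groupby(["individual", "amplicon"], sort=False):
        reps = {r: set(g["allele"]) for r, g in group.groupby("replicate")}
        if len(reps) < 2:
            continue
        for r1, r2 in combinations(sorted(reps, key=str), 2):
            rows.append(
                {
                    "individual": ind,
                    "amplicon": amp,
                    "replicate_1": r1,
                    "replicate_2": r2,
                    "reproducibility_pct": replicate_reproducibility(reps[r1], reps[r2]),
                }
            )
    if not rows:
        raise ValueError("no replicate pairs in genotype table")
    pairs = pd.DataFrame(rows)
    return float(pairs["reproducibility_pct"].mean()), pairs


@dataclass(frozen=True)
class AnchorSpec:
    """Conserved peptide-anchor residues, in a declared reference numbering.

    Each anchor is (position, required residue, tolerated residues); a
    residue in the tolerated set is reported as "tolerated" rather than a
    mismatch (e.g. arginine for lysine at class I position 146, a
    conservative basic-for-basic substitution seen in several bird and
    anuran classical class I sequences).
    """

    numbering_id: str
    anchors: tuple[tuple[int, str, tuple[str, ...]], ...]


#: Class I peptide N/C-terminus anchors in HLA-A2:01 exon 3 numbering.
CLASS_I_ANCHORS = AnchorSpec(
    "HLA-A2",
    (
        (143, "T", ()),
        (146, "K", ("R",)),
        (147, "W", ()),
        (159, "Y", ()),
        (171, "Y", ()),
    ),
)

#: Class IIB invariant peptide main-chain anchors in HLA-DRB1:0101 numbering.
CLASS_IIB_ANCHORS = AnchorSpec(
    "HLA-DRB1",
    (
        (61, "W", ()),
        (81, "H", ()),
        (82, "N", ()),
    ),
)


@dataclass(frozen=True)
class ValidationReport:
    allele_id: str
    frame: int
    has_stop: bool
    conserved_site_status: Mapping[int, str]  # position -> match/tolerated/mismatch/unmapped

    @property
    def passes(self) -> bool:
        return not self.has_stop and all(
            s in ("match", "tolerated") for s in self.conserved_site_status.values()
        )


def validate_allele(
    allele_seq: str,
    frame: int,
    anchor_spec: AnchorSpec,
    site_map: SiteMap,
    allele_id: str = "",
) -> ValidationReport:
    """Translate an allele and check stop codons plus conserved anchors.

    Anchor positions are resolved to alignment codon columns through the
    site map; positions the map does not cover (or that translate to a gap)
    are reported as "unmapped".
    """
    aa = translate_seq(allele_seq, frame)
    inverse = site_map.ref_to_column
    status: dict[int, str] = {}
    for pos, required, tolerated in anchor_spec.anchors:
        col = inverse.get(pos)
        if col is None or col >= len(aa) or aa[col] == "-":
            status[pos] = "unmapped"
            continue
        residue = aa[col]
        if residue == required:
            status[pos] = "match"
        elif residue in tolerated:
            status[pos] = "tolerated"
        else:
            status[pos] = "mismatch"
    return ValidationReport(
        allele_id=allele_id,
        frame=frame,
        has_stop="*" in aa,
        conserved_site_status=status,
    )


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


def expression_crosscheck(
    alleles: Mapping[str, str],
    transcripts: Mapping[str, str] | Sequence[str],
) -> dict[str, bool]:
    """Mark each allele expressed iff its full sequence occurs exactly
    (100% identity, ungapped) within some transcript, on either strand."""
    if isinstance(transcripts, Mapping):
        transcript_seqs = list(transcripts.values())
    else:
        transcript_seqs = list(transcripts)
    if not transcript_seqs:
        raise ValueError("transcript set is empty")
    haystacks = [t.upper() for t in transcript_seqs]
    haystacks += [reverse_complement(t) for t in haystacks[: len(transcript_seqs)]]
    result = {}
    for allele_id, seq in alleles.items():
        needle = seq.upper()
        result[allele_id] = any(needle in h for h in haystacks)
    return result


@dataclass(frozen=True)
class AlleleSummary:
    carrier_proportion: pd.Series  # (amplicon, allele) -> fraction of individuals
    alleles_per_individual: pd.Series  # (amplicon, individual) -> count
    mean_alleles: pd.Series  # amplicon -> mean alleles per genotype


def allele_summary(table: pd.DataFrame) -> AlleleSummary:
    """Per-allele carrier proportions and per-individual allele counts.

    Technical replicates are collapsed to a consensus genotype by set union
    before counting; carrier proportion is (individuals carrying the allele)
    / (individuals genotyped at that amplicon).
    """
    validate_genotype_table(table)
    consensus = (
        table.groupby(["amplicon", "individual"])["allele"]
        .agg(lambda s: frozenset(s))
        .rename("alleles")
    )
    counts = consensus.map(len).rename("n_alleles")
    mean_alleles = counts.groupby("amplicon").mean().rename("mean_alleles")
    rows = []
    for (amp, ind), alleles in consensus.items():
        for allele in alleles:
            rows.append({"amplicon": amp, "individual": ind, "allele": allele})
    carriers = pd.DataFrame(rows)
    n_individuals = consensus.groupby("amplicon").size()
    carrier_counts = carriers.groupby(["amplicon", "allele"]).size()
    proportion = (
        carrier_counts / carrier_counts.index.get_level_values("amplicon").map(n_individuals)
    ).rename("carrier_proportion")
    return AlleleSummary(
        carrier_proportion=proportion,
        alleles_per_individual=counts,
        mean_alleles=mean_alleles,
    )
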