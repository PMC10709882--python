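"""Optimal-codon determination from extreme-CAI expression partitions.

The procedure mirrors standard codon-usage practice: rank genes by CAI,
take the top and bottom 10% as proxies for highly and lowly expressed
gene sets, pool codon counts within each, and call a codon optimal when
its RSCU in the high set is >= 1.0 and its RSCU difference between the
high and low sets (dRSCU) is >= 0.08.  Codons optimal in every species
of a genus form the universal optimal codon set.

Because no external expression data or organism-specific CAI reference
is assumed, CAI is bootstrapped in two passes: a provisional ranking
against weights from the whole corpus selects a provisional top-10%
reference, and the final CAI used for partitioning is computed against
weights rebuilt from that reference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

from .codon_stats import (
    CodonCountTable,
    WTable,
    aggregate,
    build_w_table,
    cai,
    rscu,
)
from .genetics import CODON_TO_AA, NONSYNONYMOUS_SET, SENSE_CODONS

__all__ = [
    "ExpressionPartition",
    "OptimalCodonCall",
    "two_pass_cai",
    "partition_by_cai",
    "delta_rscu",
    "call_optimal",
    "universal_optimal",
    "find_optimal_codons",
]


@dataclass
class ExpressionPartition:
    """Gene ids ranked into extreme-CAI high and low expression sets."""

    high: list[str]
    low: list[str]
    fraction: float = 0.10
    ranking_statistic: str = "CAI"


@dataclass
class OptimalCodonCall:
    codon: str
    amino_acid: str
    rscu_high: float
    rscu_low: float
    delta_rscu: float
    is_optimal: bool


def two_pass_cai(
    tables: Mapping[str, CodonCountTable], fraction: float = 0.10
) -> dict[str, float]:
    """Bootstrap per-gene CAI without an external reference set.

    Pass 1 ranks genes by CAI against weights from the pooled corpus;
    pass 2 rebuilds weights from the provisional top ``fraction`` genes
    and recomputes CAI against them.  Deterministic: ties in the
    provisional ranking break by gene_id.
    """
    if not tables:
        raise ValueError("no codon tables supplied")
    corpus_w = build_w_table(list(tables.values()), "corpus")
    provisional = {g: cai(t, corpus_w) for g, t in tables.items()}
    usable = sorted(
        (g for g, v in provisional.items() if not math.isnan(v)),
        key=lambda g: (-provisional[g], g),
    )
    n_top = max(1, math.ceil(fraction * len(usable)))
    top_tables = [tables[g] for g in usable[:n_top]]
    ref_w = build_w_table(top_tables, "provisional-top")
    return {g: cai(t, ref_w) for g, t in tables.items()}


def partition_by_cai(
    cai_by_gene: Mapping[str, float],
    fraction: float = 0.10,
    min_genes: int = 20,
) -> ExpressionPartition:
    """Top/bottom ``ceil(fraction * N)`` genes by CAI (descending), ties
    broken by gene_id ascending; genes with undefined CAI are ignored."""
    if not (0 < fraction < 0.5):
        raise ValueError(f"fraction must be in (0, 0.5), got {fraction}")
    usable = {g: v for g, v in cai_by_gene.items() if not math.isnan(v)}
    if len(usable) < min_genes:
        raise ValueError(
            f"only {len(usable)} genes with defined CAI (need >= {min_genes})"
        )
    ranked = sorted(usable, key=lambda g: (-usable[g], g))
    k = math.ceil(fraction * len(ranked))
    return ExpressionPartition(high=ranked[:k], low=ranked[-k:][::-1], fraction=fraction)


def delta_rscu(
    high_counts: CodonCountTable, low_counts: CodonCountTable
) -> dict[str, tuple[float, float, float]]:
    """Per-codon (rscu_high, rscu_low, delta); nan propagates."""
    rh = rscu(high_counts)
    rl = rscu(low_counts)
    return {c: (rh[c], rl[c], rh[c] - rl[c]) for c in rh}


def call_optimal(
    delta_table: Mapping[str, tuple[float, float, float]],
    rscu_min: float = 1.0,
    delta_min: float = 0.08,
) -> list[OptimalCodonCall]:
    """Threshold calls: optimal iff RSCU(high) >= rscu_min and
    dRSCU >= delta_min (both inclusive).  ATG, TGG and stops are never
    candidates."""
    calls = []
    for codon in SENSE_CODONS:
        if codon in NONSYNONYMOUS_SET or codon not in delta_table:
            continue
        rh, rl, delta = delta_table[codon]
        is_opt = (
            not math.isnan(rh)
            and not math.isnan(delta)
            and rh >= rscu_min
            and delta >= delta_min
        )
        calls.append(
            OptimalCodonCall(codon, CODON_TO_AA[codon], rh, rl, delta, is_opt)
        )
    return calls


def universal_optimal(
    per_species: Mapping[str, set[str]], min_species: int | None = None
) -> set[str]:
    """Codons optimal in at least ``min_species`` species (default: all,
    i.e. the strict intersection)."""
    if len(per_species) < 2:
        raise ValueError("need at least 2 species")
    if min_species is None:
        min_species = len(per_species)
    if min_species > len(per_species):
        raise ValueError("min_species exceeds number of species")
    tally: dict[str, int] = {}
    for codons in per_species.values():
        for c in codons:
            tally[c] = tally.get(c, 0) + 1
    return {c for c, n in tally.items() if n >= min_species}


def find_optimal_codons(
    tables: Mapping[str, CodonCountTable],
    fraction: float = 0.10,
    rscu_min: float = 1.0,
    delta_min: float = 0.08,
    min_genes: int = 20,
) -> tuple[list[OptimalCodonCall], ExpressionPartition]:
    """Full per-species procedure: two-pass CAI, partition, pooled dRSCU,
    threshold calls."""
    cai_by_gene = two_pass_cai(tables, fraction)
    part = partition_by_cai(cai_by_gene, fraction, min_genes)
    high = aggregate([tables[g] for g in part.high], "high")
    low = aggregate([tables[g] for g in part.low], "low")
    return call_optimal(delta_rscu(high, low), rscu_min, delta_min), part
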