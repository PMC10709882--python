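"""Codon-usage statistics at gene and gene-set scope.

All quantities are computed from a :class:`CodonCountTable`: relative
synonymous codon usage (RSCU), positional GC/base composition (GC1/2/3,
GC3s, A3s/U3s/C3s/G3s), Wright's effective number of codons (ENC), the
codon adaptation index (CAI) with its relative-adaptiveness weight table,
the codon bias index (CBI), and parity-rule-2 (PR2) plot coordinates.

Conventions
-----------
* Stop codons never enter any statistic (the terminal stop is excluded at
  counting time by default).
* ATG (Met) and TGG (Trp) offer no synonymous choice: they are excluded
  from CAI, CBI, the x3s denominators and optimal-codon candidacy, and
  their RSCU is reported as 1 when observed.
* Undefined values are returned as ``math.nan``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .cds_io import CdsRecord
from .genetics import (
    AA_TO_CODONS,
    ALL_CODONS,
    CODON_TO_AA,
    DEGENERATE_FAMILIES,
    FAMILY_DEGENERACY,
    FOURFOLD_BOXES,
    NONSYNONYMOUS_SET,
    SENSE_CODONS,
    STOP_CODONS,
    codons_of,
)

__all__ = [
    "CodonCountTable",
    "CodonUsageProfile",
    "WTable",
    "count_codons",
    "aggregate",
    "rscu",
    "positional_composition",
    "enc",
    "build_w_table",
    "cai",
    "cbi",
    "pr2_point",
    "profile",
    "profile_frame",
    "rscu_frame",
]

W_FLOOR = 0.01  # relative adaptiveness assigned to unobserved codons


@dataclass
class CodonCountTable:
    """Counts over the 64 codons for one gene or one pooled gene set."""

    counts: dict[str, int]
    scope: str
    n_codons: int

    def __post_init__(self) -> None:
        for codon in ALL_CODONS:
            self.counts.setdefault(codon, 0)
        if sum(self.counts.values()) != self.n_codons:
            raise ValueError(f"{self.scope}: counts do not sum to n_codons")

    def __add__(self, other: "CodonCountTable") -> "CodonCountTable":
        merged = {c: self.counts[c] + other.counts[c] for c in ALL_CODONS}
        return CodonCountTable(
            merged, f"{self.scope}+{other.scope}", self.n_codons + other.n_codons
        )


@dataclass
class WTable:
    """Relative-adaptiveness weights w in (0, 1]; max w per family is 1."""

    w: dict[str, float]
    source_label: str


@dataclass
class CodonUsageProfile:
    """Per-scope derived statistics; nan marks undefined entries."""

    scope: str
    n_codons: int
    rscu: dict[str, float]
    gc_total: float
    gc1: float
    gc2: float
    gc3: float
    gc3s: float
    a3s: float
    u3s: float
    c3s: float
    g3s: float
    enc: float
    cai: float
    cbi: float
    pr2_x: float
    pr2_y: float


def count_codons(
    record: CdsRecord | str,
    scope: str | None = None,
    drop_terminal_stop: bool = True,
) -> CodonCountTable:
    """In-frame, non-overlapping codon counts for one CDS.

    The 3'-terminal stop codon is excluded by default so downstream
    statistics see only translated codons.
    """
    seq = record.seq if isinstance(record, CdsRecord) else record
    if scope is None:
        scope = record.gene_id if isinstance(record, CdsRecord) else "<seq>"
    codons = codons_of(seq)
    if drop_terminal_stop and codons and codons[-1] in STOP_CODONS:
        codons = codons[:-1]
    counts: dict[str, int] = {}
    for c in codons:
        if "N" in c:
            raise ValueError(f"{scope}: ambiguous codon {c!r}")
        counts[c] = counts.get(c, 0) + 1
    return CodonCountTable(counts, scope, len(codons))


def aggregate(tables: Iterable[CodonCountTable], scope: str) -> CodonCountTable:
    """Elementwise sum of count tables under a new scope label."""
    tables = list(tables)
    if not tables:
        raise ValueError("no tables to aggregate")
    counts = {c: sum(t.counts[c] for t in tables) for c in ALL_CODONS}
    return CodonCountTable(counts, scope, sum(t.n_codons for t in tables))


def rscu(table: CodonCountTable) -> dict[str, float]:
    """RSCU_ij = X_ij / ((1/n_i) * sum_j X_ij) per synonymous family.

    Families with zero observations yield nan for all members; stop codons
    are excluded; ATG and TGG report 1.0 when observed, nan otherwise.
    """
    out: dict[str, float] = {}
    for aa, codons in AA_TO_CODONS.items():
        total = sum(table.counts[c] for c in codons)
        k = len(codons)
        for c in codons:
            if total == 0:
                out[c] = math.nan
            else:
                out[c] = table.counts[c] * k / total
    return out


@dataclass
class _Composition:
    gc_total: float
    gc1: float
    gc2: float
    gc3: float
    gc3s: float
    a3s: float
    u3s: float
    c3s: float
    g3s: float


def positional_composition(table: CodonCountTable) -> _Composition:
    """GC by codon position over non-stop codons, plus third-position base
    frequencies restricted to synonymously variable codons (the "s" set:
    all sense codons except ATG and TGG)."""
    pos_base = [
        {b: 0 for b in "ACGT"},
        {b: 0 for b in "ACGT"},
        {b: 0 for b in "ACGT"},
    ]
    n = 0
    for codon in SENSE_CODONS:
        cnt = table.counts[codon]
        if cnt == 0:
            continue
        n += cnt
        for i, base in enumerate(codon):
            pos_base[i][base] += cnt
    if n == 0:
        raise ValueError(f"{table.scope}: empty codon table")

    def gc_at(i: int) -> float:
        return (pos_base[i]["G"] + pos_base[i]["C"]) / n

    gc1, gc2, gc3 = gc_at(0), gc_at(1), gc_at(2)
    gc_total = (gc1 + gc2 + gc3) / 3

    third = {b: 0 for b in "ACGT"}
    n_s = 0
    for codon in SENSE_CODONS:
        if codon in NONSYNONYMOUS_SET:
            continue
        cnt = table.counts[codon]
        third[codon[2]] += cnt
        n_s += cnt
    if n_s == 0:
        a3s = u3s = c3s = g3s = gc3s = math.nan
    else:
        a3s = third["A"] / n_s
        u3s = third["T"] / n_s
        c3s = third["C"] / n_s
        g3s = third["G"] / n_s
        gc3s = c3s + g3s
    return _Composition(gc_total, gc1, gc2, gc3, gc3s, a3s, u3s, c3s, g3s)


# ENC degeneracy classes: number of families and their ENC weight per
# Wright's formula ENC = 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6.
_ENC_CLASS_SIZE = {2: 9, 3: 1, 4: 5, 6: 3}


def _family_homozygosity(table: CodonCountTable, codons: tuple[str, ...]) -> float:
    """Wright's F-hat = (n * sum p_i^2 - 1) / (n - 1); nan if n < 2."""
    counts = [table.counts[c] for c in codons]
    n = sum(counts)
    if n < 2:
        return math.nan
    sum_p2 = sum((x / n) ** 2 for x in counts)
    return (n * sum_p2 - 1) / (n - 1)


def enc(table: CodonCountTable) -> float:
    """Wright's effective number of codons, in [20, 61].

    F-hat is averaged within each degeneracy class (families with fewer
    than 2 counts, or F-hat = 0, are dropped from their class mean).  A
    missing 3-fold class (Ile only) is imputed as 1/F3 = mean(1/F2, 1/F4);
    any other missing class makes ENC undefined (nan).
    """
    class_f: dict[int, list[float]] = {2: [], 3: [], 4: [], 6: []}
    for aa, codons in DEGENERATE_FAMILIES.items():
        f = _family_homozygosity(table, codons)
        if not math.isnan(f) and f > 0:
            class_f[len(codons)].append(f)
    mean_f = {
        k: (sum(v) / len(v) if v else math.nan) for k, v in class_f.items()
    }
    estimable = [k for k in (2, 3, 4, 6) if not math.isnan(mean_f[k])]
    if len(estimable) < 2:
        return math.nan
    if math.isnan(mean_f[3]):
        if math.isnan(mean_f[2]) or math.isnan(mean_f[4]):
            return math.nan
        inv_f3 = (1 / mean_f[2] + 1 / mean_f[4]) / 2
    else:
        inv_f3 = 1 / mean_f[3]
    if math.isnan(mean_f[2]) or math.isnan(mean_f[4]) or math.isnan(mean_f[6]):
        return math.nan
    value = 2 + 9 / mean_f[2] + inv_f3 + 5 / mean_f[4] + 3 / mean_f[6]
    return min(value, 61.0)


def build_w_table(
    reference: list[CodonCountTable], source_label: str = "reference"
) -> WTable:
    """Relative adaptiveness from a (highly expressed) reference gene set.

    Counts are pooled; within each family w_ij = RSCU_ij / max_k RSCU_ik.
    Unobserved codons of an observed family get the floor (0.01); wholly
    unobserved families are neutral (w = 1 for every member).
    """
    if not reference:
        raise ValueError("empty reference set")
    pooled = aggregate(reference, source_label)
    w: dict[str, float] = {}
    for aa, codons in AA_TO_CODONS.items():
        counts = [pooled.counts[c] for c in codons]
        total = sum(counts)
        if total == 0:
            for c in codons:
                w[c] = 1.0
            continue
        best = max(counts)
        for c, x in zip(codons, counts):
            w[c] = (x / best) if x > 0 else W_FLOOR
    return WTable(w, source_label)


def cai(table: CodonCountTable, w: WTable) -> float:
    """Geometric mean of w over the gene's codons (ATG/TGG/stops excluded)."""
    log_sum = 0.0
    length = 0
    for codon in SENSE_CODONS:
        if codon in NONSYNONYMOUS_SET:
            continue
        cnt = table.counts[codon]
        if cnt:
            log_sum += cnt * math.log(w.w[codon])
            length += cnt
    if length == 0:
        return math.nan
    return math.exp(log_sum / length)


def cbi(table: CodonCountTable, optimal: set[str]) -> float:
    """Codon bias index: (N_opt - N_ran) / (N_tot - N_ran).

    Only families containing at least one optimal codon are considered;
    N_ran is the expected optimal-codon count under uniform synonymous
    usage.  nan when the denominator is zero.
    """
    n_opt = 0
    n_tot = 0
    n_ran = 0.0
    for aa, codons in DEGENERATE_FAMILIES.items():
        k_opt = sum(1 for c in codons if c in optimal)
        if k_opt == 0:
            continue
        fam_total = sum(table.counts[c] for c in codons)
        n_tot += fam_total
        n_opt += sum(table.counts[c] for c in codons if c in optimal)
        n_ran += fam_total * k_opt / len(codons)
    denom = n_tot - n_ran
    if denom == 0:
        return math.nan
    return (n_opt - n_ran) / denom


def pr2_point(table: CodonCountTable) -> tuple[float, float]:
    """PR2 coordinates restricted to the eight fourfold codon boxes:
    x = G3/(G3+C3), y = A3/(A3+T3) at third positions; nan pair when a
    denominator is zero."""
    third = {b: 0 for b in "ACGT"}
    for box in FOURFOLD_BOXES:
        for codon in box:
            third[codon[2]] += table.counts[codon]
    gc = third["G"] + third["C"]
    at = third["A"] + third["T"]
    if gc == 0 or at == 0:
        return (math.nan, math.nan)
    return (third["G"] / gc, third["A"] / at)


def profile(
    table: CodonCountTable,
    w: WTable | None = None,
    optimal: set[str] | None = None,
) -> CodonUsageProfile:
    """Assemble the full usage profile for one scope.

    CAI requires a weight table and CBI an optimal-codon set; either is
    reported as nan when its prerequisite is not supplied.
    """
    comp = positional_composition(table)
    x, y = pr2_point(table)
    return CodonUsageProfile(
        scope=table.scope,
        n_codons=table.n_codons,
        rscu=rscu(table),
        gc_total=comp.gc_total,
        gc1=comp.gc1,
        gc2=comp.gc2,
        gc3=comp.gc3,
        gc3s=comp.gc3s,
        a3s=comp.a3s,
        u3s=comp.u3s,
        c3s=comp.c3s,
        g3s=comp.g3s,
        enc=enc(table),
        cai=cai(table, w) if w is not None else math.nan,
        cbi=cbi(table, optimal) if optimal is not None else math.nan,
        pr2_x=x,
        pr2_y=y,
    )


_PROFILE_COLUMNS = [
    "gene_id",
    "species",
    "n_codons",
    "gc",
    "gc1",
    "gc2",
    "gc3",
    "gc3s",
    "a3s",
    "u3s",
    "c3s",
    "g3s",
    "enc",
    "cai",
    "cbi",
    "pr2_x",
    "pr2_y",
]


def profile_frame(
    records: list[CdsRecord],
    w: WTable | None = None,
    optimal: set[str] | None = None,
) -> pd.DataFrame:
    """Per-gene profile table with the documented column schema."""
    rows = []
    for rec in records:
        p = profile(count_codons(rec), w=w, optimal=optimal)
        rows.append(
            {
                "gene_id": rec.gene_id,
                "species": rec.species,
                "n_codons": p.n_codons,
                "gc": p.gc_total,
                "gc1": p.gc1,
                "gc2": p.gc2,
                "gc3": p.gc3,
                "gc3s": p.gc3s,
                "a3s": p.a3s,
                "u3s": p.u3s,
                "c3s": p.c3s,
                "g3s": p.g3s,
                "enc": p.enc,
                "cai": p.cai,
                "cbi": p.cbi,
                "pr2_x": p.pr2_x,
                "pr2_y": p.pr2_y,
            }
        )
    return pd.DataFrame(rows, columns=_PROFILE_COLUMNS)


def rscu_frame(per_species: Mapping[str, CodonCountTable]) -> pd.DataFrame:
    """64-row RSCU matrix: codon, amino_acid, one column per species."""
    data: dict[str, list] = {
        "codon": list(ALL_CODONS),
        "amino_acid": [
            "*" if c in STOP_CODONS else CODON_TO_AA[c] for c in ALL_CODONS
        ],
    }
    for species, table in per_species.items():
        values = rscu(table)
        data[species] = [values.get(c, math.nan) for c in ALL_CODONS]
    return pd.DataFrame(data)


def write_tsv(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, sep="\t", index=False, float_format="%.10g")
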