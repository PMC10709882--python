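"""Ka/Ks (dN/dS) estimation and selection-pressure classification.

Two estimators over gap-free codon alignments:

* NG86 — Nei-Gojobori counting: per-codon synonymous/nonsynonymous site
  fractions (mutations to stop codons excluded from each position's
  denominator), pathway-averaged difference counts, Jukes-Cantor multiple-
  hit correction.
* YN00 — Yang-Nielsen approximate method: transition/transversion ratio
  kappa estimated from fourfold-degenerate and nondegenerate sites via
  K80, F3x4 codon frequencies, mutation-model-weighted site counting,
  likelihood-weighted pathway averaging (weights include the current
  omega), K80 correction of dS and dN, and fixed-point iteration on
  omega.

Selection classes follow the comparative-transcriptomics convention:
Ka/Ks < 0.5 purifying, between 0.5 and 1 weak positive, above 1 strong
positive; boundary values fall to the lower class, and pairs whose Ks is
outside a configurable window are left unclassified.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from functools import lru_cache
from itertools import permutations
from typing import Mapping, Sequence

from .genetics import (
    BASES,
    CODON_TO_AA,
    SENSE_CODONS,
    STOP_CODONS,
    is_transition,
    translate_codon,
)
from .orthology import OrthologPair

__all__ = [
    "KaKsResult",
    "count_sites_ng86",
    "count_differences_ng86",
    "ng86",
    "yn00",
    "classify",
    "positive_commonality",
    "CommonalityTable",
]

PURIFYING = "PURIFYING"
WEAK_POSITIVE = "WEAK_POSITIVE"
STRONG_POSITIVE = "STRONG_POSITIVE"
UNDEFINED = "UNDEFINED"


@dataclass
class KaKsResult:
    """Per-pair substitution-rate estimates and their ingredients."""

    gene_a: str
    gene_b: str
    method: str
    S: float
    N: float
    Sd: float
    Nd: float
    ps: float
    pn: float
    ka: float
    ks: float
    ratio: float
    kappa: float = math.nan
    converged: bool = True
    selection_class: str = UNDEFINED
    pair: OrthologPair | None = field(default=None, repr=False)


# ---------------------------------------------------------------- NG86


@lru_cache(maxsize=None)
def count_sites_ng86(codon: str) -> tuple[float, float]:
    """Synonymous/nonsynonymous site counts for one sense codon.

    At each position the synonymous fraction is taken over the non-stop
    single-base mutants only; s + n = 3 by construction.
    """
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon}")
    aa = CODON_TO_AA[codon]
    s = 0.0
    for p in range(3):
        mutants = [
            codon[:p] + b + codon[p + 1 :] for b in BASES if b != codon[p]
        ]
        non_stop = [m for m in mutants if m not in STOP_CODONS]
        if not non_stop:
            continue
        syn = sum(1 for m in non_stop if CODON_TO_AA[m] == aa)
        s += syn / len(non_stop)
    return s, 3.0 - s


@lru_cache(maxsize=None)
def _pathways(a: str, b: str) -> tuple[tuple[tuple[str, str, int], ...], ...]:
    """All minimal mutational pathways a -> b avoiding stop codons, as
    tuples of (from_codon, to_codon, position) steps.  Falls back to all
    pathways if every one crosses a stop (cannot happen between sense
    codons differing at <= 3 positions, but kept as a guard)."""
    diff = [p for p in range(3) if a[p] != b[p]]
    valid = []
    everything = []
    for order in permutations(diff):
        cur = a
        steps = []
        blocked = False
        for p in order:
            nxt = cur[:p] + b[p] + cur[p + 1 :]
            steps.append((cur, nxt, p))
            if nxt in STOP_CODONS and nxt != b:
                blocked = True
            cur = nxt
        everything.append(tuple(steps))
        if not blocked:
            valid.append(tuple(steps))
    return tuple(valid) if valid else tuple(everything)


@lru_cache(maxsize=None)
def _diff_counts_equal(a: str, b: str) -> tuple[float, float, float, float]:
    """Equal-weight pathway average: (sd_ts, sd_tv, nd_ts, nd_tv)."""
    if a == b:
        return (0.0, 0.0, 0.0, 0.0)
    paths = _pathways(a, b)
    acc = [0.0, 0.0, 0.0, 0.0]
    for path in paths:
        for frm, to, p in path:
            syn = translate_codon(frm) == translate_codon(to)
            ts = is_transition(frm[p], to[p])
            idx = (0 if syn else 2) + (0 if ts else 1)
            acc[idx] += 1.0
    k = len(paths)
    return tuple(x / k for x in acc)  # type: ignore[return-value]


def count_differences_ng86(a: str, b: str) -> tuple[float, float]:
    """Pathway-averaged (synonymous, nonsynonymous) difference counts."""
    for c in (a, b):
        if c in STOP_CODONS:
            raise ValueError(f"stop codon {c}")
    sd_ts, sd_tv, nd_ts, nd_tv = _diff_counts_equal(a, b)
    return sd_ts + sd_tv, nd_ts + nd_tv


def _jukes_cantor(p: float) -> float:
    if p >= 0.75:
        return math.nan
    if p == 0:
        return 0.0
    return -0.75 * math.log(1 - 4 * p / 3)


def ng86(pair: OrthologPair) -> KaKsResult:
    """Nei-Gojobori estimate with Jukes-Cantor correction."""
    cod_a, cod_b = pair.codons()

    def _sites(seq: list[str]) -> tuple[float, float]:
        s_sum = n_sum = 0.0
        for c in seq:
            s, n = count_sites_ng86(c)
            s_sum += s
            n_sum += n
        return s_sum, n_sum

    sa, na = _sites(cod_a)
    sb, nb = _sites(cod_b)
    S = (sa + sb) / 2
    N = (na + nb) / 2
    Sd = Nd = 0.0
    for ca, cb in zip(cod_a, cod_b):
        sd, nd = count_differences_ng86(ca, cb)
        Sd += sd
        Nd += nd
    ps = Sd / S if S > 0 else math.nan
    pn = Nd / N if N > 0 else math.nan
    ks = _jukes_cantor(ps) if not math.isnan(ps) else math.nan
    ka = _jukes_cantor(pn) if not math.isnan(pn) else math.nan
    ratio = ka / ks if (not math.isnan(ks) and ks > 0 and not math.isnan(ka)) else math.nan
    return KaKsResult(
        pair.gene_a, pair.gene_b, "NG86", S, N, Sd, Nd, ps, pn, ka, ks, ratio,
        pair=pair,
    )


# ---------------------------------------------------------------- YN00


def _k80_components(P: float, Q: float) -> tuple[float, float]:
    """K80 (transition distance A, transversion distance B); nan on
    saturation (log-domain violation)."""
    a = 1 - 2 * P - Q
    b = 1 - 2 * Q
    if a <= 0 or b <= 0:
        return math.nan, math.nan
    A = -0.5 * math.log(a) + 0.25 * math.log(b)
    B = -0.5 * math.log(b)
    return A, B


@lru_cache(maxsize=None)
def _position_degeneracy(codon: str, p: int) -> int:
    """Number of synonymous single-base changes at position p (0..3);
    mutations to stop codons count as nonsynonymous."""
    aa = CODON_TO_AA[codon]
    syn = 0
    for b in BASES:
        if b == codon[p]:
            continue
        m = codon[:p] + b + codon[p + 1 :]
        if m not in STOP_CODONS and CODON_TO_AA[m] == aa:
            syn += 1
    return syn


def estimate_kappa(cod_a: list[str], cod_b: list[str]) -> float:
    """Transition/transversion rate ratio from fourfold-degenerate and
    nondegenerate sites, K80-corrected per class and combined by site
    weight.  Returns 1.0 when the data cannot support an estimate."""
    L = {0: 0, 4: 0}
    ts = {0: 0, 4: 0}
    tv = {0: 0, 4: 0}
    for ca, cb in zip(cod_a, cod_b):
        for p in range(3):
            da = _position_degeneracy(ca, p)
            db = _position_degeneracy(cb, p)
            cls_a = 4 if da == 3 else (0 if da == 0 else None)
            cls_b = 4 if db == 3 else (0 if db == 0 else None)
            if cls_a is None or cls_a != cls_b:
                continue
            L[cls_a] += 1
            if ca[p] != cb[p]:
                if is_transition(ca[p], cb[p]):
                    ts[cls_a] += 1
                else:
                    tv[cls_a] += 1
    A_w = B_w = weight = 0.0
    for cls in (0, 4):
        if L[cls] == 0:
            continue
        A, B = _k80_components(ts[cls] / L[cls], tv[cls] / L[cls])
        if math.isnan(A) or math.isnan(B):
            continue
        A_w += L[cls] * A
        B_w += L[cls] * B
        weight += L[cls]
    if weight == 0 or B_w <= 0:
        return 1.0
    kappa = 2 * (A_w / weight) / (B_w / weight)
    return max(kappa, 1e-6)


def _f3x4(codons: list[str]) -> dict[str, float]:
    """Codon frequencies from position-specific base frequencies,
    normalised over the 61 sense codons."""
    pos = [{b: 1e-9 for b in BASES} for _ in range(3)]
    for c in codons:
        for i, b in enumerate(c):
            pos[i][b] += 1
    for i in range(3):
        tot = sum(pos[i].values())
        pos[i] = {b: v / tot for b, v in pos[i].items()}
    pi = {c: pos[0][c[0]] * pos[1][c[1]] * pos[2][c[2]] for c in SENSE_CODONS}
    z = sum(pi.values())
    return {c: v / z for c, v in pi.items()}


def _yn00_codon_sites(codon: str, kappa: float, pi: Mapping[str, float]) -> float:
    """Synonymous site count for one codon under the mutation model
    (kappa, pi); nonsynonymous sites are 3 minus this."""
    w_tot = w_syn = 0.0
    aa = CODON_TO_AA[codon]
    for p in range(3):
        for b in BASES:
            if b == codon[p]:
                continue
            m = codon[:p] + b + codon[p + 1 :]
            if m in STOP_CODONS:
                continue
            w = (kappa if is_transition(codon[p], b) else 1.0) * pi[m]
            w_tot += w
            if CODON_TO_AA[m] == aa:
                w_syn += w
    if w_tot == 0:
        return 0.0
    return 3 * w_syn / w_tot


def _weighted_diffs(
    a: str, b: str, kappa: float, omega: float, pi: Mapping[str, float]
) -> tuple[float, float, float, float]:
    """Pathway average weighted by step rates kappa^ts * pi(target) *
    omega^nonsyn: (sd_ts, sd_tv, nd_ts, nd_tv)."""
    if a == b:
        return (0.0, 0.0, 0.0, 0.0)
    paths = _pathways(a, b)
    weights = []
    per_path = []
    for path in paths:
        w = 1.0
        acc = [0.0, 0.0, 0.0, 0.0]
        for frm, to, p in path:
            syn = translate_codon(frm) == translate_codon(to)
            ts = is_transition(frm[p], to[p])
            w *= (kappa if ts else 1.0) * pi.get(to, 1e-12)
            if not syn:
                w *= omega
            acc[(0 if syn else 2) + (0 if ts else 1)] += 1.0
        weights.append(w)
        per_path.append(acc)
    total = sum(weights)
    if total <= 0:
        weights = [1.0] * len(paths)
        total = float(len(paths))
    out = [0.0, 0.0, 0.0, 0.0]
    for w, acc in zip(weights, per_path):
        for i in range(4):
            out[i] += w / total * acc[i]
    return tuple(out)  # type: ignore[return-value]


def yn00(
    pair: OrthologPair,
    codon_freqs: str = "F3x4",
    tol: float = 1e-6,
    max_iter: int = 100,
) -> KaKsResult:
    """Yang-Nielsen approximate dN/dS.

    ``codon_freqs`` is ``"F3x4"`` (position-specific base frequencies from
    the pair) or ``"uniform"`` (equal sense-codon frequencies, the
    oracle-test limit in which YN00 collapses toward NG86 when kappa=1).
    """
    cod_a, cod_b = pair.codons()
    if codon_freqs == "uniform":
        pi: dict[str, float] = {c: 1 / len(SENSE_CODONS) for c in SENSE_CODONS}
    elif codon_freqs == "F3x4":
        pi = _f3x4(cod_a + cod_b)
    else:
        raise ValueError(f"unknown codon_freqs {codon_freqs!r}")
    kappa = estimate_kappa(cod_a, cod_b)

    s_a = sum(_yn00_codon_sites(c, kappa, pi) for c in cod_a)
    s_b = sum(_yn00_codon_sites(c, kappa, pi) for c in cod_b)
    S = (s_a + s_b) / 2
    L3 = 3.0 * len(cod_a)
    N = L3 - S

    pair_counts = Counter(zip(cod_a, cod_b))
    omega = 1.0
    converged = False
    ka = ks = ratio = math.nan
    Sd = Nd = ps = pn = math.nan
    for _ in range(max_iter):
        acc = [0.0, 0.0, 0.0, 0.0]
        for (ca, cb), k in pair_counts.items():
            d = _weighted_diffs(ca, cb, kappa, omega, pi)
            for i in range(4):
                acc[i] += k * d[i]
        sd_ts, sd_tv, nd_ts, nd_tv = acc
        Sd = sd_ts + sd_tv
        Nd = nd_ts + nd_tv
        ps = Sd / S if S > 0 else math.nan
        pn = Nd / N if N > 0 else math.nan
        As, Bs = _k80_components(sd_ts / S, sd_tv / S) if S > 0 else (math.nan,) * 2
        An, Bn = _k80_components(nd_ts / N, nd_tv / N) if N > 0 else (math.nan,) * 2
        ks = As + Bs if not (math.isnan(As) or math.isnan(Bs)) else math.nan
        ka = An + Bn if not (math.isnan(An) or math.isnan(Bn)) else math.nan
        if math.isnan(ks) or ks <= 0 or math.isnan(ka):
            ratio = math.nan
            converged = True  # nothing to iterate on
            break
        new_omega = ka / ks
        ratio = new_omega
        if abs(new_omega - omega) < tol:
            omega = new_omega
            converged = True
            break
        omega = new_omega
    return KaKsResult(
        pair.gene_a, pair.gene_b, "YN00", S, N, Sd, Nd, ps, pn, ka, ks, ratio,
        kappa=kappa, converged=converged, pair=pair,
    )


# ------------------------------------------------------- classification


def classify(
    result: KaKsResult, ks_min: float = 1e-6, ks_max: float = 3.0
) -> str:
    """Assign the selection class from the Ka/Ks ratio.

    Pairs with undefined ratio, or Ks outside (ks_min, ks_max] (unstable
    or saturated), stay UNDEFINED.  Boundary ratios 0.5 and 1.0 map to
    the lower class.
    """
    r = result.ratio
    if (
        math.isnan(r)
        or math.isnan(result.ks)
        or result.ks <= ks_min
        or result.ks > ks_max
    ):
        result.selection_class = UNDEFINED
    elif r <= 0.5:
        result.selection_class = PURIFYING
    elif r <= 1.0:
        result.selection_class = WEAK_POSITIVE
    else:
        result.selection_class = STRONG_POSITIVE
    return result.selection_class


@dataclass
class CommonalityTable:
    """Which pairings each focal-species gene is positively selected in."""

    membership: dict[str, set[str]]
    pairings: list[str]

    def venn_cells(self) -> dict[frozenset[str], list[str]]:
        """Genes grouped by the exact combination of pairings in which
        their ratio exceeds 1."""
        cells: dict[frozenset[str], list[str]] = {}
        for gene, where in sorted(self.membership.items()):
            cells.setdefault(frozenset(where), []).append(gene)
        return cells

    def in_all_pairings(self) -> list[str]:
        full = set(self.pairings)
        return sorted(g for g, w in self.membership.items() if w == full)


def positive_commonality(
    results: Mapping[str, Sequence[KaKsResult]]
) -> CommonalityTable:
    """Cross-pairing commonality of genes with Ka/Ks > 1.

    ``results`` maps a pairing label (focal species vs partner) to its
    KaKs results; the focal gene is ``gene_a`` of each result.  All
    pairings must share the focal species.
    """
    focal_species = {
        r.pair.species_a
        for rs in results.values()
        for r in rs
        if r.pair is not None
    }
    if len(focal_species) > 1:
        raise ValueError(f"inconsistent focal species: {sorted(focal_species)}")
    membership: dict[str, set[str]] = {}
    for pairing, rs in results.items():
        for r in rs:
            if not math.isnan(r.ratio) and r.ratio > 1:
                membership.setdefault(r.gene_a, set()).add(pairing)
    return CommonalityTable(membership, sorted(results))
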