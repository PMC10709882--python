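"""Seeded synthetic CDS corpora with known ground truth.

Three generators cover the statistical structure the pipeline assumes:

* :func:`gen_biased_corpus` — one pseudo-species whose highly expressed
  genes draw synonymous codons from a distribution biased toward planted
  preferred codons (strength ``b``: probability mass moved onto the
  preferred codons of a family), while lowly expressed genes use codons
  uniformly.  This is the structure the extreme-CAI / dRSCU optimal-codon
  screen is designed to detect.
* :func:`evolve_pair` — an ortholog pair diverged from a uniform-random
  ancestor under a continuous-time codon model with transition/transversion
  ratio kappa and nonsynonymous/synonymous ratio omega (stops forbidden),
  simulated event-by-event (exact at any divergence).
* :func:`gen_two_species` — two species sharing diverged orthologs plus
  unrelated decoy genes, with a truth table of pairs and their omega.

Expression is a latent binary class rather than an expression value: the
downstream analysis only needs a CAI-correlated bias gradient.  All
generators are deterministic under their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .cds_io import CdsRecord
from .genetics import (
    DEGENERATE_FAMILIES,
    SENSE_CODONS,
    STOP_CODONS,
    is_transition,
    translate_codon,
)

__all__ = [
    "BiasConfig",
    "DivergenceConfig",
    "CorpusTruth",
    "gen_biased_corpus",
    "evolve_pair",
    "gen_two_species",
    "expected_ts_fraction",
    "sample_substitution_events",
]

#: default planted preference: the two favoured Arg codons and one Pro codon
DEFAULT_PREFERRED: dict[str, tuple[str, ...]] = {
    "R": ("AGA", "AGG"),
    "P": ("CCA",),
}

_FAMILY_AAS = tuple(sorted(DEGENERATE_FAMILIES))
_STOPS = tuple(sorted(STOP_CODONS))


@dataclass
class BiasConfig:
    """Parameters of one biased pseudo-species corpus.

    ``len_codons_range`` bounds the total codon count per gene including
    the ATG start and the stop, so genes clear the 300-bp admission rule
    whenever the minimum is at least 101.
    """

    n_genes: int = 500
    len_codons_range: tuple[int, int] = (101, 400)
    preferred_codons: Mapping[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_PREFERRED)
    )
    bias_strength: float = 0.9
    high_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.bias_strength <= 1:
            raise ValueError("bias_strength must be in [0, 1]")
        if not 0 < self.high_fraction < 1:
            raise ValueError("high_fraction must be in (0, 1)")
        lo, hi = self.len_codons_range
        if lo < 3 or hi < lo:
            raise ValueError("invalid len_codons_range")
        for aa, codons in self.preferred_codons.items():
            fam = DEGENERATE_FAMILIES.get(aa, ())
            for c in codons:
                if c not in fam:
                    raise ValueError(f"{c} is not a codon of family {aa}")


@dataclass
class DivergenceConfig:
    """Parameters of ortholog-pair divergence.

    ``t`` is the expected number of substitutions per codon per lineage
    (rates are normalised so the mean total rate over the 61 sense codons
    equals 1 per codon); ``len_codons`` counts the evolved codons between
    the fixed ATG and stop.
    """

    n_pairs: int = 50
    len_codons: int = 500
    omega: float = 0.2
    kappa: float = 2.0
    t: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.omega <= 0 or self.kappa <= 0 or self.t < 0:
            raise ValueError("omega and kappa must be > 0 and t >= 0")


@dataclass
class CorpusTruth:
    expression: dict[str, str]  # gene_id -> "high" | "low"
    planted_codons: set[str]


def _family_distribution(
    aa: str, preferred: Mapping[str, tuple[str, ...]], b: float
) -> tuple[tuple[str, ...], np.ndarray]:
    codons = DEGENERATE_FAMILIES[aa]
    k = len(codons)
    pref = preferred.get(aa, ())
    probs = np.full(k, (1 - b) / k if pref else 1 / k)
    if pref:
        for i, c in enumerate(codons):
            if c in pref:
                probs[i] += b / len(pref)
    return codons, probs


def gen_biased_corpus(
    config: BiasConfig, species: str = "synth"
) -> tuple[list[CdsRecord], CorpusTruth]:
    """One pseudo-species of in-frame CDS with planted expression-linked
    codon bias; always passes the admission filter by construction."""
    rng = np.random.default_rng(config.seed)
    b = config.bias_strength
    # cumulative synonymous-codon distributions, biased (high) and uniform (low)
    dists: dict[tuple[bool, str], tuple[np.ndarray, np.ndarray]] = {}
    for aa in _FAMILY_AAS:
        codons, probs = _family_distribution(aa, config.preferred_codons, b)
        arr = np.array(codons)
        k = len(codons)
        dists[(True, aa)] = (arr, np.cumsum(probs))
        dists[(False, aa)] = (arr, np.cumsum(np.full(k, 1 / k)))

    lo, hi = config.len_codons_range
    is_high = rng.random(config.n_genes) < config.high_fraction
    n_internal = rng.integers(lo, hi + 1, size=config.n_genes) - 2
    total = int(n_internal.sum())
    # one flat draw for every internal codon of the corpus, then split by gene
    aa_idx = rng.integers(len(_FAMILY_AAS), size=total)
    u = rng.random(total)
    gene_of = np.repeat(np.arange(config.n_genes), n_internal)
    flat = np.empty(total, dtype="<U3")
    for f, aa in enumerate(_FAMILY_AAS):
        for high in (True, False):
            mask = (aa_idx == f) & (is_high[gene_of] == high)
            if not mask.any():
                continue
            arr, cum = dists[(high, aa)]
            idx = np.searchsorted(cum, u[mask], side="right")
            flat[mask] = arr[np.minimum(idx, len(arr) - 1)]
    stops = rng.integers(len(_STOPS), size=config.n_genes)

    records: list[CdsRecord] = []
    truth = CorpusTruth(
        expression={},
        planted_codons={
            c for cods in config.preferred_codons.values() for c in cods
        },
    )
    width = len(str(config.n_genes))
    bounds = np.concatenate([[0], np.cumsum(n_internal)])
    for i in range(config.n_genes):
        gene_id = f"g{i:0{width}d}"
        seq = (
            "ATG"
            + "".join(flat[bounds[i] : bounds[i + 1]])
            + _STOPS[stops[i]]
        )
        records.append(CdsRecord(gene_id, species, seq))
        truth.expression[gene_id] = "high" if is_high[i] else "low"
    return records, truth


# ----------------------------------------------------- codon-model evolution


class _CodonModel:
    """Unnormalised GY-style rates: kappa for transitions, omega for
    nonsynonymous changes, stops forbidden; scaled so the mean total rate
    over sense codons is 1."""

    def __init__(self, omega: float, kappa: float) -> None:
        self.targets: dict[str, list[str]] = {}
        self.rates: dict[str, np.ndarray] = {}
        self.is_ts: dict[str, list[bool]] = {}
        self.is_syn: dict[str, list[bool]] = {}
        raw_total = []
        for codon in SENSE_CODONS:
            tg: list[str] = []
            rt: list[float] = []
            ts_flags: list[bool] = []
            syn_flags: list[bool] = []
            for p in range(3):
                for bs in "ACGT":
                    if bs == codon[p]:
                        continue
                    m = codon[:p] + bs + codon[p + 1 :]
                    if m in STOP_CODONS:
                        continue
                    ts = is_transition(codon[p], bs)
                    syn = translate_codon(m) == translate_codon(codon)
                    rate = (kappa if ts else 1.0) * (1.0 if syn else omega)
                    tg.append(m)
                    rt.append(rate)
                    ts_flags.append(ts)
                    syn_flags.append(syn)
            self.targets[codon] = tg
            self.rates[codon] = np.array(rt)
            self.is_ts[codon] = ts_flags
            self.is_syn[codon] = syn_flags
            raw_total.append(sum(rt))
        scale = float(np.mean(raw_total))
        for codon in SENSE_CODONS:
            self.rates[codon] = self.rates[codon] / scale
        self.total: dict[str, float] = {
            c: float(self.rates[c].sum()) for c in SENSE_CODONS
        }


_MODEL_CACHE: dict[tuple[float, float], _CodonModel] = {}


def _model(omega: float, kappa: float) -> _CodonModel:
    key = (omega, kappa)
    if key not in _MODEL_CACHE:
        _MODEL_CACHE[key] = _CodonModel(omega, kappa)
    return _MODEL_CACHE[key]


def _evolve_codons(
    codons: list[str],
    t: float,
    model: _CodonModel,
    rng: np.random.Generator,
    events: list[tuple[bool, bool]] | None = None,
) -> list[str]:
    """Exact event-by-event simulation for duration t (expected
    substitutions per codon).  Optionally records (is_ts, is_syn) per
    event."""
    seq = list(codons)
    site_rates = np.array([model.total[c] for c in seq])
    clock = 0.0
    while True:
        total = float(site_rates.sum())
        clock += rng.exponential(1.0 / total) * len(seq)
        if clock > t * len(seq):
            break
        site = int(rng.choice(len(seq), p=site_rates / total))
        codon = seq[site]
        rates = model.rates[codon]
        k = int(rng.choice(len(rates), p=rates / rates.sum()))
        if events is not None:
            events.append((model.is_ts[codon][k], model.is_syn[codon][k]))
        seq[site] = model.targets[codon][k]
        site_rates[site] = model.total[seq[site]]
    return seq


def _wrap_cds(codons: list[str], rng: np.random.Generator) -> str:
    return "ATG" + "".join(codons) + _STOPS[rng.integers(len(_STOPS))]


def evolve_pair(
    config: DivergenceConfig,
    gene_id: str = "pair0",
    species: tuple[str, str] = ("spA", "spB"),
    rng: np.random.Generator | None = None,
) -> tuple[CdsRecord, CdsRecord, float]:
    """One ortholog pair diverged 2t (t per lineage) from a uniform-random
    ancestor; returns the two CDS plus the true omega."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    model = _model(config.omega, config.kappa)
    ancestor = [
        SENSE_CODONS[i]
        for i in rng.integers(len(SENSE_CODONS), size=config.len_codons)
    ]
    a = _evolve_codons(ancestor, config.t, model, rng)
    b = _evolve_codons(ancestor, config.t, model, rng)
    stop_rng_a = _wrap_cds(a, rng)
    stop_rng_b = _wrap_cds(b, rng)
    return (
        CdsRecord(gene_id, species[0], stop_rng_a),
        CdsRecord(gene_id, species[1], stop_rng_b),
        config.omega,
    )


def expected_ts_fraction(omega: float, kappa: float) -> float:
    """Expected fraction of substitution events that are transitions,
    averaged over a uniform sense-codon composition."""
    model = _model(omega, kappa)
    ts_rate = tv_rate = 0.0
    for codon in SENSE_CODONS:
        for rate, ts in zip(model.rates[codon], model.is_ts[codon]):
            if ts:
                ts_rate += rate
            else:
                tv_rate += rate
    return ts_rate / (ts_rate + tv_rate)


def sample_substitution_events(
    config: DivergenceConfig, min_events: int = 10_000
) -> tuple[int, int]:
    """Simulate until at least ``min_events`` substitutions are recorded;
    returns (n_transitions, n_transversions)."""
    rng = np.random.default_rng(config.seed)
    model = _model(config.omega, config.kappa)
    events: list[tuple[bool, bool]] = []
    while len(events) < min_events:
        ancestor = [
            SENSE_CODONS[i]
            for i in rng.integers(len(SENSE_CODONS), size=config.len_codons)
        ]
        _evolve_codons(ancestor, config.t, model, rng, events)
    n_ts = sum(1 for ts, _ in events if ts)
    return n_ts, len(events) - n_ts


def gen_two_species(
    bias: BiasConfig,
    div: DivergenceConfig,
    n_orthologs: int = 50,
    n_decoys: int = 10,
    species: tuple[str, str] = ("spA", "spB"),
    omega_by_pair: Sequence[float] | None = None,
) -> tuple[list[CdsRecord], list[CdsRecord], list[tuple[str, str, float]]]:
    """Two pseudo-species sharing diverged orthologs plus per-species
    unrelated decoys; the truth table lists (gene_a, gene_b, omega)."""
    rng = np.random.default_rng(div.seed)
    if omega_by_pair is not None and len(omega_by_pair) != n_orthologs:
        raise ValueError("omega_by_pair length must equal n_orthologs")
    recs_a: list[CdsRecord] = []
    recs_b: list[CdsRecord] = []
    truth: list[tuple[str, str, float]] = []
    width = max(3, len(str(max(n_orthologs, n_decoys))))
    for i in range(n_orthologs):
        omega = (
            float(omega_by_pair[i]) if omega_by_pair is not None else div.omega
        )
        model = _model(omega, div.kappa)
        ancestor = [
            SENSE_CODONS[j]
            for j in rng.integers(len(SENSE_CODONS), size=div.len_codons)
        ]
        a = _evolve_codons(ancestor, div.t, model, rng)
        b = _evolve_codons(ancestor, div.t, model, rng)
        gid = f"o{i:0{width}d}"
        recs_a.append(CdsRecord(gid, species[0], _wrap_cds(a, rng)))
        recs_b.append(CdsRecord(gid, species[1], _wrap_cds(b, rng)))
        truth.append((gid, gid, omega))
    for label, out in ((species[0], recs_a), (species[1], recs_b)):
        for i in range(n_decoys):
            codons = [
                SENSE_CODONS[j]
                for j in rng.integers(len(SENSE_CODONS), size=div.len_codons)
            ]
            out.append(
                CdsRecord(f"d{i:0{width}d}", label, _wrap_cds(codons, rng))
            )
    return recs_a, recs_b, truth
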