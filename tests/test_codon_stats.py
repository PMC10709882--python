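"""Codon-usage statistics against hand values and brute-force oracles."""

import math

import numpy as np
import pytest

from codonselect.codon_stats import (
    WTable,
    aggregate,
    build_w_table,
    cai,
    cbi,
    count_codons,
    enc,
    positional_composition,
    pr2_point,
    rscu,
)
from codonselect.genetics import (
    AA_TO_CODONS,
    DEGENERATE_FAMILIES,
    SENSE_CODONS,
)

from conftest import make_cds, random_sense_table, table_from_counts

# ------------------------------------------------------------ oracles
# Independent brute-force implementations written straight from the
# defining formulas; they share nothing with the package internals.


def oracle_rscu(counts: dict[str, int]) -> dict[str, float]:
    out = {}
    for aa, codons in AA_TO_CODONS.items():
        total = sum(counts.get(c, 0) for c in codons)
        for c in codons:
            if total == 0:
                out[c] = math.nan
            else:
                out[c] = counts.get(c, 0) / (total / len(codons))
    return out


def oracle_enc(counts: dict[str, int]) -> float:
    by_class: dict[int, list[float]] = {2: [], 3: [], 4: [], 6: []}
    for aa, codons in DEGENERATE_FAMILIES.items():
        n = sum(counts.get(c, 0) for c in codons)
        if n < 2:
            continue
        f = (n * sum((counts.get(c, 0) / n) ** 2 for c in codons) - 1) / (n - 1)
        if f > 0:
            by_class[len(codons)].append(f)
    fbar = {k: sum(v) / len(v) if v else None for k, v in by_class.items()}
    if fbar[2] is None or fbar[4] is None or fbar[6] is None:
        return math.nan
    inv_f3 = 1 / fbar[3] if fbar[3] is not None else (1 / fbar[2] + 1 / fbar[4]) / 2
    return min(2 + 9 / fbar[2] + inv_f3 + 5 / fbar[4] + 3 / fbar[6], 61.0)


def oracle_cai(counts: dict[str, int], w: dict[str, float]) -> float:
    product, length = 1.0, 0
    for c, k in counts.items():
        if c in ("ATG", "TGG") or c not in SENSE_CODONS or k == 0:
            continue
        product *= w[c] ** k
        length += k
    return product ** (1 / length) if length else math.nan


def oracle_cbi(counts: dict[str, int], optimal: set[str]) -> float:
    n_opt = n_tot = 0
    n_ran = 0.0
    for aa, codons in DEGENERATE_FAMILIES.items():
        k_opt = len([c for c in codons if c in optimal])
        if not k_opt:
            continue
        fam = sum(counts.get(c, 0) for c in codons)
        n_tot += fam
        n_opt += sum(counts.get(c, 0) for c in codons if c in optimal)
        n_ran += fam * k_opt / len(codons)
    return (n_opt - n_ran) / (n_tot - n_ran) if n_tot != n_ran else math.nan


# ------------------------------------------------------------- counting


class TestCountCodons:
    def test_direct_count_and_stop_drop(self):
        t = count_codons(make_cds("ATGAAAAAATAA"))
        assert t.counts["ATG"] == 1 and t.counts["AAA"] == 2
        assert t.n_codons == 3
        assert count_codons(make_cds("ATGTAA")).n_codons == 1

    def test_additivity(self):
        t1 = count_codons(make_cds("ATGAAATAA"))
        t2 = count_codons(make_cds("ATGAAGTAA"))
        agg = aggregate([t1, t2], "set")
        assert agg.n_codons == 4
        assert agg.counts["AAA"] == 1 and agg.counts["AAG"] == 1

    def test_frame_error(self):
        with pytest.raises(ValueError):
            count_codons(make_cds("ATGA"))


class TestRscu:
    def test_lys_hand_value(self):
        t = table_from_counts({"AAA": 3, "AAG": 1})
        values = rscu(t)
        assert values["AAA"] == pytest.approx(1.5)
        assert values["AAG"] == pytest.approx(0.5)

    def test_uniform_family_is_one(self):
        t = table_from_counts({c: 5 for c in AA_TO_CODONS["A"]})
        assert all(rscu(t)[c] == pytest.approx(1.0) for c in AA_TO_CODONS["A"])

    def test_unobserved_family_is_nan(self):
        t = table_from_counts({"AAA": 2})
        assert math.isnan(rscu(t)["GGG"])

    def test_normalization_and_scale_invariance(self, rng):
        for _ in range(20):
            t = random_sense_table(rng)
            values = rscu(t)
            for aa, codons in AA_TO_CODONS.items():
                if sum(t.counts[c] for c in codons) > 0:
                    assert sum(values[c] for c in codons) == pytest.approx(
                        len(codons), abs=1e-9
                    )
            doubled = table_from_counts(
                {c: 2 * t.counts[c] for c in SENSE_CODONS}
            )
            dv = rscu(doubled)
            for c in SENSE_CODONS:
                if not math.isnan(values[c]):
                    assert dv[c] == pytest.approx(values[c], abs=1e-12)


class TestPositionalComposition:
    def test_all_gc(self):
        comp = positional_composition(table_from_counts({"GGG": 2}))
        assert comp.gc_total == pytest.approx(1.0)
        assert comp.gc3s == pytest.approx(1.0)

    def test_lys_third_positions(self):
        comp = positional_composition(table_from_counts({"AAA": 3, "AAG": 1}))
        assert comp.a3s == pytest.approx(0.75)
        assert comp.g3s == pytest.approx(0.25)
        assert comp.gc3s == pytest.approx(0.25)

    def test_only_atg_tgg_gives_nan(self):
        comp = positional_composition(table_from_counts({"ATG": 2, "TGG": 1}))
        assert math.isnan(comp.a3s) and math.isnan(comp.gc3s)

    def test_empty_table_errors(self):
        with pytest.raises(ValueError):
            positional_composition(table_from_counts({}))


class TestEnc:
    def test_maximal_bias_is_20(self):
        counts = {codons[0]: 2 for codons in DEGENERATE_FAMILIES.values()}
        assert enc(table_from_counts(counts)) == pytest.approx(20.0)

    def test_uniform_usage_approaches_61(self, rng):
        codons = rng.choice(len(SENSE_CODONS), size=20000)
        counts: dict[str, int] = {}
        for i in codons:
            c = SENSE_CODONS[int(i)]
            counts[c] = counts.get(c, 0) + 1
        assert enc(table_from_counts(counts)) >= 59.0

    def test_two_fold_hand_value(self):
        # Lys (3,1) and Asn (2,2): F = (4*(9+1)/16 - 1)/3 = 0.5 and
        # (4*0.5 - 1)/3 = 1/3; only class 2 + class 4/6 missing -> nan
        t = table_from_counts({"AAA": 3, "AAG": 1, "AAC": 2, "AAT": 2})
        assert math.isnan(enc(t))
        assert math.isnan(oracle_enc({"AAA": 3, "AAG": 1, "AAC": 2, "AAT": 2}))

    def test_oracle_equivalence_on_random_tables(self, rng):
        agree = 0
        for _ in range(50):
            t = random_sense_table(rng, n=300)
            mine = enc(t)
            ref = oracle_enc({c: t.counts[c] for c in SENSE_CODONS})
            if math.isnan(mine):
                assert math.isnan(ref)
            else:
                assert mine == pytest.approx(ref, abs=1e-9)
                agree += 1
        assert agree > 40  # the vast majority of random tables are defined

    def test_bias_monotonically_lowers_enc(self, rng):
        # plant one preferred codon per family at increasing strength
        mean_enc = []
        for b in (0.0, 0.4, 0.8):
            values = []
            for _ in range(100):
                counts: dict[str, int] = {}
                for codons in DEGENERATE_FAMILIES.values():
                    k = len(codons)
                    p = np.full(k, (1 - b) / k)
                    p[0] += b
                    draws = rng.multinomial(30, p)
                    for c, d in zip(codons, draws):
                        counts[c] = counts.get(c, 0) + int(d)
                values.append(enc(table_from_counts(counts)))
            mean_enc.append(float(np.mean(values)))
        assert mean_enc[0] > mean_enc[1] > mean_enc[2]


class TestWTableAndCai:
    def test_w_from_pooled_lys(self):
        w = build_w_table([table_from_counts({"AAA": 3, "AAG": 1})])
        assert w.w["AAA"] == pytest.approx(1.0)
        assert w.w["AAG"] == pytest.approx(1 / 3)

    def test_floor_and_neutral_families(self):
        w = build_w_table([table_from_counts({"AAA": 4})])
        assert w.w["AAA"] == 1.0
        assert w.w["AAG"] == pytest.approx(0.01)  # unobserved in observed family
        assert w.w["GGG"] == 1.0  # wholly unobserved family is neutral

    def test_cai_hand_values(self):
        w = WTable({c: 1.0 for c in SENSE_CODONS}, "unit")
        w.w["AAG"] = 0.25
        t = table_from_counts({"AAA": 1, "AAG": 1})
        assert cai(t, w) == pytest.approx(0.5)  # sqrt(1 * 0.25)
        assert cai(table_from_counts({"AAA": 7}), w) == pytest.approx(1.0)
        assert math.isnan(cai(table_from_counts({"ATG": 2, "TGG": 1}), w))

    def test_consensus_optimal_gene_scores_one(self, rng):
        reference = [random_sense_table(rng, 200) for _ in range(5)]
        w = build_w_table(reference)
        consensus = {
            max(codons, key=lambda c: w.w[c]): 3
            for codons in DEGENERATE_FAMILIES.values()
        }
        assert cai(table_from_counts(consensus), w) == pytest.approx(1.0)

    def test_oracle_equivalence_on_random_tables(self, rng):
        for _ in range(50):
            ref = random_sense_table(rng, 250)
            w = build_w_table([ref])
            t = random_sense_table(rng, 90)
            mine = cai(t, w)
            ref_value = oracle_cai({c: t.counts[c] for c in SENSE_CODONS}, w.w)
            assert mine == pytest.approx(ref_value, abs=1e-9)
            my_rscu = rscu(t)
            or_rscu = oracle_rscu({c: t.counts[c] for c in SENSE_CODONS})
            for c in SENSE_CODONS:
                if math.isnan(my_rscu[c]):
                    assert math.isnan(or_rscu[c])
                elif c not in ("ATG", "TGG"):
                    assert my_rscu[c] == pytest.approx(or_rscu[c], abs=1e-9)


class TestCbi:
    def test_bounds_and_hand_value(self):
        optimal = {"AAA"}
        only_opt = table_from_counts({"AAA": 5})
        assert cbi(only_opt, optimal) == pytest.approx(1.0)
        # one 2-fold family, 3 optimal + 1 non-optimal: (3-2)/(4-2)
        t = table_from_counts({"AAA": 3, "AAG": 1})
        assert cbi(t, optimal) == pytest.approx(0.5)
        random_usage = table_from_counts({"AAA": 2, "AAG": 2})
        assert cbi(random_usage, optimal) == pytest.approx(0.0)

    def test_oracle_equivalence(self, rng):
        optimal = {codons[0] for codons in DEGENERATE_FAMILIES.values()}
        for _ in range(25):
            t = random_sense_table(rng, 150)
            mine = cbi(t, optimal)
            ref = oracle_cbi({c: t.counts[c] for c in SENSE_CODONS}, optimal)
            if math.isnan(mine):
                assert math.isnan(ref)
            else:
                assert mine == pytest.approx(ref, abs=1e-9)


class TestPr2:
    def test_center_and_hand_value(self):
        t = table_from_counts({"GCA": 1, "GCT": 1, "GCG": 1, "GCC": 1})
        assert pr2_point(t) == pytest.approx((0.5, 0.5))
        # A3=2, T3=6, G3=6, C3=2 within fourfold boxes
        t = table_from_counts({"GCA": 2, "GCT": 6, "GCG": 6, "GCC": 2})
        assert pr2_point(t) == pytest.approx((0.75, 0.25))

    def test_no_fourfold_codons_gives_nan(self):
        x, y = pr2_point(table_from_counts({"AAA": 5, "TTT": 5}))
        assert math.isnan(x) and math.isnan(y)

    def test_uniform_corpora_center_within_3se(self, rng):
        from codonselect.synthetic_data import BiasConfig, gen_biased_corpus

        records, _ = gen_biased_corpus(BiasConfig(n_genes=150, bias_strength=0.0, seed=9))
        points = [pr2_point(count_codons(r)) for r in records]
        xs = np.array([p[0] for p in points])
        ys = np.array([p[1] for p in points])
        for arr in (xs, ys):
            se = arr.std(ddof=1) / math.sqrt(len(arr))
            assert abs(arr.mean() - 0.5) < 3 * se + 1e-3
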