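import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bpmr.instruments import (
    clump,
    exclude_regions,
    f_statistic,
    instrument_strength,
    select_significant,
    variance_explained,
)
from bpmr.simulate import SimulationConfig, simulate_pair
from bpmr.sumstats import GenomicRegion, LDReference, VariantAssociation
from conftest import make_sumstats

APOE = GenomicRegion("19", 45_116_911, 46_318_605)


def stats_with_pvalues(pvalues):
    rows = [("1", 1_000_000 * (j + 1) * 3, f"rs{j}", "A", "G", 0.3, 0.1, 0.02, p)
            for j, p in enumerate(pvalues)]
    return make_sumstats(rows)


class TestSelectSignificant:
    def test_strict_inequality_at_threshold(self):
        stats = stats_with_pvalues([1e-9, 5e-8, 1e-7])
        kept = select_significant(stats, 5e-8)
        assert list(kept.df["pvalue"]) == [1e-9]

    def test_threshold_one_keeps_everything(self):
        stats = stats_with_pvalues([1e-9, 5e-8, 0.5, 0.999])
        assert len(select_significant(stats, 1.0)) == 4

    def test_count_matches_brute_force_scan(self, rng):
        pvals = 10 ** rng.uniform(-12, 0, 1000)
        stats = stats_with_pvalues(list(pvals))
        kept = select_significant(stats, 5e-8)
        assert len(kept) == sum(1 for p in pvals if p < 5e-8)

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            select_significant(stats_with_pvalues([0.5]), 0.0)


class TestExcludeRegions:
    def test_apoe_exclusion(self):
        rows = [("19", 45_500_000, "rs_in", "A", "G", 0.3, 0.1, 0.02, 1e-9),
                ("19", 50_000_000, "rs_out", "A", "G", 0.3, 0.1, 0.02, 1e-9)]
        kept = exclude_regions(make_sumstats(rows), [APOE])
        assert list(kept.df["rsid"]) == ["rs_out"]

    def test_empty_region_list_is_identity(self, small_exposure):
        kept = exclude_regions(small_exposure, [])
        pd.testing.assert_frame_equal(kept.df, small_exposure.df)

    def test_overlapping_regions_equal_their_union(self, rng):
        rows = [("1", int(p), f"rs{j}", "A", "G", 0.3, 0.1, 0.02, 1e-9)
                for j, p in enumerate(rng.integers(1, 1000, 200))]
        stats = make_sumstats(rows)
        overlapping = [GenomicRegion("1", 100, 400), GenomicRegion("1", 300, 600)]
        union = [GenomicRegion("1", 100, 600)]
        got = exclude_regions(stats, overlapping)
        want = exclude_regions(stats, union)
        pd.testing.assert_frame_equal(got.df, want.df)

    def test_commutes_with_selection(self, rng):
        rows = [("1", int(p), f"rs{j}", "A", "G", 0.3, 0.1, 0.02,
                 float(10 ** rng.uniform(-10, 0)))
                for j, p in enumerate(rng.integers(1, 1000, 300))]
        stats = make_sumstats(rows)
        regions = [GenomicRegion("1", 200, 700)]
        a = exclude_regions(select_significant(stats, 5e-8), regions)
        b = select_significant(exclude_regions(stats, regions), 5e-8)
        pd.testing.assert_frame_equal(a.df, b.df)


def greedy_clump_oracle(df, ld, r2_threshold, window_bp):
    """Plain re-derivation of greedy clumping over explicit Python lists,
    used to verify the vectorized implementation on small instances."""
    remaining = sorted(
        df.itertuples(index=False),
        key=lambda r: (r.pvalue, str(r.chrom), r.pos),
    )
    kept = []
    while remaining:
        index = remaining.pop(0)
        kept.append(index.rsid)
        survivors = []
        for other in remaining:
            same_chrom = str(other.chrom) == str(index.chrom)
            near = same_chrom and abs(other.pos - index.pos) <= window_bp
            if near and ld.r2(index.rsid, other.rsid) >= r2_threshold:
                continue
            survivors.append(other)
        remaining = survivors
    return set(kept)


def random_clump_instance(rng, n):
    rows, ld = [], LDReference(window_bp=1_000_000)
    for j in range(n):
        chrom = str(rng.integers(1, 4))
        pos = int(rng.integers(1, 3_000_000))
        rsid = f"rs{j}"
        rows.append((chrom, pos, rsid, "A", "G", 0.3, 0.1, 0.02,
                     float(10 ** rng.uniform(-10, -1))))
        ld.add_position(rsid, chrom, pos)
    for a in range(n):
        for b in range(a + 1, n):
            if rng.random() < 0.3:
                ld.set_r2(f"rs{a}", f"rs{b}", float(rng.random()))
    return make_sumstats(rows), ld


class TestClump:
    def test_correlated_pair_keeps_best_p(self):
        rows = [("1", 1_000_000, "v1", "A", "G", 0.3, 0.1, 0.02, 1e-10),
                ("1", 1_050_000, "v2", "A", "G", 0.3, 0.1, 0.02, 1e-9),
                ("1", 2_900_000, "v3", "A", "G", 0.3, 0.1, 0.02, 1e-8)]
        stats = make_sumstats(rows)
        ld = LDReference([("v1", "v2", 0.9)],
                         positions={"v1": ("1", 1_000_000),
                                    "v2": ("1", 1_050_000),
                                    "v3": ("1", 2_900_000)})
        inst = clump(stats, ld, 0.001, 1_000_000)
        assert set(inst.rsids) == {"v1", "v3"}

    def test_no_ld_keeps_all(self, small_exposure):
        ld = LDReference(positions={r: ("1", 1000 + i * 3_000_000)
                                    for i, r in enumerate(small_exposure.df["rsid"])})
        assert len(clump(small_exposure, ld)) == 4

    def test_stored_r2_beyond_window_ignored(self):
        rows = [("1", 1_000_000, "a", "A", "G", 0.3, 0.1, 0.02, 1e-10),
                ("1", 3_000_001, "b", "A", "G", 0.3, 0.1, 0.02, 1e-9)]
        stats = make_sumstats(rows)
        ld = LDReference([("a", "b", 0.99)],
                         positions={"a": ("1", 1_000_000), "b": ("1", 3_000_001)})
        assert set(clump(stats, ld, 0.001, 1_000_000).rsids) == {"a", "b"}

    @pytest.mark.parametrize("n", [5, 10, 20])
    def test_matches_oracle_on_small_instances(self, rng, n):
        for _ in range(20):
            stats, ld = random_clump_instance(rng, n)
            got = set(clump(stats, ld, 0.1, 1_000_000).rsids)
            want = greedy_clump_oracle(stats.df, ld, 0.1, 1_000_000)
            assert got == want

    def test_invariant_to_input_row_order(self, rng):
        stats, ld = random_clump_instance(rng, 15)
        base = set(clump(stats, ld, 0.1, 1_000_000).rsids)
        for _ in range(5):
            shuffled = stats.subset(np.ones(len(stats), bool))
            shuffled.df = shuffled.df.sample(frac=1, random_state=rng.integers(1e6)).reset_index(drop=True)
            assert set(clump(shuffled, ld, 0.1, 1_000_000).rsids) == base

    def test_no_retained_pair_in_ld(self, rng):
        stats, ld = random_clump_instance(rng, 20)
        kept = clump(stats, ld, 0.1, 1_000_000).rsids
        for i, a in enumerate(kept):
            for b in kept[i + 1:]:
                assert ld.r2(a, b) < 0.1

    def test_greedy_maximality(self, rng):
        """Every removed variant conflicts with some retained variant that
        precedes it in the (p, chrom, pos) order — verified exhaustively."""
        stats, ld = random_clump_instance(rng, 20)
        kept = set(clump(stats, ld, 0.1, 1_000_000).rsids)
        order = stats.df.sort_values(["pvalue", "chrom", "pos"])
        rank = {r: i for i, r in enumerate(order["rsid"])}
        for rsid in stats.df["rsid"]:
            if rsid in kept:
                continue
            conflicts = [k for k in kept
                         if rank[k] < rank[rsid] and ld.r2(k, rsid) >= 0.1]
            assert conflicts, f"{rsid} removed without a conflicting index"


class TestStrength:
    def test_f_is_squared_wald_z(self):
        v = VariantAssociation("1", 100, "rs1", "A", "G", 0.3, 0.03, 0.005, 1e-9, 1e6)
        assert f_statistic(v) == pytest.approx(36.0)

    def test_null_effect_gives_zero(self):
        v = VariantAssociation("1", 100, "rs1", "A", "G", 0.3, 0.0, 0.005, 1.0, 1e6)
        assert f_statistic(v) == 0.0

    def test_f_based_variance_explained(self):
        v = VariantAssociation("1", 100, "rs1", "A", "G", 0.3, 0.03, 0.005, 1e-9, 1_000_000)
        assert variance_explained(v, "f_based") == pytest.approx(36 / (36 + 999_998))

    def test_freq_beta_variance_explained(self):
        v = VariantAssociation("1", 100, "rs1", "A", "G", 0.5, 0.1, 0.005, 1e-9, 1e6,)
        assert variance_explained(v, "freq_beta") == pytest.approx(0.005)

    def test_freq_beta_with_phenotypic_sd(self):
        v = VariantAssociation("1", 100, "rs1", "A", "G", 0.5, 2.0, 0.05, 1e-9, 1e6)
        # beta of 2 mm Hg standardized by SD 20 -> 0.1 on the SD scale
        assert variance_explained(v, "freq_beta", phenotypic_sd=20.0) == pytest.approx(0.005)

    def test_freq_beta_requires_eaf(self):
        v = VariantAssociation("1", 100, "rs1", "A", "G", None, 0.1, 0.005, 1e-9, 1e6)
        with pytest.raises(ValueError):
            variance_explained(v, "freq_beta")

    def test_mean_f_equals_arithmetic_mean(self, rng):
        cfg = SimulationConfig(n_variants=50, seed=11)
        exposure, _, ld, _ = simulate_pair(cfg)
        inst = clump(select_significant(exposure, 5e-8), ld)
        strength = instrument_strength(inst)
        per_variant = [f_statistic(v) for v in inst.stats.records()]
        assert strength.mean_f == pytest.approx(np.mean(per_variant))
        assert strength.min_f == pytest.approx(np.min(per_variant))

    def test_significant_synthetic_instruments_are_strong(self):
        """Genome-wide-significant simulated instruments clear the F >= 10
        weak-instrument bar."""
        cfg = SimulationConfig(n_variants=200, total_r2=0.044, seed=5)
        exposure, _, ld, _ = simulate_pair(cfg)
        inst = clump(select_significant(exposure, 5e-8), ld)
        assert len(inst) > 0
        assert all(f >= 10 for f in inst.f_stats.values())
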