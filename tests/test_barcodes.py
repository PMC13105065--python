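"""Barcode design, extraction, normalization and fold-change tests."""

import itertools
import re

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from idletrace.barcodes import (
    BarcodeCountTable,
    BarcodeDesign,
    complexity_and_sharing,
    design_space_size,
    enumerate_barcodes,
    extract_barcodes,
    filter_low_abundance,
    fold_changes,
    normalize_rpm,
    sample_library,
)
from idletrace.synthetic import gen_barcoded_reads


class TestDesignSpace:
    def test_default_design_complexity(self, design):
        # 16 SW positions, two choices each
        assert design_space_size(design) == 65536

    def test_two_position_pattern(self):
        assert design_space_size(BarcodeDesign(sw_pattern="SW")) == 4

    def test_enumeration_matches_brute_force_regex(self, tiny_design):
        enumerated = set(enumerate_barcodes(tiny_design))
        assert len(enumerated) == 16
        pattern = re.compile("^GT" + "[GC][AT]" * 2 + "$")
        brute = {
            "GT" + "".join(c)
            for c in itertools.product("GC", "AT", "GC", "AT")
        }
        assert enumerated == brute
        assert all(pattern.match(b) for b in enumerated)

    def test_invalid_pattern_rejected(self):
        with pytest.raises(ValueError):
            BarcodeDesign(sw_pattern="SX")

    @given(st.integers(0, 16))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_sampled_barcodes_conform(self, n):
        d = BarcodeDesign(shared_prefix="GT", sw_pattern="SWSW")
        lib = sample_library(d, n, seed=42)
        assert len(lib) == n
        assert all(d.conforms(b) for b in lib)

    def test_full_space_sampling_equals_enumeration(self, tiny_design):
        full = sample_library(tiny_design, 16, seed=0)
        assert full == set(enumerate_barcodes(tiny_design))

    def test_oversampling_rejected(self, tiny_design):
        with pytest.raises(ValueError):
            sample_library(tiny_design, 17, seed=0)


class TestExtraction:
    def test_error_free_roundtrip_exact(self, design):
        lib = sorted(sample_library(design, 12, seed=3))
        rng = np.random.default_rng(0)
        abund = dict(zip(lib, rng.dirichlet(np.ones(12)) + 0.01))
        reads, truth = gen_barcoded_reads(design, abund, 5000,
                                          error_rate=0.0, seed=1)
        res = extract_barcodes(reads, design)
        assert dict(res.counts) == truth["counts"]
        assert res.n_unassigned == 0

    def test_read_without_flank_unassigned(self, design):
        seq = "A" * 80
        res = extract_barcodes([seq], design)
        assert res.n_unassigned == 1
        assert not res.counts

    def test_nonconformant_candidate_excluded_in_strict_mode(self, design):
        bc = next(iter(sample_library(design, 1, seed=4)))
        # force a W position (prefix length 4, pattern starts S,W,...) to G
        bad = bc[:5] + "G" + bc[6:]
        assert not design.conforms(bad)
        read = "AC" + design.flank5 + bad + design.flank3 + "TT"
        strict = extract_barcodes([read], design, strict=True)
        assert not strict.counts
        assert strict.n_nonconformant == 1
        lenient = extract_barcodes([read], design, strict=False)
        assert lenient.counts[bad] == 1

    def test_single_flank_mismatch_tolerated(self, design):
        bc = next(iter(sample_library(design, 1, seed=5)))
        flank5 = "G" + design.flank5[1:]
        read = flank5 + bc + design.flank3
        assert extract_barcodes([read], design,
                                max_flank_mismatches=1).counts[bc] == 1
        assert not extract_barcodes([read], design,
                                    max_flank_mismatches=0).counts

    def test_noisy_recovery_correlation(self, design):
        # regression: per-base error 0.001 on 1e5 reads barely perturbs counts
        lib = sorted(sample_library(design, 20, seed=6))
        rng = np.random.default_rng(1)
        abund = dict(zip(lib, rng.dirichlet(np.ones(20)) + 0.01))
        reads, truth = gen_barcoded_reads(design, abund, 100_000,
                                          error_rate=0.001, seed=2)
        res = extract_barcodes(reads, design)
        t = np.array([truth["counts"].get(b, 0) for b in lib])
        o = np.array([res.counts.get(b, 0) for b in lib])
        assert np.corrcoef(t, o)[0, 1] >= 0.99


class TestNormalizationAndFilter:
    def test_rpm_arithmetic(self):
        tab = BarcodeCountTable.from_counts({"s": {"A": 3, "B": 1}})
        rpm = normalize_rpm(tab).sample_rpm("s")
        assert rpm["A"] == pytest.approx(750_000)
        assert rpm["B"] == pytest.approx(250_000)

    def test_single_barcode_rpm_is_one_million(self):
        tab = BarcodeCountTable.from_counts({"s": {"X": 17}})
        assert normalize_rpm(tab).sample_rpm("s")["X"] == pytest.approx(1e6)

    @given(st.lists(st.integers(1, 10_000), min_size=1, max_size=30))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_rpm_sums_to_one_million(self, counts):
        tab = BarcodeCountTable.from_counts(
            {"s": {f"b{i}": c for i, c in enumerate(counts)}})
        assert normalize_rpm(tab).sample_rpm("s").sum() == pytest.approx(1e6)

    def test_zero_total_sample_named_in_error(self):
        tab = BarcodeCountTable.from_counts({"empty": {"A": 0}})
        with pytest.raises(ValueError, match="empty"):
            normalize_rpm(tab)

    def test_threshold_boundary_strictly_less_than(self):
        # 100.0 CPM is retained, 99.99... removed ("less than" is strict)
        counts = {"at": 100, "below": 99, "big": 999_801}
        tab = normalize_rpm(BarcodeCountTable.from_counts({"s": counts}))
        kept, unique = filter_low_abundance(tab, 100.0)
        names = set(kept.sample_counts("s").index)
        assert names == {"at", "big"}
        assert unique["s"] == 2

    def test_filter_counts_match_brute_force(self):
        rng = np.random.default_rng(2)
        counts = {f"b{i}": int(c)
                  for i, c in enumerate(rng.integers(1, 3000, size=10))}
        tab = normalize_rpm(BarcodeCountTable.from_counts({"s": counts}))
        kept, unique = filter_low_abundance(tab, 100.0)
        total = sum(counts.values())
        brute = {b for b, c in counts.items() if c * 1e6 / total >= 100.0}
        assert set(kept.sample_counts("s").index) == brute
        assert unique["s"] == len(brute)

    def test_filter_idempotent_and_never_increases(self):
        rng = np.random.default_rng(3)
        counts = {f"b{i}": int(c)
                  for i, c in enumerate(rng.integers(1, 5000, size=40))}
        tab = normalize_rpm(BarcodeCountTable.from_counts({"s": counts}))
        once, u1 = filter_low_abundance(tab, 100.0)
        twice, u2 = filter_low_abundance(once, 100.0)
        assert once.data["barcode"].tolist() == twice.data["barcode"].tolist()
        assert u1.equals(u2)
        assert len(once.data) <= len(tab.data)


class TestFoldChanges:
    def _table(self, ref, trt):
        tab = BarcodeCountTable.from_counts({"ref": ref, "trt": trt})
        return normalize_rpm(tab)

    def test_identical_samples_zero(self):
        counts = {"A": 50, "B": 150}
        fc = fold_changes(self._table(counts, counts), "ref", "trt")
        assert np.allclose(fc.data["log2fc"], 0)
        assert fc.mean == 0

    def test_uniform_doubling_in_rpm_space(self):
        # doubling every count leaves RPM unchanged -> fold-change 0;
        # doubling the *share* of one barcode shows up as +1
        ref = {"A": 100, "B": 100}
        trt = {"A": 200, "B": 100}
        fc = fold_changes(self._table(ref, trt), "ref", "trt",
                          pseudocount=0.0)
        a = fc.data.set_index("barcode")["log2fc"]
        assert a["A"] == pytest.approx(np.log2((2 / 3) / 0.5))

    def test_antisymmetry_under_swap(self):
        ref = {"A": 120, "B": 40, "C": 340}
        trt = {"A": 90, "B": 80, "C": 330}
        tab = self._table(ref, trt)
        fwd = fold_changes(tab, "ref", "trt", pseudocount=0.5,
                           restrict_to_reference=False)
        rev = fold_changes(tab, "trt", "ref", pseudocount=0.5,
                           restrict_to_reference=False)
        f = fwd.data.set_index("barcode")["log2fc"]
        r = rev.data.set_index("barcode")["log2fc"]
        assert np.allclose(f, -r.loc[f.index])

    def test_top_n_restriction(self):
        ref = {f"b{i}": 1000 - i for i in range(30)}
        fc = fold_changes(self._table(ref, ref), "ref", "trt", top_n=24)
        assert fc.n == 24
        assert set(fc.data["barcode"]) == {f"b{i}" for i in range(24)}


class TestSharing:
    def _tab(self, sample, barcodes):
        return BarcodeCountTable.from_counts(
            {sample: {b: 10 for b in barcodes}})

    def test_identical_replicates_share_fully(self):
        t = {"c": [self._tab("r1", ["A", "B"]), self._tab("r2", ["A", "B"])]}
        s = complexity_and_sharing(t)
        assert s.pairwise_replicate_sharing["c"] == [1.0]

    def test_disjoint_conditions_share_nothing(self):
        t = {"u": [self._tab("r1", ["A", "B"])],
             "i": [self._tab("r1", ["C"])]}
        s = complexity_and_sharing(t, reference="u", treated="i")
        assert s.shared_between_conditions == 0
        assert s.relative_complexity_change == pytest.approx(-0.5)

    def test_random_subsets_match_set_algebra(self):
        rng = np.random.default_rng(4)
        universe = [f"b{i}" for i in range(60)]
        a = set(rng.choice(universe, 30, replace=False))
        b = set(rng.choice(universe, 40, replace=False))
        s = complexity_and_sharing(
            {"u": [self._tab("r1", a)], "i": [self._tab("r1", b)]},
            reference="u", treated="i")
        assert s.unique_per_condition == {"u": len(a), "i": len(b)}
        assert s.shared_between_conditions == len(a & b)
        assert s.relative_complexity_change == pytest.approx(
            (len(b) - len(a)) / len(a))
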