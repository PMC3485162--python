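"""Codominant seed classification, purity statistic, synthetic lots."""

import io

import pytest
from hypothesis import given, settings, strategies as st

from umpcr.puritytyping import (
    PurityReport,
    ReferenceProfiles,
    SeedCall,
    classify_seed,
    default_reference_profiles,
    make_seed_lot,
    purity,
    read_band_patterns,
    read_reference_profiles,
    write_band_patterns,
)
from umpcr.vpcr import BandPattern

LOCI = ["phi085", "phi041", "phi123", "umc1478", "umc1268"]


@pytest.fixture(scope="module")
def profiles():
    return default_reference_profiles(LOCI)


def pattern(profiles, which, sample="s1"):
    bands = {}
    for locus in profiles.loci:
        if which == "hybrid":
            bands[locus] = sorted(profiles.hybrid_expected(locus))
        elif which == "female":
            bands[locus] = sorted(profiles.female[locus])
        else:
            bands[locus] = sorted(profiles.male[locus])
    return BandPattern(sample, bands)


class TestClassifySeed:
    def test_union_pattern_is_hybrid(self, profiles):
        call = classify_seed(pattern(profiles, "hybrid"), profiles)
        assert call.seed_class == "hybrid"

    def test_female_only_pattern(self, profiles):
        call = classify_seed(pattern(profiles, "female"), profiles)
        assert call.seed_class == "female_parent"

    def test_male_only_pattern(self, profiles):
        call = classify_seed(pattern(profiles, "male"), profiles)
        assert call.seed_class == "male_parent"

    def test_foreign_allele_is_off_type(self, profiles):
        p = pattern(profiles, "hybrid")
        p.bands["phi041"] = [999]  # allele in neither parent
        assert classify_seed(p, profiles).seed_class == "off_type"

    def test_mixed_incomplete_pattern_is_off_type(self, profiles):
        p = pattern(profiles, "hybrid")
        # hybrid everywhere except one locus showing only the female allele
        p.bands["phi123"] = sorted(profiles.female["phi123"])
        assert classify_seed(p, profiles).seed_class == "off_type"

    def test_blank_locus_strict_vs_ignore(self, profiles):
        p = pattern(profiles, "hybrid")
        p.bands["umc1478"] = []
        assert classify_seed(p, profiles, "strict").seed_class == "off_type"
        assert classify_seed(p, profiles, "ignore_locus").seed_class == "hybrid"

    def test_shared_allele_tie_resolved_as_hybrid(self):
        """Where both parents carry the same single allele at every locus the
        union equals each parent; rule order calls the seed a hybrid."""
        refs = ReferenceProfiles(
            female={"a": frozenset({100})}, male={"a": frozenset({100})}
        )
        call = classify_seed(BandPattern("s", {"a": [100]}), refs)
        assert call.seed_class == "hybrid"

    def test_size_tolerance(self, profiles):
        p = pattern(profiles, "hybrid")
        p.bands["phi085"] = [b + 1 for b in p.bands["phi085"]]
        assert classify_seed(p, profiles).seed_class == "off_type"
        assert classify_seed(p, profiles, size_tolerance=1).seed_class == "hybrid"

    def test_unknown_locus_rejected(self, profiles):
        with pytest.raises(KeyError, match="absent"):
            classify_seed(BandPattern("s", {"nope": [100]}), profiles)

    def test_evidence_covers_every_locus(self, profiles):
        call = classify_seed(pattern(profiles, "hybrid"), profiles)
        assert set(call.evidence) == set(LOCI)


class TestPurity:
    def test_published_lot_counts(self):
        """192 hybrids + 4 female-parent + 4 off-type of 200 seeds -> 96.0%."""
        calls = (
            [SeedCall(f"h{i}", "hybrid") for i in range(192)]
            + [SeedCall(f"f{i}", "female_parent") for i in range(4)]
            + [SeedCall(f"o{i}", "off_type") for i in range(4)]
        )
        report = purity(calls)
        assert report.purity_percent == 96.0
        assert (report.n_hybrid, report.n_female, report.n_off_type) == (192, 4, 4)

    def test_all_hybrid(self):
        assert purity([SeedCall("s", "hybrid")] * 7).purity_percent == 100.0

    def test_one_third(self):
        calls = [SeedCall("a", "hybrid"), SeedCall("b", "off_type"),
                 SeedCall("c", "off_type")]
        assert purity(calls).purity_percent == 33.3

    def test_permutation_invariance(self):
        calls = [SeedCall("a", "hybrid"), SeedCall("b", "female_parent"),
                 SeedCall("c", "off_type")]
        assert purity(calls).purity_percent == purity(calls[::-1]).purity_percent

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            purity([])

    def test_partition_enforced(self):
        with pytest.raises(ValueError):
            PurityReport(n_total=5, n_hybrid=1, n_female=1, n_male=1, n_off_type=1)


class TestMakeSeedLot:
    def test_published_composition_recovered_exactly(self, profiles):
        patterns, labels = make_seed_lot(
            200, {"hybrid": 0.96, "female_parent": 0.02, "off_type": 0.02},
            profiles, seed=42,
        )
        calls = [classify_seed(p, profiles) for p in patterns]
        report = purity(calls)
        assert report.purity_percent == 96.0
        assert (report.n_hybrid, report.n_female, report.n_off_type) == (192, 4, 4)
        assert [c.seed_class for c in calls] == labels

    def test_all_hybrid_proportions(self, profiles):
        _, labels = make_seed_lot(10, {"hybrid": 1.0}, profiles, seed=0)
        assert labels == ["hybrid"] * 10

    def test_total_dropout_strict_all_off_type(self, profiles):
        patterns, _ = make_seed_lot(20, {"hybrid": 1.0}, profiles,
                                    dropout_rate=1.0, seed=0)
        calls = [classify_seed(p, profiles, "strict") for p in patterns]
        assert all(c.seed_class == "off_type" for c in calls)

    def test_deterministic_given_seed(self, profiles):
        a = make_seed_lot(50, {"hybrid": 0.9, "off_type": 0.1}, profiles, seed=7)
        b = make_seed_lot(50, {"hybrid": 0.9, "off_type": 0.1}, profiles, seed=7)
        assert [p.bands for p in a[0]] == [p.bands for p in b[0]]
        assert a[1] == b[1]

    @settings(derandomize=True, max_examples=30)
    @given(
        st.integers(5, 60),
        st.floats(0.5, 1.0),
        st.integers(0, 2**31 - 1),
    )
    def test_noiseless_round_trip_property(self, n, hybrid_frac, seed):
        """Any noiseless synthetic lot is recovered label-for-label."""
        refs = default_reference_profiles([f"L{i}" for i in range(4)])
        rest = 1.0 - hybrid_frac
        proportions = {
            "hybrid": hybrid_frac,
            "female_parent": rest / 2,
            "off_type": rest / 2,
        }
        patterns, labels = make_seed_lot(n, proportions, refs, seed=seed)
        calls = [classify_seed(p, refs) for p in patterns]
        assert [c.seed_class for c in calls] == labels
        report = purity(calls)
        assert report.n_hybrid == labels.count("hybrid")

    @pytest.mark.parametrize("rate_pair", [(0.0, 0.3), (0.1, 0.5), (0.3, 1.0)])
    def test_dropout_monotonically_degrades_hybrids(self, profiles, rate_pair):
        lo, hi = rate_pair
        out = []
        for rate in (lo, hi):
            patterns, _ = make_seed_lot(100, {"hybrid": 1.0}, profiles,
                                        dropout_rate=rate, seed=3)
            calls = [classify_seed(p, profiles, "strict") for p in patterns]
            out.append(sum(c.seed_class == "hybrid" for c in calls))
        assert out[1] <= out[0]

    def test_offtype_alleles_foreign_to_both_parents(self, profiles):
        patterns, labels = make_seed_lot(40, {"off_type": 1.0}, profiles, seed=1)
        for p in patterns:
            foreign = False
            for locus in profiles.loci:
                expected = profiles.hybrid_expected(locus)
                foreign |= any(b not in expected for b in p.bands[locus])
            assert foreign

    def test_bad_proportions_rejected(self, profiles):
        with pytest.raises(ValueError, match="sum to 1"):
            make_seed_lot(10, {"hybrid": 0.5}, profiles)
        with pytest.raises(ValueError, match="unknown"):
            make_seed_lot(10, {"weird": 1.0}, profiles)


class TestIO:
    def test_band_pattern_round_trip(self, profiles):
        patterns, _ = make_seed_lot(
            10, {"hybrid": 0.8, "off_type": 0.2}, profiles, seed=2
        )
        patterns[0].bands[profiles.loci[0]] = []  # null allele survives I/O
        buf = io.StringIO()
        write_band_patterns(patterns, buf)
        buf.seek(0)
        back = read_band_patterns(buf)
        assert [p.sample for p in back] == [p.sample for p in patterns]
        assert [p.bands for p in back] == [p.bands for p in patterns]

    def test_reference_profiles_json_and_tsv(self):
        json_src = io.StringIO(
            '{"female": {"a": [100, 104]}, "male": {"a": [108]}}'
        )
        refs = read_reference_profiles(json_src)
        assert refs.female["a"] == frozenset({100, 104})
        tsv_src = io.StringIO(
            "parent\tlocus\tsizes\nfemale\ta\t100,104\nmale\ta\t108\n"
        )
        refs2 = read_reference_profiles(tsv_src)
        assert refs2 == refs

    def test_mismatched_parent_loci_rejected(self):
        with pytest.raises(ValueError, match="same loci"):
            ReferenceProfiles(female={"a": frozenset({100})}, male={})
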