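"""Panel construction, design-rule validation, genome rarity, balancing."""

import io

import pytest
from hypothesis import given, settings, strategies as st

from umpcr.panel import (
    COMMON_ADAPTER,
    UNIVERSAL_ADAPTER_F,
    UNIVERSAL_ADAPTER_R,
    GenomeCount,
    LocusPrimerPair,
    PanelError,
    PrimerPanel,
    adapter_genome_count,
    balance_concentrations,
    load_maize_panel,
    make_adapter_primer,
    read_panel,
    validate_panel,
    write_panel,
)
from umpcr.seqcore import Oligo, revcomp, tm_basic

dna = st.text(alphabet="ACGT", min_size=8, max_size=30)


class TestMakeAdapterPrimer:
    def test_published_u_primer(self):
        phi085_f = Oligo("phi085-F", "AGCAGAACGGCAAGGGCTACT")
        prod = make_adapter_primer(UNIVERSAL_ADAPTER_F, phi085_f)
        assert prod.sequence == "CTCGTAGACTGCGTACCAAGCAGAACGGCAAGGGCTACT"
        assert prod.name == "U-phi085-F"
        assert prod.role == "adapter_primer"
        assert prod.tail_length == 18

    def test_published_c_primer(self):
        umc1268_r = Oligo("umc1268-R", "CAAGGCGGTTACCAAGTTTACATC")
        prod = make_adapter_primer(COMMON_ADAPTER, umc1268_r)
        assert prod.sequence == "CCTTCCTTCCTTCCCCCCCAAGGCGGTTACCAAGTTTACATC"
        assert prod.name == "C-umc1268-R"

    @settings(derandomize=True, max_examples=100)
    @given(dna, dna)
    def test_length_additivity_and_prefix(self, tail_seq, primer_seq):
        tail = Oligo("tail", tail_seq, role="adapter")
        primer = Oligo("p", primer_seq)
        prod = make_adapter_primer(tail, primer)
        assert len(prod) == len(tail) + len(primer)
        assert prod.sequence.startswith(tail.sequence)
        assert prod.core == primer.sequence
        assert prod.tail == tail.sequence

    def test_non_adapter_tail_rejected(self):
        with pytest.raises(ValueError):
            make_adapter_primer(Oligo("t", "ACGTACGT"), Oligo("p", "ACGTACGT"))


class TestValidatePanel:
    def test_u_panel_tm_window_passes(self, maize_panel):
        report = validate_panel(maize_panel)
        rule = report.rule("tm_window")
        assert rule.passed
        assert rule.measured["min"] == pytest.approx(69.92)
        assert rule.measured["max"] == pytest.approx(73.96)

    def test_c_panel_tm_window_flagged(self):
        report = validate_panel(load_maize_panel(adapters="common"))
        rule = report.rule("tm_window")
        assert not rule.passed
        assert rule.measured["max"] == pytest.approx(76.12)

    def test_adapters_only_max_run_4(self):
        """The two universal adapters stay within the six-base rule: their
        worst pairwise/self complementary run is 4 bp (adapter-F's GTAC)."""
        lp = LocusPrimerPair(
            "dummy",
            Oligo("d-F", UNIVERSAL_ADAPTER_F.sequence),
            Oligo("d-R", UNIVERSAL_ADAPTER_R.sequence),
            forward_tail=UNIVERSAL_ADAPTER_F,
            reverse_tail=UNIVERSAL_ADAPTER_R,
        )
        from umpcr.seqcore import longest_complementary_run

        pair = [UNIVERSAL_ADAPTER_F, UNIVERSAL_ADAPTER_R]
        worst = max(
            longest_complementary_run(a, b).length for a in pair for b in pair
        )
        assert worst == 4

    def test_revcomp_primer_pair_fails_dimer_rule(self):
        fwd = Oligo("x-F", "AGCAGAACGGCAAGGGCTACT")
        rev = Oligo("x-R", revcomp(fwd.sequence))
        panel = PrimerPanel(
            [LocusPrimerPair("x", fwd, rev,
                             forward_tail=UNIVERSAL_ADAPTER_F,
                             reverse_tail=UNIVERSAL_ADAPTER_R)],
            name="selfcomp",
        )
        rule = validate_panel(panel).rule("max_complementary_run")
        assert not rule.passed
        assert rule.measured >= len(fwd)

    def test_published_panel_junction_palindrome_detected(self, maize_panel):
        """U-umc1478-F carries a 10-bp self-complementary palindrome across
        the adapter/primer junction — the validator must surface it."""
        rule = validate_panel(maize_panel).rule("max_complementary_run")
        assert not rule.passed
        assert rule.measured == 10
        assert any("U-umc1478-F" in off for off in rule.offenders)

    def test_locus_order_invariance(self, maize_panel):
        reordered = PrimerPanel(
            list(reversed(maize_panel.loci)),
            adapter_f=maize_panel.adapter_f,
            adapter_r=maize_panel.adapter_r,
            name=maize_panel.name,
        )
        a = validate_panel(maize_panel)
        b = validate_panel(reordered)
        for rule_id in ("tm_window", "max_complementary_run", "hairpin_stem"):
            assert a.rule(rule_id).passed == b.rule(rule_id).passed
            assert a.rule(rule_id).measured == b.rule(rule_id).measured
            assert a.rule(rule_id).offenders == b.rule(rule_id).offenders

    def test_ssr_tm_spread_informational(self, maize_panel):
        rule = validate_panel(maize_panel).rule("ssr_tm_spread")
        assert rule.informational
        # published panel: lowest SSR Tm ~8 °C below the highest
        assert 0 < rule.measured < 10

    def test_untailed_panel_raises(self):
        bare = PrimerPanel(
            [LocusPrimerPair("x", Oligo("x-F", "AGCAGAACGGCAAGGGCTACT"),
                             Oligo("x-R", "TTTGGCACACCACGACGA"))],
            name="bare",
        )
        with pytest.raises(PanelError, match="without adapter tails"):
            validate_panel(bare)

    def test_report_serialization(self, maize_panel):
        import json

        report = validate_panel(maize_panel)
        obj = json.loads(report.to_json())
        assert obj["passed"] == report.passed
        assert {r["rule"] for r in obj["rules"]} >= {
            "tm_window", "max_complementary_run", "hairpin_stem", "ssr_tm_spread"
        }
        assert "tm_window" in report.to_text()


class TestAdapterGenomeCount:
    def _fasta(self, records):
        return io.StringIO(
            "".join(f">{rid}\n{seq}\n" for rid, seq in records)
        )

    def test_single_embedded_hit(self, rng):
        from conftest import random_dna

        adapter = UNIVERSAL_ADAPTER_F
        left = random_dna(rng, 5000)
        right = random_dna(rng, 5000)
        genome = left + adapter.sequence + right
        gc = adapter_genome_count(adapter, self._fasta([("chr1", genome)]))
        # the random flanks could by chance contain a hit; the planted one must be counted
        assert gc.total >= 1 and gc.plus >= 1

    def test_minus_strand_hit(self):
        adapter = UNIVERSAL_ADAPTER_F
        gc = adapter_genome_count(
            adapter, self._fasta([("r", revcomp(adapter.sequence))])
        )
        assert gc.total == 1 and gc.minus == 1

    def test_overlapping_matches_counted(self):
        gc = adapter_genome_count("AAAAAAAA", self._fasta([("r", "A" * 20)]))
        assert gc.plus == 13  # 20 - 8 + 1
        assert gc.minus == 0
        assert gc.total == 13

    def test_strand_symmetry(self, rng):
        from conftest import random_dna

        genome = random_dna(rng, 3000)
        fa = [("g", genome)]
        a = adapter_genome_count(UNIVERSAL_ADAPTER_F, self._fasta(fa)).total
        b = adapter_genome_count(
            revcomp(UNIVERSAL_ADAPTER_F.sequence), self._fasta(fa)
        ).total
        assert a == b

    def test_empty_genome(self):
        gc = adapter_genome_count(UNIVERSAL_ADAPTER_F, self._fasta([]))
        assert gc.total == 0 and gc.genome_length == 0

    def test_short_adapter_rejected(self):
        with pytest.raises(ValueError):
            adapter_genome_count("ACGT", self._fasta([("r", "ACGT")]))


class TestBalanceConcentrations:
    def test_published_doubling(self):
        yields = {"phi085": 0.5, "phi041": 1, "phi123": 1, "umc1478": 1,
                  "umc1268": 1}
        factors = balance_concentrations(yields)
        assert factors["phi085"] == pytest.approx(2.0)
        for locus in ("phi041", "phi123", "umc1478", "umc1268"):
            assert factors[locus] == pytest.approx(1.0)

    def test_all_equal(self):
        assert balance_concentrations({"a": 3, "b": 3}) == {"a": 1.0, "b": 1.0}

    def test_strong_locus_reduced(self):
        factors = balance_concentrations({"a": 2, "b": 1, "c": 1})
        assert factors == {"a": 0.5, "b": 1.0, "c": 1.0}

    @settings(derandomize=True, max_examples=100)
    @given(
        st.dictionaries(st.sampled_from(list("abcde")),
                        st.floats(0.1, 10), min_size=1),
        st.floats(0.01, 100),
    )
    def test_scale_invariance(self, yields, k):
        base = balance_concentrations(yields)
        scaled = balance_concentrations({l: y * k for l, y in yields.items()})
        for locus in yields:
            assert scaled[locus] == pytest.approx(base[locus], rel=1e-9)

    def test_zero_yield_rejected(self):
        with pytest.raises(ValueError):
            balance_concentrations({"a": 0.0})


class TestPanelIO:
    def test_round_trip(self, maize_panel):
        buf = io.StringIO()
        write_panel(maize_panel, buf)
        buf.seek(0)
        back = read_panel(buf, name=maize_panel.name)
        assert back.locus_names == maize_panel.locus_names
        for a, b in zip(back, maize_panel):
            assert a.forward.sequence == b.forward.sequence
            assert a.reverse.sequence == b.reverse.sequence
            assert a.concentration_factor == b.concentration_factor
        assert back.adapter_f.sequence == maize_panel.adapter_f.sequence

    def test_bundled_panel_contents(self, maize_panel):
        assert maize_panel.locus_names == [
            "phi085", "phi041", "phi123", "umc1478", "umc1268"
        ]
        assert maize_panel.loci[0].concentration_factor == 2.0
        assert all(lp.tailed for lp in maize_panel)

    def test_bad_header(self):
        with pytest.raises(PanelError, match="header"):
            read_panel(io.StringIO("a\tb\tc\nx\ty\tz\n"))

    def test_empty_file(self):
        with pytest.raises(PanelError):
            read_panel(io.StringIO("locus\tforward\treverse\n"))
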