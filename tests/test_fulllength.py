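"""ORF finding, domain spans, the paired-LTR detector and the census."""

import dataclasses

import numpy as np
import pytest

from refugium.fulllength import (
    FullLengthCriteria,
    call_fulllength_dna,
    call_fulllength_line,
    census,
    detect_ltr_elements,
    domain_span,
    find_orfs,
    score_and_filter_erv,
)
from refugium.model import ChromosomeRecord, GenomeModel, RefugiumError
from refugium.simulate import mutate_to_k, random_coding, random_seq
from refugium.fulllength import FullLengthCall

from conftest import match_span


def _rng(seed=0):
    return np.random.default_rng(seed)


class TestFindOrfs:
    def test_poly_a_has_full_frame_orfs(self):
        orfs = find_orfs("A" * 30, min_bp=9, strands=("+",))
        assert len(orfs) == 3  # one maximal ORF per frame
        assert {o.length_bp for o in orfs} >= {30, 27}

    def test_dense_stops_yield_nothing(self):
        # stops recur every <=12 bp in all three forward frames
        seq = "TAACTAGCTGAC" * 100
        assert find_orfs(seq, min_bp=600, strands=("+",)) == []

    def test_planted_orf_exact_coordinates(self):
        rng = _rng(5)
        insert = random_coding(rng, 400)  # 1200 bp stop-free in frame 0
        flank5 = "TAA" * 40
        flank3 = "TAA" * 40
        seq = flank5 + insert + flank3
        orfs = [o for o in find_orfs(seq, min_bp=1200, strands=("+",))]
        assert any(
            (o.begin, o.end) == (len(flank5), len(flank5) + 1200) for o in orfs
        )

    def test_minus_strand_coordinates_are_forward(self):
        from Bio.Seq import Seq

        rng = _rng(6)
        insert = random_coding(rng, 100)
        seq = str(Seq("TTA" * 30 + insert + "TTA" * 30).reverse_complement())
        orfs = find_orfs(seq, min_bp=300, strands=("-",))
        assert orfs and all(0 <= o.begin < o.end <= len(seq) for o in orfs)

    def test_empty_sequence_rejected(self):
        with pytest.raises(RefugiumError):
            find_orfs("", 10)


class TestDomainSpan:
    CONSENSUS = str(__import__("Bio.Seq", fromlist=["Seq"]).Seq(
        random_coding(_rng(7), 300)
    ).translate())

    def test_identity_spans_fully(self):
        hit = domain_span(self.CONSENSUS, self.CONSENSUS)
        assert hit.span_fraction == pytest.approx(1.0)

    def test_half_consensus_spans_half(self):
        half = self.CONSENSUS[: len(self.CONSENSUS) // 2]
        hit = domain_span(half, self.CONSENSUS)
        assert hit.span_fraction == pytest.approx(0.5, abs=0.05)

    def test_mutated_copy_retains_span(self):
        from Bio.Seq import Seq

        nt = random_coding(_rng(8), 300)
        mut = mutate_to_k(nt, 0.05, 2.0, _rng(9), protected=((0, len(nt)),))
        pep = str(Seq(mut).translate())
        consensus = str(Seq(nt).translate())
        assert domain_span(pep, consensus).span_fraction >= 0.9

    def test_unrelated_peptide_has_small_span(self):
        other = str(__import__("Bio.Seq", fromlist=["Seq"]).Seq(
            random_coding(_rng(10), 300)
        ).translate())
        assert domain_span(other, self.CONSENSUS).span_fraction < 0.5


@pytest.fixture(scope="module")
def line_parts():
    from Bio.Seq import Seq

    rng = _rng(11)
    en, rt = random_coding(rng, 250), random_coding(rng, 350)
    utr5, utr3 = random_seq(rng, 150), random_seq(rng, 150)
    insertion = utr5 + en + rt + utr3
    return {
        "insertion": insertion,
        "EN": str(Seq(en).translate()),
        "RT": str(Seq(rt).translate()),
        "truncated": utr5[:50] + rt + utr3,  # EN lost
    }


class TestLineDnaCalls:

    def test_intact_line_is_fulllength(self, line_parts):
        ok, ev = call_fulllength_line(
            line_parts["insertion"], FullLengthCriteria(),
            line_parts["EN"], line_parts["RT"],
        )
        assert ok and ev["orfs"]

    def test_truncated_line_is_not(self, line_parts):
        ok, _ = call_fulllength_line(
            line_parts["truncated"], FullLengthCriteria(),
            line_parts["EN"], line_parts["RT"],
        )
        assert not ok

    def test_span_threshold_gates(self, line_parts):
        # demand more span than the RT-only fragment can give
        strict = FullLengthCriteria(line_span_min=0.999)
        ok, _ = call_fulllength_line(
            line_parts["insertion"], strict, line_parts["EN"],
            line_parts["RT"] + "W" * 200,  # consensus longer than the copy
        )
        assert not ok

    def test_missing_domains_error(self, line_parts):
        with pytest.raises(RefugiumError):
            call_fulllength_line(line_parts["insertion"], FullLengthCriteria(),
                                 "", "")

    def test_dna_length_gate(self):
        from Bio.Seq import Seq

        rng = _rng(12)
        tp300 = random_coding(rng, 300)  # 900 bp ORF: below the 1 kb gate
        consensus = str(Seq(tp300).translate())
        ok, _ = call_fulllength_dna(
            random_seq(rng, 50) + tp300 + random_seq(rng, 50),
            FullLengthCriteria(), consensus,
        )
        assert not ok

    def test_dna_both_gates_met(self):
        from Bio.Seq import Seq

        rng = _rng(13)
        tp = random_coding(rng, 400)  # 1.2 kb
        consensus = str(Seq(tp).translate())
        ok, _ = call_fulllength_dna(
            random_seq(rng, 60) + tp + random_seq(rng, 60),
            FullLengthCriteria(), consensus,
        )
        assert ok


def plant_element(rng, ltr_len=300, internal_len=5000, tsd="GATCC",
                  flank=3000, internal=None):
    ltr = random_seq(rng, ltr_len)
    internal = internal if internal is not None else random_seq(rng, internal_len)
    left = random_seq(rng, flank)
    right = random_seq(rng, flank)
    seq = left + tsd + ltr + internal + ltr + tsd + right
    start = len(left) + len(tsd)
    end = start + ltr_len + len(internal) + ltr_len
    return seq, start, end


class TestLtrDetector:
    def test_planted_element_exact(self):
        rng = _rng(21)
        seq, start, end = plant_element(rng)
        cands = detect_ltr_elements(seq)
        assert len(cands) == 1
        c = cands[0]
        assert (c.begin, c.end) == (start, end)
        assert c.identity == pytest.approx(1.0)
        assert c.tsd == "GATCC"

    def test_random_sequence_yields_nothing(self):
        rng = _rng(22)
        seq = random_seq(rng, 50_000)
        assert detect_ltr_elements(seq) == []
        # brute-force confirmation: no >=100 bp direct repeat pair at any
        # plausible spacing (checked on exact 100-mers)
        k = 100
        seen = {}
        dup = False
        for i in range(0, len(seq) - k + 1):
            kmer = seq[i : i + k]
            if kmer in seen and 500 <= i - seen[kmer] <= 14_900:
                dup = True
                break
            seen.setdefault(kmer, i)
        assert not dup

    def test_solo_ltr_not_paired(self):
        rng = _rng(23)
        ltr = random_seq(rng, 300)
        seq = random_seq(rng, 3000) + "GATCC" + ltr + "GATCC" + random_seq(rng, 3000)
        assert detect_ltr_elements(seq) == []

    def test_reverse_complement_mirrors_coordinates(self):
        from Bio.Seq import Seq

        rng = _rng(24)
        seq, start, end = plant_element(rng)
        fwd = detect_ltr_elements(seq)
        rev = detect_ltr_elements(str(Seq(seq).reverse_complement()))
        assert len(fwd) == len(rev) == 1
        n = len(seq)
        assert (rev[0].begin, rev[0].end) == (n - fwd[0].end, n - fwd[0].begin)

    def test_diverged_ltr_pair_identity(self):
        rng = _rng(25)
        ltr = random_seq(rng, 300)
        ltr_b = mutate_to_k(ltr, 0.05, 2.0, rng)
        internal = random_seq(rng, 5000)
        seq = (random_seq(rng, 2000) + "CCATG" + ltr + internal + ltr_b
               + "CCATG" + random_seq(rng, 2000))
        cands = detect_ltr_elements(seq)
        assert len(cands) == 1
        assert 0.90 <= cands[0].identity < 1.0

    def test_length_bounds_respected(self):
        rng = _rng(26)
        seq, _, _ = plant_element(rng, ltr_len=80)  # below the 100 bp floor
        assert detect_ltr_elements(seq) == []


@pytest.fixture(scope="module")
def erv_setup():
    from Bio.Seq import Seq

    rng = _rng(31)
    gag, pol, env = (random_coding(rng, 300), random_coding(rng, 500),
                     random_coding(rng, 400))
    internal = (random_seq(rng, 100) + gag + "TAA" + pol + "TAA" + env
                + random_seq(rng, 100))
    doms = {g: str(Seq(s).translate()) for g, s in
            (("gag", gag), ("pol", pol), ("env", env))}
    seq, start, end = plant_element(_rng(32), internal=internal)
    return seq, start, end, doms


class TestErvScoring:

    def test_planted_fl_erv_retained(self, erv_setup):
        seq, start, end, doms = erv_setup
        cands = detect_ltr_elements(seq)
        kept = score_and_filter_erv(cands, seq, doms)
        assert len(kept) == 1
        assert (kept[0].begin, kept[0].end) == (start, end)
        assert all(v > 0.9 for v in kept[0].domain_spans.values())

    def test_random_internal_rejected(self, erv_setup):
        *_, doms = erv_setup
        seq, _, _ = plant_element(_rng(33))  # random internal, no genes
        cands = detect_ltr_elements(seq)
        assert cands  # structurally found...
        assert score_and_filter_erv(cands, seq, doms) == []  # ...but filtered

    def test_score_at_threshold_is_retained(self, erv_setup):
        seq, _, _, doms = erv_setup
        cands = detect_ltr_elements(seq)
        score = score_and_filter_erv(cands, seq, doms)[0].score
        at = FullLengthCriteria(erv_min_score=score)
        above = FullLengthCriteria(erv_min_score=score + 1e-6)
        assert len(score_and_filter_erv(cands, seq, doms, at)) == 1
        assert score_and_filter_erv(cands, seq, doms, above) == []


class TestCensus:
    def toy_genome(self):
        return GenomeModel(
            [
                ChromosomeRecord("chr1", "autosome", 1000),
                ChromosomeRecord("chr2", "autosome", 1000),
                ChromosomeRecord("chrZ", "Z", 1000),
                ChromosomeRecord("chrW", "W", 1000),
            ]
        )

    def test_zero_calls(self):
        c = census([], self.toy_genome())
        assert c.total() == 0
        assert c.class_counts() == {"autosome": 0, "Z": 0, "W": 0}

    def test_pooling_and_conservation(self):
        calls = (
            [FullLengthCall("chr1", i * 10, i * 10 + 5, "fl_erv") for i in range(3)]
            + [FullLengthCall("chr2", 0, 5, "fl_erv")]
            + [FullLengthCall("chrZ", 0, 5, "fl_line")]
            + [FullLengthCall("chrW", 0, 5, "fl_dna")] * 0
        )
        c = census(calls, self.toy_genome())
        table = c.class_table()
        assert table.loc["autosome", "fl_erv"] == 4
        assert table.loc["Z", "line_dna"] == 1
        # class totals equal sums over member chromosomes
        per = c.per_chromosome
        assert (
            per[per["te_class"] == "autosome"]["count"].sum()
            == table.loc["autosome"].drop("line_dna").sum()
        )

    def test_unknown_chromosome_rejected(self):
        with pytest.raises(RefugiumError):
            census([FullLengthCall("nope", 0, 5, "fl_erv")], self.toy_genome())


class TestRecovery:
    """End-to-end structural recovery on the planted 2 Mb scenario."""

    def test_all_planted_ervs_recovered(self, structural_sim, structural_calls):
        truth = [e for e in structural_sim.manifest.elements
                 if e.category == "fl_erv"]
        recovered = sum(
            any(match_span(c, e) for c in structural_calls) for e in truth
        )
        assert recovered / len(truth) >= 0.95

    def test_no_solo_or_fragment_false_positives(self, structural_sim,
                                                 structural_calls):
        truth = [e for e in structural_sim.manifest.elements
                 if e.category == "fl_erv"]
        for call in structural_calls:
            assert any(match_span(call, e) for e in truth)

    def test_census_equals_manifest(self, structural_sim, structural_calls):
        c = census(structural_calls, structural_sim.genome)
        got = c.class_counts("fl_erv")
        expected = {
            cls: cat.get("fl_erv", 0)
            for cls, cat in structural_sim.manifest.expected_census.items()
        }
        assert got == expected == {"autosome": 10, "Z": 2, "W": 20}

    def test_threshold_monotonicity(self, structural_sim):
        """Raising thresholds never increases the number of calls."""
        chrom = structural_sim.genome.get("chrW")
        doms = {d: structural_sim.domains[d] for d in ("gag", "pol", "env")}
        base = FullLengthCriteria()
        cands = detect_ltr_elements(chrom.sequence, base, "chrW")
        n_base = len(score_and_filter_erv(cands, chrom.sequence, doms, base))
        for stricter in (
            dataclasses.replace(base, erv_min_score=base.erv_min_score + 100),
            dataclasses.replace(base, min_ltr_identity=0.95),
            dataclasses.replace(base, erv_domain_min_span=0.95),
        ):
            cands_s = detect_ltr_elements(chrom.sequence, stricter, "chrW")
            n = len(score_and_filter_erv(cands_s, chrom.sequence, doms, stricter))
            assert n <= n_base
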