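"""Pileups, the naive mapper and the all-female/no-male linkage rule."""

import numpy as np
import pandas as pd
import pytest

from refugium.model import ConsensusLibrary, RefugiumError
from refugium.sexsnv import (
    Alignment,
    ConsensusPileup,
    PresenceThresholds,
    build_pileup,
    call_sample_presence,
    naive_map,
    read_fastq,
    sexlinked_variants,
    summarize_by_subfamily,
    transcription_check,
    write_sam,
)
from refugium.simulate import random_seq


@pytest.fixture()
def tiny_library():
    lib = ConsensusLibrary()
    rng = np.random.default_rng(3)
    lib.add("famA", random_seq(rng, 400), "LTR/ERV1")
    lib.add("famB", random_seq(rng, 400), "LINE/CR1")
    return lib


def make_sheet(rows):
    return pd.DataFrame(rows, columns=["id", "sex", "assay", "path"])


def pileup_with(lib, sample, spec):
    """Build a pileup where ``spec`` maps (family, pos) -> (depth, alt, alt_n).

    All other covered positions hold the reference at the given depth.
    """
    p = build_pileup([], lib, sample_id=sample)
    from refugium.sexsnv import BASE_INDEX

    for (fam, pos), (depth, alt, alt_n) in spec.items():
        ref = lib.sequence(fam)[pos]
        p.counts[fam][pos, BASE_INDEX[ref]] = depth - alt_n
        if alt_n:
            p.counts[fam][pos, BASE_INDEX[alt]] = alt_n
    return p


class TestPileup:
    def test_exact_read(self, tiny_library):
        ref = tiny_library.sequence("famA")
        aln = Alignment("r1", "famA", 10, ref[10:60], "I" * 50)
        p = build_pileup([aln], tiny_library)
        assert p.depth("famA", 10) == 1
        assert p.allele_count("famA", 35, ref[35]) == 1
        assert p.depth("famA", 60) == 0

    def test_mismatch_at_offset(self, tiny_library):
        ref = tiny_library.sequence("famA")
        seq = list(ref[0:50])
        alt = "A" if seq[7] != "A" else "C"
        seq[7] = alt
        p = build_pileup([Alignment("r1", "famA", 0, "".join(seq), "I" * 50)],
                         tiny_library)
        assert p.allele_count("famA", 7, alt) == 1

    def test_base_quality_floor(self, tiny_library):
        ref = tiny_library.sequence("famA")
        qual = "I" * 25 + "#" * 25  # second half Q2
        p = build_pileup([Alignment("r1", "famA", 0, ref[:50], qual)],
                         tiny_library, min_baseq=13)
        assert p.depth("famA", 10) == 1 and p.depth("famA", 40) == 0

    def test_unknown_reference_rejected(self, tiny_library):
        with pytest.raises(RefugiumError):
            build_pileup([Alignment("r1", "nope", 0, "ACGT", "IIII")],
                         tiny_library)

    def test_sam_roundtrip(self, tiny_library, tmp_path):
        ref = tiny_library.sequence("famB")
        alns = [Alignment("r1", "famB", 5, ref[5:55], "I" * 50)]
        sam = tmp_path / "x.sam"
        write_sam(alns, tiny_library, sam)
        p = build_pileup(sam, tiny_library)
        assert p.depth("famB", 30) == 1

    def test_simulated_cohort_frequencies(self, cohort_data):
        """Planted W variants show ~the predicted allele frequency in
        female pileups and zero in males."""
        sim, _, _, pileups = cohort_data
        for v in sim.manifest.variants:
            if v.carrier != "W":
                continue
            for sid, exp_freq in (("female_g1", 0.5), ("male_g1", 0.0)):
                p = pileups[sid]
                depth = p.depth(v.family, v.position)
                assert depth >= 5
                freq = p.allele_count(v.family, v.position, v.alt) / depth
                assert freq == pytest.approx(exp_freq, abs=0.2)


class TestNaiveMap:
    def test_verbatim_read_maps_at_source(self, tiny_library):
        ref = tiny_library.sequence("famA")
        alns = naive_map([("r1", ref[100:200], "I" * 100)], tiny_library)
        assert alns == [Alignment("r1", "famA", 100, ref[100:200], "I" * 100)]

    def test_reverse_complement_read_maps(self, tiny_library):
        from Bio.Seq import Seq

        ref = tiny_library.sequence("famA")
        rc = str(Seq(ref[100:200]).reverse_complement())
        alns = naive_map([("r1", rc, "I" * 100)], tiny_library)
        assert len(alns) == 1 and alns[0].pos == 100

    def test_unrelated_read_unmapped(self, tiny_library):
        rng = np.random.default_rng(99)
        read = random_seq(rng, 100)
        # brute-force check: the read shares no 20-mer with the library
        kmers = {
            s[i : i + 20]
            for s, _ in tiny_library.entries.values()
            for i in range(len(s) - 19)
        }
        assert all(read[i : i + 20] not in kmers for i in range(81))
        assert naive_map([("r1", read, "I" * 100)], tiny_library) == []

    def test_ambiguous_read_dropped(self):
        lib = ConsensusLibrary()
        shared = random_seq(np.random.default_rng(4), 200)
        lib.add("famX", shared + "AAAA", "LTR/ERV1")
        lib.add("famY", shared + "TTTT", "LTR/ERV1")
        assert naive_map([("r1", shared[:100], "I" * 100)], lib) == []

    def test_fastq_roundtrip(self, tiny_library, tmp_path):
        from refugium.simulate import write_fastq

        ref = tiny_library.sequence("famB")
        reads = [("r1", ref[50:150], "I" * 100)]
        p = tmp_path / "r.fastq"
        write_fastq(reads, p)
        assert read_fastq(p) == reads
        assert naive_map(p, tiny_library)[0].pos == 50


class TestPresenceGates:
    P = PresenceThresholds()

    def test_present(self, tiny_library):
        p = pileup_with(tiny_library, "s", {("famA", 10): (20, "A", 8)})
        ref = tiny_library.sequence("famA")[10]
        alt = "A" if ref != "A" else "C"
        p = pileup_with(tiny_library, "s", {("famA", 10): (20, alt, 8)})
        assert call_sample_presence(p, "famA", 10, alt, self.P) == "present"

    def test_absent(self, tiny_library):
        ref = tiny_library.sequence("famA")[10]
        alt = "A" if ref != "A" else "C"
        p = pileup_with(tiny_library, "s", {("famA", 10): (20, alt, 0)})
        assert call_sample_presence(p, "famA", 10, alt, self.P) == "absent"

    def test_low_depth_indeterminate(self, tiny_library):
        ref = tiny_library.sequence("famA")[10]
        alt = "A" if ref != "A" else "C"
        p = pileup_with(tiny_library, "s", {("famA", 10): (3, alt, 3)})
        assert call_sample_presence(p, "famA", 10, alt, self.P) == "indeterminate"

    def test_intermediate_frequency_indeterminate(self, tiny_library):
        ref = tiny_library.sequence("famA")[10]
        alt = "A" if ref != "A" else "C"
        p = pileup_with(tiny_library, "s", {("famA", 10): (20, alt, 2)})
        # 10% alt: above f_abs, below c_min/f_pres
        assert call_sample_presence(p, "famA", 10, alt, self.P) == "indeterminate"


def _cohort_pileups(lib, fam, pos, alt, female_alt, male_alt, depth=30,
                    n_f=3, n_m=2):
    pileups = {}
    rows = []
    for i in range(n_f):
        sid = f"f{i}"
        pileups[sid] = pileup_with(lib, sid, {(fam, pos): (depth, alt, female_alt)})
        rows.append({"id": sid, "sex": "female", "assay": "genomic", "path": "-"})
    for i in range(n_m):
        sid = f"m{i}"
        pileups[sid] = pileup_with(lib, sid, {(fam, pos): (depth, alt, male_alt)})
        rows.append({"id": sid, "sex": "male", "assay": "genomic", "path": "-"})
    return pileups, make_sheet(rows)


class TestLinkageRule:
    def setup_method(self):
        lib = ConsensusLibrary()
        lib.add("famA", random_seq(np.random.default_rng(3), 400), "LTR/ERV1")
        self.lib = lib
        self.ref = lib.sequence("famA")[50]
        self.alt = "A" if self.ref != "A" else "C"

    def test_all_female_no_male_is_linked(self):
        pileups, sheet = _cohort_pileups(self.lib, "famA", 50, self.alt, 15, 0)
        vs = sexlinked_variants(pileups, sheet, self.lib)
        assert [(v.family, v.position, v.alt) for v in vs] == [("famA", 50, self.alt)]

    def test_one_female_missing_breaks_linkage(self):
        pileups, sheet = _cohort_pileups(self.lib, "famA", 50, self.alt, 15, 0)
        pileups["f2"] = pileup_with(self.lib, "f2",
                                    {("famA", 50): (30, self.alt, 0)})
        assert sexlinked_variants(pileups, sheet, self.lib) == []

    def test_indeterminate_male_excludes_site(self):
        pileups, sheet = _cohort_pileups(self.lib, "famA", 50, self.alt, 15, 0)
        pileups["m1"] = pileup_with(self.lib, "m1",
                                    {("famA", 50): (2, self.alt, 0)})
        assert sexlinked_variants(pileups, sheet, self.lib) == []

    def test_adding_a_male_only_shrinks(self):
        pileups, sheet = _cohort_pileups(self.lib, "famA", 50, self.alt, 15, 0)
        before = sexlinked_variants(pileups, sheet, self.lib)
        pileups["m9"] = pileup_with(self.lib, "m9",
                                    {("famA", 50): (30, self.alt, 15)})
        sheet2 = pd.concat(
            [sheet, make_sheet([{"id": "m9", "sex": "male", "assay": "genomic",
                                 "path": "-"}])],
            ignore_index=True,
        )
        after = sexlinked_variants(pileups, sheet2, self.lib)
        assert {(v.family, v.position, v.alt) for v in after} <= {
            (v.family, v.position, v.alt) for v in before
        }

    def test_single_male_warns(self):
        pileups, sheet = _cohort_pileups(self.lib, "famA", 50, self.alt, 15, 0,
                                         n_m=1)
        with pytest.warns(UserWarning, match="one male"):
            sexlinked_variants(pileups, sheet, self.lib)

    def test_missing_cohort_rejected(self):
        pileups, sheet = _cohort_pileups(self.lib, "famA", 50, self.alt, 15, 0)
        with pytest.raises(RefugiumError):
            sexlinked_variants(pileups, sheet[sheet.sex == "female"], self.lib)


class TestTranscription:
    def setup_method(self):
        TestLinkageRule.setup_method(self)

    def test_female_rna_marks_transcribed(self):
        pileups, sheet = _cohort_pileups(self.lib, "famA", 50, self.alt, 15, 0)
        vs = sexlinked_variants(pileups, sheet, self.lib)
        rna = {"fr": pileup_with(self.lib, "fr", {("famA", 50): (20, self.alt, 10)})}
        sheet = pd.concat(
            [sheet, make_sheet([{"id": "fr", "sex": "female", "assay": "RNA",
                                 "path": "-"}])],
            ignore_index=True,
        )
        out = transcription_check(vs, rna, sheet)
        assert out[0].transcribed and out[0].w_linked

    def test_male_rna_discards(self):
        pileups, sheet = _cohort_pileups(self.lib, "famA", 50, self.alt, 15, 0)
        vs = sexlinked_variants(pileups, sheet, self.lib)
        rna = {"mr": pileup_with(self.lib, "mr", {("famA", 50): (20, self.alt, 10)})}
        sheet = pd.concat(
            [sheet, make_sheet([{"id": "mr", "sex": "male", "assay": "RNA",
                                 "path": "-"}])],
            ignore_index=True,
        )
        out = transcription_check(vs, rna, sheet)
        assert out[0].discarded_male_rna and not out[0].w_linked
        # flag ordering: every discarded variant was previously W-linked
        assert all(v.w_linked for v in vs)


class TestSummary:
    def test_empty(self):
        df = summarize_by_subfamily([])
        assert df.iloc[0]["n_snvs"] == 0

    def test_counting(self, tiny_library):
        from refugium.sexsnv import SexLinkedVariant

        def v(fam, pos, tr):
            ref = tiny_library.sequence(fam)[pos]
            alt = "A" if ref != "A" else "C"
            return SexLinkedVariant(fam, pos, ref, alt, transcribed=tr)

        vs = [v("famA", 1, True), v("famA", 2, True), v("famA", 3, True),
              v("famB", 1, False), v("famB", 2, False)]
        df = summarize_by_subfamily(vs, tiny_library).set_index("group")
        assert df.loc["total", "n_snvs"] == 5
        assert df.loc["total", "n_subfamilies"] == 2
        assert df.loc["total", "n_transcribed_snvs"] == 3
        assert df.loc["total", "n_transcribed_subfamilies"] == 1
        assert df.loc["LTR", "n_snvs"] == 3


class TestCohortRecovery:
    def test_planted_w_snvs_recovered_exactly(self, cohort_data):
        sim, _, sheet, pileups = cohort_data
        gen = {s: pileups[s] for s in sheet[sheet.assay == "genomic"]["id"]}
        vs = sexlinked_variants(gen, sheet, sim.library)
        called = {(v.family, v.position, v.alt) for v in vs}
        assert called == sim.manifest.expected_w_linked

    def test_transcribed_fraction_recovered(self, cohort_data):
        sim, _, sheet, pileups = cohort_data
        gen = {s: pileups[s] for s in sheet[sheet.assay == "genomic"]["id"]}
        rna = {s: pileups[s] for s in sheet[sheet.assay == "RNA"]["id"]}
        vs = transcription_check(
            sexlinked_variants(gen, sheet, sim.library), rna, sheet
        )
        got_tr = {(v.family, v.position) for v in vs if v.transcribed}
        exp_tr = {(v.family, v.position) for v in sim.manifest.variants
                  if v.carrier == "W" and v.transcribed}
        assert got_tr == exp_tr

    def test_summary_matches_truth_aggregation(self, cohort_data):
        sim, _, sheet, pileups = cohort_data
        gen = {s: pileups[s] for s in sheet[sheet.assay == "genomic"]["id"]}
        rna = {s: pileups[s] for s in sheet[sheet.assay == "RNA"]["id"]}
        vs = transcription_check(
            sexlinked_variants(gen, sheet, sim.library), rna, sheet
        )
        df = summarize_by_subfamily(vs, sim.library).set_index("group")
        truth_w = [v for v in sim.manifest.variants if v.carrier == "W"]
        assert df.loc["total", "n_snvs"] == len(truth_w)
        assert df.loc["total", "n_subfamilies"] == len({v.family for v in truth_w})
        assert df.loc["total", "n_transcribed_snvs"] == sum(
            v.transcribed for v in truth_w
        )
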