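"""Sex-linked SNV discovery in TE consensus space.

Male and female genomic read cohorts are mapped against the TE consensus
library; a variant (family, consensus position, alternate base) is called
W-linked when it is *present in every female* and *absent in every male*
genomic sample.  Presence and absence are gated on depth, alternate count
and alternate frequency, and any sample whose call is indeterminate (e.g.
insufficient coverage) removes the site — deliberately conservative, since
with small cohorts a single undersampled male can otherwise masquerade as
an absence.  W-linked variants are then checked in RNA cohorts: seen in a
female RNA sample means transcribed; seen in any male RNA sample means the
variant cannot be W-linked and is discarded as a false positive.

The module also ships a deliberately simple exact-seed read mapper so the
whole pipeline can run self-contained on synthetic cohorts; real data
should be mapped with a dedicated mapper and fed in as SAM.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .model import ConsensusLibrary, RefugiumError

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class PresenceThresholds:
    """Gates for per-sample presence/absence calls at a site.

    present: depth >= d_min AND alt count >= c_min AND alt freq >= f_pres.
    absent:  depth >= d_min AND alt freq <= f_abs.
    Anything else is indeterminate.
    """

    d_min: int = 5
    c_min: int = 3
    f_pres: float = 0.20
    f_abs: float = 0.05


class Alignment(NamedTuple):
    """A minimal ungapped read alignment against a consensus."""

    qname: str
    family: str
    pos: int  # 0-based on the consensus
    seq: str  # aligned portion, already reverse-complemented if needed
    qual: Optional[str] = None
    mapq: int = 60


@dataclass
class ConsensusPileup:
    """Per-(family, position) allele counts for one sample."""

    sample_id: str
    counts: dict[str, np.ndarray] = field(default_factory=dict)  # (L, 4) ints

    def depth(self, family: str, pos: int) -> int:
        arr = self.counts.get(family)
        return 0 if arr is None else int(arr[pos].sum())

    def allele_count(self, family: str, pos: int, base: str) -> int:
        arr = self.counts.get(family)
        return 0 if arr is None else int(arr[pos, BASE_INDEX[base]])


def _empty_counts(library: ConsensusLibrary) -> dict[str, np.ndarray]:
    return {
        fam: np.zeros((len(seq), 4), dtype=np.int64)
        for fam, (seq, _) in library.entries.items()
    }


def build_pileup(
    alignments: Union[str, Path, Iterable[Alignment]],
    library: ConsensusLibrary,
    sample_id: str = "sample",
    min_baseq: int = 13,
    min_mapq: int = 0,
) -> ConsensusPileup:
    """Pile up read alignments onto the consensus library.

    ``alignments`` is either a SAM path (parsed CIGAR-aware through pysam;
    secondary, supplementary, duplicate and unmapped records are skipped)
    or an iterable of :class:`Alignment` records from :func:`naive_map`.
    """
    counts = _empty_counts(library)
    if isinstance(alignments, (str, Path)):
        import pysam

        with pysam.AlignmentFile(str(alignments), "r", check_sq=False) as sam:
            for read in sam:
                if (read.is_unmapped or read.is_secondary or
                        read.is_supplementary or read.is_duplicate):
                    continue
                if read.mapping_quality < min_mapq:
                    continue
                fam = read.reference_name
                if fam not in counts:
                    raise RefugiumError(
                        f"SAM reference {fam!r} absent from consensus library"
                    )
                seq = read.query_sequence
                quals = read.query_qualities
                arr = counts[fam]
                for qpos, rpos in read.get_aligned_pairs(matches_only=True):
                    if quals is not None and quals[qpos] < min_baseq:
                        continue
                    base = seq[qpos]
                    if base in BASE_INDEX and rpos < arr.shape[0]:
                        arr[rpos, BASE_INDEX[base]] += 1
    else:
        for aln in alignments:
            if aln.mapq < min_mapq:
                continue
            if aln.family not in counts:
                raise RefugiumError(
                    f"alignment reference {aln.family!r} absent from library"
                )
            arr = counts[aln.family]
            for i, base in enumerate(aln.seq):
                if aln.qual is not None and ord(aln.qual[i]) - 33 < min_baseq:
                    continue
                if base in BASE_INDEX:
                    arr[aln.pos + i, BASE_INDEX[base]] += 1
    return ConsensusPileup(sample_id=sample_id, counts=counts)


# ---------------------------------------------------------------------------
# Naive mapper (self-contained cohort support)
# ---------------------------------------------------------------------------

def read_fastq(path: Union[str, Path]) -> list[tuple[str, str, str]]:
    """Read a FASTQ file into (name, sequence, quality) tuples."""
    reads = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    if len(lines) % 4:
        raise RefugiumError(f"{path}: truncated FASTQ")
    for i in range(0, len(lines), 4):
        name = lines[i].split()[0].lstrip("@")
        reads.append((name, lines[i + 1].upper(), lines[i + 3]))
    return reads


def naive_map(
    reads: Union[str, Path, Sequence[tuple[str, str, str]]],
    library: ConsensusLibrary,
    seed_len: int = 20,
    max_mismatch_frac: float = 0.10,
) -> list[Alignment]:
    """Exact k-mer seed + ungapped extension; best unique hit only.

    Reads that map equally well to two places (or overhang the consensus)
    are dropped; unmapped reads are dropped.  Deterministic.
    """
    if isinstance(reads, (str, Path)):
        reads = read_fastq(reads)
    index: dict[str, list[tuple[str, int]]] = {}
    for fam, (seq, _) in library.entries.items():
        for i in range(len(seq) - seed_len + 1):
            index.setdefault(seq[i : i + seed_len], []).append((fam, i))

    out: list[Alignment] = []
    for name, seq, qual in reads:
        if len(seq) < seed_len:
            continue
        best: Optional[tuple[int, str, int, str, str]] = None
        ambiguous = False
        for oriented, q in ((seq, qual), (_revcomp(seq), qual[::-1])):
            offsets = {0, (len(oriented) - seed_len) // 2, len(oriented) - seed_len}
            hits: set[tuple[str, int]] = set()
            for off in sorted(offsets):
                for fam, pos in index.get(oriented[off : off + seed_len], ()):
                    hits.add((fam, pos - off))
            for fam, start in sorted(hits):
                ref = library.sequence(fam)
                if start < 0 or start + len(oriented) > len(ref):
                    continue
                mism = sum(
                    a != b for a, b in zip(oriented, ref[start : start + len(oriented)])
                )
                if mism > max_mismatch_frac * len(oriented):
                    continue
                cand = (mism, fam, start, oriented, q)
                if best is None or mism < best[0]:
                    best, ambiguous = cand, False
                elif mism == best[0] and (fam, start) != (best[1], best[2]):
                    ambiguous = True
        if best is not None and not ambiguous:
            out.append(Alignment(name, best[1], best[2], best[3], best[4]))
    return out


def write_sam(
    alignments: Iterable[Alignment], library: ConsensusLibrary, path: Union[str, Path]
) -> None:
    """Write naive-mapper alignments as SAM text against the library."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for fam, (seq, _) in library.entries.items():
            fh.write(f"@SQ\tSN:{fam}\tLN:{len(seq)}\n")
        for a in alignments:
            qual = a.qual if a.qual is not None else "*"
            fh.write(
                f"{a.qname}\t0\t{a.family}\t{a.pos + 1}\t{a.mapq}\t"
                f"{len(a.seq)}M\t*\t0\t0\t{a.seq}\t{qual}\n"
            )


# ---------------------------------------------------------------------------
# Variant calling
# ---------------------------------------------------------------------------

def call_sample_presence(
    pileup: ConsensusPileup,
    family: str,
    pos: int,
    alt: str,
    thresholds: PresenceThresholds = PresenceThresholds(),
) -> str:
    """Presence status of one alternate allele in one sample."""
    depth = pileup.depth(family, pos)
    if depth < thresholds.d_min:
        return "indeterminate"
    alt_n = pileup.allele_count(family, pos, alt)
    freq = alt_n / depth
    if alt_n >= thresholds.c_min and freq >= thresholds.f_pres:
        return "present"
    if freq <= thresholds.f_abs:
        return "absent"
    return "indeterminate"


@dataclass(frozen=True)
class SexLinkedVariant:
    """A W-linked candidate SNV against a TE consensus."""

    family: str
    position: int  # 0-based on the consensus
    ref: str
    alt: str
    sample_status: dict = field(default_factory=dict, compare=False, hash=False)
    w_linked: bool = True
    transcribed: bool = False
    discarded_male_rna: bool = False

    def __post_init__(self) -> None:
        if self.alt == self.ref:
            raise RefugiumError("alternate equals reference")


def _cohort(sheet: pd.DataFrame, sex: str, assay: str) -> list[str]:
    sel = (sheet["sex"] == sex) & (sheet["assay"] == assay)
    return list(sheet.loc[sel, "id"])


def sexlinked_variants(
    pileups: Mapping[str, ConsensusPileup],
    sheet: pd.DataFrame,
    library: ConsensusLibrary,
    thresholds: PresenceThresholds = PresenceThresholds(),
) -> list[SexLinkedVariant]:
    """Call W-linked SNVs from per-sample genomic pileups.

    A site/allele is W-linked iff its status is ``present`` in every female
    genomic sample and ``absent`` in every male genomic sample; a single
    ``indeterminate`` call in any required sample excludes the site.
    """
    females = _cohort(sheet, "female", "genomic")
    males = _cohort(sheet, "male", "genomic")
    if not females or not males:
        raise RefugiumError(
            "need at least one female and one male genomic sample"
        )
    if len(males) == 1:
        warnings.warn(
            "only one male genomic sample: W-linked calls may include "
            "false positives",
            stacklevel=2,
        )
    missing = [s for s in females + males if s not in pileups]
    if missing:
        raise RefugiumError(f"missing pileups for samples {missing}")

    variants: list[SexLinkedVariant] = []
    for fam, (consensus, _) in library.entries.items():
        pooled = np.zeros((len(consensus), 4), dtype=np.int64)
        for sid in females:
            arr = pileups[sid].counts.get(fam)
            if arr is not None:
                pooled += arr
        for pos in np.nonzero(pooled.sum(axis=1) > 0)[0]:
            ref = consensus[pos]
            if ref not in BASE_INDEX:
                continue
            for alt in BASES:
                if alt == ref:
                    continue
                # necessary condition for present-in-all-females
                if pooled[pos, BASE_INDEX[alt]] < thresholds.c_min * len(females):
                    continue
                status = {
                    sid: call_sample_presence(pileups[sid], fam, int(pos), alt,
                                              thresholds)
                    for sid in females + males
                }
                ok = all(status[s] == "present" for s in females) and all(
                    status[s] == "absent" for s in males
                )
                if ok:
                    variants.append(
                        SexLinkedVariant(fam, int(pos), ref, alt,
                                         sample_status=status)
                    )
    variants.sort(key=lambda v: (v.family, v.position, v.alt))
    return variants


def transcription_check(
    variants: Sequence[SexLinkedVariant],
    rna_pileups: Mapping[str, ConsensusPileup],
    sheet: pd.DataFrame,
    thresholds: PresenceThresholds = PresenceThresholds(),
) -> list[SexLinkedVariant]:
    """Flag transcription and remove male-RNA false positives.

    ``transcribed`` iff present (same gates) in at least one female RNA
    sample; a variant present in any male RNA sample loses its W-linked
    status and is flagged ``discarded_male_rna``.
    """
    female_rna = [s for s in _cohort(sheet, "female", "RNA") if s in rna_pileups]
    male_rna = [s for s in _cohort(sheet, "male", "RNA") if s in rna_pileups]
    out = []
    for v in variants:
        transcribed = any(
            call_sample_presence(rna_pileups[s], v.family, v.position, v.alt,
                                 thresholds) == "present"
            for s in female_rna
        )
        in_male = any(
            call_sample_presence(rna_pileups[s], v.family, v.position, v.alt,
                                 thresholds) == "present"
            for s in male_rna
        )
        out.append(
            replace(
                v,
                transcribed=transcribed,
                discarded_male_rna=in_male,
                w_linked=v.w_linked and not in_male,
            )
        )
    return out


def summarize_by_subfamily(
    variants: Sequence[SexLinkedVariant],
    library: Optional[ConsensusLibrary] = None,
) -> pd.DataFrame:
    """Survey-style summary per classification group.

    Columns: ``n_snvs`` (W-linked SNVs), ``n_subfamilies`` (consensus
    families hit), ``n_transcribed_snvs``, ``n_transcribed_subfamilies``;
    one row per top-level classification group plus a ``total`` row.
    Variants discarded on male-RNA evidence are excluded.
    """
    rows = []
    for v in variants:
        if not v.w_linked:
            continue
        group = "Unknown"
        if library is not None and v.family in library:
            group = library.classification(v.family).split("/", 1)[0]
        rows.append({"group": group, "family": v.family,
                     "transcribed": v.transcribed})
    df = pd.DataFrame(rows, columns=["group", "family", "transcribed"])
    out_rows = []
    groups = sorted(df["group"].unique()) if not df.empty else []
    for g in groups + ["total"]:
        sub = df if g == "total" else df[df["group"] == g]
        tr = sub[sub["transcribed"].astype(bool)]
        out_rows.append(
            {
                "group": g,
                "n_snvs": len(sub),
                "n_subfamilies": sub["family"].nunique(),
                "n_transcribed_snvs": len(tr),
                "n_transcribed_subfamilies": tr["family"].nunique(),
            }
        )
    if not out_rows:
        out_rows = [{"group": "total", "n_snvs": 0, "n_subfamilies": 0,
                     "n_transcribed_snvs": 0, "n_transcribed_subfamilies": 0}]
    return pd.DataFrame(out_rows)


def write_variants_tsv(variants: Sequence[SexLinkedVariant], path) -> None:
    rows = [
        {
            "family": v.family,
            "position": v.position,
            "ref": v.ref,
            "alt": v.alt,
            "w_linked": v.w_linked,
            "transcribed": v.transcribed,
            "discarded_male_rna": v.discarded_male_rna,
        }
        for v in variants
    ]
    pd.DataFrame(
        rows,
        columns=["family", "position", "ref", "alt", "w_linked", "transcribed",
                 "discarded_male_rna"],
    ).to_csv(path, sep="\t", index=False)


def write_variants_vcf(
    variants: Sequence[SexLinkedVariant], library: ConsensusLibrary, path
) -> None:
    """VCF-like report in consensus space (contigs are TE consensi, not a
    genome — a non-genomic VCF dialect, documented as such)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=TR,Number=0,Type=Flag,Description="Transcribed">\n')
        for fam, (seq, _) in library.entries.items():
            fh.write(f"##contig=<ID={fam},length={len(seq)}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in variants:
            if not v.w_linked:
                continue
            info = "TR" if v.transcribed else "."
            fh.write(
                f"{v.family}\t{v.position + 1}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t{info}\n"
            )
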