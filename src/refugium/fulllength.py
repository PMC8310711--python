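"""Detection of full-length, potentially (retro)transposition-competent TEs.

Three element categories are called:

* **fl-LINE** — an annotated LINE insertion containing ORFs of at least
  600 bp whose translations span at least 90% of both the endonuclease (EN)
  and reverse-transcriptase (RT) domain consensi.  The two domains may be
  satisfied by one ORF or by two ORFs of the same insertion (configurable).
* **fl-DNA** — an annotated DNA-transposon insertion with an ORF of at
  least 1 kb spanning at least 90% of the transposase domain consensus.
* **fl-ERV** — a structural call: a pair of direct long terminal repeats
  (LTRs) of plausible length and spacing, with high LTR-pair identity,
  optionally a 4-6 bp target-site duplication (TSD), and internal ORFs with
  complete or partly complete gag/pol/env-class domain evidence.  A single
  composite score gates the final call, playing the role of the score
  thresholds of the dedicated external ERV annotators this detector
  replaces.

Solo-LTRs (one LTR, no partner) and internal-only fragments never satisfy
the paired-repeat requirement and are structurally excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import edlib
import pandas as pd
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq

from .model import (
    GenomeModel,
    RefugiumError,
    RepeatHit,
    pool_class,
)

_STOPS = {"TAA", "TAG", "TGA"}


# ---------------------------------------------------------------------------
# Criteria
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FullLengthCriteria:
    """Thresholds for full-length calls.

    The defaults implement the 600 bp / 1 kb ORF gates with 90% domain
    spans for LINEs and DNA transposons, and a paired-LTR profile (LTR
    100-1000 bp, element 1.5-15 kb, pair identity >= 0.80, TSD 4-6 bp)
    with a composite ERV score thresholded at 300 (score >= threshold is
    retained).  ``profile`` is a free-text label recorded in the census so
    runs under different criteria sets stay distinguishable.
    """

    line_min_orf_bp: int = 600
    line_span_min: float = 0.90
    line_same_orf: bool = False
    dna_min_orf_bp: int = 1000
    dna_span_min: float = 0.90

    ltr_min_len: int = 100
    ltr_max_len: int = 1000
    element_min_len: int = 1500
    element_max_len: int = 15000
    min_ltr_identity: float = 0.80
    tsd_min: int = 4
    tsd_max: int = 6
    seed_k: int = 11
    max_seed_gap: int = 40
    min_seeds: int = 2
    max_kmer_occupancy: int = 64
    xdrop: int = 10

    erv_min_score: float = 300.0
    erv_domain_min_span: float = 0.50
    erv_min_orf_bp: int = 300
    weight_identity: float = 250.0
    weight_tsd: float = 50.0
    weight_domains: float = 200.0
    profile: str = "default"

    def __post_init__(self) -> None:
        if not (0 < self.line_span_min <= 1 and 0 < self.dna_span_min <= 1):
            raise RefugiumError("span minima must be in (0, 1]")
        for v in (self.line_min_orf_bp, self.dna_min_orf_bp, self.ltr_min_len,
                  self.element_min_len, self.seed_k):
            if v <= 0:
                raise RefugiumError("criteria thresholds must be positive")


#: Table-1-style profiles; both use the same unified structural detector but
#: are tracked separately so censuses can be reported side by side.
PROFILES = {
    "retrotector-like": FullLengthCriteria(profile="retrotector-like"),
    "ltrharvest-like": FullLengthCriteria(profile="ltrharvest-like",
                                          erv_min_score=250.0),
}


# ---------------------------------------------------------------------------
# ORFs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OrfRecord:
    """A maximal stop-free ORF (start codon not required).

    ``begin``/``end`` are 0-based half-open on the *forward* strand of the
    scanned sequence regardless of ``strand``.
    """

    begin: int
    end: int
    strand: str
    frame: int
    peptide: str

    @property
    def length_bp(self) -> int:
        return self.end - self.begin


def find_orfs(
    sequence: str,
    min_bp: int,
    strands: Sequence[str] = ("+", "-"),
) -> list[OrfRecord]:
    """Maximal stop-to-stop ORFs in all three frames of the given strands."""
    if not sequence:
        raise RefugiumError("empty sequence")
    seq = sequence.upper()
    n = len(seq)
    out: list[OrfRecord] = []
    for strand in strands:
        s = seq if strand == "+" else str(Seq(seq).reverse_complement())
        for frame in range(3):
            i = frame
            run_start = i
            while i + 3 <= n:
                codon = s[i : i + 3]
                if codon in _STOPS:
                    out.extend(_emit_orf(s, run_start, i, strand, frame, min_bp, n))
                    run_start = i + 3
                i += 3
            out.extend(_emit_orf(s, run_start, i, strand, frame, min_bp, n))
    out.sort(key=lambda o: (o.begin, o.end, o.strand, o.frame))
    return out


def _emit_orf(s, begin, end, strand, frame, min_bp, total_len):
    if end - begin < min_bp:
        return []
    peptide = str(Seq(s[begin:end]).translate())
    if strand == "+":
        b, e = begin, end
    else:
        b, e = total_len - end, total_len - begin
    return [OrfRecord(b, e, strand, frame, peptide)]


# ---------------------------------------------------------------------------
# Protein-domain evidence
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DomainHit:
    """Best local alignment of a peptide against a domain consensus."""

    domain: str
    domain_length: int
    aligned_begin: int  # on the domain consensus, 0-based half-open
    aligned_end: int
    span_fraction: float
    score: float


_aligner: Optional[PairwiseAligner] = None


def _protein_aligner() -> PairwiseAligner:
    global _aligner
    if _aligner is None:
        a = PairwiseAligner()
        a.mode = "local"
        a.substitution_matrix = substitution_matrices.load("BLOSUM62")
        a.open_gap_score = -11
        a.extend_gap_score = -1
        _aligner = a
    return _aligner


def domain_span(peptide: str, domain_consensus: str, domain: str = "domain") -> DomainHit:
    """Span of a domain consensus covered by its best local alignment.

    Highest-scoring alignment wins; Biopython's alignment enumeration is
    deterministic, and the first (leftmost) optimal alignment is taken.
    Unknown residues (X, stop ``*``) are mapped to X.
    """
    if not peptide or not domain_consensus:
        raise RefugiumError("empty peptide in domain_span")
    aligner = _protein_aligner()
    alphabet = set(str(aligner.substitution_matrix.alphabet))
    pep = "".join(c if c in alphabet else "X" for c in peptide.upper())
    dom = "".join(c if c in alphabet else "X" for c in domain_consensus.upper())
    alns = aligner.align(pep, dom)
    try:
        aln = alns[0]
    except IndexError:
        return DomainHit(domain, len(dom), 0, 0, 0.0, 0.0)
    target_blocks = aln.aligned[1]
    covered = int(sum(e - b for b, e in target_blocks))
    lo = int(target_blocks[0][0]) if len(target_blocks) else 0
    hi = int(target_blocks[-1][1]) if len(target_blocks) else 0
    return DomainHit(domain, len(dom), lo, hi, covered / len(dom), float(aln.score))


def best_domain_spans(
    orfs: Iterable[OrfRecord], domain_consensi: Mapping[str, str]
) -> dict[str, float]:
    """Best span_fraction per domain over all ORFs (0.0 when never aligned)."""
    best = {d: 0.0 for d in domain_consensi}
    for orf in orfs:
        for name, consensus in domain_consensi.items():
            hit = domain_span(orf.peptide, consensus, name)
            if hit.span_fraction > best[name]:
                best[name] = hit.span_fraction
    return best


# ---------------------------------------------------------------------------
# fl-LINE / fl-DNA homology calls
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FullLengthCall:
    """A full-length TE call on a chromosome."""

    chromosome: str
    begin: int
    end: int
    category: str  # fl_erv | fl_line | fl_dna
    family: str = ""
    score: float = 0.0
    evidence: dict = field(default_factory=dict, compare=False, hash=False)


def call_fulllength_line(
    insertion_seq: str,
    criteria: FullLengthCriteria,
    en_consensus: str,
    rt_consensus: str,
) -> tuple[bool, dict]:
    """Is this LINE insertion full length (EN+RT spans >= threshold)?"""
    if not en_consensus or not rt_consensus:
        raise RefugiumError("EN and RT domain consensi are required")
    orfs = find_orfs(insertion_seq, criteria.line_min_orf_bp)
    per_orf = [
        {
            "orf": (o.begin, o.end, o.strand),
            "EN": domain_span(o.peptide, en_consensus, "EN").span_fraction,
            "RT": domain_span(o.peptide, rt_consensus, "RT").span_fraction,
        }
        for o in orfs
    ]
    if criteria.line_same_orf:
        ok = any(
            r["EN"] >= criteria.line_span_min and r["RT"] >= criteria.line_span_min
            for r in per_orf
        )
    else:
        best_en = max((r["EN"] for r in per_orf), default=0.0)
        best_rt = max((r["RT"] for r in per_orf), default=0.0)
        ok = best_en >= criteria.line_span_min and best_rt >= criteria.line_span_min
    return ok, {"orfs": per_orf, "mode": "same_orf" if criteria.line_same_orf else "any_orf"}


def call_fulllength_dna(
    insertion_seq: str,
    criteria: FullLengthCriteria,
    transposase_consensus: str,
) -> tuple[bool, dict]:
    """Is this DNA-transposon insertion full length (transposase span)?"""
    if not transposase_consensus:
        raise RefugiumError("transposase domain consensus is required")
    orfs = find_orfs(insertion_seq, criteria.dna_min_orf_bp)
    per_orf = [
        {
            "orf": (o.begin, o.end, o.strand),
            "transposase": domain_span(
                o.peptide, transposase_consensus, "transposase"
            ).span_fraction,
        }
        for o in orfs
    ]
    ok = any(r["transposase"] >= criteria.dna_span_min for r in per_orf)
    return ok, {"orfs": per_orf}


# ---------------------------------------------------------------------------
# Structural paired-LTR detector
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ErvCandidate:
    """A paired-LTR structural candidate (coordinates 0-based half-open)."""

    chromosome: str
    ltr5: tuple[int, int]
    ltr3: tuple[int, int]
    identity: float
    tsd: Optional[str] = None
    domain_spans: dict = field(default_factory=dict, compare=False, hash=False)
    score: float = 0.0

    def __post_init__(self) -> None:
        if not (self.ltr5[0] < self.ltr5[1] <= self.ltr3[0] < self.ltr3[1]):
            raise RefugiumError("LTR spans out of order")

    @property
    def begin(self) -> int:
        return self.ltr5[0]

    @property
    def end(self) -> int:
        return self.ltr3[1]

    @property
    def internal(self) -> tuple[int, int]:
        return (self.ltr5[1], self.ltr3[0])


def _pair_identity(a: str, b: str) -> float:
    """Identity of two LTR copies from a global (NW) edit distance."""
    if not a or not b:
        return 0.0
    dist = edlib.align(a, b, mode="NW", task="distance")["editDistance"]
    return 1.0 - dist / max(len(a), len(b))


def _xdrop_extend(seq: str, i: int, j: int, direction: int, xdrop: int) -> int:
    """Ungapped X-drop extension of the repeat pair (i, j) along ``direction``.

    Returns the number of additional columns retained (those up to the
    running-score maximum)."""
    n = len(seq)
    score = best = 0
    best_steps = 0
    steps = 0
    while True:
        i += direction
        j += direction
        if i < 0 or j < 0 or i >= n or j >= n or j <= i:
            break
        steps += 1
        score += 1 if seq[i] == seq[j] else -2
        if score > best:
            best, best_steps = score, steps
        if best - score > xdrop:
            break
    return best_steps


def _find_tsd(
    seq: str, start: int, end: int, criteria: FullLengthCriteria, max_shift: int = 6
) -> Optional[tuple[int, int, str]]:
    """Search for a TSD around candidate element boundaries.

    Tries boundary shifts of up to ``max_shift`` bp on each side (ungapped
    extension can slightly overshoot the true LTR edges) and prefers longer
    TSDs, then smaller total shift, then leftmost.  Returns the refined
    ``(start, end, tsd)`` or None.
    """
    n = len(seq)
    best = None
    best_key = None
    for t in range(criteria.tsd_max, criteria.tsd_min - 1, -1):
        for dl in range(-max_shift, max_shift + 1):
            s = start + dl
            if s - t < 0:
                continue
            left = seq[s - t : s]
            if "N" in left:
                continue
            for dr in range(-max_shift + abs(dl), max_shift - abs(dl) + 1):
                e = end + dr
                if e + t > n or e <= s:
                    continue
                if seq[e : e + t] != left:
                    continue
                shift = abs(dl) + abs(dr)
                # a longer TSD must pay for every base of boundary shift
                key = (t - shift, t, -shift, -abs(dl), s)
                if best_key is None or key > best_key:
                    best, best_key = (s, e, left), key
    return best


def detect_ltr_elements(
    sequence: str,
    criteria: FullLengthCriteria = FullLengthCriteria(),
    chromosome: str = "seq",
) -> list[ErvCandidate]:
    """Find paired-LTR elements in a chromosome sequence.

    Exact k-mer seeds of direct repeats on the same strand are grouped by
    diagonal (start offset), chained into runs, extended without gaps under
    an X-drop rule, refined against a flanking TSD when one exists, and
    filtered on LTR length, element span and LTR-pair identity.  Overlapping
    candidates are resolved by score, then leftmost start.
    """
    seq = sequence.upper()
    n = len(seq)
    k = criteria.seed_k
    if n < criteria.element_min_len:
        return []
    d_min = criteria.element_min_len - criteria.ltr_max_len
    d_max = criteria.element_max_len - criteria.ltr_min_len

    index: dict[str, list[int]] = {}
    for i in range(n - k + 1):
        kmer = seq[i : i + k]
        if "N" in kmer:
            continue
        index.setdefault(kmer, []).append(i)

    diagonals: dict[int, list[int]] = {}
    for positions in index.values():
        m = len(positions)
        if m < 2 or m > criteria.max_kmer_occupancy:
            continue
        for ai in range(m):
            for bi in range(ai + 1, m):
                d = positions[bi] - positions[ai]
                if d_min <= d <= d_max:
                    diagonals.setdefault(d, []).append(positions[ai])

    raw: list[tuple[int, int, int]] = []  # (ltr_start, ltr_end, d)
    for d, starts in diagonals.items():
        starts = sorted(set(starts))
        run = [starts[0]]
        for s in starts[1:]:
            if s - run[-1] <= criteria.max_seed_gap + k:
                run.append(s)
            else:
                raw.extend(_close_run(seq, run, d, k, criteria))
                run = [s]
        raw.extend(_close_run(seq, run, d, k, criteria))

    candidates: list[ErvCandidate] = []
    seen: set[tuple[int, int]] = set()
    for ls, le, d in raw:
        length = le - ls
        if not (criteria.ltr_min_len <= length <= criteria.ltr_max_len):
            continue
        span = d + length
        if not (criteria.element_min_len <= span <= criteria.element_max_len):
            continue
        start, end = ls, le + d
        tsd = None
        refined = _find_tsd(seq, start, end, criteria)
        if refined is not None:
            start, end, tsd = refined
            length = (end - d) - start
            if not (criteria.ltr_min_len <= length <= criteria.ltr_max_len):
                continue
            if not (criteria.element_min_len <= end - start <= criteria.element_max_len):
                continue
        ltr5 = (start, start + length)
        ltr3 = (end - length, end)
        if ltr5[1] > ltr3[0]:
            continue
        if (start, end) in seen:
            continue
        identity = _pair_identity(seq[slice(*ltr5)], seq[slice(*ltr3)])
        if identity < criteria.min_ltr_identity:
            continue
        seen.add((start, end))
        candidates.append(
            ErvCandidate(chromosome, ltr5, ltr3, identity, tsd)
        )

    # structural pre-score used only for overlap resolution at this stage
    def struct_score(c: ErvCandidate) -> float:
        return criteria.weight_identity * c.identity + (
            criteria.weight_tsd if c.tsd else 0.0
        )

    candidates.sort(key=lambda c: (-struct_score(c), c.begin, c.end))
    kept: list[ErvCandidate] = []
    for c in candidates:
        if all(c.end <= o.begin or c.begin >= o.end for o in kept):
            kept.append(c)
    kept.sort(key=lambda c: c.begin)
    return kept


def _close_run(seq, run, d, k, criteria):
    if len(run) < criteria.min_seeds:
        return []
    ls, le = run[0], run[-1] + k
    left = _xdrop_extend(seq, ls, ls + d, -1, criteria.xdrop)
    right = _xdrop_extend(seq, le - 1, le - 1 + d, +1, criteria.xdrop)
    return [(ls - left, le + right, d)]


def score_and_filter_erv(
    candidates: Iterable[ErvCandidate],
    sequence: str,
    domain_consensi: Mapping[str, str],
    criteria: FullLengthCriteria = FullLengthCriteria(),
) -> list[ErvCandidate]:
    """Attach domain evidence and composite scores; keep fl-ERVs.

    The composite score is ``w_id * ltr_identity + w_tsd * [TSD present] +
    w_dom * mean(gag, pol, env span fractions)`` (defaults 250/50/200, so a
    pristine element scores 500).  An element is retained iff both LTRs are
    present (structural, guaranteed by the detector), at least one internal
    domain span reaches ``erv_domain_min_span``, and score >= threshold
    (boundary retained).
    """
    seq = sequence.upper()
    kept: list[ErvCandidate] = []
    for cand in candidates:
        internal = seq[slice(*cand.internal)]
        spans: dict[str, float] = {d: 0.0 for d in domain_consensi}
        if len(internal) >= criteria.erv_min_orf_bp + 3:
            orfs = find_orfs(internal, criteria.erv_min_orf_bp)
            spans = best_domain_spans(orfs, domain_consensi)
        has_domain = any(v >= criteria.erv_domain_min_span for v in spans.values())
        mean_span = sum(spans.values()) / len(spans) if spans else 0.0
        score = (
            criteria.weight_identity * cand.identity
            + (criteria.weight_tsd if cand.tsd else 0.0)
            + criteria.weight_domains * mean_span
        )
        cand = replace(cand, domain_spans=dict(spans), score=score)
        if has_domain and score >= criteria.erv_min_score:
            kept.append(cand)
    return kept


# ---------------------------------------------------------------------------
# Census
# ---------------------------------------------------------------------------

CATEGORIES = ("fl_erv", "fl_line", "fl_dna")


@dataclass
class FullLengthCensus:
    """Counts of full-length TEs per chromosome and chromosome class."""

    per_chromosome: pd.DataFrame  # chromosome, te_class, category, count
    profile: str = "default"

    def class_counts(self, category: Optional[str] = None) -> dict[str, int]:
        """Counts per pooled class (autosome/Z/W), optionally one category.

        ``category='line_dna'`` pools fl_line + fl_dna; None pools all
        intact-TE categories (the toxicity-index convention).
        """
        df = self.per_chromosome
        if category == "line_dna":
            df = df[df["category"].isin(["fl_line", "fl_dna"])]
        elif category is not None:
            df = df[df["category"] == category]
        out = {"autosome": 0, "Z": 0, "W": 0}
        for _, row in df.iterrows():
            cls = pool_class(row["te_class"])
            if cls in out:
                out[cls] += int(row["count"])
        return out

    def class_table(self) -> pd.DataFrame:
        """Class x category table with a pooled LINE+DNA column."""
        pivot = (
            self.per_chromosome.assign(
                pooled=self.per_chromosome["te_class"].map(pool_class)
            )
            .pivot_table(
                index="pooled", columns="category", values="count",
                aggfunc="sum", fill_value=0,
            )
            .reindex(["autosome", "Z", "W"], fill_value=0)
        )
        for cat in CATEGORIES:
            if cat not in pivot.columns:
                pivot[cat] = 0
        pivot["line_dna"] = pivot["fl_line"] + pivot["fl_dna"]
        pivot.index.name = "te_class"
        return pivot[["fl_erv", "fl_line", "fl_dna", "line_dna"]].astype(int)

    def total(self) -> int:
        return int(self.per_chromosome["count"].sum())


def census(
    calls: Iterable[FullLengthCall],
    genome: GenomeModel,
    profile: str = "default",
) -> FullLengthCensus:
    """Tally full-length calls per chromosome and category."""
    counts: dict[tuple[str, str, str], int] = {}
    for call in calls:
        te_class = genome.get(call.chromosome).te_class
        key = (call.chromosome, te_class, call.category)
        counts[key] = counts.get(key, 0) + 1
    rows = [
        {"chromosome": c, "te_class": tc, "category": cat, "count": n}
        for (c, tc, cat), n in sorted(counts.items())
    ]
    df = pd.DataFrame(rows, columns=["chromosome", "te_class", "category", "count"])
    return FullLengthCensus(df, profile=profile)


# ---------------------------------------------------------------------------
# Genome-level pipeline
# ---------------------------------------------------------------------------

def detect_fulllength(
    genome: GenomeModel,
    hits: Sequence[RepeatHit],
    domain_consensi: Mapping[str, str],
    criteria: FullLengthCriteria = FullLengthCriteria(),
) -> list[FullLengthCall]:
    """Run all three callers across a genome with sequences.

    LINE and DNA insertions are taken from the annotation; ERVs are called
    structurally on each chromosome sequence.  ``domain_consensi`` must
    provide peptides for EN, RT, transposase, gag, pol and env (missing
    entries disable the corresponding caller).
    """
    calls: list[FullLengthCall] = []
    erv_doms = {d: domain_consensi[d] for d in ("gag", "pol", "env")
                if d in domain_consensi}
    for chrom in genome.placed():
        if chrom.sequence is None:
            raise RefugiumError(f"chromosome {chrom.name} has no sequence")
        if erv_doms:
            cands = detect_ltr_elements(chrom.sequence, criteria, chrom.name)
            for erv in score_and_filter_erv(cands, chrom.sequence, erv_doms, criteria):
                calls.append(
                    FullLengthCall(
                        chrom.name, erv.begin, erv.end, "fl_erv",
                        score=erv.score,
                        evidence={
                            "ltr5": erv.ltr5, "ltr3": erv.ltr3,
                            "identity": erv.identity, "tsd": erv.tsd,
                            "domains": erv.domain_spans,
                        },
                    )
                )
    for h in hits:
        if h.chromosome not in genome:
            continue
        chrom = genome.get(h.chromosome)
        if chrom.te_class == "unplaced" or chrom.sequence is None:
            continue
        insertion = chrom.sequence[h.begin : h.end]
        if h.classification_group == "LINE" and {"EN", "RT"} <= set(domain_consensi):
            ok, ev = call_fulllength_line(
                insertion, criteria, domain_consensi["EN"], domain_consensi["RT"]
            )
            if ok:
                calls.append(
                    FullLengthCall(h.chromosome, h.begin, h.end, "fl_line",
                                   family=h.family, evidence=ev)
                )
        elif h.classification_group == "DNA" and "transposase" in domain_consensi:
            ok, ev = call_fulllength_dna(
                insertion, criteria, domain_consensi["transposase"]
            )
            if ok:
                calls.append(
                    FullLengthCall(h.chromosome, h.begin, h.end, "fl_dna",
                                   family=h.family, evidence=ev)
                )
    calls.sort(key=lambda c: (c.chromosome, c.begin, c.end, c.category))
    return calls


def write_calls_gff3(calls: Iterable[FullLengthCall], path) -> None:
    """GFF3 export with LTR/TSD child features for structural fl-ERV calls."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, c in enumerate(calls, start=1):
            eid = f"flte{i}"
            fh.write(
                f"{c.chromosome}\trefugium\tmobile_genetic_element\t{c.begin + 1}\t"
                f"{c.end}\t{c.score:.1f}\t+\t.\tID={eid};category={c.category};"
                f"Name={c.family or eid}\n"
            )
            if c.category == "fl_erv" and "ltr5" in c.evidence:
                l5, l3 = c.evidence["ltr5"], c.evidence["ltr3"]
                fh.write(
                    f"{c.chromosome}\trefugium\tfive_prime_LTR\t{l5[0] + 1}\t{l5[1]}"
                    f"\t.\t+\t.\tParent={eid}\n"
                )
                fh.write(
                    f"{c.chromosome}\trefugium\tthree_prime_LTR\t{l3[0] + 1}\t{l3[1]}"
                    f"\t.\t+\t.\tParent={eid}\n"
                )
                if l5[1] < l3[0]:
                    fh.write(
                        f"{c.chromosome}\trefugium\tinternal\t{l5[1] + 1}\t{l3[0]}"
                        f"\t.\t+\t.\tParent={eid}\n"
                    )
                if c.evidence.get("tsd"):
                    t = len(c.evidence["tsd"])
                    fh.write(
                        f"{c.chromosome}\trefugium\tTSD\t{c.begin - t + 1}\t{c.begin}"
                        f"\t.\t+\t.\tParent={eid};seq={c.evidence['tsd']}\n"
                    )
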