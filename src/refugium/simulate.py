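"""Deterministic simulator of genomes with planted TEs and read cohorts.

The generator emulates the data a sex-chromosome TE survey consumes:

* chromosomes of three classes (autosomes, Z, W) built from random
  background sequence;
* planted full-length ERVs (TSD + LTR + internal gag/pol/env ORFs + LTR +
  TSD), solo-LTRs (one LTR between its TSD pair, the product of
  inter-LTR recombination), internal-only truncated fragments, full-length
  LINEs (EN+RT ORF) and DNA transposons (transposase ORF);
* copies mutated to a target Kimura 2-parameter distance K with a
  transition/transversion ratio kappa, inverting the K2P expectation to
  choose the substitution dose (stop codons are never introduced into the
  ORFs of elements meant to stay intact);
* male/female genomic and RNA read cohorts where W-restricted SNVs planted
  on W-linked copies appear only in female reads;
* a machine-readable truth manifest (planted coordinates, expected census,
  expected W-linked variant set) for recovery testing.

A single integer seed drives everything through fixed substreams, so the
same seed gives byte-identical outputs and adding new outputs never
perturbs existing ones.  Copies are planted on the forward strand and
annotations stay interval-disjoint (no nested insertions), which keeps the
census ground truth unambiguous.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
from scipy.optimize import brentq

from .landscape import k2p_from_proportions
from .model import (
    ChromosomeRecord,
    ConsensusLibrary,
    GenomeModel,
    RefugiumError,
    RepeatHit,
)

_SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]
_STOPS = {"TAA", "TAG", "TGA"}
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}


# ---------------------------------------------------------------------------
# Plans
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FamilyPlan:
    """One consensus family to synthesize."""

    name: str
    kind: str  # erv | line | dna
    classification: str
    ltr_len: int = 300
    cds_divergence: float = 0.08  # nucleotide divergence from the shared base CDS


@dataclass(frozen=True)
class ElementPlan:
    """Plant ``count`` copies of one category on one chromosome class."""

    category: str  # fl_erv | solo_ltr | truncated | fl_line | fl_dna
    family: str
    te_class: str
    count: int
    divergence_k: float = 0.0
    fragment_len: Optional[int] = None  # truncated only; default breaks domains
    transcribed_female: bool = False
    transcribed_male: bool = False


@dataclass(frozen=True)
class VariantPlan:
    """Plant ``count`` SNVs (vs the family consensus) on a carrier class."""

    family: str
    carrier: str  # "W" or "autosome"
    count: int
    transcribed: bool = False


@dataclass(frozen=True)
class ReadPlan:
    coverage: float = 30.0  # target per-base depth on diploid autosomes
    read_len: int = 100
    error_rate: float = 0.0
    n_female_genomic: int = 3
    n_male_genomic: int = 3
    n_female_rna: int = 1
    n_male_rna: int = 1


@dataclass(frozen=True)
class SimulationConfig:
    chromosomes: tuple[tuple[str, str, int], ...]  # (name, te_class, length)
    families: tuple[FamilyPlan, ...]
    elements: tuple[ElementPlan, ...] = ()
    variants: tuple[VariantPlan, ...] = ()
    reads: ReadPlan = ReadPlan()
    density_targets: tuple[tuple[str, float], ...] = ()  # (te_class, pct)
    filler_divergence_k: float = 0.15
    kappa: float = 2.0
    sex_system: str = "ZW"
    margin: int = 500  # minimum gap between planted annotations

    def __post_init__(self) -> None:
        for _, pct in self.density_targets:
            if not (0 <= pct <= 100):
                raise RefugiumError("density targets are percentages in [0, 100]")
        for e in self.elements:
            if e.count < 0:
                raise RefugiumError("negative element count")


# ---------------------------------------------------------------------------
# Truth
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedElement:
    chromosome: str
    begin: int
    end: int
    category: str
    family: str
    divergence_pct: float
    ltr_len: Optional[int] = None
    tsd: Optional[str] = None
    consensus_begin: int = 0  # consensus interval this copy represents
    consensus_end: int = 0
    transcribed_female: bool = False
    transcribed_male: bool = False


@dataclass(frozen=True)
class PlantedVariant:
    family: str
    position: int
    ref: str
    alt: str
    carrier: str
    transcribed: bool


@dataclass
class TruthManifest:
    elements: list[PlantedElement]
    variants: list[PlantedVariant]
    expected_census: dict  # te_class -> {category: count}
    class_lengths: dict

    @property
    def expected_w_linked(self) -> set[tuple[str, int, str]]:
        return {
            (v.family, v.position, v.alt)
            for v in self.variants
            if v.carrier == "W"
        }

    def to_json(self, path: Union[str, Path]) -> None:
        payload = {
            "elements": [dataclasses.asdict(e) for e in self.elements],
            "variants": [dataclasses.asdict(v) for v in self.variants],
            "expected_census": self.expected_census,
            "class_lengths": self.class_lengths,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "TruthManifest":
        payload = json.loads(Path(path).read_text())
        return cls(
            elements=[PlantedElement(**e) for e in payload["elements"]],
            variants=[PlantedVariant(**v) for v in payload["variants"]],
            expected_census=payload["expected_census"],
            class_lengths=payload["class_lengths"],
        )


# ---------------------------------------------------------------------------
# Sequence-level helpers
# ---------------------------------------------------------------------------

def _rng(seed: int, *stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, *stream])


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])


def random_coding(rng: np.random.Generator, n_codons: int) -> str:
    idx = rng.integers(0, len(_SENSE_CODONS), size=n_codons)
    return "".join(_SENSE_CODONS[i] for i in idx)


def mismatch_fraction_for_k(k_target: float, kappa: float = 2.0) -> float:
    """Invert the K2P expectation: the raw mismatch proportion d such that
    single-hit substitutions at transition share kappa/(kappa+2) give
    distance ``k_target``."""
    if k_target < 0:
        raise RefugiumError("negative divergence target")
    if k_target == 0:
        return 0.0

    def k_of_d(d: float) -> float:
        p = d * kappa / (kappa + 2.0)
        q = d * 2.0 / (kappa + 2.0)
        res = k2p_from_proportions(p, q)
        return res.distance if res.defined else np.inf

    d_sat = (kappa + 2.0) / (2.0 * kappa + 2.0) * 0.999
    if k_of_d(d_sat) < k_target:
        raise RefugiumError(f"divergence target K={k_target} is beyond saturation")
    return float(brentq(lambda d: k_of_d(d) - k_target, 1e-12, d_sat))


def _makes_stop(s: list[str], pos: int, protected: Sequence[tuple[int, int]]) -> bool:
    for start, end in protected:
        if start <= pos < end:
            cs = start + ((pos - start) // 3) * 3
            if cs + 3 <= end and "".join(s[cs : cs + 3]) in _STOPS:
                return True
            return False
    return False


def mutate_to_k(
    seq: str,
    k_target: float,
    kappa: float,
    rng: np.random.Generator,
    protected: Sequence[tuple[int, int]] = (),
) -> str:
    """Mutate a copy to a target K2P distance from its source.

    Substitutes ``round(d * L)`` distinct sites (d from
    :func:`mismatch_fraction_for_k`), each a transition with probability
    kappa/(kappa+2), else a random transversion.  Inside ``protected``
    frames a substitution that would create an in-frame stop codon is
    replaced by the next non-stop alternative.
    """
    if k_target <= 0:
        return seq
    d = mismatch_fraction_for_k(k_target, kappa)
    n = len(seq)
    m = int(round(d * n))
    if m == 0:
        return seq
    positions = rng.choice(n, size=m, replace=False)
    s = list(seq)
    for pos in sorted(int(p) for p in positions):
        base = s[pos]
        if base not in "ACGT":
            continue
        tv = list(_TRANSVERSIONS[base])
        if rng.random() < kappa / (kappa + 2.0):
            order = [_TRANSITION[base]] + ([tv[0], tv[1]] if rng.random() < 0.5
                                           else [tv[1], tv[0]])
        else:
            first = tv[int(rng.integers(0, 2))]
            second = tv[1] if first == tv[0] else tv[0]
            order = [first, second, _TRANSITION[base]]
        for cand in order:
            s[pos] = cand
            if not _makes_stop(s, pos, protected):
                break
            s[pos] = base
    return "".join(s)


def _realized_divergence(copy: str, source: str) -> float:
    mism = sum(a != b for a, b in zip(copy, source))
    return 100.0 * mism / len(copy)


# ---------------------------------------------------------------------------
# Library
# ---------------------------------------------------------------------------

@dataclass
class FamilyMeta:
    kind: str
    ltr_len: int
    internal: tuple[int, int]  # consensus coords of the internal region
    cds: tuple[int, int]  # consensus coords of the coding stretch
    orf_frames: tuple[tuple[int, int], ...]  # stop-protected frames
    truncated_slice: tuple[int, int]  # default domain-breaking fragment


@dataclass
class LibraryBundle:
    library: ConsensusLibrary
    domains: dict[str, str]  # EN/RT/transposase/gag/pol/env peptides
    meta: dict[str, FamilyMeta]


def make_library(config: SimulationConfig, seed: int) -> LibraryBundle:
    """Synthesize consensus families plus the matching domain peptides.

    ERV families share one ancestral gag/pol/env coding region, then each
    family's copy of it is diverged by ``cds_divergence`` so that reads map
    uniquely to their own family while the shared domain peptides still
    align with near-complete spans.  LINE families carry a single EN+RT
    ORF; DNA families a transposase ORF.
    """
    from Bio.Seq import Seq

    rng = _rng(seed, 1)
    gag = random_coding(rng, 300)
    pol = random_coding(rng, 500)
    env = random_coding(rng, 400)
    en = random_coding(rng, 250)
    rt = random_coding(rng, 350)
    tpase = random_coding(rng, 400)
    domains = {
        "gag": str(Seq(gag).translate()),
        "pol": str(Seq(pol).translate()),
        "env": str(Seq(env).translate()),
        "EN": str(Seq(en).translate()),
        "RT": str(Seq(rt).translate()),
        "transposase": str(Seq(tpase).translate()),
    }

    lib = ConsensusLibrary()
    meta: dict[str, FamilyMeta] = {}
    for fi, fam in enumerate(config.families):
        frng = _rng(seed, 2, fi)
        if fam.kind == "erv":
            ltr = random_seq(frng, fam.ltr_len)
            utr5 = random_seq(frng, 100)
            utr3 = random_seq(frng, 100)
            cds = gag + "TAA" + pol + "TAA" + env
            frames_rel = (
                (0, len(gag)),
                (len(gag) + 3, len(gag) + 3 + len(pol)),
                (len(gag) + len(pol) + 6, len(cds)),
            )
            cds = mutate_to_k(
                cds, fam.cds_divergence, config.kappa, frng, protected=frames_rel
            )
            internal = utr5 + cds + utr3
            consensus = ltr + internal + ltr
            cds_start = fam.ltr_len + len(utr5)
            frames = tuple((cds_start + a, cds_start + b) for a, b in frames_rel)
            # fragment from mid-gag to mid-pol: no complete domain survives
            t0 = cds_start + len(gag) // 2
            t1 = cds_start + len(gag) + 3 + len(pol) // 2
            meta[fam.name] = FamilyMeta(
                kind="erv",
                ltr_len=fam.ltr_len,
                internal=(fam.ltr_len, fam.ltr_len + len(internal)),
                cds=(cds_start, cds_start + len(cds)),
                orf_frames=frames,
                truncated_slice=(t0, t1),
            )
        elif fam.kind == "line":
            utr5 = random_seq(frng, 150)
            utr3 = random_seq(frng, 150)
            cds = mutate_to_k(
                en + rt, fam.cds_divergence, config.kappa, frng,
                protected=((0, len(en) + len(rt)),),
            )
            consensus = utr5 + cds + utr3
            cds_start = len(utr5)
            meta[fam.name] = FamilyMeta(
                kind="line",
                ltr_len=0,
                internal=(0, len(consensus)),
                cds=(cds_start, cds_start + len(cds)),
                orf_frames=((cds_start, cds_start + len(cds)),),
                # 3'-half fragment: RT present but EN lost
                truncated_slice=(cds_start + len(en), len(consensus)),
            )
        elif fam.kind == "dna":
            utr5 = random_seq(frng, 100)
            utr3 = random_seq(frng, 100)
            cds = mutate_to_k(
                tpase, fam.cds_divergence, config.kappa, frng,
                protected=((0, len(tpase)),),
            )
            consensus = utr5 + cds + utr3
            cds_start = len(utr5)
            meta[fam.name] = FamilyMeta(
                kind="dna",
                ltr_len=0,
                internal=(0, len(consensus)),
                cds=(cds_start, cds_start + len(cds)),
                orf_frames=((cds_start, cds_start + len(cds)),),
                truncated_slice=(cds_start + len(tpase) // 2, len(consensus)),
            )
        else:
            raise RefugiumError(f"unknown family kind {fam.kind!r}")
        lib.add(fam.name, consensus, fam.classification)
    return LibraryBundle(lib, domains, meta)


# ---------------------------------------------------------------------------
# Genome assembly
# ---------------------------------------------------------------------------

@dataclass
class SimulatedData:
    """Everything the simulator knows about one synthetic dataset."""

    genome: GenomeModel  # female assembly (carries the W)
    male_genome: GenomeModel
    hits: list[RepeatHit]
    library: ConsensusLibrary
    domains: dict[str, str]
    manifest: TruthManifest
    config: SimulationConfig
    seed: int


def _build_copy(
    consensus: str,
    meta: FamilyMeta,
    plan: ElementPlan,
    kappa: float,
    rng: np.random.Generator,
) -> tuple[str, Optional[str], int, int]:
    """Return (planted sequence, TSD or None, consensus_begin, consensus_end)."""
    if plan.category == "fl_erv":
        if meta.kind != "erv":
            raise RefugiumError("fl_erv plan on a non-ERV family")
        seq = mutate_to_k(consensus, plan.divergence_k, kappa, rng,
                          protected=meta.orf_frames)
        tsd = random_seq(rng, int(rng.integers(4, 7)))
        return seq, tsd, 0, len(consensus)
    if plan.category == "solo_ltr":
        ltr = consensus[: meta.ltr_len]
        seq = mutate_to_k(ltr, plan.divergence_k, kappa, rng)
        tsd = random_seq(rng, int(rng.integers(4, 7)))
        return seq, tsd, 0, meta.ltr_len
    if plan.category == "truncated":
        t0, t1 = meta.truncated_slice
        if plan.fragment_len is not None:
            t1 = min(t0 + plan.fragment_len, len(consensus))
        frag = consensus[t0:t1]
        seq = mutate_to_k(frag, plan.divergence_k, kappa, rng)
        return seq, None, t0, t1
    if plan.category in ("fl_line", "fl_dna"):
        seq = mutate_to_k(consensus, plan.divergence_k, kappa, rng,
                          protected=meta.orf_frames)
        tsd = random_seq(rng, int(rng.integers(4, 7)))
        return seq, tsd, 0, len(consensus)
    raise RefugiumError(f"unknown element category {plan.category!r}")


def _out_family(plan_category: str, family: str, meta: FamilyMeta) -> str:
    if meta.kind == "erv" and plan_category == "solo_ltr":
        return f"{family}_LTR"
    if meta.kind == "erv" and plan_category == "truncated":
        return f"{family}_I"
    return family


def plant_and_mutate(config: SimulationConfig, seed: int,
                     bundle: Optional[LibraryBundle] = None) -> SimulatedData:
    """Build the synthetic assembly: background + planted, mutated copies.

    Elements are laid out left to right per chromosome with random gaps (a
    fixed minimum margin keeps annotations disjoint); an overfull plan
    raises.  Density targets are then topped up with truncated filler
    fragments until each class reaches its requested TE percentage.
    """
    if bundle is None:
        bundle = make_library(config, seed)
    lib, meta_by_fam = bundle.library, bundle.meta

    chrom_names = [n for n, _, _ in config.chromosomes]
    classes = {n: c for n, c, _ in config.chromosomes}
    lengths = {n: ln for n, _, ln in config.chromosomes}
    by_class: dict[str, list[str]] = {}
    for n, c, _ in config.chromosomes:
        by_class.setdefault(c, []).append(n)

    # expand class-level plans to per-chromosome copy requests (round-robin)
    requests: dict[str, list[ElementPlan]] = {n: [] for n in chrom_names}
    for plan in config.elements:
        targets = by_class.get(plan.te_class)
        if not targets:
            raise RefugiumError(f"no chromosome of class {plan.te_class!r}")
        for i in range(plan.count):
            requests[targets[i % len(targets)]].append(plan)

    # density top-up with filler fragments
    filler_fam = config.families[0].name
    for te_class, pct in config.density_targets:
        targets = by_class.get(te_class)
        if not targets:
            raise RefugiumError(f"no chromosome of class {te_class!r}")
        class_len = sum(lengths[n] for n in targets)
        want_bp = int(round(class_len * pct / 100.0))
        have_bp = 0
        for n in targets:
            for plan in requests[n]:
                have_bp += _planned_len(plan, lib, meta_by_fam)
        deficit = want_bp - have_bp
        ti = 0
        fmeta = meta_by_fam[filler_fam]
        max_frag = fmeta.truncated_slice[1] - fmeta.truncated_slice[0]
        while deficit > 0:
            frag_len = min(deficit, max_frag)
            if frag_len < 30:
                break
            requests[targets[ti % len(targets)]].append(
                ElementPlan("truncated", filler_fam, te_class, 1,
                            divergence_k=config.filler_divergence_k,
                            fragment_len=frag_len)
            )
            deficit -= frag_len
            ti += 1

    sequences: dict[str, str] = {}
    planted: list[PlantedElement] = []
    hits: list[RepeatHit] = []
    frag_id = 0
    for ci, name in enumerate(chrom_names):
        rng = _rng(seed, 3, ci)
        length = lengths[name]
        background = np.array(list(random_seq(rng, length)))
        items = []
        for plan in requests[name]:
            consensus = lib.sequence(plan.family)
            fmeta = meta_by_fam[plan.family]
            seq, tsd, c0, c1 = _build_copy(consensus, fmeta, plan, config.kappa, rng)
            items.append((plan, seq, tsd, c0, c1))
        occupied = sum(len(s) + 2 * (len(t) if t else 0) for _, s, t, _, _ in items)
        free = length - occupied - config.margin * (len(items) + 1)
        if free < 0:
            raise RefugiumError(
                f"chromosome {name}: plan needs {occupied} bp + margins, "
                f"only {length} available"
            )
        if items:
            gaps = rng.multinomial(free, np.ones(len(items) + 1) / (len(items) + 1))
        else:
            gaps = [free]
        cursor = 0
        for gi, (plan, seq, tsd, c0, c1) in enumerate(items):
            cursor += config.margin + int(gaps[gi])
            start = cursor
            if tsd:
                background[start : start + len(tsd)] = list(tsd)
                start += len(tsd)
            end = start + len(seq)
            background[start:end] = list(seq)
            if tsd:
                background[end : end + len(tsd)] = list(tsd)
            cursor = end + (len(tsd) if tsd else 0)
            consensus = lib.sequence(plan.family)
            div = _realized_divergence(seq, consensus[c0:c1])
            fmeta = meta_by_fam[plan.family]
            planted.append(
                PlantedElement(
                    chromosome=name, begin=start, end=end,
                    category=plan.category, family=plan.family,
                    divergence_pct=div,
                    ltr_len=fmeta.ltr_len if fmeta.kind == "erv" else None,
                    tsd=tsd, consensus_begin=c0, consensus_end=c1,
                    transcribed_female=plan.transcribed_female,
                    transcribed_male=plan.transcribed_male,
                )
            )
            frag_id += 1
            hits.extend(
                _annotation_rows(name, start, end, plan, lib, fmeta, div, frag_id)
            )
        sequences[name] = "".join(background)

    # plant variants (after all copies exist; divergence plans for variant
    # carriers should be 0 so consensus positions still hold the reference)
    variants: list[PlantedVariant] = []
    vrng = _rng(seed, 4)
    chrom_arrays = {n: np.array(list(s)) for n, s in sequences.items()}
    used_positions: dict[str, set[int]] = {}
    for vplan in config.variants:
        consensus = lib.sequence(vplan.family)
        fmeta = meta_by_fam[vplan.family]
        cds0, cds1 = fmeta.cds
        taken = used_positions.setdefault(vplan.family, set())
        carriers = [
            e for e in planted
            if e.family == vplan.family and e.category in
            ("fl_erv", "fl_line", "fl_dna")
            and classes[e.chromosome] == ("W" if vplan.carrier == "W" else "autosome")
        ]
        if vplan.carrier == "autosome":
            carriers = carriers[:1]  # one autosomal copy carries the variant
        if not carriers:
            raise RefugiumError(
                f"no {vplan.carrier} copies of {vplan.family} to carry variants"
            )
        for _ in range(vplan.count):
            while True:
                pos = int(vrng.integers(cds0, cds1))
                if pos not in taken:
                    taken.add(pos)
                    break
            ref = consensus[pos]
            alt = _TRANSITION[ref]
            for copy in carriers:
                gpos = copy.begin + (pos - copy.consensus_begin)
                chrom_arrays[copy.chromosome][gpos] = alt
            variants.append(
                PlantedVariant(vplan.family, pos, ref, alt, vplan.carrier,
                               vplan.transcribed)
            )
    sequences = {n: "".join(a) for n, a in chrom_arrays.items()}

    expected_census: dict[str, dict[str, int]] = {}
    for plan in config.elements:
        if plan.category in ("fl_erv", "fl_line", "fl_dna"):
            cls = expected_census.setdefault(plan.te_class, {})
            cls[plan.category] = cls.get(plan.category, 0) + plan.count

    class_lengths: dict[str, int] = {}
    for n, c, ln in config.chromosomes:
        class_lengths[c] = class_lengths.get(c, 0) + ln

    female = GenomeModel(
        [ChromosomeRecord(n, classes[n], lengths[n], sequences[n])
         for n in chrom_names],
        config.sex_system,
    )
    male = GenomeModel(
        [ChromosomeRecord(n, classes[n], lengths[n], sequences[n])
         for n in chrom_names if classes[n] != "W"],
        config.sex_system,
    )
    manifest = TruthManifest(planted, variants, expected_census, class_lengths)
    return SimulatedData(female, male, hits, lib, bundle.domains, manifest,
                         config, seed)


def _planned_len(plan: ElementPlan, lib: ConsensusLibrary, meta) -> int:
    consensus_len = len(lib.sequence(plan.family))
    fmeta = meta[plan.family]
    if plan.category == "solo_ltr":
        return fmeta.ltr_len
    if plan.category == "truncated":
        t0, t1 = fmeta.truncated_slice
        return plan.fragment_len if plan.fragment_len else t1 - t0
    return consensus_len


def _annotation_rows(name, start, end, plan, lib, fmeta, div, frag_id):
    """RepeatMasker-style rows for one planted copy (ERVs split into
    LTR/internal/LTR fragments sharing one ID)."""
    cls = lib.classification(plan.family)
    fam = _out_family(plan.category, plan.family, fmeta)
    link = str(frag_id)
    if plan.category == "fl_erv":
        L = fmeta.ltr_len
        return [
            RepeatHit(name, start, start + L, "+", f"{plan.family}_LTR", cls,
                      div, link),
            RepeatHit(name, start + L, end - L, "+", f"{plan.family}_I", cls,
                      div, link),
            RepeatHit(name, end - L, end, "+", f"{plan.family}_LTR", cls,
                      div, link),
        ]
    return [RepeatHit(name, start, end, "+", fam, cls, div, link)]


# ---------------------------------------------------------------------------
# Read cohorts
# ---------------------------------------------------------------------------

Read = tuple[str, str, str]  # name, sequence, quality


def _sample_reads_from_pool(
    pool: list[tuple[str, int, int, int]],  # (chrom, begin, end, multiplicity)
    genome: GenomeModel,
    n_reads: int,
    read_len: int,
    error_rate: float,
    rng: np.random.Generator,
    name_prefix: str,
) -> list[Read]:
    weights = np.array([(e - b) * m for _, b, e, m in pool], dtype=float)
    if weights.sum() <= 0:
        return []
    counts = rng.multinomial(n_reads, weights / weights.sum())
    reads: list[Read] = []
    idx = 0
    bases = np.array(list("ACGT"))
    for (chrom, b, e, _), k in zip(pool, counts):
        if e - b < read_len:
            raise RefugiumError("read length exceeds a sampling interval")
        seq = genome.get(chrom).sequence
        starts = rng.integers(b, e - read_len + 1, size=k)
        flips = rng.random(k) < 0.5
        for s, flip in zip(starts, flips):
            r = seq[s : s + read_len]
            if error_rate > 0:
                arr = np.array(list(r))
                errs = np.nonzero(rng.random(read_len) < error_rate)[0]
                for p in errs:
                    choices = [c for c in "ACGT" if c != arr[p]]
                    arr[p] = choices[int(rng.integers(0, 3))]
                r = "".join(arr)
            if flip:
                r = r.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]
            reads.append((f"{name_prefix}:{idx}", r, "I" * read_len))
            idx += 1
    return reads


def simulate_reads(
    sim: SimulatedData, seed: Optional[int] = None
) -> tuple[dict[str, list[Read]], "pd.DataFrame"]:
    """Simulate genomic and RNA cohorts from a planted assembly.

    Genomic samples draw uniformly from the sex-appropriate diploid
    haplotype pool (female 2A + Z + W, male 2A + 2Z), so the diploid
    autosomal depth matches ``coverage`` and sex-hemizygous chromosomes get
    half of it.  RNA samples draw only from elements marked transcribed
    for that sex.  W-restricted variants therefore appear in female reads
    only.
    """
    import pandas as pd

    seed = sim.seed if seed is None else seed
    plan = sim.config.reads
    samples: dict[str, list[Read]] = {}
    rows = []

    def genomic_pool(sex: str) -> list[tuple[str, int, int, int]]:
        pool = []
        for c in sim.genome:
            if c.te_class == "W":
                mult = 1 if sex == "female" else 0
            elif c.te_class in ("Z", "X"):
                mult = 1 if sex == "female" else 2
            else:
                mult = 2
            if mult:
                pool.append((c.name, 0, c.length, mult))
        return pool

    def rna_pool(sex: str) -> list[tuple[str, int, int, int]]:
        key = "transcribed_female" if sex == "female" else "transcribed_male"
        return [
            (e.chromosome, e.begin, e.end, 1)
            for e in sim.manifest.elements
            if getattr(e, key)
        ]

    stream = 0
    for sex, n_g, n_r in (
        ("female", plan.n_female_genomic, plan.n_female_rna),
        ("male", plan.n_male_genomic, plan.n_male_rna),
    ):
        gpool = genomic_pool(sex)
        pool_len = sum((e - b) * m for _, b, e, m in gpool)
        n_reads = int(round(plan.coverage * pool_len / (plan.read_len * 2)))
        for i in range(n_g):
            sid = f"{sex}_g{i + 1}"
            stream += 1
            samples[sid] = _sample_reads_from_pool(
                gpool, sim.genome, n_reads, plan.read_len, plan.error_rate,
                _rng(seed, 5, stream), sid,
            )
            rows.append({"id": sid, "sex": sex, "assay": "genomic", "path": "-"})
        rpool = rna_pool(sex)
        rlen = sum(e - b for _, b, e, _ in rpool)
        n_rna = int(round(plan.coverage * rlen / plan.read_len)) if rlen else 0
        for i in range(n_r):
            sid = f"{sex}_rna{i + 1}"
            stream += 1
            samples[sid] = _sample_reads_from_pool(
                rpool, sim.genome, n_rna, plan.read_len, plan.error_rate,
                _rng(seed, 6, stream), sid,
            ) if rpool else []
            rows.append({"id": sid, "sex": sex, "assay": "RNA", "path": "-"})
    sheet = pd.DataFrame(rows, columns=["id", "sex", "assay", "path"])
    return samples, sheet


def write_fastq(reads: Sequence[Read], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        for name, seq, qual in reads:
            fh.write(f"@{name}\n{seq}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# Scenario presets (the study conditions of the recovery experiments)
# ---------------------------------------------------------------------------

def default_scenario() -> SimulationConfig:
    """Structural-recovery scenario: ~2 Mb, 32 fl-ERVs planted (10 A, 2 Z,
    20 W), 20 solo-LTRs and 20 truncated fragments, error-free copies."""
    fam = FamilyPlan("ERV_sim1", "erv", "LTR/ERV1")
    return SimulationConfig(
        chromosomes=(
            ("chr1", "autosome", 600_000),
            ("chr2", "autosome", 500_000),
            ("chr3", "autosome", 400_000),
            ("chrZ", "Z", 300_000),
            ("chrW", "W", 200_000),
        ),
        families=(fam,),
        elements=(
            ElementPlan("fl_erv", "ERV_sim1", "autosome", 10),
            ElementPlan("fl_erv", "ERV_sim1", "Z", 2),
            ElementPlan("fl_erv", "ERV_sim1", "W", 20),
            ElementPlan("solo_ltr", "ERV_sim1", "autosome", 8),
            ElementPlan("solo_ltr", "ERV_sim1", "Z", 2),
            ElementPlan("solo_ltr", "ERV_sim1", "W", 10),
            ElementPlan("truncated", "ERV_sim1", "autosome", 8),
            ElementPlan("truncated", "ERV_sim1", "Z", 2),
            ElementPlan("truncated", "ERV_sim1", "W", 10),
        ),
    )


def cohort_scenario() -> SimulationConfig:
    """SNV-cohort scenario: 3 females + 3 males at 30x on a small genome;
    12 W-restricted SNVs (7 in a transcribed family) and 8 autosomal SNVs,
    error-free so the W-linked truth set is exact."""
    return SimulationConfig(
        chromosomes=(
            ("chr1", "autosome", 40_000),
            ("chrZ", "Z", 25_000),
            ("chrW", "W", 25_000),
        ),
        families=(
            FamilyPlan("ERV_simA", "erv", "LTR/ERVL"),
            FamilyPlan("ERV_simW1", "erv", "LTR/ERV1"),
            FamilyPlan("ERV_simW2", "erv", "LTR/ERVK"),
        ),
        elements=(
            ElementPlan("fl_erv", "ERV_simA", "autosome", 2,
                        transcribed_female=True, transcribed_male=True),
            ElementPlan("fl_erv", "ERV_simA", "Z", 1),
            ElementPlan("fl_erv", "ERV_simW1", "autosome", 1),
            ElementPlan("fl_erv", "ERV_simW1", "W", 2,
                        transcribed_female=True),
            ElementPlan("fl_erv", "ERV_simW2", "autosome", 1),
            ElementPlan("fl_erv", "ERV_simW2", "W", 2),
        ),
        variants=(
            VariantPlan("ERV_simW1", "W", 7, transcribed=True),
            VariantPlan("ERV_simW2", "W", 5, transcribed=False),
            VariantPlan("ERV_simA", "autosome", 8),
        ),
    )


def density_scenario() -> SimulationConfig:
    """Density scenario: one chromosome per class with planted TE
    densities of 5, 10 and 60 percent."""
    return SimulationConfig(
        chromosomes=(
            ("chr1", "autosome", 100_000),
            ("chrZ", "Z", 100_000),
            ("chrW", "W", 100_000),
        ),
        families=(FamilyPlan("ERV_sim1", "erv", "LTR/ERV1"),),
        density_targets=(("autosome", 5.0), ("Z", 10.0), ("W", 60.0)),
    )


# ---------------------------------------------------------------------------
# File bundle
# ---------------------------------------------------------------------------

def write_bundle(sim: SimulatedData, outdir: Union[str, Path],
                 with_reads: bool = False) -> dict[str, Path]:
    """Write the simulated dataset as plain-text files.

    Emits female/male FASTA, the consensus library and domain peptides,
    a RepeatMasker-style ``.out``, the truth manifest JSON and (optionally)
    per-sample FASTQ plus a sample sheet.  Returns the paths written.
    """
    from . import io as rio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["female_fasta"] = outdir / "female.fa"
    rio.write_fasta({c.name: c.sequence for c in sim.genome}, paths["female_fasta"])
    paths["male_fasta"] = outdir / "male.fa"
    rio.write_fasta({c.name: c.sequence for c in sim.male_genome},
                    paths["male_fasta"])
    paths["library"] = outdir / "library.fa"
    rio.write_consensus_library(sim.library, paths["library"])
    paths["domains"] = outdir / "domains.faa"
    rio.write_fasta(sim.domains, paths["domains"])
    paths["annotation"] = outdir / "annotation.out"
    rio.write_repeatmasker_out(sim.hits, paths["annotation"])
    paths["truth"] = outdir / "truth.json"
    sim.manifest.to_json(paths["truth"])

    if with_reads:
        samples, sheet = simulate_reads(sim)
        for sid, reads in samples.items():
            p = outdir / f"{sid}.fastq"
            write_fastq(reads, p)
            sheet.loc[sheet["id"] == sid, "path"] = str(p)
            paths[f"reads_{sid}"] = p
        paths["sample_sheet"] = outdir / "samples.tsv"
        sheet.to_csv(paths["sample_sheet"], sep="\t", index=False)
    return paths
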