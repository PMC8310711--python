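"""Readers and writers for the standard formats the toolkit touches.

FASTA goes through Biopython; RepeatMasker ``.out`` (15-column dialect),
BED6 and GFF3 are simple enough that explicit line-level code with located
error messages serves better than a generic parser.  All conversions between
the 1-based inclusive conventions of ``.out``/GFF3 and the package's internal
0-based half-open coordinates happen here and nowhere else.
"""

from __future__ import annotations

import re
import sys
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import ConsensusLibrary, GenomeModel, RefugiumError, RepeatHit

PathLike = Union[str, Path]

#: Default chromosome-class rules: first matching pattern wins.
DEFAULT_CHROM_RULES: list[tuple[str, str]] = [
    (r"(?i)^(chr)?z$", "Z"),
    (r"(?i)^(chr)?w$", "W"),
    (r"(?i)^(chr)?x$", "X"),
    (r"(?i)^(chr)?y$", "Y"),
    (r"(?i)^(chr)?(\d+[a-z]?)$", "autosome"),
    (r"(?i)^(chr)?lge?\d+", "autosome"),
]


def read_fasta(path: PathLike) -> dict[str, str]:
    """Read a multi-record FASTA into an ordered ``{name: sequence}`` map.

    Names are the first whitespace-delimited token of each header; sequences
    are uppercased with U mapped to T (soft-masked lowercase accepted).
    Raises on an empty file or duplicate names.
    """
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise RefugiumError(f"{path}: duplicate FASTA record {rec.id!r}")
        out[rec.id] = str(rec.seq).upper().replace("U", "T")
    if not out:
        raise RefugiumError(f"{path}: no FASTA records found")
    return out


def write_fasta(sequences: Mapping[str, str], path: PathLike, width: int = 70) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")
    del width  # Biopython wraps at 60; kept for signature stability


def read_consensus_library(
    path: PathLike, classifications: Optional[Mapping[str, str]] = None
) -> ConsensusLibrary:
    """Read a TE consensus FASTA.

    Classification labels are taken from a ``family#CLASS/Subclass`` header
    convention (RepeatMasker library style) or from the ``classifications``
    mapping; unlabelled families get ``Unknown``.
    """
    lib = ConsensusLibrary()
    for name, seq in read_fasta(path).items():
        if "#" in name:
            family, cls = name.split("#", 1)
        else:
            family, cls = name, (classifications or {}).get(name, "Unknown")
        lib.add(family, seq, cls)
    return lib


def write_consensus_library(lib: ConsensusLibrary, path: PathLike) -> None:
    write_fasta(
        {f"{fam}#{cls}": seq for fam, (seq, cls) in lib.entries.items()}, path
    )


# ---------------------------------------------------------------------------
# RepeatMasker .out
# ---------------------------------------------------------------------------

_OUT_HEADER = (
    "   SW  perc perc perc  query     position in query     matching"
    "       repeat           position in repeat\n"
    "score  div. del. ins.  sequence  begin  end   (left)    repeat"
    "         class/family   begin  end    (left)  ID\n\n"
)


def parse_repeatmasker_out(path: PathLike) -> list[RepeatHit]:
    """Parse a RepeatMasker ``.out`` annotation into :class:`RepeatHit` rows.

    Expects the standard layout: 3 header lines then whitespace-delimited
    columns (score, div%, del%, ins%, query, qbegin, qend, qleft, strand
    ``C``/``+``, repeat, class/family, rbegin, rend, rleft, ID).  1-based
    inclusive query coordinates become 0-based half-open; strand ``C`` maps
    to ``-``; a trailing ``*`` (overlap flag) is tolerated.
    """
    hits: list[RepeatHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if lineno <= 3 and (
                stripped.startswith(("SW", "score")) or "perc" in stripped
            ):
                continue
            fields = stripped.split()
            if fields and fields[-1] == "*":
                fields = fields[:-1]
            if len(fields) not in (14, 15):
                raise RefugiumError(
                    f"{path}:{lineno}: expected 14-15 columns, got {len(fields)}"
                )
            try:
                div = float(fields[1])
                query = fields[4]
                qbegin = int(fields[5])
                qend = int(fields[6])
                strand = fields[8]
                family = fields[9]
                classification = fields[10]
                frag_id = fields[14] if len(fields) == 15 else None
            except (ValueError, IndexError) as exc:
                raise RefugiumError(f"{path}:{lineno}: malformed line ({exc})") from exc
            if strand not in ("+", "C"):
                raise RefugiumError(f"{path}:{lineno}: bad strand {strand!r}")
            hits.append(
                RepeatHit(
                    chromosome=query,
                    begin=qbegin - 1,
                    end=qend,
                    strand="-" if strand == "C" else "+",
                    family=family,
                    classification=classification,
                    divergence_pct=div,
                    fragment_link=frag_id,
                )
            )
    return hits


def write_repeatmasker_out(hits: Iterable[RepeatHit], path: PathLike) -> None:
    """Write hits in the 15-column ``.out`` dialect (round-trips with the parser)."""
    with open(path, "w") as fh:
        fh.write(_OUT_HEADER)
        for i, h in enumerate(hits, start=1):
            div = 0.0 if h.divergence_pct is None else h.divergence_pct
            strand = "C" if h.strand == "-" else "+"
            frag = h.fragment_link if h.fragment_link is not None else str(i)
            fh.write(
                f"  500 {div:5.1f}  0.0  0.0  {h.chromosome}  {h.begin + 1}  "
                f"{h.end}  (0)  {strand}  {h.family}  {h.classification}  "
                f"1  {h.length}  (0)  {frag}\n"
            )


# ---------------------------------------------------------------------------
# Chromosome classification
# ---------------------------------------------------------------------------

def classify_chromosomes(
    names: Sequence[str],
    rules: Optional[Sequence[tuple[str, str]]] = None,
    log: bool = False,
) -> dict[str, str]:
    """Assign a chromosome class to each name; first matching rule wins.

    ``rules`` is an ordered sequence of ``(regex, class)`` pairs; unmatched
    names become ``unplaced``.  Two rules that match the same name with
    different classes at the same position in the list cannot arise (the
    list is ordered), but duplicate patterns mapping to different classes
    are rejected outright.
    """
    rules = list(DEFAULT_CHROM_RULES if rules is None else rules)
    seen: dict[str, str] = {}
    for pat, cls in rules:
        if pat in seen and seen[pat] != cls:
            raise RefugiumError(
                f"conflicting rules: pattern {pat!r} maps to both "
                f"{seen[pat]!r} and {cls!r}"
            )
        seen[pat] = cls
    compiled = [(re.compile(pat), cls) for pat, cls in rules]
    out: dict[str, str] = {}
    for name in names:
        for rx, cls in compiled:
            if rx.search(name):
                out[name] = cls
                break
        else:
            out[name] = "unplaced"
    if log:
        counts: dict[str, int] = {}
        for cls in out.values():
            counts[cls] = counts.get(cls, 0) + 1
        summary = ", ".join(f"{c}={n}" for c, n in sorted(counts.items()))
        print(f"classified {len(names)} sequences: {summary}", file=sys.stderr)
    return out


# ---------------------------------------------------------------------------
# Interval export / import
# ---------------------------------------------------------------------------

def write_intervals(
    hits: Iterable[RepeatHit], fmt: str, path: PathLike
) -> None:
    """Write hits as BED6 (0-based half-open) or GFF3 (1-based inclusive)."""
    fmt = fmt.upper()
    if fmt == "BED":
        with open(path, "w") as fh:
            for h in hits:
                fh.write(
                    f"{h.chromosome}\t{h.begin}\t{h.end}\t{h.family}\t0\t{h.strand}\n"
                )
    elif fmt == "GFF3":
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for h in hits:
                attrs = f"Name={h.family};classification={h.classification}"
                if h.fragment_link is not None:
                    attrs += f";ID={h.fragment_link}"
                fh.write(
                    f"{h.chromosome}\trefugium\tdispersed_repeat\t{h.begin + 1}\t"
                    f"{h.end}\t.\t{h.strand}\t.\t{attrs}\n"
                )
    else:
        raise RefugiumError(f"unknown interval format {fmt!r} (use BED or GFF3)")


def read_bed(path: PathLike) -> list[RepeatHit]:
    """Read BED6 back into hits (classification is not stored in BED)."""
    hits = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise RefugiumError(f"{path}:{lineno}: expected >=6 BED columns")
            hits.append(
                RepeatHit(
                    chromosome=f[0],
                    begin=int(f[1]),
                    end=int(f[2]),
                    strand=f[5].strip(),
                    family=f[3],
                    classification="Unknown",
                )
            )
    return hits


# ---------------------------------------------------------------------------
# Tabular inputs
# ---------------------------------------------------------------------------

def read_sample_sheet(path: PathLike) -> pd.DataFrame:
    """Read a sample sheet TSV with columns id, sex, assay, path."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"id", "sex", "assay", "path"}
    missing = required - set(df.columns)
    if missing:
        raise RefugiumError(f"{path}: sample sheet missing columns {sorted(missing)}")
    bad_sex = set(df["sex"]) - {"male", "female"}
    if bad_sex:
        raise RefugiumError(f"{path}: bad sex values {sorted(bad_sex)}")
    bad_assay = set(df["assay"]) - {"genomic", "RNA"}
    if bad_assay:
        raise RefugiumError(f"{path}: bad assay values {sorted(bad_assay)}")
    return df


def read_count_table(path: PathLike) -> pd.DataFrame:
    """Read a featureCounts-style per-copy count table.

    Expected columns: ``copy_id``, ``chromosome``, ``length`` then one
    integer column per sample.  Copies with missing or non-positive length
    are rejected.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"copy_id", "chromosome", "length"}
    missing = required - set(df.columns)
    if missing:
        raise RefugiumError(f"{path}: count table missing columns {sorted(missing)}")
    if df["length"].isna().any() or (df["length"] <= 0).any():
        raise RefugiumError(f"{path}: copies with missing or non-positive length")
    return df


def read_domain_hits(path: PathLike) -> pd.DataFrame:
    """Read a precomputed RPS-BLAST-style domain-hit table.

    Columns: query, domain, domain_length, dstart, dend, score, evalue
    (1-based inclusive domain coordinates).  Adds a ``span_fraction`` column.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"query", "domain", "domain_length", "dstart", "dend"}
    missing = required - set(df.columns)
    if missing:
        raise RefugiumError(f"{path}: domain table missing columns {sorted(missing)}")
    df = df.copy()
    df["span_fraction"] = (df["dend"] - df["dstart"] + 1) / df["domain_length"]
    return df


def genome_from_fasta(
    path: PathLike,
    rules: Optional[Sequence[tuple[str, str]]] = None,
    sex_system: str = "ZW",
) -> GenomeModel:
    """Read an assembly FASTA and classify its chromosomes in one step."""
    from .model import genome_from_sequences

    seqs = read_fasta(path)
    classes = classify_chromosomes(list(seqs), rules)
    return genome_from_sequences(seqs, classes, sex_system)
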