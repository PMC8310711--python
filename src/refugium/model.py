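"""Domain types shared across the toolkit.

The toolkit reasons about three chromosome partitions of a genome assembly:
autosomes, the shared sex chromosome (Z or X), and the sex-limited chromosome
(W or Y).  Coordinates are 0-based half-open everywhere inside the package;
conversion to/from 1-based inclusive conventions happens only at the format
boundaries (RepeatMasker ``.out``, GFF3).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

#: Valid chromosome classes.  ``unplaced`` records are carried along but are
#: excluded from index and density computations by default.
CHROM_CLASSES = ("autosome", "Z", "W", "X", "Y", "unplaced")

#: Sex systems understood by the index machinery.
SEX_SYSTEMS = ("ZW", "XY", "XO")

#: Which class plays the shared / sex-limited role under each system.
SHARED_CLASS = {"ZW": "Z", "XY": "X", "XO": "X"}
LIMITED_CLASS = {"ZW": "W", "XY": "Y", "XO": None}


class RefugiumError(ValueError):
    """Base class for user-facing errors raised by this package."""


@dataclass(frozen=True)
class ChromosomeRecord:
    """One chromosome (or scaffold) of an assembly.

    Parameters
    ----------
    name:
        Unique identifier within the genome.
    te_class:
        One of :data:`CHROM_CLASSES`.
    length:
        Length in bp (> 0).  Includes assembly gaps (N runs) unless the
        caller chose otherwise when building the record.
    sequence:
        Optional nucleotide sequence; must match ``length`` when present.
    """

    name: str
    te_class: str
    length: int
    sequence: Optional[str] = None

    def __post_init__(self) -> None:
        if self.te_class not in CHROM_CLASSES:
            raise RefugiumError(
                f"unknown chromosome class {self.te_class!r} for {self.name!r}"
            )
        if self.length <= 0:
            raise RefugiumError(f"chromosome {self.name!r} has non-positive length")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise RefugiumError(
                f"chromosome {self.name!r}: length {self.length} != "
                f"sequence length {len(self.sequence)}"
            )

    @property
    def ungapped_length(self) -> int:
        """Length excluding N/n runs; requires the sequence."""
        if self.sequence is None:
            raise RefugiumError(f"chromosome {self.name!r} has no sequence")
        return self.length - self.sequence.upper().count("N")


@dataclass
class GenomeModel:
    """An assembly as an ordered set of classified chromosomes."""

    chromosomes: list[ChromosomeRecord]
    sex_system: str = "ZW"

    def __post_init__(self) -> None:
        if self.sex_system not in SEX_SYSTEMS:
            raise RefugiumError(f"unknown sex system {self.sex_system!r}")
        names = [c.name for c in self.chromosomes]
        if len(names) != len(set(names)):
            raise RefugiumError("duplicate chromosome names in genome")
        for cls in ("Z", "W", "X", "Y"):
            if sum(c.te_class == cls for c in self.chromosomes) > 1:
                raise RefugiumError(f"more than one chromosome of class {cls}")

    def __iter__(self):
        return iter(self.chromosomes)

    def get(self, name: str) -> ChromosomeRecord:
        for c in self.chromosomes:
            if c.name == name:
                return c
        raise RefugiumError(f"unknown chromosome {name!r}")

    def __contains__(self, name: str) -> bool:
        return any(c.name == name for c in self.chromosomes)

    def by_class(self, te_class: str) -> list[ChromosomeRecord]:
        return [c for c in self.chromosomes if c.te_class == te_class]

    def placed(self) -> list[ChromosomeRecord]:
        """Assembled chromosomes only (``unplaced`` records dropped)."""
        return [c for c in self.chromosomes if c.te_class != "unplaced"]

    def class_lengths(self, include_unplaced: bool = False) -> dict[str, int]:
        """Total bp per chromosome class."""
        out: dict[str, int] = {}
        for c in self.chromosomes:
            if c.te_class == "unplaced" and not include_unplaced:
                continue
            out[c.te_class] = out.get(c.te_class, 0) + c.length
        return out


@dataclass(frozen=True)
class RepeatHit:
    """One annotated TE interval — the atom of landscapes and densities.

    ``begin``/``end`` are 0-based half-open on ``chromosome``;
    ``divergence_pct`` is the percent divergence from the family consensus
    (RepeatMasker's div% column) when known; ``fragment_link`` joins split
    fragments of one insertion (RepeatMasker's ID column).
    """

    chromosome: str
    begin: int
    end: int
    strand: str
    family: str
    classification: str
    divergence_pct: Optional[float] = None
    fragment_link: Optional[str] = None

    def __post_init__(self) -> None:
        if not (0 <= self.begin < self.end):
            raise RefugiumError(
                f"bad span {self.begin}..{self.end} on {self.chromosome}"
            )
        if self.strand not in ("+", "-"):
            raise RefugiumError(f"bad strand {self.strand!r}")
        if self.divergence_pct is not None and self.divergence_pct < 0:
            raise RefugiumError("negative divergence")

    @property
    def length(self) -> int:
        return self.end - self.begin

    @property
    def classification_group(self) -> str:
        """Top-level classification (e.g. ``LTR`` for ``LTR/ERVL``)."""
        return self.classification.split("/", 1)[0]


@dataclass
class ConsensusLibrary:
    """TE family consensus sequences with their classification labels."""

    entries: dict[str, tuple[str, str]] = field(default_factory=dict)

    def add(self, family: str, sequence: str, classification: str) -> None:
        if family in self.entries:
            raise RefugiumError(f"duplicate family {family!r}")
        if not sequence:
            raise RefugiumError(f"empty consensus for {family!r}")
        self.entries[family] = (sequence.upper(), classification)

    def sequence(self, family: str) -> str:
        try:
            return self.entries[family][0]
        except KeyError:
            raise RefugiumError(f"family {family!r} not in library") from None

    def classification(self, family: str) -> str:
        try:
            return self.entries[family][1]
        except KeyError:
            raise RefugiumError(f"family {family!r} not in library") from None

    def families(self) -> list[str]:
        return list(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, family: str) -> bool:
        return family in self.entries


def genome_from_sequences(
    sequences: Mapping[str, str],
    classes: Mapping[str, str],
    sex_system: str = "ZW",
) -> GenomeModel:
    """Assemble a :class:`GenomeModel` from sequences plus class labels."""
    chroms = [
        ChromosomeRecord(name, classes.get(name, "unplaced"), len(seq), seq)
        for name, seq in sequences.items()
    ]
    return GenomeModel(chroms, sex_system)


def pool_class(te_class: str) -> str:
    """Pool X with Z and Y with W for reporting (shared vs sex-limited)."""
    return {"X": "Z", "Y": "W"}.get(te_class, te_class)


def check_hits_in_bounds(hits: Iterable[RepeatHit], genome: GenomeModel) -> None:
    for h in hits:
        chrom = genome.get(h.chromosome)
        if h.end > chrom.length:
            raise RefugiumError(
                f"hit {h.family} at {h.chromosome}:{h.begin}-{h.end} exceeds "
                f"chromosome length {chrom.length}"
            )
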