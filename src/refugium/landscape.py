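"""Kimura 2-parameter divergence and TE landscapes.

The landscape of a chromosome class is the amount of TE-derived sequence
(bp occupied) per divergence bin, where divergence is the Kimura (1980)
2-parameter distance of each copy to its family consensus:

    K = -1/2 * ln((1 - 2P - Q) * sqrt(1 - 2Q))

with P and Q the proportions of transition- and transversion-type
differences over ungapped, unambiguous alignment columns.  Normalizing the
per-bin bp by the class length (bp per Mb) makes landscapes comparable
between chromosomes of very different size, which is what exposes the
excess of young elements on sex-limited chromosomes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterable, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd

from .model import GenomeModel, RefugiumError, RepeatHit, check_hits_in_bounds

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")
VALID = frozenset("ACGT")


class K2PResult(NamedTuple):
    """Outcome of a K2P estimate; ``defined`` is False when the log
    argument leaves the model's domain (saturated pairs)."""

    distance: float
    p: float
    q: float
    sites: int
    defined: bool


@dataclass(frozen=True)
class AlignedPair:
    """A gapped copy/consensus alignment with its site tallies."""

    copy_seq: str
    consensus_seq: str

    def __post_init__(self) -> None:
        if len(self.copy_seq) != len(self.consensus_seq):
            raise RefugiumError("aligned sequences differ in length")

    def site_tallies(self) -> tuple[float, float, int]:
        """Return (P, Q, n) over ungapped, unambiguous columns."""
        transitions = transversions = n = 0
        for a, b in zip(self.copy_seq.upper(), self.consensus_seq.upper()):
            if a not in VALID or b not in VALID:
                continue
            n += 1
            if a == b:
                continue
            if (a in PURINES) == (b in PURINES):
                transitions += 1
            else:
                transversions += 1
        if n == 0:
            raise RefugiumError("no comparable (ungapped, unambiguous) columns")
        return transitions / n, transversions / n, n


def k2p_from_proportions(p: float, q: float, sites: int = 0) -> K2PResult:
    """Kimura 2-parameter distance from transition/transversion proportions."""
    if p < 0 or q < 0 or p + q > 1:
        raise RefugiumError(f"invalid proportions P={p}, Q={q}")
    w1 = 1.0 - 2.0 * p - q
    w2 = 1.0 - 2.0 * q
    if w1 <= 0 or w2 <= 0:
        return K2PResult(math.nan, p, q, sites, defined=False)
    k = -0.5 * math.log(w1 * math.sqrt(w2))
    # tiny negative from rounding at identity is clamped
    return K2PResult(max(k, 0.0), p, q, sites, defined=True)


def k2p_distance(pair: AlignedPair) -> K2PResult:
    """K2P distance of an aligned copy/consensus pair."""
    p, q, n = pair.site_tallies()
    return k2p_from_proportions(p, q, n)


def align_to_consensus(copy_seq: str, consensus: str) -> AlignedPair:
    """Affine-gap global alignment of a copy against its family consensus.

    Used when the annotation carries no divergence column.  Non-ACGT bases
    survive into the alignment and are excluded from the tallies by
    :meth:`AlignedPair.site_tallies`.
    """
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -4
    aligner.extend_gap_score = -1
    aln = aligner.align(copy_seq.upper(), consensus.upper())[0]
    a, b = str(aln[0]), str(aln[1])
    return AlignedPair(a, b)


# ---------------------------------------------------------------------------
# Densities
# ---------------------------------------------------------------------------

def merge_intervals(spans: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open intervals (no base counted twice)."""
    spans = sorted(spans)
    merged: list[tuple[int, int]] = []
    for b, e in spans:
        if merged and b <= merged[-1][1]:
            if e > merged[-1][1]:
                merged[-1] = (merged[-1][0], e)
        else:
            merged.append((b, e))
    return merged


def covered_bp(spans: Iterable[tuple[int, int]]) -> int:
    return sum(e - b for b, e in merge_intervals(spans))


def te_bp_by_chromosome(
    hits: Iterable[RepeatHit],
    genome: GenomeModel,
    classification_filter: Optional[Callable[[RepeatHit], bool]] = None,
    include_unplaced: bool = False,
    ungapped_lengths: bool = False,
) -> pd.DataFrame:
    """Per-chromosome TE density summary.

    Overlapping hits are flattened before summation.  Returns one row per
    included chromosome with columns ``chromosome``, ``te_class``,
    ``te_bp``, ``length_bp``, ``pct_te_obs``, ``pct_te_exp``; the expected
    density is the length-weighted genome-wide mean over included
    chromosomes, so ``pct_te_exp`` is constant down the column.
    """
    hits = [
        h for h in hits if classification_filter is None or classification_filter(h)
    ]
    check_hits_in_bounds(hits, genome)
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for h in hits:
        by_chrom.setdefault(h.chromosome, []).append((h.begin, h.end))
    rows = []
    chroms = genome.chromosomes if include_unplaced else genome.placed()
    for c in chroms:
        te_bp = covered_bp(by_chrom.get(c.name, []))
        length = c.ungapped_length if ungapped_lengths else c.length
        rows.append(
            {
                "chromosome": c.name,
                "te_class": c.te_class,
                "te_bp": te_bp,
                "length_bp": length,
                "pct_te_obs": 100.0 * te_bp / length,
            }
        )
    df = pd.DataFrame(rows)
    if df.empty:
        raise RefugiumError("no chromosomes included in density summary")
    df["pct_te_exp"] = 100.0 * df["te_bp"].sum() / df["length_bp"].sum()
    return df


def class_density(summary: pd.DataFrame) -> pd.DataFrame:
    """Collapse a per-chromosome density summary to chromosome classes."""
    g = summary.groupby("te_class", as_index=False)[["te_bp", "length_bp"]].sum()
    g["pct_te_obs"] = 100.0 * g["te_bp"] / g["length_bp"]
    g["pct_te_exp"] = 100.0 * summary["te_bp"].sum() / summary["length_bp"].sum()
    return g


# ---------------------------------------------------------------------------
# Landscapes
# ---------------------------------------------------------------------------

def build_landscape(
    hits: Iterable[RepeatHit],
    genome: GenomeModel,
    bin_width: float = 1.0,
    cap: float = 50.0,
    divergences: Optional[dict] = None,
) -> pd.DataFrame:
    """Bin TE bp by divergence per (chromosome class, classification group).

    Each hit contributes its length to exactly one left-closed bin
    ``[k*w, (k+1)*w)`` of its ``divergence_pct``; divergences at or above
    ``cap`` are pooled into the last bin.  ``divergences`` may override the
    annotation's divergence column (e.g. values recomputed from alignments),
    keyed by ``(chromosome, begin, end)``.

    Returns columns ``te_class``, ``classification_group``, ``bin_low``,
    ``bin_high``, ``bp``, ``bp_per_mb``.
    """
    if bin_width <= 0:
        raise RefugiumError("bin width must be positive")
    class_lengths = genome.class_lengths()
    n_bins = int(math.ceil(cap / bin_width))
    acc: dict[tuple[str, str, int], int] = {}
    for h in hits:
        if h.chromosome not in genome:
            raise RefugiumError(f"hit on unknown chromosome {h.chromosome!r}")
        te_class = genome.get(h.chromosome).te_class
        if te_class == "unplaced":
            continue
        div = h.divergence_pct
        if divergences is not None:
            div = divergences.get((h.chromosome, h.begin, h.end), div)
        if div is None:
            raise RefugiumError(
                f"no divergence for hit at {h.chromosome}:{h.begin}-{h.end}"
            )
        k = min(int(div // bin_width), n_bins - 1)
        key = (te_class, h.classification_group, k)
        acc[key] = acc.get(key, 0) + h.length
    rows = []
    for (te_class, group, k), bp in sorted(acc.items()):
        rows.append(
            {
                "te_class": te_class,
                "classification_group": group,
                "bin_low": k * bin_width,
                "bin_high": (k + 1) * bin_width,
                "bp": bp,
                "bp_per_mb": bp / (class_lengths[te_class] / 1e6),
            }
        )
    columns = [
        "te_class", "classification_group", "bin_low", "bin_high", "bp", "bp_per_mb",
    ]
    return pd.DataFrame(rows, columns=columns)


def plot_landscape(landscape: pd.DataFrame, path: str, max_pct: float = 50.0) -> None:
    """Stacked-bar landscape per chromosome class (one panel per class)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    classes = sorted(landscape["te_class"].unique())
    fig, axes = plt.subplots(1, len(classes), figsize=(4 * len(classes), 3),
                             squeeze=False, sharey=False)
    groups = sorted(landscape["classification_group"].unique())
    cmap = plt.get_cmap("tab10")
    for ax, te_class in zip(axes[0], classes):
        sub = landscape[landscape["te_class"] == te_class]
        bins = np.sort(sub["bin_low"].unique())
        bottom = np.zeros(len(bins))
        for gi, group in enumerate(groups):
            vals = []
            gsub = sub[sub["classification_group"] == group].set_index("bin_low")
            for b in bins:
                vals.append(gsub["bp_per_mb"].get(b, 0.0))
            vals = np.asarray(vals)
            ax.bar(bins, vals, bottom=bottom, width=0.9,
                   color=cmap(gi % 10), label=group)
            bottom += vals
        ax.set_title(te_class)
        ax.set_xlim(-0.5, max_pct)
        ax.set_xlabel("K2P divergence to consensus (%)")
        ax.set_ylabel("bp per Mb")
    axes[0][-1].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
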