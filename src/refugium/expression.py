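"""Per-chromosome TE expression summaries (TPM) and sex comparisons.

Counts of uniquely-attributed RNA-seq reads per annotated TE copy are
normalized to transcripts per million (TPM): rates ``count / length`` are
rescaled so each sample sums to 10^6.  Copies are then grouped by
chromosome class and male/female distributions compared with a two-sided
Wilcoxon rank-sum test (exact enumeration for small groups, tie-corrected
normal approximation otherwise).  Full differential-expression modelling
(dispersion estimation, Wald tests, fold-change shrinkage) is deliberately
out of scope; the summary reports a plain log2 ratio of mean TPM, which is
not a substitute for such a model.
"""

from __future__ import annotations

from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .model import GenomeModel, RefugiumError, pool_class


def tpm_normalize(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """TPM-normalize a copies x samples count matrix.

    ``TPM_ij = (count_ij / length_i) / sum_i(count_ij / length_i) * 1e6``.
    Each column of the result sums to 1e6 (unless the sample has zero
    counts everywhere, in which case it stays all-zero).
    """
    if (lengths <= 0).any():
        raise RefugiumError("copy lengths must be positive")
    rate = counts.div(lengths, axis=0)
    totals = rate.sum(axis=0)
    tpm = rate.div(totals.where(totals > 0, other=np.inf), axis=1) * 1e6
    return tpm


def chromosome_class_expression(
    table: pd.DataFrame,
    genome: GenomeModel,
    sample_sex: dict[str, str],
    drop_male_w: bool = True,
) -> pd.DataFrame:
    """Replicate-averaged per-copy TPM by chromosome class and sex.

    ``table`` is a count table with columns ``copy_id``, ``chromosome``,
    ``length`` plus one column per sample; ``sample_sex`` maps sample
    columns to ``male``/``female``.  Rows on the sex-limited chromosome are
    removed from male samples *before* normalization (their counts are
    spurious low-level cross-mapping, and keeping them would distort the
    male library-size rescaling).  Returns long-format rows
    (copy_id, te_class, sex, tpm).
    """
    samples = [c for c in table.columns if c in sample_sex]
    if not samples:
        raise RefugiumError("no sample columns matched sample_sex")
    classes = table["chromosome"].map(
        lambda c: pool_class(genome.get(c).te_class)
    )
    out_rows = []
    for sex in ("female", "male"):
        cols = [s for s in samples if sample_sex[s] == sex]
        if not cols:
            continue
        sub = table
        cls = classes
        if sex == "male" and drop_male_w:
            keep = classes != "W"
            sub = table[keep]
            cls = classes[keep]
        tpm = tpm_normalize(sub[cols], sub["length"])
        avg = tpm.mean(axis=1)
        out_rows.append(
            pd.DataFrame(
                {
                    "copy_id": sub["copy_id"],
                    "te_class": cls,
                    "sex": sex,
                    "tpm": avg,
                }
            )
        )
    return pd.concat(out_rows, ignore_index=True)


class RankSumResult(NamedTuple):
    statistic: float  # Mann-Whitney U of group 1
    p_value: float
    method: str


def ranksum_compare(
    group1: Sequence[float], group2: Sequence[float], exact_max_n: int = 20
) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum comparison of two groups.

    Exact enumeration when the combined sample size is at most
    ``exact_max_n`` and there are no ties; tie-corrected normal
    approximation otherwise.
    """
    g1 = np.asarray(group1, dtype=float)
    g2 = np.asarray(group2, dtype=float)
    if g1.size == 0 or g2.size == 0:
        raise RefugiumError("both groups must be non-empty")
    has_ties = len(np.unique(np.concatenate([g1, g2]))) < g1.size + g2.size
    if g1.size + g2.size <= exact_max_n and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = scipy.stats.mannwhitneyu(g1, g2, alternative="two-sided", method=method)
    return RankSumResult(float(res.statistic), float(res.pvalue), method)


def class_comparison(
    expr: pd.DataFrame, min_n: int = 3
) -> pd.DataFrame:
    """Male vs female rank-sum comparison per chromosome class.

    Consumes the long-format output of :func:`chromosome_class_expression`;
    reports group sizes, mean TPM per sex, a plain log2 ratio of mean TPM
    (female over male; not a modelled fold change) and the rank-sum p.
    """
    rows = []
    for te_class, sub in expr.groupby("te_class"):
        f = sub.loc[sub["sex"] == "female", "tpm"].to_numpy()
        m = sub.loc[sub["sex"] == "male", "tpm"].to_numpy()
        if f.size < min_n or m.size < min_n:
            continue
        res = ranksum_compare(f, m)
        with np.errstate(divide="ignore", invalid="ignore"):
            log2_ratio = float(np.log2(f.mean() / m.mean())) if m.mean() > 0 else np.inf
        rows.append(
            {
                "te_class": te_class,
                "n_female": f.size,
                "n_male": m.size,
                "mean_tpm_female": f.mean(),
                "mean_tpm_male": m.mean(),
                "log2_mean_ratio": log2_ratio,
                "statistic": res.statistic,
                "p_value": res.p_value,
                "method": res.method,
            }
        )
    return pd.DataFrame(rows)


def plot_class_expression(expr: pd.DataFrame, path: str) -> None:
    """Violin plot of per-copy TPM by chromosome class, split by sex."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    classes = [c for c in ("autosome", "Z", "W") if c in set(expr["te_class"])]
    fig, ax = plt.subplots(figsize=(1.8 * max(len(classes), 1) + 1, 3))
    pos = 0
    ticks, labels = [], []
    for te_class in classes:
        for sex, color in (("female", "#4477aa"), ("male", "#ee7733")):
            vals = expr.loc[
                (expr["te_class"] == te_class) & (expr["sex"] == sex), "tpm"
            ].to_numpy()
            if vals.size:
                part = ax.violinplot(np.log10(vals + 1), positions=[pos],
                                     showmedians=True)
                for body in part["bodies"]:
                    body.set_facecolor(color)
            ticks.append(pos)
            labels.append(f"{te_class}\n{sex[0].upper()}")
            pos += 1
        pos += 0.5
    ax.set_xticks(ticks)
    ax.set_xticklabels(labels, fontsize=7)
    ax.set_ylabel("log10(TPM + 1)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
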