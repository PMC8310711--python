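"""Refugium index, toxicity index and the uniform-density enrichment test.

The refugium index of a chromosome (or chromosome class) measures the
excess or depletion of TE-derived sequence relative to the genome-wide
average density:

    RI = (%TE_obs - %TE_exp) / %TE_exp

RI > 0 is an excess, RI < 0 a depletion, and the length-weighted mean of
RI over all included chromosomes is 0 by construction.

The toxicity index measures the excess of intact (full-length) TEs carried
by the heterogametic diploid over the homogametic diploid:

    TI = (2n_het - 2n_hom) / 2n_hom

where for a ZW system 2n_hom = 2A + 2Z and 2n_het = 2A + Z + W (X/Y
likewise; in XO the heterogametic total is 2A + X).  TI = 0 means no sex
difference, TI > 0 toxicity of the sex-limited chromosome, TI < 0 toxicity
of Z or X.  Intact-TE totals pool all full-length categories (fl-ERV plus
full-length LINEs and DNA transposons).

Counts are integers, so both indexes are computed with exact rational
arithmetic and rendered to 9 decimal places for reporting.

Whether full-length elements are spread uniformly over A, Z and W is
tested with a chi-square test with 2 degrees of freedom against
expectations proportional to class length; for df = 2 the survival
function has the closed form p = exp(-X^2 / 2).
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from numbers import Rational
from typing import Mapping, Union

import scipy.stats

from .model import LIMITED_CLASS, SHARED_CLASS, RefugiumError

Number = Union[int, float, Fraction]


def render9(value: Number) -> str:
    """Render an index to 9 decimal places (survey-table formatting)."""
    if isinstance(value, Rational):
        scaled = Fraction(value) * 10**9
        q = scaled.numerator // scaled.denominator
        if 2 * (scaled - q) >= 1:  # round half up, as the survey tables do
            q += 1
        sign = "-" if q < 0 else ""
        q = abs(q)
        return f"{sign}{q // 10**9}.{q % 10**9:09d}"
    return f"{value:.9f}"


def refugium_index(pct_te_obs: Number, pct_te_exp: Number) -> Number:
    """RI = (%TE_obs - %TE_exp) / %TE_exp; requires %TE_exp > 0."""
    if pct_te_exp <= 0:
        raise RefugiumError("refugium index undefined for %TE_exp <= 0")
    if isinstance(pct_te_obs, Rational) and isinstance(pct_te_exp, Rational):
        return (Fraction(pct_te_obs) - Fraction(pct_te_exp)) / Fraction(pct_te_exp)
    return (pct_te_obs - pct_te_exp) / pct_te_exp


@dataclass(frozen=True)
class DiploidCensus:
    """Intact-TE totals of the two diploid sexes."""

    n_hom: int
    n_het: int

    def __post_init__(self) -> None:
        if self.n_hom < 0 or self.n_het < 0:
            raise RefugiumError("negative diploid totals")


def diploid_totals(
    class_counts: Mapping[str, int], sex_system: str = "ZW"
) -> DiploidCensus:
    """Diploid intact-TE totals from pooled per-class counts.

    ``class_counts`` maps autosome/Z/W (or autosome/X/Y; the shared and
    limited classes of the given sex system) to intact-TE counts summed
    over all full-length categories.
    """
    shared = SHARED_CLASS.get(sex_system)
    limited = LIMITED_CLASS.get(sex_system)
    if shared is None:
        raise RefugiumError(f"unknown sex system {sex_system!r}")
    a = int(class_counts.get("autosome", 0))
    if shared not in class_counts and ("Z" in class_counts or "X" in class_counts):
        # tolerate Z-labelled counts under XY and vice versa
        shared_count = int(class_counts.get("Z", class_counts.get("X", 0)))
    else:
        if shared not in class_counts:
            raise RefugiumError(f"missing {shared} count for sex system {sex_system}")
        shared_count = int(class_counts[shared])
    if limited is None:
        limited_count = 0
    else:
        limited_count = int(
            class_counts.get(limited, class_counts.get("W", class_counts.get("Y", 0)))
        )
    n_hom = 2 * a + 2 * shared_count
    n_het = 2 * a + shared_count + limited_count
    return DiploidCensus(n_hom=n_hom, n_het=n_het)


def toxicity_index(diploid: DiploidCensus) -> Fraction:
    """TI = (2n_het - 2n_hom) / 2n_hom, exact."""
    if diploid.n_hom == 0:
        raise RefugiumError("toxicity index undefined for n_hom = 0")
    return Fraction(diploid.n_het - diploid.n_hom, diploid.n_hom)


def toxicity_index_from_totals(male_2n: int, female_2n: int,
                               heterogametic: str = "female") -> Fraction:
    """TI straight from printed diploid totals of the two sexes."""
    hom, het = (
        (male_2n, female_2n) if heterogametic == "female" else (female_2n, male_2n)
    )
    return toxicity_index(DiploidCensus(n_hom=hom, n_het=het))


@dataclass(frozen=True)
class UniformityTest:
    """Chi-square test of observed class counts against length-proportional
    expectations (A vs Z vs W pooled: 2 degrees of freedom)."""

    observed: dict
    expected: dict
    statistic: float
    df: int
    p_value: float
    ratio: dict  # obs/exp per class


def uniformity_test(
    observed: Mapping[str, Number],
    class_lengths: Mapping[str, int],
    pool_autosomes: bool = True,
) -> UniformityTest:
    """Test whether elements are uniformly dense across chromosome classes.

    ``observed`` may be counts or bp per class; expectations are
    proportional to class length.  With ``pool_autosomes`` (default) the
    classes are the three cells A/Z(or X)/W(or Y) and df = 2; otherwise one
    cell per key with df = k - 1.
    """
    keys = [k for k in observed if k in class_lengths]
    if len(keys) < 2:
        raise RefugiumError("need at least two classes with lengths")
    total_obs = float(sum(observed[k] for k in keys))
    total_len = float(sum(class_lengths[k] for k in keys))
    if total_obs <= 0:
        raise RefugiumError("observed total must be positive")
    expected = {k: total_obs * class_lengths[k] / total_len for k in keys}
    if any(e == 0 for e in expected.values()):
        raise RefugiumError("zero expected cell (zero class length)")
    x2 = sum((float(observed[k]) - expected[k]) ** 2 / expected[k] for k in keys)
    df = len(keys) - 1
    if not pool_autosomes:
        pass  # df already reflects the per-chromosome cells passed in
    p = float(scipy.stats.chi2.sf(x2, df))
    ratio = {k: float(observed[k]) / expected[k] for k in keys}
    return UniformityTest(
        observed={k: float(observed[k]) for k in keys},
        expected=expected,
        statistic=float(x2),
        df=df,
        p_value=p,
        ratio=ratio,
    )
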