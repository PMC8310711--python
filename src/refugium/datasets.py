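"""Bundled reference tables.

``avian_flte_counts.tsv`` carries published full-length TE counts for six
female avian genome assemblies: full-length LINE+DNA elements and fl-ERVs
under two structural annotation profiles (a RetroTector-style profile,
``flerv_rt``, and an LTRharvest+LTRdigest-style profile, ``flerv_ltrhd``),
per chromosome class (autosomes pooled, Z, W) together with the printed
diploid totals for males (2A + 2Z) and females (2A + Z + W).  These counts
serve as worked examples for the toxicity-index machinery.
"""

from __future__ import annotations

from fractions import Fraction
from importlib import resources

import pandas as pd

from .indices import toxicity_index_from_totals
from .model import RefugiumError

PROFILES = ("rt", "ltrhd")


def load_flte_survey() -> pd.DataFrame:
    """Load the six-species full-length TE survey counts."""
    with resources.files("refugium.data").joinpath("avian_flte_counts.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def survey_toxicity_index(
    species: str, profile: str = "ltrhd", from_classes: bool = False
) -> Fraction:
    """Toxicity index of one surveyed species under one profile.

    Intact-TE totals pool the profile's fl-ERV counts with the full-length
    LINE+DNA counts.  By default the printed per-sex diploid totals are
    used; with ``from_classes`` the totals are rebuilt from the A/Z/W
    columns (2A + 2Z vs 2A + Z + W).
    """
    if profile not in PROFILES:
        raise RefugiumError(f"unknown profile {profile!r}; use one of {PROFILES}")
    df = load_flte_survey()
    sub = df[df["species"] == species].set_index("count_type")
    if sub.empty:
        raise RefugiumError(f"species {species!r} not in survey table")
    rows = [f"flerv_{profile}", "line_dna"]
    if from_classes:
        a = int(sub.loc[rows, "autosomes"].sum())
        z = int(sub.loc[rows, "chr_z"].sum())
        w = int(sub.loc[rows, "chr_w"].sum())
        male = 2 * a + 2 * z
        female = 2 * a + z + w
    else:
        male = int(sub.loc[rows, "male_2n"].sum())
        female = int(sub.loc[rows, "female_2n"].sum())
    return toxicity_index_from_totals(male, female, heterogametic="female")
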