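"""Loaders for the reference tables shipped with the package.

Three small TSVs are bundled:

* ``epitope_catalog.tsv`` — the DQ2.5-glia-alpha1/alpha2/alpha3 9-mer
  epitope cores (non-deamidated, Q-form) and their natural variants.
* ``subgenome_motifs.tsv`` — short amino-acid motifs diagnostic for the
  A, B and D sub-genomes of wheat.
* ``expression_profiles.tsv`` — the main alpha-gliadin protein fragments
  (epitope-region amino-acid sequences) of the ten published durum-wheat
  expression profiles, with their normalised transcript abundances per
  profile and the per-profile totals.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

_PKG = "gliascan.data"


def _read(name: str) -> pd.DataFrame:
    with resources.files(_PKG).joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_epitope_catalog() -> pd.DataFrame:
    """Epitope catalog: columns name, parent, status, core."""
    df = _read("epitope_catalog.tsv")
    bad = df[df["core"].str.len() != 9]
    if len(bad):
        raise ValueError(f"epitope cores must be 9 residues: {bad['name'].tolist()}")
    return df


def load_subgenome_motifs() -> pd.DataFrame:
    """Sub-genome diagnostic motifs: columns motif, subgenome."""
    return _read("subgenome_motifs.tsv")


def load_expression_profiles() -> pd.DataFrame:
    """Published expression-profile components, indexed by fragment name.

    Rows are the main unique protein fragments (epitope region only);
    columns ``p1`` .. ``p10`` hold normalised transcript abundances and
    ``region`` the amino-acid sequence.  The ``TOTAL`` row of the source
    table is returned separately by :func:`load_profile_totals`.
    """
    df = _read("expression_profiles.tsv")
    return df[df["upf"] != "TOTAL"].set_index("upf")


def load_profile_totals() -> pd.Series:
    """Published per-profile totals of the main-component abundances."""
    df = _read("expression_profiles.tsv")
    row = df[df["upf"] == "TOTAL"].set_index("upf")
    return row.drop(columns=["region"]).iloc[0].astype(float)
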