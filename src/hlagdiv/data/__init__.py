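"""Bundled reference tables.

``allele_utr_published.tsv`` reproduces the published worldwide association
table between HLA-G coding alleles and 3'UTR haplotypes (4640 individuals;
pairs seen at least twice and with global frequency above 0.5%), with the
printed global and internal frequencies at 4-decimal precision.  It serves
as an external consistency check for :func:`hlagdiv.associate_allele_utr`:
the printed internal frequencies should be recoverable (to rounding) as
ratios of the printed global frequencies.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def load_published_allele_utr() -> pd.DataFrame:
    """The published allele <-> 3'UTR table (allele, utr, global_frequency,
    internal_frequency)."""
    with resources.files(__package__).joinpath("allele_utr_published.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def internal_from_globals(table: pd.DataFrame, allele: str) -> pd.DataFrame:
    """Recompute each partner's internal frequency for ``allele`` as the
    ratio of its printed global frequency to the allele's summed globals."""
    sub = table[table["allele"] == allele].copy()
    if not len(sub):
        raise KeyError(f"allele {allele!r} not in table")
    sub["internal_recomputed"] = sub["global_frequency"] / sub["global_frequency"].sum()
    return sub
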