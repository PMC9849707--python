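"""Packaged reference data: the Saimaa ringed seal temporal haplotype table.

The fixture is the published haplotype-by-temporal-period count table for
Lake Saimaa mtDNA control-region haplotypes (14 haplotypes H1-H14 across
five sampling periods, 321 individuals in total), together with the
corresponding temporal grouping of collection years.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from haplochron.seqio import HaplotypeTable, TemporalGrouping

#: Collection-year ranges of the five sampling periods.  Note the gap
#: 1940-1959, from which no samples exist.
SAIMAA_PERIODS = (
    ("TG1", 1894, 1939),
    ("TG2", 1960, 1979),
    ("TG3", 1980, 1989),
    ("TG4", 1990, 1999),
    ("TG5", 2000, 2011),
)


def saimaa_grouping() -> TemporalGrouping:
    """The five-period temporal grouping used for the Saimaa time series."""
    return TemporalGrouping(periods=SAIMAA_PERIODS)


def load_saimaa_table() -> HaplotypeTable:
    """The published 14-haplotype by 5-period count table (N = 321)."""
    ref = resources.files("haplochron") / "data" / "saimaa_table1.tsv"
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t", index_col=0)
    return HaplotypeTable(df)
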