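"""Reference CpG substitution counts from the gymnosperm plastome dataset.

The 17-triplet gymnosperm analysis that motivates this package reports,
for FFD and NC sites separately, the pooled counts of CpG-type transitions
(G->A read from the 5' neighbor, C->T read from the 3' neighbor) against
the other changes from the same base, split by whether the base sits in a
CG dinucleotide.  Those eight count pairs are shipped here as data so the
odds-ratio computation can be exercised against reported results without
the underlying genome alignments.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .stats import CpGTable


def load_published_cpg_counts() -> pd.DataFrame:
    """The published 2x2 CpG-effect counts, one row per (site class, reading)."""
    with resources.as_file(
            resources.files("ctxsub") / "data" / "published_cpg_counts.tsv") as p:
        return pd.read_csv(p, sep="\t")


def published_cpg_tables() -> list[CpGTable]:
    """The published counts as CpGTable objects (odds ratios recomputed)."""
    out = []
    for row in load_published_cpg_counts().itertuples(index=False):
        out.append(CpGTable(row.site_class, row.focal_change,
                            ((row.cg_focal, row.cg_other),
                             (row.noncg_focal, row.noncg_other))))
    return out


def mean_cpg_excess(tables: list[CpGTable]) -> float:
    """Mean excess of the CpG odds ratios over 1 (fractional, e.g. 0.233)."""
    ors = [t.odds_ratio for t in tables]
    return sum(o - 1.0 for o in ors) / len(ors)
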