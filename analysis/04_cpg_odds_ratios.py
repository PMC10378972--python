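#!/usr/bin/env python
"""CpG-effect odds ratios: published counts and the simulated dataset.

Feeds the published gymnosperm count tables through the odds-ratio
computation (the CpG-type transition versus other changes, in CG versus
non-CG dinucleotides, on both strand readings) and then builds the same
tables from the simulated dataset's folded matrices.  Writes
results/cpg_odds_ratios.tsv.
"""

from pathlib import Path

import pandas as pd

from ctxsub.matrices import read_matrices_tsv
from ctxsub.pipeline import cpg_frame
from ctxsub.published import mean_cpg_excess, published_cpg_tables

RESULTS = Path("results")


def main() -> None:
    pub = published_cpg_tables()
    rows = [{"source": "published", "site_class": t.site_class,
             "focal_change": t.focal_change,
             "cg_focal": t.counts[0][0], "cg_other": t.counts[0][1],
             "noncg_focal": t.counts[1][0], "noncg_other": t.counts[1][1],
             "odds_ratio": round(t.odds_ratio, 2)} for t in pub]

    sim = cpg_frame(read_matrices_tsv("scratch/pipeline/matrices.tsv"))
    sim.insert(0, "source", "simulated")
    sim["odds_ratio"] = sim["odds_ratio"].round(2)

    out = pd.concat([pd.DataFrame(rows), sim], ignore_index=True)
    out.to_csv(RESULTS / "cpg_odds_ratios.tsv", sep="\t", index=False)
    print(out.to_string(index=False))
    print(f"\npublished CpG transition excess: mean "
          f"{100 * mean_cpg_excess(pub):.1f}% across the four tables")
    print("(the simulator's rate model has no CpG-specific boost; deviations "
          "of the simulated odds ratios from 1 reflect the model's "
          "composition-driven context effects, not a CpG effect)")


if __name__ == "__main__":
    main()
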