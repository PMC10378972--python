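#!/usr/bin/env python
"""Simulate the study dataset: aligned NC and CDS triplets with ground truth.

Stands in for the plastome triplet alignments the real analysis consumes:
two ingroup sequences plus an outgroup per locus, evolved under a
context-dependent substitution process (HKY rates whose equilibrium A+T
rises with the AT index of the context) at 0.02 expected substitutions per
site per branch.  Writes FASTA + manifest + the true event log under
scratch/simdata/ (bulky, regenerable) for the downstream drivers.
"""

from pathlib import Path

from ctxsub import write_dataset
from ctxsub.scenarios import cds_default, nc_default
from ctxsub.simulate import simulate_triplet

OUT = Path("scratch/simdata")
SEED = 42


def main() -> None:
    nc_scn = nc_default(SEED, n_loci=40, locus_length=5000)
    cds_scn = cds_default(SEED + 1, n_loci=240, locus_length=3000)
    nc_alns, nc_events = simulate_triplet(nc_scn)
    cds_alns, cds_events = simulate_triplet(cds_scn)

    manifest = write_dataset(nc_alns + cds_alns, OUT)
    nc_events.to_csv(OUT / "truth_events_nc.tsv", sep="\t", index=False)
    cds_events.to_csv(OUT / "truth_events_cds.tsv", sep="\t", index=False)

    nc_kb = nc_scn.n_loci * nc_scn.locus_length / 1000
    cds_kb = cds_scn.n_loci * cds_scn.locus_length / 1000
    print(f"simulated {nc_scn.n_loci} NC loci ({nc_kb:.0f} kb, "
          f"{len(nc_events)} true events) and {cds_scn.n_loci} CDS loci "
          f"({cds_kb:.0f} kb, {len(cds_events)} true events)")
    print(f"manifest -> {manifest}")


if __name__ == "__main__":
    main()
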