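import numpy as np
import pytest

from ctxsub import TripletAlignment, extract_sites, simulate_triplet
from ctxsub.scenarios import nc_default


def make_aln(seqs, locus_type="NC", locus_id="locus", frame_offset=0):
    return TripletAlignment(locus_id, locus_type, tuple(seqs), frame_offset)


def random_triplet(rng, length, locus_type="NC", gap_p=0.0, n_p=0.0,
                   mut_p=0.05, locus_id="rand"):
    """Random alignment: shared backbone with independent noise per row."""
    bases = np.array(list("ACGT"))
    root = rng.choice(4, size=length)
    seqs = []
    for _ in range(3):
        s = root.copy()
        mut = rng.random(length) < mut_p
        s[mut] = rng.choice(4, size=int(mut.sum()))
        chars = bases[s]
        special = rng.random(length)
        chars[special < gap_p] = "-"
        chars[(special >= gap_p) & (special < gap_p + n_p)] = "N"
        seqs.append("".join(chars))
    return make_aln(seqs, locus_type, locus_id)


@pytest.fixture(scope="session")
def nc_sim():
    """A moderate simulated NC dataset shared across tests (60 kb, t=0.02)."""
    scn = nc_default(seed=101)
    alignments, events = simulate_triplet(scn)
    observations = [o for a in alignments for o in extract_sites(a)]
    return scn, alignments, events, observations
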