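"""Reading and filtering aligned three-taxon loci.

The unit of input is a *triplet alignment*: two ingroup sequences from the
same family plus one outgroup, aligned, one locus per multi-FASTA file.
Loci are either protein-coding (``CDS``) or intergenic/noncoding (``NC``).

Locus-level filters mirror the source study: CDS alignments with more than
30 gap characters in total are dropped (alignment quality proxy), as are
intergenic alignments shorter than 70 columns.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO

ROLES = ("ingroup1", "ingroup2", "outgroup")

_VALID = set("ACGT-")
# IUPAC ambiguity letters tolerated on input; masked to N and skipped later.
_AMBIGUOUS = set("NRYSWKMBDHV")


class MalformedInputError(ValueError):
    """Raised for inputs that violate the triplet-alignment contract."""


@dataclass
class TripletAlignment:
    """Three aligned sequences (ingroup1, ingroup2, outgroup) for one locus."""

    locus_id: str
    locus_type: str  # "CDS" | "NC"
    seqs: tuple[str, str, str]
    frame_offset: int = 0

    length: int = field(init=False)

    def __post_init__(self) -> None:
        if self.locus_type not in ("CDS", "NC"):
            raise MalformedInputError(
                f"{self.locus_id}: locus_type must be CDS or NC, got {self.locus_type!r}")
        if len(self.seqs) != 3:
            raise MalformedInputError(
                f"{self.locus_id}: expected 3 sequences, got {len(self.seqs)}")
        lengths = {len(s) for s in self.seqs}
        if len(lengths) != 1:
            raise MalformedInputError(
                f"{self.locus_id}: aligned sequences have unequal lengths {sorted(lengths)}")
        self.length = len(self.seqs[0])
        if self.frame_offset < 0:
            raise MalformedInputError(f"{self.locus_id}: negative frame_offset")
        if self.locus_type == "CDS" and (self.length - self.frame_offset) < 3:
            raise MalformedInputError(
                f"{self.locus_id}: CDS alignment holds no complete codon")

    @property
    def gap_count(self) -> int:
        """Total '-' characters summed over all three rows."""
        return sum(s.count("-") for s in self.seqs)

    def reverse_complement(self) -> "TripletAlignment":
        comp = str.maketrans("ACGTN-", "TGCAN-")
        rc = tuple(s.translate(comp)[::-1] for s in self.seqs)
        return TripletAlignment(self.locus_id, self.locus_type, rc, self.frame_offset)


@dataclass(frozen=True)
class FilterReport:
    locus_id: str
    kept: bool
    reason: str  # ok | cds_gap_excess | nc_too_short | malformed


def _clean_seq(raw: str, locus_id: str, ambiguous: str) -> str:
    s = raw.upper()
    bad = set(s) - _VALID
    if bad:
        if ambiguous == "reject" or not bad <= _AMBIGUOUS:
            raise MalformedInputError(
                f"{locus_id}: invalid characters {sorted(bad)} in alignment")
        s = re.sub(f"[{''.join(sorted(bad))}]", "N", s)
    return s


def read_triplet_fasta(path: str | Path, locus_type: str, *,
                       locus_id: str | None = None, frame_offset: int = 0,
                       ambiguous: str = "mask") -> TripletAlignment:
    """Read one aligned triplet locus from multi-FASTA.

    Exactly three records are required.  Records are taken in file order as
    (ingroup1, ingroup2, outgroup) unless every header carries an explicit
    ``role=ingroup1|ingroup2|outgroup`` tag, in which case tags win.

    ``ambiguous='mask'`` replaces IUPAC ambiguity letters with N (those
    columns are skipped during site extraction); ``'reject'`` raises.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 3:
        raise MalformedInputError(
            f"{path}: expected exactly 3 records, found {len(records)}")

    tags = [re.search(r"role=(\w+)", r.description) for r in records]
    if all(tags):
        by_role = {m.group(1): r for m, r in zip(tags, records)}
        if set(by_role) != set(ROLES):
            raise MalformedInputError(
                f"{path}: role tags must be exactly {ROLES}, got {sorted(by_role)}")
        records = [by_role[r] for r in ROLES]

    lid = locus_id or path.stem
    seqs = tuple(_clean_seq(str(r.seq), lid, ambiguous) for r in records)
    return TripletAlignment(lid, locus_type, seqs, frame_offset)


def filter_locus(aln: TripletAlignment, *, max_cds_gaps: int = 30,
                 min_nc_length: int = 70) -> FilterReport:
    """Apply the locus-level inclusion filters.

    CDS loci are kept iff the total gap-character count over the three rows
    is <= ``max_cds_gaps``; NC loci iff the alignment has at least
    ``min_nc_length`` columns (the boundary value itself is kept).
    """
    if aln.locus_type == "CDS":
        if aln.gap_count > max_cds_gaps:
            return FilterReport(aln.locus_id, False, "cds_gap_excess")
    else:
        if aln.length < min_nc_length:
            return FilterReport(aln.locus_id, False, "nc_too_short")
    return FilterReport(aln.locus_id, True, "ok")


def write_triplet_fasta(aln: TripletAlignment, path: str | Path) -> None:
    """Write one triplet as multi-FASTA with explicit role tags."""
    with open(path, "w") as fh:
        for role, seq in zip(ROLES, aln.seqs):
            fh.write(f">{aln.locus_id}|{role} role={role}\n{seq}\n")


def write_dataset(alignments: list[TripletAlignment], outdir: str | Path,
                  triplet_id: str = "t0") -> Path:
    """Write a set of triplets plus a manifest TSV; returns the manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for aln in alignments:
        fname = f"{aln.locus_id}.fasta"
        write_triplet_fasta(aln, outdir / fname)
        rows.append((aln.locus_id, fname, aln.locus_type, aln.frame_offset, triplet_id))
    manifest = pd.DataFrame(rows, columns=["locus_id", "path", "locus_type",
                                           "frame_offset", "triplet_id"])
    mpath = outdir / "manifest.tsv"
    manifest.to_csv(mpath, sep="\t", index=False)
    return mpath


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a batch manifest TSV: locus_id, path, locus_type[, frame_offset, triplet_id].

    Relative paths are resolved against the manifest's directory.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"locus_id": str})
    required = {"locus_id", "path", "locus_type"}
    missing = required - set(df.columns)
    if missing:
        raise MalformedInputError(f"{path}: manifest missing columns {sorted(missing)}")
    if "frame_offset" not in df.columns:
        df["frame_offset"] = 0
    df["frame_offset"] = df["frame_offset"].fillna(0).astype(int)
    if "triplet_id" not in df.columns:
        df["triplet_id"] = "t0"
    df["path"] = [str((path.parent / p).resolve()) if not Path(p).is_absolute() else p
                  for p in df["path"]]
    return df
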