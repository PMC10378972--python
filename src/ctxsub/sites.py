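"""Site extraction and outgroup polarization.

Each eligible alignment column yields one *site observation*: an ancestral
base, a derived base (equal when the site is conserved) and the
tetranucleotide context shared by all three sequences at that column.

Polarization uses parsimony on the (ingroup1, ingroup2, outgroup) pattern:
a substitution is assignable only when the ingroups differ and the outgroup
matches exactly one of them; the matching state is ancestral.  Columns where
the ingroups agree but differ from the outgroup imply a change on the
outgroup lineage and are discarded rather than counted as conserved, so the
matrix diagonal holds only triple-conserved sites.

Context assignment requires the four flanking bases to be identical,
gap-free and unambiguous in all three sequences — a changed flank would make
the context of the substitution ill-defined.
"""

from __future__ import annotations

from collections import Counter
from typing import Iterator, NamedTuple

from .contexts import FFD_PREFIXES
from .ingest import TripletAlignment

_ACGT = frozenset("ACGT")


class SiteObservation(NamedTuple):
    site_class: str  # "FFD" | "NC"
    context: str     # L2 L1 R1 R2
    ancestral: str
    derived: str
    locus_id: str
    column: int      # 0-based alignment column of the focal site


def polarize(ingroup1: str, ingroup2: str, outgroup: str) -> tuple[str, str] | None:
    """Infer (ancestral, derived) for one site pattern, or None to discard.

    Returns (b, b) when all three agree; (outgroup-matching state, other
    state) when the ingroups differ and the outgroup sides with exactly one;
    None otherwise (ingroups agree against the outgroup, three distinct
    states, or any gap/ambiguity).
    """
    if ingroup1 not in _ACGT or ingroup2 not in _ACGT or outgroup not in _ACGT:
        return None
    if ingroup1 == ingroup2:
        return (ingroup1, ingroup1) if outgroup == ingroup1 else None
    if outgroup == ingroup1:
        return (ingroup1, ingroup2)
    if outgroup == ingroup2:
        return (ingroup2, ingroup1)
    return None


def scan_nc_columns(aln: TripletAlignment,
                    skip_log: Counter | None = None
                    ) -> Iterator[tuple[int, str, tuple[str, str, str]]]:
    """Yield (column, context, (in1, in2, out)) for context-eligible NC columns.

    A column is context-eligible when its focal base is A/C/G/T in all three
    sequences and the two columns on each side are A/C/G/T and identical
    across the three sequences.  Columns closer than 2 to either alignment
    end have no defined context and are skipped.  Polarization is *not*
    applied here; this scan defines which columns the pipeline examines.
    """
    s1, s2, s3 = aln.seqs
    for i in range(2, aln.length - 2):
        b1, b2, b3 = s1[i], s2[i], s3[i]
        if b1 not in _ACGT or b2 not in _ACGT or b3 not in _ACGT:
            if skip_log is not None:
                skip_log["center_invalid"] += 1
            continue
        ctx = s1[i - 2] + s1[i - 1] + s1[i + 1] + s1[i + 2]
        ok = True
        for j in (i - 2, i - 1, i + 1, i + 2):
            if s1[j] not in _ACGT or s1[j] != s2[j] or s1[j] != s3[j]:
                ok = False
                break
        if not ok:
            if skip_log is not None:
                skip_log["context_not_conserved"] += 1
            continue
        yield i, ctx, (b1, b2, b3)


def scan_ffd_columns(aln: TripletAlignment,
                     skip_log: Counter | None = None
                     ) -> Iterator[tuple[int, str, tuple[str, str, str]]]:
    """Yield (column, context, third-position bases) for eligible FFD sites.

    Codons are read in frame starting at ``frame_offset``.  The third
    position of a codon is eligible when (a) no sequence has a gap or
    ambiguity anywhere in the codon, (b) the first two codon positions are
    identical across the three sequences and form a fourfold-degenerate
    prefix, and (c) the first two positions of the *next* codon — the right
    flank of the site — are valid and identical across the three sequences.
    The last codon has no downstream context and is never eligible.
    """
    s1, s2, s3 = aln.seqs
    # need next codon's first two columns: c+4 must exist
    for c in range(aln.frame_offset, aln.length - 5, 3):
        codon_ok = all(s[j] in _ACGT for s in aln.seqs for j in (c, c + 1, c + 2))
        if not codon_ok:
            if skip_log is not None:
                skip_log["codon_invalid"] += 1
            continue
        if not (s1[c] == s2[c] == s3[c] and s1[c + 1] == s2[c + 1] == s3[c + 1]):
            if skip_log is not None:
                skip_log["prefix_not_conserved"] += 1
            continue
        prefix = s1[c] + s1[c + 1]
        if prefix not in FFD_PREFIXES:
            if skip_log is not None:
                skip_log["prefix_not_ffd"] += 1
            continue
        ok = True
        for j in (c + 3, c + 4):
            if (s1[j] not in _ACGT or s1[j] != s2[j] or s1[j] != s3[j]):
                ok = False
                break
        if not ok:
            if skip_log is not None:
                skip_log["context_not_conserved"] += 1
            continue
        ctx = prefix + s1[c + 3] + s1[c + 4]
        yield c + 2, ctx, (s1[c + 2], s2[c + 2], s3[c + 2])


def _extract(aln: TripletAlignment, site_class: str, scan,
             skip_log: Counter | None) -> list[SiteObservation]:
    out = []
    for col, ctx, triple in scan(aln, skip_log):
        pol = polarize(*triple)
        if pol is None:
            if skip_log is not None:
                skip_log["unpolarizable"] += 1
            continue
        out.append(SiteObservation(site_class, ctx, pol[0], pol[1], aln.locus_id, col))
    return out


def extract_nc_sites(aln: TripletAlignment,
                     skip_log: Counter | None = None) -> list[SiteObservation]:
    """Polarized site observations for a noncoding locus."""
    if aln.locus_type != "NC":
        raise ValueError(f"{aln.locus_id}: extract_nc_sites needs an NC locus")
    return _extract(aln, "NC", scan_nc_columns, skip_log)


def extract_ffd_sites(aln: TripletAlignment,
                      skip_log: Counter | None = None) -> list[SiteObservation]:
    """Polarized fourfold-degenerate third-position observations for a CDS locus."""
    if aln.locus_type != "CDS":
        raise ValueError(f"{aln.locus_id}: extract_ffd_sites needs a CDS locus")
    return _extract(aln, "FFD", scan_ffd_columns, skip_log)


def extract_sites(aln: TripletAlignment,
                  skip_log: Counter | None = None) -> list[SiteObservation]:
    """Dispatch on locus type: FFD sites for CDS loci, NC sites otherwise."""
    if aln.locus_type == "CDS":
        return extract_ffd_sites(aln, skip_log)
    return extract_nc_sites(aln, skip_log)
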