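"""Tetranucleotide contexts of a focal site.

A site N0 sits at the centre of the pentanucleotide L2 L1 [N0] R1 R2; the
four flanking bases (L2, L1, R1, R2) are its *tetranucleotide context*,
represented throughout as the 4-letter string ``L2 + L1 + R1 + R2``.

Because plastid substitution data show no strand asymmetry, a context and
its reverse complement describe the same mutational environment read from
the two strands; ``canonical_context`` picks one representative per pair.
"""

from __future__ import annotations

from itertools import product

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: Codon prefixes whose third position is fourfold degenerate under the
#: standard (and plastid, table 11) genetic code.
FFD_PREFIXES = frozenset({"CT", "GT", "TC", "CC", "AC", "GC", "CG", "GG"})

#: Default AT-index weights for (L2, L1, R1, R2): inner flanks count more.
ATI_WEIGHTS = (2, 3, 3, 2)


def is_valid_context(ctx: str) -> bool:
    return len(ctx) == 4 and all(b in BASE_INDEX for b in ctx)


def revcomp_context(ctx: str) -> str:
    """Reverse complement of a context: (L2,L1,R1,R2) -> (~R2,~R1,~L1,~L2)."""
    return "".join(COMPLEMENT[b] for b in reversed(ctx))


def canonical_context(ctx: str) -> str:
    """Lexicographically smaller of a context and its reverse complement."""
    rc = revcomp_context(ctx)
    return ctx if ctx <= rc else rc


def ati(ctx: str, weights: tuple[int, int, int, int] = ATI_WEIGHTS) -> int:
    """AT index: weighted count of A/T flanking bases (default range 0-10)."""
    return sum(w for b, w in zip(ctx, weights) if b in "AT")


def at_class(ctx: str, hi: int = 9, lo: int = 5,
             weights: tuple[int, int, int, int] = ATI_WEIGHTS) -> str:
    """Classify a context as AT_rich (ATI > hi), GC_rich (ATI < lo) or mid."""
    a = ati(ctx, weights)
    if a > hi:
        return "AT_rich"
    if a < lo:
        return "GC_rich"
    return "mid"


def enumerate_contexts(site_class: str) -> list[str]:
    """All contexts in which a site of the given class can occur.

    NC sites can occur in any of the 4^4 = 256 contexts.  FFD sites only in
    the 8 x 16 = 128 contexts whose (L2, L1) pair is a fourfold-degenerate
    codon prefix (the left flank of an FFD third position is always the
    first two codon positions).
    """
    if site_class == "NC":
        return ["".join(p) for p in product(BASES, repeat=4)]
    if site_class == "FFD":
        prefixes = sorted(FFD_PREFIXES)
        return [p + "".join(s) for p in prefixes for s in product(BASES, repeat=2)]
    raise ValueError(f"unknown site class: {site_class!r}")


def canonical_classes(site_class: str) -> list[str]:
    """Sorted canonical representatives reachable by folding the class's contexts."""
    return sorted({canonical_context(c) for c in enumerate_contexts(site_class)})


def context_code(ctx: str) -> int:
    """Pack a context into an integer in [0, 256)."""
    code = 0
    for b in ctx:
        code = code * 4 + BASE_INDEX[b]
    return code


def context_from_code(code: int) -> str:
    out = []
    for _ in range(4):
        out.append(BASES[code % 4])
        code //= 4
    return "".join(reversed(out))
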