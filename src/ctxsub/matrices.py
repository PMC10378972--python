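"""Per-context 4x4 substitution count matrices and strand folding.

For each tetranucleotide context a 4x4 matrix ``M`` counts site
observations, rows indexed by ancestral and columns by derived base in the
order A, C, G, T.  The diagonal holds conserved sites; off-diagonal cells
hold inferred substitutions.

Because the two DNA strands are equivalent descriptions of the same
molecule, the matrix of a context and the complement-transformed matrix of
its reverse-complement context estimate the same process; *folding* adds
them into one canonical representative per complementary pair (256 NC
contexts fold to 136 canonical classes: 120 pairs + 16 self-complementary).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .contexts import (BASE_INDEX, BASES, canonical_context, enumerate_contexts,
                       revcomp_context)
from .sites import SiteObservation


@dataclass
class ContextMatrix:
    context: str
    site_class: str
    M: np.ndarray = field(default_factory=lambda: np.zeros((4, 4), dtype=np.int64))

    def __post_init__(self) -> None:
        self.M = np.asarray(self.M, dtype=np.int64)
        if self.M.shape != (4, 4):
            raise ValueError("count matrix must be 4x4")
        if (self.M < 0).any():
            raise ValueError("count matrix entries must be nonnegative")

    @property
    def total(self) -> int:
        return int(self.M.sum())

    @property
    def n_subs(self) -> int:
        return int(self.M.sum() - np.trace(self.M))


def complement_transform(M: np.ndarray) -> np.ndarray:
    """Map counts onto the complementary strand: M'[~a, ~d] = M[a, d].

    With the A,C,G,T ordering, complementation is index reversal, so the
    transform is a 180-degree rotation of the matrix.
    """
    return np.ascontiguousarray(M[::-1, ::-1])


def accumulate(observations: Iterable[SiteObservation], *,
               materialize: bool = True) -> dict[str, dict[str, ContextMatrix]]:
    """Tally observations into unfolded per-context matrices, per site class.

    Each observation increments exactly one cell.  With ``materialize`` every
    enumerable context of any site class seen (or both classes if nothing is
    seen) is present as an all-zero matrix, so downstream reports can tell
    "no data" from "not enumerated".
    """
    out: dict[str, dict[str, ContextMatrix]] = {}

    def _class_map(site_class: str) -> dict[str, ContextMatrix]:
        if site_class not in out:
            ctxs = enumerate_contexts(site_class) if materialize else []
            out[site_class] = {c: ContextMatrix(c, site_class) for c in ctxs}
        return out[site_class]

    for obs in observations:
        cmap = _class_map(obs.site_class)
        if obs.context not in cmap:
            if not materialize:
                cmap[obs.context] = ContextMatrix(obs.context, obs.site_class)
            else:
                raise ValueError(
                    f"context {obs.context} not enumerable for class {obs.site_class}")
        cmap[obs.context].M[BASE_INDEX[obs.ancestral], BASE_INDEX[obs.derived]] += 1
    return out


def fold_complements(matrices: Mapping[str, ContextMatrix]) -> dict[str, ContextMatrix]:
    """Combine each context with its reverse complement into one canonical matrix.

    Non-canonical matrices are complement-transformed before being added to
    the canonical partner.  A self-complementary context receives its own
    complement transform on top of itself (counts double, and the folded
    matrix satisfies M == complement_transform(M)); the doubling is a
    bookkeeping convention that leaves every rate ratio unchanged.
    """
    out: dict[str, ContextMatrix] = {}
    for ctx, cm in matrices.items():
        rc = revcomp_context(ctx)
        canon = min(ctx, rc)
        if canon not in out:
            out[canon] = ContextMatrix(canon, cm.site_class)
        if ctx == rc:
            out[canon].M += cm.M + complement_transform(cm.M)
        elif ctx == canon:
            out[canon].M += cm.M
        else:
            out[canon].M += complement_transform(cm.M)
    return dict(sorted(out.items()))


def build_folded_matrices(observations: Iterable[SiteObservation]
                          ) -> dict[str, dict[str, ContextMatrix]]:
    """Accumulate and fold in one step; keys: site_class -> canonical context."""
    return {site_class: fold_complements(cmap)
            for site_class, cmap in accumulate(observations).items()}


# ---------------------------------------------------------------- serialization

def to_long_frame(folded: Mapping[str, Mapping[str, ContextMatrix]]) -> pd.DataFrame:
    """Long-form table: site_class, context, ancestral, derived, count."""
    rows = []
    for site_class in sorted(folded):
        for ctx in sorted(folded[site_class]):
            M = folded[site_class][ctx].M
            for a in range(4):
                for d in range(4):
                    rows.append((site_class, ctx, BASES[a], BASES[d], int(M[a, d])))
    return pd.DataFrame(rows, columns=["site_class", "context", "ancestral",
                                       "derived", "count"])


def from_long_frame(df: pd.DataFrame) -> dict[str, dict[str, ContextMatrix]]:
    out: dict[str, dict[str, ContextMatrix]] = {}
    for (site_class, ctx), grp in df.groupby(["site_class", "context"], sort=True):
        cm = ContextMatrix(ctx, site_class)
        for _, r in grp.iterrows():
            cm.M[BASE_INDEX[r["ancestral"]], BASE_INDEX[r["derived"]]] = int(r["count"])
        out.setdefault(site_class, {})[ctx] = cm
    return out


def write_matrices_tsv(folded, path: str | Path) -> None:
    to_long_frame(folded).to_csv(path, sep="\t", index=False)


def read_matrices_tsv(path: str | Path) -> dict[str, dict[str, ContextMatrix]]:
    return from_long_frame(pd.read_csv(path, sep="\t"))


def write_matrices_json(folded, path: str | Path) -> None:
    obj = {site_class: {ctx: cm.M.tolist() for ctx, cm in sorted(cmap.items())}
           for site_class, cmap in sorted(folded.items())}
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True))


def read_matrices_json(path: str | Path) -> dict[str, dict[str, ContextMatrix]]:
    obj = json.loads(Path(path).read_text())
    return {site_class: {ctx: ContextMatrix(ctx, site_class, np.array(m))
                         for ctx, m in cmap.items()}
            for site_class, cmap in obj.items()}
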