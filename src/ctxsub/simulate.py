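"""Sequence-triplet simulator with neighbor-dependent substitution rates.

Sequences evolve under a continuous-time Markov process in which the
instantaneous 4x4 rate matrix of every site is looked up from its current
tetranucleotide context, so contexts co-evolve with the sites they flank.
Each branch is simulated exactly by thinning a dominating Poisson process
(candidate events at the per-site maximum rate, accepted with probability
actual/maximum), which is equivalent to Gillespie's algorithm but lets all
random draws be vectorized.

The tree is a star over (ingroup1, ingroup2, outgroup) rooted at their
common ancestor, with branch lengths in expected substitutions per site
(rate models are normalized to mean rate 1).  No indels and no selection
are modeled; CDS loci only constrain structure (codon frame, no stop codons
at the root).  Sequence ends carry two fixed immutable flanking bases so
terminal sites have defined contexts; the flanks are not emitted.

Ground truth is a log of every substitution event (site, time, branch,
from/to base, context at event time), against which the inference pipeline
can be scored (`recovery_report`).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .contexts import (BASES, ati, canonical_context, context_from_code)
from .ingest import TripletAlignment
from .matrices import build_folded_matrices
from .sites import SiteObservation, extract_sites, scan_ffd_columns, scan_nc_columns

_TS_PARTNER = (2, 3, 0, 1)  # A<->G, C<->T in A,C,G,T index order
_STOPS = {(3, 0, 0), (3, 0, 2), (3, 2, 0)}  # TAA, TAG, TGA


class RateModel:
    """Per-context instantaneous rate matrices, indexed by packed context code.

    ``Q`` has shape (256, 4, 4): ``Q[code, a, b]`` is the rate of a -> b for
    a site with context ``code``; diagonals are zero.  Models built through
    :meth:`from_context_fn` are strand-symmetric by construction (the rate
    matrix of a non-canonical context is the complement transform of its
    canonical partner's) and normalized so the mean total rate over all
    contexts and bases is 1, making branch lengths expected substitutions
    per site.
    """

    def __init__(self, Q: np.ndarray):
        Q = np.asarray(Q, dtype=float)
        if Q.shape != (256, 4, 4):
            raise ValueError("rate model must have shape (256, 4, 4)")
        if (Q < 0).any() or not np.isfinite(Q).all():
            raise ValueError("rates must be finite and nonnegative")
        if np.abs(Q[:, range(4), range(4)]).max() > 0:
            raise ValueError("rate-matrix diagonals must be zero")
        self.Q = Q
        self.row_total = Q.sum(axis=2)                     # (256, 4)
        self.r_max = float(self.row_total.max())
        with np.errstate(invalid="ignore", divide="ignore"):
            probs = Q / self.row_total[:, :, None]
        self.cum_probs = np.nan_to_num(probs).cumsum(axis=2)

    @classmethod
    def from_context_fn(cls, fn: Callable[[str], np.ndarray], *,
                        normalize: bool = True) -> "RateModel":
        """Build from a function mapping a *canonical* context to a 4x4 rate matrix."""
        Q = np.zeros((256, 4, 4))
        cache: dict[str, np.ndarray] = {}
        for code in range(256):
            ctx = context_from_code(code)
            canon = canonical_context(ctx)
            if canon not in cache:
                q = np.array(fn(canon), dtype=float)
                np.fill_diagonal(q, 0.0)
                cache[canon] = q
            q = cache[canon]
            Q[code] = q if ctx == canon else q[::-1, ::-1]
        if normalize:
            mean_rate = Q.sum(axis=2).mean()
            if mean_rate <= 0:
                raise ValueError("rate model is identically zero")
            Q = Q / mean_rate
        return cls(Q)

    @classmethod
    def jukes_cantor(cls) -> "RateModel":
        return cls.from_context_fn(lambda ctx: np.ones((4, 4)))

    @classmethod
    def k2p(cls, kappa: float | Callable[[str], float] = 2.0) -> "RateModel":
        """Kimura two-parameter rates; kappa may depend on the (canonical) context."""
        kfn = kappa if callable(kappa) else (lambda ctx: kappa)

        def fn(ctx: str) -> np.ndarray:
            q = np.ones((4, 4))
            k = kfn(ctx)
            for a in range(4):
                q[a, _TS_PARTNER[a]] = k
            return q
        return cls.from_context_fn(fn)

    @classmethod
    def hky(cls, target: Sequence[float] | Callable[[str], Sequence[float]],
            kappa: float | Callable[[str], float] = 2.0) -> "RateModel":
        """HKY-style rates q(a->b) = target[b] * (kappa if transition).

        The CTMC stationary distribution within a fixed context is exactly
        ``target`` (which may depend on the canonical context), handy as
        analytic ground truth for recovery tests.
        """
        tfn = target if callable(target) else (lambda ctx: target)
        kfn = kappa if callable(kappa) else (lambda ctx: kappa)

        def fn(ctx: str) -> np.ndarray:
            g = np.asarray(tfn(ctx), dtype=float)
            q = np.tile(g, (4, 1))
            k = kfn(ctx)
            for a in range(4):
                q[a, _TS_PARTNER[a]] *= k
            return q
        return cls.from_context_fn(fn)

    def generator(self, ctx: str) -> np.ndarray:
        """Full CTMC generator (diagonal = -row sum) for one context."""
        from .contexts import context_code
        q = self.Q[context_code(ctx)].copy()
        np.fill_diagonal(q, -q.sum(axis=1))
        return q

    def stationary(self, ctx: str) -> np.ndarray:
        """Analytic stationary distribution of the context's CTMC generator."""
        g = self.generator(ctx)
        A = g.T.copy()
        A[-1, :] = 1.0
        b = np.zeros(4)
        b[-1] = 1.0
        pi = np.linalg.solve(A, b)
        return np.clip(pi, 0, None) / np.clip(pi, 0, None).sum()

    def expected_ts_tv(self, ctx: str,
                       comp: Sequence[float] | None = None) -> float:
        """Expected substitution-count ts:tv at low divergence for one context."""
        from .contexts import context_code
        q = self.Q[context_code(ctx)]
        f = np.full(4, 0.25) if comp is None else np.asarray(comp, float)
        ts = sum(f[a] * q[a, _TS_PARTNER[a]] for a in range(4))
        tv = float((f[:, None] * q).sum()) - ts
        return ts / tv


def at_biased_target(ctx: str, lo: float = 0.15, hi: float = 0.85) -> np.ndarray:
    """Context-dependent HKY target: A+T weight rises linearly with the ATI."""
    w_at = lo + (hi - lo) * ati(ctx) / 10.0
    return np.array([w_at / 2, (1 - w_at) / 2, (1 - w_at) / 2, w_at / 2])


@dataclass
class SimScenario:
    """Ground-truth settings for one simulated set of triplet loci."""

    seed: int
    n_loci: int
    locus_length: int
    locus_type: str  # "CDS" | "NC"
    t_in1: float
    t_in2: float
    t_out: float
    rate_model: RateModel
    root_composition: np.ndarray = field(
        default_factory=lambda: np.array([0.3, 0.2, 0.2, 0.3]))

    def __post_init__(self) -> None:
        self.root_composition = np.asarray(self.root_composition, dtype=float)
        if self.root_composition.shape != (4,) or (self.root_composition < 0).any():
            raise ValueError("root_composition must be 4 nonnegative weights")
        self.root_composition = self.root_composition / self.root_composition.sum()
        if min(self.t_in1, self.t_in2, self.t_out) < 0:
            raise ValueError("branch lengths must be >= 0")
        if self.locus_type not in ("CDS", "NC"):
            raise ValueError("locus_type must be CDS or NC")
        if self.locus_type == "CDS" and self.locus_length % 3:
            raise ValueError("CDS locus_length must be a multiple of 3")
        if self.n_loci < 1 or self.locus_length < 1:
            raise ValueError("need n_loci >= 1 and locus_length >= 1")


def _root_sequence(scn: SimScenario, rng: np.random.Generator) -> np.ndarray:
    """Root plus two fixed flanking bases on each end, as base indices."""
    L = scn.locus_length
    if scn.locus_type == "NC":
        core = rng.choice(4, size=L, p=scn.root_composition)
    else:
        codons = rng.choice(4, size=(L // 3, 3), p=scn.root_composition)
        for k in range(codons.shape[0]):  # redraw in-frame stop codons
            while tuple(codons[k]) in _STOPS:
                codons[k] = rng.choice(4, size=3, p=scn.root_composition)
        core = codons.reshape(-1)
    pads = rng.choice(4, size=4, p=scn.root_composition)
    return np.concatenate([pads[:2], core, pads[2:]]).astype(np.int64)


def _evolve_branch(seq: np.ndarray, T: float, model: RateModel,
                   rng: np.random.Generator, locus_id: str, branch: str,
                   events: list) -> None:
    """Evolve ``seq`` in place for duration T, appending true events."""
    L = len(seq) - 4
    r_max = model.r_max
    if T <= 0 or r_max <= 0:
        return
    n_cand = rng.poisson(L * r_max * T)
    if n_cand == 0:
        return
    times = np.sort(rng.random(n_cand)) * T
    sites = rng.integers(2, L + 2, size=n_cand)
    u_acc = rng.random(n_cand) * r_max
    u_tgt = rng.random(n_cand)
    row_total, cum = model.row_total, model.cum_probs
    for idx in range(n_cand):
        i = sites[idx]
        ctx = ((seq[i - 2] * 4 + seq[i - 1]) * 4 + seq[i + 1]) * 4 + seq[i + 2]
        a = seq[i]
        r = row_total[ctx, a]
        if u_acc[idx] >= r:
            continue
        b = int(np.searchsorted(cum[ctx, a], u_tgt[idx], side="right"))
        b = min(b, 3)
        events.append((locus_id, branch, int(i - 2), float(times[idx]),
                       BASES[a], BASES[b], context_from_code(int(ctx))))
        seq[i] = b


EVENT_COLUMNS = ["locus_id", "branch", "column", "time",
                 "from_base", "to_base", "context"]


def simulate_triplet(scn: SimScenario
                     ) -> tuple[list[TripletAlignment], pd.DataFrame]:
    """Simulate all loci of a scenario.

    Returns gap-free aligned triplets plus the true substitution-event log
    (one row per event, with the tetranucleotide context at event time).
    """
    rng = np.random.default_rng(scn.seed)
    alignments: list[TripletAlignment] = []
    events: list = []
    for k in range(scn.n_loci):
        locus_id = f"{scn.locus_type.lower()}_{k:04d}"
        root = _root_sequence(scn, rng)
        leaves = []
        for branch, T in (("in1", scn.t_in1), ("in2", scn.t_in2),
                          ("out", scn.t_out)):
            s = root.copy()
            _evolve_branch(s, T, scn.rate_model, rng, locus_id, branch, events)
            leaves.append("".join(BASES[b] for b in s[2:-2]))
        alignments.append(TripletAlignment(locus_id, scn.locus_type,
                                           tuple(leaves), 0))
    return alignments, pd.DataFrame(events, columns=EVENT_COLUMNS)


def recovery_report(alignments: list[TripletAlignment], events: pd.DataFrame,
                    observations: list[SiteObservation] | None = None,
                    min_truth_count: int = 25) -> dict:
    """Score the inference pipeline against the simulator's event log.

    * ``polarization_sensitivity`` — among true substitution events on the
      two ingroup branches at *examined* sites (context intact in the final
      alignment and class-eligible), the fraction recovered with the correct
      ancestral -> derived assignment.  Context-disturbed sites are excluded
      from the denominator and reported separately via ``context_coverage``,
      the fraction of ingroup-event sites that remain examined.
    * ``false_polarization_rate`` — fraction of emitted substitution
      observations with no matching true ingroup event (multiple hits or
      outgroup-branch changes misread as ingroup substitutions).
    * ``median_context_count_rel_error`` — per canonical context with at
      least ``min_truth_count`` true ingroup events at examined sites, the
      median relative error of the inferred folded substitution count
      (truth restricted to examined sites, so the metric scores inference
      quality, not context-conservation coverage).
    """
    site_class = "FFD" if alignments[0].locus_type == "CDS" else "NC"
    scan = scan_ffd_columns if site_class == "FFD" else scan_nc_columns
    examined: set[tuple[str, int]] = set()
    for aln in alignments:
        for col, _ctx, _triple in scan(aln):
            examined.add((aln.locus_id, col))
    if observations is None:
        observations = [o for aln in alignments for o in extract_sites(aln)]
    obs_map = {(o.locus_id, o.column): o for o in observations}

    ing = events[events["branch"].isin(("in1", "in2"))]
    n_events = len(ing)
    n_examined = n_recovered = 0
    truth_pairs: set[tuple[str, int, str, str]] = set()
    truth_ctx: Counter = Counter()
    for ev in ing.itertuples(index=False):
        key = (ev.locus_id, ev.column)
        truth_pairs.add((ev.locus_id, ev.column, ev.from_base, ev.to_base))
        if key not in examined:
            continue
        truth_ctx[canonical_context(ev.context)] += 1
        n_examined += 1
        o = obs_map.get(key)
        if o is not None and (o.ancestral, o.derived) == (ev.from_base, ev.to_base):
            n_recovered += 1

    subs_obs = [o for o in observations if o.ancestral != o.derived]
    n_false = sum(1 for o in subs_obs
                  if (o.locus_id, o.column, o.ancestral, o.derived) not in truth_pairs)

    folded = build_folded_matrices(observations).get(site_class, {})
    rel_errors = []
    for ctx, n_true in truth_ctx.items():
        if n_true < min_truth_count:
            continue
        n_inf = folded[ctx].n_subs if ctx in folded else 0
        rel_errors.append(abs(n_inf - n_true) / n_true)

    return {
        "n_true_ingroup_events": n_events,
        "n_examined_events": n_examined,
        "n_recovered": n_recovered,
        "polarization_sensitivity": (n_recovered / n_examined
                                     if n_examined else float("nan")),
        "context_coverage": n_examined / n_events if n_events else float("nan"),
        "n_substitution_observations": len(subs_obs),
        "false_polarization_rate": (n_false / len(subs_obs)
                                    if subs_obs else 0.0),
        "n_contexts_scored": len(rel_errors),
        "median_context_count_rel_error": (float(np.median(rel_errors))
                                           if rel_errors else float("nan")),
    }
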