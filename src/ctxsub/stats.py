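"""Per-context substitution statistics and aggregate analyses.

From each folded count matrix this module derives:

* substitution rates — per ancestral base (row off-diagonal sum / row
  total), overall, and split into transitions (A<->G, C<->T) versus
  transversions, with ts:tv;
* the stationary vector pi of the empirical one-step Markov transition
  matrix P (rows of M normalized), i.e. the equilibrium base composition a
  site would evolve to if its context stayed fixed, and its A+T content;
* a bootstrap of the equilibrium A+T content, resampling each row's
  off-diagonal substitutions with replacement while keeping the diagonal
  and the row's substitution total fixed.

Aggregate operations build the CpG-effect 2x2 odds-ratio tables (focal
transition vs other changes, in CG vs non-CG dinucleotides) and compare two
per-context statistic sets (r-squared, fraction x > y, and a binomial
point-null Bayes factor for that fraction).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.special import gammaln
from scipy.stats import pearsonr

from .contexts import at_class, ati
from .matrices import ContextMatrix

# transition cells (A<->G, C<->T) in A,C,G,T index order
_TS_CELLS = ((0, 2), (2, 0), (1, 3), (3, 1))
_TS_MASK = np.zeros((4, 4), dtype=bool)
for _a, _d in _TS_CELLS:
    _TS_MASK[_a, _d] = True
_OFFDIAG = ~np.eye(4, dtype=bool)
_TV_MASK = _OFFDIAG & ~_TS_MASK


def row_rates(M: ContextMatrix | np.ndarray) -> tuple[np.ndarray, float]:
    """Per-ancestral-base and overall substitution rates.

    rate_from[b] = off-diagonal sum of row b / row b total (NaN for empty
    rows); rate_overall = total off-diagonal / matrix total (NaN for an
    all-zero matrix) — never reported as 0 for missing data.
    """
    M = M.M if isinstance(M, ContextMatrix) else np.asarray(M)
    row_tot = M.sum(axis=1).astype(float)
    off = row_tot - np.diag(M)
    with np.errstate(invalid="ignore", divide="ignore"):
        rate_from = np.where(row_tot > 0, off / row_tot, np.nan)
    total = M.sum()
    rate_overall = float(off.sum() / total) if total > 0 else float("nan")
    return rate_from, rate_overall


def ts_tv_rates(M: ContextMatrix | np.ndarray) -> tuple[float, float, float]:
    """(ts_rate, tv_rate, ts:tv); ts:tv is NaN when the tv count is zero.

    The partition ts_count + tv_count == off-diagonal total is exact in
    integer arithmetic; the corresponding rate identity
    ts_rate + tv_rate == rate_overall therefore holds exactly as a ratio of
    integers (floats agree to within one ulp).
    """
    M = M.M if isinstance(M, ContextMatrix) else np.asarray(M)
    total = M.sum()
    if total == 0:
        return float("nan"), float("nan"), float("nan")
    ts = M[_TS_MASK].sum()
    tv = M[_TV_MASK].sum()
    ts_rate = float(ts / total)
    tv_rate = float(tv / total)
    ts_tv = float(ts / tv) if tv > 0 else float("nan")
    return ts_rate, tv_rate, ts_tv


def transition_matrix(M: ContextMatrix | np.ndarray) -> np.ndarray | None:
    """Row-normalized empirical one-step transition matrix, or None if any row is empty."""
    M = M.M if isinstance(M, ContextMatrix) else np.asarray(M)
    row_tot = M.sum(axis=1).astype(float)
    if (row_tot == 0).any():
        return None
    return M / row_tot[:, None]


def _is_irreducible(P: np.ndarray) -> bool:
    n, _ = connected_components(csr_matrix(P > 0), directed=True, connection="strong")
    return n == 1


def _solve_stationary(P: np.ndarray) -> np.ndarray:
    # pi (P - I) = 0 with sum(pi) = 1: replace last equation by the normalization
    A = P.T - np.eye(4)
    A[-1, :] = 1.0
    b = np.zeros(4)
    b[-1] = 1.0
    return np.linalg.solve(A, b)


def stationary_vector(M: ContextMatrix | np.ndarray) -> np.ndarray | None:
    """Stationary distribution pi of the row-normalized matrix, pi @ P == pi.

    Returns None (a flagged, missing result) when any row total is zero or
    the chain is reducible, in which case no unique equilibrium exists.
    """
    P = transition_matrix(M)
    if P is None or not _is_irreducible(P):
        return None
    pi = _solve_stationary(P)
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


def eq_at(pi: np.ndarray | None) -> float:
    """Equilibrium A+T content of a stationary vector."""
    if pi is None:
        return float("nan")
    return float(pi[0] + pi[3])


def bootstrap_eq_at(M: ContextMatrix | np.ndarray, n_boot: int = 1000,
                    seed: int | np.random.SeedSequence | None = 0
                    ) -> tuple[float, float]:
    """Bootstrap mean and sd of equilibrium A+T.

    Each resample keeps every row's diagonal and off-diagonal total but
    redraws the row's substitutions with replacement from the observed
    off-diagonal cells (a multinomial with the observed cell proportions).
    Resamples whose chain loses irreducibility are dropped.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    M = (M.M if isinstance(M, ContextMatrix) else np.asarray(M)).astype(np.int64)
    rng = np.random.default_rng(seed)

    samples = np.repeat(M[None, :, :], n_boot, axis=0).astype(float)
    for a in range(4):
        off = np.delete(M[a], a)
        n_sub = off.sum()
        if n_sub == 0:
            continue
        draws = rng.multinomial(n_sub, off / n_sub, size=n_boot)  # (n_boot, 3)
        cols = [d for d in range(4) if d != a]
        samples[:, a, cols] = draws

    row_tot = samples.sum(axis=2)
    if (row_tot == 0).any():
        return float("nan"), float("nan")
    P = samples / row_tot[:, :, None]
    A = np.transpose(P, (0, 2, 1)) - np.eye(4)
    A[:, -1, :] = 1.0
    b = np.zeros((n_boot, 4, 1))
    b[:, -1, 0] = 1.0
    try:
        pis = np.linalg.solve(A, b)[:, :, 0]
    except np.linalg.LinAlgError:
        pis = np.full((n_boot, 4), np.nan)
        for k in range(n_boot):
            try:
                pis[k] = _solve_stationary(P[k])
            except np.linalg.LinAlgError:
                pass
    ats = pis[:, 0] + pis[:, 3]
    ats = ats[np.isfinite(ats)]
    if ats.size == 0:
        return float("nan"), float("nan")
    return float(ats.mean()), float(ats.std(ddof=0))


@dataclass
class ContextStats:
    """All derived quantities for one folded context matrix."""

    context: str
    site_class: str
    n_total: int
    n_subs: int
    rate_overall: float
    rate_from: np.ndarray  # per ancestral base, A C G T
    ts_rate: float
    tv_rate: float
    ts_tv: float
    ATI: int
    at_class: str
    pi: np.ndarray | None
    eq_AT: float
    boot_mean_AT: float
    boot_sd_AT: float
    reportable: bool


def context_stats(cm: ContextMatrix, *, n_boot: int = 1000,
                  seed: int | np.random.SeedSequence | None = 0,
                  min_subs_report: int = 25, ati_hi: int = 9,
                  ati_lo: int = 5) -> ContextStats:
    """Compute the full per-context statistics record for one folded matrix."""
    rate_from, rate_overall = row_rates(cm)
    ts_rate, tv_rate, ts_tv = ts_tv_rates(cm)
    pi = stationary_vector(cm)
    if pi is not None and cm.n_subs > 0:
        bmean, bsd = bootstrap_eq_at(cm, n_boot=n_boot, seed=seed)
    else:
        bmean, bsd = float("nan"), float("nan")
    return ContextStats(
        context=cm.context, site_class=cm.site_class,
        n_total=cm.total, n_subs=cm.n_subs,
        rate_overall=rate_overall, rate_from=rate_from,
        ts_rate=ts_rate, tv_rate=tv_rate, ts_tv=ts_tv,
        ATI=ati(cm.context), at_class=at_class(cm.context, hi=ati_hi, lo=ati_lo),
        pi=pi, eq_AT=eq_at(pi), boot_mean_AT=bmean, boot_sd_AT=bsd,
        reportable=cm.n_subs >= min_subs_report,
    )


# ----------------------------------------------------------------- CpG tables

@dataclass(frozen=True)
class CpGTable:
    """2x2 table of focal-change vs other-change counts in CG vs non-CG contexts."""

    site_class: str
    focal_change: str  # "G>A" (5' neighbor read) or "C>T" (3' neighbor read)
    counts: tuple[tuple[int, int], tuple[int, int]]  # rows: CG, non-CG

    @property
    def odds_ratio(self) -> float:
        (a, b), (c, d) = self.counts
        if min(b, c, d) == 0:
            return float("nan")
        return (a / b) / (c / d)


def odds_ratio(a: int, b: int, c: int, d: int) -> float:
    """(a/b)/(c/d) for the 2x2 table [[a, b], [c, d]]."""
    return CpGTable("", "", ((a, b), (c, d))).odds_ratio


def cpg_tables(folded: Mapping[str, ContextMatrix], site_class: str) -> list[CpGTable]:
    """Build the two CpG-effect tables from a folded per-context matrix map.

    Folding makes the two strand readings of the CpG dinucleotide explicit:
    for substitutions from G the 5' neighbor (L1) distinguishes CG from DG
    contexts; for substitutions from C the 3' neighbor (R1) distinguishes CG
    from CH.  The focal change is the CpG-type transition (G->A, resp. C->T);
    the comparison count pools the remaining changes from that base.  Outer
    context bases are marginalized by summation.
    """
    A, C, G, T = 0, 1, 2, 3
    g_tab = np.zeros((2, 2), dtype=np.int64)  # rows: CG, DG; cols: G>A, G>B
    c_tab = np.zeros((2, 2), dtype=np.int64)  # rows: CG, CH; cols: C>T, C>V
    for ctx, cm in folded.items():
        if cm.site_class != site_class:
            raise ValueError(f"matrix for {ctx} is {cm.site_class}, not {site_class}")
        M = cm.M
        g_row = 0 if ctx[1] == "C" else 1      # L1 == C -> the G sits in a CpG
        g_tab[g_row, 0] += M[G, A]
        g_tab[g_row, 1] += M[G, C] + M[G, T]
        c_row = 0 if ctx[2] == "G" else 1      # R1 == G -> the C sits in a CpG
        c_tab[c_row, 0] += M[C, T]
        c_tab[c_row, 1] += M[C, A] + M[C, G]
    return [
        CpGTable(site_class, "G>A", tuple(map(tuple, g_tab.tolist()))),
        CpGTable(site_class, "C>T", tuple(map(tuple, c_tab.tolist()))),
    ]


# ------------------------------------------------------------- set comparison

def binomial_point_null_bf10(k: int, n: int) -> float:
    """BF10 for k successes in n trials: Beta(1,1) alternative vs p = 0.5.

    Marginal likelihood under the uniform alternative is 1/(n+1); under the
    point null it is C(n, k) / 2^n.  Identical to the Savage-Dickey density
    ratio for this pair of models.
    """
    if n < 1 or not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n, n >= 1")
    log_binom = gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
    log_bf = -np.log(n + 1.0) - (log_binom - n * np.log(2.0))
    return float(np.exp(log_bf))


def compare_sets(x: Mapping[str, float], y: Mapping[str, float]
                 ) -> dict[str, float] | None:
    """Compare two per-context statistic maps over their shared finite keys.

    Returns r-squared of the least-squares fit, the percentage of contexts
    with strictly x > y, and the binomial point-null Bayes factor (BF10) for
    that count against chance; None when fewer than 3 contexts are shared.
    """
    keys = sorted(k for k in x.keys() & y.keys()
                  if np.isfinite(x[k]) and np.isfinite(y[k]))
    n = len(keys)
    if n < 3:
        return None
    xv = np.array([x[k] for k in keys])
    yv = np.array([y[k] for k in keys])
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        r2 = float("nan")
    else:
        r2 = float(pearsonr(xv, yv)[0] ** 2)
    k_gt = int((xv > yv).sum())
    return {
        "n": n,
        "r2": r2,
        "pct_x_gt_y": 100.0 * k_gt / n,
        "bayes_factor": binomial_point_null_bf10(k_gt, n),
    }
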