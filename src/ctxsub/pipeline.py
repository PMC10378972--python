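"""End-to-end orchestration: manifest in, tables out.

``run_pipeline`` drives ingest -> filter -> site extraction -> count
matrices -> folding -> per-context statistics -> CpG tables -> FFD-vs-NC
comparison, writing deterministic TSV/JSON outputs (identical config and
seed give byte-identical files).  Bootstrap random streams are derived per
(seed, site class, context), so results do not depend on iteration order.
"""

from __future__ import annotations

import hashlib
import json
import logging
from collections import Counter
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .contexts import context_code
from .ingest import filter_locus, read_manifest, read_triplet_fasta
from .matrices import build_folded_matrices, write_matrices_json, write_matrices_tsv
from .sites import extract_sites
from .stats import compare_sets, context_stats, cpg_tables

log = logging.getLogger("ctxsub")

_CLASS_CODE = {"FFD": 0, "NC": 1}


class EmptyResultError(RuntimeError):
    """No locus survived filtering; nothing to analyze."""


@dataclass
class RunConfig:
    manifest: str
    outdir: str
    seed: int = 0
    n_boot: int = 1000
    min_subs_report: int = 25
    ati_hi: int = 9
    ati_lo: int = 5
    write_observations: bool = True
    external_tables: dict = field(default_factory=dict)
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")
        if self.min_subs_report < 0:
            raise ValueError("min_subs_report must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        cfg = yaml.safe_load(Path(path).read_text())
        return cls(**cfg)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def bootstrap_seed(master_seed: int, site_class: str, context: str
                   ) -> np.random.SeedSequence:
    """Deterministic per-context bootstrap stream, independent of run order."""
    return np.random.SeedSequence(
        (master_seed, _CLASS_CODE[site_class], context_code(context)))


def stats_frame(folded: dict, config: RunConfig) -> pd.DataFrame:
    """Per-context statistics table (one row per canonical context x class)."""
    rows = []
    for site_class in sorted(folded):
        for ctx in sorted(folded[site_class]):
            cs = context_stats(
                folded[site_class][ctx], n_boot=config.n_boot,
                seed=bootstrap_seed(config.seed, site_class, ctx),
                min_subs_report=config.min_subs_report,
                ati_hi=config.ati_hi, ati_lo=config.ati_lo)
            pi = [float("nan")] * 4 if cs.pi is None else list(cs.pi)
            rows.append({
                "site_class": cs.site_class, "context": cs.context,
                "ATI": cs.ATI, "at_class": cs.at_class,
                "n_total": cs.n_total, "n_subs": cs.n_subs,
                "rate_overall": cs.rate_overall,
                "rate_from_A": cs.rate_from[0], "rate_from_C": cs.rate_from[1],
                "rate_from_G": cs.rate_from[2], "rate_from_T": cs.rate_from[3],
                "ts_rate": cs.ts_rate, "tv_rate": cs.tv_rate, "ts_tv": cs.ts_tv,
                "pi_A": pi[0], "pi_C": pi[1], "pi_G": pi[2], "pi_T": pi[3],
                "eq_AT": cs.eq_AT, "boot_mean_AT": cs.boot_mean_AT,
                "boot_sd_AT": cs.boot_sd_AT, "reportable": cs.reportable,
            })
    return pd.DataFrame(rows)


def cpg_frame(folded: dict) -> pd.DataFrame:
    rows = []
    for site_class in sorted(folded):
        for tab in cpg_tables(folded[site_class], site_class):
            (a, b), (c, d) = tab.counts
            rows.append({"site_class": site_class, "focal_change": tab.focal_change,
                         "cg_focal": a, "cg_other": b,
                         "noncg_focal": c, "noncg_other": d,
                         "odds_ratio": tab.odds_ratio})
    return pd.DataFrame(rows)


def load_external_context_table(path: str | Path) -> dict[str, float]:
    """Generic per-context statistic TSV (columns: context, value)."""
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["context"].astype(str), df["value"].astype(float)))


def _comparisons(stats: pd.DataFrame, config: RunConfig) -> dict:
    """FFD-vs-NC and external comparisons over reportable contexts."""
    out: dict = {}
    rep = stats[stats["reportable"]]

    def stat_map(site_class: str, stat: str) -> dict[str, float]:
        sub = rep[rep["site_class"] == site_class].set_index("context")
        return sub[stat].dropna().to_dict() if len(sub) else {}

    classes = set(stats["site_class"])
    if {"FFD", "NC"} <= classes:
        for stat in ("rate_overall", "eq_AT"):
            # None when fewer than 3 reportable contexts are shared
            out[f"ffd_vs_nc_{stat}"] = compare_sets(stat_map("FFD", stat),
                                                    stat_map("NC", stat))
    for name, path in sorted(config.external_tables.items()):
        ext = load_external_context_table(path)
        if "NC" in classes:
            out[f"nc_vs_{name}"] = compare_sets(stat_map("NC", "rate_overall"),
                                                ext)
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis; returns a summary dict (also written as JSON)."""
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    manifest = read_manifest(config.manifest)
    reports, kept, observations = [], [], []
    skip_log: Counter = Counter()
    for row in manifest.itertuples(index=False):
        aln = read_triplet_fasta(row.path, row.locus_type, locus_id=row.locus_id,
                                 frame_offset=row.frame_offset)
        rep = filter_locus(aln)
        reports.append(rep)
        if rep.kept:
            kept.append(aln)
            observations.extend(extract_sites(aln, skip_log))
    log.info("loci: %d in, %d kept; sites: %d emitted, skipped: %s",
             len(reports), len(kept), len(observations), dict(skip_log))

    pd.DataFrame([{"locus_id": r.locus_id, "kept": r.kept, "reason": r.reason}
                  for r in reports]).to_csv(outdir / "filter_report.tsv",
                                            sep="\t", index=False)
    if not kept:
        raise EmptyResultError("no locus passed the filters")

    if config.write_observations:
        pd.DataFrame(observations).to_csv(outdir / "site_observations.tsv",
                                          sep="\t", index=False)
    pd.DataFrame(sorted(skip_log.items()),
                 columns=["reason", "n_columns"]).to_csv(
        outdir / "skip_summary.tsv", sep="\t", index=False)

    folded = build_folded_matrices(observations)
    write_matrices_tsv(folded, outdir / "matrices.tsv")
    write_matrices_json(folded, outdir / "matrices.json")

    stats = stats_frame(folded, config)
    stats.to_csv(outdir / "context_stats.tsv", sep="\t", index=False)
    cpg = cpg_frame(folded)
    cpg.to_csv(outdir / "cpg_tables.tsv", sep="\t", index=False)

    summary = {
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "bayes_factor_method": "binomial point-null BF10, Beta(1,1) alternative",
        "n_loci_in": len(reports),
        "n_loci_kept": len(kept),
        "n_observations": len(observations),
        "skip_log": dict(sorted(skip_log.items())),
        "n_reportable": {sc: int(grp["reportable"].sum())
                         for sc, grp in stats.groupby("site_class")},
        "comparisons": _comparisons(stats, config),
        "self_complementary_note": ("self-complementary contexts hold doubled "
                                    "counts after strand folding"),
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=1,
                                                    sort_keys=True))
    return summary
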