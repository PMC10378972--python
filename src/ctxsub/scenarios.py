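"""Named simulation scenarios used by the analysis drivers and tests.

Branch lengths default to 0.01-0.02 expected substitutions per site, the
low-divergence regime in which outgroup parsimony is reliable (multiple
hits are O(t^2)) and the regime the closely-related plastome triplets of
the motivating dataset occupy.  Root composition defaults to an A+T-rich
mix (60% A+T), a plastome-like figure.
"""

from __future__ import annotations

import numpy as np

from .simulate import RateModel, SimScenario, at_biased_target


def at_biased_model(kappa: float = 2.0) -> RateModel:
    """HKY rates whose per-context target composition rises with the ATI.

    A+T-rich contexts pull sites toward A/T (equilibrium A+T from 0.15 at
    ATI 0 to 0.85 at ATI 10), giving the wide spread of per-context
    equilibrium compositions the real data show and exact analytic ground
    truth (the HKY target) for round-trip tests.
    """
    return RateModel.hky(at_biased_target, kappa=kappa)


def nc_default(seed: int, n_loci: int = 20, locus_length: int = 3000,
               t: float = 0.02) -> SimScenario:
    """Default noncoding scenario: ~60 kb over 20 intergenic-sized loci."""
    return SimScenario(seed=seed, n_loci=n_loci, locus_length=locus_length,
                       locus_type="NC", t_in1=t, t_in2=t, t_out=t,
                       rate_model=at_biased_model())


def cds_default(seed: int, n_loci: int = 30, locus_length: int = 999,
                t: float = 0.02) -> SimScenario:
    """Default coding scenario: 30 gene-sized codon-structured loci."""
    return SimScenario(seed=seed, n_loci=n_loci, locus_length=locus_length,
                       locus_type="CDS", t_in1=t, t_in2=t, t_out=t,
                       rate_model=at_biased_model())


def nc_large(seed: int, n_loci: int = 60, locus_length: int = 10_000,
             t: float = 0.02) -> SimScenario:
    """Large NC scenario (600 kb) for equilibrium-composition round trips."""
    return SimScenario(seed=seed, n_loci=n_loci, locus_length=locus_length,
                       locus_type="NC", t_in1=t, t_in2=t, t_out=t,
                       rate_model=at_biased_model())


def sensitivity_scenario(seed: int, n_loci: int = 20,
                         locus_length: int = 10_000) -> SimScenario:
    """200 kb NC at t = 0.01 per branch, for polarization-recovery scoring."""
    return SimScenario(seed=seed, n_loci=n_loci, locus_length=locus_length,
                       locus_type="NC", t_in1=0.01, t_in2=0.01, t_out=0.01,
                       rate_model=at_biased_model())


def model_from_dict(cfg: dict) -> RateModel:
    """Build a rate model from a plain config mapping (YAML-friendly)."""
    kind = cfg.get("type", "at_biased")
    if kind == "jc":
        return RateModel.jukes_cantor()
    if kind == "k2p":
        return RateModel.k2p(cfg.get("kappa", 2.0))
    if kind == "hky":
        return RateModel.hky(np.asarray(cfg["target"], float),
                             cfg.get("kappa", 2.0))
    if kind == "at_biased":
        return at_biased_model(cfg.get("kappa", 2.0))
    raise ValueError(f"unknown rate model type: {kind!r}")


def scenario_from_dict(cfg: dict) -> SimScenario:
    """Build a simulation scenario from a plain config mapping (YAML-friendly)."""
    cfg = dict(cfg)
    model = model_from_dict(cfg.pop("model", {}))
    comp = cfg.pop("root_composition", None)
    kwargs = dict(seed=cfg.pop("seed", 0), n_loci=cfg.pop("n_loci", 20),
                  locus_length=cfg.pop("locus_length", 3000),
                  locus_type=cfg.pop("locus_type", "NC"),
                  t_in1=cfg.pop("t_in1", 0.02), t_in2=cfg.pop("t_in2", 0.02),
                  t_out=cfg.pop("t_out", 0.02), rate_model=model)
    if cfg:
        raise ValueError(f"unknown scenario keys: {sorted(cfg)}")
    if comp is not None:
        kwargs["root_composition"] = np.asarray(comp, float)
    return SimScenario(**kwargs)


def kappa_recovery_scenario(seed: int, kappa: float, base: str,
                            n_loci: int = 12,
                            locus_length: int = 10_000) -> SimScenario:
    """K2P scenario with a homogeneous root (all one base).

    Concentrating the root composition on a single base makes one
    tetranucleotide context dominate the observations (>=1e5 observed sites
    in that context at these sizes), which is what a per-context ts:tv
    recovery check needs; the true count-level ts:tv is kappa/2 in every
    context, so the dominant folded class is checked against that value.
    """
    comp = np.zeros(4)
    comp["ACGT".index(base)] = 1.0
    return SimScenario(seed=seed, n_loci=n_loci, locus_length=locus_length,
                       locus_type="NC", t_in1=0.02, t_in2=0.02, t_out=0.02,
                       rate_model=RateModel.k2p(kappa), root_composition=comp)
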