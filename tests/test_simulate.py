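import numpy as np
import pytest
from scipy.stats import chi2_contingency

from ctxsub import (RateModel, SimScenario, build_folded_matrices,
                    extract_sites, recovery_report, simulate_triplet)
from ctxsub.contexts import context_code
from ctxsub.scenarios import (at_biased_model, model_from_dict,
                              scenario_from_dict)
from ctxsub.simulate import at_biased_target


def scenario(**kw):
    defaults = dict(seed=0, n_loci=4, locus_length=600, locus_type="NC",
                    t_in1=0.02, t_in2=0.02, t_out=0.02,
                    rate_model=RateModel.jukes_cantor())
    defaults.update(kw)
    return SimScenario(**defaults)


class TestRateModel:
    def test_invalid_models_rejected(self):
        with pytest.raises(ValueError):
            RateModel(np.ones((16, 4, 4)))
        Q = np.zeros((256, 4, 4))
        Q[0, 0, 1] = -1.0
        with pytest.raises(ValueError):
            RateModel(Q)
        Q = np.zeros((256, 4, 4))
        Q[0, 0, 0] = 1.0  # nonzero diagonal
        with pytest.raises(ValueError):
            RateModel(Q)

    def test_strand_symmetry_by_construction(self):
        m = at_biased_model()
        for ctx, rc in (("AACG", "CGTT"), ("GGGG", "CCCC")):
            q1 = m.Q[context_code(ctx)]
            q2 = m.Q[context_code(rc)]
            assert np.allclose(q1, q2[::-1, ::-1])

    def test_normalized_to_unit_mean_rate(self):
        m = at_biased_model()
        assert m.Q.sum(axis=2).mean() == pytest.approx(1.0)

    def test_hky_stationary_equals_target(self):
        m = RateModel.hky(at_biased_target, kappa=3.0)
        for ctx in ("AAAA", "ACGT", "AATT"):
            assert m.stationary(ctx) == pytest.approx(at_biased_target(ctx),
                                                      abs=1e-12)

    def test_k2p_expected_ts_tv_is_half_kappa(self):
        m = RateModel.k2p(5.0)
        assert m.expected_ts_tv("ACGT") == pytest.approx(2.5)


class TestSimulate:
    def test_zero_branch_lengths_give_identical_sequences(self):
        alns, events = simulate_triplet(scenario(t_in1=0, t_in2=0, t_out=0))
        assert events.empty
        for a in alns:
            assert a.seqs[0] == a.seqs[1] == a.seqs[2]
        folded = build_folded_matrices(
            [o for a in alns for o in extract_sites(a)])["NC"]
        for cmx in folded.values():
            assert cmx.n_subs == 0  # only diagonal counts

    def test_same_seed_reproduces_exactly(self):
        a1, e1 = simulate_triplet(scenario(seed=9))
        a2, e2 = simulate_triplet(scenario(seed=9))
        assert [a.seqs for a in a1] == [a.seqs for a in a2]
        assert e1.equals(e2)

    def test_cds_root_has_no_inframe_stops(self):
        alns, _ = simulate_triplet(scenario(
            locus_type="CDS", locus_length=300, t_in1=0, t_in2=0, t_out=0))
        stops = {"TAA", "TAG", "TGA"}
        for a in alns:
            codons = {a.seqs[0][i:i + 3] for i in range(0, a.length, 3)}
            assert not (codons & stops)

    def test_event_log_is_consistent_with_leaf_sequences(self):
        alns, events = simulate_triplet(scenario(seed=3, t_in1=0.3, t_in2=0.3,
                                                 t_out=0.3))
        by_aln = {a.locus_id: a for a in alns}
        branch_row = {"in1": 0, "in2": 1, "out": 2}
        for (locus, branch, col), grp in events.groupby(
                ["locus_id", "branch", "column"]):
            grp = grp.sort_values("time")
            chain = list(grp["from_base"]) + [grp["to_base"].iloc[-1]]
            # successive events at a site chain together
            assert all(chain[i + 1] == grp["to_base"].iloc[i]
                       for i in range(len(grp)))
            # last state matches the emitted leaf sequence
            assert by_aln[locus].seqs[branch_row[branch]][col] == chain[-1]

    def test_context_independent_model_gives_homogeneous_matrices(self):
        # under Jukes-Cantor rates the substitution fraction must not vary
        # across contexts beyond sampling noise
        alns, _ = simulate_triplet(scenario(seed=21, n_loci=10,
                                            locus_length=5000))
        folded = build_folded_matrices(
            [o for a in alns for o in extract_sites(a)])["NC"]
        table = [(cmx.n_subs, cmx.total - cmx.n_subs)
                 for cmx in folded.values() if cmx.total >= 200]
        assert len(table) > 50
        _, p, _, _ = chi2_contingency(np.array(table))
        assert p > 0.01

    def test_single_site_long_run_matches_analytic_stationary(self):
        # one-site loci with an all-A root: the immutable flanks fix the
        # context at AAAA, so leaf states sample the AAAA-generator's CTMC
        # equilibrium
        model = at_biased_model()
        scn = SimScenario(seed=5, n_loci=2000, locus_length=1,
                          locus_type="NC", t_in1=50.0, t_in2=0.0, t_out=0.0,
                          rate_model=model,
                          root_composition=np.array([1.0, 0, 0, 0]))
        alns, _ = simulate_triplet(scn)
        counts = np.zeros(4)
        for a in alns:
            counts["ACGT".index(a.seqs[0])] += 1
        freq = counts / counts.sum()
        target = model.stationary("AAAA")
        se = np.sqrt(target * (1 - target) / len(alns))
        assert (np.abs(freq - target) < 3 * se + 1e-9).all()

    def test_invalid_scenarios_rejected(self):
        with pytest.raises(ValueError):
            scenario(t_in1=-0.1)
        with pytest.raises(ValueError):
            scenario(locus_type="CDS", locus_length=100)  # not codon-sized
        with pytest.raises(ValueError):
            scenario(root_composition=np.array([1.0, -0.5, 0.3, 0.2]))


class TestRecovery:
    def test_zero_divergence_has_no_false_polarizations(self):
        alns, events = simulate_triplet(scenario(t_in1=0, t_in2=0, t_out=0))
        rep = recovery_report(alns, events)
        assert np.isnan(rep["polarization_sensitivity"])
        assert rep["false_polarization_rate"] == 0.0

    def test_low_divergence_recovery_is_accurate(self, nc_sim):
        _, alns, events, obs = nc_sim
        rep = recovery_report(alns, events, obs)
        assert rep["polarization_sensitivity"] > 0.9
        assert rep["false_polarization_rate"] < 0.05

    def test_mislabeled_outgroup_degrades_recovery(self, nc_sim):
        _, alns, events, obs = nc_sim
        good = recovery_report(alns, events, obs)
        swapped = [type(a)(a.locus_id, a.locus_type,
                           (a.seqs[0], a.seqs[2], a.seqs[1]), a.frame_offset)
                   for a in alns]
        bad = recovery_report(swapped, events)
        # with ingroup2 and outgroup swapped, changes on the true ingroup2
        # branch are systematically mispolarized
        assert bad["false_polarization_rate"] > \
            5 * max(good["false_polarization_rate"], 0.01)


def test_scenario_and_model_config_round_trip():
    scn = scenario_from_dict({
        "seed": 4, "n_loci": 2, "locus_length": 300, "locus_type": "NC",
        "t_in1": 0.01, "t_in2": 0.01, "t_out": 0.02,
        "model": {"type": "k2p", "kappa": 4.0},
        "root_composition": [0.4, 0.1, 0.1, 0.4]})
    assert scn.rate_model.expected_ts_tv("ACGT") == pytest.approx(2.0)
    with pytest.raises(ValueError):
        model_from_dict({"type": "nope"})
    with pytest.raises(ValueError):
        scenario_from_dict({"bogus_key": 1})
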