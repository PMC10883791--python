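"""AFD panels, self-assignment, Bayesian mixture estimation, contribution tables."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import oracles
from conftest import make_gm, three_pop_mixture_config, two_pop_config
from stockid import genio, gsi, simdata
from stockid.genio import MISSING, AlleleFreqTable


def _freq_table(freqs: dict[str, list[float]], n: int = 100) -> AlleleFreqTable:
    pops = sorted(freqs)
    L = len(next(iter(freqs.values())))
    loci = pd.DataFrame({"chrom": ["c1"] * L, "pos": range(1, L + 1),
                         "ref": "A", "alt": "C"})
    return AlleleFreqTable(pops=pops, loci=loci,
                           freqs=np.array([freqs[p] for p in pops]),
                           n_called=np.full((len(pops), L), n))


# ---------------------------------------------------------------------------
# AFD and panel construction
# ---------------------------------------------------------------------------

def test_afd_values():
    t = gsi.afd_table(_freq_table({"a": [0.2, 0.0, 0.3],
                                   "b": [0.2, 1.0, 0.7]}))
    np.testing.assert_allclose(t["a|b"], [0.0, 1.0, 0.4])


def test_afd_three_pop_hand_table():
    freqs = {"a": [0.1, 0.9, 0.5, 0.3], "b": [0.2, 0.5, 0.5, 0.8],
             "c": [0.9, 0.1, 0.4, 0.3]}
    t = gsi.afd_table(_freq_table(freqs))
    for pair in t.columns:
        x, y = pair.split("|")
        hand = [abs(p - q) for p, q in zip(freqs[x], freqs[y])]
        np.testing.assert_allclose(t[pair], hand, atol=1e-12)


def test_panel_two_pops_is_top_afd():
    freqs = {"a": [0.1, 0.5, 0.9, 0.2, 0.3],
             "b": [0.9, 0.5, 0.1, 0.6, 0.35]}
    spec = gsi.build_balanced_panel(_freq_table(freqs), 3)
    # AFDs: 0.8, 0.0, 0.8, 0.4, 0.05 -> top three are loci 0, 2, 3
    assert sorted(spec.union) == [0, 2, 3]
    assert spec.union == [0, 2, 3]   # tie between loci 0 and 2 broken by order


def test_panel_matches_hand_greedy_trace():
    freqs = {"a": [0.95, 0.1, 0.5, 0.5, 0.2, 0.8, 0.35, 0.6, 0.15, 0.45],
             "b": [0.05, 0.9, 0.5, 0.1, 0.6, 0.2, 0.65, 0.3, 0.55, 0.4],
             "c": [0.5, 0.5, 0.05, 0.9, 0.25, 0.5, 0.05, 0.9, 0.5, 0.5]}
    table = _freq_table(freqs)
    afd = gsi.afd_table(table)
    spec = gsi.build_balanced_panel(table, 7)
    hand_lists, hand_sums, hand_union = oracles.greedy_panel(
        {pair: list(afd[pair]) for pair in afd.columns}, 7)
    assert spec.union == hand_union
    for pair in afd.columns:
        assert spec.pair_lists[pair] == hand_lists[pair]
        assert spec.pair_sums[pair] == pytest.approx(hand_sums[pair], abs=1e-12)


def test_panel_balance_invariant(study_sim):
    freqs = genio.allele_freq_table(study_sim["ref"])
    spec = gsi.build_balanced_panel(freqs, 400)
    afd = gsi.afd_table(freqs)
    sums = list(spec.pair_sums.values())
    max_appended = max(
        float(afd[pair].iloc[lst[-1]] ** 2)
        for pair, lst in spec.pair_lists.items() if lst)
    assert max(sums) - min(sums) <= max_appended + 1e-12
    assert len(spec.union) == 400
    # every union locus is in at least one pair list
    listed = set()
    for lst in spec.pair_lists.values():
        listed.update(lst)
    assert set(spec.union) <= listed


def test_panel_longer_lists_for_weakly_differentiated_pair():
    """The balancing rule gives less differentiated pairs more loci."""
    cfg = simdata.study_config(seed=31, n_loci=1200, n_chrom=6,
                               full_mixture=False)
    gm, _ = simdata.simulate_reference(cfg)
    freqs = genio.allele_freq_table(gm)
    spec = gsi.build_balanced_panel(freqs, 600)
    weak = len(spec.pair_lists["DEL|GUE"])      # near-panmictic sisters
    strong = len(spec.pair_lists["CAN|NST"])    # most diverged pair
    assert weak > strong


def test_panel_determinism_under_locus_shuffle(study_sim):
    freqs = genio.allele_freq_table(study_sim["ref"])
    spec1 = gsi.build_balanced_panel(freqs, 200)
    spec2 = gsi.build_balanced_panel(freqs, 200)
    assert spec1.union == spec2.union
    assert spec1.pair_sums == spec2.pair_sums


def test_panel_target_too_large_rejected():
    with pytest.raises(ValueError, match="exceeds"):
        gsi.build_balanced_panel(_freq_table({"a": [0.1], "b": [0.9]}), 5)


# ---------------------------------------------------------------------------
# self-assignment
# ---------------------------------------------------------------------------

def test_self_assignment_accurate_at_high_fst():
    cfg = two_pop_config(seed=1, f=0.15, n_loci=500)
    gm, _ = simdata.simulate_reference(cfg)
    cv = gsi.self_assign_cv(gm, train_props=(0.7,), loci_props=(1.0,),
                            n_iter=20, seed=0)
    assert cv.accuracy["accuracy"].mean() > 0.95
    # confusion rows count every tested individual
    assert cv.confusion.to_numpy().sum() == cv.accuracy["n_test"].sum()


def test_self_assignment_chance_level_on_panmictic_split():
    rng = np.random.default_rng(5)
    d = rng.binomial(2, rng.uniform(0.2, 0.8, 400), size=(60, 400))
    gm = make_gm(d, groups=["a"] * 30 + ["b"] * 30)
    cv = gsi.self_assign_cv(gm, train_props=(0.7,), loci_props=(1.0,),
                            n_iter=30, seed=0)
    assert abs(cv.accuracy["accuracy"].mean() - 0.5) < 0.12


def test_self_assignment_accuracy_monotone_in_fst():
    means = []
    for f in (0.01, 0.05, 0.15):
        accs = []
        for seed in range(4):
            cfg = two_pop_config(seed=seed + 60, f=f, n_loci=120)
            gm, _ = simdata.simulate_reference(cfg)
            cv = gsi.self_assign_cv(gm, train_props=(0.7,), loci_props=(1.0,),
                                    n_iter=10, seed=seed)
            accs.append(cv.accuracy["accuracy"].mean())
        means.append(np.mean(accs))
    # nondecreasing in F_ST, strictly higher at the extremes
    assert means[0] <= means[1] + 0.02 and means[1] <= means[2] + 0.02
    assert means[2] > means[0] + 0.05


def test_pick_panel_rules():
    def fake_cv(acc_by_pop, sds):
        rows = []
        for it in range(4):
            for pop, (a, s) in enumerate(zip(acc_by_pop, sds)):
                rows.append({"train_prop": 0.7, "loci_prop": 1.0,
                             "iteration": it, "population": f"p{pop}",
                             "accuracy": a + (it - 1.5) * s, "n_test": 10})
        return gsi.AssignmentCv((0.7,), (1.0,), 4, pd.DataFrame(rows),
                                pd.DataFrame())
    # dominating panel wins
    cvs = {500: fake_cv([0.7, 0.9], [0.0, 0.0]),
           1000: fake_cv([0.9, 0.95], [0.0, 0.0])}
    assert gsi.pick_panel(cvs) == 1000
    # tie on min accuracy: lower SD wins
    cvs = {500: fake_cv([0.9, 0.9], [0.02, 0.02]),
           1000: fake_cv([0.9, 0.9], [0.001, 0.001])}
    assert gsi.pick_panel(cvs) == 1000
    # full tie: smaller panel wins
    cvs = {500: fake_cv([0.9, 0.9], [0.0, 0.0]),
           1000: fake_cv([0.9, 0.9], [0.0, 0.0])}
    assert gsi.pick_panel(cvs) == 500


# ---------------------------------------------------------------------------
# mixture estimation
# ---------------------------------------------------------------------------

def test_mixture_single_source_dominates():
    cfg = three_pop_mixture_config(seed=2, f=0.10, n_mix=100,
                                   props=(1.0, 0.0, 0.0))
    ref, truth = simdata.simulate_reference(cfg)
    mix, _ = simdata.simulate_mixture(cfg, truth.pop_freqs, truth)
    mr = gsi.mixture_estimate(ref, mix, n_sweeps=800, burn_in=100, seed=0)
    assert mr.proportions["A"] > 0.95


def test_mixture_posterior_rows_sum_to_one():
    cfg = three_pop_mixture_config(seed=3, n_mix=60)
    ref, truth = simdata.simulate_reference(cfg)
    mix, _ = simdata.simulate_mixture(cfg, truth.pop_freqs, truth)
    mr = gsi.mixture_estimate(ref, mix, n_sweeps=400, burn_in=50, seed=0)
    np.testing.assert_allclose(mr.posterior.sum(axis=1), 1.0, atol=1e-9)
    np.testing.assert_allclose(mr.proportions.sum(), 1.0, atol=1e-9)


def test_mixture_all_missing_individual_keeps_prior():
    cfg = three_pop_mixture_config(seed=4, n_mix=40)
    ref, truth = simdata.simulate_reference(cfg)
    mix, _ = simdata.simulate_mixture(cfg, truth.pop_freqs, truth)
    mix.dosage[0, :] = MISSING
    mr = gsi.mixture_estimate(ref, mix, n_sweeps=1500, burn_in=200, seed=0)
    assert mix.sample_ids[0] in mr.all_missing
    post = mr.posterior.iloc[0]
    # posterior follows the (sampled) mixing proportions, not the data:
    # with a flat likelihood it cannot stray far from the chain's pi
    np.testing.assert_allclose(post, mr.proportions, atol=0.12)


def test_mixture_input_validation():
    cfg = three_pop_mixture_config(seed=5, n_mix=20)
    ref, truth = simdata.simulate_reference(cfg)
    mix, _ = simdata.simulate_mixture(cfg, truth.pop_freqs, truth)
    with pytest.raises(ValueError, match="burn-in"):
        gsi.mixture_estimate(ref, mix, n_sweeps=50, burn_in=50)
    shifted = mix.loci.copy()
    shifted["pos"] = shifted["pos"] + 7
    bad = genio.GenotypeMatrix(dosage=mix.dosage, loci=shifted,
                               samples=mix.samples)
    with pytest.raises(ValueError, match="panel loci missing"):
        gsi.mixture_estimate(ref, bad)


def test_mixture_rmse_improves_with_informative_panel():
    cfg = three_pop_mixture_config(seed=6, f=0.05, n_loci=1200, n_mix=150)
    ref, truth = simdata.simulate_reference(cfg)
    mix, mtruth = simdata.simulate_mixture(cfg, truth.pop_freqs, truth)
    freqs = genio.allele_freq_table(ref)
    afd = gsi.afd_table(freqs)
    score = afd.pow(2).sum(axis=1).to_numpy()
    best = np.argsort(-score)[:200]
    worst = np.argsort(score)[:200]
    true_props = (mtruth.samples["origin"].value_counts(normalize=True)
                  .reindex(["A", "B", "C"]).fillna(0.0))

    def rmse(panel):
        mr = gsi.mixture_estimate(ref, mix, panel, n_sweeps=800, burn_in=100,
                                  seed=1)
        return float(np.sqrt(((mr.proportions - true_props) ** 2).mean()))

    assert rmse(np.sort(best)) < rmse(np.sort(worst))


# ---------------------------------------------------------------------------
# odds filter and contributions
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("posterior, kept", [
    ((0.91, 0.09), True),          # 10.1x
    ((10 / 11, 1 / 11), True),     # exactly 10x: inclusive
    ((0.8, 0.2), False),           # 4x
    ((0.5, 0.3, 0.2), False),      # second-largest matters
])
def test_odds_filter_rule(posterior, kept):
    pops = [f"p{i}" for i in range(len(posterior))]
    mr = gsi.MixtureResult(
        pops=pops,
        posterior=pd.DataFrame([posterior], index=["x"], columns=pops),
        proportions=pd.Series(posterior, index=pops),
        trace=np.zeros((1, len(pops))))
    out = gsi.odds_filter(mr, ratio=10.0)
    assert bool(out.kept.loc["x"]) is kept


def test_contribution_2020_worked_example():
    """Estuary catch with 37 marine and 104 estuarine scale reads."""
    tt = pd.DataFrame({
        "sample_id": [f"f{i}" for i in range(141)],
        "tactic": ["marine"] * 37 + ["estuarine"] * 104,
        "year": ["2020"] * 141,
    })
    assign = pd.DataFrame({"sample_id": tt["sample_id"],
                           "year": "2020", "river": "DEL"})
    out = gsi.contribution_summary(None, tactic_table=tt, assignments=assign)
    assert out["tactic_pct"].loc["2020", "estuarine"] == pytest.approx(73.8, abs=0.05)
    assert out["tactic_pct"].loc["2020", "marine"] == pytest.approx(26.2, abs=0.05)


def test_contribution_chi2_matches_hand_formula():
    tt = pd.DataFrame({
        "sample_id": [f"f{i}" for i in range(100)],
        "tactic": ["marine"] * 30 + ["estuarine"] * 20
                  + ["marine"] * 10 + ["estuarine"] * 40,
        "year": ["y1"] * 50 + ["y2"] * 50,
    })
    assign = pd.DataFrame({"sample_id": tt["sample_id"],
                           "year": tt["year"], "river": "R"})
    out = gsi.contribution_summary(None, tactic_table=tt, assignments=assign)
    hand = oracles.chi2_homogeneity([[30, 20], [10, 40]])
    assert out["tactic_chi2"] == pytest.approx(hand, abs=1e-9)
    assert out["tactic_p"] == pytest.approx(stats.chi2.sf(hand, 1), abs=1e-12)


def test_contribution_identical_years_chi2_zero():
    tt = pd.DataFrame({
        "sample_id": [f"f{i}" for i in range(80)],
        "tactic": (["marine"] * 20 + ["estuarine"] * 20) * 2,
        "year": ["y1"] * 40 + ["y2"] * 40,
    })
    assign = pd.DataFrame({"sample_id": tt["sample_id"],
                           "year": tt["year"],
                           "river": (["A"] * 30 + ["B"] * 10) * 2})
    out = gsi.contribution_summary(None, tactic_table=tt, assignments=assign)
    assert out["tactic_chi2"] == pytest.approx(0.0, abs=1e-12)
    assert out["tactic_p"] == pytest.approx(1.0)
    assert out["river_chi2"] == pytest.approx(0.0, abs=1e-12)


def test_contribution_empty_rejected():
    with pytest.raises(ValueError):
        gsi.contribution_summary(None, assignments=pd.DataFrame(
            columns=["sample_id", "year", "river"]))
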