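"""Constraint slopes, adjusted rates, HKY likelihood, MCMC dating machinery."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import integrate
from scipy.linalg import expm

from transpoly.alignment import AlleleAlignment
from transpoly.dating import (
    NEUTRAL_RATES,
    ClockConfig,
    ClockDating,
    adjusted_rate,
    constraint_slope,
    effective_sample_size,
    fit_origin_slope,
    fitch_ancestral,
    gamma_category_rates,
    hky_P,
    hpd_interval,
    jc_marginal_ancestral,
    mcmc_date,
    trace_summary,
)
from transpoly.njtree import Node
from transpoly.simulate import GeneNode, SimConfig, evolve_alignment, simulate_gene_genealogy


# ---------------------------------------------------------------------------
# constraint slope & adjusted rate


def test_origin_slope_identity_line():
    x = np.linspace(0.01, 0.3, 40)
    assert fit_origin_slope(x, x) == pytest.approx(1.0)


def test_origin_slope_regression_recovery(rng):
    x = rng.uniform(0.05, 0.3, 45)
    y = 0.8 * x + rng.normal(0, 0.01, 45)
    assert fit_origin_slope(x, y) == pytest.approx(0.8, abs=0.02)


@pytest.mark.parametrize("s", [0.5, 0.8, 1.0])
def test_origin_slope_known_values(s, rng):
    # 10 lineage members -> C(10,2)=45 pairwise points
    x = rng.uniform(0.05, 0.3, 45)
    y = s * x + rng.normal(0, 0.01, 45)
    assert fit_origin_slope(x, y) == pytest.approx(s, abs=0.05)


def test_constraint_slope_below_one_under_positive_selection():
    cfg = SimConfig(seed=21, duplication_times=(30.0,), pbr_omega=5.0)
    g, tr = simulate_gene_genealogy(cfg)
    aln, _ = evolve_alignment(g, cfg, tr)
    fit = constraint_slope(aln)
    assert 0 < fit.slope < 1
    assert len(fit.points) == len(aln) * (len(aln) - 1) // 2


def test_constraint_slope_needs_three_members():
    aln = AlleleAlignment(["a", "b"], ["ATG", "ATA"], ["s"] * 2, ["g"] * 2)
    with pytest.raises(ValueError):
        constraint_slope(aln)


def test_constraint_slope_identical_members_undefined():
    aln = AlleleAlignment(["a", "b", "c"], ["ATGGCT"] * 3, ["s"] * 3, ["g"] * 3)
    with pytest.raises(ValueError, match="undefined"):
        constraint_slope(aln)


def test_adjusted_rate_arithmetic():
    from transpoly.dating import ConstraintFit

    fit = ConstraintFit("L1", [], slope=1.0)
    assert adjusted_rate(fit, "zebra_finch") == pytest.approx(2.21e-3)
    fit.slope = 0.864
    assert adjusted_rate(fit, "zebra_finch") == pytest.approx(1.91e-3, rel=1e-3)
    fit.slope = 0.5
    assert adjusted_rate(fit, "chicken") == pytest.approx(9.55e-4, rel=1e-6)
    assert fit.neutral_rate == NEUTRAL_RATES["chicken"]


# ---------------------------------------------------------------------------
# HKY likelihood engine


def hky_Q(kappa, freqs):
    Q = np.zeros((4, 4))
    pur = (0, 2)
    for i in range(4):
        for j in range(4):
            if i == j:
                continue
            Q[i, j] = (kappa if ((i in pur) == (j in pur)) else 1.0) * freqs[j]
        Q[i, i] = -Q[i].sum()
    return Q / -np.dot(np.diag(Q), freqs)


@pytest.mark.parametrize("kappa", [1.0, 2.5, 8.0])
def test_hky_P_matches_matrix_exponential(kappa):
    freqs = np.array([0.31, 0.19, 0.23, 0.27])
    Q = hky_Q(kappa, freqs)
    for t in (0.01, 0.2, 1.5):
        assert np.abs(hky_P(np.array([t]), kappa, freqs)[0] - expm(Q * t)).max() < 1e-12


def test_hky_P_rows_sum_to_one():
    P = hky_P(np.array([0.1, 0.5]), 3.0, np.array([0.25] * 4))
    assert np.allclose(P.sum(axis=-1), 1.0)


def test_pruning_two_leaf_equals_closed_form():
    """Pruning on a 2-leaf tree equals the direct HKY transition-probability
    product, site by site, to 1e-10."""
    from transpoly.dating import _PruningEngine

    rng = np.random.default_rng(1)
    s1 = "".join("ACGT"[b] for b in rng.integers(0, 4, 120))
    s2 = "".join("ACGT"[b] for b in rng.integers(0, 4, 120))
    aln = AlleleAlignment(["a", "b"], [s1, s2], ["s"] * 2, ["g"] * 2)
    tree = Node(children=[Node(label="a", length=1), Node(label="b", length=1)])
    eng = _PruningEngine(tree, aln, ncat=4)
    kappa, shape = 3.0, 0.7
    bs = np.array([0.08, 0.12, 0.0])
    got = eng.loglik(bs, kappa, shape)
    rates = gamma_category_rates(shape, 4)
    f = eng.freqs
    expected = 0.0
    enc = {"A": 0, "C": 1, "G": 2, "T": 3}
    for c1, c2 in zip(s1, s2):
        site = 0.0
        for r in rates:
            P1 = hky_P(np.array([0.08 * r]), kappa, f)[0]
            P2 = hky_P(np.array([0.12 * r]), kappa, f)[0]
            site += np.sum(f * P1[:, enc[c1]] * P2[:, enc[c2]]) / 4
        expected += math.log(site)
    assert got == pytest.approx(expected, abs=1e-10)


# ---------------------------------------------------------------------------
# trace summaries


def test_constant_trace_zero_width():
    df = pd.DataFrame({"state": range(200), "x": [2.5] * 200})
    s = trace_summary(df)
    assert s.loc["x", "sd"] == 0.0
    assert s.loc["x", "hpd95_low"] == s.loc["x", "hpd95_high"] == 2.5


def test_iid_normal_ess_and_hpd(rng):
    x = rng.normal(size=10_000)
    ess = effective_sample_size(x)
    assert ess == pytest.approx(10_000, rel=0.2)
    lo, hi = hpd_interval(x, 0.95)
    assert lo == pytest.approx(-1.96, abs=0.12)
    assert hi == pytest.approx(1.96, abs=0.12)


def test_ar1_ess_matches_autocorrelation_formula(rng):
    rho, n = 0.9, 40_000
    x = np.empty(n)
    x[0] = rng.normal()
    eps = rng.normal(size=n) * math.sqrt(1 - rho**2)
    for i in range(1, n):
        x[i] = rho * x[i - 1] + eps[i]
    expected = n * (1 - rho) / (1 + rho)
    assert effective_sample_size(x) == pytest.approx(expected, rel=0.2)


def test_hpd_is_shortest_interval():
    # mixture concentrated at 0 with a few outliers: HPD hugs the bulk
    x = np.concatenate([np.zeros(95), np.full(5, 100.0)])
    lo, hi = hpd_interval(x, 0.95)
    assert (lo, hi) == (0.0, 0.0)


def test_trace_summary_requires_min_samples():
    df = pd.DataFrame({"state": range(50), "x": np.arange(50.0)})
    with pytest.raises(ValueError):
        trace_summary(df)


# ---------------------------------------------------------------------------
# Fitch parsimony


def cherry_tree():
    return Node(
        children=[
            Node(children=[Node(label="a"), Node(label="b")]),
            Node(children=[Node(label="c"), Node(label="d")]),
        ]
    )


def test_fitch_uniform_states_score_zero():
    sets, score = fitch_ancestral(cherry_tree(), dict.fromkeys("abcd", "x"))
    assert score == 0


def test_fitch_two_state_cherry():
    sets, score = fitch_ancestral(
        cherry_tree(), {"a": "x", "b": "x", "c": "y", "d": "y"}
    )
    assert score == 1
    assert sets[-1] == {"x", "y"}  # root set


def test_fitch_unlabeled_tip_errors():
    with pytest.raises(ValueError, match="unlabeled"):
        fitch_ancestral(cherry_tree(), {"a": "x", "b": "x", "c": "y"})


def brute_force_parsimony(tree, tip_states):
    states = sorted(set(tip_states.values()))
    internals = [n for n in tree.postorder() if not n.is_leaf]

    def cost(assign):
        total = 0
        for node in internals:
            for c in node.children:
                s_child = tip_states[c.label] if c.is_leaf else assign[id(c)]
                total += s_child != assign[id(node)]
        return total

    best = None
    for combo in itertools.product(states, repeat=len(internals)):
        assign = {id(n): s for n, s in zip(internals, combo)}
        c = cost(assign)
        best = c if best is None else min(best, c)
    return best


def test_fitch_random_eight_leaf_vs_brute_force(rng):
    for trial in range(10):
        # random 8-leaf binary topology
        nodes = [Node(label=f"t{i}") for i in range(8)]
        while len(nodes) > 1:
            i, j = sorted(rng.choice(len(nodes), 2, replace=False))
            new = Node(children=[nodes[i], nodes[j]])
            nodes = [n for q, n in enumerate(nodes) if q not in (i, j)] + [new]
        tree = nodes[0]
        states = {f"t{i}": "xyz"[int(rng.integers(0, 3))] for i in range(8)}
        _, score = fitch_ancestral(tree, states)
        assert score == brute_force_parsimony(tree, states)


def test_fitch_per_site_sequences_sum():
    states = {"a": "AA", "b": "AA", "c": "AC", "d": "CC"}
    sets, score = fitch_ancestral(cherry_tree(), states, per_site=True)
    s1 = fitch_ancestral(cherry_tree(), {k: v[0] for k, v in states.items()})[1]
    s2 = fitch_ancestral(cherry_tree(), {k: v[1] for k, v in states.items()})[1]
    assert score == s1 + s2


def test_jc_marginal_root_favors_majority():
    post = jc_marginal_ancestral(cherry_tree(), {"a": "x", "b": "x", "c": "x", "d": "y"})
    assert post["x"] > post["y"]
    assert sum(post.values()) == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# MCMC dating


def two_leaf_tree(labels):
    return Node(children=[Node(label=labels[0], length=1), Node(label=labels[1], length=1)])


def test_prior_only_two_leaf_matches_yule_exponential():
    """With the likelihood disabled and fixed birth rate lam, the 2-leaf root
    age is exponential with rate 2*lam."""
    seqs = ["ACGT" * 30] * 2
    aln = AlleleAlignment(["a", "b"], seqs, ["s"] * 2, ["g"] * 2)
    cfg = ClockConfig(clock="strict", rate=1e-3, generations=60_000,
                      likelihood_off=True, yule_rate=0.05, seed=11)
    res = mcmc_date(aln, two_leaf_tree(["a", "b"]), cfg)
    x = res.samples["root_age"].to_numpy()
    assert x.mean() == pytest.approx(10.0, rel=0.12)
    assert np.std(x) == pytest.approx(10.0, rel=0.2)


def test_prior_only_three_leaf_matches_numerical_moments():
    """3-leaf prior-only node ages agree with numerically integrated moments
    of the pure-birth density f(t1, tr) ~ exp(-lam (2 tr + t1)), t1 < tr."""
    lam = 0.05
    norm, _ = integrate.dblquad(
        lambda t1, tr: math.exp(-lam * (2 * tr + t1)), 0, np.inf, 0, lambda tr: tr
    )
    e_tr, _ = integrate.dblquad(
        lambda t1, tr: tr * math.exp(-lam * (2 * tr + t1)), 0, np.inf, 0, lambda tr: tr
    )
    e_tr /= norm
    seqs = ["ACGT" * 30] * 3
    aln = AlleleAlignment(["a", "b", "c"], seqs, ["s"] * 3, ["g"] * 3)
    tree = Node(
        children=[
            Node(children=[Node(label="a", length=1), Node(label="b", length=1)]),
            Node(label="c", length=1),
        ]
    )
    cfg = ClockConfig(clock="strict", rate=1e-3, generations=80_000,
                      likelihood_off=True, yule_rate=lam, seed=5)
    res = mcmc_date(aln, tree, cfg)
    assert res.samples["root_age"].mean() == pytest.approx(e_tr, rel=0.15)


def test_identical_sequences_posterior_mass_near_zero():
    seqs = ["ACGTTGCA" * 31] * 2
    aln = AlleleAlignment(["a", "b"], seqs, ["s"] * 2, ["g"] * 2)
    cfg = ClockConfig(clock="strict", rate=2e-3, generations=40_000, seed=2,
                      yule_rate=0.05)
    res = mcmc_date(aln, two_leaf_tree(["a", "b"]), cfg)
    # prior alone has mean 10 My; identical sequences pull the age near zero
    assert res.samples["root_age"].mean() < 3.0


def test_rate_time_confounding_scaling():
    cfg0 = SimConfig(seed=6, pbr_omega=1.0)
    g = GeneNode(None, 10.0, [GeneNode("s_L1_1", 0.0), GeneNode("s_L1_2", 0.0)])
    aln, _ = evolve_alignment(g, cfg0)
    ages = {}
    for rate in (2.21e-3, 4.42e-3):
        cfg = ClockConfig(clock="strict", rate=rate, generations=40_000, seed=3)
        res = mcmc_date(aln, two_leaf_tree(aln.labels), cfg)
        ages[rate] = res.samples["root_age"].mean()
    assert ages[2.21e-3] / ages[4.42e-3] == pytest.approx(2.0, rel=0.2)


def test_non_monophyletic_clade_errors():
    seqs = ["ACGT" * 30] * 3
    aln = AlleleAlignment(["a", "b", "c"], seqs, ["s"] * 3, ["g"] * 3)
    tree = Node(
        children=[
            Node(children=[Node(label="a", length=1), Node(label="b", length=1)]),
            Node(label="c", length=1),
        ]
    )
    cfg = ClockConfig(generations=1000, rate=1e-3)
    with pytest.raises(ValueError, match="monophyletic"):
        mcmc_date(aln, tree, cfg, clade_definitions={"bad": {"a", "c"}})


def test_clade_tmrca_respects_tree_partial_order():
    cfg = SimConfig(seed=31, duplication_times=(30.0, 25.0),
                    n_alleles_per_species_per_lineage=1)
    g, tr = simulate_gene_genealogy(cfg)
    aln, tr = evolve_alignment(g, cfg, tr)
    members = {}
    for a, l in tr.lineage_membership.items():
        members.setdefault(l, set()).add(a)
    from transpoly.njtree import midpoint_root, nj_tree
    from transpoly.distances import distance_matrix

    tree = midpoint_root(nj_tree(distance_matrix(aln.seqs), aln.labels))
    cfgd = ClockConfig(clock="strict", rate=2.21e-3, generations=30_000, seed=4)
    res = mcmc_date(aln, tree, cfgd, mrca_groups={
        "L1": members["L1"], "all": set(aln.labels)})
    assert (res.samples["tmrca_all"] >= res.samples["tmrca_L1"] - 1e-9).all()


def test_config_validation():
    with pytest.raises(ValueError):
        ClockConfig(clock="nope")
    with pytest.raises(ValueError):
        ClockConfig(rate=0.0)
    with pytest.raises(ValueError):
        ClockConfig(generations=100, burnin=100)


def test_dated_newick_has_monotone_ages():
    cfg0 = SimConfig(seed=8, pbr_omega=1.0)
    g = GeneNode(None, 10.0, [GeneNode("s_L1_1", 0.0), GeneNode("s_L1_2", 0.0)])
    aln, _ = evolve_alignment(g, cfg0)
    cfg = ClockConfig(clock="strict", rate=2.21e-3, generations=20_000, seed=1)
    res = mcmc_date(aln, two_leaf_tree(aln.labels), cfg)
    nwk = res.dated_newick()
    assert nwk.endswith(";") and "&age=" in nwk
    assert res.samples["root_age"].mean() == pytest.approx(
        float(nwk.rsplit("&age=", 1)[1].rstrip("];")), rel=1e-3
    )
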