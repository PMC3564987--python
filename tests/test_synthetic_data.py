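"""Generator tests: determinism, planted truth, zero-noise limits, and the
distributional laws the simulated tables are supposed to follow."""
import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cinslnet import (
    ConfigurationError,
    ConsistencyError,
    SimulationConfig,
    simulate_chemical_screen,
    simulate_complexes,
    simulate_gene_universe,
    simulate_gi_screen,
    simulate_proliferation,
)


@pytest.mark.parametrize("bad", [
    {"n_genes": 0},
    {"cin_fraction": 0.0},
    {"cin_fraction": 1.5},
    {"n_hubs": -1},
    {"interaction_score_mean": 0.1},
    {"score_noise_sd": -0.01},
    {"sensitive_growth_ratio": 1.0},
    {"single_kd_effect_range": (0.0, 0.5)},
    {"single_kd_effect_range": (0.9, 0.6)},
    {"planted_defect": 1.0},
    {"n_genes": 100, "cin_fraction": 0.1, "hub_cin_degree": 11},
])
def test_config_rejects_out_of_domain_values(bad):
    with pytest.raises(ConfigurationError):
        SimulationConfig(**bad)


def test_universe_counts_and_hub_placement():
    cfg = SimulationConfig(n_genes=100, cin_fraction=0.2, n_hubs=4,
                           hub_cin_degree=5, seed=3)
    ann, truth = simulate_gene_universe(cfg)
    assert len(ann) == 100
    assert ann["is_cin"].sum() == 20
    assert len(truth.hub_genes) == 4
    # hubs are array-side genes, never CIN queries
    assert truth.hub_genes.isdisjoint(truth.cin_genes)
    # every hub carries exactly hub_cin_degree planted edges to CIN genes
    for hub in truth.hub_genes:
        edges = {(q, a) for q, a in truth.planted_edges if a == hub}
        assert len(edges) == 5
        assert all(q in truth.cin_genes for q, _ in edges)
    # cancer orthologs are a CIN subset
    assert truth.cancer_genes <= truth.cin_genes


def test_no_hubs_degenerate_case():
    cfg = SimulationConfig(n_genes=50, cin_fraction=0.2, n_hubs=0,
                           hub_cin_degree=0, seed=1)
    _, truth = simulate_gene_universe(cfg)
    assert truth.hub_genes == frozenset()
    assert truth.planted_edges == frozenset()


def test_generator_is_deterministic(small_config):
    frames = []
    for _ in range(2):
        ann, truth = simulate_gene_universe(small_config)
        gi = simulate_gi_screen(small_config, truth)
        chem = simulate_chemical_screen(small_config, truth)
        cpx = simulate_complexes(small_config, truth)
        pro = simulate_proliferation(small_config, truth)
        frames.append((ann, gi, chem, cpx, pro))
    for a, b in zip(*frames):
        pd.testing.assert_frame_equal(a, b)


def test_truth_from_other_config_rejected(small_config, small_universe):
    _, truth = small_universe
    other = dataclasses.replace(small_config, seed=small_config.seed + 1)
    with pytest.raises(ConsistencyError):
        simulate_gi_screen(other, truth)


def test_gi_zero_noise_limits(noiseless_config):
    _, truth = simulate_gene_universe(noiseless_config)
    gi = simulate_gi_screen(noiseless_config, truth)
    gi = gi.set_index(["query", "array"])
    planted = gi.loc[sorted(truth.planted_edges)]
    assert (planted["score"] == noiseless_config.interaction_score_mean).all()
    assert (planted["p_value"] == 0.0).all()
    background = gi.drop(index=sorted(truth.planted_edges))
    assert (background["score"] == 0.0).all()
    assert (background["p_value"] == 1.0).all()


def test_gi_no_background_means_only_planted_edges(noiseless_config):
    cfg = dataclasses.replace(noiseless_config, background_edge_prob=0.0)
    _, truth = simulate_gene_universe(cfg)
    gi = simulate_gi_screen(cfg, truth)
    assert set(zip(gi["query"], gi["array"])) == set(truth.planted_edges)


@pytest.fixture(scope="module")
def big_planted_scores():
    # 10,000 planted edges: 100 hubs x degree 100 against 1000 CIN genes
    cfg = SimulationConfig(n_genes=4000, cin_fraction=0.25, n_hubs=100,
                           hub_cin_degree=100, background_edge_prob=0.0,
                           interaction_score_mean=-0.35, score_noise_sd=0.05,
                           seed=7)
    _, truth = simulate_gene_universe(cfg)
    gi = simulate_gi_screen(cfg, truth)
    return cfg, gi["score"].to_numpy()


def test_planted_score_tail_matches_normal_cdf(big_planted_scores):
    """Fraction of planted edges passing score <= -0.20 agrees with the
    Normal(-0.35, 0.05) tail probability within Monte-Carlo error."""
    cfg, scores = big_planted_scores
    expected = stats.norm.cdf(-0.20, loc=-0.35, scale=0.05)
    observed = float(np.mean(scores <= -0.20))
    mc_err = 3 * np.sqrt(expected * (1 - expected) / len(scores))
    assert abs(observed - expected) <= max(mc_err, 0.005)


def test_planted_scores_follow_stated_normal_law(big_planted_scores):
    cfg, scores = big_planted_scores
    assert len(scores) == 10_000
    result = stats.kstest(scores, "norm",
                          args=(cfg.interaction_score_mean, cfg.score_noise_sd))
    assert result.pvalue > 0.01


def test_chemical_screen_replicates_and_zero_noise_ratios(noiseless_config):
    _, truth = simulate_gene_universe(noiseless_config)
    chem = simulate_chemical_screen(noiseless_config, truth)
    counts = chem.groupby(["strain", "chemical", "is_control"]).size()
    assert (counts == 9).all()  # nine replicates per strain x chemical x arm
    means = chem.groupby(["strain", "chemical", "is_control"])["colony_size"].mean()
    ratio = means.xs(False, level="is_control") / means.xs(True, level="is_control")
    for chem_name, sens in truth.sensitive_genes_by_chemical.items():
        sub = ratio.xs(chem_name, level="chemical")
        assert np.allclose(sub[sub.index.isin(sens)],
                           noiseless_config.sensitive_growth_ratio)
        assert np.allclose(sub[~sub.index.isin(sens)], 1.0)


def test_complexes_structure(small_config, small_universe):
    _, truth = small_universe
    cpx = simulate_complexes(small_config, truth)
    assert len(cpx) == small_config.n_complexes * small_config.complex_size
    by_label = cpx.groupby("complex_label")
    hubs_per_complex = by_label["hub"].nunique()
    assert (hubs_per_complex == 1).all()
    # exhaustive check: no two complexes share a hub, partners distinct from hub
    hub_of = by_label["hub"].first()
    assert hub_of.is_unique
    assert (cpx["hub"] != cpx["partner"]).all()
    assert cpx.groupby("complex_label")["partner"].nunique().eq(
        small_config.complex_size).all()
    # partners are essential genes
    assert set(cpx["partner"]) <= truth.essential_genes


def test_complexes_fill_symmetric_sl_pairs(small_config, small_universe):
    _, truth = small_universe
    simulate_complexes(small_config, truth)
    for (a, b), defect in truth.sl_pairs.items():
        assert a < b
        assert defect == small_config.planted_defect
        assert truth.sl_defect(a, b) == truth.sl_defect(b, a) == defect


def test_complexes_reject_oversized_requests(small_config, small_universe):
    _, truth = small_universe
    too_many = dataclasses.replace(small_config,
                                   n_complexes=small_config.n_hubs + 1)
    with pytest.raises(ConfigurationError):
        # truth fingerprint must match, so regenerate under the bad config
        simulate_complexes(too_many, simulate_gene_universe(too_many)[1])


def test_proliferation_multiplicative_null_zero_noise(noiseless_config):
    cfg = dataclasses.replace(noiseless_config, planted_defect=0.0)
    _, truth = simulate_gene_universe(cfg)
    simulate_complexes(cfg, truth)
    pro = simulate_proliferation(cfg, truth)
    means = pro.groupby("condition")["count"].mean()
    ctrl = means["control"]
    doubles = [c for c in means.index if c.startswith("double:")]
    assert doubles
    for cond in doubles:
        a, b = cond.split(":", 1)[1].split("+")
        observed = means[cond] / ctrl
        predicted = (means[f"single:{a}"] / ctrl) * (means[f"single:{b}"] / ctrl)
        assert observed == pytest.approx(predicted, abs=1e-12)


def test_proliferation_planted_defect_exact_without_noise(noiseless_config):
    _, truth = simulate_gene_universe(noiseless_config)
    simulate_complexes(noiseless_config, truth)
    pro = simulate_proliferation(noiseless_config, truth)
    means = pro.groupby("condition")["count"].mean()
    ctrl = means["control"]
    for (a, b), delta in truth.sl_pairs.items():
        observed = means[f"double:{a}+{b}"] / ctrl
        predicted = (means[f"single:{a}"] / ctrl) * (means[f"single:{b}"] / ctrl)
        assert 1 - observed / predicted == pytest.approx(delta, abs=1e-12)


def test_recovered_defect_unbiased_under_noise():
    """Monte-Carlo: with delta=0.3, CV=0.05 and 6 replicates the mean
    recovered defect sits within +-0.05 of the planted value."""
    defects = []
    for seed in range(40):
        cfg = SimulationConfig(n_genes=300, cin_fraction=0.2, n_hubs=4,
                               hub_cin_degree=20, background_edge_prob=0.0,
                               n_complexes=3, complex_size=3,
                               planted_defect=0.3, proliferation_noise_cv=0.05,
                               n_prolif_replicates=6, n_null_pairs=0, seed=seed)
        _, truth = simulate_gene_universe(cfg)
        simulate_complexes(cfg, truth)
        pro = simulate_proliferation(cfg, truth)
        means = pro.groupby("condition")["count"].mean()
        ctrl = means["control"]
        for (a, b) in truth.sl_pairs:
            observed = means[f"double:{a}+{b}"] / ctrl
            predicted = (means[f"single:{a}"] / ctrl) * (means[f"single:{b}"] / ctrl)
            defects.append(1 - observed / predicted)
    assert len(defects) >= 200
    assert abs(np.mean(defects) - 0.3) < 0.05
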