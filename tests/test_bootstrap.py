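"""Multiscale bootstrap: BP counts, AU fitting, calibration."""

import numpy as np
import pytest
from scipy import stats

from whalesong import BootstrapConfig, bootstrap_support, fit_au
from whalesong.bootstrap import DEFAULT_SCALES


def planted_features(rng, group_size=3, m=20, sep=5.0, sd=0.05):
    """Feature matrix with two well-separated item groups (columns)."""
    a = rng.normal(0, sd, (m, group_size))
    b = rng.normal(sep, sd, (m, group_size))
    return np.hstack([a, b])


def test_config_validation():
    with pytest.raises(ValueError):
        BootstrapConfig(n_boot=0)
    with pytest.raises(ValueError):
        BootstrapConfig(scales=(0.5, 0.7))  # no r = 1
    with pytest.raises(ValueError):
        BootstrapConfig(scales=(1.0, 0.5))  # not increasing
    assert 1.0 in BootstrapConfig().scales


def test_fit_au_symmetric_null_gives_half():
    fit = fit_au({r: 0.5 for r in DEFAULT_SCALES}, 1000)
    assert fit.au == pytest.approx(0.5, abs=1e-9)
    assert fit.v == pytest.approx(fit.c, abs=1e-9)


def test_fit_au_certain_edge_is_one():
    fit = fit_au({r: 1.0 for r in DEFAULT_SCALES}, 100)
    assert fit.au == 1.0
    assert fit.degenerate
    fit0 = fit_au({r: 0.0 for r in DEFAULT_SCALES}, 100)
    assert fit0.au == 0.0
    assert fit0.degenerate


def test_fit_au_refuses_single_scale():
    with pytest.raises(ValueError):
        fit_au({1.0: 0.8}, 100)


def test_fit_au_parameter_recovery():
    """(v, c) recovered within 0.05 from synthetic binomial counts."""
    v_true, c_true, n_boot = 0.4, 0.2, 10_000
    rng = np.random.default_rng(7)
    bp = {
        r: rng.binomial(n_boot, stats.norm.sf(v_true * np.sqrt(r) + c_true / np.sqrt(r))) / n_boot
        for r in DEFAULT_SCALES
    }
    fit = fit_au(bp, n_boot)
    assert fit.v == pytest.approx(v_true, abs=0.05)
    assert fit.c == pytest.approx(c_true, abs=0.05)
    assert fit.au == pytest.approx(stats.norm.sf(v_true - c_true), abs=0.05)


def test_planted_groups_get_high_support(rng):
    X = planted_features(rng)
    labels = ["a1", "a2", "a3", "b1", "b2", "b3"]
    tree = bootstrap_support(X, BootstrapConfig(n_boot=100, seed=5), labels=labels)
    support = {n.leafset: n.support for n in tree.splits()}
    for group in (frozenset(["a1", "a2", "a3"]), frozenset(["b1", "b2", "b3"])):
        assert support[group].au >= 0.95
        assert support[group].bp >= 0.95  # present in essentially every replicate


def test_support_invariant_under_item_permutation(rng):
    X = planted_features(rng, sd=0.5)
    labels = ["a1", "a2", "a3", "b1", "b2", "b3"]
    cfg = BootstrapConfig(n_boot=50, seed=9)
    t1 = bootstrap_support(X, cfg, labels=labels)
    perm = [3, 0, 5, 1, 4, 2]
    t2 = bootstrap_support(X[:, perm], cfg, labels=[labels[i] for i in perm])
    s1 = {n.leafset: n.support.au for n in t1.splits()}
    s2 = {n.leafset: n.support.au for n in t2.splits()}
    assert s1 == s2


def test_bootstrap_is_deterministic_given_seed(rng):
    X = planted_features(rng, sd=0.8)
    cfg = BootstrapConfig(n_boot=30, seed=13)
    t1 = bootstrap_support(X, cfg)
    t2 = bootstrap_support(X, cfg)
    assert {(n.leafset, n.support.au, n.support.bp) for n in t1.splits()} == \
        {(n.leafset, n.support.au, n.support.bp) for n in t2.splits()}


def test_rejects_degenerate_inputs(rng):
    with pytest.raises(ValueError):  # fewer than 3 items
        bootstrap_support(rng.normal(size=(10, 2)), BootstrapConfig(n_boot=10))
    with pytest.raises(ValueError):  # identical feature rows
        bootstrap_support(np.ones((5, 4)), BootstrapConfig(n_boot=10))


def test_calibration_on_exchangeable_noise():
    """Without real clusters, few edges should look significant: the
    pooled fraction of splits with AU > 0.95 stays below ~10%."""
    total = significant = 0
    for seed in range(20):
        rng = np.random.default_rng(100 + seed)
        X = rng.normal(size=(30, 6))
        tree = bootstrap_support(X, BootstrapConfig(n_boot=100, seed=seed),
                                 labels=[f"i{k}" for k in range(6)])
        for n in tree.splits():
            total += 1
            significant += n.support.au > 0.95
    assert significant / total <= 0.10
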