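import math
from types import SimpleNamespace

import numpy as np
import pytest

from turnmap.motif_stats import (
    AA_ALPHABET,
    POSITIONS,
    binomial_tail,
    fractional_overrep,
    log_odds_profile,
    match_motif,
    motif_significance,
    parse_motif,
    positional_background,
    rank_motifs,
)


# ---------------------------------------------------------------------------
# grammar
# ---------------------------------------------------------------------------

def test_parse_named_motifs():
    assert parse_motif("D3S+1").constraints == (("3", "D"), ("+1", "S"))
    assert parse_motif("D1R3").constraints == (("1", "D"), ("3", "R"))
    assert parse_motif(" d3 ".upper()).name == "D3"
    assert parse_motif("E-2K+2G1").constraints == (("-2", "E"), ("+2", "K"), ("1", "G"))


@pytest.mark.parametrize("bad", ["D9", "Z3", "", "  ", "D3D3", "3D", "D3X", "D3S+1K2E4"])
def test_parse_rejects_malformed(bad):
    with pytest.raises(ValueError):
        parse_motif(bad)


def test_match_motif_indexing_and_absence():
    m = parse_motif("D3S+1")
    assert match_motif("GAADDSKL"[:4] + "D" + "S" + "SL", m)  # D at 3, S at +1
    assert not match_motif("GAADDSKL", m)
    m2 = parse_motif("G-2")
    assert match_motif("GAADDSKL", m2)
    assert not match_motif("--ADDSKL", m2)  # absent tail never matches


# ---------------------------------------------------------------------------
# significance
# ---------------------------------------------------------------------------

def mp_binomial_tail(k, n, p):
    """Arbitrary-precision oracle via the regularized incomplete beta."""
    import mpmath

    if k <= 0:
        return 1.0
    if k > n:
        return 0.0
    with mpmath.workdps(50):
        return float(mpmath.betainc(k, n - k + 1, 0, p, regularized=True))


@pytest.mark.parametrize(
    "k,n,p",
    [
        (5, 100, 0.05),
        (0, 50, 0.1),
        (10, 10, 0.5),
        (1, 1, 0.3),
        (73, 1000, 0.05),
        (520, 10000, 0.05),
        (9500, 10000, 0.94),
        (3, 10000, 0.0001),
    ],
)
def test_binomial_tail_matches_arbitrary_precision_oracle(k, n, p):
    ours = binomial_tail(k, n, p)
    ref = mp_binomial_tail(k, n, p)
    if ref == 0.0:
        assert ours == 0.0
    else:
        assert abs(ours - ref) / ref < 1e-12


def test_binomial_tail_random_cases_tight(rng):
    for _ in range(50):
        n = int(rng.integers(1, 10000))
        p = float(rng.uniform(0.001, 0.999))
        k = int(rng.integers(0, n + 1))
        ours = binomial_tail(k, n, p)
        ref = mp_binomial_tail(k, n, p)
        assert ours == pytest.approx(ref, rel=1e-12, abs=1e-300)


def test_significance_examples():
    st = motif_significance(5, 100, 0.05)
    assert st.p_value == pytest.approx(0.564, abs=0.001)
    assert st.n_expected == pytest.approx(5.0)
    assert motif_significance(0, 100, 0.05).p_value == 1.0
    assert motif_significance(10, 10, 0.5).p_value == pytest.approx(0.5 ** 10)
    with pytest.raises(ValueError):
        motif_significance(5, 100, 1.5)


@pytest.mark.parametrize(
    "n_obs,n_exp,expected",
    [(20, 8.0, 60.0), (10, 10.0, 0.0), (10, 20.0, -100.0)],
)
def test_fractional_overrep_cases(n_obs, n_exp, expected):
    assert fractional_overrep(n_obs, n_exp) == pytest.approx(expected)


def test_fractional_overrep_bounds():
    with pytest.raises(ValueError):
        fractional_overrep(0, 3.0)
    for n_obs, n_exp in [(7, 0.5), (3, 2.9), (100, 1.0)]:
        v = fractional_overrep(n_obs, n_exp)
        assert v <= 100.0
        # identity: 1 - 1/enrichment
        enrich = n_obs / n_exp
        assert v == pytest.approx(100.0 * (1 - 1 / enrich))


# ---------------------------------------------------------------------------
# profiles
# ---------------------------------------------------------------------------

def test_log_odds_profile_limits():
    bg_seqs = ["A" * 8] * 95 + ["D" * 8] * 5
    bg = positional_background(bg_seqs)
    cluster = ["D" * 8] * 500 + ["A" * 8] * 500
    prof = log_odds_profile(cluster, bg)
    # f_obs 0.5 vs f_bg 0.05 -> ~log2(10), within pseudocount wiggle
    assert prof["1"]["D"] == pytest.approx(math.log2(10), abs=0.05)
    # identical cluster and background -> ~0 everywhere
    same = log_odds_profile(bg_seqs, bg)
    assert abs(same["1"]["A"]) < 1e-9
    # amino acid absent everywhere -> exactly 0 (alpha/alpha)
    assert prof["1"]["W"] == 0.0


def test_profile_excludes_absent_tails():
    seqs = ["--ADDSKL"] * 10 + ["GAADDSKL"] * 10
    bg = positional_background(seqs)
    assert bg["-2"]["G"] == pytest.approx(1.0)  # only present tails count


# ---------------------------------------------------------------------------
# ranking
# ---------------------------------------------------------------------------

def _stub_turns(seqs, bb="C01"):
    return [
        SimpleNamespace(sequence8=s, bb_cluster=bb, classical_type="I") for s in seqs
    ]


def test_rank_motifs_finds_planted_enrichment(rng):
    background_pool = list(AA_ALPHABET)
    seqs = []
    for i in range(400):
        s = "".join(rng.choice(background_pool, size=8))
        seqs.append(s)
    turns = _stub_turns(seqs, bb="bg")
    planted = []
    for i in range(100):
        s = list(rng.choice(background_pool, size=8))
        if i < 50:
            s[2] = "D"  # position 1 in 50% of the cluster
        planted.append("".join(s))
    turns += _stub_turns(planted, bb="hot")
    ranked = rank_motifs(turns, scope="bb:hot", arity=1, min_support=10)
    assert ranked[0][0].name == "D1"
    # direct binomial cross-check of the winner
    bg = positional_background(turns)
    n_obs = sum(1 for s in planted if s[2] == "D")
    expect = binomial_tail(n_obs, 100, bg["1"]["D"])
    assert ranked[0][1].p_value == pytest.approx(expect, rel=1e-9)


def test_rank_motifs_deterministic_and_bounded(rng):
    seqs = ["".join(rng.choice(list(AA_ALPHABET), size=8)) for _ in range(150)]
    turns = _stub_turns(seqs)
    a = rank_motifs(turns, scope="global", arity=2, min_support=2)
    b = rank_motifs(turns, scope="global", arity=2, min_support=2)
    assert [(m.name, s.p_value) for m, s in a] == [(m.name, s.p_value) for m, s in b]
    assert len(a) <= 28 * 400  # C(8,2) position pairs x 20^2 pairs
    assert rank_motifs([], scope="global", arity=1) == []


def test_rank_motifs_null_calibration(rng):
    """Uniform random sequences: after Bonferroni correction over the
    enumerated family, no motif should reach 0.05 in >= 95% of runs."""
    hits = 0
    runs = 100
    for _ in range(runs):
        seqs = ["".join(rng.choice(list(AA_ALPHABET), size=8)) for _ in range(300)]
        turns = _stub_turns(seqs, bb="bg")
        for t in turns[:150]:
            t.bb_cluster = "scope"
        ranked = rank_motifs(turns, scope="bb:scope", arity=1, min_support=5)
        if ranked and ranked[0][1].p_bonferroni < 0.05:
            hits += 1
    assert hits <= runs * 0.05
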