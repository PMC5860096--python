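"""Shared fixtures and independent brute-force oracles.

The oracle functions recompute score indices, score distributions and
joint tail probabilities by exhaustive enumeration of all words, using
only the raw model tables (pfm.probs, bg.transition, bg.stationary) and
the documented rounding rule — they never call the DP under test.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

import motifclump as mc

ALPHA = "ACGT"


# -- model fixtures ----------------------------------------------------------


@pytest.fixture(scope="session")
def uniform_bg():
    return mc.uniform_background(0)


@pytest.fixture(scope="session")
def order1_bg():
    """A skewed but valid order-1 background fitted from seeded sequences."""
    rng = np.random.default_rng(20240501)
    seqs = [
        "".join(rng.choice(list(ALPHA), p=[0.35, 0.15, 0.2, 0.3], size=20000))
        for _ in range(3)
    ]
    return mc.estimate_background(seqs, 1, 1.0)


@pytest.fixture(scope="session")
def order2_bg():
    rng = np.random.default_rng(7)
    seqs = ["".join(rng.choice(list(ALPHA), p=[0.4, 0.1, 0.2, 0.3], size=30000))]
    return mc.estimate_background(seqs, 2, 1.0)


@pytest.fixture(scope="session")
def fixtures():
    return mc.fixture_motifs(0.01)


def random_pfm(rng: np.random.Generator, length: int) -> mc.PFM:
    mat = rng.random((4, length)) + 0.05
    return mc.PFM(mat / mat.sum(axis=0))


@pytest.fixture
def make_random_pfm():
    return random_pfm


# -- independent oracles -----------------------------------------------------


def bg_chain_conditional(bg, prefix_codes, letter) -> float:
    """Background conditional P(letter | prefix) from the raw tables only."""
    d = bg.order
    j = len(prefix_codes)
    if j >= d:
        ctx = 0
        for c in prefix_codes[j - d :]:
            ctx = ctx * 4 + c
        return float(bg.transition[ctx, letter])
    # factor of mu: marginal ratio over the first j letters
    mu = bg.stationary.reshape((4,) * d)
    num = mu[tuple(prefix_codes) + (letter,)].sum()
    den = mu[tuple(prefix_codes)].sum()
    return float(num / den)


def bg_word_prob(bg, codes) -> float:
    """P_B(word) starting in the stationary distribution."""
    p = 1.0
    for i, c in enumerate(codes):
        p *= bg_chain_conditional(bg, codes[:i], c)
    return p


def oracle_word_index(pfm, bg, codes, g) -> int:
    """Rounded grid score: sum of nearest-rounded per-position increments."""
    total = 0
    for j, c in enumerate(codes):
        inc = np.log(pfm.probs[c, j]) - np.log(bg_chain_conditional(bg, codes[:j], c))
        total += int(np.rint(inc / g))
    return total


def oracle_score_distribution(pfm, bg, g):
    """Exhaustive enumeration of all 4^M words -> {index: probability}."""
    M = pfm.length
    out: dict[int, float] = {}
    for codes in itertools.product(range(4), repeat=M):
        idx = oracle_word_index(pfm, bg, list(codes), g)
        out[idx] = out.get(idx, 0.0) + bg_word_prob(bg, list(codes))
    return out


def oracle_joint_tail(pfm, bg, shift, orientation, g, t_index) -> float:
    """P(S0 >= t, S_shift >= t) by enumerating all 4^(M+shift) words."""
    M = pfm.length
    rc = mc.reverse_complement_pfm(pfm)
    mat0 = rc if orientation == "rf" else pfm
    mat1 = rc if orientation == "fr" else pfm
    total = 0.0
    for codes in itertools.product(range(4), repeat=M + shift):
        codes = list(codes)
        s0 = oracle_word_index(mat0, bg, codes[:M], g)
        if s0 < t_index:
            continue
        s1 = oracle_word_index(mat1, bg, codes[shift : shift + M], g)
        if s1 >= t_index:
            total += bg_word_prob(bg, codes)
    return total


def dist_to_dict(dist) -> dict[int, float]:
    return {
        int(i): float(p)
        for i, p in zip(dist.indices, dist.probs)
        if p > 0
    }


@pytest.fixture(scope="session")
def oracles():
    """Namespace fixture bundling the brute-force oracle helpers."""

    class NS:
        chain_conditional = staticmethod(bg_chain_conditional)
        word_prob = staticmethod(bg_word_prob)
        word_index = staticmethod(oracle_word_index)
        score_distribution = staticmethod(oracle_score_distribution)
        joint_tail = staticmethod(oracle_joint_tail)
        to_dict = staticmethod(dist_to_dict)

    return NS


def workable_alpha(pfm, bg, alpha, g=0.01):
    """Smallest attainable nominal alpha at least ``alpha``.

    Short fixture words can have a top score atom whose probability
    already exceeds the requested alpha (e.g. AAAAA under an A-rich
    order-1 background), in which case no threshold attains a positive
    hit probability; bump alpha just above the top atom then.
    """
    dist = mc.score_distribution(pfm, bg, g)
    top = dist.tail(dist.offset + len(dist.probs) - 1)
    return alpha if alpha >= top else top * (1 + 1e-9)


def exact_word_threshold(pfm, bg, g=0.01):
    """Threshold admitting exactly the fixture word (and its ties)."""
    dist = mc.score_distribution(pfm, bg, g)
    top = dist.offset + len(dist.probs) - 1
    alpha = dist.tail(top) * 1.001
    return mc.choose_threshold(dist, alpha)


@pytest.fixture(scope="session")
def word_threshold():
    return exact_word_threshold


@pytest.fixture(scope="session")
def alpha_for():
    return workable_alpha
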