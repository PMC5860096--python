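"""Exact discretized log-odds score distributions under the background.

The score of a length-M window is sum_j [log p_j(w_j) - log q_j(w_j | ctx)]
where q_j is the background chain conditional (a factor of mu for the first
d positions, pi afterwards).  Each per-position increment is rounded to the
nearest multiple of the granularity g; a dynamic program over (context,
accumulated integer score) gives the exact distribution of the rounded
score, and a joint DP over a word of length M+k gives the two-dimensional
distribution for shifted and strand-flipped window pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .background import BackgroundModel
from .motifs import PFM, reverse_complement_pfm

DEFAULT_GRANULARITY = 0.01


# -- data types -------------------------------------------------------------


@dataclass
class ScoreDistribution:
    """Distribution of the rounded score; score = index * granularity."""

    granularity: float
    offset: int  # integer grid index of probs[0]
    probs: np.ndarray

    @property
    def indices(self) -> np.ndarray:
        return self.offset + np.arange(len(self.probs))

    @property
    def scores(self) -> np.ndarray:
        return self.indices * self.granularity

    def tail(self, t_index: int) -> float:
        """P(S >= t) for a grid index t."""
        lo = max(t_index - self.offset, 0)
        if lo >= len(self.probs):
            return 0.0
        return float(self.probs[lo:].sum())

    def trimmed(self) -> "ScoreDistribution":
        nz = np.flatnonzero(self.probs)
        if len(nz) == 0:
            return self
        return ScoreDistribution(
            self.granularity,
            self.offset + int(nz[0]),
            self.probs[nz[0] : nz[-1] + 1].copy(),
        )


@dataclass
class ScoreThreshold:
    t_index: int
    granularity: float
    nominal_alpha: float
    attained_alpha: float

    @property
    def t_alpha(self) -> float:
        return self.t_index * self.granularity


@dataclass
class JointScoreDistribution:
    """Sparse joint law of the rounded scores of two overlapping windows."""

    shift: int
    orientation: str  # ff, fr or rf
    granularity: float
    idx0: np.ndarray
    idx1: np.ndarray
    probs: np.ndarray

    def joint_tail(self, t_index: int) -> float:
        """P(S0 >= t, S1 >= t)."""
        sel = (self.idx0 >= t_index) & (self.idx1 >= t_index)
        return float(self.probs[sel].sum())

    def marginal(self, which: int) -> ScoreDistribution:
        idx = self.idx0 if which == 0 else self.idx1
        lo, hi = int(idx.min()), int(idx.max())
        probs = np.zeros(hi - lo + 1)
        np.add.at(probs, idx - lo, self.probs)
        return ScoreDistribution(self.granularity, lo, probs).trimmed()


# -- per-position increment tables ------------------------------------------


def _chain_conditionals(bg: BackgroundModel) -> list[np.ndarray]:
    """Background conditional tables: prefix factors of mu, then pi.

    Element j is a (4**min(j, d), 4) array; for j >= d it is pi itself.
    """
    return bg.prefix_conditionals() + [bg.transition]


def _increment_tables(pfm: PFM, bg: BackgroundModel, g: float) -> list[np.ndarray]:
    """Rounded integer score increments per motif position.

    Element j has shape (4**min(j, d), 4):
    rint((log p_j(b) - log q_j(b | ctx)) / g).
    """
    if g <= 0:
        raise ValueError("granularity must be positive")
    d = bg.order
    if d > pfm.length:
        raise ValueError("background order exceeds motif length")
    conds = _chain_conditionals(bg)
    logp = np.log(pfm.probs)  # (4, M)
    out = []
    for j in range(pfm.length):
        q = conds[min(j, d)]
        inc = np.rint((logp[:, j][None, :] - np.log(q)) / g).astype(np.int64)
        out.append(inc)
    return out


def score_word(pfm: PFM, bg: BackgroundModel, word: str) -> float:
    """Unrounded log-odds score log P_M(word) - log P_B(word)."""
    if bg.order > pfm.length:
        raise ValueError("background order exceeds motif length")
    return pfm.word_logprob(word) - bg.word_logprob(word)


def word_score_index(pfm: PFM, bg: BackgroundModel, word: str, g: float) -> int:
    """Grid score of a word with the same rounding as score_distribution."""
    from ._dna import encode

    codes = encode(word)
    if len(codes) != pfm.length:
        raise ValueError("word length must equal the motif length")
    if np.any(codes < 0):
        raise ValueError("word contains a non-ACGT letter")
    incs = _increment_tables(pfm, bg, g)
    d = bg.order
    total, ctx = 0, 0
    for j, b in enumerate(codes):
        total += int(incs[j][ctx, b])
        ctx = ctx * 4 + int(b)
        if j >= d - 1:
            ctx %= 4**d
    return total


# -- one-dimensional DP ------------------------------------------------------


def score_distribution(
    pfm: PFM, bg: BackgroundModel, granularity: float = DEFAULT_GRANULARITY
) -> ScoreDistribution:
    """Exact distribution of the rounded score under the background."""
    incs = _increment_tables(pfm, bg, granularity)
    conds = _chain_conditionals(bg)
    d = bg.order
    lo = sum(int(t.min()) for t in incs)
    width = sum(int(t.max()) - int(t.min()) for t in incs) + 1

    cur = np.zeros((1, 1))
    cur[0, 0] = 1.0
    offset = 0
    for j, inc in enumerate(incs):
        q = conds[min(j, d)]
        n_ctx_new = 4 ** min(j + 1, d)
        step_lo, step_hi = int(inc.min()), int(inc.max())
        w_new = cur.shape[1] + (step_hi - step_lo)
        new = np.zeros((n_ctx_new, w_new))
        for ctx in range(cur.shape[0]):
            row = cur[ctx]
            if not row.any():
                continue
            for b in range(4):
                nctx = (ctx * 4 + b) % n_ctx_new
                sh = int(inc[ctx, b]) - step_lo
                new[nctx, sh : sh + cur.shape[1]] += q[ctx, b] * row
        cur = new
        offset += step_lo
    probs = cur.sum(axis=0)
    return ScoreDistribution(granularity, offset, probs).trimmed()


def choose_threshold(dist: ScoreDistribution, alpha: float) -> ScoreThreshold:
    """Smallest grid score whose tail probability is at most alpha."""
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    tails = np.cumsum(dist.probs[::-1])[::-1]  # tails[i] = P(S >= offset+i)
    ok = np.flatnonzero(tails <= alpha + 1e-15)
    if len(ok) == 0:
        warnings.warn(
            "alpha is below the smallest positive tail atom; "
            "the threshold admits no hits",
            stacklevel=2,
        )
        return ScoreThreshold(
            dist.offset + len(dist.probs), dist.granularity, alpha, 0.0
        )
    i = int(ok[0])
    return ScoreThreshold(dist.offset + i, dist.granularity, alpha, float(tails[i]))


# -- joint DP ----------------------------------------------------------------

_ORIENTATIONS = ("ff", "fr", "rf")


def joint_score_distribution(
    pfm: PFM,
    bg: BackgroundModel,
    shift: int,
    orientation: str,
    granularity: float = DEFAULT_GRANULARITY,
) -> JointScoreDistribution:
    """Joint law of the scores of windows starting at 0 and at ``shift``.

    Window 0 is scored with the motif itself for ff/fr and with its reverse
    complement for rf; window ``shift`` with the motif for ff/rf and the
    reverse complement for fr.  Both windows use the stationary-start
    background probability of their own extent, exactly as in the
    one-dimensional score distribution.
    """
    if orientation not in _ORIENTATIONS:
        raise ValueError(f"orientation must be one of {_ORIENTATIONS}")
    M = pfm.length
    k_min = 0 if orientation == "fr" else 1
    if not k_min <= shift <= M - 1:
        raise ValueError(f"shift {shift} out of range for orientation {orientation}")
    rc = reverse_complement_pfm(pfm)
    mat0 = rc if orientation == "rf" else pfm
    mat1 = rc if orientation == "fr" else pfm

    d = bg.order
    conds = _chain_conditionals(bg)
    inc0 = _increment_tables(mat0, bg, granularity)
    inc1 = _increment_tables(mat1, bg, granularity)
    L = M + shift

    # state arrays: context (last min(i,d) letters), both scores, probability
    ctx = np.zeros(1, dtype=np.int64)
    s0 = np.zeros(1, dtype=np.int64)
    s1 = np.zeros(1, dtype=np.int64)
    p = np.ones(1)
    letters = np.arange(4, dtype=np.int64)
    for i in range(L):
        q = conds[min(i, d)]
        n = len(ctx)
        # expand each state by the four letters
        ctx_e = np.repeat(ctx, 4)
        b_e = np.tile(letters, n)
        p_e = np.repeat(p, 4) * q[ctx_e, b_e]
        s0_e = np.repeat(s0, 4)
        s1_e = np.repeat(s1, 4)
        if i < M:
            t = inc0[i]
            c = ctx_e % t.shape[0] if i >= d else ctx_e
            s0_e = s0_e + t[c, b_e]
        if i >= shift:
            j1 = i - shift
            t = inc1[j1]
            # context for the second window: its own last min(j1, d) letters
            c = ctx_e % t.shape[0]
            s1_e = s1_e + t[c, b_e]
        nc = 4 ** min(i + 1, d)
        ctx_e = (ctx_e * 4 + b_e) % nc if d else np.zeros_like(ctx_e)
        # aggregate duplicate states
        lo0, lo1 = s0_e.min(), s1_e.min()
        r0 = int(s0_e.max() - lo0) + 1
        r1 = int(s1_e.max() - lo1) + 1
        key = (ctx_e * r0 + (s0_e - lo0)) * r1 + (s1_e - lo1)
        uniq, inv = np.unique(key, return_inverse=True)
        p = np.bincount(inv, weights=p_e, minlength=len(uniq))
        keep = p > 0
        uniq, p = uniq[keep], p[keep]
        s1 = uniq % r1 + lo1
        rest = uniq // r1
        s0 = rest % r0 + lo0
        ctx = rest // r0
    # marginalize contexts
    lo0, lo1 = s0.min(), s1.min()
    r0 = int(s0.max() - lo0) + 1
    r1 = int(s1.max() - lo1) + 1
    key = (s0 - lo0) * r1 + (s1 - lo1)
    uniq, inv = np.unique(key, return_inverse=True)
    probs = np.bincount(inv, weights=p, minlength=len(uniq))
    return JointScoreDistribution(
        shift,
        orientation,
        granularity,
        idx0=(uniq // r1 + lo0).astype(np.int64),
        idx1=(uniq % r1 + lo1).astype(np.int64),
        probs=probs,
    )


def export_score_distribution(dist: ScoreDistribution, path) -> None:
    """Two-column TSV (score, probability)."""
    rows = "\n".join(
        f"{s:.10g}\t{float(q)!r}" for s, q in zip(dist.scores, dist.probs)
    )
    text = "score\tprobability\n" + rows + "\n"
    if hasattr(path, "write"):
        path.write(text)
    else:
        with open(path, "w") as fh:
            fh.write(text)
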