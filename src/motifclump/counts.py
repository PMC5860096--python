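"""Hit-count distributions: compound Poisson, binomial, enrichment p-values.

The number of hits X on both strands of a length-N sequence is modeled as
a Poisson(lambda) number of clumps with i.i.d. sizes theta, evaluated by
the standard compound-Poisson (Panjer) recursion.  N is treated as total
scannable length when several sequences are aggregated; per-sequence edge
effects are ignored.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from math import exp

import numpy as np
from scipy import stats

from .clump import ClumpSizeDistribution

DEFAULT_TAIL_TOL = 1e-10


@dataclass
class HitCountDistribution:
    probs: np.ndarray  # P(X = x) for x = 0..xmax
    model: str  # compound_poisson, binomial or empirical
    alpha: float = float("nan")
    N: int = 0
    M: int = 0
    lam: float = float("nan")  # compound Poisson only

    @property
    def xmax(self) -> int:
        return len(self.probs) - 1

    def mean(self) -> float:
        return float(np.arange(len(self.probs)) @ self.probs)

    def variance(self) -> float:
        x = np.arange(len(self.probs), dtype=float)
        m = self.mean()
        return float((x - m) ** 2 @ self.probs)

    def truncated_tail(self) -> float:
        return max(0.0, 1.0 - float(self.probs.sum()))

    def metadata_json(self) -> str:
        return json.dumps(
            {
                "model": self.model,
                "alpha": self.alpha,
                "N": self.N,
                "M": self.M,
                "lambda": None if np.isnan(self.lam) else self.lam,
            }
        )

    def export_tsv(self, path) -> None:
        lines = ["x\tprobability"] + [
            f"{x}\t{float(v)!r}" for x, v in enumerate(self.probs)
        ]
        text = "\n".join(lines) + "\n"
        if hasattr(path, "write"):
            path.write(text)
        else:
            with open(path, "w") as fh:
                fh.write(text)


def expected_hits(alpha_attained: float, N: int, M: int) -> float:
    """E[X] = 2 * alpha' * (N - M + 1): hits are counted on both strands."""
    if N < M:
        raise ValueError("sequence length must be at least the motif length")
    return 2.0 * alpha_attained * (N - M + 1)


def compound_poisson_counts(
    theta: ClumpSizeDistribution,
    alpha_attained: float,
    N: int,
    M: int,
    tail_tol: float = DEFAULT_TAIL_TOL,
) -> HitCountDistribution:
    """Compound Poisson hit-count distribution from a clump-size law.

    lambda = E[X] / E[C]; P(X=0) = exp(-lambda); and
    P(X=x) = (lambda / x) * sum_{x'} (x - x') theta_{x-x'} P(X=x'),
    extended until the cumulative mass reaches 1 - tail_tol (hard cap at
    the maximum possible count 2(N-M+1)).
    """
    if N < M:
        raise ValueError("sequence length must be at least the motif length")
    th = np.asarray(theta.theta, dtype=float)
    if th.size == 0:
        raise ValueError("empty clump-size distribution")
    ec = theta.expected_size()
    lam = expected_hits(alpha_attained, N, M) / ec
    hard_max = 2 * (N - M + 1)
    probs = [exp(-lam)]
    cum = probs[0]
    x = 0
    while cum < 1.0 - tail_tol and x < hard_max:
        x += 1
        cmax = min(x, len(th))
        # sum over clump sizes c = x - x' (vectorized over x')
        c = np.arange(1, cmax + 1)
        s = float((c * th[c - 1]) @ np.array(probs[x - cmax : x][::-1]))
        probs.append(lam / x * s)
        cum += probs[-1]
    return HitCountDistribution(
        np.array(probs), "compound_poisson", alpha=alpha_attained, N=N, M=M, lam=lam
    )


def binomial_counts(alpha_attained: float, N: int, M: int) -> HitCountDistribution:
    """Binomial(2(N-M+1), alpha') reference model over its full support."""
    if N < M:
        raise ValueError("sequence length must be at least the motif length")
    n = 2 * (N - M + 1)
    a = alpha_attained
    probs = stats.binom.pmf(np.arange(n + 1), n, a)
    return HitCountDistribution(probs, "binomial", alpha=a, N=N, M=M)


def enrichment_pvalue(dist: HitCountDistribution, observed: int) -> float:
    """P(X >= observed), with the truncated tail added as an upper bound."""
    if observed < 0:
        raise ValueError("observed count must be non-negative")
    if observed == 0:
        return 1.0
    tail = float(dist.probs[observed:].sum()) if observed <= dist.xmax else 0.0
    return min(1.0, tail + dist.truncated_tail())
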