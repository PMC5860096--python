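"""Marginal (gamma) and principal (beta) overlapping hit probabilities.

gamma_k is the probability of a second hit k positions downstream of a
hit, averaging over intermediate events; beta_k additionally requires
that no hit occurs in between, with events ordered Y_1 Y'_1 Y_2 Y'_2 ...
(a forward hit precedes the reverse hit at the same position).  The
three strand cases are same-strand, forward-then-reverse (3'-overlap,
defined from shift 0) and reverse-then-forward (5'-overlap).

beta is approximated from gamma by chain subtraction: every way a
marginal overlap at shift k can be explained by a *first* principal
overlap at shift j < k followed by a marginal overlap over the remaining
k-j positions is removed, including chains through the shift-0
forward/reverse pairing (beta3p_0 = gamma3p_0).  Reverse-reverse overlap
probabilities equal gamma by strand symmetry of the background.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .background import BackgroundModel
from .motifs import PFM
from .score_model import ScoreThreshold, joint_score_distribution

logger = logging.getLogger(__name__)

PERIOD_TOL = 1e-9


@dataclass
class OverlapProbabilities:
    """Overlap probability arrays, all of length M (index = shift k).

    gamma[0] and gamma5p[0] are unused slots kept at 0; gamma3p[0] is the
    probability of a reverse hit at the same start as a forward hit.
    """

    gamma: np.ndarray
    gamma3p: np.ndarray
    gamma5p: np.ndarray
    beta: np.ndarray = field(default=None)
    beta3p: np.ndarray = field(default=None)
    beta5p: np.ndarray = field(default=None)
    attained_alpha: float = 0.0

    @property
    def motif_length(self) -> int:
        return len(self.gamma)

    @property
    def B(self) -> float:
        return float(self.beta[1:].sum())

    @property
    def B3(self) -> float:
        return float(self.beta3p.sum())

    @property
    def B5(self) -> float:
        return float(self.beta5p[1:].sum())

    def gamma_aggregates(self) -> tuple[float, float, float]:
        """Marginal-mode analogues of (B, B3, B5)."""
        return (
            float(self.gamma[1:].sum()),
            float(self.gamma3p.sum()),
            float(self.gamma5p[1:].sum()),
        )


def marginal_overlaps(
    pfm: PFM,
    bg: BackgroundModel,
    thr: ScoreThreshold,
    granularity: float | None = None,
) -> OverlapProbabilities:
    """Compute gamma_k, gamma3p_k and gamma5p_k from the joint score DP."""
    g = thr.granularity if granularity is None else granularity
    alpha = thr.attained_alpha
    if alpha <= 0:
        raise ValueError("threshold admits no hits (attained alpha is 0)")
    M = pfm.length
    gamma = np.zeros(M)
    gamma3p = np.zeros(M)
    gamma5p = np.zeros(M)
    for k in range(1, M):
        jd = joint_score_distribution(pfm, bg, k, "ff", g)
        gamma[k] = jd.joint_tail(thr.t_index) / alpha
    for k in range(0, M):
        jd = joint_score_distribution(pfm, bg, k, "fr", g)
        gamma3p[k] = jd.joint_tail(thr.t_index) / alpha
    for k in range(1, M):
        jd = joint_score_distribution(pfm, bg, k, "rf", g)
        gamma5p[k] = jd.joint_tail(thr.t_index) / alpha
    np.clip(gamma, 0.0, 1.0, out=gamma)
    np.clip(gamma3p, 0.0, 1.0, out=gamma3p)
    np.clip(gamma5p, 0.0, 1.0, out=gamma5p)
    return OverlapProbabilities(gamma, gamma3p, gamma5p, attained_alpha=alpha)


def principal_overlaps(ov: OverlapProbabilities) -> OverlapProbabilities:
    """Fill the beta arrays by chain subtraction from the gamma arrays.

    Recursions (clipped into [0, gamma of the same index]; clipped values
    feed later shifts):

      beta_k   = gamma_k   - sum_{j<k}[beta_j gamma_{k-j} + beta3p_j gamma5p_{k-j}]
                           - beta3p_0 gamma5p_k
      beta3p_k = gamma3p_k - sum_{j<k}[beta_j gamma3p_{k-j} + beta3p_j gamma_{k-j}]
                           - beta3p_0 gamma_k,          beta3p_0 = gamma3p_0
      beta5p_k = gamma5p_k - sum_{j<k}[beta5p_j gamma_{k-j} + beta_j gamma5p_{k-j}]

    where the j-sums run over 1 <= j <= k-1 and reverse-reverse marginal
    overlaps equal gamma by background symmetry.
    """
    M = ov.motif_length
    ga, g3, g5 = ov.gamma, ov.gamma3p, ov.gamma5p
    b = np.zeros(M)
    b3 = np.zeros(M)
    b5 = np.zeros(M)
    b3[0] = g3[0]
    n_clipped = 0
    for k in range(1, M):
        s = b3[0] * g5[k]
        s3 = b3[0] * ga[k]
        s5 = 0.0
        for j in range(1, k):
            s += b[j] * ga[k - j] + b3[j] * g5[k - j]
            s3 += b[j] * g3[k - j] + b3[j] * ga[k - j]
            s5 += b5[j] * ga[k - j] + b[j] * g5[k - j]
        for arr, gval, sub in ((b, ga[k], s), (b3, g3[k], s3), (b5, g5[k], s5)):
            val = gval - sub
            if val < 0 or val > gval:
                n_clipped += 1
            arr[k] = min(max(val, 0.0), gval)
    if n_clipped:
        logger.info("principal_overlaps clipped %d negative chain values", n_clipped)
    return OverlapProbabilities(
        ga, g3, g5, beta=b, beta3p=b3, beta5p=b5, attained_alpha=ov.attained_alpha
    )


def compute_overlaps(
    pfm: PFM,
    bg: BackgroundModel,
    thr: ScoreThreshold,
    granularity: float | None = None,
) -> OverlapProbabilities:
    """Marginal and principal overlap probabilities in one call."""
    return principal_overlaps(marginal_overlaps(pfm, bg, thr, granularity))


def overlap_structure(
    pfm: PFM,
    bg: BackgroundModel,
    thr: ScoreThreshold,
    tol: float = PERIOD_TOL,
) -> tuple[set[int], set[int]]:
    """Same-strand periods (gamma_k > tol) and principal periods (beta_k > tol)."""
    ov = compute_overlaps(pfm, bg, thr)
    periods = {k for k in range(1, ov.motif_length) if ov.gamma[k] > tol}
    principal = {k for k in range(1, ov.motif_length) if ov.beta[k] > tol}
    return periods, principal


def export_overlaps(ov: OverlapProbabilities, path) -> None:
    """TSV with columns (k, gamma, gamma3p, gamma5p, beta, beta3p, beta5p)."""
    lines = ["k\tgamma\tgamma3p\tgamma5p\tbeta\tbeta3p\tbeta5p"]
    for k in range(ov.motif_length):
        lines.append(
            "\t".join(
                [str(k)]
                + [
                    repr(float(a[k])) if a is not None else "nan"
                    for a in (
                        ov.gamma,
                        ov.gamma3p,
                        ov.gamma5p,
                        ov.beta,
                        ov.beta3p,
                        ov.beta5p,
                    )
                ]
            )
        )
    text = "\n".join(lines) + "\n"
    if hasattr(path, "write"):
        path.write(text)
    else:
        with open(path, "w") as fh:
            fh.write(text)
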