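"""Clump-size distributions for single- and double-strand scanning.

A clump is a maximal run of mutually overlapping hits; theta_c is the
probability that a clump contains exactly c hits.  On a single strand the
clump size is geometric with ratio B (the total principal overlap mass).
On both strands the unnormalized masses follow a two-state linear
recursion over the strand of the last hit; the formulation below is
algebraically equivalent to dividing out the old clump end and
multiplying in the new one, but avoids the 0/0 of exact palindromes
(where 1 - B - B3 = 0 and all mass sits on even clump sizes).

In marginal mode the gamma aggregates replace (B, B3, B5) throughout,
which serves as the surrogate for the redundancy-prone previous model.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np

from .overlap import OverlapProbabilities

DEFAULT_TAIL_TOL = 1e-10
MAX_CLUMP_SIZE = 1000


@dataclass
class ClumpSizeDistribution:
    theta: np.ndarray  # theta[i] = P(C = i + 1)
    mode: str  # single or double
    overlap_mode: str  # principal or marginal
    B: float = 0.0
    B3: float = 0.0
    B5: float = 0.0

    @property
    def cmax(self) -> int:
        return len(self.theta)

    def expected_size(self) -> float:
        return float(np.arange(1, self.cmax + 1) @ self.theta)

    def to_json(self) -> str:
        return json.dumps(
            {
                "mode": self.mode,
                "overlap_mode": self.overlap_mode,
                "B": self.B,
                "B3": self.B3,
                "B5": self.B5,
                "cmax": self.cmax,
            }
        )

    def export_tsv(self, path) -> None:
        lines = ["c\ttheta"] + [
            f"{c + 1}\t{float(v)!r}" for c, v in enumerate(self.theta)
        ]
        text = "\n".join(lines) + "\n"
        if hasattr(path, "write"):
            path.write(text)
        else:
            with open(path, "w") as fh:
                fh.write(text)


def clump_single(
    B: float,
    cmax_tol: float = DEFAULT_TAIL_TOL,
    overlap_mode: str = "principal",
) -> ClumpSizeDistribution:
    """Geometric clump-size law for single-strand scanning."""
    if not 0 <= B < 1:
        raise ValueError("overlap mass >= 1 (or negative)")
    if B == 0:
        return ClumpSizeDistribution(np.array([1.0]), "single", overlap_mode, B=B)
    # truncate at the first c where the remaining geometric tail < cmax_tol
    # tail after c terms of (1-B) B^{c-1} is B^c
    cmax = int(np.ceil(np.log(cmax_tol) / np.log(B))) if cmax_tol > 0 else MAX_CLUMP_SIZE
    cmax = max(1, min(cmax, MAX_CLUMP_SIZE))
    raw = (1.0 - B) * B ** np.arange(cmax)
    return ClumpSizeDistribution(raw / raw.sum(), "single", overlap_mode, B=B)


def clump_double(
    B: float,
    B3: float,
    B5: float,
    pair0: float = 0.0,
    cmax_tol: float = DEFAULT_TAIL_TOL,
    overlap_mode: str = "principal",
) -> ClumpSizeDistribution:
    """Clump-size law when both strands are scanned.

    ``pair0`` is the probability of a reverse hit at the same start as a
    forward hit (beta3p_0, already included in B3); a clump can start
    with a reverse hit only when there is no forward hit at the same
    position, so the reverse start carries weight 1 - pair0.
    """
    for nm, v in (("B", B), ("B3", B3), ("B5", B5)):
        if v < 0:
            raise ValueError(f"{nm} must be non-negative")
    end_f = 1.0 - B - B3
    end_r = 1.0 - B - B5
    if end_f < 0 or end_r < 0:
        warnings.warn(
            "overlap mass exceeds 1 (degenerate palindrome artifact); "
            "clipping the 1-clump end probability at 0",
            stacklevel=2,
        )
        end_f = max(end_f, 0.0)
        end_r = max(end_r, 0.0)
    rho = B + np.sqrt(B3 * B5)  # spectral radius of the extension matrix
    if rho >= 1:
        raise ValueError("overlap mass >= 1: clump extension does not terminate")
    u, v = 1.0, 1.0 - pair0
    raw = []
    total = 0.0
    for _ in range(MAX_CLUMP_SIZE):
        t = end_f * u + end_r * v
        raw.append(t)
        total += t
        u, v = B * u + B5 * v, B3 * u + B * v
        # remaining mass is bounded by the current state times the
        # geometric tail of the spectral radius
        bound = (u + v) / max(1.0 - rho, 1e-12)
        if total > 0 and bound < cmax_tol * total:
            break
    raw = np.array(raw)
    if raw.sum() <= 0:
        raise ValueError("degenerate clump distribution (no mass)")
    return ClumpSizeDistribution(
        raw / raw.sum(), "double", overlap_mode, B=B, B3=B3, B5=B5
    )


def clump_from_overlaps(
    ov: OverlapProbabilities,
    mode: str = "double",
    overlap_mode: str = "principal",
    cmax_tol: float = DEFAULT_TAIL_TOL,
) -> ClumpSizeDistribution:
    """Build the clump-size law from overlap probabilities.

    overlap_mode='principal' uses the beta aggregates (the improved
    model); overlap_mode='marginal' substitutes the gamma aggregates (the
    previous-model surrogate).
    """
    if overlap_mode == "principal":
        B, B3, B5 = ov.B, ov.B3, ov.B5
        pair0 = float(ov.beta3p[0])
    elif overlap_mode == "marginal":
        B, B3, B5 = ov.gamma_aggregates()
        pair0 = float(ov.gamma3p[0])
    else:
        raise ValueError("overlap_mode must be 'principal' or 'marginal'")
    if mode == "single":
        return clump_single(min(B, 1 - 1e-12), cmax_tol, overlap_mode)
    if mode == "double":
        return clump_double(B, B3, B5, pair0, cmax_tol, overlap_mode)
    raise ValueError("mode must be 'single' or 'double'")
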