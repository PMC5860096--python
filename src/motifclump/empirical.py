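"""Simulation-based reference distributions and model comparison.

Sequences sampled from the background are scanned on both strands with
the identical grid rounding used by the analytic score distribution, so
empirical hit frequencies are directly comparable to the attained alpha.
Coordinates are 0-based; reverse-strand hits are reported at their
forward-strand window start.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._dna import encode
from .background import BackgroundModel
from .clump import clump_from_overlaps
from .counts import HitCountDistribution, binomial_counts, compound_poisson_counts
from .motifs import PFM, reverse_complement_pfm
from .overlap import compute_overlaps
from .score_model import (
    ScoreThreshold,
    _increment_tables,
    choose_threshold,
    score_distribution,
)


@dataclass
class Hit:
    start: int
    strand: str  # '+' or '-'
    score: float


@dataclass
class HitList:
    hits: list[Hit]
    length: int
    motif_length: int

    def __len__(self) -> int:
        return len(self.hits)

    def __iter__(self):
        return iter(self.hits)

    def starts(self, strand: str | None = None) -> np.ndarray:
        return np.array(
            [h.start for h in self.hits if strand is None or h.strand == strand],
            dtype=int,
        )


@dataclass
class EmpiricalDistribution:
    probs: np.ndarray
    n_samples: int
    q25: np.ndarray
    q75: np.ndarray
    seed: int
    model: str = field(default="empirical")

    def mean(self) -> float:
        return float(np.arange(len(self.probs)) @ self.probs)

    def variance(self) -> float:
        x = np.arange(len(self.probs), dtype=float)
        m = self.mean()
        return float((x - m) ** 2 @ self.probs)


# -- scanning ----------------------------------------------------------------


def _window_score_indices(
    codes: np.ndarray, incs: list[np.ndarray], d: int
) -> tuple[np.ndarray, np.ndarray]:
    """Rounded score index of every window plus a validity mask.

    ``incs`` are the per-position increment tables of score_model; the
    contribution of motif position j at window i is a lookup by the
    (min(j, d)+1)-mer ending at sequence position i+j, so the whole scan
    is M flat gathers.
    """
    M = len(incs)
    n = len(codes)
    if n < M:
        return np.zeros(0, dtype=np.int64), np.zeros(0, dtype=bool)
    bad = codes < 0
    clean = np.where(bad, 0, codes).astype(np.int64)
    nw = n - M + 1
    # rolling (l+1)-mer codes; R starts as 1-mers and is extended in place
    scores = np.zeros(nw, dtype=np.int64)
    R = clean.copy()
    for j in range(M):
        l = min(j, d)  # context length used at motif position j
        if j <= d:
            # R currently holds (j+1)-mer codes at each start t (valid
            # for t <= n - j - 1); gather at window starts directly
            scores += incs[j].ravel()[R[:nw]]
            if j < d:
                R[: n - j - 1] = R[: n - j - 1] * 4 + clean[j + 1 :]
        else:
            # R holds (d+1)-mer codes at start t; context ends at i+j-1
            scores += incs[j].ravel()[R[j - d : j - d + nw]]
    # windows containing non-ACGT letters are invalid
    cs = np.concatenate([[0], np.cumsum(bad)])
    valid = (cs[M:] - cs[:-M]) == 0
    return scores, valid


class _Scanner:
    """Precomputed both-strand scanner for one (pfm, bg, threshold)."""

    def __init__(self, pfm: PFM, bg: BackgroundModel, thr: ScoreThreshold):
        g = thr.granularity
        self.pfm = pfm
        self.bg = bg
        self.thr = thr
        self.M = pfm.length
        self.d = bg.order
        self.inc_fwd = _increment_tables(pfm, bg, g)
        self.inc_rev = _increment_tables(reverse_complement_pfm(pfm), bg, g)

    def hit_masks(self, codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        sf, valid = _window_score_indices(codes, self.inc_fwd, self.d)
        sr, _ = _window_score_indices(codes, self.inc_rev, self.d)
        t = self.thr.t_index
        return (sf >= t) & valid, (sr >= t) & valid

    def score_indices(self, codes: np.ndarray):
        sf, valid = _window_score_indices(codes, self.inc_fwd, self.d)
        sr, _ = _window_score_indices(codes, self.inc_rev, self.d)
        return sf, sr, valid


def scan_sequence(
    pfm: PFM, bg: BackgroundModel, thr: ScoreThreshold, sequence: str
) -> HitList:
    """All forward and reverse hits, sorted by (start, strand; + first)."""
    codes = encode(sequence)
    sc = _Scanner(pfm, bg, thr)
    sf, sr, valid = sc.score_indices(codes)
    t, g = thr.t_index, thr.granularity
    hits = []
    for i in np.flatnonzero((sf >= t) & valid):
        hits.append(Hit(int(i), "+", float(sf[i] * g)))
    for i in np.flatnonzero((sr >= t) & valid):
        hits.append(Hit(int(i), "-", float(sr[i] * g)))
    hits.sort(key=lambda h: (h.start, h.strand))
    return HitList(hits, length=len(codes), motif_length=pfm.length)


def write_bed(hitlist: HitList, path, chrom: str = "seq", name: str = "motif") -> None:
    """Hits as BED6 (end = start + M; reverse hits at forward coordinates)."""
    lines = [
        f"{chrom}\t{h.start}\t{h.start + hitlist.motif_length}\t{name}"
        f"\t{h.score:.6g}\t{h.strand}"
        for h in hitlist.hits
    ]
    text = "\n".join(lines) + ("\n" if lines else "")
    if hasattr(path, "write"):
        path.write(text)
    else:
        with open(path, "w") as fh:
            fh.write(text)


# -- empirical distributions ---------------------------------------------------


def empirical_count_distribution(
    pfm: PFM,
    bg: BackgroundModel,
    thr: ScoreThreshold,
    n_seqs: int,
    length: int,
    batches: int = 20,
    seed: int = 0,
) -> EmpiricalDistribution:
    """Both-strand hit-count PMF over sampled sequences with batch quantiles."""
    if n_seqs % batches != 0:
        raise ValueError("n_seqs must be divisible by batches")
    sc = _Scanner(pfm, bg, thr)
    codes = bg.sample_codes(n_seqs, length, seed)
    counts = np.empty(n_seqs, dtype=int)
    for i in range(n_seqs):
        hf, hr = sc.hit_masks(codes[i])
        counts[i] = int(hf.sum()) + int(hr.sum())
    xmax = int(counts.max())
    pooled = np.bincount(counts, minlength=xmax + 1) / n_seqs
    per_batch = counts.reshape(batches, n_seqs // batches)
    batch_pmfs = np.stack(
        [
            np.bincount(row, minlength=xmax + 1) / (n_seqs // batches)
            for row in per_batch
        ]
    )
    q25 = np.percentile(batch_pmfs, 25, axis=0)
    q75 = np.percentile(batch_pmfs, 75, axis=0)
    return EmpiricalDistribution(pooled, n_seqs, q25, q75, seed)


def clump_sizes_from_hits(
    starts_sorted: np.ndarray, motif_length: int
) -> np.ndarray:
    """Group hits into clumps: consecutive starts within M-1 join a clump."""
    if len(starts_sorted) == 0:
        return np.zeros(0, dtype=int)
    breaks = np.flatnonzero(np.diff(starts_sorted) > motif_length - 1)
    bounds = np.concatenate([[0], breaks + 1, [len(starts_sorted)]])
    return np.diff(bounds)


def empirical_clump_distribution(
    pfm: PFM,
    bg: BackgroundModel,
    thr: ScoreThreshold,
    total_length: int,
    seed: int = 0,
) -> np.ndarray:
    """Clump-size PMF (index c-1) counted on one sampled sequence."""
    if total_length < 10 * pfm.length:
        raise ValueError("total_length too short for clump counting")
    sc = _Scanner(pfm, bg, thr)
    codes = bg.sample_codes(1, total_length, seed)[0]
    hf, hr = sc.hit_masks(codes)
    # hits sorted by (start, strand; + before -): sort a combined key that
    # keeps the + hit first at equal starts (clumping only needs starts)
    starts = np.sort(np.concatenate([np.flatnonzero(hf), np.flatnonzero(hr)]))
    sizes = clump_sizes_from_hits(starts, pfm.length)
    if len(sizes) == 0:
        warnings.warn("no hits: empirical clump distribution is empty", stacklevel=2)
        return np.zeros(0)
    return np.bincount(sizes)[1:] / len(sizes)


# -- discrepancy statistics ----------------------------------------------------


def _probs(P) -> np.ndarray:
    return np.asarray(P.probs if hasattr(P, "probs") else P, dtype=float)


def _padded(P, Q) -> tuple[np.ndarray, np.ndarray]:
    p, q = _probs(P), _probs(Q)
    n = max(len(p), len(q))
    return (
        np.pad(p, (0, n - len(p))),
        np.pad(q, (0, n - len(q))),
    )


def distribution_distance(P, Q) -> float:
    """sum_x |P(x) - Q(x)| (the L1 statistic; twice the usual TV distance)."""
    p, q = _padded(P, Q)
    return float(np.abs(p - q).sum())


def tail_distance(P, Q) -> float:
    """Same statistic restricted to x >= the 95th percentile of P."""
    p, q = _padded(P, Q)
    cdf = np.cumsum(p)
    q95 = int(np.searchsorted(cdf, 0.95))
    return float(np.abs(p[q95:] - q[q95:]).sum())


# -- model comparison ----------------------------------------------------------


@dataclass
class ComparisonReport:
    empirical: EmpiricalDistribution
    models: dict[str, HitCountDistribution]
    distance: dict[str, float]
    tail: dict[str, float]
    delta_new_marginal: float
    delta_new_binomial: float
    attained_alpha: float

    def to_tsv(self, path=None) -> str:
        lines = ["model\tdistance\ttail_distance"]
        for nm in self.models:
            lines.append(f"{nm}\t{self.distance[nm]!r}\t{self.tail[nm]!r}")
        lines.append(f"delta_new_minus_marginal\t{self.delta_new_marginal!r}\t")
        lines.append(f"delta_new_minus_binomial\t{self.delta_new_binomial!r}\t")
        text = "\n".join(lines) + "\n"
        if path is not None:
            if hasattr(path, "write"):
                path.write(text)
            else:
                with open(path, "w") as fh:
                    fh.write(text)
        return text


def compare_models(
    pfm: PFM,
    bg: BackgroundModel,
    alpha: float,
    length: int,
    n_seqs: int,
    seed: int = 0,
    granularity: float = 0.01,
    batches: int = 20,
) -> ComparisonReport:
    """Empirical vs compound Poisson (principal and marginal) vs binomial."""
    dist = score_distribution(pfm, bg, granularity)
    thr = choose_threshold(dist, alpha)
    ov = compute_overlaps(pfm, bg, thr)
    a = thr.attained_alpha
    N, M = length, pfm.length
    models = {
        "cp_principal": compound_poisson_counts(
            clump_from_overlaps(ov, "double", "principal"), a, N, M
        ),
        "cp_marginal": compound_poisson_counts(
            clump_from_overlaps(ov, "double", "marginal"), a, N, M
        ),
        "binomial": binomial_counts(a, N, M),
    }
    emp = empirical_count_distribution(pfm, bg, thr, n_seqs, length, batches, seed)
    distance = {nm: distribution_distance(emp, m) for nm, m in models.items()}
    tail = {nm: tail_distance(emp, m) for nm, m in models.items()}
    return ComparisonReport(
        empirical=emp,
        models=models,
        distance=distance,
        tail=tail,
        delta_new_marginal=distance["cp_principal"] - distance["cp_marginal"],
        delta_new_binomial=distance["cp_principal"] - distance["binomial"],
        attained_alpha=a,
    )
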