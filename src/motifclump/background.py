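"""Order-d Markov background models with strand/reversal symmetry.

The model is estimated from (d+1)-mer counts that are averaged over the
four-element closure {identity, reverse, complement, reverse-complement},
so that under the stationary distribution a word, its reverse complement
and its reversal are equally probable.  Counting is circular within each
maximal ACGT-only segment, which makes the first-d-mer and last-d-mer
marginals of the count table identical; the stationary distribution then
equals the context marginal exactly (no eigen solve needed), and all
symmetry invariants hold to machine precision.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from ._dna import ALPHABET, encode, kmer_word

try:  # optional JIT for the chain sampler
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is normally available
    _HAVE_NUMBA = False


class InsufficientDataError(ValueError):
    """No window of length order+1 free of non-ACGT letters exists."""


class ZeroTransitionError(ValueError):
    """A symmetrized count is zero while the pseudocount is zero."""


def _orbit_permutations(k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Index permutations of all 4^k words under reverse / complement / rc."""
    n = 4**k
    idx = np.arange(n)
    digits = np.empty((k, n), dtype=np.int64)
    rest = idx.copy()
    for j in range(k - 1, -1, -1):
        digits[j] = rest % 4
        rest //= 4
    pows = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    rev = pows @ digits[::-1]
    comp = pows @ (3 - digits)
    rc = pows @ (3 - digits[::-1])
    return rev, comp, rc


def symmetrize_counts(counts: np.ndarray, k: int) -> np.ndarray:
    """Average a 4^k count vector over {id, reverse, complement, rc}."""
    rev, comp, rc = _orbit_permutations(k)
    return (counts + counts[rev] + counts[comp] + counts[rc]) / 4.0


@dataclass
class BackgroundModel:
    """Homogeneous order-d Markov model over {A,C,G,T}.

    Attributes
    ----------
    order : int
        Markov order d >= 0.
    transition : ndarray, shape (4**d, 4)
        Row-stochastic transition probabilities pi(context; letter); for
        d = 0 there is a single (empty) context and mu = pi.
    stationary : ndarray, shape (4**d,)
        Stationary distribution mu over d-mer contexts (a single 1.0 for
        d = 0, where the empty context is certain).
    pseudocount : float
        Pseudocount that was added to every (d+1)-mer count.
    """

    order: int
    transition: np.ndarray
    stationary: np.ndarray
    pseudocount: float = 1.0
    name: str = field(default="background", compare=False)

    def __post_init__(self) -> None:
        self.transition = np.asarray(self.transition, dtype=float)
        self.stationary = np.asarray(self.stationary, dtype=float)
        n_ctx = 4**self.order
        if self.transition.shape != (n_ctx, 4):
            raise ValueError(f"transition must have shape ({n_ctx}, 4)")
        if self.stationary.shape != (n_ctx,):
            raise ValueError(f"stationary must have shape ({n_ctx},)")

    # -- invariants -------------------------------------------------------

    def validate(self) -> None:
        if not np.allclose(self.transition.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("transition rows must sum to 1")
        if abs(self.stationary.sum() - 1.0) > 1e-12:
            raise ValueError("stationary distribution must sum to 1")
        if self.pseudocount > 0 and not np.all(self.transition > 0):
            raise ValueError("pi must be strictly positive for pseudocount > 0")
        # left fixed point
        flux = self._step_stationary()
        if np.max(np.abs(flux - self.stationary)) > 1e-10:
            raise ValueError("mu is not stationary under pi")
        # strand/reversal symmetry of (d+1)-word probabilities
        p = self.word_probabilities()
        rev, _, rc = _orbit_permutations(self.order + 1)
        if np.max(np.abs(p - p[rev])) > 1e-12 or np.max(np.abs(p - p[rc])) > 1e-12:
            raise ValueError("word probabilities are not strand/reversal symmetric")

    def _step_stationary(self) -> np.ndarray:
        """Propagate mu one step through pi (should return mu itself)."""
        d = self.order
        if d == 0:
            return self.stationary.copy()
        n_ctx = 4**d
        joint = self.stationary[:, None] * self.transition  # P(ctx, letter)
        out = np.zeros(n_ctx)
        ctx = np.arange(n_ctx)
        for b in range(4):
            np.add.at(out, (ctx * 4 + b) % n_ctx, joint[:, b])
        return out

    def word_probabilities(self) -> np.ndarray:
        """Stationary probabilities of all (d+1)-mers, P(a) = mu * pi."""
        return (self.stationary[:, None] * self.transition).reshape(-1)

    # -- evaluation -------------------------------------------------------

    def prefix_conditionals(self) -> list[np.ndarray]:
        """Chain factorization of mu into positionwise conditionals.

        Returns, for j = 0..d-1, an array of shape (4**j, 4) giving
        P(letter at position j | first j letters), computed from the
        marginals of mu.  The product over j telescopes exactly to mu.
        """
        d = self.order
        out = []
        for j in range(d):
            # m_{j+1}(prefix, b) / m_j(prefix)
            m = self.stationary.reshape((4,) * d)
            m_j1 = m.sum(axis=tuple(range(j + 1, d))).reshape(4**j, 4)
            denom = m_j1.sum(axis=1, keepdims=True)
            out.append(m_j1 / denom)
        return out

    def word_logprob(self, word: str) -> float:
        """Natural-log probability of ``word`` starting in mu."""
        codes = encode(word)
        if np.any(codes < 0):
            raise ValueError(f"word contains a non-ACGT letter: {word!r}")
        d = self.order
        if len(codes) < d:
            raise ValueError("word shorter than the model order")
        logp = 0.0
        ctx = 0
        if d:
            ctx = int(np.dot(codes[:d], 4 ** np.arange(d - 1, -1, -1)))
            mu = self.stationary[ctx]
            logp += float(np.log(mu))
        n_ctx = 4**d
        logtrans = np.log(self.transition)
        for b in codes[d:]:
            logp += float(logtrans[ctx, b])
            ctx = (ctx * 4 + int(b)) % n_ctx
        return logp

    # -- sampling ---------------------------------------------------------

    def sample_codes(self, count: int, length: int, seed: int) -> np.ndarray:
        """Sample ``count`` sequences of ``length`` as an int8 code matrix.

        The first d letters are drawn from mu (via its chain
        factorization), subsequent letters from pi.  The stream of uniform
        variates is consumed identically with and without numba, so the
        output is reproducible across environments.
        """
        d = self.order
        if length < max(d, 1):
            raise ValueError("length must be at least max(order, 1)")
        if count < 1:
            raise ValueError("count must be >= 1")
        rng = np.random.default_rng(seed)
        u = rng.random((count, length))
        out = np.empty((count, length), dtype=np.int8)
        ctx = np.zeros(count, dtype=np.int64)
        n_ctx = 4**d
        for j, cond in enumerate(self.prefix_conditionals()):
            cum = np.cumsum(cond, axis=1)
            letters = (u[:, j : j + 1] > cum[ctx, :3]).sum(axis=1)
            out[:, j] = letters
            ctx = ctx * 4 + letters
        cumtrans = np.cumsum(self.transition, axis=1)
        cumtrans[:, 3] = 1.0 + 1e-12  # guard against roundoff at the top
        if _HAVE_NUMBA:
            _sample_kernel_jit(u, cumtrans, ctx, out, d, n_ctx)
        else:
            _sample_kernel_py(u, cumtrans, ctx, out, d, n_ctx)
        return out

    def sample_sequences(self, count: int, length: int, seed: int) -> list[str]:
        codes = self.sample_codes(count, length, seed)
        lut = np.frombuffer(ALPHABET.encode(), dtype=np.uint8)
        return [bytes(lut[row]).decode("ascii") for row in codes]

    # -- serialization ----------------------------------------------------

    def to_json(self, path=None) -> str:
        d = self.order
        pi = {
            kmer_word(ctx * 4 + b, d + 1): self.transition[ctx, b]
            for ctx in range(4**d)
            for b in range(4)
        }
        if d == 0:
            mu = {kmer_word(b, 1): self.transition[0, b] for b in range(4)}
        else:
            mu = {kmer_word(ctx, d): self.stationary[ctx] for ctx in range(4**d)}
        text = json.dumps(
            {"order": d, "pseudocount": self.pseudocount, "pi": pi, "mu": mu},
            indent=1,
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "BackgroundModel":
        if hasattr(source, "read"):
            data = json.load(source)
        else:
            try:
                data = json.loads(source)
            except (ValueError, TypeError):
                with open(source) as fh:
                    data = json.load(fh)
        d = int(data["order"])
        trans = np.empty((4**d, 4))
        for word, p in data["pi"].items():
            codes = encode(word)
            ctx = int(np.dot(codes[:d], 4 ** np.arange(d - 1, -1, -1))) if d else 0
            trans[ctx, codes[d]] = p
        if d == 0:
            station = np.array([1.0])
        else:
            station = np.empty(4**d)
            for word, p in data["mu"].items():
                codes = encode(word)
                station[int(np.dot(codes, 4 ** np.arange(d - 1, -1, -1)))] = p
        model = cls(d, trans, station, float(data.get("pseudocount", 0.0)))
        model.validate()
        return model


def _sample_kernel_py(u, cumtrans, ctx, out, d, n_ctx):
    count, length = u.shape
    for j in range(d, length):
        rows = cumtrans[ctx]
        letters = (u[:, j : j + 1] > rows[:, :3]).sum(axis=1)
        out[:, j] = letters
        ctx[:] = (ctx * 4 + letters) % n_ctx


if _HAVE_NUMBA:

    @_njit(cache=True)
    def _sample_kernel_jit(u, cumtrans, ctx, out, d, n_ctx):  # pragma: no cover
        count, length = u.shape
        for i in range(count):
            c = ctx[i]
            for j in range(d, length):
                x = u[i, j]
                b = 0
                while b < 3 and x > cumtrans[c, b]:
                    b += 1
                out[i, j] = b
                c = (c * 4 + b) % n_ctx
            ctx[i] = c


# -- estimation -----------------------------------------------------------


def _segment_kmer_counts(codes: np.ndarray, k: int) -> np.ndarray | None:
    """Circular k-mer counts of one ACGT-only segment (None if too short)."""
    n = len(codes)
    if n < k:
        return None
    ext = np.concatenate([codes, codes[: k - 1]]).astype(np.int64)
    idx = np.zeros(n, dtype=np.int64)
    for j in range(k):
        idx = idx * 4 + ext[j : j + n]
    return np.bincount(idx, minlength=4**k).astype(float)


def estimate_background(
    sequences,
    order: int,
    pseudocount: float = 1.0,
) -> BackgroundModel:
    """Fit an order-d background from DNA strings.

    (d+1)-mer counts are tallied circularly within each maximal run of
    ACGT letters (windows containing other letters are skipped), averaged
    over the reverse/complement closure, incremented by ``pseudocount``
    and converted to transition probabilities; the stationary distribution
    is the context marginal of the symmetrized table, which is its exact
    left fixed point.
    """
    if order < 0:
        raise ValueError("order must be >= 0")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    k = order + 1
    counts = np.zeros(4**k)
    n_windows = 0
    for seq in sequences:
        codes = encode(str(seq))
        # split into maximal valid segments
        bad = np.flatnonzero(codes < 0)
        start = 0
        bounds = list(bad) + [len(codes)]
        for b in bounds:
            seg = codes[start:b]
            c = _segment_kmer_counts(seg, k)
            if c is not None:
                counts += c
                n_windows += len(seg)
            start = b + 1
    if n_windows == 0:
        raise InsufficientDataError(
            f"insufficient data: no window of length {k} free of non-ACGT letters"
        )
    counts = symmetrize_counts(counts, k)
    if pseudocount == 0 and np.any(counts == 0):
        raise ZeroTransitionError(
            "zero-probability transition: a symmetrized count is zero and "
            "pseudocount is 0 (the log-odds score requires strict positivity)"
        )
    counts += pseudocount
    table = counts.reshape(4**order, 4)
    ctx_marg = table.sum(axis=1)
    trans = table / ctx_marg[:, None]
    station = ctx_marg / ctx_marg.sum() if order else np.array([1.0])
    model = BackgroundModel(order, trans, station, pseudocount)
    # internal consistency: mu must be the left fixed point of pi
    if np.max(np.abs(model._step_stationary() - model.stationary)) > 1e-8:
        raise AssertionError("internal consistency error: mu is not stationary")
    model.validate()
    return model


def uniform_background(order: int = 0) -> BackgroundModel:
    """Uniform i.i.d.-like background of the given order."""
    n_ctx = 4**order
    return BackgroundModel(
        order,
        np.full((n_ctx, 4), 0.25),
        np.full(n_ctx, 1.0 / n_ctx) if order else np.array([1.0]),
        pseudocount=1.0,
    )


def read_fasta(path) -> list[tuple[str, str]]:
    """Read a (multi-record) FASTA file as (id, sequence) pairs."""
    from Bio import SeqIO

    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(path, "fasta")]


def word_logprob(model: BackgroundModel, word: str) -> float:
    return model.word_logprob(word)


def sample_sequences(
    model: BackgroundModel, count: int, length: int, seed: int
) -> list[str]:
    return model.sample_sequences(count, length, seed)
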