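"""Position frequency matrices: readers, reverse complement, toy fixtures."""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from ._dna import ALPHABET, encode

ROW_ORDER = tuple(ALPHABET)  # A, C, G, T


@dataclass
class PFM:
    """A 4xM column-stochastic, strictly positive motif matrix.

    Rows are in A, C, G, T order; ``probs[b, j]`` is the probability of
    base b at motif position j.
    """

    probs: np.ndarray
    name: str = field(default="motif", compare=False)

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[0] != 4:
            raise ValueError("PFM must be a 4 x M matrix")
        if self.probs.shape[1] < 1:
            raise ValueError("PFM must have at least one column")
        if not np.allclose(self.probs.sum(axis=0), 1.0, atol=1e-9):
            raise ValueError("every PFM column must sum to 1")
        if not np.all(self.probs > 0):
            raise ValueError("all PFM elements must be strictly positive")

    @property
    def length(self) -> int:
        return self.probs.shape[1]

    def word_logprob(self, word: str) -> float:
        """log P_M(word) = sum_j log p_j(w_j)."""
        codes = encode(word)
        if len(codes) != self.length:
            raise ValueError("word length must equal the motif length")
        if np.any(codes < 0):
            raise ValueError(f"word contains a non-ACGT letter: {word!r}")
        return float(np.log(self.probs[codes, np.arange(self.length)]).sum())

    def reverse_complement(self) -> "PFM":
        return PFM(self.probs[::-1, ::-1].copy(), name=self.name + "_rc")


def reverse_complement_pfm(pfm: PFM) -> PFM:
    """Reverse column order and swap A<->T, C<->G rows."""
    return pfm.reverse_complement()


# -- parsing ---------------------------------------------------------------


def _normalize_counts(counts: np.ndarray, pseudocount: float, name: str) -> PFM:
    counts = np.asarray(counts, dtype=float)
    if counts.shape[0] != 4:
        raise ValueError("expected 4 rows (A, C, G, T)")
    if np.any(counts < 0):
        raise ValueError("negative count")
    counts = counts + pseudocount
    totals = counts.sum(axis=0)
    if np.any(totals <= 0):
        raise ValueError("zero column total (increase the pseudocount)")
    return PFM(counts / totals, name=name)


def _parse_jaspar(text: str) -> tuple[np.ndarray, str]:
    """JASPAR dialects: bare 4-row counts, or '>name' + 'A [ ... ]' rows."""
    name = "motif"
    rows: dict[str, list[float]] = {}
    bare: list[list[float]] = []
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            name = line[1:].split()[0] if line[1:].split() else "motif"
            continue
        m = re.match(r"^([ACGTacgt])\s*[:|]?\s*\[?\s*([-\d.eE+\s]+?)\s*\]?\s*$", line)
        if m and m.group(1).upper() in "ACGT":
            rows[m.group(1).upper()] = [float(x) for x in m.group(2).split()]
        else:
            bare.append([float(x) for x in line.replace("|", " ").split()])
    if len(rows) == 4:
        mat = np.array([rows[b] for b in ROW_ORDER])
    elif len(bare) == 4:
        mat = np.array(bare)
    else:
        raise ValueError("could not parse JASPAR matrix: expected 4 base rows")
    return mat, name


def _parse_transfac(text: str) -> tuple[np.ndarray, str]:
    """One TRANSFAC matrix block: P0/PO header gives the base column order."""
    name = "motif"
    order: list[str] | None = None
    rows: list[list[float]] = []
    for line in text.splitlines():
        parts = line.strip().split()
        if not parts:
            continue
        tag = parts[0].upper()
        if tag in ("ID", "NA", "AC") and len(parts) > 1:
            name = parts[1]
        elif tag in ("P0", "PO"):
            order = [p.upper() for p in parts[1:5]]
            if sorted(order) != sorted(ROW_ORDER):
                raise ValueError("TRANSFAC header must name the four bases")
        elif re.fullmatch(r"\d\d", tag) and order is not None:
            rows.append([float(x) for x in parts[1:5]])
        elif tag == "//":
            break
    if order is None or not rows:
        raise ValueError("could not parse TRANSFAC matrix block")
    mat = np.array(rows).T  # bases x positions, in header order
    perm = [order.index(b) for b in ROW_ORDER]
    return mat[perm], name


def _parse_tsv(text: str) -> tuple[np.ndarray, str]:
    """Plain 4-row x M-column table, optional non-numeric header line."""
    rows = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = re.split(r"[\t, ]+", line)
        try:
            rows.append([float(x) for x in fields])
        except ValueError:
            if rows:
                raise ValueError(f"non-numeric cell in row: {line!r}")
            continue  # header line
    if len(rows) != 4:
        raise ValueError(f"expected 4 rows, found {len(rows)}")
    return np.array(rows), "motif"


_PARSERS = {"jaspar": _parse_jaspar, "transfac": _parse_transfac, "tsv": _parse_tsv}


def read_pfm(path, format: str = "jaspar", pseudocount: float = 0.0) -> PFM:
    """Read a PFM from a JASPAR, TRANSFAC or TSV file.

    ``pseudocount`` is added to every cell before column normalization.
    """
    if format not in _PARSERS:
        raise ValueError(f"unknown format {format!r}; use jaspar, transfac or tsv")
    if hasattr(path, "read"):
        text = path.read()
    else:
        with open(path) as fh:
            text = fh.read()
    mat, name = _PARSERS[format](text)
    return _normalize_counts(mat, pseudocount, name)


def write_pfm(pfm: PFM, path) -> None:
    """Write the probability matrix as 4-row TSV (A, C, G, T order)."""
    lines = ["\t".join(repr(float(v)) for v in row) for row in pfm.probs]
    text = "\n".join(lines) + "\n"
    if hasattr(path, "write"):
        path.write(text)
    else:
        with open(path, "w") as fh:
            fh.write(text)


# -- fixtures --------------------------------------------------------------


def word_motif(word: str, epsilon: float = 0.01) -> PFM:
    """Near-point-mass PFM: 1-3*epsilon on the word letter, epsilon elsewhere."""
    if not 0 < epsilon < 0.25:
        raise ValueError("epsilon must be in (0, 0.25)")
    codes = encode(word)
    if np.any(codes < 0):
        raise ValueError(f"word contains a non-ACGT letter: {word!r}")
    probs = np.full((4, len(codes)), epsilon)
    probs[codes, np.arange(len(codes))] = 1.0 - 3.0 * epsilon
    return PFM(probs, name=f"word_{word}")


def fixture_motifs(epsilon: float = 0.01) -> dict[str, PFM]:
    """Toy motifs used throughout the test-suite and simulations."""
    return {
        "nonself": word_motif("ACGGT", epsilon),
        "palindrome": word_motif("ACGCGT", epsilon),
        "repeatlike": word_motif("AAAAA", epsilon),
        "aaa": word_motif("AAA", epsilon),
    }
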