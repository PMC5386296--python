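"""Interface residue pair-potentials over the 23-class alphabet.

The potential is a quasi-chemical log-odds score: the observed frequency of
an unordered pair of contacting residue classes at interfaces is compared
to the frequency expected if the two sides of a contact were drawn
independently from the marginal contact frequencies. Scores are in natural
log units; a pseudocount keeps rare phospho classes finite.

For an unordered pair (a, b) with pseudocounted count n'(a,b) and total
N' = sum over unordered pairs:

    f_obs(a,b) = n'(a,b) / N'
    g(a)       = sum_b n'(a,b) * (1 + [a==b]) / (2 N')
    e(a,b)     = 2 g(a) g(b)   for a != b,   g(a)^2  for a == b
    s(a,b)     = ln(f_obs(a,b) / e(a,b))
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .residues import ALPHABET, PHOSPHO_CLASS, base_aa
from .structures import ContactEdge


@dataclass
class PairCountTable:
    """Symmetric counts of contacting residue-class pairs."""

    alphabet: tuple[str, ...] = ALPHABET
    counts: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        n = len(self.alphabet)
        if self.counts is None:
            self.counts = np.zeros((n, n), dtype=float)
        else:
            self.counts = np.asarray(self.counts, dtype=float)
            if self.counts.shape != (n, n):
                raise ValueError("counts shape does not match alphabet")
            if not np.allclose(self.counts, self.counts.T):
                raise ValueError("counts must be symmetric")
            if (self.counts < 0).any():
                raise ValueError("counts must be non-negative")

    def index(self, cls: str) -> int:
        try:
            return self.alphabet.index(cls)
        except ValueError:
            raise KeyError(f"residue class {cls!r} not in alphabet") from None

    def add_pair(self, cls_a: str, cls_b: str, n: float = 1) -> None:
        i, j = self.index(cls_a), self.index(cls_b)
        self.counts[i, j] += n
        if i != j:
            self.counts[j, i] += n

    def count(self, cls_a: str, cls_b: str) -> float:
        return float(self.counts[self.index(cls_a), self.index(cls_b)])

    @property
    def total_pairs(self) -> float:
        """Total number of unordered pairs counted."""
        return float(np.triu(self.counts).sum())


@dataclass
class PairPotentialMatrix:
    """Symmetric log-odds contact preferences (natural log units)."""

    alphabet: tuple[str, ...]
    scores: np.ndarray
    pseudocount: float = 0.0
    provenance: str = ""

    def __post_init__(self) -> None:
        self.alphabet = tuple(self.alphabet)
        self.scores = np.asarray(self.scores, dtype=float)
        n = len(self.alphabet)
        if self.scores.shape != (n, n):
            raise ValueError("scores shape does not match alphabet")
        with np.errstate(invalid="ignore"):
            if not np.allclose(
                np.nan_to_num(self.scores, neginf=-1e30),
                np.nan_to_num(self.scores.T, neginf=-1e30),
                atol=1e-9,
            ):
                raise ValueError("pair-potential matrix must be symmetric")

    def index(self, cls: str) -> int:
        try:
            return self.alphabet.index(cls)
        except ValueError:
            raise KeyError(f"residue class {cls!r} not in alphabet") from None

    def score(self, cls_a: str, cls_b: str) -> float:
        return float(self.scores[self.index(cls_a), self.index(cls_b)])

    def scaled(self, k: float) -> "PairPotentialMatrix":
        return PairPotentialMatrix(
            self.alphabet, self.scores * k, self.pseudocount, self.provenance
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, index=self.alphabet, columns=self.alphabet)


def count_contact_pairs(
    edges: Iterable[ContactEdge], alphabet: Sequence[str] = ALPHABET
) -> PairCountTable:
    """Tally contact edges into an unordered class-pair count table.

    The phospho flag folds S into pS (etc.); each edge increments exactly
    one unordered pair count.
    """
    table = PairCountTable(alphabet=tuple(alphabet))
    for e in edges:
        table.add_pair(e.res_a.residue_class, e.res_b.residue_class)
    return table


def _observed_expected(
    counts: np.ndarray, pseudocount: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n_prime = counts + pseudocount
    total = np.triu(n_prime).sum()
    if total <= 0:
        raise ValueError("no observed or pseudocounted pairs")
    f_obs = n_prime / total
    diag_boost = n_prime * (1.0 + np.eye(len(counts)))
    g = diag_boost.sum(axis=1) / (2.0 * total)
    e = 2.0 * np.outer(g, g)
    np.fill_diagonal(e, g**2)
    return f_obs, e, g


def estimate_pair_potential(
    counts: PairCountTable, pseudocount: float = 1.0
) -> PairPotentialMatrix:
    """Estimate the log-odds matrix from contact-pair counts.

    With ``pseudocount`` 0, pairs never observed score -inf; downstream
    scoring requires a positive pseudocount (default 1 per unordered pair).
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    f_obs, e, _ = _observed_expected(counts.counts, pseudocount)
    with np.errstate(divide="ignore"):
        scores = np.log(f_obs) - np.log(e)
    return PairPotentialMatrix(
        alphabet=counts.alphabet,
        scores=scores,
        pseudocount=pseudocount,
        provenance=f"estimated from {counts.total_pairs:.0f} contact pairs, "
        f"pseudocount {pseudocount}",
    )


def observed_expected_frequencies(
    counts: PairCountTable, pseudocount: float = 0.0
) -> tuple[np.ndarray, np.ndarray]:
    """(f_obs, e) matrices; each sums to 1 over unordered pairs."""
    f_obs, e, _ = _observed_expected(counts.counts, pseudocount)
    return f_obs, e


def delta_on_phosphorylation(
    matrix: PairPotentialMatrix,
    aa: str,
    partner_class: str,
    partner_is_mirrored_site: bool = False,
) -> float:
    """Change in pair-potential when the site residue is phosphorylated.

    For a homodimer self-pair — the partner is the mirrored copy of the
    site across a symmetric interface — both copies are taken as
    phosphorylated, so the comparison is s(p-aa, p-partner) - s(aa, partner).
    """
    if aa not in PHOSPHO_CLASS:
        raise ValueError(f"residue {aa!r} cannot be phosphorylated")
    p_aa = PHOSPHO_CLASS[aa]
    partner_mod = partner_class
    if partner_is_mirrored_site:
        base = base_aa(partner_class)
        if base not in PHOSPHO_CLASS:
            raise ValueError("mirrored site partner must be S, T or Y")
        partner_mod = PHOSPHO_CLASS[base]
    return matrix.score(p_aa, partner_mod) - matrix.score(aa, base_aa(partner_class))


def write_matrix(matrix: PairPotentialMatrix, path: str | Path, decimals: int = 6) -> None:
    """Write the matrix as labelled TSV (class labels in first row/column)."""
    frame = matrix.to_frame().round(decimals)
    frame.to_csv(path, sep="\t", index_label="")


def read_matrix(path: str | Path, atol: float = 1e-6) -> PairPotentialMatrix:
    """Read a labelled TSV matrix; rejects asymmetric or malformed input."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    frame.index = frame.index.map(str)
    frame.columns = frame.columns.map(str)
    if list(frame.index) != list(frame.columns):
        raise ValueError(f"{path}: row and column labels differ")
    values = frame.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ValueError(f"{path}: non-numeric cell in matrix")
    if np.isnan(values).any():
        raise ValueError(f"{path}: missing cell in matrix")
    if not np.allclose(values, values.T, atol=atol):
        raise ValueError(f"{path}: matrix asymmetric beyond {atol}")
    sym = (values + values.T) / 2.0
    return PairPotentialMatrix(
        alphabet=tuple(frame.index), scores=sym, provenance=f"read from {path}"
    )


def matrix_io(path: str | Path, direction: str, matrix: PairPotentialMatrix | None = None):
    """Read or write a pair-potential matrix TSV (directional convenience)."""
    if direction == "read":
        return read_matrix(path)
    if direction == "write":
        if matrix is None:
            raise ValueError("matrix required for writing")
        write_matrix(matrix, path)
        return None
    raise ValueError("direction must be 'read' or 'write'")


def calibrate_matrix(matrix: PairPotentialMatrix) -> tuple[PairPotentialMatrix, np.ndarray]:
    """Project a planted matrix onto the estimator-consistent family.

    A matrix estimated from counts always satisfies a closure condition
    (its observed frequencies are a probability distribution whose
    marginals generate the expected frequencies), so an arbitrary planted
    matrix is generally not exactly recoverable by estimation. This
    forward projection interprets the planted scores as a tilt of the
    independent uniform contact distribution — p(a,b) proportional to
    exp(s(a,b)) over ordered pairs — and returns the exact log-odds of
    that distribution together with its marginals. For small planted
    scores the projection is close to the input; the result is exactly
    recoverable from infinite sampling.
    """
    scores = matrix.scores
    if not np.isfinite(scores).all():
        raise ValueError("calibration requires finite scores")
    n = len(scores)
    p = np.exp(scores) / (n * n)
    p /= p.sum()
    g = p.sum(axis=1)
    truth = np.log(p) - np.log(np.outer(g, g))
    calibrated = PairPotentialMatrix(
        matrix.alphabet,
        (truth + truth.T) / 2.0,
        matrix.pseudocount,
        provenance=(matrix.provenance + "; calibrated").strip("; "),
    )
    return calibrated, g


def implied_pair_distribution(
    matrix: PairPotentialMatrix, atol: float = 1e-8
) -> tuple[np.ndarray, np.ndarray]:
    """Ordered contact distribution whose log-odds equal the matrix.

    Solves K g = 1 (K = exp(s), elementwise) for the marginals g by least
    squares — exact when the matrix lies in the estimator's image (any
    estimated or calibrated matrix does) — and returns the ordered pair
    probabilities p(a,b) = g_a g_b exp(s(a,b)) plus g. Raises when no
    non-negative marginals reproduce the matrix to within ``atol``.
    """
    K = np.exp(matrix.scores)
    if not np.isfinite(K).all():
        raise ValueError("matrix must be finite")
    g, *_ = np.linalg.lstsq(K, np.ones(len(K)), rcond=None)
    if (g < -atol).any() or np.abs(K @ g - 1.0).max() > atol:
        raise ValueError(
            "matrix is not estimator-consistent; calibrate it first "
            "(see calibrate_matrix)"
        )
    g = np.clip(g, 0.0, None)
    g = g / g.sum()
    p = np.outer(g, g) * K
    p /= p.sum()
    return p, g
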