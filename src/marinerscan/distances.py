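"""Pairwise distance estimation: K2P, composite-likelihood TN93, identity.

The Kimura 2-parameter distance separates transition (P) and transversion
(Q) proportions:

    d = -1/2 ln((1 - 2P - Q) * sqrt(1 - 2Q))

with the delta-method variance

    V = [a^2 P + b^2 Q - (aP + bQ)^2] / n,
    a = 1/(1 - 2P - Q),  b = (a + 1/(1 - 2Q)) / 2.

The composite-likelihood matrix estimates the Tamura-Nei (TN93) rate
parameters once, by maximizing the log-likelihood summed over all sequence
pairs, and then computes each pair's distance under the shared parameters
(the "maximum composite likelihood" scheme of distance software). Gaps and
N are handled by pairwise deletion throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.optimize import minimize, minimize_scalar

from ._align import gapped_rows, nt_aligner
from .io import AlignmentSet

__all__ = [
    "K2PResult", "DistanceMatrix",
    "k2p_distance", "jc_distance", "tn93_distance",
    "mcl_distance_matrix", "identity_matrix",
]

_IDX = {"A": 0, "C": 1, "G": 2, "T": 3}
_PURINE = frozenset("AG")
_LOG_T_BOUNDS = (-14.0, 3.0)


@dataclass
class K2PResult:
    P: float
    Q: float
    n_sites: int
    d: float          # nan when saturated
    variance: float   # nan when saturated

    @property
    def defined(self) -> bool:
        return not math.isnan(self.d)

    @property
    def se(self) -> float:
        return math.sqrt(self.variance) if self.defined else math.nan


def _site_pairs(a: str, b: str):
    for x, y in zip(a, b):
        if x in _IDX and y in _IDX:
            yield x, y


def k2p_distance(a: str, b: str, aligned: bool = True) -> K2PResult:
    """Kimura 2-parameter distance between two sequences.

    With ``aligned=True`` the inputs must be equal-length gapped rows;
    otherwise they are globally aligned first. Sites with a gap or N in
    either row are excluded (pairwise deletion). A log argument <= 0
    flags the result as saturated (d = nan).
    """
    if not aligned:
        aln = nt_aligner("global").align(a, b)[0]
        a, b = gapped_rows(aln, a, b)
    elif len(a) != len(b):
        raise ValueError("aligned rows must have equal length")
    n = ts = tv = 0
    for x, y in _site_pairs(a, b):
        n += 1
        if x == y:
            continue
        if (x in _PURINE) == (y in _PURINE):
            ts += 1
        else:
            tv += 1
    if n == 0:
        return K2PResult(P=0.0, Q=0.0, n_sites=0, d=math.nan, variance=math.nan)
    P, Q = ts / n, tv / n
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        return K2PResult(P=P, Q=Q, n_sites=n, d=math.nan, variance=math.nan)
    d = -0.5 * math.log(w1 * math.sqrt(w2))
    aa = 1.0 / w1
    bb = 0.5 * (1.0 / w1 + 1.0 / w2)
    var = (aa * aa * P + bb * bb * Q - (aa * P + bb * Q) ** 2) / n
    return K2PResult(P=P, Q=Q, n_sites=n, d=d, variance=var)


def jc_distance(a: str, b: str) -> tuple[float, float]:
    """Jukes-Cantor distance and its variance (pairwise deletion)."""
    n = diff = 0
    for x, y in _site_pairs(a, b):
        n += 1
        diff += x != y
    if n == 0:
        return math.nan, math.nan
    p = diff / n
    w = 1.0 - 4.0 * p / 3.0
    if w <= 0:
        return math.nan, math.nan
    d = -0.75 * math.log(w)
    var = p * (1 - p) / (w * w * n)
    return d, var


@dataclass
class DistanceMatrix:
    """Labelled symmetric distance matrix; undefined entries are nan."""

    taxa: list[str]
    d: np.ndarray
    model: str = "K2P"            # {"K2P", "TN93-MCL", "p-identity"}
    deletion: str = "pairwise"

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.taxa)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match taxa")
        if not np.allclose(self.d, self.d.T, equal_nan=True):
            raise ValueError("matrix not symmetric")

    def value(self, a: str, b: str) -> float:
        return float(self.d[self.taxa.index(a), self.taxa.index(b)])

    def offdiag(self) -> np.ndarray:
        iu = np.triu_indices(len(self.taxa), k=1)
        return self.d[iu]

    def undefined_pairs(self) -> list[tuple[str, str]]:
        iu = np.triu_indices(len(self.taxa), k=1)
        return [(self.taxa[i], self.taxa[j])
                for i, j in zip(*iu) if math.isnan(self.d[i, j])]

    def submatrix(self, taxa: Sequence[str]) -> "DistanceMatrix":
        idx = [self.taxa.index(t) for t in taxa]
        return DistanceMatrix(taxa=list(taxa), d=self.d[np.ix_(idx, idx)],
                              model=self.model, deletion=self.deletion)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("taxon\t" + "\t".join(self.taxa) + "\n")
            for t, row in zip(self.taxa, self.d):
                fh.write(t + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path, model: str = "K2P") -> "DistanceMatrix":
        lines = Path(path).read_text().strip().splitlines()
        taxa = lines[0].split("\t")[1:]
        d = np.array([[float(v) for v in ln.split("\t")[1:]] for ln in lines[1:]])
        return cls(taxa=taxa, d=d, model=model)


# --- TN93 composite likelihood ---------------------------------------------

def _pair_count_matrix(a: str, b: str) -> np.ndarray:
    counts = np.zeros((4, 4))
    for x, y in _site_pairs(a, b):
        counts[_IDX[x], _IDX[y]] += 1
    return counts


def _tn93_P(t: float, k1: float, k2: float, pi: np.ndarray) -> np.ndarray:
    piA, piC, piG, piT = pi
    piR, piY = piA + piG, piC + piT
    e2 = math.exp(-t)
    e3 = math.exp(-(piR * k1 + piY) * t)
    e4 = math.exp(-(piY * k2 + piR) * t)
    P = np.empty((4, 4))
    # purines (A=0, G=2)
    P[0, 0] = piA + piA * piY / piR * e2 + piG / piR * e3
    P[0, 2] = piG + piG * piY / piR * e2 - piG / piR * e3
    P[2, 0] = piA + piA * piY / piR * e2 - piA / piR * e3
    P[2, 2] = piG + piG * piY / piR * e2 + piA / piR * e3
    # pyrimidines (C=1, T=3)
    P[1, 1] = piC + piC * piR / piY * e2 + piT / piY * e4
    P[1, 3] = piT + piT * piR / piY * e2 - piT / piY * e4
    P[3, 1] = piC + piC * piR / piY * e2 - piC / piY * e4
    P[3, 3] = piT + piT * piR / piY * e2 + piC / piY * e4
    # transversions
    for i in (0, 2):
        P[i, 1] = piC * (1 - e2)
        P[i, 3] = piT * (1 - e2)
    for i in (1, 3):
        P[i, 0] = piA * (1 - e2)
        P[i, 2] = piG * (1 - e2)
    return P


def _tn93_mu(k1: float, k2: float, pi: np.ndarray) -> float:
    piA, piC, piG, piT = pi
    piR, piY = piA + piG, piC + piT
    return 2 * (k1 * piA * piG + k2 * piC * piT + piR * piY)


def _pair_loglik(t: float, k1: float, k2: float, pi: np.ndarray,
                 counts: np.ndarray) -> float:
    P = np.clip(_tn93_P(t, k1, k2, pi), 1e-300, None)
    return float(np.sum(counts * np.log(pi[:, None] * P)))


def _optimal_t(k1: float, k2: float, pi: np.ndarray, counts: np.ndarray) -> float:
    res = minimize_scalar(
        lambda lt: -_pair_loglik(math.exp(lt), k1, k2, pi, counts),
        bounds=_LOG_T_BOUNDS, method="bounded",
        options={"xatol": 1e-10})
    return float(math.exp(res.x))


def _empirical_freqs(rows: Sequence[str]) -> np.ndarray:
    counts = np.zeros(4)
    for row in rows:
        for c in row:
            if c in _IDX:
                counts[_IDX[c]] += 1
    if counts.sum() == 0:
        raise ValueError("no unambiguous bases in alignment")
    return counts / counts.sum()


def tn93_distance(a: str, b: str) -> float:
    """Single-pair TN93 maximum-likelihood distance (own parameters)."""
    dm = mcl_distance_matrix(AlignmentSet(taxa=["a", "b"], rows=[a, b]))
    return float(dm.d[0, 1])


def mcl_distance_matrix(alignment: AlignmentSet, max_iter: int = 400
                        ) -> DistanceMatrix:
    """TN93 distances with rate parameters shared across all pairs.

    The two transition/transversion rate ratios (purine and pyrimidine)
    are estimated once by maximizing the composite likelihood summed over
    every sequence pair; each pair's branch length is then the conditional
    ML distance under those shared rates, scaled to substitutions/site.
    Saturated pairs (distance at the optimizer bound) come back as nan.
    """
    if alignment.n_taxa < 2:
        raise ValueError("need at least two taxa")
    rows = alignment.rows
    pi = _empirical_freqs(rows)
    # guard degenerate compositions (missing bases) with a small floor
    pi = np.clip(pi, 1e-6, None)
    pi = pi / pi.sum()
    n = alignment.n_taxa
    pair_idx = [(i, j) for i in range(n) for j in range(i + 1, n)]
    counts = {p: _pair_count_matrix(rows[p[0]], rows[p[1]]) for p in pair_idx}

    def neg_composite(log_k: np.ndarray) -> float:
        k1, k2 = math.exp(log_k[0]), math.exp(log_k[1])
        total = 0.0
        for p in pair_idx:
            t = _optimal_t(k1, k2, pi, counts[p])
            total += _pair_loglik(t, k1, k2, pi, counts[p])
        return -total

    res = minimize(neg_composite, x0=np.log([2.0, 2.0]),
                   method="Nelder-Mead",
                   options={"maxiter": max_iter, "xatol": 1e-4, "fatol": 1e-6})
    if not res.success and res.status != 2:
        raise RuntimeError(
            f"composite-likelihood fit did not converge; last parameters "
            f"k1={math.exp(res.x[0]):.4f}, k2={math.exp(res.x[1]):.4f}")
    k1, k2 = (float(math.exp(v)) for v in res.x)
    mu = _tn93_mu(k1, k2, pi)
    t_max = math.exp(_LOG_T_BOUNDS[1]) * 0.99
    d = np.zeros((n, n))
    for i, j in pair_idx:
        t = _optimal_t(k1, k2, pi, counts[(i, j)])
        val = mu * t if t < t_max else math.nan
        d[i, j] = d[j, i] = val
    return DistanceMatrix(taxa=list(alignment.taxa), d=d, model="TN93-MCL",
                          deletion="pairwise")


# --- identity matrices -----------------------------------------------------

def _pair_identity_aligned(a: str, b: str) -> float:
    ident = compared = 0
    for x, y in zip(a, b):
        if x == "-" or y == "-" or x == "N" or y == "N":
            continue
        compared += 1
        ident += x == y
    return 100.0 * ident / compared if compared else math.nan


def identity_matrix(seqs: AlignmentSet | dict[str, str]) -> DistanceMatrix:
    """Pairwise percent-identity matrix (model ``p-identity``).

    Accepts a ready multiple alignment (columns with a gap or N in either
    row are excluded per pair) or unaligned sequences, which are globally
    aligned pair by pair. Diagonal is 100."""
    if isinstance(seqs, AlignmentSet):
        taxa, rows = list(seqs.taxa), list(seqs.rows)
        aligned = True
    else:
        taxa, rows = list(seqs.keys()), list(seqs.values())
        aligned = False
    n = len(taxa)
    if n < 2:
        raise ValueError("need at least two sequences")
    aligner = nt_aligner("global")
    d = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            if aligned:
                val = _pair_identity_aligned(rows[i], rows[j])
            else:
                aln = aligner.align(rows[i], rows[j])[0]
                ga, gb = gapped_rows(aln, rows[i], rows[j])
                val = _pair_identity_aligned(ga, gb)
            d[i, j] = d[j, i] = val
    return DistanceMatrix(taxa=taxa, d=d, model="p-identity",
                          deletion="pairwise")
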