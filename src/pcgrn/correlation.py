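"""Pearson and first-order partial correlation: the triple-gene test.

The regulatory test implemented here works on gene triples.  Two structural
genes *x* and *y* are called co-expressed when their Pearson correlation
r_xy clears a threshold (default r ≥ 0.8 with two-sided p < 0.001).  A
candidate regulator *z* is then said to *break* the pair's co-expression
when the first-order partial correlation

    r_xy|z = (r_xy − r_xz · r_yz) / (sqrt(1 − r_xz²) · sqrt(1 − r_yz²))

falls below a second threshold (default |r_xy|z| < 0.3): once the shared
influence of z is removed, x and y are no longer correlated, which is taken
as evidence that z regulates both.

Significance of the Pearson correlation uses the exact transform
t = r·sqrt((n−2)/(1−r²)) against Student's t with n−2 degrees of freedom,
two-sided.  No multiple-testing correction is applied to pair p-values; the
screening threshold is a raw p-value cut by design.

Degenerate conditioning — when a pair member is numerically collinear with
the conditioning gene (1 − r² below ``epsilon_degenerate``) — is handled in
two distinct ways on purpose.  The pure-numeric :func:`partial_cc` returns
``None`` (the formula is undefined).  The data-driven breaking test instead
reports the continuous limit 0.0: if x = αz exactly, then r_xy = r_xz·r_yz
identically and an infinitesimal independent perturbation of x drives
r_xy|z to 0, i.e. the candidate *fully explains* that member.  Treating
exact collinearity as maximal breaking (rather than as a non-event) is what
makes noiseless single-parent regulation recoverable at all.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
from scipy import stats

from .datamodel import ExpressionMatrix

__all__ = [
    "ThresholdConfig",
    "CoexpressedPair",
    "BreakResult",
    "pearson_cc",
    "partial_cc",
    "partial_cc_from_data",
    "find_coexpressed_pairs",
    "find_breaking_regulators",
    "write_pairs_tsv",
    "write_breaks_tsv",
]


@dataclass(frozen=True)
class ThresholdConfig:
    """Thresholds and switches of the co-expression / breaking test.

    cc_min:
        minimum Pearson correlation for a co-expressed pair (default 0.8).
    cc_pval_max:
        maximum two-sided p-value for the pair correlation (default 0.001).
    pcc_max:
        partial correlation below which a pair counts as broken (default 0.3).
    use_absolute_cc:
        screen pairs on \\|r\\| instead of signed r (default off: the signed
        rule reads the co-expression threshold literally; the absolute mode
        additionally captures strong repression).
    use_absolute_pcc:
        apply the breaking cut to \\|r_xy|z\\| (default on: "destroying"
        co-expression is about magnitude — a strongly negative conditional
        correlation is not destruction).
    epsilon_degenerate:
        collinearity guard on the denominator terms 1 − r².
    """

    cc_min: float = 0.8
    cc_pval_max: float = 0.001
    pcc_max: float = 0.3
    use_absolute_cc: bool = False
    use_absolute_pcc: bool = True
    epsilon_degenerate: float = 1e-8

    def __post_init__(self) -> None:
        if not 0.0 < self.cc_min <= 1.0:
            raise ValueError("cc_min must be in (0, 1]")
        if not 0.0 < self.cc_pval_max < 1.0:
            raise ValueError("cc_pval_max must be in (0, 1)")
        if not 0.0 <= self.pcc_max < 1.0:
            raise ValueError("pcc_max must be in [0, 1)")
        if not self.pcc_max < self.cc_min:
            raise ValueError("pcc_max must be below cc_min")
        if self.epsilon_degenerate <= 0:
            raise ValueError("epsilon_degenerate must be positive")


@dataclass(frozen=True)
class CoexpressedPair:
    """An unordered co-expressed structural-gene pair, stored canonically."""

    gene_a: str
    gene_b: str
    cc: float
    p_value: float

    def __post_init__(self) -> None:
        if self.gene_a == self.gene_b:
            raise ValueError("pair members must differ")
        if not self.gene_a < self.gene_b:
            raise ValueError(
                "pair must be canonical (gene_a < gene_b); use CoexpressedPair.make"
            )

    @classmethod
    def make(cls, a: str, b: str, cc: float, p_value: float) -> "CoexpressedPair":
        if a > b:
            a, b = b, a
        return cls(gene_a=a, gene_b=b, cc=cc, p_value=p_value)

    @property
    def members(self) -> Tuple[str, str]:
        return (self.gene_a, self.gene_b)


@dataclass(frozen=True)
class BreakResult:
    """Outcome of testing one candidate regulator against one pair.

    ``pcc`` is ``None`` only when the partial correlation is genuinely
    undefined; ``breaks`` is then always False.
    """

    regulator: str
    pair: CoexpressedPair
    pcc: Optional[float]
    breaks: bool

    def __post_init__(self) -> None:
        if self.breaks and self.pcc is None:
            raise ValueError("breaks=True requires a defined pcc")


def _as_vector(v, name: str) -> np.ndarray:
    arr = np.asarray(v, dtype=float).ravel()
    if arr.size < 3:
        raise ValueError(f"vector {name!r} has fewer than 3 observations")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"vector {name!r} contains non-finite values")
    return arr


def _cc(x: np.ndarray, y: np.ndarray) -> float:
    # normalize before the dot product (as scipy does) so exact linear
    # dependence yields exactly +/-1.0
    xc = x - x.mean()
    yc = y - y.mean()
    r = (xc / np.linalg.norm(xc)) @ (yc / np.linalg.norm(yc))
    return float(np.clip(r, -1.0, 1.0))


def _p_from_cc(cc: float, n: int) -> float:
    d = 1.0 - cc * cc
    if d <= 0.0:
        return 0.0
    t = abs(cc) * math.sqrt((n - 2) / d)
    return float(2.0 * stats.t.sf(t, df=n - 2))


def pearson_cc(x, y) -> Tuple[float, float]:
    """Sample Pearson correlation with its exact two-sided t-test p-value.

    Requires equal-length vectors of n ≥ 3 finite values, each with nonzero
    variance (the offending vector is named otherwise).
    """
    xv = _as_vector(x, "x")
    yv = _as_vector(y, "y")
    if xv.size != yv.size:
        raise ValueError("x and y must have equal length")
    if np.ptp(xv) == 0.0:
        raise ValueError("vector 'x' has zero variance")
    if np.ptp(yv) == 0.0:
        raise ValueError("vector 'y' has zero variance")
    cc = _cc(xv, yv)
    return cc, _p_from_cc(cc, xv.size)


def _check_r(r: float, name: str) -> float:
    if not np.isfinite(r):
        raise ValueError(f"{name} is not finite")
    if abs(r) > 1.0 + 1e-12:
        raise ValueError(f"{name}={r} outside [-1, 1]")
    return float(np.clip(r, -1.0, 1.0))


def partial_cc(
    r_xy: float, r_xz: float, r_yz: float, epsilon_degenerate: float = 1e-8
) -> Optional[float]:
    """First-order partial correlation of x and y given z, from the three
    pairwise correlations.  Returns ``None`` (undefined) when a denominator
    term 1 − r² falls at or below ``epsilon_degenerate``.
    """
    r_xy = _check_r(r_xy, "r_xy")
    r_xz = _check_r(r_xz, "r_xz")
    r_yz = _check_r(r_yz, "r_yz")
    dx = 1.0 - r_xz * r_xz
    dy = 1.0 - r_yz * r_yz
    if dx <= epsilon_degenerate or dy <= epsilon_degenerate:
        return None
    return float((r_xy - r_xz * r_yz) / (math.sqrt(dx) * math.sqrt(dy)))


def partial_cc_from_data(x, y, z, epsilon_degenerate: float = 1e-8) -> Optional[float]:
    """Partial correlation of x and y given z computed from raw profiles.

    Equals ``partial_cc`` applied to the three pairwise Pearson correlations,
    and (when defined) the Pearson correlation of the residuals of x and y
    after least-squares regression on z.
    """
    r_xy, _ = pearson_cc(x, y)
    r_xz, _ = pearson_cc(x, z)
    r_yz, _ = pearson_cc(y, z)
    return partial_cc(r_xy, r_xz, r_yz, epsilon_degenerate=epsilon_degenerate)


def _pair_passes(cc: float, p: float, config: ThresholdConfig) -> bool:
    stat = abs(cc) if config.use_absolute_cc else cc
    return stat >= config.cc_min and p < config.cc_pval_max


def _break_decision(
    r_xy: float, r_xz: float, r_yz: float, config: ThresholdConfig
) -> Tuple[Optional[float], bool]:
    """Partial correlation and breaking verdict for one (pair, candidate).

    Exact collinearity of a member with the candidate is resolved to the
    continuous limit pcc = 0 (complete breaking); see the module docstring.
    """
    dx = 1.0 - r_xz * r_xz
    dy = 1.0 - r_yz * r_yz
    eps = config.epsilon_degenerate
    if dx <= eps or dy <= eps:
        pcc = 0.0
    else:
        pcc = float((r_xy - r_xz * r_yz) / (math.sqrt(dx) * math.sqrt(dy)))
    stat = abs(pcc) if config.use_absolute_pcc else pcc
    return pcc, stat < config.pcc_max


def _correlation_submatrix(
    matrix: ExpressionMatrix, genes: Sequence[str]
) -> np.ndarray:
    X = matrix.submatrix(genes)
    if X.shape[1] < 3:
        raise ValueError("need at least 3 samples for correlation")
    stds = X.std(axis=1)
    for g, s in zip(genes, stds):
        if s == 0.0:
            raise ValueError(f"gene {g!r} has zero variance across samples")
    R = np.corrcoef(X)
    return np.clip(R, -1.0, 1.0)


def find_coexpressed_pairs(
    matrix: ExpressionMatrix,
    genes: Iterable[str],
    config: Optional[ThresholdConfig] = None,
) -> List[CoexpressedPair]:
    """All unordered pairs among ``genes`` passing the co-expression screen.

    Output is canonical (gene_a < gene_b), lexicographically sorted,
    duplicate-free.
    """
    config = config or ThresholdConfig()
    gene_list = sorted(set(genes))
    if len(gene_list) < 2:
        return []
    R = _correlation_submatrix(matrix, gene_list)
    n = matrix.n_samples
    pairs: List[CoexpressedPair] = []
    for i in range(len(gene_list)):
        for j in range(i + 1, len(gene_list)):
            cc = float(R[i, j])
            p = _p_from_cc(cc, n)
            if _pair_passes(cc, p, config):
                pairs.append(
                    CoexpressedPair.make(gene_list[i], gene_list[j], cc, p)
                )
    return pairs


def find_breaking_regulators(
    pair: CoexpressedPair,
    candidates: Iterable[str],
    matrix: ExpressionMatrix,
    config: Optional[ThresholdConfig] = None,
) -> List[BreakResult]:
    """Test each candidate regulator against one co-expressed pair.

    Returns one :class:`BreakResult` per candidate, in sorted candidate
    order.  A candidate equal to a pair member is an error.
    """
    config = config or ThresholdConfig()
    cand = sorted(set(candidates))
    for c in cand:
        if c in pair.members:
            raise ValueError(
                f"candidate {c!r} is a member of the pair under test"
            )
    if not cand:
        return []
    x = matrix.vector(pair.gene_a)
    y = matrix.vector(pair.gene_b)
    results: List[BreakResult] = []
    for c in cand:
        z = matrix.vector(c)
        r_xz, _ = pearson_cc(x, z)
        r_yz, _ = pearson_cc(y, z)
        pcc, breaks = _break_decision(pair.cc, r_xz, r_yz, config)
        results.append(BreakResult(regulator=c, pair=pair, pcc=pcc, breaks=breaks))
    return results


def write_pairs_tsv(pairs: Sequence[CoexpressedPair], path, float_fmt="%.6g") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene_a\tgene_b\tcc\tp_value\n")
        for p in pairs:
            fh.write(
                f"{p.gene_a}\t{p.gene_b}\t{float_fmt % p.cc}\t{float_fmt % p.p_value}\n"
            )


def write_breaks_tsv(results: Sequence[BreakResult], path, float_fmt="%.6g") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("regulator\tgene_a\tgene_b\tpcc\tbreaks\n")
        for r in results:
            pcc = "NA" if r.pcc is None else float_fmt % r.pcc
            fh.write(
                f"{r.regulator}\t{r.pair.gene_a}\t{r.pair.gene_b}\t{pcc}\t"
                f"{str(r.breaks).lower()}\n"
            )
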