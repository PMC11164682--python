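"""Sum-of-z-scores pathway-signature scoring of expression cohorts.

A pathway signature (e.g. a PI3K/AKT activation signature) is scored per
sample as

    score_j = sum_{g in signature} (x_gj - mean_g) / sd_g,

each gene z-scored across all samples (population standard deviation,
divisor n).  Because each gene's z-scores sum to zero over samples, the
scores themselves sum to zero over the cohort — a useful invariant check.
Downstream comparisons mirror common cohort analyses: Spearman rank
correlation of the score against a gene's expression, a median split of
the cohort on a stratifying gene, and Welch's unpaired t-test between the
resulting groups.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SignatureCoverage:
    used: tuple[str, ...]
    missing: tuple[str, ...]       # not in the matrix
    zero_variance: tuple[str, ...]  # present but constant across samples


@dataclass(frozen=True)
class SpearmanResult:
    rho: float
    p_value: float
    n: int
    method: str  # "exact" | "t-approx"


@dataclass(frozen=True)
class GroupComparison:
    group_high: tuple[str, ...]
    group_low: tuple[str, ...]
    mean_high: float
    mean_low: float
    t_statistic: float
    p_value: float
    degenerate: bool = False  # zero within-group variance in both groups


def load_expression_tsv(path: str | Path) -> pd.DataFrame:
    """Genes x samples TSV: first column gene labels, header = sample labels."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates or df.columns.has_duplicates:
        raise ValueError("duplicate gene or sample labels in expression matrix")
    return df


def load_signature(path: str | Path) -> list[str]:
    """One gene symbol per line; blank lines and '#' comments ignored."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


def signature_score(
    matrix: pd.DataFrame, signature: Sequence[str]
) -> tuple[pd.Series, SignatureCoverage]:
    """Per-sample sum of across-sample z-scores of the signature genes.

    Genes absent from the matrix or with zero variance are dropped and
    reported in the coverage record.  Requires at least one usable
    signature gene and at least two samples.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need >= 2 samples to z-score")
    present = [g for g in signature if g in matrix.index]
    missing = tuple(g for g in signature if g not in matrix.index)
    if not present:
        raise ValueError("no signature genes present in the matrix")
    sub = matrix.loc[present].astype(float)
    sd = sub.std(axis=1, ddof=0)
    zero_var = tuple(sd.index[sd == 0.0])
    usable = sd.index[sd > 0.0]
    if len(usable) == 0:
        raise ValueError("all present signature genes have zero variance")
    z = sub.loc[usable].sub(sub.loc[usable].mean(axis=1), axis=0).div(sd[usable], axis=0)
    scores = z.sum(axis=0)
    scores.name = "signature_score"
    return scores, SignatureCoverage(tuple(usable), missing, zero_var)


def median_split(matrix: pd.DataFrame, gene: str) -> tuple[list[str], list[str]]:
    """Split samples into high (> median) and low (<= median) by one gene.

    Values exactly at the median count as low — a deterministic tie rule
    that keeps the two groups disjoint and exhaustive.  A constant gene
    puts every sample in low (with a warning).
    """
    if gene not in matrix.index:
        raise KeyError(f"gene {gene!r} not in the matrix")
    values = matrix.loc[gene].astype(float)
    med = float(values.median())
    high = list(values.index[values > med])
    low = list(values.index[values <= med])
    if not high:
        logger.warning("median split on %r: no sample above the median "
                       "(constant expression?)", gene)
    return high, low


def _midranks(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def correlate(x: Sequence[float], y: Sequence[float]) -> SpearmanResult:
    """Spearman rank correlation with mid-ranks for ties.

    rho is the Pearson correlation of the mid-rank vectors.  The two-sided
    p-value uses exact enumeration of all pairings for n <= 10 and the
    t-distribution approximation above that.  Constant input is an error
    (rho undefined).
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if len(xa) != len(ya):
        raise ValueError("x and y must have the same length")
    n = len(xa)
    if n < 3:
        raise ValueError("need >= 3 paired observations")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise ValueError("Spearman rho undefined for a constant vector")
    rx, ry = _midranks(xa), _midranks(ya)
    rho = float(np.corrcoef(rx, ry)[0, 1])

    if n <= 10:
        p = _exact_spearman_p(rx, ry, rho)
        method = "exact"
    else:
        r = min(max(rho, -1.0), 1.0)
        if abs(r) == 1.0:
            p = 0.0
        else:
            t = r * math.sqrt((n - 2) / (1.0 - r * r))
            p = 2.0 * stats.t.sf(abs(t), df=n - 2)
        method = "t-approx"
    return SpearmanResult(rho=rho, p_value=float(min(p, 1.0)), n=n, method=method)


def _exact_spearman_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Enumerate all n! pairings of the rank vectors (two-sided)."""
    n = len(rx)
    sx = (rx - rx.mean()) / rx.std()
    sy = (ry - ry.mean()) / ry.std()
    target = abs(rho_obs) - 1e-12
    count = 0
    total = 0
    chunk_perms: list[tuple[int, ...]] = []
    for perm in itertools.permutations(range(n)):
        chunk_perms.append(perm)
        if len(chunk_perms) == 100_000:
            count += _count_extreme(sx, sy, chunk_perms, target)
            total += len(chunk_perms)
            chunk_perms = []
    if chunk_perms:
        count += _count_extreme(sx, sy, chunk_perms, target)
        total += len(chunk_perms)
    return count / total


def _count_extreme(sx, sy, perms, target) -> int:
    idx = np.array(perms)
    rhos = (sy[idx] @ sx) / len(sx)
    return int(np.sum(np.abs(rhos) >= target))


def compare_groups(
    scores: pd.Series, high: Sequence[str], low: Sequence[str]
) -> GroupComparison:
    """Welch's unpaired two-sided t-test on scores between two sample groups.

    Degenerate zero-variance cases are handled explicitly: identical
    groups give t = 0, p = 1; disjoint constants give the p -> 0 limit and
    the ``degenerate`` flag.
    """
    if len(high) < 2 or len(low) < 2:
        raise ValueError("each group needs >= 2 samples")
    a = scores.loc[list(high)].to_numpy(dtype=float)
    b = scores.loc[list(low)].to_numpy(dtype=float)
    if a.std(ddof=1) == 0.0 and b.std(ddof=1) == 0.0:
        if a.mean() == b.mean():
            return GroupComparison(tuple(high), tuple(low), float(a.mean()),
                                   float(b.mean()), 0.0, 1.0, degenerate=True)
        t = math.inf if a.mean() > b.mean() else -math.inf
        return GroupComparison(tuple(high), tuple(low), float(a.mean()),
                               float(b.mean()), t, 0.0, degenerate=True)
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return GroupComparison(tuple(high), tuple(low), float(a.mean()), float(b.mean()),
                           float(t), float(p))
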