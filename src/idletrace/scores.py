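"""Count scaling, gene-signature scoring, cycle classification and GO
concordance.

Matrices are genes x cells pandas DataFrames of non-negative counts.
Scaling equalises sequencing depth: each cell's column is multiplied by
(median total molecules across cells) / (that cell's total), so every
post-scaling column sums to the median depth.

Signature scoring follows the bin-matched control approach of Tirosh et al.:
genes are binned by their dataset-average expression, each signature gene
draws control genes from its own bin, and a cell's score is the mean
log1p-expression of the signature genes minus that of the controls. This
removes the depth/complexity component that a raw mean would carry. Signed
signatures (up/down member sets) score as up-score minus down-score.

Cycle classification condenses S and G2/M signature scores into a binary
slow/fast call: a cell is "fast" (S-G2-M) if either phase score is positive,
else "slow" (G1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GeneSignature",
    "ConcordanceResult",
    "scale_counts",
    "signature_score",
    "classify_cycle",
    "classify_cycle_table",
    "baseline_log2fc",
    "go_concordance",
]


@dataclass(frozen=True)
class GeneSignature:
    """Named gene set, optionally signed (up minus down)."""

    name: str
    genes: tuple[str, ...]
    down: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", tuple(self.genes))
        object.__setattr__(self, "down", tuple(self.down))
        if not self.genes:
            raise ValueError("signature needs at least one (up) gene")


def scale_counts(matrix: pd.DataFrame) -> pd.DataFrame:
    """Scale each cell to the median total molecule count.

    Idempotent: re-scaling a scaled matrix is a no-op (all totals already
    equal the median).
    """
    if (matrix.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    totals = matrix.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"cells with zero total counts: {list(zero.index)}")
    factors = totals.median() / totals
    return matrix * factors


def _mean_log1p(matrix: pd.DataFrame, genes) -> pd.Series:
    return np.log1p(matrix.loc[list(genes)]).mean(axis=0)


def _control_score(matrix: pd.DataFrame, genes: list[str],
                   bins: pd.Series, rng: np.random.Generator,
                   n_ctrl: int) -> pd.Series:
    # controls exclude the signature itself; with few genes per bin the
    # signature would otherwise serve as its own control and null the score
    exclude = set(genes)
    by_bin = bins.groupby(bins).groups
    controls: list[str] = []
    for g in genes:
        pool = [x for x in by_bin[bins[g]] if x not in exclude]
        if not pool:
            pool = [x for x in bins.index if x not in exclude]
        take = rng.choice(len(pool), size=min(n_ctrl, len(pool)),
                          replace=False)
        controls.extend(pool[i] for i in take)
    return _mean_log1p(matrix, genes) - _mean_log1p(matrix, controls)


def signature_score(
    scaled: pd.DataFrame,
    signature: GeneSignature,
    n_control_bins: int = 25,
    seed: int = 0,
    n_controls_per_gene: int = 100,
) -> pd.Series:
    """Bin-matched control score per cell for one signature.

    Genes are ranked by average scaled expression and cut into
    ``n_control_bins`` equal-occupancy bins; each signature gene samples
    ``n_controls_per_gene`` control genes (without replacement, capped at
    bin size) from its bin. Seed-reproducible.
    """
    up = [g for g in signature.genes if g in scaled.index]
    if not up:
        raise ValueError(
            f"no genes of signature {signature.name!r} present in matrix"
        )
    down = [g for g in signature.down if g in scaled.index]
    if signature.down and not down:
        raise ValueError(
            f"down subset of signature {signature.name!r} absent from matrix"
        )
    avg = scaled.mean(axis=1)
    n_bins = min(n_control_bins, avg.nunique())
    # rank-based cut gives equal-occupancy bins even with heavy ties
    bins = pd.Series(
        pd.qcut(avg.rank(method="first"), q=n_bins, labels=False),
        index=avg.index,
    )
    rng = np.random.default_rng(seed)
    score = _control_score(scaled, up, bins, rng, n_controls_per_gene)
    if down:
        score = score - _control_score(scaled, down, bins, rng,
                                       n_controls_per_gene)
    score.name = signature.name
    return score


def classify_cycle(s_score: float, g2m_score: float) -> str:
    """fast (S-G2-M) if either phase score is positive, else slow (G1).

    Exact zeros count as slow — the conservative tie decision.
    """
    if not (np.isfinite(s_score) and np.isfinite(g2m_score)):
        raise ValueError("scores must be finite")
    return "fast" if max(s_score, g2m_score) > 0 else "slow"


def classify_cycle_table(s_scores: pd.Series,
                         g2m_scores: pd.Series) -> pd.Series:
    """Vectorised slow/fast call per cell."""
    s, g = s_scores.align(g2m_scores, join="inner")
    if not (np.isfinite(s).all() and np.isfinite(g).all()):
        raise ValueError("scores must be finite")
    return pd.Series(np.where(np.maximum(s, g) > 0, "fast", "slow"),
                     index=s.index, name="cycle_class")


def baseline_log2fc(expr: pd.DataFrame, baseline_label,
                    pseudocount: float = 1.0) -> pd.DataFrame:
    """Per-gene log2((x_t + c) / (x_baseline + c)) relative to a baseline
    timepoint column; the baseline column of the result is identically 0."""
    if baseline_label not in expr.columns:
        raise ValueError(f"baseline column {baseline_label!r} not present")
    base = expr[baseline_label] + pseudocount
    if (base <= 0).any():
        raise ValueError("baseline plus pseudocount must be positive")
    return np.log2(expr.add(pseudocount).div(base, axis=0))


@dataclass
class ConcordanceResult:
    rho: float
    p_value: float
    n_shared: int
    merged: pd.DataFrame  # term, neglog10p_a, neglog10p_b


def _validate_go(table: pd.DataFrame, label: str) -> pd.DataFrame:
    if "term" not in table.columns or "pvalue" not in table.columns:
        raise ValueError(f"GO table {label} needs 'term' and 'pvalue' columns")
    p = table["pvalue"]
    if ((p <= 0) | (p > 1)).any():
        raise ValueError(f"GO table {label} p-values must lie in (0, 1]")
    return table


def go_concordance(table_a: pd.DataFrame, table_b: pd.DataFrame,
                   alpha: float = 0.05) -> ConcordanceResult:
    """Spearman rank concordance of -log10 p over shared significant GO terms.

    Both tables are first restricted to p < alpha, then intersected on term
    id; the statistic is the Spearman correlation (average ranks for ties)
    of the two -log10 p vectors. Being rank-based it is invariant to any
    strictly monotone transform of the p-values.
    """
    a = _validate_go(table_a, "A")
    b = _validate_go(table_b, "B")
    a = a[a["pvalue"] < alpha].set_index("term")["pvalue"]
    b = b[b["pvalue"] < alpha].set_index("term")["pvalue"]
    a = a[~a.index.duplicated()]
    b = b[~b.index.duplicated()]
    shared = a.index.intersection(b.index)
    if len(shared) < 3:
        raise ValueError(
            f"only {len(shared)} shared significant terms; need >= 3"
        )
    la = -np.log10(a.loc[shared])
    lb = -np.log10(b.loc[shared])
    rho, p = stats.spearmanr(la, lb)
    merged = pd.DataFrame({
        "term": shared,
        "neglog10p_a": la.values,
        "neglog10p_b": lb.values,
    }).reset_index(drop=True)
    return ConcordanceResult(rho=float(rho), p_value=float(p),
                             n_shared=int(len(shared)), merged=merged)
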