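"""Differential protein turnover between groups.

Per-protein Welch t-tests on replicate-level half-lives (in days),
Benjamini–Hochberg correction across the proteins tested within one
pairwise comparison, fraction-altered summaries, absolute half-life
difference matrices, exploratory PCA / hierarchical clustering of
half-life profiles, and a generic user-supplied-gene-set
over-representation test.

Because half-life changes are much smaller than abundance changes, no
fold-change gate is applied to turnover comparisons: significance is
``q_BH < alpha`` alone.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from sklearn.decomposition import PCA

from .errors import ConfigError, EmptyInputError, InsufficientDataError, ValidationError

logger = logging.getLogger(__name__)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values).

    Step-up with monotonicity enforcement, ties preserved, capped at 1;
    elementwise ``q >= p``. Delegates to statsmodels' ``fdr_bh``.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in [0, 1]")
    from statsmodels.stats.multitest import multipletests

    return multipletests(p, method="fdr_bh")[1]


class DifferentialTurnoverModel:
    """Group comparison of protein half-lives.

    Parameters
    ----------
    halflife_matrix : DataFrame
        Proteins × samples matrix of per-replicate protein half-lives in
        days (NaN = not quantified), e.g. from
        :meth:`lysokit.turnover.HalfLifeResults.halflife_matrix`.
    sample_groups : mapping
        sample id → group label.
    min_replicates : int
        Minimum finite replicates per group for a protein to be tested.
    alpha : float
        BH-adjusted significance threshold.
    log_scale : bool
        Run the t-tests on log-transformed half-lives (off by default; the
        difference heatmaps are in days).
    """

    def __init__(
        self,
        halflife_matrix: pd.DataFrame,
        sample_groups: Mapping[str, str],
        min_replicates: int = 3,
        alpha: float = 0.05,
        log_scale: bool = False,
    ) -> None:
        self.matrix = halflife_matrix
        self.sample_groups = dict(sample_groups)
        self.min_replicates = int(min_replicates)
        self.alpha = float(alpha)
        self.log_scale = bool(log_scale)
        unknown = set(self.matrix.columns) - set(self.sample_groups)
        if unknown:
            raise ConfigError(f"samples without a group label: {sorted(unknown)}")

    def _samples_of(self, group: str) -> list[str]:
        cols = [s for s in self.matrix.columns if self.sample_groups[s] == group]
        if not cols:
            raise ConfigError(f"group label {group!r} matches no sample")
        return cols

    def fit(self, group_a: str, group_b: str) -> "DifferentialTurnoverResults":
        """Welch two-sided t-test per protein between two groups.

        ``delta_days`` is ``mean(A) - mean(B)``; BH correction is applied
        across the proteins actually tested in this comparison. Proteins
        failing the per-group replicate minimum are excluded and counted.
        """
        cols_a = self._samples_of(group_a)
        cols_b = self._samples_of(group_b)
        if len(cols_a) < 2 or len(cols_b) < 2:
            raise InsufficientDataError("each group needs >= 2 replicate samples")
        A = self.matrix[cols_a].to_numpy(dtype=float)
        B = self.matrix[cols_b].to_numpy(dtype=float)
        n_a = np.isfinite(A).sum(axis=1)
        n_b = np.isfinite(B).sum(axis=1)
        testable = (n_a >= self.min_replicates) & (n_b >= self.min_replicates)
        n_excluded = int((~testable).sum())

        idx = self.matrix.index[testable]
        A, B = A[testable], B[testable]
        if len(idx) == 0:
            raise InsufficientDataError("no protein passes the replicate minimum in both groups")
        ta = np.log(A) if self.log_scale else A
        tb = np.log(B) if self.log_scale else B
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            tt = stats.ttest_ind(ta, tb, axis=1, equal_var=False, nan_policy="omit")
        p_raw = np.asarray(tt.pvalue, dtype=float)
        # zero-variance identical groups yield NaN p; no evidence of change
        p_raw = np.where(np.isnan(p_raw), 1.0, p_raw)

        mean_a = np.nanmean(A, axis=1)
        mean_b = np.nanmean(B, axis=1)
        table = pd.DataFrame({
            "protein_id": idx,
            "mean_half_life_a": mean_a,
            "mean_half_life_b": mean_b,
            "delta_days": mean_a - mean_b,
            "p_raw": p_raw,
            "n_a": n_a[testable],
            "n_b": n_b[testable],
        })
        # stable protein-id sort keeps BH tie handling reproducible
        table = table.sort_values("protein_id", kind="stable").reset_index(drop=True)
        table["q_bh"] = bh_adjust(table["p_raw"].to_numpy())
        table["significant"] = table["q_bh"] < self.alpha
        return DifferentialTurnoverResults(self, group_a, group_b, table, n_excluded)


class DifferentialTurnoverResults:
    """Per-protein turnover comparison between two groups."""

    def __init__(self, model: DifferentialTurnoverModel, group_a: str, group_b: str,
                 comparisons: pd.DataFrame, n_excluded: int) -> None:
        self.model = model
        self.group_a = group_a
        self.group_b = group_b
        self.comparisons = comparisons
        self.n_excluded = n_excluded

    @property
    def alpha(self) -> float:
        return self.model.alpha

    def significant_proteins(self) -> list[str]:
        return list(self.comparisons.loc[self.comparisons["significant"], "protein_id"])

    def fraction_altered(self) -> float:
        return fraction_altered(self.comparisons)

    def fraction_altered_of_quantified(self) -> float:
        """Percentage with the denominator extended to untested (excluded) proteins."""
        n_quant = len(self.comparisons) + self.n_excluded
        return 100.0 * self.comparisons["significant"].sum() / n_quant

    def volcano_table(self) -> pd.DataFrame:
        """TSV-ready table with -log10 q for volcano plotting."""
        t = self.comparisons.copy()
        with np.errstate(divide="ignore"):
            t["neg_log10_q"] = -np.log10(t["q_bh"])
        return t

    def summary(self) -> str:
        n_sig = int(self.comparisons["significant"].sum())
        return (
            f"Differential turnover: {self.group_a} vs {self.group_b}\n"
            f"  proteins tested:    {len(self.comparisons)}"
            f" (excluded below replicate minimum: {self.n_excluded})\n"
            f"  significant (q < {self.alpha:g}): {n_sig}\n"
            f"  fraction altered:   {self.fraction_altered():.1f}% of tested"
            f" ({self.fraction_altered_of_quantified():.1f}% of quantified)\n"
            f"  median |delta|:     {self.comparisons['delta_days'].abs().median():.3f} days"
        )


def fraction_altered(comparisons: pd.DataFrame) -> float:
    """Percentage of tested proteins with a significant half-life change."""
    if len(comparisons) == 0:
        raise EmptyInputError("no comparisons supplied")
    return 100.0 * float(comparisons["significant"].sum()) / len(comparisons)


def half_life_difference_matrix(
    comparisons_by_name: Mapping[str, pd.DataFrame],
    proteins: Sequence[str] | None = None,
) -> pd.DataFrame:
    """|delta_days| matrix: rows = proteins, columns = named comparisons.

    Proteins missing from any comparison are dropped with a warning.
    """
    if not comparisons_by_name:
        raise EmptyInputError("no comparisons supplied")
    series = {
        name: comp.set_index("protein_id")["delta_days"].abs()
        for name, comp in comparisons_by_name.items()
    }
    mat = pd.DataFrame(series)
    if proteins is not None:
        mat = mat.reindex([p for p in proteins if p in mat.index])
    dropped = mat.index[mat.isna().any(axis=1)]
    if len(dropped):
        logger.warning(
            "half_life_difference_matrix: dropped %d proteins absent from some comparison",
            len(dropped),
        )
    return mat.dropna()


@dataclass
class PCAClusterResult:
    """Sample embedding on the first two PCs plus a dendrogram leaf order."""

    embedding: pd.DataFrame  # samples × (PC1, PC2), plus group column
    explained_variance_ratio: tuple[float, float]
    linkage: np.ndarray
    leaf_order: list[str]
    n_proteins_used: int

    def summary(self) -> str:
        ev1, ev2 = self.explained_variance_ratio
        return (
            "PCA / clustering of half-life profiles\n"
            f"  samples:          {len(self.embedding)}\n"
            f"  proteins used:    {self.n_proteins_used} (complete-case, non-constant)\n"
            f"  PC1/PC2 variance: {100 * ev1:.1f}% / {100 * ev2:.1f}%\n"
            f"  leaf order:       {', '.join(self.leaf_order)}"
        )


def pca_and_cluster(
    halflife_matrix: pd.DataFrame,
    sample_groups: Mapping[str, str],
) -> PCAClusterResult:
    """PCA and average-linkage clustering of samples by half-life profile.

    Proteins with any missing value or zero variance are dropped; the
    remainder are z-scored per protein across samples. Samples are embedded
    on the first two principal components and clustered with average
    linkage on Euclidean distances. Deterministic given the input.
    """
    if halflife_matrix.shape[1] < 3:
        raise InsufficientDataError("PCA/clustering needs >= 3 samples")
    complete = halflife_matrix.dropna()
    variances = complete.var(axis=1, ddof=0)
    complete = complete[variances > 0]
    if complete.empty:
        raise InsufficientDataError("no complete-case, non-constant proteins")
    z = complete.sub(complete.mean(axis=1), axis=0).div(complete.std(axis=1, ddof=0), axis=0)
    X = z.T.to_numpy()  # samples × proteins
    n_comp = min(2, X.shape[0] - 1, X.shape[1])
    pca = PCA(n_components=n_comp, svd_solver="full", random_state=0)
    coords = pca.fit_transform(X)
    if n_comp < 2:  # degenerate: a single usable protein spans one axis
        coords = np.column_stack([coords, np.zeros(len(coords))])
    emb = pd.DataFrame(coords, index=complete.columns, columns=["PC1", "PC2"])
    emb["group"] = [sample_groups[s] for s in emb.index]
    link = hierarchy.linkage(X, method="average", metric="euclidean")
    order = [complete.columns[i] for i in hierarchy.leaves_list(link)]
    ev = tuple(pca.explained_variance_ratio_) + (0.0, 0.0)
    return PCAClusterResult(
        embedding=emb,
        explained_variance_ratio=ev[:2],
        linkage=link,
        leaf_order=order,
        n_proteins_used=len(complete),
    )


def gene_set_overrepresentation(
    significant: Sequence[str],
    background: Sequence[str],
    gene_sets: Mapping[str, Sequence[str]],
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of user-supplied gene sets.

    ``significant`` must be a subset of ``background``. For each set the
    tail probability P(X >= observed hits) is computed against drawing
    ``len(significant)`` genes from the background; BH correction is
    applied across the sets.
    """
    bg = set(background)
    if not bg:
        raise EmptyInputError("background set is empty")
    sig = set(significant)
    if not sig <= bg:
        raise ValidationError("significant genes must be a subset of the background")
    M, N = len(bg), len(sig)
    rows = []
    for name, members in gene_sets.items():
        inset = set(members) & bg
        k = len(inset & sig)
        # P(X >= k) for X ~ Hypergeom(M, |set∩bg|, N)
        p = float(stats.hypergeom.sf(k - 1, M, len(inset), N)) if inset else 1.0
        rows.append({"gene_set": name, "set_size_in_background": len(inset),
                     "n_hits": k, "p_hyper": min(p, 1.0)})
    out = pd.DataFrame(rows)
    out["q_bh"] = bh_adjust(out["p_hyper"].to_numpy()) if len(out) else []
    return out
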