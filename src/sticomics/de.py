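"""Two-group per-gene differential expression with BH FDR control.

``GroupComparison`` is the model object: a log-normalized expression matrix
plus a two-level group label per sample.  ``fit()`` runs a per-gene
two-sample t test (Welch by default) and Benjamini–Hochberg adjustment over
all genes, returning a ``GroupComparisonResults`` with the per-gene table,
threshold counting and a text summary.  Constant genes get p = 1 by
convention (never significant, never dropped), so gene counts are preserved.
"""

from __future__ import annotations

import pandas as pd

from .matrix import ExpressionMatrix
from .stats import TTestVariant, bh_adjust, two_sample_t_matrix

__all__ = ["GroupComparison", "GroupComparisonResults"]


class GroupComparison:
    """Per-gene two-group comparison model.

    Parameters
    ----------
    matrix : ExpressionMatrix (log_normalized)
    groups : Series/mapping, optional
        Group label per sample; defaults to the matrix ``group`` annotation.
        Exactly two levels, each with >= 2 samples.
    variant : {"welch", "pooled"}
    """

    def __init__(
        self,
        matrix: ExpressionMatrix,
        groups=None,
        variant: TTestVariant = "welch",
    ):
        if matrix.state != "log_normalized":
            raise ValueError("class comparison runs on log-normalized values")
        if groups is None:
            groups = matrix.annotation("group")
        groups = pd.Series(groups)
        missing = matrix.samples.difference(groups.index)
        if len(missing):
            raise ValueError(f"samples without a group label: {list(missing)[:5]}")
        groups = groups.loc[matrix.samples]
        if groups.isna().any():
            raise ValueError("missing group labels")
        levels = sorted(pd.unique(groups))
        if len(levels) != 2:
            raise ValueError(f"exactly two groups required, got {levels}")
        if (groups == levels[0]).sum() < 2 or (groups == levels[1]).sum() < 2:
            raise ValueError("each group needs >= 2 samples")
        # report STIC-vs-NOSTIC style orderings with the case group first
        if "STIC" in levels:
            levels = ["STIC"] + [l for l in levels if l != "STIC"]
        self.matrix = matrix
        self.groups = groups
        self.levels = levels
        self.variant = variant

    def fit(self) -> "GroupComparisonResults":
        vals = self.matrix.to_numpy()
        in1 = (self.groups == self.levels[0]).to_numpy()
        x, y = vals[:, in1], vals[:, ~in1]
        t, p = two_sample_t_matrix(x, y, variant=self.variant)
        q = bh_adjust(p)
        table = pd.DataFrame(
            {
                "diff": x.mean(axis=1) - y.mean(axis=1),
                "t": t,
                "p": p,
                "q": q,
            },
            index=self.matrix.genes,
        ).sort_values("p", kind="stable")
        return GroupComparisonResults(
            table=table,
            group_sizes=(int(in1.sum()), int((~in1).sum())),
            levels=tuple(self.levels),
            variant=self.variant,
        )


class GroupComparisonResults:
    """Per-gene effect (log2 difference), t, p and BH q, sorted by p."""

    def __init__(self, table: pd.DataFrame, group_sizes, levels, variant):
        self.table = table
        self.group_sizes = group_sizes
        self.levels = levels
        self.variant = variant

    def count_significant(
        self, raw_p_cut: float = 0.01, fdr_cut: float = 0.10
    ) -> tuple[int, int]:
        """(# genes with p < raw_p_cut, # genes with q < fdr_cut), strict."""
        for cut in (raw_p_cut, fdr_cut):
            if not 0 < cut <= 1:
                raise ValueError("thresholds must lie in (0, 1]")
        p = self.table["p"].to_numpy()
        q = self.table["q"].to_numpy()
        return int((p < raw_p_cut).sum()), int((q < fdr_cut).sum())

    def significant_genes(self, fdr_cut: float = 0.10) -> list:
        return list(self.table.index[self.table["q"].to_numpy() < fdr_cut])

    def summary(self, raw_p_cut: float = 0.01, fdr_cut: float = 0.10) -> str:
        n_raw, n_fdr = self.count_significant(raw_p_cut, fdr_cut)
        lines = [
            "Two-group class comparison",
            f"  groups: {self.levels[0]} (n={self.group_sizes[0]}) vs "
            f"{self.levels[1]} (n={self.group_sizes[1]}); {self.variant} t test",
            f"  genes tested: {len(self.table)}",
            f"  genes with raw p < {raw_p_cut:g}: {n_raw}",
            f"  genes significant at BH FDR {fdr_cut:.0%}: {n_fdr}",
        ]
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="gene")
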