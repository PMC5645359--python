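"""Tissue-of-origin signature matching.

Normal-tissue pools from fallopian tube (FT), ovarian surface epithelium
(OSE) and peritoneum (PER) are compared one-vs-rest per gene; the top
``top_n`` (default 50) most differentially expressed genes from each tissue
are combined (deduplicated union) into a tissue-type signature.  Tumors are
then matched to per-tissue prototype profiles by Spearman correlation over
the signature genes, each tumor being called for the tissue with the highest
correlation.  The headline summary is the fraction of tumors better
correlated with FT than with ovarian tissue, with an exact binomial
confidence interval.

"Most differentially expressed" ranks by ascending p-value, breaking ties by
descending absolute mean difference and then by gene id; the rule is recorded
in the signature metadata.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix
from .simulate import TISSUES, canonical_tissue
from .stats import bh_adjust, clopper_pearson_ci, spearman_rho, two_sample_t_matrix

__all__ = [
    "TissueSignature",
    "TissueAssignment",
    "TissueOriginModel",
    "TissueOriginResults",
    "derive_tissue_signature",
    "count_tissue_de",
]


@dataclass
class TissueSignature:
    """Per-tissue ranked markers, their union, and prototype profiles."""

    markers: dict[str, list[str]]  # tissue -> ranked top_n marker gene ids
    combined: list[str]  # deduplicated union, in first-appearance order
    prototypes: pd.DataFrame  # combined genes × tissues (mean log2 profile)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if sorted(self.markers) != sorted(TISSUES):
            raise ValueError(f"markers must cover exactly {TISSUES}")
        union = set()
        for t in TISSUES:
            union.update(self.markers[t])
        if set(self.combined) != union:
            raise ValueError("combined set must equal the union of the marker lists")
        if list(self.prototypes.index) != list(self.combined):
            raise ValueError("prototypes must be defined on exactly the combined set")
        sd = self.prototypes.std(axis=0, ddof=0)
        if np.any(sd.to_numpy() == 0):
            raise ValueError("constant prototype over the combined set")


@dataclass
class TissueAssignment:
    sample: str
    rho: pd.Series  # Spearman correlation per tissue (FT, OSE, PER)
    call: str  # argmax tissue
    ft_vs_ose: str  # pairwise winner between FT and ovarian tissue


def _one_vs_rest_tests(
    normals: ExpressionMatrix, tissue_labels: pd.Series
) -> dict[str, pd.DataFrame]:
    """Per-tissue one-vs-rest Welch t tests on log-normalized values."""
    if normals.state != "log_normalized":
        raise ValueError("tissue comparisons run on log-normalized values")
    labels = pd.Series(tissue_labels).loc[normals.samples].map(canonical_tissue)
    counts = labels.value_counts()
    for t in TISSUES:
        if counts.get(t, 0) < 2:
            raise ValueError(f"tissue {t} needs >= 2 pools (got {counts.get(t, 0)})")
    vals = normals.to_numpy()
    out = {}
    for t in TISSUES:
        in_t = (labels == t).to_numpy()
        tstat, p = two_sample_t_matrix(vals[:, in_t], vals[:, ~in_t], variant="welch")
        out[t] = pd.DataFrame(
            {
                "diff": vals[:, in_t].mean(axis=1) - vals[:, ~in_t].mean(axis=1),
                "t": tstat,
                "p": p,
                "q": bh_adjust(p),
            },
            index=normals.genes,
        )
    return out


def derive_tissue_signature(
    normals: ExpressionMatrix, tissue_labels=None, top_n: int = 50
) -> TissueSignature:
    """Build the tissue-type signature from normal pools.

    For each tissue: one-vs-rest test, rank genes by (p ascending,
    |mean difference| descending, gene id), keep the top ``top_n``.  The
    combined set is the deduplicated union; prototypes are per-tissue mean
    profiles over the combined set.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    if tissue_labels is None:
        tissue_labels = normals.annotation("tissue")
    labels = pd.Series(tissue_labels).loc[normals.samples].map(canonical_tissue)
    tests = _one_vs_rest_tests(normals, labels)
    markers: dict[str, list[str]] = {}
    for t in TISSUES:
        tab = tests[t].copy()
        tab.index.name = None
        tab["absdiff"] = tab["diff"].abs()
        tab["gene"] = tab.index.astype(str)
        ranked = tab.sort_values(
            by=["p", "absdiff", "gene"], ascending=[True, False, True], kind="stable"
        )
        markers[t] = list(ranked.index[: min(top_n, len(ranked))])
    combined: list[str] = []
    seen = set()
    for t in TISSUES:
        for g in markers[t]:
            if g not in seen:
                seen.add(g)
                combined.append(g)
    sub = normals.values.loc[combined]
    proto = {t: sub.loc[:, (labels == t).to_numpy()].mean(axis=1) for t in TISSUES}
    return TissueSignature(
        markers=markers,
        combined=combined,
        prototypes=pd.DataFrame(proto)[list(TISSUES)],
        metadata={
            "test": "welch_t_one_vs_rest",
            "ranking": "p asc, |diff| desc, gene id",
            "top_n": top_n,
        },
    )


def count_tissue_de(normals: ExpressionMatrix, tissue_labels=None, alpha: float = 0.05) -> pd.Series:
    """Genes with BH q < alpha in each one-vs-rest tissue comparison."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if tissue_labels is None:
        tissue_labels = normals.annotation("tissue")
    tests = _one_vs_rest_tests(normals, pd.Series(tissue_labels))
    return pd.Series(
        {t: int((tests[t]["q"].to_numpy() < alpha).sum()) for t in TISSUES},
        name=f"n_de_q<{alpha:g}",
    )


class TissueOriginModel:
    """Tissue-of-origin matcher built from normal pools.

    ``fit`` derives the signature; ``match`` scores a tumor matrix and
    returns :class:`TissueOriginResults`.
    """

    def __init__(self, normals: ExpressionMatrix, tissue_labels=None, top_n: int = 50):
        self.normals = normals
        self.tissue_labels = (
            normals.annotation("tissue") if tissue_labels is None else pd.Series(tissue_labels)
        )
        self.top_n = top_n
        self.signature: TissueSignature | None = None

    def fit(self) -> "TissueOriginModel":
        self.signature = derive_tissue_signature(self.normals, self.tissue_labels, self.top_n)
        return self

    def match(
        self, tumors: ExpressionMatrix, method: str = "average_profile"
    ) -> "TissueOriginResults":
        """Score tumors against the fitted signature.

        ``method="average_profile"`` (default) correlates each tumor with the
        per-tissue mean prototype; ``method="average_correlation"``
        correlates with every individual pool and averages the correlations
        within tissue.
        """
        if self.signature is None:
            self.fit()
        pools = None
        if method == "average_correlation":
            labels = pd.Series(self.tissue_labels).loc[self.normals.samples].map(canonical_tissue)
            sub = self.normals.values.loc[self.signature.combined]
            pools = {
                t: [sub[c].to_numpy(dtype=float) for c in sub.columns[(labels == t).to_numpy()]]
                for t in TISSUES
            }
        elif method != "average_profile":
            raise ValueError(f"unknown matching method: {method!r}")
        return TissueOriginResults(
            match_tissue(tumors, self.signature, pools=pools), self.signature
        )


def match_tissue(
    tumors: ExpressionMatrix, signature: TissueSignature, pools=None
) -> list[TissueAssignment]:
    """Spearman-match each tumor to the tissue prototypes over the combined
    signature genes.  Argmax ties break by fixed priority FT > OSE > PER
    (with a warning); the FT-vs-ovary pairwise winner is recorded separately.

    When ``pools`` (tissue -> list of pool profile arrays over the combined
    set) is given, each tumor is correlated with every pool and the
    correlations are averaged within tissue instead of correlating with the
    mean prototype.
    """
    if tumors.state != "log_normalized":
        raise ValueError("tissue matching runs on log-normalized values")
    sub = tumors.subset_genes(signature.combined)
    out: list[TissueAssignment] = []
    proto = {t: signature.prototypes[t].to_numpy() for t in TISSUES}
    for sample in sub.samples:
        profile = sub.values[sample].to_numpy(dtype=float)
        if np.ptp(profile) == 0:
            raise ValueError(f"constant tumor profile over the signature: {sample}")
        if pools is None:
            rho = pd.Series({t: spearman_rho(profile, proto[t]) for t in TISSUES})
        else:
            rho = pd.Series(
                {
                    t: float(np.mean([spearman_rho(profile, pool) for pool in pools[t]]))
                    for t in TISSUES
                }
            )
        best = float(rho.max())
        winners = [t for t in TISSUES if rho[t] == best]
        if len(winners) > 1:
            warnings.warn(
                f"tied tissue correlations for {sample}; "
                f"breaking by priority {' > '.join(TISSUES)}",
                stacklevel=2,
            )
        call = winners[0]
        ft_vs_ose = "FT" if rho["FT"] > rho["OSE"] else ("OSE" if rho["OSE"] > rho["FT"] else "FT")
        out.append(TissueAssignment(sample=str(sample), rho=rho, call=call, ft_vs_ose=ft_vs_ose))
    return out


class TissueOriginResults:
    """Per-tumor tissue correlations and calls, with the FT-vs-ovary summary."""

    def __init__(self, assignments: list[TissueAssignment], signature: TissueSignature | None = None):
        if not assignments:
            raise ValueError("no assignments to summarize")
        self.assignments = assignments
        self.signature = signature

    @property
    def table(self) -> pd.DataFrame:
        rows = [
            {
                "sample": a.sample,
                **{f"rho_{t}": a.rho[t] for t in TISSUES},
                "call": a.call,
                "ft_vs_ose": a.ft_vs_ose,
            }
            for a in self.assignments
        ]
        return pd.DataFrame(rows).set_index("sample")

    def call_counts(self) -> pd.Series:
        calls = pd.Series([a.call for a in self.assignments], dtype=object)
        return calls.value_counts().reindex(TISSUES, fill_value=0).astype(int)

    def mean_rho(self) -> pd.Series:
        """Average correlation to each tissue over tumors (the study-style
        per-tissue summary)."""
        return pd.DataFrame([a.rho for a in self.assignments]).mean(axis=0)[list(TISSUES)]

    def ft_better_than_ovary(self, level: float = 0.95):
        """(k, n, proportion, (lo, hi)): tumors better correlated with FT
        than with ovarian tissue, with the exact binomial CI."""
        n = len(self.assignments)
        k = sum(1 for a in self.assignments if a.rho["FT"] > a.rho["OSE"])
        lo, hi = clopper_pearson_ci(k, n, level)
        return k, n, k / n, (lo, hi)

    def summary(self) -> str:
        k, n, prop, (lo, hi) = self.ft_better_than_ovary()
        mean = self.mean_rho()
        counts = self.call_counts()
        lines = [
            "Tissue-of-origin matching (Spearman, combined marker signature)",
            f"  tumors: {n}",
            "  mean correlation: "
            + ", ".join(f"{t} {mean[t]:.2f}" for t in TISSUES),
            "  best-match calls: "
            + ", ".join(f"{t} {counts[t]}" for t in TISSUES),
            f"  better correlated with FT than ovarian tissue: {k}/{n} "
            f"({100 * prop:.0f}%, 95% CI ({100 * lo:.0f}-{100 * hi:.0f}%))",
        ]
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t")
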