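"""Prototype-correlation expression subtyping with abstention.

The four HGSC expression subtypes are represented by prototype (centroid)
profiles over a signature gene set (nominally 100 genes).  A tumor is
correlated with every prototype and assigned to the best-correlated subtype
only when there is a single clear best match:

* candidates are subtypes whose correlation is strictly above the floor
  (default 0.2);
* with no candidate the sample is UNASSIGNED;
* with one candidate it is assigned;
* with several, the maximum must be at least ``ratio`` (default 1.5) times
  the second highest, otherwise UNASSIGNED.

Exact ties at the maximum fail the ratio rule for positive correlations and
abstain.  Raising the floor or the ratio can only shrink the assigned set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix
from .stats import spearman_rho

__all__ = [
    "UNASSIGNED",
    "SubtypeModel",
    "SubtypeAssignment",
    "SubtypeClassifier",
    "SubtypeResults",
    "decide_assignment",
]

UNASSIGNED = "UNASSIGNED"


@dataclass
class SubtypeModel:
    """Signature gene list + one prototype (mean) profile per subtype."""

    prototypes: pd.DataFrame  # signature genes × subtypes
    metric: str = "pearson"  # or "spearman"

    def __post_init__(self) -> None:
        if self.prototypes.shape[1] < 2:
            raise ValueError("need at least 2 subtypes")
        if self.prototypes.index.has_duplicates:
            raise ValueError("duplicate signature genes")
        sd = self.prototypes.std(axis=0, ddof=0)
        if np.any(sd.to_numpy() == 0):
            bad = list(sd.index[sd == 0])
            raise ValueError(f"constant prototype(s): {bad}")
        if self.metric not in ("pearson", "spearman"):
            raise ValueError(f"unknown correlation metric: {self.metric!r}")

    @property
    def signature_genes(self) -> pd.Index:
        return self.prototypes.index

    @property
    def subtypes(self) -> list[str]:
        return list(self.prototypes.columns)


@dataclass
class SubtypeAssignment:
    sample: str
    correlations: pd.Series  # one per subtype
    call: str  # subtype name or UNASSIGNED
    rule: str  # which criterion fired


def decide_assignment(
    correlations: pd.Series, floor: float = 0.2, ratio: float = 1.5
) -> tuple[str, str]:
    """Apply the floor/ratio rule to a vector of subtype correlations.

    Returns (call, rule-trace).  ``floor`` must lie in (-1, 1), ``ratio``
    must be >= 1.
    """
    if not -1.0 < floor < 1.0:
        raise ValueError("floor must lie in (-1, 1)")
    if ratio < 1.0:
        raise ValueError("ratio must be >= 1")
    above = correlations[correlations > floor]
    if len(above) == 0:
        return UNASSIGNED, f"no correlation > floor ({floor:g})"
    if len(above) == 1:
        return str(above.index[0]), f"single correlation > floor ({floor:g})"
    ordered = above.sort_values(ascending=False, kind="stable")
    best, second = float(ordered.iloc[0]), float(ordered.iloc[1])
    if best >= ratio * second:
        return str(ordered.index[0]), f"best >= {ratio:g} x second ({best:.3f} vs {second:.3f})"
    return UNASSIGNED, f"ambiguous: best < {ratio:g} x second ({best:.3f} vs {second:.3f})"


class SubtypeClassifier:
    """Nearest-centroid classifier built from reference samples.

    Construct directly from a :class:`SubtypeModel`, or derive the model
    from a labelled reference cohort with :meth:`from_reference`.
    """

    def __init__(self, model: SubtypeModel, floor: float = 0.2, ratio: float = 1.5):
        # validate eagerly so misconfiguration fails at construction
        decide_assignment(pd.Series(0.0, index=model.subtypes), floor, ratio)
        self.model = model
        self.floor = floor
        self.ratio = ratio

    @classmethod
    def from_reference(
        cls,
        reference: ExpressionMatrix,
        reference_labels,
        signature_genes,
        metric: str = "pearson",
        floor: float = 0.2,
        ratio: float = 1.5,
    ) -> "SubtypeClassifier":
        """Build prototypes as per-gene mean expression within each labelled
        subtype, restricted to the signature genes (log-normalized scale)."""
        if reference.state != "log_normalized":
            raise ValueError("prototypes are built on log-normalized values")
        labels = pd.Series(reference_labels)
        labels = labels.loc[reference.samples]
        signature_genes = list(signature_genes)
        missing = [g for g in signature_genes if g not in reference.values.index]
        if missing:
            raise KeyError(f"signature genes absent from reference: {missing[:10]}")
        sub = reference.values.loc[signature_genes]
        proto = {}
        for subtype in sorted(pd.unique(labels)):
            cols = labels.index[labels == subtype]
            proto[str(subtype)] = sub[cols].mean(axis=1)
        model = SubtypeModel(pd.DataFrame(proto), metric=metric)
        return cls(model, floor=floor, ratio=ratio)

    def _correlate(self, profile: np.ndarray) -> pd.Series:
        if np.ptp(profile) == 0:
            raise ValueError("constant profile: correlation undefined")
        out = {}
        for subtype in self.model.subtypes:
            proto = self.model.prototypes[subtype].to_numpy()
            if self.model.metric == "spearman":
                out[subtype] = spearman_rho(profile, proto)
            else:
                out[subtype] = float(np.corrcoef(profile, proto)[0, 1])
        return pd.Series(out)

    def assign(self, profile, sample: str = "sample") -> SubtypeAssignment:
        """Classify one expression profile (indexed by gene or aligned to
        the signature)."""
        if isinstance(profile, pd.Series):
            profile = profile.reindex(self.model.signature_genes)
            if profile.isna().any():
                raise KeyError("profile missing signature genes")
            profile = profile.to_numpy(dtype=float)
        else:
            profile = np.asarray(profile, dtype=float)
            if profile.shape[0] != len(self.model.signature_genes):
                raise ValueError("profile length does not match the signature")
        corr = self._correlate(profile)
        call, rule = decide_assignment(corr, self.floor, self.ratio)
        return SubtypeAssignment(sample=sample, correlations=corr, call=call, rule=rule)

    def assign_cohort(self, matrix: ExpressionMatrix) -> "SubtypeResults":
        """Classify every sample; per-sample errors are recorded, not fatal."""
        if matrix.state != "log_normalized":
            raise ValueError("classification runs on log-normalized values")
        sub = matrix.subset_genes(list(self.model.signature_genes))
        assignments: list[SubtypeAssignment] = []
        errors: dict[str, str] = {}
        for sample in sub.samples:
            try:
                assignments.append(self.assign(sub.values[sample], sample=str(sample)))
            except ValueError as exc:
                errors[str(sample)] = str(exc)
        return SubtypeResults(assignments, self.model.subtypes, errors, self.floor, self.ratio)


class SubtypeResults:
    """Cohort assignments plus per-subtype counts (including UNASSIGNED)."""

    def __init__(self, assignments, subtypes, errors, floor, ratio):
        self.assignments = assignments
        self.subtypes = list(subtypes)
        self.errors = errors
        self.floor = floor
        self.ratio = ratio

    @property
    def table(self) -> pd.DataFrame:
        rows = []
        for a in self.assignments:
            row = {"sample": a.sample, **{f"corr_{s}": a.correlations[s] for s in self.subtypes}}
            row["call"] = a.call
            row["rule"] = a.rule
            rows.append(row)
        return pd.DataFrame(rows).set_index("sample") if rows else pd.DataFrame(
            columns=[f"corr_{s}" for s in self.subtypes] + ["call", "rule"]
        )

    def counts(self) -> pd.Series:
        calls = pd.Series([a.call for a in self.assignments], dtype=object)
        idx = self.subtypes + [UNASSIGNED]
        return calls.value_counts().reindex(idx, fill_value=0).astype(int)

    def proportions(self) -> pd.Series:
        c = self.counts()
        return c / max(len(self.assignments), 1)

    def summary(self) -> str:
        c = self.counts()
        lines = [
            "Subtype assignment (prototype correlation, "
            f"floor {self.floor:g}, ratio {self.ratio:g})",
            f"  samples classified: {len(self.assignments)}"
            + (f" ({len(self.errors)} failed)" if self.errors else ""),
        ]
        for name, count in c.items():
            lines.append(f"  {name}: {count}")
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t")
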