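"""Region-level somatic copy-number analysis.

Works on the output of segmentation: per-sample segments with mean log2
copy ratios, summarized over a fixed set of genomic regions (e.g. recurrently
altered focal regions supplied as input) into discrete calls
{-2, -1, 0, +1, +2}.  The scientific question is whether any region is
altered at a different frequency in tumors with versus without STIC lesions;
this is tested per region with Fisher's exact test and BH FDR across regions.

Deep thresholds default to |log2| >= 1 ("2+ fold amplification" and a
purity-naive homozygous-deletion proxy); single-copy calls use |log2| >= 0.3.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stats import bh_adjust, fisher_exact

__all__ = [
    "SegmentSet",
    "RegionCallMatrix",
    "call_regions",
    "fraction_genome_altered",
    "RegionFrequencyComparison",
    "RegionFrequencyResults",
]


@dataclass
class SegmentSet:
    """Segmented copy-number profiles for a set of samples.

    ``segments`` columns: sample, chrom, start, end, log2 — coordinates
    0-based half-open internally (SEG files on disk are 1-based inclusive;
    the readers/writers convert).  Segments must not overlap within a sample.
    """

    segments: pd.DataFrame

    REQUIRED = ("sample", "chrom", "start", "end", "log2")

    def __post_init__(self) -> None:
        seg = self.segments
        missing = [c for c in self.REQUIRED if c not in seg.columns]
        if missing:
            raise ValueError(f"segment table missing columns: {missing}")
        if np.any(seg["end"].to_numpy() <= seg["start"].to_numpy()):
            bad = seg[seg["end"] <= seg["start"]].iloc[0]
            raise ValueError(
                f"segment with end <= start: sample={bad['sample']} "
                f"{bad['chrom']}:{bad['start']}-{bad['end']}"
            )
        if np.any(seg["start"].to_numpy() < 0):
            raise ValueError("negative segment coordinates")
        for (sample, chrom), grp in seg.groupby(["sample", "chrom"], sort=False):
            s = grp.sort_values("start")
            overlap = s["start"].to_numpy()[1:] < s["end"].to_numpy()[:-1]
            if overlap.any():
                i = int(np.where(overlap)[0][0])
                raise ValueError(
                    f"overlapping segments in sample {sample} on {chrom} near "
                    f"position {int(s['start'].to_numpy()[1:][i])}"
                )

    @property
    def samples(self) -> list:
        return list(pd.unique(self.segments["sample"]))


@dataclass
class RegionCallMatrix:
    """Discrete alteration calls for regions × samples.

    ``regions`` columns: chrom, start, end, label (0-based half-open);
    ``calls`` is a DataFrame indexed by region label with sample columns,
    values in {-2, -1, 0, +1, +2}.
    """

    regions: pd.DataFrame
    calls: pd.DataFrame
    thresholds: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for c in ("chrom", "start", "end", "label"):
            if c not in self.regions.columns:
                raise ValueError(f"region table missing column: {c}")
        if not set(np.unique(self.calls.to_numpy())) <= {-2, -1, 0, 1, 2}:
            raise ValueError("calls must lie in {-2, -1, 0, +1, +2}")
        if list(self.calls.index) != list(self.regions["label"]):
            raise ValueError("call matrix rows must match region labels, in order")
        # regions must not overlap
        for chrom, grp in self.regions.groupby("chrom", sort=False):
            s = grp.sort_values("start")
            if np.any(s["start"].to_numpy()[1:] < s["end"].to_numpy()[:-1]):
                raise ValueError(f"overlapping regions on {chrom}")


def _region_mean_log2(seg: pd.DataFrame, chrom, start: int, end: int) -> tuple[float, int]:
    """Length-weighted mean log2 over the covered part of [start, end)."""
    on = seg[seg["chrom"] == chrom]
    s = np.maximum(on["start"].to_numpy(), start)
    e = np.minimum(on["end"].to_numpy(), end)
    w = np.clip(e - s, 0, None)
    covered = int(w.sum())
    if covered == 0:
        return 0.0, 0
    return float((on["log2"].to_numpy() * w).sum() / covered), covered


def call_regions(
    segs: SegmentSet,
    regions: pd.DataFrame,
    amp_cut: float = 1.0,
    del_cut: float = -1.0,
    shallow_cut: float = 0.3,
) -> RegionCallMatrix:
    """Summarize segments into per-region discrete calls.

    The region value is the length-weighted mean log2 ratio of overlapping
    segments; >= amp_cut gives +2, <= del_cut gives -2, then |value| >=
    shallow_cut gives a single-copy call, else 0.  A region with no covering
    segment is called 0 with a coverage warning.
    """
    if amp_cut <= 0 or del_cut >= 0 or shallow_cut <= 0:
        raise ValueError("cuts must satisfy amp_cut > 0 > del_cut, shallow_cut > 0")
    samples = segs.samples
    out = np.zeros((len(regions), len(samples)), dtype=int)
    uncovered: list[str] = []
    by_sample = dict(tuple(segs.segments.groupby("sample", sort=False)))
    for j, sample in enumerate(samples):
        seg = by_sample[sample]
        for i, region in enumerate(regions.itertuples(index=False)):
            mean, covered = _region_mean_log2(seg, region.chrom, region.start, region.end)
            if covered == 0:
                uncovered.append(f"{sample}:{region.label}")
                continue
            if mean >= amp_cut:
                out[i, j] = 2
            elif mean <= del_cut:
                out[i, j] = -2
            elif mean >= shallow_cut:
                out[i, j] = 1
            elif mean <= -shallow_cut:
                out[i, j] = -1
    if uncovered:
        warnings.warn(
            f"{len(uncovered)} region/sample pairs had no segment coverage "
            f"(called 0), e.g. {uncovered[:3]}",
            stacklevel=2,
        )
    calls = pd.DataFrame(out, index=list(regions["label"]), columns=samples)
    return RegionCallMatrix(
        regions=regions.reset_index(drop=True),
        calls=calls,
        thresholds={"amp_cut": amp_cut, "del_cut": del_cut, "shallow_cut": shallow_cut},
    )


def fraction_genome_altered(
    segs: SegmentSet, amp_cut: float = 1.0, del_cut: float = -1.0
) -> pd.Series:
    """Per-sample proportion of the covered genome in deeply altered segments.

    "Altered" means segment mean log2 >= amp_cut (2+ fold amplification at
    the default) or <= del_cut (deep/homozygous deletion proxy).  The
    denominator is the total segment-covered length of that sample.
    """
    out = {}
    for sample, seg in segs.segments.groupby("sample", sort=False):
        lengths = (seg["end"] - seg["start"]).to_numpy(dtype=float)
        total = lengths.sum()
        if total <= 0:
            raise ValueError(f"sample {sample} has zero covered genome length")
        log2 = seg["log2"].to_numpy()
        altered = lengths[(log2 >= amp_cut) | (log2 <= del_cut)].sum()
        out[sample] = altered / total
    return pd.Series(out, name="fraction_genome_altered")


class RegionFrequencyComparison:
    """Per-region alteration-frequency comparison between two groups.

    Parameters
    ----------
    calls : RegionCallMatrix
    groups : mapping or Series
        Group label per sample (exactly two distinct labels).
    deep_only : bool
        If True (default) "altered" means a call in {-2, +2}; otherwise any
        non-zero call counts.
    """

    def __init__(self, calls: RegionCallMatrix, groups, deep_only: bool = True):
        groups = pd.Series(groups)
        missing = calls.calls.columns.difference(groups.index)
        if len(missing):
            raise ValueError(f"samples without a group label: {list(missing)[:5]}")
        groups = groups.loc[calls.calls.columns]
        levels = sorted(pd.unique(groups))
        if len(levels) != 2:
            raise ValueError(f"exactly two groups required, got {levels}")
        self.calls = calls
        self.groups = groups
        self.levels = levels
        self.deep_only = deep_only

    def fit(self) -> "RegionFrequencyResults":
        g1 = self.groups == self.levels[0]
        g2 = ~g1
        mat = self.calls.calls.to_numpy()
        altered = np.isin(mat, (-2, 2)) if self.deep_only else mat != 0
        a1 = altered[:, g1.to_numpy()]
        a2 = altered[:, g2.to_numpy()]
        n1, n2 = a1.shape[1], a2.shape[1]
        rows = []
        for i, label in enumerate(self.calls.calls.index):
            k1, k2 = int(a1[i].sum()), int(a2[i].sum())
            if k1 + k2 == 0:
                p, flag = 1.0, "never_altered"
            else:
                p = fisher_exact([[k1, n1 - k1], [k2, n2 - k2]])
                flag = ""
            rows.append((label, k1 / n1, k2 / n2, p, flag))
        table = pd.DataFrame(
            rows,
            columns=["region", f"freq_{self.levels[0]}", f"freq_{self.levels[1]}", "p", "flag"],
        ).set_index("region")
        table["q"] = bh_adjust(table["p"].to_numpy())
        return RegionFrequencyResults(table, self.levels, (n1, n2), self.deep_only)


class RegionFrequencyResults:
    def __init__(self, table: pd.DataFrame, levels, group_sizes, deep_only: bool):
        self.table = table
        self.levels = levels
        self.group_sizes = group_sizes
        self.deep_only = deep_only

    def n_significant(self, fdr: float = 0.10) -> int:
        """Number of regions with BH q strictly below ``fdr``."""
        if not 0 < fdr <= 1:
            raise ValueError("fdr must lie in (0, 1]")
        return int((self.table["q"].to_numpy() < fdr).sum())

    def summary(self) -> str:
        n_sig = self.n_significant()
        lines = [
            "Region-level copy-number frequency comparison",
            f"  groups: {self.levels[0]} (n={self.group_sizes[0]}) vs "
            f"{self.levels[1]} (n={self.group_sizes[1]})",
            f"  regions tested: {len(self.table)}"
            f" ({'deep (+/-2) calls' if self.deep_only else 'any non-zero call'})",
            f"  regions with raw p < 0.05: {int((self.table['p'] < 0.05).sum())}",
            f"  regions significant at BH FDR 10%: {n_sig}",
        ]
        return "\n".join(lines)
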