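"""File formats: expression/annotation TSV, SEG segments, region tables,
gene lists, YAML run configuration.

Conventions
-----------
* Expression TSV: genes as rows, first column the gene id, header row of
  sample ids.  State is inferred (all-integer values => raw counts) unless
  given explicitly.
* SEG files are 1-based inclusive on disk (the de facto standard) and
  converted to 0-based half-open internally; writers convert back.
* Region tables are BED-like TSV (chrom, start, end, label), 0-based
  half-open on disk and in memory.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .matrix import ExpressionMatrix
from .scna import RegionCallMatrix, SegmentSet

__all__ = [
    "read_expression",
    "write_expression",
    "read_annotations",
    "write_annotations",
    "read_gene_list",
    "write_gene_list",
    "read_seg",
    "write_seg",
    "read_regions",
    "write_regions",
    "read_region_calls",
    "write_region_calls",
    "RunConfig",
    "load_config",
    "save_config",
]


def _check_header(path: Path) -> list[str]:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    names = header[1:]
    dupes = pd.Index(names)[pd.Index(names).duplicated()].unique().tolist()
    if dupes:
        raise ValueError(f"duplicate sample ids in {path}: {dupes[:5]}")
    return names


def read_expression(path, state: str | None = None) -> ExpressionMatrix:
    """Read an expression TSV.

    Distinct failures raise distinct messages: ragged rows / missing values,
    duplicate gene or sample ids, negative counts.  ``state`` overrides the
    integer-based inference.
    """
    path = Path(path)
    _check_header(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.isna().to_numpy().any():
        raise ValueError(f"ragged rows or missing values in {path}")
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene ids in {path}: {dupes[:5]}")
    arr = df.to_numpy(dtype=float)
    if state is None:
        is_int = bool(np.allclose(arr, np.round(arr))) and bool(np.all(arr >= 0))
        state = "raw_counts" if is_int else "log_normalized"
    if state == "raw_counts" and np.any(arr < 0):
        raise ValueError(f"negative counts in raw-count matrix {path}")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return ExpressionMatrix(df, state=state)  # type: ignore[arg-type]


def write_expression(m: ExpressionMatrix, path) -> None:
    vals = m.values
    if m.state == "raw_counts":
        vals = vals.astype(np.int64)
    vals.to_csv(path, sep="\t", index_label="gene")


def read_annotations(path) -> pd.DataFrame:
    """Sample annotation TSV: first column sample_id, remaining columns
    free-form (group, subtype, tissue, origin...)."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample ids in {path}: {dupes[:5]}")
    return df


def write_annotations(ann: pd.DataFrame, path) -> None:
    ann.to_csv(path, sep="\t", index_label="sample_id")


def read_gene_list(path) -> list[str]:
    genes = [line.strip() for line in open(path) if line.strip()]
    if len(set(genes)) != len(genes):
        raise ValueError(f"duplicate ids in gene list {path}")
    return genes


def write_gene_list(genes, path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in genes))


SEG_COLUMNS = ["sample", "chrom", "start", "end", "num_probes", "seg_mean"]


def read_seg(path) -> SegmentSet:
    """Read a SEG file (sample, chromosome, start, end, [num_probes],
    seg_mean; 1-based inclusive) into internal 0-based half-open segments."""
    df = pd.read_csv(path, sep="\t")
    ncol = df.shape[1]
    if ncol == 5:
        df.columns = ["sample", "chrom", "start", "end", "seg_mean"]
    elif ncol >= 6:
        df = df.iloc[:, :6]
        df.columns = SEG_COLUMNS
    else:
        raise ValueError(f"SEG file needs 5 or 6 columns, got {ncol} in {path}")
    seg = pd.DataFrame(
        {
            "sample": df["sample"].astype(str),
            "chrom": df["chrom"].astype(str),
            "start": df["start"].astype(np.int64) - 1,  # 1-based incl -> 0-based half-open
            "end": df["end"].astype(np.int64),
            "log2": df["seg_mean"].astype(float),
        }
    )
    return SegmentSet(seg)


def write_seg(segs: SegmentSet, path) -> None:
    out = segs.segments.copy()
    out = pd.DataFrame(
        {
            "sample": out["sample"],
            "chrom": out["chrom"],
            "start": out["start"].astype(np.int64) + 1,  # back to 1-based inclusive
            "end": out["end"].astype(np.int64),
            "num_probes": 0,
            "seg_mean": out["log2"],
        }
    )
    out.to_csv(path, sep="\t", index=False)


def read_regions(path) -> pd.DataFrame:
    """BED-like region TSV: chrom, start, end, label (0-based half-open)."""
    df = pd.read_csv(path, sep="\t")
    required = ["chrom", "start", "end", "label"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"region table {path} missing columns: {missing}")
    return df[required].astype({"start": np.int64, "end": np.int64})


def write_regions(regions: pd.DataFrame, path) -> None:
    regions[["chrom", "start", "end", "label"]].to_csv(path, sep="\t", index=False)


def read_region_calls(path) -> RegionCallMatrix:
    """Region-call TSV: chrom, start, end, label, then one column per sample."""
    df = pd.read_csv(path, sep="\t")
    meta = ["chrom", "start", "end", "label"]
    missing = [c for c in meta if c not in df.columns]
    if missing:
        raise ValueError(f"region-call table {path} missing columns: {missing}")
    regions = df[meta].astype({"start": np.int64, "end": np.int64})
    calls = df.drop(columns=meta)
    calls.index = list(regions["label"])
    return RegionCallMatrix(regions=regions, calls=calls.astype(int))


def write_region_calls(calls: RegionCallMatrix, path) -> None:
    out = calls.regions.copy().reset_index(drop=True)
    out = pd.concat([out, calls.calls.reset_index(drop=True)], axis=1)
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """End-to-end run configuration (YAML section names match fields).

    ``synthetic`` holds keyword overrides for the generators (sections
    ``cohort``, ``normals``, ``mirna``, ``scna``, ``origin``); stage
    parameters default to the study's choices: correlation floor 0.2,
    ambiguity ratio 1.5, top_n 50 markers per tissue, BH FDR 0.10, raw
    p cut 0.01.
    """

    outdir: str = "results"
    seed: int = 17
    synthetic: dict = field(default_factory=dict)
    paths: dict = field(default_factory=dict)
    floor: float = 0.2
    ratio: float = 1.5
    top_n: int = 50
    fdr: float = 0.10
    raw_p: float = 0.01
    k_variable: int = 1500
    power: dict = field(default_factory=dict)

    def validate(self) -> None:
        if not -1 < self.floor < 1 or self.ratio < 1:
            raise ValueError("floor must lie in (-1, 1) and ratio >= 1")
        if not 0 < self.fdr <= 1 or not 0 < self.raw_p <= 1:
            raise ValueError("fdr and raw_p must lie in (0, 1]")
        if self.top_n < 1 or self.k_variable < 1:
            raise ValueError("top_n and k_variable must be >= 1")
        for key, path in self.paths.items():
            if not Path(path).exists():
                raise FileNotFoundError(f"configured path {key!r} does not exist: {path}")


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = RunConfig(**raw)
    cfg.validate()
    return cfg


def save_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(cfg), fh, sort_keys=False)
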