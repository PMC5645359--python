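"""Synthetic cohorts with the statistical structure of the STIC study.

Generates every input the analysis consumes:

* a tumor mRNA cohort — two clinical groups (STIC / NOSTIC, 48 + 47 samples
  by default), four latent expression subtypes, negative-binomial counts on a
  log-normal mean field, an optional true group effect on a chosen set of
  genes (zero under the null, which is the study's design point);
* normal-tissue pools for fallopian tube (FT), ovarian surface epithelium
  (OSE) and peritoneum (PER), where FT carries an order of magnitude more
  tissue-specific marker genes than the two mesothelial tissues and OSE/PER
  share an extra correlated profile component;
* tumors drawn from tissue prototypes (the harness for origin matching);
* a low-abundance miRNA-like panel;
* region-level copy-number calls with focal events shared across groups.

Counts are negative binomial with mean ``libsize_j * 2**(mu_g + effects)``;
effects are additive shifts on the log2 mean, expressed in units of the
within-group biological standard deviation (``bio_sd``).  Library sizes are
log-normal (sd 0.3) so size-factor normalization is exercised non-trivially.
All generators are bit-reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix
from .scna import RegionCallMatrix, SegmentSet

__all__ = [
    "CohortConfig",
    "NormalPoolConfig",
    "MirnaConfig",
    "ScnaConfig",
    "SimulatedCohort",
    "generate_tumor_expression",
    "generate_normal_pools",
    "generate_tumors_from_tissue",
    "generate_mirna_counts",
    "generate_copy_number",
    "segments_from_calls",
    "TISSUES",
]

TISSUES = ("FT", "OSE", "PER")
_TISSUE_ALIASES = {"OV": "OSE"}

DEFAULT_SEED = 17


def canonical_tissue(name: str) -> str:
    t = _TISSUE_ALIASES.get(name, name)
    if t not in TISSUES:
        raise ValueError(f"unknown tissue {name!r}; expected one of {TISSUES} (or OV)")
    return t


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial draws parameterized by mean and dispersion.

    dispersion = 1/size; var = mean + dispersion * mean^2.  dispersion -> 0
    degenerates to Poisson.
    """
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    if dispersion == 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    # gamma-Poisson mixture keeps the mean exact for array-valued means
    lam = rng.gamma(shape=size, scale=mean / size)
    return rng.poisson(lam)


# ---------------------------------------------------------------------------
# tumor mRNA cohort
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortConfig:
    """Design of the synthetic tumor cohort.

    ``n_de_genes`` is 0 by default: the study's null, no true STIC effect.
    ``de_effect_sd`` and ``subtype_sep`` are in units of ``bio_sd`` (the
    within-subtype biological log2 standard deviation).
    """

    n_stic: int = 48
    n_nostic: int = 47
    n_genes: int = 20_000
    n_subtypes: int = 4
    subtype_sep: float = 3.0
    subtype_block_size: int = 100
    n_de_genes: int = 0
    de_effect_sd: float = 0.0
    bio_sd: float = 1.0
    baseline_log2_mean: float = 6.0
    baseline_log2_sd: float = 1.5
    nb_dispersion: float = 0.05
    libsize_log_sd: float = 0.3
    seed: int = DEFAULT_SEED

    def validate(self) -> None:
        for name in ("n_stic", "n_nostic", "n_genes", "n_subtypes", "subtype_block_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_de_genes < 0 or self.n_de_genes > self.n_genes:
            raise ValueError("n_de_genes must lie in [0, n_genes]")
        if self.de_effect_sd < 0:
            raise ValueError("de_effect_sd must be >= 0")
        if self.bio_sd < 0 or self.nb_dispersion < 0 or self.libsize_log_sd < 0:
            raise ValueError("scale parameters must be >= 0")
        if self.n_subtypes * self.subtype_block_size > self.n_genes:
            raise ValueError("subtype blocks exceed the gene count")


@dataclass
class SimulatedCohort:
    """A generated cohort plus its ground truth."""

    matrix: ExpressionMatrix
    de_genes: list[str]
    signature_genes: list[str]
    prototypes_log2: pd.DataFrame  # genes × subtypes, noise-free log2 means

    @property
    def groups(self) -> pd.Series:
        return self.matrix.annotation("group")

    @property
    def subtypes(self) -> pd.Series:
        return self.matrix.annotation("subtype")


def generate_tumor_expression(config: CohortConfig) -> SimulatedCohort:
    """Draw a STIC/NOSTIC tumor cohort with latent expression subtypes.

    Each sample's latent subtype is uniform over the subtypes; subtype
    prototypes shift disjoint ``subtype_block_size``-gene blocks by
    ``subtype_sep * bio_sd`` on the log2 scale.  When ``n_de_genes`` > 0,
    that many genes (drawn outside the subtype blocks) are shifted by
    ``de_effect_sd * bio_sd`` in the STIC group.  Group labels are assigned
    independently of expression, so n_de_genes = 0 is an exact global null.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_stic + config.n_nostic
    genes = pd.Index([f"g{i:05d}" for i in range(config.n_genes)], name="gene")
    samples = pd.Index([f"T{i:03d}" for i in range(n)], name="sample")

    mu = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, config.n_genes)
    subtype_of = rng.integers(0, config.n_subtypes, size=n)
    group = np.array(["STIC"] * config.n_stic + ["NOSTIC"] * config.n_nostic)

    # subtype prototype shifts on disjoint gene blocks
    proto = np.tile(mu[:, None], (1, config.n_subtypes))
    block = config.subtype_block_size
    signature: list[str] = []
    for k in range(config.n_subtypes):
        idx = np.arange(k * block, (k + 1) * block)
        proto[idx, k] += config.subtype_sep * config.bio_sd
        signature.extend(genes[idx])

    # genes carrying a true STIC effect, outside the subtype blocks
    non_block = np.arange(config.n_subtypes * block, config.n_genes)
    if config.n_de_genes > len(non_block):
        raise ValueError("n_de_genes exceeds the genes available outside subtype blocks")
    de_idx = rng.choice(non_block, size=config.n_de_genes, replace=False)
    de_idx.sort()

    log_mean = proto[:, subtype_of]  # genes × samples
    log_mean = log_mean + rng.normal(0.0, config.bio_sd, size=(config.n_genes, n))
    if config.n_de_genes:
        shift = config.de_effect_sd * config.bio_sd
        log_mean[np.ix_(de_idx, group == "STIC")] += shift

    libsize = np.exp(rng.normal(0.0, config.libsize_log_sd, size=n))
    mean = libsize[None, :] * np.exp2(log_mean)
    counts = _nb_counts(rng, mean, config.nb_dispersion)

    ann = pd.DataFrame(
        {"group": group, "subtype": [f"S{k + 1}" for k in subtype_of]}, index=samples
    )
    matrix = ExpressionMatrix(
        pd.DataFrame(counts, index=genes, columns=samples), state="raw_counts", annotations=ann
    )
    return SimulatedCohort(
        matrix=matrix,
        de_genes=list(genes[de_idx]),
        signature_genes=signature,
        prototypes_log2=pd.DataFrame(
            proto, index=genes, columns=[f"S{k + 1}" for k in range(config.n_subtypes)]
        ),
    )


# ---------------------------------------------------------------------------
# normal-tissue pools
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NormalPoolConfig:
    """Normal-tissue pool design.

    The marker-count asymmetry (many FT-specific genes, few OSE/PER ones)
    emulates the epithelial-vs-mesothelial contrast; ``mesothelial_corr`` is
    the log2 s.d. of a profile component shared by OSE and PER only, which
    makes the two mesothelial tissues more alike than either is to FT.
    """

    n_pools_per_tissue: int = 3
    n_genes: int = 10_000
    n_ft_markers: int = 4000
    n_ov_markers: int = 300
    n_per_markers: int = 300
    marker_shift_sd: float = 3.0
    mesothelial_corr: float = 0.5
    cross_contamination: float = 0.1
    pool_sd: float = 0.3
    baseline_log2_mean: float = 6.0
    baseline_log2_sd: float = 1.5
    nb_dispersion: float = 0.02
    libsize_log_sd: float = 0.3
    seed: int = DEFAULT_SEED

    def validate(self) -> None:
        if self.n_pools_per_tissue < 2:
            raise ValueError("need >= 2 pools per tissue (one-vs-rest testing needs replication)")
        if self.n_ft_markers + self.n_ov_markers + self.n_per_markers > self.n_genes:
            raise ValueError("marker sets exceed the gene count")
        for name in ("marker_shift_sd", "mesothelial_corr", "pool_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.cross_contamination < 0.5:
            raise ValueError("cross_contamination must lie in [0, 0.5)")


@dataclass
class SimulatedNormals:
    matrix: ExpressionMatrix  # raw counts, annotation column "tissue"
    marker_genes: dict[str, list[str]]  # true tissue-specific genes
    prototypes_log2: pd.DataFrame  # genes × tissues, noise-free log2 profiles

    @property
    def tissues(self) -> pd.Series:
        return self.matrix.annotation("tissue")


def generate_normal_pools(config: NormalPoolConfig) -> SimulatedNormals:
    """Draw replicate pools for FT, OSE and PER.

    Marker sets are disjoint by construction: the first ``n_ft_markers``
    genes are FT-specific (shifted by ``marker_shift_sd * pool_sd`` — marker
    effects are in units of the between-pool s.d. — with random sign), the
    next blocks are OSE- and PER-specific.  A shared mesothelial component
    is added to the OSE and PER profiles.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes = pd.Index([f"g{i:05d}" for i in range(config.n_genes)], name="gene")
    mu = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, config.n_genes)

    proto = {t: mu.copy() for t in TISSUES}
    bounds = np.cumsum([0, config.n_ft_markers, config.n_ov_markers, config.n_per_markers])
    markers: dict[str, list[str]] = {}
    shift_scale = config.marker_shift_sd * config.pool_sd
    for t, lo, hi in zip(TISSUES, bounds[:-1], bounds[1:]):
        idx = np.arange(lo, hi)
        signs = rng.choice([-1.0, 1.0], size=idx.size)
        proto[t][idx] += signs * shift_scale
        markers[t] = list(genes[idx])
    meso = rng.normal(0.0, config.mesothelial_corr, config.n_genes)
    proto["OSE"] = proto["OSE"] + meso
    proto["PER"] = proto["PER"] + meso
    # epithelial brushings carry a small admixture of the neighbouring
    # tissue (FT <-> ovarian surface); mix on the linear scale
    c = config.cross_contamination
    if c > 0:
        ft_pure, ose_pure = proto["FT"], proto["OSE"]
        proto["FT"] = np.log2((1 - c) * np.exp2(ft_pure) + c * np.exp2(ose_pure))
        proto["OSE"] = np.log2((1 - c) * np.exp2(ose_pure) + c * np.exp2(ft_pure))

    cols, tissues, profiles = [], [], []
    for t in TISSUES:
        for r in range(config.n_pools_per_tissue):
            cols.append(f"{t}_pool{r + 1}")
            tissues.append(t)
            profiles.append(proto[t] + rng.normal(0.0, config.pool_sd, config.n_genes))
    log_mean = np.column_stack(profiles)
    libsize = np.exp(rng.normal(0.0, config.libsize_log_sd, size=len(cols)))
    counts = _nb_counts(rng, libsize[None, :] * np.exp2(log_mean), config.nb_dispersion)

    samples = pd.Index(cols, name="sample")
    ann = pd.DataFrame({"tissue": tissues}, index=samples)
    matrix = ExpressionMatrix(
        pd.DataFrame(counts, index=genes, columns=samples), state="raw_counts", annotations=ann
    )
    return SimulatedNormals(
        matrix=matrix,
        marker_genes=markers,
        prototypes_log2=pd.DataFrame(proto, index=genes)[list(TISSUES)],
    )


def generate_tumors_from_tissue(
    prototypes_log2: pd.DataFrame,
    origin_mix: Mapping[str, float],
    n_tumors: int = 85,
    noise_sd: float = 0.5,
    seed: int = DEFAULT_SEED,
) -> ExpressionMatrix:
    """Tumors as noisy copies of normal-tissue prototypes (log2 scale).

    Each tumor's origin is drawn from ``origin_mix`` (probabilities over the
    tissues, summing to 1; "OV" is accepted as an alias for OSE); its profile
    is the origin prototype plus N(0, noise_sd) per gene.  The true origin is
    recorded in the ``origin`` annotation.  Output state is log_normalized.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if n_tumors < 1:
        raise ValueError("n_tumors must be >= 1")
    mix = {canonical_tissue(k): float(v) for k, v in origin_mix.items()}
    if abs(sum(mix.values()) - 1.0) > 1e-9 or any(v < 0 for v in mix.values()):
        raise ValueError("origin_mix must be non-negative and sum to 1")
    tissues = [t for t in TISSUES if t in mix]
    probs = np.array([mix[t] for t in tissues])
    rng = np.random.default_rng(seed)
    origins = rng.choice(tissues, size=n_tumors, p=probs)
    base = prototypes_log2[[c for c in prototypes_log2.columns]]
    vals = np.column_stack(
        [
            base[canonical_tissue(o)].to_numpy() + rng.normal(0.0, noise_sd, base.shape[0])
            for o in origins
        ]
    )
    samples = pd.Index([f"T{i:03d}" for i in range(n_tumors)], name="sample")
    ann = pd.DataFrame({"origin": origins}, index=samples)
    return ExpressionMatrix(
        pd.DataFrame(vals, index=base.index, columns=samples),
        state="log_normalized",
        annotations=ann,
    )


# ---------------------------------------------------------------------------
# miRNA-like low-abundance counts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MirnaConfig:
    """Low-abundance miRNA-like panel; true DE features (default 24, as a
    small set) sit in the low-abundance tail."""

    n_mirnas: int = 800
    n_stic: int = 48
    n_nostic: int = 47
    n_de: int = 24
    de_effect_sd: float = 1.5
    bio_sd: float = 1.0
    baseline_log2_mean: float = 1.5
    baseline_log2_sd: float = 1.5
    low_abundance_threshold: float = 50.0
    nb_dispersion: float = 0.3
    libsize_log_sd: float = 0.3
    seed: int = DEFAULT_SEED

    def validate(self) -> None:
        if min(self.n_mirnas, self.n_stic, self.n_nostic) <= 0:
            raise ValueError("counts must be positive")
        if not 0 <= self.n_de <= self.n_mirnas:
            raise ValueError("n_de must lie in [0, n_mirnas]")
        if min(self.de_effect_sd, self.bio_sd, self.nb_dispersion) < 0:
            raise ValueError("scale parameters must be >= 0")


def generate_mirna_counts(config: MirnaConfig) -> SimulatedCohort:
    """Draw a miRNA-like count panel with DE features in the low tail.

    The baseline log2 mean field is centred low so most features have small
    mean counts; the ``n_de`` true-effect features are drawn from features
    whose baseline mean is below the field median.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_stic + config.n_nostic
    genes = pd.Index([f"mir{i:04d}" for i in range(config.n_mirnas)], name="gene")
    samples = pd.Index([f"T{i:03d}" for i in range(n)], name="sample")
    mu = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, config.n_mirnas)
    group = np.array(["STIC"] * config.n_stic + ["NOSTIC"] * config.n_nostic)

    low = np.where(mu < np.median(mu))[0]
    de_idx = rng.choice(low, size=config.n_de, replace=False) if config.n_de else np.array([], int)
    de_idx.sort()

    log_mean = mu[:, None] + rng.normal(0.0, config.bio_sd, size=(config.n_mirnas, n))
    if config.n_de:
        log_mean[np.ix_(de_idx, group == "STIC")] += config.de_effect_sd * config.bio_sd
    libsize = np.exp(rng.normal(0.0, config.libsize_log_sd, size=n))
    counts = _nb_counts(rng, libsize[None, :] * np.exp2(log_mean), config.nb_dispersion)

    ann = pd.DataFrame({"group": group}, index=samples)
    matrix = ExpressionMatrix(
        pd.DataFrame(counts, index=genes, columns=samples), state="raw_counts", annotations=ann
    )
    return SimulatedCohort(
        matrix=matrix,
        de_genes=list(genes[de_idx]),
        signature_genes=[],
        prototypes_log2=pd.DataFrame(index=genes),
    )


# ---------------------------------------------------------------------------
# region-level copy number
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScnaConfig:
    """Focal copy-number region calls shared across groups.

    Each region is an amplification or deletion region (random sign); a
    sample carries the deep event (call ±2) with probability
    ``baseline_alteration_freq`` (+ ``group_delta`` in the STIC group, 0
    under the null).  ``shallow_freq`` adds independent single-copy (±1)
    events and defaults to 0 so a zero baseline yields an all-zero matrix.
    """

    n_regions: int = 82
    region_length: int = 1_000_000
    n_stic: int = 48
    n_nostic: int = 48
    baseline_alteration_freq: float = 0.2
    group_delta: float = 0.0
    shallow_freq: float = 0.0
    seed: int = DEFAULT_SEED

    def validate(self) -> None:
        if min(self.n_regions, self.region_length, self.n_stic, self.n_nostic) <= 0:
            raise ValueError("counts and lengths must be positive")
        if not 0 <= self.baseline_alteration_freq <= 1:
            raise ValueError("baseline_alteration_freq must lie in [0, 1]")
        if not 0 <= self.shallow_freq <= 1:
            raise ValueError("shallow_freq must lie in [0, 1]")
        f = self.baseline_alteration_freq + self.group_delta
        if not 0 <= f <= 1:
            raise ValueError("group_delta pushes the STIC frequency outside [0, 1]")


@dataclass
class SimulatedScna:
    calls: RegionCallMatrix
    groups: pd.Series


def generate_copy_number(config: ScnaConfig) -> SimulatedScna:
    """Draw region-level calls for two groups on a toy genome (one region
    per megabase on chromosome "chr1", separated by unaltered gaps)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_stic + config.n_nostic
    samples = pd.Index(
        [f"T{i:03d}" for i in range(n)], name="sample"
    )
    group = pd.Series(
        ["STIC"] * config.n_stic + ["NOSTIC"] * config.n_nostic, index=samples, name="group"
    )
    gap = config.region_length
    starts = np.arange(config.n_regions) * (config.region_length + gap)
    regions = pd.DataFrame(
        {
            "chrom": "chr1",
            "start": starts,
            "end": starts + config.region_length,
            "label": [f"R{i + 1:02d}" for i in range(config.n_regions)],
        }
    )
    sign = rng.choice([-2, 2], size=config.n_regions)
    p = np.full((config.n_regions, n), config.baseline_alteration_freq)
    p[:, (group == "STIC").to_numpy()] += config.group_delta
    deep = rng.random((config.n_regions, n)) < p
    calls = deep * sign[:, None]
    if config.shallow_freq > 0:
        shallow = (~deep) & (rng.random((config.n_regions, n)) < config.shallow_freq)
        calls = calls + shallow * np.where(sign > 0, 1, -1)[:, None]
    call_df = pd.DataFrame(calls.astype(int), index=list(regions["label"]), columns=samples)
    return SimulatedScna(
        calls=RegionCallMatrix(regions=regions, calls=call_df),
        groups=group,
    )


_CALL_TO_LOG2 = {-2: -1.5, -1: -0.5, 0: 0.0, 1: 0.5, 2: 1.5}


def segments_from_calls(calls: RegionCallMatrix, genome_end: int | None = None) -> SegmentSet:
    """Render a call matrix as per-sample segments (for SEG output and for
    round-trip testing of region calling).  Region segments get a log2 ratio
    representative of their call; gaps between regions are emitted as
    neutral (log2 = 0) segments."""
    rows = []
    regions = calls.regions.sort_values(["chrom", "start"])
    for sample in calls.calls.columns:
        prev_end = 0
        for region in regions.itertuples(index=False):
            if region.start > prev_end:
                rows.append((sample, region.chrom, prev_end, region.start, 0.0))
            call = int(calls.calls.loc[region.label, sample])
            rows.append((sample, region.chrom, region.start, region.end, _CALL_TO_LOG2[call]))
            prev_end = region.end
        if genome_end is not None and genome_end > prev_end:
            rows.append((sample, regions.iloc[0]["chrom"], prev_end, genome_end, 0.0))
    return SegmentSet(pd.DataFrame(rows, columns=["sample", "chrom", "start", "end", "log2"]))
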