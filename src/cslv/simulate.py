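"""Synthetic SNP-array cohorts with known copy-number ground truth.

The generator emulates, at desk scale, the structure of a genotyping
array intensity dataset: per-marker log R ratios over 22 autosomes, a
per-sample baseline shift (array-level intensity wobble), independent
per-marker Gaussian noise, background CNV events scattered across the
genome, and designated *effect regions* where CNV carriage probability
differs between cases and controls (and optionally between population
groups). Cases and controls therefore differ only through the effect
regions; everything else is exchangeable, which is what makes the
simulator usable as a null model and as a ground-truth signal-recovery
harness.

Randomness is hierarchical: one global seed spawns independent
substreams for the manifest, the sample table, CNV events and marker
noise, so e.g. changing the number of samples never perturbs the
simulated marker panel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import GenomeBuild, default_build
from .io import MarkerManifest
from .features import SegmentMap

__all__ = [
    "EffectRegion",
    "GroupSpec",
    "AgeModel",
    "SimulationConfig",
    "GroundTruth",
    "simulate_cohort",
    "effect_segment_index",
]


@dataclass(frozen=True)
class EffectRegion:
    """A genomic interval whose CNV carriage differs by class.

    A sample carrying the event has ``lrr_shift`` added to every marker
    in ``[start, end)``; carriage is Bernoulli with ``case_probability``
    or ``control_probability`` depending on the sample's label.
    """

    chromosome: str
    start: int
    end: int
    case_probability: float
    control_probability: float
    lrr_shift: float


@dataclass(frozen=True)
class GroupSpec:
    """A self-identified population group and its share of the cohort.

    ``effect_regions=None`` means the group uses the config's global
    effect regions; a list (possibly empty) overrides them, which is how
    group-specific risk architecture — and hence model-transfer
    asymmetry — is simulated.
    """

    name: str
    proportion: float
    effect_regions: tuple[EffectRegion, ...] | None = None


@dataclass(frozen=True)
class AgeModel:
    """Gaussian age distributions per label, truncated below."""

    case_mean: float = 62.0
    case_sd: float = 10.0
    control_mean: float = 55.0
    control_sd: float = 12.0
    minimum: float = 18.0


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_cases: int = 400
    n_controls: int = 1000
    markers_per_chrom: int = 500
    sigma_marker: float = 0.15
    sigma_sample: float = 0.02
    background_cnv_rate: float = 2.0
    cnv_length_bp: float = 5e6
    deletion_shift: float = -0.5
    duplication_shift: float = 0.3
    effect_regions: tuple[EffectRegion, ...] = ()
    groups: tuple[GroupSpec, ...] = (GroupSpec("unknown", 1.0),)
    age_model: AgeModel = field(default_factory=AgeModel)
    build: GenomeBuild = field(default_factory=default_build)

    def __post_init__(self) -> None:
        if self.n_cases + self.n_controls < 1:
            raise ValueError("need at least one sample")
        if self.markers_per_chrom < 1:
            raise ValueError("need at least one marker per chromosome")
        if self.sigma_marker < 0 or self.sigma_sample < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if self.background_cnv_rate < 0:
            raise ValueError("background CNV rate must be >= 0")
        props = [g.proportion for g in self.groups]
        if any(p < 0 for p in props) or abs(sum(props) - 1.0) > 1e-9:
            raise ValueError("group proportions must be non-negative and sum to 1")
        for region in self._all_regions():
            self._check_region(region)

    def _all_regions(self) -> list[EffectRegion]:
        regions = list(self.effect_regions)
        for g in self.groups:
            if g.effect_regions is not None:
                regions.extend(g.effect_regions)
        return regions

    def _check_region(self, region: EffectRegion) -> None:
        if region.chromosome not in self.build:
            raise ValueError(f"effect region on unknown chromosome {region.chromosome!r}")
        length = self.build.length(region.chromosome)
        if not (1 <= region.start < region.end <= length + 1):
            raise ValueError(
                f"effect region [{region.start}, {region.end}) outside "
                f"chromosome {region.chromosome} (length {length})"
            )
        for p in (region.case_probability, region.control_probability):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"carriage probability {p} outside [0, 1]")


@dataclass(frozen=True)
class GroundTruth:
    """What the simulator actually planted.

    ``events``: one row per placed CNV (sample_id, chromosome, start,
    end, shift, source ∈ {background, effect}).  ``samples``: the
    cohort table plus each sample's baseline intensity shift.
    """

    events: pd.DataFrame
    samples: pd.DataFrame


def _simulate_manifest(config: SimulationConfig, rng: np.random.Generator) -> MarkerManifest:
    rows = []
    for chrom in config.build.names:
        length = config.build.length(chrom)
        m = min(config.markers_per_chrom, length)
        positions: np.ndarray = np.unique(rng.integers(1, length + 1, size=m))
        while positions.size < m:  # collisions are vanishingly rare at array density
            extra = rng.integers(1, length + 1, size=m - positions.size)
            positions = np.unique(np.concatenate([positions, extra]))
        for j, pos in enumerate(np.sort(positions)):
            rows.append((f"mk_{chrom}_{j + 1:05d}", chrom, int(pos)))
    table = pd.DataFrame(rows, columns=["marker_id", "chromosome", "position"])
    return MarkerManifest(table=table, build=config.build)


def _simulate_samples(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_cases + config.n_controls
    labels = np.concatenate([np.ones(config.n_cases, int), np.zeros(config.n_controls, int)])
    rng.shuffle(labels)
    ids = np.array([f"S{i + 1:06d}" for i in range(n)])
    props = np.array([g.proportion for g in config.groups])
    groups = rng.choice([g.name for g in config.groups], size=n, p=props / props.sum())
    am = config.age_model
    means = np.where(labels == 1, am.case_mean, am.control_mean)
    sds = np.where(labels == 1, am.case_sd, am.control_sd)
    ages = np.maximum(rng.normal(means, sds), am.minimum).round(1)
    baselines = rng.normal(0.0, config.sigma_sample, size=n)
    return pd.DataFrame(
        {"sample_id": ids, "label": labels, "age": ages, "group": groups,
         "baseline": baselines}
    )


def _regions_for_group(config: SimulationConfig, group: str) -> tuple[EffectRegion, ...]:
    for g in config.groups:
        if g.name == group and g.effect_regions is not None:
            return tuple(g.effect_regions)
    return tuple(config.effect_regions)


def _simulate_events(
    config: SimulationConfig, samples: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    build = config.build
    names = build.names
    lengths = np.array([build.length(c) for c in names], dtype=float)
    chrom_probs = lengths / lengths.sum()
    rows = []
    for sample_id, label, group in samples[["sample_id", "label", "group"]].itertuples(
        index=False
    ):
        n_bg = rng.poisson(config.background_cnv_rate)
        for _ in range(n_bg):
            ci = rng.choice(len(names), p=chrom_probs)
            chrom, length = names[ci], int(lengths[ci])
            start = int(rng.integers(1, length + 1))
            span = max(1, int(round(rng.exponential(config.cnv_length_bp))))
            end = min(start + span, length + 1)
            shift = config.deletion_shift if rng.random() < 0.5 else config.duplication_shift
            rows.append((sample_id, chrom, start, end, shift, "background"))
        for region in _regions_for_group(config, group):
            p = region.case_probability if label == 1 else region.control_probability
            if rng.random() < p:
                rows.append(
                    (sample_id, region.chromosome, region.start, region.end,
                     region.lrr_shift, "effect")
                )
    return pd.DataFrame(
        rows, columns=["sample_id", "chromosome", "start", "end", "shift", "source"]
    )


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[MarkerManifest, pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate (manifest, LRR matrix, cohort table, ground truth).

    Marker LRR = sample baseline + sum of shifts of covering CNV events
    + N(0, sigma_marker) noise. Fully reproducible from ``config.seed``.
    """
    streams = np.random.SeedSequence(config.seed).spawn(4)
    rng_manifest, rng_samples, rng_events, rng_noise = map(
        np.random.default_rng, streams
    )

    manifest = _simulate_manifest(config, rng_manifest)
    samples = _simulate_samples(config, rng_samples)
    events = _simulate_events(config, samples, rng_events)

    n = len(samples)
    n_markers = len(manifest)
    values = rng_noise.normal(0.0, config.sigma_marker, size=(n, n_markers))
    values += samples["baseline"].to_numpy()[:, None]

    # per-chromosome column offsets into the manifest-ordered matrix
    chrom_cols: dict[str, tuple[int, np.ndarray]] = {}
    offset = 0
    for chrom, sub in manifest.table.groupby("chromosome", sort=False):
        chrom_cols[chrom] = (offset, sub["position"].to_numpy())
        offset += len(sub)

    row_of = {s: i for i, s in enumerate(samples["sample_id"])}
    for sample_id, chrom, start, end, shift in events[
        ["sample_id", "chromosome", "start", "end", "shift"]
    ].itertuples(index=False):
        off, positions = chrom_cols[chrom]
        lo, hi = np.searchsorted(positions, [start, end])
        if hi > lo:
            values[row_of[sample_id], off + lo : off + hi] += shift

    lrr = pd.DataFrame(
        values, index=samples["sample_id"].to_numpy(), columns=manifest.marker_ids
    )
    cohort = samples[["sample_id", "label", "age", "group"]].copy()
    return manifest, lrr, cohort, GroundTruth(events=events, samples=samples)


def effect_segment_index(config: SimulationConfig, segmap: SegmentMap) -> list[str]:
    """Feature names whose segment overlaps any configured effect region.

    Includes group-specific regions. Deterministic, ordered by segment
    map order.
    """
    regions = config._all_regions()
    for region in regions:
        config._check_region(region)
    hits = []
    for row in segmap.table.itertuples(index=False):
        for region in regions:
            if region.chromosome == row.chromosome and (
                region.start < row.end and row.start < region.end
            ):
                hits.append(row.feature)
                break
    return hits
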