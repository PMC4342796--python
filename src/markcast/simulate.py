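"""Synthetic epigenome studies with developmental-proximity structure.

The generator emulates the data regime of a cross-context enhancer
prediction study: a target tissue/stage with a set of "true" enhancers, a
developmental lineage of contexts whose histone-mark peaks cover true
enhancers with a probability that decays exponentially with developmental
distance from the target, other tissues whose peaks cover their own
enhancers, a fraction of ubiquitously active elements marked everywhere
(the tissue-specificity confound), uniform spurious background peaks, and
a second species whose datasets are degraded copies of the lineage
(unmappable regions dropped, mapped coordinates jittered - a liftOver
stand-in).

The decay model is ``p(d) = p_max * exp(-lam * d)`` with
``d = |stage - target_stage|``: the simplest monotone form consistent with
the qualitative observation that marks from developmentally nearby
contexts are the most informative. Marks are drawn independently per
(context, mark, enhancer), which makes the closed form directly checkable.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .errors import ConfigurationError
from .intervals import Genome, GenomicRegion, RegionSet, parse_bed, write_bed
from .manifest import MARKS, ContextMeta, read_manifest, write_manifest

TARGET_TISSUE = "heart"
NATIVE_SPECIES = "mouse"
CROSS_SPECIES = "human"


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of a synthetic study; defaults give a compact study that
    exercises the full pipeline in minutes on one CPU.

    Units: lengths and widths in bp, ``p_bg`` in expected spurious peaks
    per Mb of genome per dataset, ``stage_coords`` in arbitrary
    developmental-time units shared with ``target_stage``.
    """

    n_chroms: int = 4
    chrom_length: int = 10_000_000
    n_target_enhancers: int = 300
    n_other_enhancers: int = 300
    enhancer_length_range: tuple[int, int] = (500, 3500)
    target_stage: float = 5.0
    stage_coords: tuple[float, ...] = (0.0, 2.0, 4.0, 6.0, 8.0, 10.0)
    tissue_names: tuple[str, ...] = ("liver", "brain", "limb")
    p_max: float = 0.9
    lam: float = 0.35
    p_bg: float = 5.0
    shared_frac: float = 0.2
    unmappable_frac: float = 0.23
    map_jitter_sd: float = 300.0
    peak_width_range: tuple[int, int] = (500, 2000)
    seed: int = 0

    def __post_init__(self) -> None:
        probs = {
            "p_max": self.p_max,
            "shared_frac": self.shared_frac,
            "unmappable_frac": self.unmappable_frac,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name}={p} outside [0, 1]")
        if self.p_max == 0.0:
            raise ConfigurationError("p_max must be in (0, 1]")
        if self.lam < 0 or self.p_bg < 0 or self.map_jitter_sd < 0:
            raise ConfigurationError("lam, p_bg and map_jitter_sd must be >= 0")
        for name, rng_ in (
            ("enhancer_length_range", self.enhancer_length_range),
            ("peak_width_range", self.peak_width_range),
        ):
            lo, hi = rng_
            if lo <= 0 or lo > hi:
                raise ConfigurationError(f"{name}={rng_} must satisfy 0 < min <= max")
        if min(self.n_chroms, self.chrom_length) <= 0:
            raise ConfigurationError("genome dimensions must be positive")
        if min(self.n_target_enhancers, self.n_other_enhancers) < 0:
            raise ConfigurationError("enhancer counts must be >= 0")

    def genome(self) -> Genome:
        return Genome(
            {f"chr{i + 1}": self.chrom_length for i in range(self.n_chroms)}
        )

    def marking_probability(self, stage: float) -> float:
        """Closed-form per-enhancer coverage probability for a lineage stage."""
        return self.p_max * math.exp(-self.lam * abs(stage - self.target_stage))


@dataclass
class SyntheticStudy:
    """A generated study: genome, truth enhancers, peak sets, manifest."""

    genome: Genome
    target_enhancers: RegionSet
    other_enhancers: RegionSet
    peak_sets: dict[str, RegionSet]
    manifest: list[ContextMeta]
    config: SimulationConfig

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SyntheticStudy):
            return NotImplemented
        return (
            dict(self.genome.chrom_sizes) == dict(other.genome.chrom_sizes)
            and self.target_enhancers == other.target_enhancers
            and self.other_enhancers == other.other_enhancers
            and set(self.peak_sets) == set(other.peak_sets)
            and all(self.peak_sets[k] == other.peak_sets[k] for k in self.peak_sets)
            and [_strip_path(m) for m in self.manifest]
            == [_strip_path(m) for m in other.manifest]
            and self.config == other.config
        )

    def meta(self, dataset_id: str) -> ContextMeta:
        for m in self.manifest:
            if m.dataset_id == dataset_id:
                return m
        raise KeyError(dataset_id)

    def heart_dataset_ids(self) -> list[str]:
        return [
            m.dataset_id
            for m in self.manifest
            if m.tissue == TARGET_TISSUE and m.species == NATIVE_SPECIES
        ]

    def validate(self) -> None:
        self.target_enhancers.check_bounds(self.genome)
        self.other_enhancers.check_bounds(self.genome)
        for rs in self.peak_sets.values():
            rs.check_bounds(self.genome)
        for t in self.target_enhancers:
            for o in self.other_enhancers:
                if t.overlap_bp(o) > 0:
                    raise ConfigurationError(
                        f"target enhancer {t} overlaps other enhancer {o}"
                    )


def _strip_path(m: ContextMeta) -> ContextMeta:
    # path differs between an in-memory and a re-imported study; ignore it
    return ContextMeta(m.dataset_id, m.tissue, m.stage_coord, m.species, m.mark)


def _place_enhancers(config: SimulationConfig, rng: np.random.Generator):
    """Uniform non-overlapping placement of target + other enhancers."""
    genome = config.genome()
    n_total = config.n_target_enhancers + config.n_other_enhancers
    lo, hi = config.enhancer_length_range
    if n_total * hi > genome.total_bp:
        raise ConfigurationError(
            f"cannot place {n_total} enhancers of up to {hi} bp "
            f"in a {genome.total_bp} bp genome"
        )
    chroms = genome.chroms
    weights = np.array([genome.chrom_sizes[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}

    def _draw(length: int) -> GenomicRegion:
        for _ in range(10_000):
            chrom = chroms[rng.choice(len(chroms), p=weights)]
            size = genome.chrom_sizes[chrom]
            if size < length:
                continue
            start = int(rng.integers(0, size - length + 1))
            end = start + length
            if all(e <= start or s >= end for s, e in placed[chrom]):
                placed[chrom].append((start, end))
                return GenomicRegion(chrom, start, end)
        raise ConfigurationError(
            "enhancer placement exhausted; genome too crowded"
        )

    lengths = rng.integers(lo, hi + 1, size=n_total)
    target, other = [], []
    for i in range(config.n_target_enhancers):
        r = _draw(int(lengths[i]))
        target.append(
            GenomicRegion(
                r.chrom, r.start, r.end, name=f"heart_e{i:04d}", label=TARGET_TISSUE
            )
        )
    tissues = config.tissue_names
    for j in range(config.n_other_enhancers):
        tissue = tissues[j % len(tissues)] if tissues else "other"
        r = _draw(int(lengths[config.n_target_enhancers + j]))
        other.append(
            GenomicRegion(
                r.chrom, r.start, r.end, name=f"{tissue}_e{j:04d}", label=tissue
            )
        )
    return genome, RegionSet(target, "target_enhancers"), RegionSet(
        other, "other_enhancers"
    )


def _peak_over(
    enh: GenomicRegion, genome: Genome, config: SimulationConfig,
    rng: np.random.Generator,
) -> GenomicRegion:
    """A peak overlapping ``enh`` by >=1 bp: random width, uniform offset."""
    wlo, whi = config.peak_width_range
    w = int(rng.integers(wlo, whi + 1))
    size = genome.chrom_sizes[enh.chrom]
    lo = max(0, enh.start - w + 1)
    hi = min(enh.end - 1, size - w)
    if hi < lo:  # enhancer wider than chromosome margin permits; pin
        hi = lo
    start = int(rng.integers(lo, hi + 1))
    return GenomicRegion(enh.chrom, start, min(start + w, size))


def _background_peaks(
    genome: Genome, config: SimulationConfig, rng: np.random.Generator
) -> list[GenomicRegion]:
    mb = genome.total_bp / 1e6
    n = int(rng.poisson(config.p_bg * mb))
    chroms = genome.chroms
    weights = np.array([genome.chrom_sizes[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    wlo, whi = config.peak_width_range
    out = []
    for _ in range(n):
        chrom = chroms[rng.choice(len(chroms), p=weights)]
        size = genome.chrom_sizes[chrom]
        w = min(int(rng.integers(wlo, whi + 1)), size)
        start = int(rng.integers(0, size - w + 1))
        out.append(GenomicRegion(chrom, start, start + w))
    return out


def simulate_study(config: SimulationConfig) -> SyntheticStudy:
    """Generate a full study; fully deterministic given ``config.seed``.

    Dataset layout: for every lineage stage and both marks a native heart
    dataset; for every non-target tissue and both marks a tissue dataset
    (collected at the target stage); for every heart dataset a
    cross-species degraded copy.
    """
    root = np.random.SeedSequence(config.seed)
    ss_place, ss_shared, ss_data = root.spawn(3)
    rng = np.random.default_rng(ss_place)
    genome, target, other = _place_enhancers(config, rng)

    shared_rng = np.random.default_rng(ss_shared)
    shared_mask = shared_rng.random(len(other)) < config.shared_frac
    shared_other = [o for o, s in zip(other, shared_mask) if s]

    peak_sets: dict[str, RegionSet] = {}
    manifest: list[ContextMeta] = []
    data_children = iter(ss_data.spawn(
        2 * len(config.stage_coords) + 2 * len(config.tissue_names)
        + 2 * len(config.stage_coords)  # cross-species copies
    ))

    # lineage (heart) contexts
    for stage in config.stage_coords:
        p_cov = config.marking_probability(stage)
        for mark in MARKS:
            drng = np.random.default_rng(next(data_children))
            peaks = []
            cover = drng.random(len(target)) < p_cov
            for enh, c in zip(target, cover):
                if c:
                    peaks.append(_peak_over(enh, genome, config, drng))
            # ubiquitously active elements: active (hence markable at the
            # full rate p_max) in every context, not deterministically
            # peaked - ChIP-seq misses active elements too
            cover_shared = drng.random(len(shared_other)) < config.p_max
            for enh, c in zip(shared_other, cover_shared):
                if c:
                    peaks.append(_peak_over(enh, genome, config, drng))
            peaks.extend(_background_peaks(genome, config, drng))
            did = f"heart_s{stage:g}_{mark}"
            peak_sets[did] = RegionSet(peaks, did)
            manifest.append(
                ContextMeta(did, TARGET_TISSUE, stage, NATIVE_SPECIES, mark)
            )

    # non-target tissue contexts (sampled at the target stage)
    for tissue in config.tissue_names:
        own = [o for o in other if o.label == tissue]
        for mark in MARKS:
            drng = np.random.default_rng(next(data_children))
            peaks = []
            shared_names = {e.name for e in shared_other}
            own_specific = [o for o in own if o.name not in shared_names]
            cover_own = drng.random(len(own_specific)) < config.p_max
            for enh, c in zip(own_specific, cover_own):
                if c:
                    peaks.append(_peak_over(enh, genome, config, drng))
            cover_target = drng.random(len(target)) < (
                config.p_max * config.shared_frac
            )
            for enh, c in zip(target, cover_target):
                if c:
                    peaks.append(_peak_over(enh, genome, config, drng))
            cover_shared = drng.random(len(shared_other)) < config.p_max
            for enh, c in zip(shared_other, cover_shared):
                if c:
                    peaks.append(_peak_over(enh, genome, config, drng))
            peaks.extend(_background_peaks(genome, config, drng))
            did = f"{tissue}_{mark}"
            peak_sets[did] = RegionSet(peaks, did)
            manifest.append(
                ContextMeta(did, tissue, config.target_stage, NATIVE_SPECIES, mark)
            )

    # cross-species contexts: degraded copies of the lineage datasets
    for stage in config.stage_coords:
        for mark in MARKS:
            src = f"heart_s{stage:g}_{mark}"
            child = next(data_children)
            did = f"xs_{src}"
            degraded = degrade_cross_species(
                peak_sets[src], config, seed=child
            )
            peak_sets[did] = RegionSet(degraded, did)
            manifest.append(
                ContextMeta(did, TARGET_TISSUE, stage, CROSS_SPECIES, mark)
            )

    study = SyntheticStudy(genome, target, other, peak_sets, manifest, config)
    study.validate()
    return study


def degrade_cross_species(
    regions: RegionSet, config: SimulationConfig, seed
) -> RegionSet:
    """Emulate cross-species coordinate mapping of a region set.

    Each region is independently dropped with probability
    ``unmappable_frac`` (unreliably mapped regions); survivors are shifted
    by ``round(Normal(0, map_jitter_sd))`` bp, clipped to stay within
    genome bounds at unchanged length. Deterministic given ``seed`` (an
    int or a numpy SeedSequence).
    """
    rng = np.random.default_rng(seed)
    genome = config.genome()
    out = []
    keep = rng.random(len(regions)) >= config.unmappable_frac
    shifts = rng.normal(0.0, config.map_jitter_sd, size=len(regions))
    for r, k, dx in zip(regions, keep, shifts):
        if not k:
            continue
        shift = int(round(dx))
        size = genome.chrom_sizes.get(r.chrom, r.end)
        shift = max(-r.start, min(shift, size - r.end))
        out.append(
            GenomicRegion(
                r.chrom, r.start + shift, r.end + shift, name=r.name, label=r.label
            )
        )
    return RegionSet(out, source_id=f"{regions.source_id}_mapped")


def export_study(study: SyntheticStudy, directory) -> Path:
    """Write the study as BED + chrom.sizes + manifest TSV + config JSON.

    Returns the manifest path. ``import_study`` on the directory
    reproduces the study exactly; identical config+seed gives
    byte-identical exports.
    """
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    study.genome.to_file(d / "chrom.sizes")
    write_bed(study.target_enhancers, d / "enhancers_target.bed")
    for tissue in study.config.tissue_names:
        sub = RegionSet(
            [r for r in study.other_enhancers if r.label == tissue],
            source_id=f"enhancers_{tissue}",
        )
        write_bed(sub, d / f"enhancers_{tissue}.bed")
    manifest = []
    for m in study.manifest:
        bed = f"{m.dataset_id}.bed"
        write_bed(study.peak_sets[m.dataset_id], d / bed)
        manifest.append(
            ContextMeta(m.dataset_id, m.tissue, m.stage_coord, m.species, m.mark, bed)
        )
    mpath = d / "manifest.tsv"
    write_manifest(manifest, mpath)
    cfg = asdict(study.config)
    (d / "config.json").write_text(json.dumps(cfg, indent=1, sort_keys=True) + "\n")
    return mpath


def import_study(directory) -> SyntheticStudy:
    """Rebuild a :class:`SyntheticStudy` from an exported directory."""
    d = Path(directory)
    raw = json.loads((d / "config.json").read_text())
    for key in ("enhancer_length_range", "peak_width_range", "stage_coords",
                "tissue_names"):
        raw[key] = tuple(raw[key])
    config = SimulationConfig(**raw)
    genome = Genome.from_file(d / "chrom.sizes")
    target = parse_bed(d / "enhancers_target.bed", genome)
    target = RegionSet(
        [GenomicRegion(r.chrom, r.start, r.end, r.name, TARGET_TISSUE)
         for r in target],
        "target_enhancers",
    )
    other_regions = []
    for tissue in config.tissue_names:
        for r in parse_bed(d / f"enhancers_{tissue}.bed", genome):
            other_regions.append(
                GenomicRegion(r.chrom, r.start, r.end, r.name, tissue)
            )
    other = RegionSet(other_regions, "other_enhancers")
    manifest = read_manifest(d / "manifest.tsv")
    peak_sets = {}
    for m in manifest:
        rs = parse_bed(d / m.path, genome)
        peak_sets[m.dataset_id] = RegionSet(rs.regions, m.dataset_id)
    return SyntheticStudy(genome, target, other, peak_sets, manifest, config)
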