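"""Chromosome- and length-matched random background regions.

For each positive region the sampler draws ``ratio`` negatives on the same
chromosome with exactly the same length, rejecting placements that touch
any exclusion region (known-active regions, typically all enhancers of any
tissue plus the positives themselves). This mirrors randomBed-style
matched-background construction: negatives may overlap one another, since
preventing self-overlap would bias placement of long regions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import SamplingExhaustedError
from .intervals import Genome, GenomicRegion, RegionSet, overlaps


@dataclass(frozen=True)
class SamplerConfig:
    """``ratio`` negatives per positive (default 10), with ``max_tries``
    rejection-sampling attempts per negative before giving up."""

    ratio: int = 10
    max_tries: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ratio < 1 or self.max_tries < 1:
            raise ValueError("ratio and max_tries must be >= 1")


def sample_matched_negatives(
    positives: RegionSet,
    genome: Genome,
    exclusions: RegionSet,
    config: SamplerConfig,
) -> RegionSet:
    """Draw ``config.ratio`` matched negatives for every positive.

    Each negative lies on its positive's chromosome, has exactly its
    length, overlaps no exclusion region (>=1 bp criterion) and lies
    within chromosome bounds; start positions are uniform over valid
    placements by rejection sampling. Deterministic given ``config.seed``.

    Raises
    ------
    SamplingExhaustedError
        If a negative cannot be placed within ``max_tries`` attempts
        (e.g. the exclusions tile the chromosome).
    """
    positives.check_bounds(genome)
    rng = np.random.default_rng(config.seed)
    out: list[GenomicRegion] = []
    for i, pos in enumerate(positives):
        size = genome.chrom_sizes[pos.chrom]
        span = size - pos.length  # start in [0, span]
        for j in range(config.ratio):
            for _ in range(config.max_tries):
                start = int(rng.integers(0, span + 1))
                cand = GenomicRegion(
                    pos.chrom,
                    start,
                    start + pos.length,
                    name=f"{pos.name or f'pos{i}'}_bg{j}",
                )
                if not overlaps(cand, exclusions):
                    out.append(cand)
                    break
            else:
                raise SamplingExhaustedError(
                    f"could not place negative {j} for positive "
                    f"{pos.name or ''} {pos} within {config.max_tries} tries"
                )
    return RegionSet(out, source_id="matched_background")
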