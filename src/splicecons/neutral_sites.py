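"""The "Random" annotation: a neutral-evolution baseline for splice sites.

Random two-exon transcripts are placed inside the introns of the consensus
(MANE-like) catalog, away from every annotated splicing motif, so that their
"splice sites" sample neutrally evolving sequence.  Each transcript yields
exactly one donor and one acceptor site; these flow through the same
:class:`~splicecons.annotation.SpliceSite` machinery as real catalogs and
serve as the negative class for the conservation classifier.

Defaults: exon length 80-120 bp, internal intron 100-200 bp, and an
exclusion radius of 35 bp around every annotated site origin — enough to
keep a random site's whole conservation feature window (shifts -30..31)
clear of real splicing motifs.  The canonical request size of 180,000
transcripts matches a genome-scale analysis; synthetic worlds use far fewer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from splicecons.annotation import SiteIndex, Transcript, extract_sites
from splicecons.genome_align_io import Genome


@dataclass
class RandomAnnotationConfig:
    n_transcripts: int = 180_000
    exon_length: tuple[int, int] = (80, 120)
    intron_length: tuple[int, int] = (100, 200)
    exclusion_radius: int = 35
    seed: int = 0
    require_gt_ag: bool = False

    def __post_init__(self):
        if min(self.exon_length) <= 0 or min(self.intron_length) <= 0:
            raise ValueError("length ranges must be positive")
        if self.exclusion_radius < 31:
            raise ValueError(
                "exclusion radius must cover the conservation window half-width (31)"
            )

    @property
    def max_footprint(self) -> int:
        return 2 * self.exon_length[1] + self.intron_length[1]


class GenerationError(RuntimeError):
    pass


def _subtract_intervals(
    interval: tuple[int, int], holes: list[tuple[int, int]]
) -> list[tuple[int, int]]:
    """Half-open interval minus a list of half-open holes."""
    pieces = [interval]
    for hs, he in sorted(holes):
        nxt = []
        for ps, pe in pieces:
            if he <= ps or hs >= pe:
                nxt.append((ps, pe))
                continue
            if hs > ps:
                nxt.append((ps, hs))
            if he < pe:
                nxt.append((he, pe))
        pieces = nxt
    return pieces


def eligible_regions(
    mane_transcripts: list[Transcript],
    site_origins: list[tuple[str, int]],
    config: RandomAnnotationConfig,
) -> list[tuple[str, int, int]]:
    """Intervals inside MANE introns that can host a random transcript.

    Every annotated site origin (from all loaded catalogs) is excluded with
    its ``exclusion_radius`` neighbourhood; remaining pieces shorter than the
    largest possible transcript footprint are dropped.
    """
    radius = config.exclusion_radius
    origins_by_contig: dict[str, list[int]] = {}
    for contig, origin in site_origins:
        origins_by_contig.setdefault(contig, []).append(origin)
    regions = []
    for tx in mane_transcripts:
        for start, end in tx.introns:
            holes = [
                (o - radius, o + radius + 1)
                for o in origins_by_contig.get(tx.contig, [])
                if o - radius < end and o + radius + 1 > start
            ]
            for ps, pe in _subtract_intervals((start, end), holes):
                if pe - ps >= config.max_footprint:
                    regions.append((tx.contig, ps, pe))
    if not regions:
        raise GenerationError(
            "no eligible intervals: introns too short or motif exclusion too wide"
        )
    return sorted(set(regions))


def generate_random_annotation(
    regions: list[tuple[str, int, int]],
    config: RandomAnnotationConfig,
    genome: Genome,
    max_attempts_factor: int = 50,
) -> tuple[list[Transcript], SiteIndex]:
    """Draw random two-exon transcripts uniformly over eligible placements.

    All generated origins are distinct (rejection sampling on collision);
    generation is deterministic under the configured seed.  Raises
    :class:`GenerationError` reporting the achievable count when capacity is
    exhausted.
    """
    rng = np.random.default_rng(config.seed)
    capacities = np.array([e - s for _, s, e in regions], dtype=float)
    weights = capacities / capacities.sum()
    used_origins: set[tuple[str, int]] = set()
    transcripts = []
    attempts = 0
    max_attempts = max_attempts_factor * config.n_transcripts
    while len(transcripts) < config.n_transcripts:
        if attempts >= max_attempts:
            raise GenerationError(
                f"placement capacity exhausted after {attempts} attempts; "
                f"achieved {len(transcripts)} of {config.n_transcripts}"
            )
        attempts += 1
        ridx = rng.choice(len(regions), p=weights)
        contig, rs, re_ = regions[ridx]
        e1 = int(rng.integers(config.exon_length[0], config.exon_length[1] + 1))
        e2 = int(rng.integers(config.exon_length[0], config.exon_length[1] + 1))
        il = int(rng.integers(config.intron_length[0], config.intron_length[1] + 1))
        footprint = e1 + il + e2
        if re_ - rs < footprint:
            continue
        s = int(rng.integers(rs, re_ - footprint + 1))
        intron_start = s + e1
        intron_end = intron_start + il
        donor_origin = intron_start
        acceptor_origin = intron_end - 2
        if (contig, donor_origin) in used_origins or (
            contig,
            acceptor_origin,
        ) in used_origins:
            continue
        if config.require_gt_ag:
            if genome.fetch(contig, intron_start, intron_start + 2).upper() != "GT":
                continue
            if genome.fetch(contig, intron_end - 2, intron_end).upper() != "AG":
                continue
        used_origins.add((contig, donor_origin))
        used_origins.add((contig, acceptor_origin))
        n = len(transcripts)
        transcripts.append(
            Transcript(
                transcript_id=f"RAND_{n:06d}",
                gene_id=f"RANDG_{n:06d}",
                catalog="random",
                gene_type="other",
                strand="+",
                contig=contig,
                exons=((s, intron_start), (intron_end, intron_end + e2)),
            )
        )
    site_index = extract_sites(transcripts, genome)
    return transcripts, site_index
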