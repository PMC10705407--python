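"""Synthetic test world with machine-readable ground truth.

Generates a complete, self-consistent dataset for exercising the whole
pipeline: a reference genome carrying multi-exon genes with planted splice
motifs, a ladder of target species diverged from the reference at
class-dependent substitution rates, a MAF alignment with some exon/species
pairs deliberately withheld (their sequence intact in the target FASTA so
realignment can recover them), a consensus (MANE-like) catalog plus a
superset catalog with extra isoforms whose novel splice sites are drawn half
from conserved loci and half from neutral ones, a random neutral annotation,
population and clinical VCFs with class-dependent planted variants, and a
junction coverage table with category-dependent read depths.

The evolutionary model is a star phylogeny: each target genome is an
independent per-position substitution of the reference, with mismatch
probability ``d_t * multiplier(class)`` where ``d_t`` is the species'
divergence and the multiplier separates conserved splicing motifs
(``conserved_multiplier``), exon interiors (``coding_multiplier``) and
neutral background (1).  Independent substitution is sufficient because the
downstream statistics consume only per-species conservation counts; no
tree-correlated structure is modelled.

Everything is deterministic under the configured seed and the ground truth
(withheld pairs, intended site labels, planted variants, intron category
intents) is serialised alongside the outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from splicecons.annotation import (
    SiteIndex,
    Transcript,
    extract_sites,
    reverse_complement,
    write_gtf,
)
from splicecons.genome_align_io import Genome
from splicecons.neutral_sites import (
    RandomAnnotationConfig,
    eligible_regions,
    generate_random_annotation,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# per-position class codes
CLASS_NEUTRAL, CLASS_CODING, CLASS_CONSERVED = 0, 1, 2


@dataclass
class SimConfig:
    """Knobs of the synthetic world; defaults are sized for routine runs."""

    seed: int = 0
    contig: str = "chr1"
    genome_length: int = 2_000_000
    n_genes: int = 50
    exons_per_gene: tuple[int, int] = (4, 7)
    exon_length: tuple[int, int] = (90, 200)
    intron_length: tuple[int, int] = (300, 1500)
    intergenic_gap: tuple[int, int] = (8_000, 20_000)
    n_targets: int = 25
    divergence_range: tuple[float, float] = (0.02, 0.7)
    conserved_multiplier: float = 0.02
    coding_multiplier: float = 0.3
    motif_halfwidth: int = 31  # class window around intended-well site origins
    withheld_fraction: float = 0.05  # of (internal exon, species) pairs
    block_dropout: float = 0.05  # per (exon sub-block, species)
    novel_isoforms_per_gene: int = 3
    lncrna_every: int = 3  # every k-th gene is lncRNA
    n_random_sites: int = 1_000
    random_exclusion_radius: int = 35
    snp_p_canonical: dict = field(default_factory=lambda: {"well": 0.04, "less": 0.24})
    snp_p_flank: float = 0.10
    af_range: dict = field(
        default_factory=lambda: {"well": (0.0005, 0.005), "less": (0.005, 0.05)}
    )
    clinvar_p: dict = field(default_factory=lambda: {"well": 0.06, "less": 0.02})
    benign_p: float = 0.05
    coverage_means: dict = field(
        default_factory=lambda: {1: 8.0, 2: 16.0, 3: 16.0, 4: 80.0}
    )
    nb_size: float = 20.0
    n_tissues: int = 5
    indel_rate: float = 0.0  # per-position target deletion probability
    include_chry: bool = True
    chry_length: int = 40_000
    chry_genes: int = 2

    def validate(self) -> None:
        probs = [
            self.conserved_multiplier,
            self.coding_multiplier,
            self.withheld_fraction,
            self.block_dropout,
            self.snp_p_flank,
            self.benign_p,
            self.indel_rate,
            *self.snp_p_canonical.values(),
            *self.clinvar_p.values(),
            *self.divergence_range,
        ]
        if any(not 0 <= p <= 1 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if self.conserved_multiplier >= 1:
            raise ValueError("conserved multiplier must be < 1")
        span = (
            self.exons_per_gene[1] * self.exon_length[1]
            + (self.exons_per_gene[1] - 1) * self.intron_length[1]
        )
        needed = self.n_genes * (span + self.intergenic_gap[0]) + self.intergenic_gap[0]
        if needed > self.genome_length:
            raise ValueError(
                f"genome too short: {self.n_genes} genes need up to {needed} bp"
            )


@dataclass
class GeneModel:
    gene_id: str
    contig: str
    strand: str
    gene_type: str
    exons: list[tuple[int, int]]


@dataclass
class SimTruth:
    """Ground truth for every asserted property of the world."""

    divergences: dict  # species -> d_t
    withheld: list  # [contig, start, end, species]
    site_intents: dict  # "contig:strand:kind:origin" -> well | less
    intron_categories: dict  # "contig:start:end:strand" -> 1..4
    planted_variants: list  # [contig, pos0, n_hom, af, group]
    planted_clinical: list  # [contig, pos0, clnsig]
    conserved_intervals: list  # [start, end] on the main contig
    coding_intervals: list
    config: dict

    @staticmethod
    def site_key_str(key: tuple) -> str:
        return f"{key[0]}:{key[1]}:{key[2]}:{key[3]}"

    @staticmethod
    def intron_key_str(key: tuple) -> str:
        return f"{key[0]}:{key[1]}:{key[2]}:{key[3]}"


@dataclass
class SimWorld:
    config: SimConfig
    reference: Genome
    target_genomes: dict[str, Genome]
    mane_transcripts: list[Transcript]
    catalog_transcripts: list[Transcript]
    random_transcripts: list[Transcript]
    truth: SimTruth
    paths: dict[str, str]

    @property
    def target_names(self) -> list[str]:
        return list(self.target_genomes)


def _random_sequence(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.integers(0, 4, size=length, dtype=np.uint8)


def _decode(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


_MOTIF_CODES = {b: i for i, b in enumerate("ACGT")}


def _plant(seq: np.ndarray, pos: int, text: str) -> None:
    for i, b in enumerate(text):
        seq[pos + i] = _MOTIF_CODES[b]


def _plant_intron_motifs(seq: np.ndarray, start: int, end: int, strand: str) -> None:
    # transcript-orientation GT...AG; on the minus strand the forward text
    # reads CT...AC
    if strand == "+":
        _plant(seq, start, "GT")
        _plant(seq, end - 2, "AG")
    else:
        _plant(seq, start, "CT")
        _plant(seq, end - 2, "AC")


def _make_genes(
    rng: np.random.Generator,
    config: SimConfig,
    contig: str,
    length: int,
    n_genes: int,
    prefix: str,
    gap: tuple[int, int] | None = None,
) -> list[GeneModel]:
    genes = []
    gap = gap or config.intergenic_gap
    pos = int(rng.integers(*gap))
    for g in range(n_genes):
        n_exons = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
        exons = []
        cursor = pos
        for i in range(n_exons):
            elen = int(rng.integers(config.exon_length[0], config.exon_length[1] + 1))
            exons.append((cursor, cursor + elen))
            cursor += elen
            if i < n_exons - 1:
                cursor += int(rng.integers(config.intron_length[0], config.intron_length[1] + 1))
        if cursor + gap[0] > length:
            break
        strand = "+" if g % 2 == 0 else "-"
        gene_type = "lncRNA" if g % config.lncrna_every == config.lncrna_every - 1 else "coding"
        genes.append(GeneModel(f"{prefix}{g:03d}", contig, strand, gene_type, exons))
        pos = cursor + int(rng.integers(*gap))
    return genes


def _gene_breakpoints(
    rng: np.random.Generator, genes: list[GeneModel], ref_len: int
) -> dict[str, list[int]]:
    """Per-gene sorted MAF block boundaries: gene span with 100 bp flanks,
    exon boundaries, and one random split point inside each exon."""
    out = {}
    for gene in genes:
        span0, span1 = gene.exons[0][0], gene.exons[-1][1]
        breaks = {max(0, span0 - 100), min(ref_len, span1 + 100)}
        for s, e in gene.exons:
            breaks.add(s)
            breaks.add(e)
            breaks.add(int(rng.integers(s + int(0.3 * (e - s)), s + int(0.7 * (e - s)) + 1)))
        out[gene.gene_id] = sorted(breaks)
    return out


def _boundary_site_keys(contig: str, strand: str, intron: tuple[int, int]) -> dict:
    """(low-boundary key, high-boundary key) of an intron in site-key form."""
    s, e = intron
    if strand == "+":
        return {"low": (contig, "+", "donor", s), "high": (contig, "+", "acceptor", e - 2)}
    return {"low": (contig, "-", "acceptor", s + 1), "high": (contig, "-", "donor", e - 1)}


def _novel_isoforms(
    rng: np.random.Generator,
    gene: GeneModel,
    ref_codes: np.ndarray,
    n_isoforms: int,
    intent_cycle: list[str],
) -> list[tuple[Transcript, list[tuple[tuple, str]]]]:
    """Extra isoforms that shift intron boundaries to novel planted sites.

    Each isoform modifies one intron.  Intent ``"well"`` / ``"less"`` shifts a
    single boundary and intends the novel site conserved / neutral;
    ``"both-less"`` shifts both boundaries, yielding an intron whose donor and
    acceptor are both neutral novel sites (category-1 material).  Returns
    (transcript, [(novel site key, intent), ...]) pairs; at most one isoform
    touches any given intron.
    """
    out = []
    introns = [(j, gene.exons[j][1], gene.exons[j + 1][0]) for j in range(len(gene.exons) - 1)]
    usable = [(j, s, e) for j, s, e in introns if e - s >= 400]
    rng.shuffle(usable)
    for i in range(min(n_isoforms, len(usable))):
        j, s, e = usable[i]
        intent = intent_cycle[i % len(intent_cycle)]
        exons = list(gene.exons)
        novel: list[tuple[tuple, str]] = []
        if intent == "both-less":
            d1 = int(rng.integers(80, (e - s) // 2 - 60))
            d2 = int(rng.integers(80, (e - s) // 2 - 60))
            new_intron = (s + d1, e - d2)
            exons[j] = (exons[j][0], new_intron[0])
            exons[j + 1] = (new_intron[1], exons[j + 1][1])
            keys = _boundary_site_keys(gene.contig, gene.strand, new_intron)
            novel = [(keys["low"], "less"), (keys["high"], "less")]
        else:
            delta = int(rng.integers(80, e - s - 150))
            from_left = bool(rng.integers(0, 2))
            if from_left:
                new_intron = (s + delta, e)
                exons[j] = (exons[j][0], new_intron[0])
                moved = "low"
            else:
                new_intron = (s, e - delta)
                exons[j + 1] = (new_intron[1], exons[j + 1][1])
                moved = "high"
            keys = _boundary_site_keys(gene.contig, gene.strand, new_intron)
            novel = [(keys[moved], intent)]
        _plant_intron_motifs(ref_codes, new_intron[0], new_intron[1], gene.strand)
        tx = Transcript(
            transcript_id=f"{gene.gene_id}.alt{i + 1}",
            gene_id=gene.gene_id,
            catalog="catalog",
            gene_type=gene.gene_type,
            strand=gene.strand,
            contig=gene.contig,
            exons=tuple(exons),
        )
        out.append((tx, novel))
    return out


def _gene_transcript(gene: GeneModel, catalog: str, suffix: str = ".1") -> Transcript:
    return Transcript(
        transcript_id=f"{gene.gene_id}{suffix}",
        gene_id=gene.gene_id,
        catalog=catalog,
        gene_type=gene.gene_type,
        strand=gene.strand,
        contig=gene.contig,
        exons=tuple(gene.exons),
    )


def _write_maf(
    path,
    config: SimConfig,
    genes: list[GeneModel],
    breakpoints: dict[str, list[int]],
    ref_codes: np.ndarray,
    target_codes: dict[str, np.ndarray],
    deletion_masks: dict[str, np.ndarray] | None,
    skipped_blocks: set[tuple[int, int, str]],
) -> None:
    """Emit per-region MAF blocks along precomputed breakpoints.

    ``skipped_blocks`` (withheld or randomly dropped exon sub-blocks) are
    keyed by (block start, block end, species); those species rows are
    omitted from the corresponding block.
    """
    contig = config.contig
    ref_len = len(ref_codes)
    species = list(target_codes)
    # per-species forward-position map under deletions
    tpos_maps = {}
    tlens = {}
    for sp in species:
        if deletion_masks is not None and deletion_masks[sp].any():
            keep = ~deletion_masks[sp]
            tpos_maps[sp] = np.cumsum(keep) - 1
            tlens[sp] = int(keep.sum())
        else:
            tpos_maps[sp] = None
            tlens[sp] = ref_len
    with open(path, "w") as fh:
        fh.write("##maf version=1 scoring=none\n")
        for gene in genes:
            bp = breakpoints[gene.gene_id]
            for bs, be in zip(bp, bp[1:]):
                if be <= bs:
                    continue
                fh.write("\na score=0.0\n")
                ref_text = _decode(ref_codes[bs:be])
                width = be - bs
                fh.write(
                    f"s ref.{contig} {bs} {width} + {ref_len} {ref_text}\n"
                )
                for sp in species:
                    if (bs, be, sp) in skipped_blocks:
                        continue
                    tmap = tpos_maps[sp]
                    codes = target_codes[sp]
                    if tmap is None:
                        text = _decode(codes[bs:be])
                        fh.write(
                            f"s {sp}.{contig} {bs} {width} + {tlens[sp]} {text}\n"
                        )
                    else:
                        mask = ~deletion_masks[sp][bs:be]
                        size = int(mask.sum())
                        if size == 0:
                            continue
                        chars = np.full(width, ord("-"), dtype=np.uint8)
                        kept_ref = np.arange(bs, be)[mask]
                        chars[mask] = _BASES[codes[tmap[kept_ref]]]
                        start = int(tmap[kept_ref[0]])
                        fh.write(
                            f"s {sp}.{contig} {start} {size} + {tlens[sp]} "
                            f"{chars.tobytes().decode('ascii')}\n"
                        )
        fh.write("\n")


def _write_vcf(path, contig: str, contig_len: int, records: list[tuple], clinical: bool) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={contig},length={contig_len}>\n")
        if clinical:
            fh.write(
                '##INFO=<ID=CLNSIG,Number=.,Type=String,Description="Clinical significance">\n'
            )
        else:
            fh.write('##INFO=<ID=AF,Number=A,Type=Float,Description="Allele frequency">\n')
            fh.write(
                '##INFO=<ID=nhomalt,Number=A,Type=Integer,Description="Homozygous-alt count">\n'
            )
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for rec in sorted(records, key=lambda r: r[0]):
            pos0, ref, alt, info = rec
            fh.write(f"{contig}\t{pos0 + 1}\t.\t{ref}\t{alt}\t.\tPASS\t{info}\n")


def simulate_world(config: SimConfig, out_dir) -> SimWorld:
    """Generate the full synthetic world and write its files under ``out_dir``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    out_dir = Path(out_dir)
    (out_dir / "targets").mkdir(parents=True, exist_ok=True)
    contig = config.contig

    # --- reference sequence and gene models -------------------------------
    ref_codes = _random_sequence(rng, config.genome_length)
    genes = _make_genes(
        rng, config, contig, config.genome_length, config.n_genes, prefix="G"
    )
    for gene in genes:
        for j in range(len(gene.exons) - 1):
            _plant_intron_motifs(
                ref_codes, gene.exons[j][1], gene.exons[j + 1][0], gene.strand
            )

    mane_transcripts = [
        _gene_transcript(g, "mane") for g in genes if g.gene_type == "coding"
    ]
    catalog_transcripts = [_gene_transcript(g, "catalog") for g in genes]

    novel_sites: dict[tuple, str] = {}
    for gene in genes:
        for tx, novel in _novel_isoforms(
            rng,
            gene,
            ref_codes,
            config.novel_isoforms_per_gene,
            ["well", "less", "both-less"],
        ):
            catalog_transcripts.append(tx)
            for novel_key, intent in novel:
                novel_sites[novel_key] = intent

    # --- optional chrY contig (catalog-only; absent from the alignment) ---
    chry_genes: list[GeneModel] = []
    chry_codes = None
    if config.include_chry:
        chry_codes = _random_sequence(rng, config.chry_length)
        chry_cfg_genes = _make_genes(
            rng,
            config,
            "chrY",
            config.chry_length,
            config.chry_genes,
            prefix="GY",
            gap=(1000, 3000),
        )
        for gene in chry_cfg_genes:
            for j in range(len(gene.exons) - 1):
                _plant_intron_motifs(
                    chry_codes, gene.exons[j][1], gene.exons[j + 1][0], gene.strand
                )
        chry_genes = chry_cfg_genes
        catalog_transcripts += [_gene_transcript(g, "catalog") for g in chry_genes]

    # --- per-position class array -----------------------------------------
    classes = np.zeros(config.genome_length, dtype=np.uint8)
    for gene in genes:
        for s, e in gene.exons:
            classes[s:e] = CLASS_CODING
    reference = Genome("ref", {contig: _decode(ref_codes)})
    if chry_codes is not None:
        reference.contigs["chrY"] = _decode(chry_codes)

    base_index = extract_sites(
        [_gene_transcript(g, "catalog") for g in genes], reference
    )
    site_intents: dict[tuple, str] = {}
    for key in list(base_index.donors) + list(base_index.acceptors):
        site_intents[key] = "well"
    for key, intent in novel_sites.items():
        site_intents[key] = intent
    hw = config.motif_halfwidth
    for key, intent in site_intents.items():
        if intent == "well":
            origin = key[3]
            classes[max(0, origin - hw) : origin + hw + 1] = CLASS_CONSERVED

    # --- target genomes ----------------------------------------------------
    d_lo, d_hi = config.divergence_range
    divergences = {
        f"sp{i:02d}": float(d)
        for i, d in enumerate(np.linspace(d_lo, d_hi, config.n_targets))
    }
    multipliers = np.array(
        [1.0, config.coding_multiplier, config.conserved_multiplier]
    )
    p_class = multipliers[classes]
    target_codes: dict[str, np.ndarray] = {}
    deletion_masks: dict[str, np.ndarray] | None = (
        {} if config.indel_rate > 0 else None
    )
    for sp, d in divergences.items():
        mutate = rng.random(config.genome_length) < d * p_class
        codes = ref_codes.copy()
        n_mut = int(mutate.sum())
        codes[mutate] = (codes[mutate] + rng.integers(1, 4, size=n_mut, dtype=np.uint8)) % 4
        if deletion_masks is not None:
            # deletions restricted to neutral background so planted structure
            # stays intact
            dele = (rng.random(config.genome_length) < config.indel_rate) & (
                classes == CLASS_NEUTRAL
            )
            deletion_masks[sp] = dele
            target_codes[sp] = codes
        else:
            target_codes[sp] = codes

    target_genomes = {}
    for sp, codes in target_codes.items():
        if deletion_masks is not None:
            seq = _decode(codes[~deletion_masks[sp]])
        else:
            seq = _decode(codes)
        target_genomes[sp] = Genome(sp, {contig: seq})

    # --- withheld pairs and block dropout ----------------------------------
    species = list(divergences)
    block_rng = np.random.default_rng(config.seed + 1)
    breakpoints = _gene_breakpoints(block_rng, genes, config.genome_length)
    sub_blocks: dict[tuple[int, int], list[tuple[int, int]]] = {}
    for gi, gene in enumerate(genes):
        bp = breakpoints[gene.gene_id]
        for ei, (s, e) in enumerate(gene.exons):
            sub_blocks[(gi, ei)] = [
                (a, b) for a, b in zip(bp, bp[1:]) if a >= s and b <= e
            ]

    dropped_blocks: set[tuple[int, int, str]] = set()
    drop_rng = np.random.default_rng(config.seed + 2)
    for (gi, ei), blocks in sub_blocks.items():
        for bs, be in blocks:
            for sp in species:
                if drop_rng.random() < config.block_dropout:
                    dropped_blocks.add((bs, be, sp))

    # withheld (internal exon, species) pairs whose neighbours stay intact
    internal = [
        (gi, ei)
        for gi, gene in enumerate(genes)
        for ei in range(1, len(gene.exons) - 1)
    ]
    candidates = [(gi, ei, sp) for gi, ei in internal for sp in species]
    pick_rng = np.random.default_rng(config.seed + 3)
    pick_rng.shuffle(candidates)
    n_withheld = int(round(config.withheld_fraction * len(candidates)))
    withheld_pairs: list[tuple[int, int, str]] = []
    withheld_set: set[tuple[int, int, str]] = set()

    def exon_intact(gi: int, ei: int, sp: str) -> bool:
        if (gi, ei, sp) in withheld_set:
            return False
        return all(
            (bs, be, sp) not in dropped_blocks for bs, be in sub_blocks[(gi, ei)]
        )

    for gi, ei, sp in candidates:
        if len(withheld_pairs) >= n_withheld:
            break
        if (gi, ei, sp) in withheld_set:
            continue
        if not exon_intact(gi, ei - 1, sp) or not exon_intact(gi, ei + 1, sp):
            continue
        withheld_pairs.append((gi, ei, sp))
        withheld_set.add((gi, ei, sp))

    withheld_blocks: set[tuple[int, int, str]] = set()
    for gi, ei, sp in withheld_pairs:
        for bs, be in sub_blocks[(gi, ei)]:
            withheld_blocks.add((bs, be, sp))

    # --- MAF ---------------------------------------------------------------
    maf_path = out_dir / "alignment.maf"
    _write_maf(
        maf_path,
        config,
        genes,
        breakpoints,
        ref_codes,
        target_codes,
        deletion_masks,
        withheld_blocks | dropped_blocks,
    )

    # --- random (neutral) annotation ---------------------------------------
    all_origins = [(key[0], key[3]) for key in site_intents]
    rand_cfg = RandomAnnotationConfig(
        n_transcripts=config.n_random_sites,
        exclusion_radius=config.random_exclusion_radius,
        seed=config.seed + 4,
    )
    regions = eligible_regions(mane_transcripts, all_origins, rand_cfg)
    random_transcripts, random_index = generate_random_annotation(
        regions, rand_cfg, reference
    )

    # --- population and clinical VCFs --------------------------------------
    var_rng = np.random.default_rng(config.seed + 5)
    catalog_index = extract_sites(catalog_transcripts, reference)
    chr1_sites = [
        s for s in catalog_index.sites if s.contig == contig
    ] + random_index.sites
    planted: dict[int, tuple] = {}
    planted_truth = []
    snp_window = tuple(range(-4, 8))
    for site in chr1_sites:
        key = site.key()
        group = site_intents.get(key, "less")
        for shift in snp_window:
            p = (
                config.snp_p_canonical[group]
                if shift in (0, 1)
                else config.snp_p_flank
            )
            if var_rng.random() >= p:
                continue
            pos = site.position_at(shift)
            if not 0 <= pos < config.genome_length or pos in planted:
                continue
            ref_b = _decode(ref_codes[pos : pos + 1])
            alt_b = "ACGT"[(int(ref_codes[pos]) + int(var_rng.integers(1, 4))) % 4]
            lo, hi = config.af_range[group]
            af = float(var_rng.uniform(lo, hi))
            n_hom = int(var_rng.integers(1, 4))
            planted[pos] = (pos, ref_b, alt_b, f"AF={af:.6f};nhomalt={n_hom}")
            planted_truth.append([contig, int(pos), n_hom, af, group])
    # background non-homozygous variants exercise the hom filter
    for _ in range(300):
        pos = int(var_rng.integers(0, config.genome_length))
        if pos in planted:
            continue
        ref_b = _decode(ref_codes[pos : pos + 1])
        alt_b = "ACGT"[(int(ref_codes[pos]) + int(var_rng.integers(1, 4))) % 4]
        af = float(var_rng.uniform(0.0001, 0.01))
        planted[pos] = (pos, ref_b, alt_b, f"AF={af:.6f};nhomalt=0")
    vcf_path = out_dir / "variants.vcf"
    _write_vcf(vcf_path, contig, config.genome_length, list(planted.values()), clinical=False)

    clin_rng = np.random.default_rng(config.seed + 6)
    clinical: dict[int, tuple] = {}
    clinical_truth = []
    for site in chr1_sites:
        key = site.key()
        group = site_intents.get(key, "less")
        if clin_rng.random() < config.clinvar_p.get(group, 0.0):
            shift = int(clin_rng.integers(0, 2))
            pos = site.position_at(shift)
            if 0 <= pos < config.genome_length and pos not in clinical:
                sig = "Pathogenic" if clin_rng.random() < 0.5 else "Likely_pathogenic"
                ref_b = _decode(ref_codes[pos : pos + 1])
                alt_b = "ACGT"[(int(ref_codes[pos]) + int(clin_rng.integers(1, 4))) % 4]
                clinical[pos] = (pos, ref_b, alt_b, f"CLNSIG={sig}")
                clinical_truth.append([contig, int(pos), sig])
        if clin_rng.random() < config.benign_p:
            pos = site.position_at(int(clin_rng.integers(2, 6)))
            if 0 <= pos < config.genome_length and pos not in clinical:
                ref_b = _decode(ref_codes[pos : pos + 1])
                alt_b = "ACGT"[(int(ref_codes[pos]) + int(clin_rng.integers(1, 4))) % 4]
                clinical[pos] = (pos, ref_b, alt_b, "CLNSIG=Benign")
    clin_path = out_dir / "clinical.vcf"
    _write_vcf(clin_path, contig, config.genome_length, list(clinical.values()), clinical=True)

    # --- junction coverage table -------------------------------------------
    cov_rng = np.random.default_rng(config.seed + 7)
    intron_cats = {}
    for intron in catalog_index.introns.values():
        if intron.contig != contig:
            continue
        d_well = site_intents.get(intron.donor_key, "less") == "well"
        a_well = site_intents.get(intron.acceptor_key, "less") == "well"
        intron_cats[intron.key()] = 1 + (1 if d_well else 0) + (2 if a_well else 0)
    junc_path = out_dir / "junctions.tsv"
    tissue_names = [f"tissue_{i + 1}" for i in range(config.n_tissues)]
    with open(junc_path, "w") as fh:
        fh.write("contig\tstart\tend\tstrand\t" + "\t".join(tissue_names) + "\n")
        for key, cat in sorted(intron_cats.items()):
            mean = config.coverage_means[cat]
            p = config.nb_size / (config.nb_size + mean)
            counts = cov_rng.negative_binomial(config.nb_size, p, size=config.n_tissues)
            fh.write(
                f"{key[0]}\t{key[1] + 1}\t{key[2]}\t{key[3]}\t"
                + "\t".join(str(int(c)) for c in counts)
                + "\n"
            )

    # --- FASTA + GTF outputs ------------------------------------------------
    ref_path = out_dir / "ref.fa"
    reference.write_fasta(ref_path)
    target_paths = {}
    for sp, genome in target_genomes.items():
        p = out_dir / "targets" / f"{sp}.fa"
        genome.write_fasta(p)
        target_paths[sp] = str(p)
    mane_path = out_dir / "mane.gtf"
    catalog_path = out_dir / "catalog.gtf"
    random_path = out_dir / "random.gtf"
    write_gtf(mane_transcripts, mane_path, dialect="gencode")
    write_gtf(catalog_transcripts, catalog_path, dialect="gencode")
    write_gtf(
        random_transcripts,
        random_path,
        dialect="gencode",
        header_comments=(f"seed={rand_cfg.seed}",),
    )

    # --- ground truth -------------------------------------------------------
    def _intervals(mask: np.ndarray) -> list[list[int]]:
        diff = np.diff(mask.astype(np.int8))
        starts = list(np.where(diff == 1)[0] + 1)
        ends = list(np.where(diff == -1)[0] + 1)
        if mask[0]:
            starts = [0] + starts
        if mask[-1]:
            ends = ends + [len(mask)]
        return [[int(s), int(e)] for s, e in zip(starts, ends)]

    truth_intents = dict(site_intents)
    for site in random_index.sites:
        truth_intents.setdefault(site.key(), "less")
    truth = SimTruth(
        divergences=divergences,
        withheld=[
            [contig, genes[gi].exons[ei][0], genes[gi].exons[ei][1], sp]
            for gi, ei, sp in withheld_pairs
        ],
        site_intents={
            SimTruth.site_key_str(k): v for k, v in sorted(truth_intents.items())
        },
        intron_categories={
            SimTruth.intron_key_str(k): v for k, v in sorted(intron_cats.items())
        },
        planted_variants=planted_truth,
        planted_clinical=clinical_truth,
        conserved_intervals=_intervals(classes == CLASS_CONSERVED),
        coding_intervals=_intervals(classes == CLASS_CODING),
        config=asdict(config),
    )
    truth_path = out_dir / "truth.json"
    with open(truth_path, "w") as fh:
        json.dump(asdict(truth), fh, indent=1)

    paths = {
        "ref_fasta": str(ref_path),
        "maf": str(maf_path),
        "mane_gtf": str(mane_path),
        "catalog_gtf": str(catalog_path),
        "random_gtf": str(random_path),
        "variants_vcf": str(vcf_path),
        "clinical_vcf": str(clin_path),
        "junctions_tsv": str(junc_path),
        "truth_json": str(truth_path),
        **{f"target:{sp}": p for sp, p in target_paths.items()},
    }
    return SimWorld(
        config=config,
        reference=reference,
        target_genomes=target_genomes,
        mane_transcripts=mane_transcripts,
        catalog_transcripts=catalog_transcripts,
        random_transcripts=random_transcripts,
        truth=truth,
        paths=paths,
    )


def two_genome_example(out_dir):
    """A minimal two-genome worked example of the conservation function.

    A human-like reference carries one two-exon gene whose intron [20, 30)
    starts with GT and ends with AG.  A mouse-like target genome is aligned
    over the whole locus and is identical to the reference except at the
    first base of the acceptor's canonical dinucleotide (position 28, A->G).
    Consequently the donor has both canonical positions conserved,
    ``C(d1, 0, 2) = C(d1, 1, 2) = 1``, while the acceptor has
    ``C(a1, 0, 2) = 0`` and ``C(a1, 1, 2) = 1``.

    Writes ``example.maf`` under ``out_dir`` and returns
    ``(scorer, donor_site, acceptor_site)``.
    """
    from splicecons.annotation import SpliceSite
    from splicecons.conserve import ConservationScorer
    from splicecons.genome_align_io import load_maf

    ref_seq = "TTGACCGCAAATGCCGTTAGGTACGTCTAGGCTTACAAGCTGACCATAGGCTTAGAGCC"
    #          0         1         2         3         4         5
    # exon1 [10, 20), intron [20, 30) = GTACGTCTAG (GT...AG), exon2 [30, 40)
    assert ref_seq[20:22] == "GT" and ref_seq[28:30] == "AG"
    tgt_seq = ref_seq[:28] + "G" + ref_seq[29:]  # acceptor A -> G in mouse
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    maf_path = out_dir / "example.maf"
    block = ref_seq[5:45]
    tblock = tgt_seq[5:45]
    with open(maf_path, "w") as fh:
        fh.write("##maf version=1\n\n")
        fh.write("a score=0.0\n")
        fh.write(f"s human.chr1 5 40 + {len(ref_seq)} {block}\n")
        fh.write(f"s mouse.chr1 5 40 + {len(tgt_seq)} {tblock}\n\n")
    aln = load_maf(maf_path, "human")
    reference = Genome("human", {"chr1": ref_seq})
    mouse = Genome("mouse", {"chr1": tgt_seq})
    scorer = ConservationScorer(aln, reference, {"mouse": mouse})
    donor = SpliceSite(contig="chr1", strand="+", kind="donor", origin=20, dinucleotide="GT")
    acceptor = SpliceSite(
        contig="chr1", strand="+", kind="acceptor", origin=28, dinucleotide="AG"
    )
    return scorer, donor, acceptor


def truth_check(world: SimWorld, aln=None) -> list[str]:
    """Verify the world's structural invariants; returns failure messages.

    Checks that withheld exons are absent from the alignment but present in
    the target FASTA, that every emitted site carries a truth label, and that
    every planted variant appears in the VCF.
    """
    from splicecons.genome_align_io import Exon, load_maf
    from splicecons.popgen import load_variants

    failures = []
    if aln is None:
        aln = load_maf(world.paths["maf"], "ref")
    for contig, start, end, sp in world.truth.withheld:
        exon = Exon(contig, start, end)
        if aln.exon_alignment_status(exon, sp):
            failures.append(f"withheld exon {contig}:{start}-{end} aligned in {sp}")
        tgt = world.target_genomes[sp]
        if contig not in tgt.contigs or len(tgt.contigs[contig]) < end:
            failures.append(f"withheld exon {contig}:{start}-{end} missing from {sp} FASTA")
    catalog_index = extract_sites(world.catalog_transcripts, world.reference)
    random_index = extract_sites(world.random_transcripts, world.reference)
    for site in catalog_index.sites + random_index.sites:
        if site.contig != world.config.contig:
            continue
        if SimTruth.site_key_str(site.key()) not in world.truth.site_intents:
            failures.append(f"site {site.key()} has no truth label")
    vcf_positions = {
        (v.contig, v.position) for v in load_variants(world.paths["variants_vcf"])
    }
    for contig, pos, n_hom, af, group in world.truth.planted_variants:
        if (contig, pos) not in vcf_positions:
            failures.append(f"planted variant {contig}:{pos} missing from VCF")
    return failures
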