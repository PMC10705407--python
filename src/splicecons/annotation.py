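"""Gene catalog parsing, splice-site extraction, and catalog reductions.

Catalogs (GENCODE, RefSeq, CHESS, MANE) encode gene types with different
attribute dialects; :func:`parse_catalog` normalises them into ``coding``,
``lncRNA`` or ``other``.  Splice sites are extracted per intron in transcript
orientation: the *origin* ``o(s)`` of a site is the reference coordinate of
the first base of its canonical dinucleotide as read along the transcript.
On the plus strand a donor's origin is the intron start (the G of GT) and an
acceptor's origin is ``intron_end - 2`` (the A of AG); on the minus strand
the mirror positions apply, with dinucleotides reverse-complemented.

Coordinates are GTF 1-based closed on disk and 0-based half-open in memory.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import gffutils

from splicecons.genome_align_io import Genome

logger = logging.getLogger(__name__)

DIALECTS = ("gencode", "mane", "refseq", "chess")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class Transcript:
    """A multi- (or single-) exon transcript with 0-based half-open exons."""

    transcript_id: str
    gene_id: str
    catalog: str
    gene_type: str  # coding | lncRNA | other
    strand: str  # + | -
    contig: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self):
        exons = tuple(sorted(tuple(e) for e in self.exons))
        for (s1, e1), (s2, _) in zip(exons, exons[1:]):
            if e1 > s2:
                raise ValueError(f"overlapping exons in transcript {self.transcript_id}")
        object.__setattr__(self, "exons", exons)

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        """Gaps between consecutive exons, genome orientation, half-open."""
        return tuple(
            (e1, s2) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:])
        )

    @property
    def n_introns(self) -> int:
        return len(self.exons) - 1

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]


@dataclass
class SpliceSite:
    """A donor or acceptor site, uniquely keyed by (contig, strand, kind, origin)."""

    contig: str
    strand: str
    kind: str  # donor | acceptor
    origin: int
    dinucleotide: str = ""
    canonical_class: str = "other"  # GT-AG | GC-AG | AT-AC | other
    transcripts: list[str] = field(default_factory=list)
    catalogs: set[str] = field(default_factory=set)
    gene_types: set[str] = field(default_factory=set)

    def key(self) -> tuple[str, str, str, int]:
        return (self.contig, self.strand, self.kind, self.origin)

    def position_at(self, shift: int) -> int:
        """Reference position at transcript-orientation shift ``l`` from the origin."""
        return self.origin + shift if self.strand == "+" else self.origin - shift


def _classify_gencode(db, tx) -> str:
    ttype = tx.attributes.get("transcript_type", [None])[0]
    if ttype == "protein_coding":
        return "coding"
    if ttype == "lncRNA":
        return "lncRNA"
    return "other" if ttype is not None else "missing"


def _classify_chess(db, tx) -> str:
    gtype = tx.attributes.get("gene_type", [None])[0]
    if gtype == "protein_coding":
        return "coding"
    if gtype == "lncRNA":
        return "lncRNA"
    return "other" if gtype is not None else "missing"


def _classify_refseq(db, tx) -> str:
    gene_biotype = None
    gene_id = tx.attributes.get("gene_id", [None])[0]
    if gene_id is not None:
        try:
            gene = db[gene_id]
            gene_biotype = gene.attributes.get("gene_biotype", [None])[0]
        except gffutils.exceptions.FeatureNotFoundError:
            pass
    if gene_biotype is None:
        gene_biotype = tx.attributes.get("gene_biotype", [None])[0]
    tx_biotype = tx.attributes.get("transcript_biotype", [None])[0]
    if gene_biotype is None and tx_biotype is None:
        return "missing"
    if gene_biotype == "protein_coding" and tx_biotype == "mRNA":
        return "coding"
    if gene_biotype == "lncRNA" and tx_biotype == "lnc_RNA":
        return "lncRNA"
    return "other"


_CLASSIFIERS = {
    "gencode": _classify_gencode,
    "mane": _classify_gencode,
    "chess": _classify_chess,
    "refseq": _classify_refseq,
}


def parse_catalog(gtf_path, dialect: str, catalog: str | None = None) -> list[Transcript]:
    """Parse a GTF/GFF3 catalog into typed transcripts.

    ``dialect`` selects the gene-type attribute rules: GENCODE and MANE use
    the transcript's ``transcript_type``; CHESS uses ``gene_type``; RefSeq
    requires ``gene_biotype == protein_coding`` on the gene together with
    ``transcript_biotype == mRNA`` on the transcript (and the lncRNA
    analogues).  Transcripts whose dialect attribute is missing are typed
    ``other`` with a warning.
    """
    if dialect not in _CLASSIFIERS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    catalog = catalog or dialect
    db = gffutils.create_db(
        str(gtf_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
        merge_strategy="create_unique",
    )
    classify = _CLASSIFIERS[dialect]
    transcripts = []
    for tx in db.features_of_type("transcript"):
        gene_type = classify(db, tx)
        if gene_type == "missing":
            logger.warning(
                "transcript %s lacks the %s gene-type attribute; typed 'other'",
                tx.id,
                dialect,
            )
            gene_type = "other"
        exons = tuple(
            (ex.start - 1, ex.end)  # GTF 1-based closed -> 0-based half-open
            for ex in db.children(tx, featuretype="exon")
        )
        if not exons:
            continue
        transcripts.append(
            Transcript(
                transcript_id=tx.id,
                gene_id=tx.attributes.get("gene_id", [tx.id])[0],
                catalog=catalog,
                gene_type=gene_type,
                strand=tx.strand,
                contig=tx.seqid,
                exons=exons,
            )
        )
    return transcripts


@dataclass
class Intron:
    """An intron keyed by its donor and acceptor site origins."""

    contig: str
    strand: str
    start: int  # genome orientation, half-open
    end: int
    donor_key: tuple
    acceptor_key: tuple
    transcripts: list[str] = field(default_factory=list)
    gene_types: set[str] = field(default_factory=set)

    def key(self) -> tuple[str, int, int, str]:
        return (self.contig, self.start, self.end, self.strand)


@dataclass
class SiteIndex:
    """Deduplicated donor/acceptor site sets plus the intron set."""

    donors: dict[tuple, SpliceSite]
    acceptors: dict[tuple, SpliceSite]
    introns: dict[tuple, Intron]
    flagged_transcripts: list[str] = field(default_factory=list)

    @property
    def sites(self) -> list[SpliceSite]:
        return list(self.donors.values()) + list(self.acceptors.values())


def _intron_site_coords(start: int, end: int, strand: str) -> tuple[int, int]:
    """(donor origin, acceptor origin) of an intron, transcript orientation."""
    if strand == "+":
        return start, end - 2
    return end - 1, start + 1


def _site_dinucleotide(genome: Genome, contig: str, strand: str, origin: int) -> str:
    if strand == "+":
        dinuc = genome.fetch(contig, origin, origin + 2)
    else:
        dinuc = reverse_complement(genome.fetch(contig, origin - 1, origin + 1))
    return dinuc.upper()


_CANONICAL = {("GT", "AG"): "GT-AG", ("GC", "AG"): "GC-AG", ("AT", "AC"): "AT-AC"}


def extract_sites(
    transcripts: list[Transcript], genome: Genome, min_intron: int = 4
) -> SiteIndex:
    """Extract donor/acceptor sites and introns from multi-exon transcripts.

    Sites are deduplicated across transcripts on their (contig, strand, kind,
    origin) key, accumulating transcript membership and catalog lists.
    Single-exon transcripts contribute nothing; transcripts with an intron
    shorter than ``min_intron`` are flagged and their sites skipped.
    """
    donors: dict[tuple, SpliceSite] = {}
    acceptors: dict[tuple, SpliceSite] = {}
    introns: dict[tuple, Intron] = {}
    flagged = []
    for tx in transcripts:
        if tx.n_introns < 1:
            continue
        if any(e - s < min_intron for s, e in tx.introns):
            flagged.append(tx.transcript_id)
            continue
        for start, end in tx.introns:
            d_origin, a_origin = _intron_site_coords(start, end, tx.strand)
            d_dinuc = _site_dinucleotide(genome, tx.contig, tx.strand, d_origin)
            a_dinuc = _site_dinucleotide(genome, tx.contig, tx.strand, a_origin)
            cclass = _CANONICAL.get((d_dinuc, a_dinuc), "other")
            for kind, origin, dinuc, store in (
                ("donor", d_origin, d_dinuc, donors),
                ("acceptor", a_origin, a_dinuc, acceptors),
            ):
                key = (tx.contig, tx.strand, kind, origin)
                site = store.get(key)
                if site is None:
                    site = SpliceSite(
                        contig=tx.contig,
                        strand=tx.strand,
                        kind=kind,
                        origin=origin,
                        dinucleotide=dinuc,
                        canonical_class=cclass,
                    )
                    store[key] = site
                site.transcripts.append(tx.transcript_id)
                site.catalogs.add(tx.catalog)
                site.gene_types.add(tx.gene_type)
            ikey = (tx.contig, start, end, tx.strand)
            intron = introns.get(ikey)
            if intron is None:
                intron = Intron(
                    contig=tx.contig,
                    strand=tx.strand,
                    start=start,
                    end=end,
                    donor_key=(tx.contig, tx.strand, "donor", d_origin),
                    acceptor_key=(tx.contig, tx.strand, "acceptor", a_origin),
                )
                introns[ikey] = intron
            intron.transcripts.append(tx.transcript_id)
            intron.gene_types.add(tx.gene_type)
    return SiteIndex(donors=donors, acceptors=acceptors, introns=introns, flagged_transcripts=flagged)


def subtract_mane(
    catalog_sites: dict[tuple, SpliceSite], mane_sites: dict[tuple, SpliceSite]
) -> dict[tuple, SpliceSite]:
    """Remove MANE-shared sites from a catalog's protein-coding sites.

    The subtraction only affects coding sites; lncRNA (and other) sites pass
    through unchanged, mirroring the fact that the consensus catalog covers
    protein-coding genes only.
    """
    out = {}
    for key, site in catalog_sites.items():
        if "coding" in site.gene_types and key in mane_sites:
            continue
        out[key] = site
    return out


def apply_exclusions(
    transcripts: list[Transcript],
    exclude_contigs: tuple[str, ...] = ("chrY",),
    allowed_contigs: set[str] | None = None,
    drop_single_exon: bool = True,
) -> list[Transcript]:
    """Drop transcripts on excluded contigs and single-exon transcripts.

    ``allowed_contigs``, when given (e.g. the contigs present in the
    alignment), additionally removes transcripts on any contig outside it —
    the treatment of unaligned patch sequences.
    """
    out = []
    for tx in transcripts:
        if tx.contig in exclude_contigs:
            continue
        if allowed_contigs is not None and tx.contig not in allowed_contigs:
            continue
        if drop_single_exon and tx.n_introns < 1:
            continue
        out.append(tx)
    return out


def write_gtf(
    transcripts: list[Transcript],
    path,
    dialect: str = "gencode",
    header_comments: tuple[str, ...] = (),
) -> None:
    """Write transcripts as GTF with dialect-appropriate type attributes."""
    type_names = {"coding": "protein_coding", "lncRNA": "lncRNA", "other": "misc_RNA"}
    refseq_tx = {"coding": "mRNA", "lncRNA": "lnc_RNA", "other": "misc_RNA"}
    with open(path, "w") as fh:
        for line in header_comments:
            fh.write(f"#{line}\n")
        genes: dict[str, list[Transcript]] = {}
        for tx in transcripts:
            genes.setdefault(tx.gene_id, []).append(tx)
        for gene_id, txs in genes.items():
            contig, strand = txs[0].contig, txs[0].strand
            gstart = min(t.span[0] for t in txs)
            gend = max(t.span[1] for t in txs)
            gtype = type_names[txs[0].gene_type]
            if dialect == "refseq":
                gene_attrs = f'gene_id "{gene_id}"; gene_biotype "{gtype}";'
            else:
                gene_attrs = f'gene_id "{gene_id}"; gene_type "{gtype}";'
            fh.write(
                f"{contig}\tsplicecons\tgene\t{gstart + 1}\t{gend}\t.\t{strand}\t.\t{gene_attrs}\n"
            )
            for tx in txs:
                ttype = type_names[tx.gene_type]
                attrs = f'gene_id "{gene_id}"; transcript_id "{tx.transcript_id}";'
                if dialect in ("gencode", "mane"):
                    attrs += f' transcript_type "{ttype}";'
                elif dialect == "chess":
                    attrs += f' gene_type "{ttype}";'
                elif dialect == "refseq":
                    attrs += (
                        f' gene_biotype "{gtype}";'
                        f' transcript_biotype "{refseq_tx[tx.gene_type]}";'
                    )
                s, e = tx.span
                fh.write(
                    f"{contig}\tsplicecons\ttranscript\t{s + 1}\t{e}\t.\t{strand}\t.\t{attrs}\n"
                )
                for xs, xe in tx.exons:
                    fh.write(
                        f"{contig}\tsplicecons\texon\t{xs + 1}\t{xe}\t.\t{strand}\t.\t{attrs}\n"
                    )


def write_sites_tsv(site_index: SiteIndex, path) -> None:
    """BED-like TSV of extracted sites (one row per unique site)."""
    with open(path, "w") as fh:
        fh.write(
            "contig\torigin\tstrand\tkind\tdinucleotide\tcanonical_class\t"
            "catalogs\tn_transcripts\n"
        )
        for site in sorted(site_index.sites, key=lambda s: s.key()):
            fh.write(
                f"{site.contig}\t{site.origin}\t{site.strand}\t{site.kind}\t"
                f"{site.dinucleotide}\t{site.canonical_class}\t"
                f"{','.join(sorted(site.catalogs))}\t{len(site.transcripts)}\n"
            )
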