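"""Genomes and reference-anchored multiple alignments.

The central object is :class:`RefAlignment`, a partial function ``w(k, g_t)``
mapping every position ``k`` of the reference genome to its homologous
position in a target genome ``g_t`` (or to the distinguished
:data:`UNALIGNED` value).  The map is populated by walking the columns of a
MultiZ-style MAF file and is the substrate for everything downstream: exon
alignment status ``W(e, g)``, the per-exon alignment score ``r(e)``, and the
per-position conservation function.

Coordinates are 0-based half-open throughout.  Minus-strand MAF rows are
normalised to forward-strand target coordinates; the strand is retained so
that base comparison can complement the fetched target base.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
from Bio import AlignIO, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

_GAP = ord("-")

PROVENANCE_ORIGINAL = 1
PROVENANCE_RECOVERED = 2


class MafParseError(ValueError):
    """Raised when a MAF block cannot be interpreted."""


class _Unaligned:
    """Typed sentinel for 'no homologous position'; never a valid coordinate."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover - trivial
        return "UNALIGNED"

    def __bool__(self) -> bool:
        return False


#: Sentinel returned by :meth:`RefAlignment.map_position` for unmapped positions.
UNALIGNED = _Unaligned()


@dataclass(frozen=True)
class TargetPosition:
    """A homologous position in a target genome (forward-strand coordinates)."""

    contig: str
    position: int
    strand: str = "+"
    provenance: str = "original"


@dataclass(frozen=True)
class Exon:
    """A reference exon segment, 0-based half-open."""

    contig: str
    start: int
    end: int
    gene_type: str = "other"
    chrom_label: str | None = None
    catalogs: frozenset[str] = frozenset()

    def __post_init__(self):
        if not self.start < self.end:
            raise ValueError(f"exon start must precede end: {self.start} >= {self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def key(self) -> tuple[str, int, int]:
        return (self.contig, self.start, self.end)


class ExonSet:
    """A deduplicated, per-contig-sorted collection of reference exons."""

    def __init__(self, exons: Iterable[Exon] = ()):
        seen: dict[tuple[str, int, int], Exon] = {}
        for e in exons:
            k = e.key()
            if k in seen:
                old = seen[k]
                seen[k] = Exon(
                    e.contig,
                    e.start,
                    e.end,
                    gene_type=old.gene_type if old.gene_type != "other" else e.gene_type,
                    chrom_label=old.chrom_label or e.chrom_label,
                    catalogs=old.catalogs | e.catalogs,
                )
            else:
                seen[k] = e
        self.exons: list[Exon] = sorted(seen.values(), key=lambda e: (e.contig, e.start, e.end))

    def __len__(self) -> int:
        return len(self.exons)

    def __iter__(self) -> Iterator[Exon]:
        return iter(self.exons)

    def by_contig(self) -> dict[str, list[Exon]]:
        out: dict[str, list[Exon]] = {}
        for e in self.exons:
            out.setdefault(e.contig, []).append(e)
        return out

    @classmethod
    def from_transcripts(cls, transcripts, catalog: str | None = None) -> "ExonSet":
        exons = []
        for t in transcripts:
            cats = frozenset([catalog or t.catalog])
            for s, e in t.exons:
                exons.append(
                    Exon(t.contig, s, e, gene_type=t.gene_type, chrom_label=t.contig, catalogs=cats)
                )
        return cls(exons)


class Genome:
    """A named genome: a map from contig names to nucleotide strings."""

    def __init__(self, genome_id: str, contigs: Mapping[str, str]):
        self.genome_id = genome_id
        self.contigs: dict[str, str] = dict(contigs)

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.contigs.items()}

    def base(self, contig: str, position: int) -> str:
        return self.contigs[contig][position]

    def fetch(self, contig: str, start: int, end: int) -> str:
        return self.contigs[contig][start:end]

    @classmethod
    def from_fasta(cls, path, genome_id: str | None = None) -> "Genome":
        contigs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
        if genome_id is None:
            genome_id = str(path)
        return cls(genome_id, contigs)

    def write_fasta(self, path) -> None:
        records = [
            SeqRecord(Seq(seq), id=name, description="") for name, seq in self.contigs.items()
        ]
        SeqIO.write(records, str(path), "fasta")

    def __repr__(self) -> str:  # pragma: no cover - trivial
        return f"Genome({self.genome_id!r}, {len(self.contigs)} contigs)"


@dataclass
class _MapArrays:
    """Dense per-(reference contig, target) mapping arrays."""

    tpos: np.ndarray  # int64, -1 where unaligned
    tcontig: np.ndarray  # int32 index into contig name table, -1 where unaligned
    strand: np.ndarray  # int8: +1 / -1 / 0
    prov: np.ndarray  # int8: 0 none, 1 original, 2 recovered

    @classmethod
    def empty(cls, length: int) -> "_MapArrays":
        return cls(
            tpos=np.full(length, -1, dtype=np.int64),
            tcontig=np.full(length, -1, dtype=np.int32),
            strand=np.zeros(length, dtype=np.int8),
            prov=np.zeros(length, dtype=np.int8),
        )

    def copy(self) -> "_MapArrays":
        return _MapArrays(
            self.tpos.copy(), self.tcontig.copy(), self.strand.copy(), self.prov.copy()
        )


class RefAlignment:
    """The partial alignment map ``w(k, g_t)`` for one reference genome.

    Parameters
    ----------
    reference_id:
        Name of the reference genome (the genome prefix of MAF ``s`` lines).
    """

    def __init__(self, reference_id: str):
        self.reference_id = reference_id
        self.targets: list[str] = []
        self.ref_contig_lengths: dict[str, int] = {}
        self._arrays: dict[tuple[str, str], _MapArrays] = {}
        # per-target contig name table (index used by _MapArrays.tcontig)
        self._contig_names: dict[str, list[str]] = {}
        self._contig_index: dict[str, dict[str, int]] = {}
        self.target_contig_lengths: dict[str, dict[str, int]] = {}

    # -- construction ------------------------------------------------------

    def _register_target(self, target: str) -> None:
        if target not in self._contig_names:
            self.targets.append(target)
            self._contig_names[target] = []
            self._contig_index[target] = {}
            self.target_contig_lengths[target] = {}

    def _contig_id(self, target: str, contig: str, length: int | None = None) -> int:
        self._register_target(target)
        idx = self._contig_index[target]
        if contig not in idx:
            idx[contig] = len(self._contig_names[target])
            self._contig_names[target].append(contig)
            self.target_contig_lengths[target][contig] = length or 0
        elif length:
            self.target_contig_lengths[target][contig] = max(
                self.target_contig_lengths[target][contig], length
            )
        return idx[contig]

    def _ensure(self, ref_contig: str, target: str) -> _MapArrays:
        key = (ref_contig, target)
        if key not in self._arrays:
            length = self.ref_contig_lengths.get(ref_contig)
            if length is None:
                raise KeyError(f"unknown reference contig {ref_contig!r}")
            self._arrays[key] = _MapArrays.empty(length)
        return self._arrays[key]

    def set_block(
        self,
        ref_contig: str,
        ref_positions: np.ndarray,
        target: str,
        target_contig: str,
        target_positions: np.ndarray,
        strand: int = 1,
        provenance: int = PROVENANCE_ORIGINAL,
        target_contig_length: int | None = None,
    ) -> int:
        """Vectorised assignment of homologous position pairs.

        Positions already mapped are never overwritten (first wins); returns
        the number of conflicting positions that were skipped.
        """
        arrays = self._ensure(ref_contig, target)
        cid = self._contig_id(target, target_contig, target_contig_length)
        free = arrays.tpos[ref_positions] == -1
        conflicts = int((~free).sum())
        idx = ref_positions[free]
        arrays.tpos[idx] = target_positions[free]
        arrays.tcontig[idx] = cid
        arrays.strand[idx] = strand
        arrays.prov[idx] = provenance
        return conflicts

    def copy(self) -> "RefAlignment":
        new = RefAlignment(self.reference_id)
        new.targets = list(self.targets)
        new.ref_contig_lengths = dict(self.ref_contig_lengths)
        new._arrays = {k: v.copy() for k, v in self._arrays.items()}
        new._contig_names = {t: list(v) for t, v in self._contig_names.items()}
        new._contig_index = {t: dict(v) for t, v in self._contig_index.items()}
        new.target_contig_lengths = {t: dict(v) for t, v in self.target_contig_lengths.items()}
        return new

    # -- queries -----------------------------------------------------------

    def _check(self, contig: str, target: str) -> None:
        if contig not in self.ref_contig_lengths:
            raise KeyError(f"unknown reference contig {contig!r}")
        if target not in self._contig_names:
            raise KeyError(f"unknown target genome {target!r}")

    def _arrays_or_none(self, contig: str, target: str) -> _MapArrays | None:
        """Lenient lookup: contigs absent from the alignment count as unaligned."""
        if target not in self._contig_names:
            raise KeyError(f"unknown target genome {target!r}")
        return self._arrays.get((contig, target))

    def map_position(self, contig: str, k: int, target: str):
        """Return the homologous :class:`TargetPosition` of ``k`` or :data:`UNALIGNED`."""
        self._check(contig, target)
        if not 0 <= k < self.ref_contig_lengths[contig]:
            raise IndexError(f"position {k} outside contig {contig!r}")
        arrays = self._arrays.get((contig, target))
        if arrays is None or arrays.tpos[k] < 0:
            return UNALIGNED
        return TargetPosition(
            contig=self._contig_names[target][arrays.tcontig[k]],
            position=int(arrays.tpos[k]),
            strand="+" if arrays.strand[k] >= 0 else "-",
            provenance="original" if arrays.prov[k] == PROVENANCE_ORIGINAL else "recovered",
        )

    def map_arrays(self, contig: str, target: str) -> _MapArrays | None:
        """Raw mapping arrays for a (reference contig, target) pair, or None."""
        self._check(contig, target)
        return self._arrays.get((contig, target))

    def target_contig_names(self, target: str) -> list[str]:
        return self._contig_names[target]

    def exon_alignment_status(self, exon, target: str) -> bool:
        """``W(e, g)``: True iff at least one exon position is aligned in target."""
        arrays = self._arrays_or_none(exon.contig, target)
        if arrays is None:
            return False
        return bool((arrays.tpos[exon.start : exon.end] >= 0).any())

    def aligned_positions(self, exon, target: str) -> np.ndarray:
        """``A(e)``: sorted array of aligned target positions of the exon."""
        arrays = self._arrays_or_none(exon.contig, target)
        if arrays is None:
            return np.empty(0, dtype=np.int64)
        chunk = arrays.tpos[exon.start : exon.end]
        return np.unique(chunk[chunk >= 0])

    def aligned_target_contigs(self, exon, target: str) -> list[str]:
        """Distinct target contigs hit by the exon's aligned positions."""
        arrays = self._arrays_or_none(exon.contig, target)
        if arrays is None:
            return []
        chunk = arrays.tcontig[exon.start : exon.end]
        ids = np.unique(chunk[chunk >= 0])
        return [self._contig_names[target][i] for i in ids]

    def alignment_score(self, exon, target: str) -> float:
        """``r(e)``: fraction of exon positions aligned in the target."""
        if exon.length <= 0:
            raise ValueError("exon length must be positive")
        arrays = self._arrays_or_none(exon.contig, target)
        if arrays is None:
            return 0.0
        n = int((arrays.tpos[exon.start : exon.end] >= 0).sum())
        return n / exon.length


def _split_src(src: str) -> tuple[str, str]:
    if "." not in src:
        raise MafParseError(
            f"MAF source {src!r} lacks the 'genome.contig' naming convention"
        )
    genome, contig = src.split(".", 1)
    return genome, contig


def load_maf(path, reference_id: str) -> RefAlignment:
    """Build the alignment function ``w`` from a MultiZ-style MAF file.

    Every non-gap reference column paired with a non-gap target row yields one
    mapping entry.  Minus-strand target rows are converted to forward-strand
    coordinates through ``srcSize``.  When two blocks map the same reference
    position for the same target, the first block wins and a warning is logged.
    Blocks without a reference row are skipped with a warning.
    """
    aln = RefAlignment(reference_id)
    n_conflicts = 0
    with open(path) as handle:
        try:
            blocks = AlignIO.parse(handle, "maf")
            for block_no, block in enumerate(blocks):
                ref_rec = None
                for rec in block:
                    genome, _ = _split_src(rec.id)
                    if genome == reference_id:
                        ref_rec = rec
                        break
                if ref_rec is None:
                    logger.warning("MAF block %d has no reference row; skipped", block_no)
                    continue
                _, ref_contig = _split_src(ref_rec.id)
                if ref_rec.annotations["strand"] != 1:
                    raise MafParseError(
                        f"reference row of block {block_no} is not on the forward strand"
                    )
                aln.ref_contig_lengths.setdefault(
                    ref_contig, int(ref_rec.annotations["srcSize"])
                )
                ref_seq = np.frombuffer(str(ref_rec.seq).encode("ascii"), dtype=np.uint8)
                ref_nogap = ref_seq != _GAP
                ref_pos = int(ref_rec.annotations["start"]) + np.cumsum(ref_nogap) - 1
                for rec in block:
                    genome, tgt_contig = _split_src(rec.id)
                    if rec is ref_rec or genome == reference_id:
                        continue
                    tgt_seq = np.frombuffer(str(rec.seq).encode("ascii"), dtype=np.uint8)
                    if len(tgt_seq) != len(ref_seq):
                        raise MafParseError(
                            f"row length mismatch in block {block_no} for {rec.id}"
                        )
                    tgt_nogap = tgt_seq != _GAP
                    row_pos = int(rec.annotations["start"]) + np.cumsum(tgt_nogap) - 1
                    src_size = int(rec.annotations["srcSize"])
                    strand = int(rec.annotations["strand"])
                    if strand == -1:
                        fwd_pos = src_size - 1 - row_pos
                    else:
                        fwd_pos = row_pos
                    both = ref_nogap & tgt_nogap
                    n_conflicts += aln.set_block(
                        ref_contig,
                        ref_pos[both],
                        genome,
                        tgt_contig,
                        fwd_pos[both],
                        strand=strand,
                        target_contig_length=src_size,
                    )
        except ValueError as exc:
            if isinstance(exc, MafParseError):
                raise
            raise MafParseError(f"malformed MAF file {path}: {exc}") from exc
    if n_conflicts:
        logger.warning(
            "%d reference positions were mapped by more than one MAF block; "
            "first block kept",
            n_conflicts,
        )
    return aln


def alignment_status_table(
    aln: RefAlignment, exons: ExonSet, targets: Sequence[str] | None = None
):
    """Per (exon, target) table of the alignment indicator ``W(e, g)``."""
    import pandas as pd

    targets = list(targets) if targets is not None else list(aln.targets)
    rows = []
    for exon in exons:
        for t in targets:
            rows.append(
                {
                    "contig": exon.contig,
                    "start": exon.start,
                    "end": exon.end,
                    "gene_type": exon.gene_type,
                    "target": t,
                    "W": int(aln.exon_alignment_status(exon, t)),
                }
            )
    return pd.DataFrame(rows)
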