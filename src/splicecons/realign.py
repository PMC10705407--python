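"""Synteny-based recovery of missing exon alignments.

An exon that is unaligned in a target genome but whose up- and downstream
neighbours are aligned is *syntenic*: the missing homolog, if present, should
lie between the neighbours' aligned positions.  The target segment
``u = [max A(e_a) + 1, min A(e_b) - 1]`` is scanned with an infix
(exon-global, segment-local) minimum-edit-distance alignment; each exon
position landing in a match/mismatch column gains a mapping.  A realignment
of exon ``e`` is accepted only when its score ``r'(e)`` (fraction of exon
positions mapped) exceeds ``mean(R_t) - sd(R_t)``, where ``R_t`` are the
scores of the originally aligned exons in that target — a guard against
placing an exon into an unrelated stretch of sequence.

The edit-distance placement is implemented as a row-vectorised dynamic
program with unit costs and deterministic tie-breaking (leftmost optimal end
column; traceback prefers match/mismatch, then exon-gap, then segment-gap),
so that results are reproducible and testable against a reference dynamic
program.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from splicecons.genome_align_io import (
    PROVENANCE_RECOVERED,
    Exon,
    ExonSet,
    Genome,
    RefAlignment,
)

logger = logging.getLogger(__name__)

DEFAULT_SEGMENT_CAP = 100_000

# traceback move codes
_DIAG, _UP, _LEFT = 0, 1, 2


@dataclass
class ScoreBaseline:
    """Mean/sd of original alignment scores ``R_t`` for one target genome."""

    target: str
    scores: np.ndarray
    mean: float
    sd: float

    @property
    def threshold(self) -> float:
        return self.mean - self.sd


@dataclass
class RealignmentCandidate:
    """One unaligned-but-syntenic exon with its proposed target placement."""

    exon: Exon
    target: str
    flank_a: Exon
    flank_b: Exon
    segment: tuple[str, int, int] | None = None  # (target contig, start, end) half-open
    offsets: np.ndarray | None = None  # per exon position: segment offset or -1
    score_rprime: float = 0.0
    accepted: bool = False
    reason: str = ""


def compute_score_baseline(
    aln: RefAlignment, exons: ExonSet, target: str, ddof: int = 0
) -> ScoreBaseline | None:
    """``R_t`` statistics over originally aligned exons; None if fewer than 2."""
    scores = [
        aln.alignment_score(e, target) for e in exons if aln.exon_alignment_status(e, target)
    ]
    if len(scores) < 2:
        return None
    arr = np.asarray(scores, dtype=float)
    return ScoreBaseline(
        target=target, scores=arr, mean=float(arr.mean()), sd=float(arr.std(ddof=ddof))
    )


def find_syntenic_unaligned(
    aln: RefAlignment, exons: ExonSet, target: str, max_flank_scan: int = 5
) -> list[tuple[Exon, Exon, Exon]]:
    """Unaligned exons with aligned neighbours on one common target contig.

    For each unaligned exon the nearest aligned, non-overlapping flank on
    each side is taken; a bounded outward scan resolves flanks whose aligned
    positions do not share a single target contig.
    """
    out = []
    for contig, contig_exons in exons.by_contig().items():
        status = [aln.exon_alignment_status(e, target) for e in contig_exons]
        for i, exon in enumerate(contig_exons):
            if status[i]:
                continue
            left = [
                e
                for e in reversed(contig_exons[:i])
                if e.end <= exon.start and aln.exon_alignment_status(e, target)
            ][:max_flank_scan]
            right = [
                e
                for e in contig_exons[i + 1 :]
                if e.start >= exon.end and aln.exon_alignment_status(e, target)
            ][:max_flank_scan]
            found = None
            for ea in left:
                ca = aln.aligned_target_contigs(ea, target)
                if len(ca) != 1:
                    continue
                for eb in right:
                    cb = aln.aligned_target_contigs(eb, target)
                    if cb == ca:
                        found = (exon, ea, eb)
                        break
                if found:
                    break
            if found:
                out.append(found)
    return out


def target_segment(
    aln: RefAlignment, flank_a: Exon, flank_b: Exon, target: str
) -> tuple[str, int, int] | None:
    """``u = [max A(e_a) + 1, min A(e_b) - 1]`` as a half-open interval, or None.

    Returns None (INVALID) when the two anchors hit different target contigs
    or when the interval is inverted.
    """
    ca = aln.aligned_target_contigs(flank_a, target)
    cb = aln.aligned_target_contigs(flank_b, target)
    if len(ca) != 1 or ca != cb:
        return None
    pa = aln.aligned_positions(flank_a, target)
    pb = aln.aligned_positions(flank_b, target)
    lo = int(pa.max()) + 1
    hi = int(pb.min()) - 1  # inclusive end
    if lo > hi:
        return None
    return (ca[0], lo, hi + 1)


_ENC = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENC[_b] = _i
    _ENC[_b + 32] = _i


def _encode(seq: str) -> np.ndarray:
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def realign_exon(exon_sequence: str, segment_sequence: str) -> tuple[np.ndarray, float]:
    """Infix edit-distance placement of an exon inside a target segment.

    The exon is consumed in full while the segment's flanks are free.  Every
    exon position aligned in a match/mismatch column is mapped to its segment
    offset; gap columns map nothing.  Returns ``(offsets, r')`` where
    ``offsets[i]`` is the segment offset of exon position ``i`` (or -1) and
    ``r'`` the fraction of mapped positions.  Ties in the optimal placement
    are broken toward the leftmost end column, and the traceback prefers
    match/mismatch over gap moves, maximising the mapped-position count among
    cost-equal paths at each step.
    """
    if not exon_sequence or not segment_sequence:
        raise ValueError("both sequences must be non-empty")
    e = _encode(exon_sequence)
    s = _encode(segment_sequence)
    L, S = len(e), len(s)
    dp = np.empty((L + 1, S + 1), dtype=np.int32)
    dp[0, :] = 0  # free start anywhere in the segment
    js = np.arange(S + 1)
    for i in range(1, L + 1):
        # ambiguous (non-ACGT) codes never match, even against themselves
        sub = ((s != e[i - 1]) | (s == 255) | (e[i - 1] == 255)).astype(np.int32)
        t = np.empty(S + 1, dtype=np.int32)
        t[0] = i
        np.minimum(dp[i - 1, :-1] + sub, dp[i - 1, 1:] + 1, out=t[1:])
        # dp[i, j] = min_{k <= j} t[k] + (j - k): prefix-min of (t - j) plus j
        dp[i] = np.minimum.accumulate(t - js) + js
    j = int(np.argmin(dp[L]))  # argmin returns the leftmost minimum
    offsets = np.full(L, -1, dtype=np.int64)
    i = L
    mapped = 0
    while i > 0 and j >= 0:
        match = s[j - 1] == e[i - 1] and e[i - 1] != 255 if j > 0 else False
        if j > 0 and dp[i, j] == dp[i - 1, j - 1] + (0 if match else 1):
            offsets[i - 1] = j - 1
            mapped += 1
            i -= 1
            j -= 1
        elif dp[i, j] == dp[i - 1, j] + 1:
            i -= 1
        else:
            j -= 1
    return offsets, mapped / L


def accept_candidate(candidate: RealignmentCandidate, baseline: ScoreBaseline) -> bool:
    """Accept iff ``r'(e) > mean(R_t) - sd(R_t)`` (strict)."""
    return candidate.score_rprime > baseline.threshold


def realign_missing_exons(
    aln: RefAlignment,
    exons: ExonSet,
    reference: Genome,
    target_genomes: dict[str, Genome],
    targets: list[str] | None = None,
    segment_cap: int = DEFAULT_SEGMENT_CAP,
    ddof: int = 0,
) -> tuple[list[RealignmentCandidate], dict[str, ScoreBaseline]]:
    """Run the full candidate discovery / placement / filtering procedure.

    Baselines ``R_t`` are computed once from the original alignment per
    target.  Returns all candidates (with accept/reject status and reasons)
    and the per-target baselines; merge separately with
    :func:`merge_alignment`.
    """
    targets = targets if targets is not None else list(aln.targets)
    candidates: list[RealignmentCandidate] = []
    baselines: dict[str, ScoreBaseline] = {}
    for target in targets:
        baseline = compute_score_baseline(aln, exons, target, ddof=ddof)
        triples = find_syntenic_unaligned(aln, exons, target)
        if baseline is None:
            for exon, ea, eb in triples:
                candidates.append(
                    RealignmentCandidate(exon, target, ea, eb, reason="no-baseline")
                )
            continue
        baselines[target] = baseline
        genome = target_genomes[target]
        for exon, ea, eb in triples:
            cand = RealignmentCandidate(exon, target, ea, eb)
            candidates.append(cand)
            seg = target_segment(aln, ea, eb, target)
            if seg is None:
                cand.reason = "invalid-segment"
                continue
            contig, lo, hi = seg
            if hi - lo > segment_cap:
                cand.reason = "segment-too-long"
                continue
            if hi - lo <= 0:
                cand.reason = "empty-segment"
                continue
            cand.segment = seg
            exon_seq = reference.fetch(exon.contig, exon.start, exon.end)
            segment_seq = genome.fetch(contig, lo, hi)
            offsets, score = realign_exon(exon_seq, segment_seq)
            cand.offsets = offsets
            cand.score_rprime = score
            cand.accepted = accept_candidate(cand, baseline)
            cand.reason = "" if cand.accepted else "below-threshold"
    return candidates, baselines


def merge_alignment(
    aln: RefAlignment, candidates: list[RealignmentCandidate]
) -> RefAlignment:
    """Merge accepted realignments into a new alignment ``w'``.

    Positions already mapped in ``w`` are never overwritten; recovered
    positions carry ``recovered`` provenance.
    """
    merged = aln.copy()
    n_conflicts = 0
    for cand in candidates:
        if not cand.accepted or cand.offsets is None or cand.segment is None:
            continue
        contig, lo, _ = cand.segment
        mask = cand.offsets >= 0
        ref_positions = np.arange(cand.exon.start, cand.exon.end, dtype=np.int64)[mask]
        tgt_positions = lo + cand.offsets[mask]
        n_conflicts += merged.set_block(
            cand.exon.contig,
            ref_positions,
            cand.target,
            contig,
            tgt_positions,
            strand=1,
            provenance=PROVENANCE_RECOVERED,
        )
    if n_conflicts:
        logger.warning(
            "%d recovered positions conflicted with existing mappings; originals kept",
            n_conflicts,
        )
    return merged


def completeness_report(
    aln_before: RefAlignment,
    aln_after: RefAlignment | None,
    exons: ExonSet,
    targets: list[str] | None = None,
) -> pd.DataFrame:
    """Aligned (``s_a``), missing (``s_m``) and recovered (``s_r``) pair counts.

    One row per (chromosome label, gene type) stratum; ``s_a + s_m`` equals
    the number of exon/target pairs in the stratum.
    """
    targets = targets if targets is not None else list(aln_before.targets)
    acc: dict[tuple[str, str], dict[str, int]] = {}
    for exon in exons:
        label = exon.chrom_label or exon.contig
        key = (label, exon.gene_type)
        stat = acc.setdefault(key, {"s_a": 0, "s_m": 0, "s_r": 0})
        for t in targets:
            before = aln_before.exon_alignment_status(exon, t)
            if before:
                stat["s_a"] += 1
            else:
                stat["s_m"] += 1
                if aln_after is not None and aln_after.exon_alignment_status(exon, t):
                    stat["s_r"] += 1
    rows = [
        {"chromosome": k[0], "gene_type": k[1], **v} for k, v in sorted(acc.items())
    ]
    return pd.DataFrame(rows)
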