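"""Per-position conservation of splice sites across target genomes.

The conservation function ``C(s, l, t)`` is an indicator that the reference
base at transcript-orientation shift ``l`` from the origin of site ``s``
matches its aligned base in target genome ``t``.  A position that is
unaligned, falls outside the contig, or involves an ambiguous base is never
conserved.  Shifts run along the transcript: on the minus strand the
reference position of shift ``l`` is ``origin - l``, which makes donor and
acceptor profiles strand-symmetric.

Per-site feature vectors collect (1) the number of species conserving the
canonical dinucleotide *jointly* (shifts 0 and 1 both conserved) and (2) the
per-shift species counts for the 60 surrounding shifts ``l in [-30, 31]``
excluding 0 and 1 — the inputs of the splice-site classifier.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from splicecons.annotation import SpliceSite
from splicecons.genome_align_io import Genome, RefAlignment

WINDOW_START = -30
WINDOW_END = 31  # inclusive

#: classifier feature shifts: the window minus the canonical dinucleotide
FEATURE_SHIFTS = tuple(
    l for l in range(WINDOW_START, WINDOW_END + 1) if l not in (0, 1)
)
ALL_SHIFTS = tuple(range(WINDOW_START, WINDOW_END + 1))

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[_b + 32] = _i
_COMP = np.full(256, 255, dtype=np.uint8)
_COMP[:4] = [3, 2, 1, 0]


@dataclass
class ConservationVector:
    """Conservation feature counts of one splice site."""

    site_key: tuple
    joint_dinuc_count: int
    positional_counts: dict[int, int]
    m_used: int

    def to_array(self) -> np.ndarray:
        """[joint, counts at FEATURE_SHIFTS...] — the 61-feature classifier input."""
        return np.array(
            [self.joint_dinuc_count] + [self.positional_counts[l] for l in FEATURE_SHIFTS],
            dtype=float,
        )


class ConservationScorer:
    """Evaluates ``C(s, l, t)`` and feature vectors against loaded genomes.

    Contig sequences are encoded once into numeric arrays so that feature
    computation over many sites is vectorised per (contig, target) group.
    """

    def __init__(
        self,
        aln: RefAlignment,
        reference: Genome,
        target_genomes: dict[str, Genome],
        targets: list[str] | None = None,
    ):
        self.aln = aln
        self.reference = reference
        self.targets = list(targets) if targets is not None else list(aln.targets)
        missing = [t for t in self.targets if t not in target_genomes]
        if missing:
            raise KeyError(f"no sequence loaded for target genomes: {missing}")
        self.target_genomes = target_genomes
        self._ref_codes = {
            name: _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
            for name, seq in reference.contigs.items()
        }
        self._tgt_codes: dict[tuple[str, str], np.ndarray] = {}
        for t in self.targets:
            for name, seq in target_genomes[t].contigs.items():
                self._tgt_codes[(t, name)] = _CODE[
                    np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
                ]

    @property
    def m_used(self) -> int:
        return len(self.targets)

    # -- single-position indicator ----------------------------------------

    def conservation(self, site: SpliceSite, shift: int, target: str) -> int:
        """The indicator ``C(s, l, t)`` in {0, 1}."""
        pos = site.position_at(shift)
        ref_codes = self._ref_codes[site.contig]
        if not 0 <= pos < len(ref_codes):
            return 0
        tp = self.aln.map_position(site.contig, pos, target)
        if not tp:
            return 0
        ref_base = ref_codes[pos]
        tgt_codes = self._tgt_codes[(target, tp.contig)]
        tgt_base = tgt_codes[tp.position]
        if tp.strand == "-":
            tgt_base = _COMP[tgt_base]
        if ref_base == 255 or tgt_base == 255:
            return 0
        return int(ref_base == tgt_base)

    # -- vectorised feature computation -----------------------------------

    def _conservation_matrix(
        self,
        sites: list[SpliceSite],
        shifts: tuple[int, ...],
        targets: list[str] | None = None,
    ) -> np.ndarray:
        """Counts array of shape (n_sites, n_shifts): species conserving each shift."""
        targets = targets if targets is not None else self.targets
        n, k = len(sites), len(shifts)
        counts = np.zeros((n, k), dtype=np.int32)
        self._joint = np.zeros(n, dtype=np.int32)
        shifts_arr = np.asarray(shifts)
        try:
            i0 = shifts.index(0)
            i1 = shifts.index(1)
        except ValueError:
            i0 = i1 = None
        by_contig: dict[str, list[int]] = {}
        for i, s in enumerate(sites):
            by_contig.setdefault(s.contig, []).append(i)
        for contig, idx in by_contig.items():
            ref_codes = self._ref_codes[contig]
            clen = len(ref_codes)
            origins = np.array([sites[i].origin for i in idx])
            sign = np.array([1 if sites[i].strand == "+" else -1 for i in idx])
            pos = origins[:, None] + sign[:, None] * shifts_arr[None, :]
            inside = (pos >= 0) & (pos < clen)
            pos_c = np.clip(pos, 0, clen - 1)
            ref_b = ref_codes[pos_c]
            for t in targets:
                arrays = self.aln.map_arrays(contig, t)
                if arrays is None:
                    continue
                tpos = arrays.tpos[pos_c]
                tcid = arrays.tcontig[pos_c]
                strand = arrays.strand[pos_c]
                mapped = inside & (tpos >= 0)
                cons = np.zeros_like(mapped)
                names = self.aln.target_contig_names(t)
                for cid, tname in enumerate(names):
                    sel = mapped & (tcid == cid)
                    if not sel.any():
                        continue
                    codes = self._tgt_codes.get((t, tname))
                    if codes is None:
                        continue
                    tb = codes[tpos[sel]]
                    neg = strand[sel] < 0
                    tb = np.where(neg, _COMP[tb], tb)
                    rb = ref_b[sel]
                    cons[sel] = (tb == rb) & (tb != 255) & (rb != 255)
                counts[idx] += cons
                if i0 is not None:
                    self._joint[idx] += cons[:, i0] & cons[:, i1]
        return counts

    def feature_vector(self, site: SpliceSite) -> ConservationVector:
        """Joint-dinucleotide count plus the 60 positional counts of one site."""
        counts = self._conservation_matrix([site], ALL_SHIFTS)[0]
        positional = {
            l: int(counts[ALL_SHIFTS.index(l)]) for l in FEATURE_SHIFTS
        }
        return ConservationVector(
            site_key=site.key(),
            joint_dinuc_count=int(self._joint[0]),
            positional_counts=positional,
            m_used=self.m_used,
        )

    def feature_matrix(self, sites: list[SpliceSite]) -> tuple[np.ndarray, list[tuple]]:
        """(n, 61) classifier feature matrix: [joint, 60 positional counts]."""
        counts = self._conservation_matrix(list(sites), ALL_SHIFTS)
        feat_idx = [ALL_SHIFTS.index(l) for l in FEATURE_SHIFTS]
        X = np.column_stack([self._joint, counts[:, feat_idx]]).astype(float)
        return X, [s.key() for s in sites]

    def joint_dinuc_counts(self, sites: list[SpliceSite]) -> np.ndarray:
        """Per-site number of species conserving the canonical dinucleotide jointly."""
        self._conservation_matrix(list(sites), (0, 1))
        return self._joint.copy()



def dinuc_conservation_histogram(joint_counts: np.ndarray, m_used: int) -> np.ndarray:
    """Normalised histogram of joint-dinucleotide species counts (bins 0..m)."""
    if len(joint_counts) == 0:
        return np.zeros(m_used + 1)
    hist = np.bincount(np.asarray(joint_counts, dtype=int), minlength=m_used + 1).astype(
        float
    )
    return hist / hist.sum()


def positional_profile(
    scorer: ConservationScorer,
    sites: list[SpliceSite],
    shifts: tuple[int, ...] = ALL_SHIFTS,
) -> dict[int, float]:
    """Mean conserved-species fraction per shift (canonical shifts included)."""
    if not sites:
        raise ValueError("at least one site required")
    counts = scorer._conservation_matrix(list(sites), tuple(shifts))
    means = counts.mean(axis=0) / scorer.m_used
    return {l: float(means[i]) for i, l in enumerate(shifts)}


def conserved_species_ranking(
    scorer: ConservationScorer, sites: list[SpliceSite]
) -> list[tuple[str, int]]:
    """Per target genome, the number of sites whose canonical dinucleotides it
    conserves jointly, sorted descending."""
    ranking = []
    for t in scorer.targets:
        scorer._conservation_matrix(list(sites), (0, 1), targets=[t])
        ranking.append((t, int((scorer._joint > 0).sum())))
    return sorted(ranking, key=lambda x: (-x[1], x[0]))
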