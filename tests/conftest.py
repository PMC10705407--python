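"""Shared fixtures: synthetic worlds, random MAF fixtures, and oracles."""

from __future__ import annotations

import numpy as np
import pytest

from splicecons.pipeline import run_world_analysis
from splicecons.simdata import SimConfig, SimWorld, simulate_world


@pytest.fixture(scope="session")
def mini_world(tmp_path_factory) -> SimWorld:
    """A small, fast world for unit-level checks."""
    cfg = SimConfig(
        seed=7,
        genome_length=300_000,
        n_genes=10,
        n_targets=8,
        n_random_sites=150,
    )
    return simulate_world(cfg, tmp_path_factory.mktemp("mini_world"))


@pytest.fixture(scope="session")
def default_world(tmp_path_factory) -> SimWorld:
    """The default-configuration world used for the pipeline-level checks."""
    return simulate_world(SimConfig(seed=11), tmp_path_factory.mktemp("default_world"))


@pytest.fixture(scope="session")
def default_result(default_world):
    return run_world_analysis(default_world, seed=11)


@pytest.fixture(scope="session")
def mini_result(mini_world):
    return run_world_analysis(mini_world, seed=7)


# ---------------------------------------------------------------------------
# Random MAF fixtures and an independent column-walk oracle
# ---------------------------------------------------------------------------


def random_maf(
    rng: np.random.Generator,
    n_blocks: int = 20,
    ref_id: str = "ref",
    targets: tuple[str, ...] = ("tgA", "tgB"),
    ref_len: int = 2_000,
    allow_minus: bool = True,
    gap_p: float = 0.15,
) -> str:
    """Random MAF text with gapped rows, minus-strand rows and overlaps."""
    lines = ["##maf version=1", ""]
    bases = "ACGT"
    for _ in range(n_blocks):
        width = int(rng.integers(10, 40))
        ref_start = int(rng.integers(0, ref_len - width))
        cols = []
        ref_row = []
        tgt_rows = {t: [] for t in targets}
        for _c in range(width):
            ref_gap = rng.random() < gap_p
            ref_row.append("-" if ref_gap else bases[rng.integers(0, 4)])
            for t in targets:
                tgt_gap = rng.random() < gap_p
                tgt_rows[t].append("-" if tgt_gap else bases[rng.integers(0, 4)])
        ref_txt = "".join(ref_row)
        ref_size = sum(c != "-" for c in ref_txt)
        if ref_size == 0:
            continue
        lines.append("a score=1.0")
        lines.append(f"s {ref_id}.chr1 {ref_start} {ref_size} + {ref_len} {ref_txt}")
        for t in targets:
            txt = "".join(tgt_rows[t])
            size = sum(c != "-" for c in txt)
            if size == 0:
                continue
            strand = "-" if allow_minus and rng.random() < 0.3 else "+"
            src_size = 3_000
            start = int(rng.integers(0, src_size - size))
            lines.append(f"s {t}.chrT {start} {size} {strand} {src_size} {txt}")
        lines.append("")
    return "\n".join(lines) + "\n"


def column_walk_oracle(maf_text: str, ref_id: str) -> dict:
    """Character-by-character mapping oracle, independent of the loader.

    Returns {(ref_contig, ref_pos, target): (tgt_contig, fwd_pos, strand)}
    with first-block-wins semantics.
    """
    mapping: dict = {}
    blocks: list[list[tuple]] = []
    current: list[tuple] = []
    for line in maf_text.splitlines():
        if line.startswith("a"):
            if current:
                blocks.append(current)
            current = []
        elif line.startswith("s"):
            _, src, start, size, strand, src_size, text = line.split()
            current.append((src, int(start), int(size), strand, int(src_size), text))
    if current:
        blocks.append(current)
    for rows in blocks:
        ref_rows = [r for r in rows if r[0].split(".", 1)[0] == ref_id]
        if not ref_rows:
            continue
        ref = ref_rows[0]
        ref_contig = ref[0].split(".", 1)[1]
        for row in rows:
            genome, tgt_contig = row[0].split(".", 1)
            if genome == ref_id:
                continue
            ref_pos = ref[1]
            row_pos = row[1]
            for rc, tc in zip(ref[5], row[5]):
                if rc != "-" and tc != "-":
                    if row[3] == "-":
                        fwd = row[4] - 1 - row_pos
                    else:
                        fwd = row_pos
                    key = (ref_contig, ref_pos, genome)
                    if key not in mapping:
                        mapping[key] = (tgt_contig, fwd, row[3])
                if rc != "-":
                    ref_pos += 1
                if tc != "-":
                    row_pos += 1
    return mapping


@pytest.fixture()
def maf_fixture(tmp_path):
    """Factory: write random MAF text, return (path, text, oracle mapping)."""

    def make(seed: int = 0, **kwargs):
        rng = np.random.default_rng(seed)
        text = random_maf(rng, **kwargs)
        path = tmp_path / f"random_{seed}.maf"
        path.write_text(text)
        ref_id = kwargs.get("ref_id", "ref")
        return path, text, column_walk_oracle(text, ref_id)

    return make


# ---------------------------------------------------------------------------
# Reference dynamic-programming oracle for infix exon placement
# ---------------------------------------------------------------------------


def infix_dp_oracle(exon: str, segment: str) -> tuple[list[int], float, int]:
    """Quadratic pure-Python infix alignment with the package's tie-breaks.

    Returns (offsets, score, edit_distance): leftmost optimal end column,
    traceback preference match/mismatch > exon-gap > segment-gap.
    """
    e, s = exon.upper(), segment.upper()
    L, S = len(e), len(s)

    def match(i, j):
        a, b = e[i - 1], s[j - 1]
        return a == b and a in "ACGT"

    dp = [[0] * (S + 1) for _ in range(L + 1)]
    for i in range(1, L + 1):
        dp[i][0] = i
        for j in range(1, S + 1):
            dp[i][j] = min(
                dp[i - 1][j - 1] + (0 if match(i, j) else 1),
                dp[i - 1][j] + 1,
                dp[i][j - 1] + 1,
            )
    best = min(dp[L])
    j = dp[L].index(best)
    offsets = [-1] * L
    i = L
    mapped = 0
    while i > 0 and j >= 0:
        if j > 0 and dp[i][j] == dp[i - 1][j - 1] + (0 if match(i, j) else 1):
            offsets[i - 1] = j - 1
            mapped += 1
            i -= 1
            j -= 1
        elif dp[i][j] == dp[i - 1][j] + 1:
            i -= 1
        else:
            j -= 1
    return offsets, mapped / L, best
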