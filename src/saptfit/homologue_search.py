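"""Rank candidate models against a target sequence.

Candidates are scored by global pairwise alignment (BLOSUM62, affine gaps)
and filtered by a redundancy level: in a greedy pass over the input order a
candidate is discarded when its identity to an already-kept sequence exceeds
the level (e.g. 95%). Sequence identity is reported over aligned non-gap
columns.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence as TSequence

from Bio import Align
from Bio.Align import substitution_matrices

from .structures_io import AtomicModel, Chain, Residue, Sequence

__all__ = [
    "AlignmentResult",
    "align_pair",
    "remove_redundancy",
    "rank_candidates",
    "split_domains",
]


@dataclasses.dataclass
class AlignmentResult:
    """Aligned columns between target and candidate.

    ``pairs`` holds 0-based (target_index, candidate_index) tuples for every
    aligned (non-gap) column; ``target_range`` is 1-based inclusive.
    """

    pairs: list[tuple[int, int]]
    identity: float  # percent over aligned columns
    coverage: float  # fraction of target residues aligned
    target_range: tuple[int, int]
    score: float = 0.0

    def __post_init__(self) -> None:
        t_idx = [p[0] for p in self.pairs]
        c_idx = [p[1] for p in self.pairs]
        if any(b <= a for a, b in zip(t_idx, t_idx[1:])) or any(
            b <= a for a, b in zip(c_idx, c_idx[1:])
        ):
            raise ValueError("alignment pairs must be strictly increasing")
        if not (0.0 <= self.identity <= 100.0 and 0.0 <= self.coverage <= 1.0):
            raise ValueError("identity/coverage out of range")


def _make_aligner(
    matrix: str = "BLOSUM62", gap_open: float = 11.0, gap_extend: float = 1.0
) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.mode = "global"
    aligner.open_gap_score = -abs(gap_open)
    aligner.extend_gap_score = -abs(gap_extend)
    return aligner


def align_pair(
    target: Sequence | str,
    candidate: Sequence | str,
    matrix: str = "BLOSUM62",
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> AlignmentResult:
    """Optimal global alignment of target vs candidate.

    Identity is the percentage of aligned columns with identical residues;
    coverage is the fraction of target residues appearing in an aligned
    column.
    """
    t = target.residues if isinstance(target, Sequence) else Sequence("t", target).residues
    c = (
        candidate.residues
        if isinstance(candidate, Sequence)
        else Sequence("c", candidate).residues
    )
    if not t or not c:
        raise ValueError("sequences must be non-empty")
    aligner = _make_aligner(matrix, gap_open, gap_extend)
    aln = aligner.align(t, c)[0]
    pairs: list[tuple[int, int]] = []
    for (ts, te), (cs, ce) in zip(*aln.aligned):
        pairs.extend((ti, ci) for ti, ci in zip(range(ts, te), range(cs, ce)))
    if not pairs:
        return AlignmentResult([], 0.0, 0.0, (0, 0), float(aln.score))
    n_ident = sum(1 for ti, ci in pairs if t[ti] == c[ci])
    identity = 100.0 * n_ident / len(pairs)
    coverage = len(pairs) / len(t)
    target_range = (pairs[0][0] + 1, pairs[-1][0] + 1)
    return AlignmentResult(pairs, identity, coverage, target_range, float(aln.score))


def remove_redundancy(
    candidates: TSequence[Sequence], level: float = 95.0
) -> list[Sequence]:
    """Greedy redundancy filter in input order.

    A candidate is kept unless its pairwise identity to any already-kept
    sequence exceeds ``level`` percent. At level 100 only exact duplicates
    (100% identity) are removed.
    """
    if not 50.0 <= level <= 100.0:
        raise ValueError(f"redundancy level must be in [50, 100], got {level}")
    cut = 100.0 - 1e-9 if level == 100.0 else level
    kept: list[Sequence] = []
    for cand in candidates:
        redundant = any(
            align_pair(prev, cand).identity > cut for prev in kept
        )
        if not redundant:
            kept.append(cand)
    return kept


def rank_candidates(
    target: Sequence,
    library: TSequence[tuple[Sequence, str]],
) -> list[tuple[AlignmentResult, str]]:
    """Rank library entries by alignment score to the target (descending).

    Ties break by identity, then input order. Each entry keeps its
    AlignmentResult for downstream model editing.
    """
    if not library:
        raise ValueError("library must be non-empty")
    scored = []
    for order, (seq, model_path) in enumerate(library):
        aln = align_pair(target, seq)
        scored.append((-aln.score, -aln.identity, order, aln, model_path))
    scored.sort(key=lambda t: t[:3])
    return [(aln, path) for *_, aln, path in scored]


def split_domains(
    model: AtomicModel, ranges: TSequence[tuple[int, int]]
) -> list[AtomicModel]:
    """Slice a model into sub-models by residue-number ranges (inclusive).

    Ranges must be non-overlapping and fall inside the model's residue
    numbering; chain ids are preserved.
    """
    ordered = sorted(ranges)
    for (a1, b1), (a2, b2) in zip(ordered, ordered[1:]):
        if b1 >= a2:
            raise ValueError(f"overlapping ranges ({a1},{b1}) and ({a2},{b2})")
    present = {r.seq_num for c in model.chains for r in c.residues}
    out = []
    for lo, hi in ranges:
        if lo > hi:
            raise ValueError(f"empty range ({lo},{hi})")
        if lo not in present or hi not in present:
            raise ValueError(f"range ({lo},{hi}) outside model residue numbers")
        chains = []
        for c in model.chains:
            res = [
                Residue(r.seq_num, r.name, [dataclasses.replace(a) for a in r.atoms])
                for r in c.residues
                if lo <= r.seq_num <= hi
            ]
            if res:
                chains.append(Chain(c.chain_id, res))
        out.append(AtomicModel(chains))
    return out
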