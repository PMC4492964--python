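"""Multilocus-lineage (clone) assignment and the clonality index.

Two colonies are treated as ramets of the same genet when their multilocus
genotypes coincide at all but at most ``max_mismatch`` of the loci typed in
both (a single discordant locus is attributed to a somatic mutation or a
scoring error). Lineages are the single-linkage closure of that pairwise
relation, so each MLL is an equivalence class.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .genotype import MISSING, GenotypeMatrix, QCFlag, SampleRecord


class IncomparablePairError(ValueError):
    """A pair of samples shares no typed locus (or too few to compare)."""


@dataclass(frozen=True)
class PairDiff:
    n_compared: int
    n_mismatch: int

    def __post_init__(self):
        if not 0 <= self.n_mismatch <= self.n_compared:
            raise ValueError("need 0 <= n_mismatch <= n_compared")


@dataclass
class MLLPartition:
    """Colony -> lineage assignment with the headline counts."""

    assignment: dict[str, str]

    @property
    def n(self) -> int:
        return len(self.assignment)

    @property
    def n_mll(self) -> int:
        return len(set(self.assignment.values()))

    def members(self) -> dict[str, list[str]]:
        """mll_id -> colony ids, in first-appearance order."""
        out: dict[str, list[str]] = {}
        for cid, mid in self.assignment.items():
            out.setdefault(mid, []).append(cid)
        return out

    def as_labels(self, sample_ids: Sequence[str]) -> list[str]:
        return [self.assignment[s] for s in sample_ids]


def genotype_mismatch(
    sample_a: SampleRecord,
    sample_b: SampleRecord,
    loci: Sequence[str] | None = None,
) -> PairDiff:
    """Count shared typed loci and unordered-genotype mismatches."""
    if loci is None:
        loci = sorted(set(sample_a.genotypes) & set(sample_b.genotypes))
    n_compared = 0
    n_mismatch = 0
    for lid in loci:
        ga = sample_a.genotypes[lid]
        gb = sample_b.genotypes[lid]
        if ga[0] == MISSING or gb[0] == MISSING:
            continue
        n_compared += 1
        if ga != gb:
            n_mismatch += 1
    if n_compared == 0:
        raise IncomparablePairError(
            f"samples {sample_a.colony_id!r} and {sample_b.colony_id!r} share no typed locus"
        )
    return PairDiff(n_compared=n_compared, n_mismatch=n_mismatch)


def _pairwise_counts(arr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs (n_compared, n_mismatch) matrices from an allele array."""
    n = arr.shape[0]
    present = arr[:, :, 0] > MISSING
    ncmp = np.zeros((n, n), dtype=np.int64)
    nmis = np.zeros((n, n), dtype=np.int64)
    for i in range(n - 1):
        eq = (arr[i, :, 0] == arr[i + 1 :, :, 0]) & (arr[i, :, 1] == arr[i + 1 :, :, 1])
        both = present[i] & present[i + 1 :]
        c = both.sum(axis=1)
        m = (both & ~eq).sum(axis=1)
        ncmp[i, i + 1 :] = c
        ncmp[i + 1 :, i] = c
        nmis[i, i + 1 :] = m
        nmis[i + 1 :, i] = m
    return ncmp, nmis


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def assign_mlls(
    matrix: GenotypeMatrix,
    max_mismatch: int = 1,
    min_compared: int = 5,
) -> MLLPartition:
    """Partition colonies into multilocus lineages.

    A pair is linked when it shares at least ``min_compared`` typed loci
    and mismatches at no more than ``max_mismatch`` of them; lineages are
    connected components of the link graph. Lineage ids are deterministic,
    numbered by the input order of each lineage's first member, so the
    result is invariant to sample order up to relabeling.
    """
    n = matrix.n_samples
    if n == 0:
        raise ValueError("empty matrix")
    arr = matrix.allele_array()
    ncmp, nmis = _pairwise_counts(arr)

    iu = np.triu_indices(n, k=1)
    bad = np.where(ncmp[iu] == 0)[0]
    if bad.size:
        i, j = iu[0][bad[0]], iu[1][bad[0]]
        raise IncomparablePairError(
            f"samples {matrix.sample_ids[i]!r} and {matrix.sample_ids[j]!r} "
            "share no typed locus"
        )

    uf = _UnionFind(n)
    link = (ncmp >= min_compared) & (nmis <= max_mismatch)
    for i, j in zip(*np.where(np.triu(link, k=1))):
        uf.union(int(i), int(j))

    width = len(str(n))
    root_to_id: dict[int, str] = {}
    assignment: dict[str, str] = {}
    for i, sid in enumerate(matrix.sample_ids):
        root = uf.find(i)
        if root not in root_to_id:
            root_to_id[root] = f"MLL{len(root_to_id) + 1:0{width}d}"
        assignment[sid] = root_to_id[root]
    return MLLPartition(assignment=assignment)


def clonality_index(partition: MLLPartition) -> float:
    """N_MLL / N: 1 means every colony is a distinct lineage."""
    if partition.n < 1:
        raise ValueError("empty partition")
    return partition.n_mll / partition.n


def flag_single_locus_variants(
    matrix: GenotypeMatrix,
    partition: MLLPartition,
    mode: str = "drop_locus",
) -> list[QCFlag]:
    """Flag loci where ramets of one lineage disagree at exactly one locus.

    ``mode='drop_locus'`` (characterization/reference type) emits one
    locus-wide drop per affected locus. ``mode='zero_allele'`` names the
    deviant sample(s): within each lineage the minority genotype at the
    discordant locus is the one zeroed; a 1-1 tie blames the sample whose
    genotype appears later in input order.
    """
    if mode not in ("drop_locus", "zero_allele"):
        raise ValueError(f"unknown mode {mode!r}")
    idx = {sid: i for i, sid in enumerate(matrix.sample_ids)}
    arr = matrix.allele_array()
    locus_ids = matrix.locus_ids
    present = arr[:, :, 0] > MISSING

    flagged_loci: set[str] = set()
    flagged_calls: set[tuple[str, str]] = set()
    for members in partition.members().values():
        if len(members) < 2:
            continue
        rows = [idx[m] for m in members]
        discordant: set[int] = set()
        for a_pos in range(len(rows) - 1):
            i = rows[a_pos]
            for j in rows[a_pos + 1 :]:
                both = present[i] & present[j]
                diff = both & (
                    (arr[i, :, 0] != arr[j, :, 0]) | (arr[i, :, 1] != arr[j, :, 1])
                )
                if diff.sum() == 1:
                    discordant.add(int(np.where(diff)[0][0]))
        for li in discordant:
            lid = locus_ids[li]
            flagged_loci.add(lid)
            if mode == "zero_allele":
                # minority genotype among typed members is the deviant one;
                # a tie blames the genotype whose first carrier comes later
                counts: dict[tuple[int, int], list[int]] = {}
                for r in rows:
                    if present[r, li]:
                        counts.setdefault(tuple(arr[r, li]), []).append(r)
                if len(counts) < 2:
                    continue
                ranked = sorted(
                    counts.items(), key=lambda kv: (len(kv[1]), -min(kv[1]))
                )
                for r in ranked[0][1]:
                    flagged_calls.add((matrix.sample_ids[r], lid))

    if mode == "drop_locus":
        return [
            QCFlag(locus_id=lid, issue="single_locus_variant", action="drop_locus")
            for lid in sorted(flagged_loci)
        ]
    return [
        QCFlag(
            locus_id=lid,
            issue="single_locus_variant",
            action="zero_allele",
            sample_id=sid,
        )
        for sid, lid in sorted(flagged_calls)
    ]


def collapse_to_mlls(matrix: GenotypeMatrix, partition: MLLPartition) -> GenotypeMatrix:
    """Keep one representative colony per lineage: the first in input order."""
    seen: set[str] = set()
    keep: list[SampleRecord] = []
    for s in matrix.samples:
        mid = partition.assignment[s.colony_id]
        if mid in seen:
            continue
        seen.add(mid)
        keep.append(s)
    return GenotypeMatrix(loci=list(matrix.loci), samples=keep)


def write_mll_tsv(partition: MLLPartition, path) -> None:
    lines = ["colony_id\tmll_id"]
    lines += [f"{cid}\t{mid}" for cid, mid in partition.assignment.items()]
    lines.append(
        f"# N_MLL={partition.n_mll}\tN={partition.n}\t"
        f"N_MLL/N={clonality_index(partition):.3f}"
    )
    Path(path).write_text("\n".join(lines) + "\n")


def read_mll_tsv(path) -> MLLPartition:
    assignment: dict[str, str] = {}
    for line in Path(path).read_text().splitlines()[1:]:
        if not line.strip() or line.startswith("#"):
            continue
        cid, mid = line.split("\t")[:2]
        assignment[cid] = mid
    return MLLPartition(assignment=assignment)
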