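"""Cross-validation subset construction.

Redundant peptides that end up on both sides of a train/test split inflate
cross-validated performance estimates.  Three partitioning strategies are
provided: a plain random split, Hobohm-1 greedy homology clustering on
ungapped sequence identity, and common-motif clustering (single linkage on
shared identical substrings).  Clustered records are always dealt to folds
as whole clusters, optionally keeping only one representative per cluster.

No gapped alignment is used anywhere: identity between two peptides is the
best ungapped overlap over all relative offsets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np


@dataclass
class CVPartition:
    """Assignment of records to cross-validation folds.

    ``fold_of[i]`` is the fold index of record ``i``, or -1 when the record
    was disregarded (non-representative member of a cluster under
    ``representatives_only``).  When built from clusters, all members of a
    cluster share one fold.
    """

    n_folds: int
    fold_of: np.ndarray
    clusters: Optional[list[list[int]]] = None
    representatives_only: bool = False

    def fold_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_of == fold)

    @property
    def retained(self) -> np.ndarray:
        return np.flatnonzero(self.fold_of >= 0)


def random_split(n_records: int, n_folds: int, seed: int) -> CVPartition:
    """Randomly deal records into ``n_folds`` folds of near-equal size."""
    if n_folds < 2:
        raise ValueError("need at least 2 folds")
    if n_records < n_folds:
        raise ValueError(f"cannot split {n_records} records into {n_folds} folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_records)
    fold_of = np.empty(n_records, dtype=np.int64)
    fold_of[order] = np.arange(n_records) % n_folds
    return CVPartition(n_folds=n_folds, fold_of=fold_of)


def ungapped_identity(seq_a: str, seq_b: str, min_overlap: Optional[int] = None) -> float:
    """Best ungapped identity between two sequences, in [0, 1].

    The two sequences are slid against each other over all relative
    offsets; for each offset the number of matching positions in the
    overlap is counted, and the maximum count is divided by the length of
    the shorter sequence.  Overlaps shorter than ``min_overlap`` (default:
    the length of the shorter sequence) are not considered.  Symmetric in
    its arguments.
    """
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    la, lb = len(seq_a), len(seq_b)
    shorter = min(la, lb)
    if min_overlap is None:
        min_overlap = shorter
    min_overlap = max(1, min(min_overlap, shorter))
    best = 0
    # offset = start of seq_b relative to start of seq_a
    for offset in range(-(lb - 1), la):
        lo_a = max(0, offset)
        hi_a = min(la, offset + lb)
        overlap = hi_a - lo_a
        if overlap < min_overlap:
            continue
        matches = sum(
            1 for i in range(lo_a, hi_a) if seq_a[i] == seq_b[i - offset]
        )
        if matches > best:
            best = matches
    return best / shorter


def _common_flanks(sequences: Sequence[str], quorum: float = 0.95) -> tuple[int, int]:
    """Longest prefix/suffix shared by at least ``quorum`` of the sequences.

    Peptide arrays often attach constant linker flanks to every probe;
    those flanks would dominate identity estimates, so they are detected
    (allowing rare synthesis variants, hence the quorum) and trimmed before
    clustering.  Trimming is capped so the shortest sequence keeps at least
    one residue.
    """
    n = len(sequences)
    min_len = min(len(s) for s in sequences)
    need = quorum * n

    def run_length(getter) -> int:
        length = 0
        for j in range(min_len):
            counts: dict[str, int] = {}
            for s in sequences:
                ch = getter(s, j)
                counts[ch] = counts.get(ch, 0) + 1
            if max(counts.values()) >= need:
                length += 1
            else:
                break
        return length

    prefix = run_length(lambda s, j: s[j])
    suffix = run_length(lambda s, j: s[len(s) - 1 - j])
    while prefix + suffix >= min_len and (prefix or suffix):
        if suffix >= prefix:
            suffix -= 1
        else:
            prefix -= 1
    return prefix, suffix


def hobohm1_clusters(
    sequences: Sequence[str],
    threshold: float,
    trim_flanks: bool = False,
    min_overlap: Optional[int] = None,
) -> list[list[int]]:
    """Greedy Hobohm-1 clustering on ungapped identity.

    Sequences are visited in a deterministic priority order (descending
    length, ties alphabetical); each sequence joins the cluster of the
    first representative it matches with identity strictly greater than
    ``threshold``, otherwise it founds a new cluster.  Returns clusters as
    lists of original record indices, in order of foundation.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    seqs = list(sequences)
    if trim_flanks and len(seqs) > 1:
        pre, suf = _common_flanks(seqs)
        cmp_seqs = [s[pre : len(s) - suf] if suf else s[pre:] for s in seqs]
    else:
        cmp_seqs = seqs
    order = sorted(range(len(seqs)), key=lambda i: (-len(seqs[i]), seqs[i]))
    clusters: list[list[int]] = []
    reps: list[int] = []
    for idx in order:
        placed = False
        for c, rep in enumerate(reps):
            eff_overlap = min_overlap
            ident = ungapped_identity(cmp_seqs[idx], cmp_seqs[rep], eff_overlap)
            if ident > threshold:
                clusters[c].append(idx)
                placed = True
                break
        if not placed:
            clusters.append([idx])
            reps.append(idx)
    return clusters


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def common_motif_clusters(sequences: Sequence[str], motif_min_len: int) -> list[list[int]]:
    """Single-linkage clusters of "shares an identical substring of length
    >= motif_min_len".

    Two peptides share such a stretch iff they share a k-mer with
    k = motif_min_len, so clustering reduces to union-find over k-mer
    occurrence.  When a motif-length interval is scanned, the caller passes
    the smallest length in the interval.
    """
    if motif_min_len < 1:
        raise ValueError("motif_min_len must be >= 1")
    n = len(sequences)
    uf = _UnionFind(n)
    first_seen: dict[str, int] = {}
    for i, seq in enumerate(sequences):
        for j in range(len(seq) - motif_min_len + 1):
            kmer = seq[j : j + motif_min_len]
            if kmer in first_seen:
                uf.union(first_seen[kmer], i)
            else:
                first_seen[kmer] = i
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(uf.find(i), []).append(i)
    return [groups[r] for r in sorted(groups)]


def clusters_to_folds(
    clusters: list[list[int]],
    n_folds: int,
    representatives_only: bool = False,
    seed: int = 0,
) -> CVPartition:
    """Deal whole clusters onto folds, balancing retained-record counts.

    Clusters are placed largest-first onto the currently smallest fold
    (ties between equal-size clusters broken by a seed-shuffled order,
    ties between equally small folds by fold index).  Under
    ``representatives_only`` only each cluster's first member is retained;
    the rest get fold -1.
    """
    if len(clusters) < n_folds:
        raise ValueError(
            f"{len(clusters)} clusters cannot fill {n_folds} folds"
        )
    n_records = max(max(c) for c in clusters) + 1
    rng = np.random.default_rng(seed)
    shuffled = list(rng.permutation(len(clusters)))
    weight = (lambda c: 1) if representatives_only else len
    order = sorted(shuffled, key=lambda ci: -weight(clusters[ci]))
    fold_of = np.full(n_records, -1, dtype=np.int64)
    loads = np.zeros(n_folds, dtype=np.int64)
    for ci in order:
        cluster = clusters[ci]
        fold = int(np.argmin(loads))
        members = cluster[:1] if representatives_only else cluster
        for idx in members:
            fold_of[idx] = fold
        loads[fold] += len(members)
    return CVPartition(
        n_folds=n_folds,
        fold_of=fold_of,
        clusters=clusters,
        representatives_only=representatives_only,
    )


def build_partition(
    peptides: Sequence[str],
    n_folds: int,
    method: str = "random",
    threshold: float = 0.8,
    representatives_only: bool = False,
    trim_flanks: bool = False,
    motif_min_len: Optional[int] = None,
    seed: int = 0,
) -> CVPartition:
    """Build a CV partition with the configured strategy."""
    if method == "random":
        return random_split(len(peptides), n_folds, seed)
    if method == "hobohm1":
        clusters = hobohm1_clusters(
            peptides, threshold, trim_flanks=trim_flanks, min_overlap=motif_min_len
        )
    elif method == "common_motif":
        if motif_min_len is None:
            raise ValueError("common_motif clustering needs a motif length")
        clusters = common_motif_clusters(peptides, motif_min_len)
    else:
        raise ValueError(f"unknown partition method {method!r}")
    return clusters_to_folds(clusters, n_folds, representatives_only, seed)
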