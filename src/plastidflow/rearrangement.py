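"""Gene-order rearrangement analysis on circular signed permutations.

A plastome's annotated gene order induces a circular signed permutation of
synteny blocks; the number of rearrangements separating two species is then
a genome rearrangement distance on those permutations.  Two classical
distances are provided: the breakpoint distance (oriented adjacencies of one
genome missing from the other) and the double-cut-and-join (DCJ) distance,
which for unichromosomal circular genomes equals ``N - C``, the number of
blocks minus the number of cycles in the adjacency graph.  DCJ counts
minimal rearrangement events (inversions in the unichromosomal case) and is
the default "pairwise rearrangement" (PR) statistic.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genome_io import Plastome

__all__ = [
    "SignedGenome",
    "genome_to_gene_order",
    "find_synteny_blocks",
    "breakpoint_distance",
    "dcj_distance",
    "pairwise_matrix",
]

GeneOrder = list[tuple[str, int]]  # (gene_id, sign) with sign in {+1, -1}


@dataclass(frozen=True)
class SignedGenome:
    """A circular, signed order of synteny blocks for one species."""

    species: str
    blocks: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError("empty block order")
        labels = sorted(abs(b) for b in self.blocks)
        if 0 in labels or len(set(labels)) != len(labels):
            raise ValueError(f"blocks must be nonzero and unique, got {self.blocks}")

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    def adjacencies(self) -> set[frozenset]:
        """Extremity adjacencies of the circular order.

        Block ``b`` has a tail ``(b, 't')`` and a head ``(b, 'h')``; a
        positively oriented block is traversed tail→head.  The adjacency set
        is invariant under rotation and under flipping the whole molecule.
        """
        adj: set[frozenset] = set()
        n = len(self.blocks)
        for i in range(n):
            x = self.blocks[i]
            y = self.blocks[(i + 1) % n]
            right_of_x = (abs(x), "h" if x > 0 else "t")
            left_of_y = (abs(y), "t" if y > 0 else "h")
            adj.add(frozenset([right_of_x, left_of_y]))
        return adj


def genome_to_gene_order(genome: Plastome) -> GeneOrder:
    """Circular signed gene order of a plastome, by feature start position."""
    feats = sorted(genome.features, key=lambda f: f.start)
    return [(f.gene_id, 1 if f.strand == "+" else -1) for f in feats]


def _signed_adjacency_set(order: GeneOrder) -> set[tuple]:
    """Directed signed gene adjacencies, both traversal directions."""
    adj: set[tuple] = set()
    n = len(order)
    for i in range(n):
        a, sa = order[i]
        b, sb = order[(i + 1) % n]
        adj.add(((a, sa), (b, sb)))
        adj.add(((b, -sb), (a, -sa)))
    return adj


def find_synteny_blocks(
    gene_orders: Mapping[str, GeneOrder],
) -> tuple[list[list[str]], dict[str, SignedGenome]]:
    """Decompose shared single-copy genes into maximal conserved blocks.

    A block is a maximal run of genes that is consecutive, with consistent
    relative orientation, in every species.  Genes absent from any species or
    duplicated anywhere are ignored.  Returns the blocks (gene lists in
    reference order and orientation) and each species' circular signed block
    permutation.
    """
    if len(gene_orders) < 2:
        raise ValueError("need at least two species")
    species = list(gene_orders)
    counts = []
    for sp in species:
        c: dict[str, int] = {}
        for g, _ in gene_orders[sp]:
            c[g] = c.get(g, 0) + 1
        counts.append(c)
    shared = {g for g, n in counts[0].items() if n == 1}
    for c in counts[1:]:
        shared &= {g for g, n in c.items() if n == 1}
    if len(shared) < 2:
        raise ValueError(f"only {len(shared)} shared single-copy genes; need >= 2")

    filtered = {
        sp: [(g, s) for g, s in gene_orders[sp] if g in shared] for sp in species
    }
    ref = filtered[species[0]]
    other_adj = [_signed_adjacency_set(filtered[sp]) for sp in species[1:]]

    n = len(ref)
    conserved = [
        all((ref[i], ref[(i + 1) % n]) in adj for adj in other_adj) for i in range(n)
    ]  # conserved[i]: adjacency between ref[i] and ref[i+1]

    if all(conserved):
        blocks_idx = [list(range(n))]
    else:
        # cut the circle at every breakpoint
        cut_after = [i for i in range(n) if not conserved[i]]
        blocks_idx = []
        for k, start_cut in enumerate(cut_after):
            begin = (start_cut + 1) % n
            end_cut = cut_after[(k + 1) % len(cut_after)]
            run = []
            i = begin
            while True:
                run.append(i)
                if i == end_cut:
                    break
                i = (i + 1) % n
            blocks_idx.append(run)

    blocks = [[ref[i][0] for i in run] for run in blocks_idx]
    # gene -> (block id, sign of gene within the reference block orientation)
    gene_block: dict[str, tuple[int, int]] = {}
    for bid, run in enumerate(blocks_idx, start=1):
        for i in run:
            g, s = ref[i]
            gene_block[g] = (bid, s)

    genomes: dict[str, SignedGenome] = {}
    for sp in species:
        order = filtered[sp]
        m = len(order)
        # rotate so position 0 starts a block (its predecessor is in another block)
        start = 0
        if len(blocks) > 1:
            for i in range(m):
                prev_b = gene_block[order[i - 1][0]][0]
                if gene_block[order[i][0]][0] != prev_b:
                    start = i
                    break
        perm: list[int] = []
        i = 0
        while i < m:
            g, s = order[(start + i) % m]
            bid, ref_sign = gene_block[g]
            sign = 1 if s == ref_sign else -1
            perm.append(sign * bid)
            i += len(blocks[bid - 1])
        if sorted(abs(b) for b in perm) != list(range(1, len(blocks) + 1)):
            raise ValueError(
                f"inconsistent block decomposition for species {sp!r}"
            )
        genomes[sp] = SignedGenome(species=sp, blocks=tuple(perm))
    return blocks, genomes


def _check_same_blocks(a: SignedGenome, b: SignedGenome) -> None:
    if sorted(abs(x) for x in a.blocks) != sorted(abs(x) for x in b.blocks):
        raise ValueError(f"block sets differ between {a.species} and {b.species}")


def breakpoint_distance(a: SignedGenome, b: SignedGenome) -> int:
    """Number of oriented adjacencies of ``a`` absent from ``b`` (circular)."""
    _check_same_blocks(a, b)
    return len(a.adjacencies() - b.adjacencies())


def dcj_distance(a: SignedGenome, b: SignedGenome) -> int:
    """Minimal number of double-cut-and-join operations from ``a`` to ``b``.

    For unichromosomal circular genomes this is ``N - C`` where ``C`` is the
    number of cycles in the adjacency graph: the multigraph on block
    extremities whose edges are the adjacencies of ``a`` and of ``b``.
    """
    _check_same_blocks(a, b)
    parent: dict = {}

    def find(x):
        while parent.get(x, x) != x:
            parent[x] = parent.get(parent[x], parent[x])
            x = parent[x]
        return x

    def union(x, y):
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[rx] = ry

    extremities = [(abs(blk), e) for blk in a.blocks for e in ("t", "h")]
    for x in extremities:
        parent[x] = x
    for adj in list(a.adjacencies()) + list(b.adjacencies()):
        pair = list(adj)
        if len(pair) == 2:
            union(pair[0], pair[1])
    cycles = len({find(x) for x in extremities})
    # each extremity has one a-edge and one b-edge, so components are cycles;
    # a shared adjacency forms a trivial 2-cycle
    return a.n_blocks - cycles


def pairwise_matrix(
    genomes: Sequence[SignedGenome] | Mapping[str, SignedGenome],
    distance: str = "dcj",
) -> pd.DataFrame:
    """Symmetric species x species matrix of rearrangement counts."""
    if isinstance(genomes, Mapping):
        genomes = list(genomes.values())
    if len(genomes) < 2:
        raise ValueError("need at least two genomes")
    fn = {"dcj": dcj_distance, "breakpoint": breakpoint_distance}.get(distance)
    if fn is None:
        raise ValueError(f"unknown distance {distance!r}")
    names = [g.species for g in genomes]
    mat = np.zeros((len(genomes), len(genomes)), dtype=int)
    for i, j in combinations(range(len(genomes)), 2):
        d = fn(genomes[i], genomes[j])
        mat[i, j] = mat[j, i] = d
    return pd.DataFrame(mat, index=names, columns=names)
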