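"""Marker extraction from all-vs-all alignments of catalog gene variants.

Variants of the same gene family within a genus are aligned pairwise
(global alignment); every column where two variants disagree yields a
candidate *marker* on each of them -- a substitution allele or an indel
that distinguishes that variant from at least one other.  Each marker
carries a *sharing set* (which group members carry the same allele at
the homologous position) and a *uniqueness*: the number of distinct
strains in the sharing set.  Uniqueness 1 means the allele is private to
one strain, so observing it in a metagenome pins the strain down
unambiguously; higher values mean the evidence is compatible with a
group of strains.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np

from .catalog import Catalog, GeneRecord

__all__ = [
    "VariantGroup",
    "Marker",
    "MarkerSet",
    "group_variants",
    "pairwise_align",
    "extract_markers",
    "markers_for_catalog",
]

GAP = "-"

MATCH, MISMATCH, GAP_COST = 1, -1, -2


@dataclass(frozen=True)
class VariantGroup:
    """Gene variants sharing a (genus, TAS family) key."""

    key: tuple[str, str]
    members: tuple[GeneRecord, ...]


@dataclass(frozen=True)
class Marker:
    """A distinguishing position/allele on one gene variant.

    ``position`` is a 0-based offset on the owner's (ungapped) sequence.
    ``allele`` is the owner's base(s) there (empty string for a deletion
    relative to other variants).  ``sharing_set`` lists every group
    member -- the owner included -- that carries the same allele at the
    homologous position; ``uniqueness`` counts the distinct strains among
    them.
    """

    gene_id: str
    position: int
    kind: str  # substitution | insertion | deletion
    allele: str
    sharing_set: frozenset[str]
    uniqueness: int

    def __post_init__(self) -> None:
        if self.kind not in ("substitution", "insertion", "deletion"):
            raise ValueError(f"bad marker kind {self.kind!r}")
        if self.gene_id not in self.sharing_set:
            raise ValueError("owner must belong to its sharing set")
        if self.uniqueness < 1:
            raise ValueError("uniqueness must be >= 1")


@dataclass
class MarkerSet:
    """Markers for one or more variant groups, indexed by (gene, position).

    Besides the markers themselves the set keeps the per-position allele
    table (``carriers``: which members carry which allele at each marker
    position) and the group membership, both needed later to decide which
    strains are consistent with alleles observed in reads.
    """

    markers: dict[tuple[str, int], Marker] = field(default_factory=dict)
    #: (gene_id, position) -> {allele: set of carrier gene_ids}
    carriers: dict[tuple[str, int], dict[str, set[str]]] = field(default_factory=dict)
    #: gene_id -> gene_ids of its variant group (itself included)
    group_members: dict[str, set[str]] = field(default_factory=dict)
    #: gene_id -> strain label
    strain_of: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.markers)

    def __iter__(self) -> Iterator[Marker]:
        return iter(self.markers.values())

    def for_gene(self, gene_id: str) -> list[Marker]:
        return [m for (g, _), m in sorted(self.markers.items()) if g == gene_id]

    def group_strains(self, gene_id: str) -> set[str]:
        """Strains represented in the owner's variant group."""
        return {self.strain_of[g] for g in self.group_members.get(gene_id, {gene_id})}

    def update(self, other: "MarkerSet") -> None:
        self.markers.update(other.markers)
        self.carriers.update(other.carriers)
        self.group_members.update(other.group_members)
        self.strain_of.update(other.strain_of)

    # -- serialization ------------------------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        """Write markers as TSV (1-based positions in the file)."""
        with open(path, "w") as fh:
            fh.write(
                "gene_id\tposition\tkind\tallele\tsharing_set\tuniqueness\talleles\n"
            )
            for (gene_id, pos), m in sorted(self.markers.items()):
                table = {
                    allele: sorted(ids)
                    for allele, ids in self.carriers.get((gene_id, pos), {}).items()
                }
                fh.write(
                    f"{gene_id}\t{pos + 1}\t{m.kind}\t{m.allele or '.'}\t"
                    f"{','.join(sorted(m.sharing_set))}\t{m.uniqueness}\t"
                    f"{json.dumps(table)}\n"
                )

    @classmethod
    def from_tsv(cls, path: str | Path, catalog: Catalog) -> "MarkerSet":
        ms = cls()
        for group in group_variants(catalog):
            ids = {r.gene_id for r in group.members}
            for r in group.members:
                ms.group_members[r.gene_id] = ids
                ms.strain_of[r.gene_id] = r.strain
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            idx = {name: i for i, name in enumerate(header)}
            for line in fh:
                f = line.rstrip("\n").split("\t")
                gene_id = f[idx["gene_id"]]
                pos = int(f[idx["position"]]) - 1
                allele = f[idx["allele"]]
                allele = "" if allele == "." else allele
                sharing = frozenset(f[idx["sharing_set"]].split(","))
                ms.markers[(gene_id, pos)] = Marker(
                    gene_id=gene_id,
                    position=pos,
                    kind=f[idx["kind"]],
                    allele=allele,
                    sharing_set=sharing,
                    uniqueness=int(f[idx["uniqueness"]]),
                )
                ms.carriers[(gene_id, pos)] = {
                    a: set(ids) for a, ids in json.loads(f[idx["alleles"]]).items()
                }
        return ms


# ---------------------------------------------------------------------------
# grouping


def group_variants(catalog: Catalog) -> list[VariantGroup]:
    """Partition catalog records by (genus, TAS family), ordered by key."""
    buckets: dict[tuple[str, str], list[GeneRecord]] = {}
    for rec in catalog:
        buckets.setdefault((rec.genus, rec.tas_family), []).append(rec)
    return [
        VariantGroup(key=key, members=tuple(buckets[key])) for key in sorted(buckets)
    ]


# ---------------------------------------------------------------------------
# pairwise global alignment (Needleman-Wunsch, linear gap cost)
#
# Scoring is fixed at match +1 / mismatch -1 / gap -2 and the traceback
# tie-break order is fixed (substitution preferred over a gap, a gap in b
# preferred over a gap in a) so that marker extraction is deterministic.


def _dp_matrix(a: str, b: str) -> np.ndarray:
    n, m = len(a), len(b)
    bv = np.frombuffer(b.encode(), dtype=np.uint8)
    av = np.frombuffer(a.encode(), dtype=np.uint8)
    M = np.empty((n + 1, m + 1), dtype=np.int64)
    cols = np.arange(m + 1, dtype=np.int64)
    M[0] = GAP_COST * cols
    two_j = -GAP_COST * cols  # +2j offsets for the left-gap running max
    for i in range(1, n + 1):
        prev = M[i - 1]
        sub = np.where(bv == av[i - 1], MATCH, MISMATCH)
        cand = np.empty(m + 1, dtype=np.int64)
        cand[0] = GAP_COST * i
        np.maximum(prev[:-1] + sub, prev[1:] + GAP_COST, out=cand[1:])
        # close over chains of gaps in a: M[i,j] = max_k<=j (cand[k] + GAP*(j-k))
        np.subtract(np.maximum.accumulate(cand + two_j), two_j, out=M[i])
    return M


def pairwise_align(a: str, b: str) -> tuple[str, str, int]:
    """Optimal global alignment of two DNA strings.

    Returns ``(aligned_a, aligned_b, score)`` with ``-`` as the gap
    symbol.  Deterministic: ties are resolved by preferring a
    match/mismatch column, then a gap in ``b``, then a gap in ``a``.
    """
    if not a or not b:
        raise ValueError("pairwise_align requires non-empty sequences")
    M = _dp_matrix(a, b)
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = len(a), len(b)
    while i > 0 or j > 0:
        here = M[i, j]
        if i > 0 and j > 0 and here == M[i - 1, j - 1] + (
            MATCH if a[i - 1] == b[j - 1] else MISMATCH
        ):
            i -= 1
            j -= 1
            out_a.append(a[i])
            out_b.append(b[j])
        elif i > 0 and here == M[i - 1, j] + GAP_COST:
            i -= 1
            out_a.append(a[i])
            out_b.append(GAP)
        else:
            j -= 1
            out_a.append(GAP)
            out_b.append(b[j])
    return "".join(reversed(out_a)), "".join(reversed(out_b)), int(M[len(a), len(b)])


# ---------------------------------------------------------------------------
# marker extraction


def _column_view(aln_v: str, aln_w: str) -> tuple[list[str], dict[int, str]]:
    """Project an alignment onto the first sequence's coordinates.

    Returns ``chars``: for each position of v, the w character aligned to
    it (``-`` when w has a gap there), and ``inserts``: v-boundary ->
    bases that w carries where v has a gap (boundary = index of the next
    v base; len(v) for a trailing insertion).
    """
    chars: list[str] = []
    inserts: dict[int, str] = {}
    vpos = 0
    pending = ""
    for cv, cw in zip(aln_v, aln_w):
        if cv == GAP:
            pending += cw
        else:
            if pending:
                inserts[vpos] = inserts.get(vpos, "") + pending
                pending = ""
            chars.append(cw)
            vpos += 1
    if pending:
        inserts[vpos] = inserts.get(vpos, "") + pending
    return chars, inserts


def extract_markers(group: VariantGroup) -> MarkerSet:
    """Find every distinguishing position among a group's variants.

    All ordered pairs are aligned; a column where the pair disagrees
    becomes a candidate marker on the first member, at its own ungapped
    coordinate.  A run of consecutive gap columns is one indel marker at
    the run's leftmost owner coordinate.  Candidates landing on the same
    (gene, position) are merged, and the sharing set of a marker is the
    set of members whose pairwise alignment to the owner shows the
    owner's allele at that position.
    """
    ms = MarkerSet()
    ids = {r.gene_id for r in group.members}
    for rec in group.members:
        ms.group_members[rec.gene_id] = ids
        ms.strain_of[rec.gene_id] = rec.strain
    if len(group.members) < 2:
        return ms

    # project every alignment (v, w) onto v's coordinates, once
    views: dict[tuple[str, str], tuple[list[str], dict[int, str]]] = {}
    members = list(group.members)
    for v in members:
        for w in members:
            if v.gene_id == w.gene_id:
                continue
            aln_v, aln_w, _ = pairwise_align(v.sequence, w.sequence)
            views[(v.gene_id, w.gene_id)] = _column_view(aln_v, aln_w)

    # candidate markers per owner
    candidates: dict[tuple[str, int], tuple[str, str]] = {}  # -> (kind, allele)
    for v in members:
        for w in members:
            if v.gene_id == w.gene_id:
                continue
            chars, inserts = views[(v.gene_id, w.gene_id)]
            p = 0
            L = len(v.sequence)
            while p < L:
                cw = chars[p]
                if cw == GAP:
                    # w lacks a run of v bases: insertion marker on v
                    start = p
                    while p < L and chars[p] == GAP:
                        p += 1
                    key = (v.gene_id, start)
                    candidates.setdefault(
                        key, ("insertion", v.sequence[start:p])
                    )
                    continue
                if cw != v.sequence[p]:
                    key = (v.gene_id, p)
                    candidates.setdefault(key, ("substitution", v.sequence[p]))
                p += 1
            for boundary in inserts:
                # w carries bases v lacks: deletion marker on v
                pos = min(boundary, L - 1)
                candidates.setdefault((v.gene_id, pos), ("deletion", ""))

    strain = {r.gene_id: r.strain for r in members}
    by_id = {r.gene_id: r for r in members}
    for (owner_id, pos), (kind, allele) in sorted(candidates.items()):
        owner = by_id[owner_id]
        sharing = {owner_id}
        table: dict[str, set[str]] = {}
        span = len(allele) if kind != "deletion" else 0
        for u in members:
            if u.gene_id == owner_id:
                continue
            chars, inserts = views[(owner_id, u.gene_id)]
            if kind == "deletion":
                u_allele = inserts.get(pos, "")
            else:
                u_allele = "".join(
                    c for c in chars[pos : pos + max(span, 1)] if c != GAP
                )
            table.setdefault(u_allele, set()).add(u.gene_id)
            if u_allele == allele:
                sharing.add(u.gene_id)
        table.setdefault(allele, set()).add(owner_id)
        uniqueness = len({strain[g] for g in sharing})
        ms.markers[(owner_id, pos)] = Marker(
            gene_id=owner_id,
            position=pos,
            kind=kind,
            allele=allele,
            sharing_set=frozenset(sharing),
            uniqueness=uniqueness,
        )
        ms.carriers[(owner_id, pos)] = table
    return ms


def markers_for_catalog(catalog: Catalog) -> MarkerSet:
    """Extract markers for every variant group of a catalog."""
    out = MarkerSet()
    for group in group_variants(catalog):
        out.update(extract_markers(group))
    return out
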