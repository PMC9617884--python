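"""Greedy centroid clustering of Cas9 proteins at a percent-identity level.

UCLUST-style: proteins are canonically sorted (decreasing length, then id),
each joins the first existing centroid reaching the identity threshold,
otherwise founds a new cluster. Identity is computed on a global alignment
(match +1, mismatch -1, gap -2) as matching columns over alignment columns,
with terminal gap columns excluded from the denominator.
"""

from __future__ import annotations

import logging
from collections import Counter
from typing import Mapping, Sequence

from Bio import Align

from .model import Cas9Cluster, CasLocus

logger = logging.getLogger(__name__)

MIN_CAS9_LENGTH = 950


def filter_cas9_min_length(loci: Sequence[CasLocus], min_len: int = MIN_CAS9_LENGTH) -> list[CasLocus]:
    """Drop loci whose Cas9 protein is shorter than ``min_len`` amino acids.

    The bound is inclusive: a protein of exactly ``min_len`` is retained.
    """
    kept = [l for l in loci if len(l.cas9_protein) >= min_len]
    n_excluded = len(loci) - len(kept)
    if n_excluded:
        logger.info("excluded %d loci with Cas9 < %d aa", n_excluded, min_len)
    return kept


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    return aligner


def pairwise_identity(a: str, b: str) -> float:
    """Fractional identity of a global alignment of two protein sequences.

    identity = matching columns / alignment columns, where columns inside
    terminal gaps (overhangs at either end) do not enter the denominator.
    Internal gap columns count as non-matching.
    """
    if not a or not b:
        raise ValueError("empty sequence")
    if a == b:
        return 1.0
    aln = _make_aligner().align(a, b)[0]
    sa, sb = str(aln[0]), str(aln[1])
    # trim terminal gap columns: first/last column where both rows have residues
    first = 0
    while sa[first] == "-" or sb[first] == "-":
        first += 1
    last = len(sa) - 1
    while sa[last] == "-" or sb[last] == "-":
        last -= 1
    columns = last - first + 1
    matches = sum(1 for x, y in zip(sa[first : last + 1], sb[first : last + 1]) if x == y and x != "-")
    return matches / columns


def canonical_order(proteins: Mapping[str, str]) -> list[str]:
    """Decreasing length, ties broken by lexicographic id."""
    return sorted(proteins, key=lambda pid: (-len(proteins[pid]), pid))


def greedy_cluster(
    proteins: Mapping[str, str],
    level: float,
    subtypes: Mapping[str, str] | None = None,
    prefix: str = "C",
) -> list[Cas9Cluster]:
    """Greedy first-centroid-wins clustering at ``level`` identity.

    Deterministic for a fixed input set: the canonical sort fixes both the
    centroid founding order and the assignment order.
    """
    if not 0.5 <= level <= 1.0:
        raise ValueError(f"identity level {level} outside [0.5, 1.0]")
    centroids: list[tuple[str, str]] = []  # (protein id, sequence)
    members: dict[str, list[str]] = {}
    for pid in canonical_order(proteins):
        seq = proteins[pid]
        for cid, cseq in centroids:
            if pairwise_identity(seq, cseq) >= level:
                members[cid].append(pid)
                break
        else:
            centroids.append((pid, seq))
            members[pid] = [pid]
    clusters = []
    for i, (cid, _) in enumerate(centroids):
        subtype = "unknown"
        if subtypes:
            votes = Counter(subtypes.get(m, "unknown") for m in members[cid])
            subtype = max(votes, key=lambda s: (votes[s], s))
        clusters.append(
            Cas9Cluster(
                cluster_id=f"{prefix}{int(round(level * 100))}_{i:04d}",
                level=level,
                representative_id=cid,
                member_ids=members[cid],
                subtype=subtype,
            )
        )
    return clusters


def write_cluster_table(clusters: Sequence[Cas9Cluster], path) -> None:
    with open(path, "w") as fh:
        fh.write("#protein_id\tcluster_id\tlevel\trepresentative_id\tsubtype\n")
        for c in clusters:
            for m in c.member_ids:
                fh.write(f"{m}\t{c.cluster_id}\t{c.level:g}\t{c.representative_id}\t{c.subtype}\n")


def read_cluster_table(path) -> list[Cas9Cluster]:
    rows: dict[str, dict] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            pid, cid, level, rep, subtype = line.split("\t")
            rows.setdefault(cid, {"level": float(level), "rep": rep, "subtype": subtype, "members": []})
            rows[cid]["members"].append(pid)
    return [
        Cas9Cluster(cluster_id=cid, level=d["level"], representative_id=d["rep"],
                    member_ids=d["members"], subtype=d["subtype"])
        for cid, d in rows.items()
    ]
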