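"""Spacer orientation, deduplication and protospacer matching.

The matcher finds every full-length placement of a spacer on either strand
of a genome with at most ``max_variations`` combined mismatches and gap
columns. It is exact (complete): a vectorized semi-global dynamic program
computes, for every genome end position, the minimal edit cost of aligning
the whole spacer to a window ending there; candidate ends are then traced
back in a small banded window to recover start coordinates and the
mismatch/gap breakdown.

Reported placements are the non-dominated ones: a placement is suppressed
only when a strictly lower-cost placement overlaps it by at least half the
spacer length (this removes the shifted echoes every real site would
otherwise spawn, while keeping all equal-quality overlapping placements).

N is conservative: a column pairing any base with N counts as a mismatch,
even N against N.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from ._sequences import revcomp
from .model import CasLocus, GenomeRecord, ProtospacerMatch, Spacer

logger = logging.getLogger(__name__)

MIN_SPACER_LEN = 18


@dataclass
class MatchParams:
    """Parameters of the protospacer search."""

    max_variations: int = 4
    flank_len: int = 30
    both_strands: bool = True

    def __post_init__(self) -> None:
        if self.max_variations < 0:
            raise ValueError("max_variations must be >= 0")
        if self.flank_len < 1:
            raise ValueError("flank_len must be >= 1")


# ---------------------------------------------------------------------------
# Spacer orientation and deduplication
# ---------------------------------------------------------------------------

def orient_spacers(locus: CasLocus) -> list[Spacer]:
    """Orient the locus' spacers by the majority strand of cas1/cas2/cas9.

    If the majority strand is '-', spacers are reverse-complemented and the
    array order reversed; on a strand tie the spacers are returned unchanged
    with the array flagged 'unknown'.
    """
    votes = [g.strand for g in locus.cas_genes if g.name in {"cas1", "cas2", "cas9"}]
    n_minus = votes.count("-")
    n_plus = votes.count("+")
    if not votes:
        flip = False
        flag = "unknown"
        logger.warning("locus %s: no cas gene with known strand; orientation unknown", locus.locus_id)
    elif n_minus == n_plus:
        flip = False
        flag = "unknown"
        logger.warning("locus %s: cas gene strand tie; orientation unknown", locus.locus_id)
    else:
        flip = n_minus > n_plus
        flag = "reversed" if flip else "as-annotated"

    spacers: list[Spacer] = []
    for array in locus.arrays:
        array.orientation = flag
        seqs = array.spacers
        if flip:
            seqs = [revcomp(s) for s in reversed(seqs)]
        for i, seq in enumerate(seqs):
            spacers.append(
                Spacer(
                    spacer_id=f"{locus.locus_id}:{array.array_id}:{i}",
                    sequence=seq,
                    locus_id=locus.locus_id,
                )
            )
    return spacers


def dedupe_spacers(spacers: Iterable[Spacer]) -> tuple[list[Spacer], dict[str, list[Spacer]]]:
    """Collapse spacers to one per distinct sequence.

    Returns (unique spacers, provenance): provenance maps each sequence to
    every original Spacer carrying it. Unique spacer ids are ``u<N>`` in
    first-seen order, so the result is deterministic for a fixed input order.
    """
    provenance: dict[str, list[Spacer]] = defaultdict(list)
    order: list[str] = []
    for sp in spacers:
        if sp.sequence not in provenance:
            order.append(sp.sequence)
        provenance[sp.sequence].append(sp)
    unique = [
        Spacer(spacer_id=f"u{i}", sequence=seq, locus_id=provenance[seq][0].locus_id)
        for i, seq in enumerate(order)
    ]
    return unique, dict(provenance)


# ---------------------------------------------------------------------------
# Matching
# ---------------------------------------------------------------------------

def _encode(seq: str, is_query: bool) -> np.ndarray:
    # genome N -> 4, query N -> 5: N never equals anything, including N
    table = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 5 if is_query else 4}
    return np.fromiter((table[c] for c in seq), dtype=np.int8, count=len(seq))


def _end_costs(query: np.ndarray, target: np.ndarray) -> np.ndarray:
    """cost[e] = minimal unit-cost edit distance of the full query against a
    target window ending at position e+1, free start (semi-global DP)."""
    G = len(target)
    j = np.arange(G + 1, dtype=np.int32)
    prev = np.zeros(G + 1, dtype=np.int32)
    for i, q in enumerate(query, start=1):
        cur = np.empty(G + 1, dtype=np.int32)
        cur[0] = i
        np.minimum(prev[:-1] + (target != q), prev[1:] + 1, out=cur[1:])
        # horizontal pass: cur[j] = min_{j' <= j} cur[j'] + (j - j')
        cur = np.minimum.accumulate(cur - j) + j
        prev = cur
    return prev[1:]


def _traceback(spacer: str, genome: str, end: int, max_var: int) -> tuple[int, int, int]:
    """Recover (start, mismatches, gaps) for the best full-length alignment
    of ``spacer`` against the genome window ending exactly at ``end``.

    Deterministic preference at each step: diagonal, then spacer-gap-free
    vertical (genome deletion in spacer... i.e. spacer base vs gap), then
    horizontal (genome base vs gap).
    """
    L = len(spacer)
    w0 = max(0, end - L - max_var)
    window = genome[w0:end]
    n, m = L, len(window)
    D = np.zeros((n + 1, m + 1), dtype=np.int32)
    D[:, 0] = np.arange(n + 1)
    for i in range(1, n + 1):
        qi = spacer[i - 1]
        for jj in range(1, m + 1):
            sub = D[i - 1, jj - 1] + (0 if (qi == window[jj - 1] and qi != "N") else 1)
            D[i, jj] = min(sub, D[i - 1, jj] + 1, D[i, jj - 1] + 1)
    i, jj = n, m
    mismatches = gaps = 0
    while i > 0:
        qi = spacer[i - 1]
        diag_cost = 0 if (jj > 0 and qi == window[jj - 1] and qi != "N") else 1
        if jj > 0 and D[i, jj] == D[i - 1, jj - 1] + diag_cost:
            mismatches += diag_cost
            i, jj = i - 1, jj - 1
        elif D[i, jj] == D[i - 1, jj] + 1:
            gaps += 1
            i -= 1
        else:
            gaps += 1
            jj -= 1
    return w0 + jj, mismatches, gaps


def _placements_one_strand(spacer: str, genome: str, max_var: int) -> list[tuple[int, int, int, int]]:
    """All non-dominated placements (start, end, mismatches, gaps) of the
    spacer on the given (forward-encoded) genome string."""
    q = _encode(spacer, is_query=True)
    t = _encode(genome, is_query=False)
    costs = _end_costs(q, t)
    cand_ends = np.nonzero(costs <= max_var)[0] + 1
    if cand_ends.size == 0:
        return []
    L = len(spacer)
    placements = []
    for e in cand_ends.tolist():
        s, mm, gp = _traceback(spacer, genome, e, max_var)
        placements.append((s, e, mm, gp))
    # dominance: drop a placement if a strictly cheaper one overlaps >= ceil(L/2)
    min_overlap = -(-L // 2)
    kept = []
    for s, e, mm, gp in placements:
        cost = mm + gp
        dominated = any(
            (mm2 + gp2) < cost and min(e, e2) - max(s, s2) >= min_overlap
            for s2, e2, mm2, gp2 in placements
        )
        if not dominated:
            kept.append((s, e, mm, gp))
    return kept


def get_flanks(
    genome: GenomeRecord, start: int, end: int, strand: str, flank_len: int = 30
) -> tuple[str, str]:
    """Flanks of a protospacer placement, in the protospacer frame.

    For '+' placements these are the genomic context left/right of [start,
    end); for '-' placements the forward-strand context is reverse
    complemented and the sides swap, so downstream is always 3' of the
    protospacer as read along the oriented spacer. Flanks are truncated at
    contig ends.
    """
    if not 0 <= start <= end <= len(genome.sequence):
        raise ValueError("placement outside genome")
    left = genome.sequence[max(0, start - flank_len) : start]
    right = genome.sequence[end : end + flank_len]
    if strand == "+":
        return left, right
    return revcomp(right), revcomp(left)


def find_protospacers(
    spacer: Spacer, genomes: Sequence[GenomeRecord], params: MatchParams | None = None
) -> list[ProtospacerMatch]:
    """Find every retained full-length placement of ``spacer`` in ``genomes``.

    Coordinates are always on the forward strand; minus-strand placements
    carry strand '-' and frame-corrected flanks.
    """
    params = params or MatchParams()
    if len(spacer.sequence) < MIN_SPACER_LEN:
        raise ValueError(
            f"spacer {spacer.spacer_id} shorter than {MIN_SPACER_LEN} nt"
        )
    out: list[ProtospacerMatch] = []
    for genome in genomes:
        G = len(genome.sequence)
        strands = ["+", "-"] if params.both_strands else ["+"]
        for strand in strands:
            seq = genome.sequence if strand == "+" else revcomp(genome.sequence)
            for s, e, mm, gp in _placements_one_strand(spacer.sequence, seq, params.max_variations):
                if strand == "-":
                    s, e = G - e, G - s
                up, down = get_flanks(genome, s, e, strand, params.flank_len)
                m = ProtospacerMatch(
                    spacer_id=spacer.spacer_id,
                    genome_id=genome.id,
                    strand=strand,
                    start=s,
                    end=e,
                    mismatches=mm,
                    gaps=gp,
                    up_flank=up,
                    down_flank=down,
                )
                assert m.variations <= params.max_variations
                out.append(m)
    out.sort(key=lambda m: (m.genome_id, m.start, m.end, m.strand))
    return out


def match_all(
    spacers: Sequence[Spacer], genomes: Sequence[GenomeRecord], params: MatchParams | None = None
) -> list[ProtospacerMatch]:
    """Run :func:`find_protospacers` for every spacer."""
    params = params or MatchParams()
    out: list[ProtospacerMatch] = []
    for sp in spacers:
        out.extend(find_protospacers(sp, genomes, params))
    return out


def matched_segment(match: ProtospacerMatch, genome: GenomeRecord) -> str:
    """Genome substring of a placement, read in the protospacer frame."""
    seg = genome.sequence[match.start : match.end]
    return seg if match.strand == "+" else revcomp(seg)
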