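"""Flank consensus construction, anchored logos and the PAM call.

For each (Cas9 cluster, unique spacer) pair, every flanked protospacer
sequence found with that spacer (up-flank + matched segment + down-flank,
all in the protospacer frame) is multiply aligned and collapsed into one
consensus; the spacer is then relocated exactly in the consensus to anchor
the up/down flank regions. Per-cluster logos are built from these consensi
and a PAM is called when at least one position is conserved beyond
max(1 bit, Q3 + 1.5*IQR) of the pooled information distribution, on one
side only.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from ._sequences import BASES, BASE_INDEX, iupac_for_bases
from .model import DOWNSTREAM, UPSTREAM, FlankConsensus, PamLogo, PamPrediction

logger = logging.getLogger(__name__)


@dataclass
class CallParams:
    """Thresholds of the PAM call."""

    min_spacers: int = 10
    floor_bits: float = 1.0
    iqr_mult: float = 1.5
    gap_col_frac: float = 0.5

    def __post_init__(self) -> None:
        if min(self.min_spacers, self.floor_bits, self.iqr_mult, self.gap_col_frac) <= 0:
            raise ValueError("all CallParams must be positive")


# ---------------------------------------------------------------------------
# Multiple alignment (center star) and consensus
# ---------------------------------------------------------------------------

_MATCH, _MISMATCH, _GAP = 1, -1, -2


def _nw_align(a: str, b: str) -> tuple[str, str]:
    """Global alignment with match +1 / mismatch -1 / gap -2 and a fixed
    traceback preference (diagonal, then gap-in-b, then gap-in-a)."""
    n, m = len(a), len(b)
    S = np.empty((n + 1, m + 1), dtype=np.int32)
    S[0, :] = np.arange(m + 1) * _GAP
    S[:, 0] = np.arange(n + 1) * _GAP
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            d = S[i - 1, j - 1] + (_MATCH if ai == b[j - 1] else _MISMATCH)
            S[i, j] = max(d, S[i - 1, j] + _GAP, S[i, j - 1] + _GAP)
    ra, rb = [], []
    i, j = n, m
    while i > 0 or j > 0:
        if i > 0 and j > 0 and S[i, j] == S[i - 1, j - 1] + (_MATCH if a[i - 1] == b[j - 1] else _MISMATCH):
            ra.append(a[i - 1]); rb.append(b[j - 1]); i -= 1; j -= 1
        elif i > 0 and S[i, j] == S[i - 1, j] + _GAP:
            ra.append(a[i - 1]); rb.append("-"); i -= 1
        else:
            ra.append("-"); rb.append(b[j - 1]); j -= 1
    return "".join(reversed(ra)), "".join(reversed(rb))


def align_flanked_set(sequences: Sequence[str]) -> list[str]:
    """Deterministic center-star progressive multiple alignment.

    The center is the longest sequence (ties: lexicographically smallest);
    every other sequence is pairwise-aligned to it and gaps are merged with
    the usual once-a-gap-always-a-gap rule. Identical inputs align gap-free.
    """
    if not sequences:
        raise ValueError("empty sequence set")
    if len(sequences) == 1:
        return [sequences[0]]
    order = sorted(range(len(sequences)), key=lambda i: (-len(sequences[i]), sequences[i], i))
    center_idx = order[0]
    center = sequences[center_idx]

    # master center row with accumulated gaps + each aligned row
    master = list(center)
    rows: dict[int, list[str]] = {center_idx: list(center)}
    for idx in order[1:]:
        seq = sequences[idx]
        ac, asq = _nw_align(center, seq)
        # map the fresh pairwise alignment onto the master gap pattern
        merged_master: list[str] = []
        merged_rows: dict[int, list[str]] = {k: [] for k in rows}
        new_row: list[str] = []
        mi = pi = 0  # cursors into master and pairwise-center
        while mi < len(master) or pi < len(ac):
            m_gap = mi < len(master) and master[mi] == "-"
            p_gap = pi < len(ac) and ac[pi] == "-"
            if mi < len(master) and pi < len(ac) and not m_gap and not p_gap:
                merged_master.append(master[mi])
                for k in rows:
                    merged_rows[k].append(rows[k][mi])
                new_row.append(asq[pi])
                mi += 1; pi += 1
            elif m_gap:
                merged_master.append("-")
                for k in rows:
                    merged_rows[k].append(rows[k][mi])
                new_row.append("-")
                mi += 1
            else:  # p_gap (or master exhausted)
                merged_master.append("-")
                for k in rows:
                    merged_rows[k].append("-")
                new_row.append(asq[pi])
                pi += 1
        master = merged_master
        rows = merged_rows
        rows[idx] = new_row
    width = len(master)
    out = []
    for i in range(len(sequences)):
        row = "".join(rows[i])
        assert len(row) == width
        out.append(row)
    return out


def collapse_consensus(alignment: Sequence[str], gap_col_frac: float = 0.5) -> str:
    """Collapse an alignment to a consensus: columns with a gap fraction
    strictly above ``gap_col_frac`` are dropped; elsewhere the most frequent
    non-gap base wins, ties broken toward the alphabetically smallest."""
    if not alignment:
        raise ValueError("empty alignment")
    n = len(alignment)
    width = len(alignment[0])
    out = []
    for j in range(width):
        col = [row[j] for row in alignment]
        n_gaps = col.count("-")
        if n_gaps / n > gap_col_frac:
            continue
        counts = Counter(c for c in col if c != "-")
        if not counts:
            continue
        best = max(counts, key=lambda b: (counts[b], -ord(b)))
        out.append(best)
    return "".join(out)


def locate_spacer(consensus: str, spacer: str) -> Optional[int]:
    """Leftmost exact occurrence of the spacer in the consensus, or None.

    Multiple occurrences take the leftmost with a warning; zero occurrences
    mean the consensus must be discarded.
    """
    offset = consensus.find(spacer)
    if offset < 0:
        return None
    if consensus.find(spacer, offset + 1) >= 0:
        logger.warning("spacer occurs more than once in consensus; taking leftmost")
    return offset


def build_flank_consensus(
    cluster_id: str,
    spacer_seq: str,
    flanked_sequences: Sequence[str],
    params: CallParams | None = None,
    flank_len: int = 30,
) -> Optional[FlankConsensus]:
    """Align, collapse and anchor the flanked matches of one spacer.

    Returns None (discard, with a warning) when the collapsed consensus no
    longer contains the spacer exactly.
    """
    params = params or CallParams()
    alignment = align_flanked_set(flanked_sequences)
    consensus = collapse_consensus(alignment, params.gap_col_frac)
    offset = locate_spacer(consensus, spacer_seq)
    if offset is None:
        logger.warning("cluster %s: consensus lost the exact spacer; discarded", cluster_id)
        return None
    # clip flanks to the stated maximum so downstream logos stay anchored
    up_start = max(0, offset - flank_len)
    down_end = min(len(consensus), offset + len(spacer_seq) + flank_len)
    return FlankConsensus(
        cluster_id=cluster_id,
        spacer_seq=spacer_seq,
        consensus=consensus[up_start:down_end],
        spacer_offset=offset - up_start,
    )


# ---------------------------------------------------------------------------
# Logos and the PAM call
# ---------------------------------------------------------------------------

def build_logo(
    consensi: Sequence[FlankConsensus], side: str, min_coverage: int = 10, max_positions: int = 30
) -> PamLogo:
    """Anchored per-position frequencies over the consensus flanks of one
    cluster. Position i counts only the consensi covering it; positions with
    coverage below ``min_coverage`` are excluded."""
    if side not in {UPSTREAM, DOWNSTREAM}:
        raise ValueError(f"bad side {side!r}")
    counts = np.zeros((max_positions, 4), dtype=float)
    coverage = np.zeros(max_positions, dtype=int)
    for fc in consensi:
        flank = fc.up_flank if side == UPSTREAM else fc.down_flank
        if side == UPSTREAM:
            flank = flank[::-1]  # position 1 = adjacent base, counting away
        for i, base in enumerate(flank[:max_positions]):
            if base in BASE_INDEX:
                counts[i, BASE_INDEX[base]] += 1
                coverage[i] += 1
    positions = [i + 1 for i in range(max_positions) if coverage[i] >= min_coverage]
    if not positions:
        return PamLogo.empty(side)
    rows = np.array([counts[p - 1] / coverage[p - 1] for p in positions])
    return PamLogo(side=side, positions=positions, freqs=rows,
                   coverage=np.array([coverage[p - 1] for p in positions]))


def conservation_threshold(pooled_information: np.ndarray, params: CallParams) -> tuple[float, float, float]:
    """(T, Q3, IQR): T = max(floor, Q3 + iqr_mult * IQR), quartiles by
    linear interpolation between order statistics."""
    if pooled_information.size == 0:
        return params.floor_bits, 0.0, 0.0
    q1, q3 = np.percentile(pooled_information, [25.0, 75.0])
    iqr = q3 - q1
    return max(params.floor_bits, q3 + params.iqr_mult * iqr), float(q3), float(iqr)


def encode_consensus_pam(logo: PamLogo, threshold: float, cum_freq: float = 0.9) -> str:
    """IUPAC consensus of a logo: a position is non-N iff its information
    exceeds half the conservation threshold; its letter encodes the smallest
    base set, taken in decreasing frequency, reaching ``cum_freq`` cumulative
    frequency. The string spans position 1 through the last non-N position
    (trailing Ns trimmed; an all-N logo encodes to the empty string)."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    info = dict(zip(logo.positions, logo.information))
    freqs = dict(zip(logo.positions, logo.freqs))
    max_pos = max(logo.positions, default=0)
    letters = []
    for pos in range(1, max_pos + 1):
        if pos not in info or info[pos] <= threshold / 2:
            letters.append("N")
            continue
        order = sorted(range(4), key=lambda b: (-freqs[pos][b], BASES[b]))
        total = 0.0
        chosen = []
        for b in order:
            chosen.append(BASES[b])
            total += freqs[pos][b]
            if total >= cum_freq:
                break
        letters.append(iupac_for_bases(chosen))
    while letters and letters[-1] == "N":
        letters.pop()
    return "".join(letters)


def call_pam(
    up_logo: PamLogo,
    down_logo: PamLogo,
    n_spacers: int,
    cluster_id: str = "",
    params: CallParams | None = None,
) -> PamPrediction:
    """Call a PAM for one cluster from its two flank logos.

    Clusters with fewer than ``min_spacers`` mapped spacers are not
    evaluated. A position is conserved when its information exceeds
    T = max(1 bit, Q3 + 1.5*IQR) of the pooled per-position information of
    both logos; the call is 'predicted' iff the conserved set is non-empty
    and confined to one side.
    """
    params = params or CallParams()
    if n_spacers < params.min_spacers:
        return PamPrediction(
            cluster_id=cluster_id, status="none", n_spacers=n_spacers,
            reason="insufficient spacers", up_logo=up_logo, down_logo=down_logo,
        )
    pooled = np.concatenate([up_logo.information, down_logo.information])
    T, q3, iqr = conservation_threshold(pooled, params)
    conserved = set()
    for logo in (up_logo, down_logo):
        for pos, inf in zip(logo.positions, logo.information):
            if inf > T:
                conserved.add((logo.side, pos))
    sides = {s for s, _ in conserved}
    common = dict(threshold=T, floor_bits=params.floor_bits, q3=q3, iqr=iqr,
                  n_spacers=n_spacers, up_logo=up_logo, down_logo=down_logo)
    if not conserved:
        return PamPrediction(cluster_id=cluster_id, status="none",
                             reason="no conserved position", **common)
    if len(sides) == 2:
        return PamPrediction(cluster_id=cluster_id, status="ambiguous-both-sides",
                             conserved_positions=frozenset(conserved),
                             reason="conserved positions on both sides", **common)
    side = sides.pop()
    logo = up_logo if side == UPSTREAM else down_logo
    return PamPrediction(
        cluster_id=cluster_id, status="predicted", side=side,
        conserved_positions=frozenset(conserved),
        consensus=encode_consensus_pam(logo, T), **common,
    )


def predict_cluster_pam(
    cluster_id: str,
    flanked_by_spacer: Mapping[str, Sequence[str]],
    params: CallParams | None = None,
    flank_len: int = 30,
) -> tuple[PamPrediction, list[FlankConsensus]]:
    """Full per-cluster prediction from the flanked matches of each spacer.

    ``flanked_by_spacer`` maps each unique spacer sequence to the flanked
    sequences (up + matched segment + down, protospacer frame) of all its
    retained matches. Mapped spacers are counted as unique spacers with a
    surviving consensus.
    """
    params = params or CallParams()
    consensi: list[FlankConsensus] = []
    for spacer_seq in sorted(flanked_by_spacer):
        seqs = flanked_by_spacer[spacer_seq]
        if not seqs:
            continue
        fc = build_flank_consensus(cluster_id, spacer_seq, list(seqs), params, flank_len)
        if fc is not None:
            consensi.append(fc)
    up = build_logo(consensi, UPSTREAM, min_coverage=params.min_spacers)
    down = build_logo(consensi, DOWNSTREAM, min_coverage=params.min_spacers)
    pred = call_pam(up, down, n_spacers=len(consensi), cluster_id=cluster_id, params=params)
    return pred, consensi
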