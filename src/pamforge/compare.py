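"""PAM logo comparison, clustering-level selection, PAM groups and the
in vitro randomized-PAM enrichment analytics.

Logo distance is the per-position Jensen-Shannon distance (square root of
the Jensen-Shannon divergence, log base 2) summed over an anchored window
of W positions on the compared side; absent positions are padded with the
uniform distribution. Two PAMs compared this way are close when their
distance is below ~2 bits; the summed form is what gives multi-bit scale.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import jensenshannon, squareform

from ._sequences import BASE_INDEX, IUPAC_SETS
from .model import DOWNSTREAM, FlankConsensus, PamDistance, PamGroup, PamLogo, PamPrediction
from .predict import CallParams, build_logo, conservation_threshold, encode_consensus_pam

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = 10
DEFAULT_GROUP_CUTOFF = 0.4  # normalized distance; mirrors an 0.6-identity cut
DEFAULT_MIN_GROUP_SIZE = 20


def pam_distance(logo_a: PamLogo, logo_b: PamLogo, window: int = DEFAULT_WINDOW) -> PamDistance:
    """Summed per-position Jensen-Shannon distance between two same-side logos."""
    if logo_a.side != logo_b.side:
        raise ValueError(f"side mismatch: {logo_a.side} vs {logo_b.side}")
    fa = logo_a.frequency_window(window)
    fb = logo_b.frequency_window(window)
    total = 0.0
    for pa, pb in zip(fa, fb):
        d = jensenshannon(pa, pb, base=2)
        total += 0.0 if np.isnan(d) else float(d)
    return PamDistance(value=total, window=window, side=logo_a.side)


def select_clustering_level(
    level_pairs: Mapping[float, Sequence[tuple[PamLogo, PamLogo]]],
    window: int = DEFAULT_WINDOW,
) -> float:
    """Identity level whose predictions have the lowest median distance to
    their reference logos; ties go to the higher identity level."""
    if not level_pairs:
        raise ValueError("no levels provided")
    medians: dict[float, float] = {}
    for level, pairs in level_pairs.items():
        if not pairs:
            raise ValueError(f"no reference pairs for level {level}")
        dists = [pam_distance(a, b, window).value for a, b in pairs]
        medians[level] = float(np.median(dists))
    return min(medians, key=lambda lv: (medians[lv], -lv))


def group_pams(
    predictions: Sequence[PamPrediction],
    cutoff: float = DEFAULT_GROUP_CUTOFF,
    window: int = DEFAULT_WINDOW,
    min_group_size: int = DEFAULT_MIN_GROUP_SIZE,
) -> tuple[list[PamGroup], list[str]]:
    """Average-linkage agglomerative grouping of predicted PAMs.

    Distances are pam_distance / window, in [0, 1]; predictions on opposite
    sides get the maximal normalized distance 1.0, so groups are side-pure.
    Groups smaller than ``min_group_size`` are returned as unassigned
    cluster ids. Output is invariant to the input order of predictions.
    """
    preds = sorted(
        (p for p in predictions if p.status == "predicted" and p.predicted_logo is not None),
        key=lambda p: p.cluster_id,
    )
    if len(preds) < 2:
        raise ValueError("need at least 2 predictions with logos")
    n = len(preds)
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if preds[i].side != preds[j].side:
                d = 1.0
            else:
                d = pam_distance(preds[i].predicted_logo, preds[j].predicted_logo, window).value / window
            dm[i, j] = dm[j, i] = d
    Z = hierarchy.linkage(squareform(dm, checks=False), method="average")
    labels = hierarchy.fcluster(Z, t=cutoff, criterion="distance")
    by_label: dict[int, list[str]] = {}
    for lab, p in zip(labels, preds):
        by_label.setdefault(int(lab), []).append(p.cluster_id)
    groups: list[PamGroup] = []
    unassigned: list[str] = []
    for members in sorted(by_label.values(), key=lambda ms: (-len(ms), ms[0])):
        if len(members) >= min_group_size:
            groups.append(PamGroup(group_id=f"G{len(groups) + 1:03d}", member_cluster_ids=members))
        else:
            unassigned.extend(members)
    return groups, sorted(unassigned)


def group_consensus(
    group: PamGroup,
    consensi_by_cluster: Mapping[str, Sequence[FlankConsensus]],
    side: str,
    params: CallParams | None = None,
) -> str:
    """Pooled consensus PAM for a group: all members' flank consensi are
    pooled, both-side logos rebuilt, and the pooled threshold re-applied."""
    params = params or CallParams()
    pooled: list[FlankConsensus] = []
    for cid in group.member_cluster_ids:
        pooled.extend(consensi_by_cluster.get(cid, []))
    if not pooled:
        raise ValueError(f"group {group.group_id} has no flank consensi")
    up = build_logo(pooled, "upstream", min_coverage=params.min_spacers)
    down = build_logo(pooled, "downstream", min_coverage=params.min_spacers)
    pooled_info = np.concatenate([up.information, down.information])
    T, _, _ = conservation_threshold(pooled_info, params)
    logo = up if side == "upstream" else down
    return encode_consensus_pam(logo, T)


# ---------------------------------------------------------------------------
# In vitro randomized-PAM libraries
# ---------------------------------------------------------------------------

@dataclass
class AnchorSpec:
    """Locates the randomized PAM in a read: the PAM is the ``pam_len``-mer
    immediately after (pam_side='3prime') or before ('5prime') the first
    exact occurrence of the constant ``sequence``."""

    sequence: str
    pam_side: str = "3prime"
    pam_len: int = 8

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty anchor sequence")
        if self.pam_side not in {"3prime", "5prime"}:
            raise ValueError(f"bad pam_side {self.pam_side!r}")


def extract_invitro_pams(reads: Sequence[str], anchor: AnchorSpec) -> tuple[Counter, int]:
    """Count PAM k-mers from reads whose anchor matches exactly.

    Returns (counts, number of dropped reads). A read is dropped when the
    anchor is absent or the PAM k-mer is truncated by the read end.
    """
    if not reads:
        raise ValueError("no reads")
    counts: Counter = Counter()
    dropped = 0
    for read in reads:
        i = read.find(anchor.sequence)
        if i < 0:
            dropped += 1
            continue
        if anchor.pam_side == "3prime":
            pam = read[i + len(anchor.sequence) : i + len(anchor.sequence) + anchor.pam_len]
        else:
            start = i - anchor.pam_len
            pam = read[start:i] if start >= 0 else ""
        if len(pam) != anchor.pam_len:
            dropped += 1
            continue
        counts[pam] += 1
    return counts, dropped


def pam_enrichment(
    cleaved: Mapping[str, int], control: Mapping[str, int], pseudocount: float = 1.0
) -> dict[str, float]:
    """Per-k-mer enrichment: cleaved frequency / control frequency, with the
    pseudocount added to every count over the union k-mer space."""
    space = sorted(set(cleaved) | set(control))
    if not space:
        raise ValueError("empty count tables")
    c = np.array([cleaved.get(s, 0) + pseudocount for s in space])
    u = np.array([control.get(s, 0) + pseudocount for s in space])
    fc = c / c.sum()
    fu = u / u.sum()
    return dict(zip(space, (fc / fu).tolist()))


def counts_to_logo(counts: Mapping[str, int], pam_len: int = 8) -> PamLogo:
    """Position-collapsed logo of a PAM k-mer count table (downstream frame,
    position 1 = first PAM base), for distance comparison with predictions."""
    mat = np.zeros((pam_len, 4))
    for kmer, n in counts.items():
        if len(kmer) != pam_len:
            raise ValueError(f"k-mer {kmer!r} is not {pam_len} nt")
        for i, base in enumerate(kmer):
            if base in BASE_INDEX:
                mat[i, BASE_INDEX[base]] += n
    totals = mat.sum(axis=1)
    if np.any(totals == 0):
        raise ValueError("a PAM position has no counts")
    freqs = mat / totals[:, None]
    return PamLogo(side=DOWNSTREAM, positions=list(range(1, pam_len + 1)), freqs=freqs,
                   coverage=totals.astype(int))


def matches_iupac_rule(kmer: str, rule: str) -> bool:
    """True iff the k-mer satisfies the IUPAC rule over the rule's span."""
    if len(rule) > len(kmer):
        return False
    return all(base in IUPAC_SETS[r] for r, base in zip(rule, kmer))
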