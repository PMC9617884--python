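"""Domain types shared by all pipeline stages.

Coordinates are 0-based, half-open everywhere. "Upstream" and "downstream"
are always in the oriented-spacer (protospacer) reading frame: downstream
position 1 is the first base 3' of the protospacer, upstream position 1 the
first base 5' of it, counting away from the protospacer on both sides.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from ._sequences import BASES, information_bits

UPSTREAM = "upstream"
DOWNSTREAM = "downstream"


@dataclass
class GenomeRecord:
    """A nucleotide sequence (phage/viral contig) from a collection."""

    id: str
    sequence: str
    source: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("GenomeRecord id must be non-empty")
        if len(self.sequence) < 1:
            raise ValueError(f"empty sequence for record {self.id!r}")
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise ValueError(f"record {self.id!r} has non-ACGTN letters {bad}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class CasGene:
    """One annotated cas gene on a contig."""

    name: str  # cas1 | cas2 | cas9 | other
    start: int
    end: int
    strand: str  # '+' | '-'

    def __post_init__(self) -> None:
        if self.name not in {"cas1", "cas2", "cas9", "other"}:
            raise ValueError(f"unknown cas gene name {self.name!r}")
        if not 0 <= self.start < self.end:
            raise ValueError(f"bad coordinates for {self.name}: [{self.start}, {self.end})")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"bad strand {self.strand!r}")


@dataclass
class CrisprArray:
    """A CRISPR array: ordered (repeat, following-spacer) units."""

    array_id: str
    units: list[tuple[str, Optional[str]]]
    start: int = 0
    end: int = 0
    orientation: str = "as-annotated"  # as-annotated | reversed | unknown

    def __post_init__(self) -> None:
        if not self.units:
            raise ValueError(f"array {self.array_id!r} has no repeats")
        for repeat, spacer in self.units:
            if spacer is not None and not 18 <= len(spacer) <= 50:
                raise ValueError(
                    f"array {self.array_id!r}: spacer length {len(spacer)} outside [18, 50]"
                )

    @property
    def spacers(self) -> list[str]:
        return [sp for _, sp in self.units if sp is not None]


@dataclass
class CasLocus:
    """One CRISPR-Cas9 locus: cas genes, arrays and the Cas9 protein."""

    locus_id: str
    contig_id: str
    cas_genes: list[CasGene]
    arrays: list[CrisprArray]
    cas9_protein: str
    subtype: str = "unknown"  # II-A | II-B | II-C | unknown
    contig_length: Optional[int] = None

    def __post_init__(self) -> None:
        n_cas9 = sum(1 for g in self.cas_genes if g.name == "cas9")
        if n_cas9 != 1:
            raise ValueError(f"locus {self.locus_id!r} has {n_cas9} cas9 genes, expected 1")
        if self.contig_length is not None:
            for g in self.cas_genes:
                if g.end > self.contig_length:
                    raise ValueError(
                        f"locus {self.locus_id!r}: gene {g.name} ends beyond contig"
                    )

    @property
    def cas9_gene(self) -> CasGene:
        return next(g for g in self.cas_genes if g.name == "cas9")


@dataclass(frozen=True)
class Spacer:
    """An oriented CRISPR spacer with provenance."""

    spacer_id: str
    sequence: str
    locus_id: str
    cluster_id: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty spacer sequence")


@dataclass(frozen=True)
class ProtospacerMatch:
    """A retained full-length spacer placement on a viral contig.

    ``start``/``end`` are on the forward strand of the genome. Flanks are in
    the protospacer frame: for minus-strand matches they are the reverse
    complement of the forward-strand context, sides swapped, so downstream
    is always 3' of the protospacer as read along the oriented spacer.
    """

    spacer_id: str
    genome_id: str
    strand: str
    start: int
    end: int
    mismatches: int
    gaps: int
    up_flank: str
    down_flank: str

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"bad strand {self.strand!r}")
        if self.mismatches < 0 or self.gaps < 0:
            raise ValueError("negative edit counts")
        if len(self.up_flank) > 30 or len(self.down_flank) > 30:
            raise ValueError("flank longer than 30 nt")

    @property
    def variations(self) -> int:
        return self.mismatches + self.gaps


@dataclass
class PamLogo:
    """Anchored per-position nucleotide frequencies for one flank side.

    Rows of ``freqs`` correspond to ``positions`` (1-based, counting away
    from the protospacer) and are frequency vectors over A, C, G, T summing
    to 1; ``coverage[i]`` is the number of consensus sequences covering
    position i.
    """

    side: str
    positions: list[int]
    freqs: np.ndarray  # shape (n_positions, 4)
    coverage: np.ndarray  # shape (n_positions,)

    def __post_init__(self) -> None:
        if self.side not in {UPSTREAM, DOWNSTREAM}:
            raise ValueError(f"bad side {self.side!r}")
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.coverage = np.asarray(self.coverage, dtype=int)
        if self.freqs.shape != (len(self.positions), 4):
            raise ValueError("freqs shape does not match positions")
        if len(self.positions) > 30:
            raise ValueError("logo longer than 30 positions")
        if len(self.positions) and not np.allclose(self.freqs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("frequency rows must sum to 1")

    @property
    def information(self) -> np.ndarray:
        """Per-position information content, bits in [0, 2]."""
        return np.array([information_bits(row) for row in self.freqs])

    def frequency_window(self, width: int) -> np.ndarray:
        """Frequencies for positions 1..width; absent positions are uniform."""
        out = np.full((width, 4), 0.25)
        for pos, row in zip(self.positions, self.freqs):
            if 1 <= pos <= width:
                out[pos - 1] = row
        return out

    @classmethod
    def empty(cls, side: str) -> "PamLogo":
        return cls(side=side, positions=[], freqs=np.zeros((0, 4)), coverage=np.zeros(0, int))


@dataclass
class PamPrediction:
    """The PAM call for one Cas9 cluster, with the thresholds that made it."""

    cluster_id: str
    status: str  # predicted | none | ambiguous-both-sides
    side: Optional[str] = None
    conserved_positions: frozenset = frozenset()  # of (side, position)
    threshold: float = 0.0
    floor_bits: float = 1.0
    q3: float = 0.0
    iqr: float = 0.0
    consensus: str = ""
    n_spacers: int = 0
    reason: str = ""
    up_logo: Optional[PamLogo] = None
    down_logo: Optional[PamLogo] = None

    def __post_init__(self) -> None:
        if self.status == "predicted":
            if not self.conserved_positions:
                raise ValueError("predicted status requires conserved positions")
            sides = {s for s, _ in self.conserved_positions}
            if len(sides) != 1:
                raise ValueError("predicted status requires a single side")

    @property
    def predicted_logo(self) -> Optional[PamLogo]:
        if self.side == UPSTREAM:
            return self.up_logo
        if self.side == DOWNSTREAM:
            return self.down_logo
        return None


@dataclass
class VariantRecord:
    """A clinical variant with its reference context window."""

    variant_id: str
    ref: str
    alt: str
    significance: str  # pathogenic | likely-pathogenic | other
    inheritance: str
    window_seq: str
    window_offset: int

    def __post_init__(self) -> None:
        at = self.window_seq[self.window_offset : self.window_offset + len(self.ref)]
        if at != self.ref:
            raise ValueError(
                f"variant {self.variant_id!r}: ref {self.ref!r} not at offset "
                f"{self.window_offset} of window (found {at!r})"
            )

    @property
    def length_change(self) -> int:
        return len(self.alt) - len(self.ref)


@dataclass
class FlankConsensus:
    """Per (cluster, spacer) consensus of all flanked protospacer matches."""

    cluster_id: str
    spacer_seq: str
    consensus: str
    spacer_offset: int

    def __post_init__(self) -> None:
        found = self.consensus[self.spacer_offset : self.spacer_offset + len(self.spacer_seq)]
        if found != self.spacer_seq:
            raise ValueError("spacer does not occur exactly at the recorded offset")
        if len(self.up_flank) > 30 or len(self.down_flank) > 30:
            raise ValueError("consensus flank longer than 30 nt")

    @property
    def up_flank(self) -> str:
        return self.consensus[: self.spacer_offset]

    @property
    def down_flank(self) -> str:
        return self.consensus[self.spacer_offset + len(self.spacer_seq) :]


@dataclass
class Cas9Cluster:
    """Cas9 proteins grouped at a percent-identity level."""

    cluster_id: str
    level: float
    representative_id: str
    member_ids: list[str]
    subtype: str = "unknown"


@dataclass(frozen=True)
class PamDistance:
    """Summed per-position Jensen-Shannon distance between two logos."""

    value: float
    window: int
    side: str


@dataclass
class PamGroup:
    """A hierarchical group of PAM predictions with a pooled consensus."""

    group_id: str
    member_cluster_ids: list[str]
    consensus: str = ""

    @property
    def size(self) -> int:
        return len(self.member_cluster_ids)


@dataclass
class TargetabilityResult:
    """Allelic-discrimination outcome for one variant."""

    variant_id: str
    targetable: bool
    discriminating_pams: list[tuple[str, str, int]]  # (pam, strand, offset on mutated window)
    inheritance: str = ""

    def __post_init__(self) -> None:
        if self.targetable != bool(self.discriminating_pams):
            raise ValueError("targetable flag inconsistent with discriminating PAM list")
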