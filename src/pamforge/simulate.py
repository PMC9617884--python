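"""Seeded generators of synthetic study data.

These generators emulate the statistical structure the pipeline assumes:
CRISPR-Cas9 loci whose spacers recur as protospacers in a phage genome
collection, a position-weight-matrix PAM signal planted on one flank of
every protospacer, near-random non-PAM flanks, occasional escape mutations
(flank noise), decoy spacers with no genomic match, and sites truncated by
contig ends. All randomness flows from a single integer seed through one
numpy Generator, so outputs are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from ._sequences import BASES, IUPAC_SETS, revcomp
from .model import CasGene, CasLocus, CrisprArray, GenomeRecord, PamLogo

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

# NGG-like default: position 1 free, positions 2-3 strongly G
DEFAULT_PAM_PWM = np.array(
    [
        [0.25, 0.25, 0.25, 0.25],
        [0.02, 0.02, 0.94, 0.02],
        [0.02, 0.02, 0.94, 0.02],
    ]
)


@dataclass
class SimulationConfig:
    """Knobs of the planted-PAM simulation (defaults are the study
    conditions every test and example uses)."""

    seed: int = 0
    n_clusters: int = 3
    spacers_per_cluster: int = 40
    matches_per_spacer: tuple[int, int] = (1, 4)  # inclusive range of copies
    pam_pwm: np.ndarray = field(default_factory=lambda: DEFAULT_PAM_PWM.copy())
    pam_side: str = "downstream"
    flank_noise: float = 0.03  # per-base substitution probability on flanks
    decoy_fraction: float = 0.1
    n_genomes: int = 20
    genome_length: int = 5000
    edge_truncation_fraction: float = 0.05
    spacer_length: int = 30
    flank_len: int = 30

    def __post_init__(self) -> None:
        self.pam_pwm = np.asarray(self.pam_pwm, dtype=float)
        for p in (self.flank_noise, self.decoy_fraction, self.edge_truncation_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if not np.allclose(self.pam_pwm.sum(axis=1), 1.0):
            raise ValueError("PWM rows must sum to 1")
        if self.pam_side not in {"upstream", "downstream"}:
            raise ValueError(f"bad pam_side {self.pam_side!r}")


@dataclass
class PlantedSite:
    """Truth record of one embedded protospacer."""

    spacer_seq: str
    genome_id: str
    strand: str
    start: int
    end: int


@dataclass
class SimulationTruth:
    """Everything the generator planted, for end-to-end verification."""

    pam_pwm: np.ndarray
    pam_side: str
    cluster_pams: dict[str, str]
    sites: list[PlantedSite]
    decoy_spacers: dict[str, list[str]]  # cluster id -> decoy spacer sequences
    cluster_spacers: dict[str, list[str]]  # cluster id -> non-decoy oriented spacers

    def pam_logo(self, window: int = 10) -> PamLogo:
        """The planted PWM as an anchored logo (uniform beyond the PWM)."""
        n = len(self.pam_pwm)
        freqs = np.full((window, 4), 0.25)
        freqs[:n] = self.pam_pwm[:window]
        return PamLogo(side=self.pam_side, positions=list(range(1, window + 1)),
                       freqs=freqs, coverage=np.full(window, 1, dtype=int))


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list(BASES))[rng.integers(0, 4, n)])


def _sample_pwm(rng: np.random.Generator, pwm: np.ndarray) -> str:
    return "".join(BASES[rng.choice(4, p=row)] for row in pwm)


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = BASES[rng.integers(0, 4)]
    return "".join(out)


def _pwm_iupac(pwm: np.ndarray, min_freq: float = 0.5) -> str:
    """Rough IUPAC rendering of a PWM for the truth record."""
    from ._sequences import iupac_for_bases

    letters = []
    for row in pwm:
        bases = [BASES[i] for i in range(4) if row[i] >= min_freq]
        letters.append(iupac_for_bases(bases) if bases else "N")
    return "".join(letters)


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[list[GenomeRecord], list[CasLocus], SimulationTruth]:
    """Generate phage genomes, CRISPR-Cas9 loci and the planted truth.

    Protospacers are embedded with the PAM PWM sampled on the configured
    side; a fraction of spacers are decoys with no genomic site, and a
    fraction of sites sit close enough to a contig end to truncate a flank.
    Raises when the requested sites cannot be packed into the genomes.
    """
    rng = np.random.default_rng(config.seed)
    L = config.spacer_length
    slot = L + 2 * (config.flank_len + 5)
    slots_per_genome = config.genome_length // slot
    total_slots = max(0, slots_per_genome - 2) * config.n_genomes
    lo, hi = config.matches_per_spacer
    max_sites = config.n_clusters * config.spacers_per_cluster * hi
    if max_sites > total_slots:
        raise ValueError(
            f"cannot pack up to {max_sites} protospacers into "
            f"{total_slots} genome slots; enlarge or add genomes"
        )

    genomes = [
        GenomeRecord(id=f"phage{g:03d}", sequence=_random_dna(rng, config.genome_length),
                     source="synthetic")
        for g in range(config.n_genomes)
    ]
    genome_seqs = {g.id: list(g.sequence) for g in genomes}
    # the first and last slot of every genome are reserved for edge-truncated
    # sites so they can never collide with ordinary placements
    free_slots = [
        (g.id, s * slot) for g in genomes for s in range(1, slots_per_genome - 1)
    ]
    rng.shuffle(free_slots)
    start_edges = [g.id for g in genomes]
    end_edges = [g.id for g in genomes]

    pam_len = len(config.pam_pwm)
    truth = SimulationTruth(
        pam_pwm=config.pam_pwm.copy(),
        pam_side=config.pam_side,
        cluster_pams={},
        sites=[],
        decoy_spacers={},
        cluster_spacers={},
    )
    loci: list[CasLocus] = []
    subtypes = ["II-A", "II-B", "II-C"]

    for c in range(config.n_clusters):
        cluster = f"sim{c:02d}"
        truth.cluster_pams[cluster] = _pwm_iupac(config.pam_pwm)
        truth.decoy_spacers[cluster] = []
        truth.cluster_spacers[cluster] = []
        spacers: list[str] = []
        for k in range(config.spacers_per_cluster):
            spacer = _random_dna(rng, L)
            spacers.append(spacer)
            if rng.random() < config.decoy_fraction:
                truth.decoy_spacers[cluster].append(spacer)
                continue
            truth.cluster_spacers[cluster].append(spacer)
            n_copies = int(rng.integers(lo, hi + 1))
            for _ in range(n_copies):
                strand = "+" if rng.random() < 0.5 else "-"
                truncate = rng.random() < config.edge_truncation_fraction
                # oriented-frame cassette: [up flank][protospacer][down flank],
                # with the PWM sample at the anchored positions of the PAM side
                pam = _sample_pwm(rng, config.pam_pwm)
                if config.pam_side == "downstream":
                    up = _random_dna(rng, config.flank_len)
                    down = pam + _random_dna(rng, config.flank_len - pam_len)
                else:  # upstream position 1 is the base immediately 5'
                    up = _random_dna(rng, config.flank_len - pam_len) + pam[::-1]
                    down = _random_dna(rng, config.flank_len)
                up = _mutate(rng, up, config.flank_noise)
                down = _mutate(rng, down, config.flank_noise)
                cassette = up + spacer + down
                cassette_fwd = cassette if strand == "+" else revcomp(cassette)

                gid: Optional[str] = None
                if truncate:
                    # cut the 3'-most flank of the forward-frame cassette at a
                    # contig end ('+' -> genome end, '-' -> genome start)
                    keep = L + config.flank_len + int(rng.integers(5, config.flank_len))
                    edges = end_edges if strand == "+" else start_edges
                    if edges:
                        gid = edges.pop()
                        seq = genome_seqs[gid]
                        if strand == "+":
                            placed = cassette_fwd[:keep]
                            gstart = len(seq) - len(placed)
                            s0 = gstart + config.flank_len
                        else:
                            placed = cassette_fwd[-keep:]
                            gstart = 0
                            s0 = keep - config.flank_len - L
                if gid is None:
                    if not free_slots:
                        raise ValueError("ran out of genome slots while planting sites")
                    gid, gstart = free_slots.pop()
                    seq = genome_seqs[gid]
                    placed = cassette_fwd
                    s0 = gstart + config.flank_len
                seq[gstart : gstart + len(placed)] = list(placed)
                truth.sites.append(
                    PlantedSite(spacer_seq=spacer, genome_id=gid, strand=strand,
                                start=int(s0), end=int(s0 + L))
                )

        # locus bookkeeping: one locus per cluster, plus-strand cas operon
        protein_len = int(rng.integers(1000, 1400))
        protein = "".join(np.array(list(AA_ALPHABET))[rng.integers(0, 20, protein_len)])
        repeat = _random_dna(rng, 36)
        flip = bool(rng.random() < 0.3)
        stored = [revcomp(s) for s in reversed(spacers)] if flip else spacers
        units = [(repeat, s) for s in stored] + [(repeat, None)]
        strand = "-" if flip else "+"
        genes = [
            CasGene(name="cas9", start=100, end=100 + 3 * protein_len, strand=strand),
            CasGene(name="cas1", start=5000 + 3 * protein_len, end=6000 + 3 * protein_len, strand=strand),
            CasGene(name="cas2", start=6100 + 3 * protein_len, end=6400 + 3 * protein_len, strand=strand),
        ]
        array_start = 7000 + 3 * protein_len
        array_len = sum(len(r) + (len(s) if s else 0) for r, s in units)
        loci.append(
            CasLocus(
                locus_id=f"locus_{cluster}",
                contig_id=f"contig_{cluster}",
                cas_genes=genes,
                arrays=[
                    CrisprArray(array_id="arr0", units=units, start=array_start,
                                end=array_start + array_len)
                ],
                cas9_protein=protein,
                subtype=subtypes[c % 3],
                contig_length=array_start + array_len + 100,
            )
        )

    genomes = [
        GenomeRecord(id=g.id, sequence="".join(genome_seqs[g.id]), source="synthetic")
        for g in genomes
    ]
    _assert_truth_consistent(genomes, truth)
    return genomes, loci, truth


def _assert_truth_consistent(genomes: list[GenomeRecord], truth: SimulationTruth) -> None:
    by_id = {g.id: g for g in genomes}
    for site in truth.sites:
        seg = by_id[site.genome_id].sequence[site.start : site.end]
        if site.strand == "-":
            seg = revcomp(seg)
        assert seg == site.spacer_seq, "planted site does not contain its protospacer"


def simulate_protein_families(
    n_families: int = 5,
    members_per_family: int = 10,
    length_range: tuple[int, int] = (1000, 1300),
    within_divergence: float = 0.01,
    seed: int = 0,
) -> tuple[dict[str, str], dict[str, str]]:
    """Planted protein families for clustering tests.

    Returns (proteins, family assignment). The founder is the first member;
    the others carry point substitutions at ``within_divergence / 2`` per
    base, bounding the pairwise within-family divergence by roughly
    ``within_divergence``.
    """
    rng = np.random.default_rng(seed)
    proteins: dict[str, str] = {}
    families: dict[str, str] = {}
    aa = np.array(list(AA_ALPHABET))
    for f in range(n_families):
        length = int(rng.integers(*length_range))
        founder = "".join(aa[rng.integers(0, 20, length)])
        for m in range(members_per_family):
            seq = list(founder)
            if m > 0:
                for i in range(length):
                    if rng.random() < within_divergence / 2:
                        seq[i] = AA_ALPHABET[rng.integers(0, 20)]
            pid = f"fam{f}_p{m:02d}"
            proteins[pid] = "".join(seq)
            families[pid] = f"fam{f}"
    return proteins, families


def simulate_invitro_library(
    pam_rule: str,
    n_reads: int = 5000,
    selectivity: float = 0.9,
    seed: int = 0,
    anchor: str = "GTTTAAGAGC",
    pam_len: int = 8,
) -> tuple[list[str], list[str]]:
    """Cleaved and control read sets for a randomized-PAM cleavage library.

    Control PAM k-mers are uniform; a cleaved read's k-mer satisfies the
    IUPAC ``pam_rule`` with probability ``selectivity`` and is otherwise
    uniform. Each read is prefix + anchor + k-mer + suffix.
    """
    if not 0.0 <= selectivity <= 1.0:
        raise ValueError("selectivity must lie in [0, 1]")
    rng = np.random.default_rng(seed)

    def sample_kmer(selected: bool) -> str:
        out = []
        for i in range(pam_len):
            if selected and i < len(pam_rule):
                allowed = sorted(IUPAC_SETS[pam_rule[i]])
                out.append(allowed[rng.integers(0, len(allowed))])
            else:
                out.append(BASES[rng.integers(0, 4)])
        return "".join(out)

    def build_read(kmer: str) -> str:
        return _random_dna(rng, 12) + anchor + kmer + _random_dna(rng, 12)

    cleaved = [build_read(sample_kmer(rng.random() < selectivity)) for _ in range(n_reads)]
    control = [build_read(sample_kmer(False)) for _ in range(n_reads)]
    return cleaved, control


def write_fastq(reads: list[str], path) -> None:
    """Minimal FASTQ writer for simulated reads (constant quality)."""
    with open(path, "w") as fh:
        for i, read in enumerate(reads):
            fh.write(f"@read{i}\n{read}\n+\n{'I' * len(read)}\n")
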