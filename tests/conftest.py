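"""Shared fixtures: all test data is generated programmatically, seeded."""

from __future__ import annotations

import numpy as np
import pytest

from pamforge.cluster import greedy_cluster
from pamforge.match import match_all, matched_segment
from pamforge.model import Spacer
from pamforge.predict import predict_cluster_pam
from pamforge.simulate import SimulationConfig, simulate_dataset, simulate_protein_families


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


@pytest.fixture(scope="session")
def protein_families():
    """Five planted Cas9-like protein families (founder + diverged members)."""
    proteins, families = simulate_protein_families(
        n_families=5, members_per_family=10, within_divergence=0.01, seed=11
    )
    return proteins, families


@pytest.fixture(scope="session")
def family_clusterings(protein_families):
    """Greedy clusterings of the planted families at 1.0, 0.98 and 0.95."""
    proteins, _ = protein_families
    return {level: greedy_cluster(proteins, level) for level in (1.0, 0.98, 0.95)}


@pytest.fixture(scope="session")
def planted_dataset():
    """The seed-59 single-cluster simulation with a strong downstream
    NGG-like PAM, plus the match -> predict products."""
    config = SimulationConfig(
        seed=59, n_clusters=1, spacers_per_cluster=60, matches_per_spacer=(1, 5),
        flank_noise=0.03, decoy_fraction=0.1,
    )
    genomes, loci, truth = simulate_dataset(config)
    all_spacers = truth.cluster_spacers["sim00"] + truth.decoy_spacers["sim00"]
    spacers = [Spacer(f"u{i}", s, "locus_sim00") for i, s in enumerate(all_spacers)]
    matches = match_all(spacers, genomes)
    genome_by_id = {g.id: g for g in genomes}
    seq_by_id = {s.spacer_id: s.sequence for s in spacers}
    flanked: dict[str, list[str]] = {}
    for m in matches:
        seq = seq_by_id[m.spacer_id]
        flanked.setdefault(seq, []).append(
            m.up_flank + matched_segment(m, genome_by_id[m.genome_id]) + m.down_flank
        )
    prediction, consensi = predict_cluster_pam("sim00", flanked)
    return {
        "config": config,
        "genomes": genomes,
        "loci": loci,
        "truth": truth,
        "spacers": spacers,
        "matches": matches,
        "flanked": flanked,
        "prediction": prediction,
        "consensi": consensi,
    }
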