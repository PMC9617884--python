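"""Jensen-Shannon logo distance, level selection, PAM groups, in vitro."""

import math

import numpy as np
import pytest

from pamforge.compare import (
    AnchorSpec,
    counts_to_logo,
    extract_invitro_pams,
    group_consensus,
    group_pams,
    matches_iupac_rule,
    pam_distance,
    pam_enrichment,
    select_clustering_level,
)
from pamforge.model import DOWNSTREAM, UPSTREAM, FlankConsensus, PamLogo, PamPrediction
from pamforge.simulate import simulate_invitro_library

from conftest import random_dna


def one_hot_logo(bases: str, side: str = DOWNSTREAM) -> PamLogo:
    freqs = np.full((len(bases), 4), 0.0)
    for i, b in enumerate(bases):
        freqs[i, "ACGT".index(b)] = 1.0
    return PamLogo(side=side, positions=list(range(1, len(bases) + 1)), freqs=freqs,
                   coverage=np.full(len(bases), 50))


def random_logo(rng, n_pos=10, side=DOWNSTREAM) -> PamLogo:
    freqs = rng.dirichlet(np.ones(4), size=n_pos)
    return PamLogo(side=side, positions=list(range(1, n_pos + 1)), freqs=freqs,
                   coverage=np.full(n_pos, 50))


def _js_distance_oracle(p, q):
    """sqrt of the Jensen-Shannon divergence (base 2), from the definition."""
    m = [(a + b) / 2 for a, b in zip(p, q)]

    def kl(x, y):
        return sum(a * math.log2(a / b) for a, b in zip(x, y) if a > 0)

    return math.sqrt(kl(p, m) / 2 + kl(q, m) / 2)


class TestPamDistance:
    def test_self_distance_zero(self):
        logo = one_hot_logo("TGGAT")
        assert pam_distance(logo, logo).value == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_one_hot_contributes_exactly_one(self):
        a = one_hot_logo("AGG")
        b = one_hot_logo("GGG")
        assert pam_distance(a, b).value == pytest.approx(1.0)

    def test_equals_definition_oracle_on_random_logos(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            a, b = random_logo(rng), random_logo(rng)
            expected = sum(
                _js_distance_oracle(pa, pb)
                for pa, pb in zip(a.frequency_window(10), b.frequency_window(10))
            )
            assert pam_distance(a, b).value == pytest.approx(expected, abs=1e-9)

    def test_missing_positions_padded_uniform(self):
        short = one_hot_logo("G")  # only position 1
        uniform = PamLogo(side=DOWNSTREAM, positions=[], freqs=np.zeros((0, 4)),
                          coverage=np.zeros(0, int))
        d = pam_distance(short, uniform, window=10)
        assert d.value == pytest.approx(_js_distance_oracle([0, 0, 1, 0], [0.25] * 4))

    def test_side_mismatch_errors(self):
        with pytest.raises(ValueError, match="side"):
            pam_distance(one_hot_logo("G", DOWNSTREAM), one_hot_logo("G", UPSTREAM))

    def test_metric_axioms_on_random_pairs(self):
        rng = np.random.default_rng(99)
        logos = [random_logo(rng, n_pos=6) for _ in range(60)]
        pairs = [(logos[int(i)], logos[int(j)])
                 for i, j in rng.integers(0, 60, size=(1000, 2))]
        d = {}
        for a, b in pairs:
            dab = pam_distance(a, b, window=6).value
            dba = pam_distance(b, a, window=6).value
            assert dab == pytest.approx(dba, abs=1e-12)  # symmetry
            assert dab >= 0
            if a is b:
                assert dab == pytest.approx(0, abs=1e-12)
        # triangle inequality on sampled triples
        for i, j, k in rng.integers(0, 60, size=(300, 3)):
            a, b, c = logos[int(i)], logos[int(j)], logos[int(k)]
            dab = pam_distance(a, b, window=6).value
            dbc = pam_distance(b, c, window=6).value
            dac = pam_distance(a, c, window=6).value
            assert dac <= dab + dbc + 1e-9


class TestSelectLevel:
    def test_picks_level_with_lowest_median(self):
        rng = np.random.default_rng(31)
        ref = one_hot_logo("GGT")

        def noisy(eps):
            freqs = ref.frequency_window(10) * (1 - eps) + eps * 0.25
            return PamLogo(side=DOWNSTREAM, positions=list(range(1, 11)), freqs=freqs,
                           coverage=np.full(10, 50))

        level_pairs = {
            0.95: [(noisy(0.4), ref)] * 3,
            0.98: [(noisy(0.05), ref)] * 3,
            1.0: [(noisy(0.2), ref)] * 3,
        }
        assert select_clustering_level(level_pairs) == 0.98
        # median recount oracle
        meds = {
            lv: np.median([pam_distance(a, b).value for a, b in pairs])
            for lv, pairs in level_pairs.items()
        }
        assert min(meds, key=meds.get) == 0.98

    def test_single_level_returned(self):
        ref = one_hot_logo("GG")
        assert select_clustering_level({0.97: [(ref, ref)]}) == 0.97

    def test_tie_goes_to_higher_identity(self):
        ref = one_hot_logo("GG")
        assert select_clustering_level({0.95: [(ref, ref)], 1.0: [(ref, ref)]}) == 1.0

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            select_clustering_level({})
        with pytest.raises(ValueError):
            select_clustering_level({0.98: []})


def _pred(cluster_id: str, logo: PamLogo) -> PamPrediction:
    return PamPrediction(cluster_id=cluster_id, status="predicted", side=logo.side,
                         conserved_positions=frozenset({(logo.side, 1)}),
                         down_logo=logo if logo.side == DOWNSTREAM else None,
                         up_logo=logo if logo.side == UPSTREAM else None)


class TestGroupPams:
    def _noisy_logo(self, rng, bases: str) -> PamLogo:
        base_logo = one_hot_logo(bases)
        freqs = base_logo.frequency_window(10)
        freqs = np.clip(freqs + rng.normal(0, 0.02, freqs.shape), 1e-6, None)
        freqs /= freqs.sum(axis=1, keepdims=True)
        return PamLogo(side=DOWNSTREAM, positions=list(range(1, 11)), freqs=freqs,
                       coverage=np.full(10, 50))

    def test_identical_logos_form_one_group(self):
        preds = [_pred(f"c{i}", one_hot_logo("GG")) for i in range(4)]
        groups, unassigned = group_pams(preds, min_group_size=2)
        assert len(groups) == 1 and groups[0].size == 4 and unassigned == []

    def test_recovers_three_planted_motif_families(self):
        rng = np.random.default_rng(37)
        families = {"NGG": "AGG", "TTN": "TTA", "N5T": "AAAAAT"}
        preds, truth = [], {}
        for fam, bases in families.items():
            for i in range(8):
                cid = f"{fam}_{i}"
                preds.append(_pred(cid, self._noisy_logo(rng, bases)))
                truth[cid] = fam
        groups, unassigned = group_pams(preds, cutoff=0.2, min_group_size=5)
        assert unassigned == []
        got = {frozenset(g.member_cluster_ids) for g in groups}
        want = {frozenset(c for c in truth if truth[c] == f) for f in families}
        assert got == want

    def test_small_groups_reported_unassigned(self):
        rng = np.random.default_rng(11)
        preds = [_pred(f"big{i}", self._noisy_logo(rng, "AGG")) for i in range(25)]
        preds += [_pred(f"small{i}", self._noisy_logo(rng, "TTTTA")) for i in range(5)]
        groups, unassigned = group_pams(preds, min_group_size=20)
        assert len(groups) == 1 and groups[0].size == 25
        assert sorted(unassigned) == sorted(f"small{i}" for i in range(5))

    def test_invariant_to_input_permutation(self):
        rng = np.random.default_rng(13)
        preds = [_pred(f"c{i}", self._noisy_logo(rng, "AGG" if i % 2 else "TTTTA"))
                 for i in range(12)]
        g1, u1 = group_pams(preds, min_group_size=3)
        g2, u2 = group_pams(list(reversed(preds)), min_group_size=3)
        assert [sorted(g.member_cluster_ids) for g in g1] == \
               [sorted(g.member_cluster_ids) for g in g2]
        assert u1 == u2


class TestGroupConsensus:
    def _consensi(self, pam: str, n: int, seed: int) -> list[FlankConsensus]:
        # pam is an IUPAC template: N positions are sampled uniformly
        rng = np.random.default_rng(seed)
        out = []
        for _ in range(n):
            spacer = random_dna(rng, 20)
            motif = "".join(c if c != "N" else "ACGT"[rng.integers(0, 4)] for c in pam)
            down = motif + random_dna(rng, 8 - len(pam))
            out.append(FlankConsensus(cluster_id="c", spacer_seq=spacer,
                                      consensus=random_dna(rng, 8) + spacer + down,
                                      spacer_offset=8))
        return out

    def test_identical_ngg_members_give_ngg(self):
        from pamforge.model import PamGroup

        consensi = {f"c{i}": self._consensi("NGG", 15, seed=i) for i in range(3)}
        group = PamGroup(group_id="G1", member_cluster_ids=list(consensi))
        assert group_consensus(group, consensi, side=DOWNSTREAM) == "NGG"

    def test_pooled_ngg_and_nag_give_nrg(self):
        from pamforge.model import PamGroup

        consensi = {"ngg": self._consensi("NGG", 20, seed=1),
                    "nag": self._consensi("NAG", 20, seed=2)}
        group = PamGroup(group_id="G1", member_cluster_ids=["ngg", "nag"])
        assert group_consensus(group, consensi, side=DOWNSTREAM) == "NRG"

    def test_single_member_group(self):
        from pamforge.model import PamGroup

        consensi = {"c0": self._consensi("NGG", 15, seed=3)}
        group = PamGroup(group_id="G1", member_cluster_ids=["c0"])
        assert group_consensus(group, consensi, side=DOWNSTREAM) == "NGG"


class TestInVitro:
    ANCHOR = AnchorSpec("GTTTAAGAGC")

    def test_constant_eight_mer(self):
        reads = ["AAAA" + self.ANCHOR.sequence + "ACGTACGT" + "TTTT"] * 100
        counts, dropped = extract_invitro_pams(reads, self.ANCHOR)
        assert counts == {"ACGTACGT": 100} and dropped == 0

    def test_read_without_anchor_dropped(self):
        reads = ["A" * 40, "CCCC" + self.ANCHOR.sequence + "GGGGGGGG"]
        counts, dropped = extract_invitro_pams(reads, self.ANCHOR)
        assert dropped == 1 and counts == {"GGGGGGGG": 1}

    def test_truncated_pam_dropped(self):
        reads = ["AA" + self.ANCHOR.sequence + "ACG"]  # only 3 of 8 PAM bases
        counts, dropped = extract_invitro_pams(reads, self.ANCHOR)
        assert dropped == 1 and counts == {}

    def test_counts_equal_generator_tally(self):
        cleaved, _ = simulate_invitro_library("NGG", n_reads=500, selectivity=1.0, seed=41)
        counts, dropped = extract_invitro_pams(cleaved, self.ANCHOR)
        assert dropped == 0 and sum(counts.values()) == 500
        # independent tally: slice the PAM straight out of each read
        tally = {}
        for read in cleaved:
            i = read.index(self.ANCHOR.sequence) + len(self.ANCHOR.sequence)
            kmer = read[i : i + 8]
            tally[kmer] = tally.get(kmer, 0) + 1
        assert dict(counts) == tally

    def test_empty_fastq_errors(self):
        with pytest.raises(ValueError):
            extract_invitro_pams([], self.ANCHOR)


class TestEnrichment:
    def test_identical_tables_give_unity(self):
        counts = {"AAAAAAAA": 10, "CCCCCCCC": 30}
        enr = pam_enrichment(counts, dict(counts))
        assert all(v == pytest.approx(1.0) for v in enr.values())

    def test_doubled_kmer_arithmetic(self):
        control = {"AAAAAAAA": 10, "CCCCCCCC": 10}
        cleaved = {"AAAAAAAA": 20, "CCCCCCCC": 10}
        enr = pam_enrichment(cleaved, control, pseudocount=1)
        # freq_cleaved(A8) = 21/32, freq_control(A8) = 11/22
        assert enr["AAAAAAAA"] == pytest.approx((21 / 32) / (11 / 22))
        assert enr["CCCCCCCC"] == pytest.approx((11 / 32) / (11 / 22))

    def test_selective_cleavage_ranks_rule_matches_first(self):
        cleaved, control = simulate_invitro_library("NRVNRT", n_reads=6000,
                                                    selectivity=0.9, seed=43)
        anchor = AnchorSpec("GTTTAAGAGC")
        cc, _ = extract_invitro_pams(cleaved, anchor)
        uu, _ = extract_invitro_pams(control, anchor)
        enr = pam_enrichment(cc, uu)
        ranked = sorted(enr, key=lambda k: -enr[k])
        top = ranked[:30]
        assert all(matches_iupac_rule(k, "NRVNRT") for k in top)

    def test_counts_to_logo_positions(self):
        logo = counts_to_logo({"GGGGGGGG": 30, "AGGGGGGG": 10}, pam_len=8)
        np.testing.assert_allclose(logo.freqs[0], [0.25, 0, 0.75, 0])
        assert logo.positions == list(range(1, 9))
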