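"""The four-stage training pipeline and prediction."""

import numpy as np
import pytest

from lipidsites import evaluation, synth, training
from lipidsites.scoring import N_PAIRS, encode_many
from lipidsites.seqio import AA20, ModSite, Protein
from lipidsites.training import (
    TrainConfig,
    TrainingError,
    _GroupState,
    _trim_codes,
    assign_groups,
    build_training_set,
    group_objective_value,
    mutate_matrix,
    select_motif_length,
    train_weights,
)


class TestBuildTrainingSet:
    prot = Protein(id="p1", sequence="MGCGC")

    def test_myr_partition(self):
        sites = [ModSite(protein_id="p1", position=2, residue="G", mod_type="MYR")]
        ts = build_training_set([self.prot], sites, "MYR")
        assert [(pid, pos) for pid, pos, _ in ts.positives] == [("p1", 2)]
        assert [(pid, pos) for pid, pos, _ in ts.negatives] == [("p1", 4)]

    def test_palm_partition(self):
        sites = [ModSite(protein_id="p1", position=3, residue="C", mod_type="PALM")]
        ts = build_training_set([self.prot], sites, "PALM")
        assert [(pid, pos) for pid, pos, _ in ts.positives] == [("p1", 3)]
        assert [(pid, pos) for pid, pos, _ in ts.negatives] == [("p1", 5)]

    def test_protein_without_candidates_contributes_nothing(self):
        extra = Protein(id="p2", sequence="AAAA")
        sites = [ModSite(protein_id="p1", position=3, residue="C", mod_type="PALM")]
        ts = build_training_set([self.prot, extra], sites, "PALM")
        assert all(pid == "p1" for pid, _, _ in ts.positives + ts.negatives)

    def test_no_positives_errors(self):
        with pytest.raises(TrainingError):
            build_training_set([self.prot], [], "PALM")

    def test_windows_are_full_context(self):
        sites = [ModSite(protein_id="p1", position=3, residue="C", mod_type="PALM")]
        ts = build_training_set([self.prot], sites, "PALM")
        assert len(ts.positives[0][2]) == 61


def _planted_ts(offsets, n=30, length=41, seed=0, p_signal=0.95):
    """Palmitoylation set whose signal lives at the given centre offsets."""
    rng = np.random.default_rng(seed)
    letters = [a for a in AA20 if a != "C"]
    proteins, sites = [], []
    for i in range(n):
        seq = [letters[j] for j in rng.integers(len(letters), size=length)]
        c_pos = length // 2 + 1
        seq[c_pos - 1] = "C"
        for off in offsets:
            if rng.random() < p_signal:
                seq[c_pos - 1 + off] = "K"
        seq[4] = "C"  # decoy negative
        pid = f"s{i:02d}"
        proteins.append(Protein(id=pid, sequence="".join(seq)))
        sites.append(ModSite(protein_id=pid, position=c_pos, residue="C", mod_type="PALM"))
    return build_training_set(proteins, sites, "PALM")


def _single_group(ts):
    return [("g0", "consensus", np.arange(len(ts.positives), dtype=np.intp))]


class TestMotifLengthSelection:
    def test_single_candidate_forced(self):
        ts = _planted_ts([-1, 1])
        assert select_motif_length(ts, _single_group(ts), [(7, 7)]) == (7, 7)

    def test_signal_at_five_prefers_wider_window(self):
        """When the signal lives at offsets +-4/+-5, (5,5) beats (1,1)."""
        ts = _planted_ts([-5, -4, 4, 5], n=40)
        assert select_motif_length(ts, _single_group(ts), [(1, 1), (5, 5)]) == (5, 5)

    def test_tie_prefers_shorter_window(self):
        # a single strongly informative position adjacent to the centre:
        # all windows containing it perform identically
        ts = _planted_ts([1], n=20, p_signal=1.0)
        mn = select_motif_length(ts, _single_group(ts), [(3, 3), (1, 1), (5, 5)])
        assert mn == (1, 1)

    def test_candidate_beyond_context_errors(self):
        ts = _planted_ts([1])
        with pytest.raises(TrainingError):
            select_motif_length(ts, _single_group(ts), [(31, 31)])


def _state_and_negs(ts, m, n):
    pos61 = encode_many([w for _, _, w in ts.positives])
    neg61 = encode_many([w for _, _, w in ts.negatives])
    L = m + n + 1
    st = _GroupState(
        group_id="g0", kind="consensus",
        member_idx=np.arange(len(ts.positives), dtype=np.intp),
        codes=_trim_codes(pos61, m, n),
        w=np.ones(L), pair_deltas=np.zeros(N_PAIRS),
    )
    return st, _trim_codes(neg61, m, n)


class TestWeightTraining:
    def test_zero_budget_is_identity(self):
        ts = _planted_ts([-1, 1])
        st, negs = _state_and_negs(ts, 3, 3)
        train_weights(st, negs, TrainConfig(pso_iterations=0), seed=0)
        assert np.array_equal(st.w, np.ones(7))

    def test_objective_never_degrades(self):
        ts = _planted_ts([-1, 1])
        st, negs = _state_and_negs(ts, 3, 3)
        before = group_objective_value(st, negs)
        train_weights(st, negs, TrainConfig(pso_iterations=40), seed=5)
        assert group_objective_value(st, negs) >= before

    def test_signal_positions_upweighted(self):
        """Only offsets +-1 carry signal; their trained weights should
        exceed the mean weight of the uninformative positions. The signal is
        kept partial (p = 0.7) so the baseline is imperfect and weight
        training has something to gain."""
        ts = _planted_ts([-1, 1], n=40, p_signal=0.7)
        st, negs = _state_and_negs(ts, 3, 3)
        train_weights(st, negs, TrainConfig(pso_iterations=80), seed=2)
        signal = st.w[[2, 4]].mean()  # offsets -1, +1 in a (3,3) window
        noise = st.w[[0, 1, 5, 6]].mean()
        assert signal > noise

    def test_weights_stay_nonnegative(self):
        ts = _planted_ts([-1, 1])
        st, negs = _state_and_negs(ts, 3, 3)
        train_weights(st, negs, TrainConfig(pso_iterations=40), seed=1)
        assert np.all(st.w >= 0)


class TestMatrixMutation:
    def test_zero_budget_keeps_blosum(self):
        ts = _planted_ts([-1, 1])
        st, negs = _state_and_negs(ts, 3, 3)
        mutate_matrix(st, negs, TrainConfig(pso_iterations=0), seed=0)
        assert np.all(st.pair_deltas == 0)

    def test_objective_never_degrades_after_wt(self):
        ts = _planted_ts([-1, 1])
        st, negs = _state_and_negs(ts, 3, 3)
        cfg = TrainConfig(pso_iterations=30)
        train_weights(st, negs, cfg, seed=5)
        after_wt = group_objective_value(st, negs)
        mutate_matrix(st, negs, cfg, seed=6)
        assert group_objective_value(st, negs) >= after_wt

    def test_deltas_within_box(self):
        ts = _planted_ts([-1, 1])
        st, negs = _state_and_negs(ts, 3, 3)
        cfg = TrainConfig(pso_iterations=30, mam_box=4.0)
        mutate_matrix(st, negs, cfg, seed=3)
        assert np.all(np.abs(st.pair_deltas) <= 4.0)


class TestGroupAssignment:
    def test_undersized_group_merged_into_nonconsensus(self, caplog):
        # 6 CAAX termini and 2 terminal-CC sites: the CC group is too small
        proteins, sites = [], []
        for i in range(8):
            if i < 6:
                seq = "MKKAAAKKAAKKCVIM"
                pos = len(seq) - 3
            else:
                seq = "MKKAAAKKAAKKAACC"
                pos = len(seq)
            pid = f"g{i}"
            proteins.append(Protein(id=pid, sequence=seq))
            sites.append(ModSite(protein_id=pid, position=pos, residue="C", mod_type="GERA"))
        ts = build_training_set(proteins, sites, "GERA")
        defs = assign_groups(proteins, ts, TrainConfig(), seed=0)
        ids = {g for g, _, _ in defs}
        assert ids == {"consensus_caax", "nonconsensus"}
        sizes = {g: len(idx) for g, _, idx in defs}
        assert sizes["nonconsensus"] == 2

    def test_palm_uses_three_clusters_by_default(self, myr_data):
        proteins, sites = synth.generate(
            synth.SynthSpec(mod_type="PALM", n_positive=30, signal_strength=0.9, seed=4)
        )
        ts = build_training_set(proteins, sites, "PALM")
        defs = assign_groups(proteins, ts, TrainConfig(), seed=0)
        assert len(defs) == 3
        assert all(kind == "kmeans-cluster" for _, kind, _ in defs)


class TestEndToEnd:
    def test_loo_auc_on_planted_data(self, myr_model, myr_training_set):
        sl = evaluation.loo_scores(myr_model, myr_training_set)
        _, auc = evaluation.roc_auc(sl)
        assert auc >= 0.9

    def test_retraining_is_byte_identical(self, myr_data, myr_model, tmp_path):
        proteins, sites = myr_data
        again = training.train(
            proteins, sites, "MYR", TrainConfig(seed=3, pso_iterations=30)
        )
        p1, p2 = tmp_path / "a.json", tmp_path / "b.json"
        myr_model.save(p1)
        again.save(p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_model_round_trip(self, myr_model, tmp_path):
        p1, p2 = tmp_path / "a.json", tmp_path / "b.json"
        myr_model.save(p1)
        training.PredictorModel.load(p1).save(p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_thresholds_ordered(self, myr_model):
        for g in myr_model.groups:
            assert g.thresholds["high"] >= g.thresholds["medium"] >= g.thresholds["low"]


class TestPredict:
    def test_training_sites_recovered_at_low_stringency(self, myr_model, myr_data):
        proteins, sites = myr_data
        hits = {
            (s.protein_id, s.position)
            for s in training.predict(myr_model, proteins, "low")
        }
        truth = {(s.protein_id, s.position) for s in sites}
        assert truth <= hits

    def test_stringency_monotone(self, myr_model, myr_data):
        proteins, _ = myr_data
        keys = {
            level: {(s.protein_id, s.position)
                    for s in training.predict(myr_model, proteins, level)}
            for level in ("high", "medium", "low")
        }
        assert keys["high"] <= keys["medium"] <= keys["low"]

    def test_no_candidates_gives_empty_output(self, myr_model):
        prot = Protein(id="ala", sequence="AAAAAAA")
        assert training.predict(myr_model, [prot], "low") == []

    def test_predictions_carry_scores_and_groups(self, myr_model, myr_data):
        proteins, _ = myr_data
        for s in training.predict(myr_model, proteins[:3], "medium"):
            assert s.evidence == "predicted"
            assert s.score is not None and s.score >= s.cutoff
            assert s.group_id in {g.group_id for g in myr_model.groups}
            assert len(s.peptide) == myr_model.m + myr_model.n + 1
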