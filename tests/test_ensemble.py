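import io

import numpy as np
import pytest

from pepmotif.encoding import EncodingConfig
from pepmotif.ensemble import (
    CVConfig,
    Ensemble,
    TrainConfig,
    collapse_duplicate_peptides,
    evaluate,
    predict,
    run_cross_validation,
    scan_fasta,
    scan_motif_lengths,
    select_final_ensemble,
)
from pepmotif.network import TrainSchedule, best_core, score_batch
from pepmotif.encoding import encode_peptides
from pepmotif.partition import build_partition, random_split
from pepmotif.peptide_io import ProteinRecord, QuantPeptideDataset, load_model, save_model
from pepmotif.synthetic import PlantedMotifSpec, make_planted_motif_dataset

from conftest import make_random_network, random_peptides


def tiny_config(motif_lengths=(5,), **kw):
    defaults = dict(
        motif_lengths=list(motif_lengths),
        encoding=EncodingConfig(scheme="sparse", motif_len=motif_lengths[0]),
        hidden_sizes=[2],
        n_seeds=1,
        cv=CVConfig(folds=3),
        schedule=TrainSchedule(n_iterations=3),
        top_n=5,
    )
    defaults.update(kw)
    return TrainConfig(**defaults)


@pytest.fixture(scope="module")
def tiny_dataset():
    peptides = random_peptides(30, (8, 12), seed=11)
    rng = np.random.default_rng(11)
    return QuantPeptideDataset(peptides=peptides, targets=list(rng.uniform(0, 10, 30)))


class TestRunCrossValidation:
    def test_network_counting_fast_vs_exhaustive(self, tiny_dataset):
        cfg = tiny_config(n_seeds=2, cv=CVConfig(folds=5), hidden_sizes=[2])
        part = random_split(len(tiny_dataset), 5, seed=0)
        fast = run_cross_validation(tiny_dataset, cfg, 5, part, seed=0)
        assert fast.n_networks_trained == 5 * 2
        cfg_ex = tiny_config(
            n_seeds=2, cv=CVConfig(folds=5), hidden_sizes=[2], eval_mode="exhaustive"
        )
        exhaustive = run_cross_validation(tiny_dataset, cfg_ex, 5, part, seed=0)
        assert exhaustive.n_networks_trained == 5 * 4 * 2

    def test_every_record_predicted_once_by_other_folds(self, tiny_dataset):
        cfg = tiny_config()
        part = random_split(len(tiny_dataset), 3, seed=1)
        cv = run_cross_validation(tiny_dataset, cfg, 5, part, seed=1)
        assert not np.isnan(cv.predictions).any()
        # recompute fold-f predictions from fold-f networks only
        for f in range(3):
            idx = part.fold_indices(f)
            nets = cv.fold_networks[f]
            assert all(n.fold == f for n in nets)
            enc = encode_peptides([tiny_dataset.peptides[i] for i in idx], cfg.encoding_for(5))
            mean = np.mean([score_batch(n, enc)[1] for n in nets], axis=0)
            assert np.allclose(cv.predictions[idx], mean)

    def test_planted_motif_beats_shuffled_control(self):
        ds, _ = make_planted_motif_dataset(
            PlantedMotifSpec(n_peptides=400, seed=5, peptide_length_range=(9, 12))
        )
        cfg = tiny_config(
            motif_lengths=(9,),
            encoding=EncodingConfig(scheme="sparse", motif_len=9),
            schedule=TrainSchedule(n_iterations=80),
            hidden_sizes=[3],
            cv=CVConfig(folds=3),
        )
        part = random_split(len(ds), 3, seed=5)
        cv = run_cross_validation(ds, cfg, 9, part, seed=5)
        r = evaluate(cv.predictions, cv.observed_rescaled)["pearson"]
        rng = np.random.default_rng(5)
        shuffled = QuantPeptideDataset(
            peptides=ds.peptides,
            targets=list(rng.permutation(ds.targets)),
        )
        cv_sh = run_cross_validation(shuffled, cfg, 9, part, seed=5)
        r_sh = evaluate(cv_sh.predictions, cv_sh.observed_rescaled)["pearson"]
        assert r > 0.3
        assert r > r_sh

    def test_fast_equals_exhaustive_on_two_fold_toy(self, tiny_dataset):
        """With stopping off and 2 folds the nested procedure collapses
        onto the fast one: identical per-record predictions."""
        part = random_split(len(tiny_dataset), 2, seed=3)
        cfg_f = tiny_config(cv=CVConfig(folds=2), eval_mode="fast")
        cfg_e = tiny_config(cv=CVConfig(folds=2), eval_mode="exhaustive")
        fast = run_cross_validation(tiny_dataset, cfg_f, 5, part, seed=3)
        exh = run_cross_validation(tiny_dataset, cfg_e, 5, part, seed=3)
        assert np.allclose(fast.predictions, exh.predictions)

    def test_requires_targets(self):
        ds = QuantPeptideDataset(peptides=["ACDEF", "GHIKL", "MNPQR"])
        with pytest.raises(ValueError):
            run_cross_validation(ds, tiny_config(), 5, random_split(3, 3, 0))


class TestScanMotifLengths:
    def test_single_candidate_returned(self, tiny_dataset):
        cfg = tiny_config(motif_lengths=(5,))
        best, table, results = scan_motif_lengths(tiny_dataset, cfg, seed=0)
        assert best == 5
        assert list(table["motif_len"]) == [5]

    def test_one_row_per_usable_candidate(self, tiny_dataset):
        # shortest peptide is 8, so 9 must be skipped with a warning
        cfg = tiny_config(motif_lengths=(5, 7, 9))
        with pytest.warns(UserWarning, match="skipped"):
            best, table, _ = scan_motif_lengths(tiny_dataset, cfg, seed=0)
        assert list(table["motif_len"]) == [5, 7]
        assert {"rmse", "boot_mean", "boot_se"} <= set(table.columns)

    def test_rmse_matches_evaluate_on_same_predictions(self, tiny_dataset):
        cfg = tiny_config(motif_lengths=(5,))
        best, table, results = scan_motif_lengths(tiny_dataset, cfg, seed=0)
        cv = results[best]
        idx = cv.retained
        m = evaluate(cv.predictions[idx], cv.observed_rescaled[idx])
        assert table["rmse"].iloc[0] == pytest.approx(m["rmse"])

    def test_all_lengths_skipped_is_error(self, tiny_dataset):
        cfg = tiny_config(motif_lengths=(50,))
        with pytest.raises(ValueError):
            with pytest.warns(UserWarning):
                scan_motif_lengths(tiny_dataset, cfg, seed=0)


class TestSelectFinalEnsemble:
    def _cv(self, dataset, n_seeds=3):
        cfg = tiny_config(n_seeds=n_seeds)
        part = random_split(len(dataset), 3, seed=2)
        return run_cross_validation(dataset, cfg, 5, part, seed=2)

    def test_top_n_counts(self, tiny_dataset):
        cv = self._cv(tiny_dataset)
        assert len(select_final_ensemble(cv, 2).networks) == 3 * 2
        assert len(select_final_ensemble(cv, 99).networks) == 3 * 3

    def test_retained_outrank_discarded(self, tiny_dataset):
        cv = self._cv(tiny_dataset)
        ens = select_final_ensemble(cv, 1)
        kept = {id(n): n for n in ens.networks}
        for f, nets in enumerate(cv.fold_networks):
            kept_rmses = [n.stop_rmse for n in nets if id(n) in kept]
            dropped = [n.stop_rmse for n in nets if id(n) not in kept]
            assert all(k <= d for k in kept_rmses for d in dropped)


class TestPredict:
    def test_single_network_equals_best_core(self):
        net = make_random_network(motif_len=5, seed=1)
        ens = Ensemble(networks=[net], rescale_params=None)
        pep = "ACDEFGHIKL"
        table = predict(ens, [pep])
        off, score = best_core(net, pep)
        assert table["score"][0] == pytest.approx(score)
        assert table["core_offset"][0] == off

    def test_mean_bounded_by_members(self):
        nets = [make_random_network(motif_len=5, seed=s) for s in range(4)]
        ens = Ensemble(networks=nets, rescale_params=None)
        peps = random_peptides(6, (7, 12), seed=2)
        table = predict(ens, peps)
        for i, pep in enumerate(peps):
            member = [best_core(n, pep)[1] for n in nets]
            assert min(member) - 1e-12 <= table["score"][i] <= max(member) + 1e-12

    def test_exact_length_offset_zero(self):
        ens = Ensemble(networks=[make_random_network(motif_len=9)], rescale_params=None)
        assert predict(ens, ["ACDEFGHIK"])["core_offset"][0] == 0

    def test_short_peptide_gets_error_entry(self):
        ens = Ensemble(networks=[make_random_network(motif_len=9)], rescale_params=None)
        table = predict(ens, ["ACDEFGHIK", "ACD"])
        assert table["error"][0] is None
        assert "shorter" in table["error"][1]
        assert np.isnan(table["score"][1])

    def test_empty_list_rejected(self):
        ens = Ensemble(networks=[make_random_network(motif_len=5)], rescale_params=None)
        with pytest.raises(ValueError):
            predict(ens, [])

    def test_logo_offsets_shift_reported_core(self):
        net = make_random_network(motif_len=5, seed=3)
        pep = "ACDEFGHIKLMN"
        raw_off, _ = best_core(net, pep)
        net.logo_offset = 1
        ens = Ensemble(networks=[net], rescale_params=None)
        table = predict(ens, [pep])
        expected = int(np.clip(raw_off - 1, 0, len(pep) - 5))
        assert table["core_offset"][0] == expected


class TestScanFasta:
    def test_window_length_and_count(self):
        net = make_random_network(motif_len=9, flank_len=3)
        ens = Ensemble(networks=[net], rescale_params=None)
        rec = ProteinRecord(id="p", sequence="ACDEFGHIKLMNPQRSTVWY")  # 20 aa
        table = scan_fasta(ens, [rec])
        assert len(table) == 6  # 20 - 15 + 1
        assert all(len(p) == 15 for p in table["peptide"])
        assert set(table["start"]) == set(range(1, 7))

    def test_sorted_descending(self):
        net = make_random_network(motif_len=5, seed=6)
        ens = Ensemble(networks=[net], rescale_params=None)
        recs = [ProteinRecord(id="p", sequence="".join(random_peptides(1, (40, 40), 7)))]
        table = scan_fasta(ens, recs)
        assert (np.diff(table["score"]) <= 1e-15).all()

    def test_short_record_single_window_or_skip(self):
        net = make_random_network(motif_len=9, flank_len=3)
        ens = Ensemble(networks=[net], rescale_params=None)
        recs = [
            ProteinRecord(id="mid", sequence="ACDEFGHIKLMN"),  # 12: one window
            ProteinRecord(id="tiny", sequence="ACDEF"),        # 5: skipped
        ]
        with pytest.warns(UserWarning, match="tiny"):
            table = scan_fasta(ens, recs)
        assert list(table["record"]) == ["mid"]


class TestEvaluate:
    def test_perfect_predictions(self):
        obs = [0.1, 0.4, 0.6, 0.9]
        m = evaluate(obs, obs)
        assert m["pearson"] == pytest.approx(1.0)
        assert m["spearman"] == pytest.approx(1.0)
        assert m["rmse"] == 0.0

    def test_reversed_ranks(self):
        obs = [0.1, 0.2, 0.3, 0.4]
        m = evaluate(list(reversed(obs)), obs)
        assert m["spearman"] == pytest.approx(-1.0)

    def test_auc_all_pairs_concordant(self):
        # 2 positives x 2 negatives, all 4 pairs concordant -> AUC 1
        m = evaluate([0.7, 0.6, 0.3, 0.4], [0.9, 0.8, 0.1, 0.2], auc_threshold=0.5)
        assert m["auc"] == pytest.approx(1.0)

    def test_zero_variance_correlations_absent(self):
        with pytest.warns(UserWarning, match="variance"):
            m = evaluate([0.5, 0.5, 0.5], [0.1, 0.2, 0.3])
        assert m["pearson"] is None and m["spearman"] is None

    def test_single_class_auc_absent(self):
        with pytest.warns(UserWarning, match="class"):
            m = evaluate([0.1, 0.2, 0.3], [0.6, 0.7, 0.8], auc_threshold=0.5)
        assert m["auc"] is None

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            evaluate([0.1, 0.2], [0.1, 0.2])


class TestFullLoop:
    def test_train_save_load_predict_identical(self, tiny_dataset, tmp_path):
        cfg = tiny_config()
        part = random_split(len(tiny_dataset), 3, seed=4)
        cv = run_cross_validation(tiny_dataset, cfg, 5, part, seed=4)
        ens = select_final_ensemble(cv, 2, train_config=cfg)
        held_out = random_peptides(15, (6, 12), seed=99)
        before = ens.predict(held_out)
        path = tmp_path / "m.json"
        save_model(ens, str(path))
        after = load_model(str(path)).predict(held_out)
        assert (before["score"] == after["score"]).all()
        assert (before["core_offset"] == after["core_offset"]).all()


def test_collapse_duplicates():
    ds = QuantPeptideDataset(
        peptides=["AAAAA", "CCCCC", "AAAAA"], targets=[0.2, 0.5, 0.4]
    )
    out = collapse_duplicate_peptides(ds)
    assert out.peptides == ["AAAAA", "CCCCC"]
    assert out.targets == [pytest.approx(0.3), 0.5]
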