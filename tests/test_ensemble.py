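"""Vote collection, interaction calls, cutoff sweeps, networks."""

import numpy as np
import pandas as pd
import pytest

from mtqsar import (
    EnsembleConfig,
    VoteVector,
    build_network,
    call_interaction,
    collect_votes,
    degree_stats,
    filter_by_median_degree,
    predict_batch,
    sweep_cutoffs,
)
from mtqsar.ensemble import best_cutoff, read_smiles_file, vote_matrix, write_graphml, write_sif
from mtqsar.errors import BatchLimitError, DomainError, UnknownTargetError
from mtqsar.modeling import ALL_MODEL_NAMES


def make_votes(count):
    votes = {name: 0 for name in ALL_MODEL_NAMES}
    for name in list(votes)[:count]:
        votes[name] = 1
    return VoteVector("c", "t", votes)


class TestCallInteraction:
    def test_at_cutoff_is_active(self):
        assert call_interaction(make_votes(9), EnsembleConfig(cutoff=9)) == "active"

    def test_below_cutoff_inactive(self):
        assert call_interaction(make_votes(8), EnsembleConfig(cutoff=9)) == "inactive"

    def test_unanimous_active_at_every_cutoff(self):
        for cutoff in range(1, 17):
            assert call_interaction(make_votes(16), EnsembleConfig(cutoff=cutoff)) == "active"

    def test_cutoff_bounds(self):
        with pytest.raises(DomainError):
            EnsembleConfig(cutoff=0)
        with pytest.raises(DomainError):
            EnsembleConfig(cutoff=17)


class TestVoteVector:
    def test_requires_canonical_names(self):
        with pytest.raises(DomainError):
            VoteVector("c", "t", {"RF_MACCS": 1})

    def test_count_is_sum(self):
        assert make_votes(11).vote_count == 11


class TestSweep:
    def test_perfectly_separated_pair(self):
        sweep = sweep_cutoffs([16, 0], [1, 0])
        assert (sweep["SE"] == 1).all() and (sweep["SP"] == 1).all()
        assert (sweep["Q"] == 1).all() and (sweep["MCC"] == 1).all()

    def test_hand_worked_four_pairs(self):
        sweep = sweep_cutoffs([12, 10, 7, 3], [1, 1, 0, 0]).set_index("cutoff")
        at9 = sweep.loc[9]
        assert (at9["SE"], at9["SP"], at9["Q"], at9["MCC"]) == (1.0, 1.0, 1.0, 1.0)
        at11 = sweep.loc[11]
        assert at11["SE"] == 0.5 and at11["SP"] == 1.0 and at11["Q"] == 0.75
        assert at11["MCC"] == pytest.approx(0.5774, abs=1e-4)

    def test_balanced_accuracy_column(self):
        sweep = sweep_cutoffs([12, 10, 7, 3], [1, 1, 0, 0])
        assert np.allclose(sweep["AUC"], (sweep["SE"] + sweep["SP"]) / 2)

    def test_vote_count_roc_column_constant(self):
        sweep = sweep_cutoffs([12, 10, 7, 3], [1, 1, 0, 0])
        assert sweep["vote_auc"].nunique() == 1
        assert sweep["vote_auc"].iloc[0] == 1.0

    def test_monotone_se_sp_random_sets(self):
        rng = np.random.default_rng(31)
        for _ in range(25):
            n = int(rng.integers(10, 60))
            counts = rng.integers(0, 17, size=n)
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            sweep = sweep_cutoffs(counts, labels)
            assert (np.diff(sweep["SE"]) <= 1e-12).all()
            assert (np.diff(sweep["SP"]) >= -1e-12).all()

    def test_single_class_rejected(self):
        with pytest.raises(DomainError):
            sweep_cutoffs([5, 9], [1, 1])

    def test_best_cutoff_smallest_argmax(self):
        sweep = sweep_cutoffs([16, 0], [1, 0])
        assert best_cutoff(sweep, "Q") == 1  # flat maximum -> smallest cutoff


class TestCollectVotes:
    def test_sixteen_named_votes_in_order(self, tiny_results, tiny_benchmark):
        smi = tiny_benchmark.datasets["T01"].smiles()[0]
        vv = collect_votes(tiny_results.suite, smi, "T01")
        assert tuple(vv.votes) == ALL_MODEL_NAMES
        assert vv.vote_count == sum(vv.votes.values())

    def test_unknown_target(self, tiny_results):
        with pytest.raises(UnknownTargetError):
            collect_votes(tiny_results.suite, "CCO", "MISSING")

    def test_matrix_matches_single_queries(self, tiny_results, tiny_benchmark):
        smiles = tiny_benchmark.datasets["T02"].smiles()[:4]
        mat = vote_matrix(tiny_results.suite, smiles, "T02")
        for row, smi in zip(mat, smiles):
            vv = collect_votes(tiny_results.suite, smi, "T02")
            assert np.array_equal(row, list(vv.votes.values()))

    def test_signature_compound_scores_high(self, tiny_results, tiny_benchmark):
        """A strongly active training compound should collect far more votes
        than a bare ethane-like decoy."""
        ds = tiny_benchmark.datasets["T01"]
        active_smi = max(ds.records, key=lambda r: r.pic50).canonical_smiles
        n_active = collect_votes(tiny_results.suite, active_smi, "T01").vote_count
        n_decoy = collect_votes(tiny_results.suite, "CCCC", "T01").vote_count
        assert n_active > n_decoy


class TestPredictBatch:
    def test_cardinality(self, tiny_results, tiny_benchmark):
        mols = [("m1", "CCO"), ("m2", "CCN"), ("m3", "CCCC")]
        res = predict_batch(tiny_results.suite, mols)
        assert len(res.table) == 3 * 2
        assert list(res.table.columns[3:19]) == list(ALL_MODEL_NAMES)
        assert (res.table["vote_count"] ==
                res.table[list(ALL_MODEL_NAMES)].sum(axis=1)).all()

    def test_bad_smiles_rejected_not_fatal(self, tiny_results):
        mols = [("ok1", "CCO"), ("bad", "(((("), ("ok2", "CCN"),
                ("ok3", "CCC"), ("ok4", "CCCC")]
        res = predict_batch(tiny_results.suite, mols, targets=["T01"])
        assert len(res.table) == 4
        assert len(res.rejections) == 1
        assert res.rejections.iloc[0]["compound_id"] == "bad"

    def test_batch_cap_enforced(self, tiny_results):
        mols = [(f"m{i}", "CCO") for i in range(4)]
        with pytest.raises(BatchLimitError) as err:
            predict_batch(tiny_results.suite, mols, config=EnsembleConfig(batch_cap=3))
        assert "cap of 3" in str(err.value)

    def test_empty_input_empty_table(self, tiny_results):
        res = predict_batch(tiny_results.suite, [])
        assert len(res.table) == 0 and list(res.table.columns)[:2] == ["compound_id", "smiles"]

    def test_smiles_file_roundtrip(self, tiny_results, tmp_path):
        path = tmp_path / "query.smi"
        path.write_text("CCO ethanol\nCCN\n# comment\n")
        mols = read_smiles_file(path)
        assert mols[0] == ("ethanol", "CCO") and mols[1][1] == "CCN"
        res = predict_batch(tiny_results.suite, path, targets=["T01"])
        assert set(res.table["compound_id"]) == {"ethanol", "mol_2"}


def example_table():
    rows = [
        ("c1", "t1", 12, "active"),
        ("c1", "t2", 10, "active"),
        ("c2", "t1", 9, "active"),
        ("c2", "t2", 3, "inactive"),
    ]
    return pd.DataFrame(rows, columns=["compound_id", "target_id", "vote_count", "call"])


class TestNetwork:
    def test_edges_from_calls(self):
        net = build_network(example_table())
        assert net.number_of_edges() == 3
        assert net.nodes["c1"]["kind"] == "compound"

    def test_recut_with_cutoff(self):
        net = build_network(example_table(), cutoff=11)
        assert set(net.edges()) == {("c1", "t1")}

    def test_empty_and_duplicates(self):
        assert build_network(example_table().iloc[:0]).number_of_nodes() == 0
        doubled = pd.concat([example_table()] * 2)
        assert build_network(doubled).number_of_edges() == 3

    def test_degree_stats_example(self):
        net = build_network(example_table())
        stats = degree_stats(net)
        assert stats.degrees == {"c1": 2, "t1": 2, "c2": 1, "t2": 1}
        assert stats.median_degree == 1.5
        assert stats.mean_targets_per_compound == 1.5
        assert stats.mean_compounds_per_target == 1.5

    def test_star_degree(self):
        rows = [("c1", f"t{i}", 16, "active") for i in range(1, 6)]
        net = build_network(pd.DataFrame(
            rows, columns=["compound_id", "target_id", "vote_count", "call"]))
        stats = degree_stats(net)
        assert stats.degrees["c1"] == 5 and stats.median_degree == 1.0

    def test_median_filter_keeps_promiscuous_compound(self):
        filtered = filter_by_median_degree(build_network(example_table()))
        compounds = [n for n, d in filtered.nodes(data=True) if d["kind"] == "compound"]
        assert compounds == ["c1"]
        targets = {n for n, d in filtered.nodes(data=True) if d["kind"] == "target"}
        assert targets == {"t1", "t2"}

    def test_median_filter_strictness_drops_uniform(self):
        rows = [("c1", "t1", 16, "active"), ("c2", "t2", 16, "active")]
        net = build_network(pd.DataFrame(
            rows, columns=["compound_id", "target_id", "vote_count", "call"]))
        filtered = filter_by_median_degree(net)  # all degrees 1 == median
        assert not [n for n, d in filtered.nodes(data=True) if d["kind"] == "compound"]

    def test_degree_sum_is_twice_edges(self):
        net = build_network(example_table())
        assert sum(dict(net.degree()).values()) == 2 * net.number_of_edges()

    def test_exports(self, tmp_path):
        net = build_network(example_table())
        sif = tmp_path / "net.sif"
        write_sif(net, sif)
        lines = sif.read_text().strip().splitlines()
        assert len(lines) == 3 and all("interacts" in ln for ln in lines)
        write_graphml(net, tmp_path / "net.graphml")
        import networkx as nx

        back = nx.read_graphml(tmp_path / "net.graphml")
        assert back.number_of_edges() == 3
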