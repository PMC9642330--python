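"""Leave-one-out identification criteria and their invariants."""

import numpy as np
import pytest

from barcodekit.distances import DistanceMatrix, distance_matrix
from barcodekit.identify import (
    BestMatchClassifier,
    IdentificationConfig,
    all_species_barcodes,
    best_close_match,
    best_match,
    evaluate_dataset,
    percentile_threshold,
)
from barcodekit.synthgen import SynthSpec, generate_community

from conftest import make_dataset


def _dm(ids, mat):
    return DistanceMatrix(ids, np.asarray(mat, dtype=float), "k2p")


def _matrix_from_rows(rows):
    """Square matrix from {id: {other: d}} (symmetric completion)."""
    ids = list(rows)
    n = len(ids)
    m = np.zeros((n, n))
    for i, a in enumerate(ids):
        for j, b in enumerate(ids):
            if i != j:
                d = rows[a].get(b, rows[b].get(a))
                m[i, j] = m[j, i] = d
    return _dm(ids, m)


class TestPercentileThreshold:
    def test_single_value_any_percentile(self):
        dm = _dm(["a1", "a2"], [[0, 0.004], [0.004, 0]])
        labels = {"a1": "Sp", "a2": "Sp"}
        for pct in (1, 50, 95, 100):
            assert percentile_threshold(dm, labels, pct) == 0.004

    def test_nearest_rank_definition(self):
        # 20 two-member species whose conspecific distances are
        # 0.001..0.020; nearest-rank 95th percentile = 19th value = 0.019
        n = 40
        ids = [f"r{i}" for i in range(n)]
        labels = {f"r{i}": f"Sp{i // 2}" for i in range(n)}
        m = np.full((n, n), 0.3)
        np.fill_diagonal(m, 0.0)
        for k in range(20):
            d = 0.001 * (k + 1)
            m[2 * k, 2 * k + 1] = m[2 * k + 1, 2 * k] = d
        dm = _dm(ids, m)
        assert percentile_threshold(dm, labels, 95) == pytest.approx(0.019)
        assert percentile_threshold(dm, labels, 100) == pytest.approx(0.020)
        assert percentile_threshold(dm, labels, 5) == pytest.approx(0.001)

    def test_all_zero_distances(self):
        dm = _dm(["a1", "a2"], [[0, 0], [0, 0]])
        assert percentile_threshold(dm, {"a1": "Sp", "a2": "Sp"}, 95) == 0.0

    def test_no_conspecific_pairs_rejected(self):
        dm = _dm(["a1", "b1"], [[0, 0.05], [0.05, 0]])
        with pytest.raises(ValueError):
            percentile_threshold(dm, {"a1": "A", "b1": "B"}, 95)


class TestBestMatch:
    def test_unique_closest_conspecific(self):
        dm = _matrix_from_rows(
            {"q": {"a": 0.004, "b": 0.08}, "a": {"b": 0.08}, "b": {}}
        )
        labels = {"q": "SpA", "a": "SpA", "b": "SpB"}
        assert best_match("q", dm, labels) == "correct"

    def test_exact_tie_with_heterospecific_is_ambiguous(self):
        dm = _matrix_from_rows(
            {"q": {"a": 0.004, "b": 0.004}, "a": {"b": 0.08}, "b": {}}
        )
        labels = {"q": "SpA", "a": "SpA", "b": "SpB"}
        assert best_match("q", dm, labels) == "ambiguous"

    def test_singleton_query_is_incorrect(self):
        dm = _matrix_from_rows(
            {"q": {"a": 0.05, "b": 0.08}, "a": {"b": 0.01}, "b": {}}
        )
        labels = {"q": "SpQ", "a": "SpA", "b": "SpA"}
        assert best_match("q", dm, labels) == "incorrect"


class TestBestCloseMatch:
    def test_within_threshold_follows_best_match(self):
        dm = _matrix_from_rows(
            {"q": {"a": 0.004, "b": 0.08}, "a": {"b": 0.08}, "b": {}}
        )
        labels = {"q": "SpA", "a": "SpA", "b": "SpB"}
        assert best_close_match("q", dm, labels) == "correct"

    def test_beyond_threshold_is_no_match(self):
        dm = _matrix_from_rows(
            {"q": {"a": 0.03, "b": 0.08}, "a": {"b": 0.08}, "b": {}}
        )
        labels = {"q": "SpA", "a": "SpA", "b": "SpB"}
        assert best_close_match("q", dm, labels) == "no_match"


class TestAllSpeciesBarcodes:
    labels = {"q": "SpA", "a1": "SpA", "a2": "SpA", "b": "SpB"}

    def _dm_for(self, d_a1, d_a2, d_b):
        return _matrix_from_rows(
            {
                "q": {"a1": d_a1, "a2": d_a2, "b": d_b},
                "a1": {"a2": 0.004, "b": 0.08},
                "a2": {"b": 0.08},
                "b": {},
            }
        )

    def test_full_separation_is_correct(self):
        dm = self._dm_for(0.002, 0.004, 0.08)
        assert all_species_barcodes("q", dm, self.labels) == "correct"

    def test_conspecific_outside_threshold_is_ambiguous(self):
        dm = self._dm_for(0.002, 0.015, 0.08)
        assert all_species_barcodes("q", dm, self.labels) == "ambiguous"

    def test_heterospecific_interleaving_is_ambiguous(self):
        dm = self._dm_for(0.002, 0.009, 0.005)
        assert all_species_barcodes("q", dm, self.labels) == "ambiguous"

    def test_closest_heterospecific_is_incorrect(self):
        dm = self._dm_for(0.008, 0.009, 0.003)
        assert all_species_barcodes("q", dm, self.labels) == "incorrect"

    def test_everything_beyond_threshold_is_no_match(self):
        dm = self._dm_for(0.03, 0.04, 0.08)
        assert all_species_barcodes("q", dm, self.labels) == "no_match"


class TestEvaluateDataset:
    def test_clear_community_fully_correct(self, clear_community):
        ds, _ = clear_community
        dm = distance_matrix(ds, "k2p")
        labels = ds.species_of()
        # premise: the realized barcode gap brackets the threshold
        intra = [dm.data[i, j]
                 for i in range(len(ds)) for j in range(i + 1, len(ds))
                 if labels[ds.ids[i]] == labels[ds.ids[j]]]
        inter = [dm.data[i, j]
                 for i in range(len(ds)) for j in range(i + 1, len(ds))
                 if labels[ds.ids[i]] != labels[ds.ids[j]]]
        assert max(intra) < 0.01 < min(inter)
        report = evaluate_dataset(ds, IdentificationConfig(threshold=0.01))
        for criterion in report.summary.index:
            assert report.percent(criterion, "correct") == 100.0

    def test_summary_percentages_sum_to_100(self, sibling_community):
        ds, _ = sibling_community
        report = evaluate_dataset(ds)
        for criterion in report.summary.index:
            assert report.summary.loc[criterion].sum() == pytest.approx(
                100.0, abs=0.1
            )

    def test_sibling_pair_defeats_best_match(self):
        # two species at 0.3% separation with 0.5% intraspecific spread:
        # confusions appear (a stochastic claim, so pooled over seeds)
        not_correct = 0.0
        for seed in range(5):
            spec = SynthSpec(S=2, n_per_species=3, delta_intra=0.005,
                             delta_inter=0.08, sibling_pairs=((0, 1, 0.003),),
                             n_singletons=0, seed=seed)
            ds, _ = generate_community(spec)
            report = evaluate_dataset(ds)
            not_correct += (
                report.percent("best_match", "incorrect")
                + report.percent("best_match", "ambiguous")
            )
        assert not_correct > 0

    def test_confusions_confined_to_sibling_pair(self, sibling_community):
        ds, _ = sibling_community
        report = evaluate_dataset(ds)
        per = report.per_query
        bad = per[per["best_match"].isin(["incorrect", "ambiguous"])]
        sib_or_singleton = set()
        for sp in ds.species:
            members = ds.by_species(sp)
            if sp in ("Species_001", "Species_002") or len(members) == 1:
                sib_or_singleton.add(sp)
        assert set(bad["species"]) <= sib_or_singleton

    def test_singleton_queries_no_match_under_gated_criteria(
        self, sibling_community
    ):
        ds, _ = sibling_community
        report = evaluate_dataset(ds)
        per = report.per_query.set_index("id")
        singles = [sp for sp in ds.species if len(ds.by_species(sp)) == 1]
        assert singles
        for sp in singles:
            rid = ds.by_species(sp)[0].id
            assert per.loc[rid, "best_match"] == "incorrect"
            assert per.loc[rid, "best_close_match"] == "no_match"


class TestCriterionInvariants:
    def test_bcm_equals_bm_below_threshold(self, sibling_community):
        ds, _ = sibling_community
        dm = distance_matrix(ds, "k2p")
        labels = ds.species_of()
        cfg = IdentificationConfig(threshold=0.01)
        for rid in dm.ids:
            qidx = dm.ids.index(rid)
            d = np.delete(dm.data[qidx], qidx)
            bm = best_match(rid, dm, labels, cfg)
            bcm = best_close_match(rid, dm, labels, cfg)
            if np.nanmin(d) <= cfg.threshold:
                assert bcm == bm
            else:
                assert bcm == "no_match"

    def test_asb_never_more_correct_than_bcm(self, sibling_community):
        ds, _ = sibling_community
        report = evaluate_dataset(ds)
        per = report.per_query
        asb_correct = per[per["all_species_barcodes"] == "correct"]
        assert (asb_correct["best_close_match"] == "correct").all()

    def test_raising_threshold_never_increases_no_match(self, sibling_community):
        ds, _ = sibling_community
        dm = distance_matrix(ds, "k2p")
        prev = None
        for t in (0.002, 0.005, 0.01, 0.02, 0.05):
            rep = evaluate_dataset(
                ds, IdentificationConfig(threshold=t), matrix=dm
            )
            counts = {
                c: (rep.per_query[c] == "no_match").sum()
                for c in ("best_close_match", "all_species_barcodes")
            }
            if prev is not None:
                for c, v in counts.items():
                    assert v <= prev[c]
            prev = counts

    def test_percentile_mode_matches_explicit_threshold(self, clear_community):
        ds, _ = clear_community
        dm = distance_matrix(ds, "k2p")
        labels = ds.species_of()
        t = percentile_threshold(dm, labels, 95)
        rep_auto = evaluate_dataset(
            ds,
            IdentificationConfig(threshold_mode="intraspecific_percentile"),
            matrix=dm,
        )
        assert rep_auto.threshold == t


class TestBestMatchClassifier:
    def test_predicts_true_species_on_clear_community(self, clear_community):
        ds, _ = clear_community
        clf = BestMatchClassifier().fit(ds)
        preds = clf.predict([r.seq for r in ds])
        assert list(preds) == [r.species for r in ds]

    def test_distant_query_gets_no_match(self, clear_community):
        ds, _ = clear_community
        rng = np.random.default_rng(1)
        alien = "".join(rng.choice(list("ACGT"), size=ds.length))
        clf = BestMatchClassifier(threshold=0.01).fit(ds)
        assert clf.predict([alien])[0] == ""

    def test_sklearn_clone_compatible(self):
        from sklearn.base import clone

        clf = BestMatchClassifier(threshold=0.02, model="p")
        cloned = clone(clf)
        assert cloned.get_params() == clf.get_params()
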