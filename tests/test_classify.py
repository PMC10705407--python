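"""Tests for the logistic site classifier and label aggregations."""

import numpy as np
import pandas as pd
import pytest
from sklearn.utils.estimator_checks import check_estimator

from splicecons.annotation import Intron, SpliceSite, Transcript
from splicecons.classify import (
    N_FULL_FEATURES,
    SiteLabel,
    SpliceSiteClassifier,
    intron_categories,
    isoform_sharing,
    label_sites,
    load_model,
    predict_probability,
    save_model,
    score_probability_correlation,
    stratify_by_mane_exon,
    train_classifier,
    well_supported_transcripts,
)
from splicecons.simdata import SimTruth


def _vectors(rng, n, mean, m=25):
    joint = np.clip(rng.normal(mean, 1.5, n), 0, m).round()
    rest = np.clip(rng.normal(mean, 2.0, (n, N_FULL_FEATURES - 1)), 0, m).round()
    return np.column_stack([joint, rest])


class TestPredict:
    def test_all_zero_vector_gives_logistic_of_intercept(self):
        rng = np.random.default_rng(0)
        model, _ = train_classifier(
            _vectors(rng, 200, 20), _vectors(rng, 200, 5), seed=0
        )
        p = predict_probability(model, np.zeros(N_FULL_FEATURES))
        expected = 1 / (1 + np.exp(-model.intercept_))
        assert p[0] == pytest.approx(expected, abs=1e-9)

    def test_probability_matches_dot_product_oracle(self):
        rng = np.random.default_rng(1)
        model, _ = train_classifier(
            _vectors(rng, 300, 20), _vectors(rng, 300, 5), seed=1
        )
        for _ in range(50):
            x = rng.uniform(0, 25, N_FULL_FEATURES)
            z = model.intercept_ + float(np.dot(model.coef_, x))
            assert predict_probability(model, x)[0] == pytest.approx(
                1 / (1 + np.exp(-z)), abs=1e-9
            )

    def test_dinuc_model_uses_only_joint_feature(self):
        rng = np.random.default_rng(2)
        model, _ = train_classifier(
            _vectors(rng, 300, 20), _vectors(rng, 300, 5), kind="dinuc", seed=0
        )
        assert model.coef_.shape == (1,)
        x1 = np.r_[10.0, np.zeros(N_FULL_FEATURES - 1)]
        x2 = np.r_[10.0, np.full(N_FULL_FEATURES - 1, 25.0)]
        assert predict_probability(model, x1)[0] == predict_probability(model, x2)[0]

    def test_monotone_in_joint_count_when_coefficient_positive(self):
        rng = np.random.default_rng(3)
        model, _ = train_classifier(
            _vectors(rng, 300, 22), _vectors(rng, 300, 4), kind="dinuc", seed=0
        )
        assert model.coef_[0] > 0
        probs = [
            predict_probability(model, np.r_[j, np.zeros(N_FULL_FEATURES - 1)])[0]
            for j in range(0, 26)
        ]
        assert all(a < b for a, b in zip(probs, probs[1:]))

    def test_dimension_mismatch_rejected(self):
        rng = np.random.default_rng(4)
        model, _ = train_classifier(_vectors(rng, 100, 20), _vectors(rng, 100, 5), seed=0)
        with pytest.raises(ValueError):
            model.predict_proba(np.ones((1, 7)))


class TestTraining:
    def test_separable_classes_reach_perfect_auroc(self):
        rng = np.random.default_rng(5)
        pos = _vectors(rng, 300, 24)
        neg = _vectors(rng, 300, 2)
        _, ev = train_classifier(pos, neg, seed=0)
        assert ev.auroc == 1.0

    def test_shuffled_labels_give_chance_auroc(self):
        rng = np.random.default_rng(6)
        pool = _vectors(rng, 1_200, 12)
        _, ev = train_classifier(pool[:600], pool[600:], seed=0)
        assert abs(ev.auroc - 0.5) < 0.08

    def test_auroc_matches_trapezoid_oracle(self):
        rng = np.random.default_rng(7)
        pos = _vectors(rng, 250, 15)
        neg = _vectors(rng, 250, 10)
        model, ev = train_classifier(pos, neg, seed=3)
        # recompute on an independent stratified split with the same seed
        from sklearn.model_selection import train_test_split

        X = np.vstack([pos, neg])
        y = np.r_[np.ones(len(pos)), np.zeros(len(neg))]
        _, X_test, _, y_test = train_test_split(
            X, y, test_size=0.2, random_state=3, stratify=y
        )
        scores = model.predict_proba(X_test)[:, 1]
        order = np.argsort(-scores)
        tp = np.cumsum(y_test[order] == 1) / (y_test == 1).sum()
        fp = np.cumsum(y_test[order] == 0) / (y_test == 0).sum()
        auroc = np.trapezoid(np.r_[0, tp], np.r_[0, fp])
        assert ev.auroc == pytest.approx(auroc, abs=0.02)

    def test_training_reproducible_under_seed(self):
        rng = np.random.default_rng(8)
        pos, neg = _vectors(rng, 200, 20), _vectors(rng, 200, 5)
        m1, e1 = train_classifier(pos, neg, seed=9)
        m2, e2 = train_classifier(pos, neg, seed=9)
        assert np.array_equal(m1.coef_, m2.coef_)
        assert e1.auroc == e2.auroc

    def test_empty_class_rejected(self):
        rng = np.random.default_rng(9)
        with pytest.raises(ValueError):
            train_classifier(np.empty((0, N_FULL_FEATURES)), _vectors(rng, 10, 5))

    def test_model_round_trips_through_text_table(self, tmp_path):
        rng = np.random.default_rng(10)
        for kind in ("full", "dinuc"):
            model, _ = train_classifier(
                _vectors(rng, 150, 20), _vectors(rng, 150, 5), kind=kind, seed=0
            )
            path = tmp_path / f"{kind}.tsv"
            save_model(model, path, metadata={"seed": 0})
            loaded = load_model(path)
            x = rng.uniform(0, 25, N_FULL_FEATURES)
            assert predict_probability(loaded, x)[0] == pytest.approx(
                predict_probability(model, x)[0], abs=1e-9
            )

    def test_sklearn_estimator_contract(self):
        check_estimator(
            SpliceSiteClassifier(),
            expected_failed_checks={
                "check_classifiers_one_label": "single-class fit unsupported",
            },
        )


class TestLabels:
    def test_threshold_labels(self):
        rng = np.random.default_rng(11)
        model, _ = train_classifier(
            _vectors(rng, 200, 22), _vectors(rng, 200, 3), kind="dinuc", seed=0
        )
        X = np.vstack(
            [
                np.r_[24.0, np.zeros(N_FULL_FEATURES - 1)],
                np.r_[1.0, np.zeros(N_FULL_FEATURES - 1)],
            ]
        )
        labels = label_sites(model, X, ["high", "low"])
        assert labels["high"].label == "well"
        assert labels["low"].label == "less"

    def test_label_accuracy_on_generator_truth(self, mini_world, mini_result):
        intents = mini_world.truth.site_intents
        ok = tot = 0
        for key, lab in mini_result.labels.items():
            k = SimTruth.site_key_str(key)
            if k in intents:
                tot += 1
                ok += (lab.label == "well") == (intents[k] == "well")
        assert tot > 100
        assert ok / tot >= 0.9


def _tx(tid, exons, strand="+"):
    return Transcript(tid, "g", "cat", "coding", strand, "chr1", exons)


def _labels_for(tx, label="well"):
    labels = {}
    for s, e in tx.introns:
        if tx.strand == "+":
            keys = [("chr1", "+", "donor", s), ("chr1", "+", "acceptor", e - 2)]
        else:
            keys = [("chr1", "-", "donor", e - 1), ("chr1", "-", "acceptor", s + 1)]
        for k in keys:
            labels[k] = SiteLabel(k, 0.9 if label == "well" else 0.1, label)
    return labels


class TestAggregations:
    def test_all_mane_transcript_included(self):
        tx = _tx("t1", ((0, 10), (20, 30)))
        mane_keys = set(_labels_for(tx))
        accepted, counts = well_supported_transcripts([tx], {}, mane_keys)
        assert [t.transcript_id for t in accepted] == ["t1"]
        assert counts.iloc[0]["well_supported"] == 1

    def test_one_less_site_excludes_transcript(self):
        tx = _tx("t1", ((0, 10), (20, 30), (40, 50)))
        labels = _labels_for(tx, "well")
        first_key = next(iter(labels))
        labels[first_key] = SiteLabel(first_key, 0.1, "less")
        accepted, _ = well_supported_transcripts([tx], labels, set())
        assert accepted == []

    def test_unlabelled_site_raises(self):
        tx = _tx("t1", ((0, 10), (20, 30)))
        with pytest.raises(KeyError):
            well_supported_transcripts([tx], {}, set())

    def test_random_labels_match_forall_oracle(self):
        rng = np.random.default_rng(12)
        txs = []
        labels = {}
        for i in range(100):
            n_exons = int(rng.integers(2, 6))
            exons = []
            pos = int(rng.integers(0, 1000))
            for _ in range(n_exons):
                exons.append((pos, pos + 10))
                pos += 30
            strand = "+" if rng.random() < 0.5 else "-"
            tx = _tx(f"t{i}", tuple(exons), strand)
            txs.append(tx)
            for k in _labels_for(tx):
                labels.setdefault(
                    k,
                    SiteLabel(k, 0.0, "well" if rng.random() < 0.7 else "less"),
                )
        accepted, _ = well_supported_transcripts(txs, labels, set())
        expected = {
            tx.transcript_id
            for tx in txs
            if all(labels[k].label == "well" for k in _labels_for(tx))
        }
        assert {t.transcript_id for t in accepted} == expected

    def test_antitone_in_less_set(self):
        rng = np.random.default_rng(13)
        tx = _tx("t1", ((0, 10), (20, 30), (40, 50)))
        labels = _labels_for(tx, "well")
        base, _ = well_supported_transcripts([tx], labels, set())
        for key in labels:
            flipped = dict(labels)
            flipped[key] = SiteLabel(key, 0.1, "less")
            smaller, _ = well_supported_transcripts([tx], flipped, set())
            assert len(smaller) <= len(base)

    @pytest.mark.parametrize(
        "donor_label,acceptor_label,category",
        [("less", "less", 1), ("well", "less", 2), ("less", "well", 3), ("well", "well", 4)],
    )
    def test_intron_category_enumeration(self, donor_label, acceptor_label, category):
        dkey = ("chr1", "+", "donor", 10)
        akey = ("chr1", "+", "acceptor", 28)
        intron = Intron("chr1", "+", 10, 30, dkey, akey)
        labels = {
            dkey: SiteLabel(dkey, 0.5, donor_label),
            akey: SiteLabel(akey, 0.5, acceptor_label),
        }
        assert intron_categories([intron], labels)[intron.key()] == category

    def test_mane_shared_sites_count_as_well(self):
        dkey = ("chr1", "+", "donor", 10)
        akey = ("chr1", "+", "acceptor", 28)
        intron = Intron("chr1", "+", 10, 30, dkey, akey)
        labels = {akey: SiteLabel(akey, 0.5, "less")}
        assert intron_categories([intron], labels, {dkey})[intron.key()] == 2

    def test_stratify_by_mane_exon_oracle(self):
        rng = np.random.default_rng(14)
        exons = []
        pos = 0
        for _ in range(30):
            pos += int(rng.integers(10, 50))
            end = pos + int(rng.integers(5, 40))
            exons.append(("chr1", pos, end))
            pos = end
        sites, labels = [], {}
        for i in range(200):
            origin = int(rng.integers(0, pos))
            site = SpliceSite("chr1", "+", "donor", origin)
            if site.key() in labels:
                continue
            sites.append(site)
            labels[site.key()] = SiteLabel(
                site.key(), 0.0, "well" if rng.random() < 0.5 else "less"
            )
        table = stratify_by_mane_exon(sites, exons, labels)
        for inside_name, inside_flag in (("inside", True), ("outside", False)):
            for lab in ("well", "less"):
                expected = sum(
                    1
                    for s in sites
                    if any(a <= s.origin < b for _, a, b in exons) == inside_flag
                    and labels[s.key()].label == lab
                )
                assert table.loc[inside_name, lab] == expected

    def test_isoform_sharing_counts_membership(self):
        s1 = SpliceSite("chr1", "+", "donor", 10, transcripts=["a", "b", "c"])
        s2 = SpliceSite("chr1", "+", "donor", 50, transcripts=["a"])
        df = isoform_sharing([s1, s2])
        assert df.set_index("site_key")["n_isoforms"].tolist() == [3, 1]


class TestCorrelation:
    def test_identical_series_r_one(self):
        probs = {i: p for i, p in enumerate((0.1, 0.5, 0.9))}
        scores = {i: (p, p + 0.05) for i, p in enumerate((0.1, 0.5, 0.9))}
        assert score_probability_correlation(probs, scores) == pytest.approx(1.0)

    def test_anti_ordered_r_minus_one(self):
        probs = {0: 0.9, 1: 0.5, 2: 0.1}
        scores = {0: (0.1, 0.2), 1: (0.5, 0.6), 2: (0.9, 1.0)}
        assert score_probability_correlation(probs, scores) == pytest.approx(-1.0)

    def test_fewer_than_two_pairs_undefined(self):
        assert score_probability_correlation({0: 0.5}, {0: (0.1, 0.2)}) is None
        assert score_probability_correlation({0: 0.5, 1: 0.7}, {}) is None

    def test_matches_closed_form_oracle(self):
        rng = np.random.default_rng(15)
        probs = {i: float(rng.random()) for i in range(100)}
        scores = {i: (float(rng.random()), float(rng.random())) for i in range(80)}
        r = score_probability_correlation(probs, scores)
        xs = np.array([min(scores[i]) for i in range(80)])
        ys = np.array([probs[i] for i in range(80)])
        xc, yc = xs - xs.mean(), ys - ys.mean()
        expected = float((xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum()))
        assert r == pytest.approx(expected, abs=1e-9)

    def test_min_score_is_used_per_site(self):
        probs = {0: 0.2, 1: 0.8}
        scores = {0: (0.9, 0.1), 1: (0.5, 0.95)}
        r = score_probability_correlation(probs, scores)
        assert r == pytest.approx(1.0)  # mins are 0.1 < 0.5, same order as probs
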