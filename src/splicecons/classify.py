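"""Logistic classification of splice sites and downstream aggregation.

The model predicts the probability that a site shows consensus-catalog-like
(well-supported) rather than neutral-like (less-supported) conservation.
The log-odds are linear in the conservation features::

    log p/(1-p) = a0 + a1 * joint_dinuc_count + sum_l a_l * count_l

where ``joint_dinuc_count`` is the number of species conserving the canonical
dinucleotide jointly and ``count_l`` the per-shift species counts for the 60
surrounding positions.  The ``dinuc`` model variant keeps only the joint
term.  Models are trained by penalised maximum likelihood — the mild
default ridge of scikit-learn's logistic regression, which leaves the
informative coefficients essentially unshrunken while keeping the fit
finite on separable data — with a seeded stratified held-out split, and
sites are labelled *well-supported* when the predicted probability reaches
0.5.

:class:`SpliceSiteClassifier` follows the scikit-learn estimator protocol
(``fit`` / ``predict_proba`` / ``get_params``) and composes with sklearn
pipelines and model selection; the module-level functions are thin wrappers
plus the transcript-, intron- and exon-level aggregations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import f1_score, roc_auc_score, roc_curve
from sklearn.model_selection import train_test_split
from sklearn.utils.validation import check_is_fitted, check_X_y, check_array

from splicecons.annotation import Intron, SpliceSite, Transcript
from splicecons.conserve import FEATURE_SHIFTS

N_FULL_FEATURES = 1 + len(FEATURE_SHIFTS)  # joint + 60 positional counts


class SpliceSiteClassifier(ClassifierMixin, BaseEstimator):
    """Logistic splice-site conservation classifier.

    Parameters
    ----------
    kind:
        ``"full"`` uses all 61 conservation features; ``"dinuc"`` uses only
        the joint canonical-dinucleotide count (column 0 of X).
    C:
        Inverse ridge strength.  The default matches scikit-learn's standard
        logistic regression; on separable conservation counts a ridge this
        mild leaves the informative direction essentially untouched while
        preventing the coefficient blow-up an unregularised fit exhibits.
    """

    def __init__(self, kind: str = "full", C: float = 1.0, max_iter: int = 5000):
        self.kind = kind
        self.C = C
        self.max_iter = max_iter

    def _slice(self, X: np.ndarray) -> np.ndarray:
        return X[:, :1] if self.kind == "dinuc" else X

    def fit(self, X, y):
        if self.kind not in ("full", "dinuc"):
            raise ValueError(f"kind must be 'full' or 'dinuc', got {self.kind!r}")
        X, y = check_X_y(X, y)
        self._lr = LogisticRegression(
            C=self.C, max_iter=self.max_iter, solver="lbfgs"
        )
        self._lr.fit(self._slice(X), y)
        self.classes_ = self._lr.classes_
        if len(self.classes_) == 2:
            self.intercept_ = float(self._lr.intercept_[0])
            self.coef_ = self._lr.coef_[0].copy()
        else:  # the generic estimator protocol also admits multiclass targets
            self.intercept_ = self._lr.intercept_.copy()
            self.coef_ = self._lr.coef_.copy()
        self.n_features_in_ = X.shape[1]
        self.n_iter_ = self._lr.n_iter_
        return self

    def decision_function(self, X):
        check_is_fitted(self, "coef_")
        X = check_array(X)
        return self._lr.decision_function(self._slice(X))

    def predict_proba(self, X):
        check_is_fitted(self, "coef_")
        X = check_array(X)
        return self._lr.predict_proba(self._slice(X))

    def predict(self, X):
        check_is_fitted(self, "coef_")
        X = check_array(X)
        return self._lr.predict(self._slice(X))

    def coefficient_table(self) -> pd.DataFrame:
        """Named coefficients: intercept, joint term, per-shift terms."""
        check_is_fitted(self, "coef_")
        names = ["intercept", "joint_dinuc"]
        values = [self.intercept_, self.coef_[0]]
        if self.kind == "full":
            names += [f"shift_{l}" for l in FEATURE_SHIFTS]
            values += list(self.coef_[1:])
        return pd.DataFrame({"coefficient": names, "value": values})


@dataclass
class TrainingEvaluation:
    """Held-out evaluation of a trained site classifier."""

    auroc: float
    f_score: float
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    threshold: float
    n_pos: int
    n_neg: int
    seed: int
    test_fraction: float


def train_classifier(
    pos_X: np.ndarray,
    neg_X: np.ndarray,
    kind: str = "full",
    seed: int = 0,
    test_fraction: float = 0.2,
    threshold: float = 0.5,
) -> tuple[SpliceSiteClassifier, TrainingEvaluation]:
    """Fit a site classifier on positive/negative feature vectors.

    The split is stratified by class and seeded; evaluation (ROC, AUROC and
    F-score at the labelling threshold) is on the held-out fraction.
    """
    pos_X = np.asarray(pos_X, dtype=float)
    neg_X = np.asarray(neg_X, dtype=float)
    if len(pos_X) == 0 or len(neg_X) == 0:
        raise ValueError("both classes must be non-empty")
    X = np.vstack([pos_X, neg_X])
    y = np.concatenate([np.ones(len(pos_X), dtype=int), np.zeros(len(neg_X), dtype=int)])
    X_train, X_test, y_train, y_test = train_test_split(
        X, y, test_size=test_fraction, random_state=seed, stratify=y
    )
    model = SpliceSiteClassifier(kind=kind).fit(X_train, y_train)
    prob = model.predict_proba(X_test)[:, 1]
    fpr, tpr, thr = roc_curve(y_test, prob)
    evaluation = TrainingEvaluation(
        auroc=float(roc_auc_score(y_test, prob)),
        f_score=float(f1_score(y_test, (prob >= threshold).astype(int))),
        fpr=fpr,
        tpr=tpr,
        thresholds=thr,
        threshold=threshold,
        n_pos=int(len(pos_X)),
        n_neg=int(len(neg_X)),
        seed=seed,
        test_fraction=test_fraction,
    )
    return model, evaluation


def predict_probability(model: SpliceSiteClassifier, X: np.ndarray) -> np.ndarray:
    """Probability of the well-supported class for each feature vector."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    return model.predict_proba(X)[:, 1]


@dataclass(frozen=True)
class SiteLabel:
    site_key: tuple
    probability: float
    label: str  # well | less
    threshold: float = 0.5


def label_sites(
    model: SpliceSiteClassifier,
    X: np.ndarray,
    keys: list[tuple],
    threshold: float = 0.5,
) -> dict[tuple, SiteLabel]:
    """Well/less call per site; probability at or above the threshold is well."""
    probs = predict_probability(model, X)
    return {
        key: SiteLabel(
            site_key=key,
            probability=float(p),
            label="well" if p >= threshold else "less",
            threshold=threshold,
        )
        for key, p in zip(keys, probs)
    }


def _site_keys_of_transcript(tx: Transcript) -> list[tuple]:
    keys = []
    for start, end in tx.introns:
        if tx.strand == "+":
            d_origin, a_origin = start, end - 2
        else:
            d_origin, a_origin = end - 1, start + 1
        keys.append((tx.contig, tx.strand, "donor", d_origin))
        keys.append((tx.contig, tx.strand, "acceptor", a_origin))
    return keys


def well_supported_transcripts(
    transcripts: list[Transcript],
    labels: dict[tuple, SiteLabel],
    mane_site_keys: set[tuple],
) -> tuple[list[Transcript], pd.DataFrame]:
    """Transcripts whose every site is MANE-shared or labelled well-supported.

    Only transcripts with at least one intron are considered.  Also returns
    counts of considered/accepted transcripts stratified by intron count.
    Raises ``KeyError`` for a non-MANE site without a label.
    """
    accepted = []
    strata: dict[int, dict[str, int]] = {}
    for tx in transcripts:
        if tx.n_introns < 1:
            continue
        stat = strata.setdefault(tx.n_introns, {"total": 0, "well_supported": 0})
        stat["total"] += 1
        ok = True
        for key in _site_keys_of_transcript(tx):
            if key in mane_site_keys:
                continue
            if key not in labels:
                raise KeyError(f"site {key} of transcript {tx.transcript_id} is unlabelled")
            if labels[key].label != "well":
                ok = False
                break
        if ok:
            accepted.append(tx)
            stat["well_supported"] += 1
    counts = pd.DataFrame(
        [{"n_introns": k, **v} for k, v in sorted(strata.items())]
    )
    return accepted, counts


def intron_categories(
    introns: list[Intron],
    labels: dict[tuple, SiteLabel],
    mane_site_keys: set[tuple] = frozenset(),
) -> dict[tuple, int]:
    """4-way intron category from the labels of its two sites.

    1: neither site well-supported; 2: only the donor; 3: only the acceptor;
    4: both.  MANE-shared sites count as well-supported.
    """

    def is_well(key: tuple) -> bool:
        if key in mane_site_keys:
            return True
        return labels[key].label == "well"

    out = {}
    for intron in introns:
        d, a = is_well(intron.donor_key), is_well(intron.acceptor_key)
        out[intron.key()] = 1 + (1 if d else 0) + (2 if a else 0)
    return out


def stratify_by_mane_exon(
    sites: list[SpliceSite],
    mane_exons: list[tuple[str, int, int]],
    labels: dict[tuple, SiteLabel],
) -> pd.DataFrame:
    """2x2 counts of sites by (inside/outside a MANE exon) x (well/less).

    A site is *inside* iff its origin lies within any MANE exon interval.
    """
    trees: dict[str, IntervalTree] = {}
    for contig, start, end in mane_exons:
        trees.setdefault(contig, IntervalTree()).addi(start, end)
    counts = {
        ("inside", "well"): 0,
        ("inside", "less"): 0,
        ("outside", "well"): 0,
        ("outside", "less"): 0,
    }
    for site in sites:
        tree = trees.get(site.contig)
        inside = "inside" if tree is not None and tree.overlaps_point(site.origin) else "outside"
        counts[(inside, labels[site.key()].label)] += 1
    return pd.DataFrame(
        {
            "well": [counts[("inside", "well")], counts[("outside", "well")]],
            "less": [counts[("inside", "less")], counts[("outside", "less")]],
        },
        index=["inside", "outside"],
    )


def isoform_sharing(
    sites: list[SpliceSite], labels: dict[tuple, SiteLabel] | None = None
) -> pd.DataFrame:
    """Per-site transcript-use count, with the site's label when available."""
    rows = []
    for site in sites:
        label = labels[site.key()].label if labels and site.key() in labels else None
        rows.append(
            {
                "site_key": site.key(),
                "kind": site.kind,
                "n_isoforms": len(site.transcripts),
                "label": label,
            }
        )
    return pd.DataFrame(rows)


def score_probability_correlation(
    probabilities: dict[tuple, float], dinuc_scores: dict[tuple, tuple[float, float]]
) -> float | None:
    """Pearson r between model probability and min per-base conservation score.

    For each site the minimum of the two scores at its canonical
    dinucleotide positions is used; sites without scores are excluded.
    Returns None when fewer than two paired values exist.
    """
    xs, ys = [], []
    for key, prob in probabilities.items():
        if key in dinuc_scores:
            s0, s1 = dinuc_scores[key]
            xs.append(min(s0, s1))
            ys.append(prob)
    if len(xs) < 2:
        return None
    r, _ = stats.pearsonr(xs, ys)
    return float(r)


def save_model(model: SpliceSiteClassifier, path, metadata: dict | None = None) -> None:
    """Persist a fitted model as a plain-text coefficient table."""
    table = model.coefficient_table()
    with open(path, "w") as fh:
        fh.write(f"#kind={model.kind}\n")
        for k, v in (metadata or {}).items():
            fh.write(f"#{k}={v}\n")
        table.to_csv(fh, sep="\t", index=False)


def load_model(path) -> SpliceSiteClassifier:
    """Rebuild a fitted model from a coefficient table written by save_model."""
    meta = {}
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            k, _, v = line[1:].strip().partition("=")
            meta[k] = v
            body_start = i + 1
        else:
            break
    from io import StringIO

    table = pd.read_csv(StringIO("".join(lines[body_start:])), sep="\t")
    kind = meta.get("kind", "full")
    model = SpliceSiteClassifier(kind=kind)
    values = dict(zip(table["coefficient"], table["value"]))
    intercept = values.pop("intercept")
    if kind == "full":
        coef = [values["joint_dinuc"]] + [values[f"shift_{l}"] for l in FEATURE_SHIFTS]
    else:
        coef = [values["joint_dinuc"]]
    lr = LogisticRegression()
    lr.classes_ = np.array([0, 1])
    lr.intercept_ = np.array([intercept])
    lr.coef_ = np.array([coef])
    lr.n_features_in_ = len(coef)
    model._lr = lr
    model.classes_ = lr.classes_
    model.intercept_ = float(intercept)
    model.coef_ = lr.coef_[0].copy()
    model.n_features_in_ = N_FULL_FEATURES if kind == "full" else 1
    return model
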