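"""Cross-species E/I state decoder.

Sliding-window LFP features (aperiodic slope proxy, sample entropy, relative
delta and gamma power) are labeled from spike-derived network states, used to
train classical classifiers (regularized LDA, tuned kNN, SVM, tuned random
forest), and the trained model then decodes excitatory/inhibitory periods
from LFP alone.  Derived quantities: I-state incidence, state-conditioned
wPLI, permutation feature importance, and the spectral-vs-E/I feature
ablation on cohort segments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import GridSearchCV, StratifiedKFold, cross_val_score
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from . import lfp_features as lf
from .synthetic_data import E, I, CohortSegment, StateIntervals, interval_jaccard

__all__ = [
    "FEATURES",
    "DecoderModel",
    "EvalReport",
    "label_windows",
    "train_decoder",
    "evaluate",
    "feature_importance",
    "decode_lfp",
    "istate_incidence",
    "state_conditioned_wpli",
    "ablation_classify",
]

FEATURES = ("slope", "sampen", "rel_delta", "rel_gamma")

_GRIDS = {
    "RF": {"min_samples_leaf": [1, 5, 10]},
    "kNN": {"n_neighbors": [5, 15, 31]},
    "SVM": {"svc__C": [0.1, 1.0, 10.0]},
    "LDA": {},
}


@dataclass
class DecoderModel:
    algorithm: str
    estimator: object
    feature_names: tuple[str, ...]
    hyperparams: dict
    seed: int
    split: str  # description of the train/test split
    test_table: pd.DataFrame | None = field(default=None, repr=False)
    classes_: tuple[str, ...] = ()

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        self._check_schema(table)
        return self.estimator.predict(table[list(self.feature_names)].to_numpy())

    def predict_proba(self, table: pd.DataFrame, positive_class: str = E) -> np.ndarray:
        self._check_schema(table)
        proba = self.estimator.predict_proba(table[list(self.feature_names)].to_numpy())
        idx = list(self.estimator.classes_).index(positive_class)
        return proba[:, idx]

    def _check_schema(self, table: pd.DataFrame) -> None:
        missing = [f for f in self.feature_names if f not in table.columns]
        if missing:
            raise ValueError(f"feature schema mismatch; missing {missing}")


# ---------------------------------------------------------------------------
# window labeling
# ---------------------------------------------------------------------------

def label_windows(
    feature_windows: pd.DataFrame,
    spike_states: StateIntervals,
    purity: float = 0.8,
    win_s: float = 0.05,
) -> pd.DataFrame:
    """Label each sliding window by the majority spike-derived state when that
    state covers at least ``purity`` of the window; otherwise leave unlabeled
    (excluded from training)."""
    t = feature_windows["t_center_s"].to_numpy()
    lo, hi = t - win_s / 2.0, t + win_s / 2.0
    cov = {}
    for lab in (E, I):
        c = np.zeros(t.size)
        for s, e in spike_states.of_label(lab):
            c += np.clip(np.minimum(hi, e) - np.maximum(lo, s), 0.0, None)
        cov[lab] = c / win_s
    labels = np.full(t.size, "unlabeled", dtype=object)
    labels[cov[E] >= purity] = E
    labels[cov[I] >= purity] = I
    out = feature_windows.copy()
    out["label"] = labels
    if not (labels != "unlabeled").any():
        raise ValueError("zero labeled windows")
    return out


# ---------------------------------------------------------------------------
# training and evaluation
# ---------------------------------------------------------------------------

def _make_estimator(algorithm: str, hyperparams: dict, seed: int):
    if algorithm == "RF":
        hp = {"min_samples_leaf": 1, "n_estimators": 500} | hyperparams
        return RandomForestClassifier(random_state=seed, n_jobs=1, **hp)
    if algorithm == "kNN":
        hp = {"n_neighbors": 15} | hyperparams
        return make_pipeline(StandardScaler(), KNeighborsClassifier(**hp))
    if algorithm == "SVM":
        hp = {"C": 1.0, "kernel": "rbf"} | hyperparams
        return make_pipeline(
            StandardScaler(), SVC(probability=True, random_state=seed, **hp)
        )
    if algorithm == "LDA":
        return LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
    raise ValueError(f"unknown algorithm {algorithm!r}")


def train_decoder(
    labeled: pd.DataFrame,
    algorithm: str = "RF",
    hyperparams: dict | None = None,
    cv_folds: int = 5,
    seed: int = 0,
    tune: bool = False,
    test_fraction: float = 0.3,
) -> DecoderModel:
    """Train an E/I window classifier on a labeled feature table.

    The table is split 70/30; when a ``recording_id`` column is present whole
    recordings go to one side (no window leakage), otherwise the split is
    stratified by label.  With ``tune=True`` hyperparameters are selected by a
    grid search inside stratified CV on the training split.
    """
    data = labeled[labeled["label"].isin([E, I])].reset_index(drop=True)
    if data["label"].nunique() < 2:
        raise ValueError("training set contains a single class")
    rng = np.random.default_rng(seed)

    if "recording_id" in data.columns and data["recording_id"].nunique() > 1:
        recs = np.array(sorted(data["recording_id"].unique()))
        rng.shuffle(recs)
        n_test = max(1, int(round(test_fraction * recs.size)))
        test_recs = set(recs[:n_test])
        test_mask = data["recording_id"].isin(test_recs).to_numpy()
        split = f"by recording ({len(test_recs)}/{recs.size} held out)"
    else:
        test_mask = np.zeros(len(data), dtype=bool)
        for lab in (E, I):
            idx = np.where((data["label"] == lab).to_numpy())[0]
            rng.shuffle(idx)
            test_mask[idx[: int(round(test_fraction * idx.size))]] = True
        split = "stratified 70/30 by window"

    train_df = data[~test_mask]
    test_df = data[test_mask]
    X = train_df[list(FEATURES)].to_numpy()
    y = train_df["label"].to_numpy()

    hp = dict(hyperparams or {})
    est = _make_estimator(algorithm, hp, seed)
    if tune and _GRIDS[algorithm]:
        cv = StratifiedKFold(cv_folds, shuffle=True, random_state=seed)
        gs = GridSearchCV(est, _GRIDS[algorithm], cv=cv, scoring="roc_auc", n_jobs=1)
        gs.fit(X, y)
        est = gs.best_estimator_
        hp |= gs.best_params_
    else:
        est.fit(X, y)
    return DecoderModel(
        algorithm=algorithm,
        estimator=est,
        feature_names=FEATURES,
        hyperparams=hp,
        seed=seed,
        split=split,
        test_table=test_df.reset_index(drop=True),
        classes_=tuple(est.classes_),
    )


@dataclass(frozen=True)
class EvalReport:
    accuracy: float
    auc: float
    precision: float
    recall: float
    f1: float
    specificity: float
    confusion: dict[str, int]  # tp, fp, fn, tn for the positive class
    roc: tuple[np.ndarray, np.ndarray]  # fpr, tpr


def f1_from_precision_recall(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def evaluate(
    model: DecoderModel,
    test_table: pd.DataFrame | None = None,
    positive_class: str = E,
) -> EvalReport:
    """Confusion-matrix metrics at the 0.5 threshold plus ROC AUC.  The
    positive class defaults to E (the "UP state")."""
    table = test_table if test_table is not None else model.test_table
    table = table[table["label"].isin([E, I])]
    y_true = table["label"].to_numpy()
    if np.unique(y_true).size < 2:
        raise ValueError("test set lacks a class; metrics undefined")
    y_pred = model.predict(table)
    score = model.predict_proba(table, positive_class)
    pos = y_true == positive_class
    tp = int(np.sum(pos & (y_pred == positive_class)))
    fp = int(np.sum(~pos & (y_pred == positive_class)))
    fn = int(np.sum(pos & (y_pred != positive_class)))
    tn = int(np.sum(~pos & (y_pred != positive_class)))
    precision = tp / (tp + fp) if tp + fp else float("nan")
    recall = tp / (tp + fn) if tp + fn else float("nan")
    specificity = tn / (tn + fp) if tn + fp else float("nan")
    fpr, tpr, _ = roc_curve(pos.astype(int), score)
    return EvalReport(
        accuracy=(tp + tn) / len(table),
        auc=float(roc_auc_score(pos.astype(int), score)),
        precision=precision,
        recall=recall,
        f1=f1_from_precision_recall(precision, recall),
        specificity=specificity,
        confusion={"tp": tp, "fp": fp, "fn": fn, "tn": tn},
        roc=(fpr, tpr),
    )


def feature_importance(
    model: DecoderModel,
    test_table: pd.DataFrame | None = None,
    n_perm: int = 50,
    seed: int = 0,
    positive_class: str = E,
) -> pd.DataFrame:
    """Permutation importance: mean test-AUC drop when one feature column is
    shuffled; impurity importances are reported alongside when the estimator
    provides them."""
    table = (test_table if test_table is not None else model.test_table).copy()
    table = table[table["label"].isin([E, I])].reset_index(drop=True)
    y = (table["label"] == positive_class).to_numpy().astype(int)
    base = roc_auc_score(y, model.predict_proba(table, positive_class))
    rng = np.random.default_rng(seed)
    rows = []
    impurity = getattr(model.estimator, "feature_importances_", None)
    for j, feat in enumerate(model.feature_names):
        drops = np.empty(n_perm)
        for k in range(n_perm):
            perm = table.copy()
            perm[feat] = rng.permutation(perm[feat].to_numpy())
            drops[k] = base - roc_auc_score(y, model.predict_proba(perm, positive_class))
        rows.append(
            {
                "feature": feat,
                "auc_drop": float(drops.mean()),
                "auc_drop_sd": float(drops.std()),
                "impurity_importance": float(impurity[j]) if impurity is not None else np.nan,
            }
        )
    return pd.DataFrame(rows).sort_values("auc_drop", ascending=False, ignore_index=True)


# ---------------------------------------------------------------------------
# decoding LFP-only recordings
# ---------------------------------------------------------------------------

def decode_lfp(
    model: DecoderModel,
    lfp_pair: dict[str, np.ndarray] | np.ndarray,
    fs: float,
    win_s: float = 0.05,
    step_s: float = 0.025,
    min_dur_s: float = 0.05,
    smooth_windows: int = 1,
) -> tuple[StateIntervals, pd.DataFrame]:
    """Decode E/I intervals from LFP alone.

    Windows are classified with probabilities, the label sequence is smoothed
    with a short majority filter, contiguous same-class windows are merged and
    intervals shorter than ``min_dur_s`` are dropped (left unlabeled).
    """
    feats = lf.sliding_features(lfp_pair, fs, win_s=win_s, step_s=step_s)
    prob_e = model.predict_proba(feats, E)
    if smooth_windows > 1:
        kernel = np.ones(smooth_windows) / smooth_windows
        prob_e = np.convolve(prob_e, kernel, mode="same")
    labels = np.where(prob_e >= 0.5, E, I)
    feats = feats.copy()
    feats["prob_E"] = prob_e
    feats["label"] = labels

    t = feats["t_center_s"].to_numpy()
    duration = float(t[-1] + step_s / 2.0)
    intervals: list[tuple[float, float, str]] = []
    start = max(t[0] - step_s / 2.0, 0.0)
    cur = labels[0]
    for k in range(1, t.size):
        if labels[k] != cur:
            end = 0.5 * (t[k - 1] + t[k])
            intervals.append((start, end, cur))
            start, cur = end, labels[k]
    intervals.append((start, duration, cur))
    kept = [iv for iv in intervals if iv[1] - iv[0] >= min_dur_s]
    # dropping short intervals can leave same-label neighbours adjacent: merge
    merged: list[tuple[float, float, str]] = []
    for iv in kept:
        if merged and merged[-1][2] == iv[2] and abs(merged[-1][1] - iv[0]) < 1e-9:
            merged[-1] = (merged[-1][0], iv[1], iv[2])
        else:
            merged.append(iv)
    return StateIntervals(tuple(merged), duration), feats


def istate_incidence(decoded: StateIntervals | pd.DataFrame | tuple[int, int]) -> float:
    """I-state incidence in percent: I-window count / (I + E window count),
    computed with exact rational arithmetic on the counts.

    Accepts a decoded window table, decoded intervals (interval counts), or a
    raw ``(n_i, n_total)`` pair.
    """
    if isinstance(decoded, tuple):
        n_i, n_total = decoded
    elif isinstance(decoded, pd.DataFrame):
        lab = decoded["label"]
        n_i = int((lab == I).sum())
        n_total = int(lab.isin([E, I]).sum())
    else:
        n_i = sum(1 for *_, lab in decoded.intervals if lab == I)
        n_total = len(decoded.intervals)
    if n_total == 0:
        return float("nan")
    return float(Fraction(n_i, n_total) * 100)


def state_conditioned_wpli(
    decoded: StateIntervals,
    lfp_pair: dict[str, np.ndarray],
    fs: float,
    band: tuple[float, float],
    min_intervals: int = 10,
    win_s: float = 0.125,
) -> dict[str, float]:
    """wPLI computed within the concatenated samples of each decoded class.
    Classes with fewer than ``min_intervals`` intervals are omitted."""
    x = lfp_pair["BNST"]
    y = lfp_pair["NAc"]
    t = np.arange(x.size) / fs
    out: dict[str, float] = {}
    for lab in (E, I):
        ivs = decoded.of_label(lab)
        if len(ivs) < min_intervals:
            continue
        mask = decoded.label_mask(t, lab)
        out[lab] = lf.wpli(x[mask], y[mask], fs, band, win_s=win_s)
    return out


# ---------------------------------------------------------------------------
# spectral vs E/I feature ablation
# ---------------------------------------------------------------------------

def _segment_features(
    seg: CohortSegment,
    model: DecoderModel,
    band_theta: tuple[float, float] = lf.THETA_BAND,
    band_gamma: tuple[float, float] = lf.GAMMA_BAND,
) -> dict[str, float]:
    fb, fn = seg.lfp["BNST"], seg.lfp["NAc"]
    freqs_b, psd_b = lf.welch_psd(fb, seg.fs)
    freqs_n, psd_n = lf.welch_psd(fn, seg.fs)
    fit_b = lf.parameterize_spectrum(freqs_b, psd_b)
    fit_n = lf.parameterize_spectrum(freqs_n, psd_n)
    decoded, table = decode_lfp(model, seg.lfp, seg.fs)
    wp = state_conditioned_wpli(decoded, seg.lfp, seg.fs, band=lf.GAMMA_BAND)
    return {
        # spectral family
        "exponent_bnst": fit_b.exponent,
        "exponent_nac": fit_n.exponent,
        "rel_theta_bnst": lf.band_power(freqs_b, psd_b, band_theta, relative=True),
        "rel_gamma_nac": lf.band_power(freqs_n, psd_n, band_gamma, relative=True),
        "rel_delta_bnst": lf.band_power(freqs_b, psd_b, lf.DELTA_BAND, relative=True),
        # E/I family
        "i_incidence": istate_incidence(table),
        "wpli_i": wp.get(I, 0.0),
        "wpli_e": wp.get(E, 0.0),
    }


_SPECTRAL = ("exponent_bnst", "exponent_nac", "rel_theta_bnst", "rel_gamma_nac", "rel_delta_bnst")
_EI = ("i_incidence", "wpli_i", "wpli_e")


def ablation_classify(
    segments: Sequence[CohortSegment],
    model: DecoderModel,
    feature_sets: Sequence[str] = ("spectral_only", "ei_only", "combined"),
    classifier: str = "logistic",
    cv: int = 5,
    seed: int = 0,
    labels: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Cross-validated class accuracy per feature family on cohort segments
    (identical folds and seed across families).  ``labels`` defaults to each
    segment's response class."""
    feats = pd.DataFrame([_segment_features(s, model) for s in segments])
    y = np.asarray(labels if labels is not None else [s.response_class for s in segments])
    folds = StratifiedKFold(cv, shuffle=True, random_state=seed)
    split = list(folds.split(feats, y))
    rows = []
    for fset in feature_sets:
        cols = {"spectral_only": _SPECTRAL, "ei_only": _EI, "combined": _SPECTRAL + _EI}[fset]
        X = feats[list(cols)].to_numpy()
        if classifier == "logistic":
            est = make_pipeline(StandardScaler(), LogisticRegression(max_iter=1000))
        elif classifier == "RF":
            est = RandomForestClassifier(n_estimators=200, random_state=seed)
        else:
            raise ValueError(f"unknown classifier {classifier!r}")
        scores = cross_val_score(est, X, y, cv=split, scoring="accuracy")
        rows.append({"feature_set": fset, "accuracy": float(scores.mean()), "sd": float(scores.std())})
    return pd.DataFrame(rows)


def decoded_jaccard(decoded: StateIntervals, truth: StateIntervals, label: str = I) -> float:
    """Jaccard overlap between decoded and ground-truth intervals of a class."""
    return interval_jaccard(decoded.of_label(label), truth.of_label(label))
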