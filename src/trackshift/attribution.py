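"""Attributing tracking center frequencies to acoustic vs linguistic rates.

The headline question: does the center frequency (CF) of the low-frequency
coherence peak sit closer to the syllable rate of the speech or to the
acoustic modulation rate, and does that allegiance shift as intelligibility
drops? Two complementary analyses answer it: absolute differences
|CF - rate| fed into a tracking x vocoding repeated-measures ANOVA, and an
ensemble of k-nearest-neighbor classifiers trained on labeled acoustic rates
that assigns each neural CF a probability of belonging to the modulation or
the syllable class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sst
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import RepeatedStratifiedKFold, train_test_split
from sklearn.neighbors import KNeighborsClassifier

from .stats import rmcorr

__all__ = [
    "DecoderSettings",
    "RateDecoder",
    "abs_diff_table",
    "vocoding_slope",
    "aperiodic_variance_explained",
    "train_rate_decoder",
    "apply_decoder",
]

CLASSES = ("modulation", "syllable")


@dataclass
class DecoderSettings:
    n_members: int = 50
    folds: int = 5
    repetitions: int = 25
    test_fraction: float = 0.1
    max_neighbors: int = 31


@dataclass
class RateDecoder:
    """Ensemble of kNN classifiers over a single feature (frequency, Hz)."""

    members: list = field(default_factory=list)
    neighbor_counts: list = field(default_factory=list)
    confusion: np.ndarray = field(default_factory=lambda: np.zeros((2, 2)))
    test_auc: float = float("nan")
    train_min: float = float("nan")
    train_max: float = float("nan")
    settings: DecoderSettings = field(default_factory=DecoderSettings)
    seed: int = 0


def abs_diff_table(cf_table: pd.DataFrame, rates: "pd.DataFrame | dict") -> pd.DataFrame:
    """Add |CF - modulation rate| and |CF - syllable rate| columns per row.

    ``cf_table`` needs columns (subject, condition, cf); ``rates`` maps each
    condition to its average modulation rate and the (condition-independent
    or per-condition) syllable rate, either as a DataFrame with columns
    (condition, modulation_cf, syllable_rate) or a dict
    ``{condition: (modulation_cf, syllable_rate)}``. Rows with a missing CF
    are retained with NaN differences.
    """
    if isinstance(rates, dict):
        rates = pd.DataFrame(
            [{"condition": k, "modulation_cf": v[0], "syllable_rate": v[1]}
             for k, v in rates.items()]
        )
    missing = set(cf_table["condition"]) - set(rates["condition"])
    if missing:
        raise ValueError(f"rates missing for conditions: {sorted(missing)}")
    out = cf_table.merge(rates[["condition", "modulation_cf", "syllable_rate"]],
                         on="condition", how="left")
    out["abs_diff_mod"] = (out["cf"] - out["modulation_cf"]).abs()
    out["abs_diff_syll"] = (out["cf"] - out["syllable_rate"]).abs()
    return out


def vocoding_slope(
    table: pd.DataFrame,
    condition_order: list[str],
    value: str = "band_coh",
) -> pd.Series:
    """Per-subject least-squares slope of ``value`` against condition index.

    Conditions are coded 0, 1, 2, ... in ``condition_order`` (decreasing
    intelligibility); a subject missing any condition gets a NaN slope.
    """
    pos = {c: i for i, c in enumerate(condition_order)}
    slopes = {}
    for subj, grp in table.groupby("subject"):
        if set(condition_order) - set(grp["condition"]):
            slopes[subj] = float("nan")
            continue
        xs = grp["condition"].map(pos).to_numpy(dtype=float)
        ys = grp[value].to_numpy(dtype=float)
        if np.any(~np.isfinite(ys)):
            slopes[subj] = float("nan")
            continue
        slopes[subj] = float(np.polyfit(xs, ys, 1)[0])
    return pd.Series(slopes, name=f"slope_{value}")


def aperiodic_variance_explained(
    table: pd.DataFrame,
    params: tuple[str, ...] = ("offset", "exponent", "cf", "height", "bandwidth"),
    target: str = "band_coh",
) -> pd.DataFrame:
    """Squared repeated-measures correlation of each parameter with ``target``.

    Returns a DataFrame (parameter, r, r2, df, p); degenerate (zero-variance
    or insufficient) parameters get NaN.
    """
    rows = []
    for par in params:
        if par not in table.columns:
            continue
        try:
            r, df, p = rmcorr(table[par], table[target], table["subject"])
        except ValueError:
            r, df, p = float("nan"), 0, float("nan")
        rows.append({"parameter": par, "r": r, "r2": r**2 if np.isfinite(r) else float("nan"),
                     "df": df, "p": p})
    return pd.DataFrame(rows)


def _auc_for_all_k(
    x_train: np.ndarray, y_train: np.ndarray, x_val: np.ndarray, y_val: np.ndarray,
    k_grid: np.ndarray,
) -> np.ndarray:
    """ROC-AUC of a kNN vote for every neighbor count in one pass.

    Neighbors are ranked once per validation point; cumulative vote counts
    then give P(class 1) for every k simultaneously.
    """
    if np.unique(y_val).size < 2:
        return np.full(k_grid.size, np.nan)
    order = np.argsort(np.abs(x_val[:, None] - x_train[None, :]), axis=1, kind="stable")
    votes = np.cumsum(y_train[order], axis=1)  # (n_val, n_train)
    proba = votes[:, k_grid - 1] / k_grid  # (n_val, n_k)
    # AUC for every k at once from the Mann-Whitney rank-sum identity
    ranks = sst.rankdata(proba, axis=0)
    n1 = int(y_val.sum())
    n0 = y_val.size - n1
    r1 = ranks[y_val == 1].sum(axis=0)
    return (r1 - n1 * (n1 + 1) / 2.0) / (n0 * n1)


def train_rate_decoder(
    values,
    labels,
    settings: "DecoderSettings | None" = None,
    seed: int = 0,
) -> RateDecoder:
    """Train an ensemble of kNN classifiers to separate the two rate classes.

    Each of the ``n_members`` classifiers holds out a stratified
    ``test_fraction`` of the data, picks its neighbor count by maximizing
    mean ROC-AUC over a repeated stratified k-fold on the remainder (odd k
    from 1 to min(max_neighbors, n_train/2); ties to the smallest k), refits
    on the remainder, and is evaluated on its held-out split. The reported
    confusion matrix and held-out AUC are averages across members.
    """
    settings = settings or DecoderSettings()
    x = np.asarray(values, dtype=float).ravel()
    y_lab = np.asarray(labels)
    if set(np.unique(y_lab)) != set(CLASSES):
        raise ValueError(f"labels must be exactly {CLASSES}")
    y = (y_lab == CLASSES[1]).astype(int)  # 1 = syllable
    counts = np.bincount(y, minlength=2)
    if counts.min() < 20:
        raise ValueError("need at least 20 labeled values per class")
    if counts.max() / counts.min() > 4:
        raise ValueError("class imbalance exceeds 4:1")

    rng = np.random.default_rng(seed)
    members, ks, confusions, aucs = [], [], [], []
    for m in range(settings.n_members):
        state = int(rng.integers(0, 2**31 - 1))
        x_tr, x_te, y_tr, y_te = train_test_split(
            x, y, test_size=settings.test_fraction, stratify=y, random_state=state
        )
        k_max = min(settings.max_neighbors, len(x_tr) // 2)
        k_grid = np.arange(1, k_max + 1, 2)
        cv = RepeatedStratifiedKFold(
            n_splits=settings.folds, n_repeats=settings.repetitions, random_state=state
        )
        scores = np.zeros((0, k_grid.size))
        for tr_idx, va_idx in cv.split(x_tr.reshape(-1, 1), y_tr):
            s = _auc_for_all_k(x_tr[tr_idx], y_tr[tr_idx], x_tr[va_idx], y_tr[va_idx], k_grid)
            scores = np.vstack([scores, s])
        mean_auc = np.nanmean(scores, axis=0)
        best_k = int(k_grid[int(np.argmax(mean_auc))])  # argmax -> smallest k on ties
        clf = KNeighborsClassifier(n_neighbors=best_k)
        clf.fit(x_tr.reshape(-1, 1), y_tr)
        proba = clf.predict_proba(x_te.reshape(-1, 1))[:, 1]
        pred = (proba >= 0.5).astype(int)
        confusions.append(_sk_confusion(y_te, pred, labels=[0, 1]))
        if np.unique(y_te).size == 2:
            aucs.append(roc_auc_score(y_te, proba))
        members.append(clf)
        ks.append(best_k)
    return RateDecoder(
        members=members,
        neighbor_counts=ks,
        confusion=np.mean(confusions, axis=0),
        test_auc=float(np.mean(aucs)) if aucs else float("nan"),
        train_min=float(x.min()),
        train_max=float(x.max()),
        settings=settings,
        seed=seed,
    )


def apply_decoder(decoder: RateDecoder, neural_cfs) -> pd.DataFrame:
    """Ensemble-averaged class probabilities for each neural center frequency.

    Returns a DataFrame (cf, p_modulation, p_syllable, extrapolated); rows
    sum to 1, and values outside the training support are flagged rather than
    rejected.
    """
    if not decoder.members:
        raise ValueError("decoder has no trained members")
    cfs = np.asarray(neural_cfs, dtype=float).ravel()
    probas = np.mean(
        [m.predict_proba(cfs.reshape(-1, 1))[:, 1] for m in decoder.members], axis=0
    )
    return pd.DataFrame(
        {
            "cf": cfs,
            "p_modulation": 1.0 - probas,
            "p_syllable": probas,
            "extrapolated": (cfs < decoder.train_min) | (cfs > decoder.train_max),
        }
    )
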