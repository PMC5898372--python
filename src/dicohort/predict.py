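"""Additive coupling-score classifier for treatment response, with LOOCV.

A patient's responder score is the sum, over every profile factor i, of the
inferred coupling between the factor's observed state and the Res state of
the response variable; the non-responder score sums the couplings to NonRes:

    Score_Res    = sum_i e_{i,resp}(x_i, Res)
    Score_NonRes = sum_i e_{i,resp}(x_i, NonRes)

The predicted class is the one with the larger score after adding the
response variable's own field h_resp (the model's log-prior over classes);
without that term the comparison would ignore class prevalence entirely and
a no-signal model could not fall back to the majority class.  Exact ties
predict NonRes, the majority class, and are counted.

Leave-one-out cross-validation refits the full mean-field model on the
remaining N-1 profiles for every fold (one block-matrix inversion each; the
pair-count sufficient statistics are downdated by the held-out row, which is
arithmetically identical to recounting from scratch), so the held-out label
never leaks into its fold's frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import DiscreteCohort, NON_RESPONDER, RESPONDER, PatientProfile
from .dca import (
    DEFAULT_PSEUDOCOUNT,
    CouplingModel,
    _frequencies_from_gram,
    _one_hot,
    _reduced_index,
    correlation_matrix,
    fit_couplings,
)

__all__ = ["ResponseScore", "CVReport", "response_scores", "predict_batch", "loocv"]


@dataclass
class ResponseScore:
    """Per-patient additive coupling scores and the resulting call."""

    patient_id: str
    score_res: float
    score_nonres: float
    prior_res: float
    prior_nonres: float
    predicted: str
    tie: bool

    @property
    def margin(self) -> float:
        """Prior-adjusted decision margin (positive favors Res)."""
        return (self.score_res + self.prior_res) - (
            self.score_nonres + self.prior_nonres
        )


def _response_indices(model: CouplingModel, response: str) -> tuple[int, int, int]:
    r = model.index(response)
    # response alphabet is (Res, NonRes) by schema contract
    return r, 0, 1


def response_scores(
    profile: PatientProfile,
    model: CouplingModel,
    cohort_schema,
    response: str,
) -> ResponseScore:
    """Score one patient profile against a fitted coupling model."""
    r, i_res, i_non = _response_indices(model, response)
    score_res = 0.0
    score_non = 0.0
    for i, var in enumerate(cohort_schema):
        if i == r:
            continue
        x = var.index_of(profile.states[i])
        e = model.coupling(i, r)
        score_res += e[x, i_res]
        score_non += e[x, i_non]
    h = model.fields[r]
    return _make_score(
        profile.patient_id, score_res, score_non, float(h[i_res]), float(h[i_non])
    )


def _make_score(pid, score_res, score_non, prior_res, prior_non) -> ResponseScore:
    total_res = score_res + prior_res
    total_non = score_non + prior_non
    if total_res > total_non:
        predicted = RESPONDER
    else:
        predicted = NON_RESPONDER  # ties default to the majority class
    return ResponseScore(
        patient_id=str(pid),
        score_res=float(score_res),
        score_nonres=float(score_non),
        prior_res=prior_res,
        prior_nonres=prior_non,
        predicted=predicted,
        tie=score_res == score_non,
    )


def predict_batch(
    cohort: DiscreteCohort, model: CouplingModel, response: str | None = None
) -> pd.DataFrame:
    """Score every patient in a cohort; one row per ResponseScore."""
    response = response or cohort.response_variable.name
    if model.names != cohort.variable_names:
        raise ValueError("model and cohort schemas disagree")
    rows = [
        vars(response_scores(p, model, cohort.schema, response))
        for p in cohort.profiles()
    ]
    return pd.DataFrame(rows)


@dataclass
class CVReport:
    """Leave-one-out results: per-fold calls plus summary rates.

    ``accuracy`` is correct/N; ``recall_res`` and ``recall_nonres`` are the
    per-class rates; ``balanced_accuracy`` their mean, and
    ``best_class_rate`` the better of the two.
    """

    folds: pd.DataFrame  # patient_id, truth, predicted, tie
    accuracy: float
    recall_res: float
    recall_nonres: float
    balanced_accuracy: float
    best_class_rate: float
    majority_rate: float
    tie_count: int
    lam: float

    def to_json_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "recall_res": self.recall_res,
            "recall_nonres": self.recall_nonres,
            "balanced_accuracy": self.balanced_accuracy,
            "best_class_rate": self.best_class_rate,
            "majority_rate": self.majority_rate,
            "tie_count": self.tie_count,
            "lam": self.lam,
            "n": int(len(self.folds)),
        }


def loocv(
    cohort: DiscreteCohort,
    lam: float = DEFAULT_PSEUDOCOUNT,
    response: str | None = None,
) -> CVReport:
    """Leave-one-out cross-validation of the coupling-score classifier.

    For each patient the mean-field model is refitted on the other N-1
    profiles and the held-out patient is scored.  Requires ``lam > 0`` so a
    fold that loses a state entirely keeps an invertible model (the
    pseudocount carries the vanished state's mass).
    """
    response = response or cohort.response_variable.name
    if cohort.n_patients < 10:
        raise ValueError("LOOCV needs at least 10 patients")
    if lam <= 0.0:
        raise ValueError("LOOCV requires a positive pseudocount lam")
    truth = cohort.data[response]
    classes = set(truth.unique())
    if classes != {RESPONDER, NON_RESPONDER}:
        raise ValueError(
            f"response must contain both classes, found {sorted(classes)}"
        )
    names = cohort.variable_names
    qs = [v.q for v in cohort.schema]
    ref = [q - 1 for q in qs]
    r = names.index(response)
    codes = cohort.codes()
    X = _one_hot(codes, qs)
    gram = X.T @ X
    n = cohort.n_patients
    red_offsets, keep = _reduced_index(qs, ref)
    r_slice = slice(red_offsets[r], red_offsets[r + 1])
    i_res, i_non = 0, 1

    records = []
    for k in range(n):
        gram_k = gram - np.outer(X[k], X[k])
        freqs = _frequencies_from_gram(gram_k, n - 1, names, qs, lam)
        C = correlation_matrix(freqs, ref_states=ref)
        invC = np.linalg.inv(C)
        # couplings of every factor to the response, embedded on full states
        score = np.zeros(2)
        h_r = np.log(freqs.fi[r] / freqs.fi[r][ref[r]])
        for i in range(len(qs)):
            if i == r:
                continue
            e = np.zeros((qs[i], qs[r]))
            e[np.ix_(keep[i], keep[r])] = -invC[
                red_offsets[i] : red_offsets[i + 1], r_slice
            ]
            x = codes[k, i]
            score[0] += e[x, i_res]
            score[1] += e[x, i_non]
            h_r = h_r - e.T @ freqs.fi[i]
        h_r = h_r - h_r[ref[r]]
        sc = _make_score(
            cohort.data.index[k], score[0], score[1],
            float(h_r[i_res]), float(h_r[i_non]),
        )
        records.append(
            {
                "patient_id": sc.patient_id,
                "truth": truth.iloc[k],
                "predicted": sc.predicted,
                "tie": sc.tie,
                "margin": sc.margin,
            }
        )
    folds = pd.DataFrame(records)
    return _summarize_cv(folds, lam)


def _summarize_cv(folds: pd.DataFrame, lam: float) -> CVReport:
    correct = (folds["truth"] == folds["predicted"]).to_numpy()
    acc = float(correct.mean())
    res_mask = (folds["truth"] == RESPONDER).to_numpy()
    recall_res = float(correct[res_mask].mean()) if res_mask.any() else float("nan")
    recall_non = float(correct[~res_mask].mean()) if (~res_mask).any() else float("nan")
    bal = 0.5 * (recall_res + recall_non)
    majority = float(max(res_mask.mean(), 1.0 - res_mask.mean()))
    return CVReport(
        folds=folds,
        accuracy=acc,
        recall_res=recall_res,
        recall_nonres=recall_non,
        balanced_accuracy=bal,
        best_class_rate=float(max(recall_res, recall_non)),
        majority_rate=majority,
        tie_count=int(folds["tie"].sum()),
        lam=lam,
    )


def fit_and_predict(
    cohort: DiscreteCohort, lam: float = DEFAULT_PSEUDOCOUNT
) -> tuple[CouplingModel, pd.DataFrame]:
    """Fit once on the full cohort and score everyone (no held-out folds)."""
    _, model = fit_couplings(cohort, lam=lam)
    return model, predict_batch(cohort, model)
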