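"""ROC-gated weighted-mean ensembles and their variable importances.

Candidate models enter the ensemble only if their evaluation ROC exceeds
0.9; when no model clears that bar the gate falls back to 0.8 (species
whose best models sit between 0.8 and 0.9 still get an ensemble).  Member
predictions are combined as a weighted mean (EMwm) with weights
proportional to member ROC, normalised to sum 1.

Ensemble variable importance applies the member weights to the full
candidate importance set: per method, importances are averaged across
the calibration runs; each method's average is scaled by its total
member weight (methods with no gated member contribute zero); the
weighted averages are summed per variable and divided by the number of
modelling methods (10 by default); finally the per-variable scores are
expressed as percentages summing to 100.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence
import warnings

import numpy as np
import pandas as pd

from .modeling import EvalScores, FittedModel, evaluate


class NoEnsembleError(RuntimeError):
    """No candidate model cleared even the fallback ROC gate."""


@dataclass
class EnsembleModel:
    members: list[FittedModel]
    weights: np.ndarray  # normalised, aligned with members
    threshold_used: float
    scores: EvalScores | None = None
    emwm_importance: pd.Series | None = None

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return weighted_mean_predict(self.members, self.weights, X)

    @property
    def member_ids(self) -> list[tuple[str, int]]:
        return [(m.spec.method, m.spec.run) for m in self.members]


def select_members(models: Sequence[FittedModel], threshold: float = 0.9,
                   fallback: float = 0.8) -> tuple[list[FittedModel], float]:
    """Gate candidates by ROC: strictly > threshold, else > fallback."""
    if not models:
        raise NoEnsembleError("no fitted models supplied")
    members = [m for m in models if m.roc > threshold]
    used = threshold
    if not members:
        members = [m for m in models if m.roc > fallback]
        used = fallback
    if not members:
        raise NoEnsembleError(
            f"no model exceeded the fallback ROC gate of {fallback}")
    return members, used


def roc_weights(members: Sequence[FittedModel]) -> np.ndarray:
    w = np.array([m.roc for m in members], dtype=float)
    return w / w.sum()


def weighted_mean_predict(members: Sequence[FittedModel], weights: np.ndarray,
                          X: pd.DataFrame) -> np.ndarray:
    """Pointwise Σ wᵢ pᵢ over member predictions; output in [0, 1].

    A member whose backend fails at prediction time is dropped and the
    remaining weights renormalised, with a warning.
    """
    preds, kept_w = [], []
    for m, w in zip(members, weights):
        try:
            preds.append(np.asarray(m.predict(X), dtype=float))
            kept_w.append(w)
        except Exception as exc:
            warnings.warn(f"ensemble member {m.spec.method} run {m.spec.run} "
                          f"failed to predict and was dropped: {exc}")
    if not preds:
        raise NoEnsembleError("every ensemble member failed to predict")
    w = np.asarray(kept_w, dtype=float)
    w = w / w.sum()
    out = np.tensordot(w, np.stack(preds), axes=1)
    return np.clip(out, 0.0, 1.0)


def emwm_variable_importance(all_models: Sequence[FittedModel],
                             members: Sequence[FittedModel],
                             weights: np.ndarray,
                             n_methods: int = 10) -> pd.Series:
    """Per-variable ensemble importance percentages (sum to 100).

    ``all_models`` is the full candidate set whose importances feed the
    calculation; ``members``/``weights`` define each method's total gate
    weight.  All-zero scores degrade to uniform percentages with a warning.
    """
    method_weight: dict[str, float] = {}
    for m, w in zip(members, weights):
        method_weight[m.spec.method] = method_weight.get(m.spec.method, 0.0) + float(w)

    by_method: dict[str, list[pd.Series]] = {}
    for m in all_models:
        by_method.setdefault(m.spec.method, []).append(m.importance)

    variables = list(all_models[0].importance.index)
    score = pd.Series(0.0, index=variables)
    for method, imps in by_method.items():
        w = method_weight.get(method, 0.0)
        if w == 0.0:
            continue
        avg = pd.concat(imps, axis=1).mean(axis=1)
        score = score.add(w * avg, fill_value=0.0)
    score = score / n_methods

    total = score.sum()
    if total <= 0.0:
        warnings.warn("all-zero importance scores; reporting uniform percentages")
        return pd.Series(100.0 / len(variables), index=variables)
    return 100.0 * score / total


def build_ensemble(all_models: Sequence[FittedModel], threshold: float = 0.9,
                   fallback: float = 0.8, n_methods: int = 10,
                   X_test: pd.DataFrame | None = None,
                   y_test: np.ndarray | None = None) -> EnsembleModel:
    """Gate, weight, and (optionally) evaluate the EMwm ensemble."""
    members, used = select_members(all_models, threshold, fallback)
    weights = roc_weights(members)
    ens = EnsembleModel(members=members, weights=weights, threshold_used=used)
    ens.emwm_importance = emwm_variable_importance(
        all_models, members, weights, n_methods=n_methods)
    if X_test is not None and y_test is not None:
        ens.scores = evaluate_ensemble(ens, X_test, y_test)
    return ens


def evaluate_ensemble(ensemble: EnsembleModel, X: pd.DataFrame,
                      y: np.ndarray) -> EvalScores:
    """Score the weighted-mean prediction exactly as a single model."""
    return evaluate(ensemble.predict(X), y)


def ensemble_report(ensemble: EnsembleModel, species: str = "") -> pd.DataFrame:
    rows = []
    for (method, run), w in zip(ensemble.member_ids, ensemble.weights):
        rows.append({
            "species": species,
            "threshold_used": ensemble.threshold_used,
            "n_members": len(ensemble.members),
            "method": method, "run": run, "weight": float(w),
            "ensemble_roc": ensemble.scores.roc if ensemble.scores else np.nan,
            "ensemble_tss": ensemble.scores.tss if ensemble.scores else np.nan,
            "ensemble_cutoff": ensemble.scores.cutoff if ensemble.scores else np.nan,
            "ensemble_sensitivity":
                ensemble.scores.sensitivity if ensemble.scores else np.nan,
            "ensemble_specificity":
                ensemble.scores.specificity if ensemble.scores else np.nan,
        })
    return pd.DataFrame(rows)
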