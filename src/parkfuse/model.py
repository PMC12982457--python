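"""Model/Results façade over the trimodal pipeline.

:class:`TrimodalPDModel` is built from a :class:`TrimodalCohorts` bundle
(real files or the synthetic study conditions); ``fit`` runs the
subject-wise stratified cross-validation protocol end to end — unimodal
encoders, distribution-level fusion, SMOTE-balanced XGBoost with
SHAP-guided feature selection, attribution — and returns a
:class:`TrimodalPDResults` carrying pooled metrics, bootstrap confidence
intervals, the leave-one-modality-out ablation grid, per-modality
importance shares and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError
from .evaluate import (
    MetricsReport,
    bootstrap_ci,
    compute_metrics,
    stratified_kfold,
    wilcoxon_signed_rank,
)
from .explain import (
    aggregate_by_modality,
    attribution_consistency,
    shapley_sampled,
    marginal_value_fn,
    xai_feature_selection,
)
from .fusion import (
    build_fused_dataset,
    fused_matrix,
    pca_speech,
    smote_balance,
    soft_vote,
    train_xgboost,
)
from .gait import GaitUnimodalModel
from .handwriting import HandwritingUnimodalModel
from .speech import SpeechUnimodalModel
from .synthetic import TrimodalCohorts, easy_cohort_specs, make_trimodal_cohorts
from .types import MODALITIES, Embedding, class_index

_FUSED_MODALITIES = ("speech", "handwriting", "gait")


@dataclass
class _FoldOutput:
    y_true: dict[str, np.ndarray] = field(default_factory=dict)
    y_pred: dict[str, np.ndarray] = field(default_factory=dict)
    y_score: dict[str, np.ndarray] = field(default_factory=dict)
    shap_profile: np.ndarray | None = None
    modality_shares: dict[str, float] | None = None


class TrimodalPDModel:
    """Explainable trimodal Parkinson's-disease classifier.

    Parameters
    ----------
    cohorts
        Three independent modality cohorts (no shared subjects).
    n_folds
        Stratified subject-wise cross-validation folds (default 5).
    speech_pca_components
        PCA dimension for speech embeddings before fusion.
    xai_keep_fraction
        Fraction of fused features kept by SHAP-guided selection for the
        main trimodal head (the "no-XAI" ablation row skips it).
    encoder_epochs
        (handwriting, gait, speech) training epochs per fold.
    """

    def __init__(self, cohorts: TrimodalCohorts, n_folds: int = 5,
                 speech_pca_components: int = 16, xai_keep_fraction: float = 0.9,
                 encoder_epochs: tuple[int, int, int] = (10, 12, 12),
                 shap_permutations: int = 30, shap_background: int = 50,
                 shap_instances: int = 8, ensemble: str = "xgboost") -> None:
        self.cohorts = cohorts
        self.n_folds = n_folds
        self.speech_pca_components = speech_pca_components
        self.xai_keep_fraction = xai_keep_fraction
        self.encoder_epochs = encoder_epochs
        self.shap_permutations = shap_permutations
        self.shap_background = shap_background
        self.shap_instances = shap_instances
        if ensemble not in ("xgboost", "soft_vote"):
            raise ConfigError("ensemble must be 'xgboost' or 'soft_vote'")
        self.ensemble = ensemble

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_synthetic(cls, n_per_class: int = 24, seed: int = 0,
                       hard: bool = False, **kwargs) -> "TrimodalPDModel":
        specs = easy_cohort_specs(n_per_class, n_per_class, seed=seed, hard=hard)
        return cls(make_trimodal_cohorts(specs), **kwargs)

    # -- fitting -----------------------------------------------------------

    def fit(self, seed: int = 0) -> "TrimodalPDResults":
        folds_by_mod = {}
        for m in MODALITIES:
            samples = self.cohorts.samples(m)
            folds_by_mod[m] = stratified_kfold(
                [s.subject_id for s in samples], [s.label for s in samples],
                k=self.n_folds, seed=seed)

        outputs: list[_FoldOutput] = []
        loss_traces: dict[str, list[float]] = {}
        for fold in range(self.n_folds):
            outputs.append(self._run_fold(fold, folds_by_mod, seed, loss_traces))
        return TrimodalPDResults(model=self, folds=outputs, seed=seed,
                                 loss_traces=loss_traces)

    # -- internals ---------------------------------------------------------

    def _split_samples(self, modality: str, fold, samples):
        train_subj, test_subj = fold
        train = [s for s in samples if s.subject_id in set(train_subj)]
        test = [s for s in samples if s.subject_id in set(test_subj)]
        return train, test

    def _run_fold(self, fold: int, folds_by_mod, seed: int,
                  loss_traces: dict) -> _FoldOutput:
        e_hw, e_ga, e_sp = self.encoder_epochs
        fold_seed = seed * 1000 + fold
        out = _FoldOutput()

        train_emb: dict[str, list[Embedding]] = {}
        test_emb: dict[str, list[Embedding]] = {}

        for m, mdl in (("handwriting", HandwritingUnimodalModel(epochs=e_hw, seed=fold_seed)),
                       ("gait", GaitUnimodalModel(epochs=e_ga, seed=fold_seed)),
                       ("speech", SpeechUnimodalModel(epochs=e_sp, seed=fold_seed))):
            train, test = self._split_samples(m, folds_by_mod[m][fold],
                                              self.cohorts.samples(m))
            mdl.fit(train)
            if fold == 0:
                loss_traces[m] = list(getattr(mdl, "loss_trace_", []))
            proba = mdl.predict_proba(test)
            out.y_true[m] = np.array([class_index(s.label) for s in test])
            out.y_pred[m] = proba.argmax(axis=1)
            out.y_score[m] = proba[:, 1]
            train_emb[m] = mdl.embed_subjects(train)
            test_emb[m] = mdl.embed_subjects(test)

        # speech PCA fitted on the training pool only
        tr_sp = np.stack([e.vector for e in train_emb["speech"]])
        n_comp = min(self.speech_pca_components, tr_sp.shape[0], tr_sp.shape[1])
        _, basis = pca_speech(tr_sp, n_components=n_comp, seed=fold_seed)

        def reduce_speech(embs):
            z = basis.transform(np.stack([e.vector for e in embs]))
            return [Embedding(vector=v, modality="speech", subject_id=e.subject_id,
                              label=e.label) for v, e in zip(z, embs)]

        train_emb["speech"] = reduce_speech(train_emb["speech"])
        test_emb["speech"] = reduce_speech(test_emb["speech"])

        fused_train, _ = build_fused_dataset(train_emb, seed=fold_seed)
        fused_test, _ = build_fused_dataset(test_emb, seed=fold_seed + 1)
        spans = fused_train[0].spans
        x_tr_raw, y_tr = fused_matrix(fused_train)
        x_te_raw, y_te = fused_matrix(fused_test)

        from sklearn.preprocessing import StandardScaler

        scaler = StandardScaler().fit(x_tr_raw)
        x_tr, x_te = scaler.transform(x_tr_raw), scaler.transform(x_te_raw)
        x_bal, y_bal = smote_balance(x_tr, y_tr, seed=fold_seed)

        # full-feature trimodal head + SHAP on training vectors
        head_full = train_xgboost(x_bal, y_bal, seed=fold_seed)
        shap_vals = self._shap_profile(head_full, x_tr, fold_seed)
        out.shap_profile = np.abs(shap_vals).mean(axis=0)
        out.modality_shares = aggregate_by_modality(out.shap_profile, spans)

        # "no XAI selection" row: the full-feature head
        self._record(out, "trimodal_no_xai", y_te,
                     head_full.predict_proba(x_te)[:, 1])

        # main trimodal head: keep top-q features by mean |SHAP|, retrain
        keep = xai_feature_selection(shap_vals, self.xai_keep_fraction)
        head = train_xgboost(x_bal[:, keep], y_bal, seed=fold_seed)
        p_tri = head.predict_proba(x_te[:, keep])[:, 1]
        if self.ensemble == "soft_vote":
            per_mod = []
            for m in _FUSED_MODALITIES:
                s, e = spans[m]
                mh = train_xgboost(x_bal[:, s:e], y_bal, seed=fold_seed)
                per_mod.append(mh.predict_proba(x_te[:, s:e]))
            p_mean, _ = soft_vote(per_mod)
            p_tri = p_mean[:, 1]
        self._record(out, "trimodal", y_te, p_tri)

        # bimodal ablations share the same fused vectors and seeds
        for pair, name in ((("handwriting", "gait"), "handwriting+gait"),
                           (("handwriting", "speech"), "handwriting+speech"),
                           (("gait", "speech"), "gait+speech")):
            cols = np.concatenate([np.arange(*spans[m]) for m in pair])
            h = train_xgboost(x_bal[:, cols], y_bal, seed=fold_seed)
            self._record(out, name, y_te, h.predict_proba(x_te[:, cols])[:, 1])
        return out

    def _shap_profile(self, head, x_train: np.ndarray, fold_seed: int) -> np.ndarray:
        rng = np.random.default_rng(fold_seed)
        bg_idx = rng.choice(len(x_train), min(self.shap_background, len(x_train)),
                            replace=False)
        background = x_train[bg_idx]
        inst_idx = rng.choice(len(x_train), min(self.shap_instances, len(x_train)),
                              replace=False)

        def predict(x):
            return head.predict_proba(np.atleast_2d(x))[:, 1]

        rows = []
        for i in inst_idx:
            w = marginal_value_fn(predict, x_train[i], background)
            res = shapley_sampled(w, x_train.shape[1],
                                  n_permutations=self.shap_permutations,
                                  seed=int(fold_seed + i))
            rows.append(res.values)
        return np.stack(rows)

    @staticmethod
    def _record(out: _FoldOutput, name: str, y_true: np.ndarray,
                score: np.ndarray) -> None:
        out.y_true[name] = y_true
        out.y_pred[name] = (score >= 0.5).astype(int)
        out.y_score[name] = score


class TrimodalPDResults:
    """Pooled cross-validated results of a fitted :class:`TrimodalPDModel`."""

    def __init__(self, model: TrimodalPDModel, folds: list[_FoldOutput],
                 seed: int, loss_traces: dict[str, list[float]]) -> None:
        self.model = model
        self.folds = folds
        self.seed = seed
        self.loss_traces = loss_traces
        self._reports: dict[str, MetricsReport] = {}

    # -- metrics -----------------------------------------------------------

    def configurations(self) -> list[str]:
        return list(self.folds[0].y_true)

    def metrics(self, config: str = "trimodal",
                ci_resamples: int = 0) -> MetricsReport:
        key = (config, ci_resamples)
        if key in self._reports:
            return self._reports[key]
        yt = np.concatenate([f.y_true[config] for f in self.folds])
        yp = np.concatenate([f.y_pred[config] for f in self.folds])
        ys = np.concatenate([f.y_score[config] for f in self.folds])
        rep = compute_metrics(yt, yp, ys)
        rep.fold_values["accuracy"] = [
            float((f.y_true[config] == f.y_pred[config]).mean()) for f in self.folds]
        if ci_resamples:
            point, lo, hi = bootstrap_ci(
                lambda a, b: (a == b).mean(), yt, yp,
                n_resamples=ci_resamples, seed=self.seed)
            rep.ci["accuracy"] = (lo, hi)
        self._reports[key] = rep
        return rep

    def fold_accuracies(self, config: str) -> np.ndarray:
        return np.array([(f.y_true[config] == f.y_pred[config]).mean()
                         for f in self.folds])

    def compare(self, config_a: str, config_b: str) -> tuple[float, float]:
        """Wilcoxon signed-rank test on paired fold accuracies."""
        return wilcoxon_signed_rank(self.fold_accuracies(config_a),
                                    self.fold_accuracies(config_b))

    # -- explainability ----------------------------------------------------

    def modality_importance(self) -> dict[str, float]:
        """Mean per-modality SHAP share across folds (sums to 1)."""
        keys = self.folds[0].modality_shares.keys()
        return {m: float(np.mean([f.modality_shares[m] for f in self.folds]))
                for m in keys}

    def attribution_consistency(self) -> dict:
        return attribution_consistency([f.shap_profile for f in self.folds])

    # -- presentation ------------------------------------------------------

    def ablation_frame(self) -> pd.DataFrame:
        rows = {}
        for cfg in self.configurations():
            rep = self.metrics(cfg)
            row = rep.summary_row()
            row["accuracy_sd"] = float(np.std(self.fold_accuracies(cfg)))
            rows[cfg] = row
        return pd.DataFrame(rows).T

    def summary(self, ci_resamples: int = 1000) -> str:
        lines = ["Trimodal Parkinson's disease detection — cross-validated results",
                 "=" * 66,
                 f"folds: {self.model.n_folds}   seed: {self.seed}   "
                 f"ensemble: {self.model.ensemble}", ""]
        frame = self.ablation_frame().round(3)
        lines.append(frame.to_string())
        rep = self.metrics("trimodal", ci_resamples=ci_resamples)
        if "accuracy" in rep.ci:
            lo, hi = rep.ci["accuracy"]
            lines.append(f"\ntrimodal accuracy {rep.accuracy:.3f} "
                         f"(95% bootstrap CI {lo:.3f}-{hi:.3f}, "
                         f"{ci_resamples} resamples)")
        shares = self.modality_importance()
        lines.append("modality importance (mean |SHAP| share): "
                     + ", ".join(f"{m}={v:.2f}" for m, v in shares.items()))
        cons = self.attribution_consistency()
        lines.append(f"cross-fold attribution rank-correlation: "
                     f"mean {cons['mean']:.2f}, min {cons['min']:.2f}")
        return "\n".join(lines)
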