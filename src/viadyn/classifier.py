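"""Pixel classifier (11 -> 15 -> 1 network) and patient-level LOO-CV.

Each pixel's 11-point intensity curve is classified independently by a
single-hidden-layer network with 15 logistic units and a logistic
output, trained with binary cross-entropy. Patient-level leave-one-out
cross-validation guarantees that a patient's own pixels never reach the
training or validation set of the model that diagnoses them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.neural_network import MLPClassifier

from .config import PipelineConfig
from .postprocess import (LesionPrediction, ProbabilityMap, postprocess_map)
from .trainset import augment_positive


@dataclass
class NetworkSpec:
    n_inputs: int = 11
    hidden_nodes: int = 15
    hidden_layers: int = 1


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclass
class TrainedModel:
    """A fitted pixel classifier plus its training metadata.

    Holds the layer weights explicitly and evaluates its own logistic
    forward pass, so a model round-trips through save/load without
    depending on estimator internals.
    """

    coefs: list
    intercepts: list
    spec: NetworkSpec
    seed: int
    epochs_run: int = 0
    loss_trace: list = field(default_factory=list)

    def predict_proba(self, curves: np.ndarray) -> np.ndarray:
        """CIN2+ probability for each 11-point curve; shape (N,)."""
        z = np.atleast_2d(np.asarray(curves, dtype=float))
        if z.shape[1] != self.spec.n_inputs:
            raise ValueError(
                f"curves must have {self.spec.n_inputs} points, got {z.shape[1]}")
        for W, b in zip(self.coefs, self.intercepts):
            z = _sigmoid(z @ W + b)
        return np.clip(z[:, -1], 0.0, 1.0)


def train(
    features: np.ndarray,
    labels: np.ndarray,
    spec: NetworkSpec | None = None,
    rng_seed: int = 0,
    max_epochs: int = 200,
    early_stopping: bool = False,
    validation_fraction: float = 0.1,
) -> TrainedModel:
    """Fit the network on labeled curves; deterministic under the seed."""
    spec = spec or NetworkSpec()
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    if X.ndim != 2 or X.shape[1] != spec.n_inputs:
        raise ValueError(f"features must be (N, {spec.n_inputs})")
    if len(np.unique(y)) < 2:
        raise ValueError("training needs both classes present")
    mlp = MLPClassifier(
        hidden_layer_sizes=(spec.hidden_nodes,) * spec.hidden_layers,
        activation="logistic",
        solver="adam",
        max_iter=max_epochs,
        early_stopping=early_stopping,
        validation_fraction=validation_fraction,
        n_iter_no_change=10,
        random_state=int(rng_seed) % (2**31),
    )
    import warnings as _warnings
    with _warnings.catch_warnings():
        from sklearn.exceptions import ConvergenceWarning
        _warnings.simplefilter("ignore", ConvergenceWarning)
        mlp.fit(X, y)
    return TrainedModel(coefs=[W.copy() for W in mlp.coefs_],
                        intercepts=[b.copy() for b in mlp.intercepts_],
                        spec=spec, seed=int(rng_seed),
                        epochs_run=int(mlp.n_iter_),
                        loss_trace=[float(v) for v in mlp.loss_curve_])


def predict_map(
    model: TrainedModel,
    features: np.ndarray,
    reflection_mask: np.ndarray | None = None,
    valid_mask: np.ndarray | None = None,
    roi_mask: np.ndarray | None = None,
    patient_id: str = "",
) -> ProbabilityMap:
    """Per-pixel probabilities from an (H, W, 11) feature grid.

    Pixels outside ``roi_mask`` or flagged invalid get the neutral 0.5 —
    no evidence either way, the same convention reflections receive in
    postprocessing.
    """
    H, W, n = features.shape
    flat = features.reshape(H * W, n)
    evaluate = np.ones(H * W, dtype=bool)
    if valid_mask is not None:
        evaluate &= np.asarray(valid_mask, bool).ravel()
    if roi_mask is not None:
        evaluate &= np.asarray(roi_mask, bool).ravel()
    probs = np.full(H * W, 0.5)
    if evaluate.any():
        probs[evaluate] = model.predict_proba(flat[evaluate])
    refl = (np.zeros((H, W), bool) if reflection_mask is None
            else np.asarray(reflection_mask, bool))
    return ProbabilityMap(probs=probs.reshape(H, W), reflection_mask=refl,
                          patient_id=patient_id)


def save_model(model: TrainedModel, path_prefix: str | Path) -> None:
    """Weights as .npz plus JSON metadata."""
    path_prefix = Path(path_prefix)
    arrays = {}
    for i, (W, b) in enumerate(zip(model.coefs, model.intercepts)):
        arrays[f"W{i}"] = W
        arrays[f"b{i}"] = b
    np.savez(path_prefix.with_suffix(".npz"), **arrays)
    meta = {
        "n_inputs": model.spec.n_inputs,
        "hidden_nodes": model.spec.hidden_nodes,
        "hidden_layers": model.spec.hidden_layers,
        "seed": model.seed,
        "epochs_run": model.epochs_run,
        "loss_trace": model.loss_trace,
    }
    path_prefix.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_model(path_prefix: str | Path) -> TrainedModel:
    path_prefix = Path(path_prefix)
    meta = json.loads(path_prefix.with_suffix(".json").read_text())
    data = np.load(path_prefix.with_suffix(".npz"))
    spec = NetworkSpec(meta["n_inputs"], meta["hidden_nodes"], meta["hidden_layers"])
    n_layers = spec.hidden_layers + 1
    return TrainedModel(coefs=[data[f"W{i}"] for i in range(n_layers)],
                        intercepts=[data[f"b{i}"] for i in range(n_layers)],
                        spec=spec, seed=meta["seed"],
                        epochs_run=meta["epochs_run"],
                        loss_trace=meta["loss_trace"])


@dataclass
class PatientData:
    """Everything the CV harness needs about one patient, precomputed."""

    patient_id: str
    label: str  # histology: "positive" | "negative"
    features: np.ndarray  # (H, W, 11)
    reflection_mask: np.ndarray
    valid_mask: np.ndarray | None
    roi_mask: np.ndarray | None
    positive_region: np.ndarray | None  # None for negative patients
    negative_region: np.ndarray
    annotation_mask: np.ndarray | None = None


@dataclass
class CVFold:
    held_out_patient_id: str
    training_patient_ids: list
    model: TrainedModel
    n_train_pos: int = 0
    n_train_neg: int = 0
    training_pixels: list = field(default_factory=list)  # (patient_id, row, col)


@dataclass
class FoldResult:
    fold: CVFold
    probability_map: ProbabilityMap
    prediction: LesionPrediction


def _sample_fold_pixels(patients: list, held_out: str, config: PipelineConfig,
                        rng: np.random.Generator) -> tuple:
    """Gather per-patient pixel curves for one fold's training set."""
    pos_feats, neg_feats, triples = [], [], []
    for pd in patients:
        if pd.patient_id == held_out:
            continue
        exclude = pd.reflection_mask.copy()
        if pd.valid_mask is not None:
            exclude |= ~pd.valid_mask
        for region, n_req, sink, lab in (
            (pd.positive_region, config.n_pos_per_patient, pos_feats, 1),
            (pd.negative_region, config.n_neg_per_patient, neg_feats, 0),
        ):
            if region is None or not region.any():
                continue
            candidates = np.argwhere(region & ~exclude)
            n = min(n_req, len(candidates))
            if n == 0:
                continue
            picks = candidates[rng.choice(len(candidates), size=n, replace=False)]
            sink.append(pd.features[picks[:, 0], picks[:, 1]])
            triples.extend((pd.patient_id, int(r), int(c)) for r, c in picks)
    pos = np.concatenate(pos_feats) if pos_feats else np.empty((0, config.n_curve_points))
    neg = np.concatenate(neg_feats) if neg_feats else np.empty((0, config.n_curve_points))
    return pos, neg, triples


def run_loo_cv(
    patients: list,
    config: PipelineConfig | None = None,
    rng_seed: int = 0,
) -> list:
    """Patient-level leave-one-out cross-validation over prepared patients.

    Per fold: sample training pixels from every other patient, augment
    positives by curve scaling up to the negative count (exact class
    balance), train the network, predict the held-out patient's map, and
    postprocess it into a lesion prediction. Returns one FoldResult per
    patient.
    """
    config = config or PipelineConfig()
    if len(patients) < 2:
        raise ValueError("LOO-CV needs at least 2 patients")
    labels = {p.label for p in patients}
    if labels != {"positive", "negative"}:
        raise ValueError("cohort must contain both classes")

    results = []
    for k, held in enumerate(patients):
        fold_rng = np.random.default_rng([int(rng_seed) % (2**31), k])
        pos, neg, triples = _sample_fold_pixels(patients, held.patient_id,
                                                config, fold_rng)
        if len(pos) == 0 or len(neg) == 0:
            raise ValueError(
                f"fold holding out {held.patient_id} lacks a class "
                f"(pos={len(pos)}, neg={len(neg)})")
        if len(neg) > len(pos):
            pos = augment_positive(pos, len(neg), fold_rng,
                                   scale_range=config.augment_scale_range)
        elif len(pos) > len(neg):
            # more positives than negatives: subsample positives
            keep = fold_rng.choice(len(pos), size=len(neg), replace=False)
            pos = pos[keep]
        X = np.concatenate([pos, neg])
        y = np.concatenate([np.ones(len(pos), int), np.zeros(len(neg), int)])
        model = train(X, y, NetworkSpec(config.n_curve_points, config.hidden_nodes),
                      rng_seed=(int(rng_seed) * 1000003 + k) % (2**31),
                      max_epochs=config.max_epochs,
                      early_stopping=config.early_stopping,
                      validation_fraction=config.validation_fraction)
        pmap = predict_map(model, held.features, held.reflection_mask,
                           held.valid_mask, held.roi_mask, held.patient_id)
        prediction = postprocess_map(pmap, config, rng_seed=[int(rng_seed) % (2**31), k, 1])
        fold = CVFold(held.patient_id,
                      [p.patient_id for p in patients if p.patient_id != held.patient_id],
                      model, n_train_pos=len(pos), n_train_neg=len(neg),
                      training_pixels=triples)
        results.append(FoldResult(fold, pmap, prediction))
    return results
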