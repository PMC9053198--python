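"""Patient-grouped splitting and the malignancy classifier.

The classifier is a small feed-forward network mapping the 108 compositional
features plus the CAD probability to a probability of malignancy.  Splits are
grouped by patient (60/20/20) so that correlated ROIs from one patient never
straddle partitions.  Hyperparameters (hidden layout, weight decay, learning
rate) are chosen by seeded random search with early stopping on the validation
partition's log-loss, and the best configuration by validation AUC is kept.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.metrics import log_loss, roc_auc_score
from sklearn.neural_network import MLPClassifier

from .exceptions import ConfigurationError, InputError, TrainingError
from .features import FEATURE_NAMES

#: Full model input: 108 compositional features plus the CAD probability.
INPUT_COLUMNS = tuple(FEATURE_NAMES) + ("cad_probability",)


@dataclass
class SplitDataset:
    train: pd.DataFrame
    validation: pd.DataFrame
    test: pd.DataFrame
    fractions: tuple
    seed: int

    def patient_sets(self) -> tuple[set, set, set]:
        return (
            set(self.train["patient_id"]),
            set(self.validation["patient_id"]),
            set(self.test["patient_id"]),
        )


def split_by_patient(
    records: pd.DataFrame,
    fractions: tuple = (0.6, 0.2, 0.2),
    seed: int = 0,
) -> SplitDataset:
    """Shuffle patients by seed and partition all their ROIs together.

    The test partition receives ``round(f_test * n_patients)`` patients (exact
    when the patient count is divisible by 5), validation likewise, and the
    remainder trains.  No patient appears in more than one partition.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ConfigurationError("split fractions must sum to 1")
    patients = np.array(sorted(records["patient_id"].unique()))
    if len(patients) < 5:
        raise ConfigurationError("need at least 5 distinct patients to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(patients))
    patients = patients[order]
    n = len(patients)
    n_test = int(round(fractions[2] * n))
    n_val = int(round(fractions[1] * n))
    test_p = set(patients[:n_test])
    val_p = set(patients[n_test : n_test + n_val])
    train_p = set(patients[n_test + n_val :])
    by = records["patient_id"]
    return SplitDataset(
        train=records[by.isin(train_p)].reset_index(drop=True),
        validation=records[by.isin(val_p)].reset_index(drop=True),
        test=records[by.isin(test_p)].reset_index(drop=True),
        fractions=tuple(fractions),
        seed=seed,
    )


def handle_missed_lesions(split: SplitDataset) -> SplitDataset:
    """Apply the CAD-miss rule after splitting.

    ROIs the CAD surrogate missed keep a CAD probability of zero and are
    retained in the training partition only; they are removed from validation
    and test.
    """
    train = split.train.copy()
    if "cad_missed" in train.columns:
        train.loc[train["cad_missed"].astype(bool), "cad_probability"] = 0.0
        val = split.validation[~split.validation["cad_missed"].astype(bool)]
        test = split.test[~split.test["cad_missed"].astype(bool)]
    else:
        val, test = split.validation, split.test
    return SplitDataset(
        train=train,
        validation=val.reset_index(drop=True),
        test=test.reset_index(drop=True),
        fractions=split.fractions,
        seed=split.seed,
    )


@dataclass(frozen=True)
class SearchConfig:
    """Random-search space for the network.

    1-3 hidden layers of {16, 32, 64} rectified units, L2 weight decay in
    {1e-6, 1e-5, 1e-4} (the regularization axis of the search; the useful
    decision boundary contrasts lesion against ring statistics, which strong
    decay suppresses), learning rate log-uniform on [3e-4, 3e-2],
    early-stopping patience of 20 validation evaluations, and a default
    budget of 20 sampled configurations.
    """

    budget: int = 20
    hidden_sizes: tuple = (16, 32, 64)
    max_layers: int = 3
    weight_decay: tuple = (1e-6, 1e-5, 1e-4)
    lr_log_range: tuple = (3e-4, 3e-2)
    patience: int = 20
    max_epochs: int = 400
    #: covariance shrinkage for the ZCA whitening of standardized inputs;
    #: whitening equalizes feature-space variance so the low-variance
    #: lesion-vs-ring contrast directions are reachable by gradient training.
    #: None selects the Ledoit-Wolf coefficient from the training data.
    whiten_shrinkage: float | None = None


@dataclass
class ClassifierModel:
    """A trained feed-forward malignancy classifier.

    Inference standardizes inputs with training-partition statistics, applies
    the training-set ZCA whitening transform, and runs a numpy forward pass
    (ReLU hidden layers, logistic output) over the stored weights, so a
    JSON-serialized model reloads exactly.
    """

    hidden_layer_sizes: tuple
    weight_decay: float
    learning_rate: float
    coefs: list
    intercepts: list
    feature_names: tuple
    input_mean: np.ndarray
    input_sd: np.ndarray
    whitening: np.ndarray
    validation_auc: float
    #: Platt recalibration fitted on the validation partition; training with
    #: balanced oversampling skews raw output probabilities away from the
    #: cohort prevalence, and the mean-risk metrics (IDI) need calibrated
    #: probabilities.  (a, b) act on the logit: p = sigmoid(a * logit(p) + b).
    calibration: tuple = (1.0, 0.0)
    history: dict = field(default_factory=dict)

    def _matrix(self, records) -> np.ndarray:
        if isinstance(records, pd.DataFrame):
            missing = [c for c in self.feature_names if c not in records.columns]
            if missing:
                raise InputError(f"missing feature columns: {missing}")
            X = records[list(self.feature_names)].to_numpy(dtype=float)
        else:
            X = np.asarray(records, dtype=float)
            if X.ndim == 1:
                X = X[None, :]
            if X.shape[1] != len(self.feature_names):
                raise InputError(
                    f"expected {len(self.feature_names)} inputs, got {X.shape[1]}"
                )
        return X

    def predict_proba(self, records) -> np.ndarray:
        X = self._matrix(records)
        z = ((X - self.input_mean) / self.input_sd) @ self.whitening
        for W, b in zip(self.coefs[:-1], self.intercepts[:-1]):
            z = np.maximum(z @ W + b, 0.0)
        logit = (z @ self.coefs[-1] + self.intercepts[-1])[:, 0]
        a, b = self.calibration
        return expit(a * logit + b)

    def to_json(self) -> str:
        return json.dumps(
            {
                "hidden_layer_sizes": list(self.hidden_layer_sizes),
                "weight_decay": self.weight_decay,
                "learning_rate": self.learning_rate,
                "coefs": [W.tolist() for W in self.coefs],
                "intercepts": [b.tolist() for b in self.intercepts],
                "feature_names": list(self.feature_names),
                "input_mean": self.input_mean.tolist(),
                "input_sd": self.input_sd.tolist(),
                "whitening": self.whitening.tolist(),
                "calibration": list(self.calibration),
                "validation_auc": self.validation_auc,
                "history": self.history,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "ClassifierModel":
        d = json.loads(text)
        return cls(
            hidden_layer_sizes=tuple(d["hidden_layer_sizes"]),
            weight_decay=d["weight_decay"],
            learning_rate=d["learning_rate"],
            coefs=[np.asarray(W, dtype=float) for W in d["coefs"]],
            intercepts=[np.asarray(b, dtype=float) for b in d["intercepts"]],
            feature_names=tuple(d["feature_names"]),
            input_mean=np.asarray(d["input_mean"], dtype=float),
            input_sd=np.asarray(d["input_sd"], dtype=float),
            whitening=np.asarray(d["whitening"], dtype=float),
            calibration=tuple(d.get("calibration", (1.0, 0.0))),
            validation_auc=d["validation_auc"],
            history=d.get("history", {}),
        )


def _standardizer(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)  # zero-variance features pass through at 0
    return mean, sd


def _zca_whitener(Z: np.ndarray, shrinkage: float | None = None) -> np.ndarray:
    """Symmetric (ZCA) whitening matrix of standardized training inputs.

    The raw region statistics are strongly collinear (a lesion median and its
    ring medians share almost all their variance); whitening rescales the
    minor axes of the training covariance so the discriminative lesion-minus-
    ring contrasts have unit scale.  The covariance is estimated with
    Ledoit-Wolf shrinkage by default, which keeps the transform close to the
    identity when samples are scarce relative to the feature count; an
    explicit shrinkage coefficient can be supplied instead.
    """
    if shrinkage is None:
        from sklearn.covariance import LedoitWolf

        C = LedoitWolf().fit(Z).covariance_
    else:
        n_feat = Z.shape[1]
        S = np.cov(Z, rowvar=False)
        mu = np.trace(S) / n_feat
        C = (1.0 - shrinkage) * S + shrinkage * mu * np.eye(n_feat)
    s, V = np.linalg.eigh(C)
    s = np.clip(s, 1e-12, None)
    return V @ np.diag(1.0 / np.sqrt(s)) @ V.T


def _balanced_oversample(y: np.ndarray, rng) -> np.ndarray:
    """Indices that balance the classes by resampling the minority with
    replacement (stands in for inverse-frequency loss weights)."""
    idx0 = np.flatnonzero(y == 0)
    idx1 = np.flatnonzero(y == 1)
    if len(idx0) == 0 or len(idx1) == 0:
        raise TrainingError("training labels contain a single class")
    n = max(len(idx0), len(idx1))
    take0 = idx0 if len(idx0) == n else rng.choice(idx0, size=n, replace=True)
    take1 = idx1 if len(idx1) == n else rng.choice(idx1, size=n, replace=True)
    out = np.concatenate([take0, take1])
    rng.shuffle(out)
    return out


def _fit_one(Xtr, ytr, Xval, yval, hidden, alpha, lr, patience, max_epochs, seed):
    """Train one configuration with early stopping on validation log-loss."""
    mlp = MLPClassifier(
        hidden_layer_sizes=hidden,
        activation="relu",
        solver="adam",
        alpha=alpha,
        learning_rate_init=lr,
        batch_size=min(200, len(Xtr)),
        random_state=seed,
        max_iter=1,
        warm_start=False,
    )
    best_loss = np.inf
    best_weights = None
    stall = 0
    losses = []
    for _epoch in range(max_epochs):
        mlp.partial_fit(Xtr, ytr, classes=np.array([0, 1]))
        p = np.clip(mlp.predict_proba(Xval)[:, 1], 1e-12, 1 - 1e-12)
        loss = log_loss(yval, p, labels=[0, 1])
        losses.append(float(loss))
        if loss < best_loss - 1e-6:
            best_loss = loss
            best_weights = (
                [W.copy() for W in mlp.coefs_],
                [b.copy() for b in mlp.intercepts_],
            )
            stall = 0
        else:
            stall += 1
            if stall >= patience:
                break
    if best_weights is None:
        best_weights = (mlp.coefs_, mlp.intercepts_)
    return best_weights, best_loss, losses


def train_classifier(
    split: SplitDataset,
    search_config: SearchConfig | None = None,
    seed: int = 0,
) -> ClassifierModel:
    """Random hyperparameter search over small feed-forward networks.

    Features are standardized with training-partition statistics; the training
    classes are balanced by seeded oversampling; each sampled configuration is
    trained with early stopping on validation log-loss and the configuration
    with the best validation AUC is returned.  Fully seeded.
    """
    cfg = search_config or SearchConfig()
    if len(split.train) == 0 or len(split.validation) == 0:
        raise TrainingError("training and validation partitions must be nonempty")
    cols = list(INPUT_COLUMNS)
    Xtr_raw = split.train[cols].to_numpy(dtype=float)
    ytr = split.train["label"].to_numpy(dtype=int)
    Xval_raw = split.validation[cols].to_numpy(dtype=float)
    yval = split.validation["label"].to_numpy(dtype=int)
    if len(np.unique(ytr)) < 2:
        raise TrainingError("training labels contain a single class")

    mean, sd = _standardizer(Xtr_raw)
    W = _zca_whitener((Xtr_raw - mean) / sd, cfg.whiten_shrinkage)
    Xtr = ((Xtr_raw - mean) / sd) @ W
    Xval = ((Xval_raw - mean) / sd) @ W

    rng = np.random.default_rng(seed)
    take = _balanced_oversample(ytr, rng)
    Xbal, ybal = Xtr[take], ytr[take]

    best = None
    history = {"configs": []}
    for _trial in range(cfg.budget):
        n_layers = int(rng.integers(1, cfg.max_layers + 1))
        hidden = tuple(
            int(rng.choice(np.asarray(cfg.hidden_sizes))) for _ in range(n_layers)
        )
        alpha = float(rng.choice(np.asarray(cfg.weight_decay)))
        lo, hi = np.log(cfg.lr_log_range[0]), np.log(cfg.lr_log_range[1])
        lr = float(np.exp(rng.uniform(lo, hi)))
        net_seed = int(rng.integers(2**31))
        weights, val_loss, losses = _fit_one(
            Xbal, ybal, Xval, yval, hidden, alpha, lr,
            cfg.patience, cfg.max_epochs, net_seed,
        )
        model = ClassifierModel(
            hidden_layer_sizes=hidden,
            weight_decay=alpha,
            learning_rate=lr,
            coefs=weights[0],
            intercepts=weights[1],
            feature_names=tuple(cols),
            input_mean=mean,
            input_sd=sd,
            whitening=W,
            validation_auc=0.0,
        )
        pval = model.predict_proba(split.validation)
        val_auc = float(roc_auc_score(yval, pval)) if len(np.unique(yval)) > 1 else 0.5
        model.validation_auc = val_auc
        history["configs"].append(
            {"hidden": list(hidden), "alpha": alpha, "lr": lr,
             "val_loss": val_loss, "val_auc": val_auc, "epochs": len(losses)}
        )
        if best is None or val_auc > best.validation_auc:
            best = model
    _platt_recalibrate(best, split.validation, yval)
    best.history = history
    return best


def _platt_recalibrate(model: ClassifierModel, val_frame, yval) -> None:
    """Fit a monotone logistic recalibration of the output on validation."""
    if len(np.unique(yval)) < 2:
        return
    raw = np.clip(model.predict_proba(val_frame), 1e-9, 1 - 1e-9)
    logit = np.log(raw / (1 - raw))
    from sklearn.linear_model import LogisticRegression

    cal = LogisticRegression(C=1e6).fit(logit[:, None], yval)
    a = float(cal.coef_[0, 0])
    if a <= 0:  # refuse a rank-reversing recalibration
        return
    model.calibration = (a, float(cal.intercept_[0]))


def predict_malignancy(model: ClassifierModel, records) -> np.ndarray:
    """Probabilities of malignancy in [0, 1]; deterministic for a fixed model."""
    return model.predict_proba(records)
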