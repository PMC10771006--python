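"""The γ-weighted property-profile drug-likeness model (DBPP score).

A molecule is represented by a 26-value property profile: six physicochemical
values (MW, logP, TPSA, HBA, HBD, nROT) followed by twenty ADMET endpoint
probabilities.  The two blocks are combined with a weighting parameter
γ ∈ [0, 1]:

    profile = concat( (2 - 2γ) · PC_scaled , 2γ · ADMET )

At γ = 0.5 both blocks carry unit weight; γ = 1 zeroes the physicochemical
block and doubles the ADMET block, γ = 0 the reverse.  The default γ is 0.6,
the value selected by the cross-validated AUC/F1 sweep; `evaluate.gamma_sweep`
re-derives it on user data.

Raw physicochemical values live on incommensurate scales (MW in hundreds,
counts in units) while ADMET probabilities live in [0, 1]; the PC block is
therefore min–max scaled to [0, 1] on training ranges before weighting, with
out-of-range query values clipped.  Without this the γ weighting would be
meaningless.

A binary classifier (logistic regression, SVM, or gradient-boosted trees with
grid-searched hyperparameters) is trained on profiles of drugs (label 1)
versus non-drugs (label 0); its probability for the drug class is the DBPP
score.  A score strictly greater than the druggability threshold — default
0.736, the mean score of a reference approved-drug collection — flags the
molecule as druggable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from . import featurize
from .admet import EndpointPanel
from .chemprep import LabeledDataset, StandardizedMolecule

N_PC = 6
N_ADMET = 20
PROFILE_LENGTH = N_PC + N_ADMET

DEFAULT_GAMMA = 0.6
DEFAULT_THRESHOLD = 0.736

#: pinned hyperparameter grids per classifier family
GRIDS = {
    "lr": {"C": [0.01, 0.1, 1, 10, 100]},
    "svm": {"C": [0.01, 0.1, 1, 10, 100]},
    "lgbm": {"max_depth": [3, 5, 7, -1], "num_leaves": [15, 31, 63]},
}


class PCScaler:
    """Min–max scaling of the six physicochemical values to [0, 1].

    Ranges come from training data only; query values outside the training
    range are clipped.  Constant training columns map to 0.
    """

    def __init__(self) -> None:
        self.min_: Optional[np.ndarray] = None
        self.range_: Optional[np.ndarray] = None

    def fit(self, pc: np.ndarray) -> "PCScaler":
        pc = np.asarray(pc, dtype=float)
        if pc.ndim != 2 or pc.shape[1] != N_PC:
            raise ValueError(f"expected (n, {N_PC}) physicochemical matrix")
        self.min_ = pc.min(axis=0)
        self.range_ = pc.max(axis=0) - self.min_
        return self

    def transform(self, pc: np.ndarray) -> np.ndarray:
        if self.min_ is None:
            raise RuntimeError("PCScaler is not fitted")
        pc = np.asarray(pc, dtype=float)
        rng = np.where(self.range_ == 0, 1.0, self.range_)
        scaled = (pc - self.min_) / rng
        scaled[:, self.range_ == 0] = 0.0
        return np.clip(scaled, 0.0, 1.0)

    def to_dict(self) -> dict:
        return {"min": self.min_.tolist(), "range": self.range_.tolist()}

    @staticmethod
    def from_dict(d: dict) -> "PCScaler":
        s = PCScaler()
        s.min_ = np.asarray(d["min"], dtype=float)
        s.range_ = np.asarray(d["range"], dtype=float)
        return s


@dataclass
class PropertyProfile:
    """The 26-value hybrid feature vector with its γ."""

    values: np.ndarray
    gamma: float
    pc_scaler_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (PROFILE_LENGTH,):
            raise ValueError(f"profile must have length {PROFILE_LENGTH}")

    @property
    def pc_block(self) -> np.ndarray:
        return self.values[:N_PC]

    @property
    def admet_block(self) -> np.ndarray:
        return self.values[N_PC:]


def profile_weights(gamma: float) -> Tuple[float, float]:
    """Block weights (PC, ADMET) = (2 - 2γ, 2γ)."""
    if not 0.0 <= gamma <= 1.0:
        raise ValueError(f"gamma must be in [0, 1], got {gamma}")
    return 2.0 - 2.0 * gamma, 2.0 * gamma


def weight_profile_matrix(pc_scaled: np.ndarray, admet: np.ndarray, gamma: float) -> np.ndarray:
    w_pc, w_admet = profile_weights(gamma)
    return np.hstack([w_pc * np.asarray(pc_scaled, float),
                      w_admet * np.asarray(admet, float)])


def build_profile(pc, admet, gamma: float, pc_scaler: PCScaler) -> PropertyProfile:
    """Build one γ-weighted 26-value property profile.

    ``pc`` is a :class:`featurize.PhyschemProfile` or raw length-6 array;
    ``admet`` an :class:`dbpp.admet.AdmetVector` or length-20 probability
    array.  The PC block is min–max scaled then weighted by (2 − 2γ); the
    ADMET block is weighted by 2γ.
    """
    if hasattr(pc, "as_array"):
        pc = pc.as_array()
    if hasattr(admet, "values"):
        admet = admet.values
    pc = np.asarray(pc, dtype=float).reshape(1, N_PC)
    admet = np.asarray(admet, dtype=float).reshape(N_ADMET)
    pc_scaled = pc_scaler.transform(pc)[0]
    w_pc, w_admet = profile_weights(gamma)
    values = np.concatenate([w_pc * pc_scaled, w_admet * admet])
    scaler_id = hashlib.sha256(
        json.dumps(pc_scaler.to_dict()).encode()
    ).hexdigest()[:12]
    return PropertyProfile(values=values, gamma=gamma, pc_scaler_id=scaler_id)


def _base_classifier(algo: str, seed: int):
    if algo == "lgbm":
        from lightgbm import LGBMClassifier

        return LGBMClassifier(
            n_estimators=100, random_state=seed, n_jobs=1, verbose=-1,
            deterministic=True, force_row_wise=True,
        )
    if algo == "lr":
        from sklearn.linear_model import LogisticRegression

        return LogisticRegression(max_iter=5000, random_state=seed)
    if algo == "svm":
        from sklearn.svm import SVC

        return SVC(probability=True, random_state=seed)
    raise ValueError(f"unknown classifier family {algo!r}; choose lr, svm or lgbm")


@dataclass
class DBPPModel:
    """A fitted drug-likeness classifier plus its preprocessing state."""

    classifier: object
    algo: str
    gamma: float
    pc_scaler: PCScaler
    threshold: float = DEFAULT_THRESHOLD
    panel: Optional[EndpointPanel] = None
    panel_ref: str = ""
    seed: int = 0
    grid_search_record: Optional[dict] = None

    # -- scoring ------------------------------------------------------------

    def predict_proba_matrix(self, X: np.ndarray) -> np.ndarray:
        """DBPP scores for stacked raw [PC | ADMET] rows (n, 26)."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != PROFILE_LENGTH:
            raise ValueError(f"expected (n, {PROFILE_LENGTH}) [PC | ADMET] matrix")
        pc_scaled = self.pc_scaler.transform(X[:, :N_PC])
        feats = weight_profile_matrix(pc_scaled, X[:, N_PC:], self.gamma)
        return self.classifier.predict_proba(feats)[:, 1]

    def profile_for_mol(self, mol) -> PropertyProfile:
        if self.panel is None:
            raise RuntimeError("model has no endpoint panel attached")
        pc = featurize.physchem_profile(mol)
        admet = self.panel.predict_mol(mol)
        return build_profile(pc, admet, self.gamma, self.pc_scaler)

    def score_mol(self, mol) -> float:
        if self.panel is None:
            raise RuntimeError("model has no endpoint panel attached")
        pc = featurize.physchem_profile(mol).as_array()[None, :]
        admet = self.panel.predict_mol(mol).values[None, :]
        return float(self.predict_proba_matrix(np.hstack([pc, admet]))[0])

    def score_mols(self, mols: Sequence) -> np.ndarray:
        if self.panel is None:
            raise RuntimeError("model has no endpoint panel attached")
        pc = featurize.physchem_matrix(mols)
        admet = self.panel.predict_mols(mols)
        return self.predict_proba_matrix(np.hstack([pc, admet]))

    # -- persistence ---------------------------------------------------------

    def manifest(self) -> dict:
        return {
            "algo": self.algo,
            "gamma": self.gamma,
            "threshold": self.threshold,
            "pc_scaler": self.pc_scaler.to_dict(),
            "panel_hash": self.panel_ref,
            "seed": self.seed,
            "grid_search": self.grid_search_record,
        }

    def save(self, path: Union[str, Path]) -> None:
        import joblib

        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        joblib.dump(self, path)
        path.with_suffix(".manifest.json").write_text(
            json.dumps(self.manifest(), indent=2)
        )

    @staticmethod
    def load(path: Union[str, Path]) -> "DBPPModel":
        import joblib

        return joblib.load(path)


def fit_profile_classifier(
    pc: np.ndarray,
    admet: np.ndarray,
    y,
    algo: str = "lgbm",
    gamma: float = DEFAULT_GAMMA,
    seed: int = 0,
    tune: bool = True,
    threshold: float = DEFAULT_THRESHOLD,
    panel: Optional[EndpointPanel] = None,
) -> DBPPModel:
    """Fit a DBPP classifier from raw PC and ADMET matrices.

    The PC min–max scaler is fitted here — on this training data only — and
    hyperparameters are selected by grid search over the pinned grid (3-fold
    internal CV) when ``tune`` is set.  Deterministic for a fixed seed.
    """
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("training data contains a single class")
    pc = np.asarray(pc, dtype=float)
    admet = np.asarray(admet, dtype=float)
    pc_scaler = PCScaler().fit(pc)
    feats = weight_profile_matrix(pc_scaler.transform(pc), admet, gamma)

    clf = _base_classifier(algo, seed)
    grid_record = None
    if tune:
        from sklearn.model_selection import GridSearchCV, StratifiedKFold

        gs = GridSearchCV(
            clf,
            GRIDS[algo],
            scoring="roc_auc",
            cv=StratifiedKFold(n_splits=3, shuffle=True, random_state=seed),
            n_jobs=1,
        )
        gs.fit(feats, y)
        clf = gs.best_estimator_
        grid_record = {
            "grid": GRIDS[algo],
            "best_params": gs.best_params_,
            "cv_scores": {
                str(p): float(s)
                for p, s in zip(
                    gs.cv_results_["params"], gs.cv_results_["mean_test_score"]
                )
            },
        }
    else:
        clf.fit(feats, y)

    model = DBPPModel(
        classifier=clf,
        algo=algo,
        gamma=gamma,
        pc_scaler=pc_scaler,
        threshold=threshold,
        panel=panel,
        panel_ref=panel.manifest_hash() if panel is not None else "",
        seed=seed,
        grid_search_record=grid_record,
    )
    return model


def train_dbpp(
    dataset: LabeledDataset,
    panel: EndpointPanel,
    algo: str = "lgbm",
    gamma: float = DEFAULT_GAMMA,
    seed: int = 0,
    tune: bool = True,
    threshold: float = DEFAULT_THRESHOLD,
) -> DBPPModel:
    """Train a drug-likeness model from standardized molecules + fitted panel."""
    mols = dataset.records
    pc = featurize.physchem_matrix(mols)
    admet = panel.predict_mols(mols)
    return fit_profile_classifier(
        pc, admet, dataset.labels, algo=algo, gamma=gamma, seed=seed,
        tune=tune, threshold=threshold, panel=panel,
    )


def dbpp_score(model: DBPPModel, mol) -> float:
    """Probability of the drug class for one accepted molecule."""
    return model.score_mol(mol)


def classify(score: float, threshold: float = DEFAULT_THRESHOLD) -> bool:
    """Druggability call: strictly greater than the threshold."""
    if not 0.0 <= score <= 1.0:
        raise ValueError("score must be in [0, 1]")
    return score > threshold


def derive_threshold(model: DBPPModel, reference_drugs: Sequence) -> float:
    """Re-derive the druggability threshold as a reference drug set's mean score."""
    return float(np.mean(model.score_mols(reference_drugs)))


def make_builder(algo: str = "lgbm", gamma: float = DEFAULT_GAMMA,
                 seed: int = 0, tune: bool = False):
    """A training recipe over stacked [PC | ADMET] arrays for `evaluate.kfold_cv`.

    PC scaling and (optionally) grid search are fitted inside each call, i.e.
    inside each CV training fold.
    """

    def builder(X: np.ndarray, y: np.ndarray) -> DBPPModel:
        X = np.asarray(X, dtype=float)
        return fit_profile_classifier(
            X[:, :N_PC], X[:, N_PC:], y, algo=algo, gamma=gamma,
            seed=seed, tune=tune,
        )

    return builder
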