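"""Classifier layer: image-CNN training/prediction and the descriptor-table
tree-ensemble baseline.

The image route trains the reference CNN (or any estimator honouring the
fit/predict_proba contract via the ``external`` hook) on per-image labels and
emits one probability per snapshot. The baseline route computes a numeric
molecular-descriptor table and evaluates random-forest / gradient-boosting
models over repeated seeded 1:1 train/test splits, reporting the AUC of each
repeat and their mean ± sd.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from PIL import Image
from rdkit import Chem
from rdkit.Chem import Descriptors, MACCSkeys, rdFingerprintGenerator
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import train_test_split
from xgboost import XGBClassifier

from .cnn import SmallCNNClassifier

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrainingConfig:
    """Image-classifier training hyperparameters.

    Defaults are the reference CNN's desk-scale operating point; restarts
    are independent seeded trainings of which the best by validation AUC is
    kept (monitor-and-select)."""

    lr: float = 0.003
    bs: int = 32
    epochs: int = 120
    seed: int = 0
    n_restarts: int = 3
    arch: str = "small_cnn"
    external_factory: Optional[Callable] = None

    def __post_init__(self):
        if self.lr <= 0:
            raise ValueError("lr must be positive")
        if self.bs < 1:
            raise ValueError("bs must be >= 1")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.arch not in ("small_cnn", "external"):
            raise ValueError(f"unknown arch {self.arch!r}")
        if self.arch == "external" and self.external_factory is None:
            raise ValueError("arch='external' requires external_factory")


@dataclass(frozen=True)
class BaselineConfig:
    """Tree-ensemble grid point: (model, max_depth, n_estimators, max_features).

    max_features is the number of features considered per split for RF and
    the per-tree column subsample count for XGB (recorded in output metadata).
    """

    model: str = "xgb"
    max_depth: int = 3
    n_estimators: int = 5000
    max_features: int = 60
    seed: int = 0

    def __post_init__(self):
        if self.model not in ("rf", "xgb"):
            raise ValueError(f"unknown model {self.model!r}")
        if min(self.max_depth, self.n_estimators, self.max_features) < 1:
            raise ValueError("grid fields must be >= 1")


# ---------------------------------------------------------------------------
# Image route
# ---------------------------------------------------------------------------

def load_images(manifest: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Load manifest image files into an (N, H, W, 3) uint8 array plus
    binary labels (1 = active)."""
    imgs = [np.asarray(Image.open(p).convert("RGB")) for p in manifest["path"]]
    X = np.stack(imgs) if imgs else np.zeros((0, 0, 0, 3), dtype=np.uint8)
    y = (manifest["label"].astype(str) == "active").astype(int).to_numpy()
    return X, y


def train_image_classifier(
    train_images: tuple[np.ndarray, np.ndarray],
    val_images: tuple[np.ndarray, np.ndarray],
    config: TrainingConfig = TrainingConfig(),
):
    """Train an image classifier on (X, y) train/validation image sets.

    Returns (model, history) where history holds the per-epoch training
    loss, validation loss and validation accuracy monitors. An untrained
    model (epochs=0) is returned with an empty history. Single-class
    training labels are rejected.
    """
    Xt, yt = train_images
    Xv, yv = val_images
    if len(Xt) == 0 or len(Xv) == 0:
        raise ValueError("training and validation sets must be nonempty")
    if len(np.unique(yt)) < 2:
        raise ValueError("training labels contain a single class")
    if config.arch == "external":
        model = config.external_factory()
        model.fit(Xt, yt)
        return model, getattr(model, "history_", {})
    model = SmallCNNClassifier(lr=config.lr, batch_size=config.bs,
                               epochs=config.epochs, seed=config.seed,
                               n_restarts=config.n_restarts)
    if config.epochs == 0:
        # untrained network: initialise weights only
        model.epochs = 0
        model.fit(Xt, yt, Xv, yv)
        return model, model.history_
    model.fit(Xt, yt, Xv, yv)
    return model, model.history_


def predict_images(model, manifest: pd.DataFrame, images: Optional[np.ndarray] = None) -> pd.DataFrame:
    """Score every manifest image; returns the prediction table
    (mol_id, rx, ry, rz, probability) with one row per image."""
    if images is None:
        images, _ = load_images(manifest)
    if len(images) == 0:
        return pd.DataFrame(columns=["mol_id", "rx", "ry", "rz", "probability"])
    proba = model.predict_proba(images)[:, 1]
    out = manifest[["mol_id", "rx", "ry", "rz"]].copy().reset_index(drop=True)
    out["probability"] = proba
    return out


# ---------------------------------------------------------------------------
# Descriptor-table baseline
# ---------------------------------------------------------------------------

_N_MORGAN_BITS = 256


def compute_descriptors(
    molecules: Sequence[tuple[str, str]],
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Numeric descriptor table for (mol_id, smiles) pairs.

    Columns are the RDKit 2D physicochemical descriptor set, the 167 MACCS
    structural keys and a 256-bit Morgan count fingerprint (radius 2) —
    a fixed schema of well over 500 numeric features per molecule. Columns
    containing non-finite values are median-imputed; all-missing columns are
    dropped and logged. Per-molecule failures are reported and the row
    dropped. Deterministic.
    """
    morgan = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=_N_MORGAN_BITS)
    rows, index, failures = [], [], []
    desc_names = [name for name, _ in Descriptors.descList]
    for mol_id, smiles in molecules:
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            failures.append((mol_id, "unparseable"))
            continue
        try:
            desc = Descriptors.CalcMolDescriptors(mol)
            vals = [float(desc[name]) for name in desc_names]
            maccs = list(MACCSkeys.GenMACCSKeys(mol))
            counts = morgan.GetCountFingerprintAsNumPy(mol).astype(float)
        except Exception as exc:
            failures.append((mol_id, str(exc)))
            continue
        rows.append(vals + [float(v) for v in maccs] + list(counts))
        index.append(mol_id)
    columns = (
        desc_names
        + [f"maccs_{i}" for i in range(167)]
        + [f"morgan_{i}" for i in range(_N_MORGAN_BITS)]
    )
    df = pd.DataFrame(rows, index=index, columns=columns, dtype=float)
    if len(df):
        bad = ~np.isfinite(df.to_numpy())
        if bad.any():
            all_bad = [c for c, flag in zip(df.columns, bad.all(axis=0)) if flag]
            if all_bad:
                logger.warning("dropping all-missing descriptor columns: %s", all_bad)
                df = df.drop(columns=all_bad)
            df = df.mask(~np.isfinite(df)).fillna(df.median(numeric_only=True))
    return df, failures


def _make_model(config: BaselineConfig, n_features: int, seed: int):
    if config.model == "rf":
        return RandomForestClassifier(
            max_depth=config.max_depth,
            n_estimators=config.n_estimators,
            max_features=min(config.max_features, n_features),
            random_state=seed,
            n_jobs=1,
        )
    return XGBClassifier(
        max_depth=config.max_depth,
        n_estimators=config.n_estimators,
        colsample_bytree=min(1.0, config.max_features / n_features),
        random_state=seed,
        tree_method="hist",
        n_jobs=1,
        eval_metric="logloss",
        verbosity=0,
    )


def train_tree_baseline(
    table: pd.DataFrame,
    labels: Sequence[int],
    config: BaselineConfig = BaselineConfig(),
    n_repeats: int = 5,
) -> dict:
    """Repeated 1:1 hold-out evaluation of an RF/XGB grid point.

    Each repeat draws a fresh seeded 1:1 split, fits the configured model on
    one half and scores AUC on the other. Degenerate (single-class) halves
    are redrawn with the next seed and logged. Returns per-repeat AUCs,
    their mean and sd, and metadata recording the max_features mapping.
    """
    X = table.to_numpy(dtype=float)
    y = np.asarray(labels, dtype=int)
    if len(X) < 4:
        raise ValueError("need at least 4 rows for a 1:1 split evaluation")
    if len(np.unique(y)) < 2:
        raise ValueError("labels contain a single class")
    aucs = []
    seed = config.seed
    for rep in range(n_repeats):
        while True:
            Xa, Xb, ya, yb = train_test_split(
                X, y, test_size=0.5, random_state=seed & 0x7FFFFFFF, shuffle=True
            )
            seed += 1
            if len(np.unique(ya)) == 2 and len(np.unique(yb)) == 2:
                break
            logger.warning("degenerate 1:1 split redrawn (repeat %d)", rep)
        model = _make_model(config, X.shape[1], seed & 0x7FFFFFFF)
        model.fit(Xa, ya)
        aucs.append(float(roc_auc_score(yb, model.predict_proba(Xb)[:, 1])))
    return {
        "aucs": aucs,
        "mean_auc": float(np.mean(aucs)),
        "sd_auc": float(np.std(aucs, ddof=1)) if len(aucs) > 1 else 0.0,
        "model": config.model,
        "max_depth": config.max_depth,
        "n_estimators": config.n_estimators,
        "max_features": config.max_features,
        "max_features_semantics": (
            "features per split" if config.model == "rf" else "per-tree column subsample count"
        ),
        "n_repeats": n_repeats,
    }
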