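"""Terminal-peptide stability (PSI) modelling.

Global Protein Stability (GPS) assays measure the stability conferred by a
protein's terminal 23-mer as a Protein Stability Index (PSI); low PSI means
an unstable peptide that likely carries a degron. This module featurizes
terminal 23-mers with sequence-derived physicochemical descriptors computed
over nested windows (the whole peptide and the terminal 10, 8, 6, 4 and 2
residues — for N termini the initiator methionine is excluded from the
windows whether or not it is present), trains one gradient-boosted regressor
per terminus kind (N with Met cleaved, N with Met retained, C), and maps
predicted PSI onto five stability categories cut at the 20/40/60/80th
percentiles of the training distribution.

:class:`PSIRegressor` is a scikit-learn estimator (``fit``/``predict``,
``get_params``/``set_params``, fitted attributes with a trailing underscore)
whose ``X`` is a sequence of peptide strings; the module-level functions
(:func:`train_psi`, :func:`predict_psi`, ...) are thin wrappers over it.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Callable, Iterable, List, Mapping, Optional, Sequence, Union

import joblib
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.ensemble import HistGradientBoostingRegressor
from sklearn.metrics import mean_squared_error, r2_score
from sklearn.model_selection import ShuffleSplit, cross_val_score, train_test_split

from Bio.SeqUtils import molecular_weight
from Bio.SeqUtils.IsoelectricPoint import IsoelectricPoint

from ._aa import CANONICAL_AA, CANONICAL_SET, gravy
from .seqio import ProteinRecord

logger = logging.getLogger(__name__)

TERMINAL_PEPTIDE_LENGTH = 23
WINDOW_SIZES = (10, 8, 6, 4, 2)
DEFAULT_CATEGORY_QUANTILES = (0.2, 0.4, 0.6, 0.8)
DEFAULT_TEST_SIZE = 0.1          # 90:10 train:test split
DEFAULT_CV_FOLDS = 5
DEFAULT_CV_VALIDATION_SIZE = 0.2

# Approximate human-proteome amino-acid frequencies (UniProt human averages),
# used by the synthetic generator so random peptides are composition-realistic.
_HUMAN_AA_FREQ = {
    "A": 0.070, "R": 0.056, "N": 0.036, "D": 0.047, "C": 0.023,
    "Q": 0.048, "E": 0.071, "G": 0.066, "H": 0.026, "I": 0.043,
    "L": 0.100, "K": 0.057, "M": 0.021, "F": 0.037, "P": 0.063,
    "S": 0.083, "T": 0.054, "W": 0.012, "Y": 0.027, "V": 0.060,
}


class TerminusKind(str, Enum):
    N_MET_CLEAVED = "n_met_cleaved"
    N_MET_RETAINED = "n_met_retained"
    C = "c"


class StabilityCategory(str, Enum):
    MOST_UNSTABLE = "most_unstable"
    UNSTABLE = "unstable"
    MEDIUM = "medium"
    STABLE = "stable"
    MOST_STABLE = "most_stable"


_CATEGORY_ORDER = (StabilityCategory.MOST_UNSTABLE, StabilityCategory.UNSTABLE,
                   StabilityCategory.MEDIUM, StabilityCategory.STABLE,
                   StabilityCategory.MOST_STABLE)


@dataclass(frozen=True)
class TerminalPeptide:
    protein_id: str
    terminus: TerminusKind
    peptide: str


@dataclass(frozen=True)
class TrainingReport:
    r2_test: float
    rmse_test: float
    n_train: int
    n_test: int
    cv_folds: int
    cv_r2_mean: Optional[float]
    split: tuple                    # (train fraction, test fraction)


@dataclass(frozen=True)
class PSIPrediction:
    psi: float
    category: StabilityCategory
    terminus: TerminusKind


# --- descriptors ------------------------------------------------------------

def _check_peptide(peptide: str) -> str:
    peptide = peptide.upper()
    bad = sorted(set(peptide) - CANONICAL_SET)
    if bad:
        raise ValueError(f"non-canonical residue(s) {','.join(bad)} in "
                         f"peptide {peptide!r}")
    if len(peptide) < 2:
        raise ValueError("peptide must have at least 2 residues")
    return peptide


def aliphatic_index(seq: str) -> float:
    """Relative volume of aliphatic side chains (Ikai 1980), 0-~390."""
    L = len(seq)
    xa = seq.count("A") / L
    xv = seq.count("V") / L
    xil = (seq.count("I") + seq.count("L")) / L
    return 100.0 * (xa + 2.9 * xv + 3.9 * xil)


from functools import lru_cache

_BASE_NAMES = (["len"] + [f"comp_{aa}" for aa in CANONICAL_AA]
               + ["gravy", "charge_ph7", "pi", "mw", "aromaticity",
                  "aliphatic_index"])


@lru_cache(maxsize=200_000)
def _base_descriptors(seq: str) -> tuple:
    # cached: short windows (2/4-mers) repeat heavily across a dataset
    vals = [float(len(seq))]
    vals += [seq.count(aa) / len(seq) for aa in CANONICAL_AA]
    ip = IsoelectricPoint(seq)
    vals += [gravy(seq), ip.charge_at_pH(7.0), ip.pi(),
             molecular_weight(seq, seq_type="protein"),
             sum(seq.count(a) for a in "FWY") / len(seq),
             aliphatic_index(seq)]
    return tuple(vals)


def _window_descriptors(seq: str, prefix: str) -> dict:
    return {f"{prefix}_{name}": val
            for name, val in zip(_BASE_NAMES, _base_descriptors(seq))}


def featurize_terminus(peptide: Union[TerminalPeptide, str],
                       terminus: Optional[TerminusKind] = None) -> dict:
    """Descriptor vector for a terminal peptide (pure, deterministic).

    Windows of 10/8/6/4/2 residues are taken from the relevant terminus; a
    window larger than the available residues uses what is there (the
    effective length is itself a feature). For N termini with a retained
    initiator Met, the windows exclude that Met.
    """
    if isinstance(peptide, TerminalPeptide):
        terminus = peptide.terminus
        seq = peptide.peptide
    else:
        if terminus is None:
            raise ValueError("terminus required when passing a bare string")
        seq = peptide
    terminus = TerminusKind(terminus)
    seq = _check_peptide(seq)

    feats = _window_descriptors(seq, "full")
    core = seq
    if terminus is TerminusKind.N_MET_RETAINED and seq.startswith("M") and len(seq) > 2:
        core = seq[1:]             # windows exclude the initiator Met
    for w in WINDOW_SIZES:
        if terminus is TerminusKind.C:
            window = core[-w:]
        else:
            window = core[:w]
        feats.update(_window_descriptors(window, f"w{w}"))
    return feats


def feature_names(terminus: TerminusKind = TerminusKind.C) -> List[str]:
    return list(featurize_terminus("A" * TERMINAL_PEPTIDE_LENGTH, terminus))


def _feature_matrix(peptides: Sequence[str], terminus: TerminusKind,
                    names: Optional[List[str]] = None):
    rows = [featurize_terminus(p, terminus) for p in peptides]
    if names is None:
        names = list(rows[0])
    return np.array([[r[n] for n in names] for r in rows]), names


# --- categories -------------------------------------------------------------

def categorize_psi(psi: float, quantiles: Sequence[float]) -> StabilityCategory:
    """Map a PSI value to a stability category given 4 monotone cut points.

    Bins are right-closed: psi <= q20 -> most_unstable, ... psi == q80 ->
    stable, psi > q80 -> most_stable. Degenerate cuts (all equal) map
    everything to medium with a warning.
    """
    q = list(quantiles)
    if len(q) != 4 or any(b < a for a, b in zip(q, q[1:])):
        raise ValueError("quantiles must be 4 non-decreasing cut points")
    if q[0] == q[3]:
        warnings.warn("degenerate PSI quantiles (all cuts equal); "
                      "category defaults to medium", stacklevel=2)
        return StabilityCategory.MEDIUM
    for cut, cat in zip(q, _CATEGORY_ORDER):
        if psi <= cut:
            return cat
    return StabilityCategory.MOST_STABLE


# --- estimator --------------------------------------------------------------

class PSIRegressor(BaseEstimator, RegressorMixin):
    """Gradient-boosted PSI regressor for one terminus kind.

    Parameters
    ----------
    terminus : str
        One of ``n_met_cleaved``, ``n_met_retained``, ``c``.
    test_size : float
        Held-out fraction for the training report (default 0.1, i.e. 90:10).
    cv_folds : int
        Number of random-permutation CV splits (default 5) with
        ``cv_validation_size`` validation fraction each.
    category_quantiles : tuple of float
        Quantile levels defining the five stability categories.
    random_state : int
        Seed for the split, CV and the boosted trees.
    max_iter, learning_rate, max_depth
        Passed to the sklearn HistGradientBoostingRegressor backend.
    """

    def __init__(self, terminus: str = "c", test_size: float = DEFAULT_TEST_SIZE,
                 cv_folds: int = DEFAULT_CV_FOLDS,
                 cv_validation_size: float = DEFAULT_CV_VALIDATION_SIZE,
                 category_quantiles: tuple = DEFAULT_CATEGORY_QUANTILES,
                 random_state: int = 42, max_iter: int = 300,
                 learning_rate: float = 0.1, max_depth: Optional[int] = None,
                 run_cv: bool = True):
        self.terminus = terminus
        self.test_size = test_size
        self.cv_folds = cv_folds
        self.cv_validation_size = cv_validation_size
        self.category_quantiles = category_quantiles
        self.random_state = random_state
        self.max_iter = max_iter
        self.learning_rate = learning_rate
        self.max_depth = max_depth
        self.run_cv = run_cv

    def _peptides(self, X) -> List[str]:
        out = []
        for x in X:
            if isinstance(x, TerminalPeptide):
                if TerminusKind(x.terminus) != TerminusKind(self.terminus):
                    raise ValueError(
                        f"mixed termini: peptide for {x.terminus} given to a "
                        f"{self.terminus} model")
                out.append(x.peptide)
            else:
                out.append(str(x))
        return out

    def fit(self, X, y):
        peptides = self._peptides(X)
        y = np.asarray(y, dtype=float)
        if len(peptides) < 50:
            raise ValueError(f"need >= 50 training rows, got {len(peptides)}")
        if len(peptides) != len(y):
            raise ValueError("X and y length mismatch")
        terminus = TerminusKind(self.terminus)
        Xm, names = _feature_matrix(peptides, terminus)
        X_tr, X_te, y_tr, y_te = train_test_split(
            Xm, y, test_size=self.test_size, random_state=self.random_state)

        reg = HistGradientBoostingRegressor(
            max_iter=self.max_iter, learning_rate=self.learning_rate,
            max_depth=self.max_depth, random_state=self.random_state)
        cv_mean = None
        if self.run_cv and self.cv_folds:
            cv = ShuffleSplit(n_splits=self.cv_folds,
                              test_size=self.cv_validation_size,
                              random_state=self.random_state)
            cv_mean = float(np.mean(
                cross_val_score(reg, X_tr, y_tr, cv=cv, scoring="r2")))
        reg.fit(X_tr, y_tr)
        pred = reg.predict(X_te)

        self.feature_names_ = names
        self.n_features_in_ = len(names)
        self.regressor_ = reg
        self.training_quantiles_ = tuple(
            float(np.quantile(y_tr, q)) for q in self.category_quantiles)
        self.report_ = TrainingReport(
            r2_test=float(r2_score(y_te, pred)),
            rmse_test=float(np.sqrt(mean_squared_error(y_te, pred))),
            n_train=len(y_tr), n_test=len(y_te),
            cv_folds=self.cv_folds if self.run_cv else 0, cv_r2_mean=cv_mean,
            split=(1.0 - self.test_size, self.test_size))
        return self

    def predict(self, X) -> np.ndarray:
        peptides = self._peptides(X)
        Xm, _ = _feature_matrix(peptides, TerminusKind(self.terminus),
                                names=self.feature_names_)
        return self.regressor_.predict(Xm)

    def predict_with_category(self, X) -> List[PSIPrediction]:
        terminus = TerminusKind(self.terminus)
        return [PSIPrediction(psi=float(p),
                              category=categorize_psi(p, self.training_quantiles_),
                              terminus=terminus)
                for p in self.predict(X)]

    def predict_record(self, record: ProteinRecord) -> PSIPrediction:
        """Slice a protein's relevant terminal 23-mer and predict its PSI."""
        return self.predict_with_category(
            [terminal_peptide(record, TerminusKind(self.terminus)).peptide])[0]


def terminal_peptide(record: ProteinRecord, terminus: TerminusKind,
                     length: int = TERMINAL_PEPTIDE_LENGTH) -> TerminalPeptide:
    """Extract the terminal peptide a PSI model scores.

    ``n_met_cleaved`` drops a leading initiator Met (if present) before
    taking the first ``length`` residues; ``n_met_retained`` keeps the
    sequence as given; ``c`` takes the last ``length`` residues. Shorter
    proteins are used whole (logged).
    """
    terminus = TerminusKind(terminus)
    seq = record.sequence
    if terminus is TerminusKind.C:
        pep = seq[-length:]
    elif terminus is TerminusKind.N_MET_CLEAVED:
        core = seq[1:] if seq.startswith("M") and len(seq) > 1 else seq
        pep = core[:length]
    else:
        pep = seq[:length]
    if len(pep) < 2:
        raise ValueError(f"{record.id}: terminus shorter than 2 residues")
    if len(pep) < length:
        logger.info("%s: terminal peptide truncated to %d available residues",
                    record.id, len(pep))
    return TerminalPeptide(protein_id=record.id, terminus=terminus, peptide=pep)


# --- wrappers, synthetic data, persistence ----------------------------------

def train_psi(dataset: pd.DataFrame, **params) -> PSIRegressor:
    """Train a PSI model from a table with columns ``peptide``, ``psi`` and
    (optionally) ``terminus``; keyword params go to :class:`PSIRegressor`."""
    for col in ("peptide", "psi"):
        if col not in dataset.columns:
            raise ValueError(f"dataset missing column {col!r}")
    if "terminus" in dataset.columns:
        termini = set(dataset["terminus"].astype(str))
        if len(termini) > 1:
            raise ValueError(f"mixed termini in dataset: {sorted(termini)}")
        params.setdefault("terminus", termini.pop())
    model = PSIRegressor(**params)
    return model.fit(list(dataset["peptide"]), dataset["psi"].to_numpy(float))


def predict_psi(model: PSIRegressor,
                query: Union[ProteinRecord, TerminalPeptide, str]) -> PSIPrediction:
    if isinstance(query, ProteinRecord):
        return model.predict_record(query)
    pep = query.peptide if isinstance(query, TerminalPeptide) else str(query)
    return model.predict_with_category([pep])[0]


def linear_gravy_effect(slope: float = 2.0, intercept: float = 0.0) -> Callable:
    """Effect spec: PSI is linear in the full-window Gravy of the peptide."""
    def effect(peptide: str, terminus: TerminusKind) -> float:
        return intercept + slope * gravy(peptide)
    return effect


def synthesize_psi_dataset(n: int, terminus: Union[TerminusKind, str] = TerminusKind.C,
                           effect_spec: Optional[Callable] = None,
                           seed: int = 0, noise_sigma: float = 0.1,
                           length: int = TERMINAL_PEPTIDE_LENGTH) -> pd.DataFrame:
    """Synthetic GPS-style training table of (peptide, PSI) pairs.

    Peptides are random 23-mers drawn from human-proteome amino-acid
    frequencies (N-Met-retained peptides start with M); PSI is
    ``effect_spec(peptide, terminus)`` (default: linear in Gravy, slope 2)
    plus Gaussian noise. Fully reproducible under ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    terminus = TerminusKind(terminus)
    effect = effect_spec or linear_gravy_effect()
    rng = np.random.default_rng(seed)
    letters = np.array(list(_HUMAN_AA_FREQ))
    probs = np.array(list(_HUMAN_AA_FREQ.values()))
    probs = probs / probs.sum()
    rows = []
    for i in range(n):
        body_len = length - 1 if terminus is TerminusKind.N_MET_RETAINED else length
        pep = "".join(rng.choice(letters, size=body_len, p=probs))
        if terminus is TerminusKind.N_MET_RETAINED:
            pep = "M" + pep
        psi = effect(pep, terminus) + rng.normal(0.0, noise_sigma)
        rows.append({"protein_id": f"synth{i:05d}", "terminus": terminus.value,
                     "peptide": pep, "psi": psi})
    return pd.DataFrame(rows)


def load_gps_table(path) -> pd.DataFrame:
    """Load a GPS-style stability TSV (protein_id, terminus, peptide, psi)."""
    df = pd.read_csv(path, sep="\t", dtype={"peptide": str})
    missing = [c for c in ("peptide", "psi") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {','.join(missing)}")
    df["psi"] = df["psi"].astype(float)
    return df


def save_model(model: PSIRegressor, path) -> None:
    joblib.dump({"format": "degronkit-psi-v1", "model": model}, path)


def load_model(path) -> PSIRegressor:
    blob = joblib.load(path)
    if not isinstance(blob, dict) or blob.get("format") != "degronkit-psi-v1":
        raise ValueError(f"{path} is not a degronkit PSI model file")
    return blob["model"]
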