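"""Peptide-MHC binding affinity prediction.

Peptides are encoded QSAR-style: each residue is replaced by a short vector
of principal-component scores of amino-acid physicochemical properties and
the position vectors are concatenated.  Per allele, a bagged ensemble of
regressors is trained on Ln(ic50 nM): many candidates are fitted on bootstrap
resamples, ranked by out-of-bag generalization, and the best subset kept.
Predictions report the ensemble mean and standard deviation of Ln(ic50).

The predictor is pluggable: anything exposing ``allele``, ``width`` and
``predict_batch(peptides) -> (mean, sd)`` can stand in for the ensemble.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Protocol, Sequence, runtime_checkable

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import Ridge
from sklearn.neural_network import MLPRegressor

from .motif_core import AMINO_ACIDS, ProteinRecord, SequenceError, is_clean, window_peptides

# Physicochemical property table: one row per residue.
# Columns: Kyte-Doolittle hydropathy; residue volume (A^3); residue mass (Da);
# Grantham polarity; isoelectric point; Chou-Fasman helix propensity;
# Chou-Fasman sheet propensity; net side-chain charge at pH 7.
PROPERTY_NAMES = (
    "hydropathy", "volume", "mass", "polarity",
    "isoelectric_point", "helix_propensity", "sheet_propensity", "charge",
)
PROPERTY_TABLE: dict[str, tuple[float, ...]] = {
    "A": (1.8, 88.6, 71.08, 8.1, 6.00, 1.42, 0.83, 0.0),
    "C": (2.5, 108.5, 103.14, 5.5, 5.07, 0.70, 1.19, 0.0),
    "D": (-3.5, 111.1, 115.09, 13.0, 2.77, 1.01, 0.54, -1.0),
    "E": (-3.5, 138.4, 129.12, 12.3, 3.22, 1.51, 0.37, -1.0),
    "F": (2.8, 189.9, 147.18, 5.2, 5.48, 1.13, 1.38, 0.0),
    "G": (-0.4, 60.1, 57.05, 9.0, 5.97, 0.57, 0.75, 0.0),
    "H": (-3.2, 153.2, 137.14, 10.4, 7.59, 1.00, 0.87, 0.1),
    "I": (4.5, 166.7, 113.16, 5.2, 6.02, 1.08, 1.60, 0.0),
    "K": (-3.9, 168.6, 128.17, 11.3, 9.74, 1.16, 0.74, 1.0),
    "L": (3.8, 166.7, 113.16, 4.9, 5.98, 1.21, 1.30, 0.0),
    "M": (1.9, 162.9, 131.19, 5.7, 5.74, 1.45, 1.05, 0.0),
    "N": (-3.5, 114.1, 114.10, 11.6, 5.41, 0.67, 0.89, 0.0),
    "P": (-1.6, 112.7, 97.12, 8.0, 6.30, 0.57, 0.55, 0.0),
    "Q": (-3.5, 143.8, 128.13, 10.5, 5.65, 1.11, 1.10, 0.0),
    "R": (-4.5, 173.4, 156.19, 10.5, 10.76, 0.98, 0.93, 1.0),
    "S": (-0.8, 89.0, 87.08, 9.2, 5.68, 0.77, 0.75, 0.0),
    "T": (-0.7, 116.1, 101.10, 8.6, 5.60, 0.83, 1.19, 0.0),
    "V": (4.2, 140.0, 99.13, 5.9, 5.96, 1.06, 1.70, 0.0),
    "W": (-0.9, 227.8, 186.21, 5.4, 5.89, 1.08, 1.37, 0.0),
    "Y": (-1.3, 193.6, 163.18, 6.2, 5.66, 0.69, 1.47, 0.0),
}


@dataclass
class AminoAcidDescriptors:
    """Per-residue principal-component score vectors (unit variance each)."""

    vectors: dict[str, np.ndarray]
    n_components: int
    loadings: np.ndarray  # (n_properties, n_components), orthonormal columns

    def matrix(self) -> np.ndarray:
        return np.vstack([self.vectors[aa] for aa in AMINO_ACIDS])


def compute_descriptors(
    property_table: dict[str, Sequence[float]] | None = None,
    n_components: int = 3,
) -> AminoAcidDescriptors:
    """PCA of the standardized property table; sign-fixed, whitened scores.

    Columns are z-scored across the 20 residues before the eigendecomposition;
    scores are scaled to unit variance per component and each component's
    sign is fixed so its largest-magnitude loading is positive.
    """
    table = PROPERTY_TABLE if property_table is None else property_table
    missing = [aa for aa in AMINO_ACIDS if aa not in table]
    if missing:
        raise ValueError(f"property table missing residues: {missing}")
    X = np.array([table[aa] for aa in AMINO_ACIDS], dtype=float)
    if X.shape[1] < n_components:
        raise ValueError(
            f"need >= {n_components} properties, table has {X.shape[1]}"
        )
    sd = X.std(axis=0)
    if (sd == 0).any():
        raise ValueError("constant property column")
    Xs = (X - X.mean(axis=0)) / sd
    # deterministic full SVD (sklearn's randomized solver is avoided on purpose)
    U, S, Vt = np.linalg.svd(Xs, full_matrices=False)
    keep = slice(0, n_components)
    loadings = Vt[keep].T
    scores = U[:, keep] * S[keep]
    # unit variance per component
    scores = scores / scores.std(axis=0)
    # sign convention: largest-magnitude loading positive
    for j in range(n_components):
        k = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[k, j] < 0:
            loadings[:, j] *= -1.0
            scores[:, j] *= -1.0
    vectors = {aa: scores[i].copy() for i, aa in enumerate(AMINO_ACIDS)}
    return AminoAcidDescriptors(vectors, n_components, loadings)


def encode_peptide(peptide: str, descriptors: AminoAcidDescriptors) -> np.ndarray:
    """Concatenated per-position descriptor vectors (length = width * d)."""
    if not is_clean(peptide):
        raise SequenceError(f"cannot encode ambiguous peptide {peptide!r}")
    return np.concatenate([descriptors.vectors[aa] for aa in peptide])


def encode_peptides(peptides: Sequence[str], descriptors: AminoAcidDescriptors) -> np.ndarray:
    return np.vstack([encode_peptide(p, descriptors) for p in peptides])


@dataclass(frozen=True)
class TrainingExample:
    allele: str
    peptide: str
    ic50_nM: float

    def __post_init__(self):
        if self.ic50_nM <= 0:
            raise ValueError(f"ic50 must be positive, got {self.ic50_nM}")
        if len(self.peptide) not in (9, 15) or not is_clean(self.peptide):
            raise SequenceError(f"peptide must be a clean 9mer or 15mer: {self.peptide!r}")


@dataclass
class BindingPrediction:
    allele: str
    peptide: str
    mean_ln_ic50: float
    sd_ln_ic50: float


@runtime_checkable
class BindingPredictor(Protocol):
    allele: str
    width: int

    def predict_batch(self, peptides: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
        """(ensemble mean, ensemble sd) of Ln(ic50) per peptide."""
        ...


def _make_learner(kind: str, random_state: int):
    if kind == "mlp":
        return MLPRegressor(
            hidden_layer_sizes=(16,),
            solver="lbfgs",
            alpha=1e-3,
            max_iter=500,
            random_state=random_state,
        )
    if kind == "ridge":
        return Ridge(alpha=1.0, random_state=random_state)
    raise ValueError(f"unknown base learner {kind!r}")


@dataclass
class EnsembleModel:
    """Bagged regressor ensemble for one allele and one peptide width."""

    allele: str
    width: int
    members: list = field(repr=False, default_factory=list)
    descriptors: AminoAcidDescriptors = None
    selection_stats: list[dict] = field(default_factory=list)
    seed: int = 0
    base_learner: str = "mlp"

    def predict_batch(self, peptides: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
        bad = [p for p in peptides if len(p) != self.width]
        if bad:
            raise ValueError(
                f"model for {self.width}mers got peptides of other widths: {bad[:3]}"
            )
        X = encode_peptides(peptides, self.descriptors)
        preds = np.vstack([m.predict(X) for m in self.members])
        # population convention: sd over the fixed member set
        return preds.mean(axis=0), preds.std(axis=0, ddof=0)

    def predict(self, peptide: str) -> BindingPrediction:
        mean, sd = self.predict_batch([peptide])
        return BindingPrediction(self.allele, peptide, float(mean[0]), float(sd[0]))


def train_ensemble(
    examples: Sequence[TrainingExample],
    n_candidates: int = 300,
    n_keep: int = 25,
    seed: int = 0,
    base_learner: str = "mlp",
    min_examples: int = 200,
    descriptors: AminoAcidDescriptors | None = None,
) -> EnsembleModel:
    """Bagging with out-of-bag selection.

    ``n_candidates`` regressors are each trained on an n-of-n bootstrap
    resample of the Ln(ic50) targets; candidates are ranked by out-of-bag
    RMSE (R^2 tie-break) and the best ``n_keep`` form the working ensemble.
    Deterministic given ``seed``.
    """
    examples = list(examples)
    if len(examples) < min_examples:
        raise ValueError(
            f"training refused: {len(examples)} examples < floor of {min_examples}"
        )
    alleles = {e.allele for e in examples}
    if len(alleles) != 1:
        raise ValueError(f"one allele per ensemble, got {sorted(alleles)}")
    widths = {len(e.peptide) for e in examples}
    if len(widths) != 1:
        raise ValueError(f"one peptide width per ensemble, got {sorted(widths)}")
    (allele,), (width,) = alleles, widths
    if n_keep > n_candidates:
        raise ValueError("n_keep cannot exceed n_candidates")

    desc = descriptors or compute_descriptors()
    X = encode_peptides([e.peptide for e in examples], desc)
    y = np.log([e.ic50_nM for e in examples])
    n = len(examples)
    rng = np.random.default_rng(seed)

    candidates = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        candidates = _fit_candidates(X, y, n, n_candidates, base_learner, rng)

    candidates.sort(key=lambda t: (t[0], t[1], t[2]))
    kept = candidates[:n_keep]
    stats = [{"candidate": i, "oob_rmse": rmse, "oob_r2": -negr2}
             for rmse, negr2, i, _ in kept]
    return EnsembleModel(
        allele=allele, width=width,
        members=[lrn for *_, lrn in kept],
        descriptors=desc, selection_stats=stats,
        seed=seed, base_learner=base_learner,
    )


def _fit_candidates(X, y, n, n_candidates, base_learner, rng):
    candidates = []
    for i in range(n_candidates):
        boot = rng.integers(0, n, size=n)
        oob = np.setdiff1d(np.arange(n), boot)
        learner = _make_learner(base_learner, random_state=int(rng.integers(2**31 - 1)))
        learner.fit(X[boot], y[boot])
        if oob.size:
            resid = learner.predict(X[oob]) - y[oob]
            rmse = float(np.sqrt(np.mean(resid**2)))
            denom = float(np.var(y[oob]))
            r2 = 1.0 - float(np.mean(resid**2)) / denom if denom > 0 else 0.0
        else:  # tiny-n corner: no OOB points, fall back to training error
            resid = learner.predict(X) - y
            rmse, r2 = float(np.sqrt(np.mean(resid**2))), 0.0
        candidates.append((rmse, -r2, i, learner))
    return candidates


def predict_protein(
    model: BindingPredictor, protein: ProteinRecord, width: int
) -> list[BindingPrediction]:
    """One prediction per clean window; ready for within-protein Zscaling."""
    if width != model.width:
        raise ValueError(f"model predicts {model.width}mers, asked for width {width}")
    windows = window_peptides(protein, width)
    if not windows:
        return []
    peptides = [w.peptide for w in windows]
    mean, sd = model.predict_batch(peptides)
    return [
        BindingPrediction(model.allele, p, float(m), float(s))
        for p, m, s in zip(peptides, mean, sd)
    ]
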