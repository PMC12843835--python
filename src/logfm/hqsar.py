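"""Fingerprint-based atomic contributions to log FM (HQSAR-style).

A partial-least-squares model regresses log FM on folded circular
(Morgan) fingerprint bits — 2048 bits, radius 2, chirality included by
default — after a variance/support pre-selection. Each retained bit's
regression weight is then mapped back onto the atoms of the substructure
environments that set the bit, giving signed per-atom contributions whose
sum reproduces (prediction − intercept) exactly. Positive atoms promote
placental transfer, negative atoms restrict it.

Randomness (the outer 75/25 split and the inner 5-fold CV used to choose
the component count) is always an explicit seed argument.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import KFold

from .errors import ValidationError

__all__ = [
    "FingerprintRecord", "HqsarModel", "AtomContributionMap",
    "morgan_fingerprint", "fingerprint_matrix", "preselect_bits",
    "pls_fit", "cross_validate", "atom_contributions",
]


@dataclass
class FingerprintRecord:
    """Folded circular fingerprint with the full bit→environment trace."""

    compound_id: str
    bits: np.ndarray                       # uint8, length nbits
    bit_envs: dict[int, list[tuple[int, int]]]  # bit -> [(center atom, radius)]
    mol: Chem.Mol
    nbits: int = 2048
    radius: int = 2
    chirality: bool = True


@dataclass
class HqsarModel:
    """PLS regression of log FM on pre-selected fingerprint bits.

    ``weights`` are the regression coefficients in the raw-bit linear form
    y ≈ intercept + Σ_j weights[j]·bit_j over the selected bits;
    ``training_mean`` is the mean response of the training set.
    """

    n_components: int
    selected_bits: np.ndarray       # sorted indices into the 2048-bit space
    weights: np.ndarray             # aligned with selected_bits
    intercept: float
    training_mean: float
    nbits: int = 2048
    radius: int = 2
    chirality: bool = True
    q2_cv: float | None = None
    split_record: dict | None = None

    def predict_bits(self, B: np.ndarray) -> np.ndarray:
        """Predict from a full-width (n, nbits) or selected-width matrix."""
        B = np.asarray(B, dtype=float)
        if B.shape[1] == self.nbits:
            B = B[:, self.selected_bits]
        return self.intercept + B @ self.weights


@dataclass
class AtomContributionMap:
    """Signed per-heavy-atom weights (log FM units) for one compound."""

    compound_id: str
    contributions: np.ndarray
    intercept: float
    prediction: float


def morgan_fingerprint(mol: Chem.Mol, compound_id: str = "", nbits: int = 2048,
                       radius: int = 2, chirality: bool = True) -> FingerprintRecord:
    """Folded circular fingerprint with bit→(center, radius) environments."""
    gen = rdFingerprintGenerator.GetMorganGenerator(
        radius=radius, fpSize=nbits, includeChirality=chirality)
    ao = rdFingerprintGenerator.AdditionalOutput()
    ao.AllocateBitInfoMap()
    fp = gen.GetFingerprint(mol, additionalOutput=ao)
    bits = np.zeros(nbits, dtype=np.uint8)
    bits[list(fp.GetOnBits())] = 1
    envs = {int(b): [(int(a), int(r)) for a, r in info]
            for b, info in ao.GetBitInfoMap().items()}
    return FingerprintRecord(compound_id, bits, envs, mol, nbits, radius, chirality)


def fingerprint_matrix(records: list[FingerprintRecord]) -> np.ndarray:
    if not records:
        raise ValidationError("no fingerprint records")
    return np.vstack([r.bits for r in records]).astype(float)


def preselect_bits(B: np.ndarray, min_fraction: float = 0.05) -> np.ndarray:
    """Indices of bits kept for modelling.

    Drops zero-variance bits (all-zero or all-one columns) and bits set in
    fewer than ``min_fraction`` of compounds. Raises when nothing survives.
    """
    B = np.asarray(B)
    if B.size == 0:
        raise ValidationError("empty bit matrix")
    support = B.mean(axis=0)
    keep = (support > 0) & (support < 1) & (support >= min_fraction)
    idx = np.flatnonzero(keep)
    if idx.size == 0:
        raise ValidationError(
            "pre-selection removed every bit; lower min_fraction")
    return idx


def pls_fit(B: np.ndarray, y, n_components: int,
            selected_bits: np.ndarray | None = None, nbits: int = 2048,
            radius: int = 2, chirality: bool = True) -> HqsarModel:
    """NIPALS partial least squares of log FM on fingerprint bits.

    ``B`` is the (n, k) matrix of the selected bits (unscaled 0/1 columns;
    the response and predictors are mean-centered internally). The fitted
    model is re-expressed in the raw-bit linear form so per-bit weights are
    directly attributable to substructures.
    """
    B = np.asarray(B, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.ptp(y) == 0:
        raise ValidationError("response has zero variance")
    n, k = B.shape
    if not (1 <= n_components <= min(n - 1, k)):
        raise ValidationError(
            f"n_components must be in [1, min(n-1, k)] = "
            f"[1, {min(n - 1, k)}], got {n_components}")
    pls = PLSRegression(n_components=n_components, scale=False)
    pls.fit(B, y.reshape(-1, 1))
    weights = pls.coef_.ravel().astype(float)
    # affine constant of the raw-bit linear form y = intercept + B @ w
    intercept = float(y.mean() - B.mean(axis=0) @ weights)
    if selected_bits is None:
        selected_bits = np.arange(k)
    return HqsarModel(
        n_components=n_components,
        selected_bits=np.asarray(selected_bits, dtype=int),
        weights=weights,
        intercept=intercept,
        training_mean=float(y.mean()),
        nbits=nbits, radius=radius, chirality=chirality,
    )


def _q2(y_true, y_pred, ref_mean) -> float:
    y_true = np.asarray(y_true, dtype=float)
    press = float(np.sum((y_true - y_pred) ** 2))
    sstot = float(np.sum((y_true - ref_mean) ** 2))
    return 1.0 - press / sstot


def cross_validate(B: np.ndarray, y, folds: int = 5, test_fraction: float = 0.25,
                   seed: int = 0, max_components: int = 10,
                   nbits: int = 2048) -> tuple[float, int, HqsarModel]:
    """Outer seeded 75/25 split with inner k-fold component selection.

    The training portion is cross-validated fold-wise for each candidate
    component count (1 … ``max_components``, capped by rank limits); the
    count maximizing the cross-validated q² is kept, the model refitted on
    the whole training portion, and the held-out q² on the remaining 25%
    reported. Returns ``(q2_holdout, n_components, model)``.
    """
    B = np.asarray(B, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_test = max(1, int(round(test_fraction * n)))
    test_idx, train_idx = perm[:n_test], perm[n_test:]
    if folds > len(train_idx):
        raise ValidationError(
            f"{folds} folds exceed {len(train_idx)} training rows")

    Btr, ytr = B[train_idx], y[train_idx]
    cap = min(max_components, len(train_idx) - 1 - (len(train_idx) - 1) // folds,
              Btr.shape[1])
    cap = max(cap, 1)
    kf = KFold(n_splits=folds, shuffle=True,
               random_state=int(rng.integers(2 ** 31 - 1)))
    splits = list(kf.split(Btr))
    best_q2, best_nc = -np.inf, 1
    for nc in range(1, cap + 1):
        press = sstot = 0.0
        ok = True
        for tr, va in splits:
            if nc > min(len(tr) - 1, Btr.shape[1]):
                ok = False
                break
            m = pls_fit(Btr[tr], ytr[tr], nc, nbits=nbits)
            pred = m.predict_bits(Btr[va])
            press += float(np.sum((ytr[va] - pred) ** 2))
            sstot += float(np.sum((ytr[va] - ytr[tr].mean()) ** 2))
        if not ok:
            break
        q2 = 1.0 - press / sstot
        if q2 > best_q2:
            best_q2, best_nc = q2, nc

    model = pls_fit(Btr, ytr, best_nc, nbits=nbits)
    model.q2_cv = best_q2
    model.split_record = {
        "seed": seed, "folds": folds,
        "train_idx": train_idx.tolist(), "test_idx": test_idx.tolist(),
    }
    q2_hold = _q2(y[test_idx], model.predict_bits(B[test_idx]), ytr.mean())
    return q2_hold, best_nc, model


def _environment_atoms(mol: Chem.Mol, center: int, radius: int) -> list[int]:
    if radius == 0:
        return [center]
    bond_ids = Chem.FindAtomEnvironmentOfRadiusN(mol, radius, center)
    atoms = {center}
    for b in bond_ids:
        bond = mol.GetBondWithIdx(b)
        atoms.add(bond.GetBeginAtomIdx())
        atoms.add(bond.GetEndAtomIdx())
    return sorted(atoms)


def atom_contributions(model: HqsarModel, fp: FingerprintRecord) -> AtomContributionMap:
    """Distribute per-bit regression weights onto heavy atoms.

    Each set, selected bit's weight is split equally across its environment
    occurrences and, within each environment, equally across the atoms the
    environment covers (hydrogens are implicit and fold into their heavy
    neighbor). Per-atom weights sum over bits, so the total equals
    prediction − intercept by construction.
    """
    if (fp.nbits, fp.radius, fp.chirality) != (model.nbits, model.radius, model.chirality):
        raise ValidationError(
            "fingerprint parameters do not match the model "
            f"(record {fp.nbits}/{fp.radius}/chirality={fp.chirality}, "
            f"model {model.nbits}/{model.radius}/chirality={model.chirality})")
    contrib = np.zeros(fp.mol.GetNumAtoms())
    weight_of = dict(zip(model.selected_bits.tolist(), model.weights))
    for bit, envs in fp.bit_envs.items():
        w = weight_of.get(bit)
        if w is None or not fp.bits[bit]:
            continue
        w_env = w / len(envs)
        for center, radius in envs:
            atoms = _environment_atoms(fp.mol, center, radius)
            share = w_env / len(atoms)
            for a in atoms:
                contrib[a] += share
    prediction = model.intercept + float(contrib.sum())
    return AtomContributionMap(fp.compound_id, contrib, model.intercept, prediction)
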