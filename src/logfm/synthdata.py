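"""Synthetic study generators.

Two generators make every model in the package testable without any
download:

* :func:`gen_reference_table` emulates a reference table of compounds with
  experimental log FM: descriptor marginals spanning realistic ranges
  (drug-like Lipinski rate, heteroatom counts of small drug-like
  molecules, Caco-2 log-permeabilities around −5, volumes of distribution
  around 0.3 log L/kg, unbound fractions across the percent scale), a
  configurable block of collinear nuisance columns, and a response drawn
  from a known linear model plus Gaussian noise. The generating
  coefficients default to the placental-transfer model ``EQ1`` and the
  noise standard deviation to 0.18 log units, matching the magnitude of
  the reference fit's training error.

* :func:`gen_fixture_molecules` emits small, parseable molecule libraries:
  a functional-group panel tagged by hydroxyl/carbonyl/nitro/halogen/
  polycyclic features (the fragment classes with known transfer-promoting
  or -restricting roles) and a matched series of 4-hydroxy vs 4-acetoxy
  N,N-dialkyltryptamine pairs differing at exactly one substitution site.

Every generated dataset carries its own ground truth; regeneration with
the same seed is bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem

from .errors import ValidationError
from .models import EQ1, ModelCoefficients

__all__ = [
    "SyntheticStudy", "FixtureMolecule", "gen_reference_table",
    "gen_fixture_molecules", "panel_response", "PANEL_EFFECTS",
]


@dataclass
class SyntheticStudy:
    """A generated descriptor table with its recorded ground truth."""

    table: pd.DataFrame
    truth: ModelCoefficients
    sigma: float
    seed: int
    nuisance: dict = field(default_factory=dict)

    @property
    def descriptor_names(self) -> tuple[str, ...]:
        return self.truth.descriptor_names

    @property
    def X(self) -> pd.DataFrame:
        return self.table[list(self.truth.descriptor_names)]

    @property
    def y(self) -> np.ndarray:
        return self.table["logFM"].to_numpy()


def gen_reference_table(n: int = 55, coeffs: ModelCoefficients = EQ1,
                        sigma: float = 0.18, seed: int = 0,
                        n_nuisance: int = 5,
                        nuisance_corr: float = 0.5) -> SyntheticStudy:
    """Generate a synthetic reference table of ``n`` compounds.

    Marginals: Lipinski ~ Bernoulli(0.8); nHet ~ integer uniform [5, 40];
    caco2 ~ Normal(−5.0, 0.5); logVDss ~ Normal(0.3, 0.6);
    Fu ~ Uniform(1, 95). Nuisance columns are standard-normal noise given
    correlation ``nuisance_corr`` to the true columns in rotation. The
    response is the linear model plus Normal(0, sigma) noise.
    """
    if n < 10:
        raise ValidationError(f"need n >= 10, got {n}")
    if sigma < 0:
        raise ValidationError(f"sigma must be non-negative, got {sigma}")
    rng = np.random.default_rng(seed)
    cols = {
        "Lipinski": rng.binomial(1, 0.8, n).astype(float),
        "nHet": rng.integers(5, 41, n).astype(float),
        "caco2": rng.normal(-5.0, 0.5, n),
        "logVDss": rng.normal(0.3, 0.6, n),
        "Fu": rng.uniform(1.0, 95.0, n),
    }
    missing = set(coeffs.descriptor_names) - set(cols)
    if missing:
        raise ValidationError(
            f"no sampling marginal for descriptors {sorted(missing)}")

    base_names = list(coeffs.descriptor_names)
    for k in range(n_nuisance):
        anchor = cols[base_names[k % len(base_names)]]
        z = (anchor - anchor.mean()) / (anchor.std() or 1.0)
        cols[f"noise{k + 1}"] = (nuisance_corr * z
                                 + np.sqrt(1 - nuisance_corr ** 2) * rng.normal(size=n))

    y = coeffs.intercept + sum(
        b * cols[name] for name, b in coeffs.coefficients.items()
    ) + rng.normal(0.0, sigma, n)

    table = pd.DataFrame({"compound_id": [str(i + 1) for i in range(n)], **cols,
                          "logFM": y})
    return SyntheticStudy(
        table=table, truth=coeffs, sigma=sigma, seed=seed,
        nuisance={"count": n_nuisance, "correlation": nuisance_corr},
    )


@dataclass(frozen=True)
class FixtureMolecule:
    compound_id: str
    smiles: str
    tags: frozenset
    pair_id: str | None = None
    series: str | None = None


_PANEL_SMILES = [
    # hydroxyl-bearing
    "Oc1ccccc1", "OC1CCCCC1", "OCc1ccccc1", "CCCCO", "CC(C)O",
    "Cc1ccc(O)cc1", "OCCO", "OCCc1ccc(O)cc1",
    # carbonyl-bearing
    "CC(=O)c1ccccc1", "O=C1CCCCC1", "CCC(C)=O", "O=Cc1ccccc1",
    "COC(C)=O", "CC(C)=O",
    # nitro-bearing
    "O=[N+]([O-])c1ccccc1", "Cc1ccc(cc1)[N+](=O)[O-]",
    "CCC[N+](=O)[O-]", "Oc1ccc(cc1)[N+](=O)[O-]", "C[N+](=O)[O-]",
    "Nc1ccc(cc1)[N+](=O)[O-]",
    # halogenated
    "Clc1ccccc1", "Brc1ccccc1", "CCCCCl", "Fc1ccccc1", "Cc1ccc(Br)cc1",
    "ClCCl", "CCI", "Clc1ccccc1Cl",
    # polycyclic
    "c1ccc2ccccc2c1", "C1CCC2CCCCC2C1", "C1Cc2ccccc2C1",
    "c1ccc2ncccc2c1", "C1C2CC3CC1CC(C2)C3", "C1CCc2ccccc2C1", "C1CC2CCC1C2",
    # untagged scaffolds
    "CCCCCC", "Cc1ccccc1", "c1ccncc1", "COc1ccccc1", "CCc1ccccc1",
    "C1CCCCC1", "CCOCC", "CCNCC",
]

_TAG_SMARTS = {
    "hydroxyl": "[OX2H]",
    "carbonyl": "[CX3]=[OX1]",
    "nitro": "[N+](=O)[O-]",
    "halogen": "[F,Cl,Br,I]",
}

#: ground-truth effect of each tag on the panel response (log FM units)
PANEL_EFFECTS = {
    "hydroxyl": 0.35,
    "carbonyl": 0.35,
    "nitro": 0.30,
    "halogen": -0.45,
    "polycyclic": -0.25,
}


def _tags(mol: Chem.Mol) -> frozenset:
    tags = set()
    for name, smarts in _TAG_SMARTS.items():
        if mol.HasSubstructMatch(Chem.MolFromSmarts(smarts)):
            tags.add(name)
    if mol.GetRingInfo().NumRings() >= 2:
        tags.add("polycyclic")
    return frozenset(tags)


_DIALKYL = [
    ("methyl", "C", "methyl", "C"),
    ("ethyl", "CC", "ethyl", "CC"),
    ("propyl", "CCC", "propyl", "CCC"),
    ("isopropyl", "CC(C)", "isopropyl", "C(C)C"),
    ("methyl", "C", "ethyl", "CC"),
    ("methyl", "C", "propyl", "CCC"),
    ("ethyl", "CC", "propyl", "CCC"),
]


def gen_fixture_molecules(kind: str) -> list[FixtureMolecule]:
    """Fixture libraries; ``kind`` is ``"functional-group-panel"`` or
    ``"matched-series"`` (4-OH vs 4-AcO dialkyltryptamine pairs)."""
    out: list[FixtureMolecule] = []
    if kind == "functional-group-panel":
        for i, smi in enumerate(_PANEL_SMILES, 1):
            mol = Chem.MolFromSmiles(smi)
            if mol is None:
                raise ValidationError(f"panel SMILES failed to parse: {smi}")
            out.append(FixtureMolecule(f"P{i:02d}", smi, _tags(mol)))
        return out
    if kind == "matched-series":
        for i, (n1, r1, n2, r2) in enumerate(_DIALKYL, 1):
            core = f"N({r2})CCc1c[nH]c2cccc(%s)c12"
            oh = r1 + core % "O"
            aco = r1 + core % "OC(C)=O"
            label = f"{n1},{n2}"
            for smi, series in ((oh, "4-OH"), (aco, "4-AcO")):
                mol = Chem.MolFromSmiles(smi)
                if mol is None:
                    raise ValidationError(f"series SMILES failed to parse: {smi}")
                out.append(FixtureMolecule(
                    f"S{i:02d}-{series}", smi, _tags(mol),
                    pair_id=f"S{i:02d}", series=series))
        return out
    raise ValidationError(f"unknown fixture kind {kind!r}")


def panel_response(panel: list[FixtureMolecule], seed: int,
                   noise_sd: float = 0.10,
                   effects: dict | None = None) -> np.ndarray:
    """Synthetic log FM for the functional-group panel.

    Each tag contributes its :data:`PANEL_EFFECTS` increment; Gaussian
    noise with ``noise_sd`` is added on top. The tag effects are the
    recorded ground truth the attribution tests recover.
    """
    effects = effects or PANEL_EFFECTS
    rng = np.random.default_rng(seed)
    y = np.array([
        sum(effects.get(t, 0.0) for t in m.tags) for m in panel
    ], dtype=float)
    return y + rng.normal(0.0, noise_sd, len(panel))
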