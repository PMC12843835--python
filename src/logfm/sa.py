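"""Ertl-style synthetic-accessibility (SA) scoring.

The score combines a fragment-contribution term — how common a molecule's
circular (radius-2) fragments are in a large database of known compounds —
with a complexity penalty built from molecular size, stereo centers,
spiro/bridgehead ring complexity and macrocycles, plus a symmetry
correction rewarding repeated fragments. The raw sum is mapped onto the
conventional 1 (easy to make) … 10 (very difficult) scale; a screening
cut-off of 6 flags compounds that are difficult to synthesize.

The published fragment-frequency table is loaded from the RDKit
distribution's SA_Score contribution data at import of the scorer (no
re-tuning of the published parameterization).
"""

from __future__ import annotations

import gzip
import math
import os
import pickle
from dataclasses import dataclass

from rdkit import Chem, RDConfig
from rdkit.Chem import rdFingerprintGenerator, rdMolDescriptors

from .errors import ParseError, ValidationError

__all__ = ["SAScoreBreakdown", "load_fragment_scores", "ertl_sa", "screen_library"]

_FRAGMENT_SCORES: dict[int, float] | None = None


def load_fragment_scores() -> dict[int, float]:
    """Published fragment-frequency score table (circular fragment id →
    log-frequency score), cached after first load."""
    global _FRAGMENT_SCORES
    if _FRAGMENT_SCORES is None:
        path = os.path.join(RDConfig.RDContribDir, "SA_Score", "fpscores.pkl.gz")
        with gzip.open(path) as fh:
            raw = pickle.load(fh)
        table: dict[int, float] = {}
        for row in raw:
            score = float(row[0])
            for frag_id in row[1:]:
                table[int(frag_id)] = score
        _FRAGMENT_SCORES = table
    return _FRAGMENT_SCORES


@dataclass
class SAScoreBreakdown:
    """Component decomposition of one SA score."""

    fragment_score: float        # mean per-fragment database contribution
    size_penalty: float
    stereo_penalty: float
    ring_complexity_penalty: float   # spiro + bridgehead terms
    macrocycle_penalty: float
    symmetry_correction: float
    raw: float                   # before rescaling to [1, 10]
    score: float                 # final, clamped to [1, 10]


_UNKNOWN_FRAGMENT = -4.0
_RAW_MIN, _RAW_MAX = -4.0, 2.5

_count_gen = rdFingerprintGenerator.GetMorganGenerator(radius=2)


def ertl_sa(mol: Chem.Mol, fragment_table: dict[int, float] | None = None) -> SAScoreBreakdown:
    """Score one molecule; returns the full component breakdown.

    The fragment term averages database-frequency scores over all radius-≤2
    circular fragments (count-weighted; fragments absent from the table get
    the rare-fragment floor). The complexity penalty sums size, stereo,
    spiro/bridge and macrocycle terms; the symmetry correction kicks in
    when a molecule has fewer distinct fragments than heavy atoms.
    """
    if mol is None or mol.GetNumAtoms() == 0:
        raise ValidationError("empty molecule")
    table = fragment_table or load_fragment_scores()

    counts = _count_gen.GetSparseCountFingerprint(mol).GetNonzeroElements()
    total = sum(counts.values())
    frag_score = sum(
        table.get(int(frag), _UNKNOWN_FRAGMENT) * c for frag, c in counts.items()
    ) / total

    n_atoms = mol.GetNumAtoms()
    n_chiral = len(Chem.FindMolChiralCenters(mol, includeUnassigned=True))
    n_spiro = rdMolDescriptors.CalcNumSpiroAtoms(mol)
    n_bridge = rdMolDescriptors.CalcNumBridgeheadAtoms(mol)
    n_macro = sum(1 for ring in mol.GetRingInfo().AtomRings() if len(ring) > 8)

    size_penalty = n_atoms ** 1.005 - n_atoms
    stereo_penalty = math.log10(n_chiral + 1)
    ring_penalty = math.log10(n_spiro + 1) + math.log10(n_bridge + 1)
    macro_penalty = math.log10(2) if n_macro > 0 else 0.0

    symmetry = 0.0
    n_distinct = len(counts)
    if n_atoms > n_distinct:
        symmetry = math.log(float(n_atoms) / n_distinct) * 0.5

    raw = (frag_score - size_penalty - stereo_penalty - ring_penalty
           - macro_penalty + symmetry)

    # map raw range onto the 1..10 scale, soft-compress the top end
    score = 11.0 - (raw - _RAW_MIN + 1.0) / (_RAW_MAX - _RAW_MIN) * 9.0
    if score > 8.0:
        score = 8.0 + math.log(score + 1.0 - 9.0)
    score = min(max(score, 1.0), 10.0)

    return SAScoreBreakdown(
        fragment_score=frag_score,
        size_penalty=size_penalty,
        stereo_penalty=stereo_penalty,
        ring_complexity_penalty=ring_penalty,
        macrocycle_penalty=macro_penalty,
        symmetry_correction=symmetry,
        raw=raw,
        score=score,
    )


def screen_library(entries, cutoff: float = 6.0):
    """Score a library and flag compounds at or above the cut-off.

    ``entries`` is an iterable of ``(compound_id, mol_or_smiles)``. Parse
    failures are reported in the returned ``errors`` list, never silently
    dropped. Returns ``{"results": [(id, score, flagged)], "errors":
    [(id, message)], "n_flagged": int}``.
    """
    results, errors = [], []
    for cid, item in entries:
        try:
            mol = item
            if isinstance(item, str):
                mol = Chem.MolFromSmiles(item)
                if mol is None:
                    raise ParseError(item)
            score = ertl_sa(mol).score
            results.append((cid, score, score >= cutoff))
        except (ParseError, ValidationError) as exc:
            errors.append((cid, str(exc)))
    if not results and not errors:
        raise ValidationError("empty library")
    return {
        "results": results,
        "errors": errors,
        "n_flagged": sum(1 for _, _, fl in results if fl),
    }
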