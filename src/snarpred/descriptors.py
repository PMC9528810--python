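"""Feature-matrix assembly: named physical-organic feature sets, second-order
polynomial expansion, solvent principal components, and Morgan reaction
difference fingerprints.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator
from sklearn.preprocessing import PolynomialFeatures

FEATURE_SET_NAMES = ("X_full", "X_noTS", "X_small", "X_trad", "X_surf")

SOLVENT_PC_COLUMNS = ["PC1", "PC2", "PC3", "PC4", "PC5"]


def _load_manifest() -> dict:
    with resources.files("snarpred.data").joinpath("feature_sets.json").open() as fh:
        return json.load(fh)


_MANIFEST = _load_manifest()

# contract counts for the named feature sets
_EXPECTED_WIDTHS = {"X_full": 34, "X_noTS": 25, "X_small": 12, "X_trad": 20, "X_surf": 13}
for _name, _width in _EXPECTED_WIDTHS.items():
    if len(_MANIFEST["feature_sets"][_name]) != _width:
        raise RuntimeError(
            f"packaged manifest corrupt: {_name} has "
            f"{len(_MANIFEST['feature_sets'][_name])} columns, expected {_width}"
        )


def feature_set_columns(name: str) -> list[str]:
    """Ordered column list of a named feature set."""
    try:
        return list(_MANIFEST["feature_sets"][name])
    except KeyError:
        raise KeyError(
            f"unknown feature set {name!r}; known: {sorted(_MANIFEST['feature_sets'])}"
        ) from None


def ts_columns() -> list[str]:
    """Transition-state columns: the DFT barrier plus every *_TS column."""
    return list(_MANIFEST["columns_ts"])


@dataclass
class FeatureSetSpec:
    """A named (or custom) selection of descriptor columns plus options."""

    name: str = "X_full"
    columns: list[str] = field(default_factory=list)
    include_fingerprint: bool = False
    fingerprint_radius: int = 3
    fingerprint_width: int = 2048
    pf2: bool = False
    standardize: bool = True

    def __post_init__(self) -> None:
        if not self.columns:
            if self.name == "custom":
                raise ValueError("custom FeatureSetSpec requires explicit columns")
            if self.name == "X_Morgan":
                # structural fingerprint plus the five solvent components
                self.columns = list(SOLVENT_PC_COLUMNS)
                self.include_fingerprint = True
            elif self.name == "X_combined":
                self.columns = feature_set_columns("X_full")
                self.include_fingerprint = True
            else:
                self.columns = feature_set_columns(self.name)

    def manifest(self) -> dict:
        return {
            "name": self.name,
            "columns": list(self.columns),
            "include_fingerprint": self.include_fingerprint,
            "fingerprint_radius": self.fingerprint_radius,
            "fingerprint_width": self.fingerprint_width,
            "pf2": self.pf2,
            "standardize": self.standardize,
        }


def assemble(
    reaction_table: pd.DataFrame,
    descriptor_table: pd.DataFrame,
    spec: FeatureSetSpec,
    target_column: str = "dG_exp_kcal",
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Build (X, y, column manifest) for a feature set.

    Row order follows ``reaction_table``.  PF2 expansion and fingerprints, when
    requested, are appended here; standardization is left to the model layer so
    that training-partition statistics are used.
    """
    desc = descriptor_table.set_index("rxn_id")
    rxn_ids = reaction_table["rxn_id"].astype(str).tolist()
    missing_ids = [r for r in rxn_ids if r not in desc.index]
    missing_cols = [c for c in spec.columns if c not in desc.columns]
    problems = []
    if missing_ids:
        problems.append(f"unmatched rxn_ids: {missing_ids}")
    if missing_cols:
        problems.append(f"missing descriptor columns: {missing_cols}")
    if problems:
        raise ValueError("; ".join(problems))

    block = desc.loc[rxn_ids, spec.columns]
    if not np.isfinite(block.to_numpy(dtype=float)).all():
        bad = block.columns[~np.isfinite(block.to_numpy(dtype=float)).all(axis=0)]
        raise ValueError(f"non-finite descriptor values in columns: {list(bad)}")
    X = block.to_numpy(dtype=float)
    columns = list(spec.columns)

    if spec.pf2:
        X = pf2_expand(X)
        columns = pf2_column_names(columns)

    if spec.include_fingerprint:
        fps = np.vstack(
            [
                morgan_difference_fingerprint(
                    smi, radius=spec.fingerprint_radius, width=spec.fingerprint_width
                )
                for smi in reaction_table["reaction_smiles"]
            ]
        )
        X = np.hstack([X, fps])
        columns += [f"fp_{i}" for i in range(spec.fingerprint_width)]

    y = reaction_table[target_column].to_numpy(dtype=float)
    return X, y, columns


def pf2_expand(X: np.ndarray) -> np.ndarray:
    """Append all squares and pairwise products (no bias column).

    Output ordering is the d original columns followed by x_i*x_j for
    i <= j in lexicographic order, giving d + d(d+1)/2 columns.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] < 1:
        raise ValueError(f"expected 2-D matrix with >=1 column, got shape {X.shape}")
    poly = PolynomialFeatures(degree=2, include_bias=False)
    return poly.fit_transform(X)


def pf2_column_names(columns: Sequence[str]) -> list[str]:
    names = list(columns)
    d = len(columns)
    for i in range(d):
        for j in range(i, d):
            if i == j:
                names.append(f"{columns[i]}^2")
            else:
                names.append(f"{columns[i]}*{columns[j]}")
    return names


def _side_counts(smiles_list: list[str], radius: int, width: int) -> np.ndarray:
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=width)
    total = np.zeros(width, dtype=np.int64)
    for smi in smiles_list:
        if not smi:
            continue
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            raise ValueError(f"unparseable SMILES: {smi!r}")
        fp = gen.GetCountFingerprint(mol)
        for bit, count in fp.GetNonzeroElements().items():
            total[bit] += count
    return total


def morgan_difference_fingerprint(
    reaction_smiles: str, radius: int = 3, width: int = 2048
) -> np.ndarray:
    """Product-side minus reactant-side hashed Morgan count vectors.

    Agents (the middle field of reactants>agents>products) are ignored.
    Count folding preserves the antisymmetry of the difference vector under
    swapping reaction sides.
    """
    parts = reaction_smiles.split(">")
    if len(parts) != 3:
        raise ValueError(
            f"reaction SMILES must have form reactants>agents>products: "
            f"{reaction_smiles!r}"
        )
    reactants, _, products = parts
    if not reactants or not products:
        raise ValueError(f"need >=1 reactant and >=1 product: {reaction_smiles!r}")
    r_counts = _side_counts(reactants.split("."), radius, width)
    p_counts = _side_counts(products.split("."), radius, width)
    return (p_counts - r_counts).astype(float)


def attach_solvent_pcs(
    matrix: np.ndarray,
    solvent_table: pd.DataFrame,
    reactions: pd.DataFrame,
) -> np.ndarray:
    """Concatenate the five solvent principal components to a feature block."""
    table = solvent_table.set_index("solvent")
    missing = sorted(set(reactions["solvent"]) - set(table.index))
    if missing:
        raise ValueError(f"unknown solvents: {missing}")
    pcs = table.loc[reactions["solvent"], SOLVENT_PC_COLUMNS].to_numpy(dtype=float)
    return np.hstack([np.asarray(matrix, dtype=float), pcs])


def fingerprints_to_sparse_frame(
    rxn_ids: Sequence[str], fingerprints: np.ndarray
) -> pd.DataFrame:
    """Nonzero fingerprint entries as a (rxn_id, bit, count) triplet table."""
    rows = []
    for rid, vec in zip(rxn_ids, fingerprints):
        for bit in np.nonzero(vec)[0]:
            rows.append({"rxn_id": rid, "bit": int(bit), "count": float(vec[bit])})
    return pd.DataFrame(rows, columns=["rxn_id", "bit", "count"])
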