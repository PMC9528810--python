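"""Kinetic dataset handling: records, Eyring conversion, summaries and splits."""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .constants import BOLTZMANN_J_PER_K, PLANCK_J_S, R_KCAL

Grouping = Literal["none", "reaction", "electrophile", "nucleophile"]

#: Tolerance (kcal/mol) for consistency between a stored rate constant and a
#: stored experimental barrier on the same record.
EYRING_CONSISTENCY_TOL = 0.01


def eyring_barrier(rate_constant: float, temperature: float) -> float:
    """Convert a (pseudo-)first-order rate constant to an activation free energy.

    Parameters
    ----------
    rate_constant
        Rate constant in s^-1; second-order constants are assumed already
        reduced to pseudo-first-order at 1 M standard state.
    temperature
        Absolute temperature in K.

    Returns
    -------
    float
        Activation free energy dG_act = R*T*ln(kB*T/(h*k)) in kcal/mol.
    """
    if not temperature > 0:
        raise ValueError(f"temperature must be > 0 K, got {temperature!r}")
    if not rate_constant > 0:
        raise ValueError(f"rate_constant must be > 0 s^-1, got {rate_constant!r}")
    prefactor = BOLTZMANN_J_PER_K * temperature / PLANCK_J_S
    return R_KCAL * temperature * math.log(prefactor / rate_constant)


def inverse_eyring(dG: float, temperature: float) -> float:
    """Rate constant (s^-1) implied by an activation free energy at ``temperature``."""
    if not temperature > 0:
        raise ValueError(f"temperature must be > 0 K, got {temperature!r}")
    prefactor = BOLTZMANN_J_PER_K * temperature / PLANCK_J_S
    return prefactor * math.exp(-dG / (R_KCAL * temperature))


@dataclass
class ReactionRecord:
    """One kinetic measurement.

    At least one of ``rate_constant`` / ``dG_exp`` must be present; when both
    are present they must satisfy the Eyring relation to within
    ``EYRING_CONSISTENCY_TOL`` kcal/mol.
    """

    rxn_id: str
    reaction_smiles: str = ""
    nucleophile_class: str = ""
    leaving_class: str = ""
    electrophile_id: str = ""
    nucleophile_id: str = ""
    solvent: str = ""
    temperature: float = 298.15
    rate_constant: float | None = None
    dG_exp: float | None = None

    def __post_init__(self) -> None:
        if not self.temperature > 0:
            raise ValueError(
                f"record {self.rxn_id}: temperature must be > 0 K, "
                f"got {self.temperature!r}"
            )
        if self.rate_constant is None and self.dG_exp is None:
            raise ValueError(
                f"record {self.rxn_id}: needs rate_constant or dG_exp"
            )
        if self.rate_constant is not None:
            if not self.rate_constant > 0:
                raise ValueError(
                    f"record {self.rxn_id}: rate_constant must be > 0, "
                    f"got {self.rate_constant!r}"
                )
            implied = eyring_barrier(self.rate_constant, self.temperature)
            if self.dG_exp is None:
                self.dG_exp = implied
            elif abs(self.dG_exp - implied) > EYRING_CONSISTENCY_TOL:
                raise ValueError(
                    f"record {self.rxn_id}: dG_exp={self.dG_exp:.4f} inconsistent "
                    f"with Eyring value {implied:.4f} from the stored rate constant"
                )

    @property
    def reaction_key(self) -> str:
        """Key identifying the reactant/product set, ignoring conditions."""
        return self.reaction_smiles or self.rxn_id


@dataclass
class DatasetSummary:
    n_total: int
    n_unique_reactions: int
    n_single_condition: int
    n_multi_condition: int
    dG_min: float
    dG_max: float
    dG_mean: float
    nucleophile_counts: dict[str, int]
    leaving_counts: dict[str, int]
    combination_counts: dict[tuple[str, str], int]


@dataclass
class SplitPlan:
    train_ids: list[str]
    test_ids: list[str]
    seed: int
    fraction_train: float
    grouping: Grouping = "none"

    def __post_init__(self) -> None:
        overlap = set(self.train_ids) & set(self.test_ids)
        if overlap:
            raise ValueError(f"train/test overlap: {sorted(overlap)[:5]}")


def summarize(dataset: Sequence[ReactionRecord]) -> DatasetSummary:
    """Counts, barrier range and class frequency tables for a dataset."""
    if not dataset:
        raise ValueError("cannot summarize an empty dataset")
    dgs = []
    for rec in dataset:
        if rec.dG_exp is None:
            raise ValueError(f"record {rec.rxn_id}: no resolvable dG_exp")
        dgs.append(rec.dG_exp)
    by_reaction = Counter(rec.reaction_key for rec in dataset)
    n_unique = len(by_reaction)
    n_multi = sum(1 for c in by_reaction.values() if c > 1)

    def sorted_counts(counter: Counter) -> dict:
        return dict(sorted(counter.items(), key=lambda kv: (-kv[1], str(kv[0]))))

    return DatasetSummary(
        n_total=len(dataset),
        n_unique_reactions=n_unique,
        n_single_condition=n_unique - n_multi,
        n_multi_condition=n_multi,
        dG_min=float(min(dgs)),
        dG_max=float(max(dgs)),
        dG_mean=float(np.mean(dgs)),
        nucleophile_counts=sorted_counts(
            Counter(rec.nucleophile_class for rec in dataset)
        ),
        leaving_counts=sorted_counts(Counter(rec.leaving_class for rec in dataset)),
        combination_counts=sorted_counts(
            Counter((rec.nucleophile_class, rec.leaving_class) for rec in dataset)
        ),
    )


def _group_key(rec: ReactionRecord, grouping: Grouping) -> str:
    if grouping == "reaction":
        return rec.reaction_key
    if grouping == "electrophile":
        return rec.electrophile_id
    if grouping == "nucleophile":
        return rec.nucleophile_id
    raise ValueError(f"unknown grouping {grouping!r}")


def make_split(
    dataset: Sequence[ReactionRecord],
    fraction_train: float,
    seed: int,
    grouping: Grouping = "none",
) -> SplitPlan:
    """Deterministic train/test split, optionally keeping groups intact.

    Under ``grouping='none'`` the train side has exactly
    ``floor(fraction_train * n)`` rows.  Under any other grouping, whole
    groups are assigned greedily in shuffled order until the train quota is
    reached, so no group straddles the split.
    """
    if not dataset:
        raise ValueError("cannot split an empty dataset")
    if not 0.0 < fraction_train < 1.0:
        raise ValueError(f"fraction_train must be in (0,1), got {fraction_train}")
    rng = np.random.default_rng(seed)
    n = len(dataset)
    n_train = int(math.floor(fraction_train * n))
    if grouping == "none":
        order = rng.permutation(n)
        train_ids = [dataset[i].rxn_id for i in order[:n_train]]
        test_ids = [dataset[i].rxn_id for i in order[n_train:]]
    else:
        groups: dict[str, list[str]] = {}
        for rec in dataset:
            key = _group_key(rec, grouping)
            if not key:
                raise ValueError(
                    f"record {rec.rxn_id}: missing key for grouping={grouping!r}"
                )
            groups.setdefault(key, []).append(rec.rxn_id)
        keys = sorted(groups)
        rng.shuffle(keys)
        train_ids, test_ids = [], []
        filled = 0
        for key in keys:
            members = groups[key]
            if filled < n_train:
                train_ids.extend(members)
                filled += len(members)
            else:
                test_ids.extend(members)
    return SplitPlan(
        train_ids=train_ids,
        test_ids=test_ids,
        seed=seed,
        fraction_train=fraction_train,
        grouping=grouping,
    )


REACTION_TABLE_COLUMNS = [
    "rxn_id",
    "reaction_smiles",
    "nucleophile_class",
    "leaving_class",
    "electrophile_id",
    "nucleophile_id",
    "solvent",
    "temperature_K",
    "k_obs",
    "dG_exp_kcal",
]


def load_reaction_table(path) -> list[ReactionRecord]:
    """Read a reaction CSV (see ``REACTION_TABLE_COLUMNS``) into records."""
    df = pd.read_csv(path, dtype={"rxn_id": str})
    missing = set(REACTION_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"reaction table missing columns: {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        records.append(
            ReactionRecord(
                rxn_id=str(row.rxn_id),
                reaction_smiles="" if pd.isna(row.reaction_smiles) else str(row.reaction_smiles),
                nucleophile_class="" if pd.isna(row.nucleophile_class) else str(row.nucleophile_class),
                leaving_class="" if pd.isna(row.leaving_class) else str(row.leaving_class),
                electrophile_id="" if pd.isna(row.electrophile_id) else str(row.electrophile_id),
                nucleophile_id="" if pd.isna(row.nucleophile_id) else str(row.nucleophile_id),
                solvent="" if pd.isna(row.solvent) else str(row.solvent),
                temperature=float(row.temperature_K),
                rate_constant=None if pd.isna(row.k_obs) else float(row.k_obs),
                dG_exp=None if pd.isna(row.dG_exp_kcal) else float(row.dG_exp_kcal),
            )
        )
    return records


def records_to_frame(dataset: Sequence[ReactionRecord]) -> pd.DataFrame:
    rows = []
    for rec in dataset:
        rows.append(
            {
                "rxn_id": rec.rxn_id,
                "reaction_smiles": rec.reaction_smiles,
                "nucleophile_class": rec.nucleophile_class,
                "leaving_class": rec.leaving_class,
                "electrophile_id": rec.electrophile_id,
                "nucleophile_id": rec.nucleophile_id,
                "solvent": rec.solvent,
                "temperature_K": rec.temperature,
                "k_obs": rec.rate_constant,
                "dG_exp_kcal": rec.dG_exp,
            }
        )
    return pd.DataFrame(rows, columns=REACTION_TABLE_COLUMNS)


def check_solvents(dataset: Sequence[ReactionRecord], solvent_table: pd.DataFrame) -> None:
    """Warn (never fail) about solvent names absent from the solvent table."""
    known = set(solvent_table["solvent"])
    unknown = sorted({rec.solvent for rec in dataset} - known - {""})
    if unknown:
        warnings.warn(f"unresolvable solvent names: {unknown}", stacklevel=2)
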