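"""Regio- and chemoselectivity from per-site barrier predictions.

The predicted major product of a multi-site substrate is the site with the
lowest predicted activation free energy; accuracy is scored top-1, split by
whether the competing sites bear the same halogen (regio) or different
halogens (chemo).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import pandas as pd

from .constants import R_KCAL

HALOGENS = {"F", "Cl", "Br", "I"}

SelectivityClass = Literal["regio", "chemo"]


@dataclass
class Site:
    label: str
    halogen: str
    dG_pred: float
    dG_std: float | None = None


@dataclass
class SiteCompetition:
    substrate_id: str
    sites: list[Site]
    observed_major: str
    selectivity_class: SelectivityClass | None = None

    def __post_init__(self) -> None:
        if len(self.sites) < 2:
            raise ValueError(
                f"substrate {self.substrate_id}: needs >= 2 candidate sites"
            )
        labels = [s.label for s in self.sites]
        if self.observed_major not in labels:
            raise ValueError(
                f"substrate {self.substrate_id}: observed major {self.observed_major!r} "
                f"not among site labels {labels}"
            )
        if self.selectivity_class is None:
            self.selectivity_class = classify_competition(self.sites)


def classify_competition(sites: Sequence[Site]) -> SelectivityClass:
    """``regio`` when every competing site bears the same halogen, else ``chemo``."""
    halogens = [s.halogen for s in sites]
    bad = [h for h in halogens if h not in HALOGENS]
    if bad:
        raise ValueError(f"non-halogen site elements: {bad}")
    return "regio" if len(set(halogens)) == 1 else "chemo"


@dataclass
class MajorPrediction:
    site: str
    margin: float  # second-lowest minus lowest barrier, kcal/mol
    tie: bool


def predict_major(competition: SiteCompetition) -> MajorPrediction:
    """Argmin-barrier site; deterministic tie-break by site label order."""
    for s in competition.sites:
        if s.dG_pred is None or not math.isfinite(s.dG_pred):
            raise ValueError(
                f"substrate {competition.substrate_id}: site {s.label!r} has no barrier"
            )
    ordered = sorted(competition.sites, key=lambda s: (s.dG_pred, s.label))
    best, second = ordered[0], ordered[1]
    return MajorPrediction(
        site=best.label,
        margin=second.dG_pred - best.dG_pred,
        tie=second.dG_pred == best.dG_pred,
    )


def rate_ratio(margin: float, temperature: float = 298.15) -> float:
    """Boltzmann rate ratio implied by a barrier difference at ``temperature``."""
    return math.exp(margin / (R_KCAL * temperature))


@dataclass
class SelectivityReport:
    overall: float | None
    regio: float | None
    chemo: float | None
    n_total: int
    n_regio: int
    n_chemo: int
    n_correct: int
    n_correct_regio: int
    n_correct_chemo: int
    ties: int = 0

    def as_dict(self) -> dict:
        return self.__dict__.copy()


def top1_accuracy(
    competitions: Sequence[SiteCompetition],
    predictions: Sequence[MajorPrediction] | None = None,
) -> SelectivityReport:
    """Top-1 accuracy overall and split into regio/chemo classes.

    A class with zero members gets accuracy ``None`` (undefined, flagged by
    the count fields).
    """
    if predictions is None:
        predictions = [predict_major(c) for c in competitions]
    if len(predictions) != len(competitions):
        raise ValueError("every competition must be scored")
    counts = {"regio": 0, "chemo": 0}
    correct = {"regio": 0, "chemo": 0}
    ties = 0
    for comp, pred in zip(competitions, predictions):
        cls = comp.selectivity_class
        counts[cls] += 1
        ties += int(pred.tie)
        if pred.site == comp.observed_major:
            correct[cls] += 1
    n_total = len(competitions)
    n_correct = correct["regio"] + correct["chemo"]
    return SelectivityReport(
        overall=n_correct / n_total if n_total else None,
        regio=correct["regio"] / counts["regio"] if counts["regio"] else None,
        chemo=correct["chemo"] / counts["chemo"] if counts["chemo"] else None,
        n_total=n_total,
        n_regio=counts["regio"],
        n_chemo=counts["chemo"],
        n_correct=n_correct,
        n_correct_regio=correct["regio"],
        n_correct_chemo=correct["chemo"],
        ties=ties,
    )


def default_conditions(charge_state: Literal["neutral", "ionic"]) -> tuple[str, float]:
    """Default (solvent, temperature) when reaction conditions are unknown."""
    if charge_state == "neutral":
        return ("acetonitrile", 298.15)
    if charge_state == "ionic":
        return ("methanol", 298.15)
    raise ValueError(f"unknown charge state {charge_state!r}")


SITE_TABLE_COLUMNS = [
    "substrate_id",
    "site_label",
    "halogen",
    "dG_pred_kcal",
    "dG_std_kcal",
    "observed_major_flag",
]


def load_site_table(path, min_sites: int = 2) -> list[SiteCompetition]:
    """Read a per-site CSV into competitions; substrates with fewer than
    ``min_sites`` resolvable sites (after dropping rows with missing
    barriers) are excluded."""
    df = pd.read_csv(path, dtype={"substrate_id": str, "site_label": str})
    missing = set(SITE_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"site table missing columns: {sorted(missing)}")
    competitions = []
    for sid, grp in df.groupby("substrate_id", sort=True):
        grp = grp[grp["dG_pred_kcal"].notna()]
        if len(grp) < min_sites:
            continue
        sites = [
            Site(
                label=str(r.site_label),
                halogen=str(r.halogen),
                dG_pred=float(r.dG_pred_kcal),
                dG_std=None if pd.isna(r.dG_std_kcal) else float(r.dG_std_kcal),
            )
            for r in grp.itertuples(index=False)
        ]
        observed = grp.loc[grp["observed_major_flag"].astype(bool), "site_label"]
        if observed.empty:
            raise ValueError(f"substrate {sid}: no observed major site flagged")
        competitions.append(
            SiteCompetition(
                substrate_id=str(sid), sites=sites, observed_major=str(observed.iloc[0])
            )
        )
    return competitions
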