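"""Synthetic datasets with the statistical structure the pipeline assumes.

The generator emits the same table schemas as the real inputs: a reaction
table (kinetics), a descriptor table (features incl. a noisy, linearly
distorted DFT barrier), and optionally per-site competition tables.  Key
structural properties:

* descriptor columns come in correlated clusters (multicollinearity);
* the latent true barrier is a mildly nonlinear function of a few named
  descriptors (one interaction, one quadratic);
* ``dG_dft`` = a_d + b_d * true + Gaussian noise (sigma_dft, default 2.5);
* ``dG_exp`` = true + Gaussian noise (sigma_exp, default 0.3);
* categorical group labels shift feature-cluster means, so grouped
  validation is genuinely harder than random folds;
* rate constants are back-computed from ``dG_exp`` at a per-row temperature
  drawn independently of the barrier.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .descriptors import feature_set_columns
from .reaction_data import inverse_eyring

#: Feature clusters (multicollinearity blocks) over the descriptor columns.
FEATURE_CLUSTERS: dict[str, list[str]] = {
    "electrophilicity": ["Vs_C", "Es_min_C", "omega", "omega_loc_C"],
    "nucleophilicity": ["Vs_N", "Is_min_N", "N_global", "N_loc_N"],
    "charges": ["q_C", "q_N", "q_L", "V_N_C"],
    "geometry": ["V_N_N", "V_N_L", "SASA_r_C", "SASA_r_N"],
    "bonding": ["SASA_r_L", "P_int", "BO_CN", "BO_CL"],
    "ts_charges": ["q_C_TS", "q_N_TS", "q_L_TS", "V_N_C_TS"],
    "ts_geometry": ["V_N_N_TS", "V_N_L_TS", "BO_CN_TS", "BO_CL_TS"],
}

#: TS-geometry clusters share the latent factor of a ground-state cluster, so
#: TS columns are informative but largely redundant given enough data (the
#: regime structure the learning curves probe).
TS_CLUSTER_PARENT = {"ts_charges": "charges", "ts_geometry": "bonding"}

#: Default latent linear coefficients (applied to raw feature values).  The
#: small BO_CN_TS term lives only in a TS column: models without TS features
#: can proxy it through the correlated ground cluster but never fully recover
#: it, leaving a small persistent hybrid edge.
DEFAULT_COEFFICIENTS: dict[str, float] = {
    "Es_min_C": 0.40,
    "Is_min_N": 0.30,
    "Vs_C": 0.25,
    "N_global": 0.20,
    "BO_CN": 0.20,
    "PC1": 0.10,
    "BO_CN_TS": 0.12,
}

#: Default pairwise interactions.  These make part of the latent barrier slow
#: to learn from ground-state features at small n; the DFT barrier column
#: shortcuts them, which is what gives hybrid feature sets their low-data edge.
DEFAULT_INTERACTIONS: list[tuple[str, str, float]] = [
    ("Es_min_C", "Is_min_N", 0.30),
    ("Vs_C", "BO_CN", 0.26),
    ("N_global", "q_C", 0.20),
]

DEFAULT_SOLVENT_PCS: dict[str, list[float]] = {
    "water": [2.1, -0.8, 0.3, 0.1, -0.2],
    "methanol": [1.2, -0.3, 0.5, -0.4, 0.1],
    "acetonitrile": [0.4, 0.9, -0.6, 0.2, 0.3],
    "dmso": [0.8, 1.4, 0.2, 0.5, -0.1],
    "thf": [-0.9, 0.2, 0.8, -0.3, -0.4],
    "toluene": [-1.8, -0.9, -0.5, 0.4, 0.2],
}

#: Small fixed library of parseable SNAr-style reaction SMILES for
#: fingerprint tests; not meant to be chemically exhaustive.
REACTION_SMILES_LIBRARY = [
    "c1ccc(F)cc1.[O-]C>>c1ccc(OC)cc1.[F-]",
    "c1ccc(Cl)cc1.NC>>c1ccc(NC)cc1.Cl",
    "O=[N+]([O-])c1ccc(F)cc1.OC>>O=[N+]([O-])c1ccc(OC)cc1.OF",
    "c1ccc(Br)cc1.SC>>c1ccc(SC)cc1.Br",
    "Fc1ccncc1.NCC>>CCNc1ccncc1.F",
    "Clc1ncccn1.NC1CCCCC1>>Clc1ncc(N)cn1.C1CCCCC1",
]

NUCLEOPHILE_CLASSES = ["N-neutral", "O-anionic", "S-neutral", "N-anionic"]
LEAVING_CLASSES = ["F", "Cl", "Br", "NO2"]


@dataclass
class GeneratorConfig:
    n_samples: int = 400
    cluster_rho: float = 0.8
    coefficients: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COEFFICIENTS)
    )
    interactions: list[tuple[str, str, float]] = field(
        default_factory=lambda: list(DEFAULT_INTERACTIONS)
    )
    quadratic: tuple[str, float] = ("Vs_C", 0.12)
    barrier_center: float = 21.3
    barrier_scale: float = 3.5
    dft_offset: float = 2.0  # a_d
    dft_slope: float = 0.9  # b_d
    sigma_dft: float = 2.0
    sigma_exp: float = 0.4
    n_nucleophile_classes: int = 4
    n_electrophile_classes: int = 6
    class_shift_scale: float = 0.5
    solvent_pcs: dict[str, list[float]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_SOLVENT_PCS.items()}
    )
    temperature_range: tuple[float, float] = (273.15, 373.15)
    confound_temperature: bool = False  # hotter runs for higher barriers
    with_smiles: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.sigma_dft > self.sigma_exp >= 0:
            raise ValueError("need sigma_dft > sigma_exp >= 0")
        if not 0 <= self.cluster_rho < 1:
            raise ValueError("cluster_rho must be in [0, 1)")
        all_cluster_cols = [c for cols in FEATURE_CLUSTERS.values() for c in cols]
        for name in self.coefficients:
            if name not in all_cluster_cols and not name.startswith("PC"):
                raise ValueError(f"unknown driver feature {name!r}")


@dataclass
class SyntheticTruth:
    true_barrier: np.ndarray
    dft_noise: np.ndarray
    exp_noise: np.ndarray
    config: GeneratorConfig

    @property
    def sigma_true(self) -> float:
        return float(np.std(self.true_barrier, ddof=1))

    def analytic_dft_exp_correlation(self) -> float:
        """corr(dG_dft, dG_exp) implied by the generator covariance."""
        s2 = np.var(self.true_barrier, ddof=1)
        b, sd, se = self.config.dft_slope, self.config.sigma_dft, self.config.sigma_exp
        return b * s2 / np.sqrt((b**2 * s2 + sd**2) * (s2 + se**2))


@dataclass
class SyntheticDataset:
    reaction_table: pd.DataFrame
    descriptor_table: pd.DataFrame
    solvent_table: pd.DataFrame
    truth: SyntheticTruth


def _draw_clustered_features(
    rng: np.random.Generator, n: int, rho: float
) -> pd.DataFrame:
    cols = {}
    factors = {}
    for cluster, cluster_cols in FEATURE_CLUSTERS.items():
        parent = TS_CLUSTER_PARENT.get(cluster)
        z = factors[parent] if parent else rng.standard_normal(n)
        factors[cluster] = z
        for name in cluster_cols:
            eps = rng.standard_normal(n)
            cols[name] = np.sqrt(rho) * z + np.sqrt(1.0 - rho) * eps
    return pd.DataFrame(cols)


def generate(config: GeneratorConfig) -> SyntheticDataset:
    """Generate a reaction table, descriptor table and truth record."""
    rng = np.random.default_rng(config.seed)
    n = config.n_samples

    features = _draw_clustered_features(rng, n, config.cluster_rho)

    # categorical groups shift feature-cluster means, so the class structure
    # is expressible through the features (learnable by a smooth model) while
    # still making leave-one-group-out an extrapolation task
    nuc_class_idx = rng.integers(0, config.n_nucleophile_classes, size=n)
    ele_class_idx = rng.integers(0, config.n_electrophile_classes, size=n)
    nuc_shifts = rng.normal(
        0, config.class_shift_scale, size=(config.n_nucleophile_classes, 4)
    )
    ele_shifts = rng.normal(
        0, config.class_shift_scale, size=(config.n_electrophile_classes, 4)
    )
    for k, col in enumerate(FEATURE_CLUSTERS["nucleophilicity"]):
        features[col] = features[col] + nuc_shifts[nuc_class_idx, k]
    for k, col in enumerate(FEATURE_CLUSTERS["electrophilicity"]):
        features[col] = features[col] + ele_shifts[ele_class_idx, k]

    solvents = sorted(config.solvent_pcs)
    solvent_choice = rng.integers(0, len(solvents), size=n)
    solvent_names = [solvents[i] for i in solvent_choice]
    pc_matrix = np.array([config.solvent_pcs[s] for s in solvent_names])
    for j in range(5):
        features[f"PC{j + 1}"] = pc_matrix[:, j]

    raw = np.zeros(n)
    for name, coef in config.coefficients.items():
        raw += coef * features[name].to_numpy()
    for a, b, c_int in config.interactions:
        raw += c_int * features[a].to_numpy() * features[b].to_numpy()
    q, c_quad = config.quadratic
    raw += c_quad * (features[q].to_numpy() ** 2 - 1.0)
    true = config.barrier_center + config.barrier_scale * raw

    dft_noise = rng.normal(0, config.sigma_dft, size=n)
    exp_noise = rng.normal(0, config.sigma_exp, size=n)
    dG_dft = config.dft_offset + config.dft_slope * true + dft_noise
    dG_exp = true + exp_noise

    lo, hi = config.temperature_range
    if config.confound_temperature:
        # hotter runs for higher barriers (the real-data confound)
        u = (true - true.min()) / max(np.ptp(true), 1e-12)
        temperature = lo + (hi - lo) * np.clip(
            u + rng.normal(0, 0.1, size=n), 0, 1
        )
    else:
        temperature = rng.uniform(lo, hi, size=n)
    k_obs = np.array(
        [inverse_eyring(g, t) for g, t in zip(dG_exp, temperature)]
    )

    rxn_ids = [f"R{i:05d}" for i in range(n)]
    if config.with_smiles:
        lib = REACTION_SMILES_LIBRARY
        smiles = [lib[i % len(lib)] for i in range(n)]
    else:
        smiles = [""] * n
    reaction_table = pd.DataFrame(
        {
            "rxn_id": rxn_ids,
            "reaction_smiles": smiles,
            "nucleophile_class": [
                NUCLEOPHILE_CLASSES[i % len(NUCLEOPHILE_CLASSES)]
                for i in nuc_class_idx
            ],
            "leaving_class": [
                LEAVING_CLASSES[i % len(LEAVING_CLASSES)] for i in ele_class_idx
            ],
            "electrophile_id": [f"E{i}" for i in ele_class_idx],
            "nucleophile_id": [f"Nu{i}" for i in nuc_class_idx],
            "solvent": solvent_names,
            "temperature_K": temperature,
            "k_obs": k_obs,
            "dG_exp_kcal": dG_exp,
        }
    )

    descriptor_table = features.copy()
    descriptor_table.insert(0, "rxn_id", rxn_ids)
    descriptor_table["dG_dft"] = dG_dft
    # order columns to match the packaged manifest
    descriptor_table = descriptor_table[["rxn_id"] + feature_set_columns("X_full")]

    solvent_table = pd.DataFrame(
        [[s] + list(config.solvent_pcs[s]) for s in solvents],
        columns=["solvent", "PC1", "PC2", "PC3", "PC4", "PC5"],
    )

    truth = SyntheticTruth(
        true_barrier=true, dft_noise=dft_noise, exp_noise=exp_noise, config=config
    )
    return SyntheticDataset(
        reaction_table=reaction_table,
        descriptor_table=descriptor_table,
        solvent_table=solvent_table,
        truth=truth,
    )


@dataclass
class CompetitionConfig:
    n_competitions: int = 100
    n_sites: int = 2
    margin: float | None = None  # fixed margin; None -> exponential(margin_scale)
    margin_scale: float = 1.0
    sigma_pred: float = 0.5
    chemo_fraction: float = 0.4
    base_barrier_range: tuple[float, float] = (18.0, 30.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites < 2:
            raise ValueError("need >= 2 sites per substrate")
        if self.margin is None and not self.margin_scale > 0:
            raise ValueError("margin_scale must be > 0")
        if self.margin is not None and not self.margin > 0:
            raise ValueError("fixed margin must be > 0")


def generate_competitions(config: CompetitionConfig) -> tuple[pd.DataFrame, dict]:
    """Per-site competition table with ground truth.

    The observed major site is the argmin of the *true* barriers; predicted
    barriers add N(0, sigma_pred) noise.  Returns (site table, truth dict).
    """
    rng = np.random.default_rng(config.seed)
    halogens = ["F", "Cl", "Br", "I"]
    rows, truth_margins = [], []
    for i in range(config.n_competitions):
        sid = f"S{i:05d}"
        base = rng.uniform(*config.base_barrier_range)
        if config.margin is not None:
            margins = np.full(config.n_sites - 1, config.margin)
        else:
            margins = rng.exponential(config.margin_scale, size=config.n_sites - 1)
        true_barriers = np.concatenate([[0.0], np.sort(margins)]) + base
        order = rng.permutation(config.n_sites)
        true_barriers = true_barriers[order]
        pred = true_barriers + rng.normal(0, config.sigma_pred, size=config.n_sites)
        if rng.random() < config.chemo_fraction:
            hal = rng.choice(halogens, size=config.n_sites, replace=True)
            while len(set(hal)) == 1:
                hal = rng.choice(halogens, size=config.n_sites, replace=True)
        else:
            hal = [rng.choice(halogens)] * config.n_sites
        major = int(np.argmin(true_barriers))
        truth_margins.append(float(np.min(margins)))
        for j in range(config.n_sites):
            rows.append(
                {
                    "substrate_id": sid,
                    "site_label": f"site{j}",
                    "halogen": hal[j],
                    "dG_pred_kcal": pred[j],
                    "dG_std_kcal": config.sigma_pred,
                    "observed_major_flag": j == major,
                    "dG_true_kcal": true_barriers[j],
                }
            )
    table = pd.DataFrame(rows)
    truth = {
        "min_margins": np.asarray(truth_margins),
        "sigma_pred": config.sigma_pred,
        "config": config,
    }
    return table, truth


def write_bundle(dataset: SyntheticDataset, out_dir) -> dict:
    """Write the CSV bundle plus a truth JSON; returns the path map."""
    import json
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "reactions": out / "reactions.csv",
        "descriptors": out / "descriptors.csv",
        "solvents": out / "solvents.csv",
        "truth": out / "truth.json",
    }
    dataset.reaction_table.to_csv(paths["reactions"], index=False)
    dataset.descriptor_table.to_csv(paths["descriptors"], index=False)
    dataset.solvent_table.to_csv(paths["solvents"], index=False)
    cfg = dataset.truth.config
    truth_payload = {
        "seed": cfg.seed,
        "sigma_dft": cfg.sigma_dft,
        "sigma_exp": cfg.sigma_exp,
        "dft_offset": cfg.dft_offset,
        "dft_slope": cfg.dft_slope,
        "barrier_center": cfg.barrier_center,
        "barrier_scale": cfg.barrier_scale,
        "true_barrier": dataset.truth.true_barrier.tolist(),
    }
    with open(paths["truth"], "w") as fh:
        json.dump(truth_payload, fh, indent=1)
    return {k: str(v) for k, v in paths.items()}
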