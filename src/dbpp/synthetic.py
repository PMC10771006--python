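"""Synthetic fixtures: labeled property-profile tables, per-endpoint
descriptor training sets, and a small curated panel of real drug / non-drug
SMILES for end-to-end smoke runs.

The profile generator emulates the class-separated distributions seen when
profiling approved drugs against screening-library compounds: drug-class
physicochemical values are drawn from plausible drug ranges (lognormal MW
around ~350 g/mol, gamma-shaped TPSA, Poisson-like H-bond and rotatable-bond
counts), the non-drug class is shifted by per-coordinate standardized
effects, and ADMET coordinates are inverse-logit transforms of
class-dependent normals — so the per-coordinate generative AUC is available
in closed form, Φ(Δ / (σ√2)).  These are fixture conventions chosen for
controllability, not empirical claims about any real compound collection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .featurize import PHYSCHEM_NAMES

N_PC = 6
N_ADMET = 20

#: drug-class marginal scales used to convert standardized pc_effect shifts
#: into raw-unit shifts: (name, sd in raw units)
_PC_SD = np.array([120.0, 1.5, 35.0, 2.0, 1.2, 3.0])


@dataclass
class ProfileGeneratorConfig:
    """Knobs of the labeled-profile generator.

    ``pc_effect`` are standardized mean shifts (in drug-class sd units)
    applied to the non-drug class per physicochemical coordinate;
    ``admet_effect`` are mean shifts on the logit scale separating the drug
    and non-drug latent normals per endpoint coordinate.  ``noise_sd`` is the
    latent-normal sd of the ADMET coordinates.  The seed fully determines the
    output.
    """

    n_per_class: int = 500
    pc_effect: np.ndarray = field(default_factory=lambda: np.zeros(N_PC))
    admet_effect: np.ndarray = field(default_factory=lambda: np.zeros(N_ADMET))
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.pc_effect = np.broadcast_to(
            np.asarray(self.pc_effect, dtype=float), (N_PC,)
        ).copy()
        self.admet_effect = np.broadcast_to(
            np.asarray(self.admet_effect, dtype=float), (N_ADMET,)
        ).copy()
        if self.n_per_class <= 0:
            raise ValueError("n_per_class must be positive")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


@dataclass
class ProfileTable:
    """A labeled synthetic profile table: raw PC values, ADMET probabilities."""

    pc: pd.DataFrame      # (n, 6), columns PHYSCHEM_NAMES
    admet: pd.DataFrame   # (n, 20), columns endpoint_0..19
    y: np.ndarray         # 1 = drug-class, 0 = non-drug-class
    config: ProfileGeneratorConfig

    def stacked(self) -> np.ndarray:
        return np.hstack([self.pc.to_numpy(), self.admet.to_numpy()])


def per_coordinate_auc(delta: float, noise_sd: float = 1.0) -> float:
    """Closed-form generative AUC of one logit-normal ADMET coordinate."""
    return float(stats.norm.cdf(delta / (noise_sd * np.sqrt(2.0))))


def _drug_pc(rng: np.random.Generator, n: int) -> np.ndarray:
    mw = rng.lognormal(mean=np.log(350.0), sigma=0.35, size=n)
    logp = rng.normal(2.5, 1.5, size=n)
    tpsa = rng.gamma(shape=4.0, scale=20.0, size=n)
    hba = rng.poisson(4.0, size=n).astype(float)
    hbd = rng.poisson(1.5, size=n).astype(float)
    nrot = rng.poisson(5.0, size=n).astype(float)
    return np.column_stack([mw, logp, tpsa, hba, hbd, nrot])


def generate_profiles(config: ProfileGeneratorConfig) -> ProfileTable:
    """Generate a balanced labeled profile table under the given config.

    Drug class (label 1) PC values come from the plausible-drug marginals;
    the non-drug class is shifted by ``pc_effect`` (standardized units).
    ADMET coordinate j is inverse-logit of N(+Δj/2, σ) for drugs and
    N(−Δj/2, σ) for non-drugs, Δ = ``admet_effect``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_per_class

    pc_drug = _drug_pc(rng, n)
    pc_non = _drug_pc(rng, n) + config.pc_effect[None, :] * _PC_SD[None, :]
    pc_non[:, 0] = np.maximum(pc_non[:, 0], 16.0)   # MW stays physical
    pc_non[:, 2] = np.maximum(pc_non[:, 2], 0.0)    # TPSA >= 0
    pc_non[:, 3:] = np.maximum(pc_non[:, 3:], 0.0)  # counts >= 0

    half = config.admet_effect / 2.0
    z_drug = rng.normal(half[None, :], config.noise_sd, size=(n, N_ADMET))
    z_non = rng.normal(-half[None, :], config.noise_sd, size=(n, N_ADMET))
    admet_drug = 1.0 / (1.0 + np.exp(-z_drug))
    admet_non = 1.0 / (1.0 + np.exp(-z_non))

    pc = np.vstack([pc_drug, pc_non])
    admet = np.vstack([admet_drug, admet_non])
    y = np.concatenate([np.ones(n, dtype=int), np.zeros(n, dtype=int)])

    return ProfileTable(
        pc=pd.DataFrame(pc, columns=list(PHYSCHEM_NAMES)),
        admet=pd.DataFrame(
            admet, columns=[f"endpoint_{j}" for j in range(N_ADMET)]
        ),
        y=y,
        config=config,
    )


def generate_endpoint_dataset(
    n: int = 600,
    effect: float = 3.0,
    seed: int = 0,
    n_features: int = 200,
    n_informative: int = 20,
) -> Tuple[pd.DataFrame, np.ndarray]:
    """A balanced two-class Gaussian descriptor table for one ADMET endpoint.

    ``effect`` is the standardized mean shift applied to a seeded random
    subset of ``n_informative`` features for the positive class; the rest is
    isotropic noise.  Stands in for real endpoint training tables.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    rng = np.random.default_rng(seed)
    n_pos = n // 2
    n_neg = n - n_pos
    informative = rng.choice(n_features, size=n_informative, replace=False)
    X = rng.normal(size=(n, n_features))
    X[:n_pos, informative] += effect
    y = np.concatenate([np.ones(n_pos, dtype=int), np.zeros(n_neg, dtype=int)])
    perm = rng.permutation(n)
    cols = [f"desc_{j}" for j in range(n_features)]
    return pd.DataFrame(X[perm], columns=cols), y[perm]


def train_synthetic_panel(n: int = 600, effect: float = 3.0, algo: str = "lgbm",
                          seed: int = 0):
    """Fit the default 20-endpoint ADMET panel on synthetic endpoint tables.

    Each endpoint gets its own generated descriptor table (seed offset by the
    endpoint index) so the fitted panel emits informative, reproducible
    probabilities for smoke tests without any real endpoint data.
    """
    from .admet import EndpointPanel, default_panel, train_endpoint

    models = []
    for j, spec in enumerate(default_panel()):
        X, y = generate_endpoint_dataset(n=n, effect=effect, seed=seed + j)
        models.append(
            train_endpoint(spec, X.to_numpy(), y, algo=algo, seed=seed + j,
                           permissive=True)
        )
    return EndpointPanel(models=models)


# ---------------------------------------------------------------------------
# Curated real-molecule smoke panel

_DRUGS = [
    ("aspirin", "CC(=O)Oc1ccccc1C(=O)O"),
    ("paracetamol", "CC(=O)Nc1ccc(O)cc1"),
    ("ibuprofen", "CC(C)Cc1ccc(C(C)C(=O)O)cc1"),
    ("caffeine", "Cn1c(=O)c2c(ncn2C)n(C)c1=O"),
    ("atorvastatin", "CC(C)c1c(C(=O)Nc2ccccc2)c(-c2ccccc2)c(-c2ccc(F)cc2)n1CC[C@@H](O)C[C@@H](O)CC(=O)O"),
    ("metformin", "CN(C)C(=N)NC(=N)N"),
    ("omeprazole", "COc1ccc2[nH]c(S(=O)Cc3ncc(C)c(OC)c3C)nc2c1"),
    ("amoxicillin", "CC1(C)S[C@@H]2[C@H](NC(=O)[C@H](N)c3ccc(O)cc3)C(=O)N2[C@H]1C(=O)O"),
    ("diazepam", "CN1c2ccc(Cl)cc2C(c2ccccc2)=NCC1=O"),
    ("fluoxetine", "CNCCC(Oc1ccc(C(F)(F)F)cc1)c1ccccc1"),
    ("warfarin", "CC(=O)CC(c1ccccc1)c1c(O)c2ccccc2oc1=O"),
    ("propranolol", "CC(C)NCC(O)COc1cccc2ccccc12"),
    ("loratadine", "CCOC(=O)N1CCC(=C2c3ccc(Cl)cc3CCc3cccnc32)CC1"),
    ("sertraline", "CN[C@H]1CC[C@@H](c2ccc(Cl)c(Cl)c2)c2ccccc21"),
    ("sildenafil", "CCCc1nn(C)c2c(=O)[nH]c(-c3cc(S(=O)(=O)N4CCN(C)CC4)ccc3OCC)nc12"),
    ("celecoxib", "Cc1ccc(-c2cc(C(F)(F)F)nn2-c2ccc(S(N)(=O)=O)cc2)cc1"),
    ("losartan", "CCCCc1nc(Cl)c(CO)n1Cc1ccc(-c2ccccc2-c2nnn[nH]2)cc1"),
    ("gabapentin", "NCC1(CC(=O)O)CCCCC1"),
    ("naproxen", "COc1ccc2cc([C@H](C)C(=O)O)ccc2c1"),
    ("simvastatin", "CCC(C)(C)C(=O)O[C@H]1C[C@@H](C)C=C2C=C[C@H](C)[C@H](CC[C@@H]3C[C@@H](O)CC(=O)O3)[C@@H]21"),
]

_NON_DRUGS = [
    ("hexane", "CCCCCC"),
    ("toluene", "Cc1ccccc1"),
    ("styrene", "C=Cc1ccccc1"),
    ("aniline", "Nc1ccccc1"),
    ("phenol", "Oc1ccccc1"),
    ("acetonitrile", "CC#N"),
    ("dmso", "CS(C)=O"),
    ("thf", "C1CCOC1"),
    ("triethylamine", "CCN(CC)CC"),
    ("benzaldehyde", "O=Cc1ccccc1"),
    ("ethyl_acetate", "CCOC(C)=O"),
    ("dichlorobenzene", "Clc1ccc(Cl)cc1"),
    ("octadecane", "CCCCCCCCCCCCCCCCCC"),
    ("biphenyl", "c1ccc(-c2ccccc2)cc1"),
    ("naphthalene", "c1ccc2ccccc2c1"),
    ("cyclohexanone", "O=C1CCCCC1"),
    ("butyric_acid", "CCCC(=O)O"),
    ("nitrobenzene", "O=[N+]([O-])c1ccccc1"),
    ("pyridine", "c1ccncc1"),
    ("anisole", "COc1ccccc1"),
]


def fixture_molecules() -> pd.DataFrame:
    """~40 named SMILES: 20 approved drugs (label 1), 20 reagent-like
    non-drugs (label 0).  All pass standardization; used for oracle tests and
    end-to-end smoke runs."""
    rows = [
        {"name": n, "smiles": s, "label": 1, "source": "drug_fixture"}
        for n, s in _DRUGS
    ] + [
        {"name": n, "smiles": s, "label": 0, "source": "nondrug_fixture"}
        for n, s in _NON_DRUGS
    ]
    return pd.DataFrame(rows)
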