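"""Synthetic datasets and curated molecular fixtures.

``generate_dataset`` emulates the real skin-permeability table: descriptor
triples (cos²-transformed A log P in [0, 1], X3v >= 0, a 0/1 drug-likeness
indicator) with log Kp generated from the frozen three-descriptor full-set
equation plus Gaussian noise.  The default noise level (0.324 log units) is
the standard error of that published fit, so default-configuration data
carry a realistic signal-to-noise ratio and a log Kp range overlapping the
experimental [-6.10, -0.76].

Descriptors are sampled independently, which real data do not satisfy
(cos²-A log P and X3v correlate); the generator is meant for coefficient
recovery and pipeline exercising, not for reproducing the real data's
statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import QsarDataset
from .mlr import PUBLISHED_EQUATIONS

__all__ = ["SynthConfig", "generate_dataset", "fixture_molecules", "FixtureMolecule"]


@dataclass(frozen=True)
class SynthConfig:
    """Study-condition defaults for the synthetic descriptor table."""

    n: int = 274
    noise_sd: float = 0.324
    cos2_range: tuple = (0.0, 1.0)
    x3v_range: tuple = (0.0, 8.0)
    neoplastic_p: float = 0.25
    equation_id: str = "three_descriptor_full"
    seed: int = 0

    def __post_init__(self):
        if self.n < 10:
            raise ValueError("need at least 10 compounds")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be non-negative")
        if self.equation_id not in PUBLISHED_EQUATIONS:
            raise ValueError(f"unknown equation {self.equation_id!r}")


def generate_dataset(cfg: SynthConfig = SynthConfig()) -> QsarDataset:
    """Draw a synthetic descriptor table with log Kp from a frozen equation.

    Descriptors are uniform (cos2_alogp, x3v) and Bernoulli (neoplastic80);
    log Kp adds Gaussian noise of ``cfg.noise_sd`` to the equation value.
    Fully reproducible from ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    eq = PUBLISHED_EQUATIONS[cfg.equation_id]
    cos2 = rng.uniform(*cfg.cos2_range, cfg.n)
    x3v = rng.uniform(*cfg.x3v_range, cfg.n)
    neo = rng.binomial(1, cfg.neoplastic_p, cfg.n)
    signal = np.array([
        eq.predict({"cos2_alogp": c, "x3v": x, "neoplastic80": v})
        for c, x, v in zip(cos2, x3v, neo)
    ])
    logkp = signal + rng.normal(0.0, cfg.noise_sd, cfg.n)
    frame = pd.DataFrame({
        "id": [f"S{i + 1:03d}" for i in range(cfg.n)],
        "name": [f"synthetic-{i + 1}" for i in range(cfg.n)],
        "smiles": "",
        "logkp": logkp,
        "cos2_alogp": cos2,
        "x3v": x3v,
        "neoplastic80": neo,
    })
    return QsarDataset(frame, descriptor_source="tabulated")


@dataclass(frozen=True)
class FixtureMolecule:
    """A micro-fixture: SMILES plus independently derived descriptor facts."""

    name: str
    smiles: str
    facts: dict


def fixture_molecules() -> list:
    """Curated micro-set with hand-derived connectivity values and gates.

    X3v values for the alkanes follow from enumerating 4-vertex paths by
    hand: propane has none; n-butane has one with degrees (1,2,2,1) giving
    1/sqrt(4); n-pentane has two, each (1,2,2,2) giving 2/sqrt(8); benzene
    (aromatic CH has valence degree 4 - 1 = 3) has six distinct 4-vertex
    ring paths of weight (3*3*3*3)^-1/2 each, so X3v = 6/9.
    """
    return [
        FixtureMolecule("methane", "C", {"n_heavy": 1, "x3v": 0.0}),
        FixtureMolecule("ethanol", "CCO", {
            "n_heavy": 3, "delta": (1, 2, 1), "delta_v": (1.0, 2.0, 5.0),
            "x3v": 0.0, "neoplastic80": 0,
        }),
        FixtureMolecule("propane", "CCC", {"x3v": 0.0}),
        FixtureMolecule("n-butane", "CCCC", {"x3v": 0.5}),
        FixtureMolecule("n-pentane", "CCCCC", {"x3v": 2.0 / 8.0**0.5}),
        FixtureMolecule("benzene", "c1ccccc1", {
            "n_heavy": 6, "x3v": 6.0 / 9.0, "neoplastic80": 0,
        }),
        FixtureMolecule("testosterone", "CC12CCC3C(C1CCC2O)CCC4=CC(=O)CCC34C", {
            # drug-like: keto + alcoholic hydroxyl, MW 288, inside every gate
            "neoplastic80": 1,
        }),
    ]
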