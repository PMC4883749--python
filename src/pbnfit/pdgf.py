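"""The packaged case study: deregulated PDGF signalling in GIST.

A PDGFRα D842V-driven signalling network reconstructed for the Hek293
Flp-In cell system: the doxycycline-inducible constitutively active receptor
(mPDGFR) feeding the MAPK, PI3K/AKT and PLCγ/PKC pathways plus STAT5, with
receptor-site knockouts (DV-dMAPK abrogates SHP2 recruitment, DV-dPI3K the
receptor-mediated PI3K recruitment) and four inhibitor inputs (Wortmannin,
U0126, GF109203X, Gö6976) encoded as clampable nodes.

Three model variants are shipped as rule files:

* ``initial`` — the literature-derived backbone, 27 nodes / 40 edges, 23
  optimisable selection probabilities;
* ``refined`` — adds a receptor-independent basal PKC activity rule (25
  free weights);
* ``final`` — refined plus the PI3K → MEK1,2 crosstalk (27 free weights).
  The final rule file also carries the packaged reference weights used by
  the synthetic stand-in data generator; the MEK crosstalk/main pair
  (0.226/0.774), the Wortmannin→PI3K pair (0.893/0.107) and the basal-PKC
  pair (0.997/0.003) are the published interaction strengths, the rest are
  synthetic placeholders.

The measurement data of the original study are not redistributable, so
:func:`synthetic_study_dataset` generates a stand-in with the same layout
(10 conditions × 5–6 readouts, values in [0, 1]) by simulating the reference
model and adding truncated Gaussian noise.  Users who hold the original
normalised measurements can drop them into the shipped
``data/study_data_template.csv`` layout and load them with
:func:`pbnfit.data.read_measurements_csv`.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import Condition, PBNModel
from .data import (MEASUREMENT_COLUMNS, NormalisedDataset, parse_model_text,
                   read_conditions_csv, split_dataset)
from .selection import CrosstalkCandidate, read_candidates_csv
from .steady import EstimatorSettings, estimate_marginals

VARIANTS = ("initial", "refined", "final")

#: Measured molecules (Western-blot readouts) -> model nodes.
READOUT_NODES = {
    "pSTAT5": "STAT5",
    "pPDGFR": "mPDGFR",
    "pPLCg": "PLCg",
    "pERK": "ERK",
    "pAKT": "AKT",
    "pPKC": "PKC",
}

#: The five readouts of the main dataset, in reporting order.
READOUTS = ("pSTAT5", "pPDGFR", "pPLCg", "pERK", "pAKT")


def _data_path(name: str) -> Path:
    return Path(resources.files("pbnfit").joinpath("data", name))


def build_pdgf_model(variant: str = "initial", p: float = 0.001) -> PBNModel:
    """Load one of the packaged PDGF-GIST model variants."""
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    return parse_model_text(_data_path(f"pdgf_{variant}.rules").read_text(), p=p)


def build_conditions() -> list[Condition]:
    """The 10 modelling conditions (6 training + 4 combined-perturbation).

    Every condition clamps the doxycycline input, the four inhibitor inputs
    and the two basal-activity inputs; knockout mutants additionally clamp
    the abrogated recruitment node OFF (DV-dMAPK → SHP2, DV-dPI3K →
    PI3Krec).
    """
    return read_conditions_csv(_data_path("conditions.csv"))


def additional_conditions() -> list[Condition]:
    """The PKC-inhibitor conditions of the follow-up experiment."""
    base = {"DOX": 1, "Wortmannin": 0, "U0126": 0, "GF109": 0, "Go6976": 0,
            "bPTEN": 1, "bPDK": 1}
    return [
        Condition("DV-WT+Go6976", {**base, "Go6976": 1}),
        Condition("DV-WT+GF109", {**base, "GF109": 1}),
        Condition("DV-WT+Go6976+Wortmannin", {**base, "Go6976": 1, "Wortmannin": 1}),
    ]


def load_crosstalk_candidates() -> list[CrosstalkCandidate]:
    """The nine literature-proposed crosstalk interactions."""
    return read_candidates_csv(_data_path("crosstalk_candidates.csv"))


def reference_model(p: float = 0.001) -> PBNModel:
    """The final variant carrying the packaged reference weights."""
    return build_pdgf_model("final", p=p)


def synthetic_study_dataset(seed: int = 0, noise_sd: float = 0.0,
                            sd: float = 0.05, scheme: str = "refined",
                            settings: EstimatorSettings | None = None,
                            model: PBNModel | None = None) -> NormalisedDataset:
    """Synthetic stand-in for the study's normalised measurement table.

    Simulates the packaged reference model (or ``model``) under the 10
    modelling conditions, adds truncated Gaussian noise of scale
    ``noise_sd``, and reports ``sd`` as the per-cell standard deviation.
    Negative-control phospho-readouts are fixed to zero by convention rather
    than simulated; the refined scheme additionally carries the three pPKC
    training cells.  This is generated data with the study's layout, not the
    study's measurements.
    """
    if settings is None:
        settings = EstimatorSettings(r=0.0125, s=0.95, pilot=2000)
    model = reference_model() if model is None else model
    rng = np.random.default_rng(seed)
    conditions = build_conditions()
    molecules_by_condition: dict[str, list[str]] = {
        c.name: list(READOUTS) for c in conditions}
    if scheme == "refined":
        for cond_name in ("ND", "DV-WT", "DV-WT+Wortmannin"):
            molecules_by_condition[cond_name].append("pPKC")

    rows = []
    seeds = np.random.SeedSequence(seed).generate_state(len(conditions))
    for cond_seed, condition in zip(seeds, conditions):
        molecules = molecules_by_condition[condition.name]
        nodes = [READOUT_NODES[m] for m in molecules]
        est = estimate_marginals(model, condition, nodes,
                                 settings=settings, seed=int(cond_seed))
        for molecule, node in zip(molecules, nodes):
            if condition.name == "ND" and molecule != "pPKC":
                mean = 0.0  # negative-control convention: assumed zero
            else:
                mean = est[node]
                if noise_sd > 0:
                    mean = float(np.clip(mean + rng.normal(0.0, noise_sd), 0.0, 1.0))
            rows.append({"condition": condition.name, "molecule": molecule,
                         "mean": mean, "sd": sd, "n": 3, "split": "train"})
    dataset = NormalisedDataset(pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS))
    train, valid = split_dataset(dataset, scheme=scheme)
    merged = pd.concat([train.frame, valid.frame], ignore_index=True)
    return NormalisedDataset(merged)


@dataclass
class PredictionReport:
    """Per-cell validation predictions and the within-SD summary."""

    rows: pd.DataFrame          # condition, molecule, simulated, mean, sd, within_sd
    excluded: pd.DataFrame      # cells without a usable SD
    n_within: int
    n_total: int

    def __str__(self) -> str:
        return f"{self.n_within} of {self.n_total} validation points within experimental SD"


def evaluate_predictions(model: PBNModel, validation: NormalisedDataset,
                         conditions: Sequence[Condition] | Mapping[str, Condition] | None = None,
                         settings: EstimatorSettings | None = None,
                         seed: int = 0,
                         readout_map: Mapping[str, str] | None = None) -> PredictionReport:
    """Simulate validation conditions and score predictions against data.

    A cell counts as correctly predicted when |simulated − measured mean| ≤
    measured SD.  Cells without a finite SD are excluded from the summary and
    listed separately.
    """
    if settings is None:
        settings = EstimatorSettings()
    if conditions is None:
        conditions = build_conditions()
    if isinstance(conditions, Mapping):
        by_name = dict(conditions)
    else:
        by_name = {c.name: c for c in conditions}
    readout_map = dict(readout_map or READOUT_NODES)

    cells = list(validation.cells())
    by_condition: dict[str, list[tuple[str, float, float]]] = {}
    for cond_name, molecule, mean, sd_value in cells:
        by_condition.setdefault(cond_name, []).append((molecule, mean, sd_value))

    rows, excluded = [], []
    seeds = np.random.SeedSequence(seed).generate_state(max(len(by_condition), 1))
    for cond_seed, (cond_name, triples) in zip(seeds, by_condition.items()):
        condition = by_name[cond_name]
        nodes = sorted({readout_map.get(m, m) for m, _, _ in triples})
        est = estimate_marginals(model, condition, nodes,
                                 settings=settings, seed=int(cond_seed))
        for molecule, mean, sd_value in triples:
            simulated = est[readout_map.get(molecule, molecule)]
            record = {"condition": cond_name, "molecule": molecule,
                      "simulated": simulated, "mean": mean, "sd": sd_value}
            if not np.isfinite(sd_value):
                excluded.append(record)
            else:
                record["within_sd"] = bool(abs(simulated - mean) <= sd_value)
                rows.append(record)
    frame = pd.DataFrame(rows, columns=["condition", "molecule", "simulated",
                                        "mean", "sd", "within_sd"])
    excluded_frame = pd.DataFrame(excluded, columns=["condition", "molecule",
                                                     "simulated", "mean", "sd"])
    return PredictionReport(rows=frame, excluded=excluded_frame,
                            n_within=int(frame["within_sd"].sum()) if len(frame) else 0,
                            n_total=len(frame))
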