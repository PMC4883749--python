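"""Datasets, the Western-blot normalisation pipeline, and file formats.

Measured steady-state readouts enter the fitting cost as per-(condition,
molecule) means in [0, 1].  Raw blot intensities are normalised in the order:
per-blot tubulin quality control, division by the tubulin loading control,
division by the calibrator sample of the same blot and molecule, averaging of
technical replicates within each biological replicate, pooling of biological
means, and finally division by the per-molecule maximum so every molecule's
largest mean is 1.

File formats
------------
* Rule file: one rule per line, ``target = expression , flag[:weight]``;
  ``#`` starts a comment.
* Condition CSV: columns ``condition_name, node, clamp_value``.
* Measurement CSV: columns ``condition, molecule, mean, sd, n, split``.
* Raw blot CSV: columns ``blot, condition, molecule, bio_rep, tech_rep,
  signal, tubulin, is_calibrator``.

Writers add a JSON sidecar (``<name>.meta.json``) recording settings, seed
and package version.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import BooleanRule, Condition, PBNModel
from .expr import ExpressionError, parse_expression

#: Tubulin signals below this fraction of the per-blot maximum are discarded.
TUBULIN_QC_FRACTION = 0.20

MEASUREMENT_COLUMNS = ["condition", "molecule", "mean", "sd", "n", "split"]
RAW_COLUMNS = ["blot", "condition", "molecule", "bio_rep", "tech_rep",
               "signal", "tubulin", "is_calibrator"]


class DataError(ValueError):
    pass


@dataclass(frozen=True)
class RawBlotMeasurement:
    """One quantified band: a (blot, condition, molecule, replicate) signal."""

    blot: str
    condition: str
    molecule: str
    bio_rep: int
    tech_rep: int
    signal: float
    tubulin: float
    is_calibrator: bool = False

    def __post_init__(self):
        if self.signal < 0 or self.tubulin < 0:
            raise DataError("signal and tubulin intensities must be non-negative")


class NormalisedDataset:
    """Per-(condition, molecule) normalised means with SD and split labels.

    Thin wrapper around a DataFrame with columns ``condition, molecule, mean,
    sd, n, split``.  Missing cells are simply absent rows (never imputed);
    the fitting cost skips them.
    """

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in MEASUREMENT_COLUMNS if c not in frame.columns]
        if missing:
            raise DataError(f"dataset missing column(s) {missing}")
        frame = frame[MEASUREMENT_COLUMNS].reset_index(drop=True)
        if len(frame) and ((frame["mean"] < -1e-9).any() or (frame["mean"] > 1 + 1e-9).any()):
            raise DataError("normalised means must lie in [0, 1]")
        self.frame = frame

    def __len__(self) -> int:
        return len(self.frame)

    def __eq__(self, other) -> bool:
        return isinstance(other, NormalisedDataset) and self.frame.equals(other.frame)

    def cells(self) -> Iterable[tuple[str, str, float, float]]:
        """Yield (condition, molecule, mean, sd) per non-missing cell."""
        for row in self.frame.itertuples(index=False):
            yield row.condition, row.molecule, float(row.mean), float(row.sd)

    def subset(self, split: str) -> "NormalisedDataset":
        return NormalisedDataset(self.frame[self.frame["split"] == split])

    @property
    def conditions(self) -> list[str]:
        return list(dict.fromkeys(self.frame["condition"]))

    @property
    def molecules(self) -> list[str]:
        return list(dict.fromkeys(self.frame["molecule"]))

    def with_split(self, labels: dict[str, str], default: str = "train") -> "NormalisedDataset":
        frame = self.frame.copy()
        frame["split"] = frame["condition"].map(labels).fillna(default)
        return NormalisedDataset(frame)


def normalise_raw(raw: Iterable[RawBlotMeasurement] | pd.DataFrame,
                  calibrate: bool = True) -> NormalisedDataset:
    """Run the blot normalisation pipeline on raw intensities.

    ``calibrate=False`` skips the calibrator division (tubulin and max
    normalisation only), the variant used for experiments quantified without
    a cross-blot calibrator.
    """
    if isinstance(raw, pd.DataFrame):
        df = raw.copy()
    else:
        df = pd.DataFrame([m.__dict__ for m in raw])
    missing = [c for c in RAW_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"raw data missing column(s) {missing}")
    if (df["signal"] < 0).any() or (df["tubulin"] < 0).any():
        raise DataError("negative intensities")

    # per-blot tubulin QC
    max_tub = df.groupby("blot")["tubulin"].transform("max")
    df = df[df["tubulin"] >= TUBULIN_QC_FRACTION * max_tub].copy()
    df["value"] = df["signal"] / df["tubulin"]

    if calibrate:
        cal = df[df["is_calibrator"]]
        if len(cal) == 0:
            raise DataError("no calibrator sample present")
        cal_means = cal.groupby(["blot", "molecule"])["value"].mean()
        missing_cal = set(map(tuple, df[["blot", "molecule"]].drop_duplicates().values)) \
            - set(cal_means.index)
        if missing_cal:
            raise DataError(f"blot/molecule without calibrator: {sorted(missing_cal)}")
        df["value"] = df["value"] / df.set_index(["blot", "molecule"]).index.map(cal_means).values

    df = df[~df["is_calibrator"]]
    # technical means within biological replicates, pooled across replicates
    bio = (df.groupby(["condition", "molecule", "bio_rep"])["value"]
             .mean().reset_index())
    pooled = (bio.groupby(["condition", "molecule"])["value"]
                 .agg(["mean", "std", "count"]).reset_index()
                 .rename(columns={"mean": "mean", "std": "sd", "count": "n"}))
    pooled["sd"] = pooled["sd"].fillna(0.0)
    # max-normalisation per molecule (means and SDs share the scale factor)
    mol_max = pooled.groupby("molecule")["mean"].transform("max")
    pooled = pooled[mol_max > 0].copy()
    mol_max = mol_max[mol_max > 0]
    pooled["mean"] = pooled["mean"] / mol_max
    pooled["sd"] = pooled["sd"] / mol_max
    pooled["split"] = "train"
    return NormalisedDataset(pooled.rename(columns=str)[MEASUREMENT_COLUMNS])


# --- train / validation split catalogues ----------------------------------

TRAIN_CONDITIONS = ("ND", "DV-WT", "DV-dMAPK", "DV-dPI3K",
                    "DV-WT+Wortmannin", "DV-WT+U0126")
VALIDATION_CONDITIONS = ("DV-dMAPK+Wortmannin", "DV-dMAPK+U0126",
                         "DV-dPI3K+Wortmannin", "DV-dPI3K+U0126")
#: Extra training cells of the refined scheme: the pPKC readout under no
#: induction, induction alone, and induction + Wortmannin.
REFINED_EXTRA_CELLS = (("ND", "pPKC"), ("DV-WT", "pPKC"),
                       ("DV-WT+Wortmannin", "pPKC"))


def split_dataset(data: NormalisedDataset,
                  scheme: str = "base") -> tuple[NormalisedDataset, NormalisedDataset]:
    """Split into training and validation datasets.

    ``base``: 6 single-perturbation/control conditions train, the 4
    combined-perturbation conditions validate.  ``refined``: additionally
    keeps the three pPKC cells (no-induction, induction, induction +
    Wortmannin) in the training set.
    """
    if scheme not in ("base", "refined"):
        raise DataError(f"unknown split scheme {scheme!r}")
    frame = data.frame
    if len(frame) == 0:
        return NormalisedDataset(frame.copy()), NormalisedDataset(frame.copy())
    known = set(TRAIN_CONDITIONS) | set(VALIDATION_CONDITIONS)
    unknown = sorted(set(frame["condition"]) - known)
    if unknown:
        raise DataError(f"condition name(s) not in the split catalogue: {unknown}")
    in_train = frame["condition"].isin(TRAIN_CONDITIONS)
    if scheme == "base":
        in_train &= frame["molecule"] != "pPKC"
    else:
        extra = set(REFINED_EXTRA_CELLS)
        is_extra = [
            (c, m) in extra
            for c, m in zip(frame["condition"], frame["molecule"])]
        in_train = (in_train & (frame["molecule"] != "pPKC")) | pd.Series(is_extra, index=frame.index)
    train = frame[in_train].copy()
    train["split"] = "train"
    valid = frame[frame["condition"].isin(VALIDATION_CONDITIONS)].copy()
    valid["split"] = "validation"
    return NormalisedDataset(train), NormalisedDataset(valid)


# --- rule file parsing ----------------------------------------------------

_RULE_LINE = re.compile(r"^(?P<target>[A-Za-z_][A-Za-z0-9_]*)\s*=\s*(?P<expr>[^,]+?)\s*"
                        r"(?:,\s*(?P<flag>[A-Za-z]+)\s*(?::\s*(?P<weight>[0-9.eE+-]+))?)?$")


def parse_model_text(text: str, p: float = 0.001) -> PBNModel:
    """Parse a rule file into a model.

    Raises with the offending line number on syntax errors or references to
    undeclared nodes.  Missing flags default to FIXED; missing weights to 1
    (weights are re-normalised per target by the model constructor).
    """
    entries: list[tuple[int, str, str, str, float]] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.split("#", 1)[0].strip()
        if not stripped:
            continue
        match = _RULE_LINE.match(stripped)
        if match is None:
            raise DataError(f"line {lineno}: malformed rule {stripped!r}")
        flag = (match.group("flag") or "FIXED").upper()
        weight = float(match.group("weight")) if match.group("weight") else 1.0
        entries.append((lineno, match.group("target"), match.group("expr"), flag, weight))

    rules = []
    for lineno, target, expr_text, flag, weight in entries:
        try:
            expression = parse_expression(expr_text)
        except ExpressionError as exc:
            raise DataError(f"line {lineno}: {exc}") from exc
        try:
            rules.append(BooleanRule(target, expression, weight=weight, flag=flag))
        except ValueError as exc:
            raise DataError(f"line {lineno}: {exc}") from exc
    declared = {r.target for r in rules}
    for (lineno, target, _, _, _), rule in zip(entries, rules):
        undeclared = rule.parents - declared
        if undeclared:
            raise DataError(f"line {lineno}: rule for {target} references "
                            f"undeclared node(s) {sorted(undeclared)}")
    return PBNModel(rules, p=p)


def write_model_text(model: PBNModel) -> str:
    """Serialise a model to the rule-file format (weights included)."""
    lines = [f"# {len(model.nodes)} nodes, {len(model.edges())} edges, p={model.p}"]
    for name in model.nodes:
        for rule in model.rules[name]:
            lines.append(f"{name} = {rule.expression.unparse()} , {rule.flag}:{rule.weight:.10g}")
    return "\n".join(lines) + "\n"


def read_model(path: str | Path, p: float = 0.001) -> PBNModel:
    return parse_model_text(Path(path).read_text(), p=p)


def write_model(model: PBNModel, path: str | Path) -> None:
    Path(path).write_text(write_model_text(model))


# --- condition and measurement CSVs ---------------------------------------

def read_conditions_csv(path: str | Path) -> list[Condition]:
    df = pd.read_csv(path)
    needed = {"condition_name", "node", "clamp_value"}
    if not needed.issubset(df.columns):
        raise DataError(f"condition file needs columns {sorted(needed)}")
    out = []
    for name, group in df.groupby("condition_name", sort=False):
        clamps = {str(r.node): int(r.clamp_value) for r in group.itertuples(index=False)}
        out.append(Condition(str(name), clamps))
    return out


def write_conditions_csv(conditions: Sequence[Condition], path: str | Path) -> None:
    rows = [{"condition_name": c.name, "node": n, "clamp_value": v}
            for c in conditions for n, v in sorted(c.clamps.items())]
    pd.DataFrame(rows, columns=["condition_name", "node", "clamp_value"]).to_csv(path, index=False)


def read_measurements_csv(path: str | Path) -> NormalisedDataset:
    df = pd.read_csv(path)
    if "split" not in df.columns:
        df["split"] = "train"
    if "n" not in df.columns:
        df["n"] = np.nan
    return NormalisedDataset(df)


def write_measurements_csv(data: NormalisedDataset, path: str | Path,
                           metadata: dict | None = None) -> None:
    path = Path(path)
    data.frame.to_csv(path, index=False)
    _write_sidecar(path, metadata)


def _write_sidecar(path: Path, metadata: dict | None) -> None:
    from . import __version__
    payload = {"version": __version__, **(metadata or {})}
    path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(payload, indent=2))
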