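"""End-to-end study pipeline: fit → crosstalk scan → refit → predict.

``run_study`` executes the full contextualisation workflow on a model, a
condition panel and a normalised dataset: fit the base variant, scan the
candidate crosstalks, pick the best variant (lowest fitting cost, AIC
tie-break), refit it, evaluate the validation predictions and classify the
fitted interaction weights.  Every run writes a manifest (config snapshot,
seeds, input hashes, versions, wall-clock) so results can be reproduced
bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import Condition, PBNModel
from .data import NormalisedDataset, write_model
from .fitting import FitResult, fit, summarize_top
from .pdgf import PredictionReport, evaluate_predictions
from .selection import (CrosstalkCandidate, comparison_table, crosstalk_scan)
from .steady import EstimatorSettings

#: Interaction-weight classification bins.
WEIGHT_CLASSES = (
    (0.1, "very low"),
    (0.3, "low"),
    (0.7, "medium"),
    (0.9, "high"),
    (1.0 + 1e-12, "very high"),
)


def classify_weight(weight: float) -> str:
    """Bin a selection probability: very low (<0.1), low (0.1–0.3),
    medium (0.3–0.7), high (0.7–0.9), very high (>0.9)."""
    if not (0.0 <= weight <= 1.0):
        raise ValueError(f"weight {weight} outside [0, 1]")
    for upper, label in WEIGHT_CLASSES:
        if weight <= upper:
            return label
    return "very high"


def weight_classification(result: FitResult) -> pd.DataFrame:
    weights = result.space.normalised_weights(result.best_theta)
    return pd.DataFrame({
        "parameter": result.param_names,
        "weight": weights,
        "class": [classify_weight(w) for w in weights],
    })


def _hash_text(text: str) -> str:
    return hashlib.sha256(text.encode()).hexdigest()[:16]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_study(model: PBNModel,
              train: NormalisedDataset,
              validation: NormalisedDataset,
              conditions: Sequence[Condition] | Mapping[str, Condition],
              candidates: Sequence[CrosstalkCandidate] = (),
              n_eval: int = 1000,
              scan_n_eval: int | None = None,
              n_repeats: int = 3,
              seed: int = 0,
              settings: EstimatorSettings = EstimatorSettings(),
              readout_map: Mapping[str, str] | None = None,
              algorithm: str = "de",
              out_dir: str | Path | None = None,
              **fit_kwargs) -> dict:
    """Run the full contextualisation study.

    With ``n_eval == 0`` nothing is executed: the planned stages are listed
    (dry run).  Otherwise returns a result bundle with the scan table, the
    refitted best variant, the prediction report and the weight
    classification; ``out_dir`` additionally receives CSV/JSON outputs and
    the run manifest.  ``n_repeats`` independent optimisation repeats are
    run per fitted variant and the best kept.
    """
    stages = ["fit-base", "scan-crosstalks", "select-best", "refit-best",
              "evaluate-predictions", "classify-weights"]
    if n_eval == 0:
        return {"dry_run": True, "stages": stages}
    scan_n_eval = n_eval if scan_n_eval is None else scan_n_eval
    started = time.time()
    bundle: dict = {"dry_run": False, "seed": seed}

    def repeat_fit(target_model: PBNModel, base_seed: int, budget: int) -> FitResult:
        results = [fit(target_model, train, conditions, algorithm=algorithm,
                       n_eval=budget, seed=base_seed + 17 * rep,
                       settings=settings, readout_map=readout_map, **fit_kwargs)
                   for rep in range(n_repeats)]
        return min(results, key=lambda r: r.best_sse)

    stage = "fit-base"
    try:
        base_fit = repeat_fit(model, seed, n_eval)
        bundle["base_fit"] = base_fit

        stage = "scan-crosstalks"
        scan_rows = crosstalk_scan(model, candidates, train, conditions,
                                   mode="single", n_eval=scan_n_eval,
                                   seed=seed + 5000, settings=settings,
                                   readout_map=readout_map, **fit_kwargs)
        # fold the (better-optimised) base fit into the base row
        if base_fit.best_sse < scan_rows[0].sse:
            scan_rows[0].sse = base_fit.best_sse
        bundle["scan"] = comparison_table(scan_rows)

        stage = "select-best"
        best_row = min(scan_rows, key=lambda r: (r.sse, r.aic))
        bundle["selected_variant"] = best_row.variant
        if best_row.variant == "base":
            best_model = model
        else:
            from .selection import add_crosstalk
            best_model = model
            for cand in candidates:
                if str(cand.index) == best_row.variant:
                    best_model = add_crosstalk(model, cand)
                    break

        stage = "refit-best"
        final_fit = repeat_fit(best_model, seed + 9000, n_eval)
        bundle["final_fit"] = final_fit
        bundle["top_summary"] = summarize_top(final_fit,
                                              k=min(500, len(final_fit.sses)))

        stage = "evaluate-predictions"
        report: PredictionReport = evaluate_predictions(
            final_fit.best_model(), validation, conditions=conditions,
            settings=settings, seed=seed + 13000, readout_map=readout_map)
        bundle["predictions"] = report

        stage = "classify-weights"
        bundle["weights"] = weight_classification(final_fit)
    except Exception as exc:  # preserve partial outputs with the stage name
        if out_dir is not None:
            _write_outputs(bundle, model, Path(out_dir), seed, started, failed=stage)
        raise StageError(stage, exc) from exc

    bundle["wall_clock_s"] = time.time() - started
    if out_dir is not None:
        _write_outputs(bundle, model, Path(out_dir), seed, started)
    return bundle


def _write_outputs(bundle: dict, model: PBNModel, out_dir: Path, seed: int,
                   started: float, failed: str | None = None) -> None:
    from . import __version__
    from .data import write_model_text

    out_dir.mkdir(parents=True, exist_ok=True)
    outputs = []
    if "scan" in bundle:
        bundle["scan"].to_csv(out_dir / "scan.csv", index=False)
        outputs.append("scan.csv")
    if "final_fit" in bundle:
        bundle["final_fit"].save(out_dir / "fit.json")
        write_model(bundle["final_fit"].best_model(), out_dir / "fitted_model.rules")
        outputs += ["fit.json", "fit.archive.csv", "fitted_model.rules"]
    if "predictions" in bundle:
        bundle["predictions"].rows.to_csv(out_dir / "predictions.csv", index=False)
        outputs.append("predictions.csv")
    if "weights" in bundle:
        bundle["weights"].to_csv(out_dir / "weights.csv", index=False)
        outputs.append("weights.csv")
    manifest = {
        "command": "run_study",
        "seed": seed,
        "version": __version__,
        "numpy": np.__version__,
        "model_hash": _hash_text(write_model_text(model)),
        "selected_variant": bundle.get("selected_variant"),
        "wall_clock_s": time.time() - started,
        "outputs": outputs,
        "failed_stage": failed,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
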