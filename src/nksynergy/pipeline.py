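"""One-call orchestration of the full analysis with per-stage artifacts.

Stages, in order: load → per-group donor weights → combined day-9 response
Y → imputation-map enumeration and constraint filtering → (map x family)
LOOCV selection → coefficient bootstrap on the winner → day-8 condition
comparisons.  Each stage writes a machine-readable artifact into the output
directory; a failure aborts with a stage-named error and keeps the partial
artifacts.  The summary embeds the config hash and all seeds so that
deterministic stages reproduce bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .imputation_maps import enumerate_maps
from .inference import bootstrap_beta, predict_condition
from .regression import FAMILIES, build_design, fit, select_optimal
from .imputation_maps import activation_matrix
from .resampling import (
    bootstrap_condition_distributions,
    fisher_lsd_omnibus,
    permutation_test_vs_reference,
)
from .rrelief import filter_maps
from .study_data import (
    CytokineCondition,
    FoldExpansionTable,
    load_condition_registry,
    load_fold_expansion,
    modeled_conditions,
)
from .weighting import combined_Y, deviance_weights, donor_variances

__all__ = ["RunConfig", "StageError", "run_full_analysis"]


@dataclass
class RunConfig:
    """Configuration for :func:`run_full_analysis`."""

    table: FoldExpansionTable | str | Path
    registry: Sequence[CytokineCondition] | str | Path
    out_dir: str | Path
    day: int = 9
    k_range: tuple[int, ...] = tuple(range(2, 11))
    k_rule: str = "all"
    families: tuple[str, ...] = FAMILIES
    # Model selection is regularized with Ridge (stable LOOCV extrapolation
    # on underdetermined designs); coefficient interpretation uses LASSO.
    selection_regularization: str = "ridge"
    selection_lam: float | str = 0.1
    coef_regularization: str = "lasso"
    coef_lam: float = 0.01
    n_bootstrap_beta: int = 1000
    n_condition_bootstrap: int = 10_000
    n_perm: int = 10_000
    seed: int = 0
    reference_condition: int = 3
    comparison_conditions: tuple[int, ...] = (1, 2, 3, 4, 5, 6)

    def validate(self) -> None:
        if not self.families:
            raise ValueError("family list is empty")
        unknown = set(self.families) - set(FAMILIES)
        if unknown:
            raise ValueError(f"unknown families: {sorted(unknown)}")
        if not self.k_range:
            raise ValueError("k_range is empty")

    def hash(self) -> str:
        payload = {
            k: (str(v) if isinstance(v, (Path, FoldExpansionTable)) else v)
            for k, v in asdict(self).items()
            if k not in {"table", "registry", "out_dir"}
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:16]


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name prefixes the message."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.__cause__ = cause


def run_full_analysis(config: RunConfig) -> dict:
    """Execute every stage and return the summary dict (also written to disk)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def stage(name):
        def deco(fn):
            try:
                return fn()
            except Exception as exc:  # noqa: BLE001 - re-raised with stage context
                raise StageError(name, exc) from exc

        return deco

    @stage("load")
    def loaded():
        table = (
            config.table
            if isinstance(config.table, FoldExpansionTable)
            else load_fold_expansion(config.table)
        )
        registry = (
            list(config.registry)
            if not isinstance(config.registry, (str, Path))
            else load_condition_registry(config.registry)
        )
        return table, modeled_conditions(registry)

    table, conditions = loaded

    @stage("weights")
    def weights_rows():
        rows = []
        for g in table.groups:
            var = donor_variances(table, config.day, g)
            w = deviance_weights(var, g.group_id)
            for d, v, dev, wt in zip(w.donor_ids, w.variances, w.deviances, w.weights):
                rows.append({"group": g.group_id, "donor_id": d, "variance": v, "deviance": dev, "weight": wt})
        df = pd.DataFrame(rows)
        df.to_csv(out / "weights.csv", index=False)
        return df

    _ = weights_rows

    @stage("Y")
    def response():
        Y = combined_Y(table, config.day)
        Y.as_series().rename_axis("condition_id").to_csv(out / "Y.csv")
        return Y

    Y = response

    @stage("filter_maps")
    def feasible():
        results = filter_maps(enumerate_maps(), conditions, Y, config.k_range, config.k_rule)
        payload = [
            {
                "map_index": r.map_index,
                "signature": r.map_signature,
                "constraint1": r.passes_constraint1,
                "constraint2": r.passes_constraint2,
                "k_passed": list(r.k_passed),
                "feasible": r.feasible,
            }
            for r in results
        ]
        (out / "feasible.json").write_text(json.dumps(payload, indent=2))
        keep = {r.map_index for r in results if r.feasible}
        maps = [m for m in enumerate_maps() if m.map_index in keep]
        if not maps:
            raise ValueError("no imputation map survives the constraint filter")
        return maps

    maps = feasible

    @stage("select")
    def selection():
        sel = select_optimal(
            maps, conditions, Y, config.families, config.selection_regularization, config.selection_lam
        )
        sel.table().to_csv(out / "selection.csv", index=False)
        return sel

    sel = selection

    @stage("bootstrap_beta")
    def beta():
        winner_map = next(m for m in maps if m.content_signature == sel.best.map_signature)
        bb = bootstrap_beta(
            table,
            winner_map,
            sel.best.family,
            conditions,
            n=config.n_bootstrap_beta,
            seed=config.seed,
            day=config.day,
            regularization=config.coef_regularization,
            lam=config.coef_lam,
        )
        payload = {
            "labels": list(bb.labels),
            "mean": bb.mean.tolist(),
            "sd": bb.sd.tolist(),
            "ratio": bb.ratio.tolist(),
            "call": list(bb.calls),
            "n": bb.n_replicates,
            "seed": bb.seed,
            "n_redrawn": bb.n_redrawn,
        }
        (out / "beta.json").write_text(json.dumps(payload, indent=2))
        return winner_map, bb

    winner_map, _bb = beta

    @stage("comparison")
    def comparison():
        comp = bootstrap_condition_distributions(
            table, config.comparison_conditions, n=config.n_condition_bootstrap, seed=config.seed
        )
        omnibus_p = fisher_lsd_omnibus(table, config.comparison_conditions)
        pairwise = {}
        for other in config.comparison_conditions:
            if other == config.reference_condition:
                continue
            pairwise[str(other)] = permutation_test_vs_reference(
                table, config.reference_condition, other, n_perm=config.n_perm, seed=config.seed
            )
        payload = {
            "conditions": list(comp.condition_ids),
            "mean": comp.means.tolist(),
            "ci_low": comp.ci_low.tolist(),
            "ci_high": comp.ci_high.tolist(),
            "n_bootstrap": comp.n_replicates,
            "omnibus_p": omnibus_p,
            "permutation_p_vs_reference": pairwise,
            "reference": config.reference_condition,
            "seed": config.seed,
        }
        (out / "comparison.json").write_text(json.dumps(payload, indent=2))
        return payload

    comp_payload = comparison

    @stage("summary")
    def summary():
        X = build_design(activation_matrix(winner_map, conditions), sel.best.family)
        full = fit(X, np.asarray(Y.values), config.coef_regularization, config.coef_lam)
        preds = {c.condition_id: predict_condition(full, winner_map, c) for c in conditions}
        ranked = sorted(preds, key=preds.get, reverse=True)
        payload = {
            "version": __version__,
            "config_hash": config.hash(),
            "seed": config.seed,
            "optimal_map_signature": sel.best.map_signature,
            "optimal_map_index": sel.best.map_index,
            "optimal_family": sel.best.family,
            "rss": sel.best.rss,
            "r2": sel.best.r2,
            "tie_note": sel.tie_note,
            "in_sample_predictions": {str(k): v for k, v in preds.items()},
            "ranked_conditions": ranked,
            "omnibus_p": comp_payload["omnibus_p"],
            "permutation_p_vs_reference": comp_payload["permutation_p_vs_reference"],
        }
        (out / "summary.json").write_text(json.dumps(payload, indent=2, sort_keys=True))
        return payload

    return summary
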