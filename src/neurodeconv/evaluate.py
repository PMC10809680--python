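"""Accuracy metrics and multi-panel benchmark reports.

Two metrics capture deconvolution accuracy: the CETYGO score (usable when the
true composition is unknown) and the weight RMSE / per-fraction Pearson r and
signed error (which require the truth).  Signed error is estimated minus true
proportion, so positive values mean overestimation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError
from .io import MethylationMatrix
from .panels import PanelSpec, applicable_methods


@dataclass
class EvaluationReport:
    """Tidy per-mixture table plus per-fraction summary and run metadata."""

    mixtures: pd.DataFrame
    fractions: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.mixtures.to_csv(out / "mixtures.tsv", sep="\t", index=False, float_format="%.8g")
        self.fractions.to_csv(out / "fractions.tsv", sep="\t", index=False, float_format="%.8g")
        (out / "summary.json").write_text(json.dumps(self.summary(), indent=1, default=str))

    def summary(self) -> dict:
        out = dict(self.metadata)
        if len(self.mixtures):
            out["mean_cetygo"] = float(self.mixtures["cetygo"].mean())
            out["mean_rmse"] = float(self.mixtures["rmse"].mean())
            out["n_mixtures"] = int(len(self.mixtures))
        return out

    @staticmethod
    def concat(reports: Sequence["EvaluationReport"]) -> "EvaluationReport":
        return EvaluationReport(
            mixtures=pd.concat([r.mixtures for r in reports], ignore_index=True),
            fractions=pd.concat([r.fractions for r in reports], ignore_index=True),
            metadata={"runs": [r.metadata for r in reports]},
        )


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson r; NaN when undefined (< 3 pairs or zero variance)."""
    if len(x) < 3 or np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def accuracy_metrics(truth: pd.DataFrame, estimates: pd.DataFrame) -> EvaluationReport:
    """Compare estimated against true weight tables.

    Both tables need a ``sample_id`` column and one column per fraction.
    Returns a report with per-mixture RMSE and signed errors and a pooled
    per-fraction summary (Pearson r across mixtures, RMSE, median signed
    error).  r is reported as NaN (undefined), never 0, for fewer than 3
    mixtures or degenerate variance.
    """
    fracs = [c for c in truth.columns if c != "sample_id"]
    missing = set(fracs) - set(estimates.columns)
    if missing:
        raise ParameterError(f"estimates missing fraction columns {sorted(missing)}")
    merged = truth.merge(estimates, on="sample_id", suffixes=(":true", ":est"))
    if len(merged) != len(truth):
        raise ParameterError("sample ids of truth and estimates do not match")
    rows = []
    for _, r in merged.iterrows():
        err = np.array([r[f"{f}:est"] - r[f"{f}:true"] for f in fracs])
        row = {"sample_id": r["sample_id"], "rmse": float(np.sqrt(np.mean(err**2)))}
        for f, e in zip(fracs, err):
            row[f"err:{f}"] = float(e)
            row[f"est:{f}"] = float(r[f"{f}:est"])
            row[f"true:{f}"] = float(r[f"{f}:true"])
        rows.append(row)
    mixtures = pd.DataFrame(rows)
    fractions = fraction_summary(mixtures, fracs)
    return EvaluationReport(mixtures=mixtures, fractions=fractions)


def fraction_summary(mixtures: pd.DataFrame, fracs: Sequence[str]) -> pd.DataFrame:
    """Per-fraction Pearson r, RMSE and median signed error pooled over rows."""
    rows = []
    for f in fracs:
        est = mixtures[f"est:{f}"].to_numpy(dtype=float)
        true = mixtures[f"true:{f}"].to_numpy(dtype=float)
        err = est - true
        row = {
            "fraction": f,
            "pearson_r": _pearson(true, est),
            "rmse": float(np.sqrt(np.mean(err**2))),
            "median_signed_error": float(np.median(err)),
            "n": int(len(err)),
        }
        for col in ("panel", "method", "n_per_type"):
            if col in mixtures.columns:
                row[col] = mixtures[col].iloc[0]
        rows.append(row)
    return pd.DataFrame(rows)


def benchmark_panels(
    ref: MethylationMatrix,
    sheet: pd.DataFrame,
    panels: Sequence[PanelSpec],
    methods: Sequence[str] = ("anova", "idol"),
    n_per_type: int = 100,
    n_splits: int = 10,
    seed: int = 0,
    idol_kwargs: dict | None = None,
) -> EvaluationReport:
    """Run the validation for every applicable (panel, method) pair.

    IDOL is applicable only to panels with K > 2 cell types; inapplicable or
    failing pairs are recorded in the metadata (``skipped`` / ``failed``)
    and the run continues.  All pairs share the same seed for comparability.
    """
    from .simulate import run_validation

    reports = []
    skipped, failed = [], []
    for panel in panels:
        for method in methods:
            if method not in applicable_methods(panel):
                skipped.append({"panel": panel.panel_id, "method": method,
                                "reason": f"K={panel.k} <= 2"})
                continue
            try:
                reports.append(
                    run_validation(
                        ref, sheet, panel, method=method, n_per_type=n_per_type,
                        n_splits=n_splits, seed=seed, idol_kwargs=idol_kwargs,
                    )
                )
            except Exception as exc:  # noqa: BLE001 - per-pair failures must not abort
                failed.append({"panel": panel.panel_id, "method": method, "error": str(exc)})
    combined = EvaluationReport.concat(reports) if reports else EvaluationReport(
        mixtures=pd.DataFrame(), fractions=pd.DataFrame()
    )
    combined.metadata["skipped"] = skipped
    combined.metadata["failed"] = failed
    combined.metadata["n_models"] = len(reports)
    combined.metadata["seed"] = seed
    return combined
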