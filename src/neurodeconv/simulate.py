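"""Pseudo-bulk mixture simulation and the train/test validation experiment.

Reconstructed ("pseudo-bulk") profiles are weighted linear sums of purified
cell-fraction profiles with pre-specified proportions.  The composition grid
enumerates every proportion vector on a 0.1 step where each cell type holds
at least 0.1, at most 0.9, and the total is exactly 1 — C(9, K-1) mixtures
for K cell types (9, 36, 84, 126 for K = 2..5).

``run_validation`` performs the repeated hold-out experiment: per split, one
sample of each fraction is held out, a deconvolution model is trained on the
rest, pseudo-bulk mixtures are built from the held-out samples over the full
grid, deconvolved, and scored (CETYGO and RMSE/signed error vs the known
truth).  With 10 splits this evaluates |grid(K)| x 10 mixtures, i.e. 90 for
K = 2 up to 1260 for K = 5.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InfeasibilityError, ParameterError
from .io import MethylationMatrix
from .panels import PanelSpec, subset_reference
from .projection import cetygo_score, project_cell_types
from .selection import anova_select, idol_select


@dataclass
class CompositionGrid:
    k: int
    step: float
    rows: np.ndarray  # n_mixtures x K, each row sums to 1

    @property
    def n_mixtures(self) -> int:
        return self.rows.shape[0]


@dataclass
class MixtureSet:
    """Pseudo-bulk profiles plus the true weights that generated them."""

    bulk: MethylationMatrix
    truth: pd.DataFrame  # sample_id + one column per fraction
    split_id: int


def composition_grid(k: int, step: float = 0.1) -> CompositionGrid:
    """Enumerate all weight vectors on the grid (multiples of ``step``,
    minimum ``step`` per cell type, summing to 1)."""
    if abs(round(1.0 / step) - 1.0 / step) > 1e-9:
        raise ParameterError(f"1/step must be integral, got step={step}")
    s = round(1.0 / step)
    if k < 2:
        raise ParameterError(
            f"K={k} infeasible: a single cell type would need proportion 1.0 > {1 - step:g}"
        )
    if k > s:
        raise ParameterError(f"K={k} cell types cannot each hold >= {step} summing to 1")
    rows = []
    # compositions of s into k positive parts via cut points (stars and bars)
    for cuts in combinations(range(1, s), k - 1):
        bounds = (0, *cuts, s)
        rows.append([(bounds[i + 1] - bounds[i]) * step for i in range(k)])
    arr = np.asarray(rows, dtype=float)
    return CompositionGrid(k=k, step=step, rows=arr)


def reconstruct_bulk(profiles: np.ndarray, weights: Sequence[float]) -> np.ndarray:
    """Weighted linear sum of cell-type beta profiles (columns of ``profiles``)."""
    profiles = np.asarray(profiles, dtype=float)
    w = np.asarray(weights, dtype=float)
    if profiles.shape[1] != w.shape[0]:
        raise ParameterError(
            f"{profiles.shape[1]} profiles but {w.shape[0]} weights"
        )
    if (w < 0).any():
        raise ParameterError("mixture weights must be non-negative")
    return profiles @ w


def make_splits(
    ref: MethylationMatrix,
    sheet: pd.DataFrame,
    panel: PanelSpec,
    n_splits: int = 10,
    seed: int = 0,
) -> list[tuple[pd.DataFrame, pd.DataFrame]]:
    """Hold-one-out-per-fraction train/test splits.

    Per split exactly one sample of each panel fraction is held out (samples
    may recur as held-out across splits).  Returns (train_sheet, test_sheet)
    pairs; deterministic given ``seed``.
    """
    _, sheet_p = subset_reference(ref, sheet, panel)
    rng = np.random.default_rng(seed)
    splits = []
    for _ in range(n_splits):
        test_ids = []
        for frac in panel.fraction_labels:
            ids = sheet_p.loc[sheet_p["fraction_label"] == frac, "sample_id"].to_numpy()
            if len(ids) < 2:
                raise InfeasibilityError(f"fraction {frac!r} has < 2 samples")
            test_ids.append(rng.choice(ids))
        test = sheet_p[sheet_p["sample_id"].isin(test_ids)].reset_index(drop=True)
        train = sheet_p[~sheet_p["sample_id"].isin(test_ids)].reset_index(drop=True)
        splits.append((train, test))
    return splits


def make_mixtures(
    ref: MethylationMatrix,
    test_sheet: pd.DataFrame,
    panel: PanelSpec,
    grid: CompositionGrid,
    split_id: int = 0,
) -> MixtureSet:
    """Reconstruct pseudo-bulk profiles from one held-out sample per fraction."""
    profiles = np.column_stack(
        [
            ref.data[test_sheet.loc[test_sheet["fraction_label"] == f, "sample_id"].iloc[0]]
            for f in panel.fraction_labels
        ]
    )
    bulk_values = profiles @ grid.rows.T  # sites x n_mixtures
    names = [f"s{split_id}_mix{i:04d}" for i in range(grid.n_mixtures)]
    bulk = MethylationMatrix(
        pd.DataFrame(bulk_values, index=ref.data.index, columns=names), validate=False
    )
    truth = pd.DataFrame(grid.rows, columns=list(panel.fraction_labels))
    truth.insert(0, "sample_id", names)
    return MixtureSet(bulk=bulk, truth=truth, split_id=split_id)


def _train(method: str, ref, train_sheet, panel, n_per_type, seed, idol_kwargs):
    if method == "anova":
        return anova_select(ref, train_sheet, panel, n_per_type=n_per_type)
    if method == "idol":
        kw = dict(idol_kwargs or {})
        kw.setdefault("seed", seed)
        return idol_select(ref, train_sheet, panel, **kw)
    raise ParameterError(f"unknown selection method {method!r}")


def run_validation(
    ref: MethylationMatrix,
    sheet: pd.DataFrame,
    panel: PanelSpec,
    method: str = "anova",
    n_per_type: int = 100,
    n_splits: int = 10,
    seed: int = 0,
    step: float = 0.1,
    idol_kwargs: dict | None = None,
):
    """Repeated hold-out validation of a panel/selection-method combination.

    Returns an :class:`~neurodeconv.evaluate.EvaluationReport` whose mixture
    table has one row per (split, grid mixture) with the CETYGO score, the
    weight RMSE against the known truth and per-fraction signed errors, and
    whose fraction table pools Pearson r / RMSE / median signed error across
    all splits.
    """
    from .evaluate import EvaluationReport, fraction_summary

    grid = composition_grid(panel.k, step=step)
    splits = make_splits(ref, sheet, panel, n_splits=n_splits, seed=seed)
    frames = []
    models = []
    for split_id, (train_sheet, test_sheet) in enumerate(splits):
        model = _train(method, ref, train_sheet, panel, n_per_type, seed + split_id, idol_kwargs)
        models.append(model)
        mixtures = make_mixtures(ref, test_sheet, panel, grid, split_id=split_id)
        bulk_sub = mixtures.bulk.data.loc[model.site_ids].to_numpy()
        rows = []
        for i, sample_id in enumerate(mixtures.truth["sample_id"]):
            b = bulk_sub[:, i]
            w, n_used = project_cell_types(b, model)
            score = cetygo_score(b, model, w)
            true_w = grid.rows[i]
            rmse = float(np.sqrt(np.mean((w - true_w) ** 2)))
            row = {
                "split": split_id,
                "sample_id": sample_id,
                "cetygo": score,
                "rmse": rmse,
                "n_sites_used": n_used,
            }
            for frac, est, tru in zip(panel.fraction_labels, w, true_w):
                row[f"est:{frac}"] = float(est)
                row[f"true:{frac}"] = float(tru)
                row[f"err:{frac}"] = float(est - tru)
            rows.append(row)
        frames.append(pd.DataFrame(rows))
    mixtures_df = pd.concat(frames, ignore_index=True)
    mixtures_df.insert(0, "panel", panel.panel_id)
    mixtures_df.insert(1, "method", method)
    mixtures_df.insert(2, "n_per_type", n_per_type if method == "anova" else -1)
    fractions_df = fraction_summary(mixtures_df, list(panel.fraction_labels))
    metadata = {
        "panel": panel.panel_id,
        "method": method,
        "n_per_type": n_per_type,
        "n_splits": n_splits,
        "seed": seed,
        "grid_size": grid.n_mixtures,
        "n_mixtures_total": grid.n_mixtures * n_splits,
        "model_sizes": [m.n_sites for m in models],
    }
    return EvaluationReport(mixtures=mixtures_df, fractions=fractions_df, metadata=metadata)


def site_count_sweep(
    ref: MethylationMatrix,
    sheet: pd.DataFrame,
    panel: PanelSpec,
    method: str = "anova",
    counts: Sequence[int] = tuple(range(20, 201, 20)),
    n_splits: int = 10,
    seed: int = 0,
    idol_kwargs: dict | None = None,
) -> dict[int, "object"]:
    """Re-run the validation at a range of sites-per-cell-type counts.

    For ANOVA the count is ``n_per_type``; for IDOL it sets the library size
    to ``count x K``.  Returns {count: EvaluationReport}.
    """
    out = {}
    for count in counts:
        kw = dict(idol_kwargs or {})
        if method == "idol":
            kw["library_size"] = count * panel.k
        out[count] = run_validation(
            ref, sheet, panel, method=method, n_per_type=count,
            n_splits=n_splits, seed=seed, idol_kwargs=kw or None,
        )
    return out
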