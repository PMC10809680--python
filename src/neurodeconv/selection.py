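"""Training deconvolution models: cell-specific site selection + reference means.

Two selection strategies are provided.

``anova_select``
    Per-fraction one-vs-rest pooled-variance t-tests (the pickCompProbes
    approach popularised by minfi's estimateCellCounts): sites with two-sided
    p < 1e-8 are candidates; for each fraction the top n/2 hypermethylated
    (largest positive t) and n/2 hypomethylated (largest negative t)
    candidates are kept, and the deduplicated union over fractions defines
    the model sites.  Deterministic; ties broken by larger absolute mean
    difference, then lexicographic site id.

``idol_select``
    IDOL (IDentifying Optimal Libraries): starting from a large t-ranked
    candidate pool, iteratively samples site libraries according to
    per-site inclusion weights, scores each library by the mean RMSE of
    deconvolved vs true proportions on internal reconstructed mixtures of
    known composition, up/down-weights sites by their leave-one-out effect,
    and keeps the best-scoring library.

A trained :class:`DeconvolutionModel` stores the selected site ids, the
M x K matrix of per-fraction reference means (mu) and provenance, and can be
serialized to a single JSON bundle.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ApplicabilityError, ParameterError, SelectionError
from .io import MethylationMatrix
from .panels import PanelSpec, subset_reference
from .projection import project_many


@dataclass
class DeconvolutionModel:
    """Selected cell-specific sites plus per-fraction reference means."""

    site_ids: list[str]
    mu: np.ndarray  # M x K, beta scale
    fraction_labels: list[str]
    method: str  # "anova" | "idol"
    n_per_type: int | None = None
    provenance: dict = field(default_factory=dict)

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    @property
    def k(self) -> int:
        return len(self.fraction_labels)

    def mu_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.mu, index=self.site_ids, columns=self.fraction_labels)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "site_ids": self.site_ids,
            "mu": [[float(v) for v in row] for row in self.mu],
            "fraction_labels": self.fraction_labels,
            "method": self.method,
            "n_per_type": self.n_per_type,
            "provenance": self.provenance,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "DeconvolutionModel":
        payload = json.loads(Path(path).read_text())
        return cls(
            site_ids=list(payload["site_ids"]),
            mu=np.asarray(payload["mu"], dtype=float),
            fraction_labels=list(payload["fraction_labels"]),
            method=payload["method"],
            n_per_type=payload.get("n_per_type"),
            provenance=payload.get("provenance", {}),
        )


def compute_reference_means(
    ref: MethylationMatrix, sheet: pd.DataFrame, site_ids: Sequence[str],
    fraction_labels: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-fraction arithmetic means of beta values at the given sites.

    Reference data must be complete (no missing values) over the selected
    sites.  Returns an M x K DataFrame (rows = sites, columns = fractions).
    """
    sub = ref.data.loc[list(site_ids)]
    if fraction_labels is None:
        fraction_labels = list(dict.fromkeys(sheet["fraction_label"]))
    cols = {}
    for frac in fraction_labels:
        ids = sheet.loc[sheet["fraction_label"] == frac, "sample_id"]
        block = sub.loc[:, list(ids)]
        if block.isna().any().any():
            site = block.index[block.isna().any(axis=1)][0]
            raise ParameterError(
                f"missing value at selected site {site!r} in fraction {frac!r}; "
                "reference data must be complete over model sites"
            )
        cols[frac] = block.mean(axis=1)
    return pd.DataFrame(cols)


def t_statistics_one_vs_rest(values: np.ndarray, in_group: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise pooled-variance two-sample t-test of group vs rest.

    Returns (t, two-sided p).  ``values`` is sites x samples; ``in_group`` a
    boolean sample mask.  Degrees of freedom n1 + n2 - 2.
    """
    a = values[:, in_group]
    b = values[:, ~in_group]
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # near-constant rows (e.g. clipped values) trigger benign precision warnings
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=True)
    t = np.nan_to_num(t, nan=0.0)
    p = np.where(np.isnan(p), 1.0, p)
    return t, p


def _rank_order(t: np.ndarray, absdiff: np.ndarray, site_ids: np.ndarray) -> np.ndarray:
    """Indices sorted by descending t, then descending |mean diff|, then site id."""
    # np.lexsort sorts ascending by the last key first
    return np.lexsort((site_ids, -absdiff, -t))


def anova_select(
    ref: MethylationMatrix,
    sheet: pd.DataFrame,
    panel: PanelSpec,
    n_per_type: int = 100,
    p_threshold: float = 1e-8,
    f_prefilter: bool = False,
) -> DeconvolutionModel:
    """Select cell-specific sites by thresholded one-vs-rest t-ranking.

    ``n_per_type`` is the total number of sites per fraction, split evenly
    between hypermethylated and hypomethylated (n/2 each).  Candidate sites
    must pass two-sided p < ``p_threshold``; if one direction has too few
    candidates the deficit is backfilled from the other direction (with a
    warning).  ``f_prefilter`` additionally gates candidates by a global
    one-way F-test across fractions at the same threshold.
    """
    ref_p, sheet_p = subset_reference(ref, sheet, panel)
    values = ref_p.values
    if np.isnan(values).any():
        raise ParameterError("reference matrix has missing values; training needs complete data")
    site_ids = np.asarray(ref_p.site_ids)
    labels = np.asarray(sheet_p["fraction_label"])
    # align columns to sheet order
    values = ref_p.data.loc[:, list(sheet_p["sample_id"])].to_numpy()

    f_ok = np.ones(len(site_ids), dtype=bool)
    if f_prefilter:
        groups = [values[:, labels == f] for f in panel.fraction_labels]
        _, f_p = stats.f_oneway(*groups, axis=1)
        f_ok = np.where(np.isnan(f_p), 1.0, f_p) < p_threshold

    n_half = n_per_type // 2
    chosen: dict[str, list[str]] = {}
    for frac in panel.fraction_labels:
        in_group = labels == frac
        t, p = t_statistics_one_vs_rest(values, in_group)
        mean_diff = values[:, in_group].mean(axis=1) - values[:, ~in_group].mean(axis=1)
        candidates = (p < p_threshold) & f_ok
        if not candidates.any():
            raise SelectionError(
                f"no site passes p < {p_threshold:g} for fraction {frac!r}"
            )
        idx = np.flatnonzero(candidates)
        order = _rank_order(t[idx], np.abs(mean_diff[idx]), site_ids[idx])
        ranked = idx[order]  # descending t
        hyper = [i for i in ranked if t[i] > 0][:n_half]
        hypo = [i for i in ranked[::-1] if t[i] < 0][:n_half]
        deficit = (n_half - len(hyper)) + (n_half - len(hypo))
        if deficit > 0:
            warnings.warn(
                f"fraction {frac!r}: fewer than {n_half} candidates in one direction; "
                "backfilling from the other", stacklevel=2,
            )
            taken = set(hyper) | set(hypo)
            extra = [i for i in ranked if i not in taken][: n_half - len(hyper)]
            hyper += extra
            taken |= set(extra)
            extra = [i for i in ranked[::-1] if i not in taken][: n_half - len(hypo)]
            hypo += extra
        chosen[frac] = [site_ids[i] for i in hyper + hypo]

    selected = sorted(set().union(*chosen.values()))
    mu = compute_reference_means(ref_p, sheet_p, selected, panel.fraction_labels)
    return DeconvolutionModel(
        site_ids=selected,
        mu=mu.to_numpy(),
        fraction_labels=list(panel.fraction_labels),
        method="anova",
        n_per_type=n_per_type,
        provenance={
            "p_threshold": p_threshold,
            "f_prefilter": f_prefilter,
            "per_fraction_sites": {f: list(map(str, s)) for f, s in chosen.items()},
        },
    )


def _loo_scores(
    mu_lib: np.ndarray, bulk: np.ndarray, truth: np.ndarray, base_w: np.ndarray
) -> np.ndarray:
    """Leave-one-site-out mixture RMSE for every site of a library.

    Uses rank-one downdates of the normal equations (the exact unconstrained
    solution); columns where a downdated weight goes negative are re-solved
    with NNLS.  Returns the mean weight-RMSE after removing each site.
    """
    from .projection import _nnls

    m, k = mu_lib.shape
    ata = mu_lib.T @ mu_lib
    atb = mu_lib.T @ bulk
    scores = np.empty(m)
    for j in range(m):
        a_j = ata - np.outer(mu_lib[j], mu_lib[j])
        b_j = atb - np.outer(mu_lib[j], bulk[j])
        try:
            w = np.linalg.solve(a_j, b_j)
        except np.linalg.LinAlgError:
            scores[j] = np.inf  # singular without this site: maximally beneficial
            continue
        bad = (w < 0).any(axis=0)
        if bad.any():
            rows = np.arange(m) != j
            for c in np.flatnonzero(bad):
                w[:, c] = _nnls(mu_lib[rows], bulk[rows, c])
        err = w - truth.T
        scores[j] = float(np.mean(np.sqrt(np.mean(err**2, axis=0))))
    return scores


def idol_select(
    ref: MethylationMatrix,
    sheet: pd.DataFrame,
    panel: PanelSpec,
    candidate_per_type: int = 150,
    library_size: int | None = None,
    max_iter: int = 300,
    seed: int = 0,
    patience: int = 50,
    p_threshold: float = 1e-8,
) -> DeconvolutionModel:
    """Select a site library with the IDOL iterative optimisation.

    Only applicable to panels with K > 2 cell types.  The candidate pool
    takes, per fraction, the ``candidate_per_type`` sites with largest and
    the ``candidate_per_type`` with smallest one-vs-rest t-statistics.
    Internal test mixtures are reconstructed from one randomly chosen
    training sample per fraction combined over the full 0.1-step composition
    grid.  Each iteration samples ``library_size`` sites according to the
    current inclusion weights, deconvolves the mixtures, scores the mean
    RMSE of estimated vs true proportions, and multiplicatively up/down
    weights sites by their leave-one-out effect (factor 1 +/- 0.1).  The
    incumbent library is replaced whenever the score improves; the search
    stops after ``max_iter`` iterations or ``patience`` non-improving ones.
    Deterministic given ``seed``.
    """
    from .simulate import composition_grid  # local import to avoid a cycle

    if panel.k <= 2:
        raise ApplicabilityError(
            f"IDOL applies only to panels with > 2 cell types (panel {panel.panel_id!r} has K={panel.k})"
        )
    ref_p, sheet_p = subset_reference(ref, sheet, panel)
    values = ref_p.data.loc[:, list(sheet_p["sample_id"])].to_numpy()
    if np.isnan(values).any():
        raise ParameterError("reference matrix has missing values; training needs complete data")
    site_ids = np.asarray(ref_p.site_ids)
    labels = np.asarray(sheet_p["fraction_label"])
    k = panel.k
    if library_size is None:
        library_size = 50 * k

    # candidate pool: per fraction, extremes of the t-statistic ranking
    pool_idx: set[int] = set()
    for frac in panel.fraction_labels:
        in_group = labels == frac
        t, _ = t_statistics_one_vs_rest(values, in_group)
        mean_diff = values[:, in_group].mean(axis=1) - values[:, ~in_group].mean(axis=1)
        order = _rank_order(t, np.abs(mean_diff), site_ids)
        pool_idx.update(order[:candidate_per_type])
        pool_idx.update(order[::-1][:candidate_per_type])
    pool = np.array(sorted(pool_idx))
    if library_size > len(pool):
        raise ParameterError(
            f"library_size {library_size} exceeds candidate pool of {len(pool)} sites"
        )

    rng = np.random.default_rng(seed)
    # reference means over pool sites, from all training samples
    mu_pool = np.column_stack(
        [values[pool][:, labels == f].mean(axis=1) for f in panel.fraction_labels]
    )
    # internal test mixtures: one random training sample per fraction x full grid
    donors = np.column_stack(
        [values[pool][:, rng.choice(np.flatnonzero(labels == f))] for f in panel.fraction_labels]
    )
    grid = composition_grid(k).rows  # n_mix x K
    bulk = donors @ grid.T  # pool x n_mix

    weights = np.ones(len(pool))
    best_score = np.inf
    first_score = None
    best_lib: np.ndarray | None = None
    since_improved = 0
    iterations = 0
    for _ in range(max_iter):
        iterations += 1
        probs = weights / weights.sum()
        lib = rng.choice(len(pool), size=library_size, replace=False, p=probs)
        lib.sort()
        mu_lib = mu_pool[lib]
        w_est = project_many(bulk[lib], mu_lib)
        err = w_est - grid.T
        score = float(np.mean(np.sqrt(np.mean(err**2, axis=0))))
        if first_score is None:
            first_score = score
        if score < best_score:
            best_score, best_lib = score, lib
            since_improved = 0
        else:
            since_improved += 1
        # leave-one-out: sites whose removal worsens the fit are beneficial
        loo = _loo_scores(mu_lib, bulk[lib], grid, w_est)
        delta = loo - score
        weights[lib[delta > 0]] *= 1.1
        weights[lib[delta < 0]] *= 0.9
        weights /= weights.mean()
        if since_improved >= patience:
            break

    assert best_lib is not None
    selected = [str(s) for s in site_ids[pool[best_lib]]]
    mu = compute_reference_means(ref_p, sheet_p, selected, panel.fraction_labels)
    return DeconvolutionModel(
        site_ids=selected,
        mu=mu.to_numpy(),
        fraction_labels=list(panel.fraction_labels),
        method="idol",
        n_per_type=None,
        provenance={
            "seed": seed,
            "candidate_per_type": candidate_per_type,
            "library_size": library_size,
            "max_iter": max_iter,
            "patience": patience,
            "iterations_run": iterations,
            "first_score": first_score,
            "best_score": best_score,
        },
    )
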