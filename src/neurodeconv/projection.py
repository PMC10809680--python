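"""Constrained-projection estimation of cell proportions and the CETYGO score.

Given a reference mean matrix mu (M sites x K cell types) and a bulk beta
vector b, cell proportions w are estimated by least squares under
non-negativity:

    w_hat = argmin_w  sum_j ( b_j - sum_k w_k mu_jk )^2   s.t.  w_k >= 0.

This is the Houseman constrained-projection model; by default no sum
constraint is imposed, so the weights need not total 1 (optional ``sumleq`` /
``sumeq`` constraints are available).  Missing bulk values are dropped from
the objective per sample.

CETYGO (CEll TYpe deconvolution GOodness) is the root mean square error
between the observed bulk profile and its reconstruction mu @ w_hat over the
non-missing model sites.  Zero means a perfect fit; empirically, scores above
0.1 indicate an incorrect or incomplete reference panel.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import optimize

from .errors import CoverageError, ParameterError
from .io import MethylationMatrix

#: CETYGO level above which the reference panel is likely incomplete/incorrect.
CETYGO_PANEL_THRESHOLD = 0.1

#: Interpretive flag attached to results whose CETYGO exceeds the threshold.
PANEL_FLAG = "incomplete/incorrect reference panel"


def interpret_cetygo(score: float) -> str | None:
    """Return an interpretive flag for a CETYGO score, or None if unremarkable."""
    if score > CETYGO_PANEL_THRESHOLD:
        return PANEL_FLAG
    return None


def _nnls(mu: np.ndarray, b: np.ndarray) -> np.ndarray:
    w, _ = optimize.nnls(mu, b)
    return w


def _constrained(mu: np.ndarray, b: np.ndarray, constraint: str) -> np.ndarray:
    """Solve the projection with an additional sum constraint via SLSQP."""
    k = mu.shape[1]
    w0 = np.full(k, 1.0 / k)
    ata = mu.T @ mu
    atb = mu.T @ b

    def obj(w):
        return float(w @ ata @ w - 2 * atb @ w)

    def grad(w):
        return 2 * (ata @ w - atb)

    cons = []
    if constraint == "sumleq":
        cons.append({"type": "ineq", "fun": lambda w: 1.0 - w.sum(), "jac": lambda w: -np.ones(k)})
    elif constraint == "sumeq":
        cons.append({"type": "eq", "fun": lambda w: w.sum() - 1.0, "jac": lambda w: np.ones(k)})
    else:
        raise ParameterError(f"unknown constraint {constraint!r}")
    res = optimize.minimize(
        obj, w0, jac=grad, bounds=[(0.0, None)] * k, constraints=cons, method="SLSQP",
        options={"maxiter": 200, "ftol": 1e-14},
    )
    return np.clip(res.x, 0.0, None)


def project_cell_types(
    bulk_vector: np.ndarray,
    model,
    constraint: str = "nonneg",
    min_coverage: float = 0.5,
) -> tuple[np.ndarray, int]:
    """Estimate non-negative cell proportions for one bulk sample.

    Parameters
    ----------
    bulk_vector
        Beta values at the model's M sites (NaN = missing, dropped).
    model
        A trained deconvolution model, or directly an M x K reference mean
        matrix mu.
    constraint
        ``"nonneg"`` (default), ``"sumleq"`` (sum <= 1) or ``"sumeq"`` (sum == 1).

    Returns the weight vector and the number of sites used.  Raises
    :class:`CoverageError` when fewer than ``min_coverage`` of the model sites
    are present.
    """
    b = np.asarray(bulk_vector, dtype=float)
    mu = np.asarray(getattr(model, "mu", model), dtype=float)
    if b.shape[0] != mu.shape[0]:
        raise ParameterError(f"bulk vector length {b.shape[0]} != model sites {mu.shape[0]}")
    mask = ~np.isnan(b)
    n_used = int(mask.sum())
    if n_used < min_coverage * mu.shape[0] or n_used == 0:
        raise CoverageError(
            f"only {n_used}/{mu.shape[0]} model sites present in bulk sample "
            f"(need >= {min_coverage:.0%})"
        )
    if n_used < mu.shape[0]:
        warnings.warn(f"bulk sample covers {n_used}/{mu.shape[0]} model sites", stacklevel=2)
    mu_used, b_used = mu[mask], b[mask]
    if np.linalg.matrix_rank(mu_used) < mu.shape[1]:
        # nnls still returns a (minimum-norm within its active set) solution
        warnings.warn("reference mean matrix is rank deficient over the used sites", stacklevel=2)
    if constraint == "nonneg":
        return _nnls(mu_used, b_used), n_used
    return _constrained(mu_used, b_used, constraint), n_used


def project_many(bulk: np.ndarray, mu: np.ndarray) -> np.ndarray:
    """Vectorised non-negative projection of many complete bulk vectors.

    ``bulk`` is M x n (no missing values).  Solves the unconstrained normal
    equations for all samples at once and falls back to per-sample NNLS only
    where the unconstrained solution leaves the feasible region.  Returns a
    K x n weight matrix.
    """
    mu = np.asarray(mu, dtype=float)
    bulk = np.asarray(bulk, dtype=float)
    ata = mu.T @ mu
    atb = mu.T @ bulk
    try:
        w = np.linalg.solve(ata, atb)
    except np.linalg.LinAlgError:
        w = np.linalg.lstsq(mu, bulk, rcond=None)[0]
    bad = (w < 0).any(axis=0)
    if bad.any():
        for j in np.flatnonzero(bad):
            w[:, j] = _nnls(mu, bulk[:, j])
    return w


def cetygo_score(bulk_vector: np.ndarray, model, weights: np.ndarray) -> float:
    """Root mean square error between a bulk profile and its reconstruction.

    Computed over the non-missing model sites; 0 is a perfect fit.
    ``model`` may be a trained model or directly the M x K mean matrix.
    """
    b = np.asarray(bulk_vector, dtype=float)
    mu = np.asarray(getattr(model, "mu", model), dtype=float)
    mask = ~np.isnan(b)
    if not mask.any():
        raise CoverageError("no non-missing model sites; cannot compute CETYGO")
    resid = b[mask] - mu[mask] @ np.asarray(weights, dtype=float)
    return float(np.sqrt(np.mean(resid**2)))


def deconvolve(
    bulk: MethylationMatrix,
    model,
    constraint: str = "nonneg",
    min_coverage: float = 0.5,
) -> pd.DataFrame:
    """Deconvolve every sample of a bulk beta matrix with a trained model.

    Returns one row per bulk sample, in input order, with estimated weights
    per fraction, the weight sum, the CETYGO score, the number of model sites
    used and an interpretive flag.  Per-sample failures (e.g. insufficient
    site coverage) become flagged rows rather than aborting the batch.
    """
    present = [s for s in model.site_ids if s in bulk.data.index]
    site_pos = {s: i for i, s in enumerate(model.site_ids)}
    rows = []
    for sample_id in bulk.sample_ids:
        b = np.full(len(model.site_ids), np.nan)
        if present:
            vals = bulk.data.loc[present, sample_id].to_numpy(dtype=float)
            b[[site_pos[s] for s in present]] = vals
        row: dict[str, object] = {"sample_id": sample_id}
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                w, n_used = project_cell_types(b, model.mu, constraint, min_coverage)
            score = cetygo_score(b, model.mu, w)
        except CoverageError as exc:
            for frac in model.fraction_labels:
                row[frac] = np.nan
            row.update(
                weight_sum=np.nan, cetygo=np.nan,
                n_sites_used=int((~np.isnan(b)).sum()), flag=f"error: {exc}",
            )
            rows.append(row)
            continue
        for frac, wk in zip(model.fraction_labels, w):
            row[frac] = float(wk)
        row.update(
            weight_sum=float(w.sum()),
            cetygo=score,
            n_sites_used=n_used,
            flag=interpret_cetygo(score) or "",
        )
        rows.append(row)
    cols = ["sample_id", *model.fraction_labels, "weight_sum", "cetygo", "n_sites_used", "flag"]
    return pd.DataFrame(rows, columns=cols)
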