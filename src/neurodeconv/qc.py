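"""PCA-based verification of FANS fraction labels (the maxSD classifier).

Sorted-nuclei reference data can fail in two ways: an individual sample may
be mislabelled, or a whole sort may fail so that every "fraction" from that
donor is really an unsorted mixture.  Because cell type dominates the major
axes of methylation variation, both failure modes are visible in the first
two principal components.

The procedure:

1. PCA over complete-case sites; keep PC1 and PC2 sample scores.
2. Studentize each PC across all samples; samples with |z| > 1.5 on either
   PC are excluded from the per-fraction summary statistics (to keep
   outliers from corrupting the fraction means).
3. For each fraction compute mean and SD of PC1/PC2 from the non-excluded
   samples; each sample's **maxSD** is the maximum over the two PCs of
   |PC - fraction mean| / fraction SD.
4. Per individual, the median of its samples' maxSD flags failed sorts
   (median > 5): all of that individual's samples are dropped.
5. Studentized values and fraction summaries are recomputed on the remaining
   samples, and a sample is retained only if it lies within 2 SD of its
   labelled fraction's mean on both PCs.

Restricting to autosomal sites (if applicable) is the caller's
responsibility; site ids are opaque here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .errors import InfeasibilityError, ParameterError
from .io import MethylationMatrix


@dataclass
class QCReport:
    samples: pd.DataFrame  # per-sample scores and decisions
    individuals: pd.DataFrame  # per-individual median maxSD and sort_failed flag
    metadata: dict = field(default_factory=dict)


def _studentize(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=0)
    if sd == 0:
        raise ParameterError("zero variance principal component; cannot Studentize")
    return (x - x.mean()) / sd


def _fraction_stats(
    pcs: np.ndarray, labels: np.ndarray, include: np.ndarray
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-fraction (mean, SD) of the PC columns over included samples."""
    out = {}
    for frac in pd.unique(labels):
        mask = (labels == frac) & include
        if mask.sum() == 0:
            out[frac] = (np.full(pcs.shape[1], np.nan), np.full(pcs.shape[1], np.nan))
            continue
        block = pcs[mask]
        out[frac] = (block.mean(axis=0), block.std(axis=0, ddof=0))
    return out


def _maxsd(pcs: np.ndarray, labels: np.ndarray, stats: dict) -> np.ndarray:
    scores = np.empty(len(labels))
    for i, frac in enumerate(labels):
        mean, sd = stats[frac]
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.abs(pcs[i] - mean) / sd
        valid = ~np.isnan(z)
        scores[i] = z[valid].max() if valid.any() else np.nan
    return scores


def fans_qc(
    matrix: MethylationMatrix,
    sheet: pd.DataFrame,
    outlier_z: float = 1.5,
    individual_threshold: float = 5.0,
    retain_sd: float = 2.0,
    recompute_pca: bool = False,
) -> QCReport:
    """Classify FANS reference samples by similarity to their labelled fraction.

    Returns a :class:`QCReport` with per-sample PC scores, Studentized
    values, maxSD, outlier/retention flags, and per-individual median maxSD
    with the sort_failed decision.  ``recompute_pca=True`` re-runs the PCA
    itself (not just the Studentization) after dropping failed individuals.
    """
    sheet = sheet.reset_index(drop=True)
    fracs = sheet["fraction_label"].to_numpy()
    if len(pd.unique(fracs)) < 2:
        raise InfeasibilityError("need >= 2 fractions for QC")
    counts = pd.Series(fracs).value_counts()
    if (counts < 2).any():
        raise InfeasibilityError("every fraction needs >= 2 samples for QC")

    sub = matrix.subset_samples(sheet["sample_id"])
    complete = ~np.isnan(sub.values).any(axis=1)
    x = sub.values[complete].T  # samples x sites
    if x.shape[1] == 0:
        raise InfeasibilityError("no complete-case sites available for PCA")
    if np.allclose(x.var(axis=0), 0):
        raise ParameterError("constant matrix; PCA is singular")

    def _pc_scores(xmat: np.ndarray) -> np.ndarray:
        return PCA(n_components=2, svd_solver="full").fit_transform(
            xmat - xmat.mean(axis=0)
        )

    pcs = _pc_scores(x)
    z = np.column_stack([_studentize(pcs[:, 0]), _studentize(pcs[:, 1])])
    non_outlier = (np.abs(z) <= outlier_z).all(axis=1)
    stats0 = _fraction_stats(pcs, fracs, non_outlier)
    maxsd0 = _maxsd(pcs, fracs, stats0)

    individuals = sheet["individual_id"].to_numpy()
    ind_rows = []
    failed_individuals = set()
    for ind in pd.unique(individuals):
        med = float(np.median(maxsd0[individuals == ind]))
        fail = med > individual_threshold
        if fail:
            failed_individuals.add(ind)
        ind_rows.append({"individual_id": ind, "median_maxsd": med, "sort_failed": fail})
    ind_df = pd.DataFrame(ind_rows)

    keep = ~np.isin(individuals, list(failed_individuals))
    retained = np.zeros(len(sheet), dtype=bool)
    maxsd_final = maxsd0.copy()
    excluded2 = np.zeros(len(sheet), dtype=bool)
    unusable_fractions: list[str] = []
    if keep.any():
        if recompute_pca:
            pcs_kept = _pc_scores(x[keep])
        else:
            pcs_kept = pcs[keep]
        z2 = np.column_stack([_studentize(pcs_kept[:, 0]), _studentize(pcs_kept[:, 1])])
        non_outlier2 = (np.abs(z2) <= outlier_z).all(axis=1)
        fr_kept = fracs[keep]
        stats2 = _fraction_stats(pcs_kept, fr_kept, non_outlier2)
        maxsd2 = _maxsd(pcs_kept, fr_kept, stats2)
        maxsd_final[keep] = maxsd2
        retained[keep] = maxsd2 <= retain_sd
        tmp = np.zeros(len(sheet), dtype=bool)
        tmp[keep] = ~non_outlier2
        excluded2 = tmp
        for frac in pd.unique(fracs):
            if not retained[fracs == frac].any():
                unusable_fractions.append(str(frac))
    else:
        unusable_fractions = [str(f) for f in pd.unique(fracs)]

    samples = pd.DataFrame(
        {
            "sample_id": sheet["sample_id"],
            "fraction_label": fracs,
            "individual_id": individuals,
            "pc1": pcs[:, 0],
            "pc2": pcs[:, 1],
            "z_pc1": z[:, 0],
            "z_pc2": z[:, 1],
            "excluded_outlier": ~non_outlier,
            "maxsd_initial": maxsd0,
            "maxsd": maxsd_final,
            "individual_failed": ~keep,
            "excluded_outlier_final": excluded2,
            "retained": retained,
        }
    )
    metadata = {
        "n_complete_sites": int(complete.sum()),
        "outlier_z": outlier_z,
        "individual_threshold": individual_threshold,
        "retain_sd": retain_sd,
        "recompute_pca": recompute_pca,
        "unusable_fractions": unusable_fractions,
    }
    return QCReport(samples=samples, individuals=ind_df, metadata=metadata)
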