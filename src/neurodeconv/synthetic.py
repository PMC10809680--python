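"""Synthetic FANS-style reference data with planted cell-specific structure.

Real reference panels for brain deconvolution are built from fluorescence
activated nuclei sorting (FANS) fractions: antibody-gated populations such as
NeuNPos (neuronal), NeuNNeg/SOX10Pos (oligodendrocyte enriched) or SATB2Pos
(excitatory neuronal).  Different gating strategies yield *overlapping*
fractions — NeuNPos and SATB2Pos both capture excitatory neurons — which is
exactly the structure this generator reproduces.

The model is two-layered:

* an :class:`AtomicCellModel` holds latent *atomic* cell types (excitatory and
  inhibitory neurons; oligodendrocytes, microglia, astrocytes) with a shared
  bimodal background beta distribution and, per atomic type, a set of planted
  differentially methylated positions (DMPs) of effect size ``delta``;
* a :class:`FractionScheme` maps each FANS fraction label to mixing weights
  over the atomic types, so overlapping fractions are simply different
  mixtures of the same latent cells.

Sampling a reference dataset draws, per fraction and individual, the
scheme-weighted mean profile plus truncated-Gaussian measurement noise on the
beta scale (clipped to [0, 1]); optional batch shifts emulate chip effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, ParameterError
from .io import MethylationMatrix

#: Latent atomic cell types.  Excitatory neurons are split into an
#: upper-layer-like (SATB2-enriched) and a deep-layer-like sub-population:
#: the SATB2 and NeuN gating strategies sample these sub-populations with
#: different efficiencies, which is what makes the overlapping NeuNPos /
#: SATB2Pos fractions distinguishable at all in real sorted data.
DEFAULT_ATOMIC_LABELS = (
    "excitatory_upper",
    "excitatory_deep",
    "inhibitory",
    "oligodendrocyte",
    "microglia",
    "astrocyte",
)

#: Lineage groups sharing planted signature sites.  The dominant axis of
#: methylation variation in brain separates neurons from glia, so every
#: neuronal type shares neuronal-lineage sites and every glial type shares
#: glial-lineage sites, in addition to its type-specific sites.
DEFAULT_LINEAGES: dict[str, tuple[str, ...]] = {
    "neuronal": ("excitatory_upper", "excitatory_deep", "inhibitory"),
    "excitatory": ("excitatory_upper", "excitatory_deep"),
    "glial": ("oligodendrocyte", "microglia", "astrocyte"),
}

#: Fraction -> mixing weights over atomic types.  Emulates the ten FANS
#: fractions used for cortical reference panels, including the overlapping
#: NeuNPos / SATB2Pos pair (both dominated by excitatory neurons).
DEFAULT_FRACTION_SCHEME: dict[str, dict[str, float]] = {
    "NeuNPos": {"excitatory_upper": 0.48, "excitatory_deep": 0.32, "inhibitory": 0.2},
    "SATB2Pos": {"excitatory_upper": 0.85, "excitatory_deep": 0.15},
    "SATB2Neg": {"inhibitory": 0.4, "oligodendrocyte": 0.2, "microglia": 0.2, "astrocyte": 0.2},
    "NeuNPos/SOX6Pos": {"inhibitory": 1.0},
    "NeuNPos/SOX6Neg": {"excitatory_upper": 0.6, "excitatory_deep": 0.4},
    "NeuNNeg": {"oligodendrocyte": 0.4, "microglia": 0.25, "astrocyte": 0.35},
    "NeuNNeg/SOX10Pos": {"oligodendrocyte": 1.0},
    "NeuNNeg/SOX10Neg": {"microglia": 0.5, "astrocyte": 0.5},
    "NeuNNeg/SOX10Neg/IRF8Pos": {"microglia": 1.0},
    "NeuNNeg/SOX10Neg/IRF8Neg": {"astrocyte": 1.0},
}

#: Per-fraction reference sample counts mirroring a realistic FANS study
#: (a few dozen donors, small n for the rarer sorts).
DEFAULT_N_PER_FRACTION: dict[str, int] = {
    "NeuNPos": 28,
    "NeuNNeg/SOX10Pos": 24,
    "NeuNNeg/SOX10Neg": 21,
    "NeuNNeg/SOX10Neg/IRF8Pos": 17,
    "NeuNNeg/SOX10Neg/IRF8Neg": 7,
    "SATB2Pos": 9,
    "SATB2Neg": 6,
    "NeuNPos/SOX6Pos": 4,
    "NeuNPos/SOX6Neg": 3,
    "NeuNNeg": 4,
}


@dataclass
class AtomicCellModel:
    """Latent atomic cell types with planted type- and lineage-specific DMPs."""

    site_ids: list[str]
    atomic_labels: list[str]
    mean_profiles: np.ndarray  # n_sites x n_atomic, beta scale
    dmp_index: dict[str, dict[str, np.ndarray]]  # label -> {"hyper": idx, "hypo": idx}
    delta: float
    lineage_dmp: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)
    lineages: dict[str, tuple[str, ...]] = field(default_factory=dict)
    seed: int | None = None

    @property
    def n_sites(self) -> int:
        return self.mean_profiles.shape[0]

    def planted_sites(self, label: str) -> set[str]:
        idx = self.dmp_index[label]
        sites = np.concatenate([idx["hyper"], idx["hypo"]])
        return {self.site_ids[i] for i in sites}

    def lineage_sites(self, lineage: str) -> set[str]:
        idx = self.lineage_dmp[lineage]
        sites = np.concatenate([idx["hyper"], idx["hypo"]])
        return {self.site_ids[i] for i in sites}

    def all_planted_sites(self) -> set[str]:
        out: set[str] = set()
        for label in self.dmp_index:
            out |= self.planted_sites(label)
        for lineage in self.lineage_dmp:
            out |= self.lineage_sites(lineage)
        return out


@dataclass
class FractionScheme:
    """Mapping from fraction labels to mixing weights over atomic types."""

    weights: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_FRACTION_SCHEME.items()}
    )

    def __post_init__(self) -> None:
        for frac, w in self.weights.items():
            if any(v < 0 for v in w.values()):
                raise ConfigError(f"negative mixing weight in fraction {frac!r}")
            total = sum(w.values())
            if abs(total - 1.0) > 1e-9:
                raise ConfigError(f"fraction {frac!r} weights sum to {total}, expected 1")

    @property
    def fraction_labels(self) -> list[str]:
        return list(self.weights)

    def mixing_matrix(self, atomic_labels: Sequence[str], fractions: Sequence[str] | None = None) -> np.ndarray:
        """Return an n_atomic x n_fraction weight matrix in the given label orders."""
        fractions = list(fractions) if fractions is not None else self.fraction_labels
        out = np.zeros((len(atomic_labels), len(fractions)))
        pos = {a: i for i, a in enumerate(atomic_labels)}
        for j, frac in enumerate(fractions):
            if frac not in self.weights:
                raise ConfigError(f"unknown fraction label {frac!r}")
            for atom, w in self.weights[frac].items():
                if atom not in pos:
                    raise ConfigError(f"fraction {frac!r} references unknown atomic label {atom!r}")
                out[pos[atom], j] = w
        return out


def generate_atomic_profiles(
    n_sites: int = 3000,
    atomic_labels: Sequence[str] = DEFAULT_ATOMIC_LABELS,
    n_dmp_per_type: int = 100,
    delta: float = 0.4,
    seed: int = 0,
    lineages: Mapping[str, Sequence[str]] | None = None,
    n_dmp_per_lineage: int | None = None,
    background_means: tuple[float, float] = (0.1, 0.9),
    background_sd: float = 0.05,
) -> AtomicCellModel:
    """Generate latent atomic mean profiles with planted DMPs.

    Background sites share a bimodal beta-like distribution across atomic
    types (components centred near ``background_means``, emulating the
    genome-wide distribution of methylation).  Each atomic type receives
    ``n_dmp_per_type`` hypermethylated and ``n_dmp_per_type`` hypomethylated
    planted sites whose mean differs from every other type by at least
    ``delta``.  In addition, each lineage group (by default neuronal vs
    glial) receives shared signature sites at which *all* member types
    differ from all non-members by ``delta`` — mirroring the fact that
    lineage dominates the between-cell-type methylation differences in
    brain.  Deterministic given ``seed``.
    """
    labels = list(atomic_labels)
    n_atomic = len(labels)
    if lineages is None:
        lineages = {
            k: v for k, v in DEFAULT_LINEAGES.items() if set(v) <= set(labels)
        }
    lineages = {k: tuple(v) for k, v in lineages.items()}
    for lin, members in lineages.items():
        unknown = set(members) - set(labels)
        if unknown:
            raise ParameterError(f"lineage {lin!r} references unknown types {sorted(unknown)}")
    if n_dmp_per_lineage is None:
        n_dmp_per_lineage = n_dmp_per_type
    if not 0.0 < delta < 1.0:
        raise ParameterError(f"delta must lie in (0, 1), got {delta}")
    if delta > 0.9:
        raise ParameterError(f"delta {delta} infeasible within [0, 1] with margin for noise")
    n_planted = n_atomic * n_dmp_per_type * 2 + len(lineages) * n_dmp_per_lineage * 2
    if n_sites < n_planted:
        raise ParameterError(
            f"n_sites={n_sites} too small for {n_planted} planted sites "
            f"({n_atomic} types x {n_dmp_per_type} x 2 + "
            f"{len(lineages)} lineages x {n_dmp_per_lineage} x 2)"
        )

    rng = np.random.default_rng(seed)
    # shared bimodal background
    component = rng.random(n_sites) < 0.5
    base = np.where(
        component,
        rng.normal(background_means[0], background_sd, n_sites),
        rng.normal(background_means[1], background_sd, n_sites),
    )
    base = np.clip(base, 0.02, 0.98)
    means = np.tile(base[:, None], (1, n_atomic))

    # disjoint planted positions, scattered over the site index
    planted_pos = rng.choice(n_sites, size=n_planted, replace=False)
    margin = 0.02
    lo_hi = 1.0 - delta - margin  # highest admissible "low" level
    cursor = 0

    def _plant(columns: np.ndarray, n_dmp: int) -> dict[str, np.ndarray]:
        nonlocal cursor
        hyper = planted_pos[cursor : cursor + n_dmp]
        cursor += n_dmp
        hypo = planted_pos[cursor : cursor + n_dmp]
        cursor += n_dmp
        low = rng.uniform(margin, lo_hi, n_dmp)
        means[hyper, :] = low[:, None]
        means[np.ix_(hyper, columns)] = (low + delta)[:, None]
        high = rng.uniform(margin + delta, 1.0 - margin, n_dmp)
        means[hypo, :] = high[:, None]
        means[np.ix_(hypo, columns)] = (high - delta)[:, None]
        return {"hyper": np.sort(hyper), "hypo": np.sort(hypo)}

    dmp_index = {
        label: _plant(np.array([a]), n_dmp_per_type) for a, label in enumerate(labels)
    }
    pos_of = {label: i for i, label in enumerate(labels)}
    lineage_dmp = {
        lin: _plant(np.array([pos_of[m] for m in members]), n_dmp_per_lineage)
        for lin, members in lineages.items()
    }

    width = len(str(n_sites))
    site_ids = [f"cg{i:0{width}d}" for i in range(n_sites)]
    return AtomicCellModel(
        site_ids=site_ids,
        atomic_labels=labels,
        mean_profiles=means,
        dmp_index=dmp_index,
        delta=delta,
        lineage_dmp=lineage_dmp,
        lineages=lineages,
        seed=seed,
    )


def sample_reference(
    model: AtomicCellModel,
    scheme: FractionScheme | None = None,
    n_per_fraction: Mapping[str, int] | None = None,
    noise_sd: float = 0.02,
    batch_effects: Mapping[str, float] | None = None,
    noise_model: str = "truncnorm",
    seed: int = 0,
) -> tuple[MethylationMatrix, pd.DataFrame]:
    """Sample a purified-fraction reference dataset and its sample sheet.

    Each sample's expected profile is the scheme-weighted sum of atomic means;
    noise is additive Gaussian on the beta scale clipped to [0, 1]
    (``noise_model="logitnorm"`` instead perturbs on the logit scale).  One
    individual contributes at most one sample per fraction, mirroring a FANS
    design where each donor is sorted once into every fraction.  With batch
    effects, individuals are assigned to batches round-robin and a constant
    beta-scale shift is added to all of a batch's samples.
    """
    scheme = scheme or FractionScheme()
    if n_per_fraction is None:
        n_per_fraction = {f: DEFAULT_N_PER_FRACTION.get(f, 4) for f in scheme.fraction_labels}
    for frac, n in n_per_fraction.items():
        if n < 1:
            raise ParameterError(f"n_per_fraction[{frac!r}] must be >= 1, got {n}")
    if noise_model not in ("truncnorm", "logitnorm"):
        raise ParameterError(f"unknown noise_model {noise_model!r}")

    fractions = [f for f in scheme.fraction_labels if f in n_per_fraction]
    mix = scheme.mixing_matrix(model.atomic_labels, fractions)  # A x F
    expected = model.mean_profiles @ mix  # n_sites x F

    rng = np.random.default_rng(seed)
    batch_labels = list(batch_effects) if batch_effects else [None]

    columns: dict[str, np.ndarray] = {}
    rows = []
    for j, frac in enumerate(fractions):
        n = n_per_fraction[frac]
        for i in range(n):
            individual = f"ind{i + 1:03d}"
            batch = batch_labels[i % len(batch_labels)]
            profile = expected[:, j].copy()
            if batch_effects and batch is not None:
                profile = profile + batch_effects[batch]
            if noise_sd > 0:
                if noise_model == "truncnorm":
                    profile = profile + rng.normal(0.0, noise_sd, model.n_sites)
                else:
                    eps = 1e-6
                    logit = np.log(np.clip(profile, eps, 1 - eps) / np.clip(1 - profile, eps, 1 - eps))
                    logit = logit + rng.normal(0.0, noise_sd, model.n_sites)
                    profile = 1.0 / (1.0 + np.exp(-logit))
            profile = np.clip(profile, 0.0, 1.0)
            sample_id = f"{frac.replace('/', '.')}_{individual}"
            columns[sample_id] = profile
            rows.append(
                {
                    "sample_id": sample_id,
                    "fraction_label": frac,
                    "individual_id": individual,
                    "batch": batch,
                }
            )

    data = pd.DataFrame(columns, index=pd.Index(model.site_ids, name="site_id"))
    sheet = pd.DataFrame(rows, columns=["sample_id", "fraction_label", "individual_id", "batch"])
    return MethylationMatrix(data, validate=False), sheet
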