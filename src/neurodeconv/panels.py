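"""Reference panels: named combinations of FANS fractions used for deconvolution.

A panel is an ordered list of K >= 2 fraction labels.  The eight preset
panels combine the ten available nuclei fractions into increasingly refined
references; panels 4 and 5 deliberately include the overlapping NeuNPos /
SATB2Pos pair (both capture excitatory neurons) and are flagged as such —
the algorithms run on them unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from .errors import ConfigError, InfeasibilityError
from .io import MethylationMatrix


@dataclass(frozen=True)
class PanelSpec:
    panel_id: str
    fraction_labels: tuple[str, ...]
    overlapping: bool = False

    def __post_init__(self) -> None:
        if len(self.fraction_labels) < 2:
            raise ConfigError(f"panel {self.panel_id!r}: need K >= 2 fractions")
        if len(set(self.fraction_labels)) != len(self.fraction_labels):
            raise ConfigError(f"panel {self.panel_id!r}: duplicate fraction labels")

    @property
    def k(self) -> int:
        return len(self.fraction_labels)


def preset_panels() -> list[PanelSpec]:
    """The eight preset reference panels.

    Panels 1-3 and 6-8 are non-overlapping; 4 and 5 include both NeuNPos and
    SATB2Pos.  IDOL site selection applies only to panels with K > 2.
    """
    return [
        PanelSpec("1", ("NeuNPos", "NeuNNeg/SOX10Pos", "NeuNNeg/SOX10Neg")),
        PanelSpec(
            "2",
            (
                "NeuNPos",
                "NeuNNeg/SOX10Pos",
                "NeuNNeg/SOX10Neg/IRF8Pos",
                "NeuNNeg/SOX10Neg/IRF8Neg",
            ),
        ),
        PanelSpec("3", ("SATB2Pos", "SATB2Neg")),
        PanelSpec(
            "4",
            ("NeuNPos", "SATB2Pos", "NeuNNeg/SOX10Pos", "NeuNNeg/SOX10Neg"),
            overlapping=True,
        ),
        PanelSpec(
            "5",
            (
                "NeuNPos",
                "SATB2Pos",
                "NeuNNeg/SOX10Pos",
                "NeuNNeg/SOX10Neg/IRF8Pos",
                "NeuNNeg/SOX10Neg/IRF8Neg",
            ),
            overlapping=True,
        ),
        PanelSpec("6", ("NeuNPos/SOX6Pos", "NeuNPos/SOX6Neg", "NeuNNeg")),
        PanelSpec(
            "7",
            ("NeuNPos/SOX6Pos", "NeuNPos/SOX6Neg", "NeuNNeg/SOX10Pos", "NeuNNeg/SOX10Neg"),
        ),
        PanelSpec(
            "8",
            (
                "NeuNPos/SOX6Pos",
                "NeuNPos/SOX6Neg",
                "NeuNNeg/SOX10Pos",
                "NeuNNeg/SOX10Neg/IRF8Pos",
                "NeuNNeg/SOX10Neg/IRF8Neg",
            ),
        ),
    ]


def get_preset_panel(panel_id: str) -> PanelSpec:
    for panel in preset_panels():
        if panel.panel_id == str(panel_id):
            return panel
    raise ConfigError(f"no preset panel with id {panel_id!r}")


def applicable_methods(panel: PanelSpec) -> tuple[str, ...]:
    """Selection methods usable on this panel: IDOL needs K > 2 cell types."""
    return ("anova", "idol") if panel.k > 2 else ("anova",)


def load_panel(path: str | Path) -> PanelSpec:
    """Load a panel from a YAML/JSON config ``{panel_id, fractions: [...]}``."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict) or "fractions" not in cfg:
        raise ConfigError(f"{path}: expected a mapping with a 'fractions' list")
    return PanelSpec(
        str(cfg.get("panel_id", Path(path).stem)),
        tuple(cfg["fractions"]),
        overlapping=bool(cfg.get("overlapping", False)),
    )


def subset_reference(
    matrix: MethylationMatrix, sheet: pd.DataFrame, panel: PanelSpec
) -> tuple[MethylationMatrix, pd.DataFrame]:
    """Restrict a reference dataset to the samples of a panel's fractions.

    Variance-based site selection needs replicates, so every panel fraction
    must be present with at least two samples.
    """
    counts = sheet["fraction_label"].value_counts()
    for frac in panel.fraction_labels:
        n = int(counts.get(frac, 0))
        if n < 2:
            raise InfeasibilityError(
                f"panel {panel.panel_id!r}: fraction {frac!r} has {n} sample(s); "
                "need >= 2 for training"
            )
    keep = sheet[sheet["fraction_label"].isin(panel.fraction_labels)].reset_index(drop=True)
    return matrix.subset_samples(keep["sample_id"]), keep
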