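"""Probe-level expression matrix container and its disk format.

The container wraps a probes x samples :class:`pandas.DataFrame` together
with the two pieces of metadata the downstream chain needs: a sample -> group
assignment (``control`` / ``treated``) and a probe -> gene symbol map (many
probes may map to one gene; probes without a mapping are tolerated and
counted when genes are called).  ``scale`` records whether values are raw
linear intensities or already log2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ContractError

CONTROL = "control"
TREATED = "treated"


@dataclass
class ExpressionMatrix:
    values: pd.DataFrame                 # probes x samples
    groups: pd.Series                    # sample -> {control, treated}
    probe_to_gene: dict[str, str] = field(default_factory=dict)
    scale: str = "linear"                # {linear, log2}
    probe_sets: dict[str, str] = field(default_factory=dict)  # probe -> set id

    def __post_init__(self):
        if self.scale not in ("linear", "log2"):
            raise ContractError(f"scale must be linear or log2, got {self.scale!r}")
        if not self.values.index.is_unique:
            raise ContractError("probe ids must be unique")
        self.groups = pd.Series(self.groups)
        missing = set(self.values.columns) - set(self.groups.index)
        if missing:
            raise ContractError(f"samples without group label: {sorted(missing)}")
        bad = set(self.groups.loc[list(self.values.columns)]) - {CONTROL, TREATED}
        if bad:
            raise ContractError(f"unknown group labels: {sorted(bad)}")
        for group in (CONTROL, TREATED):
            if (self.groups.loc[list(self.values.columns)] == group).sum() < 2:
                raise ContractError(f"need >=2 samples in group {group!r}")
        if not np.issubdtype(self.values.to_numpy().dtype, np.number):
            raise ContractError("expression values must be numeric")
        if self.scale == "linear" and (self.values.to_numpy() < 0).any():
            raise ContractError("linear-scale intensities must be non-negative")

    # -- views -------------------------------------------------------------

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_in(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.groups[s] == group]

    def log2_values(self) -> pd.DataFrame:
        """Values on the log2 scale (offset +1 guards zero intensities)."""
        if self.scale == "log2":
            return self.values
        return np.log2(self.values + 1.0)

    def linear_values(self) -> pd.DataFrame:
        if self.scale == "linear":
            return self.values
        return 2.0 ** self.values

    def with_values(self, values: pd.DataFrame, scale: str | None = None
                    ) -> "ExpressionMatrix":
        return ExpressionMatrix(
            values=values,
            groups=self.groups,
            probe_to_gene=self.probe_to_gene,
            scale=scale or self.scale,
            probe_sets=self.probe_sets,
        )

    # -- disk format -------------------------------------------------------

    def save(self, matrix_path: Path | str, groups_path: Path | str,
             annotation_path: Path | str | None = None) -> None:
        self.values.to_csv(matrix_path, index_label="probe_id")
        pd.DataFrame({
            "sample": list(self.groups.index),
            "group": list(self.groups.values),
        }).to_csv(groups_path, sep="\t", index=False)
        if annotation_path is not None:
            pd.DataFrame({
                "probe_id": list(self.probe_to_gene),
                "gene": list(self.probe_to_gene.values()),
            }).to_csv(annotation_path, sep="\t", index=False)


def load_expression(matrix_path: Path | str, groups_path: Path | str,
                    annotation_path: Path | str | None = None,
                    scale: str = "linear") -> ExpressionMatrix:
    """Read a matrix (CSV/TSV), sample sheet and optional probe annotation."""
    matrix_path = Path(matrix_path)
    sep = "\t" if matrix_path.suffix in (".tsv", ".txt") else ","
    values = pd.read_csv(matrix_path, sep=sep, index_col=0)
    values.index = values.index.astype(str)
    sheet = pd.read_csv(groups_path, sep=None, engine="python")
    groups = pd.Series(
        sheet.iloc[:, 1].astype(str).values,
        index=sheet.iloc[:, 0].astype(str).values,
    )
    probe_to_gene: dict[str, str] = {}
    if annotation_path is not None:
        ann = pd.read_csv(annotation_path, sep=None, engine="python")
        probe_to_gene = dict(zip(ann.iloc[:, 0].astype(str), ann.iloc[:, 1].astype(str)))
    return ExpressionMatrix(values=values, groups=groups,
                            probe_to_gene=probe_to_gene, scale=scale)
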