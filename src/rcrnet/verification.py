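"""Network verification: consistency matrices, coverage, expansion candidates.

Verification confronts the scored hypotheses from several datasets with
curated knowledge about each network node's expected effect on the phenotype
(pro- or anti-proliferative, supplied as an annotation table — never inferred
here).  A node's prediction in a dataset is *consistent* when

    predicted direction x expected effect == observed phenotype direction

e.g. a pro-proliferative node predicted increased in a dataset where
proliferation increased, or an anti-proliferative node predicted increased
where proliferation decreased.

Coverage asks a structural question: of the network's nodes, how many could
RCR ever predict (enough measured downstream mRNA targets in the reasoning
substrate — the "possible nodes"), and how many of those were actually
predicted in at least one dataset.

Expansion candidates are significant hypotheses for nodes *outside* the
network: a ranked worklist for human curation, never auto-merged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import ContractError
from .graph import CausalGraph, downstream_mrna_targets
from .rcr import Hypothesis, RCRConfig

CONSISTENT = "consistent"
INCONSISTENT = "inconsistent"
NOT_PREDICTED = "not-predicted"


@dataclass(frozen=True)
class ExpectedDirectionAnnotation:
    """Curated expected effect of a node on the phenotype."""

    node_id: str
    expected_effect: int          # +1 pro-proliferative, -1 anti-proliferative
    origin: str = "L"             # L = literature model, D = data-set-derived

    def __post_init__(self):
        if self.expected_effect not in (+1, -1):
            raise ContractError("expected_effect must be +-1")
        if self.origin not in ("L", "D"):
            raise ContractError("origin must be 'L' or 'D'")


@dataclass
class DatasetOutcome:
    """One dataset's observed phenotype direction and its scored hypotheses."""

    dataset_id: str
    observed_direction: int       # +1 proliferation increased, -1 decreased
    hypotheses: list[Hypothesis]

    def __post_init__(self):
        if self.observed_direction not in (+1, -1):
            raise ContractError("observed_direction must be +-1")


def classify_cell(predicted: int | None, expected: int, observed: int) -> str:
    """Pure sign rule for one consistency-matrix cell."""
    if predicted is None:
        return NOT_PREDICTED
    return CONSISTENT if predicted * expected == observed else INCONSISTENT


def best_hypothesis_per_node(hypotheses: list[Hypothesis]
                             ) -> dict[str, Hypothesis]:
    """Best-scoring *significant* hypothesis per node.

    Ranking: lowest concordance_p, then lowest richness_p, then +1 before -1
    (a deterministic tie-break; the underlying scores rarely tie).
    """
    best: dict[str, Hypothesis] = {}
    for h in sorted(
        (h for h in hypotheses if h.significant),
        key=lambda h: (h.concordance_p, h.richness_p, -h.direction),
    ):
        best.setdefault(h.node_id, h)
    return best


@dataclass
class ConsistencyMatrix:
    """Annotated nodes x datasets classification of predictions."""

    predicted: pd.DataFrame       # int direction or 0 when not predicted
    status: pd.DataFrame          # consistent / inconsistent / not-predicted
    annotations: dict[str, ExpectedDirectionAnnotation]
    observed: dict[str, int]      # dataset -> phenotype direction
    unannotated_predicted: list[str] = field(default_factory=list)

    def counts(self) -> dict[str, int]:
        flat = self.status.to_numpy().ravel()
        return {
            CONSISTENT: int((flat == CONSISTENT).sum()),
            INCONSISTENT: int((flat == INCONSISTENT).sum()),
            NOT_PREDICTED: int((flat == NOT_PREDICTED).sum()),
        }

    def save(self, path: Path | str, header_lines: list[str] | None = None
             ) -> None:
        rows = []
        for node in self.status.index:
            ann = self.annotations[node]
            row = {"node_id": node, "expected": ann.expected_effect,
                   "origin": ann.origin}
            for ds in self.status.columns:
                row[f"{ds}:predicted"] = self.predicted.at[node, ds]
                row[f"{ds}:status"] = self.status.at[node, ds]
            rows.append(row)
        body = pd.DataFrame(rows).to_csv(sep="\t", index=False)
        text = "".join(f"{line}\n" for line in (header_lines or [])) + body
        Path(path).write_text(text, encoding="utf-8")

    def plot(self, path: Path | str | None = None):
        """Render the matrix as a heatmap (optional matplotlib figure)."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        import numpy as np

        coded = np.zeros(self.status.shape)
        for i, node in enumerate(self.status.index):
            for j, ds in enumerate(self.status.columns):
                cell = self.status.iat[i, j]
                coded[i, j] = {NOT_PREDICTED: 0, CONSISTENT: 1,
                               INCONSISTENT: -1}[cell]
        fig, ax = plt.subplots(
            figsize=(2 + 0.6 * len(self.status.columns),
                     1 + 0.3 * len(self.status.index)))
        ax.imshow(coded, cmap="RdYlGn", vmin=-1, vmax=1, aspect="auto")
        ax.set_xticks(range(len(self.status.columns)),
                      labels=list(self.status.columns), rotation=45)
        ax.set_yticks(range(len(self.status.index)),
                      labels=list(self.status.index), fontsize=7)
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=120)
            plt.close(fig)
        return fig


def build_consistency_matrix(
    outcomes: list[DatasetOutcome],
    annotations: list[ExpectedDirectionAnnotation],
) -> ConsistencyMatrix:
    """Classify each annotated node in each dataset by the sign rule."""
    ann_map: dict[str, ExpectedDirectionAnnotation] = {}
    for ann in annotations:
        if ann.node_id in ann_map:
            raise ContractError(f"duplicate annotation for node {ann.node_id!r}")
        ann_map[ann.node_id] = ann
    dataset_ids = [o.dataset_id for o in outcomes]
    if len(set(dataset_ids)) != len(dataset_ids):
        raise ContractError("duplicate dataset ids in outcomes")

    nodes = sorted(ann_map)
    predicted = pd.DataFrame(0, index=nodes, columns=dataset_ids, dtype=int)
    status = pd.DataFrame(NOT_PREDICTED, index=nodes, columns=dataset_ids,
                          dtype=object)
    unannotated: set[str] = set()
    for outcome in outcomes:
        best = best_hypothesis_per_node(outcome.hypotheses)
        unannotated |= set(best) - set(ann_map)
        for node in nodes:
            hyp = best.get(node)
            direction = hyp.direction if hyp is not None else None
            cell = classify_cell(direction, ann_map[node].expected_effect,
                                 outcome.observed_direction)
            status.at[node, outcome.dataset_id] = cell
            predicted.at[node, outcome.dataset_id] = direction or 0
    return ConsistencyMatrix(
        predicted=predicted, status=status, annotations=ann_map,
        observed={o.dataset_id: o.observed_direction for o in outcomes},
        unannotated_predicted=sorted(unannotated),
    )


# -- coverage --------------------------------------------------------------


@dataclass
class CoverageReport:
    """How much of the network the datasets could and did predict."""

    n_network_nodes: int
    n_possible: int
    n_predicted_union: int
    per_dataset: dict[str, int]
    possible_nodes: list[str] = field(default_factory=list)
    predicted_nodes: list[str] = field(default_factory=list)

    @property
    def percent_predicted(self) -> float:
        return 100.0 * self.n_predicted_union / self.n_possible \
            if self.n_possible else 0.0

    def percent_for(self, dataset_id: str) -> float:
        return 100.0 * self.per_dataset[dataset_id] / self.n_possible \
            if self.n_possible else 0.0

    def to_dict(self) -> dict:
        return {
            "n_network_nodes": self.n_network_nodes,
            "n_possible": self.n_possible,
            "n_predicted_union": self.n_predicted_union,
            "percent_predicted": round(self.percent_predicted, 2),
            "per_dataset": {
                ds: {"n": n, "percent": round(self.percent_for(ds), 2)}
                for ds, n in sorted(self.per_dataset.items())
            },
        }


def coverage_report(
    network: CausalGraph,
    kb: CausalGraph,
    outcomes: list[DatasetOutcome],
    config: RCRConfig | None = None,
    universes: dict[str, set[str]] | None = None,
    mode: str = "kb-targets",
) -> CoverageReport:
    """Possible vs predicted network nodes against a reasoning substrate.

    ``mode="kb-targets"`` (default): a network node is *possible* if, in at
    least one dataset's measured universe, it has >= ``min_targets``
    measured downstream mRNA targets in ``kb``.  ``mode="consistent-changes"``:
    possible if at least one of its scored hypotheses has
    >= ``min_consistent`` direction-consistent observed changes.
    """
    if mode not in ("kb-targets", "consistent-changes"):
        raise ContractError(f"unknown coverage mode {mode!r}")
    config = config or RCRConfig()
    universes = universes or {}

    possible: set[str] = set()
    network_ids = set(network.nodes)
    if mode == "kb-targets":
        kb_targets: dict[str, dict[str, int]] = {
            nid: downstream_mrna_targets(kb, nid, depth=config.depth)
            for nid in network_ids & set(kb.nodes)
        }
        dataset_universes = list(universes.values()) or [None]
        for nid, targets in kb_targets.items():
            for universe in dataset_universes:
                measured = (
                    targets if universe is None
                    else {g: s for g, s in targets.items() if g in universe}
                )
                if len(measured) >= config.min_targets:
                    possible.add(nid)
                    break
    else:
        for outcome in outcomes:
            for h in outcome.hypotheses:
                if h.node_id in network_ids and \
                        h.n_correct >= config.min_consistent:
                    possible.add(h.node_id)

    per_dataset: dict[str, int] = {}
    predicted_union: set[str] = set()
    for outcome in outcomes:
        hits = {
            h.node_id for h in outcome.hypotheses
            if h.significant and h.node_id in possible
        }
        per_dataset[outcome.dataset_id] = len(hits)
        predicted_union |= hits
    return CoverageReport(
        n_network_nodes=len(network_ids),
        n_possible=len(possible),
        n_predicted_union=len(predicted_union),
        per_dataset=per_dataset,
        possible_nodes=sorted(possible),
        predicted_nodes=sorted(predicted_union),
    )


# -- expansion candidates --------------------------------------------------


def expansion_candidates(
    outcomes: list[DatasetOutcome], network: CausalGraph
) -> list[tuple[str, int, list[str]]]:
    """Significant hypotheses for nodes absent from the network.

    One row per (node, direction), tagged with the datasets supporting it;
    this is an input worklist for manual curation.
    """
    support: dict[tuple[str, int], list[str]] = {}
    for outcome in outcomes:
        for h in outcome.hypotheses:
            if h.significant and h.node_id not in network.nodes:
                support.setdefault((h.node_id, h.direction), []).append(
                    outcome.dataset_id
                )
    return [
        (node, direction, sorted(set(datasets)))
        for (node, direction), datasets in sorted(support.items())
    ]


# -- annotation I/O --------------------------------------------------------


def load_annotations(path: Path | str) -> list[ExpectedDirectionAnnotation]:
    """Read an annotation TSV: node_id, expected_direction (+-1), origin."""
    annotations = []
    for lineno, line in enumerate(
        Path(path).read_text(encoding="utf-8").splitlines(), start=1
    ):
        if not line.strip() or line.startswith("#") or \
                line.startswith("node_id\t"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ContractError(f"annotation row {lineno}: need >=2 columns")
        annotations.append(ExpectedDirectionAnnotation(
            node_id=parts[0],
            expected_effect=int(parts[1]),
            origin=parts[2] if len(parts) > 2 and parts[2] else "L",
        ))
    return annotations


def save_annotations(annotations: list[ExpectedDirectionAnnotation],
                     path: Path | str) -> None:
    lines = ["node_id\texpected_direction\torigin"]
    for ann in annotations:
        lines.append(f"{ann.node_id}\t{ann.expected_effect:+d}\t{ann.origin}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
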