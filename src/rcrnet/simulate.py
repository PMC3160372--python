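"""Synthetic causal graphs and expression data with planted controllers.

The generator emulates the minimal structure upstream-controller inference
needs: a bipartite-ish knowledge graph in which *controller* nodes (activity
class) carry signed causal edges to mRNA nodes, and a two-group log-normal
expression experiment in which a chosen subset of controllers is "active".
Genes downstream of an active controller are shifted in the treated group by

    effect_size_delta x (planted direction) x (edge sign)   [log2 units]

on top of i.i.d. Gaussian noise; all other genes are exchangeable between
groups.  The full gene pool (targeted plus background) forms the measured
universe, so enrichment nulls behave as they would on a real platform.

Everything is reproducible under ``seed``: each operation derives its own
independent stream so stages can be regenerated in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .diffexp import DEThresholds, DifferentialExpression, StateChangeSet
from .errors import ConfigError
from .expression import CONTROL, TREATED, ExpressionMatrix
from .graph import CausalGraph, EntityNode, Evidence
from .rcr import (Hypothesis, RCRConfig, ReverseCausalReasoning,
                  candidate_hypotheses)


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic benchmark run.

    Defaults describe a platform-scale experiment: 200 controllers with 10
    downstream mRNA targets each inside a 5000-gene measured pool, 20 active
    (planted) controllers shifting their targets by 2.0 log2 units against
    0.5 log2 units of noise, three replicates per group, baseline intensity
    2^8 = 256.
    """

    n_controllers: int = 200
    targets_per_controller: int | tuple[int, int] = 10
    sign_positive_prob: float = 0.5
    n_background_genes: int = 5000     # total measured gene pool
    n_planted: int = 20
    planted_directions: list[int] | None = None
    effect_size_delta: float = 2.0
    noise_sd: float = 0.5
    replicates_per_group: int = 3
    baseline_log2_mean: float = 8.0
    seed: int = 0
    overlap_allowed: bool = False

    def __post_init__(self):
        if self.n_controllers < 1 or self.n_background_genes < 1:
            raise ConfigError("controller and gene counts must be positive")
        if self.n_planted < 0 or self.n_planted > self.n_controllers:
            raise ConfigError("n_planted must lie in [0, n_controllers]")
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be positive")
        if self.replicates_per_group < 2:
            raise ConfigError("need >=2 replicates per group")
        if not 0 <= self.sign_positive_prob <= 1:
            raise ConfigError("sign_positive_prob must lie in [0, 1]")
        lo, hi = self.target_range
        if lo < 1:
            raise ConfigError("targets_per_controller must be >= 1")
        if not self.overlap_allowed and self.n_controllers * hi > \
                self.n_background_genes:
            raise ConfigError(
                "disjoint target blocks need n_controllers x max targets "
                f"<= gene pool ({self.n_controllers}x{hi} > "
                f"{self.n_background_genes}); set overlap_allowed=True or "
                "enlarge the pool"
            )
        if hi > self.n_background_genes:
            raise ConfigError("more targets requested than genes available")
        if self.planted_directions is not None and \
                len(self.planted_directions) != self.n_planted:
            raise ConfigError("planted_directions length must equal n_planted")

    @property
    def target_range(self) -> tuple[int, int]:
        if isinstance(self.targets_per_controller, int):
            return (self.targets_per_controller, self.targets_per_controller)
        lo, hi = self.targets_per_controller
        return int(lo), int(hi)

    def gene_ids(self) -> list[str]:
        return [f"G{i:05d}" for i in range(self.n_background_genes)]

    def controller_ids(self) -> list[str]:
        return [f"CTRL{i:03d}|taof" for i in range(self.n_controllers)]

    def to_dict(self) -> dict:
        return {
            "n_controllers": self.n_controllers,
            "targets_per_controller": self.targets_per_controller,
            "sign_positive_prob": self.sign_positive_prob,
            "n_background_genes": self.n_background_genes,
            "n_planted": self.n_planted,
            "planted_directions": self.planted_directions,
            "effect_size_delta": self.effect_size_delta,
            "noise_sd": self.noise_sd,
            "replicates_per_group": self.replicates_per_group,
            "baseline_log2_mean": self.baseline_log2_mean,
            "seed": self.seed,
            "overlap_allowed": self.overlap_allowed,
        }


@dataclass
class SimulationTruth:
    """Ground truth of one simulated experiment."""

    active: list[tuple[str, int]]              # (controller, direction)
    downstream_expected: dict[str, int]        # gene -> expected observed sign
    conflicted_genes: set[str] = field(default_factory=set)
    shifts: dict[str, float] = field(default_factory=dict)  # gene -> log2 shift


# -- graph simulation ------------------------------------------------------


def simulate_kam(config: SimulationConfig) -> CausalGraph:
    """Random controller -> mRNA causal graph under the configured sizes.

    Controllers are transcriptional-activity nodes; every gene that receives
    an edge gets an mRNA node.  With ``overlap_allowed=False`` (default) the
    controllers' target sets are disjoint blocks of a seeded permutation of
    the gene pool, so planted signals never collide.
    """
    rng = np.random.default_rng(config.seed)
    genes = config.gene_ids()
    lo, hi = config.target_range
    graph = CausalGraph(name=f"simulated-kam-seed{config.seed}",
                        species="synthetic",
                        provenance="rcrnet.simulate.simulate_kam")

    counts = rng.integers(lo, hi + 1, size=config.n_controllers)
    if config.overlap_allowed:
        assignments = [
            list(rng.choice(len(genes), size=c, replace=False))
            for c in counts
        ]
    else:
        perm = rng.permutation(len(genes))
        assignments, cursor = [], 0
        for c in counts:
            assignments.append(list(perm[cursor:cursor + c]))
            cursor += c

    for cid, targets in zip(config.controller_ids(), assignments):
        graph.add_node(EntityNode(
            node_id=cid, label=cid, entity_class="activity",
            activity_kind="transcriptional", base_entity=cid.split("|")[0],
        ))
        signs = np.where(
            rng.random(len(targets)) < config.sign_positive_prob, 1, -1
        )
        for gene_index, sign in zip(targets, signs):
            gene = genes[gene_index]
            node_id = f"{gene}|mRNA"
            if node_id not in graph.nodes:
                graph.add_node(EntityNode(
                    node_id=node_id, label=gene, entity_class="mRNA",
                    base_entity=gene,
                ))
            graph.add_causal_edge(cid, node_id, int(sign), Evidence(
                citation_id=f"SIM:{cid}", species="unspecified",
                quote="", tissue="synthetic",
            ))
    return graph


def choose_planted(config: SimulationConfig) -> list[tuple[str, int]]:
    """Seeded choice of active controllers and their directions."""
    rng = np.random.default_rng(config.seed + 1)
    controllers = config.controller_ids()
    chosen = sorted(rng.choice(config.n_controllers, size=config.n_planted,
                               replace=False))
    if config.planted_directions is not None:
        directions = list(config.planted_directions)
    else:
        directions = list(np.where(rng.random(config.n_planted) < 0.5, 1, -1))
    return [(controllers[i], int(d)) for i, d in zip(chosen, directions)]


# -- expression simulation -------------------------------------------------


def simulate_expression(
    graph: CausalGraph,
    planted: list[tuple[str, int]],
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, SimulationTruth]:
    """Two-group log-normal expression data with the planted shifts applied.

    Control samples draw Normal(baseline, noise_sd) per gene in log2 space;
    treated samples add ``delta x direction x edge sign`` to each gene
    downstream of an active controller.  When two active controllers imply
    opposite signs on one gene the shifts sum (they may cancel) and the gene
    is flagged conflicted in the truth record.  The matrix is emitted on the
    linear scale.
    """
    for cid, direction in planted:
        if cid not in graph.nodes:
            raise ConfigError(f"planted controller {cid!r} not in graph")
        if direction not in (+1, -1):
            raise ConfigError("planted directions must be +-1")

    implied: dict[str, set[int]] = {}
    shift: dict[str, float] = {}
    for cid, direction in planted:
        for edge in graph.out_edges(cid):
            target = graph.nodes[edge.target]
            if target.entity_class != "mRNA":
                continue
            gene = target.gene_symbol
            sign = direction * edge.sign
            implied.setdefault(gene, set()).add(sign)
            shift[gene] = shift.get(gene, 0.0) + \
                config.effect_size_delta * sign
    truth = SimulationTruth(
        active=list(planted),
        downstream_expected={
            g: (next(iter(s)) if len(s) == 1 else 0)
            for g, s in implied.items()
        },
        conflicted_genes={g for g, s in implied.items() if len(s) > 1},
        shifts=shift,
    )

    rng = np.random.default_rng(config.seed + 2)
    genes = config.gene_ids()
    reps = config.replicates_per_group
    baseline = config.baseline_log2_mean + np.zeros((len(genes), 1))
    noise = rng.normal(0.0, config.noise_sd, size=(len(genes), 2 * reps))
    log2 = baseline + noise
    shifts = np.array([shift.get(g, 0.0) for g in genes])
    log2[:, reps:] += shifts[:, None]

    samples = [f"ctrl_{i + 1}" for i in range(reps)] + \
              [f"trt_{i + 1}" for i in range(reps)]
    matrix = ExpressionMatrix(
        values=pd.DataFrame(2.0 ** log2, index=genes, columns=samples),
        groups=pd.Series(
            [CONTROL] * reps + [TREATED] * reps, index=samples
        ),
        probe_to_gene={g: g for g in genes},
        scale="linear",
    )
    return matrix, truth


# -- end-to-end recovery harness -------------------------------------------


@dataclass
class RecoveryMetrics:
    """End-to-end planted-controller recovery scores."""

    sensitivity: float            # planted (node, dir) pairs found significant
    direction_accuracy: float     # recovered controllers with correct direction
    precision: float              # significant hypotheses that are planted
    null_significant_fraction: float   # sig. fraction in matched delta=0 run
    n_planted: int
    n_significant: int
    n_candidates: int
    n_state_changes: int

    def to_dict(self) -> dict:
        return {
            "sensitivity": self.sensitivity,
            "direction_accuracy": self.direction_accuracy,
            "precision": self.precision,
            "null_significant_fraction": self.null_significant_fraction,
            "n_planted": self.n_planted,
            "n_significant": self.n_significant,
            "n_candidates": self.n_candidates,
            "n_state_changes": self.n_state_changes,
        }


@dataclass
class RecoveryRun:
    """Artifacts of one harness execution (for inspection in tests)."""

    graph: CausalGraph
    planted: list[tuple[str, int]]
    matrix: ExpressionMatrix
    truth: SimulationTruth
    state_changes: StateChangeSet
    hypotheses: list[Hypothesis]


def run_pipeline_once(
    config: SimulationConfig,
    thresholds: DEThresholds | None = None,
    rcr_config: RCRConfig | None = None,
) -> RecoveryRun:
    """simulate -> differential expression -> RCR, returning all artifacts."""
    thresholds = thresholds or DEThresholds(abundance_applies=False)
    rcr_config = rcr_config or RCRConfig()
    graph = simulate_kam(config)
    planted = choose_planted(config)
    matrix, truth = simulate_expression(graph, planted, config)
    results = DifferentialExpression(matrix).fit(moderation="empirical-bayes")
    state_changes = results.state_changes(thresholds)
    rcr_results = ReverseCausalReasoning(graph, state_changes, rcr_config).fit()
    return RecoveryRun(graph=graph, planted=planted, matrix=matrix,
                       truth=truth, state_changes=state_changes,
                       hypotheses=rcr_results.hypotheses)


def recovery_harness(
    config: SimulationConfig,
    thresholds: DEThresholds | None = None,
    rcr_config: RCRConfig | None = None,
    return_runs: bool = False,
):
    """Score planted-controller recovery end to end.

    Runs the full pipeline on the configured conditions, then once more with
    ``effect_size_delta = 0`` (same seed) to measure the null rate of
    significant hypotheses among candidates.
    """
    run = run_pipeline_once(config, thresholds, rcr_config)
    significant = {(h.node_id, h.direction)
                   for h in run.hypotheses if h.significant}
    planted = set(run.planted)
    sensitivity = (
        len(significant & planted) / len(planted) if planted else float("nan")
    )

    planted_dir = dict(run.planted)
    from .verification import best_hypothesis_per_node
    best = best_hypothesis_per_node(run.hypotheses)
    recovered = [cid for cid in planted_dir if cid in best]
    direction_accuracy = (
        sum(1 for cid in recovered
            if best[cid].direction == planted_dir[cid]) / len(recovered)
        if recovered else float("nan")
    )
    precision = (
        len(significant & planted) / len(significant)
        if significant else float("nan")
    )

    null_config = replace(config, effect_size_delta=0.0)
    null_run = run_pipeline_once(null_config, thresholds, rcr_config)
    null_candidates = candidate_hypotheses(
        null_run.graph, set(null_run.state_changes.universe),
        rcr_config or RCRConfig(),
    )
    null_significant = sum(1 for h in null_run.hypotheses if h.significant)
    null_fraction = (
        null_significant / len(null_candidates) if null_candidates else 0.0
    )

    metrics = RecoveryMetrics(
        sensitivity=sensitivity,
        direction_accuracy=direction_accuracy,
        precision=precision,
        null_significant_fraction=null_fraction,
        n_planted=len(planted),
        n_significant=len(significant),
        n_candidates=len(candidate_hypotheses(
            run.graph, set(run.state_changes.universe),
            rcr_config or RCRConfig(),
        )),
        n_state_changes=len(run.state_changes),
    )
    if return_runs:
        return metrics, run, null_run
    return metrics
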