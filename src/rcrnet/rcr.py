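"""Reverse Causal Reasoning: scoring upstream-controller hypotheses.

Given a signed causal graph and a set of State Changes, every non-mRNA node
with enough measured downstream mRNA targets yields two *hypotheses*: the
node's activity increased (+1) or decreased (-1).  Each hypothesis is scored
with two tail probabilities:

richness
    the probability, under hypergeometric sampling of the node's measured
    targets from the measured-gene universe, of seeing at least the observed
    number of State Changes among them — connectivity enrichment, direction
    ignored;
concordance
    the probability, under a binomial null in which each directional change
    independently agrees with the hypothesis with probability ``q`` (default
    0.5), of seeing at least the observed number of direction-consistent
    changes.

A hypothesis is *significant* when both p-values clear their cutoffs
(default 0.1 each) and at least ``min_consistent`` (default 4) observed
changes agree with the predicted direction.  Targets reachable with
conflicting path signs count toward richness (they attest connectivity) but
are excluded from the concordance trials (they carry no direction).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from scipy import stats

from .diffexp import StateChangeSet
from .errors import ContractError
from .graph import AMBIGUOUS, CausalGraph, downstream_mrna_targets

HYPOTHESIS_COLUMNS = [
    "node_id", "direction", "n_universe", "n_targets", "n_changed_total",
    "n_overlap", "n_correct", "n_contra", "n_ambiguous",
    "richness_p", "concordance_p", "significant",
]


@dataclass
class RCRConfig:
    """Cutoffs and counting rules for hypothesis generation.

    ``universe_mode`` picks the richness null universe: ``"platform"`` (all
    measured genes — the default) or ``"kb-covered"`` (only measured genes
    that are downstream of at least one graph node).  ``concordance_q`` is
    either a float success probability or the string ``"empirical"`` (the
    observed up-fraction among all State Changes).
    """

    alpha_richness: float = 0.1
    alpha_concordance: float = 0.1
    min_targets: int = 4
    min_consistent: int = 4
    concordance_q: float | str = 0.5
    depth: int = 1
    universe_mode: str = "platform"

    def __post_init__(self):
        for alpha in (self.alpha_richness, self.alpha_concordance):
            if not 0 < alpha < 1:
                raise ContractError("alpha cutoffs must lie in (0, 1)")
        if self.min_targets < 1 or self.min_consistent < 1:
            raise ContractError("minimum counts must be >= 1")
        if self.depth < 1:
            raise ContractError("depth must be >= 1")
        if self.universe_mode not in ("platform", "kb-covered"):
            raise ContractError(f"unknown universe_mode {self.universe_mode!r}")
        if not isinstance(self.concordance_q, str):
            if not 0 < self.concordance_q < 1:
                raise ContractError("concordance_q must lie in (0, 1)")
        elif self.concordance_q != "empirical":
            raise ContractError("concordance_q must be a float or 'empirical'")

    def to_dict(self) -> dict:
        return {
            "alpha_richness": self.alpha_richness,
            "alpha_concordance": self.alpha_concordance,
            "min_targets": self.min_targets,
            "min_consistent": self.min_consistent,
            "concordance_q": self.concordance_q,
            "depth": self.depth,
            "universe_mode": self.universe_mode,
        }


@dataclass
class Hypothesis:
    """One scored (node, direction) candidate."""

    node_id: str
    direction: int
    n_universe: int
    n_targets: int
    n_changed_total: int
    n_overlap: int
    n_correct: int
    n_contra: int
    n_ambiguous: int
    richness_p: float
    concordance_p: float
    significant: bool

    def __post_init__(self):
        if self.n_correct + self.n_contra + self.n_ambiguous != self.n_overlap:
            raise ContractError("overlap decomposition does not add up")


# -- scoring ---------------------------------------------------------------


def score_richness(n_universe: int, n_targets: int, n_changed_total: int,
                   n_overlap: int) -> float:
    """Hypergeometric upper tail P(X >= n_overlap).

    X is the number of State Changes among ``n_targets`` genes drawn without
    replacement from a universe of ``n_universe`` genes of which
    ``n_changed_total`` changed.
    """
    if not 0 <= n_overlap <= min(n_targets, n_changed_total) <= n_universe:
        raise ContractError(
            f"inconsistent richness counts: universe={n_universe}, "
            f"targets={n_targets}, changed={n_changed_total}, overlap={n_overlap}"
        )
    if n_targets > n_universe:
        raise ContractError("more targets than universe genes")
    if n_overlap == 0:
        return 1.0
    return float(stats.hypergeom.sf(
        n_overlap - 1, n_universe, n_changed_total, n_targets
    ))


def score_concordance(n_directional: int, n_correct: int, q: float = 0.5) -> float:
    """Binomial upper tail P(X >= n_correct) on ``n_directional`` trials."""
    if not 0 < q < 1:
        raise ContractError("q must lie in (0, 1)")
    if not 0 <= n_correct <= n_directional:
        raise ContractError(
            f"inconsistent concordance counts: correct={n_correct}, "
            f"directional={n_directional}"
        )
    if n_correct == 0:
        return 1.0
    return float(stats.binom.sf(n_correct - 1, n_directional, q))


# -- candidate enumeration -------------------------------------------------


def _target_maps(graph: CausalGraph, universe: set[str], config: RCRConfig
                 ) -> dict[str, dict[str, int]]:
    """Measured downstream-target sign map per eligible node."""
    # A node's own gene symbol is excluded inside downstream_mrna_targets,
    # so an mRNA node is never a candidate for its own expression.
    maps = {}
    for node_id in graph.nodes:
        targets = downstream_mrna_targets(graph, node_id, depth=config.depth)
        measured = {g: s for g, s in targets.items() if g in universe}
        if measured:
            maps[node_id] = measured
    return maps


def candidate_hypotheses(graph: CausalGraph, universe: set[str],
                         config: RCRConfig | None = None
                         ) -> list[tuple[str, int]]:
    """All (node, direction) pairs with enough measured downstream targets."""
    config = config or RCRConfig()
    if not universe:
        raise ContractError("universe must be non-empty")
    out = []
    for node_id, measured in sorted(_target_maps(graph, universe, config).items()):
        if len(measured) >= config.min_targets:
            out.append((node_id, +1))
            out.append((node_id, -1))
    return out


# -- hypothesis generation -------------------------------------------------


def generate_hypotheses(graph: CausalGraph, state_changes: StateChangeSet,
                        config: RCRConfig | None = None) -> list[Hypothesis]:
    """Score every candidate against the State Changes; ranked output.

    Sorted by (concordance_p, richness_p) ascending with deterministic
    tie-breaks on node id and direction, so output is byte-reproducible.
    """
    config = config or RCRConfig()
    universe = set(state_changes.universe)
    if not universe:
        raise ContractError("State-Change universe is empty")
    maps = _target_maps(graph, universe, config)
    if config.universe_mode == "kb-covered":
        covered = set()
        for measured in maps.values():
            covered |= set(measured)
        universe = covered
        maps = {
            nid: {g: s for g, s in m.items() if g in universe}
            for nid, m in maps.items()
        }

    changes = {g: d for g, d in state_changes.changes.items() if g in universe}
    n_universe = len(universe)
    n_changed_total = len(changes)
    if config.concordance_q == "empirical":
        ups = sum(1 for d in changes.values() if d > 0)
        q = ups / n_changed_total if n_changed_total else 0.5
        q = min(max(q, 1e-9), 1 - 1e-9)
    else:
        q = float(config.concordance_q)

    hypotheses = []
    for node_id in sorted(maps):
        measured = maps[node_id]
        if len(measured) < config.min_targets:
            continue
        overlap = {g: s for g, s in measured.items() if g in changes}
        n_overlap = len(overlap)
        n_ambiguous = sum(1 for s in overlap.values() if s == AMBIGUOUS)
        richness_p = score_richness(
            n_universe, len(measured), n_changed_total, n_overlap
        )
        for direction in (+1, -1):
            n_correct = sum(
                1 for g, s in overlap.items()
                if s != AMBIGUOUS and changes[g] == direction * s
            )
            n_contra = n_overlap - n_ambiguous - n_correct
            concordance_p = score_concordance(
                n_overlap - n_ambiguous, n_correct, q
            )
            significant = (
                richness_p <= config.alpha_richness
                and concordance_p <= config.alpha_concordance
                and n_correct >= config.min_consistent
            )
            hypotheses.append(Hypothesis(
                node_id=node_id, direction=direction,
                n_universe=n_universe, n_targets=len(measured),
                n_changed_total=n_changed_total, n_overlap=n_overlap,
                n_correct=n_correct, n_contra=n_contra,
                n_ambiguous=n_ambiguous, richness_p=richness_p,
                concordance_p=concordance_p, significant=significant,
            ))
    hypotheses.sort(key=lambda h: (
        h.concordance_p, h.richness_p, h.node_id, -h.direction
    ))
    return hypotheses


def hypotheses_to_frame(hypotheses: list[Hypothesis]) -> pd.DataFrame:
    return pd.DataFrame(
        [[getattr(h, c) for c in HYPOTHESIS_COLUMNS] for h in hypotheses],
        columns=HYPOTHESIS_COLUMNS,
    )


# -- model / results interface --------------------------------------------


class ReverseCausalReasoning:
    """RCR model: a causal graph confronted with one State-Change set."""

    def __init__(self, graph: CausalGraph, state_changes: StateChangeSet,
                 config: RCRConfig | None = None):
        self.graph = graph
        self.state_changes = state_changes
        self.config = config or RCRConfig()

    def fit(self) -> "RCRResults":
        hypotheses = generate_hypotheses(
            self.graph, self.state_changes, self.config
        )
        return RCRResults(self, hypotheses)


class RCRResults:
    """Ranked scored hypotheses with tabular and text views."""

    def __init__(self, model: ReverseCausalReasoning,
                 hypotheses: list[Hypothesis]):
        self.model = model
        self.hypotheses = hypotheses

    @property
    def significant(self) -> list[Hypothesis]:
        return [h for h in self.hypotheses if h.significant]

    def to_frame(self) -> pd.DataFrame:
        return hypotheses_to_frame(self.hypotheses)

    def save(self, path: Path | str, header_lines: list[str] | None = None
             ) -> None:
        frame = self.to_frame()
        body = frame.to_csv(sep="\t", index=False)
        text = "".join(f"{line}\n" for line in (header_lines or [])) + body
        Path(path).write_text(text, encoding="utf-8")

    def summary(self, top: int = 10) -> str:
        frame = self.to_frame()
        cfg = self.model.config
        lines = [
            "Reverse Causal Reasoning",
            f"  universe: {self.hypotheses[0].n_universe if self.hypotheses else 0} genes"
            f"   state changes: {len(self.model.state_changes)}",
            f"  candidates scored: {len(self.hypotheses)}"
            f"   significant: {len(self.significant)}"
            f" (richness<={cfg.alpha_richness},"
            f" concordance<={cfg.alpha_concordance},"
            f" >={cfg.min_consistent} consistent)",
            "",
            frame.head(top).to_string(
                index=False, float_format=lambda v: f"{v:.4g}"
            ),
        ]
        return "\n".join(lines)
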