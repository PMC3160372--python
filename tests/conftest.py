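import numpy as np
import pandas as pd
import pytest

from rcrnet import (CausalGraph, EntityNode, Evidence, ExpressionMatrix,
                    StateChangeSet)


def make_node(node_id, entity_class="protein", **kwargs):
    if entity_class == "activity":
        kwargs.setdefault("activity_kind", "kinase")
    if entity_class == "modified-protein":
        kwargs.setdefault("modification", "P@S373")
    kwargs.setdefault("label", node_id)
    return EntityNode(node_id=node_id, entity_class=entity_class, **kwargs)


@pytest.fixture
def toy_graph():
    """A controller TF1 with five signed mRNA targets, plus form edges.

    TF1 -> m1..m5 with signs (+, -, +, +, -); K1 reaches m1 with both signs
    (ambiguous) and m2, m3 with +; P1 has-activity TF1.
    """
    g = CausalGraph(name="toy", species="human")
    g.add_node(make_node("TF1", "activity", activity_kind="transcriptional"))
    g.add_node(make_node("K1", "activity"))
    g.add_node(make_node("P1", "protein"))
    for i in range(1, 7):
        g.add_node(make_node(f"m{i}", "mRNA", base_entity=f"g{i}"))
    ev = Evidence(citation_id="PMID:1", species="human", tissue="lung")
    for gene, sign in [("m1", 1), ("m2", -1), ("m3", 1), ("m4", 1), ("m5", -1)]:
        g.add_causal_edge("TF1", gene, sign, ev)
    g.add_causal_edge("K1", "m1", 1, Evidence(citation_id="PMID:2"))
    g.add_causal_edge("K1", "m1", -1, Evidence(citation_id="PMID:3"))
    g.add_causal_edge("K1", "m2", 1, Evidence(citation_id="PMID:2"))
    g.add_causal_edge("K1", "m3", 1, Evidence(citation_id="PMID:4"))
    g.add_noncausal_edge("P1", "TF1", "has-activity")
    return g


@pytest.fixture
def toy_matrix():
    """6 probes x 6 samples, log2 scale, with two strongly shifted probes.

    Probes p1 (up) and p2 (down) move by +-3 log2 units; p5 and p6 map to
    the same gene g5 in opposite directions (conflict); p3, p4 are flat.
    """
    rng = np.random.default_rng(0)
    base = rng.normal(8.0, 0.1, size=(6, 6))
    base[0, 3:] += 3.0
    base[1, 3:] -= 3.0
    base[4, 3:] += 3.0
    base[5, 3:] -= 3.0
    samples = ["c1", "c2", "c3", "t1", "t2", "t3"]
    values = pd.DataFrame(base, index=[f"p{i}" for i in range(1, 7)],
                          columns=samples)
    return ExpressionMatrix(
        values=values,
        groups=pd.Series(["control"] * 3 + ["treated"] * 3, index=samples),
        probe_to_gene={"p1": "g1", "p2": "g2", "p3": "g3", "p4": "g4",
                       "p5": "g5", "p6": "g5"},
        scale="log2",
    )


@pytest.fixture
def toy_state_changes():
    return StateChangeSet(
        changes={"g1": 1, "g2": -1, "g3": 1, "g4": 1, "g5": -1},
        universe={f"g{i}" for i in range(1, 11)},
    )
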