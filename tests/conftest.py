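import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import triomics as t

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def seven_node_model():
    return t.seven_node_example_model()


@pytest.fixture(scope="session")
def seven_node_cohort(seven_node_model):
    return t.simulate_cohort(seven_node_model, 5000, seed=42)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_typed_meta(rng, p):
    """Random node catalog mixing all six types."""
    types = rng.choice(["MG", "MM", "MP", "NG", "NM", "NP"], size=p)
    meta = []
    for k, ty in enumerate(types):
        meta.append(
            t.NodeMeta(
                f"v{k}",
                ty,
                timepoint={"MM": "fasting", "NM": "cord"}.get(ty, "none"),
                chromosome=str(rng.integers(1, 4)) if ty in ("MG", "NG") else None,
                metabolite_class="AA" if ty in ("MM", "NM") else None,
                role="outcome" if ty == "NP" else "intermediate",
            )
        )
    return meta


def random_typed_dag_edges(rng, meta, p_edge=0.3):
    """Random blocklist-respecting DAG over a typed catalog."""
    bl = t.build_blocklist(meta)
    order = rng.permutation(len(meta))
    edges = []
    for a in range(len(meta)):
        for b in range(a + 1, len(meta)):
            u, v = meta[order[a]], meta[order[b]]
            if rng.random() < p_edge and not bl.is_forbidden(u, v):
                edges.append((u.node_id, v.node_id))
    return edges
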