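import numpy as np
import pandas as pd
import pytest

from rasnet import FixtureSpec, simulate_counts, toy_shared_enzyme_graph

MINIMAL_KGML = """<?xml version="1.0"?>
<pathway name="path:hsa00600" org="hsa" number="00600" title="test">
  <entry id="1" name="cpd:C1" type="compound">
    <graphics name="CompoundOne" type="circle"/>
  </entry>
  <entry id="2" name="cpd:C2" type="compound"/>
  <entry id="3" name="hsa:111 hsa:222" type="gene" reaction="rn:R001"/>
  <reaction id="10" name="rn:R001" type="{rtype}">
    <substrate id="1" name="cpd:C1"/>
    <product id="2" name="cpd:C2"/>
  </reaction>
</pathway>
"""


@pytest.fixture
def toy_graph():
    return toy_shared_enzyme_graph()


@pytest.fixture
def toy_counts(toy_graph):
    spec = FixtureSpec(samples_per_group=6, n_background=20, seed=7)
    return simulate_counts(toy_graph, spec)


@pytest.fixture
def toy_expression(toy_graph):
    """Deterministic non-degenerate expression for the toy graph genes."""
    genes = sorted(toy_graph.gene_universe)
    rng = np.random.default_rng(11)
    values = rng.uniform(0.5, 4.0, size=(len(genes), 5))
    return pd.DataFrame(values, index=genes,
                        columns=[f"S{i}" for i in range(5)])


@pytest.fixture
def kgml_file(tmp_path):
    def write(rtype="irreversible", name="test.xml", text=None):
        path = tmp_path / name
        path.write_text(text if text is not None
                        else MINIMAL_KGML.format(rtype=rtype))
        return path

    return write
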