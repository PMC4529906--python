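import pytest

from subpathnet import (
    ExpressionDataset,
    SignedPathwayGraph,
    load_reported_subpathways,
    parse_subpathway_notation,
)


@pytest.fixture(scope="session")
def reported_chains():
    """The bundled reported subpathway chains as (pathway, dataset, text, p) rows."""
    frame = load_reported_subpathways()
    return list(frame.itertuples(index=False))


@pytest.fixture(scope="session")
def parsed_reported_chains(reported_chains):
    """Each reported chain parsed into (Subpathway, fold-change map, dataset id)."""
    out = []
    for row in reported_chains:
        sub, fcs = parse_subpathway_notation(
            row.subpathway, pathway_id=row.kegg_pathway
        )
        out.append((sub, fcs, row.dataset_id))
    return out


@pytest.fixture
def chain_graph():
    """A -> B -> C, all activation."""
    return SignedPathwayGraph(
        "chain01", "chain", {"A", "B", "C"}, {("A", "B", 1), ("B", "C", 1)}
    )


@pytest.fixture
def cycle_graph():
    """3-cycle A -> B -> C -> A."""
    return SignedPathwayGraph(
        "cycle01", "cycle", {"A", "B", "C"},
        {("A", "B", 1), ("B", "C", 1), ("C", "A", 1)},
    )


def make_dataset(fcs, dataset_id="TEST", label="other"):
    return ExpressionDataset(dataset_id, label, fcs)


@pytest.fixture
def make_ds():
    return make_dataset
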