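import pytest

from phenolink import (
    build_hierarchy,
    build_reference_fixture,
    build_search_index,
    condense_cycles,
    load_terminology,
)


@pytest.fixture(scope="session")
def ref_paths(tmp_path_factory):
    """Reference mini-terminology written to disk once per session."""
    outdir = tmp_path_factory.mktemp("reference_fixture")
    return build_reference_fixture().write(outdir)


def _load(paths, include_suppressed=False):
    return load_terminology(
        paths["concepts"],
        paths["relations"],
        paths["semantic_types"],
        paths["attributes"],
        include_suppressed=include_suppressed,
    )


@pytest.fixture(scope="session")
def graph(ref_paths):
    return _load(ref_paths)


@pytest.fixture(scope="session")
def graph_with_suppressed(ref_paths):
    return _load(ref_paths, include_suppressed=True)


@pytest.fixture(scope="session")
def view(graph):
    return build_hierarchy(graph)


@pytest.fixture(scope="session")
def dag(view):
    return condense_cycles(view)


@pytest.fixture(scope="session")
def index(graph):
    return build_search_index(graph)
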