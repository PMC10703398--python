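import pytest

from provreplay import (
    AnalysisSpec,
    build_dag,
    discover_archives,
    parse_provenance_tree,
    simulate_analysis,
    union,
)


@pytest.fixture(scope="session")
def small_analysis(tmp_path_factory):
    """One seeded synthetic analysis: (archive paths, ground truth, archives)."""
    out_dir = tmp_path_factory.mktemp("small")
    paths, ground_truth = simulate_analysis(
        AnalysisSpec(seed=11, n_imports=1, n_actions=4), out_dir
    )
    return paths, ground_truth, discover_archives([out_dir])


@pytest.fixture(scope="session")
def small_dag(small_analysis):
    _, _, archives = small_analysis
    return union([build_dag(parse_provenance_tree(a)) for a in archives])
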