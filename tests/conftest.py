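import pytest

from occumeta.curation import ReferenceSet, parse_candidates, read_hits
from occumeta.simulate import make_curation_fixtures


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """Curation fixture files written once per session."""
    fx = make_curation_fixtures(seed=0)
    outdir = tmp_path_factory.mktemp("curation_fixture")
    paths = fx.write(outdir)
    return fx, paths


@pytest.fixture(scope="session")
def fixture_inputs(fixture_dir):
    """Parsed in-memory curation inputs plus the expected ledger."""
    fx, paths = fixture_dir
    refs = ReferenceSet.from_files(paths["references"], paths["labels"])
    cands = parse_candidates(paths["candidates"])
    hits = read_hits(paths["hits"])
    return {
        "panel": fx.panel,
        "refs": refs,
        "cands": cands,
        "hits": hits,
        "tree": paths["tree"],
        "expected": fx.expected,
    }
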