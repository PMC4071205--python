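import pytest

from tjkit import ColumnConfig, build_catalog
from tjkit.fixtures import FixtureSpec, generate_fixture

# A published one-line example of the hybrid format: two plain numeric
# cells flanking a JSON gene annotation.
EXAMPLE_LINE = (
    "1024\t145.6\t"
    '{"_type":"gene","_strand":"+","_minBP":10954,"_maxBP":11507,'
    '"note":"similarity to: 1 Protein","GeneID":"100506145"}'
    "\t12.334"
)

VARIANT_CONFIG = "\n".join(
    [
        "1\tCHROM\tlandmark",
        "2\tSTART\tstart",
        "3\tEND\tend",
        "4\tID\tid",
        "5\tREF\tref_allele",
        "6\tALTS\talt_alleles\tlist\t,",
    ]
)


@pytest.fixture
def example_line():
    return EXAMPLE_LINE


@pytest.fixture
def example_json(example_line):
    return example_line.split("\t")[2]


@pytest.fixture
def variant_config():
    return ColumnConfig.parse(VARIANT_CONFIG)


@pytest.fixture
def small_catalog(tmp_path, variant_config):
    """3 positional entries (rs2 duplicated) plus one position-independent."""
    rows = [
        "chr1\t100\t100\trs7\tA\tT,C",
        "chr1\t250\t250\trs2\tG\tA",
        "chr1\t250\t250\trs2\tG\tC",
        "chr2\t\t\trsPI\tC\tG",
    ]
    return build_catalog(rows, variant_config, tmp_path / "small")


@pytest.fixture(scope="session")
def fixture_set(tmp_path_factory):
    """The standard 50-variant, 60%-overlap annotation universe."""
    outdir = tmp_path_factory.mktemp("fx")
    return generate_fixture(
        FixtureSpec(seed=7, n_variants=50, overlap_fraction=0.6), outdir
    )
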