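import pytest

import exont
from exont.annotation import read_feature_table


@pytest.fixture(scope="session")
def fixture(tmp_path_factory):
    """Default synthetic study: ~220 coding exons, 28 terms, seed 3."""
    return exont.generate_fixture(seed=3, outdir=tmp_path_factory.mktemp("fx"))


@pytest.fixture(scope="session")
def models(fixture):
    return exont.read_gene_models(fixture.paths["models"])


@pytest.fixture(scope="session")
def tree(fixture):
    return exont.load_ontology(fixture.paths["ontology"], fixture.paths["root_map"])


@pytest.fixture(scope="session")
def store(fixture, models, tree):
    feats = read_feature_table(fixture.paths["features"])
    return exont.annotate_exons(feats, models, tree, propagate=True)


@pytest.fixture(scope="session")
def pool(models):
    return models.control_pool("all_coding")


MINI_GFF = """\
##gff-version 3
chr1\ttest\tgene\t101\t1000\t.\t+\t.\tID=gplus
chr1\ttest\tmRNA\t101\t1000\t.\t+\t.\tID=gplus.t1;Parent=gplus
chr1\ttest\texon\t101\t250\t.\t+\t.\tParent=gplus.t1
chr1\ttest\tCDS\t161\t250\t.\t+\t0\tParent=gplus.t1
chr1\ttest\texon\t401\t520\t.\t+\t.\tParent=gplus.t1
chr1\ttest\tCDS\t401\t520\t.\t+\t0\tParent=gplus.t1
chr1\ttest\texon\t801\t1000\t.\t+\t.\tParent=gplus.t1
chr1\ttest\tCDS\t801\t890\t.\t+\t0\tParent=gplus.t1
chr2\ttest\tgene\t101\t1000\t.\t-\t.\tID=gminus
chr2\ttest\tmRNA\t101\t1000\t.\t-\t.\tID=gminus.t1;Parent=gminus
chr2\ttest\texon\t101\t250\t.\t-\t.\tParent=gminus.t1
chr2\ttest\tCDS\t161\t250\t.\t-\t0\tParent=gminus.t1
chr2\ttest\texon\t401\t520\t.\t-\t.\tParent=gminus.t1
chr2\ttest\tCDS\t401\t520\t.\t-\t0\tParent=gminus.t1
chr2\ttest\texon\t801\t1000\t.\t-\t.\tParent=gminus.t1
chr2\ttest\tCDS\t801\t890\t.\t-\t0\tParent=gminus.t1
"""


@pytest.fixture(scope="session")
def mini_models(tmp_path_factory):
    """Two 3-exon genes, one per strand, with UTR-bearing terminal exons.

    Plus-strand CDS walks 160..250, 400..520, 800..890 (0-based
    half-open); minus-strand CDS walks 800..890 downwards first.
    """
    p = tmp_path_factory.mktemp("mini") / "mini.gff3"
    p.write_text(MINI_GFF)
    return exont.read_gene_models(p)
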