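import dendropy
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


ANNOTATED_NEWICK = (
    "((A,B)'[q1=0.6;q2=0.3;q3=0.1;EN=10000]',"
    "((C,D)'[q1=0.34;q2=0.33;q3=0.33;EN=9000]',E));"
)

COUNT_ANNOTATED_NEWICK = "((A,B)'[f1=6000;f2=3000;f3=1000]',(C,D));"


@pytest.fixture
def annotated_tree():
    from treediscord.astral_io import parse_annotated_newick

    return parse_annotated_newick(ANNOTATED_NEWICK)


@pytest.fixture
def annotated_tree_file(tmp_path):
    path = tmp_path / "species.nwk"
    path.write_text(ANNOTATED_NEWICK + "\n")
    return path


def gene_tree(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=newick, schema="newick",
                             suppress_internal_node_taxa=True,
                             preserve_underscores=True)


def gene_trees(*newicks) -> dendropy.TreeList:
    return dendropy.TreeList.get(data="\n".join(newicks), schema="newick",
                                 suppress_internal_node_taxa=True,
                                 preserve_underscores=True)
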