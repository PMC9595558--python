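import io

import pytest

from taxensemble import ReadAssignmentTable, load_taxonomy

# Small Drosophila-centred tree: a family/genus spine, three species, a
# subspecies and a strain-style "no rank" node below species level, and a
# rankless clade with no species ancestor.
FIXTURE_TAXONOMY_TSV = """\
taxid\tparent\trank\tname
1\t1\tno rank\troot
7214\t1\tfamily\tDrosophilidae
7215\t7214\tgenus\tDrosophila
7227\t7215\tspecies\tDrosophila melanogaster
7240\t7215\tspecies\tDrosophila simulans
7244\t7215\tspecies\tDrosophila virilis
7228\t7227\tsubspecies\tDrosophila melanogaster ssp
46245\t7227\tno rank\tDrosophila melanogaster strain
7208\t1\tno rank\tunranked clade
"""

SPECIES_TAXIDS = (7227, 7240, 7244)


@pytest.fixture(scope="session")
def taxonomy():
    return load_taxonomy(io.StringIO(FIXTURE_TAXONOMY_TSV))


def make_table(assignments, sample_id="s1", classifier_id="c"):
    return ReadAssignmentTable(
        sample_id=sample_id, classifier_id=classifier_id, assignments=dict(assignments)
    )
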