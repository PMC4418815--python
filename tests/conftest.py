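import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from csscmp import (ContingencyMatrix, GeneSetSubmatrix, StudyGeneList,
                    build_contingency)

TOY_OBO = """\
format-version: 1.2

[Term]
id: GO:0000001
name: root process
namespace: biological_process

[Term]
id: GO:0000002
name: child process
namespace: biological_process
is_a: GO:0000001 ! root

[Term]
id: GO:0000003
name: part process
namespace: biological_process
relationship: part_of GO:0000002 ! child

[Term]
id: GO:0000004
name: obsolete process
namespace: biological_process
is_obsolete: true

[Term]
id: GO:0000010
name: molecular thing
namespace: molecular_function
"""

_GAF_ROWS = [
    # db, obj_id, symbol, qualifier, go_id, evidence, aspect, taxon
    ("UniProtKB", "P1", "GATA4", "", "GO:0000002", "IDA", "P", "taxon:9606"),
    ("UniProtKB", "P2", "NPPA", "", "GO:0000003", "TAS", "P", "taxon:9606"),
    ("UniProtKB", "P3", "IEAGENE", "", "GO:0000002", "IEA", "P",
     "taxon:9606"),
    ("UniProtKB", "P4", "NOTGENE", "NOT", "GO:0000002", "IDA", "P",
     "taxon:9606"),
    ("UniProtKB", "P5", "MOUSEG", "", "GO:0000002", "IDA", "P",
     "taxon:10090"),
    ("UniProtKB", "P6", "MFGENE", "", "GO:0000010", "IDA", "F",
     "taxon:9606"),
]


def _gaf_line(db, oid, sym, qual, go, ev, aspect, taxon):
    fields = [db, oid, sym, qual, go, "PMID:1", ev, "", aspect, "name", "",
              "protein", taxon, "20120101", "UniProt", "", ""]
    return "\t".join(fields)


TOY_GAF = "!gaf-version: 2.1\n" + "\n".join(
    _gaf_line(*row) for row in _GAF_ROWS) + "\n"


@pytest.fixture
def toy_obo(tmp_path):
    p = tmp_path / "toy.obo"
    p.write_text(TOY_OBO)
    return p


@pytest.fixture
def toy_gaf(tmp_path):
    p = tmp_path / "toy.gaf"
    p.write_text(TOY_GAF)
    return p


@pytest.fixture
def toy_matrix():
    """4x3 matrix from lists A={g1,g2,g4}, B={g1,g2,g3}, C={g1}."""
    lists = [
        StudyGeneList("A", frozenset({"G1", "G2", "G4"})),
        StudyGeneList("B", frozenset({"G1", "G2", "G3"})),
        StudyGeneList("C", frozenset({"G1"})),
    ]
    return build_contingency(lists)


@pytest.fixture
def worked_submatrix():
    """Hand-computable 2x3 submatrix: rows (1,1,1) and (1,1,0)."""
    return GeneSetSubmatrix("toy", ["G1", "G2"],
                            np.array([[1, 1, 1], [1, 1, 0]]))


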