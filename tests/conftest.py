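"""Shared fixtures: a hand-built toy ontology and annotation corpus.

Toy DAG (edges point child -> parent):

    HP:0000001 (root, depth 0)
    HP:0000002 A (root)          HP:0000003 B (root)
    HP:0000004 C (A, B)  -- diamond, depth 2
    HP:0000005 D (C)     -- chain, depth 3
    HP:0000006 E (A)     -- depth 2
    HP:0000007 F (C)     -- sibling of D under C, depth 3
    HP:0000008 G (B)     -- depth 2, never annotated (infinite IC)
    HP:0000099 obsolete, replaced_by HP:0000004

Corpus (4 diseases): DA={D}, DB={F}, DC={E}, DD={B}.
Direct IC counts: root=4, A=3 (DA,DB,DC), B=3 (DA,DB,DD), C=2 (DA,DB),
D=1, F=1, E=1, G=0 -> inf.
"""
import io
import math

import pytest

from diseasegps.ontology import compute_ic, load_hpoa, parse_obo

ROOT, A, B, C, D, E, F, G = (
    "HP:0000001",
    "HP:0000002",
    "HP:0000003",
    "HP:0000004",
    "HP:0000005",
    "HP:0000006",
    "HP:0000007",
    "HP:0000008",
)

TOY_OBO = """\
format-version: 1.2
ontology: hp-toy

[Term]
id: HP:0000001
name: All

[Term]
id: HP:0000002
name: term A
alt_id: HP:0000202
is_a: HP:0000001 ! All

[Term]
id: HP:0000003
name: term B
is_a: HP:0000001 ! All

[Term]
id: HP:0000004
name: term C
is_a: HP:0000002 ! term A
is_a: HP:0000003 ! term B

[Term]
id: HP:0000005
name: term D
is_a: HP:0000004 ! term C

[Term]
id: HP:0000006
name: term E
is_a: HP:0000002 ! term A

[Term]
id: HP:0000007
name: term F
is_a: HP:0000004 ! term C

[Term]
id: HP:0000008
name: term G
is_a: HP:0000003 ! term B

[Term]
id: HP:0000099
name: retired term
is_obsolete: true
replaced_by: HP:0000004
"""

TOY_HPOA = """\
#description: toy annotations
#database_id\tdisease_name\tqualifier\thpo_id
OMIM:000001\tDisease DA\tP\tHP:0000005
OMIM:000002\tDisease DB\tP\tHP:0000007
OMIM:000003\tDisease DC\tP\tHP:0000006
OMIM:000004\tDisease DD\tP\tHP:0000003
OMIM:000004\tDisease DD\tNOT\tHP:0000006
"""


@pytest.fixture(scope="session")
def toy_ontology():
    return parse_obo(io.StringIO(TOY_OBO))


@pytest.fixture(scope="session")
def toy_corpus(toy_ontology):
    return load_hpoa(io.StringIO(TOY_HPOA), toy_ontology)


@pytest.fixture(scope="session")
def toy_ic(toy_ontology, toy_corpus):
    return compute_ic(toy_ontology, toy_corpus)


LN2 = math.log(2)
LN4 = math.log(4)
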