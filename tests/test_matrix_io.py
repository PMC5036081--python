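import pytest

import cladistron as cl
from cladistron.matrix_io import (
    CharacterDefinition,
    CharType,
    MatrixParseError,
    MatrixValidationError,
    build_matrix,
    parse_nexus_matrix,
    parse_tnt_matrix,
    write_nexus_matrix,
    write_tnt_matrix,
)

TOY_NEXUS = """#NEXUS
BEGIN DATA;
  DIMENSIONS NTAX=2 NCHAR=1;
  FORMAT DATATYPE=STANDARD SYMBOLS="01" MISSING=? GAP=-;
  MATRIX
    A 0
    B 1
  ;
END;
"""

MIXED_NEXUS = """#NEXUS
BEGIN DATA;
  DIMENSIONS NTAX=4 NCHAR=5;
  FORMAT DATATYPE=STANDARD SYMBOLS="0123" MISSING=? GAP=-;
  MATRIX
    tax1 01{01}2?
    tax2 10(23)0-
    tax3 0122?
    tax4 1?032
  ;
END;
BEGIN ASSUMPTIONS;
  TYPESET * default = ord: 4, unord: 3 5;
END;
BEGIN SETS;
  TAXSET outgroup = 4;
END;
"""

TOY_TNT = """xread
'toy export'
3 3
A 010
B 1[01]0
C 0?1
;
ccode + 0 2;
proc /;
"""


def test_toy_nexus_parses():
    m = parse_nexus_matrix(TOY_NEXUS)
    assert m.n_taxa == 2 and m.n_chars == 1
    assert m.cells[0][0] == frozenset([0])


def test_mixed_nexus_codings():
    m = parse_nexus_matrix(MIXED_NEXUS)
    assert m.cells[0][2] == frozenset([0, 1])  # {01} polymorphism
    assert m.cells[1][2] == frozenset([2, 3])  # (23) polymorphism
    assert m.cells[0][4] == frozenset()  # ? missing
    assert m.cells[1][4] == frozenset()  # gap '-' treated as missing
    # 1-based TYPESET: char 4 ordered, 3 and 5 unordered (where multistate)
    assert m.characters[3].char_type is CharType.ORDERED
    assert m.characters[2].char_type is CharType.UNORDERED
    assert m.characters[0].char_type is CharType.BINARY
    assert m.ingroup == [True, True, True, False]


def test_tnt_ccode_zero_based():
    m = parse_tnt_matrix(TOY_TNT)
    assert m.n_taxa == 3 and m.n_chars == 3
    assert m.cells[1][1] == frozenset([0, 1])  # [01] polymorphism
    # declared additive characters keep their class even with 2 observed states
    assert m.characters[0].char_type is CharType.ORDERED
    assert m.characters[2].char_type is CharType.ORDERED
    assert m.characters[1].char_type is CharType.BINARY


@pytest.mark.parametrize("dialect", ["nexus", "tnt"])
def test_round_trip_simulated_matrix(small_sim, dialect, tmp_path):
    m = small_sim.matrix
    path = tmp_path / f"m.{dialect}"
    cl.write_matrix(m, path, dialect)
    m2 = cl.read_matrix(path, dialect)
    assert m2 == m  # cells, types and taxon order preserved exactly


def test_round_trip_outgroup_flags(small_sim, tmp_path):
    m = small_sim.matrix
    m.ingroup = [True] * (m.n_taxa - 2) + [False, False]
    text = write_nexus_matrix(m)
    m2 = parse_nexus_matrix(text)
    assert m2.ingroup == m.ingroup


def test_summary_counts_are_consistent(study_shaped_sim):
    s = study_shaped_sim.matrix.summarize()
    assert s.n_taxa == 34 and s.n_chars == 51
    assert s.n_binary + s.n_ordered + s.n_unordered == s.n_chars
    assert s.n_ingroup + s.n_outgroup == s.n_taxa
    assert (s.n_binary, s.n_ordered, s.n_unordered) == (28, 19, 4)


def test_all_binary_matrix_summary():
    m = build_matrix(
        ["a", "b", "c"],
        [[frozenset([0]), frozenset([1])],
         [frozenset([1]), frozenset([0])],
         [frozenset([0]), frozenset([0])]],
        ordered=set(),
    )
    s = m.summarize()
    assert (s.n_ordered, s.n_unordered) == (0, 0)


def test_validation_rejects_duplicate_taxa():
    with pytest.raises(MatrixValidationError, match="duplicate"):
        cl.CharacterMatrix(
            ["a", "a"],
            [[frozenset([0])], [frozenset([1])]],
            [CharacterDefinition(0, CharType.BINARY, 2)],
        )


def test_validation_rejects_state_outside_alphabet():
    with pytest.raises(MatrixValidationError, match="character 1"):
        cl.CharacterMatrix(
            ["a", "b"],
            [[frozenset([0])], [frozenset([5])]],
            [CharacterDefinition(0, CharType.BINARY, 2)],
        )


def test_validation_rejects_ragged_rows():
    with pytest.raises(MatrixValidationError, match="row length"):
        cl.CharacterMatrix(
            ["a", "b"],
            [[frozenset([0])], []],
            [CharacterDefinition(0, CharType.BINARY, 2)],
        )


def test_parse_errors_name_a_location():
    with pytest.raises(MatrixParseError, match="line 1"):
        parse_nexus_matrix("BEGIN DATA;\nMATRIX\nA 01\n;\nEND;")
    bad = TOY_NEXUS.replace("DIMENSIONS NTAX=2", "DIMENSIONS NTAX=3")
    with pytest.raises(MatrixParseError, match="NTAX"):
        parse_nexus_matrix(bad)
    with pytest.raises(MatrixParseError, match="unexpected symbol"):
        parse_nexus_matrix(TOY_NEXUS.replace("B 1", "B Z"))


def test_character_definition_invariants():
    with pytest.raises(MatrixValidationError):
        CharacterDefinition(0, CharType.BINARY, 3)
    with pytest.raises(MatrixValidationError):
        CharacterDefinition(0, CharType.ORDERED, 2)


def test_tree_io_round_trip(tmp_path):
    trees = [cl.simulate_tree(7, seed=s) for s in (1, 2)]
    for dialect in ("newick", "nexus"):
        path = tmp_path / f"t.{dialect}"
        cl.write_trees(trees, path, dialect=dialect)
        back = cl.read_trees(path, dialect=dialect)
        assert len(back) == 2
        for a, b in zip(trees, back):
            assert cl.robinson_foulds(a, b) == 0


def test_annotated_tree_round_trips_labels(tmp_path):
    t = cl.Tree.from_newick("((A,B)75,(C,D)40);")
    path = tmp_path / "ann.nwk"
    cl.write_trees([t], path)
    (back,) = cl.read_trees(path)
    labels = {n.label for n in back.postorder() if n.children}
    assert {"75", "40"} <= labels
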