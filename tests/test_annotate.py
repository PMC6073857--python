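import re

import numpy as np
import pytest

from neuromine.annotate import (
    CleavageRules,
    CleavageSite,
    annotate_precursor,
    assign_family,
    derive_mature_peptides,
    fragment_partition,
    load_motif_table,
    predict_cleavage_sites,
    predict_signal_peptide,
    search_reference,
)
from neuromine.synthetic import LINKER_ALPHABET, build_signal, _subseed

# ---------------------------------------------------------------------------
# signal peptide


def test_generated_signal_cleaved_at_exact_position(rng):
    for length in (13, 15, 17, 22, 30, 40):
        signal = build_signal(length, rng)
        mature = "".join(rng.choice(list(LINKER_ALPHABET), 60))
        pred = predict_signal_peptide(signal + mature)
        assert pred.present, (length, signal)
        assert pred.cleavage_after == length, (length, signal)


def test_poly_ser_has_no_signal():
    pred = predict_signal_peptide("S" * 50)
    assert not pred.present


def test_short_sequence_reports_reason():
    pred = predict_signal_peptide("MKLLVALLLA")
    assert not pred.present
    assert "short" in pred.reason


def test_gpb5_standin_signal_is_17(worked_examples):
    pred = predict_signal_peptide(worked_examples["gpb5"])
    assert pred.present and pred.cleavage_after == 17


# ---------------------------------------------------------------------------
# cleavage grammar


def test_single_dibasic_site():
    sites = predict_cleavage_sites("AAKRAA")
    assert [(s.position, s.motif) for s in sites] == [(4, "KR")]


def test_no_motifs_empty():
    assert predict_cleavage_sites("AAAAAA") == []


def _oracle_sites(aa: str, rules: CleavageRules):
    """Regex-based brute force over the motif grammar, greedy left to
    right with motif-residue consumption."""
    used = set()
    sites = []
    for i in range(1, len(aa) + 1):
        if rules.dibasic and i >= 2 and re.fullmatch("KR|RR|KK", aa[i - 2 : i]):
            if i - 1 not in used and i not in used:
                sites.append((i, aa[i - 2 : i]))
                used |= {i - 1, i}
                continue
        if rules.monobasic and aa[i - 1] == "R" and i not in used:
            upstream = any(
                i - off >= 1 and aa[i - off - 1] in "KR" for off in rules.monobasic_offsets
            )
            if upstream or i == len(aa):
                sites.append((i, "R"))
                used.add(i)
    return sites


def test_cleavage_sites_match_regex_oracle(rng):
    rules = CleavageRules()
    alphabet = list("ARKGLSQPE")
    for _ in range(200):
        aa = "".join(rng.choice(alphabet, rng.integers(5, 60)))
        got = [(s.position, s.motif) for s in predict_cleavage_sites(aa, rules)]
        assert got == _oracle_sites(aa, rules), aa
        positions = [p for p, _ in got]
        assert positions == sorted(positions)


def test_monobasic_requires_upstream_basic_or_terminus():
    assert [(s.position, s.motif) for s in predict_cleavage_sites("KAR")] == [(3, "R")]
    assert predict_cleavage_sites("GAR")[0].motif == "R"  # terminal R
    assert predict_cleavage_sites("GARA") == []


# ---------------------------------------------------------------------------
# mature peptides


def test_rpch_proform_renders_printed_peptide():
    pro = "QLNFSPGWGKR"
    sites = predict_cleavage_sites(pro)
    peps = derive_mature_peptides(pro, sites)
    assert [p.rendered for p in peps] == ["pQLNFSPGWamide"]
    assert peps[0].n_term == "pyroGlu" and peps[0].c_term == "amide"


def test_corazonin_proform_renders_printed_peptide():
    pro = "QTFQYSRGWTNGKR"
    peps = derive_mature_peptides(pro, predict_cleavage_sites(pro))
    assert [p.rendered for p in peps] == ["pQTFQYSRGWTNamide"]


def test_identity_case_no_sites_no_termini():
    pro = "ALSPTMNDW"
    peps = derive_mature_peptides(pro, [])
    assert len(peps) == 1
    assert peps[0].sequence == pro
    assert peps[0].n_term == "none" and peps[0].c_term == "none"
    assert peps[0].span == (1, len(pro))


def test_short_fragments_discarded():
    pro = "AAKRAA"  # two 2-residue fragments
    peps = derive_mature_peptides(pro, predict_cleavage_sites(pro))
    assert peps == []


def test_overlapping_sites_rejected():
    with pytest.raises(ValueError, match="overlap"):
        fragment_partition("AKRRA", [CleavageSite(3, "KR"), CleavageSite(4, "RR")])


def test_fragment_conservation_reconstructs_proprotein(rng):
    alphabet = list("ARKGLSQPEC")
    for _ in range(100):
        pro = "".join(rng.choice(alphabet, rng.integers(4, 80)))
        sites = predict_cleavage_sites(pro)
        fragments, removed = fragment_partition(pro, sites)
        pieces = sorted(fragments + removed)
        rebuilt = "".join(pro[a - 1 : b] for a, b in pieces)
        assert rebuilt == pro


def test_modifications_require_their_donors(rng):
    alphabet = list("ARKGQLSPEC")
    for _ in range(100):
        pro = "".join(rng.choice(alphabet, rng.integers(8, 60)))
        peps = derive_mature_peptides(pro, predict_cleavage_sites(pro))
        for p in peps:
            frag = pro[p.span[0] - 1 : p.span[1]]
            if p.c_term == "amide":
                assert frag.endswith("G")
            if p.n_term == "pyroGlu":
                assert p.sequence.startswith("Q")
            assert p.cys_count == p.sequence.count("C")


# ---------------------------------------------------------------------------
# family assignment


def test_rpch_family_assignment():
    table = load_motif_table()
    pro = "QLNFSPGWGKR"
    peps = derive_mature_peptides(pro, predict_cleavage_sites(pro))
    family, pattern, repetitive = assign_family(peps, table)
    assert family == "AKH/RPCH"
    assert pattern is not None and not repetitive


def test_no_peptides_unassigned():
    family, pattern, repetitive = assign_family([], load_motif_table())
    assert family == "unassigned" and pattern is None and not repetitive


def test_three_matching_peptides_set_repetitive():
    table = load_motif_table()
    pro = "APYAFGLGKRAPYAFGLGKRAPYAFGLGKR"
    peps = derive_mature_peptides(pro, predict_cleavage_sites(pro))
    family, _, repetitive = assign_family(peps, table)
    assert family == "allatostatin-A" and repetitive


def test_malformed_pattern_raises(tmp_path):
    bad = tmp_path / "motifs.tsv"
    bad.write_text("family\tpattern\nx\t[unclosed\n")
    with pytest.raises(ValueError, match="malformed pattern"):
        load_motif_table(bad)


# ---------------------------------------------------------------------------
# annotation contract


def test_annotation_deterministic_and_flag_consistent(worked_examples):
    for name, protein in worked_examples.items():
        a1 = annotate_precursor(protein, protein_id=name)
        a2 = annotate_precursor(protein, protein_id=name)
        assert a1 == a2
        assert a1.amidated == any(p.c_term == "amide" for p in a1.peptides)
        assert a1.has_signal == a1.signal.present
        if a1.repetitive:
            assert sum(1 for p in a1.peptides) >= 2


# ---------------------------------------------------------------------------
# reference search


def _sw_oracle(a: str, b: str, gap_open=11.0, gap_extend=1.0):
    """Quadratic Smith-Waterman DP, affine gaps (first gap residue costs
    gap_open, the rest gap_extend each), BLOSUM62."""
    from Bio.Align import substitution_matrices

    B = substitution_matrices.load("BLOSUM62")
    n, m = len(a), len(b)
    NEG = -1e9
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), NEG)
    F = np.full((n + 1, m + 1), NEG)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i, j] = max(H[i, j - 1] - gap_open, E[i, j - 1] - gap_extend)
            F[i, j] = max(H[i - 1, j] - gap_open, F[i - 1, j] - gap_extend)
            H[i, j] = max(0.0, H[i - 1, j - 1] + B[a[i - 1]][b[j - 1]], E[i, j], F[i, j])
            best = max(best, H[i, j])
    return best


def test_search_scores_match_dp_oracle(rng, amino_acids):
    panel = [
        (f"p{k}", "".join(rng.choice(list(amino_acids), rng.integers(8, 25))))
        for k in range(4)
    ]
    for _ in range(5):
        query = "".join(rng.choice(list(amino_acids), rng.integers(8, 30)))
        hits = dict(search_reference(query, panel))
        for pid, pseq in panel:
            expected = _sw_oracle(query, pseq)
            if expected > 0:
                assert hits[pid] == pytest.approx(expected)
            else:
                assert pid not in hits


def test_query_equal_to_panel_entry_is_top_hit():
    panel = [("self", "QLNFSPGW"), ("other", "NSELINSLLGL")]
    hits = search_reference("QLNFSPGW", panel)
    assert hits[0][0] == "self"
    assert hits[0][1] == _sw_oracle("QLNFSPGW", "QLNFSPGW")


def test_dissimilar_query_reports_no_hit():
    assert search_reference("WWWW", [("polyA", "AAAAAAAA")]) == []


def test_empty_query_rejected():
    with pytest.raises(ValueError):
        search_reference("", [("x", "AAA")])
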