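"""Clamp-residue evaluation, substitution typing, verdicts and the census."""
import pytest

from cctpr.clamp import (
    ARCHITECTURE_CLASSES,
    SUBSTITUTION_CLASSES,
    architecture_census,
    classify_protein,
    evaluate_clamp,
    substitution_status,
)
from cctpr.scanner import TprDomain, TprMotif, domain_from_fixture_rows, \
    register_rescue
from cctpr.screen import classify_fixture_proteins, fixture_domains
from cctpr.seqio import AMINO_ACIDS


def test_classes_partition_the_alphabet():
    seen = set()
    for cls in SUBSTITUTION_CLASSES:
        assert not (cls & seen)
        seen |= cls
    assert seen == set(AMINO_ACIDS)


@pytest.mark.parametrize(
    "expected,observed,status",
    [
        ("K", "K", "consensus"),
        ("K", "R", "conservative"),  # the common K5/K2 -> R replacement
        ("N", "Q", "conservative"),  # N9 -> Q in motif I
        ("K", "E", "radical"),       # the noteworthy K5 -> E case
        ("R", "A", "radical"),       # R6 -> A in the Hop orthologs
        ("R", "M", "radical"),       # R6 -> M in the CHIP ortholog
        ("N", "S", "radical"),       # N6 -> S in two Phox-domain proteins
        ("N", "D", "radical"),
        ("K", "X", "radical"),
        ("R", "K", "conservative"),
    ],
)
def test_substitution_status_calls(expected, observed, status):
    assert substitution_status(expected, observed) == status


def test_hop_reference_is_all_consensus(at_triplets):
    ev = evaluate_clamp(domain_from_fixture_rows(at_triplets["Human_Hop"]))
    assert ev.statuses == ("consensus",) * 5
    assert ev.n_match == 5


def test_athop1_statuses(at_triplets):
    ev = evaluate_clamp(domain_from_fixture_rows(at_triplets["AtHop1"]))
    assert ev.statuses == ("consensus", "consensus", "consensus",
                          "conservative", "radical")
    assert ev.n_match == 4


def test_attpr4_statuses(at_triplets):
    ev = evaluate_clamp(domain_from_fixture_rows(at_triplets["AtTPR4"]))
    assert ev.statuses == ("consensus", "radical", "consensus",
                          "radical", "consensus")
    assert ev.n_match == 3


def test_fully_mutated_domain_is_negative(at_triplets):
    rows = at_triplets["Human_Hop"]
    motifs = []
    for row in rows:
        seq = list(row.motif_seq)
        from cctpr.profiles import CLAMP_CONSENSUS

        for q in CLAMP_CONSENSUS[row.motif_index]:
            seq[q - 1] = "G"
        motifs.append(TprMotif(motif_index=row.motif_index, start=row.start,
                               window="".join(seq), score=0.0))
    verdict = classify_protein("mutant", [TprDomain(motifs=tuple(motifs))])
    assert not verdict.is_cc_tpr
    assert verdict.n_match == 0


def test_no_domains_is_negative():
    verdict = classify_protein("empty", [])
    assert not verdict.is_cc_tpr
    assert verdict.n_domains == 0


def test_every_fixture_protein_reaches_min_matches(at_rows, os_rows):
    for rows in (at_rows, os_rows):
        for v in classify_fixture_proteins(rows, include_reference=True):
            assert v.n_match >= 3, v.protein_id


def test_statuses_agree_with_printed_markup(at_rows, os_rows):
    """Bold (consensus) markup at clamp positions must evaluate consensus;
    bold-italic (substitution) markup must evaluate non-consensus.

    Printed positions are mapped through any register shift applied by the
    rescue step.
    """
    from cctpr.profiles import CLAMP_CONSENSUS
    from cctpr.seqio import group_by_protein

    checked = 0
    for rows in (at_rows, os_rows):
        grouped = group_by_protein(rows)
        domains = fixture_domains(rows)
        for name, triplet in grouped.items():
            domain = domains[name]
            ev = evaluate_clamp(domain)
            by_site = {(s.motif_index, s.position): s for s in ev.sites}
            for row, motif in zip(triplet, domain.motifs):
                for q in CLAMP_CONSENSUS[row.motif_index]:
                    printed = q + motif.register_shift
                    if not 1 <= printed <= len(row.motif_seq):
                        continue
                    flag = row.residue_markup[printed - 1]
                    status = by_site[(row.motif_index, q)].status
                    if flag == "C":
                        assert status == "consensus", (name, q)
                        checked += 1
                    elif flag == "S":
                        assert status != "consensus", (name, q)
                        checked += 1
    assert checked > 300  # the five clamp sites across both tables


def test_architecture_census_of_novel_proteins(at_rows, meta):
    verdicts = classify_fixture_proteins(at_rows)
    census = architecture_census(verdicts, meta)
    assert census["novel"] == {
        "single_TPR": 8,
        "single_TPR_plus_domain": 7,
        "multi_TPR": 3,
        "multi_TPR_plus_domain": 6,
    }
    assert sum(census["all"].values()) == 36
    assert sum(census["known"].values()) == 12


def test_census_empty_verdicts():
    census = architecture_census([], [])
    assert all(census["all"][c] == 0 for c in ARCHITECTURE_CLASSES)


def test_census_external_annotations_override(at_rows, meta):
    verdicts = classify_fixture_proteins(at_rows)
    # pretend an external scan found a domain in AtTPR1
    census = architecture_census(verdicts, meta,
                                 annotations={"AtTPR1": ["kinase"]})
    assert census["novel"]["single_TPR"] == 7
    assert census["novel"]["single_TPR_plus_domain"] == 8


def test_rescued_anomaly_rows_evaluate_all_five_sites(os_rows):
    domains = fixture_domains(os_rows)
    ev = evaluate_clamp(domains["Os05g03910"])
    assert len(ev.sites) == 5
    assert ev.n_match == 5  # N restored to motif-II position 6 by the rescue
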