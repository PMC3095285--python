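"""Spliced alignment, ORF calling, flank scans, allele calls, amplicons."""

import warnings
from dataclasses import replace

import numpy as np
import pytest

from genarch.models import (GeneModel, NoConfidentModel,
                            classify_allele_vs_isogene, find_orf_and_translate,
                            model_from_alignment, predict_amplicon,
                            scan_flanks, spliced_align)
from genarch.seqs import revcomp
from genarch.simulate import (EvolParams, SignalFlags, implant_signals,
                              simulate_family)

RNG = np.random.default_rng(21)


def _random_seq(n, rng=RNG):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


# ---------------------------------------------------------------------------
# spliced alignment


def test_exact_substring_gives_single_block(family4):
    g = sorted(family4.genes)[0]
    cdna = family4.cdnas[g][:300]
    window = _random_seq(500) + cdna + _random_seq(500)
    aln = spliced_align(cdna, window)
    assert len(aln.blocks) == 1
    assert aln.introns == []
    assert aln.identity == 1.0
    assert aln.blocks[0][1] == (500, 800)


def test_truth_exons_recovered_for_every_family_gene(family4):
    for g, m in family4.genes.items():
        aln = spliced_align(family4.cdnas[g],
                            family4.scaffolds[m.scaffold_id])
        assert aln.strand == m.strand
        assert [gg for _, gg in aln.blocks] == list(m.exons)
        assert aln.identity == 1.0
        assert all(i.canonical for i in aln.introns)
        assert not aln.mrna_is_revcomp


def test_antisense_query_recovers_same_exons(family4):
    g = sorted(family4.genes)[0]
    m = family4.genes[g]
    aln = spliced_align(revcomp(family4.cdnas[g]),
                        family4.scaffolds[m.scaffold_id])
    assert aln.mrna_is_revcomp
    assert [gg for _, gg in aln.blocks] == list(m.exons)
    assert aln.mrna == family4.cdnas[g]


def test_non_canonical_intron_is_flagged(family4):
    g = sorted(family4.genes)[0]
    m = family4.genes[g]
    scaf = family4.scaffolds[m.scaffold_id]
    s, e = m.introns_genomic()[0]
    pos = s if m.strand == "+" else e - 2   # donor's genomic location
    mutated = scaf[:pos] + "CC" + scaf[pos + 2:]
    aln = spliced_align(family4.cdnas[g], mutated)
    assert any(not i.canonical for i in aln.introns)
    assert any(f.startswith("non-canonical-intron") for f in aln.flags)


def test_unrelated_cdna_raises_no_confident_model(family4):
    g = sorted(family4.genes)[0]
    with pytest.raises((NoConfidentModel, ValueError)):
        spliced_align(_random_seq(400, np.random.default_rng(5)),
                      family4.scaffolds[family4.genes[g].scaffold_id])


def test_strand_symmetry_under_window_reversal(family4):
    g = sorted(family4.genes)[0]
    m = family4.genes[g]
    scaf = family4.scaffolds[m.scaffold_id]
    aln_f = spliced_align(family4.cdnas[g], scaf)
    aln_r = spliced_align(family4.cdnas[g], revcomp(scaf))
    assert aln_f.strand != aln_r.strand
    L = len(scaf)
    reflected = sorted((L - e, L - s) for _, (s, e) in aln_r.blocks)
    assert reflected == sorted(gg for _, gg in aln_f.blocks)


def test_exon_lengths_sum_to_cdna_span(family4):
    for g, m in family4.genes.items():
        aln = spliced_align(family4.cdnas[g],
                            family4.scaffolds[m.scaffold_id])
        assert sum(e - s for _, (s, e) in aln.blocks) == len(family4.cdnas[g])


def test_model_from_alignment_round_trips_truth(family4):
    g = sorted(family4.genes)[1]
    m = family4.genes[g]
    aln = spliced_align(family4.cdnas[g], family4.scaffolds[m.scaffold_id])
    model = model_from_alignment(aln, g, m.scaffold_id)
    assert model.exons == m.exons
    assert model.protein == m.protein
    model.validate(family4.scaffolds[m.scaffold_id])


# ---------------------------------------------------------------------------
# ORF calling


def test_minimal_orf():
    cds, protein, flags = find_orf_and_translate("ATGAAATAA")
    assert cds == (0, 9)
    assert protein == "MK"
    assert "fragment" in flags            # < 50 codons


def test_orf_matches_truth_protein(family4):
    for g in family4.genes:
        cds, protein, flags = find_orf_and_translate(family4.cdnas[g])
        assert protein == family4.genes[g].protein
        assert "fragment" not in flags


def test_equal_length_orfs_take_five_prime_most_with_flag():
    orf = "ATG" + "GCA" * 60 + "TAA"
    cdna = orf + "CCC" + orf
    cds, protein, flags = find_orf_and_translate(cdna)
    assert cds[0] == 0
    assert "orf-tie" in flags


# ---------------------------------------------------------------------------
# flank scanning


def _fragment_without_first_exon(truth, gid):
    m = truth.genes[gid]
    rest = m.exons[1:]
    lost = m.exons[0][1] - m.exons[0][0]
    prot_rest = m.protein[max(0, (lost - m.cds_start)) // 3:]
    return GeneModel(gene_id=f"{gid}_frag", scaffold_id=m.scaffold_id,
                     strand=m.strand, exons=rest, cds_start=0,
                     cds_end=(sum(e - s for s, e in rest) // 3) * 3,
                     protein=prot_rest)


def test_withheld_first_exon_found_among_top_upstream_candidates():
    p = EvolParams(tree="((a:0.2,b:0.2):0.1,(c:0.2,d:0.2):0.1);", seed=23,
                   n_codons=220, n_ancestral_introns=4)
    truth = implant_signals(simulate_family(p),
                            {"a": SignalFlags(transit_peptide=True)})
    frag = _fragment_without_first_exon(truth, "a")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cands = scan_flanks(frag, truth.scaffolds[frag.scaffold_id])
    assert cands["upstream"], "implanted transit peptide not recovered"
    assert cands["upstream"][0].score >= 0.45


def test_no_signal_means_no_upstream_candidates_usually():
    hits = 0
    for seed in range(20):
        p = EvolParams(tree="(a:0.2,b:0.2);", seed=seed + 300, n_codons=180,
                       n_ancestral_introns=2)
        truth = simulate_family(p)
        m = truth.genes["a"]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cands = scan_flanks(m, truth.scaffolds[m.scaffold_id])
        hits += bool(cands["upstream"])
    assert hits <= 2                      # specificity >= 90%


def test_all_n_window_is_empty_with_warning(family4):
    g = sorted(family4.genes)[0]
    m = family4.genes[g]
    with pytest.warns(UserWarning):
        cands = scan_flanks(m, "N" * len(family4.scaffolds[m.scaffold_id]))
    assert cands["upstream"] == []


def test_downstream_scan_finds_implanted_anchor_exon():
    """A TM-anchor-coding stretch in the downstream window is reported."""
    p = EvolParams(tree="(a:0.1,b:0.1);", seed=31, n_codons=180,
                   n_ancestral_introns=2)
    truth = implant_signals(simulate_family(p),
                            {"a": SignalFlags(tm_anchor=True)})
    m = truth.genes["a"]
    trunc = replace(m, exons=m.exons[:-1],
                    cds_start=0,
                    cds_end=(sum(e - s for s, e in m.exons[:-1]) // 3) * 3,
                    protein=m.protein[:100])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cands = scan_flanks(trunc, truth.scaffolds[m.scaffold_id])
    assert cands["downstream"]


# ---------------------------------------------------------------------------
# allele vs isogene


def test_model_vs_itself_is_allele(family4):
    g = sorted(family4.genes)[0]
    call = classify_allele_vs_isogene(family4.genes[g], family4.genes[g],
                                      family4.scaffolds)
    assert call.verdict == "allele"
    assert call.cdna_identity == 1.0
    assert call.flank_identity == 1.0


def test_mutated_haplotype_copy_is_allele(family4):
    g = sorted(family4.genes)[0]
    m = family4.genes[g]
    scaf = family4.scaffolds[m.scaffold_id]
    rng = np.random.default_rng(6)
    hap = list(scaf)
    for pos in rng.choice(len(hap), int(0.005 * len(hap)), replace=False):
        hap[pos] = "ACGT"[("ACGT".index(hap[pos]) + 1) % 4]
    scaffolds = dict(family4.scaffolds)
    scaffolds["scaf_hap"] = "".join(hap)
    twin = replace(m, gene_id="twin", scaffold_id="scaf_hap")
    call = classify_allele_vs_isogene(m, twin, scaffolds)
    assert call.verdict == "allele"
    assert call.cdna_identity >= 0.98


def test_retrocopy_vs_parent_is_isogene(implanted_family):
    call = classify_allele_vs_isogene(implanted_family.genes["b"],
                                      implanted_family.genes["b_r"],
                                      implanted_family.scaffolds)
    assert call.verdict == "isogene"
    assert call.cdna_identity == 1.0
    assert call.flank_identity < 0.9


def test_paralogs_are_isogenes(family4):
    genes = sorted(family4.genes)
    call = classify_allele_vs_isogene(family4.genes[genes[0]],
                                      family4.genes[genes[-1]],
                                      family4.scaffolds)
    assert call.verdict == "isogene"


# ---------------------------------------------------------------------------
# in-silico RT-PCR


def test_amplicon_length_arithmetic():
    fwd = "ACGTACGTACGTACGTACGT"
    rev = "TTGGCCAATTGGCCAATTGG"
    template = fwd + "N" * 100 + revcomp(rev)
    assert predict_amplicon(fwd, rev, template) == [140]


def test_amplicon_on_synthetic_cdna_matches_truth_distance(family4):
    g = sorted(family4.genes)[0]
    cdna = family4.cdnas[g]
    fwd, rev = cdna[10:30], revcomp(cdna[600:620])
    assert predict_amplicon(fwd, rev, cdna) == [610]


def test_single_mismatch_kills_amplicon(family4):
    g = sorted(family4.genes)[0]
    cdna = family4.cdnas[g]
    fwd = cdna[10:30]
    fwd = fwd[:9] + ("A" if fwd[9] != "A" else "C") + fwd[10:]
    rev = revcomp(cdna[600:620])
    assert predict_amplicon(fwd, rev, cdna) == []


def test_short_primer_rejected():
    with pytest.raises(ValueError):
        predict_amplicon("ACGTACGT", "ACGTACGTACGTACGTA", "ACGT" * 100)
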