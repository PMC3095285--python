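"""Synthetic gene families evolved along a known tree.

The generator emulates the situations a comparative gene-structure study
must resolve: amino-acid divergence along a phylogeny (equal-rates Poisson
model), intron gain and loss at defined codon phases with GT..AG intron
sequences, noisy single-pass EST fragments (optionally from unspliced
hnRNA, i.e. retained introns), implanted N-terminal chloroplast transit
peptides, C-terminal hydrophobic membrane anchors, and an intronless
retro-copy of a parent gene at an unrelated locus. Every event is recorded
so downstream inference can be scored against ground truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table

from .localization import KD
from .models import GeneModel
from .seqs import AMINO_ACIDS, DNA, revcomp, write_fasta
from .trees import Node, parse_newick

_CODONS: dict[str, list[str]] = {}
for codon, aa in standard_dna_table.forward_table.items():
    _CODONS.setdefault(aa, []).append(codon)
for aa in _CODONS:
    _CODONS[aa].sort()
_STOPS = sorted(standard_dna_table.stop_codons)


@dataclass(frozen=True)
class EvolParams:
    """Family-evolution settings.

    Branch lengths of `tree` are expected amino-acid substitutions per
    site; `intron_gain_rate` is expected gains per gene per unit branch
    length and `intron_loss_rate` expected losses per existing intron per
    unit branch length.
    """
    tree: str                                   # newick
    n_codons: int = 300
    n_ancestral_introns: int = 5
    aa_sub_rate_model: str = "poisson-equal"
    intron_gain_rate: float = 0.3
    intron_loss_rate: float = 0.3
    intron_len_range: tuple[int, int] = (60, 300)
    phase_distribution: tuple[float, float, float] = (0.5, 0.3, 0.2)
    utr5_range: tuple[int, int] = (20, 60)
    utr3_range: tuple[int, int] = (30, 90)
    flank_len: int = 800
    minus_strand_prob: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.n_codons < 150:
            raise ValueError("ancestral CDS must be >= 150 codons")
        if self.intron_gain_rate < 0 or self.intron_loss_rate < 0:
            raise ValueError("rates must be non-negative")
        if self.intron_len_range[0] < 20:
            raise ValueError("minimum intron length must be >= 20 bp")
        if abs(sum(self.phase_distribution) - 1.0) > 1e-9:
            raise ValueError("phase probabilities must sum to 1")
        if self.aa_sub_rate_model != "poisson-equal":
            raise ValueError("only the poisson-equal model is implemented")


@dataclass(frozen=True)
class ESTSimParams:
    coverage: float = 8.0          # mean ESTs per transcript
    frag_len_range: tuple[int, int] = (350, 600)
    error_rate: float = 0.01       # per-base substitution probability
    retained_intron_prob: float = 0.05
    end_bias: tuple[float, float] = (0.40, 0.45)   # P(5'-anchored), P(3')
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.error_rate < 0.5:
            raise ValueError("error_rate must be in [0, 0.5)")
        if not 0 <= self.retained_intron_prob <= 1:
            raise ValueError("retained_intron_prob must be in [0, 1]")


@dataclass(frozen=True)
class SignalFlags:
    transit_peptide: bool = False
    tm_anchor: bool = False
    retrocopy: bool = False


@dataclass
class _Blueprint:
    """Sequence-level description of a gene before genomic realisation."""
    protein: str                                # no stop; starts with M
    introns: list[tuple[int, str]]              # (cds_offset, class_id) sorted


@dataclass
class FamilyTruth:
    tree: str
    genes: dict[str, GeneModel]
    scaffolds: dict[str, str]
    cdnas: dict[str, str]                       # spliced transcript incl. UTRs
    premrnas: dict[str, str]                    # unspliced transcript
    intron_homology: dict[tuple[str, int], str]
    signals: dict[str, SignalFlags]
    blueprints: dict[str, _Blueprint]
    params: EvolParams
    n_gain_events: int = 0
    n_loss_events: int = 0

    @property
    def proteins(self) -> dict[str, str]:
        return {g: m.protein for g, m in self.genes.items()}

    def homology_classes(self) -> dict[str, set[tuple[str, int]]]:
        out: dict[str, set[tuple[str, int]]] = {}
        for intron_id, cls in self.intron_homology.items():
            out.setdefault(cls, set()).add(intron_id)
        return out

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        gene_ids = sorted(self.genes)
        write_fasta(((f"scaf_{g}", self.scaffolds[f"scaf_{g}"])
                     for g in gene_ids if f"scaf_{g}" in self.scaffolds),
                    outdir / "genomic.fasta")
        write_fasta(((g, self.cdnas[g]) for g in gene_ids),
                    outdir / "cdna.fasta")
        write_fasta(((g, self.genes[g].protein) for g in gene_ids),
                    outdir / "protein.fasta")
        (outdir / "tree.nwk").write_text(self.tree + "\n"
                                         if not self.tree.endswith("\n")
                                         else self.tree)
        write_gff3(self.genes.values(), outdir / "genes.gff3",
                   seed=self.params.seed)
        rows = [dict(gene_id=g, intron_index=i, homology_class=c)
                for (g, i), c in sorted(self.intron_homology.items())]
        pd.DataFrame(rows, columns=["gene_id", "intron_index",
                                    "homology_class"]
                     ).to_csv(outdir / "intron_truth.tsv", sep="\t",
                              index=False)
        sig = [dict(gene_id=g, transit_peptide=s.transit_peptide,
                    tm_anchor=s.tm_anchor, retrocopy=s.retrocopy)
               for g, s in sorted(self.signals.items())]
        pd.DataFrame(sig).to_csv(outdir / "signals.tsv", sep="\t", index=False)


def write_gff3(models, path, seed: Optional[int] = None) -> None:
    """GFF3 (1-based inclusive) with gene/mRNA/exon/CDS features."""
    lines = ["##gff-version 3"]
    if seed is not None:
        lines.append(f"#!generator-seed {seed}")
    for m in sorted(models, key=lambda m: m.gene_id):
        lo, hi = m.genomic_span()
        base = f"{m.scaffold_id}\tgenarch\t"
        tail = f"\t.\t{m.strand}\t"
        lines.append(base + f"gene\t{lo + 1}\t{hi}" + tail +
                     f".\tID={m.gene_id}")
        lines.append(base + f"mRNA\t{lo + 1}\t{hi}" + tail +
                     f".\tID={m.gene_id}.t1;Parent={m.gene_id}")
        exons = sorted(m.exons)
        for i, (s, e) in enumerate(exons, 1):
            lines.append(base + f"exon\t{s + 1}\t{e}" + tail +
                         f".\tID={m.gene_id}.e{i};Parent={m.gene_id}.t1")
        # CDS pieces: intersect exons with the CDS in transcript coords
        cum = 0
        cds_parts = []
        for s, e in m.exons:   # transcript order
            length = e - s
            t0, t1 = cum, cum + length
            lo_t = max(t0, m.cds_start)
            hi_t = min(t1, m.cds_end)
            if lo_t < hi_t:
                if m.strand == "+":
                    gs = s + (lo_t - t0)
                    ge = s + (hi_t - t0)
                else:
                    ge = e - (lo_t - t0)
                    gs = e - (hi_t - t0)
                cds_parts.append((gs, ge, lo_t - m.cds_start))
            cum = t1
        for i, (gs, ge, cds_off) in enumerate(cds_parts, 1):
            phase = (3 - cds_off % 3) % 3
            lines.append(base + f"CDS\t{gs + 1}\t{ge}\t.\t{m.strand}\t"
                         f"{phase}\tID={m.gene_id}.c{i};Parent={m.gene_id}.t1")
    Path(path).write_text("\n".join(lines) + "\n")


def read_gff3_exons(path) -> dict[str, dict]:
    """Exon intervals (0-based half-open, transcript order) per gene."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["seqid", "source", "type", "start", "end",
                            "score", "strand", "phase", "attrs"])
    out: dict[str, dict] = {}
    for r in df[df.type == "exon"].itertuples():
        gid = dict(kv.split("=") for kv in r.attrs.split(";"))["Parent"]
        gid = gid.removesuffix(".t1")
        rec = out.setdefault(gid, dict(scaffold=r.seqid, strand=r.strand,
                                       exons=[]))
        rec["exons"].append((r.start - 1, r.end))
    for rec in out.values():
        rec["exons"].sort()
        if rec["strand"] == "-":
            rec["exons"].reverse()
        rec["exons"] = tuple(map(tuple, rec["exons"]))
    return out


# ---------------------------------------------------------------------------
# family evolution


def _evolve_protein(protein: str, bl: float, rng: np.random.Generator) -> str:
    n_sub = rng.poisson(bl * len(protein))
    seq = list(protein)
    for _ in range(n_sub):
        pos = int(rng.integers(1, len(seq)))        # keep the initiator M
        choices = [a for a in AMINO_ACIDS if a != seq[pos]]
        seq[pos] = choices[int(rng.integers(len(choices)))]
    return "".join(seq)


#: minimum exon length the generator will produce (bp); micro-exons are
#: excluded on purpose — they are rare in real genes and unresolvable by
#: overlap-based EST evidence.
MIN_EXON_SPACING = 45


def _draw_intron_position(n_codons: int, taken: set[int],
                          phases: tuple[float, float, float],
                          rng: np.random.Generator) -> Optional[int]:
    for _ in range(200):
        aa = int(rng.integers(6, n_codons - 4))      # clear of the CDS ends
        phase = int(rng.choice(3, p=list(phases)))
        off = 3 * (aa - 1) + phase
        if all(abs(off - t) >= MIN_EXON_SPACING for t in taken):
            return off
    return None


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(DNA[i] for i in rng.integers(0, 4, size=n))


def _scrub_atg(seq: str) -> str:
    while "ATG" in seq:
        i = seq.index("ATG")
        seq = seq[:i] + "ACG" + seq[i + 3:]
    return seq


def _back_translate(protein: str, rng: np.random.Generator) -> str:
    parts = []
    for aa in protein:
        codons = _CODONS[aa]
        parts.append(codons[int(rng.integers(len(codons)))])
    parts.append(_STOPS[int(rng.integers(len(_STOPS)))])
    return "".join(parts)


def _make_intron(rng: np.random.Generator,
                 len_range: tuple[int, int]) -> str:
    n = int(rng.integers(len_range[0], len_range[1] + 1))
    return "GT" + _random_dna(rng, n - 4) + "AG"


def _realize_gene(gene_id: str, bp: _Blueprint, params: EvolParams,
                  rng: np.random.Generator
                  ) -> tuple[GeneModel, str, str, str]:
    """Build scaffold + model from a blueprint.

    Returns (model, scaffold_seq, spliced_cdna, premrna)."""
    cds = _back_translate(bp.protein, rng)
    utr5 = _scrub_atg(_random_dna(rng, int(rng.integers(*params.utr5_range))))
    utr3 = _scrub_atg(_random_dna(rng, int(rng.integers(*params.utr3_range))))
    cdna = utr5 + cds + utr3
    cds_start = len(utr5)
    positions = [cds_start + off for off, _ in bp.introns]
    intron_seqs = [_make_intron(rng, params.intron_len_range)
                   for _ in positions]
    flank5 = _random_dna(rng, params.flank_len)
    flank3 = _random_dna(rng, params.flank_len)
    pieces, bounds, prev = [], [], 0
    for pos, iseq in zip(positions, intron_seqs):
        pieces.append(cdna[prev:pos])
        bounds.append((prev, pos))
        pieces.append(iseq)
        prev = pos
    pieces.append(cdna[prev:])
    bounds.append((prev, len(cdna)))
    locus = "".join(pieces)
    premrna = locus
    strand = "-" if rng.random() < params.minus_strand_prob else "+"
    scaffold = flank5 + locus + flank3
    # genomic exon intervals on the forward scaffold, transcript order
    exons = []
    gpos = len(flank5)
    for (t0, t1), iseq in zip(bounds, intron_seqs + [""]):
        exons.append((gpos, gpos + (t1 - t0)))
        gpos += (t1 - t0) + len(iseq)
    if strand == "-":
        scaffold = revcomp(scaffold)
        L = len(scaffold)
        exons = [(L - e, L - s) for s, e in exons]
    model = GeneModel(gene_id=gene_id, scaffold_id=f"scaf_{gene_id}",
                      strand=strand, exons=tuple(exons),
                      cds_start=cds_start, cds_end=cds_start + len(cds),
                      protein=bp.protein)
    return model, scaffold, cdna, premrna


def simulate_family(params: EvolParams) -> FamilyTruth:
    """Evolve a gene family along `params.tree` and realise genomic loci.

    Deterministic for a fixed seed: one generator drives the whole run and
    the seed is recorded in the GFF3 header on write().
    """
    rng = np.random.default_rng(params.seed)
    root = parse_newick(params.tree)
    leaves = root.leaf_names()
    if len(leaves) < 2:
        raise ValueError("tree must have >= 2 leaves")
    if len(set(leaves)) != len(leaves):
        raise ValueError("duplicate leaf labels")

    anc_protein = "M" + "".join(
        AMINO_ACIDS[i] for i in rng.integers(0, 20, size=params.n_codons - 1))
    taken: set[int] = set()
    anc_introns: list[tuple[int, str]] = []
    for k in range(params.n_ancestral_introns):
        off = _draw_intron_position(params.n_codons, taken,
                                    params.phase_distribution, rng)
        if off is None:
            raise ValueError("could not place ancestral introns")
        taken.add(off)
        anc_introns.append((off, f"anc{k + 1:02d}"))
    anc_introns.sort()

    blueprints: dict[str, _Blueprint] = {}
    counters = {"gain": 0, "loss": 0}

    def descend(node: Node, protein: str, introns: list[tuple[int, str]]):
        for child in node.children:
            bl = child.length
            prot = _evolve_protein(protein, bl, rng)
            cur = list(introns)
            # losses: each intron independently
            p_loss = 1.0 - np.exp(-params.intron_loss_rate * bl)
            kept = []
            for item in cur:
                if rng.random() < p_loss:
                    counters["loss"] += 1
                else:
                    kept.append(item)
            cur = kept
            # gains
            n_gain = rng.poisson(params.intron_gain_rate * bl)
            occupied = {off for off, _ in cur}
            for _ in range(n_gain):
                off = _draw_intron_position(params.n_codons, occupied,
                                            params.phase_distribution, rng)
                if off is None:
                    continue
                counters["gain"] += 1
                occupied.add(off)
                cur.append((off, f"gain{counters['gain']:03d}"))
            cur.sort()
            if child.is_leaf():
                blueprints[child.name] = _Blueprint(protein=prot,
                                                    introns=cur)
            else:
                descend(child, prot, cur)

    descend(root, anc_protein, anc_introns)

    genes, scaffolds, cdnas, premrnas = {}, {}, {}, {}
    homology: dict[tuple[str, int], str] = {}
    for gid in sorted(blueprints):
        bp = blueprints[gid]
        model, scaffold, cdna, pre = _realize_gene(gid, bp, params, rng)
        genes[gid] = model
        scaffolds[model.scaffold_id] = scaffold
        cdnas[gid] = cdna
        premrnas[gid] = pre
        for i, (_, cls) in enumerate(bp.introns, 1):
            homology[(gid, i)] = cls
    signals = {gid: SignalFlags() for gid in genes}
    return FamilyTruth(tree=params.tree, genes=genes, scaffolds=scaffolds,
                       cdnas=cdnas, premrnas=premrnas,
                       intron_homology=homology, signals=signals,
                       blueprints=blueprints, params=params,
                       n_gain_events=counters["gain"],
                       n_loss_events=counters["loss"])


# ---------------------------------------------------------------------------
# signal implantation


def _sample_composition(rng: np.random.Generator, length: int,
                        weights: dict[str, float]) -> str:
    letters = sorted(weights)
    p = np.array([weights[a] for a in letters])
    p = p / p.sum()
    idx = rng.choice(len(letters), size=length, p=p)
    return "".join(letters[i] for i in idx)


_TP_WEIGHTS = {"S": 0.23, "T": 0.16, "R": 0.13, "K": 0.08, "A": 0.12,
               "L": 0.06, "V": 0.05, "P": 0.07, "G": 0.06, "N": 0.02,
               "Q": 0.01, "F": 0.01}
_TM_WEIGHTS = {"L": 0.45, "I": 0.20, "V": 0.15, "F": 0.12, "A": 0.08}


def _make_transit_peptide(rng: np.random.Generator) -> str:
    length = int(rng.integers(50, 81))
    for _ in range(100):
        pep = _sample_composition(rng, length, _TP_WEIGHTS)
        st = sum(pep.count(a) for a in "ST") / length
        rk = sum(pep.count(a) for a in "RK") / length
        de = sum(pep.count(a) for a in "DE") / length
        if st >= 0.34 and rk >= 0.17 and de <= 0.03:
            return pep
    raise RuntimeError("failed to sample a transit peptide")


def _make_tm_anchor(rng: np.random.Generator, length: int = 22) -> str:
    for _ in range(100):
        pep = _sample_composition(rng, length, _TM_WEIGHTS)
        if sum(KD[a] for a in pep) / length >= 2.0:
            return pep
    raise RuntimeError("failed to sample a TM anchor")


def implant_signals(truth: FamilyTruth,
                    which: dict[str, SignalFlags]) -> FamilyTruth:
    """Return a new FamilyTruth with the requested signals implanted.

    Transit peptides extend the N-terminus (within exon 1, shifting
    downstream intron offsets); anchors extend the C-terminus; a
    retro-copy duplicates the gene's cDNA into an intronless gene at a
    fresh locus. Affected genes are re-realised deterministically.
    """
    unknown = set(which) - set(truth.genes)
    if unknown:
        raise ValueError(f"flags reference unknown genes: {sorted(unknown)}")
    new = FamilyTruth(tree=truth.tree, genes=dict(truth.genes),
                      scaffolds=dict(truth.scaffolds),
                      cdnas=dict(truth.cdnas),
                      premrnas=dict(truth.premrnas),
                      intron_homology=dict(truth.intron_homology),
                      signals=dict(truth.signals),
                      blueprints=dict(truth.blueprints), params=truth.params,
                      n_gain_events=truth.n_gain_events,
                      n_loss_events=truth.n_loss_events)
    for k, gid in enumerate(sorted(which)):
        flags = which[gid]
        rng = np.random.default_rng([truth.params.seed % (2**31), 977, k])
        bp = truth.blueprints[gid]
        protein, introns = bp.protein, list(bp.introns)
        if flags.transit_peptide:
            pep = _make_transit_peptide(rng)
            protein = "M" + pep + protein[1:]
            shift = 3 * len(pep)
            introns = [(off + shift if off >= 3 else off, cls)
                       for off, cls in introns]
        if flags.tm_anchor:
            protein = protein + _make_tm_anchor(rng)
        if flags.transit_peptide or flags.tm_anchor:
            nbp = _Blueprint(protein=protein, introns=introns)
            model, scaffold, cdna, pre = _realize_gene(
                gid, nbp, truth.params, rng)
            new.genes[gid] = model
            new.scaffolds[model.scaffold_id] = scaffold
            new.cdnas[gid] = cdna
            new.premrnas[gid] = pre
            new.blueprints[gid] = nbp
            new.signals[gid] = replace(
                new.signals[gid], transit_peptide=flags.transit_peptide,
                tm_anchor=flags.tm_anchor)
        if flags.retrocopy:
            # reverse transcription copies the (possibly updated) mature
            # mRNA verbatim: identical cDNA, no introns, unrelated flanks
            rid = f"{gid}_r"
            cdna = new.cdnas[gid]
            parent = new.genes[gid]
            flank5 = _random_dna(rng, truth.params.flank_len)
            flank3 = _random_dna(rng, truth.params.flank_len)
            strand = ("-" if rng.random() < truth.params.minus_strand_prob
                      else "+")
            scaffold = flank5 + cdna + flank3
            exons = [(len(flank5), len(flank5) + len(cdna))]
            if strand == "-":
                scaffold = revcomp(scaffold)
                L = len(scaffold)
                exons = [(L - e, L - s) for s, e in exons]
            model = GeneModel(gene_id=rid, scaffold_id=f"scaf_{rid}",
                              strand=strand, exons=tuple(exons),
                              cds_start=parent.cds_start,
                              cds_end=parent.cds_end,
                              protein=parent.protein)
            new.genes[rid] = model
            new.scaffolds[model.scaffold_id] = scaffold
            new.cdnas[rid] = cdna
            new.premrnas[rid] = cdna
            new.blueprints[rid] = _Blueprint(protein=parent.protein,
                                             introns=[])
            new.signals[rid] = SignalFlags(retrocopy=True)
    return new


# ---------------------------------------------------------------------------
# EST simulation


@dataclass(frozen=True)
class ESTRecord:
    est_id: str
    seq: str


def simulate_ests(truth: FamilyTruth, params: ESTSimParams
                  ) -> tuple[list[ESTRecord], pd.DataFrame]:
    """Noisy single-pass EST fragments plus a hidden truth table.

    Each EST is a contiguous substring of its gene's spliced cDNA (or,
    with `retained_intron_prob`, of the unspliced pre-mRNA), with i.i.d.
    substitution errors, random orientation, and 5'/3' end bias
    (cDNA libraries are end-anchored far more often than uniform).
    """
    rng = np.random.default_rng(params.seed)
    records: list[ESTRecord] = []
    rows = []
    if params.coverage == 0:
        warnings.warn("coverage 0: no ESTs generated")
    p5, p3 = params.end_bias
    for gid in sorted(truth.genes):
        n = int(rng.poisson(params.coverage))
        for i in range(n):
            unspliced = rng.random() < params.retained_intron_prob
            src = truth.premrnas[gid] if unspliced else truth.cdnas[gid]
            flen = int(rng.integers(params.frag_len_range[0],
                                    params.frag_len_range[1] + 1))
            flen = min(flen, len(src))
            u = rng.random()
            if u < p5:
                start = 0
            elif u < p5 + p3:
                start = len(src) - flen
            else:
                start = int(rng.integers(0, len(src) - flen + 1))
            frag = src[start:start + flen]
            n_err = rng.binomial(flen, params.error_rate)
            if n_err:
                positions = rng.choice(flen, size=n_err, replace=False)
                frag_l = list(frag)
                for pos in positions:
                    alts = [b for b in DNA if b != frag_l[pos]]
                    frag_l[pos] = alts[int(rng.integers(3))]
                frag = "".join(frag_l)
            strand = "-" if rng.random() < 0.5 else "+"
            est_id = f"{gid}_est{i + 1:03d}"
            records.append(ESTRecord(est_id,
                                     frag if strand == "+" else revcomp(frag)))
            rows.append(dict(est_id=est_id, gene_id=gid, start=start,
                             end=start + flen, strand=strand,
                             unspliced=unspliced, n_errors=int(n_err)))
    table = pd.DataFrame(rows, columns=["est_id", "gene_id", "start", "end",
                                        "strand", "unspliced", "n_errors"])
    return records, table
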