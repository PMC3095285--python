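"""Gene models and spliced cDNA-to-genome alignment.

The spliced aligner is a seed-and-chain design: exact k-mer seeds are
collapsed into diagonal anchor blocks, blocks are chained collinearly, and
exon/intron junctions are polished within a small window to the
highest-scoring canonical (GT..AG on the transcript strand) placement.
Full dynamic programming is deliberately avoided so that genes with long
introns stay cheap to align.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import edlib

from .seqs import revcomp, translate
from . import localization

MIN_INTRON_LEN = 20


@dataclass(frozen=True)
class GeneModel:
    """Exon-intron structure of one gene on one scaffold.

    `exons` are scaffold-forward 0-based half-open intervals, listed in
    transcript (5'->3') order: ascending starts on '+', descending on '-'.
    `cds_start`/`cds_end` are transcript coordinates of the CDS including
    the stop codon; `protein` excludes the stop.
    """

    gene_id: str
    scaffold_id: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_start: int
    cds_end: int
    protein: str
    flags: tuple[str, ...] = ()

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        for s, e in self.exons:
            if e <= s:
                raise ValueError(f"empty exon ({s},{e})")
        starts = [s for s, _ in self.exons]
        if self.strand == "+" and starts != sorted(starts):
            raise ValueError("'+' exons must ascend in transcript order")
        if self.strand == "-" and starts != sorted(starts, reverse=True):
            raise ValueError("'-' exons must descend in transcript order")
        if (self.cds_end - self.cds_start) % 3:
            raise ValueError("CDS length not divisible by 3")

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def transcript_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def spliced(self, scaffold_seq: str) -> str:
        parts = []
        for s, e in self.exons:
            seg = scaffold_seq[s:e]
            parts.append(seg if self.strand == "+" else revcomp(seg))
        return "".join(parts)

    def cds(self, scaffold_seq: str) -> str:
        return self.spliced(scaffold_seq)[self.cds_start:self.cds_end]

    def intron_transcript_positions(self) -> list[int]:
        """Transcript coordinate of the first base after each intron's
        upstream exon (i.e. where the intron interrupts the transcript)."""
        out, cum = [], 0
        for s, e in self.exons[:-1]:
            cum += e - s
            out.append(cum)
        return out

    def introns_genomic(self) -> list[tuple[int, int]]:
        """Genomic intervals (scaffold-forward) of introns, transcript order."""
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if self.strand == "+":
                out.append((e1, s2))
            else:
                out.append((e2, s1))
        return out

    def genomic_span(self) -> tuple[int, int]:
        lo = min(s for s, _ in self.exons)
        hi = max(e for _, e in self.exons)
        return lo, hi

    def location_string(self) -> str:
        """1-based inclusive 'scaffold: start-end' (report style)."""
        lo, hi = self.genomic_span()
        return f"{self.scaffold_id}: {lo + 1}-{hi}"

    def validate(self, scaffold_seq: Optional[str] = None) -> None:
        if scaffold_seq is not None:
            spliced = self.spliced(scaffold_seq)
            cds = spliced[self.cds_start:self.cds_end]
            prot = translate(cds)
            if prot.endswith("*"):
                prot = prot[:-1]
            if prot != self.protein:
                raise ValueError(f"{self.gene_id}: CDS translation != protein")


@dataclass(frozen=True)
class Intron:
    start: int          # scaffold-forward, 0-based half-open
    end: int
    donor: str          # transcript-strand dinucleotides
    acceptor: str
    canonical: bool


@dataclass
class SplicedAlignment:
    blocks: list[tuple[tuple[int, int], tuple[int, int]]]  # (mRNA, genomic)
    introns: list[Intron]
    identity: float
    strand: str                 # gene strand on the genomic sequence
    mrna: str                   # transcript-orientation query sequence
    mrna_is_revcomp: bool       # query was the antisense of the mRNA
    flags: list[str] = field(default_factory=list)


class NoConfidentModel(ValueError):
    pass


# ---------------------------------------------------------------------------
# seed-and-chain spliced alignment


def _anchor_blocks(q: str, t: str, k: int) -> list[tuple[int, int, int]]:
    """Maximal same-diagonal anchor groups as (q_start, q_end, diag),
    diag = t_pos - q_pos."""
    index: dict[str, list[int]] = {}
    for i in range(len(t) - k + 1):
        index.setdefault(t[i:i + k], []).append(i)
    hits: dict[int, list[int]] = {}
    for i in range(len(q) - k + 1):
        for j in index.get(q[i:i + k], ()):
            hits.setdefault(j - i, []).append(i)
    blocks = []
    for diag, qpos in hits.items():
        qpos.sort()
        start = prev = qpos[0]
        for p in qpos[1:]:
            if p - prev > 3 * k:          # break far-apart runs on one diagonal
                blocks.append((start, prev + k, diag))
                start = p
            prev = p
        blocks.append((start, prev + k, diag))
    blocks.sort(key=lambda b: (b[0], b[2]))
    return blocks


def _chain(blocks: list[tuple[int, int, int]], min_intron: int
           ) -> list[tuple[int, int, int]]:
    """Collinear chain maximising covered query length minus intron cost."""
    n = len(blocks)
    if n == 0:
        return []
    score = [float(b[1] - b[0]) for b in blocks]
    back = [-1] * n
    for i in range(n):
        qs_i, qe_i, d_i = blocks[i]
        for j in range(i):
            qs_j, qe_j, d_j = blocks[j]
            if d_j == d_i or qe_j > qs_i + 10:
                continue
            gap = d_i - d_j
            if gap < min_intron:
                continue
            cost = 10.0 + 0.01 * gap
            s = score[j] + (qe_i - qs_i) - cost
            if s > score[i]:
                score[i] = s
                back[i] = j
    best = max(range(n), key=lambda i: (score[i], -blocks[i][0]))
    chain = []
    while best != -1:
        chain.append(blocks[best])
        best = back[best]
    chain.reverse()
    # merge chained blocks that ended up on one diagonal
    merged: list[tuple[int, int, int]] = []
    for b in chain:
        if merged and merged[-1][2] == b[2]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], b[1]), b[2])
        else:
            merged.append(b)
    return merged


def _matches(q: str, t: str, qs: int, qe: int, diag: int) -> int:
    m = 0
    for i in range(qs, qe):
        j = i + diag
        if 0 <= j < len(t) and q[i] == t[j]:
            m += 1
    return m


def _polish_junction(q: str, t: str, left_end: int, right_start: int,
                     d1: int, d2: int, donor: str, acceptor: str,
                     pad: int = 8) -> tuple[int, bool]:
    """Choose the query split point between two chained blocks.

    Scores every candidate split j by exon-side matches plus a bonus for a
    canonical donor/acceptor pair on the intron's genomic ends; ties go to
    the smallest j."""
    lo = max(1, min(left_end, right_start) - pad)
    hi = min(len(q) - 1, max(left_end, right_start) + pad)
    best_j, best_score, best_canon = lo, -1.0, False
    for j in range(lo, hi + 1):
        s = _matches(q, t, lo, j, d1) + _matches(q, t, j, hi, d2)
        g1, g2 = j + d1, j + d2
        canon = (t[g1:g1 + 2] == donor) and (t[g2 - 2:g2] == acceptor)
        sc = s + (4.0 if canon else 0.0)
        if sc > best_score:
            best_j, best_score, best_canon = j, sc, canon
    return best_j, best_canon


def _align_one_config(q: str, t: str, min_intron: int, k: int,
                      donor: str, acceptor: str):
    blocks = _chain(_anchor_blocks(q, t, k), min_intron)
    if not blocks:
        return None
    # extend outer blocks to the query ends along their diagonals
    first = blocks[0]
    blocks[0] = (0, first[1], first[2])
    last = blocks[-1]
    blocks[-1] = (last[0], len(q), last[2])
    if len(blocks) == 1:
        d = blocks[0][2]
        if d < 0 or d + len(q) > len(t):
            return None
        exons_q = [(0, len(q))]
        diags = [d]
        canon_flags: list[bool] = []
    else:
        splits, canon_flags = [], []
        for (qs1, qe1, d1), (qs2, qe2, d2) in zip(blocks, blocks[1:]):
            j, canon = _polish_junction(q, t, qe1, qs2, d1, d2, donor, acceptor)
            splits.append(j)
            canon_flags.append(canon)
        bounds = [0] + splits + [len(q)]
        exons_q = list(zip(bounds, bounds[1:]))
        diags = [b[2] for b in blocks]
        if any(qe <= qs for qs, qe in exons_q):
            return None
        if any(qs + d < 0 or qe + d > len(t)
               for (qs, qe), d in zip(exons_q, diags)):
            return None
    matches = sum(_matches(q, t, qs, qe, d)
                  for (qs, qe), d in zip(exons_q, diags))
    return exons_q, diags, canon_flags, matches / len(q)


def spliced_align(cdna: str, genomic: str, min_intron_len: int = MIN_INTRON_LEN,
                  k: int = 15, min_identity: float = 0.9) -> SplicedAlignment:
    """Align a cDNA to a genomic window allowing spliceosomal introns.

    Four configurations are scored — either query orientation may match
    the forward genomic strand, and independently the gene may lie on
    either strand (a minus-strand gene's introns read CT..AC on the
    forward strand). The winner is chosen by (identity, number of
    canonical junctions). The returned alignment is canonicalised to
    transcript orientation: `mrna` is the query sequence in mRNA sense and
    blocks/introns are listed 5'->3' along the transcript.

    Raises NoConfidentModel below `min_identity`.
    """
    if len(cdna) < 60:
        raise ValueError("cDNA shorter than 60 bp")
    rc = revcomp(cdna)
    configs = [
        # (query aligned to forward genome, donor, acceptor, gene strand,
        #  mRNA sequence, query-was-antisense, query is mRNA)
        (cdna, "GT", "AG", "+", cdna, False),
        (cdna, "CT", "AC", "-", rc, True),
        (rc, "GT", "AG", "+", rc, True),
        (rc, "CT", "AC", "-", cdna, False),
    ]
    cand = []
    for qseq, donor, acceptor, strand, mrna, is_rc in configs:
        res = _align_one_config(qseq, genomic, min_intron_len, k,
                                donor, acceptor)
        if res is None:
            continue
        exons_q, diags, canon, identity = res
        cand.append((identity, sum(canon), strand == "+",
                     (qseq, strand, mrna, is_rc, exons_q, diags, canon)))
    if not cand:
        raise NoConfidentModel("no anchor chain in any orientation")
    cand.sort(key=lambda c: c[:3], reverse=True)
    identity, n_canon, _, payload = cand[0]
    if identity < min_identity:
        raise NoConfidentModel(
            f"best chain identity {identity:.3f} < {min_identity}")
    qseq, strand, mrna, is_rc, exons_q, diags, canon = payload

    blocks, introns, flags = [], [], []
    L = len(qseq)
    for i, ((qs, qe), d) in enumerate(zip(exons_q, diags)):
        g = (qs + d, qe + d)
        if strand == "+":
            blocks.append(((qs, qe), g))      # qseq IS the mRNA here
        else:
            blocks.append(((L - qe, L - qs), g))
        if i < len(exons_q) - 1:
            g1 = qe + d
            g2 = exons_q[i + 1][0] + diags[i + 1]
            iv = genomic[g1:g2]
            if strand == "+":
                donor, acceptor = iv[:2], iv[-2:]
            else:
                donor, acceptor = revcomp(iv[-2:]), revcomp(iv[:2])
            is_canon = donor == "GT" and acceptor == "AG"
            introns.append(Intron(g1, g2, donor, acceptor, is_canon))
    if strand == "-":
        blocks.reverse()
        introns.reverse()
    for i, intron in enumerate(introns, 1):
        if not intron.canonical:
            flags.append(f"non-canonical-intron-{i}")
    if len(blocks) == 1:
        flags.append("strand-ambiguous")
    return SplicedAlignment(blocks=blocks, introns=introns,
                            identity=identity, strand=strand, mrna=mrna,
                            mrna_is_revcomp=is_rc, flags=flags)


def model_from_alignment(aln: SplicedAlignment, gene_id: str,
                         scaffold_id: str) -> GeneModel:
    """Build a GeneModel (transcript = the alignment's mRNA sense)."""
    exons = tuple(g for _, g in aln.blocks)
    cds, protein, orf_flags = find_orf_and_translate(aln.mrna)
    return GeneModel(gene_id=gene_id, scaffold_id=scaffold_id,
                     strand=aln.strand, exons=exons,
                     cds_start=cds[0], cds_end=cds[1], protein=protein,
                     flags=tuple(aln.flags) + tuple(orf_flags))


# ---------------------------------------------------------------------------
# ORF calling


def find_orf_and_translate(cdna: str, min_codons: int = 50
                           ) -> tuple[tuple[int, int], str, list[str]]:
    """Longest ATG-initiated ORF over the three forward frames.

    Returns ((cds_start, cds_end), protein, flags); the CDS interval
    includes the stop codon when present, the protein never does. Ties on
    length go to the 5'-most start (flagged). ORFs running off the 3' end
    are allowed and flagged 'no-stop'.
    """
    if not cdna:
        raise ValueError("empty cDNA")
    stops = {"TAA", "TAG", "TGA"}
    candidates = []  # (length_codons, start, end, has_stop)
    for frame in range(3):
        i = frame
        open_start = None
        while i + 3 <= len(cdna):
            codon = cdna[i:i + 3]
            if open_start is None and codon == "ATG":
                open_start = i
            if open_start is not None and codon in stops:
                candidates.append(((i + 3 - open_start) // 3, open_start,
                                   i + 3, True))
                open_start = None
            i += 3
        if open_start is not None:
            end = open_start + ((len(cdna) - open_start) // 3) * 3
            candidates.append(((end - open_start) // 3, open_start, end, False))
    if not candidates:
        raise ValueError("no ATG in any forward frame")
    candidates.sort(key=lambda c: (-c[0], c[1]))
    length, start, end, has_stop = candidates[0]
    flags = []
    if len(candidates) > 1 and candidates[1][0] == length:
        flags.append("orf-tie")
    if not has_stop:
        flags.append("no-stop")
    if length < min_codons + (1 if has_stop else 0):
        flags.append("fragment")
    protein = translate(cdna[start:end])
    if protein.endswith("*"):
        protein = protein[:-1]
    return (start, end), protein, flags


# ---------------------------------------------------------------------------
# flank scanning for missed terminal exons


@dataclass(frozen=True)
class FlankCandidate:
    side: str            # 'upstream' | 'downstream'
    frame: int
    peptide: str
    score: float
    detail: str = ""


def _upstream_window(model: GeneModel, scaffold: str, size: int
                     ) -> tuple[str, bool]:
    s0, e0 = model.exons[0]
    if model.strand == "+":
        lo = max(0, s0 - size)
        return scaffold[lo:s0], lo == 0 and s0 < size
    hi = min(len(scaffold), e0 + size)
    return revcomp(scaffold[e0:hi]), hi == len(scaffold) and len(scaffold) - e0 < size


def _downstream_window(model: GeneModel, scaffold: str, size: int
                       ) -> tuple[str, bool]:
    sl, el = model.exons[-1]
    if model.strand == "+":
        hi = min(len(scaffold), el + size)
        return scaffold[el:hi], hi == len(scaffold) and len(scaffold) - el < size
    lo = max(0, sl - size)
    return revcomp(scaffold[lo:sl]), lo == 0 and sl < size


def scan_flanks(model: GeneModel, scaffold: str, upstream: int = 2000,
                downstream: int = 2000, species_profile: str = "default",
                top: int = 10) -> dict[str, list[FlankCandidate]]:
    """Screen genomic flanks for missed terminal coding exons.

    Upstream: three-frame translations are scanned for stop-free peptides
    that, prepended to the current protein, score as plastid-targeting
    candidates. Downstream: three-frame translations are scanned for
    hydrophobic (membrane-anchor-like) helices. Candidates are ranked and
    never auto-accepted.
    """
    out: dict[str, list[FlankCandidate]] = {"upstream": [], "downstream": []}
    up, up_trunc = _upstream_window(model, scaffold, upstream)
    down, down_trunc = _downstream_window(model, scaffold, downstream)
    if up_trunc or down_trunc:
        warnings.warn(f"{model.gene_id}: flank window truncated at scaffold edge")
    if set(up) <= {"N"} and up:
        warnings.warn(f"{model.gene_id}: upstream window is all N")
        up = ""
    for frame in range(3):
        pep = translate(up[frame:frame + ((len(up) - frame) // 3) * 3]) if len(up) > frame + 2 else ""
        # a missed first exon may sit beyond an intron, so every stop-free
        # stretch is a candidate; suffixes approximate cleavage variants
        for seg in pep.split("*"):
            if len(seg) < 40:
                continue
            best_cand = None
            # exon boundaries are unknown inside a stop-free stretch, so a
            # transit-sized window slides over the whole segment
            width = 60
            if len(seg) <= width:
                windows = [(0, seg)]
            else:
                windows = [(o, seg[o:o + width])
                           for o in range(0, len(seg) - width + 1, 3)]
            for off, cand in windows:
                ts = localization.transit_peptide_score(
                    cand + model.protein, species_profile=species_profile)
                if ts.call != "plastid-candidate":
                    continue
                if best_cand is None or ts.score > best_cand.score:
                    best_cand = FlankCandidate(
                        "upstream", frame, cand, ts.score, f"offset={off}")
            if best_cand is not None:
                out["upstream"].append(best_cand)
    for frame in range(3):
        pep = translate(down[frame:frame + ((len(down) - frame) // 3) * 3]) if len(down) > frame + 2 else ""
        for seg in pep.split("*"):
            if len(seg) < 19:
                continue
            for hx in localization.tm_scan(seg):
                out["downstream"].append(FlankCandidate(
                    "downstream", frame, seg[hx.start - 1:hx.end],
                    hx.mean_hydropathy, f"span={hx.start}-{hx.end}"))
    for side in out:
        out[side].sort(key=lambda c: (-c.score, c.frame, c.peptide))
        out[side] = out[side][:top]
    return out


# ---------------------------------------------------------------------------
# allele vs isogene


@dataclass(frozen=True)
class AlleleCall:
    verdict: str                 # 'allele' | 'isogene' | 'undetermined'
    cdna_identity: float
    flank_identity: Optional[float]


def _edlib_identity(a: str, b: str, mode: str = "NW") -> float:
    if not a or not b:
        return 0.0
    res = edlib.align(a, b, mode=mode, task="distance")
    denom = len(a) if mode == "HW" else max(len(a), len(b))
    return max(0.0, 1.0 - res["editDistance"] / denom)


def classify_allele_vs_isogene(model_a: GeneModel, model_b: GeneModel,
                               scaffolds: dict[str, str], flank: int = 10000,
                               cdna_min: float = 0.98, flank_min: float = 0.90,
                               min_flank_len: int = 200) -> AlleleCall:
    """Allele iff the cDNAs are near-identical AND the gene environments
    (genomic flanks) are similar; otherwise isogene."""
    sa = scaffolds[model_a.scaffold_id]
    sb = scaffolds[model_b.scaffold_id]
    ca, cb = model_a.spliced(sa), model_b.spliced(sb)
    cid = max(_edlib_identity(ca, cb), _edlib_identity(ca, revcomp(cb)))
    sides = []
    for getter in (_upstream_window, _downstream_window):
        fa, _ = getter(model_a, sa, flank)
        fb, _ = getter(model_b, sb, flank)
        if len(fa) >= min_flank_len and len(fb) >= min_flank_len:
            q, t = (fa, fb) if len(fa) <= len(fb) else (fb, fa)
            sides.append(_edlib_identity(q, t, mode="HW"))
    if not sides:
        return AlleleCall("undetermined", cid, None)
    fid = sum(sides) / len(sides)
    verdict = "allele" if (cid >= cdna_min and fid >= flank_min) else "isogene"
    return AlleleCall(verdict, cid, fid)


# ---------------------------------------------------------------------------
# in-silico RT-PCR


def predict_amplicon(fwd_primer: str, rev_primer: str, template: str,
                     max_len: int = 5000) -> list[int]:
    """Exact-match amplicon lengths (RT-PCR product-size prediction).

    The forward primer anneals on the '+' strand, the reverse primer as its
    reverse complement downstream; a single mismatch yields no product."""
    if len(fwd_primer) < 15 or len(rev_primer) < 15:
        raise ValueError("primers must be >= 15 nt")
    rc = revcomp(rev_primer)
    products = []
    start = template.find(fwd_primer)
    while start != -1:
        pos = template.find(rc, start + 1)
        while pos != -1:
            length = pos + len(rc) - start
            if length <= max_len:
                products.append(length)
            pos = template.find(rc, pos + 1)
        start = template.find(fwd_primer, start + 1)
    return sorted(set(products))
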