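"""Splice-site homology on protein alignments, GC content, diagrams.

An intron interrupting a coding sequence is summarised as (residue index,
codon phase): phase 0 means the intron falls exactly between two codons,
phase 1/2 after the first/second base of the codon of the reported
residue. Projecting these labels onto a protein multiple alignment makes
intron positions comparable across family members: sites sharing an
alignment column and phase are taken as descendants of one ancestral
insertion (conserved), sites one column apart at equal phase as
near-conserved ("one codon length" shifts), the rest as unique.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .models import GeneModel
from .seqs import gc_fraction

GAP_CHARS = "-."


@dataclass(frozen=True)
class SpliceSite:
    gene_id: str
    intron_index: int        # 1-based along the transcript
    aa_index: int            # 1-based residue carrying/preceding the intron
    phase: int               # 0|1|2

    @property
    def label(self) -> str:
        return f"aa{self.aa_index}-{self.phase}"


@dataclass(frozen=True)
class AlignedSpliceSite:
    site: SpliceSite
    column: int              # 1-based MSA column of the residue

    @property
    def key(self) -> tuple[int, int]:
        return (self.column, self.site.phase)

    @property
    def label(self) -> str:
        return f"aa{self.column}-{self.site.phase}"


@dataclass
class ConservationClass:
    key: tuple[int, int]                      # anchor (column, phase)
    members: list[AlignedSpliceSite]
    status: str                               # conserved|near-conserved|unique
    near_members: list[AlignedSpliceSite] = field(default_factory=list)

    def all_sites(self) -> list[AlignedSpliceSite]:
        return self.members + self.near_members

    def genes(self) -> set[str]:
        return {s.site.gene_id for s in self.all_sites()}


@dataclass
class ConservationReport:
    classes: list[ConservationClass]
    pairwise_conserved: pd.DataFrame          # gene x gene shared classes
    excluded: list[tuple[SpliceSite, str]] = field(default_factory=list)

    def n_conserved(self) -> int:
        return sum(c.status == "conserved" for c in self.classes)

    def n_near_conserved(self) -> int:
        return sum(c.status == "near-conserved" for c in self.classes)


# ---------------------------------------------------------------------------


def splice_sites_from_model(model: GeneModel
                            ) -> tuple[list[SpliceSite], list[tuple[SpliceSite, str]]]:
    """(residue, phase) for every CDS intron of a gene model.

    For an intron whose first base sits at CDS offset c (0-based):
    aa_index = c // 3 + 1 and phase = c % 3. Introns outside the CDS are
    returned separately, flagged as UTR introns.
    """
    sites: list[SpliceSite] = []
    excluded: list[tuple[SpliceSite, str]] = []
    cds_len = model.cds_end - model.cds_start
    for idx, tpos in enumerate(model.intron_transcript_positions(), start=1):
        off = tpos - model.cds_start
        aa = off // 3 + 1
        phase = off % 3
        site = SpliceSite(model.gene_id, idx, max(aa, 0), phase)
        if off <= 0:
            excluded.append((site, "UTR intron (5')"))
        elif off >= cds_len:
            excluded.append((site, "UTR intron (3')"))
        else:
            sites.append(site)
    return sites, excluded


def project_to_alignment(sites: Sequence[SpliceSite], msa: dict[str, str],
                         offset_map: Optional[dict[str, int]] = None
                         ) -> list[AlignedSpliceSite]:
    """Map each site's residue index to its MSA column (1-based).

    `offset_map[gene]` is subtracted from aa_index first — it absorbs any
    difference between full-protein numbering and the (possibly
    transit-trimmed) row in the alignment.
    """
    offset_map = offset_map or {}
    nongap: dict[str, list[int]] = {}
    for gene, row in msa.items():
        nongap[gene] = [i for i, ch in enumerate(row) if ch not in GAP_CHARS]
    out: list[AlignedSpliceSite] = []
    for s in sites:
        if s.gene_id not in msa:
            raise ValueError(f"gene {s.gene_id} missing from the alignment")
        idx = s.aa_index - offset_map.get(s.gene_id, 0)
        positions = nongap[s.gene_id]
        if not 1 <= idx <= len(positions):
            raise ValueError(
                f"site {s.label} of {s.gene_id}: residue {idx} outside the "
                f"{len(positions)}-residue alignment row")
        out.append(AlignedSpliceSite(site=s, column=positions[idx - 1] + 1))
    return out


def compare_splice_sites(aligned: Sequence[AlignedSpliceSite],
                         tolerance: int = 1) -> ConservationReport:
    """Group projected sites into conserved / near-conserved / unique classes.

    Exact (column, phase) groups of size >= 2 are conserved. Remaining
    singletons are merged closest-first: into an existing class at equal
    phase within `tolerance` columns (joining as a near member), or with
    another singleton to form a near-conserved class; ties prefer the
    lower column. Leftovers are unique.
    """
    genes = sorted({a.site.gene_id for a in aligned})
    groups: dict[tuple[int, int], list[AlignedSpliceSite]] = {}
    for a in sorted(aligned, key=lambda a: (a.column, a.site.phase,
                                            a.site.gene_id, a.site.intron_index)):
        groups.setdefault(a.key, []).append(a)
    classes: list[ConservationClass] = []
    singles: list[AlignedSpliceSite] = []
    for key in sorted(groups):
        members = groups[key]
        if len(members) >= 2:
            classes.append(ConservationClass(key, members, "conserved"))
        else:
            singles.append(members[0])

    merged: set[int] = set()
    for i, s in enumerate(singles):
        if i in merged:
            continue
        best = None  # (|dcol|, column, kind, ref)
        for cl in classes:
            if cl.key[1] == s.site.phase and cl.genes() != {s.site.gene_id}:
                d = abs(cl.key[0] - s.column)
                if 0 < d <= tolerance:
                    cand = (d, cl.key[0], 0, cl)
                    if best is None or cand[:2] < best[:2]:
                        best = cand
        for j, t in enumerate(singles):
            if j == i or j in merged:
                continue
            if t.site.phase == s.site.phase and t.site.gene_id != s.site.gene_id:
                d = abs(t.column - s.column)
                if 0 < d <= tolerance:
                    cand = (d, min(s.column, t.column), 1, (j, t))
                    if best is None or cand[:2] < best[:2]:
                        best = cand
        if best is None:
            classes.append(ConservationClass(s.key, [s], "unique"))
        elif best[2] == 0:
            best[3].near_members.append(s)
            merged.add(i)
        else:
            j, t = best[3]
            classes.append(ConservationClass(
                (min(s.column, t.column), s.site.phase), [s, t],
                "near-conserved"))
            merged.add(i)
            merged.add(j)

    classes.sort(key=lambda c: c.key)
    mat = pd.DataFrame(0, index=genes, columns=genes, dtype=int)
    for cl in classes:
        if cl.status != "conserved":
            continue
        gs = sorted({m.site.gene_id for m in cl.members})
        for x in gs:
            for y in gs:
                if x != y:
                    mat.loc[x, y] += 1
    return ConservationReport(classes=classes, pairwise_conserved=mat)


def gc_content(seq: str) -> float:
    """GC percentage over unambiguous bases, one decimal (report scale)."""
    return round(100.0 * gc_fraction(seq), 1)


# ---------------------------------------------------------------------------
# structure diagrams


def diagram_tracks(models: Sequence[GeneModel]) -> pd.DataFrame:
    """Proportional exon/intron track table, one row per feature."""
    rows = []
    for m in models:
        pos = 0
        intron_lens = [e - s for s, e in m.introns_genomic()]
        for i, (s, e) in enumerate(m.exons):
            rows.append(dict(gene=m.gene_id, feature="exon", index=i + 1,
                             bp=e - s, x0=pos, x1=pos + (e - s)))
            pos += e - s
            if i < len(intron_lens):
                rows.append(dict(gene=m.gene_id, feature="intron", index=i + 1,
                                 bp=intron_lens[i], x0=pos,
                                 x1=pos + intron_lens[i]))
                pos += intron_lens[i]
    return pd.DataFrame(rows)


def structure_diagram(models: Sequence[GeneModel],
                      report: Optional[ConservationReport] = None,
                      width: float = 720.0) -> tuple[pd.DataFrame, str]:
    """Deterministic SVG of exon/intron tracks with connectors between
    members of conserved / near-conserved splice-site classes."""
    tracks = diagram_tracks(models)
    span = max(tracks.x1.max(), 1)
    scale = (width - 120) / span
    row_h, pad = 46, 60
    order = {m.gene_id: i for i, m in enumerate(models)}
    intron_x: dict[tuple[str, int], float] = {}
    for r in tracks.itertuples():
        if r.feature == "intron":
            intron_x[(r.gene, r.index)] = pad + scale * (r.x0 + r.x1) / 2

    parts = [f'<svg xmlns="http://www.w3.org/2000/svg" width="{width:.0f}" '
             f'height="{len(models) * row_h + 40}">']
    if report is not None:
        for cl in report.classes:
            if cl.status == "unique":
                continue
            pts = sorted(
                (order[s.site.gene_id],
                 intron_x.get((s.site.gene_id, s.site.intron_index)))
                for s in cl.all_sites()
                if (s.site.gene_id, s.site.intron_index) in intron_x)
            dash = "" if cl.status == "conserved" else ' stroke-dasharray="4 3"'
            for (r1, x1), (r2, x2) in zip(pts, pts[1:]):
                parts.append(
                    f'<line x1="{x1:.1f}" y1="{20 + r1 * row_h + 8}" '
                    f'x2="{x2:.1f}" y2="{20 + r2 * row_h - 8}" '
                    f'stroke="#777" stroke-width="1"{dash}/>')
    for m in models:
        y = 20 + order[m.gene_id] * row_h
        parts.append(f'<text x="4" y="{y + 5}" font-size="11">{m.gene_id}</text>')
        sub = tracks[tracks.gene == m.gene_id]
        for r in sub.itertuples():
            x0, x1 = pad + scale * r.x0, pad + scale * r.x1
            if r.feature == "exon":
                parts.append(f'<rect x="{x0:.1f}" y="{y - 8}" '
                             f'width="{x1 - x0:.1f}" height="16" '
                             f'fill="#2b6cb0" stroke="black" stroke-width="0.5"/>')
            else:
                parts.append(f'<line x1="{x0:.1f}" y1="{y}" x2="{x1:.1f}" '
                             f'y2="{y}" stroke="black" stroke-width="1"/>')
    if report is not None:
        by_gene: dict[tuple[str, int], AlignedSpliceSite] = {}
        for cl in report.classes:
            for s in cl.all_sites():
                by_gene[(s.site.gene_id, s.site.intron_index)] = s
        for (gene, idx), s in sorted(by_gene.items()):
            if (gene, idx) in intron_x:
                y = 20 + order[gene] * row_h
                parts.append(f'<text x="{intron_x[(gene, idx)]:.1f}" '
                             f'y="{y - 12}" font-size="8" '
                             f'text-anchor="middle">{s.label}</text>')
    parts.append("</svg>")
    return tracks, "\n".join(parts)
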