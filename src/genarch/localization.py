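"""Composition-based targeting and membrane-anchor heuristics.

These are explicit, documented surrogates for the black-box targeting and
transmembrane predictors commonly used in organelle proteomics: a
chloroplast transit-peptide propensity computed from N-terminal residue
composition (transit peptides are serine/threonine-rich and carry net
positive charge), and a Kyte-Doolittle sliding-window scan for
transmembrane helices, with a C-terminal-anchor classification on top.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

# Kyte & Doolittle hydropathy scale
KD = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2,
}

#: score cutoffs per species profile; the relaxed chlorophyte profile
#: reflects that Chlamydomonas-style transit peptides are weaker than the
#: land-plant consensus.
PROFILES = {"default": 0.45, "chlorophyte": 0.30}

CTERM_ANCHOR_WINDOW = 40   # residues from the C-terminus counting as "terminal"


@dataclass(frozen=True)
class TargetingScore:
    window_len: int
    frac_ST: float
    frac_RK: float
    frac_DE: float
    score: float
    call: str                       # 'plastid-candidate' | 'none'
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class TMHelix:
    start: int                      # 1-based inclusive residue indices
    end: int
    mean_hydropathy: float          # peak sliding-window mean within the span
    is_cterminal: bool


def transit_peptide_score(protein: str, window_len: int = 60,
                          cutoff: Optional[float] = None,
                          species_profile: str = "default") -> TargetingScore:
    """Transit-peptide propensity of the N-terminal window.

    score = frac(S+T) + frac(R+K) - frac(D+E); the call is purely
    score-vs-cutoff, where the cutoff comes from the species profile unless
    given explicitly. Deterministic and permutation-invariant within the
    window (pure composition).
    """
    if not protein:
        raise ValueError("empty protein sequence")
    if cutoff is None:
        cutoff = PROFILES[species_profile]
    flags: tuple[str, ...] = ()
    if len(protein) < window_len:
        window = protein
        flags = ("short-window",)
    else:
        window = protein[:window_len]
    n = len(window)
    frac_st = sum(window.count(a) for a in "ST") / n
    frac_rk = sum(window.count(a) for a in "RK") / n
    frac_de = sum(window.count(a) for a in "DE") / n
    score = frac_st + frac_rk - frac_de
    call = "plastid-candidate" if score >= cutoff else "none"
    return TargetingScore(window_len=n, frac_ST=frac_st, frac_RK=frac_rk,
                          frac_DE=frac_de, score=score, call=call, flags=flags)


def tm_scan(protein: str, window: int = 19, threshold: float = 1.6,
            min_helix_len: int = 18) -> list[TMHelix]:
    """Sliding-window Kyte-Doolittle transmembrane-helix scan.

    Windows whose mean hydropathy reaches `threshold` are merged into
    maximal runs; merged spans shorter than `min_helix_len` are discarded.
    Non-standard residues score 0 (with a warning).
    """
    if len(protein) < window:
        return []
    unknown = set(protein) - set(KD)
    if unknown:
        warnings.warn(f"non-standard residues scored 0: {sorted(unknown)}")
    vals = [KD.get(a, 0.0) for a in protein]
    prefix = [0.0]
    for v in vals:
        prefix.append(prefix[-1] + v)
    above = [i for i in range(len(protein) - window + 1)
             if (prefix[i + window] - prefix[i]) / window >= threshold]
    helices: list[TMHelix] = []
    run_start = None
    prev = None
    for i in above + [None]:
        if run_start is not None and (i is None or i != prev + 1):
            lo, hi = run_start, prev + window     # 0-based half-open span
            if hi - lo >= min_helix_len:
                # the merged span's flanks may dip below threshold; report
                # the peak window mean, which by construction is >= it
                mh = max((prefix[s + window] - prefix[s]) / window
                         for s in range(lo, hi - window + 1))
                helices.append(TMHelix(
                    start=lo + 1, end=hi, mean_hydropathy=mh,
                    is_cterminal=hi > len(protein) - CTERM_ANCHOR_WINDOW))
            run_start = None
        if i is not None and run_start is None:
            run_start = i
        prev = i
    return helices


def classify_membrane_form(protein_or_model, **scan_kw) -> str:
    """'membrane-anchored' iff a helix ends within the C-terminal window
    (the thylakoid-APx-style tail anchor situation), else 'soluble'."""
    protein = getattr(protein_or_model, "protein", protein_or_model)
    return ("membrane-anchored"
            if any(h.is_cterminal for h in tm_scan(protein, **scan_kw))
            else "soluble")


def bipartite_signal_flag(protein: str, transit_len: int = 80,
                          threshold: float = 1.6) -> bool:
    """Descriptive flag: a hydrophobic stretch inside the N-terminal
    transit region (bipartite, thylakoid-lumen-style signals)."""
    region = protein[:transit_len]
    return bool(tm_scan(region, window=11, threshold=threshold,
                        min_helix_len=8))
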