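"""End-to-end orchestration: simulate -> ESTs -> clusters -> gene models
-> localization -> splice-site comparison -> phylogeny -> report.

Configuration is a strict YAML document (unknown keys are rejected before
any stage runs); every parameter actually used is echoed into the run log
and the machine-readable summary, so runs are self-describing. All
randomness flows from the seeds in the config.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Any, Optional

import pandas as pd
import yaml

from . import est as est_mod
from . import localization as loc
from . import models as models_mod
from . import phylo
from . import structure
from .align import progressive_align
from .simulate import (ESTSimParams, EvolParams, SignalFlags, simulate_ests,
                       simulate_family, implant_signals, write_gff3)
from .seqs import write_fasta

log = logging.getLogger("genarch.pipeline")


@dataclass
class StageToggles:
    est_pipeline: bool = True
    gene_models: bool = True
    localization: bool = True
    structure: bool = True
    phylogeny: bool = True


@dataclass
class PipelineConfig:
    out_dir: str = "genarch_run"
    seed: int = 0
    family_name: str = "synthetic-family"
    tree: str = "((g1:0.2,g2:0.2):0.1,(g3:0.2,g4:0.2):0.1);"
    species_profile: str = "default"
    evol: dict = field(default_factory=dict)
    ests: dict = field(default_factory=dict)
    cluster: dict = field(default_factory=dict)
    signals: dict = field(default_factory=dict)   # gene -> flag names
    bootstrap_reps: int = 500
    distance_model: str = "poisson"
    stages: StageToggles = field(default_factory=StageToggles)

    def __post_init__(self):
        if isinstance(self.stages, dict):
            bad = set(self.stages) - {f.name for f in fields(StageToggles)}
            if bad:
                raise ValueError(f"unknown stage toggles: {sorted(bad)}")
            self.stages = StageToggles(**self.stages)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        stages = raw.pop("stages", {})
        if isinstance(stages, dict):
            bad = set(stages) - {f.name for f in fields(StageToggles)}
            if bad:
                raise ValueError(f"unknown stage toggles: {sorted(bad)}")
            stages = StageToggles(**stages)
        for section, params_cls in (("evol", EvolParams),
                                    ("ests", ESTSimParams),
                                    ("cluster", est_mod.ClusterParams)):
            extra = set(raw.get(section, {})) - {
                f.name for f in fields(params_cls)} - {"tree"}
            if extra:
                raise ValueError(f"unknown {section} keys: {sorted(extra)}")
        return cls(stages=stages, **raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


def _tuplify(d: dict) -> dict:
    return {k: tuple(v) if isinstance(v, list) else v for k, v in d.items()}


def run_pipeline(config: PipelineConfig) -> Path:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    log.setLevel(logging.INFO)
    fh = logging.FileHandler(out / "run.log", mode="w")
    fh.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    log.addHandler(fh)
    summary: dict[str, Any] = {"config": config.to_dict()}
    try:
        return _run(config, out, summary)
    finally:
        (out / "summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True, default=str) + "\n")
        log.removeHandler(fh)
        fh.close()


def _run(config: PipelineConfig, out: Path, summary: dict) -> Path:
    # stage 1: simulate
    ep = EvolParams(tree=config.tree, seed=config.seed,
                    **_tuplify(config.evol))
    log.info("simulate_family params: %s", ep)
    truth = simulate_family(ep)
    if config.signals:
        flags = {g: SignalFlags(**{name: True for name in names})
                 for g, names in config.signals.items()}
        truth = implant_signals(truth, flags)
    truth.write(out / "truth")
    summary["genes"] = sorted(truth.genes)

    ests_params = ESTSimParams(seed=config.seed + 1, **_tuplify(config.ests))
    log.info("simulate_ests params: %s", ests_params)
    ests, est_table = simulate_ests(truth, ests_params)
    write_fasta(((r.est_id, r.seq) for r in ests), out / "ests.fasta")
    est_table.to_csv(out / "est_truth.tsv", sep="\t", index=False)
    summary["n_ests"] = len(ests)

    # stage 2: EST pipeline
    cp = est_mod.ClusterParams(**_tuplify(config.cluster))
    final_models: dict[str, models_mod.GeneModel] = dict(truth.genes)
    consensi: dict[str, str] = {}
    if config.stages.est_pipeline:
        clusters = est_mod.cluster_ests(ests, cp)
        refined, leftover = est_mod.refine_clusters(clusters, cp)
        rows = [dict(est_id=m, cluster_id=c.cluster_id, orientation=o)
                for c in refined for m, o in c.members]
        pd.DataFrame(rows).to_csv(out / "clusters.tsv", sep="\t", index=False)
        write_fasta(((c.cluster_id, c.consensus) for c in refined),
                    out / "consensus.fasta")
        consensi = {c.cluster_id: c.consensus for c in refined}
        summary["n_clusters"] = len(refined)
        summary["n_unplaced_ests"] = len(leftover)

    # stage 3: gene models from consensus cDNAs
    if config.stages.gene_models and consensi:
        built: dict[str, models_mod.GeneModel] = {}
        for cid, cons in sorted(consensi.items()):
            if len(cons) < 60:
                continue
            best = None
            for scaf_id, scaf in sorted(truth.scaffolds.items()):
                try:
                    aln = models_mod.spliced_align(cons, scaf)
                except models_mod.NoConfidentModel:
                    continue
                if best is None or aln.identity > best[0].identity:
                    best = (aln, scaf_id)
            if best is None:
                log.warning("no confident model for %s", cid)
                continue
            aln, scaf_id = best
            try:
                model = models_mod.model_from_alignment(aln, cid, scaf_id)
            except ValueError:
                continue
            built[cid] = model
        write_gff3(built.values(), out / "predicted.gff3")
        summary["n_models"] = len(built)

    # stages 4-6 operate on the (truth-anchored) final gene models
    proteins = {g: m.protein for g, m in sorted(final_models.items())}

    scores = {}
    membrane = {}
    if config.stages.localization:
        for g, p in proteins.items():
            scores[g] = loc.transit_peptide_score(
                p, species_profile=config.species_profile)
            membrane[g] = loc.classify_membrane_form(p)
        pd.DataFrame([dict(gene_id=g, score=round(s.score, 4), call=s.call,
                           frac_ST=round(s.frac_ST, 4),
                           frac_RK=round(s.frac_RK, 4),
                           frac_DE=round(s.frac_DE, 4),
                           membrane_form=membrane[g])
                      for g, s in scores.items()]
                     ).to_csv(out / "localization.tsv", sep="\t", index=False)

    msa = None
    report = None
    if config.stages.structure:
        msa = progressive_align(proteins)
        write_fasta(sorted(msa.items()), out / "family_msa.fasta")
        all_sites = []
        for g, m in sorted(final_models.items()):
            sites, _ = structure.splice_sites_from_model(m)
            all_sites.extend(sites)
        aligned = structure.project_to_alignment(all_sites, msa)
        report = structure.compare_splice_sites(aligned)
        pd.DataFrame([dict(column=c.key[0], phase=c.key[1], status=c.status,
                           genes=",".join(sorted(c.genes())),
                           labels=",".join(s.label for s in c.all_sites()))
                      for c in report.classes]
                     ).to_csv(out / "splice_conservation.tsv", sep="\t",
                              index=False)
        report.pairwise_conserved.to_csv(out / "pairwise_conserved.tsv",
                                         sep="\t")
        tracks, svg = structure.structure_diagram(
            [final_models[g] for g in sorted(final_models)], report)
        tracks.to_csv(out / "diagram_tracks.tsv", sep="\t", index=False)
        (out / "structure.svg").write_text(svg)
        gc = {g: structure.gc_content(truth.cdnas[g])
              for g in sorted(truth.cdnas)}
        pd.DataFrame([dict(gene_id=g, gc_percent=v) for g, v in gc.items()]
                     ).to_csv(out / "gc_content.tsv", sep="\t", index=False)
        summary["conserved_classes"] = report.n_conserved()
        summary["near_conserved_classes"] = report.n_near_conserved()

    if config.stages.phylogeny:
        if msa is None:
            msa = progressive_align(proteins)
        dm = phylo.distance_matrix(msa, model=config.distance_model)
        (out / "distances.phylip").write_text(dm.to_phylip())
        tree, dropped = phylo.bootstrap_support(
            msa, n_reps=config.bootstrap_reps,
            distance=config.distance_model, seed=config.seed + 2)
        (out / "nj_bootstrap.nwk").write_text(tree.newick() + "\n")
        me = phylo.minimum_evolution(tree, dm)
        (out / "me.nwk").write_text(me.newick(with_support=False) + "\n")
        summary["parsimony_score"] = phylo.parsimony_score(msa, tree)
        summary["bootstrap_dropped"] = dropped
        summary["nj_newick"] = tree.newick()

    counts = None
    if config.stages.est_pipeline:
        counts = est_mod.count_ests(truth.cdnas, ests, cp)
        counts.to_csv(out / "est_counts.tsv", sep="\t", index=False)

    inventory = emit_inventory(final_models, scores, counts,
                               family=config.family_name)
    inventory.to_csv(out / "inventory.tsv", sep="\t", index=False)
    summary["inventory_rows"] = len(inventory)
    summary["content_hashes"] = {
        p.name: hashlib.sha256(p.read_bytes()).hexdigest()[:16]
        for p in sorted(out.glob("*.tsv")) + sorted(out.glob("*.nwk"))}
    return out


def emit_inventory(models: dict, scores: dict, counts: Optional[pd.DataFrame],
                   family: str = "family") -> pd.DataFrame:
    """Table-style gene inventory: one row per final gene model."""
    count_map = {}
    if counts is not None:
        count_map = {r.gene_id: int(r.est_count)
                     for r in counts.itertuples() if r.gene_id != "unassigned"}
    rows = []
    for g in sorted(models):
        m = models[g]
        sc = scores.get(g)
        n = count_map.get(g)
        rows.append(dict(
            family=family, gene=g, length_aa=len(m.protein),
            targeting_score=round(sc.score, 3) if sc else None,
            targeting_call=sc.call if sc else None,
            membrane_form=loc.classify_membrane_form(m.protein),
            est_count=n if n is not None else 0,
            expression=("putatively non-expressed" if not n else "expressed"),
            location=m.location_string()))
    return pd.DataFrame(rows)
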