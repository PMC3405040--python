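"""End-to-end orchestration: data -> motif -> trees -> synteny -> epochs.

A single config (YAML on disk, dict in memory) drives the run; every
stage writes its outputs under the run directory and contributes to one
``summary.json``.  The defaults are the study conditions: a 5 Mb
neighbor window, at least 3 supporting anchors, and 1000 bootstrap
replicates (reducible from the config/CLI).  A stage failure leaves a
``FAILED`` marker and aborts the stages downstream of it.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict
from pathlib import Path

from . import motif as motif_mod
from . import phylo, synteny, wgd
from .formats import read_alignment, read_fasta, read_gene_table, write_newick
from .simulate import SimulationConfig, simulate_dataset

logger = logging.getLogger(__name__)

DEFAULTS = {
    "window_bp": 5_000_000,
    "min_anchors": 3,
    "bootstrap_replicates": 1000,
    "min_support": 50,
    "correction": "kimura",
    "seed": 0,
    "anchor_family": "PALM",
}


class PipelineError(RuntimeError):
    pass


def _stage(summary: dict, out: Path, name: str):
    def deco(fn):
        def run(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                result = fn(*args, **kwargs)
            except Exception as exc:
                (out / "FAILED").write_text(f"{name}: {exc}\n")
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            dt = time.perf_counter() - t0
            logger.info("stage=%s status=ok duration_s=%.2f", name, dt)
            summary["stages"][name] = {"duration_s": round(dt, 3)}
            return result

        return run

    return deco


def run_pipeline(config: dict, out_dir: str | Path) -> dict:
    """Run every stage on simulated or user-supplied inputs.

    *config* keys: either a ``simulate`` block (SimulationConfig field
    overrides) or explicit paths (``gene_tables``: list of TSVs,
    ``alignments``: {family: fasta}, ``gene_trees``: {family: newick
    path}, ``species_tree``: newick path); plus the knobs in
    :data:`DEFAULTS`, a ``pattern`` (PHI text) and optional
    ``reference_species``.
    """
    cfg = {**DEFAULTS, **config}
    for key, value in config.items():
        if key in DEFAULTS and DEFAULTS[key] != value:
            logger.info("config override: %s=%r (default %r)", key, value, DEFAULTS[key])
    out = Path(out_dir)
    if "simulate" not in cfg:
        for key in ("gene_tables", "species_tree"):
            if key not in cfg:
                raise PipelineError(
                    f"config lacks both a 'simulate' block and {key!r}"
                )
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "config": {k: v for k, v in cfg.items()},
        "seed": cfg["seed"],
        "stages": {},
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }

    # -- stage: data ---------------------------------------------------
    @_stage(summary, out, "data")
    def stage_data():
        if "simulate" in cfg:
            sim_cfg = SimulationConfig(
                seed=cfg["seed"], **{k: v for k, v in cfg["simulate"].items() if k != "seed"}
            )
            data_dir = out / "data"
            truth, seqs = simulate_dataset(sim_cfg, data_dir, force=True)
            tables = {sp: loci for sp, loci in truth.gene_tables.items()}
            alignments = {
                fam: d["alignment"] for fam, d in seqs.items() if d["alignment"]
            }
            gene_trees = truth.gene_trees
            species_tree = wgd.read_species_tree(
                truth.species_tree_newick, is_string=True
            )
            families = list(sim_cfg.family_names)
            anchor = sim_cfg.anchor_family
            return tables, alignments, gene_trees, species_tree, families, anchor
        tables = {}
        for path in cfg["gene_tables"]:
            for locus in read_gene_table(path):
                tables.setdefault(locus.species, []).append(locus)
        alignments = {
            fam: read_alignment(p) for fam, p in cfg.get("alignments", {}).items()
        }
        gene_trees = {
            fam: Path(p).read_text().strip()
            for fam, p in cfg.get("gene_trees", {}).items()
        }
        species_tree = wgd.read_species_tree(cfg["species_tree"])
        families = sorted({g.family for loci in tables.values() for g in loci})
        return (
            tables,
            alignments,
            gene_trees,
            species_tree,
            families,
            cfg["anchor_family"],
        )

    tables, alignments, gene_trees, species_tree, families, anchor = stage_data()

    # -- stage: motif --------------------------------------------------
    @_stage(summary, out, "motif")
    def stage_motif():
        pattern_text = cfg.get("pattern")
        if pattern_text is None and "simulate" in cfg:
            spec = cfg.get("simulate", {}).get("motif_spec")
            pattern_text = spec[0][1] if spec else None
        if pattern_text is None:
            from .simulate import DEFAULT_MOTIF

            pattern_text = DEFAULT_MOTIF if "simulate" in cfg else None
        if pattern_text is None:
            return {"skipped": "no pattern configured"}
        pattern = motif_mod.parse_phi_pattern(pattern_text)
        hits = []
        for fam, aln in sorted(alignments.items()):
            for row in aln.rows:
                seq_hits = motif_mod.scan_sequence(
                    pattern, (row.id, row.ungapped())
                )
                hits.extend(
                    {"family": fam, **h._asdict()}
                    if hasattr(h, "_asdict")
                    else {"family": fam, **asdict(h)}
                    for h in seq_hits
                )
        report = {
            "pattern": pattern_text,
            "summary": motif_mod.pattern_summary(pattern),
            "n_hits": len(hits),
            "n_exact": sum(h["exact"] for h in hits),
            "hits": hits,
        }
        (out / "motif_hits.json").write_text(json.dumps(report, indent=1))
        return report

    motif_report = stage_motif()

    # -- stage: phylo --------------------------------------------------
    @_stage(summary, out, "phylo")
    def stage_phylo():
        report = {}
        focal = anchor if anchor in alignments else None
        targets = [focal] if focal else sorted(alignments)[:1]
        for fam in targets:
            result = phylo.bootstrap_nj(
                alignments[fam],
                n_replicates=int(cfg["bootstrap_replicates"]),
                seed=int(cfg["seed"]),
                correction=cfg["correction"],
            )
            nwk = write_newick(result.main_tree, out / f"nj_{fam}.nwk")
            supports = sorted(result.support.values())
            report[fam] = {
                "newick_file": f"nj_{fam}.nwk",
                "n_replicates": result.n_replicates,
                "n_bipartitions": len(result.support),
                "min_support": supports[0] if supports else None,
                "max_support": supports[-1] if supports else None,
                "newick": nwk.strip(),
            }
        return report

    phylo_report = stage_phylo()

    # -- stage: synteny ------------------------------------------------
    @_stage(summary, out, "synteny")
    def stage_synteny():
        ref = cfg.get("reference_species")
        if ref is None:
            # default to the genome with the most surviving anchor genes
            ref = min(
                sorted(tables),
                key=lambda sp: -sum(g.family == anchor for g in tables[sp]),
            )
        calls = synteny.neighbor_families(
            tables[ref],
            anchor_family=anchor,
            window_bp=int(cfg["window_bp"]),
            min_anchors=int(cfg["min_anchors"]),
        )
        selected = [c.family for c in calls if c.selected]
        blocks = synteny.build_blocks(
            [loc for loci in tables.values() for loc in loci],
            anchor_family=anchor,
            neighbor_family_names=selected,
            max_gap_bp=int(cfg["window_bp"]),
        )
        block_membership = {}
        for i, b in enumerate(blocks):
            bid = f"{b.species}:{b.chromosome}:{i}"
            for gid in b.gene_ids():
                block_membership[gid] = bid
        report = {
            "reference_species": ref,
            "calls": [
                {
                    "family": c.family,
                    "selected": c.selected,
                    "n_anchors": len(c.supporting_anchors),
                }
                for c in calls
            ],
            "selected_families": selected,
            "n_blocks": len(blocks),
        }
        (out / "synteny.json").write_text(json.dumps(report, indent=1))
        return report, blocks, block_membership, selected

    synteny_report, blocks, block_membership, selected = stage_synteny()

    # -- stage: wgd ----------------------------------------------------
    @_stage(summary, out, "wgd")
    def stage_wgd():
        calls_by_family = {}
        for fam, nwk in sorted(gene_trees.items()):
            from .formats import read_newick

            tree = read_newick(nwk, is_string=True, rooted=True)
            calls_by_family[fam] = wgd.classify_duplications(
                tree,
                species_tree,
                min_support=float(cfg["min_support"]),
            )
        report = {
            fam: {
                "n_duplications": sum(c.is_duplication for c in calls),
                "epochs": sorted(
                    {c.epoch for c in calls if c.is_duplication and c.epoch}
                ),
            }
            for fam, calls in calls_by_family.items()
        }
        (out / "duplication_calls.json").write_text(
            json.dumps(
                {f: wgd.calls_to_json(c) for f, c in calls_by_family.items()},
                indent=1,
            )
        )
        return report, calls_by_family

    wgd_report, calls_by_family = stage_wgd()

    # -- stage: concordance --------------------------------------------
    @_stage(summary, out, "concordance")
    def stage_concordance():
        if anchor not in calls_by_family or not selected:
            return {"skipped": "no anchor calls or no selected neighbor families"}
        relevant = {
            f: calls_by_family[f]
            for f in [anchor] + [f for f in selected if f in calls_by_family]
        }
        focal_epochs = sorted(
            {
                c.epoch
                for c in calls_by_family[anchor]
                if c.is_duplication
                and c.epoch not in (wgd.LINEAGE_SPECIFIC, wgd.PRE_ROOT, None)
            }
        )
        if not focal_epochs:
            return {"skipped": "anchor family has no WGD-epoch duplication call"}
        per_epoch = {}
        for epoch in focal_epochs:
            report = wgd.paralogon_concordance(
                relevant, block_membership, focal_family=anchor, epoch=epoch
            )
            per_epoch[epoch] = {
                "concordance": report.concordance,
                "agreement": report.agreement,
            }
        return per_epoch

    concordance_report = stage_concordance()

    summary.update(
        {
            "motif": {
                k: v for k, v in motif_report.items() if k != "hits"
            },
            "phylo": phylo_report,
            "synteny": synteny_report,
            "wgd": wgd_report,
            "concordance": concordance_report,
        }
    )
    (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    return summary
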