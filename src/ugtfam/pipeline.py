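"""End-to-end orchestration: simulate → mine → tree → introns → expression
→ qPCR, with a reproducibility manifest.

Stages communicate only through the documented FASTA/GFF3/Newick/TSV files
written into the output directory, so any stage can be re-run or replaced
by external tooling. The manifest records the configuration snapshot, the
seed, SHA-256 digests of every file written, and per-stage record counts;
re-running with the same config and seed reproduces byte-identical
tabular outputs.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any

from . import __version__
from . import expressionx, intronics, mining, phylo, simkit
from .formats import (read_gene_models, write_ct_table, write_expression_tsv,
                      write_newick)

DEFAULT_CONFIG: dict[str, Any] = {
    "simulate": {
        "n_leaves": 16,
        "subst_rate": 0.5,
        "indel_rate": 0.01,
        "n_intron_classes": 4,
        "p_loss": 0.3,
        "jitter": 5,
        "decoy_frac": 0.30,
        "n_groups": 4,
    },
    "mine": {"length_min": 375, "length_max": 530, "max_introns": 2},
    "tree": {"model": "p_distance", "n_reps": 100,
             "support_threshold": 85.0, "max_gap_frac": 0.20},
    "introns": {"window_aa": 45, "model": "dollo",
                "min_groups": 2, "min_members": 10},
    "express": {"n_ests": 2000, "error_rate": 0.01, "k": 11,
                "min_identity": 0.95, "min_match_len": 100},
    "qpcr": {"reference_gene": "ETIF5A", "n_bio": 3, "n_tech": 2,
             "sd_ct": 0.1},
}

_REQUIRED_SECTIONS = tuple(DEFAULT_CONFIG)


def _merge(default: dict, user: dict) -> dict:
    out = {}
    for key, val in default.items():
        if isinstance(val, dict):
            out[key] = _merge(val, user.get(key, {}))
        else:
            out[key] = user.get(key, val)
    unknown = set(user) - set(default)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return out


def validate_config(config: dict | None) -> dict:
    """Merge a user config over the defaults; unknown keys are an error."""
    config = config or {}
    unknown = set(config) - set(_REQUIRED_SECTIONS)
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")
    return {sec: _merge(DEFAULT_CONFIG[sec], config.get(sec, {}))
            for sec in _REQUIRED_SECTIONS}


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(config: dict | None, outdir: str | Path, seed: int = 0) -> dict:
    """Run the whole pipeline on a simulated family; returns the manifest.

    The manifest (also written to ``manifest.json``) carries the config
    snapshot, seed, file digests and per-stage counts.
    """
    cfg = validate_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "version": __version__, "seed": seed, "config": cfg,
        "stages": {}, "files": {},
    }

    # -- simulate -----------------------------------------------------------
    sim = simkit.simulate_family(seed=seed, **cfg["simulate"])
    paths = sim.write(outdir)
    manifest["stages"]["simulate"] = {
        "genes": len(sim.proteins), "decoys": len(sim.truth.decoys)}

    # -- mine ---------------------------------------------------------------
    models = {m.gene_id: m for m in read_gene_models(paths["gff3"],
                                                     paths["genome"])}
    proteins = {g: m.protein for g, m in models.items()}
    hits = mining.scan_motif(proteins, simkit.PSPG_CONSENSUS)
    mc = cfg["mine"]
    candidates = mining.filter_candidates(
        hits, models, length_range=(mc["length_min"], mc["length_max"]),
        max_introns=mc["max_introns"])
    accepted = sorted(candidates.accepted)
    acc_path = outdir / "accepted.tsv"
    with open(acc_path, "w") as fh:
        fh.write("gene\tstatus\treason\n")
        for g in accepted:
            fh.write(f"{g}\taccepted\t.\n")
        for g, why in sorted(candidates.rejected.items()):
            fh.write(f"{g}\trejected\t{why}\n")
    manifest["stages"]["mine"] = {
        "scanned": len(proteins), "accepted": len(accepted),
        "rejected": len(candidates.rejected)}

    # -- tree ---------------------------------------------------------------
    tc = cfg["tree"]
    alignment = sim.truth.true_alignment.subset(
        [g for g in accepted if g in sim.truth.true_alignment.rows])
    trimmed = alignment.drop_gappy_columns(tc["max_gap_frac"])
    tree = phylo.bootstrap(trimmed, n_reps=tc["n_reps"], seed=seed,
                           model=tc["model"])
    write_newick(tree, outdir / "family_tree.nwk")
    refs = {}
    for grp in sorted(set(sim.truth.group_map.values())):
        leaf = min(g for g, gg in sim.truth.group_map.items()
                   if gg == grp and g in alignment.rows)
        refs[leaf] = grp
    groups = phylo.assign_groups(tree, refs,
                                 support_threshold=tc["support_threshold"])
    with open(outdir / "groups.tsv", "w") as fh:
        fh.write("gene\tgroup\n")
        for g in sorted(groups):
            fh.write(f"{g}\t{groups[g]}\n")
    manifest["stages"]["tree"] = {
        "leaves": len(alignment.ids), "columns": trimmed.n_cols,
        "parsimony_score": phylo.parsimony_score(tree, trimmed)}

    # -- introns ------------------------------------------------------------
    ic = cfg["introns"]
    records = []
    for g in accepted:
        records.extend(intronics.extract_introns(models[g]))
    for r in records:
        r.column = intronics.project_to_alignment(r, alignment)
    classes = intronics.cluster_intron_classes(
        records, window_aa=ic["window_aa"], group_map=groups,
        min_groups=ic["min_groups"], min_members=ic["min_members"])
    presence = intronics.presence_matrix(classes, accepted)
    rooted = sim.truth.tree
    events = intronics.infer_events(rooted, presence, model=ic["model"])
    census = intronics.intron_census(records, accepted)
    with open(outdir / "introns.tsv", "w") as fh:
        fh.write("gene\tindex\tcds_offset\tphase\tprotein_pos\tcolumn\n")
        for r in sorted(records, key=lambda r: (r.gene_id, r.intron_index)):
            fh.write(f"{r.gene_id}\t{r.intron_index}\t{r.cds_offset}\t"
                     f"{r.phase}\t{r.protein_pos}\t{r.column}\n")
    with open(outdir / "intron_events.tsv", "w") as fh:
        fh.write("class\tgain_branch\tloss_branches\tconserved\tancestral\n")
        for c in classes:
            fh.write(f"{c.class_id}\t{events.gain_branch.get(c.class_id)}\t"
                     f"{','.join(sorted(events.loss_branches.get(c.class_id, set()))) or '.'}\t"
                     f"{c.conserved}\t{c.class_id in events.ancestral_classes}\n")
    manifest["stages"]["introns"] = {
        "introns": len(records), "classes": len(classes),
        "total_events": events.total_events,
        "census": {"mean_per_gene": census.mean_per_gene,
                   "total": census.total_introns}}

    # -- expression ---------------------------------------------------------
    ec = cfg["express"]
    est_sim = simkit.simulate_ests(sim, n_ests=ec["n_ests"],
                                   error_rate=ec["error_rate"], seed=seed)
    est_sim.write(outdir / "ests.fasta")
    family_cds = {g: sim.cds[g] for g in sim.family_genes}
    mapping = expressionx.map_ests(est_sim.records, family_cds, k=ec["k"],
                                   min_identity=ec["min_identity"],
                                   min_match_len=ec["min_match_len"])
    write_expression_tsv(mapping.counts, outdir / "est_counts.tsv",
                         header_lines=[
                             f"k={ec['k']} min_identity={ec['min_identity']} "
                             f"min_match_len={ec['min_match_len']} seed={seed}"])
    summary = expressionx.expression_summary(mapping.counts, groups)
    with open(outdir / "expression_summary.tsv", "w") as fh:
        fh.write(f"# total_ests\t{summary.total_ests}\n")
        fh.write(f"# expressed_genes\t{summary.expressed_genes}\n")
        fh.write(f"# pct_expressed\t{summary.pct_expressed}\n")
        fh.write(f"# mean_per_expressed\t{summary.mean_per_expressed}\n")
        summary.per_tissue.to_csv(fh, sep="\t")
    clust = expressionx.cluster_expression(mapping.counts)
    with open(outdir / "heatmap_order.tsv", "w") as fh:
        fh.write("gene\n")
        fh.writelines(f"{g}\n" for g in clust.order)
    manifest["stages"]["express"] = {
        "ests": len(est_sim.records), "mapped": len(
            [v for v in mapping.assignments.values() if v]),
        "unmapped": mapping.unmapped, "ties": mapping.discarded_ties}

    # -- qpcr ---------------------------------------------------------------
    qc = cfg["qpcr"]
    ct = simkit.simulate_qpcr(sim, reference_gene=qc["reference_gene"],
                              n_bio=qc["n_bio"], n_tech=qc["n_tech"],
                              sd_ct=qc["sd_ct"], seed=seed)
    write_ct_table(ct, outdir / "ct_table.tsv")
    abundance = expressionx.delta_ct(ct, qc["reference_gene"])
    abundance.to_csv(outdir / "qpcr_abundance.tsv", sep="\t", index=False)
    manifest["stages"]["qpcr"] = {"measurements": len(ct),
                                  "cells": len(abundance)}

    # -- manifest -----------------------------------------------------------
    for f in sorted(outdir.iterdir()):
        if f.name != "manifest.json" and f.is_file():
            manifest["files"][f.name] = _digest(f)
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n")
    return manifest
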