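"""End-to-end orchestration: filter -> cluster -> modelgate -> profile -> classify.

Each stage writes its own TSV next to a machine-readable run summary
(JSON).  Stages whose inputs are absent are skipped and the skip is
logged; thresholds actually used are logged and recorded in the summary
for reproducibility.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import active_site, domain_filter, model_quality, motif_engine
from . import io_core, rough_cluster
from .errors import PaofamError

log = logging.getLogger("paofam")


@dataclass
class PipelineConfig:
    fasta: str | None = None
    domains: str | None = None
    msa: str | None = None
    quality: str | None = None
    out_dir: str = "paofam_out"
    # stage thresholds; defaults are the pipeline's published constants
    max_missing_per_side: int = 50
    max_internal_indel: int = 150
    min_flank: int = 5
    max_length: int = 700
    target_domain: str = "PF01593"
    cluster_threshold: float = 0.3
    qmean_abs_max: float = 4.5
    gmqe_min: float = 0.6
    ref_id: str = "O64411"
    seed: int = 0

    def filter_config(self) -> domain_filter.FilterConfig:
        return domain_filter.FilterConfig(
            max_missing_per_side=self.max_missing_per_side,
            max_internal_indel=self.max_internal_indel,
            min_flank=self.min_flank,
            max_length=self.max_length,
            target_domain=self.target_domain,
        )


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute every stage whose inputs are present; return the summary."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"thresholds": {
        "max_missing_per_side": cfg.max_missing_per_side,
        "max_internal_indel": cfg.max_internal_indel,
        "min_flank": cfg.min_flank,
        "max_length": cfg.max_length,
        "cluster_threshold": cfg.cluster_threshold,
        "qmean_abs_max": cfg.qmean_abs_max,
        "gmqe_min": cfg.gmqe_min,
    }, "stages": {}}
    log.info("thresholds: %s", summary["thresholds"])

    records = None
    if cfg.fasta and cfg.domains:
        records = io_core.read_fasta(cfg.fasta)
        hits = io_core.read_domain_table(cfg.domains)
        survivors, reports = domain_filter.filter_database(
            records, hits, cfg.filter_config())
        io_core.write_fasta(survivors, out / "survivors.fasta")
        pd.DataFrame(
            [{"seq_id": r.seq_id, "passed": r.passed,
              "failures": ";".join(r.failures),
              "missing_left": r.missing_left, "missing_right": r.missing_right,
              "indel_excess": r.indel_excess, "flank_left": r.flank_left,
              "flank_right": r.flank_right, "length": r.length}
             for r in reports]
        ).to_csv(out / "filter_report.tsv", sep="\t", index=False)
        summary["stages"]["filter"] = {
            "input": len(records), "surviving": len(survivors)}
        records = survivors
    else:
        log.info("filter stage skipped (fasta/domains not provided)")
        if cfg.fasta:
            records = io_core.read_fasta(cfg.fasta)

    assignment = None
    msa = None
    if cfg.msa:
        msa = io_core.read_msa(cfg.msa)
        dm = rough_cluster.p_distance(msa)
        tree = rough_cluster.upgma(dm)
        assignment = rough_cluster.cut_clusters(tree, cfg.cluster_threshold)
        (out / "tree.nwk").write_text(rough_cluster.write_newick(tree) + "\n")
        pd.DataFrame(
            sorted(assignment.mapping.items()),
            columns=["seq_id", "cluster_index"],
        ).to_csv(out / "clusters.tsv", sep="\t", index=False)
        summary["stages"]["cluster"] = {
            "n_sequences": dm.n, "n_clusters": assignment.n_clusters,
            "threshold": cfg.cluster_threshold}
    else:
        log.info("cluster stage skipped (msa not provided)")

    if cfg.quality and assignment is not None:
        quality = model_quality.read_quality_table(cfg.quality)
        by_seq: dict[str, list] = {}
        for q in quality:
            by_seq.setdefault(q.seq_id, []).append(q)
        rows = []
        n_pao = 0
        for idx, members in enumerate(assignment.clusters()):
            clade_records = [q for m in members for q in by_seq.get(m, [])]
            ok = model_quality.clade_is_pao(clade_records)
            n_pao += ok
            rows.append({
                "clade_id": idx, "is_pao": ok,
                "best_template":
                    model_quality.best_template_for_clade(clade_records) or "NONE",
                "n_acceptable": model_quality.n_acceptable(clade_records)})
        pd.DataFrame(rows).to_csv(out / "modelgate.tsv", sep="\t", index=False)
        summary["stages"]["modelgate"] = {
            "n_clades": len(rows), "n_pao_clades": n_pao}
    else:
        log.info("modelgate stage skipped (quality/clusters not available)")

    if msa is not None and assignment is not None and cfg.ref_id in msa.ids:
        spec = active_site.ActiveSitePositions(ref_id=cfg.ref_id)
        columns = active_site.map_reference_columns(msa, spec)
        rows = []
        for idx, members in enumerate(assignment.clusters()):
            members = [m for m in members if m != cfg.ref_id]
            if not members:
                continue
            prof = active_site.profile_clade(
                msa, columns, members, clade_id=str(idx), ref_id=cfg.ref_id)
            sandwich = active_site.has_aromatic_sandwich(prof, spec)
            mode = active_site.predict_reaction_mode(prof, spec)
            for pos, _ in spec.positions:
                top = sorted(prof.frequencies[pos].items(),
                             key=lambda t: -t[1])[:3]
                rows.append({
                    "clade_id": idx, "position": pos,
                    "summary": prof.summaries[pos],
                    "top_frequencies":
                        ";".join(f"{ch}:{f:.3f}" for ch, f in top),
                    "sandwich": sandwich, "predicted_mode": mode})
        pd.DataFrame(rows).to_csv(out / "profile.tsv", sep="\t", index=False)
        summary["stages"]["profile"] = {
            "n_clades": len({r['clade_id'] for r in rows})}
    else:
        log.info("profile stage skipped (msa/clusters/reference not available)")

    if records is not None:
        patterns = motif_engine.load_packaged_motifs()
        rows = []
        counts: dict[str, int] = {}
        for rec in records:
            call = motif_engine.classify(rec, patterns)
            counts[call.call.value] = counts.get(call.call.value, 0) + 1
            first = call.evidence[0] if call.evidence else None
            rows.append({
                "seq_id": rec.id, "call": call.call.value,
                "matched_patterns": ";".join(sorted(call.matched_patterns)),
                "match_start": first.start if first else "",
                "match_end": first.end if first else ""})
        pd.DataFrame(rows).to_csv(out / "classify.tsv", sep="\t", index=False)
        summary["stages"]["classify"] = {
            "n_sequences": len(rows), "calls": counts}
    else:
        log.info("classify stage skipped (no sequences)")

    with open(out / "run_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
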