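"""End-to-end orchestration of the analysis stages on files in an output directory.

``run_demo`` generates a synthetic study (transcriptome, RIP/input libraries,
stable- and control-mode FLASH libraries, DE table, decay timecourses) and
runs every stage over the emitted files, so the whole flow -- including the
parsers -- is exercised.  All outputs are deterministic functions of the
seed; a manifest lists every result file with its SHA-256 checksum and the
run's parameters, so identical re-runs are byte-verifiable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from ripflash import cluster_calling, duplex_thermo, hybrid_analysis, integration
from ripflash import io_formats, profiles_motifs, synthetic_data

logger = logging.getLogger(__name__)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_dir: Path, config: synthetic_data.SimulationConfig) -> Path:
    """Checksum every result file and serialize the run parameters."""
    with open(out_dir / "params.json", "w") as fh:
        json.dump(dataclasses.asdict(config), fh, indent=2, sort_keys=True)
    files = sorted(
        p for p in out_dir.rglob("*")
        if p.is_file() and p.name not in ("manifest.tsv", "run.log")
    )
    manifest = out_dir / "manifest.tsv"
    with open(manifest, "w") as fh:
        fh.write("path\tsha256\tbytes\n")
        for p in files:
            fh.write(f"{p.relative_to(out_dir)}\t{_sha256(p)}\t{p.stat().st_size}\n")
    return manifest


def run_demo(
    seed: int = 0,
    out_dir: str | Path = "ripflash_demo",
    config: synthetic_data.SimulationConfig | None = None,
) -> dict:
    """Synthetic end-to-end run; returns the headline numbers it computed.

    Stage order matters: FLASH planting edits 3'UTR sequences (to embed the
    stable duplexes), so the FLASH stage runs first and its returned
    transcriptome is the one written out and used by every other stage.
    """
    out = Path(out_dir)
    (out / "truth").mkdir(parents=True, exist_ok=True)
    cfg = config or synthetic_data.SimulationConfig(seed=seed, n_genes=150,
                                                    n_reads_rip=30_000,
                                                    n_reads_input=30_000,
                                                    n_reads_flash=100_000)
    cfg.seed = seed
    results: dict = {"seed": seed}

    # --- simulate ---------------------------------------------------------
    models = synthetic_data.simulate_transcriptome(cfg)
    models, flash_reads, flash_truth = synthetic_data.simulate_flash_reads(cfg, models, "stable")
    control_cfg = dataclasses.replace(cfg, hybrid_fraction=0.0003)
    _, control_reads, _ = synthetic_data.simulate_flash_reads(control_cfg, models, "control")
    rip, inp, rip_truth = synthetic_data.simulate_rip_reads(cfg, models)

    io_formats.write_annotation(models.values(), out / "annotation.gtf", out / "transcripts.fa")
    io_formats.write_alignments_sam(rip, models, out / "rip.sam")
    io_formats.write_alignments_sam(inp, models, out / "input.sam")
    synthetic_data.write_fastq(flash_reads, out / "flash.fastq")
    synthetic_data.write_fastq(control_reads, out / "flash_control.fastq")
    truth = synthetic_data.GroundTruth(
        planted_clusters=rip_truth.planted_clusters,
        planted_hybrids=flash_truth.planted_hybrids,
    )

    # --- read everything back through the parsers -------------------------
    models = io_formats.read_annotation(out / "annotation.gtf", out / "transcripts.fa")
    rip = io_formats.read_alignments(out / "rip.sam", "sam").records
    inp = io_formats.read_alignments(out / "input.sam", "sam").records
    flash_reads = synthetic_data.read_fastq(out / "flash.fastq")
    control_reads = synthetic_data.read_fastq(out / "flash_control.fastq")

    # --- clusters ---------------------------------------------------------
    significant, candidates = cluster_calling.call_clusters(rip, models, inp)
    io_formats.write_clusters(significant, out / "clusters.tsv")
    all_bio, nc_bio = cluster_calling.biotype_proportions(significant)
    all_bio.to_csv(out / "biotype_proportions.tsv", sep="\t", index=False)
    results["n_significant_clusters"] = len(significant)
    coding_pct = all_bio.loc[all_bio.biotype == "protein_coding", "percentage"]
    results["pct_clusters_protein_coding"] = float(coding_pct.iloc[0]) if len(coding_pct) else 0.0

    # --- hybrids ----------------------------------------------------------
    index = hybrid_analysis.build_index(models)
    det = hybrid_analysis.detect_chimeras(flash_reads, index)
    det_ctrl = hybrid_analysis.detect_chimeras(control_reads, index)
    frac, lo, hi = hybrid_analysis.hybrid_fraction(len(det.hybrids), len(flash_reads))
    frac_ctrl, _, _ = hybrid_analysis.hybrid_fraction(len(det_ctrl.hybrids), len(control_reads))
    results["n_reads_flash"] = len(flash_reads)
    results["n_hybrids"] = len(det.hybrids)
    results["n_hybrids_control"] = len(det_ctrl.hybrids)
    results["hybrid_fraction_pct"] = frac
    results["hybrid_fraction_ci_pct"] = (lo, hi)
    results["control_hybrid_fraction_pct"] = frac_ctrl
    comp = hybrid_analysis.class_composition(det.hybrids)
    comp.to_csv(out / "hybrid_composition.tsv", sep="\t", index=False)
    intra = comp.loc[comp.category == "mRNA_3utr::mRNA_3utr_self", "share_pct"]
    results["intramolecular_3utr_share_pct"] = float(intra.iloc[0]) if len(intra) else 0.0

    # --- duplex energies --------------------------------------------------
    duplex_thermo.annotate_hybrid_energies(det.hybrids, models)
    duplex_thermo.annotate_hybrid_energies(det_ctrl.hybrids, models)
    io_formats.write_hybrids(det.hybrids, out / "hybrids.tsv")
    io_formats.write_hybrids(det_ctrl.hybrids, out / "hybrids_control.tsv")
    emap = duplex_thermo.energy_map(
        [h.delta_g for h in det.hybrids], [h.category for h in det.hybrids]
    )
    emap.to_csv(out / "energy_map.tsv", sep="\t", index=False)
    dg = [h.delta_g for h in det.hybrids if h.delta_g < 0]
    dg_ctrl = [h.delta_g for h in det_ctrl.hybrids if h.delta_g < 0]
    results["mean_dg_flash"] = float(np.mean(dg)) if dg else 0.0
    results["mean_dg_control"] = float(np.mean(dg_ctrl)) if dg_ctrl else 0.0
    if len(dg) >= 2 and len(dg_ctrl) >= 2:
        rs = duplex_thermo.wilcoxon_rank_sum(dg, dg_ctrl)
        results["energy_ranksum_p"] = rs.p_value
    uniq = hybrid_analysis.unique_interactions(det.hybrids, models)
    uniq.to_csv(out / "unique_interactions.tsv", sep="\t", index=False)
    results["n_unique_interactions"] = len(uniq)

    # --- profiles & motifs ------------------------------------------------
    profile = profiles_motifs.metagene_profile(significant, models)
    profile.as_table().to_csv(out / "metagene.tsv", sep="\t", index=False)
    d5, d3, body = profiles_motifs.end_density(significant, models)
    results["end_density_5prime"], results["end_density_3prime"] = d5, d3
    results["end_density_body"] = body

    utr3_seqs = []
    cluster_txs = {c.transcript_id for c in significant}
    for tx in sorted(cluster_txs):
        r = models[tx].region_of("utr3")
        if r is not None:
            utr3_seqs.append(models[tx].sequence[r[1]:r[2]])
    if utr3_seqs:
        kmers = profiles_motifs.kmer_zscores(utr3_seqs, k=6, n_shuffles=50, seed=seed)
        kmers.head(100).to_csv(out / "kmer_zscores.tsv", sep="\t", index=False)
        results["top_kmer"] = str(kmers.iloc[0]["kmer"])

    mirna_seqs = {tx: m.sequence for tx, m in models.items() if m.biotype == "miRNA"}
    utr_map = {}
    for tx, m in models.items():
        r = m.region_of("utr3")
        if r is not None:
            utr_map[tx] = m.sequence[r[1]:r[2]]
    if mirna_seqs and utr_map:
        sites = profiles_motifs.scan_mirna_sites(utr_map, mirna_seqs)
        pd.DataFrame([dataclasses.asdict(s) for s in sites]).to_csv(
            out / "mirna_sites.tsv", sep="\t", index=False)
        results["n_mirna_sites"] = len(sites)

    # --- integration ------------------------------------------------------
    bound_genes = sorted({models[tx].gene_id for tx, _, _ in truth.planted_clusters})
    coding_genes = sorted({m.gene_id for m in models.values() if m.biotype == "protein_coding"})
    de = synthetic_data.simulate_de_table(cfg, bound_genes, coding_genes, truth)
    io_formats.write_de_table(de, out / "de_table.tsv")
    de = io_formats.read_de_table(out / "de_table.tsv")
    stats_df, audit = integration.compute_gene_stats(rip, inp, models, de, det.hybrids)
    io_formats.write_gene_stats(stats_df.to_dict("records"), out / "gene_stats.tsv")
    assoc = integration.binding_regulation_association(stats_df)
    assoc["scatter"].to_csv(out / "binding_scatter.tsv", sep="\t", index=False)
    results["join_audit"] = audit
    for metric, short in (("log_cov_ratio", "cov"), ("log_rpkm_ratio", "rpkm")):
        test = assoc["tests"].get(f"down_vs_unregulated_{metric}")
        if test is not None:
            results[f"down_vs_unregulated_p_{short}"] = test.p_value
    reg_table = integration.hybrid_regulation_table(det.hybrids, de, models)
    reg_table.to_csv(out / "hybrid_regulation.tsv", sep="\t", index=False)

    de_genes = set(de.loc[de.direction != "unregulated", "gene_id"])
    rip_genes = {models[c.transcript_id].gene_id for c in significant}
    chip_rng = synthetic_data.stage_rng(seed, "chip")
    chip = set(chip_rng.choice(coding_genes, size=min(40, len(coding_genes)), replace=False))
    pairwise, membership = integration.overlap_report(
        {"rip": rip_genes, "de": de_genes, "chip": chip}
    )
    pairwise.to_csv(out / "overlaps.tsv", sep="\t", index=False)
    membership.to_csv(out / "set_membership.tsv", sep="\t", index=False)

    decay_genes = bound_genes[:4] if len(bound_genes) >= 4 else bound_genes
    hl_ctrl = {g: hl for g, hl in zip(decay_genes, (0.5, 1.0, 2.0, 4.0))}
    hl_kd = {g: hl / 3.0 for g, hl in hl_ctrl.items()}
    tp = [0, 1, 2, 4, 8]
    tc_ctrl = synthetic_data.simulate_decay_series(hl_ctrl, tp, 0.05, seed, n_replicates=3)
    tc_kd = synthetic_data.simulate_decay_series(hl_kd, tp, 0.05, seed + 1, n_replicates=3)
    tc_ctrl.to_csv(out / "decay_control.tsv", sep="\t", index=False)
    tc_kd.to_csv(out / "decay_knockdown.tsv", sep="\t", index=False)
    fits = integration.compare_half_lives(
        integration.fit_decay_table(tc_ctrl), integration.fit_decay_table(tc_kd)
    )
    fits.to_csv(out / "half_lives.tsv", sep="\t", index=False)
    results["n_genes_destabilized"] = int(fits["destabilized"].sum())
    results["n_decay_genes"] = len(fits)

    synthetic_data.write_ground_truth(truth, out / "truth")
    write_manifest(out, cfg)
    return results
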