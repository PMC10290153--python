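"""Staged pipeline orchestration with manifests.

Each stage reads the outputs of its upstream stages from the run directory,
writes TSV/JSON outputs plus a manifest recording the config hash and input
hashes, and is skipped on rerun when nothing changed (unless forced).
Ground-truth files emitted by the simulator carry the ``.truth.json``
suffix and are refused by every stage loader: the pipeline must work from
data alone.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any, Callable, Optional

import pandas as pd

from . import integration, metabolomics, simulate, targets as targets_mod
from .annotation import intersect_trna, match_genome
from .config import GROUP_COARSE, GROUP_FINE, QC_ROLE, PipelineConfig
from .differential import build_count_matrix, ddct, diff_results_frame, group_ttest
from .errors import ConfigError, DataError
from .integration import DepCutoffs
from .seqio import (read_fasta, read_loci_tsv, write_fasta, write_fastq,
                    write_loci_tsv)
from .simulate import TRUTH_SUFFIX
from .spectrum import (PeakParams, decompose_peak, detect_anomalous_peaks,
                       filter_by_length, length_spectrum, load_reads)

STAGES = ["simulate", "spectrum", "decompose", "annotate", "diff", "targets",
          "proteome", "integrate", "metabolome", "report"]

_UPSTREAM = {
    "simulate": [],
    "spectrum": ["simulate"],
    "decompose": ["spectrum"],
    "annotate": ["decompose"],
    "diff": ["decompose"],
    "targets": ["decompose"],
    "proteome": ["simulate"],
    "integrate": ["targets", "proteome"],
    "metabolome": ["simulate"],
    "report": ["spectrum", "annotate", "diff", "integrate", "metabolome"],
}


def guard_not_truth(path: Path) -> Path:
    """Refuse ground-truth files as pipeline inputs."""
    if str(path).endswith(TRUTH_SUFFIX):
        raise DataError(f"refusing to read ground-truth file: {path}")
    return path


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _config_hash(cfg: PipelineConfig) -> str:
    return hashlib.sha256(
        json.dumps(cfg.to_dict(), sort_keys=True).encode()).hexdigest()


def _manifest_path(outdir: Path, stage: str) -> Path:
    return outdir / f"{stage}.manifest.json"


def _load_manifest(outdir: Path, stage: str) -> Optional[dict]:
    p = _manifest_path(outdir, stage)
    if not p.exists():
        return None
    return json.loads(p.read_text())


def _up_to_date(outdir: Path, stage: str, cfg_hash: str,
                inputs: list[Path]) -> bool:
    man = _load_manifest(outdir, stage)
    if man is None or man.get("config_hash") != cfg_hash:
        return False
    recorded = man.get("input_hashes", {})
    if set(recorded) != {str(p) for p in inputs}:
        return False
    for p in inputs:
        if not p.exists() or _sha256(p) != recorded[str(p)]:
            return False
    return all((outdir / name).exists() for name in man.get("outputs", []))


def _write_manifest(outdir: Path, stage: str, cfg_hash: str,
                    inputs: list[Path], outputs: list[str]) -> None:
    man = {
        "stage": stage,
        "config_hash": cfg_hash,
        "input_hashes": {str(p): _sha256(p) for p in inputs},
        "outputs": outputs,
    }
    _manifest_path(outdir, stage).write_text(json.dumps(man, indent=1))


def _require_upstream(outdir: Path, stage: str) -> None:
    for dep in _UPSTREAM[stage]:
        if _load_manifest(outdir, dep) is None:
            raise DataError(
                f"stage '{stage}' needs outputs of stage '{dep}': "
                f"run `trfscan {dep}` first")


def _write_json(outdir: Path, name: str, obj: Any) -> None:
    (outdir / name).write_text(json.dumps(obj, indent=1, default=str))


def _read_json(outdir: Path, name: str) -> Any:
    return json.loads(guard_not_truth(outdir / name).read_text())


def _load_samples(outdir: Path) -> pd.DataFrame:
    return pd.read_csv(guard_not_truth(outdir / "samples.tsv"), sep="\t")


def _role_of(col: str) -> str:
    base = col.rsplit("_", 1)[0]
    return QC_ROLE if base.upper() == "QC" else base


def run_stage(stage: str, cfg: PipelineConfig, force: bool = False) -> dict:
    """Run one pipeline stage; returns a summary dict.

    Reruns with unchanged config and inputs are a no-op unless ``force``.
    """
    if stage not in STAGES:
        raise ConfigError(f"unknown stage '{stage}'; choose from {STAGES}")
    outdir = cfg.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    if stage != "simulate":
        _require_upstream(outdir, stage)
    cfg_hash = _config_hash(cfg)
    impl: Callable[[PipelineConfig, Path], tuple[list[Path], list[str], dict]]
    impl = _STAGE_IMPL[stage]
    inputs = _stage_inputs(stage, outdir)
    if not force and _up_to_date(outdir, stage, cfg_hash, inputs):
        return {"stage": stage, "skipped": True}
    _, outputs, summary = impl(cfg, outdir)
    _write_manifest(outdir, stage, cfg_hash, inputs, outputs)
    summary.update({"stage": stage, "skipped": False})
    return summary


def _stage_inputs(stage: str, outdir: Path) -> list[Path]:
    """Input files whose hashes gate the stage's no-op rerun check."""
    name_map = {
        "simulate": [],
        "spectrum": ["samples.tsv"],
        "decompose": ["samples.tsv", "peaks.json"],
        "annotate": ["genome.fasta", "loci.tsv", "composition.json"],
        "diff": ["samples.tsv", "composition.json", "qpcr_trf.tsv",
                 "qpcr_trna.tsv"],
        "targets": ["utrs.fasta", "composition.json"],
        "proteome": ["proteome.tsv"],
        "integrate": ["predicted_genes.txt", "deps.tsv", "proteome.tsv",
                      "gene_sets.gmt"],
        "metabolome": ["metabolome.tsv"],
        "report": ["peaks.json", "fragment_hits.tsv", "diff.tsv",
                   "overlap.json", "significant_metabolites.tsv"],
    }
    return [outdir / n for n in name_map[stage] if (outdir / n).exists()]


# ---------------------------------------------------------------------------
# stage implementations
# ---------------------------------------------------------------------------

def _stage_simulate(cfg: PipelineConfig, outdir: Path):
    sim = cfg.sim
    genome, loci = simulate.generate_toy_genome(sim)
    write_fasta(genome, outdir / "genome.fasta")
    write_loci_tsv(loci, outdir / "loci.tsv")
    readsets = simulate.simulate_small_rna_reads(genome, loci, sim)
    rows = []
    for rs in readsets:
        fq = f"reads_{rs.sample_id}.fastq"
        write_fastq(rs.reads, outdir / fq, prefix=rs.sample_id)
        rows.append({"sample_id": rs.sample_id, "group": rs.group, "fastq": fq})
    pd.DataFrame(rows).to_csv(outdir / "samples.tsv", sep="\t", index=False)
    prot, prot_groups, prot_truth = simulate.simulate_proteome(sim)
    prot.to_csv(outdir / "proteome.tsv", sep="\t")
    fragment = simulate.fragment_sequence(genome, loci, sim.fragment_length)
    utrs = simulate.generate_utrs(sim, list(prot.index), prot_truth["targets"],
                                  fragment)
    write_fasta(utrs, outdir / "utrs.fasta")
    gene_sets = simulate.make_gene_sets(list(prot.index), prot_truth, sim)
    integration.write_gmt(gene_sets, outdir / "gene_sets.gmt")
    metab, metab_roles, metab_truth = simulate.simulate_metabolome(sim)
    metab.to_csv(outdir / "metabolome.tsv", sep="\t")
    simulate.simulate_qpcr(sim, fold_coarse_over_fine=sim.trf_fold).to_csv(
        outdir / "qpcr_trf.tsv", sep="\t", index=False)
    simulate.simulate_qpcr(sim, fold_coarse_over_fine=1.0 / sim.trna_fold,
                           stream=14).to_csv(
        outdir / "qpcr_trna.tsv", sep="\t", index=False)
    truth = {"fragment": fragment,
             "decoys": simulate.decoy_sequences(genome, loci, sim),
             "proteome": prot_truth, "metabolome": metab_truth,
             "trf_fold": sim.trf_fold, "trna_fold": sim.trna_fold}
    (outdir / f"sim{TRUTH_SUFFIX}").write_text(json.dumps(truth, indent=1))
    outputs = (["genome.fasta", "loci.tsv", "samples.tsv", "proteome.tsv",
                "utrs.fasta", "gene_sets.gmt", "metabolome.tsv",
                "qpcr_trf.tsv", "qpcr_trna.tsv"]
               + [r["fastq"] for r in rows])
    return [], outputs, {"n_samples": len(rows), "n_loci": len(loci)}


def _load_readsets(cfg: PipelineConfig, outdir: Path):
    samples = _load_samples(outdir)
    readsets = []
    for _, row in samples.iterrows():
        rs = load_reads(guard_not_truth(outdir / row["fastq"]),
                        row["sample_id"], row["group"])
        readsets.append(filter_by_length(
            rs, cfg.spectrum.get("min_len", cfg.sim.min_len),
            cfg.spectrum.get("max_len", cfg.sim.max_len)))
    return readsets


def _stage_spectrum(cfg: PipelineConfig, outdir: Path):
    readsets = _load_readsets(cfg, outdir)
    window = (cfg.spectrum.get("min_len", cfg.sim.min_len),
              cfg.spectrum.get("max_len", cfg.sim.max_len))
    spectra = [length_spectrum(rs, window) for rs in readsets]
    long = pd.DataFrame([
        {"sample_id": s.sample_id, "group": s.group, "length": L,
         "count": s.counts[L], "rpm": s.normalized[L]}
        for s in spectra for L in sorted(s.counts)])
    long.to_csv(outdir / "spectra.tsv", sep="\t", index=False)
    params = PeakParams(
        canonical_window=tuple(cfg.spectrum.get("canonical_window", (20, 24))),
        min_ratio=cfg.spectrum.get("min_ratio", 0.25),
        alpha=cfg.spectrum.get("alpha", 0.05),
        min_fold=cfg.spectrum.get("min_fold", 2.0),
        bh=cfg.spectrum.get("bh", False))
    calls = detect_anomalous_peaks(spectra, params, groups=cfg.groups)
    _write_json(outdir, "peaks.json", [vars(c) for c in calls])
    return [], ["spectra.tsv", "peaks.json"], {
        "n_peaks": len(calls),
        "peak_lengths": [c.length for c in calls]}


def _peak_length(outdir: Path, cfg: PipelineConfig) -> int:
    calls = _read_json(outdir, "peaks.json")
    if calls:
        return int(calls[0]["length"])
    return cfg.sim.fragment_length


def _stage_decompose(cfg: PipelineConfig, outdir: Path):
    readsets = _load_readsets(cfg, outdir)
    length = _peak_length(outdir, cfg)
    comp = decompose_peak(readsets, length)
    obj = {key: {"length": c.length,
                 "entries": [{"sequence": s, "count": n, "fraction": f}
                             for s, n, f in c.entries[:50]],
                 "dominant": (None if c.dominant is None else
                              {"sequence": c.dominant[0],
                               "count": c.dominant[1],
                               "fraction": c.dominant[2]})}
           for key, c in comp.items()}
    _write_json(outdir, "composition.json", obj)
    dom = obj["pooled"]["dominant"]
    return [], ["composition.json"], {
        "peak_length": length,
        "dominant_sequence": None if dom is None else dom["sequence"],
        "dominant_fraction_pooled": None if dom is None else dom["fraction"]}


def _dominant_fragment(outdir: Path) -> str:
    comp = _read_json(outdir, "composition.json")
    dom = comp["pooled"]["dominant"]
    if dom is None:
        raise DataError("no dominant sequence in composition.json")
    return dom["sequence"]


def _stage_annotate(cfg: PipelineConfig, outdir: Path):
    fragment = _dominant_fragment(outdir)
    genome = read_fasta(guard_not_truth(outdir / "genome.fasta"))
    loci = read_loci_tsv(guard_not_truth(outdir / "loci.tsv"),
                         zero_based=cfg.annotation.get("bed_zero_based", False))
    hits = match_genome(fragment, genome,
                        max_mismatches=cfg.annotation.get("max_mismatches", 0))
    fhits = intersect_trna(hits, loci,
                           trailer=cfg.annotation.get("trailer", 50))
    rows = [{"chrom": fh.hit.chrom, "start": fh.hit.start, "end": fh.hit.end,
             "strand": fh.hit.strand,
             "gene_name": fh.locus.gene_name if fh.locus else ".",
             "offset5": fh.offset5 if fh.offset5 is not None else ".",
             "fragment_class": fh.fragment_class,
             "reported_label": fh.reported_label}
            for fh in fhits]
    pd.DataFrame(rows).to_csv(outdir / "fragment_hits.tsv", sep="\t", index=False)
    classes = sorted({r["fragment_class"] for r in rows})
    return [], ["fragment_hits.tsv"], {"n_hits": len(rows), "classes": classes}


def _stage_diff(cfg: PipelineConfig, outdir: Path):
    readsets = _load_readsets(cfg, outdir)
    comp = _read_json(outdir, "composition.json")
    seqs = [e["sequence"] for e in comp["pooled"]["entries"][:4]]
    cm = build_count_matrix(readsets, seqs)
    results = group_ttest(cm, groups=cfg.groups)
    diff_results_frame(results).to_csv(outdir / "diff.tsv", sep="\t", index=False)
    qpcr_out = {}
    for assay, fname in (("trf", "qpcr_trf.tsv"), ("trna", "qpcr_trna.tsv")):
        q = pd.read_csv(guard_not_truth(outdir / fname), sep="\t")
        qpcr_out[assay] = ddct(q, control_group=cfg.groups[1])
    _write_json(outdir, "qpcr.json", qpcr_out)
    top = results[0] if results else None
    return [], ["diff.tsv", "qpcr.json"], {
        "n_tested": len(results),
        "top_fold": None if top is None else top.fold,
        "qpcr": qpcr_out}


def _stage_targets(cfg: PipelineConfig, outdir: Path):
    fragment = _dominant_fragment(outdir)
    utrs = read_fasta(guard_not_truth(outdir / "utrs.fasta"))
    params = targets_mod.DuplexParams(**cfg.targets) if cfg.targets \
        else targets_mod.DuplexParams()
    hits = targets_mod.scan_targets(fragment, utrs, params)
    rows = [{"utr_id": h.utr_id, "start": h.start, "end": h.end,
             "score": h.score, "stability": h.stability}
            for hl in hits.values() for h in hl]
    pd.DataFrame(rows, columns=["utr_id", "start", "end", "score", "stability"]
                 ).to_csv(outdir / "target_hits.tsv", sep="\t", index=False)
    genes = sorted(targets_mod.predicted_genes(hits))
    (outdir / "predicted_genes.txt").write_text("\n".join(genes) + "\n")
    return [], ["target_hits.tsv", "predicted_genes.txt"], {
        "n_predicted_genes": len(genes)}


def _stage_proteome(cfg: PipelineConfig, outdir: Path):
    table = pd.read_csv(guard_not_truth(outdir / "proteome.tsv"),
                        sep="\t", index_col=0)
    groups = {c: _role_of(c) for c in table.columns}
    cutoffs = DepCutoffs(**cfg.proteome) if cfg.proteome else DepCutoffs()
    up, down, statsdf = integration.call_deps(table, groups,
                                              group_pair=cfg.groups,
                                              cutoffs=cutoffs)
    statsdf.to_csv(outdir / "deps.tsv", sep="\t")
    (outdir / "up_deps.txt").write_text("\n".join(sorted(up)) + "\n")
    (outdir / "down_deps.txt").write_text("\n".join(sorted(down)) + "\n")
    return [], ["deps.tsv", "up_deps.txt", "down_deps.txt"], {
        "n_up": len(up), "n_down": len(down)}


def _stage_integrate(cfg: PipelineConfig, outdir: Path):
    predicted = [g for g in (outdir / "predicted_genes.txt"
                             ).read_text().splitlines() if g]
    down = [g for g in (outdir / "down_deps.txt").read_text().splitlines() if g]
    table = pd.read_csv(guard_not_truth(outdir / "proteome.tsv"),
                        sep="\t", index_col=0)
    universe = list(table.index)
    res = integration.overlap_targets_deps(predicted, down, universe)
    _write_json(outdir, "overlap.json", vars(res))
    gene_sets = integration.read_gmt(guard_not_truth(outdir / "gene_sets.gmt"))
    overlap_genes = sorted(set(predicted) & set(down))
    oradf = integration.ora(overlap_genes, gene_sets, universe)
    oradf.to_csv(outdir / "ora.tsv", sep="\t", index=False)
    return [], ["overlap.json", "ora.tsv"], {
        "n_overlap": res.n_overlap, "pct_of_down": res.pct_of_down,
        "hypergeom_p": res.hypergeom_p}


def _stage_metabolome(cfg: PipelineConfig, outdir: Path):
    table = pd.read_csv(guard_not_truth(outdir / "metabolome.tsv"),
                        sep="\t", index_col=0).fillna(0.0)
    roles = {c: _role_of(c) for c in table.columns}
    kept = metabolomics.prevalence_filter(table, roles)
    norm = metabolomics.normalize_total_intensity(kept)
    scaled = metabolomics.pareto_scale(norm)
    scores, _loadings, var_frac = metabolomics.pca_scores(scaled, k=2)
    scores.to_csv(outdir / "pca_scores.tsv", sep="\t")
    qc = metabolomics.qc_tightness(scores, roles)
    vip = metabolomics.plsda_vip(
        scaled, roles, n_components=cfg.metabolome.get("n_components", 2),
        group_pair=cfg.groups)
    vip.scores.to_csv(outdir / "vip.tsv", sep="\t")
    stats_table = metabolomics.group_ttest_table(norm, roles,
                                                 group_pair=cfg.groups)
    sig = metabolomics.screen_metabolites(
        vip, stats_table,
        vip_cutoff=cfg.metabolome.get("vip_cutoff", 1.0),
        alpha=cfg.metabolome.get("alpha", 0.05))
    sig.to_csv(outdir / "significant_metabolites.tsv", sep="\t")
    summary = {"n_kept": int(len(kept)), "n_significant": int(len(sig)),
               "pc_variance_fractions": [float(v) for v in var_frac], **qc}
    _write_json(outdir, "metabolome_summary.json", summary)
    return [], ["pca_scores.tsv", "vip.tsv", "significant_metabolites.tsv",
                "metabolome_summary.json"], summary


def _stage_report(cfg: PipelineConfig, outdir: Path):
    peaks = _read_json(outdir, "peaks.json")
    hits = pd.read_csv(guard_not_truth(outdir / "fragment_hits.tsv"), sep="\t")
    diff = pd.read_csv(guard_not_truth(outdir / "diff.tsv"), sep="\t")
    overlap = _read_json(outdir, "overlap.json")
    metab = _read_json(outdir, "metabolome_summary.json")
    qpcr = _read_json(outdir, "qpcr.json")
    comp = _read_json(outdir, "composition.json")
    report = {
        "peak_calls": peaks,
        "fragment_annotation": {
            "n_hits": int(len(hits)),
            "classes": sorted(hits["fragment_class"].unique().tolist()),
            "reported_labels": sorted(hits["reported_label"].unique().tolist()),
        },
        "dominant_fraction": {
            grp: (comp[grp]["dominant"] or {}).get("fraction")
            for grp in comp},
        "fold_changes": diff.to_dict(orient="records"),
        "qpcr": qpcr,
        "overlap": overlap,
        "metabolome": metab,
    }
    _write_json(outdir, "report.json", report)
    return [], ["report.json"], {"report": "report.json"}


_STAGE_IMPL = {
    "simulate": _stage_simulate,
    "spectrum": _stage_spectrum,
    "decompose": _stage_decompose,
    "annotate": _stage_annotate,
    "diff": _stage_diff,
    "targets": _stage_targets,
    "proteome": _stage_proteome,
    "integrate": _stage_integrate,
    "metabolome": _stage_metabolome,
    "report": _stage_report,
}
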