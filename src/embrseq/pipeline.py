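"""End-to-end orchestration: simulate -> demux -> align -> quant -> hotspots -> design.

A single configured run writes every stage's outputs under one directory and
a machine-readable ``report.json`` recording the resolved configuration, a
SHA-256 checksum per output file, and the headline metrics (class fractions,
fold rRNA depletion, called hotspots).  Reruns with identical configuration
reproduce identical checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Any

from embrseq import align as al
from embrseq import demux as dm
from embrseq import hotspots as hs
from embrseq import operons as opn
from embrseq import primers as pr
from embrseq import quant as qt
from embrseq import simulate as sim
from embrseq.reference import ReferenceSet, annotation_from_records

logger = logging.getLogger("embrseq")

STAGES = ("simulate", "demux", "align", "quant", "hotspots", "design", "operon_bias")

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "stages": {s: (s != "operon_bias") for s in STAGES},
    "simulate": {"presets": ["control", "embr"], "n_reads": 50_000},
    "demux": {"whitelist": list(dm.DEFAULT_WHITELIST), "allow_one_mismatch": False},
    "align": {"k": 25},
    "hotspots": {"window": 50, "min_fold": 5.0, "min_share": 0.02, "refs": ["rRNA_16S", "rRNA_23S"]},
    "design": {"tm_min": 65.0, "offset": 100, "length": 30},
    "operon_bias": {"sam": None, "operon_table": None, "nbins": 50,
                    "min_genes": 2, "min_reads": 200},
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: dict[str, Any], out_dir: str | Path) -> dict[str, Any]:
    """Execute the configured stages in dependency order; returns the report dict.

    On stage failure, a report with a ``failed_stage`` marker is written
    alongside any partial outputs before the error propagates.
    """
    cfg = _merge(DEFAULT_CONFIG, config or {})
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    report: dict[str, Any] = {"config": cfg, "seed": seed, "stages": {}, "metrics": {}, "outputs": {}}
    outputs: list[Path] = []
    enabled = cfg["stages"]

    state: dict[str, Any] = {}
    try:
        current = "simulate"
        if enabled["simulate"]:
            _stage_simulate(cfg, seed, out, state, report, outputs)
        current = "demux"
        if enabled["demux"] and "fastq" in state:
            _stage_demux(cfg, out, state, report, outputs)
        current = "align"
        if enabled["align"] and "demuxed" in state:
            _stage_align(cfg, out, state, report, outputs)
        current = "quant"
        if enabled["quant"] and "alignments" in state:
            _stage_quant(cfg, out, state, report, outputs)
        current = "hotspots"
        if enabled["hotspots"] and "alignments" in state:
            _stage_hotspots(cfg, out, state, report, outputs)
        current = "design"
        if enabled["design"] and "ref" in state:
            _stage_design(cfg, out, state, report, outputs)
        current = "operon_bias"
        if enabled["operon_bias"] and cfg["operon_bias"]["sam"]:
            _stage_operon(cfg, out, report, outputs)
    except Exception as exc:
        report["failed_stage"] = current
        report["error"] = str(exc)
        report["outputs"] = {str(p.relative_to(out)): _sha256(p) for p in outputs}
        (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
        raise RuntimeError(f"pipeline stage {current!r} failed: {exc}") from exc

    report["outputs"] = {str(p.relative_to(out)): _sha256(p) for p in outputs}
    (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
    return report


# ----------------------------------------------------------------- stages


def _stage_simulate(cfg, seed, out, state, report, outputs) -> None:
    t0 = time.time()
    sim_cfg = cfg["simulate"]
    presets = sim_cfg["presets"]
    n_reads = int(sim_cfg["n_reads"])
    state["fastq"], state["truth"], state["sim_configs"] = {}, {}, {}
    for name in presets:
        if name == "control":
            config = sim.control_preset(n_reads=n_reads, seed=seed)
        elif name == "embr":
            config = sim.embr_preset(n_reads=n_reads, seed=seed)
        else:
            raise ValueError(f"unknown simulate preset {name!r}")
        ref = sim.build_reference(config)
        if "ref" not in state:
            state["ref"] = ref
            ref.write_fasta(out / "reference.fasta")
            ref.write_annotation(out / "annotation.tsv")
            outputs.extend([out / "reference.fasta", out / "annotation.tsv"])
        pairs, truth = sim.simulate_reads(ref, config)
        r1, r2 = out / f"{name}_R1.fastq", out / f"{name}_R2.fastq"
        sim.write_paired_fastq(pairs, r1, r2)
        sim.write_truth(truth, out / f"{name}_truth.tsv")
        config.save(out / f"{name}_sim_config.yaml")
        outputs.extend([r1, r2, out / f"{name}_truth.tsv", out / f"{name}_sim_config.yaml"])
        state["fastq"][name] = (r1, r2)
        state["truth"][name] = truth
        state["sim_configs"][name] = config
        logger.info("simulated %s preset: %d reads", name, n_reads)
    report["stages"]["simulate"] = {"presets": presets, "n_reads": n_reads,
                                    "seconds": round(time.time() - t0, 2)}


def _stage_demux(cfg, out, state, report, outputs) -> None:
    t0 = time.time()
    d = cfg["demux"]
    state["demuxed"] = {}
    stats = {}
    for name, (r1, r2) in state["fastq"].items():
        pairs = dm.read_paired_fastq(r1, r2)
        assigned, discarded = dm.demultiplex(pairs, d["whitelist"], d["allow_one_mismatch"])
        barcode = state["sim_configs"][name].barcode
        state["demuxed"][name] = assigned[barcode]
        path = out / f"{name}_demux.tsv"
        dm.write_demux_report(assigned, discarded, path)
        outputs.append(path)
        stats[name] = {"assigned": sum(len(v) for v in assigned.values()), "discarded": discarded}
    report["stages"]["demux"] = {**stats, "seconds": round(time.time() - t0, 2)}


def _stage_align(cfg, out, state, report, outputs) -> None:
    t0 = time.time()
    k = int(cfg["align"]["k"])
    state["alignments"] = {}
    for name, pairs in state["demuxed"].items():
        alns = al.align_exact(pairs, state["ref"], k=k)
        state["alignments"][name] = alns
        path = out / f"{name}.sam"
        al.write_sam(alns, state["ref"], path)
        outputs.append(path)
    report["stages"]["align"] = {
        name: {"mapped": sum(a.mapped for a in alns), "total": len(alns)}
        for name, alns in state["alignments"].items()
    } | {"seconds": round(time.time() - t0, 2)}


def _stage_quant(cfg, out, state, report, outputs) -> None:
    t0 = time.time()
    ann = annotation_from_records(state["ref"])
    counts = {
        name: qt.classify_and_count(alns, ann, sample_id=name)
        for name, alns in state["alignments"].items()
    }
    state["counts"] = counts
    qt.write_class_fractions(list(counts.values()), out / "class_fractions.tsv")
    qt.write_gene_matrix(list(counts.values()), out / "gene_counts.tsv")
    outputs.extend([out / "class_fractions.tsv", out / "gene_counts.tsv"])
    metrics: dict[str, Any] = {
        name: {k: round(v, 6) for k, v in c.fractions.items()} for name, c in counts.items()
    }
    if {"control", "embr"} <= counts.keys():
        dep = qt.depletion_metrics(counts["embr"], counts["control"])
        metrics["fold_rRNA_depletion"] = dep.fold_rRNA_depletion
        metrics["fold_mRNA_enrichment"] = dep.fold_mRNA_enrichment
    report["metrics"].update(metrics)
    report["stages"]["quant"] = {"seconds": round(time.time() - t0, 2)}


def _stage_hotspots(cfg, out, state, report, outputs) -> None:
    t0 = time.time()
    h = cfg["hotspots"]
    called: dict[str, list] = {}
    # hotspots are read off the residual rRNA profile of the *blocked* sample
    # when present, else the first sample
    name = "embr" if "embr" in state["alignments"] else next(iter(state["alignments"]))
    alns = state["alignments"][name]
    for ref_id in h["refs"]:
        if ref_id not in state["ref"]:
            continue
        profile = hs.readstart_profile(alns, ref_id, state["ref"].length_of(ref_id))
        spots = hs.call_hotspots(profile, h["window"], h["min_fold"], h["min_share"])
        called[ref_id] = spots
        hs.write_profile_tsv(profile, out / f"{name}_{ref_id}_profile.tsv")
        outputs.append(out / f"{name}_{ref_id}_profile.tsv")
    all_spots = [s for spots in called.values() for s in spots]
    hs.write_hotspots_tsv(all_spots, out / "hotspots.tsv")
    outputs.append(out / "hotspots.tsv")
    state["called_hotspots"] = all_spots
    report["metrics"]["hotspots"] = {
        ref_id: [s.coordinate for s in spots] for ref_id, spots in called.items()
    }
    report["stages"]["hotspots"] = {"sample": name, "seconds": round(time.time() - t0, 2)}


def _stage_design(cfg, out, state, report, outputs) -> None:
    t0 = time.time()
    d = cfg["design"]
    ref: ReferenceSet = state["ref"]
    designs: list[pr.PrimerCandidate] = []
    for rec in ref.by_class("rRNA"):
        designs.append(pr.design_3prime_blocker(rec.sequence, d["length"], target_ref=rec.ref_id))
    for spot in state.get("called_hotspots", []):
        res = pr.design_hotspot_blocker(
            ref[spot.ref_id].sequence, spot.coordinate,
            offset=d["offset"], length=d["length"], tm_min=d["tm_min"],
            target_ref=spot.ref_id,
        )
        if res.accepted:
            designs.append(res.candidate)
        else:
            logger.warning("no Tm-satisfying blocker for %s:%d (best %.1f C)",
                           spot.ref_id, spot.coordinate, res.candidate.tm)
    pr.write_primers_tsv(designs, out / "primers.tsv")
    outputs.append(out / "primers.tsv")
    report["stages"]["design"] = {"n_primers": len(designs),
                                  "seconds": round(time.time() - t0, 2)}


def _stage_operon(cfg, out, report, outputs) -> None:
    t0 = time.time()
    o = cfg["operon_bias"]
    alns = al.read_sam(o["sam"])
    operons = opn.read_operon_table(o["operon_table"])
    profile = opn.operon_profile(alns, operons, nbins=int(o["nbins"]),
                                 min_genes=int(o["min_genes"]), min_reads=int(o["min_reads"]))
    opn.write_profile_tsv(profile, out / "operon_bias.tsv")
    outputs.append(out / "operon_bias.tsv")
    report["metrics"]["operon_bias_n_operons"] = profile.n_operons_used
    report["stages"]["operon_bias"] = {"seconds": round(time.time() - t0, 2)}
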