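"""End-to-end orchestration: simulate/load -> align -> classify -> junctions
-> copy number (-> walk), with machine-readable reports.

Every stage consumes and produces documented text formats (FASTA, FASTQ,
SAM, TSV, JSON), so a run can be resumed from any stage's outputs or fed
with externally produced alignments.  Runs are deterministic given the
config seed; the ``threads`` option exists for interface compatibility and
never changes results.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import yaml

from . import synth
from .align import PairAlignment, ReferenceIndex, align_pair
from .classify import ClassCounts, InformativeClass, PairClassifier, count_classes, nominate_integration_contigs
from .depth import copy_table, depth_profile, normalize_depth
from .junctions import (
    JunctionCall,
    call_junctions,
    extract_softclips,
    junctions_to_frame,
    match_junctions,
    realign_clips,
)
from .records import GenomeSet, write_fastq_pairs, read_fastq_pairs
from .samio import write_sam

logger = logging.getLogger("insertmap")

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 1,
    "scenario": "default",  # "default", "walk", or a path to a scenario YAML
    "coverage": 30.0,
    "read_len": 150,
    "insert_mean": 500.0,
    "insert_sd": 50.0,
    "error_rate": 0.0,
    "min_clip": 20,
    "min_support": 3,
    "position_tolerance": 2,
    "depth_window": 500,
    "k": 21,
    "compare_truth": True,
    "threads": 1,
}


@dataclass
class RunReport:
    config: dict
    class_counts: dict
    nominated_contigs: list[str]
    junctions: list[dict]
    copy_calls: list[dict]
    truth_metrics: dict | None = None

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(self.__dict__, indent=2, default=str)
        if path is not None:
            Path(path).write_text(payload)
        return payload


def load_config(config: dict | str | Path) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh) or {}
    merged = dict(DEFAULT_CONFIG)
    merged.update(config)
    return merged


def align_all(
    read_pairs: list[tuple[str, str, str]],
    index: ReferenceIndex,
    insert_mean: float = 500.0,
    insert_sd: float = 50.0,
) -> list[PairAlignment]:
    lo = max(50, int(insert_mean - 5 * insert_sd))
    hi = int(insert_mean + 5 * insert_sd)
    return [
        align_pair(s1, s2, index, read_id=rid, insert_min=lo, insert_max=hi)
        for rid, s1, s2 in read_pairs
    ]


def primary_alignments(pairs: list[PairAlignment]):
    out = []
    for p in pairs:
        if p.primary1:
            out.append(p.primary1)
        if p.primary2:
            out.append(p.primary2)
    return out


def discover(
    reference: GenomeSet,
    read_pairs: list[tuple[str, str, str]],
    cfg: dict,
) -> tuple[ClassCounts, list[str], list[JunctionCall], list, list[PairAlignment]]:
    """Core discovery chain on in-memory inputs; returns
    (class counts, nominations, junction calls, normalized depth profiles,
    aligned pairs)."""
    index = ReferenceIndex(reference.records, k=cfg["k"])
    aligned = align_all(read_pairs, index, cfg["insert_mean"], cfg["insert_sd"])
    classifier = PairClassifier(index, min_clip=cfg["min_clip"])
    classified = [(p, classifier.classify_pair(p)) for p in aligned]
    counts = count_classes(classified, index)
    nominations = nominate_integration_contigs(counts, min_support=cfg["min_support"])

    primaries = primary_alignments(aligned)
    clips = extract_softclips(primaries, min_clip=cfg["min_clip"])
    candidates = realign_clips(
        clips, reference.records, min_clip=cfg["min_clip"], index=classifier._clip_index
    )
    calls = call_junctions(
        candidates,
        min_support=cfg["min_support"],
        position_tolerance=cfg["position_tolerance"],
        min_self_distance=cfg["read_len"],
    )

    profiles = [
        depth_profile(primaries, rec, window=cfg["depth_window"]) for rec in reference
    ]
    profiles = normalize_depth(profiles)
    return counts, nominations, calls, profiles, aligned


def run_discovery(config: dict | str | Path, outdir: str | Path) -> RunReport:
    """Execute the full pipeline per config and write every intermediate.

    The config either names a simulation scenario (with truth comparison) or
    points at existing FASTA/FASTQ inputs."""
    cfg = load_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()

    truth = None
    features = []
    if "inputs" in cfg:
        inputs = cfg["inputs"]
        for key in ("reference_fasta", "fastq_r1", "fastq_r2"):
            if key not in inputs or not Path(inputs[key]).exists():
                raise FileNotFoundError(f"input {key!r} missing or not found: {inputs.get(key)}")
        reference = GenomeSet.read_fasta(inputs["reference_fasta"])
        read_pairs = read_fastq_pairs(inputs["fastq_r1"], inputs["fastq_r2"])
    else:
        name = cfg.get("scenario", "default")
        if name == "default":
            scenario = synth.default_scenario(cfg["seed"])
        elif name == "walk":
            scenario = synth.walk_scenario(cfg["seed"])
        else:
            scenario = synth.build_scenario(
                synth.ScenarioConfig.from_yaml(name), cfg["seed"]
            )
        reference = scenario.reference
        truth = scenario.truth
        # GS is excluded: its sequence is shared with the host homolog, so
        # depth on the construct copy is not meaningful (see depth module)
        features = [
            f for f in reference.features if f.label in ("HC", "LC", "amplified-region")
        ]
        read_pairs = synth.simulate_reads(
            scenario.integrant,
            coverage=cfg["coverage"],
            read_len=cfg["read_len"],
            insert_mean=cfg["insert_mean"],
            insert_sd=cfg["insert_sd"],
            error_rate=cfg["error_rate"],
            seed=cfg["seed"],
        )
        reference.write_fasta(outdir / "reference.fasta")
        write_fastq_pairs(read_pairs, outdir / "reads_R1.fastq", outdir / "reads_R2.fastq")
    logger.info("inputs ready in %.1fs", time.time() - t0)

    t1 = time.time()
    counts, nominations, calls, profiles, aligned = discover(reference, read_pairs, cfg)
    logger.info("discovery stages done in %.1fs", time.time() - t1)

    write_sam(aligned, reference.records, outdir / "alignments.sam")
    counts.to_frame().to_csv(outdir / "class_counts.tsv", sep="\t", index=False)
    counts.support_frame().to_csv(outdir / "contig_support.tsv", sep="\t", index=False)
    junctions_to_frame(calls).to_csv(outdir / "junctions.tsv", sep="\t", index=False)
    import pandas as pd

    pd.concat([p.to_frame() for p in profiles]).to_csv(
        outdir / "depth.tsv", sep="\t", index=False
    )
    copies_df = copy_table(profiles, features) if features else None
    copy_calls: list[dict] = []
    if copies_df is not None:
        copies_df.to_csv(outdir / "copy_calls.tsv", sep="\t", index=False)
        copy_calls = copies_df.to_dict("records")

    truth_metrics = None
    if truth is not None and cfg.get("compare_truth", True):
        truth_metrics = compare_to_truth(calls, truth, cfg["position_tolerance"], copy_calls)

    report = RunReport(
        config={k: v for k, v in cfg.items() if k != "inputs"},
        class_counts={
            cls.value: counts.pair_counts.get(cls, 0) for cls in InformativeClass
        },
        nominated_contigs=nominations,
        junctions=junctions_to_frame(calls).to_dict("records"),
        copy_calls=copy_calls,
        truth_metrics=truth_metrics,
    )
    report.to_json(outdir / "report.json")
    logger.info("run complete: %s pairs, %s junction calls", counts.total, len(calls))
    return report


def compare_to_truth(
    calls: list[JunctionCall],
    truth: synth.TruthSet,
    tolerance: int = 0,
    copy_calls: list[dict] | None = None,
) -> dict:
    """Junction precision/recall at a positional tolerance plus copy-call
    exact-match fraction."""
    if not truth.junctions:
        raise ValueError("truth junction list is empty")
    metrics = match_junctions(calls, truth.junctions, tolerance=tolerance)
    if copy_calls:
        expected = truth.cassette_copies
        scored = [c for c in copy_calls if c["label"] in expected]
        if scored:
            hits = sum(1 for c in scored if c["copies"] == expected[c["label"]])
            metrics["copy_call_accuracy"] = hits / len(scored)
    return metrics
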