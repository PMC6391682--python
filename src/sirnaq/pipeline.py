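"""Manifest-driven end-to-end runs: trim -> align -> quantify -> clusters -> hairpin.

A run manifest (YAML) lists samples with group/replicate labels and
FASTQ (or externally mapped SAM) inputs, reference and annotation paths,
and optional parameter overrides.  All tabular outputs are sorted
deterministically, so re-running an unchanged manifest reproduces
byte-identical results.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from . import alignment as aln_mod
from . import clusters as cl_mod
from . import hairpin as hp_mod
from . import quantify as q_mod
from .read_prep import TrimConfig, TrimReport, read_fastq, trim_reads


@dataclass
class SampleSpec:
    sample_id: str
    group: str
    replicate: int
    fastq: Optional[str] = None
    sam: Optional[str] = None


@dataclass
class RunManifest:
    samples: list[SampleSpec]
    genome: str
    plasmids: list[str] = field(default_factory=list)
    mirna_gff3: Optional[str] = None
    exons_gff3: Optional[str] = None
    repeats_bed: Optional[str] = None
    misc_gff3: Optional[str] = None
    hairpins: list[str] = field(default_factory=list)
    params: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunManifest":
        with open(path) as handle:
            data = yaml.safe_load(handle)
        return cls.from_dict(data, base=Path(path).parent)

    @classmethod
    def from_dict(cls, data: dict, base: Optional[Path] = None) -> "RunManifest":
        def resolve(p):
            if p is None:
                return None
            p = Path(p)
            return str(p if p.is_absolute() or base is None else base / p)

        samples = [
            SampleSpec(
                sample_id=str(s["sample_id"]), group=str(s.get("group", "")),
                replicate=int(s.get("replicate", 1)),
                fastq=resolve(s.get("fastq")), sam=resolve(s.get("sam")),
            )
            for s in data.get("samples", [])
        ]
        ref = data.get("reference", {})
        annot = data.get("annotations", {})
        return cls(
            samples=samples,
            genome=resolve(ref.get("genome")),
            plasmids=[resolve(p) for p in ref.get("plasmids", [])],
            mirna_gff3=resolve(annot.get("mirna_gff3")),
            exons_gff3=resolve(annot.get("exons_gff3")),
            repeats_bed=resolve(annot.get("repeats_bed")),
            misc_gff3=resolve(annot.get("misc_gff3")),
            hairpins=[resolve(p) for p in data.get("hairpins", [])],
            params=dict(data.get("params", {})),
        )


def validate_manifest(manifest: RunManifest) -> list[str]:
    """Existence, uniqueness and parameter-range checks; [] when valid."""
    issues: list[str] = []
    ids = [s.sample_id for s in manifest.samples]
    if not ids:
        issues.append("manifest lists no samples")
    dupes = {i for i in ids if ids.count(i) > 1}
    if dupes:
        issues.append(f"duplicate sample_id(s): {sorted(dupes)}")
    for s in manifest.samples:
        if (s.fastq is None) == (s.sam is None):
            issues.append(f"sample {s.sample_id!r}: exactly one of fastq/sam required")
        if s.replicate < 1:
            issues.append(f"sample {s.sample_id!r}: replicate must be >= 1")
        for path in (s.fastq, s.sam):
            if path is not None and not Path(path).exists():
                issues.append(f"sample {s.sample_id!r}: missing input file {path}")
    if manifest.genome is None:
        issues.append("reference.genome is required")
    for label, path in [("reference.genome", manifest.genome),
                        *[(f"reference.plasmids[{i}]", p)
                          for i, p in enumerate(manifest.plasmids)],
                        ("annotations.mirna_gff3", manifest.mirna_gff3),
                        ("annotations.exons_gff3", manifest.exons_gff3),
                        ("annotations.repeats_bed", manifest.repeats_bed),
                        ("annotations.misc_gff3", manifest.misc_gff3),
                        *[(f"hairpins[{i}]", p)
                          for i, p in enumerate(manifest.hairpins)]]:
        if path is not None and not Path(path).exists():
            issues.append(f"{label}: missing file {path}")
    params = manifest.params
    if params.get("rpm_threshold", 3.0) <= 0:
        issues.append("params.rpm_threshold must be > 0")
    if params.get("join_distance", 50) < 0:
        issues.append("params.join_distance must be >= 0")
    if params.get("min_length", 15) < 1:
        issues.append("params.min_length must be >= 1")
    return issues


def _cluster_params(params: dict) -> cl_mod.ClusterParams:
    return cl_mod.ClusterParams(
        read_lengths=tuple(params.get("read_lengths", (21, 23))),
        rpm_threshold=float(params.get("rpm_threshold", 3.0)),
        join_distance=int(params.get("join_distance", 50)),
        log_floor=float(params.get("log_floor", 0.1)),
    )


def _trim_config(params: dict) -> TrimConfig:
    kwargs = {k: params[k] for k in
              ("adapter", "min_match_full", "min_match_end", "max_mismatch_full",
               "force_trim_5p", "force_trim_3p", "min_length") if k in params}
    return TrimConfig(**kwargs)


def run_pipeline(manifest: RunManifest, out_dir) -> Path:
    """Execute the full pipeline for a validated manifest.

    Output tree: per-sample trim reports, alignment TSVs and length
    histograms under ``samples/``; per-group intersected clusters and the
    merged, annotated cluster set under ``clusters/``; per-hairpin
    density/phasing/length tables under ``hairpin/``; a machine-readable
    ``run_log.json``.
    """
    issues = validate_manifest(manifest)
    if issues:
        raise ValueError("invalid manifest:\n" + "\n".join(f"- {i}" for i in issues))
    out = Path(out_dir)
    (out / "samples").mkdir(parents=True, exist_ok=True)
    (out / "clusters").mkdir(exist_ok=True)
    log: dict = {"params": manifest.params, "samples": {}, "stages": []}

    reference = aln_mod.build_reference(manifest.genome, manifest.plasmids)
    annotations = q_mod.AnnotationSet.from_files(
        mirna_gff3=manifest.mirna_gff3, exons_gff3=manifest.exons_gff3,
        repeats_bed=manifest.repeats_bed, misc_gff3=manifest.misc_gff3,
    )
    trim_cfg = _trim_config(manifest.params)
    params = _cluster_params(manifest.params)

    libraries: list[q_mod.SmallRnaLibrary] = []
    for sample in manifest.samples:
        try:
            if sample.fastq is not None:
                report = TrimReport()
                trimmed = list(trim_reads(read_fastq(sample.fastq), trim_cfg, report))
                library = aln_mod.align_library(
                    trimmed, reference, sample_id=sample.sample_id,
                    group=sample.group, replicate=sample.replicate)
                sample_log = {"n_input": report.n_input,
                              "n_adapter_trimmed": report.n_adapter_trimmed,
                              "n_discarded": report.n_discarded,
                              "n_retained": report.n_retained}
            else:
                aligns, sam_report = aln_mod.import_sam(sample.sam, reference)
                denominator = len({a.read_id for a in aligns})
                library = q_mod.SmallRnaLibrary(
                    sample_id=sample.sample_id, group=sample.group,
                    replicate=sample.replicate, alignments=aligns,
                    denominator=denominator)
                sample_log = {"trim": "skipped (SAM input)", **sam_report}
        except Exception as exc:
            raise RuntimeError(
                f"stage 'trim/align' failed for sample {sample.sample_id!r}: {exc}"
            ) from exc
        sample_log["denominator"] = library.denominator
        log["samples"][sample.sample_id] = sample_log
        libraries.append(library)
        sorted_alns = sorted(library.alignments,
                             key=lambda a: (a.contig, a.start, a.end, a.read_id))
        aln_mod.write_alignments(
            sorted_alns, out / "samples" / f"{sample.sample_id}.alignments.tsv",
            header_meta={"sample_id": sample.sample_id, "group": sample.group,
                         "replicate": sample.replicate,
                         "denominator": library.denominator})
        hist = q_mod.length_histogram(library, length_range=(15, 30))
        pd.DataFrame(sorted(hist.items()), columns=["length", "rpm"]).to_csv(
            out / "samples" / f"{sample.sample_id}.length_hist.tsv",
            sep="\t", index=False)

    # per-group cluster calling with replicate intersection
    groups = sorted({lib.group for lib in libraries})
    group_clusters: dict[str, list[cl_mod.Cluster]] = {}
    for group in groups:
        replicate_sets = [cl_mod.call_sample_clusters(lib, params)
                          for lib in libraries if lib.group == group]
        group_clusters[group] = cl_mod.intersect_replicates(replicate_sets)
        log["stages"].append({"stage": "clusters", "group": group,
                              "n_intersected": len(group_clusters[group])})

    merged = cl_mod.merge_between_samples(group_clusters, libraries, params)
    rows = []
    for cluster in merged:
        category = cl_mod.annotate_cluster(cluster, annotations)
        rows.append({
            "contig": cluster.contig, "start": cluster.start, "end": cluster.end,
            "category": category,
            "median_log10_rpm": round(cl_mod.summarize_cluster(cluster, params.log_floor), 6),
            **{f"rpm_{s}": round(v, 6)
               for s, v in sorted(cluster.sample_rpms.items())},
        })
    cluster_frame = pd.DataFrame(rows)
    cluster_frame.to_csv(out / "clusters" / "clusters_merged.tsv", sep="\t", index=False)
    (out / "clusters" / "clusters_merged.bed").write_text(
        cl_mod.clusters_to_bed(merged, params.log_floor))
    log["stages"].append({"stage": "merge", "n_merged": len(merged)})

    # repeat-class aggregation per sample
    if manifest.repeats_bed:
        tables = {lib.sample_id: q_mod.aggregate_by_repeat_class(lib, annotations)
                  for lib in libraries}
        repeat_frame = pd.DataFrame(tables).fillna(0.0).sort_index()
        repeat_frame.round(6).to_csv(out / "clusters" / "repeat_class_rpm.tsv", sep="\t")
        if len(groups) == 2:
            frames = {
                g: pd.DataFrame({lib.sample_id: tables[lib.sample_id]
                                 for lib in libraries if lib.group == g}).fillna(0.0)
                for g in groups
            }
            if all(f.shape[1] >= 2 for f in frames.values()):
                q_mod.compare_groups(frames[groups[0]], frames[groups[1]]).round(6).to_csv(
                    out / "clusters" / "repeat_class_test.tsv", sep="\t")

    # hairpin profiling
    if manifest.hairpins:
        (out / "hairpin").mkdir(exist_ok=True)
        for hp_path in manifest.hairpins:
            spec = hp_mod.HairpinSpec.from_yaml(hp_path)
            stem = Path(hp_path).stem
            for lib in libraries:
                prefix = out / "hairpin" / f"{stem}.{lib.sample_id}"
                up, dn = hp_mod.arm_density(lib, spec)
                pd.DataFrame({"position": up.positions,
                              "up_cpm": up.cpm.round(6),
                              "down_cpm": dn.cpm.round(6)}).to_csv(
                    f"{prefix}.density.tsv", sep="\t", index=False)
                prof = hp_mod.phasing_profile(lib, spec)
                pd.DataFrame({"register": range(1, prof.period + 1),
                              "proportion": prof.proportions.round(6)}).to_csv(
                    f"{prefix}.phasing.tsv", sep="\t", index=False)
                lengths = hp_mod.hairpin_length_abundance(lib, spec)
                pd.DataFrame(sorted(lengths.items()),
                             columns=["length", "rpm"]).round(6).to_csv(
                    f"{prefix}.lengths.tsv", sep="\t", index=False)
        log["stages"].append({"stage": "hairpin", "n_specs": len(manifest.hairpins)})

    with open(out / "run_log.json", "w") as handle:
        json.dump(log, handle, indent=2, sort_keys=True)
    return out
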