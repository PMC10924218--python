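"""End-to-end pipeline: simulate → assign/count → classify → image-quantify.

A single YAML config drives the full run; every output file is recorded in
a manifest JSON with its SHA-256 checksum, so reruns under the same config
and seed can be verified byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import pandas as pd
import tifffile
import yaml

from gvreprog import __version__
from gvreprog.containers import CountMatrix
from gvreprog.expression import (
    ClassificationConfig,
    call_inducible,
    classify_response,
    cluster_order,
    compute_tpm,
    correlate_groups,
    find_resistant,
    response_summary,
    top_expressed,
)
from gvreprog.hybrid import assign_reads, build_hybrid_reference, count_by_gene
from gvreprog.imaging import (
    WatershedParams,
    compare_chromatin_areas,
    hp1a_occupancy,
    huang_threshold,
    iterative_otsu,
    measure_chromatin_area,
    recursive_watershed,
)
from gvreprog.synthetic import (
    ExprSimConfig,
    ImgSimConfig,
    simulate_expression,
    simulate_image_pair,
    simulate_images,
    write_fixture_genome,
)

log = logging.getLogger("gvreprog")


@dataclass
class PipelineConfig:
    """Flat run configuration; unknown sub-config keys raise."""

    outdir: str = "gvreprog_run"
    seed: int = 0
    stages: tuple[str, ...] = ("expression", "hybrid", "imaging")
    expression_sim: dict = field(default_factory=dict)
    image_sim: dict = field(default_factory=dict)
    classification: dict = field(default_factory=dict)
    watershed: dict = field(default_factory=dict)
    count_table: str | None = None  # precomputed counts TSV (skips simulation)
    sample_metadata: str | None = None
    pixel_size_um: float = 1.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    def validate(self) -> None:
        valid = {"expression", "hybrid", "imaging"}
        bad = set(self.stages) - valid
        if bad:
            raise ValueError(f"unknown stages: {sorted(bad)}")
        if "expression" in self.stages and self.count_table is not None:
            if self.sample_metadata is None:
                raise ValueError("count_table given without sample_metadata")
            for p in (self.count_table, self.sample_metadata):
                if not Path(p).exists():
                    raise ValueError(f"missing input: {p}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_json(path: Path, payload) -> None:
    path.write_text(json.dumps(payload, indent=1, sort_keys=True, default=str))


def _run_expression(cfg: PipelineConfig, outdir: Path, files: list[Path]) -> None:
    clf = ClassificationConfig(**cfg.classification)
    if cfg.count_table is not None:
        cm = CountMatrix.from_tsv(cfg.count_table, cfg.sample_metadata)
    else:
        sim = ExprSimConfig(**{"seed": cfg.seed, **cfg.expression_sim})
        cm, truth = simulate_expression(sim)
        truth.to_json(outdir / "expression_truth.json")
        files.append(outdir / "expression_truth.json")
    cm.to_tsv(outdir / "counts.tsv", outdir / "sample_metadata.tsv")
    files += [outdir / "counts.tsv", outdir / "sample_metadata.tsv"]

    expr = compute_tpm(cm)
    expr.to_tsv(outdir / "tpm.tsv")
    files.append(outdir / "tpm.tsv")

    cell_types = sorted(
        cm.metadata.loc[cm.metadata["condition"] == "NT", "cell_type"].unique()
    )
    inducible = call_inducible(expr, clf, cell_types)
    _write_json(
        outdir / "inducible_venn.json",
        {"sizes": inducible.sizes, "union": len(inducible.union), "venn": inducible.venn},
    )
    files.append(outdir / "inducible_venn.json")

    responses = {ct: classify_response(expr, clf, ct) for ct in cell_types}
    resp_all = pd.concat(responses.values())
    resp_all.to_csv(outdir / "response_table.tsv", sep="\t", index_label="gene_id")
    files.append(outdir / "response_table.tsv")
    summary = pd.DataFrame({ct: response_summary(r) for ct, r in responses.items()})
    summary.to_csv(outdir / "response_summary.tsv", sep="\t", index_label="class")
    files.append(outdir / "response_summary.tsv")

    resistant = find_resistant(expr, responses, clf)
    _write_json(
        outdir / "resistant_genes.json",
        {ct: sorted(genes) for ct, genes in resistant.items()},
    )
    files.append(outdir / "resistant_genes.json")

    correlations = {}
    for ct in cell_types:
        try:
            correlations[f"{ct}_donor_vs_NT"] = correlate_groups(
                expr,
                {"cell_type": ct, "condition": "donor"},
                {"cell_type": ct, "condition": "NT"},
                clf,
            )
            correlations[f"{ct}_NT_24h_vs_48h"] = correlate_groups(
                expr,
                {"cell_type": ct, "condition": "NT", "timepoint": "24h"},
                {"cell_type": ct, "condition": "NT", "timepoint": "48h"},
                clf,
            )
        except ValueError:
            # a condition or timepoint absent from real-data imports
            continue
    _write_json(outdir / "correlations.json", correlations)
    files.append(outdir / "correlations.json")

    # heatmap export: top expressed genes in the last cell type's NT
    # samples, log2(TPM+1), rows/columns in clustering leaf order
    focus = cell_types[-1]
    top = top_expressed(expr, focus, "NT", n=min(1500, len(expr.genes)), cfg=clf)
    sample_order, gene_order = cluster_order(expr, top, clf)
    heat = clf.log(expr.tpm.loc[gene_order, sample_order])
    heat.to_csv(outdir / "heatmap_matrix.tsv", sep="\t", index_label="gene_id",
                float_format="%.4f")
    files.append(outdir / "heatmap_matrix.tsv")
    _write_json(
        outdir / "heatmap_orders.json",
        {"focus_cell_type": focus, "samples": list(sample_order), "genes": list(gene_order)},
    )
    files.append(outdir / "heatmap_orders.json")


def _run_hybrid(cfg: PipelineConfig, outdir: Path, files: list[Path]) -> None:
    fixdir = outdir / "fixture"
    paths = write_fixture_genome(fixdir, seed=cfg.seed)
    files += [paths.fasta_a, paths.fasta_b, paths.gtf_a, paths.gtf_b, paths.fastq]
    ref = build_hybrid_reference(paths.fasta_a, paths.fasta_b, paths.gtf_a, paths.gtf_b)
    # pyfaidx leaves .fai indexes beside the FASTAs; account for them
    files += [Path(str(paths.fasta_a) + ".fai"), Path(str(paths.fasta_b) + ".fai")]
    assignment = assign_reads(paths.fastq, ref)
    meta = pd.DataFrame(
        {
            "cell_type": ["MEF"],
            "condition": ["NT"],
            "timepoint": ["24h"],
            "replicate": [1],
            "female_id": ["F1"],
        },
        index=pd.Index(["fixture_s1"], name="sample_id"),
    )
    cm, summary = count_by_gene({"fixture_s1": assignment}, ref, meta)
    cm.to_tsv(outdir / "fixture_counts.tsv", outdir / "fixture_metadata.tsv")
    summary.to_csv(outdir / "species_summary.tsv", sep="\t", index_label="sample_id")
    files += [
        outdir / "fixture_counts.tsv",
        outdir / "fixture_metadata.tsv",
        outdir / "species_summary.tsv",
    ]
    # accuracy vs the truth encoded in read names
    truth = assignment.table.index.str.split("|", expand=True)
    truth_species = truth.get_level_values(1).map({"A": "species_A", "B": "species_B"})
    truth_gene = truth.get_level_values(2)
    correct = (
        (assignment.table["label"].values == truth_species.values)
        & (assignment.table["gene_id"].values == truth_gene.values)
    ).mean()
    _write_json(outdir / "assignment_accuracy.json", {"accuracy": float(correct)})
    files.append(outdir / "assignment_accuracy.json")


def _analyze_image(img, ws: WatershedParams, pixel_size_um: float):
    dna, hp1 = img[0], img[1]
    t_huang = huang_threshold(dna)
    seg = recursive_watershed(dna > t_huang, ws)
    part = iterative_otsu(dna)  # background cut is iteration 1
    occ = hp1a_occupancy(part.class_map, hp1)
    areas = measure_chromatin_area(seg, part.class_map, pixel_size_um)
    report = {
        "huang_threshold": int(t_huang),
        "otsu_thresholds": list(part.thresholds),
        "n_segments": len(seg.segments),
        "n_unresolved": len(seg.unresolved),
        "hp1_occupancy": {str(k): v for k, v in occ.occupancy.items()},
        "hp1_threshold": occ.threshold,
    }
    return seg, areas, report


def _segment_table(seg, pixel_size_um: float) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "label": [s.label for s in seg.segments],
            "area_px": [s.area_px for s in seg.segments],
            "area_um2": [s.area_um2(pixel_size_um) for s in seg.segments],
            "depth": [s.extraction_depth for s in seg.segments],
        }
    )


def _run_imaging(cfg: PipelineConfig, outdir: Path, files: list[Path]) -> None:
    sim = ImgSimConfig(**{"seed": cfg.seed, **cfg.image_sim})
    ws = WatershedParams(**cfg.watershed)
    results = {}

    # clustered single-timepoint set: segmentation, density, occupancy
    images, _truths = simulate_images(sim)
    for i, img in enumerate(images):
        tiff_path = outdir / f"image_{i}.tif"
        tifffile.imwrite(tiff_path, img)
        files.append(tiff_path)
        seg, _areas, report = _analyze_image(img, ws, cfg.pixel_size_um)
        _segment_table(seg, cfg.pixel_size_um).to_csv(
            outdir / f"segments_{i}.tsv", sep="\t", index=False
        )
        files.append(outdir / f"segments_{i}.tsv")
        results[f"image_{i}"] = report

    # cluster-free paired set for the 0h vs 24h chromatin-area change;
    # both groups use one widened gate that admits dispersed nuclei
    pair_sim = replace(sim, cluster_spec=())
    ws_pair = replace(ws, max_area=int(ws.max_area * max(sim.dispersal_factor, 1.0)) + 1)
    pair = simulate_image_pair(pair_sim)
    areas = {}
    for tp in ("0h", "24h"):
        tp_areas: list[float] = []
        for i, img in enumerate(pair[tp][0]):
            tiff_path = outdir / f"image_pair_{tp}_{i}.tif"
            tifffile.imwrite(tiff_path, img)
            files.append(tiff_path)
            seg, seg_areas, report = _analyze_image(img, ws_pair, cfg.pixel_size_um)
            tp_areas += seg_areas
            results[f"pair_{tp}_{i}"] = report
        areas[tp] = tp_areas
    results["area_comparison"] = compare_chromatin_areas(areas["0h"], areas["24h"])
    _write_json(outdir / "imaging_results.json", results)
    files.append(outdir / "imaging_results.json")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages and write a checksummed run manifest."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    # run.log mirrors stderr logging; timestamp-free so reruns match
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    files: list[Path] = []
    try:
        if "expression" in config.stages:
            log.info("running expression stage")
            _run_expression(config, outdir, files)
        if "hybrid" in config.stages:
            log.info("running hybrid-reference stage")
            _run_hybrid(config, outdir, files)
        if "imaging" in config.stages:
            log.info("running imaging stage")
            _run_imaging(config, outdir, files)
    finally:
        log.removeHandler(handler)
        handler.close()
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "stages": list(config.stages),
        "config": asdict(config),
        "outputs": {str(p.relative_to(outdir)): _sha256(p) for p in sorted(set(files))},
    }
    _write_json(outdir / "manifest.json", manifest)
    return manifest
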