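"""End-to-end orchestration: annotate -> classify-habitat -> screen ->
cluster -> localization, driven by one YAML config, with a JSON run manifest.

The manifest records, for every stage, the outputs written with content
checksums, the parameters actually used (config after default-filling — no
hidden defaults), and any warnings raised. A stage failure aborts the run
with the stage name and cause; outputs already written are retained and a
FAILED marker file is left in the output directory.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .annotation import (
    DEFAULT_EVALUE_MAX,
    PresenceMatrix,
    annotation_fraction,
    assign_best_hits,
    build_presence_matrix,
)
from .clustering import cluster_profiles, filter_informative, partition_agreement
from .habitat import CatalogFilterParams, classify_habitat
from .io_formats import (
    Habitat,
    read_alignment_table,
    read_annotation_table,
    read_genome_metadata,
    read_length_table,
)
from .localization import cohort_summary, correlation_panel
from .io_formats import read_localization_table
from .screen import (
    DEFAULT_DELTA_MIN,
    category_composition,
    count_representation,
    distribution_grid,
    group_by_description,
    group_presence,
    screen_matrix,
)

logger = logging.getLogger("gutnog")

__all__ = ["RunConfig", "run_pipeline"]

_PARAM_DEFAULTS: dict[str, Any] = {
    "evalue_max": DEFAULT_EVALUE_MAX,
    "min_identity": 95.0,
    "min_coverage": 0.90,
    "gut_min_fraction": 5.0,
    "nongut_max_fraction": 0.5,
    "delta_min": DEFAULT_DELTA_MIN,
    "informative_min": 2,
    "informative_max": None,  # None -> n - 1
    "distance": "euclidean_binary",
    "linkage": "complete",
    "cut_k": 2,
}


@dataclass
class RunConfig:
    """Validated pipeline configuration.

    ``inputs`` must name genomes, hits_dir and annotations; localization and
    the catalog trio (catalog_dir, catalog_lengths, gene counts come from
    genome metadata) are optional — stages without inputs are skipped and
    marked as such in the manifest.
    """

    inputs: dict[str, str]
    output_dir: str
    params: dict[str, Any] = field(default_factory=dict)
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        for required in ("genomes", "hits_dir", "annotations"):
            if required not in self.inputs:
                raise ValueError(f"config inputs must include {required!r}")
        filled = dict(_PARAM_DEFAULTS)
        unknown = set(self.params) - set(filled)
        if unknown:
            raise ValueError(f"unknown parameters in config: {sorted(unknown)}")
        filled.update(self.params)
        self.params = filled
        if self.params["nongut_max_fraction"] >= self.params["gut_min_fraction"]:
            raise ValueError(
                "nongut_max_fraction must be below gut_min_fraction "
                f"({self.params['nongut_max_fraction']} >= {self.params['gut_min_fraction']})"
            )
        CatalogFilterParams(
            min_identity=self.params["min_identity"],
            min_coverage=self.params["min_coverage"],
            gut_min_fraction=self.params["gut_min_fraction"],
            nongut_max_fraction=self.params["nongut_max_fraction"],
        )
        if self.params["evalue_max"] <= 0:
            raise ValueError("evalue_max must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides: Any) -> "RunConfig":
        with open(path, encoding="utf-8") as handle:
            raw = yaml.safe_load(handle) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    digest.update(path.read_bytes())
    return digest.hexdigest()


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Run all stages in dependency order; return (and write) the manifest."""
    logging.basicConfig(level=config.log_level, format="%(name)s: %(message)s")
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    failed_marker = out / "FAILED"
    if failed_marker.exists():
        failed_marker.unlink()

    manifest: dict[str, Any] = {
        "parameters": dict(config.params),
        "seed": config.seed,
        "inputs": dict(config.inputs),
        "stages": [],
    }

    genomes = read_genome_metadata(config.inputs["genomes"])
    state: dict[str, Any] = {"genomes": genomes}

    stages = [
        ("annotate", _stage_annotate),
        ("classify-habitat", _stage_classify_habitat),
        ("screen", _stage_screen),
        ("cluster", _stage_cluster),
        ("localization", _stage_localization),
    ]
    for name, stage in stages:
        entry: dict[str, Any] = {"stage": name, "status": "PASSED", "outputs": {}, "warnings": []}
        logger.info("stage %s: starting", name)
        try:
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                outputs = stage(config, state, out)
            entry["warnings"] = [str(w.message) for w in caught]
            if outputs is None:
                entry["status"] = "SKIPPED"
            else:
                entry["outputs"] = {k: {"path": str(p), "sha256": _sha256(p)} for k, p in outputs.items()}
        except Exception as exc:
            entry["status"] = "FAILED"
            entry["error"] = str(exc)
            manifest["stages"].append(entry)
            failed_marker.write_text(f"stage {name}: {exc}\n", encoding="utf-8")
            _write_manifest(out, manifest)
            raise RuntimeError(f"stage {name} failed: {exc}") from exc
        manifest["stages"].append(entry)
        logger.info("stage %s: %s", name, entry["status"])

    _write_manifest(out, manifest)
    return manifest


def _write_manifest(out: Path, manifest: dict[str, Any]) -> None:
    with open(out / "manifest.json", "w", encoding="utf-8") as handle:
        json.dump(manifest, handle, indent=2, sort_keys=True)
        handle.write("\n")


def _stage_annotate(config: RunConfig, state: dict[str, Any], out: Path) -> dict[str, Path]:
    hits_dir = Path(config.inputs["hits_dir"])
    evalue_max = config.params["evalue_max"]
    assignments = []
    summaries = []
    for genome in state["genomes"]:
        hits_path = hits_dir / f"{genome.genome_id}.hits.tsv"
        if not hits_path.exists():
            raise FileNotFoundError(f"no hits table for genome {genome.genome_id!r} at {hits_path}")
        hits = read_alignment_table(hits_path)
        genome_assignments = assign_best_hits(hits, genome.genome_id, evalue_max=evalue_max)
        assignments.extend(genome_assignments)
        summaries.append(annotation_fraction(genome_assignments, genome))
    matrix = build_presence_matrix(assignments, state["genomes"])
    state["matrix"] = matrix
    matrix_path = out / "presence_matrix.tsv"
    matrix.write(matrix_path)
    summary_path = out / "annotation_summary.tsv"
    with open(summary_path, "w", encoding="utf-8") as handle:
        handle.write("genome_id\tn_assigned\tfraction_assigned\n")
        for s in summaries:
            handle.write(f"{s.genome_id}\t{s.n_assigned}\t{s.fraction_assigned}\n")
    return {"matrix": matrix_path, "summary": summary_path}


def _stage_classify_habitat(config: RunConfig, state: dict[str, Any], out: Path) -> dict[str, Path] | None:
    catalog_dir = config.inputs.get("catalog_dir")
    lengths_path = config.inputs.get("catalog_lengths")
    if catalog_dir is None:
        logger.info("stage classify-habitat: no catalog inputs configured")
        return None
    if lengths_path is None:
        raise ValueError("catalog_dir configured without catalog_lengths")
    lengths = read_length_table(lengths_path)
    params = CatalogFilterParams(
        min_identity=config.params["min_identity"],
        min_coverage=config.params["min_coverage"],
        gut_min_fraction=config.params["gut_min_fraction"],
        nongut_max_fraction=config.params["nongut_max_fraction"],
    )
    results = []
    for genome in state["genomes"]:
        path = Path(catalog_dir) / f"{genome.genome_id}.catalog.tsv"
        hits = read_alignment_table(path, lengths=lengths) if path.exists() else []
        results.append(
            classify_habitat(hits, genome.genome_id, genome.total_proteins, params)
        )
    out_path = out / "habitat_classification.tsv"
    with open(out_path, "w", encoding="utf-8") as handle:
        handle.write("genome_id\tn_genes\tn_matched\tfraction_matched\tlabel\n")
        for r in results:
            handle.write(
                f"{r.genome_id}\t{r.n_genes}\t{r.n_matched}\t{r.fraction_matched_display}\t{r.label.value}\n"
            )
    return {"classification": out_path}


def _write_records(path: Path, records, annotations_by_id, member_map=None) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        handle.write(
            "feature\tfunction\tcategories\tgut_count\tnongut_count\tdelta\tstatus\tgut_pct\tnongut_pct\n"
        )
        for r in records:
            ann = annotations_by_id.get(r.feature_id)
            if ann is not None:
                function = ann.description
                categories = "".join(sorted(ann.categories))
            elif member_map is not None:
                function = r.feature_id
                categories = "".join(sorted(member_map.get(r.feature_id, frozenset())))
            else:
                function, categories = "", ""
            handle.write(
                f"{r.feature_id}\t{function}\t{categories}\t{r.gut_count}\t{r.nongut_count}\t"
                f"{r.delta}\t{r.status.value}\t{r.gut_abundance_pct}\t{r.nongut_abundance_pct}\n"
            )


def _stage_screen(config: RunConfig, state: dict[str, Any], out: Path) -> dict[str, Path]:
    matrix: PresenceMatrix = state["matrix"]
    genomes = state["genomes"]
    delta_min = config.params["delta_min"]
    annotations = read_annotation_table(config.inputs["annotations"])
    annotations_by_id = {a.nog_id: a for a in annotations}

    nog_records = screen_matrix(matrix, genomes, delta_min=delta_min)
    nog_path = out / "screen_nog.tsv"
    _write_records(nog_path, nog_records, annotations_by_id)

    groups = group_by_description(annotations)
    with warnings.catch_warnings():
        # members that were never observed in any genome are expected here
        warnings.simplefilter("ignore")
        grouped = group_presence(matrix, groups)
    group_records = screen_matrix(grouped, genomes, delta_min=delta_min)
    # union of member categories for each description-level feature
    member_categories = {
        g.group_key: frozenset().union(
            *(annotations_by_id[n].categories for n in g.member_nogs if n in annotations_by_id)
        )
        for g in groups
    }
    group_path = out / "screen_groups.tsv"
    _write_records(group_path, group_records, {}, member_map=member_categories)

    counts = count_representation(matrix, genomes)
    n_gut = sum(1 for g in genomes if g.habitat is Habitat.GUT)
    n_nongut = sum(1 for g in genomes if g.habitat is Habitat.NON_GUT)
    grid = distribution_grid(counts, n_gut, n_nongut, exclude_singletons=True)
    grid_path = out / "distribution_grid.tsv"
    with open(grid_path, "w", encoding="utf-8") as handle:
        handle.write("gut_count\t" + "\t".join(str(j) for j in range(n_nongut + 1)) + "\n")
        for i, row in enumerate(grid.counts):
            handle.write(str(i) + "\t" + "\t".join(str(v) for v in row) + "\n")

    composition = category_composition(nog_records, annotations_by_id)
    composition_path = out / "category_composition.tsv"
    composition.to_csv(composition_path, sep="\t", index_label="status")

    state["nog_records"] = nog_records
    state["group_records"] = group_records
    return {
        "nog_records": nog_path,
        "group_records": group_path,
        "grid": grid_path,
        "composition": composition_path,
    }


def _stage_cluster(config: RunConfig, state: dict[str, Any], out: Path) -> dict[str, Path]:
    matrix: PresenceMatrix = state["matrix"]
    informative = filter_informative(
        matrix,
        min_genomes=config.params["informative_min"],
        max_genomes=config.params["informative_max"],
    )
    result = cluster_profiles(
        informative,
        distance=config.params["distance"],
        linkage_method=config.params["linkage"],
    )
    k = config.params["cut_k"]
    assignments = result.cut(k)
    labels = {g.genome_id: g.habitat.value for g in state["genomes"]}
    agreement = partition_agreement(assignments, labels) if k == 2 else None

    tree_path = out / "cluster_tree.nwk"
    tree_path.write_text(result.to_newick() + "\n", encoding="utf-8")
    assign_path = out / "cluster_assignments.tsv"
    with open(assign_path, "w", encoding="utf-8") as handle:
        handle.write("genome_id\tcluster\thabitat_label\n")
        for genome_id in result.genome_ids:
            handle.write(f"{genome_id}\t{assignments[genome_id]}\t{labels[genome_id]}\n")
        if agreement is not None:
            handle.write(f"# habitat_agreement\t{agreement}\n")
    return {"tree": tree_path, "assignments": assign_path}


def _stage_localization(config: RunConfig, state: dict[str, Any], out: Path) -> dict[str, Path] | None:
    loc_path = config.inputs.get("localization")
    if loc_path is None:
        logger.info("stage localization: no localization inputs configured")
        return None
    profiles = read_localization_table(loc_path)
    genomes = state["genomes"]
    habitat_of = {g.genome_id: g.habitat for g in genomes}
    summary_rows = []
    for cohort in (Habitat.GUT, Habitat.NON_GUT):
        members = [p for p in profiles if habitat_of.get(p.genome_id) is cohort]
        for variable in ("pse", "sec", "cyto", "mem", "total"):
            s = cohort_summary([getattr(p, variable) for p in members], cohort.value, variable)
            mean, sem = s.display(0)
            summary_rows.append((s.cohort, s.variable, s.n, int(mean), int(sem)))
        sec_frac = [100.0 * p.sec / p.total for p in members]
        s = cohort_summary(sec_frac, cohort.value, "sec_fraction_pct")
        mean, sem = s.display(1)
        summary_rows.append((s.cohort, s.variable, s.n, mean, sem))
    summary_path = out / "localization_summary.tsv"
    with open(summary_path, "w", encoding="utf-8") as handle:
        handle.write("cohort\tvariable\tn\tmean\tsem\n")
        for row in summary_rows:
            handle.write("\t".join(str(v) for v in row) + "\n")

    panel = correlation_panel(profiles, genomes)
    panel_path = out / "localization_correlations.tsv"
    panel.to_csv(panel_path, sep="\t", index=False)
    return {"summary": summary_path, "correlations": panel_path}
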