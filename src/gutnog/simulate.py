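"""Seeded generators for every input the pipeline consumes.

Three generators with exact, emitted ground truth:

* a pan-genome with a shared core, cohort-enriched ("planted over") and
  cohort-depleted ("planted under") ortholog groups whose realized
  genome-count differences equal the planted delta by construction, plus
  background groups whose differences stay below the screen threshold;
* catalog alignment tables realizing an exact matched-gene fraction for the
  habitat classifier;
* localization count profiles in which membrane and surface-exposed counts
  scale with proteome size in both cohorts while secreted counts scale only
  in the non-gut cohort.

Which genomes carry a planted group is sampled, but the per-cohort counts
are fixed, so screen recovery is deterministic rather than probabilistic.
All generators are pure functions of their scenario (seed included).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ._round import round_half_up
from .annotation import OrthologAssignment
from .habitat import CatalogFilterParams
from .io_formats import (
    AlignmentHit,
    GenomeRecord,
    Habitat,
    LocalizationProfile,
    OrthologGroupAnnotation,
    write_alignment_table,
    write_annotation_table,
    write_genome_metadata,
    write_length_table,
    write_localization_table,
)

__all__ = [
    "GroundTruth",
    "LocalizationScenario",
    "PanGenome",
    "PanGenomeScenario",
    "generate_catalog_alignments",
    "generate_localization_profiles",
    "generate_pangenome",
    "write_catalog_inputs",
    "write_localization_inputs",
    "write_pangenome_inputs",
]

#: default functional-category weights for planted annotations; the heavy
#: tail on S (unknown) and R (general prediction) mirrors typical ortholog
#: catalogs, J/K/C/E/G the well-populated metabolism/information categories.
DEFAULT_CATEGORY_WEIGHTS = {
    "S": 0.22, "R": 0.14, "J": 0.09, "K": 0.09, "C": 0.08, "E": 0.08,
    "G": 0.08, "M": 0.07, "F": 0.05, "N": 0.05, "T": 0.05,
}


@dataclass(frozen=True)
class PanGenomeScenario:
    """Study-design parameters for the synthetic pan-genome.

    Cohort sizes default to the 23 + 23 study design; ``planted_delta``
    defaults to the screen threshold (12). ``description_sharing`` plants
    multi-group shared-description features of the given sizes;
    ``frac_undescribed`` defaults to the 31.2% of ortholog groups that carry
    no description in the reference catalog. Group counts are scaled down
    from catalog scale (hundreds, not tens of thousands) to keep generated
    datasets small.
    """

    n_gut: int = 23
    n_nongut: int = 23
    n_core: int = 5
    n_over: int = 10
    n_under: int = 10
    planted_delta: int = 12
    n_background: int = 200
    description_sharing: tuple[int, ...] = (6, 3, 2)
    frac_undescribed: float = 0.312
    category_weights: tuple[tuple[str, float], ...] = tuple(DEFAULT_CATEGORY_WEIGHTS.items())
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_over > 0 and self.planted_delta > self.n_gut:
            raise ValueError(
                f"planted_delta {self.planted_delta} exceeds gut cohort size {self.n_gut}"
            )
        if self.n_under > 0 and self.planted_delta > self.n_nongut:
            raise ValueError(
                f"planted_delta {self.planted_delta} exceeds non-gut cohort size {self.n_nongut}"
            )
        if not 0.0 <= self.frac_undescribed <= 1.0:
            raise ValueError("frac_undescribed must be in [0, 1]")
        if self.planted_delta < 1:
            raise ValueError("planted_delta must be positive")


@dataclass(frozen=True)
class GroundTruth:
    core: frozenset[str]
    over: frozenset[str]
    under: frozenset[str]
    background: frozenset[str]


@dataclass
class PanGenome:
    genomes: list[GenomeRecord]
    annotations: list[OrthologGroupAnnotation]
    assignments: list[OrthologAssignment]
    ground_truth: GroundTruth


def _pick(rng: np.random.Generator, ids: list[str], k: int) -> list[str]:
    return sorted(rng.choice(ids, size=k, replace=False)) if k else []


def generate_pangenome(scenario: PanGenomeScenario = PanGenomeScenario()) -> PanGenome:
    """Construct genomes, group annotations and protein assignments.

    Planted over (under) groups realize gut - non-gut genome-count
    differences of exactly ``planted_delta`` (resp. the negative); background
    group differences are sampled strictly below the threshold in absolute
    value. Every present (genome, group) pair is realized by at least one
    assigned protein; proteome sizes are drawn so the assigned fraction sits
    near the cohort-typical 60% (gut) / 71% (non-gut).
    """
    rng = np.random.default_rng(scenario.seed)
    gut_ids = [f"gut{i + 1:02d}" for i in range(scenario.n_gut)]
    nongut_ids = [f"nongut{i + 1:02d}" for i in range(scenario.n_nongut)]

    n_groups = scenario.n_core + scenario.n_over + scenario.n_under + scenario.n_background
    nog_ids = [f"synNOG{i + 1:05d}" for i in range(n_groups)]
    cursor = 0

    def take(k: int) -> list[str]:
        nonlocal cursor
        out = nog_ids[cursor:cursor + k]
        cursor += k
        return out

    core = take(scenario.n_core)
    over = take(scenario.n_over)
    under = take(scenario.n_under)
    background = take(scenario.n_background)

    presence: dict[str, list[str]] = {}  # nog -> genomes carrying it
    for nog in core:
        presence[nog] = gut_ids + nongut_ids
    for nog in over:
        gut_count = int(rng.integers(scenario.planted_delta, scenario.n_gut + 1))
        nongut_count = gut_count - scenario.planted_delta
        presence[nog] = _pick(rng, gut_ids, gut_count) + _pick(rng, nongut_ids, nongut_count)
    for nog in under:
        nongut_count = int(rng.integers(scenario.planted_delta, scenario.n_nongut + 1))
        gut_count = nongut_count - scenario.planted_delta
        presence[nog] = _pick(rng, gut_ids, gut_count) + _pick(rng, nongut_ids, nongut_count)
    for nog in background:
        while True:
            gut_count = int(rng.integers(0, scenario.n_gut + 1))
            nongut_count = int(rng.integers(0, scenario.n_nongut + 1))
            delta = gut_count - nongut_count
            # below the screen threshold, not absent everywhere, and not
            # present everywhere (all-present would be indistinguishable
            # from a planted core group)
            if (
                abs(delta) < scenario.planted_delta
                and gut_count + nongut_count >= 1
                and not (gut_count == scenario.n_gut and nongut_count == scenario.n_nongut)
            ):
                break
        presence[nog] = _pick(rng, gut_ids, gut_count) + _pick(rng, nongut_ids, nongut_count)

    # annotations: undescribed fraction, shared-description blocks, the rest unique
    n_undescribed = int(round(scenario.frac_undescribed * n_groups))
    undescribed = set(rng.choice(nog_ids, size=n_undescribed, replace=False))
    described = [n for n in nog_ids if n not in undescribed]
    letters = [c for c, _ in scenario.category_weights]
    weights = np.array([w for _, w in scenario.category_weights], dtype=float)
    weights = weights / weights.sum()

    shared_of: dict[str, str] = {}
    pool = described.copy()
    for block_index, size in enumerate(scenario.description_sharing):
        if size > len(pool):
            raise ValueError("description_sharing blocks exceed the number of described groups")
        chosen = sorted(rng.choice(pool, size=size, replace=False))
        for nog in chosen:
            shared_of[nog] = f"shared function block {block_index + 1}"
        pool = [n for n in pool if n not in set(chosen)]

    annotations = []
    for nog in nog_ids:
        if nog in undescribed:
            annotations.append(OrthologGroupAnnotation(nog_id=nog, description=""))
        else:
            description = shared_of.get(nog, f"unique function of {nog}")
            category = frozenset([str(rng.choice(letters, p=weights))])
            annotations.append(
                OrthologGroupAnnotation(nog_id=nog, description=description, categories=category)
            )

    # one assigned protein per present (genome, group)
    carried: dict[str, list[str]] = {g: [] for g in gut_ids + nongut_ids}
    for nog in nog_ids:
        for genome in presence[nog]:
            carried[genome].append(nog)
    assignments: list[OrthologAssignment] = []
    genomes: list[GenomeRecord] = []
    for genome_id in gut_ids + nongut_ids:
        habitat = Habitat.GUT if genome_id.startswith("gut") else Habitat.NON_GUT
        target_fraction = 0.60 if habitat is Habitat.GUT else 0.71
        for k, nog in enumerate(carried[genome_id]):
            evalue = float(10.0 ** rng.uniform(-60.0, -10.0))
            assignments.append(
                OrthologAssignment(
                    genome_id=genome_id,
                    protein_id=f"{genome_id}_p{k + 1:05d}",
                    nog_id=nog,
                    evalue=evalue,
                )
            )
        n_assigned = len(carried[genome_id])
        total = max(n_assigned, int(round(n_assigned / target_fraction))) if n_assigned else 1
        genomes.append(GenomeRecord(genome_id=genome_id, habitat=habitat, total_proteins=total))

    return PanGenome(
        genomes=genomes,
        annotations=annotations,
        assignments=assignments,
        ground_truth=GroundTruth(
            core=frozenset(core),
            over=frozenset(over),
            under=frozenset(under),
            background=frozenset(background),
        ),
    )


def generate_catalog_alignments(
    n_genes: int,
    target_fraction: float,
    params: CatalogFilterParams | None = None,
    seed: int = 0,
) -> tuple[list[AlignmentHit], dict[str, int]]:
    """Catalog hits realizing an exact matched-gene fraction.

    Exactly ``round(target_fraction * n_genes)`` genes receive one hit that
    passes the identity/coverage filter; the remaining genes are split
    randomly between no hit at all and one clearly failing hit (identity or
    coverage below threshold). Returns the hit list and the sequence-length
    table covering genes and catalog subjects.
    """
    if not 0.0 <= target_fraction <= 1.0:
        raise ValueError(f"target_fraction must be in [0, 1], got {target_fraction}")
    params = params or CatalogFilterParams()
    rng = np.random.default_rng(seed)
    n_matched = int(round_half_up(target_fraction * n_genes))
    gene_ids = [f"gene{i + 1:06d}" for i in range(n_genes)]
    matched = set(rng.choice(gene_ids, size=n_matched, replace=False))

    hits: list[AlignmentHit] = []
    lengths: dict[str, int] = {}
    for i, gene in enumerate(gene_ids):
        length = int(rng.integers(300, 3001))
        lengths[gene] = length
        subject = f"cat{i + 1:06d}"
        if gene in matched:
            lengths[subject] = length
            hits.append(
                AlignmentHit(
                    query_id=gene,
                    subject_id=subject,
                    percent_identity=float(rng.uniform(params.min_identity, 100.0)),
                    alignment_length=length,  # coverage 1.0 of the longest
                    evalue=float(10.0 ** rng.uniform(-80.0, -20.0)),
                    bit_score=float(rng.uniform(200.0, 2000.0)),
                    query_length=length,
                    subject_length=length,
                )
            )
        elif rng.random() < 0.5:
            lengths[subject] = length
            if rng.random() < 0.5:  # fail on identity
                identity = float(rng.uniform(50.0, max(50.0, params.min_identity - 5.0)))
                aln = length
            else:  # fail on coverage
                identity = float(rng.uniform(params.min_identity, 100.0))
                aln = max(1, int(length * params.min_coverage * 0.5))
            hits.append(
                AlignmentHit(
                    query_id=gene,
                    subject_id=subject,
                    percent_identity=identity,
                    alignment_length=aln,
                    evalue=float(10.0 ** rng.uniform(-20.0, -2.0)),
                    bit_score=float(rng.uniform(40.0, 200.0)),
                    query_length=length,
                    subject_length=length,
                )
            )
        # else: no hit for this gene
    return hits, lengths


@dataclass(frozen=True)
class LocalizationScenario:
    """Generator settings for localization counts vs proteome size.

    Proteome totals are drawn uniformly from ``total_range`` (the span seen
    across the study genomes). Surface-exposed and membrane counts scale with
    the total in both cohorts; secreted counts scale with the total only in
    the non-gut cohort and sit at a size-independent mean in the gut cohort.
    Default slopes and the gut secreted mean match the study cohort means
    (pse ~ 300, mem ~ 480, non-gut sec ~ 156, gut sec ~ 102 at total ~ 3450).
    """

    n_per_cohort: int = 23
    total_range: tuple[int, int] = (1500, 7500)
    pse_slope: float = 0.087
    pse_noise_sd: float = 40.0
    mem_slope: float = 0.14
    mem_noise_sd: float = 40.0
    sec_nongut_slope: float = 0.045
    sec_gut_mean: float = 102.0
    sec_noise_sd: float = 25.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_cohort < 4:
            raise ValueError("need at least 4 genomes per cohort for the correlation panel")
        if self.total_range[0] > self.total_range[1] or self.total_range[0] < 1:
            raise ValueError(f"invalid total_range {self.total_range}")


def generate_localization_profiles(
    scenario: LocalizationScenario = LocalizationScenario(),
) -> tuple[list[LocalizationProfile], list[GenomeRecord]]:
    """Localization profiles plus matching labeled genome records."""
    rng = np.random.default_rng(scenario.seed)
    profiles: list[LocalizationProfile] = []
    genomes: list[GenomeRecord] = []
    for habitat, prefix in ((Habitat.GUT, "gut"), (Habitat.NON_GUT, "nongut")):
        for i in range(scenario.n_per_cohort):
            genome_id = f"{prefix}{i + 1:02d}"
            total = int(rng.integers(scenario.total_range[0], scenario.total_range[1] + 1))
            pse = scenario.pse_slope * total + rng.normal(0.0, scenario.pse_noise_sd)
            mem = scenario.mem_slope * total + rng.normal(0.0, scenario.mem_noise_sd)
            if habitat is Habitat.GUT:
                sec = scenario.sec_gut_mean + rng.normal(0.0, scenario.sec_noise_sd)
            else:
                sec = scenario.sec_nongut_slope * total + rng.normal(0.0, scenario.sec_noise_sd)
            pse, sec, mem = (int(np.clip(round(v), 0, total)) for v in (pse, sec, mem))
            cyto = max(0, total - pse - sec - mem)
            profiles.append(
                LocalizationProfile(
                    genome_id=genome_id, pse=pse, sec=sec, cyto=cyto, mem=mem, total=total
                )
            )
            genomes.append(GenomeRecord(genome_id=genome_id, habitat=habitat, total_proteins=total))
    return profiles, genomes


# ---------------------------------------------------------------------------
# writing a scenario to disk in the pipeline's input formats


def write_pangenome_inputs(
    pangenome: PanGenome,
    out_dir: str | Path,
    decoy_evalue: float = 1e-2,
) -> dict[str, Path]:
    """Materialize a pan-genome as the file set the pipeline reads.

    Writes genomes.tsv, annotations.tsv and one 12-column hits table per
    genome under hits/ (one passing hit per assignment, plus one decoy hit
    above the assignment threshold per genome so that best-hit selection is
    exercised, not bypassed). Returns the paths written.
    """
    out = Path(out_dir)
    (out / "hits").mkdir(parents=True, exist_ok=True)
    paths = {
        "genomes": out / "genomes.tsv",
        "annotations": out / "annotations.tsv",
        "hits_dir": out / "hits",
    }
    write_genome_metadata(paths["genomes"], pangenome.genomes)
    write_annotation_table(paths["annotations"], pangenome.annotations)
    by_genome: dict[str, list[OrthologAssignment]] = {g.genome_id: [] for g in pangenome.genomes}
    for a in pangenome.assignments:
        by_genome[a.genome_id].append(a)
    for genome in pangenome.genomes:
        hits = [
            AlignmentHit(
                query_id=a.protein_id,
                subject_id=a.nog_id,
                percent_identity=90.0,
                alignment_length=100,
                evalue=a.evalue,
                bit_score=200.0,
            )
            for a in by_genome[genome.genome_id]
        ]
        if hits:  # a decoy that must be rejected by the e-value threshold
            first = by_genome[genome.genome_id][0]
            hits.append(
                AlignmentHit(
                    query_id=first.protein_id,
                    subject_id="synNOGdecoy",
                    percent_identity=40.0,
                    alignment_length=50,
                    evalue=decoy_evalue,
                    bit_score=30.0,
                )
            )
        write_alignment_table(out / "hits" / f"{genome.genome_id}.hits.tsv", hits)
    return paths


def write_localization_inputs(
    profiles: list[LocalizationProfile],
    genomes: list[GenomeRecord],
    out_dir: str | Path,
) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {"localization": out / "localization.tsv", "genomes": out / "genomes.tsv"}
    write_localization_table(paths["localization"], profiles)
    write_genome_metadata(paths["genomes"], genomes)
    return paths


def write_catalog_inputs(
    hits: list[AlignmentHit],
    lengths: dict[str, int],
    out_dir: str | Path,
    genome_id: str = "genome",
) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "catalog_hits": out / f"{genome_id}.catalog.tsv",
        "catalog_lengths": out / "catalog_lengths.tsv",
    }
    write_alignment_table(paths["catalog_hits"], hits)
    write_length_table(paths["catalog_lengths"], lengths)
    return paths
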