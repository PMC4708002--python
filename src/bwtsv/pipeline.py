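"""Pipeline orchestration: simulate/map -> discordant -> cluster -> predict ->
scan -> evaluate, with deterministic seeding and stage-level logging.

The stages are plain library calls; this module wires them together for the
common tumor/normal workflow and computes the evaluation report (sensitivity
against a TruthSet, false-detection rate) used by the synthetic benchmarks.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, asdict

import numpy as np

from .breakpoint_scan import BreakpointCall, ScanParams, scan_region
from .discordant import cluster_points, label_somatic
from .genome_index import GenomeIndex, GlobalGenome
from .mapping import MapperIndex, discordant_points_from_mapping, map_reads
from .read_index import ReadIndex
from .region_prediction import InsertModel, predict_cluster_regions
from .simulate import (
    ReadSet,
    ReadSimParams,
    RearrangementSpec,
    TruthSet,
    add_snps,
    make_cancer_genome,
    make_genome,
    mix_purity,
    simulate_reads,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All pipeline tunables with their defaults.

    insert_mean / insert_sd are estimated from accordant pairs when left
    unset.  Scan thresholds are documented on :class:`ScanParams`."""

    mapq_min: int = 30
    insert_mean: float | None = None
    insert_sd: float | None = None
    min_cluster_support: int = 3
    tau: float = 0.5
    alpha: int = 3
    ext_len: int = 20
    min_support: int = 2
    low_thresh: float = 0.1
    high_thresh: float = 0.3
    somatic_rate: float = 0.9
    truth_tol: int = 10
    seed: int = 0

    def scan_params(self, insert_len: int) -> ScanParams:
        return ScanParams(
            alpha=self.alpha,
            ext_len=self.ext_len,
            min_support=self.min_support,
            low_thresh=self.low_thresh,
            high_thresh=self.high_thresh,
            margin=int(insert_len),
        )


@dataclass
class PipelineResult:
    calls: list[BreakpointCall]
    regions: list
    clusters: list
    insert_model: InsertModel
    counters: dict = field(default_factory=dict)
    evaluation: dict | None = None


def estimate_insert_model(
    tlens, min_pairs: int = 1000, fallback: InsertModel | None = None
) -> InsertModel:
    """Robust insert model from accordant-pair template lengths.

    Median for the mean; 1.4826 x MAD for the sd (floored at 1), so a few
    percent of outlying artefact pairs cannot distort the model."""
    tlens = np.abs(np.asarray(tlens, dtype=np.float64))
    tlens = tlens[tlens > 0]
    if tlens.size < min_pairs:
        if fallback is not None:
            return fallback
        raise ValueError(
            f"only {tlens.size} accordant pairs; configure insert mean/sd explicitly"
        )
    med = float(np.median(tlens))
    sd = float(max(1.4826 * np.median(np.abs(tlens - med)), 1.0))
    return InsertModel(L=med, sigma=sd)


def _dedupe_calls(calls: list[BreakpointCall], tol: int = 3) -> list[BreakpointCall]:
    out: list[BreakpointCall] = []
    for c in sorted(calls, key=lambda c: (-c.support, c.x0, c.y0)):
        if any(
            abs(c.x0 - k.x0) <= tol
            and abs(c.y0 - k.y0) <= tol
            and c.orientation_class == k.orientation_class
            for k in out
        ):
            continue
        out.append(c)
    out.sort(key=lambda c: (c.x0, c.y0))
    return out


def run_pipeline(
    reference: GlobalGenome,
    tumor_reads: ReadSet,
    normal_reads: ReadSet,
    config: PipelineConfig,
    truth: TruthSet | None = None,
    genome_index: GenomeIndex | None = None,
    collect_profiles: bool = False,
    mapper: MapperIndex | None = None,
    normal_mapping=None,
    ridx_normal: ReadIndex | None = None,
) -> PipelineResult:
    """Run map -> extract -> cluster -> predict -> detect (-> evaluate).

    The mapper index, the normal sample's mapping and its read index can be
    passed in prebuilt when several tumor samples share one matched normal."""
    counters: dict = {}
    t0 = time.time()

    if mapper is None:
        mapper = MapperIndex(reference)
    mt = map_reads(tumor_reads, mapper, config.insert_mean or 760, config.insert_sd or 45)
    mn = normal_mapping
    if mn is None:
        mn = map_reads(normal_reads, mapper, config.insert_mean or 760, config.insert_sd or 45)
    counters["tumor_mapped"] = int((mt.pos >= 0).sum())
    counters["normal_mapped"] = int((mn.pos >= 0).sum())
    logger.info("mapping done (%.1fs)", time.time() - t0)

    if config.insert_mean is not None and config.insert_sd is not None:
        model = InsertModel(config.insert_mean, config.insert_sd)
    else:
        model = estimate_insert_model(mn.tlen[mn.proper])
    counters["insert_mean"] = model.L
    counters["insert_sd"] = model.sigma

    points = discordant_points_from_mapping(mt, reference, config.mapq_min)
    points += discordant_points_from_mapping(mn, reference, config.mapq_min)
    counters["discordant_points"] = len(points)

    insert_len = int(round(model.L))
    clusters = cluster_points(points, insert_len, min_support=config.min_cluster_support)
    for c in clusters:
        label_somatic(c, config.somatic_rate)
    counters["clusters"] = len(clusters)
    logger.info("%d clusters (%.1fs)", len(clusters), time.time() - t0)

    if genome_index is None:
        genome_index = GenomeIndex(reference)
    regions = []
    for cid, c in enumerate(clusters):
        regions.extend(predict_cluster_regions(c, model, tau=config.tau, cluster_id=cid))
    counters["regions"] = len(regions)
    logger.info("%d regions (%.1fs)", len(regions), time.time() - t0)

    ridx_t = ReadIndex.build_from_matrices(
        [tumor_reads.r1, tumor_reads.r2], sample_label="tumor"
    )
    ridx_n = ridx_normal
    if ridx_n is None:
        ridx_n = ReadIndex.build_from_matrices(
            [normal_reads.r1, normal_reads.r2], sample_label="normal"
        )
    logger.info("read indexes built (%.1fs)", time.time() - t0)

    params = config.scan_params(insert_len)
    calls: list[BreakpointCall] = []
    profiles = {}
    for rid, region in enumerate(regions):
        rcalls, rprof = scan_region(
            region, ridx_t, ridx_n, genome_index, params,
            region_id=rid, collect_profiles=collect_profiles,
        )
        calls.extend(rcalls)
        if collect_profiles:
            profiles[rid] = rprof
    calls = _dedupe_calls(calls)
    counters["calls"] = len(calls)
    logger.info("%d calls (%.1fs)", len(calls), time.time() - t0)

    result = PipelineResult(
        calls=calls,
        regions=regions,
        clusters=clusters,
        insert_model=model,
        counters=counters,
    )
    if collect_profiles:
        result.counters["profiles"] = profiles
    if truth is not None:
        result.evaluation = evaluate_calls(calls, regions, truth, tol=config.truth_tol)
    return result


def evaluate_calls(calls, regions, truth: TruthSet, tol: int = 10) -> dict:
    """Sensitivity/FDR report against a TruthSet.

    'predicted' counts truth junctions covered by some predicted region
    (region-level); 'detected' counts truth junctions matched by a call
    within tol on both coordinates (base-level)."""
    matched_j, matched_c = truth.match_calls(calls, tol=tol)
    n_truth = len(truth)
    predicted = 0
    margin = 760
    for j in truth.junctions:
        for r in regions:
            if (
                r.projection_a[0] - margin <= j.x < r.projection_a[1] + margin
                and r.projection_b[0] - margin <= j.y < r.projection_b[1] + margin
                and r.orientation_class == j.orientation_class
            ):
                predicted += 1
                break
    n_calls = len(calls)
    false_calls = n_calls - len(matched_c)
    return {
        "n_truth": n_truth,
        "n_predicted": predicted,
        "n_detected": len(matched_j),
        "n_calls": n_calls,
        "n_false_calls": false_calls,
        "sensitivity": len(matched_j) / n_truth if n_truth else float("nan"),
        "fdr": false_calls / n_calls if n_calls else float("nan"),
    }


# -- simulation-driven benchmark --------------------------------------


@dataclass
class SimulationConfig:
    """The synthetic benchmark's study conditions (desk scale)."""

    n_chrom: int = 2
    chrom_length: int = 500_000
    snp_rate: float = 0.001
    events_per_type: int = 4
    length_range: tuple[int, int] = (300, 5_000)
    coverage: float = 40.0
    purity: float = 1.0
    read_len: int = 90
    insert_mean: float = 760.0
    insert_sd: float = 45.0
    error_rate: float = 0.001


@dataclass
class SimulatedInputs:
    reference: GlobalGenome
    tumor_reads: ReadSet
    normal_reads: ReadSet
    truth: TruthSet
    normal_genome: list = field(default_factory=list)  # (name, codes) pairs


def simulate_inputs(sim: SimulationConfig, seed: int) -> SimulatedInputs:
    """Generate reference, truth and tumor/normal samples for one run."""
    ss = np.random.SeedSequence(seed)
    seeds = [int(s) % (2**31 - 1) for s in ss.generate_state(6)]
    ref_genome = make_genome(sim.n_chrom, [sim.chrom_length] * sim.n_chrom, seeds[0])
    normal_genome, _ = add_snps(ref_genome, sim.snp_rate, seeds[1])
    spec = RearrangementSpec(
        events_per_type=sim.events_per_type, length_range=sim.length_range
    )
    cancer_genome, truth = make_cancer_genome(normal_genome, spec, seeds[2])
    params = ReadSimParams(
        read_len=sim.read_len,
        insert_mean=sim.insert_mean,
        insert_sd=sim.insert_sd,
        coverage=sim.coverage,
        error_rate=sim.error_rate,
    )
    cancer_reads = simulate_reads(cancer_genome, params, seeds[3], "tumor")
    normal_reads = simulate_reads(normal_genome, params, seeds[4], "normal")
    if sim.purity < 1.0:
        # an independent normal-genome read pool for contaminating the tumor
        pool = simulate_reads(normal_genome, params, seeds[5], "tumor")
        tumor_reads = mix_purity(cancer_reads, pool, sim.purity, seeds[5] ^ 0x5EED)
    else:
        tumor_reads = cancer_reads
    reference = GlobalGenome([n for n, _ in ref_genome], [s for _, s in ref_genome])
    return SimulatedInputs(reference, tumor_reads, normal_reads, truth, normal_genome)


def run_simulation(
    sim: SimulationConfig, seed: int, config: PipelineConfig | None = None
) -> PipelineResult:
    """Simulate one tumor/normal pair and run the full pipeline against it."""
    config = config or PipelineConfig(
        insert_mean=sim.insert_mean, insert_sd=sim.insert_sd
    )
    inputs = simulate_inputs(sim, seed)
    return run_pipeline(
        inputs.reference,
        inputs.tumor_reads,
        inputs.normal_reads,
        config,
        truth=inputs.truth,
    )


def run_purity_sweep(seed: int, purities=(1.0, 0.2, 0.1), sim: SimulationConfig | None = None):
    """The three-point purity benchmark on one shared genome/normal sample.

    The genome, truth set and matched normal are generated once; only the
    tumor mix varies with purity.  Returns {purity: PipelineResult}."""
    base = sim or SimulationConfig()
    ss = np.random.SeedSequence(seed)
    seeds = [int(s) % (2**31 - 1) for s in ss.generate_state(len(purities) + 1)]
    full = simulate_inputs(
        SimulationConfig(**{**asdict(base), "purity": 1.0}), seeds[0]
    )
    params = ReadSimParams(
        read_len=base.read_len,
        insert_mean=base.insert_mean,
        insert_sd=base.insert_sd,
        coverage=base.coverage,
        error_rate=base.error_rate,
    )
    results = {}
    gidx = GenomeIndex(full.reference)
    mapper = MapperIndex(full.reference)
    config = PipelineConfig(insert_mean=base.insert_mean, insert_sd=base.insert_sd)
    normal_mapping = map_reads(
        full.normal_reads, mapper, base.insert_mean, base.insert_sd
    )
    ridx_normal = ReadIndex.build_from_matrices(
        [full.normal_reads.r1, full.normal_reads.r2], sample_label="normal"
    )
    for purity, sub_seed in zip(purities, seeds[1:]):
        if purity < 1.0:
            # normal-genome contamination pool, independent of the matched normal
            pool = simulate_reads(full.normal_genome, params, sub_seed, "tumor")
            tumor = mix_purity(full.tumor_reads, pool, purity, sub_seed ^ 0x5EED)
        else:
            tumor = full.tumor_reads
        results[purity] = run_pipeline(
            full.reference,
            tumor,
            full.normal_reads,
            config,
            truth=full.truth,
            genome_index=gidx,
            mapper=mapper,
            normal_mapping=normal_mapping,
            ridx_normal=ridx_normal,
        )
    return results
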