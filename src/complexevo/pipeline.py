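"""End-to-end orchestration: ingest → weight → cluster → benchmark →
annotate → homology → correlated pairs → ages, from one configuration.

The report is fully determined by (inputs, configuration, seed): every
randomised stage draws its own child seed from the run seed by a fixed
derivation, so re-running a configuration reproduces the report.
"""

from __future__ import annotations

import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import __version__
from .annotation import function_profile, read_funcat_tsv
from .benchmark import benchmark_scores, randomized_baseline
from .correlated import correlated_pair_enrichment, find_correlated_pairs
from .homology import (
    complexes_with_homolog_pairs,
    pair_interaction_enrichment,
    read_domains_tsv,
    spread_regression,
    superfamily_distribution_test,
)
from .interactions import (
    expand_records,
    read_pairwise_tsv,
    read_psimi_tab,
    read_tap_tsv,
    read_weighted_edges_tsv,
    write_edges_tsv,
)
from .io import read_complexes_tsv, write_complexes_tsv
from .mcl import MCLParams, filter_singletons, inflation_sweep, mcl
from .network import WeightedNetwork, union_networks
from .ontology import build_go, filter_annotations, read_gaf_tsv, read_obo, weight_edges
from .phylo import age_chisq, age_distribution, read_orthology_tsv

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "genome_coverage", "run_pipeline", "derive_seed"]


def derive_seed(seed: int, stage: str) -> int:
    """Fixed per-stage child seed: SeedSequence([seed, crc32(stage)])."""
    ss = np.random.SeedSequence([int(seed), zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def genome_coverage(n_complex_proteins: int, genome_size: int) -> int:
    """Percentage of the genome covered, rounded half-up to an integer."""
    if genome_size <= 0:
        raise ValueError("genome size must be positive")
    if n_complex_proteins < 0:
        raise ValueError("protein count must be non-negative")
    return int(100.0 * n_complex_proteins / genome_size + 0.5)


@dataclass
class RunConfig:
    """One pipeline run: input paths, model switches, seeds, output dir.

    File-path fields may be omitted (``None``) to skip the corresponding
    stage.  ``edges`` accepts several files whose interaction sets are
    unioned.
    """

    out_dir: str = "complexevo_run"
    seed: int = 0
    edges: list[str] = field(default_factory=list)
    edges_format: str = "tsv"  # tsv | psimi
    tap: str | None = None
    tap_model: str = "spoke"
    obo: str | None = None
    gaf: str | None = None
    include_iea: bool = False
    gold: str | None = None
    inflation: float | None = 2.2
    sweep: list[float] | None = None
    funcat: str | None = None
    domains: str | None = None
    orthology: str | None = None
    age_groups: list[str] = field(default_factory=list)
    genome_size: int | None = None
    n_random: int = 10000
    alpha: float = 0.01
    min_members: int = 5

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def require(self, *paths: str | None) -> None:
        for p in paths:
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"configured input does not exist: {p}")


def _load_network(cfg: RunConfig) -> WeightedNetwork:
    nets: list[WeightedNetwork] = []
    reader = {"tsv": read_pairwise_tsv, "psimi": read_psimi_tab}[cfg.edges_format]
    for path in cfg.edges:
        nets.append(reader(path))
    if cfg.tap:
        records = read_tap_tsv(cfg.tap)
        nets.append(expand_records(records, model=cfg.tap_model))
    if not nets:
        raise ValueError("no interaction inputs configured (edges or tap)")
    return union_networks(nets) if len(nets) > 1 else nets[0]


def run_pipeline(cfg: RunConfig) -> dict[str, Any]:
    """Execute all configured stages; returns (and writes) the run report.

    Any stage failure aborts with the stage name attached; partial outputs
    already written stay on disk.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {
        "version": __version__,
        "config": {k: v for k, v in vars(cfg).items()},
        "stages": {},
    }
    stage = "ingest"
    try:
        cfg.require(
            cfg.tap, cfg.obo, cfg.gaf, cfg.gold, cfg.funcat, cfg.domains,
            cfg.orthology, *cfg.edges,
        )

        t0 = time.perf_counter()
        net = _load_network(cfg)
        _log_stage(report, "ingest", t0, proteins=len(net), edges=net.n_edges)

        stage = "weight"
        if cfg.obo and cfg.gaf:
            t0 = time.perf_counter()
            parents = read_obo(cfg.obo)
            annotations = filter_annotations(
                read_gaf_tsv(cfg.gaf), include_iea=cfg.include_iea
            )
            go = build_go(parents, annotations)
            net = weight_edges(net, go)
            write_edges_tsv(net, out / "weighted_edges.tsv")
            _log_stage(report, "weight", t0, terms=len(go.terms),
                       annotated=len([p for p, t in go.annotations.items() if t]))
        else:
            go = None

        stage = "cluster"
        t0 = time.perf_counter()
        gold = read_complexes_tsv(cfg.gold, provenance="gold") if cfg.gold else None
        if cfg.sweep:
            if gold is None:
                raise ValueError("an inflation sweep requires a gold standard")
            table = inflation_sweep(
                net, gold, cfg.sweep, n_random=cfg.n_random,
                seed=derive_seed(cfg.seed, "sweep"),
            )
            table.to_csv(out / "sweep.tsv", sep="\t", index=False)
            best = table.attrs["best_inflation"]
            report["stages"]["sweep"] = {
                "best_inflation": best,
                "table": table.to_dict(orient="records"),
            }
            inflation = best
        else:
            inflation = cfg.inflation or 2.2
        clusters = filter_singletons(mcl(net, MCLParams(inflation=inflation)))
        write_complexes_tsv(clusters, out / "complexes.tsv")
        _log_stage(report, "cluster", t0, inflation=inflation,
                   complexes=len(clusters),
                   proteins=len(clusters.proteins))
        if cfg.genome_size:
            report["stages"]["cluster"]["genome_coverage_percent"] = genome_coverage(
                len(clusters.proteins), cfg.genome_size
            )

        stage = "benchmark"
        if gold is not None:
            t0 = time.perf_counter()
            scores = benchmark_scores(clusters, gold)
            rmean, rsd = randomized_baseline(
                clusters, gold, n=cfg.n_random,
                seed=derive_seed(cfg.seed, "baseline"),
            )
            _log_stage(report, "benchmark", t0,
                       sensitivity=scores.sensitivity, ppv=scores.ppv,
                       accuracy=scores.accuracy,
                       random_mean=rmean, random_sd=rsd)

        stage = "annotate"
        if cfg.funcat:
            t0 = time.perf_counter()
            ft = read_funcat_tsv(cfg.funcat)
            profile = function_profile(clusters, ft)
            profile.to_csv(out / "function_profile.tsv", sep="\t", index=False)
            _log_stage(report, "annotate", t0,
                       n_terms=len(profile),
                       n_excluded=profile.attrs["n_excluded"],
                       profile=profile.to_dict(orient="records"))

        stage = "homology"
        homolog_pairs = None
        da = read_domains_tsv(cfg.domains) if cfg.domains else None
        if da is not None:
            t0 = time.perf_counter()
            results, significant = superfamily_distribution_test(
                clusters, da, min_members=cfg.min_members,
                n_rand=cfg.n_random, alpha=cfg.alpha,
                seed=derive_seed(cfg.seed, "distribution"),
            )
            domain_res = complexes_with_homolog_pairs(
                clusters, da, mode="domain", n_rand=cfg.n_random,
                seed=derive_seed(cfg.seed, "homolog-domain"),
            )
            arch_res = complexes_with_homolog_pairs(
                clusters, da, mode="architecture", n_rand=cfg.n_random,
                seed=derive_seed(cfg.seed, "homolog-architecture"),
            )
            homolog_pairs = domain_res.pairs
            interaction_p = (
                pair_interaction_enrichment(
                    domain_res.pairs, clusters, net, n_rand=cfg.n_random,
                    seed=derive_seed(cfg.seed, "homolog-interaction"),
                )
                if domain_res.pairs
                else None
            )
            points, r2 = spread_regression(da, clusters)
            _log_stage(
                report, "homology", t0,
                n_superfamilies_tested=len(results),
                nonrandom_superfamilies=sorted(significant),
                domain={"count": domain_res.count,
                        "fraction": domain_res.fraction,
                        "fold_vs_null": domain_res.fold_vs_null,
                        "p_value": domain_res.permutation.p_value},
                architecture={"count": arch_res.count,
                              "fraction": arch_res.fraction,
                              "fold_vs_null": arch_res.fold_vs_null,
                              "p_value": arch_res.permutation.p_value},
                homolog_pair_interaction_p=interaction_p,
                spread_r_squared=r2,
                spread_points=len(points),
            )

        stage = "correlated"
        correlated_proteins: set[str] = set()
        if da is not None:
            t0 = time.perf_counter()
            pairs = find_correlated_pairs(
                clusters, da, n_rand=cfg.n_random, p_max=cfg.alpha,
                seed=derive_seed(cfg.seed, "correlated"),
            )
            for cp in pairs:
                for _, p, q in cp.supporting:
                    correlated_proteins |= {p, q}
            enrichment = None
            if pairs and go is not None:
                ip, gp = correlated_pair_enrichment(
                    pairs, clusters, net, go, n_rand=cfg.n_random,
                    seed=derive_seed(cfg.seed, "correlated-enrichment"),
                )
                enrichment = {"interaction_p": ip, "goss_p": gp}
            _log_stage(
                report, "correlated", t0,
                n_pairs=len(pairs),
                pairs=[{"sfam_a": cp.sfam_a, "sfam_b": cp.sfam_b,
                        "n_complexes": cp.n_complexes, "p_value": cp.p_value,
                        "n_witnesses": len(cp.supporting)} for cp in pairs],
                enrichment=enrichment,
            )

        stage = "ages"
        if cfg.orthology:
            t0 = time.perf_counter()
            groups = cfg.age_groups
            if not groups:
                raise ValueError("age_groups must be configured with orthology")
            profile = read_orthology_tsv(cfg.orthology, group_order=groups)
            all_proteins = clusters.proteins
            ages: dict[str, Any] = {
                "all": age_distribution(all_proteins, profile).to_dict("records")
            }
            for name, members in (
                ("homolog_pairs", {p for pr in homolog_pairs or [] for p in pr}),
                ("correlated_pairs", correlated_proteins),
            ):
                if not members:
                    continue
                dist = age_distribution(members, profile)
                bg = age_distribution(all_proteins - members, profile)
                try:
                    stat, dof, p = age_chisq(dist, bg)
                except ValueError as exc:
                    ages[name] = {"error": str(exc)}
                    continue
                ages[name] = {
                    "distribution": dist.to_dict("records"),
                    "chi2": stat, "dof": dof, "p_value": p,
                }
            _log_stage(report, "ages", t0, **ages)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report


def _log_stage(report: dict, name: str, t0: float, **payload: Any) -> None:
    elapsed = time.perf_counter() - t0
    logger.info("stage %-12s done in %.2fs", name, elapsed)
    report["stages"][name] = payload
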