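"""End-to-end orchestration: filter, detect, compare, enrich, report.

``run_all`` ties the stages together in the canonical order — hyper-altered
exclusion, per-type detection, pan-cancer detection, differential screen,
PPI enrichment, and (optionally) saturation curves and in-region gene
ranking — writing TSV/JSON/GraphML outputs plus a provenance record, so
that identical config + seed reproduce an identical results directory.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .data_model import (
    PAN,
    eligible_pairs,
    filter_hypermutated,
    filter_recurrent,
    load_events,
)
from .differential import (
    differential_network,
    differential_screen,
    differential_to_frame,
    screen_summary,
)
from .drivers import rank_genes_in_region, ranks_to_frame
from .enrichment import PPINetwork, enrichment_score
from .interaction import detect_interactions, results_to_frame, write_network
from .permutation import PermutationPlan
from .saturation import saturation_by_type, saturation_within_type

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Validated configuration of one end-to-end run."""

    events_path: str
    meta_path: str
    out_dir: str
    ppi_path: str | None = None
    expression_path: str | None = None
    scopes: list[str] | None = None  # None = every cancer type + PAN
    n_permutations: int = 10_000
    seed: int = 0
    fdr: float = 0.1
    fdr_strict: float = 0.05
    min_frequency: float = 0.02
    hyper_multiplier: float = 4.5
    hyper_scope: str = "global"
    run_differential: bool = True
    run_enrichment: bool = True
    run_saturation: bool = False
    run_gene_ranking: bool = False
    saturation_step: int = 10
    saturation_reps: int = 3
    saturation_n_permutations: int = 1_000
    enrichment_resamples: int = 1_000

    def __post_init__(self) -> None:
        for thr in (self.fdr, self.fdr_strict, self.min_frequency):
            if not 0 < thr <= 1:
                raise ValueError("thresholds must lie in (0, 1]")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        return cls(**data)

    def validate_paths(self) -> None:
        for p in (
            self.events_path,
            self.meta_path,
            self.ppi_path,
            self.expression_path,
        ):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)


def _stage_marker(out: Path, name: str):
    """On stage failure, retain partial outputs and leave a marker file."""
    from contextlib import contextmanager

    @contextmanager
    def guard():
        try:
            yield
        except Exception as exc:
            (out / f"FAILED_{name}").write_text(repr(exc) + "\n")
            raise

    return guard()


def run_all(config: RunConfig) -> Path:
    """Execute every configured stage; returns the results directory."""
    config.validate_paths()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    matrix = load_events(config.events_path, config.meta_path)
    matrix, report = filter_hypermutated(
        matrix, multiplier=config.hyper_multiplier, scope=config.hyper_scope
    )
    (out / "filter_report.json").write_text(report.to_json())
    report.to_frame().to_csv(out / "filter_report.tsv", sep="\t", index=False)

    plan = PermutationPlan(
        n_permutations=config.n_permutations, seed=config.seed
    )
    scopes = config.scopes or (matrix.cancer_type_labels() + [PAN])

    networks = {}
    frames = []
    for scope in scopes:
        network = detect_interactions(
            matrix,
            plan,
            scope=scope,
            threshold=config.fdr,
            min_frequency=config.min_frequency,
        )
        networks[scope] = network
        frames.append(results_to_frame(network.results))
        write_network(
            network,
            graphml_path=out / f"network_{scope}.graphml",
            sif_path=out / f"network_{scope}.sif",
        )
        logger.info(
            "scope %s: %d pairs tested, %d detected at FDR %.2g",
            scope, len(network.results), len(network.edges), config.fdr,
        )
    if frames:
        pd.concat(frames, ignore_index=True).to_csv(
            out / "interactions.tsv", sep="\t", index=False
        )

    if config.run_differential:
        with _stage_marker(out, "differential"):
            per_type = {s: n for s, n in networks.items() if s != PAN}
            diff = differential_screen(
                per_type,
                matrix,
                plan,
                threshold=config.fdr,
                min_frequency=config.min_frequency,
            )
            differential_to_frame(diff).to_csv(
                out / "differential.tsv", sep="\t", index=False
            )
            (out / "differential_summary.json").write_text(
                json.dumps(screen_summary(diff), indent=2)
            )
            graph = differential_network(diff)
            if graph.number_of_edges():
                import networkx as nx

                nx.write_graphml(graph, out / "differential_network.graphml")

    if config.run_enrichment and config.ppi_path is not None:
        with _stage_marker(out, "enrichment"):
            network = PPINetwork.from_tsv(config.ppi_path)
            pan = filter_recurrent(
                matrix, min_frequency=config.min_frequency, scope=PAN
            )
            pool = eligible_pairs(pan)
            detected = sorted(
                {r.pair for net in networks.values() for r in net.edges}
            )
            detected = [p for p in detected if p in set(pool)]
            if detected:
                enr = enrichment_score(
                    detected,
                    pool,
                    pan,
                    network,
                    n_resamples=config.enrichment_resamples,
                    rng=config.seed,
                )
                (out / "enrichment.json").write_text(
                    json.dumps(dataclasses.asdict(enr), indent=2)
                )

    if config.run_saturation:
        with _stage_marker(out, "saturation"):
            sat_plan = plan.with_(n_permutations=config.saturation_n_permutations)
            curves = []
            for t in matrix.cancer_type_labels():
                n_t = int(matrix.sample_mask(t).sum())
                if n_t >= config.saturation_step:
                    curves.append(
                        saturation_within_type(
                            matrix, t, sat_plan,
                            step=config.saturation_step,
                            reps=config.saturation_reps,
                            threshold=config.fdr,
                            min_frequency=config.min_frequency,
                        ).to_frame().assign(cancer_type=t)
                    )
            if len(matrix.cancer_type_labels()) >= 2:
                curves.append(
                    saturation_by_type(
                        matrix, sat_plan,
                        threshold=config.fdr,
                        min_frequency=config.min_frequency,
                    ).to_frame().assign(cancer_type=PAN)
                )
            if curves:
                pd.concat(curves, ignore_index=True).to_csv(
                    out / "saturation.tsv", sep="\t", index=False
                )

    if config.run_gene_ranking and config.expression_path is not None:
        with _stage_marker(out, "gene_ranking"):
            expr = pd.read_csv(config.expression_path, sep="\t", index_col=0)
            rank_frames = []
            for scope, network in networks.items():
                if scope == PAN:
                    continue
                regions = {
                    a
                    for r in network.edges
                    for a in r.pair
                    if matrix.meta_of(a).alteration_class.is_cna
                }
                for region in sorted(regions):
                    ranks = rank_genes_in_region(region, matrix, expr, scope)
                    if ranks:
                        rank_frames.append(
                            ranks_to_frame(region, ranks).assign(cancer_type=scope)
                        )
            if rank_frames:
                pd.concat(rank_frames, ignore_index=True).to_csv(
                    out / "gene_ranks.tsv", sep="\t", index=False
                )

    provenance = {
        "version": __version__,
        "seed": config.seed,
        "n_permutations": config.n_permutations,
        "fdr": config.fdr,
        "fdr_strict": config.fdr_strict,
        "min_frequency": config.min_frequency,
        "hyper_multiplier": config.hyper_multiplier,
        "hyper_scope": config.hyper_scope,
        "scopes": list(scopes),
        "n_samples_after_filter": matrix.n_samples,
        "n_alterations": matrix.n_alterations,
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2))
    return out
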