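"""End-to-end orchestration: load or simulate a web, derive traits and
interaction strengths, then run the cascade, homophily and motif/null
analyses from a single configuration, producing a machine-readable report."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from webcva import __version__
from webcva.cascade import (
    CascadeConfig,
    randomized_cascade_experiment,
    select_pool,
)
from webcva.core import (
    FoodWeb,
    Group,
    Residency,
    group_degree_stats,
    read_edge_list,
    trophic_levels,
    write_edge_list,
    write_node_table,
)
from webcva.energetics import (
    diet_preferences,
    interaction_strengths,
    metabolic_demands,
    read_traits,
    solve_fluxes,
    write_strengths,
    write_traits,
)
from webcva.structure import coleman_homophily, motif_zscores
from webcva.synthetic import generate_web, mojave_like_config

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "validate_report", "POOL_SELECTORS"]

POOL_SELECTORS: dict[str, tuple[Group, Residency | None]] = {
    "birds": (Group.bird, None),
    "birds-resident": (Group.bird, Residency.resident),
    "birds-nonresident": (Group.bird, Residency.nonresident),
    "mammals": (Group.mammal, None),
    "reptiles": (Group.reptile, None),
}


@dataclass
class RunConfig:
    """Configuration for one full analysis run.

    Either ``preset`` names a synthetic preset (currently ``"mojave"``) or
    ``edges_path``/``nodes_path``/``traits_path`` point to input CSVs.
    """

    preset: str | None = "mojave"
    edges_path: str | None = None
    nodes_path: str | None = None
    traits_path: str | None = None
    thresholds: Sequence[float] = (0.6, 0.7, 0.8, 0.9)
    pools: Sequence[str] = (
        "birds",
        "birds-resident",
        "birds-nonresident",
        "mammals",
        "reptiles",
    )
    custom_pools: Mapping[str, Sequence[str]] = field(default_factory=dict)
    n_replicates: int = 100
    n_null: int = 100
    induced: bool = True
    invert_homophily: bool = True
    seed: int = 0
    outdir: str | None = None

    def __post_init__(self) -> None:
        for t in self.thresholds:
            if not (0.0 <= t <= 1.0):
                raise ValueError(f"threshold {t} outside [0, 1]")
        if self.preset is None and (self.edges_path is None or self.nodes_path is None):
            raise ValueError("supply either a preset or edges/nodes paths")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        data = (
            json.loads(text)
            if str(path).endswith(".json")
            else yaml.safe_load(text)
        )
        return cls(**data)

    def digest(self) -> str:
        payload = {k: v for k, v in asdict(self).items() if k != "outdir"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _subseed(master: int, *key: int) -> int:
    """Deterministic named sub-seed below 2**31."""
    state = np.random.SeedSequence([master, *key]).generate_state(1)[0]
    return int(state) & 0x7FFFFFFF


def _resolve_pool(web: FoodWeb, name: str, custom: Mapping) -> tuple[str, ...]:
    if name in custom:
        return tuple(custom[name])
    if name not in POOL_SELECTORS:
        raise ValueError(f"unknown pool {name!r}")
    group, residency = POOL_SELECTORS[name]
    return select_pool(web, group, residency)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages in dependency order and return the report dict.

    Stages: acquire web (+ traits) → web summary statistics → diet
    preferences and flux-based interaction strengths → bottom-up homophily →
    cascade ensembles per pool × threshold → motif/null comparison. Any
    stage failure aborts with a stage-named error. When ``config.outdir``
    is set, the report (JSON) and per-table CSVs are written there.
    """
    stage = "acquire"
    try:
        if config.preset is not None:
            if config.preset != "mojave":
                raise ValueError(f"unknown preset {config.preset!r}")
            syn = generate_web(
                mojave_like_config(seed=_subseed(config.seed, 1))
            )
            web, traits = syn.web, syn.traits
        else:
            web = read_edge_list(config.edges_path, node_table=config.nodes_path)
            if config.traits_path is None:
                raise ValueError("traits_path required for loaded webs")
            traits = read_traits(config.traits_path)
            missing = [i for i in web.ids if i not in traits.index]
            if missing:
                raise ValueError(
                    f"traits missing for node(s): {sorted(missing)[:5]}"
                )

        stage = "web_summary"
        deg = group_degree_stats(web)
        tl = pd.Series(trophic_levels(web))
        tl_by_group = {
            g.value: {
                "mean": float(tl[web.group_members(g)].mean()),
                "sd": float(tl[web.group_members(g)].std(ddof=1)),
            }
            for g in Group
            if web.group_members(g)
        }
        counts = {g.value: len(web.group_members(g)) for g in Group}

        stage = "strengths"
        w = diet_preferences(web, traits)
        demands = metabolic_demands(web, traits)
        flux = solve_fluxes(web, w, demands)
        strengths = interaction_strengths(flux)

        stage = "homophily"
        hom = coleman_homophily(web, invert=config.invert_homophily)

        stage = "cascades"
        cascades = {}
        ensembles = {}
        for pi, pool_name in enumerate(config.pools):
            pool = _resolve_pool(web, pool_name, config.custom_pools)
            for ti, t in enumerate(config.thresholds):
                ens = randomized_cascade_experiment(
                    web,
                    strengths,
                    CascadeConfig(
                        threshold=t,
                        pool=pool,
                        n_replicates=config.n_replicates,
                        seed=_subseed(config.seed, 2, pi, ti),
                    ),
                )
                key = f"{pool_name}@{t}"
                ensembles[key] = ens
                cascades[key] = {
                    "pool": pool_name,
                    "threshold": t,
                    "pool_size": len(pool),
                    "final_mean": float(ens.mean[-1]),
                    "final_lo": float(ens.lo[-1]),
                    "final_hi": float(ens.hi[-1]),
                    "first_secondary_median_step": _median_first(ens.first_secondary),
                }

        stage = "motifs"
        motifs = motif_zscores(
            web,
            n_null=config.n_null,
            seed=_subseed(config.seed, 3),
            induced=config.induced,
        )
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    report = {
        "web_summary": {
            "n_nodes": len(web),
            "n_edges": web.n_edges,
            "group_counts": counts,
            "degree_stats": deg.to_dict(orient="index"),
            "trophic_levels": tl_by_group,
        },
        "homophily": hom["H"].to_dict(),
        "cascades": cascades,
        "motifs": motifs.to_dict(orient="records"),
        "provenance": {
            "seed": config.seed,
            "config_hash": config.digest(),
            "webcva_version": __version__,
        },
    }

    if config.outdir:
        out = Path(config.outdir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(report, indent=2, default=float))
        deg.rename_axis("group").to_csv(out / "degree_stats.csv")
        hom.rename_axis("group").to_csv(out / "homophily.csv")
        motifs.to_csv(out / "motifs.csv", index=False)
        tl.rename_axis("id").rename("trophic_level").to_csv(
            out / "trophic_levels.csv"
        )
        write_edge_list(web, out / "edges.csv")
        write_node_table(web, out / "nodes.csv")
        write_traits(traits, out / "traits.csv")
        write_strengths(strengths, out / "strengths.csv")
        casc_dir = out / "cascades"
        casc_dir.mkdir(exist_ok=True)
        for key, ens in ensembles.items():
            ens.to_frame().to_csv(
                casc_dir / f"{key.replace('@', '_t')}.csv", index=False
            )
        logger.info("report written to %s", out)
    return report


def _median_first(firsts: list[int | None]) -> float | None:
    vals = [f for f in firsts if f is not None]
    return float(np.median(vals)) if vals else None


_REPORT_KEYS = {
    "web_summary": dict,
    "homophily": dict,
    "cascades": dict,
    "motifs": list,
    "provenance": dict,
}


def validate_report(report: Mapping) -> None:
    """Check the report against the stable schema; raises on violation."""
    for key, typ in _REPORT_KEYS.items():
        if key not in report:
            raise ValueError(f"report missing section {key!r}")
        if not isinstance(report[key], typ):
            raise ValueError(f"report section {key!r} has wrong type")
    ws = report["web_summary"]
    for key in ("n_nodes", "n_edges", "group_counts", "degree_stats"):
        if key not in ws:
            raise ValueError(f"web_summary missing {key!r}")
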