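"""End-to-end orchestration: fuse → screen → assemble → prune → fit → infer → rank.

The pipeline is configured from a single YAML file (or a PipelineConfig
built in code), runs each stage with stage-tagged error reporting, and
writes all artifacts plus a manifest sufficient to reproduce the run.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import __version__
from .errors import PipelineStageError, ValidationError
from .evidence_fusion import (
    ScreeningRule,
    SourceSupport,
    aggregate_responses,
    fused_table,
    read_responses,
    screen_edges,
)
from .factor_model import IncidenceMatrix, default_catalog, read_incidence
from .inference_engine import posterior
from .network_structure import (
    DEFAULT_CMI_THRESHOLD,
    assemble_graph,
    prune_edges,
    to_dot,
    write_edge_list,
)
from .parameter_estimation import BayesianNetworkModel, EstimationConfig, fit_parameters
from .scenario_analysis import (
    enumerate_scenarios,
    rank_risk_factors,
    top_scenarios,
    write_scenario_csv,
)

__all__ = ["PipelineConfig", "run_pipeline", "validate_cases", "load_config",
           "STAGES"]

STAGES = ("load", "fuse", "screen", "assemble", "prune", "fit", "infer", "scenarios")


@dataclass
class PipelineConfig:
    incidence_csv: str
    output_dir: str
    responses_csv: str | None = None  # per-respondent scores
    supports_csv: str | None = None  # panel-level supports (from,to,expert_support,frontline_support)
    extra_cmi_triples: list[list[str]] = field(default_factory=list)  # [from,to,conditioner]
    alpha: float = 1.0
    fallback: str = "geometric_mean"
    cmi_threshold: float = DEFAULT_CMI_THRESHOLD
    cmi_log_base: float = 2.0
    bel_min: float = 0.8
    k_max: float = 0.5
    outcome_id: str = "FFHA"
    scenario_parent_order: list[str] | None = None
    top_n: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.responses_csv is None and self.supports_csv is None:
            raise ValidationError(
                "config needs responses_csv (raw scores) or supports_csv (panel supports)"
            )


def load_config(path: str | Path) -> PipelineConfig:
    payload = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    return PipelineConfig(**payload)


def _load_supports(config: PipelineConfig) -> list[SourceSupport]:
    if config.supports_csv is not None:
        df = pd.read_csv(config.supports_csv)
        return [
            SourceSupport(
                (str(r["from"]), str(r["to"])),
                float(r["expert_support"]),
                float(r["frontline_support"]),
            )
            for _, r in df.iterrows()
        ]
    return [aggregate_responses(r) for r in read_responses(config.responses_csv)]


def run_pipeline(config: PipelineConfig) -> dict[str, object]:
    """Execute all stages and write artifacts under ``config.output_dir``.

    Returns a dict with the in-memory artifacts (graph, model, tables).  On
    stage failure the partial outputs written so far are retained next to a
    ``FAILED`` marker naming the stage, and a PipelineStageError is raised.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, object] = {}
    stage = "load"
    try:
        matrix = read_incidence(config.incidence_csv, default_catalog())
        supports = _load_supports(config)
        artifacts["matrix"] = matrix

        stage = "fuse"
        rule = ScreeningRule(config.bel_min, config.k_max)
        fused = fused_table(supports, rule)
        fused.to_csv(out / "fused_edges.csv", index=False)
        artifacts["fused"] = fused

        stage = "screen"
        from .evidence_fusion import combine_supports

        kept = screen_edges(combine_supports(supports), rule)
        artifacts["kept_edges"] = kept

        stage = "assemble"
        graph = assemble_graph(kept)

        stage = "prune"
        extra = [((a, b), z) for a, b, z in config.extra_cmi_triples]
        pruned, tests = prune_edges(
            graph,
            matrix,
            threshold=config.cmi_threshold,
            extra=extra,
            log_base=config.cmi_log_base,
        )
        pd.DataFrame(
            [
                {
                    "from": t.edge[0],
                    "to": t.edge[1],
                    "conditioner": t.conditioner,
                    "cmi": t.value,
                    "verdict": "independent" if t.independent else "dependent",
                }
                for t in tests
            ]
        ).to_csv(out / "cmi_tests.csv", index=False)
        write_edge_list(pruned, out / "pruned_graph.csv")
        to_dot(pruned, out / "pruned_graph.dot")
        artifacts["graph"], artifacts["cmi_tests"] = pruned, tests

        stage = "fit"
        parent_order = (
            {config.outcome_id: config.scenario_parent_order}
            if config.scenario_parent_order
            else None
        )
        model = fit_parameters(
            matrix,
            pruned,
            EstimationConfig(config.alpha, config.fallback),
            outcome_id=config.outcome_id,
            parent_order=parent_order,
        )
        model.to_json(out / "model.json")
        artifacts["model"] = model

        stage = "infer"
        rankings = rank_risk_factors(model, config.outcome_id)
        rankings.to_csv(out / "rankings.csv", index=False)
        artifacts["rankings"] = rankings

        stage = "scenarios"
        table = enumerate_scenarios(model, config.outcome_id)
        write_scenario_csv(table, out / "scenarios.csv")
        top = top_scenarios(table, min(config.top_n, len(table)))
        lines = []
        for rank, s in enumerate(top, start=1):
            states = ", ".join(
                f"{p}={'TRUE' if v else 'FALSE'}" for p, v in s.assignment
            )
            lines.append(f"{rank}. P({config.outcome_id}=TRUE) = {100 * s.p_outcome:.2f}%  [{states}]")
        (out / "top_scenarios.txt").write_text("\n".join(lines) + "\n", encoding="utf-8")
        artifacts["scenarios"], artifacts["top"] = table, top
    except Exception as exc:  # noqa: BLE001 - re-raised with stage context
        (out / "FAILED").write_text(f"{stage}: {exc}\n", encoding="utf-8")
        raise PipelineStageError(stage, exc) from exc

    manifest = {
        "config": asdict(config),
        "seed": config.seed,
        "versions": _versions(),
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=1), encoding="utf-8"
    )
    artifacts["manifest"] = manifest
    return artifacts


def _versions() -> dict[str, str]:
    import networkx
    import numpy
    import pandas

    return {
        "ffhrisk": __version__,
        "numpy": numpy.__version__,
        "pandas": pandas.__version__,
        "networkx": networkx.__version__,
    }


def validate_cases(
    model: BayesianNetworkModel,
    cases: dict[str, Sequence[str]] | str | Path,
    outcome_id: str = "FFHA",
) -> pd.DataFrame:
    """Posterior P(outcome=TRUE | observed factors TRUE) for each held-out case.

    ``cases`` maps a case name to the list of factors observed present
    (e.g. ``{"T01": ["D1", "B2", "B7", "B1"]}``), or is a YAML file with the
    same mapping.  Unlisted factors are left unobserved.
    """
    if not isinstance(cases, dict):
        cases = yaml.safe_load(Path(cases).read_text(encoding="utf-8"))
    rows = []
    for name, factors in cases.items():
        unknown = [f for f in factors if f not in model.cpts]
        if unknown:
            raise ValidationError(f"case {name!r} names unknown nodes: {unknown}")
        evidence = {f: True for f in factors}
        p = posterior(model, outcome_id, evidence).p_true
        rows.append(
            {
                "case": name,
                "evidence": ",".join(factors),
                "p_outcome": p,
                "formatted": f"{100 * p:.1f}%",
            }
        )
    return pd.DataFrame(rows)
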