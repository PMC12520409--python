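"""Dempster–Shafer fusion of two elicitation panels' per-edge support.

Each candidate causal edge between risk factors is scored 0–10 by two
independent panels (senior experts and frontline practitioners).  Panel
scores are aggregated to a unit-interval support mass and the two masses are
combined with Dempster's rule on the two-element frame
{edge exists, edge does not exist}.  No mass is committed to the frame
itself (Bayesian masses), under which belief and plausibility coincide with
the fused mass.  Edges are kept when both Bel and Pl clear a support
threshold and the conflict coefficient k stays below a conflict ceiling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import FusionError

__all__ = [
    "Edge",
    "ResponseSet",
    "SourceSupport",
    "FusedEdge",
    "ScreeningRule",
    "aggregate_responses",
    "dempster_combine",
    "combine_supports",
    "screen_edges",
    "load_elicited_supports",
    "read_responses",
    "fused_table",
]

Edge = tuple[str, str]


@dataclass(frozen=True)
class ResponseSet:
    """Raw 0–10 scores for one candidate edge, one list per panel."""

    edge: Edge
    expert_scores: tuple[int, ...]
    frontline_scores: tuple[int, ...]

    def __post_init__(self):
        for panel, scores in (
            ("expert", self.expert_scores),
            ("frontline", self.frontline_scores),
        ):
            if any(not 0 <= s <= 10 for s in scores):
                raise ValueError(f"{panel} scores must lie in [0, 10]")


@dataclass(frozen=True)
class SourceSupport:
    edge: Edge
    m1: float  # expert panel
    m2: float  # frontline panel

    def __post_init__(self):
        if not (0.0 <= self.m1 <= 1.0 and 0.0 <= self.m2 <= 1.0):
            raise ValueError("support masses must lie in [0, 1]")


@dataclass(frozen=True)
class FusedEdge:
    edge: Edge
    m: float
    k: float
    bel: float
    pl: float

    def rounded(self, ndigits: int = 4) -> "FusedEdge":
        """Display copy rounded half-even, matching 4-decimal reporting."""
        return FusedEdge(
            self.edge,
            round(self.m, ndigits),
            round(self.k, ndigits),
            round(self.bel, ndigits),
            round(self.pl, ndigits),
        )


@dataclass(frozen=True)
class ScreeningRule:
    bel_min: float = 0.8
    k_max: float = 0.5

    def __post_init__(self):
        if not 0 < self.bel_min < 1:
            raise ValueError("bel_min must lie in (0, 1)")
        if not 0 < self.k_max <= 1:
            raise ValueError("k_max must lie in (0, 1]")

    def keeps(self, fused: FusedEdge) -> bool:
        return (
            fused.bel >= self.bel_min
            and fused.pl >= self.bel_min
            and fused.k < self.k_max
        )


def aggregate_responses(responses: ResponseSet) -> SourceSupport:
    """Panel support mass = arithmetic mean of the 0–10 scores, rescaled to [0, 1]."""
    if not responses.expert_scores or not responses.frontline_scores:
        raise ValueError(f"empty panel for edge {responses.edge}")
    m1 = sum(responses.expert_scores) / len(responses.expert_scores) / 10.0
    m2 = sum(responses.frontline_scores) / len(responses.frontline_scores) / 10.0
    return SourceSupport(responses.edge, m1, m2)


def dempster_combine(m1: float, m2: float, edge: Edge = ("", "")) -> FusedEdge:
    """Dempster's rule on the frame {exists, not-exists} with Bayesian masses.

    k = m1(1−m2) + (1−m1)m2 is the mass the product measure puts on
    contradictory source combinations; the fused mass renormalizes the
    agreeing part: m = m1·m2 / (1−k).  Bel = Pl = m because no mass rests on
    the frame.
    """
    if not (0.0 <= m1 <= 1.0 and 0.0 <= m2 <= 1.0):
        raise ValueError("masses must lie in [0, 1]")
    k = m1 * (1.0 - m2) + (1.0 - m1) * m2
    if k >= 1.0:
        raise FusionError(
            f"total conflict between sources (m1={m1}, m2={m2}): k = 1"
        )
    m = m1 * m2 / (1.0 - k)
    return FusedEdge(edge, m=m, k=k, bel=m, pl=m)


def combine_supports(supports: Iterable[SourceSupport]) -> list[FusedEdge]:
    return [dempster_combine(s.m1, s.m2, s.edge) for s in supports]


def screen_edges(
    fused: Sequence[FusedEdge], rule: ScreeningRule = ScreeningRule()
) -> list[Edge]:
    """Edges surviving the Bel/Pl ≥ bel_min and k < k_max screen, input order kept."""
    return [f.edge for f in fused if rule.keeps(f)]


def load_elicited_supports() -> pd.DataFrame:
    """The bundled panel-level elicitation summary for the 25 surviving candidate edges.

    Columns: from, to, expert_support, frontline_support and the published
    fused bel/pl/k values (reference output, recomputable from the supports).
    """
    with resources.files("ffhrisk.data").joinpath("elicited_edges.csv").open(
        "r", encoding="utf-8"
    ) as fh:
        return pd.read_csv(fh)


def read_responses(path: str | Path) -> list[ResponseSet]:
    """Read raw per-respondent scores.

    CSV columns: edge_from, edge_to, panel (expert|frontline), respondent_id,
    score.  Rows are grouped per edge in first-appearance order.
    """
    df = pd.read_csv(path, dtype={"score": int})
    out: list[ResponseSet] = []
    seen: dict[Edge, dict[str, list[int]]] = {}
    order: list[Edge] = []
    for row in df.itertuples(index=False):
        edge = (str(row.edge_from), str(row.edge_to))
        if edge not in seen:
            seen[edge] = {"expert": [], "frontline": []}
            order.append(edge)
        if row.panel not in ("expert", "frontline"):
            raise ValueError(f"unknown panel {row.panel!r} for edge {edge}")
        seen[edge][row.panel].append(int(row.score))
    for edge in order:
        out.append(
            ResponseSet(
                edge,
                tuple(seen[edge]["expert"]),
                tuple(seen[edge]["frontline"]),
            )
        )
    return out


def fused_table(
    supports: Sequence[SourceSupport], rule: ScreeningRule = ScreeningRule()
) -> pd.DataFrame:
    """Fusion report mirroring the elicitation summary layout, with a kept flag."""
    rows = []
    for s in supports:
        f = dempster_combine(s.m1, s.m2, s.edge).rounded()
        rows.append(
            {
                "from": s.edge[0],
                "to": s.edge[1],
                "m1": s.m1,
                "m2": s.m2,
                "bel": f.bel,
                "pl": f.pl,
                "k": f.k,
                "kept": rule.keeps(f),
            }
        )
    return pd.DataFrame(rows)
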