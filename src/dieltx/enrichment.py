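"""Pathway x peak-time enrichment of diel gene families.

For every (taxon bin, sampling hour, pathway) combination a 2x2 table is
built over the bin's detected gene-family universe:

    a = in pathway and diel peaking at t     b = in pathway, not diel@t
    c = not in pathway, diel@t               d = neither

and tested one-sided (greater) with Fisher's exact test; "diel@t" means the
family was called diel with its peak assigned to hour t (the alternative
reading — diel at any hour — is available via ``mode="any"``). Tables whose
pathway has no detected member in the bin are removed before testing, and
BH correction runs once across every retained table of the run.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .rhythm import bh_adjust


@dataclass(frozen=True)
class ContingencyTable:
    a: int
    b: int
    c: int
    d: int
    taxon_id: str
    pathway_id: str
    hour: float

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


def fisher_greater(table: ContingencyTable) -> tuple[float, float]:
    """One-sided (greater) Fisher exact p and the cross-product odds ratio.

    p is the upper hypergeometric tail P(X >= a) with margins fixed; the
    odds ratio is the unconditional a*d / (b*c) (inf when b*c = 0 and
    a*d > 0, nan for 0/0).
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    p = float(stats.hypergeom.sf(a - 1, table.n, a + b, a + c))
    if b * c > 0:
        odds = a * d / (b * c)
    elif a * d > 0:
        odds = float("inf")
    else:
        odds = float("nan")
    return odds, min(p, 1.0)


def diel_sets(
    rhythm_results: pd.DataFrame, mode: str = "peak"
) -> dict[tuple[str, float], set[str]]:
    """Map (taxon_id, hour) -> families counted as diel at that hour."""
    if mode not in ("peak", "any"):
        raise ValueError(f"unknown enrichment mode {mode!r}")
    out: dict[tuple[str, float], set[str]] = {}
    diel = rhythm_results[rhythm_results["is_diel"]]
    for (taxon, hour), sub in diel.groupby(["taxon_id", "peak_hour"]):
        out[(taxon, float(hour))] = set(sub["gene_family_id"])
    return out


def build_contingency(
    bin_universe: set[str],
    taxon_id: str,
    pathway_map: dict[str, set[str]],
    rhythm_results: pd.DataFrame,
    hour: float,
    hours: tuple[float, ...],
    mode: str = "peak",
) -> list[ContingencyTable]:
    """All testable tables for one bin at one hour.

    ``bin_universe`` is every gene family detected in the bin; tables with
    no pathway member detected in the bin (a + b = 0) are dropped.
    """
    if hour not in hours:
        raise ValueError(f"hour {hour!r} is not a sampling hour of the design")
    sub = rhythm_results[rhythm_results["taxon_id"] == taxon_id]
    if mode == "peak":
        diel_at_t = set(
            sub.loc[sub["is_diel"] & (sub["peak_hour"] == hour), "gene_family_id"]
        )
    else:
        diel_at_t = set(sub.loc[sub["is_diel"], "gene_family_id"])
    diel_at_t &= bin_universe
    tables = []
    for pid in sorted(pathway_map):
        members = pathway_map[pid] & bin_universe
        if not members:
            continue
        a = len(members & diel_at_t)
        b = len(members) - a
        c = len(diel_at_t) - a
        d = len(bin_universe) - a - b - c
        tables.append(ContingencyTable(a, b, c, d, taxon_id, pid, hour))
    return tables


def enrich_all(
    bin_universes: dict[str, set[str]],
    pathway_map: dict[str, set[str]],
    rhythm_results: pd.DataFrame,
    hours: tuple[float, ...],
    alpha: float = 0.05,
    mode: str = "peak",
    rank: str = "genus",
    exclude_pathways: set[str] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Test every (bin, hour, pathway) combination with a single BH run.

    Returns the result frame (one row per retained table) and a summary of
    the bookkeeping: combinations enumerated, tables retained after the
    empty-pathway filter, and triples flagged enriched.
    """
    if exclude_pathways:
        pathway_map = {k: v for k, v in pathway_map.items() if k not in exclude_pathways}
    enumerated = len(bin_universes) * len(hours) * len(pathway_map)
    rows = []
    for taxon_id in sorted(bin_universes):
        for hour in hours:
            for tab in build_contingency(
                bin_universes[taxon_id],
                taxon_id,
                pathway_map,
                rhythm_results,
                hour,
                hours,
                mode,
            ):
                odds, p = fisher_greater(tab)
                rows.append(
                    {
                        "taxon_id": tab.taxon_id,
                        "rank": rank,
                        "hour": tab.hour,
                        "pathway_id": tab.pathway_id,
                        "a": tab.a,
                        "b": tab.b,
                        "c": tab.c,
                        "d": tab.d,
                        "odds_ratio": odds,
                        "p_raw": p,
                    }
                )
    df = pd.DataFrame(
        rows,
        columns=["taxon_id", "rank", "hour", "pathway_id", "a", "b", "c", "d", "odds_ratio", "p_raw"],
    )
    if len(df):
        adjusted, flags, critical = bh_adjust(df["p_raw"].to_numpy(), alpha)
    else:
        adjusted, flags, critical = np.array([]), np.array([], dtype=bool), 0.0
    df["p_adjusted"] = adjusted
    df["enriched"] = flags
    summary = {
        "enumerated": int(enumerated),
        "retained": int(len(df)),
        "enriched": int(flags.sum()) if len(df) else 0,
        "alpha": alpha,
        "critical_p": float(critical),
        "mode": mode,
        "rank": rank,
    }
    return df, summary


def pathway_map_from_frame(pathways: pd.DataFrame) -> dict[str, set[str]]:
    """(pathway_id, gene_family_id) long frame -> pathway_id -> family set."""
    return {
        pid: set(sub["gene_family_id"])
        for pid, sub in pathways.groupby("pathway_id")
    }
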