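"""Crosstalk inference: cross-reference a PPI table against DE gene sets.

Curated protein-protein interaction edges (e.g. HIPPIE v2.3) are checked
against two differential-expression results: genes differing between
core- and periphery-resident leukemic B cells, and genes differing among
stromal (BMSC) single-cell clusters (kept only when expressed in at least
10% of cells in some cluster). Each surviving edge is classified:

* ``B_BMSC``  — one partner in the B-cell DE set, the other a qualifying
  stromal gene (a putative tumor-stroma communication channel);
* ``B_B``     — both partners in the B-cell DE set (core/periphery pairs);
* ``self_ligand`` — a self-edge whose gene qualifies on either side.

A gene present in both DE sets yields one record per orientation, flagged.
Condition-exclusive cluster detection (the contact-induced stromal cluster
logic) also lives here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

__all__ = [
    "InteractionRecord",
    "ClusterComposition",
    "read_ppi_table",
    "filter_bmsc_genes",
    "cross_reference",
    "condition_exclusivity",
    "interactions_to_frame",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class InteractionRecord:
    gene_a: str
    gene_b: str
    interaction_class: str  # B_BMSC | B_B | self_ligand
    b_side: tuple[tuple[str, str], ...]  # (gene, direction) pairs
    bmsc_side: tuple[tuple[str, tuple[int, ...]], ...]  # (gene, clusters)
    confidence: float
    dual_membership: bool = False  # some partner sits in both DE sets


@dataclass(frozen=True)
class ClusterComposition:
    cluster: int
    counts: dict[str, int]
    exclusivity: float
    dominant_condition: str
    exclusive: bool


# ---------------------------------------------------------------------------
# input tables

def _canonical_edges(rows: list[tuple[str, str, float]]) -> pd.DataFrame:
    """Uppercase, collapse duplicate unordered pairs keeping max confidence."""
    best: dict[tuple[str, str], float] = {}
    for a, b, conf in rows:
        a, b = a.upper(), b.upper()
        key = (a, b) if a <= b else (b, a)
        if key not in best or conf > best[key]:
            best[key] = conf
    return pd.DataFrame(
        [{"gene_a": a, "gene_b": b, "confidence": c} for (a, b), c in sorted(best.items())]
    )


def read_ppi_table(
    path: str | Path,
    dialect: str = "generic_tsv",
    min_confidence: float = 0.0,
) -> pd.DataFrame:
    """Read a PPI edge table; columns gene_a, gene_b, confidence.

    ``hippie_v23``: native tab format with uniprot-style ``SYMBOL_HUMAN``
    identifiers in columns 1 and 3 and the confidence score in column 5;
    rows whose symbols cannot be resolved are skipped with a logged count.
    ``generic_tsv``: three columns (gene_a, gene_b, confidence), header
    optional. Edges below ``min_confidence`` are dropped; duplicate
    unordered pairs collapse to the maximum confidence; self-edges are kept.
    """
    path = Path(path)
    rows: list[tuple[str, str, float]] = []
    skipped = 0
    with path.open() as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if dialect == "hippie_v23":
                if len(fields) < 5:
                    raise ValueError(
                        f"{path}:{lineno}: malformed HIPPIE row ({len(fields)} columns)"
                    )
                sym_a = fields[0].split("_")[0].strip()
                sym_b = fields[2].split("_")[0].strip()
                if not sym_a or not sym_b:
                    skipped += 1
                    continue
                try:
                    conf = float(fields[4])
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: bad confidence") from exc
            elif dialect == "generic_tsv":
                if len(fields) < 3:
                    raise ValueError(
                        f"{path}:{lineno}: expected 3 columns, got {len(fields)}"
                    )
                sym_a, sym_b = fields[0].strip(), fields[1].strip()
                try:
                    conf = float(fields[2])
                except ValueError:
                    if lineno == 1:  # header row
                        continue
                    raise ValueError(f"{path}:{lineno}: bad confidence") from None
            else:
                raise ValueError(f"unknown dialect {dialect!r}")
            rows.append((sym_a, sym_b, conf))
    if skipped:
        log.info("%s: skipped %d rows with unresolvable symbols", path, skipped)
    edges = _canonical_edges(rows)
    if len(edges):
        edges = edges[edges["confidence"] >= min_confidence].reset_index(drop=True)
    return edges


def de_gene_directions(b_de_table: pd.DataFrame, alpha: float = 0.05) -> dict[str, str]:
    """Significant B-cell DE genes mapped to their direction (core/periphery up)."""
    sig = b_de_table[b_de_table["adj_p"] < alpha]
    return {str(g).upper(): str(d) for g, d in zip(sig["gene"], sig["direction"])}


def filter_bmsc_genes(
    cluster_de_table: pd.DataFrame,
    min_pct: float = 0.10,
    alpha: float = 0.05,
) -> dict[str, tuple[int, ...]]:
    """Stromal genes DE in some cluster and expressed in >=10% of cells somewhere.

    A gene qualifies iff it has adj_p < alpha in at least one cluster contrast
    and pct_expressing >= min_pct (inclusive) in at least one cluster. The
    returned map lists, per qualifying gene, the clusters where pct >= min_pct.
    """
    qualifying: dict[str, tuple[int, ...]] = {}
    for gene, group in cluster_de_table.groupby("gene", sort=True):
        if not (group["adj_p"] < alpha).any():
            continue
        hits = group.loc[group["pct_expressing"] >= min_pct, "cluster"]
        if hits.empty:
            continue
        qualifying[str(gene).upper()] = tuple(sorted(int(c) for c in hits))
    return qualifying


# ---------------------------------------------------------------------------
# cross-referencing

def cross_reference(
    ppi: pd.DataFrame,
    b_de: pd.DataFrame | dict[str, str],
    bmsc_map: dict[str, tuple[int, ...]],
    alpha: float = 0.05,
    b_bmsc_only: bool = False,
) -> list[InteractionRecord]:
    """Classify every PPI edge against the two DE gene sets.

    Output is deterministic: sorted by class, then gene pair. With
    ``b_bmsc_only`` only the tumor-stroma class is emitted (the strict
    methods-text reading); by default the core/periphery ``B_B`` pairs and
    ``self_ligand`` edges reported alongside the network are included too.
    """
    directions = b_de if isinstance(b_de, dict) else de_gene_directions(b_de, alpha)
    records: list[InteractionRecord] = []
    for row in ppi.itertuples():
        a, b = str(row.gene_a).upper(), str(row.gene_b).upper()
        conf = float(row.confidence)
        a_b, b_b = a in directions, b in directions
        a_m, b_m = a in bmsc_map, b in bmsc_map
        if a == b:
            if b_bmsc_only:
                continue
            if a_b or a_m:
                records.append(
                    InteractionRecord(
                        gene_a=a, gene_b=b, interaction_class="self_ligand",
                        b_side=((a, directions[a]),) if a_b else (),
                        bmsc_side=((a, bmsc_map[a]),) if a_m else (),
                        confidence=conf,
                        dual_membership=a_b and a_m,
                    )
                )
            continue
        # tumor-stroma orientations (both emitted when a gene is in both sets)
        for b_gene, m_gene in ((a, b), (b, a)):
            if b_gene in directions and m_gene in bmsc_map:
                records.append(
                    InteractionRecord(
                        gene_a=min(a, b), gene_b=max(a, b),
                        interaction_class="B_BMSC",
                        b_side=((b_gene, directions[b_gene]),),
                        bmsc_side=((m_gene, bmsc_map[m_gene]),),
                        confidence=conf,
                        dual_membership=(b_gene in bmsc_map) or (m_gene in directions),
                    )
                )
        if not b_bmsc_only and a_b and b_b:
            records.append(
                InteractionRecord(
                    gene_a=min(a, b), gene_b=max(a, b), interaction_class="B_B",
                    b_side=tuple(sorted(((a, directions[a]), (b, directions[b])))),
                    bmsc_side=(),
                    confidence=conf,
                    dual_membership=a_m or b_m,
                )
            )
    records.sort(key=lambda r: (r.interaction_class, r.gene_a, r.gene_b, r.b_side))
    return records


def interactions_to_frame(records: list[InteractionRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "gene_a": r.gene_a,
                "gene_b": r.gene_b,
                "class": r.interaction_class,
                "b_side": ";".join(f"{g}:{d}" for g, d in r.b_side),
                "bmsc_side": ";".join(
                    f"{g}:{','.join(map(str, cl))}" for g, cl in r.bmsc_side
                ),
                "confidence": r.confidence,
                "dual_membership": r.dual_membership,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_a", "gene_b", "class", "b_side", "bmsc_side",
            "confidence", "dual_membership",
        ],
    )


# ---------------------------------------------------------------------------
# condition-exclusive clusters

def condition_exclusivity(
    assignments: dict,
    conditions: dict,
    exclusive_min: float = 0.95,
) -> list[ClusterComposition]:
    """Per-cluster condition composition and exclusivity flags.

    Exclusivity is the largest per-condition share of a cluster's cells;
    clusters at or above ``exclusive_min`` are flagged condition-exclusive
    (the signature of a stromal state arising only after tumor contact).
    Cells without a condition raise; empty clusters are skipped.
    """
    missing = [c for c in assignments if c not in conditions]
    if missing:
        raise ValueError(f"{len(missing)} assigned cells lack a condition: {missing[:5]}")
    tallies: dict[int, dict[str, int]] = {}
    for cell, cluster in assignments.items():
        cond = str(conditions[cell])
        tallies.setdefault(int(cluster), {}).setdefault(cond, 0)
        tallies[int(cluster)][cond] += 1
    out = []
    for cluster in sorted(tallies):
        counts = tallies[cluster]
        total = sum(counts.values())
        if total == 0:
            log.warning("cluster %d is empty; excluded", cluster)
            continue
        dominant = max(sorted(counts), key=lambda c: counts[c])
        excl = counts[dominant] / total
        out.append(
            ClusterComposition(
                cluster=cluster,
                counts=dict(sorted(counts.items())),
                exclusivity=excl,
                dominant_condition=dominant,
                exclusive=excl >= exclusive_min,
            )
        )
    return out
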