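"""Gene x xenobiotic interaction mapping from curated chemical-gene records.

Records are filtered to a single organism (human by default) and to a
whitelist of chemicals joined strictly by MeSH ID — chemical names are
display-only.  Surviving records collapse into unique (gene, chemical)
pairs weighted by the number of distinct supporting publications, from
which per-gene and per-chemical degrees and the heatmap matrix derive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd

from .types import ChemicalEntry, InteractionRecord, ValidationError


@dataclass(frozen=True)
class InteractionPair:
    gene_symbol: str
    chemical_mesh_id: str
    chemical_name: str
    group: str
    n_refs: int
    #: True when every supporting record lacked publication identifiers
    unreferenced: bool = False


@dataclass
class DegreeSummary:
    gene_degree: dict[str, int]      # distinct whitelist chemicals per gene
    chemical_degree: dict[str, int]  # distinct genes per chemical (MeSH keyed)

    @property
    def n_pairs(self) -> int:
        return sum(self.gene_degree.values())


def filter_records(records: Iterable[InteractionRecord],
                   whitelist: Sequence[ChemicalEntry],
                   organism: str = "Homo sapiens") -> list[InteractionRecord]:
    """Keep records matching the organism (case-insensitive, trimmed) whose
    chemical MeSH ID is on the whitelist."""
    mesh_ids = {c.mesh_id for c in whitelist}
    if len(mesh_ids) != len(whitelist):
        raise ValidationError("whitelist MeSH IDs are not unique")
    want = organism.strip().lower()
    return [r for r in records
            if r.organism.strip().lower() == want
            and r.chemical_mesh_id in mesh_ids]


def build_pairs(records: Iterable[InteractionRecord],
                whitelist: Sequence[ChemicalEntry]) -> list[InteractionPair]:
    """Deduplicate records into (gene, MeSH ID) pairs.

    ``n_refs`` is the cardinality of the union of PMIDs across the pair's
    records; pairs supported only by records without publication identifiers
    are kept with ``n_refs = 0`` and flagged ``unreferenced``.
    """
    by_mesh = {c.mesh_id: c for c in whitelist}
    acc: dict[tuple[str, str], set[str]] = {}
    for r in records:
        if r.chemical_mesh_id not in by_mesh:
            raise ValidationError(
                f"record chemical {r.chemical_mesh_id!r} not on whitelist; "
                "run filter_records first"
            )
        acc.setdefault((r.gene_symbol, r.chemical_mesh_id), set()).update(r.pmids)
    pairs = []
    for (gene, mesh), pmids in sorted(acc.items()):
        chem = by_mesh[mesh]
        pairs.append(InteractionPair(
            gene_symbol=gene, chemical_mesh_id=mesh, chemical_name=chem.name,
            group=chem.group, n_refs=len(pmids), unreferenced=not pmids,
        ))
    return pairs


def degrees(pairs: Sequence[InteractionPair]) -> DegreeSummary:
    gene_degree: dict[str, int] = {}
    chemical_degree: dict[str, int] = {}
    seen = set()
    for p in pairs:
        key = (p.gene_symbol, p.chemical_mesh_id)
        if key in seen:
            raise ValidationError(f"duplicate pair {key}")
        seen.add(key)
        gene_degree[p.gene_symbol] = gene_degree.get(p.gene_symbol, 0) + 1
        chemical_degree[p.chemical_mesh_id] = \
            chemical_degree.get(p.chemical_mesh_id, 0) + 1
    return DegreeSummary(gene_degree=gene_degree, chemical_degree=chemical_degree)


def degree_ordered_axes(pairs: Sequence[InteractionPair],
                        genes: Sequence[str],
                        whitelist: Sequence[ChemicalEntry]
                        ) -> tuple[list[str], list[str]]:
    """Axes sorted by degree descending, ties alphabetical; zero-degree
    entries are retained at the end of each axis."""
    d = degrees(pairs)
    gene_axis = sorted(genes, key=lambda g: (-d.gene_degree.get(g, 0), g))
    chem_axis = sorted((c.mesh_id for c in whitelist),
                       key=lambda m: (-d.chemical_degree.get(m, 0), m))
    return gene_axis, chem_axis


def matrix(pairs: Sequence[InteractionPair], gene_axis: Sequence[str],
           chemical_axis: Sequence[str]) -> pd.DataFrame:
    """Genes x chemicals reference-count matrix (0 = no pair).

    Cells hold ``n_refs``; a pair with no supporting publications still
    marks its cell with 1 so the pair remains visible in the rendered map.
    Raises when a pair references a gene or chemical off-axis.
    """
    mat = pd.DataFrame(0, index=list(gene_axis), columns=list(chemical_axis),
                       dtype=int)
    for p in pairs:
        if p.gene_symbol not in mat.index:
            raise ValidationError(f"pair gene {p.gene_symbol!r} off the gene axis")
        if p.chemical_mesh_id not in mat.columns:
            raise ValidationError(
                f"pair chemical {p.chemical_mesh_id!r} off the chemical axis"
            )
        mat.loc[p.gene_symbol, p.chemical_mesh_id] = max(p.n_refs, 1)
    return mat


def group_rollup(pairs: Sequence[InteractionPair]) -> dict[str, int]:
    """Convenience: number of pairs per chemical group."""
    out: dict[str, int] = {}
    for p in pairs:
        out[p.group] = out.get(p.group, 0) + 1
    return out


def pct_chemicals_with_pairs(pairs: Sequence[InteractionPair],
                             whitelist: Sequence[ChemicalEntry]) -> float:
    """Percentage of whitelist chemicals with at least one pair (0 dp)."""
    hit = {p.chemical_mesh_id for p in pairs}
    return round(100.0 * len(hit) / len(whitelist))


def write_pairs(pairs: Sequence[InteractionPair], path) -> None:
    pd.DataFrame(
        [(p.gene_symbol, p.chemical_mesh_id, p.chemical_name, p.group,
          p.n_refs, p.unreferenced) for p in pairs],
        columns=["gene", "mesh_id", "chemical", "group", "n_refs", "unreferenced"],
    ).to_csv(path, sep="\t", index=False)


def write_degrees(summary: DegreeSummary, path) -> None:
    rows = [("gene", g, n) for g, n in sorted(summary.gene_degree.items(),
                                              key=lambda kv: (-kv[1], kv[0]))]
    rows += [("chemical", c, n) for c, n in sorted(summary.chemical_degree.items(),
                                                   key=lambda kv: (-kv[1], kv[0]))]
    pd.DataFrame(rows, columns=["axis", "id", "degree"]).to_csv(
        path, sep="\t", index=False)
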