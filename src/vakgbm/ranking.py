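"""Cognate microRNA-gene network construction and the 4-variable rank score.

Within each VAK class, edges join a class-associated microRNA to a
class-associated gene when (a) the binding table predicts the pair and (b) the
two are inversely expressed (opposite fold-regulation signs). Every connected
molecule receives a rank score: the product of -log10(p), |fold regulation|,
binding strength (mean algorithm count over its inverse partners) and the
number of distinct inversely expressed partners. microRNA scores are negative,
mRNA scores positive — the sign encodes the inverse-expression relationship.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import math

import numpy as np
import pandas as pd

from .classify import VAK_A, VAK_B
from .io import BindingTable
from .markers import MarkerResult


@dataclass
class RankedMolecule:
    feature_id: str
    kind: str                 # gene | microRNA
    vak_class: str
    p: float
    fold_regulation: float
    binding_strength: float   # mean n_algorithms over inverse partners
    n_targets: int            # distinct inversely expressed partners
    rank_score: float


@dataclass
class CognateNetwork:
    """Bipartite inverse-expression network for one VAK class.

    ``module`` lists the connected molecules (>= 1 inverse edge) sorted by
    |rank_score| descending, ties broken by |fold_regulation| then feature id.
    """

    vak_class: str
    nodes: list[RankedMolecule] = field(default_factory=list)
    edges: list[tuple[str, str, int]] = field(default_factory=list)  # (miRNA, gene, n_algorithms)

    @property
    def module(self) -> list[RankedMolecule]:
        return sorted(
            self.nodes,
            key=lambda m: (-abs(m.rank_score), -abs(m.fold_regulation), m.feature_id),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(m) for m in self.module])


def rank_score(
    p: float,
    fold_regulation: float,
    binding_strength: float,
    n_targets: int,
    kind: str,
) -> float:
    """Signed product score: (-log10 p) * |fold| * strength * n_targets.

    Negative for microRNAs, positive for mRNAs. Zero whenever the molecule has
    no inverse partners (n_targets or strength zero).
    """
    if p <= 0:
        raise ValueError("p must be in (0, 1]")
    magnitude = (-math.log10(p)) * abs(fold_regulation) * binding_strength * n_targets
    return -magnitude if kind == "microRNA" else magnitude


def inverse_pairs(
    top_genes: pd.DataFrame,
    top_mirnas: pd.DataFrame,
    binding: BindingTable,
) -> list[tuple[str, str, int]]:
    """Edges (miRNA, gene, n_algorithms) for predicted pairs with opposite fold signs."""
    lookup = binding.lookup()
    gene_fold = dict(zip(top_genes["feature_id"], top_genes["fold_regulation"]))
    mirna_fold = dict(zip(top_mirnas["feature_id"], top_mirnas["fold_regulation"]))
    edges = []
    for (m, g), n_alg in lookup.items():
        if m in mirna_fold and g in gene_fold:
            if np.sign(mirna_fold[m]) == -np.sign(gene_fold[g]):
                edges.append((m, g, n_alg))
    return sorted(edges)


def build_cognate_network(
    markers: MarkerResult,
    binding: BindingTable,
    vak_class: str,
    strength_mode: str = "mean",
) -> CognateNetwork:
    """Build the cognate network for one VAK class from the marker top lists.

    Node scores use binding_strength = mean (or sum, per ``strength_mode``) of
    n_algorithms over incident inverse edges and n_targets = number of distinct
    inverse partners. Molecules without any inverse edge are excluded (the
    module is the connected part).
    """
    if vak_class not in (VAK_A, VAK_B):
        raise ValueError(f"unknown VAK class '{vak_class}'")
    if strength_mode not in ("mean", "sum"):
        raise ValueError("strength_mode must be 'mean' or 'sum'")
    table = markers.table.set_index("feature_id")
    gene_ids = markers.top[(vak_class, "gene")]
    mirna_ids = markers.top[(vak_class, "microRNA")]
    top_genes = table.loc[gene_ids].reset_index()
    top_mirnas = table.loc[mirna_ids].reset_index()
    edges = inverse_pairs(top_genes, top_mirnas, binding)

    partners: dict[str, dict[str, list[int]]] = {}
    for m, g, n_alg in edges:
        partners.setdefault(m, {}).setdefault(g, []).append(n_alg)
        partners.setdefault(g, {}).setdefault(m, []).append(n_alg)

    nodes = []
    for fid, partner_map in partners.items():
        row = table.loc[fid]
        counts = [max(v) for v in partner_map.values()]  # one count per distinct partner
        strength = float(np.mean(counts) if strength_mode == "mean" else np.sum(counts))
        n_targets = len(partner_map)
        nodes.append(
            RankedMolecule(
                feature_id=fid,
                kind=str(row["kind"]),
                vak_class=vak_class,
                p=float(row["p"]),
                fold_regulation=float(row["fold_regulation"]),
                binding_strength=strength,
                n_targets=n_targets,
                rank_score=rank_score(
                    float(row["p"]), float(row["fold_regulation"]), strength, n_targets,
                    str(row["kind"]),
                ),
            )
        )
    return CognateNetwork(vak_class=vak_class, nodes=nodes, edges=edges)


def select_signature(
    network_A: CognateNetwork,
    network_B: CognateNetwork,
    size_A: int = 12,
    size_B: int = 13,
) -> tuple[list[str], list[str]]:
    """Top molecules per class module by |rank_score|: the 25-molecule signature.

    Defaults (12 + 13) mirror the reported module sizes. Raises if a module has
    fewer connected molecules than requested, reporting the deficit.
    """
    sets = []
    for net, size in ((network_A, size_A), (network_B, size_B)):
        module = net.module
        if len(module) < size:
            raise ValueError(
                f"{net.vak_class} module has {len(module)} connected molecules, "
                f"{size} requested (deficit {size - len(module)})"
            )
        sets.append([m.feature_id for m in module[:size]])
    return sets[0], sets[1]
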