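"""Two-layer network assembly and Model I/II/III co-regulation classifiers.

Each regulator (a DRBP-SF) carries a transcriptional target set and a
splicing target set.  Three co-regulation patterns connect the layers:

* **Model I** — the regulator hits the *same* gene at both layers
  (promoter binding and pre-RNA binding): the plain intersection of its two
  target sets.
* **Model II** — the regulator transcriptionally regulates a splicing factor
  partner and the two share splicing targets: one assignment per
  ``(regulator, partner SF, shared splicing target)`` triple.
* **Model III** — the mirror image: the regulator splicing-regulates a
  transcription-factor partner and the two share transcriptional targets.

Protein-protein interaction edges act as an optional corroborating filter
(assignments whose regulator-partner pair lacks a sufficiently confident
edge are dropped); Model I assignments have no partner and always pass.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "RegulatorProfile",
    "ModelAssignment",
    "PPIEdge",
    "model_I",
    "model_II",
    "model_III",
    "ppi_filter",
    "disease_annotation",
    "summarize",
    "export_network",
    "read_ppi_table",
    "read_gene_disease_table",
]


@dataclass
class RegulatorProfile:
    """One regulator's called target sets on both layers."""

    regulator: str
    tx_targets: dict[str, str] = field(default_factory=dict)  # gene -> direction
    sp_targets: set[str] = field(default_factory=set)
    n_events: int = 0

    @property
    def tx_set(self) -> set[str]:
        return set(self.tx_targets)


@dataclass(frozen=True)
class ModelAssignment:
    model: str  # 'I' | 'II' | 'III'
    regulator: str
    partner: str | None
    gene: str

    def __post_init__(self) -> None:
        if self.model not in ("I", "II", "III"):
            raise ValueError(f"model must be I, II or III, got {self.model!r}")
        if self.model == "I" and self.partner is not None:
            raise ValueError("Model I assignments carry no partner")
        if self.model in ("II", "III") and self.partner is None:
            raise ValueError(f"Model {self.model} requires a partner")


@dataclass(frozen=True)
class PPIEdge:
    protein_a: str
    protein_b: str
    confidence: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.confidence <= 1.0):
            raise ValueError("PPI confidence must be in [0,1]")

    @property
    def key(self) -> frozenset:
        return frozenset((self.protein_a, self.protein_b))


def model_I(profile: RegulatorProfile) -> set[str]:
    """Genes the regulator targets at both layers."""
    return profile.tx_set & profile.sp_targets


def model_II(
    profile: RegulatorProfile,
    partner_profiles: Mapping[str, RegulatorProfile],
    sf_set: set[str],
) -> list[ModelAssignment]:
    """Triples (regulator, SF partner, shared splicing target).

    Partners are SFs among the regulator's transcriptional targets that have
    their own profile; the regulator itself is never its own partner.
    Candidate SFs lacking a profile are skipped.  Output ordered by
    (partner, gene) for determinism.
    """
    out: list[ModelAssignment] = []
    for partner in sorted(profile.tx_set & sf_set):
        if partner == profile.regulator or partner not in partner_profiles:
            continue
        shared = profile.sp_targets & partner_profiles[partner].sp_targets
        out.extend(
            ModelAssignment("II", profile.regulator, partner, g) for g in sorted(shared)
        )
    return out


def model_III(
    profile: RegulatorProfile,
    partner_profiles: Mapping[str, RegulatorProfile],
    tf_set: set[str],
) -> list[ModelAssignment]:
    """Mirror of Model II: TF partners from the splicing layer, shared
    transcriptional targets."""
    out: list[ModelAssignment] = []
    for partner in sorted(profile.sp_targets & tf_set):
        if partner == profile.regulator or partner not in partner_profiles:
            continue
        shared = profile.tx_set & partner_profiles[partner].tx_set
        out.extend(
            ModelAssignment("III", profile.regulator, partner, g) for g in sorted(shared)
        )
    return out


def ppi_filter(
    assignments: Iterable[ModelAssignment],
    edges: Iterable[PPIEdge],
    min_confidence: float = 0.7,
) -> list[ModelAssignment]:
    """Keep partnerless assignments plus those backed by a PPI edge with
    confidence strictly above ``min_confidence``."""
    if not (0.0 <= min_confidence <= 1.0):
        raise ValueError("min_confidence must be in [0,1]")
    best: dict[frozenset, float] = {}
    for e in edges:
        best[e.key] = max(best.get(e.key, 0.0), e.confidence)
    out = []
    for a in assignments:
        if a.partner is None:
            out.append(a)
        elif best.get(frozenset((a.regulator, a.partner)), 0.0) > min_confidence:
            out.append(a)
    return out


def disease_annotation(
    genes: set[str], gene_disease: Sequence[tuple[str, str]]
) -> dict[str, float | None]:
    """Fraction of ``genes`` annotated to each disease class.

    Duplicate table rows are harmless (set semantics).  An empty gene set
    yields None per class (undefined, not zero).
    """
    by_class: dict[str, set[str]] = {}
    for gene, cls in gene_disease:
        by_class.setdefault(cls, set()).add(gene)
    if not genes:
        return {cls: None for cls in by_class}
    return {cls: len(genes & members) / len(genes) for cls, members in by_class.items()}


def summarize(profiles: Mapping[str, RegulatorProfile]) -> pd.DataFrame:
    """Per-regulator counts: tx targets, sp targets, events, dual (Model I) targets."""
    rows = [
        {
            "regulator": reg,
            "n_tx_targets": len(p.tx_targets),
            "n_sp_targets": len(p.sp_targets),
            "n_events": p.n_events,
            "n_dual_targets": len(model_I(p)),
        }
        for reg, p in sorted(profiles.items())
    ]
    return pd.DataFrame(
        rows, columns=["regulator", "n_tx_targets", "n_sp_targets", "n_events",
                       "n_dual_targets"]
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_ppi_table(path: str | Path) -> list[PPIEdge]:
    df = pd.read_csv(path, sep="\t")
    return [
        PPIEdge(str(r.protein_a), str(r.protein_b), float(r.confidence))
        for r in df.itertuples(index=False)
    ]


def read_gene_disease_table(path: str | Path) -> list[tuple[str, str]]:
    df = pd.read_csv(path, sep="\t")
    return [(str(r.gene_id), str(r.disease_class)) for r in df.itertuples(index=False)]


def export_network(
    profiles: Mapping[str, RegulatorProfile],
    assignments: Sequence[ModelAssignment],
    out_dir: str | Path,
    ppi_edges: Sequence[PPIEdge] = (),
    config: Mapping | None = None,
) -> dict[str, Path]:
    """Write node/edge TSVs plus a JSON run bundle; deterministic ordering.

    Edge types: ``tx-regulates`` (regulator -> tx target, with direction),
    ``splice-regulates`` (regulator -> sp target) and ``ppi``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    models_by_gene: dict[str, set[str]] = {}
    for a in assignments:
        models_by_gene.setdefault(a.gene, set()).add(a.model)

    nodes: dict[str, dict] = {}

    def touch(node: str, role: str) -> None:
        rec = nodes.setdefault(node, {"roles": set(), "models": set()})
        rec["roles"].add(role)
        rec["models"] |= models_by_gene.get(node, set())

    edges: list[tuple[str, str, str, str]] = []
    for reg in sorted(profiles):
        p = profiles[reg]
        touch(reg, "regulator")
        for gene in sorted(p.tx_targets):
            touch(gene, "tx_target")
            edges.append((reg, gene, "tx-regulates", p.tx_targets[gene]))
        for gene in sorted(p.sp_targets):
            touch(gene, "sp_target")
            edges.append((reg, gene, "splice-regulates", "."))
    for e in sorted(ppi_edges, key=lambda e: (e.protein_a, e.protein_b)):
        edges.append((e.protein_a, e.protein_b, "ppi", format(e.confidence, "g")))

    node_path = out_dir / "nodes.tsv"
    with open(node_path, "w") as fh:
        fh.write("node\troles\tmodels\n")
        for node in sorted(nodes):
            rec = nodes[node]
            fh.write(
                f"{node}\t{','.join(sorted(rec['roles']))}"
                f"\t{','.join(sorted(rec['models'])) or '.'}\n"
            )

    edge_path = out_dir / "edges.tsv"
    with open(edge_path, "w") as fh:
        fh.write("source\ttarget\tedge_type\tattr\n")
        for s, t, k, attr in edges:
            fh.write(f"{s}\t{t}\t{k}\t{attr}\n")

    assign_path = out_dir / "assignments.tsv"
    with open(assign_path, "w") as fh:
        fh.write("model\tregulator\tpartner\tgene\n")
        for a in sorted(assignments, key=lambda a: (a.model, a.regulator, a.partner or "", a.gene)):
            fh.write(f"{a.model}\t{a.regulator}\t{a.partner or '.'}\t{a.gene}\n")

    bundle_path = out_dir / "network.json"
    bundle = {
        "n_regulators": len(profiles),
        "n_nodes": len(nodes),
        "n_edges": len(edges),
        "n_assignments": len(assignments),
        "config": dict(config) if config else {},
    }
    with open(bundle_path, "w") as fh:
        json.dump(bundle, fh, indent=2, sort_keys=True)
        fh.write("\n")

    return {"nodes": node_path, "edges": edge_path,
            "assignments": assign_path, "bundle": bundle_path}
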