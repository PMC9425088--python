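"""DNA- and RNA-binding protein (DRBP) catalog construction.

A DRBP is a protein with documented binding evidence for *both* DNA and RNA.
Evidence comes in four classes, ordered by reliability:

    high_throughput > curated_experimental > annotated > predicted

A protein's confidence per molecule is its *best* record for that molecule;
its overall confidence is the *weaker* of the two sides, because an
unsupported side caps how much the dual-binding claim can be trusted.
Proteins with evidence on one side only are not DRBPs.

The DRBP-SF set — the regulators at the center of the two-layer network — is
the plain intersection of the DRBP set with a splicing-factor list.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "EVIDENCE_CLASSES",
    "EvidenceRecord",
    "ProteinConfidence",
    "rank_protein",
    "rank_proteins",
    "identify_drbps",
    "identify_drbp_sfs",
    "read_evidence_table",
    "read_protein_list",
    "catalog_report",
    "DEFAULT_SOURCE_CLASS_MAP",
]

# Ascending reliability; index in this tuple is the comparable rank.
EVIDENCE_CLASSES = ("predicted", "annotated", "curated_experimental", "high_throughput")
_CLASS_RANK = {c: i for i, c in enumerate(EVIDENCE_CLASSES)}

MOLECULES = ("dna", "rna")

# Default mapping from source-database confidence labels to evidence classes,
# editable data rather than code: load-time callers may supply their own map.
DEFAULT_SOURCE_CLASS_MAP: dict[str, str] = {
    "High": "high_throughput",
    "Medium": "annotated",
    "Low": "annotated",
    "Experimental": "curated_experimental",
    "Predicted": "predicted",
}


@dataclass(frozen=True)
class EvidenceRecord:
    protein: str
    molecule: str  # 'dna' or 'rna'
    evidence_class: str
    source: str = ""

    def __post_init__(self) -> None:
        if self.molecule not in MOLECULES:
            raise ValueError(f"molecule must be in {MOLECULES}, got {self.molecule!r}")
        if self.evidence_class not in _CLASS_RANK:
            raise ValueError(
                f"evidence_class must be in {EVIDENCE_CLASSES}, got {self.evidence_class!r}"
            )


@dataclass(frozen=True)
class ProteinConfidence:
    protein: str
    dna_level: str | None
    rna_level: str | None

    @property
    def overall(self) -> str | None:
        """The weaker of the DNA and RNA sides; None unless both sides exist."""
        if self.dna_level is None or self.rna_level is None:
            return None
        return min(self.dna_level, self.rna_level, key=_CLASS_RANK.__getitem__)


def rank_protein(records: Iterable[EvidenceRecord]) -> ProteinConfidence:
    """Collapse one protein's evidence records into a confidence profile."""
    records = list(records)
    if not records:
        raise ValueError("no evidence records supplied")
    proteins = {r.protein for r in records}
    if len(proteins) != 1:
        raise ValueError(f"records span multiple proteins: {sorted(proteins)}")
    best: dict[str, str | None] = {"dna": None, "rna": None}
    for r in records:
        cur = best[r.molecule]
        if cur is None or _CLASS_RANK[r.evidence_class] > _CLASS_RANK[cur]:
            best[r.molecule] = r.evidence_class
    return ProteinConfidence(proteins.pop(), best["dna"], best["rna"])


def rank_proteins(records: Iterable[EvidenceRecord]) -> list[ProteinConfidence]:
    """Group records by protein and rank each; output sorted by protein id."""
    by_protein: dict[str, list[EvidenceRecord]] = {}
    for r in records:
        by_protein.setdefault(r.protein, []).append(r)
    return [rank_protein(by_protein[p]) for p in sorted(by_protein)]


def identify_drbps(
    confidences: Iterable[ProteinConfidence], min_level: str | None = None
) -> set[str]:
    """Proteins whose overall (dual-binding) confidence is defined and >= min_level."""
    if min_level is not None and min_level not in _CLASS_RANK:
        raise ValueError(f"unknown evidence class {min_level!r}")
    floor = -1 if min_level is None else _CLASS_RANK[min_level]
    return {
        c.protein
        for c in confidences
        if c.overall is not None and _CLASS_RANK[c.overall] >= floor
    }


def identify_drbp_sfs(drbps: set[str], sfs: set[str]) -> set[str]:
    """DRBPs that are also splicing factors."""
    return set(drbps) & set(sfs)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_evidence_table(
    path: str | Path, source_class_map: Mapping[str, str] | None = None
) -> list[EvidenceRecord]:
    """Read the evidence TSV (protein, molecule, evidence_class, source).

    If the evidence_class column carries source-confidence labels instead of
    class names, ``source_class_map`` translates them at load time.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"protein", "molecule", "evidence_class"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: needs columns {sorted(required)}")
    records = []
    for row in df.itertuples(index=False):
        cls = row.evidence_class
        if source_class_map and cls in source_class_map:
            cls = source_class_map[cls]
        records.append(
            EvidenceRecord(
                protein=row.protein,
                molecule=row.molecule,
                evidence_class=cls,
                source=getattr(row, "source", "") or "",
            )
        )
    return records


def read_protein_list(path: str | Path) -> set[str]:
    """One protein symbol per line; blank lines and '#' comments skipped."""
    out = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.add(line)
    return out


def catalog_report(
    confidences: Iterable[ProteinConfidence], sfs: set[str]
) -> pd.DataFrame:
    """Per-protein report: dna_level, rna_level, overall, is_sf; sorted by id."""
    rows = [
        {
            "protein": c.protein,
            "dna_level": c.dna_level or "none",
            "rna_level": c.rna_level or "none",
            "overall": c.overall or "none",
            "is_sf": c.protein in sfs,
        }
        for c in confidences
    ]
    return pd.DataFrame(rows).sort_values("protein").reset_index(drop=True)
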