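"""Splicing-layer target inference from replicate PSI values and eCLIP peaks.

An alternative-splicing event (exon skipping ES, alternative 3'/5' splice
site A3SS/A5SS, intron retention RI) carries per-replicate percent-spliced-in
(PSI) values under control and knockdown conditions.  An event is
*differential* when |ΔPSI| = |mean(kd) − mean(ctrl)| clears an effect-size
gate and a Welch two-sample t-test on the replicate PSI values is significant.
A gene is a splicing target via the event route when at least one of its
events is both differential and bound (a stranded eCLIP peak overlaps the
flanked event span); a parallel gene-body-binding flag records whether the
regulator binds anywhere in the gene region, which the motif workflow uses.

With only two replicates per condition — the typical shRNA knockdown design —
the t-test is underpowered and the ΔPSI gate does most of the work; this is a
deliberately simple differential caller, not a hierarchical count model.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genomic import GeneModel, Interval, Peak, peaks_in_gene_body

__all__ = [
    "EVENT_TYPES",
    "ASEvent",
    "EventCall",
    "SpTargetCall",
    "compute_psi",
    "differential_event",
    "event_binding",
    "call_sp_targets",
    "read_event_table",
    "write_event_table",
]

EVENT_TYPES = ("ES", "A3SS", "A5SS", "RI")


@dataclass(frozen=True)
class ASEvent:
    event_id: str
    gene_id: str
    event_type: str
    interval: Interval
    psi_ctrl: tuple[float, ...]
    psi_kd: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise ValueError(f"event_type must be in {EVENT_TYPES}, got {self.event_type!r}")
        for psi in (*self.psi_ctrl, *self.psi_kd):
            if not (0.0 <= psi <= 1.0):
                raise ValueError(f"PSI values must be in [0,1], got {psi}")

    @property
    def dpsi(self) -> float:
        """ΔPSI = mean knockdown PSI − mean control PSI."""
        return float(np.mean(self.psi_kd) - np.mean(self.psi_ctrl))


@dataclass(frozen=True)
class EventCall:
    event_id: str
    label: str  # included_up | included_down | none | untestable
    dpsi: float
    p: float | None


@dataclass(frozen=True)
class SpTargetCall:
    gene_id: str
    n_events: int
    event_ids: tuple[str, ...]
    any_body_binding: bool


def compute_psi(inclusion_count: int, exclusion_count: int) -> float:
    """PSI = inclusion / (inclusion + exclusion)."""
    if inclusion_count < 0 or exclusion_count < 0:
        raise ValueError("counts must be non-negative")
    total = inclusion_count + exclusion_count
    if total == 0:
        raise ValueError("PSI undefined: both inclusion and exclusion counts are zero")
    return inclusion_count / total


def differential_event(
    event: ASEvent, dpsi_thresh: float = 0.05, alpha: float = 0.05
) -> EventCall:
    """Call one event differential via the ΔPSI gate plus Welch's t-test.

    Label is ``included_up``/``included_down`` by the sign of ΔPSI when both
    |ΔPSI| >= dpsi_thresh and p < alpha; ``untestable`` below the 2-replicate
    floor.
    """
    if len(event.psi_ctrl) < 2 or len(event.psi_kd) < 2:
        return EventCall(event.event_id, "untestable", event.dpsi, None)
    dpsi = event.dpsi
    if np.allclose(event.psi_ctrl, event.psi_ctrl[0]) and np.allclose(
        event.psi_kd, event.psi_kd[0]
    ) and np.isclose(event.psi_ctrl[0], event.psi_kd[0]):
        # degenerate: all replicates identical across conditions
        return EventCall(event.event_id, "none", 0.0, 1.0)
    t = stats.ttest_ind(event.psi_kd, event.psi_ctrl, equal_var=False)
    p = float(t.pvalue)
    if np.isnan(p):  # zero variance in both groups but unequal means
        p = 0.0
    if abs(dpsi) >= dpsi_thresh and p < alpha:
        label = "included_up" if dpsi > 0 else "included_down"
    else:
        label = "none"
    return EventCall(event.event_id, label, dpsi, p)


def event_binding(event: ASEvent, peaks: Sequence[Peak], flank: int = 300) -> bool:
    """True when a strand-matched eCLIP peak overlaps the flanked event span.

    The span is ``[start - flank, end + flank)`` (clipped at zero) on the
    event's chromosome; unstranded peaks match any strand.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    lo = max(0, event.interval.start - flank)
    hi = event.interval.end + flank
    for p in peaks:
        if p.interval.chrom != event.interval.chrom:
            continue
        if p.interval.strand != "." and event.interval.strand != "." and \
                p.interval.strand != event.interval.strand:
            continue
        if p.interval.start < hi and lo < p.interval.end:
            return True
    return False


def call_sp_targets(
    events: Sequence[ASEvent],
    peaks: Sequence[Peak],
    genes: Sequence[GeneModel],
    dpsi_thresh: float = 0.05,
    alpha: float = 0.05,
    flank: int = 300,
) -> tuple[dict[str, SpTargetCall], dict[str, int], list[EventCall]]:
    """Splicing-layer call for one regulator.

    Returns ``(targets, per_type_counts, event_calls)``: a gene is a target
    when >=1 of its events is differential AND bound; every gene with any
    body-level binding is additionally flagged (the ``any_body_binding``
    route used by the motif workflow).  ``per_type_counts`` counts
    differential+bound events per event type.
    """
    gene_by_id = {g.gene_id: g for g in genes}
    event_calls: list[EventCall] = []
    support: dict[str, list[str]] = {}
    per_type = {t: 0 for t in EVENT_TYPES}

    for ev in events:
        if ev.gene_id not in gene_by_id:
            raise ValueError(f"event {ev.event_id} references unknown gene {ev.gene_id}")
        call = differential_event(ev, dpsi_thresh=dpsi_thresh, alpha=alpha)
        event_calls.append(call)
        if call.label in ("included_up", "included_down") and event_binding(ev, peaks, flank):
            support.setdefault(ev.gene_id, []).append(ev.event_id)
            per_type[ev.event_type] += 1

    body_binding = {
        g.gene_id: bool(peaks_in_gene_body(g, peaks, stranded=True)) for g in genes
    }
    targets: dict[str, SpTargetCall] = {}
    for gid, ev_ids in support.items():
        targets[gid] = SpTargetCall(gid, len(ev_ids), tuple(ev_ids), body_binding[gid])
    return targets, per_type, event_calls


# ---------------------------------------------------------------------------
# I/O — event table TSV
# ---------------------------------------------------------------------------

def read_event_table(path: str | Path) -> list[ASEvent]:
    """Read the AS event TSV.

    Fixed columns: event_id, gene_id, event_type, chrom, start, end, strand.
    Replicate columns are either ``psi_ctrl_<i>``/``psi_kd_<i>`` or count
    pairs ``inc_ctrl_<i>``/``exc_ctrl_<i>`` (same for kd), converted with
    :func:`compute_psi`.
    """
    df = pd.read_csv(path, sep="\t")
    psi_ctrl_cols = sorted(c for c in df.columns if c.startswith("psi_ctrl_"))
    psi_kd_cols = sorted(c for c in df.columns if c.startswith("psi_kd_"))
    inc_ctrl_cols = sorted(c for c in df.columns if c.startswith("inc_ctrl_"))
    inc_kd_cols = sorted(c for c in df.columns if c.startswith("inc_kd_"))

    events = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        if psi_ctrl_cols:
            ctrl = tuple(float(d[c]) for c in psi_ctrl_cols)
            kd = tuple(float(d[c]) for c in psi_kd_cols)
        elif inc_ctrl_cols:
            ctrl = tuple(
                compute_psi(int(d[c]), int(d[c.replace("inc_", "exc_")]))
                for c in inc_ctrl_cols
            )
            kd = tuple(
                compute_psi(int(d[c]), int(d[c.replace("inc_", "exc_")]))
                for c in inc_kd_cols
            )
        else:
            raise ValueError(f"{path}: no psi_* or inc_*/exc_* replicate columns found")
        events.append(
            ASEvent(
                event_id=str(d["event_id"]),
                gene_id=str(d["gene_id"]),
                event_type=str(d["event_type"]),
                interval=Interval(str(d["chrom"]), int(d["start"]), int(d["end"]), str(d["strand"])),
                psi_ctrl=ctrl,
                psi_kd=kd,
            )
        )
    return events


def write_event_table(events: Iterable[ASEvent], path: str | Path) -> None:
    events = list(events)
    if not events:
        raise ValueError("no events to write")
    n_ctrl = len(events[0].psi_ctrl)
    n_kd = len(events[0].psi_kd)
    cols = (
        ["event_id", "gene_id", "event_type", "chrom", "start", "end", "strand"]
        + [f"psi_ctrl_{i+1}" for i in range(n_ctrl)]
        + [f"psi_kd_{i+1}" for i in range(n_kd)]
    )
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for ev in events:
            iv = ev.interval
            row = [ev.event_id, ev.gene_id, ev.event_type, iv.chrom,
                   str(iv.start), str(iv.end), iv.strand]
            row += [format(x, ".6f") for x in ev.psi_ctrl]
            row += [format(x, ".6f") for x in ev.psi_kd]
            fh.write("\t".join(row) + "\n")


def write_sp_targets(
    targets: dict[str, SpTargetCall], per_type: dict[str, int], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tn_events\tevent_ids\tany_body_binding\n")
        for gid in sorted(targets):
            t = targets[gid]
            fh.write(f"{gid}\t{t.n_events}\t{','.join(t.event_ids)}\t{int(t.any_body_binding)}\n")
        fh.write("# per-type differential bound events: "
                 + ", ".join(f"{k}={per_type[k]}" for k in per_type) + "\n")
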