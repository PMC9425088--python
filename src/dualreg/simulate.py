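"""Seed-reproducible synthetic datasets with planted two-layer network structure.

The generator emulates the input landscape of a four-regulator two-layer
study: a single-chromosome genome with non-overlapping gene bodies; per
regulator a ChIP-seq peak file, an eCLIP peak file, a knockdown
differential-expression table and an alternative-splicing event table; a
motif file; protein evidence for the catalog stage; PPI edges and a
gene-disease table.  Every file is written in exactly the formats the
analysis modules consume, and a ground-truth bundle records what was
planted so recovery can be scored.

Generative conventions (stated assumptions, not estimates from data):

* True transcriptional targets receive ``n_peaks_per_target`` ChIP peaks at
  half-normal ``|N(0, tx_peak_sd)|`` offsets from their TSS, a strong
  log2 fold change of the regulator's direction, and a very small adjusted
  p (log-uniform in [1e-8, 1e-4]).
* Decoy differentially expressed genes emulate indirect/secondary expression
  responses: real DE status but adjusted p log-uniform in [1e-3, 9e-3] and
  no planted binding — they populate the candidate pool the rank-product
  integration has to sort.
* Background ChIP/eCLIP peaks fall uniformly on the chromosome at
  ``peak_noise_rate`` / ``eclip_noise_rate`` peaks per gene.
* True splicing targets carry one differential event (|ΔPSI| = psi_effect
  plus replicate noise) with an overlapping strand-matched eCLIP peak;
  other events are null.
* Planted Model II/III structure links regulator pairs through shared
  targets; ground-truth Model I/II/III assignments are then *derived* by
  applying the set classifiers to the true target sets, so incidental
  overlaps between planted sets count as truth too.
* Regulator motif instances (sampled from an IUPAC consensus) are embedded
  at peak centers of Model-I genes: a ``direct_fraction`` of them get the
  regulator's own motif, the rest a partner regulator's motif (indirect).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import network as net
from .genomic import (
    GeneModel,
    Interval,
    Peak,
    reverse_complement,
    write_bed,
    write_fasta,
    write_gene_table,
)
from .motifs import IUPAC_DNA, PWM, iupac_to_pwm, write_meme_motifs
from .splicing import ASEvent, write_event_table

__all__ = ["SimConfig", "simulate_genome", "simulate_two_layer", "recovery_report"]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

DEFAULT_CONSENSI = ("CCAWMCCKCC", "GGTAKGGRCA", "TTCYRCTSAA", "CATCMGCWGT")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic two-layer benchmark."""

    n_genes: int = 300
    n_regulators: int = 4
    chrom_length: int = 12_000_000
    fraction_tf: float = 0.15
    fraction_sf: float = 0.15
    # transcriptional layer
    n_tx_targets_per_direction: int = 20
    n_decoy_de_per_direction: int = 65
    n_peaks_per_target: int = 5
    tx_peak_sd: float = 20_000.0
    decoy_peak_sd: float = 60_000.0
    peak_noise_rate: float = 0.1  # background ChIP peaks per gene
    de_effect: float = 2.5  # mean |log2FC| of true targets
    de_lfc_sd: float = 0.3
    # splicing layer
    n_sp_targets: int = 40
    psi_effect: float = 0.3  # planted |ΔPSI|
    psi_noise_sd: float = 0.02
    replicates: int = 3
    eclip_noise_rate: float = 0.1
    # co-regulation models
    n_model1: int = 10
    n_model2_triples: int = 10
    n_model3_triples: int = 10
    # motifs
    motif_consensus: tuple[str, ...] = DEFAULT_CONSENSI
    direct_fraction: float = 0.7
    motif_p_thresh: float = 1e-5
    seed: int = 1

    def __post_init__(self) -> None:
        if self.chrom_length < self.n_genes * 10_000:
            raise ValueError("chrom_length must be >= n_genes * 10 kb")
        for frac in (self.fraction_tf, self.fraction_sf, self.direct_fraction):
            if not (0.0 <= frac <= 1.0):
                raise ValueError("fractions must be in [0,1]")
        if self.n_genes < self.n_regulators + 2 * self.n_tx_targets_per_direction:
            raise ValueError("not enough genes for the planted targets")
        if self.n_regulators > len(self.motif_consensus):
            raise ValueError("need one motif consensus per regulator")
        if self.n_model1 > 2 * self.n_tx_targets_per_direction:
            raise ValueError("n_model1 exceeds planted transcriptional targets")
        if self.n_model1 > self.n_sp_targets:
            raise ValueError("n_model1 exceeds planted splicing targets")


# ---------------------------------------------------------------------------
# Genome
# ---------------------------------------------------------------------------

def simulate_genome(config: SimConfig, rng: np.random.Generator | None = None
                    ) -> tuple[list[GeneModel], dict[str, str], np.ndarray]:
    """Gene annotation plus an i.i.d. ACGT genome.

    Gene bodies occupy disjoint slots of chrom_length / n_genes bp with
    jittered starts; every regulator gene is flagged TF and SF.  Returns
    ``(genes, genome, seq_array)`` where ``seq_array`` is the mutable uint8
    view used for motif embedding.
    """
    rng = rng or np.random.default_rng(config.seed)
    seq = _BASES[rng.integers(0, 4, size=config.chrom_length)]
    slot = config.chrom_length // config.n_genes
    if slot < 10_000:
        raise ValueError("infeasible gene packing")
    genes: list[GeneModel] = []
    # regulator genes spread evenly through the chromosome
    reg_idx = set(
        int(i) for i in np.linspace(0, config.n_genes - 1, config.n_regulators + 2)[1:-1]
    )
    while len(reg_idx) < config.n_regulators:  # degenerate tiny-n fallback
        reg_idx.add(len(reg_idx))
    reg_idx = set(sorted(reg_idx)[: config.n_regulators])

    for i in range(config.n_genes):
        body_len = int(rng.integers(5_000, min(10_000, slot - 1_000)))
        start = i * slot + int(rng.integers(0, slot - body_len))
        strand = "+" if rng.random() < 0.5 else "-"
        gid = f"G{i:04d}"
        is_reg = i in reg_idx
        genes.append(
            GeneModel(
                gene_id=gid,
                symbol=gid,
                interval=Interval("chr1", start, start + body_len, strand),
                is_tf=is_reg or rng.random() < config.fraction_tf,
                is_sf=is_reg or rng.random() < config.fraction_sf,
            )
        )
    genome = {"chr1": seq.tobytes().decode("ascii")}
    return genes, genome, seq


# ---------------------------------------------------------------------------
# Two-layer bundle
# ---------------------------------------------------------------------------

def _sample_iupac_word(consensus: str, rng: np.random.Generator) -> str:
    return "".join(
        IUPAC_DNA[ch][int(rng.integers(0, len(IUPAC_DNA[ch])))] for ch in consensus.upper()
    )


def _embed(seq: np.ndarray, pos: int, word: str) -> None:
    arr = np.frombuffer(word.encode("ascii"), dtype=np.uint8)
    lo = max(0, min(pos, len(seq) - len(arr)))
    seq[lo : lo + len(arr)] = arr


def _chip_peak(center: int, rng: np.random.Generator, chrom_len: int) -> Peak:
    half = int(rng.integers(75, 200))
    lo = max(0, min(center - half, chrom_len - 2 * half - 1))
    return Peak(Interval("chr1", lo, lo + 2 * half, "."),
                score=float(np.round(rng.uniform(5, 100), 3)), assay="chip")


def simulate_two_layer(config: SimConfig, out_dir: str | Path) -> dict:
    """Write the full dataset bundle plus ground truth; returns the truth dict."""
    rng = np.random.default_rng(config.seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    genes, genome, seq = simulate_genome(config, rng)
    by_id = {g.gene_id: g for g in genes}
    # regulator genes are the evenly spaced ones forced TF+SF in simulate_genome
    reg_positions = set(
        int(i) for i in np.linspace(0, config.n_genes - 1, config.n_regulators + 2)[1:-1]
    )
    while len(reg_positions) < config.n_regulators:
        reg_positions.add(len(reg_positions))
    regulators = [f"G{i:04d}" for i in sorted(reg_positions)[: config.n_regulators]]

    non_reg = [g.gene_id for g in genes if g.gene_id not in regulators]
    R = len(regulators)

    # --- planted model II/III pairs -------------------------------------
    pairs2 = [(k, (k + 1) % R) for k in range(0, R - 1, 2)] if R > 1 else []
    pairs3 = [(k, (k + 1) % R) for k in range(1, R, 2)] if R > 1 else []
    share2 = max(1, config.n_model2_triples // max(1, len(pairs2))) if pairs2 else 0
    share3 = max(1, config.n_model3_triples // max(1, len(pairs3))) if pairs3 else 0

    # --- true target sets ------------------------------------------------
    tx_truth: dict[str, dict[str, str]] = {r: {} for r in regulators}
    sp_truth: dict[str, set[str]] = {r: set() for r in regulators}

    for k, r in enumerate(regulators):
        picks = rng.choice(non_reg, size=2 * config.n_tx_targets_per_direction,
                           replace=False)
        for j, gid in enumerate(picks):
            tx_truth[r][str(gid)] = "up" if j < config.n_tx_targets_per_direction else "down"
        sp_picks = rng.choice(non_reg, size=config.n_sp_targets, replace=False)
        sp_truth[r].update(str(g) for g in sp_picks)
        # Model I: force n_model1 tx targets into the splicing set too
        m1 = list(tx_truth[r])[: config.n_model1]
        sp_truth[r].update(m1)

    for (a, b) in pairs2:  # f=reg[a] tx-regulates reg[b]; shared splicing targets
        f, s = regulators[a], regulators[b]
        tx_truth[f][s] = "up"
        shared = rng.choice(non_reg, size=share2, replace=False)
        sp_truth[f].update(str(g) for g in shared)
        sp_truth[s].update(str(g) for g in shared)

    for (a, b) in pairs3:  # f=reg[a] splice-regulates reg[b]; shared tx targets
        f, t = regulators[a], regulators[b]
        sp_truth[f].add(t)
        shared = rng.choice(non_reg, size=share3, replace=False)
        for g in shared:
            tx_truth[f].setdefault(str(g), "up")
            tx_truth[t].setdefault(str(g), "up")

    # --- ground-truth model assignments from the true sets ---------------
    sf_set = {g.gene_id for g in genes if g.is_sf}
    tf_set = {g.gene_id for g in genes if g.is_tf}
    true_profiles = {
        r: net.RegulatorProfile(r, dict(tx_truth[r]), set(sp_truth[r]))
        for r in regulators
    }
    truth_m1 = {r: sorted(net.model_I(true_profiles[r])) for r in regulators}
    truth_m2 = [
        (a.regulator, a.partner, a.gene)
        for r in regulators
        for a in net.model_II(true_profiles[r], true_profiles, sf_set)
    ]
    truth_m3 = [
        (a.regulator, a.partner, a.gene)
        for r in regulators
        for a in net.model_III(true_profiles[r], true_profiles, tf_set)
    ]

    # --- per-regulator emissions ------------------------------------------
    pwms = {
        r: iupac_to_pwm(config.motif_consensus[k], alphabet="dna", pseudocount=0.0,
                        name=r)
        for k, r in enumerate(regulators)
    }
    binding_truth: dict[str, dict[str, dict]] = {r: {} for r in regulators}
    event_counter = 0

    for k, r in enumerate(regulators):
        # decoys: secondary expression responders with one weak distal peak
        decoys = rng.choice(
            [g for g in non_reg if g not in tx_truth[r]],
            size=2 * config.n_decoy_de_per_direction, replace=False,
        )
        decoy_index = {str(g): j for j, g in enumerate(decoys)}

        chip: list[Peak] = []
        first_chip_center: dict[str, int] = {}
        for gid in tx_truth[r]:
            tss = by_id[gid].tss
            for p_i in range(config.n_peaks_per_target):
                offset = int(abs(rng.normal(0.0, config.tx_peak_sd)))
                sign = -1 if rng.random() < 0.5 else 1
                center = int(np.clip(tss + sign * offset, 100, config.chrom_length - 100))
                if p_i == 0:
                    first_chip_center[gid] = center
                chip.append(_chip_peak(center, rng, config.chrom_length))
        for gid in decoy_index:
            tss = by_id[gid].tss
            offset = int(abs(rng.normal(0.0, config.decoy_peak_sd)))
            sign = -1 if rng.random() < 0.5 else 1
            center = int(np.clip(tss + sign * offset, 100, config.chrom_length - 100))
            chip.append(_chip_peak(center, rng, config.chrom_length))
        n_noise = rng.poisson(config.peak_noise_rate * config.n_genes)
        for _ in range(n_noise):
            center = int(rng.integers(200, config.chrom_length - 200))
            chip.append(_chip_peak(center, rng, config.chrom_length))
        chip.sort(key=lambda p: (p.interval.start, p.interval.end))
        write_bed(chip, out / f"chip_{r}.bed")

        # DE table
        de_rows = []
        for g in genes:
            gid = g.gene_id
            if gid in tx_truth[r]:
                sign = 1.0 if tx_truth[r][gid] == "up" else -1.0
                lfc = sign * max(1.2, rng.normal(config.de_effect, config.de_lfc_sd))
                adj_p = 10.0 ** rng.uniform(-8, -4)
            elif gid in decoy_index:
                sign = 1.0 if decoy_index[gid] < config.n_decoy_de_per_direction else -1.0
                lfc = sign * max(1.2, rng.normal(config.de_effect, config.de_lfc_sd))
                adj_p = 10.0 ** rng.uniform(-3.0, np.log10(0.009))
            else:
                lfc = float(np.clip(rng.normal(0.0, 0.3), -0.95, 0.95))
                adj_p = rng.uniform(0.02, 1.0)
            de_rows.append((gid, lfc, adj_p))
        with open(out / f"de_{r}.tsv", "w") as fh:
            fh.write("gene_id\tlog2fc\tadj_p\n")
            for gid, lfc, adj_p in de_rows:
                fh.write(f"{gid}\t{lfc:.4f}\t{adj_p:.6g}\n")

        # splicing events + eCLIP peaks
        events: list[ASEvent] = []
        eclip: list[Peak] = []
        bound_event_peak_center: dict[str, int] = {}
        for g in genes:
            gid = g.gene_id
            is_target = gid in sp_truth[r]
            n_ev = 2 if is_target else 1
            for e_i in range(n_ev):
                event_counter += 1
                etype = ("ES", "A3SS", "A5SS", "RI")[event_counter % 4]
                body = g.interval
                ev_len = int(rng.integers(500, min(2000, body.length - 10)))
                ev_start = body.start + int(rng.integers(0, body.length - ev_len))
                iv = Interval(body.chrom, ev_start, ev_start + ev_len, g.strand)
                base = rng.uniform(0.3, 0.7)
                differential = is_target and e_i == 0
                if differential:
                    sign = 1.0 if rng.random() < 0.5 else -1.0
                    dpsi = sign * config.psi_effect
                    if not (0.05 <= base + dpsi <= 0.95):
                        dpsi = -dpsi
                else:
                    dpsi = 0.0
                ctrl = np.clip(
                    base + rng.normal(0, config.psi_noise_sd, config.replicates),
                    0.01, 0.99,
                )
                kd = np.clip(
                    base + dpsi + rng.normal(0, config.psi_noise_sd, config.replicates),
                    0.01, 0.99,
                )
                ev = ASEvent(f"E{event_counter:05d}", gid, etype, iv,
                             tuple(np.round(ctrl, 6)), tuple(np.round(kd, 6)))
                events.append(ev)
                if differential:
                    center = iv.center + int(rng.integers(-ev_len // 4, ev_len // 4))
                    half = int(rng.integers(20, 40))
                    eclip.append(
                        Peak(Interval("chr1", max(0, center - half), center + half,
                                      g.strand),
                             score=float(np.round(rng.uniform(2, 50), 3)), assay="eclip")
                    )
                    bound_event_peak_center[gid] = center
        n_noise_ec = rng.poisson(config.eclip_noise_rate * config.n_genes)
        for _ in range(n_noise_ec):
            center = int(rng.integers(100, config.chrom_length - 100))
            half = int(rng.integers(20, 40))
            strand = "+" if rng.random() < 0.5 else "-"
            eclip.append(Peak(Interval("chr1", center - half, center + half, strand),
                              score=float(np.round(rng.uniform(2, 50), 3)), assay="eclip"))
        eclip.sort(key=lambda p: (p.interval.start, p.interval.end))
        write_bed(eclip, out / f"eclip_{r}.bed")
        write_event_table(events, out / f"events_{r}.tsv")

        # motif embedding + direct/indirect truth for Model-I genes
        partner = regulators[(k + 1) % R]
        for gid in truth_m1[r]:
            modes = {}
            for layer, center_map in (("dna", first_chip_center),
                                      ("rna", bound_event_peak_center)):
                if gid not in center_map:
                    continue
                direct = rng.random() < config.direct_fraction
                src = r if direct else partner
                word = _sample_iupac_word(config.motif_consensus[regulators.index(src)], rng)
                if layer == "rna" and by_id[gid].strand == "-":
                    word = reverse_complement(word)
                _embed(seq, center_map[gid] - len(word) // 2, word)
                modes[layer] = {"mode": "direct" if direct else "indirect",
                                "partner": None if direct else src}
            binding_truth[r][gid] = modes

    # genome written after embedding
    genome = {"chr1": seq.tobytes().decode("ascii")}
    write_fasta(genome, out / "genome.fa")
    write_gene_table(genes, out / "genes.tsv")
    write_meme_motifs([pwms[r] for r in regulators], out / "motifs.meme")

    # --- catalog inputs ---------------------------------------------------
    with open(out / "evidence.tsv", "w") as fh:
        fh.write("protein\tmolecule\tevidence_class\tsource\n")
        for r in regulators:
            fh.write(f"{r}\tdna\thigh_throughput\tsim_chip\n")
            fh.write(f"{r}\trna\thigh_throughput\tsim_eclip\n")
        # distractors: one-sided or low-evidence proteins
        others = [g for g in non_reg[:20]]
        for i, p in enumerate(others):
            if i % 3 == 0:
                fh.write(f"{p}\tdna\tcurated_experimental\tsim_db\n")
            elif i % 3 == 1:
                fh.write(f"{p}\trna\tannotated\tsim_db\n")
            else:
                fh.write(f"{p}\tdna\tpredicted\tsim_pred\n")
                fh.write(f"{p}\trna\tpredicted\tsim_pred\n")
    with open(out / "sf_list.txt", "w") as fh:
        for s in sorted(sf_set):
            fh.write(s + "\n")

    # --- PPI + disease ----------------------------------------------------
    ppi_rows = []
    for (a, b) in pairs2 + pairs3:
        ppi_rows.append((regulators[a], regulators[b],
                         float(np.round(rng.uniform(0.75, 0.95), 3))))
    for _ in range(30):
        pa, pb = rng.choice(config.n_genes, size=2, replace=False)
        ppi_rows.append((f"G{pa:04d}", f"G{pb:04d}",
                         float(np.round(rng.uniform(0.1, 0.6), 3))))
    with open(out / "ppi.tsv", "w") as fh:
        fh.write("protein_a\tprotein_b\tconfidence\n")
        for a, b, c in ppi_rows:
            fh.write(f"{a}\t{b}\t{c:g}\n")

    disease_rows = []
    coreg = set()
    for r in regulators:
        coreg |= set(truth_m1[r])
    coreg |= {g for (_, _, g) in truth_m2} | {g for (_, _, g) in truth_m3}
    for gid in sorted(coreg):
        if rng.random() < 0.8:
            disease_rows.append((gid, "neoplastic process"))
            if rng.random() < 0.4:
                disease_rows.append((gid, "leukemia"))
    for g in genes:
        if g.gene_id not in coreg and rng.random() < 0.2:
            disease_rows.append((g.gene_id, "neoplastic process"))
    with open(out / "gene_disease.tsv", "w") as fh:
        fh.write("gene_id\tdisease_class\n")
        for gid, cls in disease_rows:
            fh.write(f"{gid}\t{cls}\n")

    truth = {
        "regulators": regulators,
        "tx_targets": {r: dict(sorted(tx_truth[r].items())) for r in regulators},
        "sp_targets": {r: sorted(sp_truth[r]) for r in regulators},
        "model1": truth_m1,
        "model2": sorted(truth_m2),
        "model3": sorted(truth_m3),
        "binding_mode": binding_truth,
        "config": dataclasses.asdict(config),
    }
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return truth


# ---------------------------------------------------------------------------
# Recovery scoring
# ---------------------------------------------------------------------------

def _prf(inferred: set, truth: set) -> dict[str, float | None]:
    tp = len(inferred & truth)
    precision = tp / len(inferred) if inferred else None
    recall = tp / len(truth) if truth else None
    if not inferred and not truth:
        f1: float | None = None
    elif not inferred or not truth or tp == 0:
        f1 = 0.0
    else:
        f1 = 2 * precision * recall / (precision + recall)  # type: ignore
    return {"precision": precision, "recall": recall, "f1": f1,
            "n_inferred": len(inferred), "n_truth": len(truth)}


def recovery_report(
    profiles: Mapping[str, net.RegulatorProfile],
    assignments: Sequence[net.ModelAssignment],
    truth: Mapping,
) -> dict:
    """Pooled precision/recall/F1 per layer and per co-regulation model.

    Set elements are (regulator, gene) pairs for the layers and Model I, and
    (regulator, partner, gene) triples for Models II/III, pooled over all
    regulators.
    """
    regs = truth["regulators"]
    unknown = set(profiles) - set(regs)
    if unknown:
        raise ValueError(f"inferred profiles for unknown regulators: {sorted(unknown)}")

    tx_inf = {(r, g) for r, p in profiles.items() for g in p.tx_targets}
    tx_true = {(r, g) for r in regs for g in truth["tx_targets"][r]}
    sp_inf = {(r, g) for r, p in profiles.items() for g in p.sp_targets}
    sp_true = {(r, g) for r in regs for g in truth["sp_targets"][r]}
    m1_inf = {(r, g) for r, p in profiles.items() for g in net.model_I(p)}
    m1_true = {(r, g) for r in regs for g in truth["model1"][r]}
    m2_inf = {(a.regulator, a.partner, a.gene) for a in assignments if a.model == "II"}
    m2_true = {tuple(t) for t in truth["model2"]}
    m3_inf = {(a.regulator, a.partner, a.gene) for a in assignments if a.model == "III"}
    m3_true = {tuple(t) for t in truth["model3"]}

    return {
        "tx_targets": _prf(tx_inf, tx_true),
        "sp_targets": _prf(sp_inf, sp_true),
        "model1": _prf(m1_inf, m1_true),
        "model2": _prf(m2_inf, m2_true),
        "model3": _prf(m3_inf, m3_true),
    }
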