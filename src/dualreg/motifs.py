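"""PWM motif scanning with exact p-values and binding-mode classification.

Scoring follows the standard log-odds convention: a window ``w`` of the same
width as the PWM scores ``sum_j log2(p_j(w_j) / bg(w_j))`` bits.  P-values
are *exact* under the i.i.d. background model: per-column scores are
integerized at a configurable granularity (default 1/1000 bit) and the full
null score distribution is built by dynamic programming (convolution across
columns), so ``P(score >= t)`` is a finite sum, not an approximation beyond
the quantization.  Zero-probability entries (pseudocount 0) score -inf and
can never reach a finite threshold.

Binding-mode classification reproduces the two-layer direct/indirect logic:
a regulator binds a target *directly* when one of its own motifs hits an
eligible peak sequence; failing that, the partner-library motif with the
best (smallest) hit p-value explains the peak *indirectly*; with no
sub-threshold hit at all the gene stays *unresolved*.  DNA-layer peaks are
standardized to 500 bp and restricted to within 100 kb of the TSS; RNA-layer
peaks are standardized to 100 bp, restricted to the gene body, and extracted
strand-aware as RNA.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .genomic import (
    GeneModel,
    Interval,
    Peak,
    extract_sequence,
    peaks_in_gene_body,
    peaks_near_tss,
    reverse_complement,
    standardize_peak,
)

__all__ = [
    "PWM",
    "MotifHit",
    "BindingCall",
    "iupac_to_pwm",
    "log_odds_score",
    "score_pvalue",
    "scan",
    "classify_binding_mode",
    "motif_similarity",
    "read_meme_motifs",
    "write_meme_motifs",
    "read_jaspar_pfm",
]

NEG_INF = float("-inf")

IUPAC_DNA: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}


@dataclass(frozen=True)
class PWM:
    """Position probability matrix, columns ordered A, C, G, T/U."""

    name: str
    matrix: tuple[tuple[float, float, float, float], ...]
    alphabet: str = "dna"  # 'dna' or 'rna'
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    pseudocount: float = 0.0

    def __post_init__(self) -> None:
        if self.alphabet not in ("dna", "rna"):
            raise ValueError("alphabet must be 'dna' or 'rna'")
        for j, col in enumerate(self.matrix):
            if abs(sum(col) - 1.0) > 1e-9:
                raise ValueError(f"column {j} sums to {sum(col)}, not 1")
        if abs(sum(self.background) - 1.0) > 1e-9:
            raise ValueError("background must sum to 1")

    @property
    def width(self) -> int:
        return len(self.matrix)

    def log_odds(self) -> np.ndarray:
        """width x 4 matrix of log2(p/bg) with -inf for zero probabilities."""
        m = np.asarray(self.matrix, dtype=float)
        bg = np.asarray(self.background, dtype=float)
        with np.errstate(divide="ignore"):
            return np.where(m > 0, np.log2(np.maximum(m, 1e-300) / bg), NEG_INF)

    def reverse_complement(self) -> "PWM":
        if self.alphabet != "dna":
            raise ValueError("reverse complement only defined for DNA motifs")
        rc = tuple(tuple(col[::-1]) for col in self.matrix[::-1])
        bg = self.background
        return PWM(self.name + "_rc", rc, self.alphabet,
                   (bg[3], bg[2], bg[1], bg[0]), self.pseudocount)


@dataclass(frozen=True)
class MotifHit:
    sequence_id: str
    motif: str
    offset: int  # 0-based start on the forward sequence
    strand: str  # '+' or '-' (always '+' for RNA)
    score: float  # bits
    p: float


@dataclass(frozen=True)
class BindingCall:
    gene_id: str
    mode: str  # direct | indirect | unresolved
    partner: str | None = None
    best_hit: MotifHit | None = None


def iupac_to_pwm(
    consensus: str,
    alphabet: str = "dna",
    pseudocount: float = 0.0,
    name: str | None = None,
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25),
) -> PWM:
    """Build a PWM from an IUPAC consensus: uniform over each code's bases,
    then pseudocount-smoothed and renormalized."""
    cols = []
    for ch in consensus.upper():
        if ch not in IUPAC_DNA:
            raise ValueError(f"invalid IUPAC code {ch!r} in {consensus!r}")
        allowed = IUPAC_DNA[ch]
        col = np.full(4, pseudocount, dtype=float)
        for b in allowed:
            col[_BASE_INDEX[b]] += 1.0 / len(allowed)
        col /= col.sum()
        cols.append(tuple(col))
    return PWM(name or consensus, tuple(cols), alphabet, background, pseudocount)


_ENCODE_TABLE = np.full(128, -1, dtype=np.int64)
for _ch, _idx in _BASE_INDEX.items():
    _ENCODE_TABLE[ord(_ch)] = _idx
    _ENCODE_TABLE[ord(_ch.lower())] = _idx


def _encode(seq: str) -> np.ndarray:
    """Map a sequence to base indices; unknown characters (N etc.) -> -1."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _ENCODE_TABLE[np.minimum(raw, 127)]


def log_odds_score(pwm: PWM, window: str) -> float:
    """Log-odds score in bits of one window (length must equal PWM width)."""
    if len(window) != pwm.width:
        raise ValueError(f"window length {len(window)} != PWM width {pwm.width}")
    lo = pwm.log_odds()
    total = 0.0
    for j, ch in enumerate(window.upper()):
        idx = _BASE_INDEX.get(ch)
        if idx is None:
            raise ValueError(f"character {ch!r} not in alphabet")
        v = lo[j, idx]
        if v == NEG_INF:
            return NEG_INF
        total += v
    return total


# ---------------------------------------------------------------------------
# Exact null distribution
# ---------------------------------------------------------------------------

def _integer_scores(pwm: PWM, granularity: float) -> np.ndarray:
    """Integerized log-odds matrix (np.int64, iinfo.min marks -inf)."""
    lo = pwm.log_odds()
    out = np.full(lo.shape, np.iinfo(np.int64).min, dtype=np.int64)
    finite = np.isfinite(lo)
    out[finite] = np.rint(lo[finite] / granularity).astype(np.int64)
    return out


def score_distribution(
    pwm: PWM, granularity: float = 1e-3
) -> tuple[np.ndarray, int]:
    """Exact null distribution of the integerized score.

    Returns ``(probs, min_score)``: ``probs[k]`` is the background probability
    of integer score ``min_score + k`` over all-finite windows; words hitting
    a zero-probability column carry the remaining mass at -inf.
    """
    ints = _integer_scores(pwm, granularity)
    sentinel = np.iinfo(np.int64).min
    bg = np.asarray(pwm.background, dtype=float)

    dist = np.array([1.0])
    offset = 0  # integer score of dist[0]
    for j in range(pwm.width):
        col_scores = ints[j]
        finite = col_scores != sentinel
        if not finite.any():
            return np.array([]), 0  # every word scores -inf
        ks = col_scores[finite]
        ps = bg[finite]
        lo_k, hi_k = int(ks.min()), int(ks.max())
        col = np.zeros(hi_k - lo_k + 1)
        for k, p in zip(ks, ps):
            col[int(k) - lo_k] += p
        dist = np.convolve(dist, col)
        offset += lo_k
    return dist, offset


def score_pvalue(pwm: PWM, score: float, granularity: float = 1e-3) -> float:
    """Exact P(background window score >= ``score``) at the DP granularity."""
    if score == NEG_INF:
        return 1.0
    dist, offset = score_distribution(pwm, granularity)
    if dist.size == 0:
        return 0.0
    t = int(np.rint(score / granularity))
    idx = t - offset
    if idx <= 0:
        # threshold at or below the minimum finite score: only -inf words fail
        return float(dist.sum())
    if idx >= dist.size:
        return 0.0
    return float(dist[idx:].sum())


# ---------------------------------------------------------------------------
# Scanning
# ---------------------------------------------------------------------------

def _scan_one_strand(
    encoded: np.ndarray, ints: np.ndarray, granularity: float
) -> tuple[np.ndarray, np.ndarray]:
    """Integer scores for every window (valid windows only); -inf windows are
    marked with the int64 sentinel."""
    w = ints.shape[0]
    n = len(encoded) - w + 1
    sentinel = np.iinfo(np.int64).min
    scores = np.zeros(n, dtype=np.int64)
    ok = np.ones(n, dtype=bool)
    for j in range(w):
        bases = encoded[j : j + n]
        valid = bases >= 0
        col = np.where(valid, ints[j, np.clip(bases, 0, 3)], sentinel)
        bad = col == sentinel
        ok &= ~bad
        scores = np.where(bad, sentinel, scores + np.where(bad, 0, col))
    scores[~ok] = sentinel
    return scores, ok


def scan(
    sequence: str,
    pwm: PWM,
    p_thresh: float = 1e-4,
    both_strands: bool = False,
    sequence_id: str = "",
    granularity: float = 1e-3,
) -> list[MotifHit]:
    """FIMO-style scan: every offset whose exact p-value is <= ``p_thresh``.

    With ``both_strands`` (DNA only) the reverse strand is scanned too; minus
    strand hits report the offset of the matching window on the *forward*
    sequence.  Hits are sorted by offset, then strand.
    """
    if both_strands and pwm.alphabet != "dna":
        raise ValueError("both_strands scanning is DNA-only")
    if len(sequence) < pwm.width:
        return []
    dist, offset = score_distribution(pwm, granularity)
    if dist.size == 0:
        return []
    # survival[k] = P(int score >= offset + k)
    survival = np.cumsum(dist[::-1])[::-1]
    ints = _integer_scores(pwm, granularity)

    hits: list[MotifHit] = []

    def collect(seq: str, strand: str) -> None:
        encoded = _encode(seq)
        scores, ok = _scan_one_strand(encoded, ints, granularity)
        L, w = len(seq), pwm.width
        for i in np.nonzero(ok)[0]:
            idx = int(scores[i]) - offset
            # idx <= 0: every all-finite word scores at least this much
            p = float(survival[0]) if idx <= 0 else (
                0.0 if idx >= dist.size else float(survival[idx]))
            if p <= p_thresh:
                fwd_offset = int(i) if strand == "+" else L - w - int(i)
                hits.append(
                    MotifHit(sequence_id, pwm.name, fwd_offset, strand,
                             float(scores[i]) * granularity, p)
                )

    collect(sequence, "+")
    if both_strands:
        collect(reverse_complement(sequence), "-")
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


# ---------------------------------------------------------------------------
# Direct / indirect binding classification
# ---------------------------------------------------------------------------

def eligible_peak_sequences(
    gene: GeneModel,
    peaks: Sequence[Peak],
    layer: str,
    genome: Mapping[str, str],
    window: int = 100_000,
    chip_width: int = 500,
    eclip_width: int = 100,
) -> list[tuple[str, str]]:
    """Standardized, layer-eligible peak sequences for one gene.

    DNA layer: peaks within ``window`` of the TSS, standardized to 500 bp,
    forward-strand sequence.  RNA layer: strand-matched peaks in the gene
    body, standardized to 100 bp, strand-aware RNA sequence.
    """
    if layer == "dna":
        eligible = peaks_near_tss(gene, peaks, window)
        width = chip_width
    elif layer == "rna":
        eligible = peaks_in_gene_body(gene, peaks, stranded=True)
        width = eclip_width
    else:
        raise ValueError("layer must be 'dna' or 'rna'")
    out = []
    for i, p in enumerate(eligible):
        sp = standardize_peak(p, width)
        iv = sp.interval
        chrom_len = len(genome[iv.chrom])
        end = min(iv.end, chrom_len)
        if end - iv.start < 1:
            continue
        if layer == "rna":
            iv = Interval(iv.chrom, iv.start, end, gene.strand)
            seq = extract_sequence(genome, iv, as_rna=True)
        else:
            iv = Interval(iv.chrom, iv.start, end, ".")
            seq = extract_sequence(genome, iv, as_rna=False)
        out.append((f"{gene.gene_id}_peak{i}", seq))
    return out


def classify_binding_mode(
    gene: GeneModel,
    peaks: Sequence[Peak],
    self_pwms: Sequence[PWM],
    partner_library: Sequence[PWM],
    layer: str,
    genome: Mapping[str, str],
    p_thresh: float = 1e-4,
    window: int = 100_000,
    max_self_motifs: int = 3,
) -> BindingCall:
    """Direct / indirect / unresolved binding of a regulator at one gene.

    Direct: any of the (first ``max_self_motifs``) self-motifs hits an
    eligible peak at p <= p_thresh.  Indirect: otherwise, the partner-library
    motif with the overall best hit, if sub-threshold.  Unresolved: no hit,
    or no eligible peak at all.
    """
    seqs = eligible_peak_sequences(gene, peaks, layer, genome, window=window)
    if not seqs:
        return BindingCall(gene.gene_id, "unresolved")
    both = layer == "dna"

    best_self: MotifHit | None = None
    for pwm in self_pwms[:max_self_motifs]:
        for sid, seq in seqs:
            for h in scan(seq, pwm, p_thresh=p_thresh, both_strands=both, sequence_id=sid):
                if best_self is None or h.p < best_self.p:
                    best_self = h
    if best_self is not None:
        return BindingCall(gene.gene_id, "direct", None, best_self)

    best_partner: MotifHit | None = None
    for pwm in partner_library:
        for sid, seq in seqs:
            for h in scan(seq, pwm, p_thresh=p_thresh, both_strands=both, sequence_id=sid):
                if best_partner is None or h.p < best_partner.p:
                    best_partner = h
    if best_partner is not None:
        return BindingCall(gene.gene_id, "indirect", best_partner.motif, best_partner)
    return BindingCall(gene.gene_id, "unresolved")


# ---------------------------------------------------------------------------
# Motif similarity
# ---------------------------------------------------------------------------

def motif_similarity(
    a: PWM, b: PWM, min_overlap: int = 4
) -> tuple[float, int, str]:
    """Best Pearson correlation of aligned PWM columns.

    Slides ``b`` across ``a`` over every offset with >= ``min_overlap``
    aligned columns (DNA: both orientations of ``b``); the aligned columns
    are flattened and correlated.  Returns ``(best_r, offset, orientation)``
    where ``offset`` is the position of b's first column relative to a's.
    """
    if a.alphabet != b.alphabet:
        raise ValueError("PWMs must share an alphabet")
    wa, wb = a.width, b.width
    if min_overlap > min(wa, wb):
        raise ValueError("min_overlap exceeds the shorter motif's width")
    ma = np.asarray(a.matrix)
    orientations = [("+", np.asarray(b.matrix))]
    if a.alphabet == "dna":
        orientations.append(("-", np.asarray(b.reverse_complement().matrix)))

    best = (-2.0, 0, "+")
    for orient, mb in orientations:
        for off in range(-(wb - min_overlap), wa - min_overlap + 1):
            lo_a, hi_a = max(0, off), min(wa, off + wb)
            if hi_a - lo_a < min_overlap:
                continue
            xa = ma[lo_a:hi_a].ravel()
            xb = mb[lo_a - off : hi_a - off].ravel()
            if np.std(xa) == 0 or np.std(xb) == 0:
                continue
            r = float(np.corrcoef(xa, xb)[0, 1])
            if r > best[0]:
                best = (r, off, orient)
    return best


# ---------------------------------------------------------------------------
# Motif file I/O
# ---------------------------------------------------------------------------

def read_meme_motifs(path: str | Path, alphabet: str = "dna") -> list[PWM]:
    """Read MEME minimal motif format (letter-probability matrices)."""
    pwms: list[PWM] = []
    background = (0.25, 0.25, 0.25, 0.25)
    name = None
    rows: list[tuple[float, float, float, float]] = []
    in_matrix = False
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("Background letter frequencies"):
            parts = lines[i + 1].split()
            background = tuple(float(parts[k]) for k in (1, 3, 5, 7))  # type: ignore
            i += 2
            continue
        if line.startswith("MOTIF"):
            if name is not None and rows:
                pwms.append(PWM(name, tuple(rows), alphabet, background))
            name = line.split()[1]
            rows = []
            in_matrix = False
        elif line.startswith("letter-probability matrix"):
            in_matrix = True
        elif in_matrix and line and line[0] in "0123456789.":
            vals = [float(x) for x in line.split()]
            total = sum(vals)
            rows.append(tuple(v / total for v in vals))  # type: ignore
        elif in_matrix and not line:
            in_matrix = False
        i += 1
    if name is not None and rows:
        pwms.append(PWM(name, tuple(rows), alphabet, background))
    return pwms


def write_meme_motifs(pwms: Iterable[PWM], path: str | Path) -> None:
    pwms = list(pwms)
    alphabet = "ACGT" if not pwms or pwms[0].alphabet == "dna" else "ACGU"
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= " + alphabet + "\n\n")
        fh.write("strands: + -\n\n" if alphabet == "ACGT" else "strands: +\n\n")
        if pwms:
            bg = pwms[0].background
            fh.write("Background letter frequencies\n")
            fh.write(
                f"{alphabet[0]} {bg[0]:.5f} {alphabet[1]} {bg[1]:.5f} "
                f"{alphabet[2]} {bg[2]:.5f} {alphabet[3]} {bg[3]:.5f}\n\n"
            )
        for p in pwms:
            fh.write(f"MOTIF {p.name}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {p.width} "
                f"nsites= 20 E= 0\n"
            )
            for col in p.matrix:
                fh.write(" ".join(f"{v:.6f}" for v in col) + "\n")
            fh.write("\n")


def read_jaspar_pfm(path: str | Path, alphabet: str = "dna") -> list[PWM]:
    """Read JASPAR-style PFM files (>name header, 4 count rows A/C/G/T)."""
    pwms = []
    with open(path) as fh:
        content = fh.read()
    blocks = [b for b in content.split(">") if b.strip()]
    for block in blocks:
        lines = block.strip().splitlines()
        name = lines[0].split()[0]
        counts = []
        for row in lines[1:5]:
            row = row.strip()
            if row and row[0] in "ACGTU":  # "A [ 3 5 ... ]" style
                row = row[1:]
            row = row.replace("[", " ").replace("]", " ")
            nums = [float(x) for x in row.split() if _is_number(x)]
            counts.append(nums)
        mat = np.asarray(counts, dtype=float).T  # width x 4
        mat = mat / mat.sum(axis=1, keepdims=True)
        pwms.append(PWM(name, tuple(tuple(c) for c in mat), alphabet))
    return pwms


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def write_hits(hits: Iterable[MotifHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sequence_id\tmotif\toffset\tstrand\tscore\tp\n")
        for h in hits:
            fh.write(f"{h.sequence_id}\t{h.motif}\t{h.offset}\t{h.strand}"
                     f"\t{h.score:.4f}\t{h.p:.6g}\n")
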