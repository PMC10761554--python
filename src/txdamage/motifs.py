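"""PWM promoter scanning and the empirical permutation enrichment test.

A motif occurrence is a scanning window (either strand) whose log-odds
score reaches a threshold calibrated against the exact null score
distribution under the background model. Enrichment of a target promoter
set is assessed by resampling size-matched promoter sets from the universe
and counting how often the null occurrence ratio reaches the observed one.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from ._rng import child_rng

ALPHABET = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}
_SCORE_BIN = 1e-3
_MAX_EXACT_WIDTH = 25


@dataclass(frozen=True)
class PWM:
    """Position probability matrix over (A, C, G, T) with a background model."""

    name: str
    probs: np.ndarray  # width x 4
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self):
        probs = np.asarray(self.probs, dtype=float)
        bg = np.asarray(self.background, dtype=float)
        if probs.ndim != 2 or probs.shape[1] != 4 or probs.shape[0] < 1:
            raise ValueError("probs must be a width x 4 matrix with width >= 1")
        if np.any(np.abs(probs.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError("each PWM position must sum to 1")
        if bg.shape != (4,) or abs(bg.sum() - 1.0) > 1e-9:
            raise ValueError("background must be 4 probabilities summing to 1")
        object.__setattr__(self, "probs", probs)
        object.__setattr__(self, "background", bg)

    @property
    def width(self) -> int:
        return self.probs.shape[0]


@dataclass(frozen=True)
class Hit:
    position: int
    strand: str
    score: float


@dataclass
class EnrichmentResult:
    observed_ratio: float
    null_ratios: np.ndarray
    p_empirical: float
    p_upper: float
    n_iter: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "observed_ratio": self.observed_ratio,
            "p_empirical": self.p_empirical,
            "p_upper": self.p_upper,
            "n_iter": self.n_iter,
            "seed": self.seed,
            "null_ratio_mean": float(np.mean(self.null_ratios)),
        }


def pwm_logodds(pwm: PWM, pseudocount: float = 1e-3) -> np.ndarray:
    """log2((p + pc*bg) / ((1+pc)*bg)) per position and base; finite everywhere."""
    if np.any(pwm.background <= 0):
        raise ValueError("background probabilities must be positive")
    bg = pwm.background[None, :]
    return np.log2((pwm.probs + pseudocount * bg) / ((1.0 + pseudocount) * bg))


def _discretize(logodds: np.ndarray, bin_size: float = _SCORE_BIN) -> np.ndarray:
    return np.rint(logodds / bin_size).astype(np.int64)


def score_threshold(
    logodds: np.ndarray,
    background: Sequence[float],
    p_cut: float = 1e-4,
    bin_size: float = _SCORE_BIN,
) -> float:
    """Smallest score whose null tail probability is <= p_cut.

    The null score distribution is computed exactly by position-wise
    convolution over the background, on scores discretized to `bin_size`
    bins. If even the maximal score exceeds p_cut in mass, a value above the
    maximum is returned (no window can be called).
    """
    lo = np.asarray(logodds, dtype=float)
    if lo.shape[0] > _MAX_EXACT_WIDTH:
        raise ValueError(
            f"width {lo.shape[0]} > {_MAX_EXACT_WIDTH}: exact convolution "
            "infeasible; subsample the motif or use a sampled null"
        )
    bg = np.asarray(background, dtype=float)
    binned = _discretize(lo, bin_size)
    cur = {0: 1.0}
    for row_bins in binned:
        nxt: dict = {}
        for s, p in cur.items():
            for b in range(4):
                key = s + int(row_bins[b])
                nxt[key] = nxt.get(key, 0.0) + p * bg[b]
        cur = nxt
    sums = np.array(sorted(cur))
    mass = np.array([cur[s] for s in sums])
    tail = np.cumsum(mass[::-1])[::-1]  # tail[i] = P(S >= sums[i])
    ok = tail <= p_cut
    if not ok.any():
        return float((sums[-1] + 1) * bin_size)
    return float(sums[np.argmax(ok)] * bin_size)


def exact_null_tail(
    logodds: np.ndarray, background: Sequence[float], score: float, bin_size: float = _SCORE_BIN
) -> float:
    """P(null window score >= score) under the discretized null (test oracle aid)."""
    lo = np.asarray(logodds, dtype=float)
    bg = np.asarray(background, dtype=float)
    binned = _discretize(lo, bin_size)
    cur = {0: 1.0}
    for row_bins in binned:
        nxt: dict = {}
        for s, p in cur.items():
            for b in range(4):
                key = s + int(row_bins[b])
                nxt[key] = nxt.get(key, 0.0) + p * bg[b]
        cur = nxt
    thr = int(round(score / bin_size))
    return float(sum(p for s, p in cur.items() if s >= thr))


_ENCODE_TABLE = np.full(256, -1, dtype=np.int8)
for _b, _i in _BASE_INDEX.items():
    _ENCODE_TABLE[ord(_b)] = _i
    _ENCODE_TABLE[ord(_b.lower())] = _i


def encode_sequence(sequence: str) -> np.ndarray:
    """A/C/G/T -> 0..3; anything else (N) -> -1."""
    return _ENCODE_TABLE[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]


def scan_sequence(sequence: str, logodds: np.ndarray, threshold: float) -> list:
    """Hits on both strands: windows scoring >= threshold.

    Minus-strand hits score the reverse complement of the window and are
    reported at the window's plus-strand offset. Windows containing N are
    skipped. A sequence shorter than the motif yields an empty result.

    Scores are quantized to the same 1e-3 bins used by
    :func:`score_threshold`, so a threshold from the exact null calibration
    is directly comparable.
    """
    lo = _discretize(np.asarray(logodds, dtype=float)) * _SCORE_BIN
    w = lo.shape[0]
    enc = encode_sequence(sequence)
    n = enc.size
    if n < w:
        return []
    # reverse complement matrix: reversed positions, complemented base order
    lo_rc = lo[::-1, ::-1]
    windows = np.lib.stride_tricks.sliding_window_view(enc, w)
    valid = (windows >= 0).all(axis=1)
    safe = np.where(windows < 0, 0, windows)
    cols = np.arange(w)
    fwd = lo[cols, safe].sum(axis=1)
    rev = lo_rc[cols, safe].sum(axis=1)
    eps = 1e-9
    hits = []
    for pos in np.nonzero(valid & (fwd >= threshold - eps))[0]:
        hits.append(Hit(int(pos), "+", float(fwd[pos])))
    for pos in np.nonzero(valid & (rev >= threshold - eps))[0]:
        hits.append(Hit(int(pos), "-", float(rev[pos])))
    hits.sort(key=lambda h: (h.position, h.strand))
    return hits


def has_occurrence(sequence: str, logodds: np.ndarray, threshold: float) -> bool:
    return bool(scan_sequence(sequence, logodds, threshold))


def occurrence_ratio(sequences: Sequence[str], logodds: np.ndarray, threshold: float) -> float:
    """Fraction of promoters containing >= 1 hit on either strand."""
    if len(sequences) == 0:
        raise ValueError("occurrence_ratio requires >= 1 promoter")
    n_hit = sum(has_occurrence(s, logodds, threshold) for s in sequences)
    return n_hit / len(sequences)


def _gc_of(seq: str) -> float:
    s = seq.upper()
    gc = s.count("G") + s.count("C")
    tot = gc + s.count("A") + s.count("T")
    return gc / tot if tot else 0.0


def permutation_test(
    target_ids: Sequence[str],
    universe: Mapping[str, str],
    pwm: PWM,
    threshold: float | None = None,
    n_iter: int = 1000,
    seed: int = 0,
    p_cut: float = 1e-4,
    pseudocount: float = 1e-3,
    gc_matched: bool = False,
    gc_bins: int = 10,
) -> EnrichmentResult:
    """Empirical enrichment of motif occurrence in target promoters.

    Each iteration draws |target| promoters from the universe without
    replacement (target promoters stay in the sampling pool) and records the
    occurrence ratio; p_empirical = #{null ratio >= observed} / n_iter. Zero
    exceedances give p_empirical = 0 with p_upper = 1/n_iter as the
    resolution bound. With gc_matched=True the draw preserves the target's
    promoter GC-bin composition.
    """
    target_ids = list(target_ids)
    if len(target_ids) == 0:
        raise ValueError("target set must be non-empty")
    missing = [t for t in target_ids if t not in universe]
    if missing:
        raise ValueError(f"target promoters not in universe: {missing[:5]}")
    if len(universe) < len(target_ids):
        raise ValueError("universe smaller than target set")

    logodds = pwm_logodds(pwm, pseudocount)
    if threshold is None:
        threshold = score_threshold(logodds, pwm.background, p_cut)

    ids = sorted(universe)
    has_hit = np.array(
        [has_occurrence(universe[i], logodds, threshold) for i in ids], dtype=float
    )
    idx_of = {i: k for k, i in enumerate(ids)}
    target_idx = np.array([idx_of[t] for t in target_ids])
    observed = float(has_hit[target_idx].mean())

    rng = child_rng(seed, "motif-permutation")
    n_univ = len(ids)
    k = len(target_ids)
    null_ratios = np.empty(n_iter)
    if gc_matched:
        gc = np.array([_gc_of(universe[i]) for i in ids])
        edges = np.quantile(gc, np.linspace(0, 1, gc_bins + 1))
        bins = np.clip(np.searchsorted(edges, gc, side="right") - 1, 0, gc_bins - 1)
        target_bins, needed = np.unique(bins[target_idx], return_counts=True)
        pools = {b: np.nonzero(bins == b)[0] for b in target_bins}
        for it in range(n_iter):
            draw = np.concatenate(
                [rng.choice(pools[b], size=c, replace=False) for b, c in zip(target_bins, needed)]
            )
            null_ratios[it] = has_hit[draw].mean()
    else:
        for it in range(n_iter):
            draw = rng.choice(n_univ, size=k, replace=False)
            null_ratios[it] = has_hit[draw].mean()

    exceed = int(np.sum(null_ratios >= observed - 1e-12))
    p_emp = exceed / n_iter
    return EnrichmentResult(
        observed_ratio=observed,
        null_ratios=null_ratios,
        p_empirical=p_emp,
        p_upper=max(p_emp, 1.0 / n_iter),
        n_iter=n_iter,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# motif file formats


def read_meme(path) -> list:
    """Parse a MEME-minimal motif file into PWM objects."""
    pwms = []
    background = np.full(4, 0.25)
    name = None
    rows: list = []
    expect_bg = False

    def flush():
        nonlocal name, rows
        if name is not None:
            if not rows:
                raise ValueError(f"motif {name!r}: empty probability matrix")
            pwms.append(PWM(name=name, probs=np.array(rows), background=background.copy()))
        name, rows = None, []

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if expect_bg:
                parts = line.split()
                freq = {parts[i]: float(parts[i + 1]) for i in range(0, len(parts), 2)}
                background = np.array([freq.get(b, 0.25) for b in ALPHABET])
                background = background / background.sum()
                expect_bg = False
                continue
            if line.startswith("Background letter frequencies"):
                expect_bg = True
            elif line.startswith("MOTIF"):
                flush()
                name = line.split()[1]
            elif name is not None and line and line[0] in "0123456789.":
                vals = [float(v) for v in line.split()]
                if len(vals) != 4:
                    raise ValueError(f"motif {name!r}: expected 4 columns, got {len(vals)}")
                total = sum(vals)
                rows.append([v / total for v in vals])
    flush()
    if not pwms:
        raise ValueError(f"no motifs found in {path}")
    return pwms


def write_meme(path, pwms: Sequence[PWM]):
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        bg = pwms[0].background
        fh.write("Background letter frequencies\n")
        fh.write(" ".join(f"{b} {f:.6f}" for b, f in zip(ALPHABET, bg)) + "\n\n")
        for p in pwms:
            fh.write(f"MOTIF {p.name}\n")
            fh.write(f"letter-probability matrix: alength= 4 w= {p.width}\n")
            for row in p.probs:
                fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")
            fh.write("\n")


def read_pfm_tsv(path, name: str | None = None) -> PWM:
    """4-column (A, C, G, T) position frequency table; rows are normalized."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    cols = [c.upper() for c in df.columns]
    if sorted(cols) != ["A", "C", "G", "T"]:
        raise ValueError("PFM TSV must have exactly columns A, C, G, T")
    mat = df[[df.columns[cols.index(b)] for b in ALPHABET]].to_numpy(dtype=float)
    mat = mat / mat.sum(axis=1, keepdims=True)
    return PWM(name=name or "pfm", probs=mat)
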