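"""RNA-recognition-element (PFM) scanning and enrichment z-scores.

PFMs in the CisBP-RNA text layout (header ``Pos A C G U``) are scanned over
RNA-sense sequences with a log-odds score against a uniform background; a
window is a hit when its score reaches a configurable fraction (default 80%)
of the motif's maximal achievable score.  Enrichment of a motif in target
intervals (alternatively spliced exons with intronic flanks, retained
introns) versus background intervals is a per-interval presence/absence
binomial z-score — robust to the large length differences between exon
bodies and flank bins.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .gene_model import Gene, GeneModel, SplicingEvent

BASES = "ACGU"
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "U": 3, "T": 3, "N": 4}
DEFAULT_PSEUDOCOUNT = 1e-3
DEFAULT_SCORE_FRACTION = 0.8


@dataclass
class PositionFrequencyMatrix:
    """Base frequencies per motif position over {A, C, G, U}."""

    motif_id: str
    rbp_name: str
    matrix: np.ndarray  # (width, 4), rows sum to 1

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("PFM matrix must be positions x 4")
        if self.width < 3:
            raise ValueError("PFM width must be >= 3")
        if np.any(self.matrix < 0):
            raise ValueError("PFM frequencies must be non-negative")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("PFM rows must sum to 1 (after normalization)")

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    def log_odds(self) -> np.ndarray:
        """Per-position log-odds against a uniform 0.25 background."""
        return np.log2(self.matrix / 0.25)

    def max_score(self) -> float:
        return float(self.log_odds().max(axis=1).sum())

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.matrix.argmax(axis=1))


def normalize_pfm_rows(raw: np.ndarray,
                       pseudocount: float = DEFAULT_PSEUDOCOUNT) -> np.ndarray:
    raw = np.asarray(raw, dtype=float) + pseudocount
    return raw / raw.sum(axis=1, keepdims=True)


def read_cisbp_pfm(stream, motif_id: str | None = None,
                   rbp_name: str = "",
                   pseudocount: float = DEFAULT_PSEUDOCOUNT,
                   ) -> list[PositionFrequencyMatrix]:
    """Parse PFMs from CisBP-RNA-style text.

    Layout: optional ``key value`` header lines (``Motif``/``TF Name``/...),
    a column header ``Pos A C G U`` (T accepted as U) and one whitespace-
    separated row per position.  Several concatenated records are supported.
    Rows are pseudocounted and renormalised; a row whose raw sum is far from
    1 triggers a warning, a non-numeric cell is a parse error.
    """
    if isinstance(stream, str):
        lines = stream.splitlines()
    else:
        lines = stream.read().splitlines()

    pfms: list[PositionFrequencyMatrix] = []
    cur_rows: list[list[float]] = []
    cur_id = motif_id
    cur_name = rbp_name
    in_matrix = False

    def flush() -> None:
        nonlocal cur_rows, cur_id, cur_name, in_matrix
        if cur_rows:
            raw = np.array(cur_rows)
            for i, row in enumerate(raw):
                if not math.isclose(row.sum(), 1.0, abs_tol=0.05):
                    warnings.warn(
                        f"PFM {cur_id or '?'} row {i + 1} sums to {row.sum():.3f}, "
                        "renormalizing", stacklevel=2)
            pfms.append(PositionFrequencyMatrix(
                motif_id=cur_id or f"motif{len(pfms) + 1}",
                rbp_name=cur_name,
                matrix=normalize_pfm_rows(raw, pseudocount),
            ))
        cur_rows, in_matrix = [], False

    for lineno, line in enumerate(lines, start=1):
        fields = line.split()
        if not fields:
            flush()
            continue
        key = fields[0].lower()
        if key == "pos" or (key in "acgtu" and len(fields) == 4 and not in_matrix
                            and all(f.upper() in "ACGTUN" for f in fields)):
            # column header: "Pos A C G U" (or a bare "A C G U" variant)
            flush()
            in_matrix = True
            continue
        if key in ("motif", "motif_id"):
            flush()
            cur_id = fields[-1]
            continue
        if key in ("tf", "rbp", "name", "tf_name", "rbp_name"):
            cur_name = fields[-1]
            continue
        if in_matrix:
            try:
                values = [float(f) for f in fields[1:]] if len(fields) == 5 \
                    else [float(f) for f in fields]
            except ValueError as exc:
                raise ValueError(f"non-numeric PFM cell at line {lineno}: {line!r}") \
                    from exc
            if len(values) != 4:
                raise ValueError(f"PFM row must have 4 frequencies at line {lineno}")
            cur_rows.append(values)
    flush()
    return pfms


# ---------------------------------------------------------------------------
# Interval extraction


def extract_intervals(events: Sequence[SplicingEvent], model: GeneModel,
                      flank: int = 500) -> list[dict]:
    """Genomic bins to scan per event.

    Exon-type events yield three bins — upstream intronic flank, exon body,
    downstream intronic flank — with flanks truncated at the nearest
    neighbouring exon and at position 0; intron-retention events yield the
    retained intron.  Flank orientation is transcript-relative (upstream =
    5' of the exon in transcription direction).
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    genes = {g.gene_id: g for g in model.genes}
    out: list[dict] = []
    for ev in events:
        gene = genes.get(ev.gene_id)
        if gene is None:
            warnings.warn(f"event {ev.event_id} has no locatable gene; skipped",
                          stacklevel=2)
            continue
        s, t = ev.target_start, ev.target_end
        if ev.event_type == "intron-retention":
            out.append(_bin(ev, "intron", s, t))
            continue
        left_bound = max([e for _, e in gene.exon_set() if e <= s], default=0)
        right_bound = min([b for b, _ in gene.exon_set() if b >= t], default=t + flank)
        left = (max(s - flank, left_bound, 0), s)
        right = (t, max(t, min(t + flank, right_bound)))
        up, down = (left, right) if ev.strand == "+" else (right, left)
        if flank > 0 and up[1] > up[0]:
            out.append(_bin(ev, "upstream_flank", *up))
        out.append(_bin(ev, "exon", s, t))
        if flank > 0 and down[1] > down[0]:
            out.append(_bin(ev, "downstream_flank", *down))
    return out


def _bin(ev: SplicingEvent, role: str, start: int, end: int) -> dict:
    return {"event_id": ev.event_id, "role": role, "chromosome": ev.chrom,
            "start": start, "end": end, "strand": ev.strand}


_COMPLEMENT = str.maketrans("ACGTUN", "TGCAAN")


def interval_sequences(intervals: Iterable[dict],
                       genome: Mapping[str, str]) -> list[tuple[str, str]]:
    """Fetch RNA-sense sequences for extracted bins from chrom → sequence.

    Minus-strand intervals are reverse-complemented; DNA T is left in place
    (the scanner treats T as U).
    """
    out = []
    for iv in intervals:
        chrom_seq = genome[iv["chromosome"]]
        seq = chrom_seq[iv["start"]:iv["end"]].upper()
        if iv["strand"] == "-":
            seq = seq.translate(_COMPLEMENT)[::-1]
        out.append((f"{iv['event_id']}|{iv['role']}", seq))
    return out


# ---------------------------------------------------------------------------
# Scanning


@dataclass(frozen=True)
class MotifHit:
    position: int
    score: float


def _encode(seq: str) -> np.ndarray:
    try:
        return np.array([_BASE_INDEX[c] for c in seq.upper()], dtype=np.int8)
    except KeyError as exc:
        raise ValueError(f"sequence contains invalid character {exc}") from None


def scan_sequence(seq: str, pfm: PositionFrequencyMatrix,
                  score_fraction: float = DEFAULT_SCORE_FRACTION) -> list[MotifHit]:
    """All windows whose log-odds score reaches score_fraction × max score.

    Scanning is single-stranded (RNA sense); N positions contribute the
    background log-odds, i.e. zero.  Sequences shorter than the motif return
    no hits.
    """
    w = pfm.width
    enc = _encode(seq)
    n_windows = len(enc) - w + 1
    if n_windows <= 0:
        return []
    lut = np.hstack([pfm.log_odds(), np.zeros((w, 1))])  # column 4: N -> 0
    scores = np.zeros(n_windows)
    for offset in range(w):
        scores += lut[offset, enc[offset:offset + n_windows]]
    threshold = score_fraction * pfm.max_score()
    hits = np.flatnonzero(scores >= threshold - 1e-12)
    return [MotifHit(int(i), float(scores[i])) for i in hits]


def _has_hit(seqs: Sequence[str], pfm: PositionFrequencyMatrix,
             score_fraction: float) -> np.ndarray:
    return np.array([len(scan_sequence(s, pfm, score_fraction)) > 0 for s in seqs])


@dataclass
class EnrichmentResult:
    """Per-interval presence/absence enrichment of one motif."""

    motif_id: str
    rbp_name: str
    n_target: int
    k_target: int
    n_bg: int
    k_bg: int
    z: float

    def as_dict(self) -> dict:
        return {"motif_id": self.motif_id, "rbp_name": self.rbp_name,
                "k_target": self.k_target, "n_target": self.n_target,
                "k_bg": self.k_bg, "n_bg": self.n_bg, "z": self.z}


def enrichment_z(target_seqs: Sequence[str], bg_seqs: Sequence[str],
                 pfm: PositionFrequencyMatrix,
                 score_fraction: float = DEFAULT_SCORE_FRACTION) -> EnrichmentResult:
    """Binomial z-score for motif presence in targets vs background.

    With p̂ the background fraction of intervals containing ≥1 hit (clamped
    away from 0 and 1 by the half-count continuity rule),
    z = (k_target − n_target·p̂) / sqrt(n_target·p̂·(1−p̂)).
    """
    if not len(target_seqs) or not len(bg_seqs):
        raise ValueError("target and background sets must be nonempty")
    k_t = int(_has_hit(target_seqs, pfm, score_fraction).sum())
    k_b = int(_has_hit(bg_seqs, pfm, score_fraction).sum())
    n_t, n_b = len(target_seqs), len(bg_seqs)
    p_hat = k_b / n_b
    lo, hi = 1.0 / (2 * n_b), 1.0 - 1.0 / (2 * n_b)
    p_hat = min(max(p_hat, lo), hi)
    z = (k_t - n_t * p_hat) / math.sqrt(n_t * p_hat * (1.0 - p_hat))
    return EnrichmentResult(pfm.motif_id, pfm.rbp_name, n_t, k_t, n_b, k_b, z)


def enrichment_table(target_seqs: Sequence[str], bg_seqs: Sequence[str],
                     pfms: Sequence[PositionFrequencyMatrix],
                     score_fraction: float = DEFAULT_SCORE_FRACTION) -> pd.DataFrame:
    """Enrichment z-scores for a collection of motifs, sorted by z."""
    rows = [enrichment_z(target_seqs, bg_seqs, p, score_fraction).as_dict()
            for p in pfms]
    return (pd.DataFrame(rows)
            .sort_values(["z", "motif_id"], ascending=[False, True], kind="mergesort")
            .reset_index(drop=True))
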