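"""Directional concordance between splicing signatures.

A splicing signature is the set of significant events of one two-group
comparison, each carrying the sign of its ΔPSI (+1 inclusion increased, −1
decreased).  For events shared between two signatures, a pair is concordant
when the signs agree and anti-concordant when they oppose; under independent
random directions the expected concordance is 50%, which is the null against
which observed percentages are read.  Events are matched across comparisons
by their coordinate-derived event_id, the only key stable across datasets.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

SIGNATURE_COLUMNS = ["comparison_id", "event_id", "direction", "delta_psi"]


@dataclass
class SplicingSignature:
    """Directed event set of one comparison.

    ``directions`` maps event_id → ±1; ``magnitudes`` optionally carries the
    ΔPSI magnitude used by the magnitude-weighted concordance mode.
    """

    comparison_id: str
    directions: dict[str, int] = field(default_factory=dict)
    magnitudes: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {e: d for e, d in self.directions.items() if d not in (1, -1)}
        if bad:
            raise ValueError(f"directions must be +1/-1, got {bad}")

    def __len__(self) -> int:
        return len(self.directions)

    def event_ids(self) -> set[str]:
        return set(self.directions)

    def flipped(self, comparison_id: str | None = None) -> "SplicingSignature":
        return SplicingSignature(
            comparison_id=comparison_id or f"{self.comparison_id}_flipped",
            directions={e: -d for e, d in self.directions.items()},
            magnitudes=dict(self.magnitudes),
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [{
            "comparison_id": self.comparison_id,
            "event_id": e,
            "direction": d,
            "delta_psi": self.magnitudes.get(e, math.nan),
        } for e, d in sorted(self.directions.items())]
        return pd.DataFrame(rows, columns=SIGNATURE_COLUMNS)

    def to_tsv(self) -> str:
        return self.to_frame().to_csv(sep="\t", index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame,
                   comparison_id: str | None = None) -> "SplicingSignature":
        if comparison_id is None:
            ids = df["comparison_id"].unique()
            if len(ids) != 1:
                raise ValueError("frame holds multiple comparison_ids; pass one explicitly")
            comparison_id = str(ids[0])
        else:
            df = df[df["comparison_id"] == comparison_id]
        if df["event_id"].duplicated().any():
            raise ValueError("duplicate event_ids in signature")
        return cls(
            comparison_id=comparison_id,
            directions={str(r.event_id): int(r.direction) for r in df.itertuples()},
            magnitudes={str(r.event_id): float(r.delta_psi) for r in df.itertuples()
                        if not pd.isna(r.delta_psi)},
        )

    @classmethod
    def from_tsv(cls, stream, comparison_id: str | None = None) -> "SplicingSignature":
        return cls.from_frame(pd.read_csv(stream, sep="\t"), comparison_id)


@dataclass
class ConcordanceResult:
    """Shared-event direction agreement between two signatures.

    ``pct_concordant`` is NaN (flagged undefined) when no events are shared —
    never reported as 0 or 50.
    """

    n_shared: int
    n_concordant: int
    n_anti: int

    def __post_init__(self) -> None:
        if self.n_concordant + self.n_anti != self.n_shared:
            raise ValueError("concordant + anti must equal shared")

    @property
    def defined(self) -> bool:
        return self.n_shared > 0

    @property
    def pct_concordant(self) -> float:
        if not self.defined:
            return math.nan
        return 100.0 * self.n_concordant / self.n_shared

    @property
    def pct_anti(self) -> float:
        if not self.defined:
            return math.nan
        return 100.0 * self.n_anti / self.n_shared


def overlap_signatures(a: SplicingSignature, b: SplicingSignature) -> list[str]:
    """Sorted event_ids present in both signatures."""
    return sorted(a.event_ids() & b.event_ids())


def concordance(a: SplicingSignature, b: SplicingSignature,
                weighted: bool = False) -> ConcordanceResult:
    """Directional concordance over the shared events of two signatures.

    Symmetric in its arguments.  With ``weighted=True`` each shared event
    contributes its mean |ΔPSI| magnitude instead of a unit count (counts are
    then rounded totals of the weighted fractions).
    """
    shared = overlap_signatures(a, b)
    if not weighted:
        n_conc = sum(1 for e in shared if a.directions[e] == b.directions[e])
        return ConcordanceResult(len(shared), n_conc, len(shared) - n_conc)
    if not shared:
        return ConcordanceResult(0, 0, 0)
    w = np.array([(abs(a.magnitudes.get(e, 1.0)) + abs(b.magnitudes.get(e, 1.0))) / 2
                  for e in shared])
    agree = np.array([a.directions[e] == b.directions[e] for e in shared])
    frac = float(np.sum(w[agree]) / np.sum(w)) if np.sum(w) > 0 else math.nan
    n_conc = int(round(frac * len(shared)))
    return ConcordanceResult(len(shared), n_conc, len(shared) - n_conc)


def rank_signatures(reference: SplicingSignature,
                    candidates: Sequence[SplicingSignature],
                    sort_by: str = "n_shared") -> pd.DataFrame:
    """Concordance of many candidate signatures against one reference.

    Returns a table with one row per candidate (n_shared, pct_concordant,
    pct_anti), sorted by ``sort_by`` ∈ {"n_shared", "pct_concordant",
    "pct_anti"} descending.  Undefined concordances sort last; ties break by
    comparison_id, so the ranking is invariant to candidate input order.
    """
    if not candidates:
        raise ValueError("at least one candidate signature is required")
    if sort_by not in ("n_shared", "pct_concordant", "pct_anti"):
        raise ValueError(f"cannot sort by {sort_by!r}")
    rows = []
    for cand in candidates:
        res = concordance(reference, cand)
        rows.append({
            "comparison_id": cand.comparison_id,
            "n_shared": res.n_shared,
            "pct_concordant": res.pct_concordant,
            "pct_anti": res.pct_anti,
        })
    df = pd.DataFrame(rows)
    df["_undef"] = df["pct_concordant"].isna()
    df = df.sort_values(by=["_undef", sort_by, "comparison_id"],
                        ascending=[True, False, True],
                        na_position="last", kind="mergesort")
    return df.drop(columns="_undef").reset_index(drop=True)


@dataclass
class NullConcordanceSummary:
    mean_pct: float
    sd_pct: float
    ci_low: float
    ci_high: float
    n_shared: int
    reps: int


def null_concordance(n_shared: int, reps: int = 1000,
                     seed: int | None = None) -> NullConcordanceSummary:
    """Random-overlap null: concordance of independent fair direction signs.

    Simulates ``reps`` pairs of uniform ±1 vectors of length ``n_shared`` and
    summarises the percent-concordant distribution (mean, sd, central 95%
    interval).  The expectation is 50%, the random-overlap benchmark.
    """
    if n_shared < 1:
        raise ValueError("n_shared must be >= 1")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    # agreement of two independent fair signs is a fair Bernoulli coin
    agree = rng.random((reps, n_shared)) < 0.5
    pct = 100.0 * agree.mean(axis=1)
    lo, hi = np.percentile(pct, [2.5, 97.5])
    return NullConcordanceSummary(
        mean_pct=float(pct.mean()),
        sd_pct=float(pct.std(ddof=1)) if reps > 1 else 0.0,
        ci_low=float(lo), ci_high=float(hi),
        n_shared=n_shared, reps=reps,
    )


def intersect_gene_signatures(signatures: Mapping[str, Iterable[str]] |
                              Sequence[Iterable[str]]) -> tuple[pd.DataFrame, list[str]]:
    """Venn-region counts for up to six gene-symbol sets.

    Gene symbols are upper-cased and deduplicated.  Returns (region table,
    members of the full intersection).  Each region is the set of elements in
    exactly the named member sets and none of the others.
    """
    if isinstance(signatures, Mapping):
        named = {str(k): {str(g).upper() for g in v} for k, v in signatures.items()}
    else:
        named = {f"set{i + 1}": {str(g).upper() for g in s}
                 for i, s in enumerate(signatures)}
    if len(named) > 6:
        raise ValueError("at most 6 sets are supported")
    if len(named) < 1:
        raise ValueError("at least one set is required")
    names = list(named)
    rows = []
    for include in itertools.product([False, True], repeat=len(names)):
        if not any(include):
            continue
        inside = [n for n, inc in zip(names, include) if inc]
        outside = [n for n, inc in zip(names, include) if not inc]
        region = set.intersection(*(named[n] for n in inside))
        for n in outside:
            region -= named[n]
        rows.append({
            "region": "&".join(inside),
            "n_sets": len(inside),
            "count": len(region),
        })
    full = sorted(set.intersection(*named.values()))
    return pd.DataFrame(rows), full
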