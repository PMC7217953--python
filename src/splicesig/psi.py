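"""Percent-spliced-in (PSI) quantification from junction-spanning read counts.

PSI for an event is I/(I+E), with I the summed inclusion-junction reads and
E the summed exclusion-junction reads.  For intron retention I is the mean
of the two exon–intron boundary counts, so a single retained intron is not
double-counted against its spliced junction.  A PSI value is *detected* in a
sample only when the supporting depth I+E reaches ``min_reads``; undetected
cells are missing (NaN).  The detection filter keeps events detected in
strictly more than ``min_fraction`` of samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .gene_model import EXON_INTRON, Junction, SplicingEvent

DEFAULT_MIN_READS = 10

COUNT_COLUMNS = ["chromosome", "donor", "acceptor", "strand", "kind", "count"]


@dataclass
class JunctionCountTable:
    """Per-sample junction read counts keyed by :class:`Junction`.

    Junctions absent from the table are treated as zero-read observations;
    missingness is decided downstream at the event level by depth.
    """

    sample_id: str
    counts: dict[Junction, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for j, c in self.counts.items():
            if c < 0:
                raise ValueError(f"negative count for {j} in sample {self.sample_id}")

    def get(self, junction: Junction) -> int:
        return self.counts.get(junction, 0)

    def total(self) -> int:
        return sum(self.counts.values())

    @classmethod
    def from_tsv(cls, sample_id: str, stream) -> "JunctionCountTable":
        df = pd.read_csv(stream, sep="\t")
        missing = [c for c in COUNT_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"junction count table missing columns: {missing}")
        counts: dict[Junction, int] = {}
        for row in df.itertuples(index=False):
            j = Junction(str(row.chromosome), int(row.donor), int(row.acceptor),
                         str(row.strand), str(row.kind))
            counts[j] = int(row.count)
        return cls(sample_id, counts)

    def to_tsv(self) -> str:
        rows = ["\t".join(COUNT_COLUMNS)]
        for j in sorted(self.counts):
            rows.append(f"{j.chrom}\t{j.donor}\t{j.acceptor}\t{j.strand}\t{j.kind}\t"
                        f"{self.counts[j]}")
        return "\n".join(rows) + "\n"


def compute_psi(event: SplicingEvent, counts: JunctionCountTable,
                min_reads: int = DEFAULT_MIN_READS) -> float:
    """PSI of one event in one sample, or NaN when supporting depth is low.

    Supporting depth is I+E; intron-retention inclusion I is the mean of the
    two exon–intron boundary counts.
    """
    if min_reads < 1:
        raise ValueError("min_reads must be >= 1")
    inc = [counts.get(j) for j in event.inclusion_junctions]
    exc = [counts.get(j) for j in event.exclusion_junctions]
    if event.event_type == "intron-retention":
        i_reads = float(np.mean(inc))
    else:
        i_reads = float(sum(inc))
    e_reads = float(sum(exc))
    depth = i_reads + e_reads
    if depth < min_reads:
        return math.nan
    return i_reads / depth


def _event_depth(event: SplicingEvent, counts: JunctionCountTable) -> float:
    inc = [counts.get(j) for j in event.inclusion_junctions]
    exc = [counts.get(j) for j in event.exclusion_junctions]
    if event.event_type == "intron-retention":
        return float(np.mean(inc)) + float(sum(exc))
    return float(sum(inc)) + float(sum(exc))


@dataclass
class PsiMatrix:
    """Events × samples PSI values with per-cell supporting depth.

    ``psi`` and ``depth`` are aligned DataFrames indexed by event_id; NaN in
    ``psi`` marks an undetected cell.  ``events`` maps event_id to its
    :class:`SplicingEvent` when the matrix was built from a gene model.
    """

    psi: pd.DataFrame
    depth: pd.DataFrame
    events: dict[str, SplicingEvent] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.psi.index.equals(self.depth.index) or \
                not self.psi.columns.equals(self.depth.columns):
            raise ValueError("psi and depth matrices must be aligned")
        vals = self.psi.to_numpy(dtype=float)
        ok = np.isnan(vals) | ((vals >= 0.0) & (vals <= 1.0))
        if not ok.all():
            raise ValueError("non-missing PSI values must lie in [0, 1]")

    @property
    def event_ids(self) -> list[str]:
        return list(self.psi.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.psi.columns)

    def detected_fraction(self) -> pd.Series:
        return self.psi.notna().mean(axis=1)

    def to_tsv(self) -> str:
        return self.psi.to_csv(sep="\t", na_rep="NA", index_label="event_id")

    @classmethod
    def from_tsv(cls, stream) -> "PsiMatrix":
        df = pd.read_csv(stream, sep="\t", index_col="event_id", na_values=["NA"])
        depth = pd.DataFrame(np.nan, index=df.index, columns=df.columns)
        return cls(df, depth)


def build_psi_matrix(events: Sequence[SplicingEvent],
                     count_tables: Sequence[JunctionCountTable],
                     min_reads: int = DEFAULT_MIN_READS) -> PsiMatrix:
    """Assemble the PSI matrix over all events and samples.

    Events are ordered by genomic position, samples by input order.
    """
    if not count_tables:
        raise ValueError("at least one sample is required")
    sample_ids = [t.sample_id for t in count_tables]
    if len(set(sample_ids)) != len(sample_ids):
        raise ValueError("duplicate sample_id in count tables")
    ordered = sorted(events, key=lambda e: (e.chrom, e.target_start, e.target_end,
                                            e.event_id))
    psi = np.full((len(ordered), len(count_tables)), np.nan)
    depth = np.zeros((len(ordered), len(count_tables)))
    for i, ev in enumerate(ordered):
        for j, table in enumerate(count_tables):
            psi[i, j] = compute_psi(ev, table, min_reads)
            depth[i, j] = _event_depth(ev, table)
    index = pd.Index([e.event_id for e in ordered], name="event_id")
    return PsiMatrix(
        psi=pd.DataFrame(psi, index=index, columns=sample_ids),
        depth=pd.DataFrame(depth, index=index, columns=sample_ids),
        events={e.event_id: e for e in ordered},
    )


def detection_filter(matrix: PsiMatrix, min_fraction: float = 0.5) -> PsiMatrix:
    """Keep events whose detected fraction is strictly greater than
    ``min_fraction`` (default: detected in >50% of samples)."""
    if not 0 < min_fraction < 1:
        raise ValueError("min_fraction must be in (0, 1)")
    keep = matrix.detected_fraction() > min_fraction
    kept_ids = matrix.psi.index[keep]
    return PsiMatrix(
        psi=matrix.psi.loc[kept_ids],
        depth=matrix.depth.loc[kept_ids],
        events={k: v for k, v in matrix.events.items() if k in set(kept_ids)},
    )
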