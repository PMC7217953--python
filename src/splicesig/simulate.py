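"""Synthetic gene models, junction counts, signatures and motif sequences.

The generator emulates the statistical structure a junction-based PSI
analysis assumes: per-sample event depth drawn from a negative binomial
(uneven junction coverage), sample-level PSI drawn from a beta distribution
around the group mean with intra-class correlation ``rho`` (biological
overdispersion beyond binomial counting noise), and inclusion reads binomial
at that PSI.  Every dataset ships with a machine-readable truth table so the
whole pipeline — event enumeration, PSI quantification, detection filtering,
moderated-t calls, concordance and motif enrichment — can be validated
end-to-end without external sequencing data.

Gene structures are built per planted event type: a cassette gene has an
inclusion and a skipping transcript, an intron-retention gene a single
two-exon transcript, alternative splice-site genes two transcripts sharing
one splice site, and alternative-promoter genes two transcripts with
disjoint first exons.  Events enumerated from those genes beyond the planted
one (e.g. the retained-intron events of a cassette gene's introns) are
non-differential background.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .gene_model import (Gene, GeneModel, SplicingEvent, Transcript,
                         enumerate_events, to_gtf)
from .motifs import BASES, PositionFrequencyMatrix
from .psi import JunctionCountTable
from .concordance import SplicingSignature


class ConfigError(ValueError):
    """Infeasible or invalid simulation configuration."""


@dataclass
class PlantedEvent:
    event_type: str
    psi_a: float
    psi_b: float

    def __post_init__(self) -> None:
        from .gene_model import EVENT_TYPES

        if self.event_type not in EVENT_TYPES:
            raise ConfigError(f"unknown planted event type {self.event_type!r}")
        for p in (self.psi_a, self.psi_b):
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"planted PSI must be in [0,1], got {p}")


@dataclass
class SimulationConfig:
    """Study conditions for the two-group junction-count simulation.

    Defaults mirror a typical shRNA knockdown RNA-seq contrast: 10 samples
    per group, ~200 junction reads supporting an average event, moderate
    depth unevenness, and mild biological PSI overdispersion (rho = 0.05).
    """

    n_genes: int = 100
    exons_per_gene: tuple[int, int] = (2, 6)
    n_samples_per_group: int = 10
    mean_depth: float = 200.0
    depth_dispersion: float = 0.3
    planted_events: list[PlantedEvent] = field(default_factory=list)
    rho: float = 0.05
    seed: int = 0
    group_labels: tuple[str, str] = ("A", "B")

    def __post_init__(self) -> None:
        lo, hi = self.exons_per_gene
        if lo < 2 or hi < lo:
            raise ConfigError("exons_per_gene must satisfy 2 <= min <= max")
        if self.n_genes < 1 or self.n_samples_per_group < 1:
            raise ConfigError("n_genes and n_samples_per_group must be >= 1")
        if self.mean_depth < 1:
            raise ConfigError("mean_depth must be >= 1")
        if not 0.0 <= self.rho < 1.0:
            raise ConfigError("rho must be in [0, 1)")
        if len(self.planted_events) > self.n_genes:
            raise ConfigError("more planted events than genes")
        needs_three = {"cassette-exon", "alt-promoter"}
        for pe in self.planted_events:
            if pe.event_type in needs_three and hi < 3:
                raise ConfigError(
                    f"{pe.event_type} requires genes with >= 3 exons, "
                    f"but exons_per_gene max is {hi}")

    @classmethod
    def from_yaml(cls, stream) -> "SimulationConfig":
        data = yaml.safe_load(stream) or {}
        planted = [PlantedEvent(**p) for p in data.pop("planted_events", [])]
        if "exons_per_gene" in data:
            data["exons_per_gene"] = tuple(data["exons_per_gene"])
        if "group_labels" in data:
            data["group_labels"] = tuple(data["group_labels"])
        return cls(planted_events=planted, **data)

    def to_yaml(self) -> str:
        data = asdict(self)
        data["exons_per_gene"] = list(self.exons_per_gene)
        data["group_labels"] = list(self.group_labels)
        return yaml.safe_dump(data, sort_keys=False)


# ---------------------------------------------------------------------------
# Gene model generation

_GENE_SPACING = 20_000


def _make_gene(gene_id: str, chrom: str, offset: int, event_type: str | None,
               rng: np.random.Generator, max_exons: int) -> Gene:
    strand = "+" if rng.random() < 0.5 else "-"

    def exon_len() -> int:
        return int(rng.integers(80, 201))

    def intron_len() -> int:
        return int(rng.integers(300, 1201))

    if event_type in ("cassette-exon", "alt-promoter"):
        n_exons = 3
    else:
        n_exons = int(rng.integers(2, max(3, min(max_exons, 4)) + 1))
        n_exons = max(2, min(n_exons, max_exons))
    starts, ends = [], []
    pos = offset
    for _ in range(n_exons):
        starts.append(pos)
        pos += exon_len()
        ends.append(pos)
        pos += intron_len()
    exons = list(zip(starts, ends))

    if event_type == "cassette-exon":
        txs = [Transcript("t1", list(exons)),
               Transcript("t2", [exons[0], exons[2]])]
    elif event_type == "alt-promoter":
        # disjoint first exons in transcription order, shared downstream
        if strand == "+":
            txs = [Transcript("t1", [exons[0], exons[2]]),
                   Transcript("t2", [exons[1], exons[2]])]
        else:
            txs = [Transcript("t1", [exons[0], exons[2]]),
                   Transcript("t2", [exons[0], exons[1]])]
    elif event_type == "alt-5ss":
        a, b = exons[0], exons[1]
        shift = int(rng.integers(20, 60))
        if strand == "+":
            txs = [Transcript("t1", [a, b]),
                   Transcript("t2", [(a[0], a[1] - shift), b])]
        else:
            txs = [Transcript("t1", [a, b]),
                   Transcript("t2", [a, (b[0] + shift, b[1])])]
    elif event_type == "alt-3ss":
        a, b = exons[0], exons[1]
        shift = int(rng.integers(20, 60))
        if strand == "+":
            txs = [Transcript("t1", [a, b]),
                   Transcript("t2", [a, (b[0] + shift, b[1])])]
        else:
            txs = [Transcript("t1", [a, b]),
                   Transcript("t2", [(a[0], a[1] - shift), b])]
    else:  # intron-retention or unplanted background gene
        txs = [Transcript("t1", list(exons))]
    return Gene(gene_id, chrom, strand, txs)


def simulate_gene_model(config: SimulationConfig) -> GeneModel:
    """Deterministic gene model containing one gene per planted event plus
    background genes, laid out along chr1."""
    rng = np.random.default_rng(config.seed)
    genes = []
    offset = 1000
    for i in range(config.n_genes):
        etype = (config.planted_events[i].event_type
                 if i < len(config.planted_events) else None)
        gene = _make_gene(f"G{i + 1:05d}", "chr1", offset, etype, rng,
                          config.exons_per_gene[1])
        genes.append(gene)
        offset = max(e for t in gene.transcripts for _, e in t.exons) + _GENE_SPACING
    model = GeneModel(genes)
    model.validate()
    return model


def _match_planted(model: GeneModel, events: Sequence[SplicingEvent],
                   config: SimulationConfig) -> dict[str, PlantedEvent]:
    """Map event_id → planted spec for the designated event of each planted gene."""
    by_gene: dict[str, list[SplicingEvent]] = {}
    for ev in events:
        by_gene.setdefault(ev.gene_id, []).append(ev)
    planted: dict[str, PlantedEvent] = {}
    for i, pe in enumerate(config.planted_events):
        gid = f"G{i + 1:05d}"
        cands = sorted((ev for ev in by_gene.get(gid, [])
                        if ev.event_type == pe.event_type),
                       key=lambda e: e.event_id)
        if not cands:
            raise ConfigError(
                f"gene {gid} produced no {pe.event_type} event for planting")
        planted[cands[0].event_id] = pe
    return planted


def _beta_psi(mu: float, rho: float, size: int, rng: np.random.Generator) -> np.ndarray:
    mu = min(max(mu, 1e-6), 1.0 - 1e-6)
    if rho <= 0:
        return np.full(size, mu)
    a = mu * (1.0 - rho) / rho
    b = (1.0 - mu) * (1.0 - rho) / rho
    return rng.beta(a, b, size=size)


def _nb_depth(mean: float, dispersion: float, size: int,
              rng: np.random.Generator) -> np.ndarray:
    if dispersion <= 0:
        return rng.poisson(mean, size=size)
    n = 1.0 / dispersion
    p = n / (n + mean)
    return rng.negative_binomial(n, p, size=size)


def simulate_junction_counts(model: GeneModel, config: SimulationConfig,
                             ) -> tuple[list[JunctionCountTable], pd.DataFrame]:
    """Per-sample junction counts with a complete truth table.

    Each event is simulated independently at its own junctions; when two
    enumerated events compete for a junction (e.g. a cassette inclusion
    junction doubling as the spliced form of an intron-retention event) the
    planted event wins and the other is left unsimulated — it still appears
    in the truth table as non-differential.  Boundary counts of retained
    introns are an even binomial split of twice the inclusion draw, so their
    mean equals the inclusion read count.
    """
    rng = np.random.default_rng(config.seed + 1)
    events = enumerate_events(model)
    planted = _match_planted(model, events, config)

    n = config.n_samples_per_group
    ga, gb = config.group_labels
    sample_ids = [f"{ga}{i + 1}" for i in range(n)] + [f"{gb}{i + 1}" for i in range(n)]
    counts: list[dict] = [dict() for _ in sample_ids]

    # planted events claim their junctions first, then background events
    ordered = sorted(events, key=lambda e: (e.event_id not in planted, e.event_id))
    claimed: set = set()
    truth_rows = []
    for ev in ordered:
        spec = planted.get(ev.event_id)
        if spec is not None:
            mu_a, mu_b = spec.psi_a, spec.psi_b
        else:
            mu_a = mu_b = float(rng.uniform(0.1, 0.9))
        simulated = not (ev.junctions() & claimed)
        if simulated:
            claimed |= ev.junctions()
            mus = np.concatenate([np.full(n, mu_a), np.full(n, mu_b)])
            depth = _nb_depth(config.mean_depth, config.depth_dispersion,
                              len(sample_ids), rng)
            for s_idx, (mu, dep) in enumerate(zip(mus, depth)):
                psi_s = float(_beta_psi(mu, config.rho, 1, rng)[0])
                inc = int(rng.binomial(dep, psi_s))
                exc = int(dep) - inc
                inc_j = sorted(ev.inclusion_junctions)
                exc_j = sorted(ev.exclusion_junctions)
                c = counts[s_idx]
                if ev.event_type == "intron-retention":
                    b1 = int(rng.binomial(2 * inc, 0.5))
                    b2 = 2 * inc - b1
                    c[inc_j[0]] = c.get(inc_j[0], 0) + b1
                    c[inc_j[1]] = c.get(inc_j[1], 0) + b2
                elif len(inc_j) == 2:
                    c1 = int(rng.binomial(inc, 0.5))
                    c[inc_j[0]] = c.get(inc_j[0], 0) + c1
                    c[inc_j[1]] = c.get(inc_j[1], 0) + inc - c1
                else:
                    c[inc_j[0]] = c.get(inc_j[0], 0) + inc
                c[exc_j[0]] = c.get(exc_j[0], 0) + exc
        delta = mu_a - mu_b
        truth_rows.append({
            "event_id": ev.event_id,
            "gene_id": ev.gene_id,
            "event_type": ev.event_type,
            "cluster_id": ev.cluster_id,
            "is_differential": spec is not None and mu_a != mu_b,
            "true_delta_psi": delta,
            "direction": int(np.sign(delta)),
            "psi_a": mu_a,
            "psi_b": mu_b,
            "simulated": simulated,
        })
    tables = [JunctionCountTable(sid, c) for sid, c in zip(sample_ids, counts)]
    truth = pd.DataFrame(truth_rows).set_index("event_id").sort_index()
    return tables, truth


def design_frame(config: SimulationConfig) -> pd.DataFrame:
    """Two-group design table matching `simulate_junction_counts` sample ids."""
    n = config.n_samples_per_group
    ga, gb = config.group_labels
    rows = ([{"sample_id": f"{ga}{i + 1}", "group": ga} for i in range(n)]
            + [{"sample_id": f"{gb}{i + 1}", "group": gb} for i in range(n)])
    return pd.DataFrame(rows)


def simulate_dataset(config: SimulationConfig):
    """Convenience wrapper: (model, count tables, design, truth table)."""
    model = simulate_gene_model(config)
    tables, truth = simulate_junction_counts(model, config)
    return model, tables, design_frame(config), truth


# ---------------------------------------------------------------------------
# Paired signatures with controlled concordance structure


def simulate_paired_comparisons(n_shared: int, anti_fraction: float,
                                n_private_each: int = 0, seed: int = 0,
                                ) -> tuple[SplicingSignature, SplicingSignature, dict]:
    """Two signatures sharing n_shared events, a controlled fraction of which
    carry opposite direction signs.

    Exactly ``round(anti_fraction * n_shared)`` shared events are
    anti-concordant; each signature additionally has ``n_private_each``
    events of its own.  Deterministic under seed.
    """
    if not 0.0 <= anti_fraction <= 1.0:
        raise ValueError("anti_fraction must be in [0, 1]")
    if n_shared < 0 or n_private_each < 0:
        raise ValueError("counts must be non-negative")
    rng = np.random.default_rng(seed)
    shared_ids = [f"evt:chr1:+:{1000 * i}-{1000 * i + 100}" for i in range(n_shared)]
    n_anti = int(round(anti_fraction * n_shared))
    anti_ids = set(rng.choice(shared_ids, size=n_anti, replace=False)) \
        if n_anti else set()
    dirs_a, dirs_b, mag_a, mag_b = {}, {}, {}, {}
    for eid in shared_ids:
        d = int(rng.choice([-1, 1]))
        dirs_a[eid] = d
        dirs_b[eid] = -d if eid in anti_ids else d
        mag_a[eid] = float(rng.uniform(0.1, 0.6))
        mag_b[eid] = float(rng.uniform(0.1, 0.6))
    for k in range(n_private_each):
        ida = f"evt:chr2:+:{1000 * k}-{1000 * k + 100}"
        idb = f"evt:chr3:+:{1000 * k}-{1000 * k + 100}"
        dirs_a[ida] = int(rng.choice([-1, 1]))
        dirs_b[idb] = int(rng.choice([-1, 1]))
    sig_a = SplicingSignature("sim_a", dirs_a, mag_a)
    sig_b = SplicingSignature("sim_b", dirs_b, mag_b)
    truth = {"n_shared": n_shared, "n_anti": n_anti,
             "anti_event_ids": sorted(anti_ids)}
    return sig_a, sig_b, truth


# ---------------------------------------------------------------------------
# Motif-planted sequence sets


def simulate_sequences_with_motif(pfm: PositionFrequencyMatrix, n_seqs: int,
                                  seq_len: int, plant_rate: float,
                                  bg_composition: Sequence[float] | None = None,
                                  seed: int = 0,
                                  ) -> tuple[list[tuple[str, str]], list[tuple[str, str]]]:
    """Target sequences with motif instances planted at rate ``plant_rate``
    plus a pure-composition background set.

    Motif instances are sampled per position from the PFM columns (consensus-
    biased, not the bare consensus).  Returns ``(targets, background)`` as
    lists of (name, RNA sequence).  Deterministic under seed.
    """
    if seq_len < pfm.width:
        raise ValueError("seq_len must be >= motif width")
    if not 0.0 <= plant_rate <= 1.0:
        raise ValueError("plant_rate must be in [0, 1]")
    comp = np.asarray(bg_composition if bg_composition is not None
                      else [0.25] * 4, dtype=float)
    comp = comp / comp.sum()
    rng = np.random.default_rng(seed)

    def bg_seq() -> np.ndarray:
        return rng.choice(4, size=seq_len, p=comp)

    def motif_instance() -> np.ndarray:
        return np.array([rng.choice(4, p=row) for row in pfm.matrix])

    targets, background = [], []
    for i in range(n_seqs):
        enc = bg_seq()
        if rng.random() < plant_rate:
            pos = int(rng.integers(0, seq_len - pfm.width + 1))
            enc[pos:pos + pfm.width] = motif_instance()
        targets.append((f"target_{i + 1}", "".join(BASES[b] for b in enc)))
    for i in range(n_seqs):
        enc = bg_seq()
        background.append((f"bg_{i + 1}", "".join(BASES[b] for b in enc)))
    return targets, background


def records_to_fasta(records: Sequence[tuple[str, str]]) -> str:
    """Serialise (name, sequence) pairs as FASTA text."""
    from io import StringIO

    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    buf = StringIO()
    seqio_write([SeqRecord(Seq(s), id=n, description="") for n, s in records],
                buf, "fasta")
    return buf.getvalue()
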