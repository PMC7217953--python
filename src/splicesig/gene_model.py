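"""Gene models, splice junctions and alternative-splicing event enumeration.

A :class:`GeneModel` holds genes → transcripts → exon intervals parsed from
GTF.  From transcript structure we derive splice junctions (exon–exon gaps
and exon–intron boundaries) and enumerate the competing splicing choices a
junction-based PSI analysis can quantify: cassette exons, retained introns,
alternative 5'/3' splice sites and alternative promoters.  Events that
compete over the same junction neighbourhood share a ``cluster_id`` so that
downstream reporting can be deduplicated to one result per junction cluster.

All internal coordinates are 0-based half-open; GTF is read (and written by
the simulator) as 1-based inclusive.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

from gffutils.feature import feature_from_line

EXON_EXON = "exon-exon"
EXON_INTRON = "exon-intron"

EVENT_TYPES = (
    "cassette-exon",
    "intron-retention",
    "alt-5ss",
    "alt-3ss",
    "alt-promoter",
)


class GtfParseError(ValueError):
    """Malformed GTF input; carries the offending line number."""


class GtfStructureError(ValueError):
    """Structurally invalid gene model (e.g. exon without a transcript parent)."""


class ClassificationError(ValueError):
    """Junction geometry that fits none of the known event categories."""


@dataclass(frozen=True, order=True)
class Junction:
    """A splice junction on the genome axis (donor < acceptor).

    ``donor``/``acceptor`` are genomic left/right coordinates irrespective of
    strand.  Exon–exon junctions span an excised intron ``[donor, acceptor)``;
    exon–intron junctions span a single exon/intron boundary (one endpoint in
    the exon, one in the intron).
    """

    chrom: str
    donor: int
    acceptor: int
    strand: str
    kind: str = EXON_EXON

    def __post_init__(self) -> None:
        if self.donor >= self.acceptor:
            raise ValueError(f"junction donor must precede acceptor: {self}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-': {self.strand!r}")
        if self.kind not in (EXON_EXON, EXON_INTRON):
            raise ValueError(f"unknown junction kind: {self.kind!r}")

    def coords(self) -> str:
        return f"{self.donor}-{self.acceptor}"


@dataclass
class Transcript:
    transcript_id: str
    exons: list[tuple[int, int]] = field(default_factory=list)

    def sorted_exons(self) -> list[tuple[int, int]]:
        return sorted(self.exons)

    def introns(self) -> list[tuple[int, int]]:
        ex = self.sorted_exons()
        return [(ex[i][1], ex[i + 1][0]) for i in range(len(ex) - 1)]


@dataclass
class Gene:
    gene_id: str
    chrom: str
    strand: str
    transcripts: list[Transcript] = field(default_factory=list)

    def exon_set(self) -> set[tuple[int, int]]:
        return {e for t in self.transcripts for e in t.exons}


@dataclass
class GeneModel:
    genes: list[Gene] = field(default_factory=list)

    def __iter__(self) -> Iterator[Gene]:
        return iter(self.genes)

    def __len__(self) -> int:
        return len(self.genes)

    def gene(self, gene_id: str) -> Gene:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    def validate(self) -> None:
        for g in self.genes:
            for t in g.transcripts:
                if not t.exons:
                    raise GtfStructureError(
                        f"transcript {t.transcript_id} of {g.gene_id} has no exons"
                    )
                ex = t.sorted_exons()
                for (s0, e0), (s1, e1) in zip(ex, ex[1:]):
                    if s1 < e0:
                        raise GtfStructureError(
                            f"overlapping exons in transcript {t.transcript_id}"
                        )


@dataclass(frozen=True)
class SplicingEvent:
    """One alternative-splicing choice: inclusion vs exclusion junction sets.

    For intron retention the inclusion evidence is the pair of exon–intron
    boundary junctions and the exclusion evidence the single spliced
    exon–exon junction; for every other type both sets are exon–exon.
    """

    event_id: str
    gene_id: str
    event_type: str
    chrom: str
    strand: str
    target_start: int
    target_end: int
    inclusion_junctions: frozenset[Junction]
    exclusion_junctions: frozenset[Junction]
    cluster_id: str = ""

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise ValueError(f"unknown event type {self.event_type!r}")
        if not self.inclusion_junctions or not self.exclusion_junctions:
            raise ValueError("inclusion and exclusion junction sets must be nonempty")
        if self.inclusion_junctions & self.exclusion_junctions:
            raise ValueError("inclusion and exclusion junction sets must be disjoint")
        for j in self.junctions():
            if j.chrom != self.chrom or j.strand != self.strand:
                raise ValueError("all junctions of an event share chromosome and strand")

    def junctions(self) -> frozenset[Junction]:
        return self.inclusion_junctions | self.exclusion_junctions

    @property
    def target_interval(self) -> tuple[int, int]:
        return (self.target_start, self.target_end)


# ---------------------------------------------------------------------------
# GTF parsing


def parse_gene_model(gtf_stream) -> GeneModel:
    """Parse gene/transcript/exon GTF records into a :class:`GeneModel`.

    Accepts a text stream or a string.  1-based inclusive GTF coordinates are
    converted to 0-based half-open.  Feature types other than
    gene/transcript/exon are ignored.  Genes and transcripts may be declared
    implicitly by their exons' attributes.
    """
    if isinstance(gtf_stream, str):
        gtf_stream = io.StringIO(gtf_stream)

    genes: dict[str, Gene] = {}
    transcripts: dict[tuple[str, str], Transcript] = {}

    for lineno, line in enumerate(gtf_stream, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        try:
            feat = feature_from_line(line)
        except Exception as exc:  # gffutils raises assorted exceptions
            raise GtfParseError(f"malformed GTF at line {lineno}: {exc}") from exc
        ftype = feat.featuretype
        if ftype not in ("gene", "transcript", "exon"):
            continue
        attrs = feat.attributes
        if "gene_id" not in attrs:
            raise GtfParseError(f"missing gene_id attribute at line {lineno}")
        gene_id = attrs["gene_id"][0]
        gene = genes.get(gene_id)
        if gene is None:
            gene = genes[gene_id] = Gene(gene_id, feat.seqid, feat.strand)
        if ftype == "gene":
            continue
        if "transcript_id" not in attrs:
            raise GtfParseError(f"missing transcript_id attribute at line {lineno}")
        tx_id = attrs["transcript_id"][0]
        key = (gene_id, tx_id)
        tx = transcripts.get(key)
        if tx is None:
            tx = transcripts[key] = Transcript(tx_id)
            gene.transcripts.append(tx)
        if ftype == "exon":
            # GTF 1-based inclusive -> 0-based half-open
            tx.exons.append((feat.start - 1, feat.end))

    model = GeneModel(list(genes.values()))
    for g in model.genes:
        if not g.transcripts:
            raise GtfStructureError(f"gene {g.gene_id} declared without transcripts")
    model.validate()
    return model


def to_gtf(model: GeneModel, source: str = "splicesig") -> str:
    """Serialise a gene model as GTF text (1-based inclusive coordinates)."""
    lines = []
    for g in model.genes:
        g_start = min(s for t in g.transcripts for s, _ in t.exons)
        g_end = max(e for t in g.transcripts for _, e in t.exons)
        lines.append(
            f"{g.chrom}\t{source}\tgene\t{g_start + 1}\t{g_end}\t.\t{g.strand}\t.\t"
            f'gene_id "{g.gene_id}";'
        )
        for t in g.transcripts:
            ex = t.sorted_exons()
            lines.append(
                f"{g.chrom}\t{source}\ttranscript\t{ex[0][0] + 1}\t{ex[-1][1]}\t.\t"
                f'{g.strand}\t.\tgene_id "{g.gene_id}"; transcript_id "{t.transcript_id}";'
            )
            for s, e in ex:
                lines.append(
                    f"{g.chrom}\t{source}\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                    f'gene_id "{g.gene_id}"; transcript_id "{t.transcript_id}";'
                )
    return "\n".join(lines) + ("\n" if lines else "")


# ---------------------------------------------------------------------------
# Event enumeration


def _event_id(event_type: str, chrom: str, strand: str, t0: int, t1: int,
              exclusion: Iterable[Junction]) -> str:
    exc = ";".join(j.coords() for j in sorted(exclusion))
    return f"{event_type}:{chrom}:{strand}:{t0}-{t1}:{exc}"


def _ir_events(gene: Gene) -> list[SplicingEvent]:
    events = []
    introns = sorted({iv for t in gene.transcripts for iv in t.introns()})
    for a, b in introns:
        if b - a < 1:
            continue
        spliced = Junction(gene.chrom, a, b, gene.strand, EXON_EXON)
        left = Junction(gene.chrom, a - 1, a, gene.strand, EXON_INTRON)
        right = Junction(gene.chrom, b - 1, b, gene.strand, EXON_INTRON)
        events.append(
            SplicingEvent(
                event_id=_event_id("intron-retention", gene.chrom, gene.strand, a, b,
                                   [spliced]),
                gene_id=gene.gene_id,
                event_type="intron-retention",
                chrom=gene.chrom,
                strand=gene.strand,
                target_start=a,
                target_end=b,
                inclusion_junctions=frozenset([left, right]),
                exclusion_junctions=frozenset([spliced]),
            )
        )
    return events


def _cassette_events(gene: Gene) -> list[SplicingEvent]:
    all_junctions = {
        Junction(gene.chrom, a, b, gene.strand, EXON_EXON)
        for t in gene.transcripts
        for a, b in t.introns()
    }
    seen: set[tuple[tuple[int, int], Junction]] = set()
    events = []
    for t in gene.transcripts:
        ex = t.sorted_exons()
        for i in range(1, len(ex) - 1):
            s, e = ex[i]
            up = Junction(gene.chrom, ex[i - 1][1], s, gene.strand, EXON_EXON)
            down = Junction(gene.chrom, e, ex[i + 1][0], gene.strand, EXON_EXON)
            for skip in all_junctions:
                if skip.donor <= up.donor and skip.acceptor >= down.acceptor:
                    key = ((s, e), skip)
                    if key in seen:
                        continue
                    seen.add(key)
                    events.append(
                        SplicingEvent(
                            event_id=_event_id("cassette-exon", gene.chrom, gene.strand,
                                               s, e, [skip]),
                            gene_id=gene.gene_id,
                            event_type="cassette-exon",
                            chrom=gene.chrom,
                            strand=gene.strand,
                            target_start=s,
                            target_end=e,
                            inclusion_junctions=frozenset([up, down]),
                            exclusion_junctions=frozenset([skip]),
                        )
                    )
    return events


def _alt_promoter_events(gene: Gene) -> list[SplicingEvent]:
    """Pairs of transcripts with non-overlapping first exons but identical
    downstream splice structure."""
    events = []
    seen: set[frozenset[Junction]] = set()
    txs = [t for t in gene.transcripts if len(t.exons) >= 2]
    for i in range(len(txs)):
        for j in range(i + 1, len(txs)):
            ta, tb = txs[i], txs[j]
            exa, exb = ta.sorted_exons(), tb.sorted_exons()
            if gene.strand == "-":
                # first exon in transcription order is the genomic-rightmost
                exa, exb = exa[::-1], exb[::-1]
            first_a, first_b = exa[0], exb[0]
            if exa[1:] != exb[1:]:
                continue
            # first exons must be disjoint intervals (a genuinely different
            # promoter, not an alternative splice site on a shared exon)
            if min(first_a[1], first_b[1]) > max(first_a[0], first_b[0]):
                continue
            if first_a == first_b:
                continue
            ja = _first_junction(gene, exa)
            jb = _first_junction(gene, exb)
            if ja is None or jb is None or ja == jb:
                continue
            pair = frozenset([ja, jb])
            if pair in seen:
                continue
            seen.add(pair)
            inc_j, exc_j = sorted([ja, jb])
            inc_first = first_a if ja == inc_j else first_b
            events.append(
                SplicingEvent(
                    event_id=_event_id("alt-promoter", gene.chrom, gene.strand,
                                       inc_first[0], inc_first[1], [exc_j]),
                    gene_id=gene.gene_id,
                    event_type="alt-promoter",
                    chrom=gene.chrom,
                    strand=gene.strand,
                    target_start=inc_first[0],
                    target_end=inc_first[1],
                    inclusion_junctions=frozenset([inc_j]),
                    exclusion_junctions=frozenset([exc_j]),
                )
            )
    return events


def _first_junction(gene: Gene, exons_tx_order: Sequence[tuple[int, int]]):
    """Junction following the first exon, in genomic (donor < acceptor) terms."""
    if len(exons_tx_order) < 2:
        return None
    a, b = exons_tx_order[0], exons_tx_order[1]
    if gene.strand == "+":
        return Junction(gene.chrom, a[1], b[0], gene.strand, EXON_EXON)
    return Junction(gene.chrom, b[1], a[0], gene.strand, EXON_EXON)


def _alt_ss_events(gene: Gene, exclude_pairs: set[frozenset[Junction]]) -> list[SplicingEvent]:
    junctions = sorted({
        Junction(gene.chrom, a, b, gene.strand, EXON_EXON)
        for t in gene.transcripts
        for a, b in t.introns()
    })
    events = []
    for i in range(len(junctions)):
        for j in range(i + 1, len(junctions)):
            j1, j2 = junctions[i], junctions[j]
            pair = frozenset([j1, j2])
            if pair in exclude_pairs:
                continue
            if j1.donor == j2.donor and j1.acceptor != j2.acceptor:
                shared = "left"
                lo, hi = sorted([j1.acceptor, j2.acceptor])
            elif j1.acceptor == j2.acceptor and j1.donor != j2.donor:
                shared = "right"
                lo, hi = sorted([j1.donor, j2.donor])
            else:
                continue
            # variable region [lo, hi): included by the shorter junction
            if shared == "left":
                etype = "alt-3ss" if gene.strand == "+" else "alt-5ss"
            else:
                etype = "alt-5ss" if gene.strand == "+" else "alt-3ss"
            shorter = j1 if (j1.acceptor - j1.donor) < (j2.acceptor - j2.donor) else j2
            longer = j2 if shorter is j1 else j1
            events.append(
                SplicingEvent(
                    event_id=_event_id(etype, gene.chrom, gene.strand, lo, hi, [longer]),
                    gene_id=gene.gene_id,
                    event_type=etype,
                    chrom=gene.chrom,
                    strand=gene.strand,
                    target_start=lo,
                    target_end=hi,
                    inclusion_junctions=frozenset([shorter]),
                    exclusion_junctions=frozenset([longer]),
                )
            )
    return events


def _assign_clusters(gene_id: str, events: list[SplicingEvent]) -> list[SplicingEvent]:
    """Connected components of events sharing any junction, ordered by the
    leftmost coordinate touched by each component."""
    if not events:
        return []
    parent = list(range(len(events)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: int, y: int) -> None:
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[max(rx, ry)] = min(rx, ry)

    by_junction: dict[Junction, int] = {}
    for idx, ev in enumerate(events):
        for jn in ev.junctions():
            if jn in by_junction:
                union(idx, by_junction[jn])
            else:
                by_junction[jn] = idx

    comp_members: dict[int, list[int]] = {}
    for idx in range(len(events)):
        comp_members.setdefault(find(idx), []).append(idx)

    def comp_key(members: list[int]) -> tuple[int, str]:
        left = min(min(j.donor for j in events[m].junctions()) for m in members)
        return (left, min(events[m].event_id for m in members))

    ordered = sorted(comp_members.values(), key=comp_key)
    out: dict[int, SplicingEvent] = {}
    for k, members in enumerate(ordered, start=1):
        cid = f"{gene_id}.c{k}"
        for m in members:
            ev = events[m]
            out[m] = SplicingEvent(
                event_id=ev.event_id, gene_id=ev.gene_id, event_type=ev.event_type,
                chrom=ev.chrom, strand=ev.strand,
                target_start=ev.target_start, target_end=ev.target_end,
                inclusion_junctions=ev.inclusion_junctions,
                exclusion_junctions=ev.exclusion_junctions,
                cluster_id=cid,
            )
    return [out[i] for i in range(len(events))]


def enumerate_events(model: GeneModel) -> list[SplicingEvent]:
    """Enumerate all candidate splicing events in a gene model.

    Deterministic: the same model always yields the same events, ids and
    cluster assignments.  Events are returned sorted by genomic position.
    """
    all_events: list[SplicingEvent] = []
    for gene in model.genes:
        events = []
        events.extend(_ir_events(gene))
        cassettes = _cassette_events(gene)
        events.extend(cassettes)
        promoters = _alt_promoter_events(gene)
        events.extend(promoters)
        exclude: set[frozenset[Junction]] = set()
        for ev in cassettes:
            exc = next(iter(ev.exclusion_junctions))
            for inc in ev.inclusion_junctions:
                exclude.add(frozenset([inc, exc]))
        for ev in promoters:
            exclude.add(ev.junctions())
        events.extend(_alt_ss_events(gene, exclude))
        all_events.extend(_assign_clusters(gene.gene_id, events))
    all_events.sort(key=lambda e: (e.chrom, e.target_start, e.target_end, e.event_id))
    ids = [e.event_id for e in all_events]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"non-unique event ids generated: {dup[:3]}")
    return all_events


def classify_event(event: SplicingEvent) -> str:
    """Re-derive the event-type label from junction geometry.

    Raises :class:`ClassificationError` when the geometry fits no category —
    never silently defaults.  Idempotent and consistent with
    :func:`enumerate_events`.
    """
    inc = sorted(event.inclusion_junctions)
    exc = sorted(event.exclusion_junctions)
    if any(j.kind == EXON_INTRON for j in inc):
        if (len(inc) == 2 and len(exc) == 1
                and all(j.kind == EXON_INTRON for j in inc)
                and exc[0].kind == EXON_EXON):
            return "intron-retention"
        raise ClassificationError(f"mixed boundary-junction geometry: {event.event_id}")
    if len(inc) == 2 and len(exc) == 1:
        skip = exc[0]
        if (skip.donor <= min(j.donor for j in inc)
                and skip.acceptor >= max(j.acceptor for j in inc)):
            return "cassette-exon"
        raise ClassificationError(f"two-junction inclusion not spanned: {event.event_id}")
    if len(inc) == 1 and len(exc) == 1:
        j1, j2 = inc[0], exc[0]
        lo_hi = tuple(sorted([j1.acceptor, j2.acceptor])) if j1.donor == j2.donor \
            else tuple(sorted([j1.donor, j2.donor])) if j1.acceptor == j2.acceptor \
            else None
        if lo_hi is None:
            raise ClassificationError(f"single-junction pair shares no endpoint: {event.event_id}")
        if event.target_interval == lo_hi:
            if j1.donor == j2.donor:
                return "alt-3ss" if event.strand == "+" else "alt-5ss"
            return "alt-5ss" if event.strand == "+" else "alt-3ss"
        # alt-promoter: target is the divergent first exon, abutting its junction
        if j1.acceptor == j2.acceptor:
            if event.strand == "+" and event.target_end == j1.donor:
                return "alt-promoter"
        if j1.donor == j2.donor:
            if event.strand == "-" and event.target_start == j1.acceptor:
                return "alt-promoter"
        raise ClassificationError(f"target interval matches no category: {event.event_id}")
    raise ClassificationError(f"unsupported junction multiplicity: {event.event_id}")


# ---------------------------------------------------------------------------
# Events table I/O

EVENTS_TABLE_COLUMNS = [
    "event_id", "gene_id", "cluster_id", "event_type", "chromosome", "strand",
    "target_start", "target_end", "inclusion_junctions", "exclusion_junctions",
]


def events_to_table(events: Sequence[SplicingEvent]):
    """Events as a tab-serialisable :class:`pandas.DataFrame`."""
    import pandas as pd

    rows = []
    for e in events:
        rows.append({
            "event_id": e.event_id,
            "gene_id": e.gene_id,
            "cluster_id": e.cluster_id,
            "event_type": e.event_type,
            "chromosome": e.chrom,
            "strand": e.strand,
            "target_start": e.target_start,
            "target_end": e.target_end,
            "inclusion_junctions": ";".join(j.coords() for j in sorted(e.inclusion_junctions)),
            "exclusion_junctions": ";".join(j.coords() for j in sorted(e.exclusion_junctions)),
        })
    return pd.DataFrame(rows, columns=EVENTS_TABLE_COLUMNS)
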