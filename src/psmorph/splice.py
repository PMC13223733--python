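"""Local splicing variation (LSV) stratification and polyA-evidence counting.

An LSV groups the splice junctions sharing one source (shared donor) or
target (shared acceptor) exon.  Differential splicing tools report, per
junction, a deltaPSI (change in percent-selected-index between conditions)
and a probability that the LSV changed.  This module applies the
regulated / non-regulated calling rules, reduces LSVs to their two main
junctions (binary stratification), classifies binary events geometrically,
and counts reads carrying non-templated 3' adenosine tails (soft-clipped
A-runs) as evidence of polyadenylated transcript ends.

Genomic coordinates are 0-based half-open internally and 1-based closed at
TSV interfaces (see ``synthetic.read_lsv_table`` / ``write_lsv_table``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pysam

#: deltaPSI (percent) above which an LSV can be called regulated
REGULATED_DPSI = 5.0
#: change probability above which an LSV can be called regulated
REGULATED_PROB = 0.5
#: deltaPSI (percent) below which an LSV can be called non-regulated
NONREGULATED_DPSI = 2.0


@dataclass(frozen=True)
class Junction:
    """A splice junction (or unspliced intron) as a genomic interval."""

    start: int  # donor-side coordinate, 0-based
    end: int    # acceptor-side coordinate, half-open
    kind: str = "junction"  # "junction" | "intron"


@dataclass
class LSVRecord:
    gene_id: str
    lsv_id: str
    orientation: str  # "source" | "target"
    junctions: list[Junction]
    delta_psi: list[float]  # percent, one per junction; sums to ~0
    probability: float      # change probability in [0, 1]

    def __post_init__(self) -> None:
        if len(self.junctions) != len(self.delta_psi):
            raise ValueError("one deltaPSI per junction required")
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError("probability must be in [0, 1]")


def lsv_from_row(row) -> LSVRecord:
    """Build an LSVRecord from one row of a (read-back) LSV table."""
    kinds = row["junction_kinds"]
    return LSVRecord(
        gene_id=row["gene_id"], lsv_id=row["lsv_id"],
        orientation=row["orientation"],
        junctions=[Junction(s, e, k) for (s, e), k in zip(row["junctions"], kinds)],
        delta_psi=list(row["delta_psi"]),
        probability=float(row["probability"]),
    )


def classify_regulated(lsv: LSVRecord) -> str:
    """Call an LSV regulated, non-regulated, or ambiguous.

    Regulated: max |deltaPSI| > 5 percent and change probability > 0.5.
    Non-regulated: max |deltaPSI| < 2 percent and probability exactly 0.
    Everything else (the 2–5 percent gap, or strong deltaPSI with weak
    probability) is ambiguous rather than silently dropped.
    """
    m = max(abs(d) for d in lsv.delta_psi)
    if m > REGULATED_DPSI and lsv.probability > REGULATED_PROB:
        return "regulated"
    if m < NONREGULATED_DPSI and lsv.probability == 0.0:
        return "non_regulated"
    return "ambiguous"


@dataclass
class BinaryLSV:
    lsv: LSVRecord
    main: Junction
    second: Junction
    main_dpsi: float
    second_dpsi: float


def binarize_lsv(lsv: LSVRecord) -> BinaryLSV | None:
    """Reduce an LSV to its two main junctions, or reject it.

    Junctions are ranked by |deltaPSI|.  The LSV is retained when the
    second-strongest junction explains at least half of the change of the
    strongest one (|dPSI2| >= 0.5 |dPSI1|) with the opposite sign — i.e.
    the variation is essentially a binary switch between two junctions.
    """
    if len(lsv.junctions) < 2:
        raise ValueError("an LSV needs at least 2 junctions")
    order = sorted(range(len(lsv.junctions)),
                   key=lambda i: abs(lsv.delta_psi[i]), reverse=True)
    i1, i2 = order[0], order[1]
    d1, d2 = lsv.delta_psi[i1], lsv.delta_psi[i2]
    if abs(d2) < 0.5 * abs(d1):
        return None
    if d1 * d2 > 0:
        return None
    return BinaryLSV(lsv, lsv.junctions[i1], lsv.junctions[i2], d1, d2)


@dataclass
class EventCall:
    event_type: str  # intron_retention | alt_3ss | alt_5ss | cassette
    cassette_subtype: str = "n/a"
    source_id: str = ""
    target_id: str = ""
    middle_exon: tuple[int, int] | None = None
    junction_pairs: list[tuple[Junction, Junction]] = field(default_factory=list)


def _cassette_patterns(src_juncs: Sequence[Junction],
                       tgt_juncs: Sequence[Junction],
                       ) -> list[tuple[Junction, Junction, Junction]]:
    """All (src_inclusion, tgt_inclusion, shared_skip) cassette patterns."""
    out = []
    skips = {(j.start, j.end) for j in src_juncs if j.kind == "junction"} & \
            {(j.start, j.end) for j in tgt_juncs if j.kind == "junction"}
    for s, e in skips:
        skip = Junction(s, e)
        for si in src_juncs:
            if si.kind != "junction" or (si.start, si.end) == (s, e):
                continue
            for ti in tgt_juncs:
                if ti.kind != "junction" or (ti.start, ti.end) == (s, e):
                    continue
                # inclusion junctions bracket a middle exon nested in the skip
                if (si.start == skip.start and ti.end == skip.end
                        and si.end < ti.start):
                    out.append((si, ti, skip))
    return out


def classify_event(source: LSVRecord, target: LSVRecord) -> EventCall:
    """Classify a binary splicing event from its source and target LSVs.

    Both LSVs must be regulated and pass :func:`binarize_lsv`.  Geometry,
    on each LSV's two main junctions:

    * an "intron"-kind junction among the mains         -> intron_retention
    * a shared skipping junction with nested inclusion
      junctions bracketing a middle exon                -> cassette
    * all mains sharing the donor, acceptors differing  -> alt_3ss
    * all mains sharing the acceptor, donors differing  -> alt_5ss
    """
    for lsv in (source, target):
        if classify_regulated(lsv) != "regulated":
            raise ValueError(f"LSV {lsv.lsv_id} is not regulated")
    bs, bt = binarize_lsv(source), binarize_lsv(target)
    if bs is None or bt is None:
        raise ValueError("both LSVs must pass binary stratification")
    mains = [bs.main, bs.second, bt.main, bt.second]

    if any(j.kind == "intron" for j in mains):
        return EventCall("intron_retention", source_id=source.lsv_id,
                         target_id=target.lsv_id)

    patterns = _cassette_patterns([bs.main, bs.second], [bt.main, bt.second])
    if patterns:
        si, ti, skip = patterns[0]
        # every pattern supported by non-main junctions marks complexity later
        all_patterns = _cassette_patterns(source.junctions, target.junctions)
        return EventCall("cassette", source_id=source.lsv_id,
                         target_id=target.lsv_id,
                         middle_exon=(si.end, ti.start),
                         junction_pairs=[(p[0], p[1]) for p in all_patterns])

    starts = {j.start for j in mains}
    ends = {j.end for j in mains}
    if len(starts) == 1 and len(ends) > 1:
        return EventCall("alt_3ss", source_id=source.lsv_id,
                         target_id=target.lsv_id)
    if len(ends) == 1 and len(starts) > 1:
        return EventCall("alt_5ss", source_id=source.lsv_id,
                         target_id=target.lsv_id)
    raise ValueError("junction geometry matches no supported event type")


def subclassify_cassette(event: EventCall,
                         transcript_exons: Sequence[tuple[int, int]] | None = None,
                         ) -> str:
    """Sub-classify a cassette event.

    ``transcript_exons`` is the ordered exon list of the transcript model.
    The event is *complex* when more than one inclusion-junction pattern
    supports it; otherwise *alt_first_exon* / *alt_last_exon* when the
    variable exon is transcript-terminal, else *simple*.  Without a model
    the terminal calls cannot be made and non-complex events fall back to
    "simple".
    """
    if event.event_type != "cassette":
        raise ValueError("not a cassette event")
    if len(event.junction_pairs) > 1:
        event.cassette_subtype = "complex"
        return "complex"
    if transcript_exons and event.middle_exon is not None:
        lo, hi = event.middle_exon
        first, last = transcript_exons[0], transcript_exons[-1]
        if first[0] <= lo and hi <= first[1]:
            event.cassette_subtype = "alt_first_exon"
            return "alt_first_exon"
        if last[0] <= lo and hi <= last[1]:
            event.cassette_subtype = "alt_last_exon"
            return "alt_last_exon"
    event.cassette_subtype = "simple"
    return "simple"


# ---------------------------------------------------------------------------
# polyA-evidence read counting
# ---------------------------------------------------------------------------

@dataclass
class PAReadCount:
    chrom: str
    start: int
    end: int
    n_pa_reads: int
    n_total_reads: int
    log2_fold_change: float = float("nan")  # vs a reference count, +1 pseudocount


def _soft_clip_tail(read: pysam.AlignedSegment) -> str:
    """Return the soft-clipped bases at the read's 3' end ('' if none).

    On forward reads the 3' end is the right end of the alignment (trailing
    soft clip); on reverse reads it is the left end, and a genomic-plus
    A-tail appears as leading soft-clipped T's.
    """
    cig = read.cigartuples
    seq = read.query_sequence
    if not cig or seq is None:
        return ""
    if read.is_reverse:
        op, ln = cig[0]
        return seq[:ln] if op == 4 else ""
    op, ln = cig[-1]
    return seq[-ln:] if op == 4 else ""


def is_pa_read(read: pysam.AlignedSegment, min_tail: int = 6,
               min_a_frac: float = 0.8) -> bool:
    """True when the read carries a non-templated 3' A-tail.

    The 3' soft clip must be at least ``min_tail`` nt with an A fraction
    (T on reverse-strand reads) of at least ``min_a_frac``.  Template-
    encoded A-runs do not qualify: only soft-clipped bases count.
    """
    tail = _soft_clip_tail(read)
    if len(tail) < min_tail:
        return False
    base = "T" if read.is_reverse else "A"
    return tail.upper().count(base) / len(tail) >= min_a_frac


def _three_prime_end(read: pysam.AlignedSegment) -> int:
    return read.reference_start if read.is_reverse else read.reference_end - 1


def count_pa_reads(reads: Iterable[pysam.AlignedSegment],
                   region: tuple[str, int, int], min_tail: int = 6,
                   min_a_frac: float = 0.8,
                   reference_count: int | None = None) -> PAReadCount:
    """Count reads whose aligned 3' end lies in ``region``, flagging pA ones.

    ``region`` is (chrom, start, end), 0-based half-open.  When
    ``reference_count`` (the pA count of a reference sample, e.g. the first
    timepoint) is given, a log2 fold change with a +1 pseudocount on both
    sides is reported.
    """
    chrom, start, end = region
    if end <= start:
        raise ValueError("empty region")
    n_pa = n_total = 0
    for read in reads:
        if read.is_unmapped or read.reference_name != chrom:
            continue
        if not (start <= _three_prime_end(read) < end):
            continue
        n_total += 1
        if is_pa_read(read, min_tail, min_a_frac):
            n_pa += 1
    lfc = float("nan")
    if reference_count is not None:
        lfc = float(np.log2((n_pa + 1.0) / (reference_count + 1.0)))
    return PAReadCount(chrom, start, end, n_pa, n_total, lfc)
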