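"""Transcript-to-locus assignment.

De novo assembled transcripts are aligned against a reference of discrete
TE insertions; a transcript is quantified only if it aligns to exactly one
locus with high identity over most of its length.  This module implements
that reduction: the identity/coverage filter, strict multi-map removal,
and the collapse of transcript counts onto unique loci.  A small
semi-global dynamic-programming aligner is included so toy fixtures can be
recomputed from FASTA alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConsistencyError, InputError, UsageError

#: Fixed family -> class lookup.  Families used by the synthetic reference
#: plus a few common real ones; the class vocabulary follows RepeatMasker.
FAMILY_TO_CLASS: dict[str, str] = {
    # LINE
    "L1HS": "LINE", "L1PA2": "LINE", "L1PA4": "LINE", "L1M3": "LINE",
    "L1M5": "LINE", "L1ME3D": "LINE", "L2a": "LINE", "L2b": "LINE",
    # SINE
    "AluY": "SINE", "AluSx": "SINE", "AluJb": "SINE", "MIRb": "SINE",
    # LTR
    "LTR5_Hs": "LTR", "HERVK-int": "LTR", "LTR7": "LTR", "MER21A": "LTR",
    "MER52A": "LTR", "LTR15": "LTR",
    # SVA
    "SVA_E": "SVA", "SVA_D": "SVA", "SVA_B": "SVA",
    # DNA
    "HSMAR1": "DNA", "MER1A": "DNA", "Charlie1": "DNA", "Tigger1": "DNA",
}

#: Families regarded as evolutionarily recent (primate/human specific).
RECENT_FAMILIES: frozenset[str] = frozenset(
    {"L1HS", "L1PA2", "AluY", "LTR5_Hs", "HERVK-int", "LTR7", "SVA_E", "SVA_D"}
)

TE_CLASSES = ("LINE", "SINE", "LTR", "SVA", "DNA")


@dataclass(frozen=True)
class TELocus:
    """One reference TE insertion: the unit of all downstream analysis."""

    locus_id: str
    chrom: str
    start: int  # 0-based, half-open
    end: int
    strand: str
    family: str
    te_class: str
    consensus_len: int
    recent: bool = False

    def __post_init__(self):
        if self.start >= self.end:
            raise InputError(
                f"locus {self.locus_id}: start must be < end "
                f"({self.start} >= {self.end})"
            )
        expected = FAMILY_TO_CLASS.get(self.family)
        if expected is not None and expected != self.te_class:
            raise InputError(
                f"locus {self.locus_id}: family {self.family} is class "
                f"{expected}, not {self.te_class}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class AlignmentRecord:
    """One transcript-vs-reference alignment (BLAST outfmt-6 dialect + qlen)."""

    transcript_id: str
    locus_id: str
    pident: float
    aln_len: int
    qlen: int
    bitscore: float = 0.0
    evalue: float = 0.0
    mismatch: int = 0
    gapopen: int = 0
    qstart: int = 1
    qend: int = 0
    sstart: int = 1
    send: int = 0

    @property
    def coverage(self) -> float:
        if self.qlen <= 0:
            raise InputError(
                f"transcript {self.transcript_id}: qlen must be positive"
            )
        return self.aln_len / self.qlen


@dataclass
class AssignmentTable:
    """Unique transcript -> locus map plus the discard log."""

    assigned: dict[str, str] = field(default_factory=dict)
    discarded: list[tuple[str, str]] = field(default_factory=list)

    @property
    def discarded_ids(self) -> set[str]:
        return {t for t, _ in self.discarded}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"transcript_id": t, "locus_id": l, "status": "assigned", "reason": ""}
            for t, l in sorted(self.assigned.items())
        ]
        rows += [
            {"transcript_id": t, "locus_id": "", "status": "discarded", "reason": r}
            for t, r in sorted(self.discarded)
        ]
        return pd.DataFrame(rows, columns=["transcript_id", "locus_id", "status", "reason"])


def records_from_frame(df: pd.DataFrame) -> list[AlignmentRecord]:
    """Build AlignmentRecords from a BLAST tabular DataFrame (see io module)."""
    out = []
    for row in df.itertuples(index=False):
        out.append(AlignmentRecord(
            transcript_id=str(row.qseqid), locus_id=str(row.sseqid),
            pident=float(row.pident), aln_len=int(row.length),
            qlen=int(row.qlen), bitscore=float(row.bitscore),
            evalue=float(row.evalue), mismatch=int(row.mismatch),
            gapopen=int(row.gapopen), qstart=int(row.qstart),
            qend=int(row.qend), sstart=int(row.sstart), send=int(row.send),
        ))
    return out


def filter_alignments(
    records: list[AlignmentRecord],
    min_identity: float = 95.0,
    min_coverage: float = 0.90,
) -> list[AlignmentRecord]:
    """Keep alignments with pident >= min_identity and coverage >= min_coverage.

    Thresholds are inclusive: a transcript at exactly 95% identity covering
    exactly 90% of its length passes.  Order of the input is preserved.
    """
    if not (0 < min_identity <= 100):
        raise UsageError(f"min_identity must be in (0, 100], got {min_identity}")
    if not (0 < min_coverage <= 1):
        raise UsageError(f"min_coverage must be in (0, 1], got {min_coverage}")
    kept = []
    for r in records:
        if r.qlen <= 0:
            raise InputError(
                f"transcript {r.transcript_id}: alignment record has qlen=0"
            )
        if r.pident >= min_identity and r.coverage >= min_coverage:
            kept.append(r)
    return kept


def discard_reasons(
    records: list[AlignmentRecord],
    min_identity: float = 95.0,
    min_coverage: float = 0.90,
) -> dict[str, str]:
    """Per-transcript reason for failing the filter (identity checked first).

    A transcript is 'failed' only if none of its alignments pass; the reason
    reported is that of its best-identity record.
    """
    by_transcript: dict[str, list[AlignmentRecord]] = {}
    for r in records:
        by_transcript.setdefault(r.transcript_id, []).append(r)
    reasons = {}
    for tid, recs in by_transcript.items():
        if any(r.pident >= min_identity and r.coverage >= min_coverage for r in recs):
            continue
        best = max(recs, key=lambda r: r.pident)
        if best.pident < min_identity:
            reasons[tid] = "low_identity"
        else:
            reasons[tid] = "low_coverage"
    return reasons


def resolve_unique(
    records: list[AlignmentRecord],
    best_hit_margin: float | None = None,
) -> AssignmentTable:
    """Assign each transcript to its unique passing locus.

    Transcripts whose passing alignments hit two or more distinct loci are
    discarded (reason ``multimap``); several alignments to the *same* locus
    (split alignments) count as one.  The result does not depend on input
    order.

    ``best_hit_margin`` (off by default) enables a rescue extension: a
    multi-locus transcript is still assigned when its best locus's top
    bitscore exceeds every other locus's by at least the margin.
    """
    loci_by_transcript: dict[str, dict[str, float]] = {}
    for r in records:
        scores = loci_by_transcript.setdefault(r.transcript_id, {})
        scores[r.locus_id] = max(scores.get(r.locus_id, -np.inf), r.bitscore)
    table = AssignmentTable()
    for tid in sorted(loci_by_transcript):
        scores = loci_by_transcript[tid]
        if len(scores) == 1:
            table.assigned[tid] = next(iter(scores))
            continue
        if best_hit_margin is not None:
            ranked = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
            if ranked[0][1] - ranked[1][1] >= best_hit_margin:
                table.assigned[tid] = ranked[0][0]
                continue
        table.discarded.append((tid, "multimap"))
    return table


def assign_transcripts(
    records: list[AlignmentRecord],
    min_identity: float = 95.0,
    min_coverage: float = 0.90,
    best_hit_margin: float | None = None,
) -> AssignmentTable:
    """Filter then resolve, logging every discarded transcript with a reason."""
    passing = filter_alignments(records, min_identity, min_coverage)
    table = resolve_unique(passing, best_hit_margin)
    for tid, reason in discard_reasons(records, min_identity, min_coverage).items():
        table.discarded.append((tid, reason))
    table.discarded.sort()
    return table


_VALID_NT = frozenset("ACGTN")


def align_semiglobal(
    query: str,
    target: str,
    match: int = 1,
    mismatch: int = -2,
    gap: int = -2,
    transcript_id: str = "query",
    locus_id: str = "target",
) -> AlignmentRecord:
    """Optimal semi-global alignment (free end gaps on the target).

    A toy-scale stand-in for a seeded local aligner, used to recompute
    identity and coverage of small fixtures directly from sequence.  The
    query must align end-to-end up to internal gaps; the target contributes
    any substring.  pident is matches over aligned columns x 100 and
    aln_len is the aligned query span.
    """
    q, t = query.upper(), target.upper()
    for name, s in (("query", q), ("target", t)):
        if not s:
            raise InputError(f"{name} sequence is empty")
        bad = set(s) - _VALID_NT
        if bad:
            raise InputError(f"{name} contains illegal characters: {sorted(bad)}")
    nq, nt = len(q), len(t)
    NEG = -(10 ** 9)
    # score[i][j]: best score aligning q[:i] with t ending at j (free start on t)
    score = np.full((nq + 1, nt + 1), NEG, dtype=np.int64)
    ptr = np.zeros((nq + 1, nt + 1), dtype=np.int8)  # 0 diag, 1 up(q gap?), 2 left
    score[0, :] = 0  # free leading target gap
    for i in range(1, nq + 1):
        score[i, 0] = score[i - 1, 0] + gap
        ptr[i, 0] = 1
    for i in range(1, nq + 1):
        diag = score[i - 1, :-1] + np.where(
            np.frombuffer(q[i - 1].encode(), dtype=np.uint8)
            == np.frombuffer(t.encode(), dtype=np.uint8),
            match, mismatch,
        )
        up = score[i - 1, 1:] + gap  # consume q[i-1] against a gap
        row = np.maximum(diag, up)
        choice = np.where(diag >= up, 0, 1)
        # left moves (gap in query) require a sequential pass
        for j in range(1, nt + 1):
            left = score[i, j - 1] + gap
            best = row[j - 1]
            if left > best:
                score[i, j] = left
                ptr[i, j] = 2
            else:
                score[i, j] = best
                ptr[i, j] = choice[j - 1]
    j_end = int(np.argmax(score[nq, :]))
    # traceback
    i, j = nq, j_end
    matches = cols = 0
    q_lo, q_hi = nq, 0
    t_lo, t_hi = j_end, 0
    while i > 0:
        move = ptr[i, j]
        if move == 0 and j > 0:
            cols += 1
            if q[i - 1] == t[j - 1]:
                matches += 1
            q_lo, q_hi = i - 1, max(q_hi, i)
            t_lo, t_hi = j - 1, max(t_hi, j)
            i, j = i - 1, j - 1
        elif move == 1 or j == 0:
            cols += 1
            q_lo, q_hi = i - 1, max(q_hi, i)
            i -= 1
        else:
            cols += 1
            t_lo, t_hi = j - 1, max(t_hi, j)
            j -= 1
    pident = 100.0 * matches / cols if cols else 0.0
    aln_len = q_hi - q_lo if q_hi > q_lo else 0
    return AlignmentRecord(
        transcript_id=transcript_id, locus_id=locus_id,
        pident=pident, aln_len=aln_len, qlen=nq,
        bitscore=float(score[nq, j_end]), evalue=0.0,
        mismatch=cols - matches, gapopen=0,
        qstart=q_lo + 1, qend=q_hi, sstart=t_lo + 1, send=max(t_hi, t_lo),
    )


def collapse_to_loci(
    table: AssignmentTable, transcript_counts: pd.DataFrame
) -> pd.DataFrame:
    """Sum assigned transcripts' counts per locus; discarded ones contribute 0.

    ``transcript_counts`` is transcripts x samples.  Every transcript in the
    counts must appear in the assignment table (either side); an empty
    result (zero loci) is returned if everything was discarded.
    """
    known = set(table.assigned) | table.discarded_ids
    missing = set(transcript_counts.index.astype(str)) - known
    if missing:
        raise ConsistencyError(
            f"{len(missing)} transcripts in counts are absent from the "
            f"assignment table (e.g. {sorted(missing)[:3]})"
        )
    keep = [t for t in transcript_counts.index.astype(str) if t in table.assigned]
    if not keep:
        return pd.DataFrame(columns=transcript_counts.columns)
    sub = transcript_counts.loc[keep]
    loci = pd.Series({t: table.assigned[t] for t in keep}, name="locus_id")
    out = sub.groupby(loci).sum()
    out.index.name = "locus_id"
    return out.sort_index()
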