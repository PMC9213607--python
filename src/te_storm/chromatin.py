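"""Chromatin-state annotation of TE loci against 15-state segmentations.

Each tissue contributes a genome segmentation into the 15 Roadmap core
states (TssA ... Quies).  A locus overlapping exactly one state inherits
that state's label; a locus straddling two or more states is labeled
``Mx`` (mixed); a locus with no segmentation coverage is ``NA``.  The
module also summarizes how much of a differential set falls in
functionally active states, runs per-state Fisher enrichment, and measures
cross-tissue label concordance.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage

from .assignment import TELocus
from .errors import InputError, UsageError

STATE_LABELS: tuple[str, ...] = (
    "1_TssA", "2_TssAFlnk", "3_TxFlnk", "4_Tx", "5_TxWk", "6_EnhG", "7_Enh",
    "8_ZNF/Rpts", "9_Het", "10_TssBiv", "11_BivFlnk", "12_EnhBiv",
    "13_ReprPC", "14_ReprPCWk", "15_Quies",
)

MX = "Mx"
NA = "NA"

#: Transcription / enhancer / promoter block treated as functionally active
#: by default; configurable, and echoed in every report that uses it.
DEFAULT_ACTIVE_STATES: frozenset[str] = frozenset(STATE_LABELS[:8])

_BY_MNEMONIC = {s.split("_", 1)[1]: s for s in STATE_LABELS}


def canonical_state(label: str) -> str:
    """Accept '5_TxWk', 'TxWk', or 'm5_TxWk' spellings; return '5_TxWk'."""
    label = label.strip()
    if label in STATE_LABELS or label in (MX, NA):
        return label
    m = re.match(r"^m?(\d+)_(.+)$", label)
    if m:
        cand = f"{int(m.group(1))}_{m.group(2)}"
        if cand in STATE_LABELS:
            return cand
    if label in _BY_MNEMONIC:
        return _BY_MNEMONIC[label]
    raise InputError(f"unknown chromatin state label: {label!r}")


@dataclass
class StateAssignment:
    """Per-locus, per-tissue label plus the bp overlap breakdown."""

    labels: pd.DataFrame  # loci x tissues, entries in STATE_LABELS | {Mx, NA}
    #: long format: locus_id, tissue, state, bp
    breakdown: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def tissues(self) -> list[str]:
        return list(self.labels.columns)


def _merge_same_state(df: pd.DataFrame) -> pd.DataFrame:
    """Merge adjacent same-state runs so labeling is split-invariant."""
    out = []
    for chrom, grp in df.groupby("chrom", sort=True):
        grp = grp.sort_values("start")
        cur = None
        for row in grp.itertuples(index=False):
            if cur is not None and row.state == cur[3] and row.start == cur[2]:
                cur[2] = row.end
            else:
                if cur is not None:
                    out.append(cur)
                cur = [chrom, row.start, row.end, row.state]
        if cur is not None:
            out.append(cur)
    return pd.DataFrame(out, columns=["chrom", "start", "end", "state"])


def _validate_segmentation(df: pd.DataFrame, tissue: str) -> pd.DataFrame:
    df = df.copy()
    df["state"] = df["state"].map(canonical_state)
    for chrom, grp in df.groupby("chrom"):
        grp = grp.sort_values("start")
        if (grp["end"].to_numpy()[:-1] > grp["start"].to_numpy()[1:]).any():
            raise InputError(
                f"tissue {tissue}: overlapping segmentation intervals on {chrom}"
            )
    return df


def overlap_states(
    loci: Sequence[TELocus],
    segmentation: Mapping[str, pd.DataFrame],
    min_minor_fraction: float = 0.0,
) -> StateAssignment:
    """Half-open interval intersection of loci with each tissue's states.

    ``min_minor_fraction`` ignores states whose overlap is below that
    fraction of the locus's total covered bp before deciding between a
    single-state label and Mx (default 0: any 1-bp second state makes Mx).
    """
    tissues = list(segmentation)
    lids = [l.locus_id for l in loci]
    labels = pd.DataFrame(NA, index=pd.Index(lids, name="locus_id"), columns=tissues)
    rows = []
    for tissue in tissues:
        seg = _validate_segmentation(segmentation[tissue], tissue)
        seg = _merge_same_state(seg)
        by_chrom = {c: g.sort_values("start") for c, g in seg.groupby("chrom")}
        for l in loci:
            g = by_chrom.get(l.chrom)
            if g is None:
                continue
            starts = g["start"].to_numpy()
            ends = g["end"].to_numpy()
            lo = int(np.searchsorted(ends, l.start, side="right"))
            hi = int(np.searchsorted(starts, l.end, side="left"))
            bp_by_state: dict[str, int] = {}
            for i in range(lo, hi):
                ov = min(int(ends[i]), l.end) - max(int(starts[i]), l.start)
                if ov > 0:
                    st = g["state"].iat[i]
                    bp_by_state[st] = bp_by_state.get(st, 0) + ov
            if not bp_by_state:
                continue
            total = sum(bp_by_state.values())
            major = {
                s: bp for s, bp in bp_by_state.items()
                if bp >= min_minor_fraction * total
            } or bp_by_state
            labels.loc[l.locus_id, tissue] = (
                next(iter(major)) if len(major) == 1 else MX
            )
            for s, bp in sorted(bp_by_state.items()):
                rows.append({"locus_id": l.locus_id, "tissue": tissue,
                             "state": s, "bp": bp})
    breakdown = pd.DataFrame(rows, columns=["locus_id", "tissue", "state", "bp"])
    return StateAssignment(labels=labels, breakdown=breakdown)


def active_fraction(
    assignment: StateAssignment,
    de_set: Iterable[str],
    tissue: str,
    active_set: Iterable[str] = DEFAULT_ACTIVE_STATES,
) -> dict[str, float]:
    """Fraction of the set sitting in functionally active chromatin.

    Returns both readings of "active": ``label_based`` counts loci whose
    single-state label is active (Mx loci count only via their overlap),
    and ``any_overlap`` counts loci any of whose overlapping states is
    active.
    """
    if tissue not in assignment.labels.columns:
        raise UsageError(f"unknown tissue {tissue!r}")
    active = {canonical_state(s) for s in active_set}
    ids = [i for i in de_set]
    missing = set(ids) - set(assignment.labels.index)
    if missing:
        raise UsageError(f"loci not in assignment: {sorted(missing)[:5]}")
    if not ids:
        return {"label_based": float("nan"), "any_overlap": float("nan"), "n": 0}
    lab = assignment.labels.loc[ids, tissue]
    n_assigned = int((lab != NA).sum())
    bd = assignment.breakdown
    bd = bd[(bd["tissue"] == tissue) & bd["locus_id"].isin(ids)]
    any_active = bd[bd["state"].isin(active)]["locus_id"].unique()
    label_based = (lab.isin(active) | (lab.eq(MX) & lab.index.isin(any_active))).sum()
    denom = max(n_assigned, 1)
    return {
        "label_based": float((lab.isin(active)).sum() / denom),
        "any_overlap": float(len(set(any_active)) / denom),
        "mixed_counted_active": float(label_based / denom),
        "n": n_assigned,
    }


def state_enrichment(
    assignment: StateAssignment,
    de_set: Iterable[str],
    background: Iterable[str],
    tissue: str,
) -> pd.DataFrame:
    """Fisher 2x2 enrichment of each state label (Mx included) in a DE set."""
    from .enrichment import fisher_exact_2x2

    if tissue not in assignment.labels.columns:
        raise UsageError(f"unknown tissue {tissue!r}")
    de = set(de_set)
    bg = set(background)
    if not de <= bg:
        raise UsageError("de_set must be a subset of background")
    lab = assignment.labels[tissue]
    de_lab = lab.loc[sorted(de)]
    rest_lab = lab.loc[sorted(bg - de)]
    rows = []
    for state in list(STATE_LABELS) + [MX]:
        a = int((de_lab == state).sum())
        b = len(de_lab) - a
        c = int((rest_lab == state).sum())
        d = len(rest_lab) - c
        if a + c == 0:
            continue  # state absent everywhere: nothing to test
        oratio, p = fisher_exact_2x2(a, b, c, d)
        rows.append({
            "state": state, "a": a, "b": b, "c": c, "d": d,
            "odds_ratio": oratio, "p": p,
            "significant": p <= 0.01,
            "direction": "enriched" if (a * (c + d)) > (c * (a + b)) else "depleted",
        })
    return pd.DataFrame(rows)


def cross_tissue_consistency(
    assignment: StateAssignment,
    tissue_groups: Mapping[str, Sequence[str]] | None = None,
) -> dict:
    """Label agreement across tissues plus average-linkage tissue clustering.

    Returns per-locus agreement (mean pairwise label equality over
    tissues), a tissue x tissue agreement-distance matrix (1 - agreement),
    and, when >= 2 tissues, the scipy average-linkage matrix over that
    distance.
    """
    lab = assignment.labels
    tissues = list(lab.columns)
    covered = lab.replace(NA, np.nan)
    n_t = len(tissues)
    per_locus = pd.Series(np.nan, index=lab.index, name="agreement")
    if n_t >= 2:
        agree_sum = np.zeros(len(lab))
        pair_count = np.zeros(len(lab))
        for i in range(n_t):
            for j in range(i + 1, n_t):
                a, b = covered.iloc[:, i], covered.iloc[:, j]
                both = a.notna() & b.notna()
                agree_sum += ((a == b) & both).to_numpy()
                pair_count += both.to_numpy()
        with np.errstate(invalid="ignore"):
            per_locus = pd.Series(
                np.where(pair_count > 0, agree_sum / np.maximum(pair_count, 1), np.nan),
                index=lab.index, name="agreement",
            )
    dist = pd.DataFrame(0.0, index=tissues, columns=tissues)
    for i in range(n_t):
        for j in range(i + 1, n_t):
            a, b = covered.iloc[:, i], covered.iloc[:, j]
            both = a.notna() & b.notna()
            agr = float(((a == b) & both).sum() / both.sum()) if both.any() else 0.0
            dist.iloc[i, j] = dist.iloc[j, i] = 1.0 - agr
    result = {"per_locus_agreement": per_locus, "distance": dist, "linkage": None,
              "tissue_groups": dict(tissue_groups or {})}
    if n_t >= 2:
        from scipy.spatial.distance import squareform
        result["linkage"] = linkage(squareform(dist.to_numpy(), checks=False),
                                    method="average")
    return result
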