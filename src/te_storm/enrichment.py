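"""TE class/family enrichment, DE-set intersection, and cis gene assignment.

Enrichment of a differential set against the expressed background uses the
two-sided Fisher exact test with the point-probability ordering rule (the
two-sided p is the sum of probabilities of all tables, at fixed margins,
no more likely than the observed one).  The DE-set intersection test is the
one-sided hypergeometric tail.  Cis assignment maps each locus to the
protein-coding genes whose interval intersects the locus expanded by a
+-window (default 5000 bp) on both sides.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .assignment import TELocus
from .errors import ConsistencyError, UsageError

#: relative slack when comparing table probabilities, guards FP noise in the
#: point-probability ordering rule
_GAMMA = 1 + 1e-7


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Two-sided Fisher exact test for a 2x2 table.

    Returns ``(odds_ratio, p)`` where the odds ratio is ``ad/bc`` (0 and
    inf conventions when a cell is empty) and p sums the hypergeometric
    probabilities of every table with the observed margins whose
    probability does not exceed the observed table's.  Degenerate margins
    give p = 1.
    """
    for name, v in zip("abcd", (a, b, c, d)):
        if v < 0 or int(v) != v:
            raise UsageError(f"cell {name} must be a non-negative integer, got {v}")
    a, b, c, d = int(a), int(b), int(c), int(d)
    n = a + b + c + d
    if n == 0:
        raise UsageError("table total must be positive")
    if b * c == 0:
        oratio = np.nan if a * d == 0 else np.inf
    else:
        oratio = (a * d) / (b * c)
    r1, c1 = a + b, a + c
    if r1 == 0 or c1 == 0 or r1 == n or c1 == n:
        return oratio, 1.0
    lo = max(0, r1 + c1 - n)
    hi = min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, n, r1, c1)
    p_obs = pmf[a - lo]
    p = float(pmf[pmf <= p_obs * _GAMMA].sum())
    return oratio, min(p, 1.0)


@dataclass
class EnrichmentResult:
    label: str
    a: int
    b: int
    c: int
    d: int
    odds_ratio: float
    p: float
    direction: str
    significant: bool

    def as_dict(self) -> dict:
        return self.__dict__.copy()


def class_enrichment(
    de_set: Iterable[str],
    background: Iterable[str],
    class_of: Mapping[str, str],
    by: str = "class",
    alpha: float = 0.01,
) -> pd.DataFrame:
    """One Fisher 2x2 per TE class (or family) of a DE set vs the background.

    ``background`` is the full expressed set (the DE set must be contained
    in it); the comparison group is background \\ de_set.  Significance is
    flagged at raw p <= alpha (no correction across classes); BH-adjusted
    values are also written for transparency.
    """
    if by not in ("class", "family"):
        raise UsageError(f"by must be 'class' or 'family', got {by!r}")
    de = set(de_set)
    bg = set(background)
    if not de <= bg:
        raise ConsistencyError("de_set must be a subset of the background")
    rest = bg - de
    labels = sorted({class_of[x] for x in bg if x in class_of})
    rows = []
    for lab in labels:
        a = sum(1 for x in de if class_of.get(x) == lab)
        b = len(de) - a
        c = sum(1 for x in rest if class_of.get(x) == lab)
        d = len(rest) - c
        oratio, p = fisher_exact_2x2(a, b, c, d)
        expected = (a + b) * (a + c) / max(len(bg), 1)
        rows.append(EnrichmentResult(
            label=lab, a=a, b=b, c=c, d=d, odds_ratio=oratio, p=p,
            direction="enriched" if a > expected else "depleted",
            significant=p <= alpha,
        ).as_dict())
    out = pd.DataFrame(rows, columns=[
        "label", "a", "b", "c", "d", "odds_ratio", "p", "direction", "significant",
    ])
    out.insert(0, "by", by)
    if len(out):
        out["fdr"] = stats.false_discovery_control(out["p"], method="bh")
    else:
        out["fdr"] = pd.Series(dtype=float)
    return out


def intersection_test(
    set1: Iterable[str],
    set2: Iterable[str],
    universe: Iterable[str],
    directions1: Mapping[str, str] | None = None,
    directions2: Mapping[str, str] | None = None,
) -> dict:
    """Is the overlap of two DE sets larger than chance?

    Hypergeometric upper tail for the observed overlap given the universe
    of tested loci, plus (when per-locus directions are supplied) the
    up/down cross-tabulation of the shared loci.
    """
    u = set(universe)
    if not u:
        raise UsageError("universe must be non-empty")
    s1, s2 = set(set1), set(set2)
    if not (s1 <= u and s2 <= u):
        raise ConsistencyError("both sets must be subsets of the universe")
    overlap = s1 & s2
    k = len(overlap)
    # P(X >= k), X ~ Hypergeom(|U|, |s1|, |s2|)
    p = float(stats.hypergeom.sf(k - 1, len(u), len(s1), len(s2))) if k > 0 else 1.0
    table = pd.DataFrame(0, index=["up", "down"], columns=["up", "down"])
    concordant = np.nan
    if directions1 is not None and directions2 is not None and overlap:
        for lid in overlap:
            d1 = directions1.get(lid, "ns")
            d2 = directions2.get(lid, "ns")
            if d1 in table.index and d2 in table.columns:
                table.loc[d1, d2] += 1
        tot = table.to_numpy().sum()
        concordant = float(np.trace(table.to_numpy()) / tot) if tot else np.nan
    return {
        "overlap": k,
        "overlap_ids": sorted(overlap),
        "p": p,
        "expected": len(s1) * len(s2) / len(u),
        "direction_table": table,
        "direction_concordance": concordant,
    }


def cis_genes(
    loci: Sequence[TELocus],
    genes: pd.DataFrame,
    window: int = 5000,
) -> pd.DataFrame:
    """Genes whose interval intersects a locus expanded by +-window bp.

    ``genes`` is a BED6-style frame (chrom/start/end/name[/score/strand]).
    Intersection is half-open on the expanded interval
    ``[start - window, end + window)``.  The relation is reported relative
    to the locus strand (upstream = the locus's 5' side).  Chromosomes
    present on only one side produce a warning, not an error.
    """
    locus_chroms = {l.chrom for l in loci}
    gene_chroms = set(genes["chrom"].astype(str))
    odd = locus_chroms ^ gene_chroms
    if odd:
        warnings.warn(
            f"{len(odd)} chromosome names present on only one side: {sorted(odd)[:5]}"
        )
    by_chrom = {c: g.sort_values("start") for c, g in genes.groupby("chrom")}
    rows = []
    for l in loci:
        g = by_chrom.get(l.chrom)
        if g is None:
            continue
        win_lo = max(0, l.start - window)
        win_hi = l.end + window
        starts = g["start"].to_numpy()
        ends = g["end"].to_numpy()
        hit = (starts < win_hi) & (ends > win_lo)
        for _, row in g[hit].iterrows():
            if row["end"] <= l.start:
                distance = int(l.start - row["end"])
                side = "left"
            elif row["start"] >= l.end:
                distance = int(row["start"] - l.end)
                side = "right"
            else:
                distance = 0
                side = "overlap"
            if side == "overlap":
                relation = "overlap"
            elif l.strand == "-":
                relation = "upstream" if side == "right" else "downstream"
            else:
                relation = "upstream" if side == "left" else "downstream"
            rows.append({
                "locus_id": l.locus_id, "gene_id": str(row["name"]),
                "distance": distance, "relation": relation,
            })
    return pd.DataFrame(rows, columns=["locus_id", "gene_id", "distance", "relation"])


def fold_change_correlation(
    results1: pd.DataFrame, results2: pd.DataFrame
) -> dict:
    """Pearson and Spearman correlation of log2FC over shared loci."""
    shared = results1.index.intersection(results2.index)
    if len(shared) < 3:
        warnings.warn("fewer than 3 shared loci; correlation undefined")
        return {"n": int(len(shared)), "pearson_r": np.nan, "pearson_p": np.nan,
                "spearman_r": np.nan, "spearman_p": np.nan}
    x = results1.loc[shared, "logFC"].to_numpy()
    y = results2.loc[shared, "logFC"].to_numpy()
    pr = stats.pearsonr(x, y)
    sr = stats.spearmanr(x, y)
    return {
        "n": int(len(shared)),
        "pearson_r": float(pr.statistic), "pearson_p": float(pr.pvalue),
        "spearman_r": float(sr.statistic), "spearman_p": float(sr.pvalue),
    }
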