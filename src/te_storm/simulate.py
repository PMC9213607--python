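"""Synthetic data generator for the whole pipeline.

Emulates the structure of a blood-transcriptome TE study with a paired
converter design: the same subjects sampled before (``Converter_pre``) and
after (``Converter_post``) phenoconversion, plus an independent group of
never-converting controls (``NC``).  Counts are negative-binomial with a
per-locus, per-subject log-normal random intercept shared by a subject's
pre and post samples, planted log2 fold-changes concentrated in chosen TE
classes, and an age covariate generated independently of expression (a
null covariate for QC).  Transcript/alignment fixtures carry exact planted
identity, coverage, and multi-mapping so the assignment filters can be
checked against ground truth.

Every generator draws from its own RNG stream derived from the master
seed by a fixed label, so outputs are reproducible and stable when one
generator's call count changes.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io as teio
from .assignment import (
    FAMILY_TO_CLASS,
    RECENT_FAMILIES,
    AlignmentRecord,
    TELocus,
)
from .errors import ConfigurationError
from .normalize import ExpressionMatrix

CONTRASTS = ("pre_vs_post", "pre_vs_nc", "nc_vs_post")
GROUPS = ("NC", "Converter_pre", "Converter_post")

#: condition pairs per contrast; log2FC is second condition over first.
CONTRAST_CONDITIONS = {
    "pre_vs_post": ("Converter_pre", "Converter_post"),
    "pre_vs_nc": ("Converter_pre", "NC"),
    "nc_vs_post": ("NC", "Converter_post"),
}

_DEFAULT_CLASS_MIX = {
    "LINE": 0.35, "SINE": 0.30, "LTR": 0.20, "SVA": 0.05, "DNA": 0.10,
}

#: Relative sampling weight of each class when planting DE loci; mimics the
#: observed concentration of differential TE expression in LINE and LTR
#: elements, with SINE/Alu under-represented.
_DEFAULT_DE_CLASS_BIAS = {
    "LINE": 2.5, "SINE": 0.25, "LTR": 2.5, "SVA": 1.5, "DNA": 1.0,
}

_CLASS_FAMILIES = {
    "LINE": ("L1HS", "L1PA2", "L1PA4", "L1M3", "L2a"),
    "SINE": ("AluY", "AluSx", "MIRb"),
    "LTR": ("LTR5_Hs", "HERVK-int", "LTR7", "MER21A"),
    "SVA": ("SVA_E", "SVA_D"),
    "DNA": ("HSMAR1", "MER1A", "Charlie1"),
}

_RNG_LABELS = {
    "reference": 1,
    "transcripts": 2,
    "de_selection": 3,
    "counts": 4,
    "tracks": 5,
    "genes": 6,
    "metadata": 7,
}


def _rng(seed: int, label: str, extra: int | None = None) -> np.random.Generator:
    key = (_RNG_LABELS[label],) if extra is None else (_RNG_LABELS[label], extra)
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


@dataclass
class SimulationConfig:
    """Study-design and noise parameters for the synthetic dataset.

    Defaults mirror the emulated study: 25 paired converter subjects, 64
    independent controls, NB dispersion 0.1, planted |log2FC| = 2
    concentrated in LINE/LTR classes, with ~86% of planted effects elevated
    in the presymptomatic state.
    """

    n_loci: int = 2000
    class_mix: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_CLASS_MIX))
    n_subjects_conv: int = 25
    n_controls: int = 64
    de_fraction: float = 0.05
    frac_shared: float = 0.4
    frac_up: float = 0.86
    planted_lfc: float = 2.0
    dispersion: float = 0.1
    subject_sd: float = 0.7
    abundance_sd: float = 1.8
    lib_size_range: tuple[int, int] = (800_000, 1_200_000)
    n_tissues: int = 3
    frac_multimap: float = 0.3
    frac_lowid: float = 0.1
    frac_lowcov: float = 0.05
    de_class_bias: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_DE_CLASS_BIAS))
    seed: int = 0

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if self.n_loci <= 0:
            raise ConfigurationError(f"n_loci must be positive, got {self.n_loci}")
        total = sum(self.class_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(f"class_mix must sum to 1, sums to {total}")
        unknown = set(self.class_mix) - set(_CLASS_FAMILIES)
        if unknown:
            raise ConfigurationError(f"unknown TE classes in class_mix: {sorted(unknown)}")
        for name in ("de_fraction", "frac_shared", "frac_up", "frac_multimap",
                     "frac_lowid", "frac_lowcov"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if self.frac_multimap + self.frac_lowid + self.frac_lowcov > 1:
            raise ConfigurationError(
                "frac_multimap + frac_lowid + frac_lowcov must not exceed 1"
            )
        if self.planted_lfc < 0:
            raise ConfigurationError("planted_lfc must be >= 0")
        if self.dispersion <= 0:
            raise ConfigurationError("dispersion must be > 0")
        if self.n_subjects_conv < 2 or self.n_controls < 0:
            raise ConfigurationError("need >= 2 paired subjects and >= 0 controls")
        lo, hi = self.lib_size_range
        if not (0 < lo <= hi):
            raise ConfigurationError(f"bad lib_size_range {self.lib_size_range}")
        if self.n_tissues < 1:
            raise ConfigurationError("n_tissues must be >= 1")

    def replace(self, **kw) -> "SimulationConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class GroundTruth:
    """Planted structure the pipeline is expected to recover."""

    #: contrast -> {locus_id: planted log2FC, second condition over first}
    de_loci_per_contrast: dict[str, dict[str, float]] = field(default_factory=dict)
    #: transcript_id -> true source locus
    transcript_locus_truth: dict[str, str] = field(default_factory=dict)
    #: transcript_id -> expected assignment outcome
    transcript_status_truth: dict[str, str] = field(default_factory=dict)
    #: loci carrying the pre-specific signature (input to the ML stage)
    informative_features: list[str] = field(default_factory=list)

    def to_json_dict(self) -> dict:
        return {
            "de_loci_per_contrast": self.de_loci_per_contrast,
            "transcript_locus_truth": self.transcript_locus_truth,
            "transcript_status_truth": self.transcript_status_truth,
            "informative_features": sorted(self.informative_features),
        }


# ---------------------------------------------------------------------------
# reference

def generate_te_reference(cfg: SimulationConfig) -> tuple[list[TELocus], dict[str, str]]:
    """Toy TE reference: non-overlapping loci on a few toy chromosomes.

    Each locus gets a class drawn from ``class_mix``, a family within the
    class, a strand, and a random sequence of 300-7000 nt.  Deterministic
    given the seed.
    """
    cfg.validate()
    rng = _rng(cfg.seed, "reference")
    classes = sorted(cfg.class_mix)
    probs = np.array([cfg.class_mix[c] for c in classes], dtype=float)
    cls_draw = rng.choice(len(classes), size=cfg.n_loci, p=probs)

    n_chrom = max(1, min(5, cfg.n_loci // 50 + 1))
    per_chrom = np.array_split(np.arange(cfg.n_loci), n_chrom)
    loci: list[TELocus] = []
    seqs: dict[str, str] = {}
    width = max(4, len(str(cfg.n_loci)))
    for ci, idxs in enumerate(per_chrom):
        chrom = f"chr{ci + 1}"
        pos = int(rng.integers(500, 2000))
        for i in idxs:
            te_class = classes[cls_draw[i]]
            family = str(rng.choice(_CLASS_FAMILIES[te_class]))
            length = int(rng.integers(300, 7001))
            strand = "+" if rng.random() < 0.5 else "-"
            lid = f"TE{str(i + 1).zfill(width)}"
            locus = TELocus(
                locus_id=lid, chrom=chrom, start=pos, end=pos + length,
                strand=strand, family=family, te_class=FAMILY_TO_CLASS[family],
                consensus_len=length, recent=family in RECENT_FAMILIES,
            )
            loci.append(locus)
            seqs[lid] = "".join(rng.choice(list("ACGT"), size=length))
            pos += length + int(rng.integers(200, 2001))
    return loci, seqs


def loci_to_frame(loci: Sequence[TELocus]) -> pd.DataFrame:
    df = pd.DataFrame([dataclasses.asdict(l) for l in loci])
    return df.set_index("locus_id", drop=False)


def chromosome_extents(loci: Sequence[TELocus], margin: int = 1000) -> dict[str, int]:
    """Toy chromosome lengths implied by the reference (last locus + margin)."""
    ext: dict[str, int] = {}
    for l in loci:
        ext[l.chrom] = max(ext.get(l.chrom, 0), l.end + margin)
    return ext


# ---------------------------------------------------------------------------
# planted differential expression (shared between counts and transcripts)

def select_de_loci(cfg: SimulationConfig, loci: Sequence[TELocus]) -> dict[str, dict[str, float]]:
    """Choose planted DE loci per contrast, biased toward configured classes.

    A ``frac_shared`` portion of the planted loci forms a pre-specific
    signature: their expression is shifted in the Converter_pre condition
    only, so they are differential in *both* the pre-vs-post and pre-vs-NC
    contrasts with a concordant direction.  The remainder is contrast
    specific.  Signs follow ``frac_up`` (probability the locus is elevated
    in the presymptomatic state).

    Returns {contrast: {locus_id: planted log2FC (second cond over first)}}.
    """
    rng = _rng(cfg.seed, "de_selection")
    ids = np.array([l.locus_id for l in loci])
    weights = np.array(
        [cfg.de_class_bias.get(l.te_class, 1.0) for l in loci], dtype=float)
    n_de = int(round(cfg.de_fraction * len(ids)))
    if n_de == 0 or cfg.planted_lfc == 0:
        return {c: {} for c in CONTRASTS}
    n_shared = int(round(cfg.frac_shared * n_de))
    n_pp_only = n_de - n_shared
    n_pn_only = n_de - n_shared
    total = n_shared + n_pp_only + n_pn_only
    total = min(total, len(ids))
    p = weights / weights.sum()
    chosen = rng.choice(len(ids), size=total, replace=False, p=p)
    shared = ids[chosen[:n_shared]]
    pp_only = ids[chosen[n_shared:n_shared + n_pp_only]]
    pn_only = ids[chosen[n_shared + n_pp_only:]]

    lfc = cfg.planted_lfc
    de: dict[str, dict[str, float]] = {c: {} for c in CONTRASTS}
    for lid in shared:
        # elevated (or depressed) in pre only: both contrasts move together
        up_in_pre = rng.random() < cfg.frac_up
        effect = -lfc if up_in_pre else lfc  # second condition over pre
        de["pre_vs_post"][lid] = effect
        de["pre_vs_nc"][lid] = effect
    for lid in pp_only:
        up_in_pre = rng.random() < cfg.frac_up
        de["pre_vs_post"][lid] = -lfc if up_in_pre else lfc
    for lid in pn_only:
        up_in_pre = rng.random() < cfg.frac_up
        de["pre_vs_nc"][lid] = -lfc if up_in_pre else lfc
    return de


def group_log2_offsets(
    cfg: SimulationConfig, loci: Sequence[TELocus],
    de: dict[str, dict[str, float]] | None = None,
) -> pd.DataFrame:
    """Per-locus log2 expression offset of each group relative to baseline."""
    if de is None:
        de = select_de_loci(cfg, loci)
    ids = [l.locus_id for l in loci]
    delta = pd.DataFrame(0.0, index=ids, columns=list(GROUPS))
    # shared signature loci: shift the pre condition itself
    for lid, effect in de["pre_vs_post"].items():
        if lid in de["pre_vs_nc"] and np.isclose(de["pre_vs_nc"][lid], effect):
            delta.loc[lid, "Converter_pre"] = -effect
        else:
            delta.loc[lid, "Converter_post"] = effect
    for lid, effect in de["pre_vs_nc"].items():
        if lid in de["pre_vs_post"]:
            continue  # shared, already handled
        delta.loc[lid, "NC"] = effect
    return delta


# ---------------------------------------------------------------------------
# transcripts and alignments

def generate_transcripts(
    loci: Sequence[TELocus],
    seqs: Mapping[str, str],
    cfg: SimulationConfig,
) -> tuple[dict[str, str], list[AlignmentRecord], GroundTruth]:
    """One transcript per locus, with planted filter classes.

    Exact counts of low-identity, low-coverage, and multi-mapping
    transcripts are forced by construction (``round(frac * n)`` each); the
    recorded identity and coverage equal the values implied by the edits.
    Planted DE loci are kept out of the discard classes so downstream
    stages observe them.
    """
    if not loci:
        raise ConfigurationError("loci must be non-empty")
    cfg.validate()
    rng = _rng(cfg.seed, "transcripts")
    n = len(loci)
    n_lowid = int(round(cfg.frac_lowid * n))
    n_lowcov = int(round(cfg.frac_lowcov * n))
    n_multi = int(round(cfg.frac_multimap * n))

    de = select_de_loci(cfg, loci)
    protected = set()
    for d in de.values():
        protected |= set(d)
    order = np.array([l.locus_id for l in loci])
    unprotected = [i for i, lid in enumerate(order) if lid not in protected]
    protected_idx = [i for i, lid in enumerate(order) if lid in protected]
    pool = np.array(unprotected + protected_idx)  # prefer non-DE for discards
    perm = np.concatenate([
        rng.permutation(len(unprotected)),
        len(unprotected) + rng.permutation(len(protected_idx)),
    ])
    pool = pool[perm]
    lowid_set = set(pool[:n_lowid].tolist())
    lowcov_set = set(pool[n_lowid:n_lowid + n_lowcov].tolist())
    multi_set = set(pool[n_lowid + n_lowcov:n_lowid + n_lowcov + n_multi].tolist())

    nts = np.array(list("ACGT"))
    transcripts: dict[str, str] = {}
    records: list[AlignmentRecord] = []
    truth = GroundTruth(de_loci_per_contrast=de)
    for i, locus in enumerate(loci):
        lid = locus.locus_id
        tid = f"TR_{lid}"
        ref = seqs[lid]
        L = len(ref)
        al = int(rng.integers(max(50, int(0.6 * L)), L + 1))
        offset = int(rng.integers(0, L - al + 1))
        if i in lowid_set:
            target_id = rng.uniform(85.0, 94.5)
            status = "low_identity"
        else:
            target_id = rng.uniform(96.5, 100.0)
            status = "assigned"
        n_sub = int(round((1 - target_id / 100.0) * al))
        # keep the planted class on the correct side of the 95% threshold
        while status == "low_identity" and 100.0 * (al - n_sub) / al >= 95.0:
            n_sub += 1
        while status != "low_identity" and 100.0 * (al - n_sub) / al < 95.0:
            n_sub -= 1
        n_sub = max(0, n_sub)
        seg = np.array(list(ref[offset:offset + al]))
        if n_sub:
            pos = rng.choice(al, size=n_sub, replace=False)
            for pth in pos:
                cur = seg[pth]
                seg[pth] = rng.choice(nts[nts != cur])
        pident = 100.0 * (al - n_sub) / al
        if i in lowcov_set:
            cov = rng.uniform(0.5, 0.88)
            tail_len = int(np.ceil(al * (1.0 / cov - 1.0)))
            while al / (al + tail_len) >= 0.9:
                tail_len += 1
            tail = "".join(rng.choice(nts, size=tail_len))
            status = "low_coverage"
        else:
            tail = ""
        tseq = "".join(seg) + tail
        qlen = len(tseq)
        rec = AlignmentRecord(
            transcript_id=tid, locus_id=lid, pident=pident, aln_len=al,
            qlen=qlen, bitscore=2.0 * (al - n_sub), evalue=1e-50,
            mismatch=n_sub, gapopen=0, qstart=1, qend=al,
            sstart=offset + 1, send=offset + al,
        )
        records.append(rec)
        if i in multi_set and n > 1:
            status = "multimap"
            other = loci[(i + 1) % n]
            records.append(AlignmentRecord(
                transcript_id=tid, locus_id=other.locus_id,
                pident=max(95.0, pident - rng.uniform(0.0, 1.0)),
                aln_len=al, qlen=qlen, bitscore=2.0 * (al - n_sub) - 5,
                evalue=1e-45, mismatch=n_sub, gapopen=0,
                qstart=1, qend=al, sstart=1, send=al,
            ))
        transcripts[tid] = tseq
        truth.transcript_locus_truth[tid] = lid
        truth.transcript_status_truth[tid] = status
    truth.informative_features = sorted(
        set(de["pre_vs_post"]) & set(de["pre_vs_nc"]))
    return transcripts, records, truth


# ---------------------------------------------------------------------------
# counts

def generate_metadata(cfg: SimulationConfig) -> pd.DataFrame:
    """Sample sheet: paired converter pre/post samples plus NC controls.

    Ages are drawn independently of expression (a null covariate); sex
    ratios follow the emulated cohort (~56% F among converters, ~67% F in
    the control group).
    """
    rng = _rng(cfg.seed, "metadata")
    rows = []
    for s in range(1, cfg.n_subjects_conv + 1):
        subj = f"Conv{s:02d}"
        age = float(np.round(np.clip(rng.normal(81.2, 4.1), 75, 95), 1))
        sex = "F" if rng.random() < 0.56 else "M"
        for cond, suffix in (("Converter_pre", "pre"), ("Converter_post", "post")):
            rows.append({
                "sample_id": f"{subj}_{suffix}", "subject_id": subj,
                "group": cond, "sex": sex, "age": age, "pair_id": subj,
            })
    for s in range(1, cfg.n_controls + 1):
        subj = f"NC{s:02d}"
        age = float(np.round(np.clip(rng.normal(81.6, 3.9), 75, 95), 1))
        sex = "F" if rng.random() < 0.67 else "M"
        rows.append({
            "sample_id": f"{subj}", "subject_id": subj,
            "group": "NC", "sex": sex, "age": age, "pair_id": "",
        })
    return pd.DataFrame(rows)


def planted_effects(
    cfg: SimulationConfig, loci: Sequence[TELocus]
) -> tuple[pd.Series, pd.DataFrame]:
    """Baseline log2 abundance and per-locus subject random intercepts.

    A deterministic mirror of the draws ``generate_counts`` makes from its
    RNG stream, so tests can compare fitted coefficients against the
    planted values.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence(cfg.seed, spawn_key=(_RNG_LABELS["counts"], 1)))
    ids = [l.locus_id for l in loci]
    a = pd.Series(rng.normal(3.0, cfg.abundance_sd, size=len(ids)), index=ids)
    subjects = generate_metadata(cfg)["subject_id"].unique()
    eta = pd.DataFrame(
        rng.normal(0.0, cfg.subject_sd, size=(len(ids), len(subjects))),
        index=ids, columns=subjects,
    )
    return a, eta


def generate_counts(
    loci: Sequence[TELocus],
    cfg: SimulationConfig,
    de: dict[str, dict[str, float]] | None = None,
) -> tuple[ExpressionMatrix, GroundTruth]:
    """NB counts with a paired design.

    Mean model per locus g and sample k of subject s in group c:
    ``mu = N_k * softmax_g(a_g + delta_{g,c} + eta_{g,s})`` where ``a_g`` is a
    log2-normal baseline, ``delta`` the planted group offsets, and ``eta``
    the per-locus subject random intercept shared by a subject's two
    samples.  Counts are NB(mu, dispersion).
    """
    cfg.validate()
    rng = _rng(cfg.seed, "counts")
    if de is None:
        de = select_de_loci(cfg, loci)
    meta = generate_metadata(cfg)
    ids = [l.locus_id for l in loci]
    G, K = len(ids), len(meta)
    delta = group_log2_offsets(cfg, loci, de)  # loci x groups, log2

    a, eta = planted_effects(cfg, loci)
    a = a.to_numpy()
    lo, hi = cfg.lib_size_range
    lib = rng.integers(lo, hi + 1, size=K)

    counts = np.zeros((G, K), dtype=np.int64)
    log2 = np.log(2.0)
    for k, row in enumerate(meta.itertuples(index=False)):
        base = a + eta[row.subject_id].to_numpy()
        lam = base + delta[row.group].to_numpy()
        # normalize by the *baseline* composition: planted effects are extra
        # (or missing) reads on top of it, so per-locus fold changes land
        # exactly at the planted value while the realized library size
        # drifts slightly with planted content (which TMM then absorbs)
        w = np.exp(lam * log2)
        pi = w / np.exp(base * log2).sum()
        mu = lib[k] * pi
        r = 1.0 / cfg.dispersion
        p = r / (r + mu)
        counts[:, k] = rng.negative_binomial(r, p)
    frame = pd.DataFrame(counts, index=pd.Index(ids, name="locus_id"),
                         columns=meta["sample_id"].tolist())
    lengths = pd.Series({l.locus_id: l.length for l in loci}, name="length")
    em = ExpressionMatrix(counts=frame, meta=meta, lengths=lengths)
    truth = GroundTruth(
        de_loci_per_contrast=de,
        informative_features=sorted(set(de["pre_vs_post"]) & set(de["pre_vs_nc"])),
    )
    return em, truth


def split_counts_to_transcripts(
    counts: pd.DataFrame, truth: GroundTruth
) -> pd.DataFrame:
    """Transcript-level counts: each transcript carries its source locus counts."""
    rows, index = [], []
    for tid, lid in sorted(truth.transcript_locus_truth.items()):
        if lid in counts.index:
            rows.append(counts.loc[lid].to_numpy())
            index.append(tid)
    out = pd.DataFrame(rows, index=pd.Index(index, name="transcript_id"),
                       columns=counts.columns)
    return out


# ---------------------------------------------------------------------------
# chromatin tracks

from .chromatin import STATE_LABELS  # noqa: E402  (alphabet lives with the consumer)

_DEFAULT_STATE_PROPS = {
    "1_TssA": 0.03, "2_TssAFlnk": 0.02, "3_TxFlnk": 0.01, "4_Tx": 0.05,
    "5_TxWk": 0.12, "6_EnhG": 0.02, "7_Enh": 0.08, "8_ZNF/Rpts": 0.01,
    "9_Het": 0.07, "10_TssBiv": 0.005, "11_BivFlnk": 0.005, "12_EnhBiv": 0.01,
    "13_ReprPC": 0.04, "14_ReprPCWk": 0.08, "15_Quies": 0.45,
}


def default_tissue_names(n_tissues: int) -> list[str]:
    base = ["blood", "adult_brain", "fetal_brain"]
    names = base[:n_tissues]
    i = 1
    while len(names) < n_tissues:
        names.append(f"tissue_{i:02d}")
        i += 1
    return names


def generate_chromatin_tracks(
    cfg: SimulationConfig,
    loci: Sequence[TELocus],
    state_props: Mapping[str, float] | None = None,
    straddle_loci: set[str] | frozenset[str] = frozenset(),
    tissue_names: Sequence[str] | None = None,
) -> dict[str, pd.DataFrame]:
    """Per-tissue 15-state segmentations tiling each toy chromosome.

    Segment boundaries are placed at locus edges so every locus outside
    ``straddle_loci`` sits inside exactly one segment whose state is drawn
    from ``state_props``; straddle loci get an internal boundary with two
    distinct states on either side.  Intervals tile each chromosome with no
    gaps or overlaps.
    """
    cfg.validate()
    props = dict(state_props or _DEFAULT_STATE_PROPS)
    unknown = set(props) - set(STATE_LABELS)
    if unknown:
        raise ConfigurationError(f"unknown chromatin states: {sorted(unknown)}")
    labels = [s for s in STATE_LABELS if props.get(s, 0) > 0]
    p = np.array([props[s] for s in labels], dtype=float)
    p = p / p.sum()
    if straddle_loci and len(labels) < 2:
        raise ConfigurationError(
            "straddle loci require at least two states with positive proportion"
        )
    tissues = list(tissue_names or default_tissue_names(cfg.n_tissues))
    if len(tissues) != cfg.n_tissues:
        raise ConfigurationError("tissue_names length must equal n_tissues")
    extents = chromosome_extents(loci)
    by_chrom: dict[str, list[TELocus]] = {}
    for l in sorted(loci, key=lambda x: (x.chrom, x.start)):
        by_chrom.setdefault(l.chrom, []).append(l)

    tracks: dict[str, pd.DataFrame] = {}
    for ti, tissue in enumerate(tissues):
        rng = _rng(cfg.seed, "tracks", ti)
        rows = []
        for chrom, clen in sorted(extents.items()):
            cuts = {0, clen}
            straddle_cut: dict[int, str] = {}
            for l in by_chrom.get(chrom, []):
                cuts.add(l.start)
                cuts.add(l.end)
                if l.locus_id in straddle_loci and l.length >= 2:
                    inner = int(rng.integers(l.start + 1, l.end))
                    cuts.add(inner)
                    straddle_cut[inner] = l.locus_id
            edges = sorted(cuts)
            prev_state = None
            for s0, s1 in zip(edges[:-1], edges[1:]):
                state = str(rng.choice(labels, p=p))
                if s0 in straddle_cut and state == prev_state:
                    others = [x for x in labels if x != prev_state]
                    pw = np.array([props[x] for x in others], dtype=float)
                    state = str(rng.choice(others, p=pw / pw.sum()))
                rows.append({"chrom": chrom, "start": s0, "end": s1, "state": state})
                prev_state = state
        tracks[tissue] = pd.DataFrame(rows, columns=["chrom", "start", "end", "state"])
    return tracks


# ---------------------------------------------------------------------------
# gene annotation

def generate_gene_annotation(
    cfg: SimulationConfig,
    loci: Sequence[TELocus],
    window: int = 5000,
) -> pd.DataFrame:
    """Toy protein-coding gene BED with planted cis relationships.

    Cycles through overlap / upstream-within-window / downstream-within-
    window / outside-window placements so the +-window gene assignment has
    known positives and negatives.
    """
    rng = _rng(cfg.seed, "genes")
    extents = chromosome_extents(loci, margin=window + 20_000)
    rows = []
    relations = ("overlap", "upstream", "downstream", "far")
    for i, l in enumerate(sorted(loci, key=lambda x: (x.chrom, x.start))):
        if i % 3 != 0:
            continue
        rel = relations[(i // 3) % len(relations)]
        glen = int(rng.integers(500, 3001))
        if rel == "overlap":
            gstart = max(0, l.start + l.length // 4)
        elif rel == "upstream":
            gap = int(rng.integers(0, window - 1))
            gstart = l.start - gap - glen
        elif rel == "downstream":
            gap = int(rng.integers(0, window - 1))
            gstart = l.end + gap
        else:
            gstart = l.end + window + int(rng.integers(1000, 10_000))
        if gstart < 0:
            gstart = l.end + window + 2000
        gend = min(gstart + glen, extents[l.chrom])
        rows.append({
            "chrom": l.chrom, "start": gstart, "end": gend,
            "name": f"G{i:05d}", "score": 0,
            "strand": "+" if rng.random() < 0.5 else "-",
        })
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"])


# ---------------------------------------------------------------------------
# one-call dataset writer

def write_dataset(cfg: SimulationConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate and write every pipeline input; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    loci, seqs = generate_te_reference(cfg)
    transcripts, records, truth_t = generate_transcripts(loci, seqs, cfg)
    em, truth_c = generate_counts(loci, cfg)
    truth = GroundTruth(
        de_loci_per_contrast=truth_c.de_loci_per_contrast,
        transcript_locus_truth=truth_t.transcript_locus_truth,
        transcript_status_truth=truth_t.transcript_status_truth,
        informative_features=truth_c.informative_features,
    )
    tcounts = split_counts_to_transcripts(em.counts, truth)
    straddle = {loci[0].locus_id} if loci else set()
    tracks = generate_chromatin_tracks(cfg, loci, straddle_loci=straddle)
    genes = generate_gene_annotation(cfg, loci)

    paths: dict[str, Path] = {}
    ldf = loci_to_frame(loci).rename(columns={"locus_id": "name"})
    ldf["score"] = 0
    paths["te_bed"] = outdir / "te_loci.bed"
    teio.write_bed6(ldf, paths["te_bed"])
    paths["te_table"] = outdir / "te_loci.tsv"
    ldf2 = loci_to_frame(loci)
    ldf2["name"] = ldf2["locus_id"]
    teio.write_repeatmasker_table(ldf2, paths["te_table"])
    paths["reference_fasta"] = outdir / "te_reference.fa"
    teio.write_fasta(seqs, paths["reference_fasta"])
    paths["transcript_fasta"] = outdir / "transcripts.fa"
    teio.write_fasta(transcripts, paths["transcript_fasta"])
    paths["alignments"] = outdir / "alignments.tsv"
    teio.write_blast_tabular(records, paths["alignments"])
    paths["counts"] = outdir / "locus_counts.tsv"
    teio.write_counts(em.counts, paths["counts"])
    paths["transcript_counts"] = outdir / "transcript_counts.tsv"
    tcounts.to_csv(paths["transcript_counts"], sep="\t", index_label="transcript_id")
    paths["metadata"] = outdir / "metadata.tsv"
    teio.write_metadata(em.meta, paths["metadata"])
    trackdir = outdir / "tracks"
    trackdir.mkdir(exist_ok=True)
    for tissue, df in tracks.items():
        p = trackdir / f"{tissue}.bed"
        teio.write_bed4(df, p)
        paths[f"track_{tissue}"] = p
    paths["genes"] = outdir / "genes.bed"
    teio.write_bed6(genes, paths["genes"])
    paths["ground_truth"] = outdir / "ground_truth.json"
    teio.write_json(truth.to_json_dict(), paths["ground_truth"])
    return paths
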