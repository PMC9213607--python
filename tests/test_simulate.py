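"""Generator behavior: determinism, planted structure, format invariants."""

import collections
import filecmp

import numpy as np
import pandas as pd
import pytest

from te_storm.errors import ConfigurationError
from te_storm.simulate import (
    SimulationConfig,
    generate_chromatin_tracks,
    generate_counts,
    generate_metadata,
    generate_te_reference,
    generate_transcripts,
    select_de_loci,
    write_dataset,
)


class TestConfigValidation:
    def test_rejects_bad_values(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(n_loci=0)
        with pytest.raises(ConfigurationError):
            SimulationConfig(class_mix={"LINE": 0.5, "SINE": 0.4})
        with pytest.raises(ConfigurationError):
            SimulationConfig(dispersion=0.0)
        with pytest.raises(ConfigurationError):
            SimulationConfig(frac_multimap=0.7, frac_lowid=0.4)
        with pytest.raises(ConfigurationError):
            SimulationConfig(planted_lfc=-1)


class TestReference:
    def test_class_mix_counts_at_seeded_draw(self):
        mix = {c: 0.2 for c in ("LINE", "SINE", "LTR", "SVA", "DNA")}
        cfg = SimulationConfig(n_loci=100, class_mix=mix, seed=7)
        loci, _ = generate_te_reference(cfg)
        counts = collections.Counter(l.te_class for l in loci)
        assert sum(counts.values()) == 100
        # multinomial(100, 0.2) stays well inside +-4 sd of 20
        assert all(5 <= v <= 35 for v in counts.values()), counts
        loci2, _ = generate_te_reference(cfg)
        assert collections.Counter(l.te_class for l in loci2) == counts

    def test_degenerate_mix_single_line_locus(self):
        cfg = SimulationConfig(n_loci=1, class_mix={"LINE": 1.0},
                               n_subjects_conv=2, n_controls=0)
        loci, seqs = generate_te_reference(cfg)
        assert len(loci) == 1 and loci[0].te_class == "LINE"
        assert 300 <= len(seqs[loci[0].locus_id]) <= 7000

    def test_intervals_non_overlapping_half_open(self, small_reference):
        loci, _ = small_reference
        by_chrom = {}
        for l in loci:
            by_chrom.setdefault(l.chrom, []).append((l.start, l.end))
        for ivs in by_chrom.values():
            ivs.sort()
            for (s0, e0), (s1, _) in zip(ivs[:-1], ivs[1:]):
                assert s0 < e0 <= s1

    def test_sequence_lengths_match_annotation(self, small_reference):
        loci, seqs = small_reference
        for l in loci:
            assert len(seqs[l.locus_id]) == l.end - l.start

    def test_seeded_determinism_byte_identical_outputs(self, tmp_path):
        cfg = SimulationConfig(n_loci=40, n_subjects_conv=3, n_controls=2,
                               seed=13)
        write_dataset(cfg, tmp_path / "a")
        write_dataset(cfg, tmp_path / "b")
        for name in ("te_reference.fa", "te_loci.bed", "transcripts.fa",
                     "alignments.tsv", "locus_counts.tsv", "metadata.tsv",
                     "ground_truth.json", "genes.bed"):
            assert filecmp.cmp(tmp_path / "a" / name, tmp_path / "b" / name,
                               shallow=False), name


class TestTranscripts:
    def test_planted_filter_class_counts_exact(self):
        cfg = SimulationConfig(n_loci=50, frac_lowid=0.2, frac_multimap=0.2,
                               frac_lowcov=0.0, n_subjects_conv=2,
                               n_controls=0, seed=3)
        loci, seqs = generate_te_reference(cfg)
        _, records, truth = generate_transcripts(loci, seqs, cfg)
        n_lowid = sum(1 for r in records if r.pident < 95.0)
        assert n_lowid == 10
        status = collections.Counter(truth.transcript_status_truth.values())
        assert status["low_identity"] == 10
        assert status["multimap"] == 10

    def test_no_multimap_means_one_record_each(self):
        cfg = SimulationConfig(n_loci=30, frac_multimap=0.0, frac_lowid=0.0,
                               frac_lowcov=0.0, n_subjects_conv=2,
                               n_controls=0, seed=4)
        loci, seqs = generate_te_reference(cfg)
        _, records, _ = generate_transcripts(loci, seqs, cfg)
        per = collections.Counter(r.transcript_id for r in records)
        assert set(per.values()) == {1}

    def test_recorded_identity_matches_edit_trace(self, small_reference,
                                                  small_cfg):
        """Recompute pident/coverage from the sequences themselves."""
        loci, seqs = small_reference
        transcripts, records, truth = generate_transcripts(loci, seqs, small_cfg)
        primary = {}
        for r in records:
            if truth.transcript_locus_truth[r.transcript_id] == r.locus_id:
                primary[r.transcript_id] = r
        for tid, r in primary.items():
            tseq = transcripts[tid]
            ref = seqs[r.locus_id][r.sstart - 1:r.send]
            aligned = tseq[r.qstart - 1:r.qend]
            assert len(aligned) == len(ref) == r.aln_len
            matches = sum(a == b for a, b in zip(aligned, ref))
            assert matches / r.aln_len * 100 == pytest.approx(r.pident, abs=1e-12)
            assert r.aln_len / len(tseq) == pytest.approx(r.coverage, abs=1e-12)

    def test_planted_de_loci_stay_assignable(self, small_transcripts,
                                             small_cfg, small_reference):
        loci, _ = small_reference
        _, _, truth = small_transcripts
        de = select_de_loci(small_cfg, loci)
        planted = set(de["pre_vs_post"]) | set(de["pre_vs_nc"])
        for tid, lid in truth.transcript_locus_truth.items():
            if lid in planted:
                assert truth.transcript_status_truth[tid] == "assigned"


class TestCounts:
    def test_null_config_log_ratios_center_on_zero(self):
        cfg = SimulationConfig(n_loci=400, n_subjects_conv=10, n_controls=0,
                               de_fraction=0.0, subject_sd=0.3, seed=9)
        loci, _ = generate_te_reference(cfg)
        em, truth = generate_counts(loci, cfg)
        assert truth.de_loci_per_contrast["pre_vs_post"] == {}
        meta = em.meta.set_index("sample_id")
        pre = em.counts[meta.index[meta["group"] == "Converter_pre"]]
        post = em.counts[meta.index[meta["group"] == "Converter_post"]]
        lr = np.log2(post.mean(axis=1) + 1) - np.log2(pre.mean(axis=1) + 1)
        assert abs(lr.mean()) < 0.05

    def test_planted_lfc_recovered_within_sampling_error(self):
        cfg = SimulationConfig(n_loci=500, n_subjects_conv=20, n_controls=0,
                               de_fraction=0.1, frac_shared=0.0, frac_up=0.0,
                               planted_lfc=2.0, dispersion=0.1,
                               subject_sd=0.2,
                               lib_size_range=(1_000_000, 1_000_000), seed=21)
        loci, _ = generate_te_reference(cfg)
        em, truth = generate_counts(loci, cfg)
        planted = truth.de_loci_per_contrast["pre_vs_post"]
        assert planted and all(v == 2.0 for v in planted.values())
        meta = em.meta.set_index("sample_id")
        pre = em.counts[meta.index[meta["group"] == "Converter_pre"]]
        post = em.counts[meta.index[meta["group"] == "Converter_post"]]
        lids = list(planted)
        # nominal library sizes are equal, so raw count ratios carry the effect
        lr = (np.log2(post.loc[lids].mean(axis=1))
              - np.log2(pre.loc[lids].mean(axis=1)))
        se = lr.std() / np.sqrt(len(lr))
        assert abs(lr.mean() - 2.0) < 3 * se + 0.05

    def test_fixed_library_size_column_sums_concentrate(self):
        # light-tailed abundances so no single locus dominates the library
        # and the column sums concentrate near the nominal size
        cfg = SimulationConfig(n_loci=800, n_subjects_conv=4, n_controls=2,
                               lib_size_range=(1_000_000, 1_000_000),
                               de_fraction=0.0, abundance_sd=0.8,
                               subject_sd=0.2, dispersion=0.05, seed=5)
        loci, _ = generate_te_reference(cfg)
        em, _ = generate_counts(loci, cfg)
        sums = em.counts.sum(axis=0)
        assert np.all(np.abs(sums - 1e6) / 1e6 < 0.05)

    def test_age_independent_of_expression_labels(self):
        meta = generate_metadata(SimulationConfig(seed=10))
        conv = meta[meta["group"] != "NC"]
        assert (conv.groupby("subject_id")["age"].nunique() == 1).all()
        assert meta["age"].between(75, 95).all()

    def test_paired_samples_share_subject_effect(self, small_dataset):
        em, _ = small_dataset
        meta = em.meta
        pairs = meta[meta["group"] != "NC"].groupby("subject_id")
        for subj, grp in pairs:
            assert set(grp["group"]) == {"Converter_pre", "Converter_post"}
            assert grp["pair_id"].nunique() == 1


class TestChromatinTracks:
    def test_degenerate_proportions_single_state(self, small_reference,
                                                 small_cfg):
        loci, _ = small_reference
        tracks = generate_chromatin_tracks(
            small_cfg, loci, state_props={"15_Quies": 1.0})
        for df in tracks.values():
            assert set(df["state"]) == {"15_Quies"}

    def test_straddle_locus_overlaps_two_states_every_tissue(
            self, small_reference, small_cfg):
        loci, _ = small_reference
        lid = loci[3].locus_id
        tracks = generate_chromatin_tracks(small_cfg, loci,
                                           straddle_loci={lid})
        target = loci[3]
        for df in tracks.values():
            seg = df[(df["chrom"] == target.chrom)
                     & (df["start"] < target.end)
                     & (df["end"] > target.start)]
            assert seg["state"].nunique() >= 2

    def test_tiling_no_gaps_no_overlaps(self, small_reference, small_cfg):
        loci, _ = small_reference
        tracks = generate_chromatin_tracks(small_cfg, loci)
        for df in tracks.values():
            for _, grp in df.groupby("chrom"):
                grp = grp.sort_values("start")
                assert grp["start"].iloc[0] == 0
                assert (grp["end"].to_numpy()[:-1]
                        == grp["start"].to_numpy()[1:]).all()

    def test_unknown_state_label_rejected(self, small_reference, small_cfg):
        loci, _ = small_reference
        with pytest.raises(ConfigurationError):
            generate_chromatin_tracks(small_cfg, loci,
                                      state_props={"16_Bogus": 1.0})


class TestSharedSignature:
    def test_shared_loci_concordant_and_sized(self):
        cfg = SimulationConfig(n_loci=300, de_fraction=0.1, frac_shared=0.65,
                               n_subjects_conv=4, n_controls=4, seed=1)
        loci, _ = generate_te_reference(cfg)
        de = select_de_loci(cfg, loci)
        shared = set(de["pre_vs_post"]) & set(de["pre_vs_nc"])
        assert len(shared) == 20  # round(0.65 * 30)
        for lid in shared:
            assert de["pre_vs_post"][lid] == de["pre_vs_nc"][lid]

    def test_de_selection_biased_toward_line_ltr(self):
        cfg = SimulationConfig(n_loci=1000, de_fraction=0.1, seed=2,
                               n_subjects_conv=2, n_controls=0)
        loci, _ = generate_te_reference(cfg)
        de = select_de_loci(cfg, loci)
        cls = {l.locus_id: l.te_class for l in loci}
        planted = [cls[x] for x in de["pre_vs_post"]]
        frac_line_ltr = np.mean([c in ("LINE", "LTR") for c in planted])
        bg = np.mean([l.te_class in ("LINE", "LTR") for l in loci])
        assert frac_line_ltr > bg + 0.1
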