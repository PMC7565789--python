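"""Generative simulator: reference building, read emission, closed-form oracle."""

import numpy as np
import pytest

from embrseq.config import Blocker, HotspotSpec, SimConfig
from embrseq.simulate import (
    build_reference,
    control_preset,
    embr_preset,
    expected_class_fractions,
    expected_rrna_fraction,
    simulate_reads,
)


def small_config(**kw):
    defaults = dict(n_tRNA=2, n_mRNA=5, n_reads=500, seed=7)
    defaults.update(kw)
    return SimConfig(**defaults)


class TestBuildReference:
    def test_default_composition(self):
        ref = build_reference(SimConfig(seed=1))
        rrna = ref.by_class("rRNA")
        assert sorted(len(r) for r in rrna) == [120, 1542, 2904]
        sixteen = ref["rRNA_16S"]
        assert sixteen.class_label == "rRNA" and len(sixteen) == 1542
        assert all(len(r) == 76 for r in ref.by_class("tRNA"))
        assert len(ref.by_class("mRNA")) == 60

    def test_zero_mrna_gives_rrna_trna_only(self):
        ref = build_reference(small_config(n_mRNA=0))
        assert {r.class_label for r in ref} == {"rRNA", "tRNA"}

    def test_same_seed_reproduces_sequences(self):
        a = build_reference(small_config(seed=42))
        b = build_reference(small_config(seed=42))
        assert [r.sequence for r in a] == [r.sequence for r in b]
        c = build_reference(small_config(seed=43))
        assert [r.sequence for r in a] != [r.sequence for r in c]

    @pytest.mark.parametrize("kw", [{"n_mRNA": -1}, {"tRNA_length": 0},
                                    {"mRNA_length_range": (0, 100)}])
    def test_invalid_counts_or_lengths_rejected(self, kw):
        with pytest.raises(ValueError):
            small_config(**kw)


class TestSimulateReads:
    def test_deterministic_byte_identical(self):
        cfg = small_config()
        ref = build_reference(cfg)
        p1, t1 = simulate_reads(ref, cfg)
        p2, t2 = simulate_reads(ref, cfg)
        assert p1 == p2
        assert t1.equals(t2)

    def test_truth_conservation(self):
        cfg = small_config(n_reads=800)
        ref = build_reference(cfg)
        pairs, truth = simulate_reads(ref, cfg)
        assert len(pairs) == len(truth) == 800
        assert truth["read_id"].is_unique
        assert set(truth["read_id"]) == {rid for rid, _, _ in pairs}
        for row in truth.itertuples(index=False):
            L = ref.length_of(row.ref_id)
            assert 0 <= row.read_start and row.read_end <= L
            assert 1 <= row.three_prime_end <= L

    def test_reads_match_reference_when_error_free(self):
        cfg = small_config(error_rate=0.0)
        ref = build_reference(cfg)
        pairs, truth = simulate_reads(ref, cfg)
        for (rid, left, right), row in zip(pairs, truth.itertuples(index=False)):
            assert right == ref[row.ref_id].sequence[row.read_start : row.read_end]
            assert left.startswith(cfg.barcode)
            assert set(left[6:]) == {"T"}

    def test_fully_blocked_native_rrna_emits_none(self):
        """Perfect blockers on all native rRNA 3' termini with no fragmentation."""
        cfg = small_config(frag_rate=0.0, n_reads=300)
        ref = build_reference(cfg)
        cfg.blockers = [
            Blocker(r.ref_id, len(r) - 29, len(r), 1.0) for r in ref.by_class("rRNA")
        ]
        _, truth = simulate_reads(ref, cfg)
        assert (truth["class"] == "rRNA").sum() == 0

    def test_read_len_longer_than_shortest_reference_rejected(self):
        cfg = small_config(read_len=80, fragment_len=(90, 160))  # tRNA is 76 nt
        ref = build_reference(cfg)
        with pytest.raises(ValueError, match="shortest reference"):
            simulate_reads(ref, cfg)

    def test_unknown_hotspot_or_out_of_range_rejected(self):
        cfg = small_config()
        ref = build_reference(cfg)
        cfg.hotspots = [HotspotSpec("nope", 10, 1.0)]
        with pytest.raises(ValueError):
            simulate_reads(ref, cfg)
        cfg.hotspots = [HotspotSpec("rRNA_5S", 9999, 1.0)]
        with pytest.raises(ValueError):
            simulate_reads(ref, cfg)


class TestClosedFormOracle:
    def test_control_fraction_within_3_binomial_se(self, control_sample):
        cfg, truth = control_sample.config, control_sample.truth
        expected = expected_rrna_fraction(control_sample.ref, cfg)
        observed = (truth["class"] == "rRNA").mean()
        se = np.sqrt(expected * (1 - expected) / len(truth))
        assert abs(observed - expected) < 3 * se

    def test_embr_preset_calibrated_to_16_percent(self, embr_sample):
        cfg = embr_sample.config
        expected = expected_rrna_fraction(embr_sample.ref, cfg)
        assert expected == pytest.approx(0.16, abs=1e-6)
        observed = (embr_sample.truth["class"] == "rRNA").mean()
        se = np.sqrt(0.16 * 0.84 / len(embr_sample.truth))
        assert abs(observed - 0.16) < 3 * se

    def test_control_preset_class_fractions_closed_form(self):
        cfg = control_preset(n_reads=100, seed=5)
        ref = build_reference(cfg)
        fracs = expected_class_fractions(ref, cfg)
        assert fracs["rRNA"] == pytest.approx(0.64, abs=1e-9)
        assert fracs["tRNA"] == pytest.approx(0.0037, abs=1e-9)

    def test_beta_monotone_in_closed_form(self):
        cfg = embr_preset(n_reads=100, seed=5)
        ref = build_reference(cfg)
        fractions = []
        for beta in [0.0, 0.25, 0.5, 0.75, 1.0]:
            cfg.blockers = [Blocker(b.ref_id, b.start, b.end, beta) for b in cfg.blockers]
            fractions.append(expected_rrna_fraction(ref, cfg))
        assert all(a >= b - 1e-12 for a, b in zip(fractions, fractions[1:]))

    def test_beta_monotone_in_simulation(self, control_sample, embr_sample):
        """Same pool and seed; blockers on (beta ~0.97) vs off (beta 0)."""
        f_on = (embr_sample.truth["class"] == "rRNA").mean()
        f_off = (control_sample.truth["class"] == "rRNA").mean()
        assert f_on < f_off


class TestDegradationKnob:
    def test_more_fragmentation_concentrates_reads_at_hotspots(self):
        def hotspot_start_fraction(delta):
            cfg = small_config(frag_rate=delta, n_reads=4000, seed=3)
            cfg.hotspots = [HotspotSpec("rRNA_16S", 682, 1.0), HotspotSpec("rRNA_23S", 375, 1.0)]
            ref = build_reference(cfg)
            _, truth = simulate_reads(ref, cfg)
            rr = truth[truth["class"] == "rRNA"]
            near = 0
            for row in rr.itertuples(index=False):
                coords = [681] if row.ref_id == "rRNA_16S" else ([374] if row.ref_id == "rRNA_23S" else [])
                near += any(abs(row.read_start - c) <= cfg.hotspot_jitter for c in coords)
            return near / max(len(rr), 1)

        assert hotspot_start_fraction(0.6) > hotspot_start_fraction(0.05)


class TestConfigRoundTrip:
    def test_yaml_save_load(self, tmp_path):
        cfg = embr_preset(n_reads=1000, seed=9)
        path = tmp_path / "cfg.yaml"
        cfg.save(path)
        loaded = SimConfig.load(path)
        assert loaded.to_dict() == cfg.to_dict()
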