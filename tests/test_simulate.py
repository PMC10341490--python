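"""Tests of the synthetic panning simulator against analytic expectations."""

import dataclasses
import hashlib

import numpy as np
import pytest

import vhhscreen as v
from vhhscreen.simulate import ConfigurationError, GenerationError

from conftest import truth_aa_counts


def _neutralize(repertoire):
    return [
        dataclasses.replace(c, binding_weight={k: 1.0 for k in c.binding_weight})
        for c in repertoire
    ]


class TestGenerateRepertoire:
    def test_role_counts_forced_by_config(self):
        cfg = v.PanningConfig(seed=7, n_clones=1000, binder_fraction=0.02,
                              cross_reactive_fraction=0.005)
        rep = v.generate_repertoire(cfg)
        assert len(rep) == 1000
        n_lines_gt1 = [sum(w > 1 for w in c.binding_weight.values()) for c in rep]
        assert sum(k == 1 for k in n_lines_gt1) == 20
        assert sum(k >= 2 for k in n_lines_gt1) == 5
        assert sum(k == 0 for k in n_lines_gt1) == 975

    def test_determinism(self):
        cfg = v.PanningConfig(seed=7, n_clones=100)
        assert v.generate_repertoire(cfg) == v.generate_repertoire(cfg)

    def test_clone_invariants(self, small_repertoire):
        from vhhscreen.reads import FWD_PRIMER
        for c in small_repertoire:
            assert c.true_cdr3 in c.aa_seq
            assert all(w >= 0 for w in c.binding_weight.values())
            assert c.nt_seq.startswith(FWD_PRIMER)
            coding = c.nt_seq[len(FWD_PRIMER):]
            aa, reason = v.translate_frame0(coding, min_aa_len=1)
            assert reason is None
            assert aa.startswith(c.aa_seq)

    def test_binder_weight_law_matches_lognormal_oracle(self):
        # weights for binders are lognormal(3, 0.5) draws: the fraction > 1
        # should match a direct Monte-Carlo of that lognormal over 1e4 draws
        cfg = v.PanningConfig(seed=5, n_clones=10_000, binder_fraction=0.9,
                              cross_reactive_fraction=0.05)
        rep = v.generate_repertoire(cfg)
        weights = np.array([
            max(c.binding_weight.values()) for c in rep
            if any(w != 1.0 for w in c.binding_weight.values())
        ])
        assert len(weights) >= 9000
        oracle = np.random.default_rng(0).lognormal(3.0, 0.5, 10_000)
        assert abs((weights > 1).mean() - (oracle > 1).mean()) < 0.01
        # and the location parameter itself: median of lognormal(3, .) is e^3
        assert np.median(np.log(weights)) == pytest.approx(3.0, abs=0.05)

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigurationError):
            v.PanningConfig(seed=1, binder_fraction=0.0)
        with pytest.raises(ConfigurationError):
            v.PanningConfig(seed=1, rounds=0)
        with pytest.raises(ConfigurationError):
            v.PanningConfig(seed=1, reads_per_round=0)


class TestSimulatePanning:
    def test_columns_sum_to_reads_per_round(self, small_repertoire, small_cfg):
        table = v.simulate_panning(small_repertoire, "S1T", small_cfg)
        assert (table.sum(axis=0) == small_cfg.reads_per_round).all()
        assert table.shape[1] == small_cfg.rounds + 1

    def test_round0_shared_across_cell_lines(self, small_repertoire, small_cfg):
        a = v.simulate_panning(small_repertoire, "S1T", small_cfg)
        b = v.simulate_panning(small_repertoire, "HepG2", small_cfg)
        assert (a["round_0"] == b["round_0"]).all()

    def test_unknown_cell_line(self, small_repertoire, small_cfg):
        with pytest.raises(KeyError):
            v.simulate_panning(small_repertoire, "NIH3T3", small_cfg)

    def test_neutral_selection_has_no_drift(self, small_cfg):
        # with all weights 1 the expected frequencies are unchanged; the mean
        # drift of abundant clones over 20 replicates stays within 3 SE
        rep = _neutralize(v.generate_repertoire(small_cfg))
        drifts = []
        for k in range(20):
            cfg = dataclasses.replace(small_cfg, seed=1000 + k)
            t = v.simulate_panning(rep, "S1T", cfg)
            f0 = t["round_0"] / cfg.reads_per_round
            ff = t[f"round_{cfg.rounds}"] / cfg.reads_per_round
            top = f0.nlargest(5).index
            drifts.append((ff[top] - f0[top]).to_numpy())
        drifts = np.array(drifts)
        mean = drifts.mean(axis=0)
        se = drifts.std(axis=0, ddof=1) / np.sqrt(len(drifts))
        assert np.all(np.abs(mean) <= 3 * se + 1e-12)

    def test_two_clone_expected_ratio(self, small_repertoire):
        # weights 2:1 from an equal start give an expected 2:1 frequency
        # ratio after one round (closed form), within binomial standard error
        rep = small_repertoire[:2]
        rep = [
            dataclasses.replace(rep[0], binding_weight={"S1T": 2.0, "HepG2": 1.0}),
            dataclasses.replace(rep[1], binding_weight={"S1T": 1.0, "HepG2": 1.0}),
        ]
        fracs = []
        for k in range(20):
            cfg = v.PanningConfig(seed=2000 + k, n_clones=2, rounds=1,
                                  reads_per_round=10_000,
                                  cell_lines=("S1T", "HepG2"))
            t = v.simulate_panning(rep, "S1T", cfg, p0=np.array([0.5, 0.5]))
            fracs.append(t["round_1"].iloc[0] / cfg.reads_per_round)
        fracs = np.array(fracs)
        se = fracs.std(ddof=1) / np.sqrt(len(fracs))
        assert abs(fracs.mean() - 2 / 3) <= 3 * se + 1e-9

    def test_strong_binder_realized_fold(self, small_repertoire):
        # weight 10 at start frequency 1e-3 over 2 rounds: expected fold
        # follows f' = 10 f / (1 + 9 f) iterated twice (~98x), within noise
        n = len(small_repertoire)
        rep = _neutralize(small_repertoire)
        rep[0] = dataclasses.replace(rep[0], binding_weight={"S1T": 10.0, "HepG2": 1.0})
        p0 = np.full(n, (1 - 1e-3) / (n - 1))
        p0[0] = 1e-3
        f = 1e-3
        for _ in range(2):
            f = 10 * f / (1 + 9 * f)
        expected_fold = f / 1e-3
        folds = []
        for k in range(10):
            cfg = v.PanningConfig(seed=3000 + k, n_clones=n, rounds=2,
                                  reads_per_round=100_000,
                                  cell_lines=("S1T", "HepG2"))
            t = v.simulate_panning(rep, "S1T", cfg, p0=p0)
            folds.append(t["round_2"].iloc[0] / max(t["round_0"].iloc[0], 1))
        folds = np.array(folds)
        se = folds.std(ddof=1) / np.sqrt(len(folds))
        assert abs(folds.mean() - expected_fold) <= 4 * se + 0.05 * expected_fold


class TestEmitFastq:
    def test_seed_determinism_byte_identical(self, small_cfg, small_repertoire, tmp_path):
        table = v.simulate_panning(small_repertoire, "S1T", small_cfg)
        sums = []
        for sub in ("a", "b"):
            paths = v.emit_fastq(table, small_repertoire, small_cfg,
                                 tmp_path / sub, "S1T", rounds=[2])
            with open(paths[2][0], "rb") as fh:
                sums.append(hashlib.md5(fh.read()).hexdigest())
        assert sums[0] == sums[1]

    def test_read_counts_match_table(self, small_cfg, small_repertoire, tmp_path):
        table = v.simulate_panning(small_repertoire, "S1T", small_cfg)
        paths = v.emit_fastq(table, small_repertoire, small_cfg, tmp_path, "S1T", rounds=[0])
        n_reads = sum(1 for _ in v.reads.iter_fastq_pairs(*paths[0]))
        assert n_reads == small_cfg.reads_per_round

    def test_error_rate_binomial(self, small_repertoire, tmp_path):
        # 100 reads at 1% error: mean mismatches per 300-nt read is ~3
        cfg = v.PanningConfig(seed=9, n_clones=len(small_repertoire),
                              per_base_error_rate=0.01,
                              cell_lines=("S1T", "HepG2"))
        clone = small_repertoire[0]
        rng = np.random.default_rng(123)
        r1, r2 = tmp_path / "e_R1.fastq", tmp_path / "e_R2.fastq"
        v.simulate.emit_round_fastq({clone.clone_id: 100}, small_repertoire, cfg, r1, r2, rng)
        template = clone.nt_seq[: cfg.read_len]
        mismatches = [
            sum(a != b for a, b in zip(pair.r1_seq, template))
            for pair in v.reads.iter_fastq_pairs(r1, r2)
        ]
        mean = np.mean(mismatches)
        sigma_mean = np.sqrt(300 * 0.01 * 0.99) / np.sqrt(100)
        assert abs(mean - 3.0) <= 3 * sigma_mean

    def test_empty_count_table(self, small_cfg, small_repertoire, tmp_path):
        r1, r2 = tmp_path / "empty_R1.fastq", tmp_path / "empty_R2.fastq"
        v.simulate.emit_round_fastq({}, small_repertoire, small_cfg, r1, r2,
                                    np.random.default_rng(0))
        assert r1.read_bytes() == b"" and r2.read_bytes() == b""
        assert list(v.reads.iter_fastq_pairs(r1, r2)) == []

    def test_amplicon_too_long_names_clone(self, small_cfg, small_repertoire, tmp_path):
        bad = dataclasses.replace(small_repertoire[0], nt_seq="A" * 700)
        with pytest.raises(GenerationError, match=bad.clone_id):
            v.simulate.emit_round_fastq({bad.clone_id: 1}, [bad], small_cfg,
                                        tmp_path / "x1", tmp_path / "x2",
                                        np.random.default_rng(0))

    def test_errorfree_roundtrip_recovers_count_table(self, errorfree_fixtures, small_repertoire):
        fx = errorfree_fixtures
        lib = fx.run_config.libraries[0]
        processed = v.reads.process_fastq_pair(lib.fastq_r1, lib.fastq_r2)
        expected = truth_aa_counts(fx.repertoire, fx.count_tables[lib.name]["round_2"].to_dict())
        assert processed.aa_counts == expected
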