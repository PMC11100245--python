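from __future__ import annotations

import math

import numpy as np
import pytest

from faersig.dedup import deduplicate, remove_deleted
from faersig.io import parse_deleted_list, parse_quarter
from faersig.synthetic import (
    DrugSpec,
    PtSpec,
    SignalPair,
    SynthConfig,
    TruncatedGeometric,
    expected_ebgm,
    generate,
    _presence_probability,
)
from tests.conftest import small_synth_config


class TestTruncatedGeometric:
    def test_pmf_mean_matches(self):
        dist = TruncatedGeometric(mean=1.3, max_value=5)
        pmf = dist.pmf()
        assert pmf.sum() == pytest.approx(1.0)
        assert float((np.arange(1, 6) * pmf).sum()) == pytest.approx(1.3, abs=1e-9)

    def test_degenerate_mean_one(self):
        pmf = TruncatedGeometric(mean=1, max_value=4).pmf()
        assert pmf[0] == 1.0

    def test_invalid_mean(self):
        with pytest.raises(ValueError):
            TruncatedGeometric(mean=6, max_value=5)


class TestConfigValidation:
    def test_lam_too_large_for_baseline(self):
        with pytest.raises(ValueError, match="lam too large"):
            SynthConfig(
                n_reports=10,
                drugs=[DrugSpec("D", 1.0)],
                pts=[PtSpec("P", "S", 0.2)],
                signal_pairs=[SignalPair("D", "P", 6.0)],
            )

    def test_lam_below_one_rejected(self):
        with pytest.raises(ValueError, match="lam"):
            SynthConfig(
                n_reports=10,
                drugs=[DrugSpec("D", 1.0)],
                pts=[PtSpec("P", "S", 0.1)],
                signal_pairs=[SignalPair("D", "P", 0.5)],
            )

    def test_pt_in_two_signal_pairs_rejected(self):
        with pytest.raises(ValueError, match="more than one"):
            SynthConfig(
                n_reports=10,
                drugs=[DrugSpec("D", 0.5), DrugSpec("E", 0.5)],
                pts=[PtSpec("P", "S", 0.01)],
                signal_pairs=[SignalPair("D", "P", 2.0), SignalPair("E", "P", 2.0)],
            )

    def test_fraction_bounds(self):
        with pytest.raises(ValueError):
            small_synth_config(duplicate_fraction=1.0)

    def test_from_dict_round_trip(self):
        cfg = SynthConfig.from_dict({
            "n_reports": 50,
            "drugs": [{"name": "D", "weight": 0.5}, {"name": "E", "weight": 0.5}],
            "pts": [{"pt": "P", "soc": "S", "baseline": 0.1}],
            "signal_pairs": [{"drug": "D", "pt": "P", "lam": 3.0}],
            "drugs_per_report": {"mean": 1.5, "max_value": 3},
            "seed": 9,
        })
        assert cfg.signal_pairs[0].lam == 3.0
        assert cfg.drugs_per_report.max_value == 3


class TestGenerate:
    def test_reproducible_files(self, tmp_path):
        cfg = small_synth_config(n=500, seed=5, duplicate_fraction=0.1, deleted_fraction=0.05)
        d1, d2 = tmp_path / "one", tmp_path / "two"
        generate(cfg, d1)
        generate(cfg, d2)
        for name in ("DEMO.txt", "DRUG.txt", "REAC.txt", "OUTC.txt", "THER.txt", "DELETED.txt", "truth.json"):
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes(), name

    def test_different_seeds_differ(self, tmp_path):
        b1, _ = generate(small_synth_config(n=500, seed=1))
        b2, _ = generate(small_synth_config(n=500, seed=2))
        assert not b1.demo.equals(b2.demo)

    def test_duplicate_fraction_row_counts(self):
        cfg = small_synth_config(n=1000, seed=3, duplicate_fraction=0.2)
        bundle, truth = generate(cfg)
        assert len(bundle.demo) == 1200
        deduped = deduplicate(bundle.demo)
        assert len(deduped) == 1000
        assert deduped["caseid"].is_unique

    def test_duplicates_have_larger_fda_dt(self):
        cfg = small_synth_config(n=400, seed=3, duplicate_fraction=0.25)
        bundle, truth = generate(cfg)
        for cid in truth.duplicated_caseids[:20]:
            versions = bundle.demo[bundle.demo["caseid"] == cid].sort_values("primaryid")
            assert len(versions) == 2
            assert versions["fda_dt"].iloc[1] > versions["fda_dt"].iloc[0]

    def test_dedup_recovery_with_deletions(self):
        cfg = small_synth_config(n=1000, seed=4, duplicate_fraction=0.3, deleted_fraction=0.1)
        bundle, truth = generate(cfg)
        demo = remove_deleted(deduplicate(bundle.demo), set(truth.deleted_caseids))
        assert len(demo) == cfg.n_reports - len(truth.deleted_caseids)

    def test_files_parse_back(self, tmp_path):
        cfg = small_synth_config(n=300, seed=6, duplicate_fraction=0.1, deleted_fraction=0.05)
        bundle, truth = generate(cfg, tmp_path)
        b = parse_quarter(tmp_path / "DEMO.txt", tmp_path / "DRUG.txt", tmp_path / "REAC.txt",
                          tmp_path / "OUTC.txt", tmp_path / "THER.txt", "SYNTH")
        assert len(b.demo) == len(bundle.demo)
        assert len(b.reactions) == len(bundle.reactions)
        assert parse_deleted_list(tmp_path / "DELETED.txt") == set(truth.deleted_caseids)

    def test_signal_count_within_poisson_bound(self):
        cfg = small_synth_config(n=20_000, lam=20.0, seed=7)
        bundle, _ = generate(cfg)
        cohort_drugs = bundle.drugs[bundle.drugs["drugname"] == "TARGETOL"]
        cohort = set(cohort_drugs["primaryid"])
        signal = bundle.reactions[bundle.reactions["pt"] == "SIGNAL EVENT"]
        a = len(set(signal["primaryid"]) & cohort)
        p_d = _presence_probability(cfg, "TARGETOL")
        expected_a = cfg.n_reports * p_d * min(0.02 * 20.0, 1.0)
        assert abs(a - expected_a) <= 3 * math.sqrt(expected_a)

    def test_roles_first_mention_ps(self):
        bundle, _ = generate(small_synth_config(n=300, seed=8))
        firsts = bundle.drugs[bundle.drugs["drug_seq"] == 1]
        assert (firsts["role_cod"] == "PS").all()

    def test_vocabulary_frame_covers_pts(self):
        cfg = small_synth_config()
        vf = cfg.vocabulary_frame()
        assert set(vf["pt"]) == {p.pt for p in cfg.pts}
        assert vf.groupby("soc_name")["soc_code"].nunique().eq(1).all()


class TestExpectedEbgm:
    def test_null_pair_is_one(self):
        cfg = small_synth_config(lam=0)
        assert expected_ebgm(cfg, "TARGETOL", "EVENT 00") == pytest.approx(1.0)

    def test_near_lam_when_marginal_small(self):
        # tiny drug share and thin signal PT: the background barely moves
        drugs = [DrugSpec("D", 0.001)] + [DrugSpec(f"O{i}", 0.0999) for i in range(10)]
        pts = [PtSpec(f"P{i}", "S", 0.05) for i in range(40)] + [PtSpec("SIG", "S", 0.001)]
        cfg = SynthConfig(n_reports=10, drugs=drugs, pts=pts,
                          signal_pairs=[SignalPair("D", "SIG", 10.0)])
        assert expected_ebgm(cfg, "D", "SIG") == pytest.approx(10.0, rel=0.02)

    def test_capped_probability_reflected(self):
        cfg = SynthConfig(
            n_reports=10,
            drugs=[DrugSpec("D", 0.01), DrugSpec("O", 0.99)],
            pts=[PtSpec("SIG", "S", 0.6), PtSpec("P", "S", 0.5)],
            signal_pairs=[SignalPair("D", "SIG", 1.5)],  # 0.9 <= 1, but capped logic applies
        )
        value = expected_ebgm(cfg, "D", "SIG")
        assert value < 1.5  # finite background + cap keep it below the design ratio

    def test_unknown_pair_rejected(self):
        with pytest.raises(ValueError):
            expected_ebgm(small_synth_config(), "TARGETOL", "NO SUCH PT")

    def test_pipeline_estimate_matches_expectation(self):
        cfg = small_synth_config(n=50_000, lam=20.0, seed=12)
        bundle, _ = generate(cfg)
        from faersig.contingency import build_pairs, contingency_table
        from faersig.profile import DrugQuery, select_target_reports
        from faersig.stats import ebgm

        q = DrugQuery(names=("targetol",), roles=frozenset({"PS", "SS", "C", "I"}))
        cohort = select_target_reports(bundle, q)
        u = build_pairs(bundle, cohort, level="PT")
        t = contingency_table(u, "SIGNAL EVENT")
        observed, _, _ = ebgm(t)
        assert observed == pytest.approx(expected_ebgm(cfg, "TARGETOL", "SIGNAL EVENT"), rel=0.2)
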