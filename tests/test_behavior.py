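"""SUDO thresholding, BH-FDR, and the mixed-effects threshold model."""

import itertools
import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from idcmod.behavior import (FilamentLadder, bh_fdr, fit_lmm, load_blocks,
                             run_staircase, sudo_threshold)

LADDER = FilamentLadder()


def brute_force_sudo(forces, start, outcomes):
    """Independent staircase enumerator: explicit trial-by-trial walk."""
    forces = list(forces)
    visited = []
    idx = start
    for o in outcomes:
        visited.append(idx)
        if o == "X":
            idx = idx - 1
        else:
            idx = idx + 1
        idx = min(max(idx, 0), len(forces) - 1)
    n5 = visited[4]
    adj = n5 + (0.5 if outcomes[4] == "O" else -0.5)
    left = min(max(int(np.floor(adj)), 0), len(forces) - 1)
    right = min(max(int(np.ceil(adj)), 0), len(forces) - 1)
    return (forces[left] * forces[right]) ** 0.5


class TestSudo:
    def test_worked_staircase_example(self):
        # start 5, O O X O X: trials at 5,6,7,6,7; last X -> index 6.5
        got = sudo_threshold(LADDER, 5, "OOXOX")
        assert got == pytest.approx(np.sqrt(LADDER[6] * LADDER[7]))

    def test_all_ascending_clamps_at_top(self):
        k = 3
        assert sudo_threshold(LADDER, k, "OOOOO") == pytest.approx(
            np.sqrt(LADDER[k + 4] * LADDER[k + 5]))
        top = len(LADDER) - 1
        assert sudo_threshold(LADDER, top, "OOOOO") == pytest.approx(LADDER[top])

    def test_all_descending_clamps_at_bottom(self):
        assert sudo_threshold(LADDER, 0, "XXXXX") == pytest.approx(LADDER[0])

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            sudo_threshold(LADDER, 5, "OOXO")

    def test_bad_symbol_rejected(self):
        with pytest.raises(ValueError):
            sudo_threshold(LADDER, 5, "OOXOZ")

    def test_bad_start_rejected(self):
        with pytest.raises(ValueError):
            sudo_threshold(LADDER, 99, "OOXOX")

    def test_exhaustive_agreement_with_brute_force(self):
        # all 2^5 outcome sequences at every valid start index
        for start in range(len(LADDER)):
            for bits in itertools.product("XO", repeat=5):
                seq = "".join(bits)
                assert sudo_threshold(LADDER, start, seq) == pytest.approx(
                    brute_force_sudo(LADDER.forces, start, seq), rel=1e-12), \
                    (start, seq)

    def test_staircase_consistency_deterministic_rule(self):
        # estimate within one ladder step of the true threshold when in range
        for true in (0.5, 1.7, 5.0, 9.0, 20.0, 80.0):
            start = LADDER.index_nearest(true)
            outcomes = run_staircase(LADDER, start, lambda f: f >= true)
            est = sudo_threshold(LADDER, start, outcomes)
            i_est = LADDER.index_nearest(est)
            i_true = LADDER.index_nearest(true)
            assert abs(i_est - i_true) <= 1, (true, outcomes, est)


class TestLadder:
    def test_needs_two_filaments(self):
        with pytest.raises(ValueError):
            FilamentLadder(forces=(1.0,))

    def test_strictly_increasing(self):
        with pytest.raises(ValueError):
            FilamentLadder(forces=(1.0, 1.0, 2.0))

    def test_default_span(self):
        assert LADDER[0] == 0.008 and LADDER[len(LADDER) - 1] == 300.0


class TestBhFdr:
    def test_single_p_unchanged(self):
        assert bh_fdr([0.03])[0] == pytest.approx(0.03)

    def test_step_up_by_hand(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_all_equal_stay_equal(self):
        np.testing.assert_allclose(bh_fdr([0.2, 0.2, 0.2]), 0.2)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    def test_q_never_below_p(self, rng):
        p = rng.uniform(size=20)
        assert np.all(bh_fdr(p) >= p - 1e-12)


def balanced_table(effects, noise_sd, n_per_cell, rng, n_rats=2, n_sessions=3):
    rows = []
    for r in range(n_rats):
        for s in range(n_sessions):
            for a, eff in effects.items():
                for _ in range(n_per_cell):
                    rows.append((f"r{r}", f"s{s}", a,
                                 10.0 + eff + rng.normal(0, noise_sd)))
    return pd.DataFrame(rows, columns=["rat", "session", "amplitude_ua",
                                       "threshold_g"])


class TestFitLmm:
    def test_null_effects_recovered_near_zero(self, rng):
        df = balanced_table({0: 0.0, 20: 0.0, 40: 0.0}, 0.05, 10, rng)
        fit = fit_lmm(df)
        assert np.all(np.abs(fit.contrasts["estimate_g"]) < 0.1)

    def test_known_effect_recovered(self, rng):
        df = balanced_table({0: 0.0, 20: -4.0}, 0.2, 40, rng)
        fit = fit_lmm(df)
        est = fit.contrasts.set_index("amplitude_ua").loc[20, "estimate_g"]
        assert est == pytest.approx(-4.0, rel=0.05)

    def test_ols_equivalence_when_variances_vanish(self, rng):
        # balanced design, no rat/session structure: estimates are the plain
        # per-amplitude mean differences
        df = balanced_table({0: 0.0, -40: 4.2, 20: -3.8}, 1.0, 25, rng)
        fit = fit_lmm(df)
        means = df.groupby("amplitude_ua")["threshold_g"].mean()
        for a in (-40, 20):
            expected = means[a] - means[0]
            est = fit.contrasts.set_index("amplitude_ua").loc[a, "estimate_g"]
            assert est == pytest.approx(expected, abs=0.02)

    def test_ci_contains_estimate_and_q_monotone(self, rng):
        df = balanced_table({0: 0.0, -40: 4.0, -20: 0.1, 20: -3.5, 40: -4.5},
                            1.5, 8, rng)
        fit = fit_lmm(df)
        c = fit.contrasts
        assert np.all((c["ci_low"] <= c["estimate_g"])
                      & (c["estimate_g"] <= c["ci_high"]))
        assert np.all(c["q"] >= c["p"] - 1e-12)
        assert fit.df_method == "residual"

    def test_requires_reference_level(self, rng):
        df = balanced_table({20: 0.0, 40: 0.0}, 1.0, 5, rng)
        with pytest.raises(ValueError):
            fit_lmm(df)

    def test_matches_lme4_reference_fit(self, rng, tmp_path):
        # independent cross-check of the mixed model against R lme4
        df = balanced_table({0: 0.0, 20: -3.0, 40: -4.0}, 1.0, 6, rng,
                            n_rats=3, n_sessions=4)
        fit = fit_lmm(df)
        csv = tmp_path / "blocks.csv"
        df.to_csv(csv, index=False)
        rscript = shutil.which("Rscript")
        assert rscript is not None, "Rscript expected on PATH"
        code = textwrap.dedent(f"""
            suppressMessages(library(lme4))
            d <- read.csv("{csv}")
            d$amp <- relevel(factor(d$amplitude_ua), ref = "0")
            d$rs <- interaction(d$rat, d$session)
            m <- lmer(threshold_g ~ amp + (1 | rat) + (1 | rs), data = d,
                      REML = TRUE)
            fe <- fixef(m)
            cat(fe["amp20"], fe["amp40"], sep = "\\n")
        """)
        out = subprocess.run([rscript, "-e", code], capture_output=True,
                             text=True, timeout=300)
        assert out.returncode == 0, out.stderr
        ref20, ref40 = (float(x) for x in out.stdout.strip().splitlines())
        got = fit.contrasts.set_index("amplitude_ua")["estimate_g"]
        assert got[20] == pytest.approx(ref20, abs=0.01)
        assert got[40] == pytest.approx(ref40, abs=0.01)


class TestLoadBlocks:
    def test_recompute_and_exclusion(self, tmp_path):
        df = pd.DataFrame({
            "rat": ["r0", "r0", "r1"],
            "session": ["s0", "s0", "s1"],
            "paw": ["contra"] * 3,
            "amplitude_ua": [0, 20, 0],
            "start_index": [5, 5, 5],
            "outcomes": ["OOXOX", "OOX", "XXOXO"],
        })
        path = tmp_path / "blocks.csv"
        df.to_csv(path, index=False)
        with pytest.warns(UserWarning, match="excluding 1 blocks"):
            out = load_blocks(path)
        assert len(out) == 2
        assert out.loc[0, "threshold_g"] == pytest.approx(
            sudo_threshold(LADDER, 5, "OOXOX"))

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        pd.DataFrame({"rat": ["r0"]}).to_csv(path, index=False)
        with pytest.raises(ValueError, match="missing columns"):
            load_blocks(path)
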