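"""Von Frey SUDO thresholding and mixed-effects analysis of iDC behavior.

The Simplified Up-Down (SUDO) estimator runs a five-trial staircase over a
calibrated filament ladder: a withdrawal ("X") steps one filament lower, no
withdrawal ("O") one higher.  The 50% withdrawal threshold index is the
index of the fifth trial adjusted by -0.5 (X) or +0.5 (O), and the threshold
force is the geometric mean of the two ladder forces flanking that index.

Per paw, withdrawal thresholds are modelled as

    threshold_g ~ 1 + amplitude + (1 | rat) + (1 | rat:session)

with iDC amplitude categorical (0 uA reference) and random intercepts for
rat and session-within-rat, fit by REML.  Planned contrasts against 0 uA use
Wald t tests; the false discovery rate across amplitudes within a paw is
controlled with Benjamini-Hochberg.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TOUCH_TEST_FORCES",
    "FilamentLadder",
    "DESIGN_AMPLITUDES",
    "LMMFit",
    "run_staircase",
    "sudo_threshold",
    "fit_lmm",
    "bh_fdr",
    "load_blocks",
]

#: Standard Touch Test monofilament forces in grams.
TOUCH_TEST_FORCES = (0.008, 0.02, 0.04, 0.07, 0.16, 0.4, 0.6, 1, 1.4, 2,
                     4, 6, 8, 10, 15, 26, 60, 100, 180, 300)

#: iDC amplitudes in the behavioral design, microamperes.
DESIGN_AMPLITUDES = (-40, -20, 0, 20, 40)


@dataclass(frozen=True)
class FilamentLadder:
    """Strictly increasing ordered filament forces (grams)."""

    forces: tuple = TOUCH_TEST_FORCES

    def __post_init__(self) -> None:
        f = np.asarray(self.forces, dtype=float)
        if f.size < 2:
            raise ValueError("ladder needs at least 2 filaments")
        if np.any(np.diff(f) <= 0):
            raise ValueError("forces must be strictly increasing")
        object.__setattr__(self, "forces", tuple(float(x) for x in f))

    def __len__(self) -> int:
        return len(self.forces)

    def __getitem__(self, i):
        return self.forces[i]

    def index_nearest(self, force_g: float) -> int:
        return int(np.argmin(np.abs(np.asarray(self.forces) - force_g)))


def run_staircase(ladder: FilamentLadder, start_index: int, respond,
                  n_trials: int = 5) -> str:
    """Run the up-down staircase with a response callable.

    ``respond(force_g) -> bool`` returns True for a withdrawal.  The index
    clamps at the ladder ends.  Returns the outcome string (e.g. "OOXOX").
    """
    if not (0 <= start_index < len(ladder)):
        raise ValueError(f"start_index {start_index} outside ladder")
    i = start_index
    out = []
    for _ in range(n_trials):
        withdrew = bool(respond(ladder[i]))
        out.append("X" if withdrew else "O")
        i = max(0, i - 1) if withdrew else min(len(ladder) - 1, i + 1)
    return "".join(out)


def sudo_threshold(ladder: FilamentLadder, start_index: int, outcomes) -> float:
    """SUDO 50% withdrawal threshold (grams) from five staircase outcomes.

    The adjusted index N5 -+ 0.5 is clamped to the ladder ends, so an
    out-of-range staircase returns the end force.
    """
    seq = list(outcomes)
    if len(seq) != 5:
        raise ValueError(f"exactly 5 outcomes required, got {len(seq)}")
    if any(o not in ("X", "O") for o in seq):
        raise ValueError("outcomes must be 'X' or 'O'")
    if not (0 <= start_index < len(ladder)):
        raise ValueError(f"start_index {start_index} outside ladder")
    i = start_index
    for o in seq:
        n5 = i
        i = max(0, i - 1) if o == "X" else min(len(ladder) - 1, i + 1)
    adjusted = n5 - 0.5 if seq[-1] == "X" else n5 + 0.5
    lo = int(np.clip(np.floor(adjusted), 0, len(ladder) - 1))
    hi = int(np.clip(np.ceil(adjusted), 0, len(ladder) - 1))
    return float(np.sqrt(ladder[lo] * ladder[hi]))


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q values (monotone)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class LMMFit:
    """Fixed-effect contrasts vs 0 uA and variance components of one paw."""

    contrasts: pd.DataFrame      # amplitude_ua, estimate_g, se_g, df, t, p, q, ci_low, ci_high
    variance_components: dict    # rat, rat_session, residual (variances, g^2)
    df_method: str = "residual"
    n_blocks: int = 0
    converged: bool = True


def fit_lmm(blocks: pd.DataFrame, alpha: float = 0.05) -> LMMFit:
    """Fit the per-paw threshold mixed model and contrast amplitudes vs 0 uA.

    ``blocks`` needs columns rat, session, amplitude_ua, threshold_g (one
    paw's data).  Degrees of freedom are residual (n - rank(X)); the fit
    object records this in ``df_method``.
    """
    df = blocks.copy()
    amps = sorted(df["amplitude_ua"].unique())
    if 0 not in amps or len(amps) < 2:
        raise ValueError("need >= 2 amplitudes including the 0 uA reference")
    others = [a for a in amps if a != 0]
    df["amp"] = pd.Categorical(df["amplitude_ua"], categories=[0] + others)
    df["rat_session"] = df["rat"].astype(str) + ":" + df["session"].astype(str)
    if df["rat"].nunique() < 2:
        warnings.warn("single rat: rat variance component is at the boundary")
    model = MixedLM.from_formula(
        "threshold_g ~ C(amp)", data=df, groups="rat",
        re_formula="1", vc_formula={"session": "0 + C(rat_session)"},
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(reml=True)
    n = len(df)
    rank = np.linalg.matrix_rank(res.model.exog)
    ddf = n - rank
    rows = []
    for a in others:
        name = f"C(amp)[T.{a}]"
        est = float(res.params[name])
        se = float(res.bse[name])
        t = est / se
        p = 2 * stats.t.sf(abs(t), ddf)
        tcrit = stats.t.ppf(1 - alpha / 2, ddf)
        rows.append((a, est, se, float(ddf), t, p,
                     est - tcrit * se, est + tcrit * se))
    contrasts = pd.DataFrame(rows, columns=["amplitude_ua", "estimate_g",
                                            "se_g", "df", "t", "p",
                                            "ci_low", "ci_high"])
    contrasts["q"] = bh_fdr(contrasts["p"].to_numpy())
    contrasts = contrasts[["amplitude_ua", "estimate_g", "se_g", "df", "t",
                           "p", "q", "ci_low", "ci_high"]]
    vc = {
        "rat": float(res.cov_re.iloc[0, 0]) if res.cov_re.size else 0.0,
        "rat_session": float(res.vcomp[0]) if res.vcomp.size else 0.0,
        "residual": float(res.scale),
    }
    return LMMFit(contrasts=contrasts, variance_components=vc,
                  df_method="residual", n_blocks=n,
                  converged=bool(res.converged))


def load_blocks(path, ladder: FilamentLadder | None = None,
                recompute: bool = True) -> pd.DataFrame:
    """Load a Von Frey block table (CSV), recomputing SUDO thresholds.

    Expected columns: rat, session, paw, amplitude_ua, start_index, outcomes
    (a 5-character X/O string); threshold_g is recomputed unless
    ``recompute=False`` and present.  Blocks with fewer than 5 scored trials
    are excluded, mirroring the a-priori exclusion rule.
    """
    ladder = ladder or FilamentLadder()
    df = pd.read_csv(path, dtype={"outcomes": str})
    required = {"rat", "session", "paw", "amplitude_ua", "start_index", "outcomes"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"block table missing columns: {sorted(missing)}")
    valid = df["outcomes"].str.fullmatch("[XO]{5}").fillna(False)
    n_dropped = int((~valid).sum())
    if n_dropped:
        warnings.warn(f"excluding {n_dropped} blocks with <5 valid trials")
        df = df[valid].copy()
    if recompute or "threshold_g" not in df.columns:
        df["threshold_g"] = [
            sudo_threshold(ladder, int(s), o)
            for s, o in zip(df["start_index"], df["outcomes"])
        ]
    return df.reset_index(drop=True)
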